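"""Macroscale clot: a 3D lattice of fibrin fibers under a tPA bolus.

The clot is a cubic lattice in a chamber of ``width x depth x (height + H)``
um^3, one periodic slab one pore deep; every lattice edge below the clot
surface is a fibrin fiber.  A bolus of discrete tPA molecules is placed in
the fibrin-free region of height ``H`` above the clot and performs a
nearest-neighbor random walk with step ``pore_size`` and time step
``dt = pore_size^2 / (6 D)``.  A molecule adjacent to an intact or degrading
fiber binds it with probability ``1 - exp(-k_on [sites] dt)`` per step; each
binding draws a residence time and, with the single-fiber lysis probability,
a degradation delay from a microscale :class:`~fibrolysis.distributions.MicroSummaryPack`.
The fiber degrades at the earliest scheduled delay; bound tPA is released
when its residence expires or its fiber degrades.

Lysis proceeds as a front: the front depth is the mean per-column depth to
which every fiber has degraded, and the front velocity is the least-squares
slope of depth against time.  Runs where degradation happens deep inside the
clot instead of at a front are flagged rather than summarized by a velocity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _macro_kernel as mack
from .distributions import MicroSummaryPack
from .geometry import (
    BolusSpec,
    FiberGeometry,
    concentration_to_number_density,
    grid_size,
)
from .kinetics import KineticParameters

#: default effective tPA diffusion coefficient, um^2/s (2.5e-7 cm^2/s; free-solution
#: tPA diffuses at ~5e-7 cm^2/s, roughly halved by tortuosity in a fibrin network).
D_TPA_UM2_S = 25.0

FINE_PORE_UM = 1.37
FINE_DIAMETER_NM = 97.5
COARSE_PORE_UM = 2.74
COARSE_DIAMETER_NM = 195.0


@dataclass
class ClotLattice:
    """Edge state of one periodic clot slab plus its geometry.

    Edge arrays hold the scheduled lysis time (+inf = intact, unscheduled);
    an edge is degraded once the clock passes that time.
    """

    pore_size: float  # um
    fiber_diameter: float  # nm
    nx: int  # node columns (periodic in x)
    nzc: int  # fiber levels (clot height in pores)
    nzf: int  # fibrin-free node levels above the clot
    lex: np.ndarray  # (nx, nzc) x-edges
    ley: np.ndarray  # (nx, nzc) y-edges (periodic slab, one pore deep)
    lez: np.ndarray  # (nx, max(nzc-1, 0)) z-edges between levels

    @property
    def nz_total(self) -> int:
        return self.nzc + self.nzf

    @property
    def clot_height(self) -> float:
        return self.nzc * self.pore_size

    @property
    def n_fibers(self) -> int:
        return self.lex.size + self.ley.size + self.lez.size

    def n_degraded(self, t: float) -> int:
        return int((self.lex <= t).sum() + (self.ley <= t).sum() + (self.lez <= t).sum())

    def copy(self) -> "ClotLattice":
        return ClotLattice(
            self.pore_size,
            self.fiber_diameter,
            self.nx,
            self.nzc,
            self.nzf,
            self.lex.copy(),
            self.ley.copy(),
            self.lez.copy(),
        )


@dataclass
class TPAParticles:
    """Structure-of-arrays container for the discrete tPA molecules."""

    px: np.ndarray  # node column
    pz: np.ndarray  # node level
    btype: np.ndarray  # -1 free; 0/1/2 bound to x/y/z edge
    bx: np.ndarray
    bz: np.ndarray
    t_leave: np.ndarray
    dispx: np.ndarray  # unwrapped displacement, um
    dispy: np.ndarray
    dispz: np.ndarray

    @property
    def n(self) -> int:
        return int(self.px.size)

    @property
    def n_bound(self) -> int:
        return int((self.btype >= 0).sum())

    @property
    def n_free(self) -> int:
        return self.n - self.n_bound

    def msd(self) -> float:
        """Mean squared displacement (um^2) since placement."""
        return float((self.dispx**2 + self.dispy**2 + self.dispz**2).mean())


@dataclass
class FrontTrace:
    times: np.ndarray  # s
    front_depth: np.ndarray  # um, non-decreasing
    n_degraded: np.ndarray
    n_degraded_below_front: np.ndarray
    n_free: np.ndarray
    n_bound: np.ndarray
    seed: int
    clot_height: float
    n_fibers: int


def build_clot(
    pore_size: float,
    fiber_diameter: float,
    width: float = 100.0,
    clot_height: float = 100.0,
    free_height: float = 2.935,
) -> ClotLattice:
    """Cubic-lattice clot slab; all edges start intact (+inf lysis time)."""
    if pore_size <= 0:
        raise ValueError("pore_size must be positive")
    nx = round(width / pore_size)
    nzc = round(clot_height / pore_size)
    nzf = max(1, round(free_height / pore_size))
    if nx < 1 or nzc < 1:
        raise ValueError("domain smaller than one pore")
    inf = np.inf
    return ClotLattice(
        pore_size=pore_size,
        fiber_diameter=fiber_diameter,
        nx=nx,
        nzc=nzc,
        nzf=nzf,
        lex=np.full((nx, nzc), inf),
        ley=np.full((nx, nzc), inf),
        lez=np.full((nx, max(nzc - 1, 0)), inf),
    )


def place_bolus(lattice: ClotLattice, bolus: BolusSpec, seed: int) -> TPAParticles:
    """Place ``N = round(density * width * depth * H)`` molecules uniformly
    over the fibrin-free nodes.  The slab depth is one pore."""
    density = concentration_to_number_density(bolus.concentration)
    width = lattice.nx * lattice.pore_size
    n_mol = round(density * width * lattice.pore_size * bolus.free_region_height)
    if n_mol == 0:
        warnings.warn("bolus contains zero tPA molecules; nothing will lyse")
    rng = np.random.default_rng(seed)
    px = rng.integers(0, lattice.nx, n_mol)
    pz = rng.integers(lattice.nzc, lattice.nz_total, n_mol)
    return TPAParticles(
        px=px.astype(np.int64),
        pz=pz.astype(np.int64),
        btype=np.full(n_mol, -1, dtype=np.int64),
        bx=np.zeros(n_mol, dtype=np.int64),
        bz=np.zeros(n_mol, dtype=np.int64),
        t_leave=np.zeros(n_mol),
        dispx=np.zeros(n_mol),
        dispy=np.zeros(n_mol),
        dispz=np.zeros(n_mol),
    )


def binding_site_concentration(
    pore_size: float, fiber_diameter: float, geom: FiberGeometry | None = None
) -> float:
    """Binding-doublet concentration (uM) seen by a tPA in contact with a fiber.

    A fiber carries ``6 n^2`` binding doublets per longitudinal site spacing
    (22.5 nm); the concentration a surface-adjacent tPA encounters is that
    count over the fiber-slab volume (equal-area square cross-section x
    22.5 nm).  Fibrin protein density inside a fiber is diameter-independent,
    so fine and coarse fibers present the same local concentration (~4.8 mM)
    and tPA binds within a few lattice steps of touching the clot -- the
    strong-binding regime that confines baseline lysis to a front.
    """
    if geom is None:
        geom = FiberGeometry(fiber_diameter=fiber_diameter)
    from .geometry import cross_section_square_side

    n = grid_size(fiber_diameter, geom)
    side_um = cross_section_square_side(fiber_diameter) * 1e-3
    slab_um = geom.longitudinal_site_spacing * 1e-3
    per_um3 = 6 * n * n / (side_um**2 * slab_um)
    return per_um3 / 602.214076  # molecules/um^3 -> uM


def step(
    lattice: ClotLattice,
    particles: TPAParticles,
    params: KineticParameters,
    pack: MicroSummaryPack,
    t: float,
    dt: float,
    n_steps: int = 1,
    d_tpa: float = D_TPA_UM2_S,
    schedule_mode: int = 0,
) -> float:
    """Advance the walk/bind/degrade dynamics ``n_steps`` steps; returns the
    new time.  RNG state is module-global; seed with :func:`seed_rng`."""
    site_conc = binding_site_concentration(lattice.pore_size, lattice.fiber_diameter)
    p_bind = 1.0 - math.exp(-params.k_on_tpa * site_conc * dt)
    return mack.advance(
        particles.px,
        particles.pz,
        particles.btype,
        particles.bx,
        particles.bz,
        particles.t_leave,
        particles.dispx,
        particles.dispy,
        particles.dispz,
        lattice.lex,
        lattice.ley,
        lattice.lez,
        lattice.nx,
        lattice.nzc,
        lattice.nz_total,
        lattice.pore_size,
        t,
        dt,
        n_steps,
        p_bind,
        pack.tpa_residence.values,
        pack.lysis_probability,
        pack.lysis_delay.values,
        schedule_mode,
    )


def seed_rng(seed: int) -> None:
    mack._seed_rng(int(seed))


def _column_depths(lattice: ClotLattice, t: float) -> np.ndarray:
    """Per-column count of contiguous fully-degraded levels from the top."""
    deg_x = lattice.lex <= t
    deg_y = lattice.ley <= t
    if lattice.nzc > 1:
        deg_zup = np.concatenate(
            [lattice.lez <= t, np.ones((lattice.nx, 1), dtype=bool)], axis=1
        )
    else:
        deg_zup = np.ones((lattice.nx, 1), dtype=bool)
    level_clear = deg_x & deg_y & deg_zup
    return np.cumprod(level_clear[:, ::-1], axis=1).sum(axis=1)


def front_depth(lattice: ClotLattice, t: float) -> float:
    """Mean over columns of the depth (um) to which every fiber at or above
    that depth has degraded; 0 while the top layer is intact."""
    return float(_column_depths(lattice, t).mean() * lattice.pore_size)


def _degraded_below_front(lattice: ClotLattice, t: float) -> int:
    d = _column_depths(lattice, t)
    zb = lattice.nzc - d  # first level index of the cleared region, per column
    zidx = np.arange(lattice.nzc)[None, :]
    below = zidx < zb[:, None]
    n = int(((lattice.lex <= t) & below).sum() + ((lattice.ley <= t) & below).sum())
    if lattice.nzc > 1:
        zidx_e = np.arange(lattice.nzc - 1)[None, :]
        below_e = zidx_e < (zb[:, None] - 1)
        n += int(((lattice.lez <= t) & below_e).sum())
    return n


def run_single(
    lattice: ClotLattice,
    particles: TPAParticles,
    params: KineticParameters,
    pack: MicroSummaryPack,
    seed: int,
    t_max: float = 7200.0,
    out_dt: float = 10.0,
    d_tpa: float = D_TPA_UM2_S,
) -> FrontTrace:
    """One macroscale replicate.  Mutates the lattice and particles in place."""
    dt = lattice.pore_size**2 / (6.0 * d_tpa)
    steps_per_out = max(1, int(round(out_dt / dt)))
    seed_rng(seed)
    times = [0.0]
    depths = [front_depth(lattice, 0.0)]
    n_deg = [lattice.n_degraded(0.0)]
    n_below = [0]
    n_free = [particles.n_free]
    n_bound = [particles.n_bound]
    t = 0.0
    while t < t_max:
        t = step(lattice, particles, params, pack, t, dt, steps_per_out, d_tpa)
        times.append(t)
        depths.append(front_depth(lattice, t))
        n_deg.append(lattice.n_degraded(t))
        n_below.append(_degraded_below_front(lattice, t))
        n_free.append(particles.n_free)
        n_bound.append(particles.n_bound)
        if depths[-1] >= lattice.clot_height - 1e-9:
            break
    return FrontTrace(
        times=np.array(times),
        front_depth=np.array(depths),
        n_degraded=np.array(n_deg),
        n_degraded_below_front=np.array(n_below),
        n_free=np.array(n_free),
        n_bound=np.array(n_bound),
        seed=seed,
        clot_height=lattice.clot_height,
        n_fibers=lattice.n_fibers,
    )


def front_velocity(trace: FrontTrace) -> tuple[float, str]:
    """Least-squares front speed in um/min over the window from first fiber
    degradation to full lysis (or end of trace); (0, "no-lysis") if the
    front never moves."""
    moved = np.flatnonzero(trace.n_degraded > 0)
    if moved.size == 0 or trace.front_depth[-1] <= 0:
        return 0.0, "no-lysis"
    start = moved[0]
    full = np.flatnonzero(trace.front_depth >= trace.clot_height - 1e-9)
    stop = full[0] if full.size else len(trace.times) - 1
    tt = trace.times[start : stop + 1]
    dd = trace.front_depth[start : stop + 1]
    if tt.size < 2 or dd[-1] <= dd[0]:
        return 0.0, "no-lysis"
    slope = np.polyfit(tt, dd, 1)[0]
    return float(slope * 60.0), "ok"


def front_like(trace: FrontTrace, threshold: float = 0.2) -> bool:
    """A run is front-like if, at half-lysis, at most ``threshold`` of the
    degraded fibers lie below (deeper than) the cleared front."""
    half = np.flatnonzero(trace.n_degraded >= 0.5 * trace.n_fibers)
    idx = half[0] if half.size else len(trace.times) - 1
    if trace.n_degraded[idx] == 0:
        return True  # nothing degraded anywhere; vacuously front-like
    frac = trace.n_degraded_below_front[idx] / trace.n_degraded[idx]
    return bool(frac <= threshold)


@dataclass
class ExperimentResult:
    traces: list[FrontTrace]
    velocities: np.ndarray  # per-replicate um/min (NaN where flagged)
    mean_velocity: float
    sd_velocity: float
    flags: list[str]

    @property
    def front_like_all(self) -> bool:
        return all(f == "ok" for f in self.flags)


def run_experiment(
    pack: MicroSummaryPack,
    params: KineticParameters,
    bolus: BolusSpec,
    pore_size: float,
    fiber_diameter: float,
    width: float = 100.0,
    clot_height: float = 100.0,
    n_replicates: int = 10,
    base_seed: int = 0,
    t_max: float = 7200.0,
    out_dt: float = 10.0,
    d_tpa: float = D_TPA_UM2_S,
) -> ExperimentResult:
    """Independent seeded replicates of one bolus/clot condition."""
    if pack is None:
        raise ValueError("a MicroSummaryPack is required")
    traces = []
    vels = []
    flags = []
    for rep in range(n_replicates):
        seed = (int(base_seed) + 7919 * rep) % 2147483647
        lattice = build_clot(
            pore_size, fiber_diameter, width, clot_height, bolus.free_region_height
        )
        particles = place_bolus(lattice, bolus, seed)
        trace = run_single(
            lattice, particles, params, pack, seed, t_max=t_max, out_dt=out_dt, d_tpa=d_tpa
        )
        v, flag = front_velocity(trace)
        if flag == "ok" and not front_like(trace):
            flag = "not-front-like"
        traces.append(trace)
        vels.append(v if flag == "ok" else np.nan)
        flags.append(flag)
    vels = np.array(vels)
    good = vels[~np.isnan(vels)]
    return ExperimentResult(
        traces=traces,
        velocities=vels,
        mean_velocity=float(good.mean()) if good.size else float("nan"),
        sd_velocity=float(good.std(ddof=1)) if good.size > 1 else float("nan"),
        flags=flags,
    )


def crossover_ratio(
    ratios: np.ndarray, v_fine: np.ndarray, v_coarse: np.ndarray
) -> float:
    """tPA-per-surface-area ratio at which fine and coarse clots lyse equally
    fast: fit a line to v_fine/v_coarse against the ratio and solve for 1.

    Below the returned ratio coarse clots lyse faster (fewer fibers to cut);
    above it fine clots win (thin fibers cut sooner).
    """
    ratios = np.asarray(ratios, dtype=float)
    v_fine = np.asarray(v_fine, dtype=float)
    v_coarse = np.asarray(v_coarse, dtype=float)
    if ratios.size < 1:
        raise ValueError("need at least one sweep point")
    rel = v_fine / v_coarse
    exact = np.flatnonzero(rel == 1.0)
    if ratios.size == 1:
        if exact.size:
            return float(ratios[exact[0]])
        raise ValueError("single sweep point does not cross ratio 1")
    if rel.min() > 1.0 or rel.max() < 1.0:
        raise ValueError(
            f"velocity ratio never crosses 1 over the sweep "
            f"(range {rel.min():.3f}..{rel.max():.3f})"
        )
    slope, intercept = np.polyfit(ratios, rel, 1)
    if slope == 0:
        raise ValueError("velocity ratio is flat; no crossover")
    return float((1.0 - intercept) / slope)
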