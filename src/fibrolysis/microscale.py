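"""Stochastic single-fiber lysis: one tPA molecule on a fiber cross-section.

The cross-section of a cylindrical fibrin fiber is approximated by a square of
equal area, tiled into an n x n grid of binding locations at the protofibril
pitch.  Each location carries 6 binding doublets (pairs of binding sites for
tPA, plasminogen and plasmin); initially one doublet per location is exposed
and 5 are cryptic.  A run places a single tPA molecule on a random perimeter
location and follows the exact Gillespie dynamics of plasminogen binding,
ternary-complex activation to plasmin, cryptic-site exposure, fibrin
degradation, and plasmin crawling, until the tPA has left and all plasmin is
gone, the cross-section is cut through, or the censoring horizon is reached.

Solution-phase plasminogen can only reach *accessible* locations -- the fiber
surface plus locations opened up by degradation -- because the inter-protofibril
gaps (~4.8 nm) are smaller than a plasminogen molecule.  Plasmin, created in
place, moves only by crawling and is instantly inhibited by alpha2-antiplasmin
whenever it ends up in solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _micro_kernel as mk
from .geometry import FiberGeometry, grid_size
from .kinetics import KineticParameters

DEFAULT_T_MAX = 12.0 * 3600.0  # 12 h censoring horizon


@dataclass(frozen=True)
class MicroRules:
    """Model details the published description leaves open.

    * ``spare_own_doublet`` -- a plasmin cleaves fibrin around it but not the
      doublet its own limbs occupy; that doublet can still be degraded by
      another plasmin at the same location.
    * ``relocate_displaced`` -- a plasmin whose doublet is degraded rebinds a
      nearby doublet (crawl target rule) instead of being released and
      inhibited; degradation creates the C-terminal lysines it rebinds.
    * ``crawl_opens_cryptic`` -- crawl/relocation targets include cryptic
      (not yet exposed) non-degraded doublets; landing on one exposes it,
      i.e. the plasmin opens its own path as it processes the fiber.
    * ``cut_threshold`` -- a location counts as structurally severed once at
      least this many of its 6 doublets are degraded.
    * ``stop_at_lysis`` -- end the run at transection (the severed piece
      carries any still-bound tPA away) rather than running the chemistry to
      exhaustion.
    """

    spare_own_doublet: bool = True
    relocate_displaced: bool = True
    crawl_opens_cryptic: bool = True
    cut_threshold: int = 1
    stop_at_lysis: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.cut_threshold <= 6:
            raise ValueError("cut_threshold must be in 1..6")


DEFAULT_RULES = MicroRules()


@dataclass
class MicroRunResult:
    """Outcome of one microscale run."""

    tpa_leave_time: float  # s; < 0 if censored with tPA still bound
    leave_mode: str  # "kinetic" | "forced" | "censored"
    plasmin_created: int
    lysis_occurred: bool
    lysis_time: float | None
    seed: int
    censored: bool = False
    n_events: int = 0
    checksum: int = 0


@dataclass
class EnsembleSummary:
    n_runs: int
    n_forced: int
    n_kinetic: int
    n_with_plasmin: int  # plasmin created AND single-fiber lysis occurred
    n_lysed: int
    n_censored: int

    @property
    def forced_fraction(self) -> float:
        non_censored = self.n_runs - self.n_censored
        return self.n_forced / non_censored if non_censored else float("nan")

    @property
    def lysis_fraction(self) -> float:
        non_censored = self.n_runs - self.n_censored
        return self.n_lysed / non_censored if non_censored else float("nan")


@dataclass
class MicroState:
    """Inspectable snapshot of a cross-section (mirrors the kernel layout)."""

    n: int
    exposed: np.ndarray  # (L, 6) uint8
    fstate: np.ndarray  # (L, 6) uint8: 0 intact, 1 nicked, 2 degraded
    plg: np.ndarray  # (L, 6) uint8
    pli: np.ndarray  # (L, 6) uint8
    accessible: np.ndarray  # (L,) uint8
    tpa: tuple[int, int] | None = None  # (location, doublet)


def build_cross_section(
    fiber_diameter: float,
    geom: FiberGeometry | None = None,
    seed: int = 0,
    place_tpa: bool = True,
) -> MicroState:
    """Fresh cross-section grid; optionally place the tPA on a random perimeter
    location's exposed doublet (doublet 0 of every location starts exposed)."""
    n = grid_size(fiber_diameter, geom)
    L = n * n
    state = MicroState(
        n=n,
        exposed=np.zeros((L, 6), dtype=np.uint8),
        fstate=np.zeros((L, 6), dtype=np.uint8),
        plg=np.zeros((L, 6), dtype=np.uint8),
        pli=np.zeros((L, 6), dtype=np.uint8),
        accessible=np.zeros(L, dtype=np.uint8),
    )
    state.exposed[:, 0] = 1
    rows, cols = np.divmod(np.arange(L), n)
    perim = (rows == 0) | (rows == n - 1) | (cols == 0) | (cols == n - 1)
    state.accessible[perim] = 1
    if place_tpa:
        rng = np.random.default_rng(seed)
        state.tpa = (int(rng.choice(np.flatnonzero(perim))), 0)
    return state


def enumerate_reactions(
    state: MicroState, params: KineticParameters
) -> list[tuple[str, int, int, float]]:
    """Every enabled event as ``(kind, location, doublet, propensity)``.

    Inspection/debugging surface over a state snapshot; the production path is
    the compiled kernel, whose class propensities are the sums of these.
    Molecule-level events (crawl, unbind, activation) are listed per molecule
    with their total propensity; an empty list means the simulation is over.
    """
    events: list[tuple[str, int, int, float]] = []
    L = state.n * state.n
    nondeg = state.fstate < 2
    for loc in range(L):
        acc = state.accessible[loc] == 1
        n_plg_loc = int(state.plg[loc].sum())
        n_cry = int(((state.exposed[loc] == 0) & nondeg[loc]).sum())
        n_nond = int(nondeg[loc].sum())
        for d in range(6):
            if nondeg[loc, d] and state.exposed[loc, d] == 1 and not state.plg[loc, d]:
                if acc:
                    k_on = (
                        params.k_on_plg_intact
                        if state.fstate[loc, d] == 0
                        else params.k_on_plg_nicked
                    )
                    events.append(
                        ("plg_bind", loc, d, k_on * params.plg_concentration)
                    )
            if state.plg[loc, d]:
                events.append(("plg_unbind", loc, d, params.k_off_plg))
            if state.pli[loc, d]:
                events.append(("pli_crawl", loc, d, params.k_crawl_pli))
                events.append(("pli_unbind", loc, d, params.k_unbind_pli))
                if n_cry:
                    events.append(("expose", loc, d, params.k_cat_n * n_cry))
                if n_nond:
                    events.append(("degrade", loc, d, params.k_deg * n_nond))
        if state.tpa is not None and state.tpa[0] == loc:
            d = state.tpa[1]
            k_off = (
                params.k_off_tpa_with_plg
                if state.plg[loc, d]
                else params.k_off_tpa_without_plg
            )
            events.append(("tpa_unbind", loc, d, k_off))
            if n_plg_loc:
                events.append(("activate", loc, d, params.k_cat_ap * n_plg_loc))
    return events


def _result_from_row(row: np.ndarray) -> MicroRunResult:
    censored = bool(row[mk.RES_CENSORED])
    mode = {0.0: "kinetic", 1.0: "forced", 2.0: "severed"}.get(row[mk.RES_MODE], "censored")
    lysed = bool(row[mk.RES_LYSED])
    return MicroRunResult(
        tpa_leave_time=float(row[mk.RES_LEAVE_T]),
        leave_mode=mode,
        plasmin_created=int(row[mk.RES_PLI_CREATED]),
        lysis_occurred=lysed,
        lysis_time=float(row[mk.RES_LYSIS_T]) if lysed else None,
        seed=int(row[mk.RES_SEED]),
        censored=censored,
        n_events=int(row[mk.RES_NEVENTS]),
        checksum=int(row[mk.RES_CHECK]),
    )


def gillespie_run(
    params: KineticParameters,
    fiber_diameter: float,
    seed: int,
    t_max: float = DEFAULT_T_MAX,
    geom: FiberGeometry | None = None,
    require_full_grid: bool = False,
    rules: MicroRules = DEFAULT_RULES,
    return_state: bool = False,
):
    """One exact-SSA microscale run; identical inputs give identical results."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    n = grid_size(fiber_diameter, geom)
    ws = mk.make_workspace(n)
    mk.micro_ssa(
        n,
        params.as_array(),
        int(seed),
        float(t_max),
        require_full_grid,
        rules.spare_own_doublet,
        rules.cut_threshold,
        rules.relocate_displaced,
        rules.crawl_opens_cryptic,
        rules.stop_at_lysis,
        **ws,
    )
    out = ws["out"]
    if not out[mk.RES_OK]:
        raise RuntimeError("microscale kernel counter cross-check failed")
    result = _result_from_row(out)
    if return_state:
        state = MicroState(
            n=n,
            exposed=ws["exposed"],
            fstate=ws["fstate"],
            plg=ws["plg"],
            pli=ws["pli"],
            accessible=ws["accessible"],
        )
        return result, state
    return result


def run_ensemble(
    params: KineticParameters,
    fiber_diameter: float,
    n_runs: int,
    base_seed: int,
    t_max: float = DEFAULT_T_MAX,
    geom: FiberGeometry | None = None,
    require_full_grid: bool = False,
    rules: MicroRules = DEFAULT_RULES,
) -> tuple[list[MicroRunResult], EnsembleSummary]:
    """Independent seeded runs plus the ensemble tallies."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    n = grid_size(fiber_diameter, geom)
    ws = mk.make_workspace(n)
    res = np.empty((int(n_runs), mk.N_RES), dtype=np.float64)
    mk.micro_ensemble_kernel(
        n,
        params.as_array(),
        int(n_runs),
        int(base_seed),
        float(t_max),
        require_full_grid,
        rules.spare_own_doublet,
        rules.cut_threshold,
        rules.relocate_displaced,
        rules.crawl_opens_cryptic,
        rules.stop_at_lysis,
        **ws,
        res=res,
    )
    if not res[:, mk.RES_OK].all():
        raise RuntimeError("microscale kernel counter cross-check failed")
    results = [_result_from_row(row) for row in res]
    summary = EnsembleSummary(
        n_runs=n_runs,
        n_forced=sum(r.leave_mode == "forced" for r in results),
        n_kinetic=sum(r.leave_mode == "kinetic" for r in results),
        n_with_plasmin=sum(
            r.plasmin_created >= 1 and r.lysis_occurred for r in results
        ),
        n_lysed=sum(r.lysis_occurred for r in results),
        n_censored=sum(r.censored for r in results),
    )
    return results, summary


def results_to_frame(results: list[MicroRunResult]) -> pd.DataFrame:
    """TSV-ready table, one row per run."""
    return pd.DataFrame(
        {
            "tpa_leave_time": [r.tpa_leave_time for r in results],
            "leave_mode": [r.leave_mode for r in results],
            "plasmin_created": [r.plasmin_created for r in results],
            "lysis_occurred": [r.lysis_occurred for r in results],
            "lysis_time": [r.lysis_time if r.lysis_time is not None else np.nan for r in results],
            "seed": [r.seed for r in results],
            "censored": [r.censored for r in results],
            "n_events": [r.n_events for r in results],
        }
    )


def frame_to_results(frame: pd.DataFrame) -> list[MicroRunResult]:
    out = []
    for row in frame.itertuples(index=False):
        lysed = bool(row.lysis_occurred)
        out.append(
            MicroRunResult(
                tpa_leave_time=float(row.tpa_leave_time),
                leave_mode=str(row.leave_mode),
                plasmin_created=int(row.plasmin_created),
                lysis_occurred=lysed,
                lysis_time=float(row.lysis_time) if lysed else None,
                seed=int(row.seed),
                censored=bool(row.censored),
                n_events=int(getattr(row, "n_events", 0)),
            )
        )
    return out
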