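"""Static fiber/clot geometry and unit conversions.

All closed-form quantities used to frame the stochastic simulations live here:
molarity <-> number-density conversion, tPA-per-exposed-surface-area ratios,
molecular volumes, protofibril packing, and the equal-area square approximation
of a circular fiber cross-section.

Unit conventions (package-wide): lengths are nm on the fiber microscale and um
on the clot macroscale; time is seconds; concentrations are uM internally, with
nM accepted where a bolus is specified.  Every conversion constant is defined
once, in this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Avogadro's number (1/mol).
N_AVOGADRO = 6.02214076e23

#: molecules per um^3 for a 1 nM solution: 1e-9 mol/L * N_A / (1e15 um^3/L).
MOLECULES_PER_UM3_PER_NM = N_AVOGADRO * 1e-9 * 1e-15

#: molecules per um^3 for a 1 uM solution.
MOLECULES_PER_UM3_PER_UM = MOLECULES_PER_UM3_PER_NM * 1e3

NM_PER_UM = 1e3


@dataclass(frozen=True)
class FiberGeometry:
    """Structural parameters of a fibrin fiber.

    Fibrin fibers are loosely packed lateral aggregates of ~4.8 nm protofibrils
    and are only ~20% protein by volume; plasminogen/plasmin binding sites sit
    ~6 nm apart transversely and ~22.5 nm apart longitudinally along a fiber.
    """

    fiber_diameter: float = 97.5  # nm
    protein_fraction: float = 0.20  # dimensionless, area fraction of protein
    protofibril_diameter: float = 4.8  # nm
    transverse_site_spacing: float = 6.0  # nm
    longitudinal_site_spacing: float = 22.5  # nm

    def __post_init__(self) -> None:
        if self.fiber_diameter <= 0:
            raise ValueError("fiber_diameter must be positive")
        if not 0.0 < self.protein_fraction < math.pi / 4:
            raise ValueError(
                "protein_fraction must lie in (0, pi/4): circles on a square "
                "lattice cannot occupy more than pi/4 of the cross-section"
            )
        if self.protofibril_diameter <= 0:
            raise ValueError("protofibril_diameter must be positive")


@dataclass(frozen=True)
class BolusSpec:
    """A tPA bolus added to the fibrin-free region above the clot.

    The chamber is ``slab_width x slab_depth x (clot height + free_region_height)``
    um^3; the bolus fills the fibrin-free region of height H above the clot
    surface at the given concentration.
    """

    concentration: float  # nM
    free_region_height: float  # um (H)
    slab_width: float = 100.0  # um
    slab_depth: float = 1.37  # um (one pore, the periodic slab depth)

    def __post_init__(self) -> None:
        for name in ("concentration", "free_region_height", "slab_width", "slab_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def concentration_to_number_density(concentration_nM: float) -> float:
    """Convert a molar concentration (nM) to molecules per um^3.

    0.6022 molecules/um^3 per nM; e.g. a 5 nM tPA bolus is only ~3 molecules
    per cubic micron of pore space.
    """
    if concentration_nM < 0:
        raise ValueError("concentration must be non-negative")
    return concentration_nM * MOLECULES_PER_UM3_PER_NM


def tpa_per_surface_area(bolus: BolusSpec) -> float:
    """Number of bolus tPA molecules per um^2 of exposed clot surface.

    Equals number-density x free-region height and is independent of the slab
    footprint: the exposed surface area and the bolus volume share the same
    width x depth factor.  This is the ratio against which fine vs coarse lysis
    speed flips.
    """
    return concentration_to_number_density(bolus.concentration) * bolus.free_region_height


def bolus_molecule_count(bolus: BolusSpec) -> tuple[float, int]:
    """Number of tPA molecules in the bolus, exact and rounded (half-to-even).

    The simulations consume the integer; the exact real is kept for reporting.
    """
    exact = (
        concentration_to_number_density(bolus.concentration)
        * bolus.slab_width
        * bolus.slab_depth
        * bolus.free_region_height
    )
    return exact, round(exact)


def sphere_volume(diameter_nm: float) -> float:
    """Volume (um^3) of a sphere of the given diameter (nm).

    A tPA molecule is ~10 nm long; treating it as a sphere gives
    5.24e-7 um^3, so >1e6 tPA molecules would fit in a 1 um^3 pore.
    """
    if diameter_nm < 0:
        raise ValueError("diameter must be non-negative")
    d_um = diameter_nm / NM_PER_UM
    return math.pi / 6.0 * d_um**3


def protofibril_spacing(geom: FiberGeometry, packing: str = "square") -> dict[str, float]:
    """Center-to-center and edge-to-edge protofibril spacing (nm).

    Protofibrils are modeled as circles of diameter ``d`` on a regular lattice
    occupying an area fraction ``f`` of the cross-section:

    * square lattice (default): ``c2c = d * sqrt(pi / (4 f))``
    * hexagonal lattice:        ``c2c = d * sqrt(pi / (2 sqrt(3) f))``

    With f = 0.20 and d = 4.8 nm the square lattice gives an edge-to-edge gap
    of ~4.8 nm -- too narrow for a 9-11 nm plasminogen molecule, which is why
    solution-phase macromolecules only reach the fiber surface until
    degradation opens the interior.  Result is independent of fiber diameter.
    """
    d = geom.protofibril_diameter
    f = geom.protein_fraction
    if packing == "square":
        c2c = d * math.sqrt(math.pi / (4.0 * f))
    elif packing in ("hex", "hexagonal"):
        c2c = d * math.sqrt(math.pi / (2.0 * math.sqrt(3.0) * f))
    else:
        raise ValueError(f"unknown packing {packing!r}")
    return {"center_to_center": c2c, "edge_to_edge": c2c - d}


def cross_section_square_side(fiber_diameter_nm: float) -> float:
    """Side (nm) of the square of equal area to the circular cross-section."""
    if fiber_diameter_nm <= 0:
        raise ValueError("fiber_diameter must be positive")
    return math.sqrt(math.pi) * fiber_diameter_nm / 2.0


def grid_size(fiber_diameter_nm: float, geom: FiberGeometry | None = None) -> int:
    """Number of binding locations per side of the microscale grid.

    The equal-area square is tiled at the protofibril center-to-center pitch
    (~9.5 nm at default packing), one binding location per pitch cell:
    a 97.5 nm fiber gives a 9x9 grid, a 195 nm fiber an 18x18 grid.
    """
    if geom is None:
        geom = FiberGeometry(fiber_diameter=fiber_diameter_nm)
    pitch = protofibril_spacing(geom)["center_to_center"]
    n = round(cross_section_square_side(fiber_diameter_nm) / pitch)
    if n < 2:
        raise ValueError(
            f"fiber diameter {fiber_diameter_nm} nm is thinner than two "
            f"protofibril pitch cells (grid {n} < 2)"
        )
    return n


def analytics_report(
    geom: FiberGeometry | None = None, bolus: BolusSpec | None = None
) -> dict:
    """JSON-serializable report of the closed-form quantities for a config."""
    geom = geom or FiberGeometry()
    bolus = bolus or BolusSpec(concentration=5.0, free_region_height=2.935)
    spacing = protofibril_spacing(geom)
    exact, n_mol = bolus_molecule_count(bolus)
    return {
        "number_density_per_um3": concentration_to_number_density(bolus.concentration),
        "tpa_per_surface_area_per_um2": tpa_per_surface_area(bolus),
        "bolus_molecules_exact": exact,
        "bolus_molecules": n_mol,
        "tpa_molecular_volume_um3": sphere_volume(10.0),
        "protofibril_center_to_center_nm": spacing["center_to_center"],
        "protofibril_edge_to_edge_nm": spacing["edge_to_edge"],
        "cross_section_square_side_nm": cross_section_square_side(geom.fiber_diameter),
        "grid_size": grid_size(geom.fiber_diameter, geom),
    }
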