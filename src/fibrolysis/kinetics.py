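"""Kinetic rate constants for the fibrinolytic reaction network.

Single source of truth for the chemistry of both engines.  Defaults are the
literature baseline set: plasminogen (PLG) binding depends on whether fibrin
is intact or nicked (plasmin-cleaved fibrin exposes C-terminal lysines and
binds PLG ~17x faster); tPA unbinding depends on whether a PLG shares its
binding doublet (the ternary complex is much longer-lived); plasmin (PLi)
crawls between doublets far faster than it unbinds.  The cryptic-site
exposure rate is taken equal to the degradation rate, there being no
independent measurement of it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

# Index layout of KineticParameters.as_array(), shared with the numba kernels.
R_DEG = 0
R_OFF_PLG = 1
R_ON_PLG_INTACT = 2
R_ON_PLG_NICKED = 3
R_CRAWL_PLI = 4
R_UNBIND_PLI = 5
R_OFF_TPA_WITH_PLG = 6
R_OFF_TPA_WITHOUT_PLG = 7
R_ON_TPA = 8
R_CAT_AP = 9
R_CAT_N = 10
R_PLG_CONC = 11
N_RATES = 12


@dataclass(frozen=True)
class KineticParameters:
    """Baseline rate constants (s^-1, uM^-1 s^-1) and solution concentrations (uM)."""

    k_deg: float = 5.0  # s^-1, plasmin-mediated fibrin degradation
    k_off_plg: float = 3.8  # s^-1
    k_on_plg_intact: float = 0.1  # uM^-1 s^-1
    k_on_plg_nicked: float = 1.72  # uM^-1 s^-1
    k_crawl_pli: float = 57.6  # s^-1
    k_unbind_pli: float = 0.05  # s^-1
    k_off_tpa_with_plg: float = 0.0002  # s^-1 (ternary complex)
    k_off_tpa_without_plg: float = 0.0036  # s^-1
    k_on_tpa: float = 0.01  # uM^-1 s^-1 (macroscale binding)
    k_cat_ap: float = 0.1  # s^-1, PLG -> PLi activation by tPA
    k_cat_n: float = 5.0  # s^-1, cryptic doublet exposure (= k_deg by default)
    plg_concentration: float = 2.0  # uM, plasma plasminogen
    tpa_concentration: float = 0.005  # uM, macroscale bolus default (5 nM)

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            if getattr(self, field.name) < 0:
                raise ValueError(f"{field.name} must be non-negative")

    def replace(self, **overrides: float) -> "KineticParameters":
        return dataclasses.replace(self, **overrides)

    def as_array(self) -> np.ndarray:
        """Rate vector consumed by the microscale kernel (layout: R_* indices)."""
        return np.array(
            [
                self.k_deg,
                self.k_off_plg,
                self.k_on_plg_intact,
                self.k_on_plg_nicked,
                self.k_crawl_pli,
                self.k_unbind_pli,
                self.k_off_tpa_with_plg,
                self.k_off_tpa_without_plg,
                self.k_on_tpa,
                self.k_cat_ap,
                self.k_cat_n,
                self.plg_concentration,
            ],
            dtype=np.float64,
        )
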