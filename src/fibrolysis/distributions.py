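"""Empirical distributions coupling the microscale to the macroscale.

The macroscale clot model never runs the fiber chemistry directly: each tPA
binding event draws a residence time (when the molecule unbinds) and, with the
single-fiber lysis probability, a degradation delay (when the fiber is cut)
from distributions compiled over a microscale ensemble.  Raw samples are kept
and sampled by inverse CDF; no parametric fit is imposed.

Residence time and lysis delay are drawn independently per macroscale binding
event.  The two are correlated within a microscale run; independence is a
declared approximation isolated behind this interface so a joint-sampling
variant can be swapped in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .microscale import EnsembleSummary, MicroRunResult

FORMAT_VERSION = 1


@dataclass
class EmpiricalDistribution:
    """Uniformly weighted sample distribution with inverse-CDF sampling."""

    values: np.ndarray  # sorted ascending, finite, >= 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if v.size and (not np.isfinite(v).all() or (v < 0).any()):
            raise ValueError("values must be finite and non-negative")
        self.values = np.sort(v)

    def __len__(self) -> int:
        return int(self.values.size)

    def sample(self, u: float | np.ndarray) -> float | np.ndarray:
        """Inverse-CDF lookup of the right-continuous step CDF.

        ``u = 0`` returns the minimum, ``u = 1`` the maximum.
        """
        if len(self) == 0:
            raise ValueError("cannot sample from an empty distribution")
        u = np.asarray(u, dtype=float)
        if (u < 0).any() or (u > 1).any():
            raise ValueError("u must lie in [0, 1]")
        idx = np.minimum((u * len(self)).astype(np.int64), len(self) - 1)
        out = self.values[idx]
        return float(out) if out.ndim == 0 else out

    def quantile(self, q: float) -> float:
        return float(self.sample(q))

    @property
    def mean(self) -> float:
        return float(self.values.mean()) if len(self) else float("nan")


@dataclass
class MicroSummaryPack:
    """Everything the macroscale needs from a microscale ensemble."""

    tpa_residence: EmpiricalDistribution
    forced_probability: float
    lysis_probability: float
    lysis_delay: EmpiricalDistribution
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("forced_probability", "lysis_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.lysis_probability > 0 and len(self.lysis_delay) == 0:
            raise ValueError("lysis delay distribution empty despite lysis probability > 0")


def build_pack(
    results: list[MicroRunResult],
    summary: EnsembleSummary | None = None,
    metadata: dict | None = None,
) -> MicroSummaryPack:
    """Compile a pack from microscale results; censored runs are excluded
    from every distribution and probability but counted in the metadata."""
    non_censored = [r for r in results if not r.censored]
    if not non_censored:
        raise ValueError("no non-censored microscale results to build a pack from")
    n = len(non_censored)
    residence = np.array([r.tpa_leave_time for r in non_censored])
    n_forced = sum(r.leave_mode in ("forced", "severed") for r in non_censored)
    lysed = [r for r in non_censored if r.lysis_occurred]
    delays = np.array([r.lysis_time for r in lysed]) if lysed else np.empty(0)
    meta = dict(metadata or {})
    meta.update(
        n=n,
        censored=len(results) - n,
        seed_range=[min(r.seed for r in results), max(r.seed for r in results)],
    )
    return MicroSummaryPack(
        tpa_residence=EmpiricalDistribution(residence, {"kind": "tpa_residence", **meta}),
        forced_probability=n_forced / n,
        lysis_probability=len(lysed) / n,
        lysis_delay=EmpiricalDistribution(delays, {"kind": "lysis_delay", **meta}),
        metadata=meta,
    )


def save_pack(pack: MicroSummaryPack, path: str | Path) -> None:
    """Write a pack as a single JSON document (raw samples, full precision)."""
    doc = {
        "format": "fibrolysis-micro-pack",
        "version": FORMAT_VERSION,
        "metadata": pack.metadata,
        "forced_probability": pack.forced_probability,
        "lysis_probability": pack.lysis_probability,
        "tpa_residence": pack.tpa_residence.values.tolist(),
        "lysis_delay": pack.lysis_delay.values.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_pack(path: str | Path) -> MicroSummaryPack:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not a valid pack file ({exc})") from exc
    if doc.get("format") != "fibrolysis-micro-pack":
        raise ValueError(f"{path}: not a fibrolysis micro pack")
    if doc.get("version") != FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported pack version {doc.get('version')!r}"
        )
    meta = doc.get("metadata", {})
    return MicroSummaryPack(
        tpa_residence=EmpiricalDistribution(
            np.array(doc["tpa_residence"]), {"kind": "tpa_residence", **meta}
        ),
        forced_probability=doc["forced_probability"],
        lysis_probability=doc["lysis_probability"],
        lysis_delay=EmpiricalDistribution(
            np.array(doc["lysis_delay"]), {"kind": "lysis_delay", **meta}
        ),
        metadata=meta,
    )
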