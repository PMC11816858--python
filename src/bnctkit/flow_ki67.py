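"""Ki67 proliferation gating from two-channel flow-cytometry event tables.

Events carry a Ki67-antibody intensity (channel C3) and a propidium-iodide
intensity (channel C6).  The Ki67-positive fraction is the share of
non-debris events whose C3 intensity exceeds a gate threshold; the gate is
derived as a high quantile (default 99th percentile) of an unstained or
untreated control sample, a standard isotype/FMO-style strategy.  The PI
channel is used only to exclude debris (zero-PI events).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .comet_stats import ALPHA, variance_of_mean, welch_t_test
from .errors import GatingError, InputDomainError

__all__ = [
    "GateStrategy",
    "GateConfig",
    "FlowEventTable",
    "derive_gate",
    "positive_fraction",
    "median_intensity",
    "ki67_summary",
    "MIN_EVENTS",
]

logger = logging.getLogger(__name__)

MIN_EVENTS = 500


class GateStrategy(str, enum.Enum):
    control_quantile = "control_quantile"
    fixed = "fixed"


@dataclass(frozen=True)
class GateConfig:
    ki67_threshold: float
    strategy: GateStrategy = GateStrategy.control_quantile
    control_quantile: float = 0.99

    def __post_init__(self):
        if self.strategy is GateStrategy.fixed and self.ki67_threshold <= 0:
            raise InputDomainError("fixed gate threshold must be positive")


@dataclass
class FlowEventTable:
    """Per-event intensities for one sample."""

    c3_ki67: np.ndarray
    c6_pi: np.ndarray
    group: str = ""
    dose_group: str = "none"
    time_h: float = 0.0
    sample_id: str = ""

    def __post_init__(self):
        self.c3_ki67 = np.asarray(self.c3_ki67, dtype=float)
        self.c6_pi = np.asarray(self.c6_pi, dtype=float)
        if self.c3_ki67.shape != self.c6_pi.shape:
            raise InputDomainError("channel arrays must align")
        if (self.c3_ki67 < 0).any() or (self.c6_pi < 0).any():
            raise InputDomainError("intensities must be nonnegative")

    @property
    def n_events(self) -> int:
        return int(self.c3_ki67.size)


def derive_gate(control: FlowEventTable, q: float = 0.99) -> GateConfig:
    """Gate at the q-quantile of the control sample's Ki67 channel."""
    if not 0 < q <= 1:
        raise InputDomainError("quantile must be in (0, 1]")
    if control.n_events < MIN_EVENTS:
        raise GatingError(
            f"only {control.n_events} control events; need >= {MIN_EVENTS} to gate"
        )
    thr = float(np.quantile(control.c3_ki67, q))
    return GateConfig(ki67_threshold=thr, strategy=GateStrategy.control_quantile,
                      control_quantile=q)


def _non_debris(events: FlowEventTable) -> np.ndarray:
    keep = events.c6_pi > 0
    return events.c3_ki67[keep] if keep.any() else events.c3_ki67


def positive_fraction(events: FlowEventTable, gate: GateConfig) -> float:
    """Fraction of non-debris events above the Ki67 gate."""
    c3 = _non_debris(events)
    if c3.size == 0:
        raise InputDomainError("no events")
    return float(np.mean(c3 > gate.ki67_threshold))


def median_intensity(events: FlowEventTable) -> float:
    """Median Ki67 intensity of non-debris events (secondary readout)."""
    c3 = _non_debris(events)
    return float(np.median(c3))


def ki67_summary(
    samples: list[FlowEventTable],
    gate: GateConfig,
    control_group: str = "C",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-(group, dose_group, time) Ki67-positive summary with Welch flags.

    Replicate samples within a stratum are summarized as mean +/- Delta of
    their positive fractions; each non-control stratum is tested against
    the control samples at the same time point.  Missing controls skip the
    comparison with a log entry.
    """
    rows = []
    for s in samples:
        rows.append({
            "sample_id": s.sample_id,
            "group": s.group,
            "dose_group": s.dose_group,
            "time_h": s.time_h,
            "positive_fraction": positive_fraction(s, gate),
            "median_c3": median_intensity(s),
        })
    per_sample = pd.DataFrame(rows)
    out = []
    for (grp, dg, t), sub in per_sample.groupby(["group", "dose_group", "time_h"]):
        fracs = sub["positive_fraction"].to_numpy()
        rec = {
            "group": grp, "dose_group": dg, "time_h": t,
            "mean_fraction": float(fracs.mean()),
            "delta": variance_of_mean(fracs) if len(fracs) > 1 else 0.0,
            "n_samples": int(len(fracs)),
            "median_c3": float(sub["median_c3"].median()),
            "p_vs_control": np.nan,
            "significant": False,
        }
        ctrl = per_sample[(per_sample["group"] == control_group)
                          & (per_sample["time_h"] == t)]
        if grp != control_group:
            cvals = ctrl["positive_fraction"].to_numpy()
            if len(cvals) >= 2 and len(fracs) >= 2:
                res = welch_t_test(fracs, cvals, alpha=alpha)
                rec["p_vs_control"] = res.p
                rec["significant"] = res.significant
            else:
                logger.warning(
                    "no/insufficient control at t=%s h for group %s; comparison skipped",
                    t, grp,
                )
        out.append(rec)
    return pd.DataFrame(out)
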