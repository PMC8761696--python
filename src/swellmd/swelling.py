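"""Swelling curves and response metrics from per-frame organoid areas.

A well's area series is normalized to percent of its t=0 area; the response
readout is the trapezoidal area under that curve above the 100% baseline
over 0-60 min (%·min). Negative values (shrinkage) are reported, not
clipped. Treatment effects are expressed as baseline-corrected AUC
differences, integer fold changes of group means, and a synergy score for
potentiator combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SwellingSeries",
    "FISResult",
    "ConditionSummary",
    "DegenerateWellError",
    "CoverageError",
    "PairingError",
    "SummaryError",
    "normalize_series",
    "auc",
    "baseline_correct",
    "fold_change",
    "synergy_score",
    "summarize_condition",
]


class DegenerateWellError(ValueError):
    """The well has no measurable area at t=0 and must be excluded."""


class CoverageError(ValueError):
    """The time grid does not cover the integration interval."""


class PairingError(ValueError):
    """Baseline correction attempted across mismatched conditions."""


class SummaryError(ValueError):
    """A condition group is empty."""


@dataclass
class SwellingSeries:
    """Area trajectory of one well, raw and as percent of t=0."""

    times: np.ndarray  # minutes
    raw_area: np.ndarray  # px^2
    normalized: np.ndarray  # % of t=0; normalized[0] == 100 exactly

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.raw_area = np.asarray(self.raw_area, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        if not (len(self.times) == len(self.raw_area) == len(self.normalized)):
            raise ValueError("times, raw_area and normalized must share one length")
        if self.normalized[0] != 100.0:
            raise ValueError("normalized[0] must be exactly 100")


@dataclass
class FISResult:
    """AUC of one well plus its condition metadata."""

    auc: float  # %·min above the 100% baseline
    condition: dict = field(default_factory=dict)
    well_id: str | None = None
    replicate_id: str | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.auc):
            raise ValueError("auc must be finite")


@dataclass
class ConditionSummary:
    condition: tuple
    mean_auc: float
    sd_auc: float  # sample SD (ddof=1); 0 with single_well flag when n == 1
    n_wells: int
    n_flagged: int = 0
    single_well: bool = False
    baseline_corrected_auc: float | None = None


def normalize_series(times, raw_area) -> SwellingSeries:
    """Normalize a well's area series to percent of its t=0 area."""
    times = np.asarray(times, dtype=float)
    raw_area = np.asarray(raw_area, dtype=float)
    if len(times) != len(raw_area):
        raise ValueError("times and raw_area must share one length")
    if raw_area[0] <= 0:
        raise DegenerateWellError("raw_area[0] must be > 0 (empty or failed well)")
    normalized = 100.0 * raw_area / raw_area[0]
    normalized[0] = 100.0
    return SwellingSeries(times=times, raw_area=raw_area, normalized=normalized)


def auc(series: SwellingSeries, t_start: float = 0.0, t_end: float = 60.0) -> float:
    """Trapezoidal integral of (normalized - 100) over [t_start, t_end], %·min."""
    t = series.times
    if t[0] > t_start or t[-1] < t_end:
        raise CoverageError(
            f"time grid [{t[0]}, {t[-1]}] does not cover [{t_start}, {t_end}]"
        )
    dev = series.normalized - 100.0
    inside = (t > t_start) & (t < t_end)
    xs = np.concatenate(([t_start], t[inside], [t_end]))
    ys = np.concatenate(
        ([np.interp(t_start, t, dev)], dev[inside], [np.interp(t_end, t, dev)])
    )
    return float(np.trapezoid(ys, xs))


_PAIRING_KEYS = ("genotype", "fsk_um")


def baseline_correct(
    auc_treated: float,
    auc_untreated: float,
    treated_condition: Mapping | None = None,
    untreated_condition: Mapping | None = None,
) -> float:
    """Treated minus untreated AUC; conditions (if given) must match on
    genotype and forskolin concentration."""
    if treated_condition is not None and untreated_condition is not None:
        for key in _PAIRING_KEYS:
            if treated_condition.get(key) != untreated_condition.get(key):
                raise PairingError(
                    f"condition mismatch on {key!r}: "
                    f"{treated_condition.get(key)} vs {untreated_condition.get(key)}"
                )
    return float(auc_treated) - float(auc_untreated)


def fold_change(value_a: float, value_b: float, round_to_integer: bool = True):
    """Ratio a/b, optionally rounded to the nearest integer fold."""
    if value_b <= 0:
        raise ValueError("denominator must be > 0")
    ratio = float(value_a) / float(value_b)
    return int(round(ratio)) if round_to_integer else ratio


def synergy_score(auc_combo: float, auc_a: float, auc_b: float) -> float:
    """Combination response minus the sum of the single responses.

    Positive values flag synergy; all inputs should be baseline-corrected
    AUCs from matched conditions.
    """
    return float(auc_combo) - (float(auc_a) + float(auc_b))


def summarize_condition(
    results: Iterable[FISResult],
    grouping: Sequence[str] = ("genotype", "fsk_um", "treatment"),
) -> list[ConditionSummary]:
    """Mean and sample SD (ddof=1) of AUC per condition group.

    Flagged wells are excluded from the statistics but counted. A group with
    a single usable well reports SD 0 with ``single_well=True``.
    """
    groups: dict[tuple, list[FISResult]] = {}
    for r in results:
        key = tuple(r.condition.get(k) for k in grouping)
        groups.setdefault(key, []).append(r)
    if not groups:
        raise SummaryError("no results to summarize")
    out = []
    for key in groups:
        members = groups[key]
        usable = [r.auc for r in members if not r.flagged]
        n_flagged = len(members) - len(usable)
        if not usable:
            raise SummaryError(f"group {key} has no usable wells")
        vals = np.asarray(usable, dtype=float)
        single = len(vals) == 1
        out.append(
            ConditionSummary(
                condition=key,
                mean_auc=float(vals.mean()),
                sd_auc=0.0 if single else float(vals.std(ddof=1)),
                n_wells=len(vals),
                n_flagged=n_flagged,
                single_well=single,
            )
        )
    return out
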