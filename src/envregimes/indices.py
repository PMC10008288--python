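"""Numerical kernels for the 11 elementary environmental-regime indices.

The indices summarize one window of values in three facets:

* magnitude — MA1 mean, MA2 median, MA3 coefficient of variation (%),
  MA4 skewness;
* frequency — ML1/MH1 counts of low/high pulses (beyond the window's own
  25th/75th percentile), EL1/EH1 counts of extreme low/high pulses (beyond
  the 10th/90th percentile);
* rate of change — RC mean successive change per step, RH1/RL1 counts of
  positive/negative successive changes.

Every kernel takes a plain 1-D float array for one window; NaN marks a
missing measurement.  Pulse thresholds are always computed from the
window's own values, never from the full record, so a "high pulse" means
high *relative to that window*.  Choices the index definitions leave open
(tie handling at the threshold, the percentile interpolation rule, the
skewness estimator, whether a pulse is a qualifying day or a contiguous
excursion, signed vs absolute rate of change) are explicit
:class:`RegimeConfig` fields with documented defaults.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

from .errors import ValidationError

logger = logging.getLogger("envregimes")

__all__ = [
    "INDEX_CODES",
    "RegimeConfig",
    "RegimeIndexSet",
    "ma1_mean",
    "ma2_median",
    "ma3_cv",
    "ma4_skew",
    "pulse_thresholds",
    "count_pulses",
    "rc_rate_of_change",
    "count_changes",
    "compute_index_set",
]

#: The 11 index codes, in canonical output order.
INDEX_CODES = ("MA1", "MA2", "MA3", "MA4", "ML1", "MH1", "EL1", "EH1", "RC", "RH1", "RL1")

#: Codes that are event counts (non-negative integers when present).
COUNT_CODES = ("ML1", "MH1", "EL1", "EH1", "RH1", "RL1")


@dataclass(frozen=True)
class RegimeConfig:
    """Tunable choices for the regime-index kernels.

    Attributes
    ----------
    low_p, high_p, ext_low_p, ext_high_p
        Percentile probabilities defining low/high (0.25/0.75) and extreme
        low/high (0.10/0.90) pulse thresholds, matching the hydrologic
        convention.
    pulse_mode
        ``timepoints`` counts every qualifying timestamp; ``runs`` counts
        maximal contiguous excursions (a run interrupted by a missing value
        counts as two).
    strict_inequality
        Whether "below/above the threshold" excludes values equal to it.
    skew_kind
        ``moment``: Fisher-Pearson m3 / m2^(3/2) (biased moment estimator);
        ``mean_over_median``: mean/median, the hydrologic skewness.
    rc_kind
        ``signed_mean``: mean of successive differences; ``abs_mean``: mean
        absolute successive difference.
    min_n
        Windows with fewer non-missing values yield missing for the
        variability, frequency and rate indices instead of raising.
    percentile_method
        Interpolation rule passed to :func:`numpy.percentile`.
    """

    low_p: float = 0.25
    high_p: float = 0.75
    ext_low_p: float = 0.10
    ext_high_p: float = 0.90
    pulse_mode: Literal["timepoints", "runs"] = "timepoints"
    strict_inequality: bool = True
    skew_kind: Literal["moment", "mean_over_median"] = "moment"
    rc_kind: Literal["signed_mean", "abs_mean"] = "signed_mean"
    min_n: int = 2
    percentile_method: str = "linear"

    def __post_init__(self) -> None:
        if not (0 <= self.ext_low_p < self.low_p < self.high_p < self.ext_high_p <= 1):
            raise ValidationError(
                "percentile probabilities must satisfy "
                "ext_low_p < low_p < high_p < ext_high_p within [0, 1]"
            )
        if self.min_n < 2:
            raise ValidationError(f"min_n must be >= 2, got {self.min_n}")
        if self.pulse_mode not in ("timepoints", "runs"):
            raise ValidationError(f"unknown pulse_mode {self.pulse_mode!r}")
        if self.skew_kind not in ("moment", "mean_over_median"):
            raise ValidationError(f"unknown skew_kind {self.skew_kind!r}")
        if self.rc_kind not in ("signed_mean", "abs_mean"):
            raise ValidationError(f"unknown rc_kind {self.rc_kind!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "RegimeConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_yaml(cls, path) -> "RegimeConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        return cls.from_mapping(data)


@dataclass(frozen=True)
class RegimeIndexSet:
    """The 11 index values for one window (missing encoded as NaN)."""

    values: dict[str, float] = field(default_factory=dict)
    n: int = 0

    def __post_init__(self) -> None:
        if tuple(self.values) != INDEX_CODES:
            raise ValidationError("index set must hold exactly the 11 codes in order")
        for code in COUNT_CODES:
            v = self.values[code]
            if not math.isnan(v) and (v < 0 or v != int(v)):
                raise ValidationError(f"{code} must be a non-negative integer, got {v}")

    def __getitem__(self, code: str) -> float:
        return self.values[code]


def _clean(values) -> np.ndarray:
    vals = np.asarray(values, dtype=float).ravel()
    return vals[~np.isnan(vals)]


def ma1_mean(values) -> float:
    """MA1: arithmetic mean of the window values."""
    x = _clean(values)
    return float(np.mean(x)) if x.size else math.nan


def ma2_median(values) -> float:
    """MA2: sample median (even n: mean of the two central order statistics)."""
    x = _clean(values)
    return float(np.median(x)) if x.size else math.nan


def ma3_cv(values, min_n: int = 2) -> float:
    """MA3: coefficient of variation in percent, 100 * sd / mean (sd with n-1)."""
    x = _clean(values)
    if x.size < min_n:
        return math.nan
    m = np.mean(x)
    if m == 0:
        logger.warning("MA3 undefined: window mean is zero")
        return math.nan
    if np.ptp(x) == 0:  # exactly constant window: CV is 0, not fp residue
        return 0.0
    return float(100.0 * np.std(x, ddof=1) / m)


def ma4_skew(values, skew_kind: str = "moment") -> float:
    """MA4: window skewness.

    ``moment`` is the biased Fisher-Pearson estimator m3 / m2^(3/2) (needs
    n >= 3 and non-zero variance); ``mean_over_median`` is the hydrologic
    mean/median ratio (needs a non-zero median).
    """
    x = _clean(values)
    if skew_kind == "mean_over_median":
        if x.size == 0:
            return math.nan
        med = np.median(x)
        if med == 0:
            logger.warning("MA4 (mean/median) undefined: window median is zero")
            return math.nan
        return float(np.mean(x) / med)
    if x.size < 3:
        return math.nan
    if np.ptp(x) == 0:  # zero variance
        return math.nan
    dev = x - np.mean(x)
    m2 = np.mean(dev**2)
    if m2 == 0:
        return math.nan
    m3 = np.mean(dev**3)
    return float(m3 / m2**1.5)


def pulse_thresholds(values, config: RegimeConfig) -> tuple[float, float, float, float]:
    """Window-internal (ext_low, low, high, ext_high) percentile thresholds."""
    x = _clean(values)
    if x.size < config.min_n:
        return (math.nan,) * 4
    probs = [config.ext_low_p, config.low_p, config.high_p, config.ext_high_p]
    t = np.percentile(x, [100 * p for p in probs], method=config.percentile_method)
    return tuple(float(v) for v in t)


def count_pulses(
    values,
    threshold: float,
    direction: Literal["below", "above"],
    pulse_mode: Literal["timepoints", "runs"] = "timepoints",
    strict_inequality: bool = True,
) -> int:
    """Count pulse events beyond a threshold.

    ``timepoints`` counts qualifying timestamps; ``runs`` counts maximal
    contiguous excursions, with missing values breaking a run in two.
    """
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size == 0 or math.isnan(threshold):
        return 0
    with np.errstate(invalid="ignore"):
        if direction == "below":
            mask = vals < threshold if strict_inequality else vals <= threshold
        elif direction == "above":
            mask = vals > threshold if strict_inequality else vals >= threshold
        else:
            raise ValidationError(f"unknown direction {direction!r}")
    mask &= ~np.isnan(vals)  # NaN never qualifies
    if pulse_mode == "timepoints":
        return int(mask.sum())
    starts = mask & ~np.concatenate(([False], mask[:-1]))
    return int(starts.sum())


def _pair_diffs(values) -> np.ndarray:
    """Successive differences over pairs of adjacent non-missing values."""
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size < 2:
        return np.empty(0)
    d = np.diff(vals)
    return d[~np.isnan(d)]


def rc_rate_of_change(values, rc_kind: str = "signed_mean") -> float:
    """RC: mean rate of change per step over adjacent non-missing pairs.

    ``signed_mean`` averages the signed differences (on a gapless window it
    telescopes to (last - first)/(n - 1)); ``abs_mean`` averages their
    absolute values.
    """
    d = _pair_diffs(values)
    if d.size == 0:
        return math.nan
    return float(np.mean(np.abs(d)) if rc_kind == "abs_mean" else np.mean(d))


def count_changes(values, sign: Literal["rising", "declining"]) -> float:
    """RH1/RL1: number of positive (rising) or negative (declining) steps.

    Zero differences count in neither direction; returns NaN when the
    window has no adjacent non-missing pair.
    """
    d = _pair_diffs(values)
    if d.size == 0:
        return math.nan
    if sign == "rising":
        return int((d > 0).sum())
    if sign == "declining":
        return int((d < 0).sum())
    raise ValidationError(f"unknown sign {sign!r}")


def compute_index_set(values, config: RegimeConfig | None = None) -> RegimeIndexSet:
    """Compute all 11 indices for one window of values.

    Indices whose preconditions fail (too few values, zero mean/variance,
    no valid successive pair) come back as NaN rather than raising, so one
    degenerate window cannot abort a whole run.
    """
    config = config or RegimeConfig()
    vals = np.asarray(values, dtype=float).ravel()
    n = int(np.sum(~np.isnan(vals)))

    out: dict[str, float] = {}
    out["MA1"] = ma1_mean(vals)
    out["MA2"] = ma2_median(vals)
    out["MA3"] = ma3_cv(vals, min_n=config.min_n)
    out["MA4"] = ma4_skew(vals, skew_kind=config.skew_kind) if n >= config.min_n else math.nan

    ext_low, low, high, ext_high = pulse_thresholds(vals, config)
    if math.isnan(low):
        out["ML1"] = out["MH1"] = out["EL1"] = out["EH1"] = math.nan
    else:
        kw = dict(pulse_mode=config.pulse_mode, strict_inequality=config.strict_inequality)
        out["ML1"] = count_pulses(vals, low, "below", **kw)
        out["MH1"] = count_pulses(vals, high, "above", **kw)
        out["EL1"] = count_pulses(vals, ext_low, "below", **kw)
        out["EH1"] = count_pulses(vals, ext_high, "above", **kw)

    if n < config.min_n:
        out["RC"] = out["RH1"] = out["RL1"] = math.nan
    else:
        out["RC"] = rc_rate_of_change(vals, rc_kind=config.rc_kind)
        out["RH1"] = count_changes(vals, "rising")
        out["RL1"] = count_changes(vals, "declining")

    return RegimeIndexSet(values={c: out[c] for c in INDEX_CODES}, n=n)
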