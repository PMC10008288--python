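"""Independent brute-force re-derivation of the 11 regime indices.

Pure-Python loops and closed-form formulas only — no numpy, no imports
from the package under test — so agreement with the library is a real
dual-route check, not the same code called twice.
"""

import math


def _clean(values):
    return [float(v) for v in values if not (isinstance(v, float) and math.isnan(v))]


def mean(values):
    x = _clean(values)
    return sum(x) / len(x) if x else math.nan


def median(values):
    x = sorted(_clean(values))
    n = len(x)
    if n == 0:
        return math.nan
    mid = n // 2
    return x[mid] if n % 2 else (x[mid - 1] + x[mid]) / 2.0


def cv_percent(values, min_n=2):
    x = _clean(values)
    if len(x) < min_n:
        return math.nan
    m = sum(x) / len(x)
    if m == 0:
        return math.nan
    if min(x) == max(x):
        return 0.0
    var = sum((v - m) ** 2 for v in x) / (len(x) - 1)
    return 100.0 * math.sqrt(var) / m


def skew_moment(values):
    x = _clean(values)
    if len(x) < 3 or min(x) == max(x):
        return math.nan
    m = sum(x) / len(x)
    m2 = sum((v - m) ** 2 for v in x) / len(x)
    if m2 == 0:
        return math.nan
    m3 = sum((v - m) ** 3 for v in x) / len(x)
    return m3 / m2**1.5


def skew_mean_over_median(values):
    med = median(values)
    if math.isnan(med) or med == 0:
        return math.nan
    return mean(values) / med


def percentile_linear(values, p):
    """Linear interpolation between order statistics at probability p."""
    x = sorted(_clean(values))
    if not x:
        return math.nan
    h = (len(x) - 1) * p
    lo = math.floor(h)
    if lo == len(x) - 1:
        return x[-1]
    return x[lo] + (h - lo) * (x[lo + 1] - x[lo])


def count_beyond(values, threshold, direction, mode="timepoints", strict=True):
    """Count qualifying timepoints, or maximal runs of them."""
    def q(v):
        if isinstance(v, float) and math.isnan(v):
            return False
        if direction == "below":
            return v < threshold if strict else v <= threshold
        return v > threshold if strict else v >= threshold

    flags = [q(v) for v in values]
    if mode == "timepoints":
        return sum(flags)
    runs, prev = 0, False
    for f in flags:
        if f and not prev:
            runs += 1
        prev = f
    return runs


def _diffs(values):
    out = []
    for a, b in zip(values, values[1:]):
        if any(isinstance(v, float) and math.isnan(v) for v in (a, b)):
            continue
        out.append(b - a)
    return out


def rate_of_change(values, kind="signed_mean"):
    d = _diffs(values)
    if not d:
        return math.nan
    if kind == "abs_mean":
        return sum(abs(v) for v in d) / len(d)
    return sum(d) / len(d)


def count_changes(values, sign):
    d = _diffs(values)
    if not d:
        return math.nan
    return sum(1 for v in d if (v > 0 if sign == "rising" else v < 0))


def index_set(values, min_n=2, pulse_mode="timepoints", strict=True,
              skew_kind="moment", rc_kind="signed_mean"):
    """All 11 indices from first principles, mirroring the prose definitions."""
    n = len(_clean(values))
    out = {
        "MA1": mean(values),
        "MA2": median(values),
        "MA3": cv_percent(values, min_n),
        "MA4": (skew_moment(values) if skew_kind == "moment"
                else skew_mean_over_median(values)) if n >= min_n else math.nan,
    }
    if n < min_n:
        out.update({k: math.nan for k in ("ML1", "MH1", "EL1", "EH1", "RC", "RH1", "RL1")})
        return out
    out["ML1"] = count_beyond(values, percentile_linear(values, 0.25), "below", pulse_mode, strict)
    out["MH1"] = count_beyond(values, percentile_linear(values, 0.75), "above", pulse_mode, strict)
    out["EL1"] = count_beyond(values, percentile_linear(values, 0.10), "below", pulse_mode, strict)
    out["EH1"] = count_beyond(values, percentile_linear(values, 0.90), "above", pulse_mode, strict)
    out["RC"] = rate_of_change(values, rc_kind)
    out["RH1"] = count_changes(values, "rising")
    out["RL1"] = count_changes(values, "declining")
    return out
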