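"""Agreement and robustness statistics: Bland-Altman, Pearson r, an exact
tie-aware Wilcoxon signed-rank test, covariate bias screens and the
rotational-perturbation report.

Differences are oriented auto - manual throughout: a positive bias means the
automated measurement overestimates. Limits of agreement use bias +/- 1.96
times the sample SD (n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "AgreementStats",
    "WilcoxonResult",
    "bland_altman",
    "pearson_r",
    "wilcoxon_signed_rank",
    "covariate_bias_screen",
    "perturbation_report",
]

_EXACT_LIMIT = 25
_LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementStats:
    n: int
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    mae: float
    pearson_r: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "bias": self.bias,
            "sd": self.sd,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "mae": self.mae,
            "pearson_r": self.pearson_r,
        }


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W = sum of ranks of positive differences
    p_two_sided: float
    n_effective: int
    method: str  # "exact" | "normal_approx"


def _as_finite_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(a)):
        raise InputError(f"{name} contains non-finite values")
    return a


def bland_altman(auto, manual) -> AgreementStats:
    """Bland-Altman agreement of paired measurements (differences auto - manual)."""
    a = _as_finite_array(auto, "auto")
    m = _as_finite_array(manual, "manual")
    if a.shape != m.shape:
        raise InputError(f"length mismatch: {a.size} vs {m.size}")
    if a.size < 2:
        raise InputError("Bland-Altman requires n >= 2 pairs")
    d = a - m
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    try:
        r = pearson_r(a, m)
    except InputError:
        r = float("nan")
    return AgreementStats(
        n=int(a.size),
        bias=bias,
        sd=sd,
        loa_low=bias - _LOA_MULTIPLIER * sd,
        loa_high=bias + _LOA_MULTIPLIER * sd,
        mae=float(np.abs(d).mean()),
        pearson_r=r,
    )


def pearson_r(x, y) -> float:
    """Product-moment correlation; constant input is an error, not a silent 0."""
    a = _as_finite_array(x, "x")
    b = _as_finite_array(y, "y")
    if a.shape != b.shape:
        raise InputError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 3:
        raise InputError("Pearson r requires n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise InputError("Pearson r undefined for constant input")
    return float(stats.pearsonr(a, b).statistic)


def _exact_two_sided_p(ranks2: np.ndarray, w2: int) -> float:
    """Exact two-sided p for the signed-rank sum via subset-sum counting.

    ``ranks2`` are doubled mid-ranks (integers), ``w2`` the doubled observed
    positive-rank sum. Counts are exact in float64 for n <= 25.
    """
    tot = int(ranks2.sum())
    counts = np.zeros(tot + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: tot + 1 - r]
        counts = counts + shifted
    total = counts.sum()
    p_le = counts[: w2 + 1].sum() / total
    p_ge = counts[w2:].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(a, b=None) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired samples (or differences directly).

    Zero differences are dropped; tied magnitudes receive mid-ranks. For
    n_eff <= 25 the two-sided p is exact (full enumeration of sign
    assignments, computed by dynamic programming); beyond that a normal
    approximation with tie correction and 0.5 continuity correction is used.
    """
    x = _as_finite_array(a, "a")
    if b is not None:
        y = _as_finite_array(b, "b")
        if x.shape != y.shape:
            raise InputError(f"length mismatch: {x.size} vs {y.size}")
        d = x - y
    else:
        d = x
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise InputError("all differences are zero; signed-rank test undefined")
    ranks = stats.rankdata(np.abs(d))  # mid-ranks; values are multiples of 0.5
    w = float(ranks[d > 0].sum())
    if n <= _EXACT_LIMIT:
        ranks2 = np.rint(2 * ranks).astype(int)
        p = _exact_two_sided_p(ranks2, int(round(2 * w)))
        return WilcoxonResult(w, p, n, "exact")
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts) / 48.0).sum())
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        raise InputError("degenerate variance in normal approximation")
    cc = 0.5 * np.sign(w - mean)
    z = (w - mean - cc) / np.sqrt(var)
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return WilcoxonResult(w, p, n, "normal_approx")


def covariate_bias_screen(abs_err, covariates: pd.DataFrame) -> pd.DataFrame:
    """Screen absolute errors against covariates.

    Continuous columns: Pearson r with its t-based two-sided p. Binary
    columns (exactly two distinct values): Welch two-sample t-test on the
    absolute errors. Returns one row per covariate with stat, p and n.
    """
    err = _as_finite_array(abs_err, "abs_err")
    if len(covariates) != err.size:
        raise InputError("covariate table length does not match abs_err")
    rows = []
    for col in covariates.columns:
        vals = np.asarray(covariates[col])
        uniq = pd.unique(vals)
        if len(uniq) < 2:
            raise InputError(f"covariate {col!r} is constant")
        if len(uniq) == 2:
            g1 = err[vals == uniq[0]]
            g2 = err[vals == uniq[1]]
            if len(g1) < 3 or len(g2) < 3:
                raise InputError(f"covariate {col!r}: each group needs n >= 3")
            if np.ptp(g1) == 0 and np.ptp(g2) == 0 and g1[0] == g2[0]:
                t, p = 0.0, 1.0
            else:
                res = stats.ttest_ind(g1, g2, equal_var=False)
                t, p = float(res.statistic), float(res.pvalue)
                if np.isnan(t):
                    t, p = 0.0, 1.0
            rows.append({"covariate": col, "kind": "binary", "stat": t, "p": p, "n": err.size})
        else:
            x = vals.astype(float)
            if err.size < 3:
                raise InputError("continuous screen requires n >= 3")
            r = pearson_r(x, err)
            res = stats.pearsonr(x, err)
            rows.append(
                {"covariate": col, "kind": "continuous", "stat": r, "p": float(res.pvalue), "n": err.size}
            )
    return pd.DataFrame(rows)


def perturbation_report(
    baseline_ei,
    perturbed: Mapping[tuple[str, float], Sequence[float]],
    comparator: Mapping[tuple[str, float], Sequence[float]] | None = None,
) -> pd.DataFrame:
    """Summarize rotational-perturbation errors per (axis, angle).

    ``perturbed`` maps (axis, angle_deg) to per-case EI values aligned with
    ``baseline_ei``. For each cell the report gives the median and IQR of
    |EI_perturbed - EI_baseline| and, when a ``comparator`` cell is present
    (typically corrected-mode EIs for the same rotation), a Wilcoxon
    signed-rank test of the perturbed absolute errors against the comparator
    residuals — the synthetic stand-in for a neutral-orientation error
    distribution, which for a deterministic pipeline is identically zero.

    The returned frame carries ``attrs["monotone"]``: per axis, whether the
    median absolute error (pooled over +/- at each magnitude) is
    non-decreasing in |angle|.
    """
    base = _as_finite_array(baseline_ei, "baseline_ei")
    rows = []
    pooled: dict[str, dict[float, list[np.ndarray]]] = {}
    for (axis, angle), eis in sorted(perturbed.items()):
        e = _as_finite_array(eis, f"perturbed[{axis},{angle}]")
        if e.shape != base.shape:
            raise InputError(f"cell ({axis}, {angle}) length mismatch with baseline")
        abs_err = np.abs(e - base)
        q25, q75 = np.percentile(abs_err, [25, 75])
        w = p = float("nan")
        if comparator is not None and (axis, angle) in comparator:
            resid = np.abs(_as_finite_array(comparator[(axis, angle)], "comparator") - base)
            diffs = abs_err - resid
            if np.any(diffs != 0):
                res = wilcoxon_signed_rank(abs_err, resid)
                w, p = res.statistic, res.p_two_sided
        rows.append(
            {
                "axis": axis,
                "angle_deg": float(angle),
                "median_abs_err": float(np.median(abs_err)),
                "iqr": float(q75 - q25),
                "W": w,
                "p": p,
            }
        )
        pooled.setdefault(axis, {}).setdefault(abs(float(angle)), []).append(abs_err)
    if comparator is not None:
        missing = set(comparator) - set(perturbed)
        if missing:
            raise InputError(f"comparator has cells absent from perturbed: {sorted(missing)}")
    report = pd.DataFrame(rows)
    monotone = {}
    for axis, by_mag in pooled.items():
        mags = sorted(by_mag)
        medians = [float(np.median(np.concatenate(by_mag[m]))) for m in mags]
        monotone[axis] = all(b >= a - 1e-12 for a, b in zip(medians, medians[1:]))
    report.attrs["monotone"] = monotone
    return report
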