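"""Paired-modality agreement statistics.

Sign convention: all normalized differences are
``d = 100 * (PET - SPECT) / SPECT`` (percent, relative to SPECT), so a
positive median means PET reads higher. Nonparametric Bland-Altman limits of
agreement are the empirical 2.5th and 97.5th percentiles of the differences,
computed by linear interpolation between order statistics at
``h = (n - 1) * p + 1``. Medians of even-length samples are the mean of the
two central order statistics. Rank tests use exact null enumeration at small
n without ties and a tie/continuity-corrected normal approximation otherwise;
zero differences are dropped before ranking (classical convention). No
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError

__all__ = [
    "RegressionResult",
    "BlandAltmanResult",
    "least_squares_fit",
    "percentile",
    "bland_altman_median",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "normality_gate",
    "size_stratified_summary",
    "site_background_summary",
    "WILCOXON_EXACT_MAX_N",
    "MANNWHITNEY_EXACT_MAX_N",
]

WILCOXON_EXACT_MAX_N = 25
MANNWHITNEY_EXACT_MAX_N = 20


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass
class BlandAltmanResult:
    median_diff_pct: float
    loa_low_pct: float
    loa_high_pct: float
    n: int
    normalization: str
    differences: np.ndarray = field(repr=False)
    means: np.ndarray = field(repr=False)


def least_squares_fit(x, y) -> RegressionResult:
    """Ordinary least-squares line with coefficient of determination.

    R^2 = 1 - SS_res / SS_tot; if y is constant (SS_tot = 0) R^2 is defined
    as 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise DegenerateInputError("x values are constant; regression undefined")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return RegressionResult(slope, intercept, float(r2), n)


def percentile(values, p: float) -> float:
    """Empirical percentile by linear interpolation at h = (n-1)p + 1."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("empty sample")
    h = (n - 1) * (p / 100.0)
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))


def bland_altman_median(spect_vals, pet_vals, normalize: str = "spect") -> BlandAltmanResult:
    """Nonparametric Bland-Altman summary of paired values.

    Differences are ``100 * (PET - SPECT) / SPECT`` when ``normalize="spect"``
    (the default) or raw ``PET - SPECT`` when ``normalize="none"``. Limits of
    agreement are the 2.5th/97.5th empirical percentiles.
    """
    spect = np.asarray(spect_vals, dtype=float)
    pet = np.asarray(pet_vals, dtype=float)
    if spect.shape != pet.shape or spect.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    if spect.size < 3:
        raise ValueError("need at least 3 pairs")
    if normalize == "spect":
        if np.any(spect <= 0):
            raise ValueError("all SPECT values must be positive when normalizing")
        d = 100.0 * (pet - spect) / spect
        label = "relative to SPECT"
    elif normalize == "none":
        d = pet - spect
        label = "absolute"
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    return BlandAltmanResult(
        median_diff_pct=percentile(d, 50.0),
        loa_low_pct=percentile(d, 2.5),
        loa_high_pct=percentile(d, 97.5),
        n=spect.size,
        normalization=label,
        differences=d,
        means=(spect + pet) / 2.0,
    )


def _signed_ranks(d: np.ndarray) -> np.ndarray:
    return stats.rankdata(np.abs(d))


def _exact_wplus_pmf(ranks: np.ndarray) -> np.ndarray:
    """Null distribution of W+ over all sign assignments (integer ranks)."""
    max_w = int(ranks.sum())
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: max_w + 1 - r]
        counts = counts + shifted
    return counts / counts.sum()


def wilcoxon_signed_rank(differences, exact_max_n: int = WILCOXON_EXACT_MAX_N):
    """Wilcoxon signed-rank test of paired differences against zero.

    Zero differences are dropped. Exact enumeration of the W+ null
    distribution for n <= ``exact_max_n`` with untied |d|; normal
    approximation with tie and continuity correction otherwise.

    Returns ``(w_plus, p_two_sided, method)``.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks = _signed_ranks(d)
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n
    if n <= exact_max_n and not has_ties:
        pmf = _exact_wplus_pmf(ranks)
        w = int(round(w_plus))
        cdf = float(pmf[: w + 1].sum())
        sf = float(pmf[w:].sum())
        p = min(1.0, 2.0 * min(cdf, sf))
        return w_plus, p, "exact"
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        raise DegenerateInputError("degenerate rank variance")
    dev = w_plus - mu
    z = (dev - 0.5 * np.sign(dev)) / np.sqrt(sigma2)  # continuity correction
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return w_plus, float(p), "normal"


def _exact_u_pmf(m: int, n: int) -> np.ndarray:
    """Null distribution of U (untied) for group sizes m, n.

    Counts label sequences over the sorted combined sample: placing an "a" at
    a position adds the number of "b"s already placed (the a > b pairs it
    creates) to U. All C(m+n, m) labelings are equally likely under the null.
    """
    dp = np.zeros((m + 1, m * n + 1))
    dp[0, 0] = 1.0
    for pos in range(m + n):
        new = np.zeros_like(dp)
        for k in range(min(pos, m) + 1):
            b_used = pos - k
            if b_used > n:
                continue
            row = dp[k]
            nz = row.nonzero()[0]
            if nz.size == 0:
                continue
            if b_used < n:  # next label is b
                new[k, nz] += row[nz]
            if k < m:  # next label is a, gaining one inversion per placed b
                new[k + 1, nz + b_used] += row[nz]
        dp = new
    pmf = dp[m]
    return pmf / pmf.sum()


def mann_whitney_u(
    group_a,
    group_b,
    alternative: str = "two-sided",
    exact_max_n: int = MANNWHITNEY_EXACT_MAX_N,
):
    """Mann-Whitney U test; U counts pairs with a > b (ties count 1/2).

    Exact enumeration for combined n <= ``exact_max_n`` without ties, normal
    approximation with tie correction otherwise. ``alternative`` is
    ``"two-sided"`` or ``"greater"`` (group_a stochastically larger).

    Returns ``(u, p, method)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    m, n = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    ra = ranks[:m].sum()
    u = float(ra - m * (m + 1) / 2.0)
    has_ties = np.unique(combined).size < m + n
    if m + n <= exact_max_n and not has_ties:
        pmf = _exact_u_pmf(m, n)
        ui = int(round(u))
        sf = float(pmf[ui:].sum())
        cdf = float(pmf[: ui + 1].sum())
        if alternative == "greater":
            p = sf
        else:
            p = min(1.0, 2.0 * min(cdf, sf))
        return u, float(p), "exact"
    mu = m * n / 2.0
    big_n = m + n
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (big_n * (big_n - 1))
    sigma2 = m * n / 12.0 * ((big_n + 1) - tie_term)
    if sigma2 <= 0:
        raise DegenerateInputError("degenerate rank variance (all values tied)")
    dev = u - mu
    z = (dev - 0.5 * np.sign(dev)) / np.sqrt(sigma2)
    if alternative == "greater":
        p = float(stats.norm.sf(z))
    else:
        p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return u, float(p), "normal"


def normality_gate(values, alpha: float = 0.05):
    """Shapiro-Wilk normality check gating parametric vs median summaries.

    Returns ``(is_normal, p)`` with ``is_normal = (p > alpha)``. Delegates the
    W computation to scipy's published-algorithm implementation.
    """
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ValueError("zero-variance sample: W undefined")
    w, p = stats.shapiro(v)
    return bool(p > alpha), float(p)


def _median_iqr(v: np.ndarray) -> tuple[float, float, float]:
    return percentile(v, 50.0), percentile(v, 25.0), percentile(v, 75.0)


def size_stratified_summary(
    records: pd.DataFrame,
    measures=("suv_max", "suv_peak", "suv_mean"),
    n_strata: int = 4,
    volume_col: str = "volume_cm3",
) -> pd.DataFrame:
    """Median (IQR) normalized PET-vs-SPECT differences per volume stratum.

    ``records`` is a wide per-lesion frame with ``volume_col`` and, per
    measure, ``<measure>_spect`` / ``<measure>_pet`` columns. Strata are
    equal-count bins of the volume order (quartiles by default; with n not
    divisible by n_strata the earlier bins hold the extra records).
    """
    if len(records) < n_strata:
        raise ValueError(f"need at least {n_strata} records for {n_strata} strata")
    order = records.sort_values(volume_col, kind="mergesort").index.to_numpy()
    strata = np.array_split(order, n_strata)
    rows = []
    for i, idx in enumerate(strata):
        sub = records.loc[idx]
        row: dict = {
            "stratum": i + 1,
            "n": len(sub),
            "volume_min_cm3": float(sub[volume_col].min()),
            "volume_max_cm3": float(sub[volume_col].max()),
        }
        for meas in measures:
            spect = sub[f"{meas}_spect"].to_numpy(dtype=float)
            pet = sub[f"{meas}_pet"].to_numpy(dtype=float)
            d = 100.0 * (pet - spect) / spect
            med, q1, q3 = _median_iqr(d)
            row[f"{meas}_median_pct"] = med
            row[f"{meas}_q1_pct"] = q1
            row[f"{meas}_q3_pct"] = q3
        rows.append(row)
    return pd.DataFrame(rows)


def site_background_summary(
    records: pd.DataFrame,
    sites=("skull", "spine", "rib_cage", "pelvis", "limbs"),
    spect_col: str = "suv_mean_bg_spect",
    pet_col: str = "suv_mean_bg_pet",
    site_col: str = "site",
) -> pd.DataFrame:
    """Per-site median (IQR) background SUVs per modality plus the Wilcoxon
    signed-rank p-value of the paired PET-SPECT difference."""
    unknown = set(records[site_col]) - set(sites)
    if unknown:
        raise ValueError(f"unknown site labels: {sorted(unknown)}")
    rows = []
    for site in sites:
        sub = records[records[site_col] == site]
        if sub.empty:
            continue
        spect = sub[spect_col].to_numpy(dtype=float)
        pet = sub[pet_col].to_numpy(dtype=float)
        d = pet - spect
        med_s, q1_s, q3_s = _median_iqr(spect)
        med_p, q1_p, q3_p = _median_iqr(pet)
        med_d, q1_d, q3_d = _median_iqr(d)
        if np.any(d != 0):
            _, p, _ = wilcoxon_signed_rank(d)
        else:
            p = float("nan")
        rows.append(
            {
                "site": site,
                "n": len(sub),
                "pet_median": med_p, "pet_q1": q1_p, "pet_q3": q3_p,
                "spect_median": med_s, "spect_q1": q1_s, "spect_q3": q3_s,
                "diff_median": med_d, "diff_q1": q1_d, "diff_q3": q3_d,
                "wilcoxon_p": p,
            }
        )
    return pd.DataFrame(rows)
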