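"""Group statistics: Monte-Carlo permutation t-test, BH-FDR, baseline
contrast, and scaled-MAD outlier replacement.

The permutation test compares two independent groups feature-by-feature by
randomly reassigning group labels (5000 Monte-Carlo draws by default, with
automatic exhaustive enumeration for small groups) and referring the observed
two-sample t statistic to the permutation distribution of |t|.  Multiple
features are corrected with the Benjamini–Hochberg step-up rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "FDRResult",
    "permutation_ttest",
    "fdr_bh",
    "baseline_ttest",
    "replace_outliers",
]

MAD_SCALE = 1.4826  # normal-consistency constant


@dataclass
class PermutationResult:
    observed_t: np.ndarray
    p_values: np.ndarray
    n_permutations: int
    seed: int | None
    exhaustive: bool


@dataclass
class FDRResult:
    q: float
    rejected: np.ndarray
    adjusted_p: np.ndarray


def _tstat(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per feature; ±inf for zero-variance
    separation, 0 for fully degenerate features.

    ``a`` and ``b`` may carry leading batch axes; samples are axis −2,
    features axis −1.
    """
    na, nb = a.shape[-2], b.shape[-2]
    diff = a.mean(axis=-2) - b.mean(axis=-2)
    ssq = a.var(axis=-2, ddof=1) * (na - 1) + b.var(axis=-2, ddof=1) * (nb - 1)
    se = np.sqrt(ssq / (na + nb - 2) * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t = np.where((se == 0) & (diff != 0), np.sign(diff) * np.inf, t)
    return np.where((se == 0) & (diff == 0), 0.0, t)


def permutation_ttest(
    group_a,
    group_b,
    n_permutations: int = 5000,
    seed: int | None = None,
) -> PermutationResult:
    """Label-permutation two-sample t-test (two-sided) per feature.

    Uses exhaustive enumeration of all label arrangements when their number
    does not exceed ``n_permutations`` (p = count/total); otherwise Monte
    Carlo with the add-one correction p = (1 + #{|t*| >= |t|}) / (1 + n).
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(group_b, dtype=np.float64))
    if a.ndim == 2 and a.shape[0] == 1 and a.shape[1] > 1 and np.ndim(group_a) == 1:
        a, b = a.T, b.T
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 samples")
    na, nb = a.shape[0], b.shape[0]
    pooled = np.vstack([a, b])
    t_obs = _tstat(a, b)

    degenerate = (pooled.std(axis=0) == 0)
    if degenerate.any():
        warnings.warn("zero-variance feature(s): p set to 1", RuntimeWarning, stacklevel=2)

    n_total = math.comb(na + nb, na)
    exhaustive = n_total <= n_permutations
    if exhaustive:
        idx_a = np.array(list(combinations(range(na + nb), na)))  # (n_total, na)
        mask = np.zeros((n_total, na + nb), dtype=bool)
        np.put_along_axis(mask, idx_a, True, axis=1)
        idx_b = np.nonzero(~mask)[1].reshape(n_total, nb)
        n_used = n_total
    else:
        rng = np.random.default_rng(seed)
        order = rng.permuted(
            np.tile(np.arange(na + nb), (n_permutations, 1)), axis=1
        )
        idx_a, idx_b = order[:, :na], order[:, na:]
        n_used = n_permutations
    # batch in chunks to bound memory for large feature counts
    count = np.zeros(a.shape[1])
    chunk = max(1, int(2e7 // (pooled.size or 1)))
    for s in range(0, idx_a.shape[0], chunk):
        t_perm = _tstat(pooled[idx_a[s : s + chunk]], pooled[idx_b[s : s + chunk]])
        count += (np.abs(t_perm) >= np.abs(t_obs)).sum(axis=0)
    if exhaustive:
        p = count / n_total
    else:
        p = (1.0 + count) / (1.0 + n_permutations)
    p = np.where(degenerate, 1.0, p)
    return PermutationResult(
        observed_t=t_obs, p_values=p, n_permutations=n_used, seed=seed, exhaustive=exhaustive
    )


def fdr_bh(p_values, q: float = 0.05) -> FDRResult:
    """Benjamini–Hochberg step-up FDR control at level ``q``."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    rejected, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return FDRResult(q=q, rejected=rejected, adjusted_p=adjusted)


def baseline_ttest(post_values, baseline_values) -> tuple[float, float]:
    """Paired one-tailed t-test of post-stimulus > baseline.

    Returns (t, p).  A constant positive shift (zero-variance difference)
    gives t = +inf and p at the numeric floor; a constant zero difference
    gives t = 0, p = 0.5.
    """
    post = np.asarray(post_values, dtype=np.float64)
    base = np.asarray(baseline_values, dtype=np.float64)
    if post.shape != base.shape or post.size < 2:
        raise ValueError("need >= 2 paired samples")
    d = post - base
    if d.std(ddof=1) == 0:
        if d[0] > 0:
            return math.inf, float(np.finfo(float).tiny)
        if d[0] < 0:
            return -math.inf, 1.0
        return 0.0, 0.5
    res = spstats.ttest_rel(post, base, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def replace_outliers(series) -> tuple[np.ndarray, np.ndarray]:
    """Flag values beyond 3 scaled MADs and repair them by interpolation.

    Scaled MAD = 1.4826 × median(|x − median(x)|).  Flagged interior values
    are linearly interpolated between the nearest unflagged neighbours;
    flagged edge values take the nearest unflagged value.  Returns
    (cleaned series, boolean outlier mask).
    """
    x = np.asarray(series, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    med = np.median(x)
    mad = MAD_SCALE * np.median(np.abs(x - med))
    mask = np.abs(x - med) > 3.0 * mad
    if mask.all():
        raise ValueError("all samples flagged as outliers")
    cleaned = x.copy()
    if mask.any():
        idx = np.arange(x.size)
        cleaned[mask] = np.interp(idx[mask], idx[~mask], x[~mask])
    return cleaned, mask
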