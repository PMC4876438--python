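"""Group inference: label-permutation tests with FDR control, rank
correlations, and demographic comparisons.

The group-difference statistic is the difference of group means
(amusic - control by convention of the callers).  Two-tailed
permutation p-values use the add-one estimator
p = (1 + #{|perm| >= |obs|}) / (n_perm + 1), so p is never zero and has
resolution 1/(n_perm + 1).  Nodal tests form an N-node family corrected
with Benjamini-Hochberg FDR; the four global metrics are tested
individually without the nodal family correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from wmnet._seeds import derive_seed

__all__ = [
    "GroupComparisonResult",
    "CorrelationResult",
    "permutation_test",
    "nodal_family_test",
    "spearman",
    "partial_spearman",
    "demographic_tests",
]


@dataclass(frozen=True)
class GroupComparisonResult:
    metric: str
    observed_diff: float
    p_value: float
    n_permutations: int
    family: str = "global"
    fdr_significant: bool | None = None


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    rho: float
    p_value: float
    n: int
    controlled_for: str | None = None


def _perm_index_matrix(n: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    # each row is an independent uniform permutation of range(n)
    return np.argsort(rng.random((n_perm, n)), axis=1)


def permutation_test(values_a, values_b, n_perm: int = 10000, rng_seed=0,
                     metric: str = "metric", family: str = "global") -> GroupComparisonResult:
    """Two-tailed label-permutation test of the difference in means.

    ``values_a`` minus ``values_b`` is the observed statistic; labels
    are shuffled ``n_perm`` times (default 10,000).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(rng_seed)
    pooled = np.concatenate([a, b])
    na = a.size
    obs = a.mean() - b.mean()
    idx = _perm_index_matrix(pooled.size, n_perm, rng)
    shuffled = pooled[idx]
    stat = shuffled[:, :na].mean(axis=1) - shuffled[:, na:].mean(axis=1)
    p = (1 + int(np.sum(np.abs(stat) >= np.abs(obs) - 1e-12))) / (n_perm + 1)
    return GroupComparisonResult(metric=metric, observed_diff=float(obs),
                                 p_value=float(p), n_permutations=n_perm,
                                 family=family)


def nodal_family_test(values_a: np.ndarray, values_b: np.ndarray,
                      alpha: float = 0.05, n_perm: int = 10000, rng_seed=0,
                      labels=None, chunk: int = 1000) -> pd.DataFrame:
    """Per-node permutation tests with Benjamini-Hochberg FDR flags.

    ``values_a`` and ``values_b`` are (subjects x nodes) arrays of one
    AUC per subject per node.  A single sequence of label permutations
    is shared across nodes, preserving the cross-node dependence of
    the statistics.  Returns a frame with columns node, observed_diff,
    p_value, fdr_significant.
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("group arrays differ in node count")
    na, n_nodes = a.shape
    pooled = np.vstack([a, b])
    n = pooled.shape[0]
    obs = a.mean(axis=0) - b.mean(axis=0)
    rng = np.random.default_rng(rng_seed)
    exceed = np.zeros(n_nodes, dtype=int)
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        idx = _perm_index_matrix(n, size, rng)
        ga = pooled[idx[:, :na]].mean(axis=1)  # (size, n_nodes)
        gb = pooled[idx[:, na:]].mean(axis=1)
        exceed += np.sum(np.abs(ga - gb) >= np.abs(obs)[None, :] - 1e-12, axis=0)
        done += size
    p = (1 + exceed) / (n_perm + 1)
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    if labels is None:
        labels = [str(i + 1) for i in range(n_nodes)]
    return pd.DataFrame({
        "node": list(labels),
        "observed_diff": obs,
        "p_value": p,
        "fdr_significant": reject,
    })


def spearman(x, y, pair: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(pair=pair, rho=float(rho), p_value=float(p), n=x.size)


def partial_spearman(x, y, z, pair: tuple[str, str] = ("x", "y"),
                     controlled_for: str = "z") -> CorrelationResult:
    """Rank-based partial correlation of x and y controlling z.

    All three variables are rank-transformed (average ranks), x and y
    are residualized on z by least squares, and the residuals are
    correlated; the p-value uses the t reference with n - 3 degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = x.size
    if not (y.size == n == z.size) or n < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    if np.ptp(z) == 0:
        raise ValueError("control variable has zero variance")
    rx, ry, rz = (sps.rankdata(v) for v in (x, y, z))
    design = np.column_stack([np.ones(n), rz])
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    denom = np.sqrt(np.sum(res_x**2) * np.sum(res_y**2))
    if denom < 1e-12 * n:
        # x or y fully explained by z: nothing left to correlate
        return CorrelationResult(pair=pair, rho=0.0, p_value=1.0, n=n,
                                 controlled_for=controlled_for)
    r = float(np.sum(res_x * res_y) / denom)
    df = n - 3
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    tstat = r_clip * np.sqrt(df / (1 - r_clip**2))
    p = float(2 * sps.t.sf(abs(tstat), df))
    return CorrelationResult(pair=pair, rho=r, p_value=p, n=n,
                             controlled_for=controlled_for)


def demographic_tests(pheno: pd.DataFrame, group_col: str = "group",
                      case_label: str = "amusic") -> pd.DataFrame:
    """Standard demographic/behavioural comparisons between the groups.

    Independent-samples t tests for age, IQ and brain size; Pearson
    chi-square for the sex ratio; Mann-Whitney U for the MBEA and
    lexical-tone scores (which are bounded and typically non-normal).
    """
    groups = sorted(pheno[group_col].unique())
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    case = pheno[pheno[group_col] == case_label]
    ctrl = pheno[pheno[group_col] != case_label]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("each group needs at least two subjects")
    rows = []
    for col in ("age", "iq", "brain_size"):
        t, p = sps.ttest_ind(case[col], ctrl[col])
        rows.append((col, "t_test", float(t), float(p)))
    table = pd.crosstab(pheno[group_col], pheno["sex"])
    chi2, p, _, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
    rows.append(("sex", "chi_square", float(chi2), float(p)))
    for col in ("mbea", "tone"):
        u, p = sps.mannwhitneyu(case[col], ctrl[col], alternative="two-sided")
        rows.append((col, "mann_whitney", float(u), float(p)))
    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "p_value"])
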