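"""Alpha diversity, Bray-Curtis beta diversity, PCoA and permutation tests.

The three dissimilarity tests (ANOSIM, one-factor PERMANOVA / adonis,
MRPP) are implemented directly from their distance-matrix definitions so
permutation seeding and p-value conventions are fully under our control:
p = (1 + #{permuted statistic at least as extreme}) / (n_perm + 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import AnalysisError
from .table_io import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with sample ids."""

    data: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = self.data.shape[0]
        if self.data.shape != (n, n):
            raise AnalysisError("distance matrix must be square")
        if len(self.ids) != n:
            raise AnalysisError("id count does not match matrix size")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise AnalysisError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.data)) > 1e-12):
            raise AnalysisError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    n_permutations: int = 0
    seed: int | None = None
    extra: dict | None = None


@dataclass
class Ordination:
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray
    ids: list[str]


# ---------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------

def alpha_diversity(table: FeatureTable) -> pd.DataFrame:
    """Per-sample Chao1 (bias-corrected), Shannon (nats) and Simpson dominance.

    chao1 = S_obs + F1 (F1 - 1) / (2 (F2 + 1)); shannon = -sum p ln p;
    dominance = sum p^2. All-zero samples yield NaN in every column.
    """
    records = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        total = col.sum()
        if total == 0:
            logger.warning("sample %s has no reads; diversity undefined", sid)
            records.append((np.nan, np.nan, np.nan))
            continue
        present = col[col > 0]
        s_obs = present.size
        f1 = int((present == 1).sum())
        f2 = int((present == 2).sum())
        chao1 = s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
        p = present / total
        shannon = float(-(p * np.log(p)).sum())
        dominance = float((p**2).sum())
        records.append((chao1, shannon, dominance))
    return pd.DataFrame(
        records, index=table.sample_ids, columns=["chao1", "shannon", "dominance"]
    )


# ---------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------

def bray_curtis_matrix(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, d = sum|x-y| / sum(x+y)."""
    if table.n_samples < 2:
        raise AnalysisError("need at least two samples")
    x = table.counts.T.astype(float)
    zero = x.sum(axis=1) == 0
    if zero.sum() >= 2:
        raise AnalysisError(
            "Bray-Curtis undefined between all-zero samples: "
            + ", ".join(np.asarray(table.sample_ids)[zero][:2])
        )
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, list(table.sample_ids))


def pcoa(dist: DistanceMatrix, k: int = 2) -> Ordination:
    """Classical principal-coordinate analysis (Gower double centering).

    Negative eigenvalues are dropped from both the axes and the
    variance-explained denominator; requesting more axes than positive
    eigenvalues truncates with a warning.
    """
    d2 = dist.data**2
    n = dist.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0]) if eigvals.size else 0)
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating from {k} axes",
            stacklevel=2,
        )
        k = n_pos
    lam = eigvals[:n_pos]
    coords = eigvecs[:, :k] * np.sqrt(lam[:k])
    return Ordination(coords, lam, lam / lam.sum(), list(dist.ids))


# ---------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------

def _check_groups(labels: np.ndarray) -> list[np.ndarray]:
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise AnalysisError("need at least two groups")
    groups = [np.flatnonzero(labels == g) for g in uniq]
    for g, idx in zip(uniq, groups):
        if idx.size < 2:
            raise AnalysisError(f"group {g!r} has fewer than two samples")
    return groups


def _within_mask(labels: np.ndarray) -> np.ndarray:
    """Condensed-form boolean mask of within-group pairs."""
    n = labels.size
    iu, ju = np.triu_indices(n, k=1)
    return labels[iu] == labels[ju]


def _anosim_stat(ranks: np.ndarray, labels: np.ndarray) -> float:
    within = _within_mask(labels)
    m = ranks.size
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return (rb - rw) / (m / 2.0)


def _adonis_stat(d2: np.ndarray, labels: np.ndarray) -> float:
    n = labels.size
    ss_total = d2.sum() / (2 * n)  # full square matrix sum
    ss_within = 0.0
    uniq = np.unique(labels)
    for g in uniq:
        idx = labels == g
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * idx.sum())
    a = uniq.size
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def _mrpp_stat(d: np.ndarray, labels: np.ndarray) -> float:
    n = labels.size
    delta = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d[np.ix_(idx, idx)]
        m = idx.size
        delta += (m / n) * (sub.sum() / (m * (m - 1)))
    return delta


def dissimilarity_test(
    dist: DistanceMatrix,
    labels,
    method: str = "anosim",
    n_perm: int = 999,
    seed: int | None = None,
) -> TestResult:
    """Permutation test of group separation on a distance matrix.

    method 'anosim': rank-based R in [-1, 1]; 'adonis': one-factor
    PERMANOVA pseudo-F; 'mrpp': weighted mean within-group distance
    (delta, smaller = tighter) with chance-corrected A reported in
    ``extra``.
    """
    labels = np.asarray(labels)
    if labels.size != dist.n:
        raise AnalysisError("labels length does not match distance matrix")
    _check_groups(labels)
    rng = np.random.default_rng(seed)
    if method == "anosim":
        ranks = stats.rankdata(dist.condensed())
        stat_fn = lambda lab: _anosim_stat(ranks, lab)  # noqa: E731
        larger_extreme = True
    elif method == "adonis":
        d2 = dist.data**2
        stat_fn = lambda lab: _adonis_stat(d2, lab)  # noqa: E731
        larger_extreme = True
    elif method == "mrpp":
        stat_fn = lambda lab: _mrpp_stat(dist.data, lab)  # noqa: E731
        larger_extreme = False  # small delta = strong grouping
    else:
        raise AnalysisError(f"unknown method {method!r}")
    observed = stat_fn(labels)
    perm_stats = np.empty(n_perm)
    for i in range(n_perm):
        perm_stats[i] = stat_fn(rng.permutation(labels))
    if larger_extreme:
        hits = int((perm_stats >= observed - 1e-12).sum())
    else:
        hits = int((perm_stats <= observed + 1e-12).sum())
    p = (1 + hits) / (n_perm + 1)
    extra: dict = {}
    if method == "mrpp":
        expected = perm_stats.mean()
        extra["A"] = 1.0 - observed / expected if expected > 0 else np.nan
        extra["expected_delta"] = expected
    return TestResult(method, float(observed), float(p), n_perm, seed, extra or None)


# ---------------------------------------------------------------------
# two-group comparison rule
# ---------------------------------------------------------------------

def compare_groups(values_a, values_c, alpha: float = 0.05) -> TestResult:
    """Shapiro-gated two-group comparison.

    If both groups pass Shapiro-Wilk normality (p > alpha) and Levene's
    test finds comparable variances, a two-sample t-test is used;
    otherwise the two-sided Wilcoxon rank-sum test. The branch taken is
    recorded in ``extra['branch']``.
    """
    a = np.asarray(values_a, dtype=float)
    c = np.asarray(values_c, dtype=float)
    if a.size < 3 or c.size < 3:
        raise AnalysisError("each group needs at least three values")
    branch = "wilcoxon"
    normal = False
    if np.ptp(a) > 0 and np.ptp(c) > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw_a = stats.shapiro(a).pvalue
            sw_c = stats.shapiro(c).pvalue
        normal = sw_a > alpha and sw_c > alpha
        if normal:
            equal_var = stats.levene(a, c).pvalue > alpha
            res = stats.ttest_ind(a, c, equal_var=equal_var)
            branch = "t-test" if equal_var else "welch-t"
            return TestResult(
                "compare_groups", float(res.statistic), float(res.pvalue),
                extra={"branch": branch},
            )
    else:
        logger.warning("constant input; normality undefined, using Wilcoxon")
    res = stats.ranksums(a, c)
    return TestResult(
        "compare_groups", float(res.statistic), float(res.pvalue),
        extra={"branch": branch},
    )
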