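"""Correlation matrices and the random-matrix-theory network threshold.

The cutoff for turning a Pearson correlation matrix into a co-occurrence
network is chosen where the nearest-neighbour spacing distribution (NNSD)
of the thresholded matrix's unfolded eigenvalues transitions from
Wigner-Dyson (GOE, level repulsion) to Poisson (independent levels)
statistics. Conformity to Poisson is judged by a chi-squared
goodness-of-fit against the Exp(1) spacing law using equal-probability
bins; the smallest scanned threshold that conforms, and stays conforming
at every larger threshold still rich enough in eigenvalues to test, is
chosen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .errors import AnalysisError

logger = logging.getLogger(__name__)

DEFAULT_MIN_EIGS = 100


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise AnalysisError("correlation matrix must be square")
        if len(self.ids) != n:
            raise AnalysisError("id count does not match matrix size")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise AnalysisError("correlation matrix must be symmetric")
        if np.any(np.abs(self.values) > 1 + 1e-10):
            raise AnalysisError("correlations must lie in [-1, 1]")
        np.fill_diagonal(self.values, 1.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class NNSDResult:
    spacings: np.ndarray
    chi2: float
    p_value: float
    n_bins: int


@dataclass
class ScanRecord:
    threshold: float
    n_edges: int
    n_eigenvalues: int
    chi2: float | None
    p_value: float | None
    conforming: bool
    enough_eigenvalues: bool


@dataclass
class ThresholdScan:
    records: list[ScanRecord] = field(default_factory=list)
    chosen_threshold: float | None = None


def pearson_matrix(log_abund) -> CorrelationMatrix:
    """All-pairs Pearson r of an ASV x sample abundance frame.

    Rows must have positive variance (filter upstream); diagonal is set
    to exactly 1.
    """
    values = np.asarray(log_abund, dtype=float)
    ids = [str(i) for i in getattr(log_abund, "index", range(values.shape[0]))]
    if values.shape[1] < 4:
        raise AnalysisError("need at least four samples for Pearson correlation")
    sd = values.std(axis=1)
    if np.any(sd == 0):
        bad = ids[int(np.argmax(sd == 0))]
        raise AnalysisError(f"zero-variance ASV {bad!r}; apply prevalence filter first")
    corr = np.corrcoef(values)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(corr, ids)


# ---------------------------------------------------------------------
# NNSD machinery
# ---------------------------------------------------------------------

def _unique_eigenvalues(eigenvalues: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Sorted eigenvalues with degeneracies collapsed.

    Thresholded correlation matrices carry large degenerate clusters
    (e.g. isolated rows all contribute eigenvalue 1); degenerate levels
    produce an artificial spike of zero spacings and are removed before
    unfolding, as in standard RMT practice.
    """
    ev = np.sort(np.asarray(eigenvalues, dtype=float))
    if ev.size == 0:
        return ev
    keep = np.concatenate(([True], np.diff(ev) > tol))
    return ev[keep]


def unfold(eigenvalues: np.ndarray, degree: int = 5) -> np.ndarray:
    """Map eigenvalues to unit mean spacing via a smooth staircase fit.

    A low-order polynomial is fitted to the empirical cumulative level
    count and each eigenvalue is replaced by its fitted rank.
    """
    ev = np.sort(np.asarray(eigenvalues, dtype=float))
    n = ev.size
    ranks = np.arange(1, n + 1) - 0.5
    deg = min(degree, n - 1)
    coeffs = np.polynomial.polynomial.polyfit(ev, ranks, deg)
    unfolded = np.polynomial.polynomial.polyval(ev, coeffs)
    return np.sort(unfolded)


def nnsd(
    eigenvalues,
    n_bins: int | None = None,
    min_eigs: int = DEFAULT_MIN_EIGS,
) -> NNSDResult:
    """Nearest-neighbour spacings of unfolded eigenvalues vs Poisson.

    Spacings are rescaled to unit mean and tested against the Exp(1)
    law P(d) = e^{-d} with a chi-squared GOF on equal-probability bins
    (sqrt(n) bins by default). A large p-value means the spectrum is
    consistent with Poisson statistics.
    """
    ev = _unique_eigenvalues(eigenvalues)
    if ev.size < min_eigs:
        raise AnalysisError(
            f"only {ev.size} distinct eigenvalues (< {min_eigs}); "
            "use a smaller threshold step or more ASVs"
        )
    unfolded = unfold(ev)
    spacings = np.diff(unfolded)
    spacings = spacings[spacings > 0]
    spacings = spacings / spacings.mean()
    n = spacings.size
    if n_bins is None:
        n_bins = max(4, int(np.sqrt(n)))
    # equal-probability bins under Exp(1)
    qs = np.arange(1, n_bins) / n_bins
    edges = np.concatenate(([0.0], -np.log1p(-qs), [np.inf]))
    observed, _ = np.histogram(spacings, bins=edges)
    expected = np.full(n_bins, n / n_bins)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=n_bins - 1))
    return NNSDResult(spacings, chi2, p, n_bins)


def _thresholded(values: np.ndarray, s: float) -> np.ndarray:
    a = np.abs(values).copy()
    a[a < s] = 0.0
    np.fill_diagonal(a, 1.0)
    return a


def scan_threshold(
    corr: CorrelationMatrix,
    s_min: float = 0.30,
    s_max: float = 0.99,
    step: float = 0.01,
    alpha: float = 0.001,
    min_eigs: int = DEFAULT_MIN_EIGS,
    persistence: int = 3,
) -> ThresholdScan:
    """Scan candidate cutoffs and pick the GOE-to-Poisson transition.

    For each threshold s the matrix |r| is hard-thresholded at s
    (diagonal kept) and its eigenvalue NNSD is tested against Poisson.
    The chosen threshold is the smallest s that conforms (p > alpha)
    and opens a run of ``persistence`` consecutive testable thresholds
    that all conform; a pure "conforms at every larger s" rule is too
    brittle because nearly-eroded correlation blocks reintroduce level
    repulsion just before they vanish. Raises with the full scan
    attached when no s qualifies.
    """
    thresholds = np.round(np.arange(s_min, s_max + step / 2, step), 10)
    scan = ThresholdScan()
    for s in thresholds:
        a = _thresholded(corr.values, float(s))
        off = a.copy()
        np.fill_diagonal(off, 0.0)
        n_edges = int((off > 0).sum() // 2)
        ev = np.linalg.eigvalsh(a)
        n_uniq = _unique_eigenvalues(ev).size
        if n_uniq < min_eigs:
            scan.records.append(
                ScanRecord(float(s), n_edges, n_uniq, None, None, False, False)
            )
            continue
        res = nnsd(ev, min_eigs=min_eigs)
        scan.records.append(
            ScanRecord(
                float(s), n_edges, n_uniq, res.chi2, res.p_value,
                res.p_value > alpha, True,
            )
        )
    testable = [r for r in scan.records if r.enough_eigenvalues]
    if not testable:
        raise AnalysisError(
            "no scanned threshold retains enough eigenvalues to test"
        )
    testable_records = [r for r in scan.records if r.enough_eigenvalues]
    for i, rec in enumerate(testable_records):
        window = testable_records[i:i + persistence]
        if all(r.conforming for r in window):
            scan.chosen_threshold = rec.threshold
            break
    if scan.chosen_threshold is None:
        raise AnalysisError(
            "no conforming threshold found; scan: "
            + "; ".join(
                f"s={r.threshold:.2f} p={r.p_value!r}" for r in scan.records
            )
        )
    return scan


# ---------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------

def build_network(
    corr: CorrelationMatrix,
    threshold: float,
    provenance: dict | None = None,
) -> nx.Graph:
    """Signed co-occurrence graph: edge iff |r| >= threshold, weight r.

    Nodes with no surviving edge are dropped. Graph attributes record
    the threshold and any provenance (e.g. group, month).
    """
    if not 0 < threshold <= 1:
        raise AnalysisError("threshold must lie in (0, 1]")
    g = nx.Graph(threshold=float(threshold), **(provenance or {}))
    n = corr.n
    iu, ju = np.triu_indices(n, k=1)
    mask = np.abs(corr.values[iu, ju]) >= threshold
    for i, j in zip(iu[mask], ju[mask]):
        r = float(corr.values[i, j])
        g.add_edge(corr.ids[i], corr.ids[j], weight=r, sign=1 if r > 0 else -1)
    if g.number_of_edges() == 0:
        logger.warning("network empty at threshold %.3f", threshold)
    return g
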