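"""Locus- and sample-level quality control.

Canonical filter order: minor-allele frequency, then call rate, then the
Hardy-Weinberg exact test (the order the QCReport records). LD pruning and
MDS ancestry screening operate on the filtered matrix.

The Hardy-Weinberg test is the Levene-Haldane exact test: conditional on
the observed allele counts, heterozygote counts are enumerated and the
two-sided P-value sums the probabilities of all counts no more likely than
the observed one. An exact test is preferred over chi-square because it
stays calibrated at rare alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import MISSING, GenotypeMatrix

logger = logging.getLogger("rgikit")

__all__ = [
    "QCReport",
    "hwe_exact_p",
    "filter_maf",
    "filter_call_rate",
    "filter_hwe",
    "apply_qc",
    "ld_prune",
    "mds_ancestry",
    "MAFFilter",
    "CallRateFilter",
    "HWEFilter",
    "LDPruner",
    "AncestryMDS",
]


@dataclass
class QCReport:
    """Counts of loci/samples removed per filter, with thresholds used."""

    n_loci_in: int = 0
    n_removed_maf: int = 0
    n_removed_callrate: int = 0
    n_removed_hwe: int = 0
    n_samples_removed_ancestry: int = 0
    maf_threshold: float | None = None
    callrate_threshold: float | None = None
    hwe_threshold: float | None = None
    ld_r2_threshold: float | None = None
    hwe_cohort: str | None = None
    filter_order: list = field(default_factory=lambda: ["maf", "call_rate", "hwe"])

    @property
    def n_loci_removed(self) -> int:
        return self.n_removed_maf + self.n_removed_callrate + self.n_removed_hwe

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _hwe_log_probs(n_a: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of every attainable heterozygote count.

    ``n_a`` is the count of the rarer allele, ``n`` the number of diploid
    individuals. Returns (het_counts, log_probs) under the Levene-Haldane
    conditional distribution.
    """
    n_b = 2 * n - n_a
    h = np.arange(n_a % 2, min(n_a, n_b) + 1, 2)
    hom_a = (n_a - h) // 2
    hom_b = (n_b - h) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(hom_a + 1)
        - gammaln(h + 1)
        - gammaln(hom_b + 1)
        + h * np.log(2.0)
    )
    logp -= np.logaddexp.reduce(logp)
    return h, logp


def hwe_exact_p(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Two-sided exact Hardy-Weinberg P-value for one locus.

    Conditions on the allele counts implied by the genotype counts and sums
    the probabilities of every heterozygote count whose conditional
    probability does not exceed that of the observed count.
    """
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_a + n_het + n_hom_b
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_a = 2 * n_hom_a + n_het
    n_b = 2 * n_hom_b + n_het
    n_rare = min(n_a, n_b)
    if n_rare == 0:  # monomorphic: single attainable configuration
        return 1.0
    h, logp = _hwe_log_probs(n_rare, n)
    p_obs = logp[np.searchsorted(h, n_het)]
    # tolerance guards against log-space ties being split by rounding
    return float(min(1.0, np.exp(np.logaddexp.reduce(logp[logp <= p_obs + 1e-10]))))


def _hwe_p_per_locus(counts: np.ndarray) -> np.ndarray:
    return np.array([hwe_exact_p(*row) for row in counts])


# ---------------------------------------------------------------------------
# sklearn-style locus filters
# ---------------------------------------------------------------------------

def _as_calls(X) -> np.ndarray:
    if isinstance(X, GenotypeMatrix):
        return X.calls
    return np.asarray(X)


class _LocusSelector(BaseEstimator, TransformerMixin):
    """Base for filters that keep a boolean mask of loci (features)."""

    def _mask(self, calls: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def fit(self, X, y=None):
        self.support_mask_ = self._mask(_as_calls(X))
        self.n_removed_ = int((~self.support_mask_).sum())
        return self

    def transform(self, X):
        if isinstance(X, GenotypeMatrix):
            return X.select_loci(self.support_mask_)
        return _as_calls(X)[:, self.support_mask_]

    def get_support(self) -> np.ndarray:
        return self.support_mask_


class MAFFilter(_LocusSelector):
    """Remove loci with minor-allele frequency below ``threshold``."""

    def __init__(self, threshold: float = 0.01):
        self.threshold = threshold

    def _mask(self, calls):
        if not 0 < self.threshold <= 0.5:
            raise ValueError("MAF threshold must be in (0, 0.5]")
        obs = calls != MISSING
        n_obs = obs.sum(axis=0)
        n_b = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = n_b / (2 * n_obs)
        maf = np.minimum(f, 1 - f)
        return ~(maf < self.threshold)  # NaN (all-missing) loci also removed


class CallRateFilter(_LocusSelector):
    """Remove loci whose fraction of non-missing calls is below ``threshold``."""

    def __init__(self, threshold: float = 0.99):
        self.threshold = threshold

    def _mask(self, calls):
        if not 0 < self.threshold <= 1:
            raise ValueError("call-rate threshold must be in (0, 1]")
        rate = (calls != MISSING).sum(axis=0) / calls.shape[0]
        return ~(rate < self.threshold)


class HWEFilter(_LocusSelector):
    """Remove loci whose exact Hardy-Weinberg P-value is below ``threshold``."""

    def __init__(self, threshold: float = 1e-4):
        self.threshold = threshold

    def _mask(self, calls):
        if not 0 < self.threshold <= 1:
            raise ValueError("HWE P threshold must be in (0, 1]")
        counts = np.stack([(calls == g).sum(axis=0) for g in (0, 1, 2)], axis=1)
        p = _hwe_p_per_locus(counts)
        return ~(p < self.threshold)


def filter_maf(gm: GenotypeMatrix, threshold: float = 0.01):
    f = MAFFilter(threshold).fit(gm)
    report = QCReport(
        n_loci_in=gm.n_loci, n_removed_maf=f.n_removed_, maf_threshold=threshold
    )
    return f.transform(gm), report


def filter_call_rate(gm: GenotypeMatrix, threshold: float = 0.99):
    f = CallRateFilter(threshold).fit(gm)
    report = QCReport(
        n_loci_in=gm.n_loci, n_removed_callrate=f.n_removed_, callrate_threshold=threshold
    )
    return f.transform(gm), report


def filter_hwe(gm: GenotypeMatrix, p_threshold: float = 1e-4):
    f = HWEFilter(p_threshold).fit(gm)
    report = QCReport(
        n_loci_in=gm.n_loci,
        n_removed_hwe=f.n_removed_,
        hwe_threshold=p_threshold,
        hwe_cohort=gm.cohort,
    )
    return f.transform(gm), report


def apply_qc(
    gm: GenotypeMatrix,
    maf: float = 0.01,
    call_rate: float = 0.99,
    hwe: float = 1e-4,
) -> tuple[GenotypeMatrix, QCReport]:
    """Run the canonical locus-filter pipeline: MAF -> call rate -> HWE."""
    report = QCReport(
        n_loci_in=gm.n_loci,
        maf_threshold=maf,
        callrate_threshold=call_rate,
        hwe_threshold=hwe,
        hwe_cohort=gm.cohort,
    )
    gm, r1 = filter_maf(gm, maf)
    gm, r2 = filter_call_rate(gm, call_rate)
    gm, r3 = filter_hwe(gm, hwe)
    report.n_removed_maf = r1.n_removed_maf
    report.n_removed_callrate = r2.n_removed_callrate
    report.n_removed_hwe = r3.n_removed_hwe
    return gm, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

class LDPruner(BaseEstimator, TransformerMixin):
    """Greedy windowed LD pruning on squared Pearson correlation of codes.

    Within each sliding window, while any retained pair correlates above
    ``r2_threshold``, the member with the lower call rate is removed (ties
    broken by removing the higher locus index). PLINK-convention defaults:
    window of 50 loci advancing by 5.
    """

    def __init__(self, r2_threshold: float = 0.5, window: int = 50, step: int = 5):
        self.r2_threshold = r2_threshold
        self.window = window
        self.step = step

    def fit(self, X, y=None):
        calls = _as_calls(X)
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        n_loci = calls.shape[1]
        retained = np.ones(n_loci, dtype=bool)
        call_rate = (calls != MISSING).sum(axis=0) / calls.shape[0]
        masked = np.ma.masked_equal(calls.astype(float), MISSING)

        start = 0
        while True:
            idx = np.flatnonzero(retained[start : start + self.window]) + start
            if len(idx) >= 2:
                r = np.ma.corrcoef(masked[:, idx], rowvar=False)
                r2 = np.ma.filled(np.asarray(r) ** 2, 0.0)
                np.fill_diagonal(r2, 0.0)
                alive = np.ones(len(idx), dtype=bool)
                while True:
                    sub = np.where(np.outer(alive, alive), r2, 0.0)
                    i, j = np.unravel_index(np.argmax(sub), sub.shape)
                    if sub[i, j] <= self.r2_threshold:
                        break
                    gi, gj = idx[i], idx[j]
                    if call_rate[gi] < call_rate[gj]:
                        drop = i
                    elif call_rate[gj] < call_rate[gi]:
                        drop = j
                    else:
                        drop = max(i, j)  # tie: drop the later locus
                    alive[drop] = False
                    retained[idx[drop]] = False
            if start + self.window >= n_loci:
                break
            start += self.step
        self.support_mask_ = retained
        return self

    def transform(self, X):
        if isinstance(X, GenotypeMatrix):
            return X.select_loci(self.support_mask_)
        return _as_calls(X)[:, self.support_mask_]

    def get_support(self) -> np.ndarray:
        return self.support_mask_


def ld_prune(
    gm: GenotypeMatrix, r2_threshold: float = 0.5, window: int = 50, step: int = 5
) -> GenotypeMatrix:
    return LDPruner(r2_threshold, window, step).fit(gm).transform(gm)


# ---------------------------------------------------------------------------
# MDS ancestry screening
# ---------------------------------------------------------------------------

def allele_sharing_distance(calls: np.ndarray) -> np.ndarray:
    """Pairwise distance D(i,j) = mean over co-observed loci of |g_i - g_j|/2.

    Computed from genotype-indicator matrix products, so missing calls are
    excluded pairwise without an explicit loop.
    """
    obs = (calls != MISSING).astype(np.float64)
    ind = [(calls == g).astype(np.float64) for g in (0, 1, 2)]
    diff = (
        ind[0] @ ind[1].T
        + ind[1] @ ind[0].T
        + ind[1] @ ind[2].T
        + ind[2] @ ind[1].T
        + 2.0 * (ind[0] @ ind[2].T + ind[2] @ ind[0].T)
    )
    n_shared = obs @ obs.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = diff / (2.0 * n_shared)
    d[n_shared == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return d


class AncestryMDS(BaseEstimator):
    """Classical metric MDS (principal coordinates) with outlier flagging.

    Samples are embedded by eigendecomposition of the double-centred
    squared allele-sharing distance matrix. A sample is flagged as an
    ancestry outlier when its embedded distance to the reference-cluster
    centroid exceeds ``c`` times that cluster's root-mean-square centroid
    distance. With no reference labels the whole cohort is the reference
    cluster.
    """

    def __init__(self, n_components: int = 2, c: float = 3.0):
        self.n_components = n_components
        self.c = c

    def fit(self, X, y=None, reference_labels=None, reference_label=None):
        calls = _as_calls(X)
        n = calls.shape[0]
        if n < 3:
            raise ValueError("MDS ancestry screening needs at least 3 samples")
        d = allele_sharing_distance(calls)
        self.distance_matrix_ = d
        d2 = d**2
        j = np.eye(n) - np.full((n, n), 1.0 / n)
        b = -0.5 * j @ d2 @ j
        vals, vecs = np.linalg.eigh(b)
        order = np.argsort(vals)[::-1][: self.n_components]
        vals_k = np.clip(vals[order], 0.0, None)
        self.eigenvalues_ = vals_k
        self.embedding_ = vecs[:, order] * np.sqrt(vals_k)

        if reference_labels is not None:
            labels = np.asarray(reference_labels)
            if reference_label is None:
                uniq, cnt = np.unique(labels, return_counts=True)
                reference_label = uniq[np.argmax(cnt)]
            ref_mask = labels == reference_label
            if not ref_mask.any():
                raise ValueError(f"no samples carry reference label {reference_label!r}")
        else:
            ref_mask = np.ones(n, dtype=bool)
        centroid = self.embedding_[ref_mask].mean(axis=0)
        dist = np.linalg.norm(self.embedding_ - centroid, axis=1)
        rms = np.sqrt(np.mean(dist[ref_mask] ** 2))
        self.centroid_ = centroid
        self.rms_ = rms
        self.outlier_mask_ = dist > self.c * rms if rms > 0 else np.zeros(n, bool)
        return self

    def fit_transform(self, X, y=None, **kw):
        return self.fit(X, y, **kw).embedding_


def mds_ancestry(
    gm: GenotypeMatrix,
    reference_labels=None,
    k: int = 2,
    c: float = 3.0,
    reference_label=None,
):
    """Functional wrapper: returns (coordinates, outlier flags)."""
    est = AncestryMDS(n_components=k, c=c).fit(
        gm, reference_labels=reference_labels, reference_label=reference_label
    )
    return est.embedding_, est.outlier_mask_
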