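"""Relative genome information: the population measure and surprisal scores.

The reference cohort defines, locus by locus, a categorical distribution
over the three biallelic genotypes (the population measure, a product
measure over loci). A genome's relative local information (RLI) at a locus
is the surprisal -log2 p of its observed genotype under that distribution;
summing RLI over the shared locus set gives the relative genome
information (RGI), and dividing by the number of loci n gives the expected
information per locus (EIL), comparable across locus sets of different
size. Missing genotypes contribute the locus Shannon entropy — the
expected surprisal — so missingness does not shift EIL systematically.

:class:`RGIScorer` exposes this as a scikit-learn style estimator:
``fit`` estimates the measure from the reference cohort, ``transform``
returns the per-locus RLI matrix and ``score_samples`` the per-genome EIL,
in the manner of a density model scored on held-out data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import (
    MISSING,
    GenotypeMatrix,
    Locus,
    LocusMeasure,
    PopulationMeasure,
    RGIProfile,
)

__all__ = [
    "RGIScorer",
    "estimate_measure",
    "rli",
    "rgi",
    "profile_cohort",
    "save_measure",
    "load_measure",
]


def _entropy_bits(probs: np.ndarray) -> np.ndarray:
    """Shannon entropy in bits along the last axis; 0*log0 = 0."""
    p = np.asarray(probs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=-1)


class RGIScorer(BaseEstimator, TransformerMixin):
    """Score genomes by their information content relative to a reference.

    Parameters
    ----------
    pseudocount : float, default 0.5
        Added to each genotype-category count when estimating per-locus
        frequencies. Bounds the surprisal of genotypes unseen in the
        reference; 0 reproduces the plain frequency estimator, which
        raises on zero-probability observations (infinite surprisal).
    missing : {"impute", "drop"}, default "impute"
        "impute" assigns missing genotypes the locus entropy and
        normalizes EIL by the full locus count; "drop" excludes a
        sample's missing loci from both its RGI sum and its n.

    Attributes
    ----------
    probs_ : ndarray (n_loci, 3)
        Estimated genotype distributions.
    entropy_bits_ : ndarray (n_loci,)
        Per-locus Shannon entropies.
    n_obs_ : ndarray (n_loci,)
        Non-missing reference genotypes per locus.
    measure_ : PopulationMeasure
        Available when fitted on a GenotypeMatrix (carries locus metadata).
    """

    def __init__(self, pseudocount: float = 0.5, missing: str = "impute"):
        self.pseudocount = pseudocount
        self.missing = missing

    # -- fitting --------------------------------------------------------
    def fit(self, X, y=None):
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.missing not in ("impute", "drop"):
            raise ValueError("missing must be 'impute' or 'drop'")
        gm = X if isinstance(X, GenotypeMatrix) else None
        calls = X.calls if gm is not None else np.asarray(X)
        if calls.shape[0] == 0:
            raise ValueError("reference cohort is empty")
        counts = np.stack([(calls == g).sum(axis=0) for g in (0, 1, 2)], axis=1)
        n_obs = counts.sum(axis=1)
        if (n_obs == 0).any():
            j = int(np.flatnonzero(n_obs == 0)[0])
            name = gm.loci[j].id if gm is not None else f"column {j}"
            raise ValueError(f"locus {name} has no non-missing reference calls")
        probs = (counts + self.pseudocount) / (
            n_obs[:, None] + 3.0 * self.pseudocount
        )
        self.probs_ = probs
        self.entropy_bits_ = _entropy_bits(probs)
        self.n_obs_ = n_obs
        self.n_loci_ = calls.shape[1]
        self.locus_ids_ = gm.locus_ids() if gm is not None else None
        self.measure_ = (
            PopulationMeasure(
                measures=[
                    LocusMeasure(
                        locus=gm.loci[j],
                        probs=probs[j],
                        entropy_bits=float(self.entropy_bits_[j]),
                        n_obs=int(n_obs[j]),
                    )
                    for j in range(calls.shape[1])
                ],
                smoothing=self.pseudocount,
            )
            if gm is not None
            else None
        )
        return self

    # -- scoring --------------------------------------------------------
    def _check_aligned(self, X) -> np.ndarray:
        calls = X.calls if isinstance(X, GenotypeMatrix) else np.atleast_2d(np.asarray(X))
        if calls.shape[1] != self.n_loci_:
            raise ValueError(
                f"cohort has {calls.shape[1]} loci; measure was fitted on {self.n_loci_}"
            )
        if isinstance(X, GenotypeMatrix) and self.locus_ids_ is not None:
            if X.locus_ids() != self.locus_ids_:
                raise ValueError("cohort locus ids/order do not match the fitted measure")
        return calls

    def transform(self, X) -> np.ndarray:
        """Per-locus RLI matrix (n_samples, n_loci), in bits.

        Missing genotypes contribute the locus entropy regardless of the
        ``missing`` mode; "drop" only changes how they are aggregated.
        """
        calls = self._check_aligned(X)
        with np.errstate(divide="ignore"):
            surprisal = -np.log2(self.probs_)  # (n_loci, 3)
        obs = calls != MISSING
        codes = np.where(obs, calls, 0)
        rli_mat = surprisal[np.arange(self.n_loci_)[None, :], codes]
        if np.isinf(rli_mat[obs]).any():
            raise ValueError(
                "observed genotype has zero estimated probability; "
                "use a positive pseudocount to bound the surprisal"
            )
        rli_mat = np.where(obs, rli_mat, self.entropy_bits_[None, :])
        return rli_mat

    def profile(self, X, keep_rli: bool = False) -> RGIProfile:
        """Full per-sample profile (RGI, EIL, missing counts)."""
        calls = self._check_aligned(X)
        if calls.shape[0] == 0:
            raise ValueError("cohort is empty")
        rli_mat = self.transform(X)
        obs = calls != MISSING
        n_missing = (~obs).sum(axis=1)
        if self.missing == "impute":
            rgi_bits = rli_mat.sum(axis=1)
            n = np.full(calls.shape[0], self.n_loci_)
        else:
            rgi_bits = np.where(obs, rli_mat, 0.0).sum(axis=1)
            n = obs.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            eil = rgi_bits / n
        gm = X if isinstance(X, GenotypeMatrix) else None
        return RGIProfile(
            samples=gm.samples if gm is not None else [str(i) for i in range(calls.shape[0])],
            rgi_bits=rgi_bits,
            eil_bits=eil,
            n_loci=int(self.n_loci_),
            n_missing=n_missing,
            rli_matrix=rli_mat if keep_rli else None,
            sex=gm.sex if gm is not None else None,
            cohort=gm.cohort if gm is not None else None,
            locus_ids=self.locus_ids_,
        )

    def score_samples(self, X) -> np.ndarray:
        """Per-sample EIL in bits (mean surprisal per locus)."""
        return self.profile(X).eil_bits


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def estimate_measure(
    reference: GenotypeMatrix, pseudocount: float = 0.5
) -> PopulationMeasure:
    """Estimate the per-locus genotype distributions from a reference cohort."""
    return RGIScorer(pseudocount=pseudocount).fit(reference).measure_


def _scorer_from_measure(measure: PopulationMeasure, missing: str = "impute") -> RGIScorer:
    est = RGIScorer(pseudocount=measure.smoothing, missing=missing)
    est.probs_ = measure.probs
    est.entropy_bits_ = measure.entropy_bits
    est.n_obs_ = np.array([m.n_obs for m in measure.measures])
    est.n_loci_ = measure.n_loci
    est.locus_ids_ = measure.locus_ids()
    est.measure_ = measure
    return est


def rli(measure_l: LocusMeasure, genotype: int) -> float:
    """Relative local information of one genotype at one locus, in bits."""
    if genotype == MISSING:
        return float(measure_l.entropy_bits)
    p = measure_l.probs[genotype]
    if p == 0:
        raise ValueError(
            f"locus {measure_l.locus.id}: genotype {genotype} has zero probability "
            "(infinite surprisal); re-estimate the measure with a positive pseudocount"
        )
    return float(-np.log2(p))


def rgi(
    measure: PopulationMeasure, genome: np.ndarray, missing: str = "impute"
) -> tuple[float, float, np.ndarray]:
    """RGI, EIL and the per-locus RLI vector for a single genome."""
    est = _scorer_from_measure(measure, missing=missing)
    prof = est.profile(np.asarray(genome, dtype=np.int8).reshape(1, -1), keep_rli=True)
    return float(prof.rgi_bits[0]), float(prof.eil_bits[0]), prof.rli_matrix[0]


def profile_cohort(
    measure: PopulationMeasure,
    cohort: GenotypeMatrix,
    keep_rli: bool = False,
    missing: str = "impute",
) -> RGIProfile:
    """Profile every genome in a cohort against an estimated measure."""
    est = _scorer_from_measure(measure, missing=missing)
    return est.profile(cohort, keep_rli=keep_rli)


# ---------------------------------------------------------------------------
# measure (de)serialization — JSON, for the CLI pipeline
# ---------------------------------------------------------------------------

def save_measure(measure: PopulationMeasure, path: str | Path) -> None:
    payload = {
        "smoothing": measure.smoothing,
        "loci": [
            {
                "id": m.locus.id,
                "chromosome": m.locus.chromosome,
                "position": m.locus.position,
                "allele_a": m.locus.allele_a,
                "allele_b": m.locus.allele_b,
                "probs": [float(p) for p in m.probs],
                "entropy_bits": float(m.entropy_bits),
                "n_obs": int(m.n_obs),
            }
            for m in measure.measures
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_measure(path: str | Path) -> PopulationMeasure:
    payload = json.loads(Path(path).read_text())
    measures = [
        LocusMeasure(
            locus=Locus(
                id=rec["id"],
                chromosome=rec["chromosome"],
                position=rec["position"],
                allele_a=rec["allele_a"],
                allele_b=rec["allele_b"],
            ),
            probs=np.array(rec["probs"]),
            entropy_bits=rec["entropy_bits"],
            n_obs=rec["n_obs"],
        )
        for rec in payload["loci"]
    ]
    return PopulationMeasure(measures=measures, smoothing=payload["smoothing"])
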