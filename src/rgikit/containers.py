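"""In-memory containers for cohort genotypes and information profiles.

Genotypes are stored as biallelic codes: 0 = allele_a/allele_a,
1 = heterozygote (unordered), 2 = allele_b/allele_b, -1 = missing.
``allele_b`` is the counted allele (PLINK A1 / VCF ALT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Locus:
    """A biallelic autosomal SNP.

    ``allele_b`` is the counted allele: genotype code equals the number of
    copies of ``allele_b``. Coordinates are 1-based.
    """

    id: str
    chromosome: int
    position: int
    allele_a: str
    allele_b: str
    annotation: str | None = None

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(f"locus {self.id}: alleles must differ")
        if not (1 <= self.chromosome <= 22):
            raise ValueError(f"locus {self.id}: chromosome {self.chromosome} not autosomal")
        if self.position < 1:
            raise ValueError(f"locus {self.id}: position must be >= 1")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_a, self.allele_b)


class GenotypeMatrix:
    """samples x loci matrix of unordered biallelic genotype codes.

    Parameters
    ----------
    calls : ndarray of shape (n_samples, n_loci), int8
        Genotype codes in {0, 1, 2} or :data:`MISSING` (-1).
    loci : sequence of Locus
    samples : sequence of str
        Sample identifiers, unique.
    sex : optional sequence of str or None ("M"/"F"), per sample.
    cohort : optional str label for the whole matrix.
    """

    def __init__(
        self,
        calls: np.ndarray,
        loci: Sequence[Locus],
        samples: Sequence[str],
        sex: Sequence[str | None] | None = None,
        cohort: str | None = None,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.ndim != 2:
            raise ValueError("calls must be 2-D (samples x loci)")
        if calls.shape != (len(samples), len(loci)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(samples)} samples x {len(loci)} loci"
            )
        valid = np.isin(calls, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(calls[~valid])
            raise ValueError(f"invalid genotype codes {bad.tolist()}")
        ids = [l.id for l in loci]
        if len(set(ids)) != len(ids):
            raise ValueError("locus ids are not unique")
        self.calls = calls
        self.loci = list(loci)
        self.samples = list(samples)
        self.sex = list(sex) if sex is not None else None
        self.cohort = cohort

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_samples, self.n_loci)

    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]

    # -- summaries ------------------------------------------------------
    def genotype_counts(self) -> np.ndarray:
        """Per-locus counts of genotype codes 0/1/2, shape (n_loci, 3)."""
        out = np.empty((self.n_loci, 3), dtype=np.int64)
        for g in (0, 1, 2):
            out[:, g] = (self.calls == g).sum(axis=0)
        return out

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per locus."""
        if self.n_samples == 0:
            return np.full(self.n_loci, np.nan)
        return (self.calls != MISSING).sum(axis=0) / self.n_samples

    def minor_allele_frequency(self) -> np.ndarray:
        """Per-locus MAF over non-missing calls; NaN if all missing."""
        counts = self.genotype_counts()
        n_obs = counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_b = (counts[:, 1] + 2 * counts[:, 2]) / (2 * n_obs)
        return np.minimum(f_b, 1.0 - f_b)

    # -- subsetting -----------------------------------------------------
    def select_loci(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.calls[:, index],
            [self.loci[i] for i in index],
            self.samples,
            sex=self.sex,
            cohort=self.cohort,
        )

    def select_samples(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.calls[index, :],
            self.loci,
            [self.samples[i] for i in index],
            sex=[self.sex[i] for i in index] if self.sex is not None else None,
            cohort=self.cohort,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.calls, other.calls)
            and self.loci == other.loci
            and self.samples == other.samples
        )

    def __repr__(self) -> str:
        label = f" cohort={self.cohort!r}" if self.cohort else ""
        return f"<GenotypeMatrix {self.n_samples} samples x {self.n_loci} loci{label}>"


@dataclass
class LocusMeasure:
    """Estimated genotype distribution at one locus, with its entropy.

    ``probs`` is the categorical distribution over genotype codes (0, 1, 2);
    ``entropy_bits`` is its Shannon entropy in bits.
    """

    locus: Locus
    probs: np.ndarray
    entropy_bits: float
    n_obs: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"locus {self.locus.id}: probs must be a length-3 distribution")
        self.probs = p


@dataclass
class PopulationMeasure:
    """Product measure over a shared locus set: one LocusMeasure per locus.

    The product structure means loci are scored independently; the measure
    is estimated from reference-cohort genotype frequencies with optional
    pseudocount smoothing (recorded in ``smoothing``).
    """

    measures: list[LocusMeasure]
    smoothing: float

    def __post_init__(self) -> None:
        for m in self.measures:
            if m.n_obs < 1:
                raise ValueError(f"locus {m.locus.id}: measure has no observations")

    @property
    def n_loci(self) -> int:
        return len(self.measures)

    @property
    def probs(self) -> np.ndarray:
        """(n_loci, 3) matrix of genotype probabilities."""
        return np.vstack([m.probs for m in self.measures])

    @property
    def entropy_bits(self) -> np.ndarray:
        return np.array([m.entropy_bits for m in self.measures])

    def locus_ids(self) -> list[str]:
        return [m.locus.id for m in self.measures]

    def to_frame(self) -> pd.DataFrame:
        p = self.probs
        return pd.DataFrame(
            {
                "snp_id": self.locus_ids(),
                "p_hom_a": p[:, 0],
                "p_het": p[:, 1],
                "p_hom_b": p[:, 2],
                "entropy_bits": self.entropy_bits,
                "n_obs": [m.n_obs for m in self.measures],
            }
        )


@dataclass
class RGIProfile:
    """Per-sample relative genome information.

    rgi_bits is the total surprisal of each genome under the population
    measure; eil_bits = rgi_bits / n_loci. Missing genotypes contribute the
    locus entropy (neutral imputation), so n_loci is the full shared set.
    """

    samples: list[str]
    rgi_bits: np.ndarray
    eil_bits: np.ndarray
    n_loci: int
    n_missing: np.ndarray
    rli_matrix: np.ndarray | None = None
    sex: list[str | None] | None = None
    cohort: str | None = None
    locus_ids: list[str] | None = field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.samples,
                "rgi_bits": self.rgi_bits,
                "eil_bits": self.eil_bits,
                "n_loci": self.n_loci,
                "n_missing": self.n_missing,
            }
        )
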