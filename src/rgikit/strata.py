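"""EIL within genome strata: chromosomes, SNP annotations, and sex.

Stratum EIL for a sample is the mean RLI over the stratum's loci, so
strata of different sizes are comparable and the locus-count-weighted mean
of stratum EILs reconstructs the global EIL exactly. Each stratum family
(chromosomes; annotation categories) is tested with one-sided Wilcoxon
rank-sum (cases > controls) and BH-adjusted within the family only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_fdr, wilcoxon_rank_sum

__all__ = ["StratumResult", "stratum_eil", "eil_by_stratum", "eil_by_sex"]


@dataclass
class StratumResult:
    label: str
    n_loci: int
    case_median: float
    case_ci: tuple
    control_median: float
    control_ci: tuple
    statistic: float
    p_value: float
    p_adjusted: float | None = None


def _boot_median_ci(
    values: np.ndarray, rng: np.random.Generator, n_boot: int = 1000
) -> tuple[float, float]:
    """Percentile-bootstrap 95% CI for the median."""
    meds = np.median(
        values[rng.integers(0, len(values), size=(n_boot, len(values)))], axis=1
    )
    lo, hi = np.percentile(meds, [2.5, 97.5])
    return float(lo), float(hi)


def stratum_eil(rli_matrix: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-sample EIL restricted to the loci selected by ``mask``."""
    return np.asarray(rli_matrix, float)[:, mask].mean(axis=1)


def eil_by_stratum(
    case_rli: np.ndarray,
    control_rli: np.ndarray,
    strata,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> list[StratumResult]:
    """Stratified case-vs-control EIL comparison.

    ``strata`` is a per-locus label sequence; loci labelled None are
    excluded (e.g. unannotated loci in the annotation family). Labels are
    one BH family: adjusted P-values never mix families, so chromosome and
    annotation analyses are separate calls.
    """
    case_rli = np.asarray(case_rli, float)
    control_rli = np.asarray(control_rli, float)
    labels = np.asarray(strata, dtype=object)
    if labels.shape[0] != case_rli.shape[1] or case_rli.shape[1] != control_rli.shape[1]:
        raise ValueError("strata labels must align with the shared locus set")
    uniq = [u for u in pd.unique(labels) if u is not None]
    if not uniq:
        raise ValueError("no labelled loci")
    rng = np.random.default_rng(seed)
    results = []
    for u in uniq:
        mask = labels == u
        case_eil = stratum_eil(case_rli, mask)
        ctrl_eil = stratum_eil(control_rli, mask)
        stat, p = wilcoxon_rank_sum(case_eil, ctrl_eil, sided="greater")
        results.append(
            StratumResult(
                label=str(u),
                n_loci=int(mask.sum()),
                case_median=float(np.median(case_eil)),
                case_ci=_boot_median_ci(case_eil, rng, n_boot),
                control_median=float(np.median(ctrl_eil)),
                control_ci=_boot_median_ci(ctrl_eil, rng, n_boot),
                statistic=stat,
                p_value=p,
            )
        )
    for r, q in zip(results, bh_fdr([r.p_value for r in results])):
        r.p_adjusted = float(q)
    return results


def eil_by_sex(
    eil: np.ndarray,
    sex,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> StratumResult:
    """Two-sided male-vs-female EIL comparison within one cohort.

    A negative control: sex should not associate with EIL on autosomes.
    The returned record reports males in the "case" slots and females in
    the "control" slots purely positionally.
    """
    eil = np.asarray(eil, float)
    sex = np.asarray(sex, dtype=object)
    males = eil[sex == "M"]
    females = eil[sex == "F"]
    if males.size == 0 or females.size == 0:
        raise ValueError("need both male and female samples")
    stat, p = wilcoxon_rank_sum(males, females, sided="two")
    rng = np.random.default_rng(seed)
    return StratumResult(
        label="M|F",
        n_loci=0,
        case_median=float(np.median(males)),
        case_ci=_boot_median_ci(males, rng, n_boot),
        control_median=float(np.median(females)),
        control_ci=_boot_median_ci(females, rng, n_boot),
        statistic=stat,
        p_value=p,
        p_adjusted=None,
    )
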