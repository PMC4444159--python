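"""Case-control statistics over EIL distributions.

Rank and distribution tests (Wilcoxon rank-sum, two-sample
Kolmogorov-Smirnov), Benjamini-Hochberg FDR adjustment, Fisher's exact
test, top-percentile odds ratios, and a smooth odds-vs-EIL curve fitted by
a logistic generalized additive model (penalized B-splines, smoothing
selected by generalized cross-validation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wilcoxon_rank_sum",
    "ks_two_sample",
    "bh_fdr",
    "fisher_exact_2x2",
    "percentile_odds",
    "odds_curve",
    "compare_cohorts",
    "FisherResult",
    "PercentileOdds",
    "OddsCurve",
    "TestRecord",
    "CohortComparison",
]


def wilcoxon_rank_sum(x, y, sided: str = "two") -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test with midranks for ties.

    ``sided="greater"`` tests the alternative that ``x`` tends larger than
    ``y``. Exact enumeration is used for small tie-free samples, otherwise
    the normal approximation with continuity correction.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[sided]
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic P)."""
    res = sps.ks_2samp(np.asarray(x, float), np.asarray(y, float), method="asymp")
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class FisherResult:
    odds_ratio: float
    p_value: float
    haldane_corrected: bool


def fisher_exact_2x2(table) -> FisherResult:
    """Conditional exact two-sided Fisher test on a 2x2 table.

    The odds ratio is the sample estimate ad/bc, with a 0.5 Haldane
    correction applied to every cell iff any cell is zero (flagged).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    p = float(sps.fisher_exact(t, alternative="two-sided")[1])
    haldane = bool((t == 0).any())
    tc = t + 0.5 if haldane else t.astype(float)
    odds = float(tc[0, 0] * tc[1, 1] / (tc[0, 1] * tc[1, 0]))
    return FisherResult(odds_ratio=odds, p_value=p, haldane_corrected=haldane)


@dataclass
class PercentileOdds:
    percentile: float
    threshold: float
    odds_ratio: float
    fisher_p: float
    haldane_corrected: bool
    table: np.ndarray = field(repr=False, default=None)


def percentile_odds(
    cases_eil, controls_eil, percentile: float = 99, pooled: bool = True
) -> PercentileOdds:
    """Odds ratio of case status above vs below an upper EIL percentile.

    The threshold is the given percentile of the pooled EIL distribution
    (or of the controls alone with ``pooled=False``); the 2x2 table is
    case/control status crossed with above/below threshold.
    """
    cases = np.asarray(cases_eil, float)
    controls = np.asarray(controls_eil, float)
    if not 50 < percentile < 100:
        raise ValueError("percentile must be in (50, 100)")
    ref = np.concatenate([cases, controls]) if pooled else controls
    threshold = float(np.percentile(ref, percentile))
    table = np.array(
        [
            [(cases > threshold).sum(), (cases <= threshold).sum()],
            [(controls > threshold).sum(), (controls <= threshold).sum()],
        ]
    )
    fr = fisher_exact_2x2(table)
    return PercentileOdds(
        percentile=percentile,
        threshold=threshold,
        odds_ratio=fr.odds_ratio,
        fisher_p=fr.p_value,
        haldane_corrected=fr.haldane_corrected,
        table=table,
    )


@dataclass
class OddsCurve:
    """Fitted odds ratio vs EIL, anchored at OR=1 on the reference EIL."""

    grid: np.ndarray
    odds_ratio: np.ndarray
    log_or: np.ndarray
    ci_low: np.ndarray | None
    ci_high: np.ndarray | None
    reference_eil: float
    alpha: float
    separation: bool


def _gcv_alpha(y, exog, smoother, alphas) -> float:
    """Select the GAM penalty by generalized cross-validation n*D/(n-edf)^2."""
    n = len(y)
    best_alpha, best_gcv = alphas[0], np.inf
    for a in alphas:
        try:
            res = GLMGam(
                y, exog=exog, smoother=smoother, family=sm.families.Binomial(), alpha=a
            ).fit()
        except Exception:
            continue
        edf = float(np.sum(res.edf))
        gcv = n * res.deviance / (n - edf) ** 2
        if np.isfinite(gcv) and gcv < best_gcv:
            best_gcv, best_alpha = gcv, a
    return float(best_alpha)


def odds_curve(
    cases_eil,
    controls_eil,
    grid_size: int = 50,
    df: int = 6,
    alphas=None,
) -> OddsCurve:
    """Logistic GAM of case status on EIL, reported as an odds-ratio curve.

    A penalized cubic B-spline smooth of EIL is fitted to the case/control
    indicator; the penalty weight is chosen by GCV over a log-spaced grid.
    The curve is anchored so the odds ratio equals 1 at the control median
    EIL, with pointwise 95% intervals from the penalized covariance.
    Perfect separation suppresses the intervals with a warning.
    """
    cases = np.asarray(cases_eil, float)
    controls = np.asarray(controls_eil, float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both groups must be non-empty")
    x = np.concatenate([cases, controls])
    y = np.concatenate([np.ones(cases.size), np.zeros(controls.size)])
    ref = float(np.median(controls))

    smoother = BSplines(x[:, None], df=[df], degree=[3])
    exog = np.ones((len(y), 1))
    if alphas is None:
        alphas = np.logspace(-4, 6, 21)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alpha = _gcv_alpha(y, exog, smoother, alphas)
        res = GLMGam(
            y, exog=exog, smoother=smoother, family=sm.families.Binomial(), alpha=alpha
        ).fit()
        fitted = res.predict()

    separation = bool(np.any(fitted < 1e-8) or np.any(fitted > 1 - 1e-8))
    if separation:
        warnings.warn(
            "perfect separation detected in odds curve; pointwise intervals suppressed"
        )

    grid = np.linspace(x.min(), x.max(), grid_size)
    design_grid = np.column_stack([np.ones(grid_size), smoother.transform(grid[:, None])])
    design_ref = np.column_stack([[1.0], smoother.transform(np.array([[ref]]))])
    params = np.asarray(res.params)
    log_or = design_grid @ params - float((design_ref @ params).item())
    if separation:
        ci_low = ci_high = None
    else:
        diff = design_grid - design_ref
        cov = np.asarray(res.cov_params())
        se = np.sqrt(np.einsum("ij,jk,ik->i", diff, cov, diff))
        ci_low = np.exp(log_or - 1.96 * se)
        ci_high = np.exp(log_or + 1.96 * se)
    return OddsCurve(
        grid=grid,
        odds_ratio=np.exp(log_or),
        log_or=log_or,
        ci_low=ci_low,
        ci_high=ci_high,
        reference_eil=ref,
        alpha=alpha,
        separation=separation,
    )


# ---------------------------------------------------------------------------
# the full battery
# ---------------------------------------------------------------------------

@dataclass
class TestRecord:
    name: str
    sided: str
    statistic: float
    p_value: float
    p_adjusted: float | None = None


@dataclass
class CohortComparison:
    group_labels: list
    case_groups: list
    tests: list
    odds_curve: OddsCurve | None
    percentile_or: PercentileOdds | None

    def to_dict(self) -> dict:
        out = {
            "groups": list(self.group_labels),
            "case_groups": list(self.case_groups),
            "tests": [
                {
                    "name": t.name,
                    "sided": t.sided,
                    "statistic": t.statistic,
                    "p_value": t.p_value,
                    "p_adjusted": t.p_adjusted,
                }
                for t in self.tests
            ],
        }
        if self.percentile_or is not None:
            po = self.percentile_or
            out["percentile_or"] = {
                "percentile": po.percentile,
                "threshold_eil": po.threshold,
                "odds_ratio": po.odds_ratio,
                "fisher_p": po.fisher_p,
                "haldane_corrected": po.haldane_corrected,
            }
        if self.odds_curve is not None:
            oc = self.odds_curve
            out["odds_curve"] = {
                "grid": oc.grid.tolist(),
                "odds_ratio": oc.odds_ratio.tolist(),
                "reference_eil": oc.reference_eil,
                "separation": oc.separation,
            }
        return out


def compare_cohorts(
    groups: dict,
    case_groups: list,
    percentile: float = 99,
    fit_odds_curve: bool = True,
    pooled_percentile: bool = True,
) -> CohortComparison:
    """Run the full case-control battery over named EIL vectors.

    Every pair of groups is compared by a two-sided Wilcoxon rank-sum test
    (BH-adjusted across the pairwise family). Groups named in
    ``case_groups`` are then amalgamated into one case set and the rest
    into one control set for the one-sided Wilcoxon, the KS distribution
    test, the odds-vs-EIL curve and the top-percentile odds ratio.
    """
    labels = list(groups)
    if not set(case_groups) <= set(labels):
        raise ValueError("case_groups must name keys of groups")
    if not case_groups or set(case_groups) == set(labels):
        raise ValueError("need at least one case group and one control group")

    tests: list[TestRecord] = []
    pairwise: list[TestRecord] = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            stat, p = wilcoxon_rank_sum(groups[a], groups[b], sided="two")
            pairwise.append(TestRecord(f"wilcoxon:{a}|{b}", "two", stat, p))
    adj = bh_fdr([t.p_value for t in pairwise])
    for t, q in zip(pairwise, adj):
        t.p_adjusted = float(q)
    tests.extend(pairwise)

    cases = np.concatenate([np.asarray(groups[g], float) for g in case_groups])
    controls = np.concatenate(
        [np.asarray(groups[g], float) for g in labels if g not in case_groups]
    )
    stat, p = wilcoxon_rank_sum(cases, controls, sided="greater")
    tests.append(TestRecord("wilcoxon:cases|controls", "greater", stat, p))
    d, p = ks_two_sample(cases, controls)
    tests.append(TestRecord("ks:cases|controls", "two", d, p))

    po = percentile_odds(cases, controls, percentile=percentile, pooled=pooled_percentile)
    oc = odds_curve(cases, controls) if fit_odds_curve else None
    return CohortComparison(
        group_labels=labels,
        case_groups=list(case_groups),
        tests=tests,
        odds_curve=oc,
        percentile_or=po,
    )
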