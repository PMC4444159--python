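"""Resampling attribution: how many distinct loci carry the EIL gap.

For a given percentile, the target information gap is
``n_loci * (Q_case(p) - Q_control(p))`` on the EIL scale, i.e. the
total-bits difference between the case and control EIL quantiles. Each
replicate draws (case genome, locus) pairs uniformly with replacement,
accumulating that genome's RLI excess over the control locus mean — draws
may decrease the running sum — until the target is met, and records how
many distinct loci were touched. The replicate counts are summarized by
their median and 2.5/97.5% quantiles.

The count measures how widely the resampling must range over the locus
panel before the gap is covered: when the excess is spread over many loci
the count approaches the panel size, which is the diagnostic signature of
a polygenic (rather than few-locus) difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AttributionRow", "AttributionResult", "loci_to_account", "attribution_profile"]


@dataclass
class AttributionRow:
    percentile: float
    target_bits: float
    median_loci: float
    ci_low: float
    ci_high: float
    n_replicates: int
    n_capped: int
    not_applicable: bool

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class AttributionResult:
    rows: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_dict() for r in self.rows])


def _replicate_counts(
    excess: np.ndarray,
    target: float,
    n_replicates: int,
    rng: np.random.Generator,
    draw_cap: int,
    block: int = 4096,
) -> tuple[np.ndarray, int]:
    """Distinct-locus count per replicate; capped replicates return -1."""
    n_case, n_loci = excess.shape
    counts = np.empty(n_replicates, dtype=np.int64)
    n_capped = 0
    for r in range(n_replicates):
        total = 0.0
        n_drawn = 0
        seen = np.zeros(n_loci, dtype=bool)
        done = False
        while n_drawn < draw_cap:
            b = min(block, draw_cap - n_drawn)
            s = rng.integers(0, n_case, size=b)
            l = rng.integers(0, n_loci, size=b)
            run = total + np.cumsum(excess[s, l])
            hit = np.flatnonzero(run >= target)
            if hit.size:
                stop = hit[0] + 1
                seen[l[:stop]] = True
                done = True
                break
            total = run[-1]
            seen[l] = True
            n_drawn += b
        if done:
            counts[r] = int(seen.sum())
        else:
            counts[r] = -1
            n_capped += 1
    return counts, n_capped


def loci_to_account(
    case_rli: np.ndarray,
    control_rli: np.ndarray,
    percentile: float,
    n_replicates: int = 10_000,
    seed: int | np.random.Generator | None = None,
    draw_cap: int = 1_000_000,
) -> AttributionRow:
    """Estimate the distinct-locus count covering the EIL gap at one percentile.

    A non-positive gap (cases not exceeding controls at that percentile)
    yields a row flagged ``not_applicable``. Replicates that hit the draw
    cap before reaching the target are excluded, with their count reported.
    """
    case_rli = np.asarray(case_rli, float)
    control_rli = np.asarray(control_rli, float)
    if case_rli.shape[1] != control_rli.shape[1]:
        raise ValueError("case and control RLI matrices must share the locus set")
    if not 50 <= percentile <= 99.5:
        raise ValueError("percentile must be in [50, 99.5]")
    n_loci = case_rli.shape[1]
    q_case = np.percentile(case_rli.mean(axis=1), percentile)
    q_ctrl = np.percentile(control_rli.mean(axis=1), percentile)
    target = n_loci * (q_case - q_ctrl)
    if target <= 0:
        return AttributionRow(
            percentile=percentile,
            target_bits=float(target),
            median_loci=np.nan,
            ci_low=np.nan,
            ci_high=np.nan,
            n_replicates=0,
            n_capped=0,
            not_applicable=True,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    excess = case_rli - control_rli.mean(axis=0)[None, :]
    counts, n_capped = _replicate_counts(excess, target, n_replicates, rng, draw_cap)
    ok = counts[counts >= 0]
    if ok.size == 0:
        raise RuntimeError("every replicate hit the draw cap; mean excess may be <= 0")
    lo, med, hi = np.percentile(ok, [2.5, 50, 97.5])
    return AttributionRow(
        percentile=percentile,
        target_bits=float(target),
        median_loci=float(med),
        ci_low=float(lo),
        ci_high=float(hi),
        n_replicates=int(ok.size),
        n_capped=int(n_capped),
        not_applicable=False,
    )


def attribution_profile(
    case_rli: np.ndarray,
    control_rli: np.ndarray,
    percentiles,
    n_replicates: int = 10_000,
    seed: int | None = None,
    draw_cap: int = 1_000_000,
) -> AttributionResult:
    """Distinct-locus counts across a percentile grid (for count-vs-percentile plots)."""
    percentiles = list(percentiles)
    if not percentiles:
        raise ValueError("percentile grid is empty")
    rng = np.random.default_rng(seed)  # shared stream: rows consume it in grid order
    rows = [
        loci_to_account(
            case_rli,
            control_rli,
            p,
            n_replicates=n_replicates,
            seed=rng,
            draw_cap=draw_cap,
        )
        for p in percentiles
    ]
    return AttributionResult(rows=rows)
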