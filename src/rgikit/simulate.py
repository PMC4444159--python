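"""Synthetic SNP-array cohorts with a polygenic case-enrichment model.

Emulates the cohort design the scoring method assumes: one reference
cohort used to estimate the population measure, independent control
cohorts drawn from the same population, and case cohorts ascertained
through a liability-threshold model — liability is a weighted minor-allele
count over a set of risk loci plus standard normal noise, and individuals
in the upper tail of the population liability distribution become cases.
Because risk alleles are minor alleles (by default), ascertained cases
carry rarer genotypes more often and are therefore information-richer
relative to the reference measure: the phenomenon the scoring method is
designed to detect.

Loci are biallelic autosomal SNPs in Hardy-Weinberg equilibrium with
allele frequencies drawn from a configurable spectrum; no linkage
disequilibrium is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import MISSING, GenotypeMatrix, Locus

__all__ = ["SimulationConfig", "SimulatedCohorts", "simulate_population", "simulate_rli_design"]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Generator settings.

    Frequencies are for the counted (minor) allele; ``spectrum`` is
    "uniform" on [f_min, f_max] or "beta" (Beta(a, b) truncated below at
    f_min and folded above 0.5). ``beta`` is the per-risk-locus liability
    weight per minor-allele copy; cases are the individuals whose
    liability exceeds the population ``ascertainment_quantile``.
    """

    n_loci: int = 10_000
    n_reference: int = 1_000
    n_controls: int = 300
    n_cases: int = 300
    f_min: float = 0.05
    f_max: float = 0.5
    spectrum: str = "uniform"
    beta_a: float = 0.5
    beta_b: float = 2.0
    n_risk_loci: int = 500
    beta: float = 0.3
    ascertainment_quantile: float = 0.9
    missingness: float = 0.0
    seed: int = 0
    n_chromosomes: int = 22
    annotation_proportions: dict = field(
        default_factory=lambda: {
            "utr": 0.05,
            "exonic": 0.10,
            "intronic": 0.35,
            "intergenic": 0.50,
        }
    )
    risk_allele_minor: bool = True
    max_attempt_batches: int = 200

    def validate(self) -> None:
        if not 0 < self.f_min <= self.f_max <= 0.5:
            raise ValueError("need 0 < f_min <= f_max <= 0.5")
        if self.n_risk_loci > self.n_loci:
            raise ValueError("n_risk_loci cannot exceed n_loci")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0, 1)")
        if not 0 < self.ascertainment_quantile < 1:
            raise ValueError("ascertainment_quantile must be in (0, 1)")
        if self.spectrum not in ("uniform", "beta"):
            raise ValueError("spectrum must be 'uniform' or 'beta'")


@dataclass
class SimulatedCohorts:
    reference: GenotypeMatrix
    controls: GenotypeMatrix
    cases: GenotypeMatrix
    truth: dict


def _draw_frequencies(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.spectrum == "uniform":
        return rng.uniform(cfg.f_min, cfg.f_max, size=cfg.n_loci)
    f = np.empty(cfg.n_loci)
    filled = 0
    while filled < cfg.n_loci:
        draw = rng.beta(cfg.beta_a, cfg.beta_b, size=2 * (cfg.n_loci - filled))
        draw = np.minimum(draw, 1.0 - draw)  # fold onto the minor-allele scale
        draw = draw[draw >= cfg.f_min][: cfg.n_loci - filled]
        f[filled : filled + draw.size] = draw
        filled += draw.size
    return f


def _make_loci(cfg: SimulationConfig, rng: np.random.Generator) -> list[Locus]:
    chroms = 1 + (np.arange(cfg.n_loci) * cfg.n_chromosomes) // cfg.n_loci
    cats = list(cfg.annotation_proportions)
    probs = np.array([cfg.annotation_proportions[c] for c in cats], float)
    probs /= probs.sum()
    annotations = rng.choice(cats, size=cfg.n_loci, p=probs)
    a_idx = rng.integers(0, 4, size=cfg.n_loci)
    b_idx = (a_idx + rng.integers(1, 4, size=cfg.n_loci)) % 4
    pos = 1
    loci = []
    prev_chrom = 1
    for j in range(cfg.n_loci):
        c = int(chroms[j])
        if c != prev_chrom:
            pos, prev_chrom = 1, c
        loci.append(
            Locus(
                id=f"rs{j}",
                chromosome=c,
                position=pos,
                allele_a=str(_BASES[a_idx[j]]),
                allele_b=str(_BASES[b_idx[j]]),
                annotation=str(annotations[j]),
            )
        )
        pos += int(rng.integers(500, 5000))
    return loci


def _draw_genotypes(f: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """HWE genotypes: minor-allele copies ~ Binomial(2, f)."""
    return rng.binomial(2, f, size=(n, f.size)).astype(np.int8)


def _mask_missing(calls: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate > 0:
        calls = calls.copy()
        calls[rng.random(calls.shape) < rate] = MISSING
    return calls


def simulate_population(config: SimulationConfig) -> SimulatedCohorts:
    """Generate reference, control and liability-ascertained case cohorts."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    freqs = _draw_frequencies(cfg, rng)
    loci = _make_loci(cfg, rng)

    risk_idx = np.sort(rng.choice(cfg.n_loci, size=cfg.n_risk_loci, replace=False))
    betas = np.full(cfg.n_risk_loci, cfg.beta, dtype=float)
    if not cfg.risk_allele_minor:
        betas *= rng.choice([-1.0, 1.0], size=cfg.n_risk_loci)

    reference = _draw_genotypes(freqs, cfg.n_reference, rng)
    controls = _draw_genotypes(freqs, cfg.n_controls, rng)

    # liability threshold calibrated on a large unconditional draw of the
    # risk-locus genotypes only (cheap; avoids a normal approximation)
    calib = rng.binomial(2, freqs[risk_idx], size=(20_000, cfg.n_risk_loci))
    calib_liab = calib @ betas + rng.standard_normal(20_000)
    threshold = float(np.quantile(calib_liab, cfg.ascertainment_quantile))

    case_rows: list[np.ndarray] = []
    n_found = 0
    accept = 1.0 - cfg.ascertainment_quantile
    # batches sized by the expected acceptance rate (20% headroom), capped
    # so a single batch stays within ~2e7 genotype draws
    batch_cap = max(cfg.n_cases, 20_000_000 // max(cfg.n_loci, 1))
    for _ in range(cfg.max_attempt_batches):
        n_batch = max(cfg.n_cases, int(np.ceil(1.2 * (cfg.n_cases - n_found) / accept)))
        n_batch = min(n_batch, batch_cap)
        batch = _draw_genotypes(freqs, n_batch, rng)
        liab = batch[:, risk_idx] @ betas + rng.standard_normal(n_batch)
        hits = batch[liab > threshold]
        if hits.size:
            case_rows.append(hits)
            n_found += hits.shape[0]
        if n_found >= cfg.n_cases:
            break
    else:
        raise RuntimeError(
            f"liability ascertainment found only {n_found}/{cfg.n_cases} cases after "
            f"{cfg.max_attempt_batches} batches (quantile={cfg.ascertainment_quantile}, "
            f"threshold={threshold:.3f}); loosen the quantile or raise max_attempt_batches"
        )
    cases = np.vstack(case_rows)[: cfg.n_cases]

    reference = _mask_missing(reference, cfg.missingness, rng)
    controls = _mask_missing(controls, cfg.missingness, rng)
    cases = _mask_missing(cases, cfg.missingness, rng)

    def _wrap(calls: np.ndarray, name: str, n: int, all_female: bool) -> GenotypeMatrix:
        sex = (
            ["F"] * n
            if all_female
            else [("M", "F")[i] for i in rng.integers(0, 2, size=n)]
        )
        return GenotypeMatrix(
            calls,
            loci,
            [f"{name}{i}" for i in range(n)],
            sex=sex,
            cohort=name,
        )

    truth = {
        "risk_locus_ids": [loci[i].id for i in risk_idx],
        "risk_locus_index": risk_idx.tolist(),
        "betas": betas.tolist(),
        "liability_threshold": threshold,
        "frequencies": freqs.tolist(),
    }
    return SimulatedCohorts(
        reference=_wrap(reference, "ref", cfg.n_reference, False),
        controls=_wrap(controls, "ctrl", cfg.n_controls, False),
        cases=_wrap(cases, "case", cfg.n_cases, True),
        truth=truth,
    )


def simulate_rli_design(
    n_loci: int,
    n_case: int,
    n_control: int,
    excess_loci,
    excess_bits: float,
    seed: int | None = 0,
    case_multipliers: np.ndarray | None = None,
    base_mean: float = 1.0,
    base_sd: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct RLI-matrix fixtures for the attribution procedure.

    Control RLI values are i.i.d. Gamma with the given mean and standard
    deviation; case matrices are identical in distribution except shifted
    by ``excess_bits`` at the listed loci. ``case_multipliers`` (one per
    case genome) grades the planted shift across cases, e.g. to
    concentrate excess in the case upper tail.
    """
    rng = np.random.default_rng(seed)
    shape = (base_mean / base_sd) ** 2
    scale = base_sd**2 / base_mean
    control = rng.gamma(shape, scale, size=(n_control, n_loci))
    case = rng.gamma(shape, scale, size=(n_case, n_loci))
    excess_loci = np.asarray(excess_loci, dtype=int)
    if excess_loci.size and excess_bits != 0:
        mult = (
            np.ones(n_case) if case_multipliers is None else np.asarray(case_multipliers, float)
        )
        case[:, excess_loci] += excess_bits * mult[:, None]
    return case, control
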