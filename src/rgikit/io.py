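"""Cohort genotype I/O and cross-cohort harmonization.

Supports PLINK 1 binary triples (.bed/.bim/.fam, SNP-major) and VCF 4.x.
Genotype codes count copies of the PLINK A1 allele (VCF ALT allele), which
is stored as ``Locus.allele_b``; ``allele_a`` is A2/REF. Non-autosomal
records are dropped on read (the method operates on autosomes only).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, Locus

logger = logging.getLogger("rgikit")

__all__ = [
    "FormatError",
    "read_plink",
    "write_plink",
    "read_vcf",
    "read_annotation",
    "read_samples",
    "intersect_cohorts",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# PLINK 2-bit codes (LSB-first within a byte):
#   00 -> homozygous A1 (2 copies of counted allele)
#   01 -> missing
#   10 -> heterozygous
#   11 -> homozygous A2 (0 copies)
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

# 256 -> 4 sample codes lookup, built once
_BYTE_LUT = np.empty((256, 4), dtype=np.int8)
for _byte in range(256):
    for _i in range(4):
        _BYTE_LUT[_byte, _i] = _BED_DECODE[(_byte >> (2 * _i)) & 0b11]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _autosome(chrom: str) -> int | None:
    """Parse a chromosome label; return 1-22 or None for non-autosomes."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    try:
        n = int(c)
    except ValueError:
        return None
    return n if 1 <= n <= 22 else None


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 binary fileset ``prefix``.bed/.bim/.fam.

    Genotype code = number of copies of the .bim allele-1 (column 5)
    allele, stored as ``allele_b``. Non-autosomal loci are dropped with a
    logged count.
    """
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        f = prefix.with_suffix(ext)
        if not f.exists():
            raise FileNotFoundError(f"PLINK file not found: {f}")

    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    n_samples, n_loci = len(fam), len(bim)

    raw = prefix.with_suffix(".bed").read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise FormatError(f"{prefix.with_suffix('.bed')}: bad PLINK magic bytes")
    if raw[2] != _SNP_MAJOR:
        raise FormatError(f"{prefix.with_suffix('.bed')}: not SNP-major")
    bytes_per_snp = (n_samples + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_snp * n_loci:
        raise FormatError(
            f"{prefix.with_suffix('.bed')}: payload of {payload.size} bytes does not "
            f"match {n_loci} SNPs x {n_samples} samples"
        )
    # decode: (n_loci, bytes_per_snp) -> (n_loci, 4*bytes_per_snp) -> trim
    codes = _BYTE_LUT[payload.reshape(n_loci, bytes_per_snp)].reshape(n_loci, -1)
    calls = codes[:, :n_samples].T.copy()

    keep, loci = [], []
    for j, row in enumerate(bim.itertuples(index=False)):
        chrom = _autosome(row.chrom)
        if chrom is None:
            continue
        keep.append(j)
        loci.append(
            Locus(
                id=row.snp_id,
                chromosome=chrom,
                position=int(row.pos),
                allele_a=row.a2,
                allele_b=row.a1,
            )
        )
    n_dropped = n_loci - len(keep)
    if n_dropped:
        logger.info("read_plink(%s): dropped %d non-autosomal loci", prefix, n_dropped)

    sex = [{1: "M", 2: "F"}.get(int(s)) for s in fam["sex"]]
    return GenotypeMatrix(
        calls[:, keep], loci, fam["iid"].tolist(), sex=sex, cohort=prefix.name
    )


def write_plink(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``gm`` as a PLINK 1 binary fileset (SNP-major)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    n_samples = gm.n_samples
    bytes_per_snp = (n_samples + 3) // 4
    twobit = np.empty((gm.n_loci, n_samples), dtype=np.uint8)
    for code, bits in _BED_ENCODE.items():
        twobit[gm.calls.T == code] = bits
    padded = np.zeros((gm.n_loci, bytes_per_snp * 4), dtype=np.uint8)
    # pad positions encode 0b00 (hom A1); PLINK ignores them on read, as do we
    padded[:, :n_samples] = twobit
    shifts = np.tile([0, 2, 4, 6], bytes_per_snp)
    packed = (padded << shifts).reshape(gm.n_loci, bytes_per_snp, 4).sum(axis=2)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.astype(np.uint8).tobytes())

    with open(prefix.with_suffix(".bim"), "w") as fh:
        for l in gm.loci:
            fh.write(f"{l.chromosome}\t{l.id}\t0\t{l.position}\t{l.allele_b}\t{l.allele_a}\n")

    sex_code = {"M": 1, "F": 2}
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i, s in enumerate(gm.samples):
            sx = sex_code.get(gm.sex[i], 0) if gm.sex is not None else 0
            fh.write(f"{s}\t{s}\t0\t0\t{sx}\t-9\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF 4.x file.

    Multi-allelic records, indels and non-autosomal records are skipped
    with logged counts. Phase is ignored (genotypes are unordered pairs);
    genotype code counts ALT-allele copies (``allele_b`` = ALT).
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF file not found: {path}")
    vcf = VCF(str(path), gts012=True)
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise FormatError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vcf.samples)

    loci: list[Locus] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        chrom = _autosome(var.CHROM)
        if (
            chrom is None
            or len(var.ALT) != 1
            or len(var.REF) != 1
            or len(var.ALT[0]) != 1
            or var.REF not in "ACGT"
            or var.ALT[0] not in "ACGT"
        ):
            n_skipped += 1
            continue
        # gts012: 0/1/2 = ALT copies, 3 = unknown
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        rows.append(g)
        loci.append(
            Locus(
                id=var.ID or f"{var.CHROM}:{var.POS}",
                chromosome=chrom,
                position=var.POS,
                allele_a=var.REF,
                allele_b=var.ALT[0],
            )
        )
    if n_skipped:
        logger.info("read_vcf(%s): skipped %d non-biallelic-SNP/non-autosomal records", path, n_skipped)
    calls = (
        np.vstack(rows).T if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(calls, loci, samples, cohort=path.stem)


def read_annotation(path: str | Path) -> dict[str, str]:
    """Read a SNP annotation table: TSV with header ``snp_id<TAB>category``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["snp_id", "category"]:
        raise FormatError(f"{path}: expected header 'snp_id\\tcategory'")
    return dict(zip(df["snp_id"], df["category"]))


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata table: TSV with header ``sample_id\\tsex\\tcohort``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:3]) != ["sample_id", "sex", "cohort"]:
        raise FormatError(f"{path}: expected header 'sample_id\\tsex\\tcohort'")
    return df


def _harmonize_to(ref: Locus, other: Locus) -> str | None:
    """How to transform ``other``'s codes to match ``ref``'s allele labels.

    Returns "same", "swap" (codes 0<->2), or None (irreconcilable).
    Strand-flipped matches (complement alleles) are accepted, but
    palindromic A/T and C/G SNPs are only accepted on an exact in-order
    match — a swap there cannot be distinguished from a strand flip.
    """
    a, b = ref.allele_a, ref.allele_b
    oa, ob = other.allele_a, other.allele_b
    if (oa, ob) == (a, b):
        return "same"
    palindromic = _COMPLEMENT[a] == b
    if palindromic:
        return None
    if (oa, ob) == (b, a):
        return "swap"
    ca, cb = _COMPLEMENT[oa], _COMPLEMENT[ob]
    if (ca, cb) == (a, b):
        return "same"
    if (ca, cb) == (b, a):
        return "swap"
    return None


def intersect_cohorts(matrices: Sequence[GenotypeMatrix]) -> list[GenotypeMatrix]:
    """Restrict cohorts to their shared loci, harmonizing allele labels.

    The shared loci keep the order they have in the first matrix. Where a
    cohort codes a locus with alleles in the opposite order, its codes are
    flipped (0 <-> 2) and the allele labels rewritten so the returned
    matrices agree byte-for-byte on every locus. Loci whose allele pairs
    cannot be reconciled (directly or by strand complement) are dropped
    with a logged count.
    """
    if len(matrices) < 2:
        raise ValueError("intersect_cohorts needs at least 2 matrices")
    id_maps = [{l.id: j for j, l in enumerate(gm.loci)} for gm in matrices]
    shared = [l.id for l in matrices[0].loci if all(l.id in m for m in id_maps[1:])]
    if not shared:
        raise ValueError("no shared loci across cohorts")

    plans: list[list[tuple[int, str]]] = [[] for _ in matrices]  # (col, action)
    kept_ids = []
    n_irreconcilable = 0
    for sid in shared:
        ref_locus = matrices[0].loci[id_maps[0][sid]]
        actions = ["same"]
        ok = True
        for m_idx in range(1, len(matrices)):
            other = matrices[m_idx].loci[id_maps[m_idx][sid]]
            act = _harmonize_to(ref_locus, other)
            if act is None:
                ok = False
                break
            actions.append(act)
        if not ok:
            n_irreconcilable += 1
            continue
        kept_ids.append(sid)
        for m_idx, act in enumerate(actions):
            plans[m_idx].append((id_maps[m_idx][sid], act))
    if n_irreconcilable:
        logger.info("intersect_cohorts: dropped %d loci with irreconcilable alleles", n_irreconcilable)
    if not kept_ids:
        raise ValueError("no reconcilable shared loci across cohorts")

    ref_loci = [matrices[0].loci[id_maps[0][sid]] for sid in kept_ids]
    out = []
    for gm, plan in zip(matrices, plans):
        cols = [c for c, _ in plan]
        calls = gm.calls[:, cols].copy()
        flip = np.array([act == "swap" for _, act in plan])
        if flip.any():
            sub = calls[:, flip]
            flipped = sub.copy()
            flipped[sub == 0] = 2
            flipped[sub == 2] = 0
            calls[:, flip] = flipped
        out.append(
            GenotypeMatrix(calls, ref_loci, gm.samples, sex=gm.sex, cohort=gm.cohort)
        )
    return out
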