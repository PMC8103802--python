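"""Presence/absence genotype calling from per-site allele depths.

In a high polyploid a single variant-bearing haplotype among ~12 copies
contributes only ~8 % of reads, so diploid genotype likelihoods do not
apply.  Instead each accession x site cell is coded by depth/frequency
rules: the variant is PRESENT when seen at least ``min_alt_count`` times
at >= ``min_alt_freq`` frequency, ABSENT when unseen or seen once below
``max_err_freq`` (a putative sequencing error), and MISSING when depth is
below ``min_depth`` or the evidence is ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeCall",
    "AlleleDepth",
    "SNPRecord",
    "GenotypeCallingConfig",
    "GenotypeMatrix",
    "call_genotype",
    "call_matrix",
    "read_vcf",
    "filter_reads_by_kmer",
]


class GenotypeCall(IntEnum):
    VARIANT_ABSENT = 0
    VARIANT_PRESENT = 1
    MISSING = -1


@dataclass(frozen=True)
class AlleleDepth:
    ref_count: int
    alt_count: int
    depth: int

    def __post_init__(self) -> None:
        if min(self.ref_count, self.alt_count, self.depth) < 0:
            raise ValueError("allele depths must be non-negative")
        if self.ref_count + self.alt_count > self.depth:
            raise ValueError("ref_count + alt_count exceeds total depth")


@dataclass(frozen=True)
class SNPRecord:
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be 1-based (>= 1)")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError("SNPRecord is single-nucleotide only")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref_allele}>{self.alt_allele}"


@dataclass
class GenotypeCallingConfig:
    min_depth: int = 30
    min_alt_count: int = 2
    min_alt_freq: float = 0.04
    max_err_freq: float = 0.01
    #: denominator of the variant frequency: total site depth ("depth")
    #: or ref+alt reads only ("refalt")
    freq_denominator: str = "depth"

    def __post_init__(self) -> None:
        if not (0 <= self.max_err_freq < self.min_alt_freq <= 1):
            raise ValueError("need 0 <= max_err_freq < min_alt_freq <= 1")
        if self.min_depth < 1 or self.min_alt_count < 1:
            raise ValueError("min_depth and min_alt_count must be >= 1")
        if self.freq_denominator not in ("depth", "refalt"):
            raise ValueError("freq_denominator must be 'depth' or 'refalt'")


def call_genotype(ad: AlleleDepth, cfg: GenotypeCallingConfig | None = None) -> GenotypeCall:
    """Code one accession x site cell as PRESENT / ABSENT / MISSING."""
    if cfg is None:
        cfg = GenotypeCallingConfig()
    if ad.depth < cfg.min_depth:
        return GenotypeCall.MISSING
    denom = ad.depth if cfg.freq_denominator == "depth" else ad.ref_count + ad.alt_count
    freq = ad.alt_count / denom if denom > 0 else 0.0
    if ad.alt_count >= cfg.min_alt_count and freq >= cfg.min_alt_freq:
        return GenotypeCall.VARIANT_PRESENT
    if ad.alt_count == 0 or (ad.alt_count == 1 and freq < cfg.max_err_freq):
        return GenotypeCall.VARIANT_ABSENT
    return GenotypeCall.MISSING


class GenotypeMatrix:
    """Sites x accessions grid of presence/absence/missing calls.

    Backed by an int8 DataFrame coded 1 (present) / 0 (absent) / -1
    (missing), indexed by site ids ``chrom:pos:ref>alt``.
    """

    def __init__(self, calls: pd.DataFrame, sites: pd.DataFrame | None = None):
        if calls.index.has_duplicates or calls.columns.has_duplicates:
            raise ValueError("site and accession ids must be unique")
        self.calls = calls.astype(np.int8)
        self.sites = sites

    @property
    def accessions(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def site_ids(self) -> list[str]:
        return list(self.calls.index)

    def to_tsv(self, path: Path) -> Path:
        out = self.calls.replace(-1, pd.NA)
        out.to_csv(path, sep="\t", index_label="site_id", na_rep="NA")
        return Path(path)

    @classmethod
    def from_tsv(cls, path: Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="site_id")
        return cls(df.fillna(-1).astype(np.int8))


def call_matrix(
    ref_counts: np.ndarray,
    alt_counts: np.ndarray,
    depths: np.ndarray,
    cfg: GenotypeCallingConfig | None = None,
    site_ids: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Vectorized element-wise genotype coding of a depth grid."""
    if cfg is None:
        cfg = GenotypeCallingConfig()
    alt = np.asarray(alt_counts)
    depth = np.asarray(depths)
    ref = np.asarray(ref_counts)
    denom = depth if cfg.freq_denominator == "depth" else ref + alt
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(denom > 0, alt / np.maximum(denom, 1), 0.0)
    present = (alt >= cfg.min_alt_count) & (freq >= cfg.min_alt_freq)
    absent = (alt == 0) | ((alt == 1) & (freq < cfg.max_err_freq))
    calls = np.full(alt.shape, int(GenotypeCall.MISSING), dtype=np.int8)
    calls[absent] = int(GenotypeCall.VARIANT_ABSENT)
    calls[present] = int(GenotypeCall.VARIANT_PRESENT)  # present rule wins
    calls[depth < cfg.min_depth] = int(GenotypeCall.MISSING)
    if site_ids is None:
        site_ids = [f"site{i}" for i in range(alt.shape[0])]
    if sample_ids is None:
        sample_ids = [f"acc{j}" for j in range(alt.shape[1])]
    df = pd.DataFrame(calls, index=list(site_ids), columns=list(sample_ids))
    return GenotypeMatrix(df)


def read_vcf(
    path: Path, sample_ids: Sequence[str] | None = None
) -> tuple[list[SNPRecord], np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Read per-sample allele depths from a VCF with AD annotations.

    Multi-allelic records are decomposed into one biallelic SNPRecord per
    alternate allele; non-SNP alleles are skipped (counted in the log).
    Returns (records, ref_counts, alt_counts, depths, samples), arrays
    shaped (n_records, n_samples) in file order.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample_ids is not None:
        keep = [samples.index(s) for s in sample_ids]
        samples = list(sample_ids)
    else:
        keep = list(range(len(samples)))

    records: list[SNPRecord] = []
    refs, alts, deps = [], [], []
    n_skipped = 0
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            raise ValueError(
                f"record {rec.CHROM}:{rec.POS} lacks the AD (allele depth) annotation"
            )
        ad = np.asarray(ad)
        ad = np.where(ad < 0, 0, ad)  # cyvcf2 encodes '.' as negative
        dp = rec.format("DP")
        if dp is not None:
            depth_row = np.asarray(dp).reshape(-1)
            depth_row = np.where(depth_row < 0, 0, depth_row)
        else:
            depth_row = ad.sum(axis=1)
        for ai, alt_allele in enumerate(rec.ALT):
            if len(rec.REF) != 1 or len(alt_allele) != 1 or alt_allele not in "ACGT":
                n_skipped += 1
                continue
            records.append(SNPRecord(rec.CHROM, rec.POS, rec.REF, alt_allele))
            refs.append(ad[keep, 0])
            alts.append(ad[keep, ai + 1])
            deps.append(depth_row[keep])
    if n_skipped:
        logger.info("skipped %d non-SNP alternate alleles", n_skipped)
    shape = (len(records), len(samples))
    return (
        records,
        np.array(refs, dtype=np.int64).reshape(shape),
        np.array(alts, dtype=np.int64).reshape(shape),
        np.array(deps, dtype=np.int64).reshape(shape),
        samples,
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def filter_reads_by_kmer(
    reads: Iterable[str], targets: Iterable[str], k: int = 20
) -> list[str]:
    """Keep the reads sharing at least one k-mer (either strand of the
    read) with any target sequence."""
    if k <= 0:
        raise ValueError("k must be positive")
    target_kmers: set[str] = set()
    for t in targets:
        t = t.upper()
        for i in range(len(t) - k + 1):
            target_kmers.add(t[i : i + k])
    if not target_kmers:
        return []
    kept = []
    for read in reads:
        r = read.upper()
        hit = False
        for strand in (r, _revcomp(r)):
            for i in range(len(strand) - k + 1):
                if strand[i : i + k] in target_kmers:
                    hit = True
                    break
            if hit:
                break
        if hit:
            kept.append(read)
    return kept
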