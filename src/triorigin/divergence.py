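"""Nei–Gojobori (NG86) synonymous divergence and molecular-clock dating.

For each codon, synonymous site counts are the fraction of viable
single-base neighbours (mutations to stop codons excluded) that preserve
the encoded amino acid; differences between codon pairs are classified by
averaging over all stop-free orderings of single-base steps.  The
proportion of synonymous differences ps = Sd/S is Jukes–Cantor corrected,
Ks = -(3/4) ln(1 - (4/3) ps), and divergence time follows the clock
T = Ks / (2 mu) with mu the per-site per-year substitution rate.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "SENSE_CODONS",
    "SENSE_INDICES",
    "STOP_INDICES",
    "CodonAlignment",
    "KsResult",
    "DatingConfig",
    "SaturationError",
    "ng86_sites",
    "ng86_differences",
    "ks_pairwise",
    "ks_between",
    "backtranslate",
    "divergence_time",
    "group_mean_ks",
    "codon_index_to_str",
]

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_AA))

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def _codon_to_index(codon: str) -> int:
    return (
        16 * _BASE_INDEX[codon[0]] + 4 * _BASE_INDEX[codon[1]] + _BASE_INDEX[codon[2]]
    )


def codon_index_to_str(idx: np.ndarray | int) -> str:
    """Decode codon index array (base-4 little table) to a DNA string."""
    arr = np.atleast_1d(np.asarray(idx, dtype=np.int64))
    chars = []
    for v in arr:
        chars.append(_BASES[(v // 16) % 4] + _BASES[(v // 4) % 4] + _BASES[v % 4])
    return "".join(chars)


SENSE_INDICES = np.array([_codon_to_index(c) for c in SENSE_CODONS], dtype=np.int64)
STOP_INDICES = frozenset(_codon_to_index(c) for c in STOP_CODONS)


class SaturationError(ValueError):
    """ps >= 3/4: the Jukes–Cantor correction is undefined."""


def ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    s sums, over the three positions, the fraction of viable one-step
    neighbours (stops excluded) encoding the same amino acid; n = 3 - s.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no NG86 site counts")
    if codon not in _AA:
        raise ValueError(f"not an unambiguous sense codon: {codon!r}")
    aa = _AA[codon]
    s = 0.0
    for pos in range(3):
        viable = syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1 :]
            if nb in STOP_CODONS:
                continue
            viable += 1
            if _AA[nb] == aa:
                syn += 1
        if viable:
            s += syn / viable
    return s, 3.0 - s


def ng86_differences(codon1: str, codon2: str) -> tuple[float, float] | None:
    """(synonymous, nonsynonymous) difference counts between two sense codons.

    Multi-base differences are averaged over all orderings of single-base
    steps whose intermediates are sense codons; returns None when every
    pathway passes through a stop codon (the pair must then be masked).
    """
    c1, c2 = codon1.upper(), codon2.upper()
    for c in (c1, c2):
        if c not in _AA:
            raise ValueError(f"not an unambiguous sense codon: {c!r}")
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    sd_total = nd_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _AA[cur] == _AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            sd_total += sd
            nd_total += nd
            n_paths += 1
    if n_paths == 0:
        return None
    return sd_total / n_paths, nd_total / n_paths


# ---------------------------------------------------------------------------
# precomputed lookup tables over the 64-codon index space

_S_ARR: np.ndarray | None = None
_N_ARR: np.ndarray | None = None
_SD_MAT: np.ndarray | None = None
_ND_MAT: np.ndarray | None = None


def _tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    global _S_ARR, _N_ARR, _SD_MAT, _ND_MAT
    if _S_ARR is None:
        s_arr = np.full(64, np.nan)
        n_arr = np.full(64, np.nan)
        sd = np.full((64, 64), np.nan)
        nd = np.full((64, 64), np.nan)
        for c1 in SENSE_CODONS:
            i = _codon_to_index(c1)
            s_arr[i], n_arr[i] = ng86_sites(c1)
            for c2 in SENSE_CODONS:
                j = _codon_to_index(c2)
                res = ng86_differences(c1, c2)
                if res is not None:
                    sd[i, j], nd[i, j] = res
        _S_ARR, _N_ARR, _SD_MAT, _ND_MAT = s_arr, n_arr, sd, nd
    return _S_ARR, _N_ARR, _SD_MAT, _ND_MAT


@dataclass
class KsResult:
    S: float  # synonymous sites (fractional)
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences
    ps: float  # Sd / S
    ks: float  # Jukes-Cantor corrected
    n_codons: int  # codons compared


@dataclass
class CodonAlignment:
    """A pairwise codon alignment with a per-codon exclusion mask."""

    seq1: str
    seq2: str
    mask: np.ndarray  # True = excluded codon column

    @classmethod
    def build(cls, row1: str, row2: str) -> "CodonAlignment":
        """Pairwise masking: exclude codon columns where either row has a
        gap, an ambiguous base, or a stop codon."""
        if len(row1) != len(row2):
            raise ValueError("aligned rows must have equal length")
        if len(row1) % 3 != 0:
            raise ValueError("aligned length must be a multiple of 3")
        n = len(row1) // 3
        mask = np.zeros(n, dtype=bool)
        for i in range(n):
            for row in (row1, row2):
                cod = row[3 * i : 3 * i + 3].upper()
                if any(b not in _BASES for b in cod) or cod in STOP_CODONS:
                    mask[i] = True
                    break
        return cls(seq1=row1.upper(), seq2=row2.upper(), mask=mask)

    def codon_indices(self) -> tuple[np.ndarray, np.ndarray]:
        idx1, idx2 = [], []
        for i in np.flatnonzero(~self.mask):
            idx1.append(_codon_to_index(self.seq1[3 * i : 3 * i + 3]))
            idx2.append(_codon_to_index(self.seq2[3 * i : 3 * i + 3]))
        return np.array(idx1, dtype=np.int64), np.array(idx2, dtype=np.int64)


def _ks_from_indices(idx1: np.ndarray, idx2: np.ndarray) -> KsResult:
    s_arr, n_arr, sd_mat, nd_mat = _tables()
    sd_vals = sd_mat[idx1, idx2]
    valid = ~np.isnan(sd_vals)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("dropped %d codon pairs with stop-only pathways", n_dropped)
    i1, i2 = idx1[valid], idx2[valid]
    if i1.size == 0:
        raise ValueError("no comparable codons")
    S = 0.5 * (s_arr[i1].sum() + s_arr[i2].sum())
    N = 0.5 * (n_arr[i1].sum() + n_arr[i2].sum())
    Sd = float(sd_mat[i1, i2].sum())
    Nd = float(nd_mat[i1, i2].sum())
    if S == 0:
        raise ValueError("zero synonymous sites")
    ps = Sd / S
    if ps >= 0.75:
        raise SaturationError(f"ps = {ps:.3f} >= 3/4: Ks undefined (saturation)")
    ks = -0.75 * math.log1p(-(4.0 / 3.0) * ps)
    return KsResult(S=float(S), N=float(N), Sd=Sd, Nd=Nd, ps=float(ps), ks=float(ks),
                    n_codons=int(i1.size))


def ks_pairwise(alignment: CodonAlignment) -> KsResult:
    """NG86 Ks for one pairwise codon alignment."""
    idx1, idx2 = alignment.codon_indices()
    if idx1.size == 0:
        raise ValueError("alignment has no unmasked codons")
    return _ks_from_indices(idx1, idx2)


def ks_between(seq1: str, seq2: str) -> KsResult:
    """Convenience wrapper: build the pairwise alignment, then Ks."""
    return ks_pairwise(CodonAlignment.build(seq1, seq2))


def ks_from_codon_indices(idx1: np.ndarray, idx2: np.ndarray) -> KsResult:
    """Ks directly from codon-index arrays (fast path for simulations)."""
    stops = np.array(sorted(STOP_INDICES))
    valid = ~(np.isin(idx1, stops) | np.isin(idx2, stops))
    return _ks_from_indices(np.asarray(idx1)[valid], np.asarray(idx2)[valid])


def backtranslate(
    protein_alignment: Mapping[str, str], cds_sequences: Mapping[str, str]
) -> dict[str, str]:
    """Thread each CDS onto its aligned protein row (PAL2NAL-style).

    Each protein residue expands to its source codon and each gap to
    ``---``; the CDS must translate exactly to the ungapped protein row
    (a trailing stop codon on the CDS is tolerated and dropped).
    """
    out: dict[str, str] = {}
    for sid, prot_row in protein_alignment.items():
        if sid not in cds_sequences:
            raise KeyError(f"no CDS for aligned protein {sid!r}")
        cds = cds_sequences[sid].upper()
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS {sid!r} length is not a multiple of 3")
        translated = str(Seq(cds).translate())
        if translated.endswith("*"):
            translated = translated[:-1]
            cds = cds[:-3]
        if "*" in translated:
            raise ValueError(
                f"CDS {sid!r} has an internal stop at codon {translated.index('*') + 1}"
            )
        ungapped = prot_row.replace("-", "")
        if translated != ungapped:
            for k, (a, b) in enumerate(zip(translated, ungapped)):
                if a != b:
                    raise ValueError(
                        f"translation mismatch for {sid!r} at residue {k + 1}: "
                        f"CDS gives {a!r}, alignment has {b!r}"
                    )
            raise ValueError(
                f"translation length mismatch for {sid!r}: "
                f"{len(translated)} vs {len(ungapped)} residues"
            )
        codons = []
        ci = 0
        for aa in prot_row:
            if aa == "-":
                codons.append("---")
            else:
                codons.append(cds[3 * ci : 3 * ci + 3])
                ci += 1
        out[sid] = "".join(codons)
    lengths = {len(v) for v in out.values()}
    if len(lengths) > 1:
        raise ValueError("aligned protein rows have unequal lengths")
    return out


@dataclass
class DatingConfig:
    mu: float = 6.5e-9  # substitutions / site / year
    decimals: int = 2

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")


def divergence_time(mean_ks: float, cfg: DatingConfig | None = None) -> float:
    """Clock conversion T = Ks / (2 mu), reported in Mya (half-up rounding)."""
    if cfg is None:
        cfg = DatingConfig()
    if mean_ks < 0:
        raise ValueError("mean Ks must be non-negative")
    mya = mean_ks / (2.0 * cfg.mu) / 1e6
    q = Decimal(1).scaleb(-cfg.decimals)
    return float(Decimal(repr(mya)).quantize(q, rounding=ROUND_HALF_UP))


def group_mean_ks(records: pd.DataFrame) -> pd.DataFrame:
    """Mean Ks per pair label, pooled over regions and per region.

    ``records`` needs columns ``label``, ``region`` and ``ks``.  The pooled
    mean is the arithmetic mean over all gene pairs of a label (so regions
    with more pairs weigh more, unlike an average of region means).
    """
    required = {"label", "region", "ks"}
    if not required <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    if records.empty:
        raise ValueError("no Ks records")
    pooled = (
        records.groupby("label")["ks"].agg(["mean", "count"]).reset_index()
    )
    pooled["region"] = "pooled"
    per_region = (
        records.groupby(["label", "region"])["ks"].agg(["mean", "count"]).reset_index()
    )
    out = pd.concat([pooled, per_region], ignore_index=True)[
        ["label", "region", "mean", "count"]
    ]
    return out.rename(columns={"mean": "mean_ks", "count": "n_pairs"})
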