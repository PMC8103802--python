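"""Independent brute-force oracles, written against the method
definitions only — they share no code with the package implementations."""

from __future__ import annotations

import itertools
import math

from Bio.Data import CodonTable

_tab = CodonTable.unambiguous_dna_by_id[1]
_AA = dict(_tab.forward_table)
_STOPS = set(_tab.stop_codons)
_BASES = "ACGT"


def bf_sites(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts by explicit neighbour listing."""
    aa = _AA[codon]
    s = 0.0
    for pos in range(3):
        neighbours = [
            codon[:pos] + b + codon[pos + 1 :]
            for b in _BASES
            if b != codon[pos]
        ]
        viable = [nb for nb in neighbours if nb not in _STOPS]
        if viable:
            s += sum(1 for nb in viable if _AA[nb] == aa) / len(viable)
    return s, 3.0 - s


def bf_differences(c1: str, c2: str):
    """Difference counts by explicit pathway enumeration; None when all
    pathways cross a stop codon."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(positions):
        cur, sd, nd, valid = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                valid = False
                break
            if _AA[cur] == _AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if valid:
            results.append((sd, nd))
    if not results:
        return None
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


def bf_ks(seq1: str, seq2: str):
    """Full brute-force NG86 Ks over two equal-length coding sequences.

    Codon pairs with gaps, ambiguity, stops, or stop-only pathways are
    skipped, mirroring the stated comparison rules.
    """
    assert len(seq1) == len(seq2) and len(seq1) % 3 == 0
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        a, b = seq1[i : i + 3].upper(), seq2[i : i + 3].upper()
        if any(ch not in _BASES for ch in a + b) or a in _STOPS or b in _STOPS:
            continue
        diffs = bf_differences(a, b)
        if diffs is None:
            continue
        sa = bf_sites(a)
        sb = bf_sites(b)
        S += (sa[0] + sb[0]) / 2
        N += (sa[1] + sb[1]) / 2
        Sd += diffs[0]
        Nd += diffs[1]
    ps = Sd / S
    ks = -0.75 * math.log(1 - (4.0 / 3.0) * ps)
    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "ps": ps, "ks": ks}


def bf_kmer_set(seq: str, k: int, drop_homopolymers: bool = True) -> set[str]:
    """All k-length substrings by nested scanning."""
    out = set()
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if any(c not in _BASES for c in km):
            continue
        if drop_homopolymers and len(set(km)) == 1:
            continue
        out.add(km)
    return out


def bf_symmetric_difference(s1: set[str], s2: set[str]) -> int:
    """Symmetric difference size by explicit membership scans."""
    n = 0
    for x in s1:
        if x not in s2:
            n += 1
    for x in s2:
        if x not in s1:
            n += 1
    return n
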