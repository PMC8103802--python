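"""Alignment-free phylogeny of haplotype segments from 30-mer profiles.

Each segment is decomposed into its distinct k-length substrings
(homopolymeric k-mers discarded); the distance between two segments is
the size of the symmetric difference of their k-mer sets, and the
resulting matrix feeds a neighbour-joining tree.  A single substitution
in otherwise identical non-repetitive sequences perturbs k overlapping
windows in each copy, so the expected distance is 2k per substitution at
low divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

logger = logging.getLogger(__name__)

__all__ = [
    "KmerConfig",
    "KmerProfile",
    "build_profile",
    "profile_distance",
    "distance_matrix",
    "nj_tree",
    "write_newick",
    "forms_clade",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class KmerConfig:
    k: int = 30
    drop_homopolymers: bool = True
    canonicalize_strand: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class KmerProfile:
    kmers: frozenset[str]
    k: int
    source_id: str
    source_length: int


def build_profile(
    seq: str, cfg: KmerConfig | None = None, source_id: str = ""
) -> KmerProfile:
    """Distinct k-mers of a sequence; windows containing N are skipped,
    homopolymeric k-mers dropped when configured."""
    if cfg is None:
        cfg = KmerConfig()
    s = seq.upper()
    k = cfg.k
    if k > len(s):
        logger.info("k=%d exceeds sequence length %d for %s", k, len(s), source_id)
    kmers: set[str] = set()
    for i in range(len(s) - k + 1):
        km = s[i : i + k]
        if any(b not in "ACGT" for b in km):
            continue
        if cfg.drop_homopolymers and km == km[0] * k:
            continue
        if cfg.canonicalize_strand:
            km = min(km, km.translate(_COMPLEMENT)[::-1])
        kmers.add(km)
    return KmerProfile(
        kmers=frozenset(kmers), k=k, source_id=source_id, source_length=len(s)
    )


def profile_distance(p: KmerProfile, q: KmerProfile, normalized: bool = False) -> float:
    """Number of k-mers found in one profile but not the other."""
    if p.k != q.k:
        raise ValueError(f"mismatched k: {p.k} vs {q.k}")
    d = len(p.kmers ^ q.kmers)
    if normalized:
        tot = len(p.kmers) + len(q.kmers)
        return d / tot if tot else 0.0
    return float(d)


def distance_matrix(
    profiles: Sequence[KmerProfile], normalized: bool = False
) -> DistanceMatrix:
    ids = [p.source_id for p in profiles]
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = profile_distance(profiles[i], profiles[j], normalized)
    return DistanceMatrix(d, ids=ids)


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Neighbour-joining tree (Saitou–Nei criterion, Studier–Keppler
    updates); negative branch lengths are clamped to zero."""
    if matrix.shape[0] < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    return nj(matrix, neg_as_zero=True)


def write_newick(tree: TreeNode, path: Path) -> Path:
    path = Path(path)
    tree.write(str(path), format="newick")
    return path


def forms_clade(tree: TreeNode, names: Iterable[str]) -> bool:
    """True when some edge of the (unrooted) tree bipartitions the leaves
    into ``names`` versus the rest."""
    target = set(names)
    all_names = {t.name for t in tree.tips()}
    if not target or not target <= all_names:
        return False
    for node in tree.traverse(include_self=True):
        leaves = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        if leaves == target or all_names - leaves == target:
            return True
    return False
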