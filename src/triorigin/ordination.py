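"""SNP dissimilarity and principal-coordinates ordination of accessions.

The dissimilarity between two accessions is the proportion of mismatching
presence/absence calls over sites where both are genotyped.  Classical
metric multidimensional scaling (principal coordinates) of this matrix
separates the two germplasm pools on the first axis; accessions falling
between the pools' axis-1 envelopes are flagged as putative interspecific
hybrids for review, so they can be excluded from the pool representatives
used by the specificity analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .variants import GenotypeCall, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DissimilarityMatrix",
    "OrdinationResult",
    "snp_dissimilarity",
    "pcoa",
    "flag_intermediates",
]


@dataclass
class DissimilarityMatrix:
    d: pd.DataFrame           # values in [0, 1]; NaN when no shared sites
    n_compared: pd.DataFrame  # co-non-missing site counts per pair
    flagged_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return list(self.d.index)


def snp_dissimilarity(gm: GenotypeMatrix, min_compared: int = 1) -> DissimilarityMatrix:
    """Pairwise mismatch proportion over co-genotyped sites."""
    ids = gm.accessions
    if len(ids) < 2:
        raise ValueError("need at least two accessions")
    X = gm.calls.to_numpy(dtype=float)
    X[X == int(GenotypeCall.MISSING)] = np.nan
    n = len(ids)
    d = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    flagged = []
    for i in range(n):
        counts[i, i] = int(np.isfinite(X[:, i]).sum())
        for j in range(i + 1, n):
            both = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            m = int(both.sum())
            counts[i, j] = counts[j, i] = m
            if m == 0:
                d[i, j] = d[j, i] = np.nan
                flagged.append((ids[i], ids[j]))
            else:
                val = float(np.abs(X[both, i] - X[both, j]).mean())
                d[i, j] = d[j, i] = val
                if m < min_compared:
                    flagged.append((ids[i], ids[j]))
    if flagged:
        logger.info("%d accession pairs below the compared-site minimum", len(flagged))
    return DissimilarityMatrix(
        d=pd.DataFrame(d, index=ids, columns=ids),
        n_compared=pd.DataFrame(counts, index=ids, columns=ids),
        flagged_pairs=flagged,
    )


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame        # accessions x retained axes
    eigvals: pd.Series               # positive eigenvalues, decreasing
    proportion_explained: pd.Series  # of the positive inertia
    negative_inertia: float          # |sum of negative eigenvalues|


def pcoa(dm: DissimilarityMatrix, m: int = 2) -> OrdinationResult:
    """Classical scaling (principal coordinates) of the dissimilarity.

    Missing pairs are imputed with the mean of each member's observed
    dissimilarities (logged); axes with negative eigenvalues are dropped
    and their total magnitude reported.
    """
    vals = dm.d.to_numpy(dtype=float).copy()
    ids = dm.ids
    if np.isnan(vals).any():
        n_imputed = int(np.isnan(vals[np.triu_indices_from(vals, 1)]).sum())
        logger.info("imputing %d missing dissimilarities with row/column means", n_imputed)
        for i, j in zip(*np.where(np.isnan(vals))):
            ri = np.nanmean(vals[i]) if np.isfinite(vals[i]).any() else 0.0
            rj = np.nanmean(vals[:, j]) if np.isfinite(vals[:, j]).any() else 0.0
            vals[i, j] = 0.5 * (ri + rj)
        vals = 0.5 * (vals + vals.T)
        np.fill_diagonal(vals, 0.0)

    # negative inertia from the double-centred Gower matrix spectrum
    A = -0.5 * vals**2
    n = len(ids)
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    eig = np.linalg.eigvalsh(G)
    negative_inertia = float(-eig[eig < -1e-12].sum())

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(SkbioDistanceMatrix(vals, ids=ids))
    eigvals = res.eigvals[res.eigvals > 1e-12]
    n_pos = len(eigvals)
    if m > n_pos:
        logger.warning("requested %d axes but only %d positive; truncating", m, n_pos)
        m = n_pos
    coords = res.samples.iloc[:, :n_pos]
    coords.index = ids
    prop = res.proportion_explained[: n_pos]
    total = eigvals.sum()
    prop = eigvals / total if total > 0 else prop
    return OrdinationResult(
        coordinates=coords.iloc[:, : max(m, n_pos) if m == 0 else n_pos],
        eigvals=eigvals,
        proportion_explained=prop,
        negative_inertia=negative_inertia,
    )


def flag_intermediates(
    result: OrdinationResult,
    pools: pd.Series,
    axis: int = 0,
    margin: float = 0.0,
) -> list[str]:
    """Accessions whose axis-1 coordinate falls strictly between the two
    pools' coordinate envelopes — candidate hybrids, returned for review.

    ``pools`` maps accession id to a pool label; labels other than the two
    pool names (or missing accessions) are still screened but never define
    an envelope.  ``margin`` shrinks each envelope to the central
    [margin, 1 - margin] quantile range.
    """
    coords = result.coordinates.iloc[:, axis]
    pool_names = sorted(set(pools.dropna()) & {"offrob", "spont"})
    if len(pool_names) < 2:
        return []
    envelopes = {}
    for p in pool_names:
        members = [a for a in pools.index if pools[a] == p and a in coords.index]
        if not members:
            return []
        v = coords.loc[members]
        envelopes[p] = (float(v.quantile(margin)), float(v.quantile(1 - margin)))
    lo_pool, hi_pool = sorted(pool_names, key=lambda p: envelopes[p][0])
    gap = (envelopes[lo_pool][1], envelopes[hi_pool][0])
    if gap[0] >= gap[1]:
        logger.info("pool envelopes overlap on axis %d; nothing flagged", axis + 1)
        return []
    flagged = [a for a in coords.index if gap[0] < coords[a] < gap[1]]
    return sorted(flagged)
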