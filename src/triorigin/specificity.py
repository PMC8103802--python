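"""Haplotype-group- and germplasm-pool-specific SNP classification.

The origin of the three haplotype groups (A, B, C) is inferred by two
reciprocal analyses.  First, SNPs carried by haplotypes of exactly one
group (with every group contributing at least one covered haplotype at the
site) are located among accessions representative of the two germplasm
pools (officinarum/robustum vs spontaneum): a group-specific SNP carried
by >= min_carriers accessions of one pool and absent from the other is
evidence that the group derives from that pool, while carriage in both
pools marks an ancestral polymorphism.  Second, SNPs specific to one pool
are mapped back onto the haplotype panel to see which groups carry them.
Both cross-tabulations must point to the same pool for a verdict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import GenotypeCall, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GROUP_LABELS",
    "POOL_LABELS",
    "HaplotypePanel",
    "SpecificityConfig",
    "find_group_specific_snps",
    "assign_group_snp_origin",
    "find_pool_specific_snps",
    "map_pool_snps_to_haplotypes",
    "infer_group_origin",
    "apply_exclusions",
]

GROUPS = ("A", "B", "C")
GROUP_LABELS = ("GROUP_A", "GROUP_B", "GROUP_C")
POOLS = ("offrob", "spont")
POOL_LABELS = {"offrob": "POOL_OFFROB", "spont": "POOL_SPONT"}
UNINFORMATIVE = "UNINFORMATIVE"
ANCESTRAL = "ANCESTRAL"


@dataclass
class HaplotypePanel:
    """Per-haplotype variant presence and coverage at reference sites.

    ``presence`` and ``covered`` are boolean DataFrames (sites x
    haplotypes); ``groups`` maps haplotype id to its group label.
    """

    presence: pd.DataFrame
    covered: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        for df in (self.presence, self.covered):
            df.index.name = "site_id"
        if not self.presence.index.equals(self.covered.index) or not (
            self.presence.columns.equals(self.covered.columns)
        ):
            raise ValueError("presence and covered must share shape and labels")
        if (self.presence & ~self.covered).any().any():
            raise ValueError("variant_present implies covered")
        missing = set(self.presence.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"haplotypes without a group label: {sorted(missing)}")
        for g in GROUPS:
            if (self.groups == g).sum() < 1:
                raise ValueError(f"haplotype group {g} has no haplotypes")

    @property
    def haplotypes(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def site_ids(self) -> list[str]:
        return list(self.presence.index)

    def to_tsv(self, path: Path) -> Path:
        """1 = covered & carries the variant, 0 = covered & reference,
        NA = site not covered by that haplotype's BAC."""
        codes = self.presence.astype(int).astype("object").where(self.covered, other=pd.NA)
        with open(path, "w") as fh:
            for hap in self.presence.columns:
                fh.write(f"#group\t{hap}\t{self.groups[hap]}\n")
            codes.to_csv(fh, sep="\t", index_label="site_id", na_rep="NA")
        return Path(path)

    @classmethod
    def from_tsv(cls, path: Path) -> "HaplotypePanel":
        groups = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#group\t"):
                _, hap, grp = line.rstrip("\n").split("\t")
                groups[hap] = grp
                body_start = i + 1
            else:
                break
        from io import StringIO

        df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t",
                         index_col="site_id")
        covered = df.notna()
        presence = df.fillna(0).astype(float).astype(bool)
        return cls(presence=presence, covered=covered,
                   groups=pd.Series(groups, name="group"))


@dataclass
class SpecificityConfig:
    min_carriers: int = 2       # accessions carrying a pool-diagnostic SNP
    min_pool_data: int = 5      # accessions with data required in each pool
    min_group_coverage: int = 1  # covered haplotypes required per group
    max_exceptions: int = 1     # contradicting SNPs tolerated per verdict

    def __post_init__(self) -> None:
        if min(self.min_carriers, self.min_pool_data, self.min_group_coverage) < 1:
            raise ValueError("specificity thresholds must be >= 1")


def find_group_specific_snps(
    panel: HaplotypePanel, cfg: SpecificityConfig | None = None
) -> pd.DataFrame:
    """Label each panel site GROUP_A/B/C or UNINFORMATIVE.

    A site is group-specific when every group has >= min_group_coverage
    covered haplotypes there and the variant is present in >= 1 haplotype
    of exactly one group (uncovered haplotypes do not veto).
    """
    if cfg is None:
        cfg = SpecificityConfig()
    cols: dict[str, pd.Series] = {}
    for g in GROUPS:
        haps = panel.groups.index[panel.groups == g]
        haps = [h for h in haps if h in panel.presence.columns]
        cols[f"covered_{g}"] = panel.covered[haps].sum(axis=1)
        cols[f"carriers_{g}"] = panel.presence[haps].sum(axis=1)
    df = pd.DataFrame(cols, index=panel.presence.index)
    covered_ok = np.logical_and.reduce(
        [df[f"covered_{g}"] >= cfg.min_group_coverage for g in GROUPS]
    )
    carrier_flags = np.stack([df[f"carriers_{g}"] > 0 for g in GROUPS], axis=1)
    n_groups_with_carriers = carrier_flags.sum(axis=1)
    label = np.full(len(df), UNINFORMATIVE, dtype=object)
    single = covered_ok & (n_groups_with_carriers == 1)
    which = carrier_flags.argmax(axis=1)
    for gi, g in enumerate(GROUPS):
        label[single & (which == gi)] = f"GROUP_{g}"
    df.insert(0, "label", label)
    df.index.name = "site_id"
    return df


def _pool_counts(
    gm: GenotypeMatrix, pools: pd.Series, site_ids: Sequence[str]
) -> dict[str, pd.DataFrame]:
    """Per-pool carrier and with-data counts for the requested sites."""
    out = {}
    calls = gm.calls.loc[list(site_ids)]
    for pool in POOLS:
        members = [a for a in pools.index if pools[a] == pool and a in calls.columns]
        if not members:
            raise ValueError(f"pool {pool!r} has no representative accessions")
        sub = calls[members]
        out[pool] = pd.DataFrame(
            {
                "carriers": (sub == int(GenotypeCall.VARIANT_PRESENT)).sum(axis=1),
                "with_data": (sub != int(GenotypeCall.MISSING)).sum(axis=1),
            }
        )
    return out


def assign_group_snp_origin(
    group_snps: pd.DataFrame,
    gm: GenotypeMatrix,
    pools: pd.Series,
    cfg: SpecificityConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Locate each group-specific SNP in the germplasm pools.

    Labels: POOL_OFFROB / POOL_SPONT (>= min_carriers in exactly one pool,
    zero carriers in the other), ANCESTRAL (>= min_carriers in both), or
    UNINFORMATIVE (insufficient data or carriers).  Sites must have data
    in >= min_pool_data accessions of both pools to be classified.
    Returns the annotated per-SNP table and the group x pool-origin
    cross-tabulation.
    """
    if cfg is None:
        cfg = SpecificityConfig()
    specific = group_snps[group_snps["label"].isin(GROUP_LABELS)].copy()
    keep = [s for s in specific.index if s in gm.calls.index]
    dropped = len(specific) - len(keep)
    if dropped:
        logger.info("%d group-specific SNPs absent from the genotype matrix", dropped)
    specific = specific.loc[keep]
    counts = _pool_counts(gm, pools, specific.index)
    c_off, c_sp = counts["offrob"], counts["spont"]
    specific["carriers_offrob"] = c_off["carriers"]
    specific["data_offrob"] = c_off["with_data"]
    specific["carriers_spont"] = c_sp["carriers"]
    specific["data_spont"] = c_sp["with_data"]

    enough = (c_off["with_data"] >= cfg.min_pool_data) & (
        c_sp["with_data"] >= cfg.min_pool_data
    )
    off_only = (c_off["carriers"] >= cfg.min_carriers) & (c_sp["carriers"] == 0)
    sp_only = (c_sp["carriers"] >= cfg.min_carriers) & (c_off["carriers"] == 0)
    both = (c_off["carriers"] >= cfg.min_carriers) & (
        c_sp["carriers"] >= cfg.min_carriers
    )
    pool_label = np.full(len(specific), UNINFORMATIVE, dtype=object)
    pool_label[(enough & off_only).to_numpy()] = POOL_LABELS["offrob"]
    pool_label[(enough & sp_only).to_numpy()] = POOL_LABELS["spont"]
    pool_label[(enough & both).to_numpy()] = ANCESTRAL
    specific["pool_label"] = pool_label

    rows = []
    for g in GROUPS:
        sub = specific[specific["label"] == f"GROUP_{g}"]
        off = int((sub["pool_label"] == POOL_LABELS["offrob"]).sum())
        sp = int((sub["pool_label"] == POOL_LABELS["spont"]).sum())
        anc = int((sub["pool_label"] == ANCESTRAL).sum())
        rows.append({"group": g, "offrob_only": off, "spont_only": sp,
                     "both_pools": anc, "total": off + sp + anc})
    table = pd.DataFrame(rows).set_index("group")
    table.loc["Total"] = table.sum()
    return specific, table


def find_pool_specific_snps(
    gm: GenotypeMatrix, pools: pd.Series, cfg: SpecificityConfig | None = None
) -> pd.DataFrame:
    """Label every genotyped site POOL_OFFROB / POOL_SPONT / UNINFORMATIVE.

    Symmetric rule: >= min_carriers carriers in one pool, zero in the
    other, and data in >= min_pool_data accessions of both pools.
    """
    if cfg is None:
        cfg = SpecificityConfig()
    counts = _pool_counts(gm, pools, gm.site_ids)
    c_off, c_sp = counts["offrob"], counts["spont"]
    df = pd.DataFrame(
        {
            "carriers_offrob": c_off["carriers"],
            "data_offrob": c_off["with_data"],
            "carriers_spont": c_sp["carriers"],
            "data_spont": c_sp["with_data"],
        },
        index=gm.calls.index,
    )
    enough = (c_off["with_data"] >= cfg.min_pool_data) & (
        c_sp["with_data"] >= cfg.min_pool_data
    )
    off_only = (c_off["carriers"] >= cfg.min_carriers) & (c_sp["carriers"] == 0)
    sp_only = (c_sp["carriers"] >= cfg.min_carriers) & (c_off["carriers"] == 0)
    label = np.full(len(df), UNINFORMATIVE, dtype=object)
    label[(enough & off_only).to_numpy()] = POOL_LABELS["offrob"]
    label[(enough & sp_only).to_numpy()] = POOL_LABELS["spont"]
    df.insert(0, "label", label)
    df.index.name = "site_id"
    return df


_COMBO_COLUMNS = ("A", "B", "A_and_B", "C", "other")


def map_pool_snps_to_haplotypes(
    pool_snps: pd.DataFrame, panel: HaplotypePanel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distribute pool-specific SNPs over the haplotype groups.

    Each pool-specific SNP is assigned the combination of groups whose
    covered haplotypes carry it (A, B, A_and_B, C; anything else under
    ``other``); SNPs at sites carried by no covered haplotype are
    excluded and logged.  Returns the annotated table and the pool x
    group-combination cross-tabulation.
    """
    specific = pool_snps[pool_snps["label"].isin(POOL_LABELS.values())].copy()
    combos = []
    n_excluded = 0
    group_of = panel.groups
    for site in specific.index:
        if site not in panel.presence.index:
            combos.append(None)
            n_excluded += 1
            continue
        pres = panel.presence.loc[site]
        cov = panel.covered.loc[site]
        carrier_groups = sorted(
            {group_of[h] for h in panel.haplotypes if cov[h] and pres[h]}
        )
        if not carrier_groups:
            combos.append(None)
            n_excluded += 1
        elif carrier_groups == ["A"]:
            combos.append("A")
        elif carrier_groups == ["B"]:
            combos.append("B")
        elif carrier_groups == ["A", "B"]:
            combos.append("A_and_B")
        elif carrier_groups == ["C"]:
            combos.append("C")
        else:
            combos.append("other")
    if n_excluded:
        logger.info(
            "%d pool-specific SNPs carried by no covered haplotype; excluded",
            n_excluded,
        )
    specific["group_combo"] = combos
    kept = specific[specific["group_combo"].notna()]
    rows = []
    for pool in POOLS:
        sub = kept[kept["label"] == POOL_LABELS[pool]]
        row = {"pool": pool}
        for col in _COMBO_COLUMNS:
            row[col] = int((sub["group_combo"] == col).sum())
        row["total"] = int(len(sub))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("pool")
    table.loc["Total"] = table.sum()
    return specific, table


def infer_group_origin(
    group_table: pd.DataFrame,
    pool_table: pd.DataFrame,
    cfg: SpecificityConfig | None = None,
) -> dict[str, dict]:
    """Per-group origin verdict from the two reciprocal cross-tabs.

    A group is assigned a pool when both analyses give it a strictly
    greater supporting count there; minority SNPs are reported as
    exceptions, and more than ``max_exceptions`` of them flags a
    conflict.  Ties or disagreements yield UNRESOLVED.  In the second
    analysis the ``A_and_B`` column supports groups A and B alike.
    """
    if cfg is None:
        cfg = SpecificityConfig()
    verdicts: dict[str, dict] = {}
    for g in GROUPS:
        s1 = {
            "offrob": int(group_table.loc[g, "offrob_only"]),
            "spont": int(group_table.loc[g, "spont_only"]),
        }
        col = g if g in ("A", "C") else "B"
        s2 = {
            p: int(pool_table.loc[p, col])
            + (int(pool_table.loc[p, "A_and_B"]) if g in ("A", "B") else 0)
            for p in POOLS
        }
        winners = []
        for s in (s1, s2):
            if s["offrob"] > s["spont"]:
                winners.append("offrob")
            elif s["spont"] > s["offrob"]:
                winners.append("spont")
            else:
                winners.append(None)
        if winners[0] is not None and winners[0] == winners[1]:
            verdict = "OFFROB" if winners[0] == "offrob" else "SPONT"
            loser = "spont" if winners[0] == "offrob" else "offrob"
            exceptions = s1[loser] + s2[loser]
        else:
            verdict, exceptions = "UNRESOLVED", 0
        verdicts[g] = {
            "verdict": verdict,
            "support_group_analysis": s1,
            "support_pool_analysis": s2,
            "exceptions": exceptions,
            "conflict": exceptions > cfg.max_exceptions,
        }
    return verdicts


def apply_exclusions(pools: pd.Series, exclude: Iterable[str]) -> pd.Series:
    """Drop flagged hybrid accessions from the pool-representative map."""
    exclude = set(exclude)
    kept = pools[~pools.index.isin(exclude)]
    kept = kept[kept.isin(POOLS)]
    return kept
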