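"""Simulation of diverging founder genomes and polyploid accession panels.

Three founder lineages (A, B, C) diverge on the fixed topology ((A,B),C)
under a molecular clock: substitutions accumulate on each branch as a
Poisson process with expectation ``T_branch * mu * L``.  Polyploid
accessions are haplotype multisets over the founders (e.g. a modern
cultivar carrying 9 A : 2 B : 1 C copies), germplasm pools group species
classes (officinarum/robustum carry A+B, spontaneum carries C), and
per-site allele depths mimic short-read counts against a monoploid
reference.  Every planted substitution is recorded in a truth registry so
downstream classification can be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LINEAGES",
    "SimulationConfig",
    "RegistryVariant",
    "FounderGenomes",
    "SiteVariant",
    "Accession",
    "AccessionSet",
    "DepthData",
    "simulate_founders",
    "registry_from_sequences",
    "simulate_accessions",
    "simulate_allele_depths",
    "simulate_gene_families",
    "simulate_coding_pair",
    "simulate_haplotype_segments",
    "write_fixture",
]

LINEAGES = ("A", "B", "C")

#: per-branch carrier sets on the fixed ((A,B),C) topology
_BRANCH_CARRIERS = {
    "A": frozenset({"A"}),
    "B": frozenset({"B"}),
    "AB": frozenset({"A", "B"}),
    "C": frozenset({"C"}),
}

_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_PLOIDY: dict[str, dict[str, int]] = {
    "officinarum": {"A": 6, "B": 2},
    "robustum": {"A": 6, "B": 2},
    "spontaneum": {"C": 8},
    "cultivar": {"A": 9, "B": 2, "C": 1},
}
DEFAULT_POOL_OF_CLASS = {
    "officinarum": "offrob",
    "robustum": "offrob",
    "spontaneum": "spont",
    "cultivar": "hybrid",
}
DEFAULT_POOL_SIZES = {"officinarum": 4, "robustum": 2, "spontaneum": 6, "cultivar": 1}


@dataclass
class SimulationConfig:
    """Parameters of the founder-divergence study conditions.

    mu is the per-site per-year substitution rate (6.5e-9, the grass
    synonymous clock); t_split_ab and t_split_abc are the A/B and (A,B)/C
    split ages in years (0.84 and 1.29 Mya).
    """

    seed: int = 0
    genome_length: int = 50_000
    n_genes: int = 20
    gene_length: int = 900
    mu: float = 6.5e-9
    t_split_ab: float = 0.84e6
    t_split_abc: float = 1.29e6
    pool_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_POOL_SIZES))
    ploidy_spec: dict[str, dict[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PLOIDY.items()}
    )
    pool_of_class: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_POOL_OF_CLASS)
    )
    within_pool_theta: float = 1e-3
    depth_mean: float = 60.0
    depth_dispersion: float = 0.2
    error_rate: float = 1e-3
    reference: str = "ancestral"  # "ancestral" or "A"
    panel_class: str = "cultivar"

    def __post_init__(self) -> None:
        if self.gene_length % 3 != 0:
            raise ValueError("gene_length must be a multiple of 3")
        if not (self.t_split_abc >= self.t_split_ab >= 0):
            raise ValueError("need t_split_abc >= t_split_ab >= 0")
        for name in ("within_pool_theta", "error_rate"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.reference not in ("ancestral", "A"):
            raise ValueError("reference must be 'ancestral' or 'A'")
        unknown = set(self.ploidy_spec) ^ set(self.pool_sizes)
        if unknown - set(self.ploidy_spec) or unknown - set(self.pool_sizes):
            raise ValueError(f"pool_sizes/ploidy_spec class mismatch: {sorted(unknown)}")


@dataclass(frozen=True)
class RegistryVariant:
    """A substitution planted on one branch of the founder topology."""

    pos: int  # 0-based on the simulated genome
    ancestral: str
    derived: str
    carriers: frozenset[str]  # lineages carrying the derived allele
    branch: str


@dataclass
class FounderGenomes:
    ancestral: str
    sequences: dict[str, str]
    registry: list[RegistryVariant]

    @property
    def length(self) -> int:
        return len(self.ancestral)

    def reference_sequence(self, reference: str = "ancestral") -> str:
        if reference == "ancestral":
            return self.ancestral
        return self.sequences[reference]

    def to_ref_variants(self, reference: str = "ancestral") -> list["SiteVariant"]:
        """Express the registry relative to the chosen mapping reference.

        A substitution carried by the reference lineage itself flips: the
        observable ALT is then the ancestral base, carried by the
        complementary lineages.
        """
        out = []
        for rv in self.registry:
            if reference != "ancestral" and reference in rv.carriers:
                ref, alt = rv.derived, rv.ancestral
                alt_lineages = frozenset(LINEAGES) - rv.carriers
            else:
                ref, alt = rv.ancestral, rv.derived
                alt_lineages = rv.carriers
            if not alt_lineages:
                continue  # allele fixed in every lineage relative to reference
            out.append(
                SiteVariant(
                    pos=rv.pos,
                    ref=ref,
                    alt=alt,
                    alt_lineages=alt_lineages,
                    origin=f"founder:{rv.branch}",
                )
            )
        return out


@dataclass(frozen=True)
class SiteVariant:
    """A biallelic site expressed relative to the mapping reference."""

    pos: int  # 0-based
    ref: str
    alt: str
    alt_lineages: frozenset[str]  # empty for within-pool (non-founder) variants
    origin: str

    @property
    def site_id(self) -> str:
        return f"chr1:{self.pos + 1}:{self.ref}>{self.alt}"


@dataclass
class Accession:
    accession_id: str
    species: str
    pool: str
    haplotypes: dict[str, int]  # lineage -> copy number
    extra_dosage: dict[int, int] = field(default_factory=dict)  # variant index -> copies

    @property
    def total_copies(self) -> int:
        return sum(self.haplotypes.values())


@dataclass
class AccessionSet:
    accessions: list[Accession]
    variants: list[SiteVariant]
    reference: str  # reference sequence string

    @property
    def sample_ids(self) -> list[str]:
        return [a.accession_id for a in self.accessions]

    def dosage_matrix(self) -> np.ndarray:
        """(n_sites, n_accessions) count of haplotype copies carrying ALT."""
        n_sites, n_acc = len(self.variants), len(self.accessions)
        dos = np.zeros((n_sites, n_acc), dtype=np.int64)
        for j, acc in enumerate(self.accessions):
            for i, var in enumerate(self.variants):
                d = sum(acc.haplotypes.get(l, 0) for l in var.alt_lineages)
                d += acc.extra_dosage.get(i, 0)
                dos[i, j] = d
        return dos


@dataclass
class DepthData:
    sites: pd.DataFrame  # chrom, pos (1-based), ref, alt, site_id
    sample_ids: list[str]
    depth: np.ndarray  # (n_sites, n_samples)
    alt_count: np.ndarray

    @property
    def ref_count(self) -> np.ndarray:
        return self.depth - self.alt_count


def _idx_to_seq(idx: np.ndarray) -> str:
    return _BASE_LUT[idx].tobytes().decode("ascii")


def _branch_times(config: SimulationConfig) -> dict[str, float]:
    return {
        "A": config.t_split_ab,
        "B": config.t_split_ab,
        "AB": config.t_split_abc - config.t_split_ab,
        "C": config.t_split_abc,
    }


def simulate_founders(config: SimulationConfig) -> FounderGenomes:
    """Plant Poisson substitutions on each branch of ((A,B),C).

    Positions are drawn without replacement across all branches, so no site
    is hit twice and the registry diffs back exactly; saturation (expected
    substitutions reaching the number of sites) is an error rather than a
    modelled regime.
    """
    L = config.genome_length
    if L <= 0:
        raise ValueError("genome_length must be positive")
    times = _branch_times(config)
    expected = config.mu * L * sum(times.values())
    if expected >= L:
        raise ValueError(
            f"expected substitutions ({expected:.0f}) >= sites ({L}): saturated"
        )
    rng = np.random.default_rng(config.seed)
    anc = rng.integers(0, 4, size=L, dtype=np.int64)
    branches = ["A", "B", "AB", "C"]
    counts = {b: int(rng.poisson(config.mu * L * times[b])) for b in branches}
    total = sum(counts.values())
    if total >= L:
        raise ValueError("realized substitutions >= sites: saturated")
    positions = rng.choice(L, size=total, replace=False)
    shifts = rng.integers(1, 4, size=total)

    registry: list[RegistryVariant] = []
    seqs = {lin: anc.copy() for lin in LINEAGES}
    k = 0
    for b in branches:
        carriers = _BRANCH_CARRIERS[b]
        for _ in range(counts[b]):
            pos = int(positions[k])
            derived = int((anc[pos] + shifts[k]) % 4)
            for lin in carriers:
                seqs[lin][pos] = derived
            registry.append(
                RegistryVariant(
                    pos=pos,
                    ancestral="ACGT"[anc[pos]],
                    derived="ACGT"[derived],
                    carriers=carriers,
                    branch=b,
                )
            )
            k += 1
    registry.sort(key=lambda r: r.pos)
    return FounderGenomes(
        ancestral=_idx_to_seq(anc),
        sequences={lin: _idx_to_seq(seqs[lin]) for lin in LINEAGES},
        registry=registry,
    )


def registry_from_sequences(founders: FounderGenomes) -> list[RegistryVariant]:
    """Re-derive the registry by diffing sequences (test oracle)."""
    out = []
    anc = founders.ancestral
    for pos in range(len(anc)):
        carriers = frozenset(
            lin for lin in LINEAGES if founders.sequences[lin][pos] != anc[pos]
        )
        if not carriers:
            continue
        derived = {founders.sequences[lin][pos] for lin in carriers}
        if len(derived) != 1:  # pragma: no cover - never under single-hit placement
            raise AssertionError(f"multiple derived alleles at {pos}")
        branch = {
            frozenset({"A"}): "A",
            frozenset({"B"}): "B",
            frozenset({"A", "B"}): "AB",
            frozenset({"C"}): "C",
        }[carriers]
        out.append(
            RegistryVariant(pos, anc[pos], derived.pop(), carriers, branch)
        )
    return out


def simulate_accessions(
    founders: FounderGenomes, config: SimulationConfig
) -> AccessionSet:
    """Build accessions as haplotype multisets plus within-pool mutations.

    Within-pool polymorphism: for each species class, Poisson(theta * L)
    extra sites are mutated, each private to a random non-empty subset of
    that class's accessions and to a random number of copies of one founder
    lineage — enough structure to make pool representatives polymorphic
    without modelling a full coalescent.
    """
    rng = np.random.default_rng([1, config.seed])
    ref = founders.reference_sequence(config.reference)
    variants = founders.to_ref_variants(config.reference)

    accessions: list[Accession] = []
    for cls in sorted(config.pool_sizes):
        multiset = {l: int(n) for l, n in config.ploidy_spec[cls].items() if n > 0}
        if not multiset:
            raise ValueError(f"class {cls!r} has an empty haplotype multiset")
        for i in range(config.pool_sizes[cls]):
            accessions.append(
                Accession(
                    accession_id=f"{cls}_{i + 1:02d}",
                    species=cls,
                    pool=config.pool_of_class.get(cls, "none"),
                    haplotypes=dict(multiset),
                )
            )

    extra_variants: list[SiteVariant] = []
    extra_carriers: list[dict[int, int]] = []  # accession index -> copies
    if config.within_pool_theta > 0:
        used = {v.pos for v in variants}
        free = np.setdiff1d(
            np.arange(founders.length), np.fromiter(used, dtype=np.int64, count=len(used))
        )
        rng.shuffle(free)
        cursor = 0
        acc_by_class: dict[str, list[int]] = {}
        for j, acc in enumerate(accessions):
            acc_by_class.setdefault(acc.species, []).append(j)
        for cls in sorted(acc_by_class):
            members = acc_by_class[cls]
            multiset = {l: n for l, n in config.ploidy_spec[cls].items() if n > 0}
            lineages = sorted(multiset)
            weights = np.array([multiset[l] for l in lineages], dtype=float)
            weights /= weights.sum()
            n_poly = int(rng.poisson(config.within_pool_theta * founders.length))
            n_poly = min(n_poly, len(free) - cursor)
            for _ in range(n_poly):
                pos = int(free[cursor])
                cursor += 1
                lin = lineages[int(rng.choice(len(lineages), p=weights))]
                alt = "ACGT"[("ACGT".index(ref[pos]) + int(rng.integers(1, 4))) % 4]
                take = rng.random(len(members)) < 0.5
                if not take.any():
                    take[int(rng.integers(len(members)))] = True
                carriers = {}
                for m, flag in zip(members, take):
                    if flag:
                        carriers[m] = int(rng.integers(1, multiset[lin] + 1))
                extra_variants.append(
                    SiteVariant(pos, ref[pos], alt, frozenset(), f"within:{cls}")
                )
                extra_carriers.append(carriers)

    all_variants = variants + extra_variants
    order = sorted(range(len(all_variants)), key=lambda i: (all_variants[i].pos, all_variants[i].alt))
    all_variants = [all_variants[i] for i in order]
    # remap within-pool carrier dosages to the sorted variant indices
    new_index = {old: new for new, old in enumerate(order)}
    for old_i, carriers in enumerate(extra_carriers):
        vi = new_index[len(variants) + old_i]
        for acc_j, copies in carriers.items():
            accessions[acc_j].extra_dosage[vi] = copies
    return AccessionSet(accessions=accessions, variants=all_variants, reference=ref)


def simulate_allele_depths(
    accessions: AccessionSet, config: SimulationConfig
) -> DepthData:
    """Draw per-site depths and alt read counts for every accession.

    Depth is negative-binomial with mean ``depth_mean`` and variance
    ``m + d m^2`` (Poisson when the dispersion d is 0); alt reads are
    binomial with success probability equal to the alt-haplotype dosage
    fraction, perturbed by the per-read error rate (a true-alt read
    misread with probability e, a non-alt read misread to this alt with
    probability e/3).
    """
    if config.depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    rng = np.random.default_rng([2, config.seed])
    dos = accessions.dosage_matrix()
    totals = np.array([a.total_copies for a in accessions.accessions], dtype=float)
    p = dos / totals[None, :]
    e = config.error_rate
    p_eff = p * (1 - e) + (1 - p) * e / 3.0

    shape = dos.shape
    m, d = config.depth_mean, config.depth_dispersion
    if d > 0:
        n = 1.0 / d
        depth = rng.negative_binomial(n, n / (n + m), size=shape)
    else:
        depth = rng.poisson(m, size=shape)
    alt = rng.binomial(depth, p_eff)

    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": [v.pos + 1 for v in accessions.variants],
            "ref": [v.ref for v in accessions.variants],
            "alt": [v.alt for v in accessions.variants],
            "site_id": [v.site_id for v in accessions.variants],
        }
    )
    return DepthData(
        sites=sites,
        sample_ids=accessions.sample_ids,
        depth=depth.astype(np.int64),
        alt_count=alt.astype(np.int64),
    )


# ---------------------------------------------------------------------------
# coding sequences for the Ks stage

_SENSE_CODONS: list[str] | None = None


def _sense_codons() -> list[str]:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        from .divergence import SENSE_CODONS

        _SENSE_CODONS = list(SENSE_CODONS)
    return _SENSE_CODONS


def _mutate_coding(codons: np.ndarray, n_subs: int, rng: np.random.Generator) -> None:
    """Apply n_subs random substitutions in place, re-drawing any that
    would create a stop codon (stops are purged by selection)."""
    from .divergence import STOP_INDICES

    n_codons = codons.size
    applied = 0
    while applied < n_subs:
        ci = int(rng.integers(n_codons))
        pos = int(rng.integers(3))
        shift = int(rng.integers(1, 4))
        div = 4 ** (2 - pos)
        base = (codons[ci] // div) % 4
        new = codons[ci] + ((base + shift) % 4 - base) * div
        if int(new) in STOP_INDICES:
            continue
        codons[ci] = new
        applied += 1


def simulate_coding_pair(
    length_nt: int, t_years: float, mu: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two coding sequences (codon-index arrays) split ``t_years`` ago.

    Each branch carries Poisson(mu * t * L) substitutions; multiple hits
    are allowed (the Jukes–Cantor correction in Ks absorbs them).
    """
    from .divergence import SENSE_INDICES

    if length_nt % 3 != 0:
        raise ValueError("length_nt must be a multiple of 3")
    n_codons = length_nt // 3
    anc = rng.choice(SENSE_INDICES, size=n_codons)
    a, b = anc.copy(), anc.copy()
    for arr in (a, b):
        _mutate_coding(arr, int(rng.poisson(mu * t_years * length_nt)), rng)
    return a, b


def simulate_gene_families(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, dict[str, str]]:
    """Per-gene CDS for each lineage, diverged on ((A,B),C).

    Returns {gene_id: {lineage: cds}}; stop-creating substitutions are
    redrawn so every CDS stays a clean open reading frame.
    """
    from .divergence import SENSE_INDICES, codon_index_to_str

    if rng is None:
        rng = np.random.default_rng([3, config.seed])
    times = _branch_times(config)
    n_codons = config.gene_length // 3
    genes: dict[str, dict[str, str]] = {}
    for g in range(config.n_genes):
        anc = rng.choice(SENSE_INDICES, size=n_codons)
        per_branch = {}
        for b in ("A", "B", "AB", "C"):
            arr = anc.copy()
            if b == "AB":
                _mutate_coding(
                    arr, int(rng.poisson(config.mu * times[b] * config.gene_length)), rng
                )
                per_branch["AB"] = arr
            else:
                per_branch[b] = arr
        # tip branches start from their parent state
        seqs = {}
        for lin in ("A", "B"):
            arr = per_branch["AB"].copy()
            _mutate_coding(
                arr, int(rng.poisson(config.mu * times[lin] * config.gene_length)), rng
            )
            seqs[lin] = arr
        arr = anc.copy()
        _mutate_coding(
            arr, int(rng.poisson(config.mu * times["C"] * config.gene_length)), rng
        )
        seqs["C"] = arr
        genes[f"gene{g + 1:02d}"] = {
            lin: codon_index_to_str(seqs[lin]) for lin in LINEAGES
        }
    return genes


def simulate_haplotype_segments(
    founders: FounderGenomes,
    config: SimulationConfig,
    copies: Mapping[str, int] | None = None,
    t_within: float = 0.17e6,
    length: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str, str]]:
    """Per-haplotype genomic segments for the alignment-free phylogeny.

    Each haplotype copy is its founder segment plus Poisson(mu * t_within * L)
    private tip substitutions, emulating within-group divergence (the
    within-A scale of ~0.34 Mya pairwise corresponds to t_within ~ 0.17 Mya
    per tip).  Returns (haplotype_id, group, sequence) triples.
    """
    if rng is None:
        rng = np.random.default_rng([4, config.seed])
    if copies is None:
        copies = config.ploidy_spec.get(config.panel_class, {"A": 9, "B": 2, "C": 1})
    out = []
    for lin in LINEAGES:
        n = int(copies.get(lin, 0))
        base = founders.sequences[lin]
        if length is not None:
            base = base[:length]
        arr0 = np.frombuffer(base.encode("ascii"), dtype=np.uint8).copy()
        lut = {65: 0, 67: 1, 71: 2, 84: 3}
        idx0 = np.array([lut[b] for b in arr0], dtype=np.int64)
        for i in range(n):
            idx = idx0.copy()
            n_subs = int(rng.poisson(config.mu * t_within * idx.size))
            if n_subs:
                positions = rng.choice(idx.size, size=min(n_subs, idx.size), replace=False)
                shifts = rng.integers(1, 4, size=positions.size)
                idx[positions] = (idx[positions] + shifts) % 4
            out.append((f"{lin}{i + 1}", lin, _idx_to_seq(idx)))
    return out


# ---------------------------------------------------------------------------
# truth labels and fixture serialization


def expected_truth(
    accessions: AccessionSet, config: SimulationConfig
) -> pd.DataFrame:
    """Expected specificity labels for every simulated variant site.

    The expected group label considers the haplotype groups present in the
    panel class; the expected pool label considers which germplasm pools'
    accessions carry at least one copy of the ALT allele.
    """
    panel_copies = config.ploidy_spec[config.panel_class]
    panel_groups = {l for l, n in panel_copies.items() if n > 0}
    rows = []
    pool_lineages: dict[str, set[str]] = {}
    for cls, pool in config.pool_of_class.items():
        if pool in ("offrob", "spont") and config.pool_sizes.get(cls, 0) > 0:
            pool_lineages.setdefault(pool, set()).update(
                l for l, n in config.ploidy_spec[cls].items() if n > 0
            )
    for v in accessions.variants:
        groups = sorted(v.alt_lineages & panel_groups)
        if len(groups) == 1:
            group_label = f"GROUP_{groups[0]}"
        else:
            group_label = "UNINFORMATIVE"
        pools_carrying = sorted(
            p for p, lins in pool_lineages.items() if v.alt_lineages & lins
        )
        if pools_carrying == ["offrob"]:
            pool_label = "POOL_OFFROB"
        elif pools_carrying == ["spont"]:
            pool_label = "POOL_SPONT"
        elif len(pools_carrying) == 2:
            pool_label = "ANCESTRAL"
        else:
            pool_label = "UNINFORMATIVE"
        rows.append(
            {
                "site_id": v.site_id,
                "pos": v.pos + 1,
                "ref": v.ref,
                "alt": v.alt,
                "origin": v.origin,
                "alt_lineages": ",".join(sorted(v.alt_lineages)),
                "expected_group": group_label,
                "expected_pool": pool_label,
                "group_combo": "_and_".join(groups) if groups else "",
            }
        )
    return pd.DataFrame(rows).set_index("site_id")


def build_panel_frames(
    accessions: AccessionSet, config: SimulationConfig, coverage: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Haplotype panel (presence, covered, groups) from the panel class.

    One panel haplotype per copy of the panel class's multiset, named like
    BAC clones A1..A9, B1, B2, C1.  ``coverage`` < 1 masks a random
    contiguous fraction of sites per haplotype, emulating partial BAC
    overlap with the reference segment.
    """
    if rng is None:
        rng = np.random.default_rng([5, config.seed])
    copies = config.ploidy_spec[config.panel_class]
    hap_ids, groups = [], []
    for lin in LINEAGES:
        for i in range(int(copies.get(lin, 0))):
            hap_ids.append(f"{lin}{i + 1}")
            groups.append(lin)
    site_ids = [v.site_id for v in accessions.variants]
    presence = pd.DataFrame(False, index=site_ids, columns=hap_ids)
    covered = pd.DataFrame(True, index=site_ids, columns=hap_ids)
    positions = np.array([v.pos for v in accessions.variants])
    for hap, lin in zip(hap_ids, groups):
        carries = np.array(
            [lin in v.alt_lineages for v in accessions.variants], dtype=bool
        )
        presence[hap] = carries
        if coverage < 1.0:
            span = int(round((1 - coverage) * len(site_ids)))
            if span > 0 and len(site_ids) > span:
                start = int(rng.integers(len(site_ids) - span))
                mask_pos = positions[np.argsort(positions)][start : start + span]
                masked = np.isin(positions, mask_pos)
                covered[hap] = ~masked
                presence.loc[masked, hap] = False
    return presence, covered, pd.Series(groups, index=hap_ids, name="group")


def write_vcf(depths: DepthData, path: Path, contig_length: int) -> Path:
    """Minimal multi-sample VCF 4.2 with DP/AD per sample."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=chr1,length={contig_length}>\n")
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(depths.sample_ids)
            + "\n"
        )
        ref_counts = depths.ref_count
        for i, row in enumerate(depths.sites.itertuples()):
            cells = [
                f"{depths.depth[i, j]}:{ref_counts[i, j]},{depths.alt_count[i, j]}"
                for j in range(len(depths.sample_ids))
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t.\tDP:AD\t"
                + "\t".join(cells)
                + "\n"
            )
    return path


def write_fixture(
    founders: FounderGenomes,
    accessions: AccessionSet,
    depths: DepthData,
    outdir: Path,
    config: SimulationConfig,
    panel_coverage: float = 1.0,
) -> dict[str, Path]:
    """Serialize a complete analysis fixture (FASTA/VCF/TSV) to ``outdir``."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    from .specificity import HaplotypePanel

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ref = accessions.reference
    paths["reference"] = outdir / "reference.fasta"
    SeqIO.write(
        [SeqRecord(Seq(ref), id="chr1", description="monoploid reference")],
        paths["reference"],
        "fasta",
    )

    paths["vcf"] = write_vcf(depths, outdir / "variants.vcf", len(ref))

    presence, covered, groups = build_panel_frames(
        accessions, config, coverage=panel_coverage
    )
    panel = HaplotypePanel(presence=presence, covered=covered, groups=groups)
    paths["panel"] = outdir / "panel.tsv"
    panel.to_tsv(paths["panel"])

    meta = pd.DataFrame(
        {
            "accession_id": [a.accession_id for a in accessions.accessions],
            "species": [a.species for a in accessions.accessions],
            "pool": [a.pool for a in accessions.accessions],
        }
    )
    paths["metadata"] = outdir / "metadata.tsv"
    meta.to_csv(paths["metadata"], sep="\t", index=False)

    truth = expected_truth(accessions, config)
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t")

    genes = simulate_gene_families(config)
    cds_records, prot_records = [], []
    for gid, per_lin in genes.items():
        for lin, cds in per_lin.items():
            cds_records.append(SeqRecord(Seq(cds), id=f"{gid}_{lin}", description=""))
            prot_records.append(
                SeqRecord(Seq(cds).translate(), id=f"{gid}_{lin}", description="")
            )
    paths["cds"] = outdir / "genes_cds.fasta"
    SeqIO.write(cds_records, paths["cds"], "fasta")
    paths["protein_aln"] = outdir / "genes_protein_aln.fasta"
    SeqIO.write(prot_records, paths["protein_aln"], "fasta")

    segments = simulate_haplotype_segments(founders, config)
    seg_records = [
        SeqRecord(Seq(seq), id=hap, description=f"group={grp}")
        for hap, grp, seq in segments
    ]
    paths["segments"] = outdir / "segments.fasta"
    SeqIO.write(seg_records, paths["segments"], "fasta")
    return paths
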