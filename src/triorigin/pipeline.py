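"""End-to-end orchestration: simulate -> genotype -> ordinate -> origin
-> Ks dating -> k-mer tree, with a structured config and a run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .divergence import (
    CodonAlignment,
    DatingConfig,
    divergence_time,
    group_mean_ks,
    ks_pairwise,
)
from .kmer_phylo import KmerConfig, build_profile, distance_matrix, nj_tree, write_newick
from .ordination import flag_intermediates, pcoa, snp_dissimilarity
from .simdata import (
    SimulationConfig,
    simulate_accessions,
    simulate_allele_depths,
    simulate_founders,
    simulate_gene_families,
    simulate_haplotype_segments,
    write_fixture,
)
from .specificity import (
    HaplotypePanel,
    SpecificityConfig,
    apply_exclusions,
    assign_group_snp_origin,
    find_group_specific_snps,
    find_pool_specific_snps,
    infer_group_origin,
    map_pool_snps_to_haplotypes,
)
from .variants import GenotypeCallingConfig, call_matrix, read_vcf

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_pipeline", "config_hash"]

_STAGES = ("simulate", "genotype", "ordinate", "origin", "ks", "kmer_tree")


@dataclass
class RunConfig:
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in _STAGES}
    )
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    calling: GenotypeCallingConfig = field(default_factory=GenotypeCallingConfig)
    specificity: SpecificityConfig = field(default_factory=SpecificityConfig)
    dating: DatingConfig = field(default_factory=DatingConfig)
    kmer: KmerConfig = field(default_factory=KmerConfig)
    axes: int = 2
    exclude: list[str] = field(default_factory=list)
    log_level: str = "INFO"

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_SECTION_TYPES = {
    "sim": SimulationConfig,
    "calling": GenotypeCallingConfig,
    "specificity": SpecificityConfig,
    "dating": DatingConfig,
    "kmer": KmerConfig,
}


def validate_config(source: Path | str | Mapping | None) -> RunConfig:
    """Load and normalize a run config (YAML path or mapping).

    Missing keys take defaults; unknown keys and type/range violations are
    all reported together.
    """
    if source is None:
        data: dict = {}
    elif isinstance(source, Mapping):
        data = dict(source)
    else:
        text = Path(source).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config root must be a mapping")

    errors: list[str] = []
    kwargs: dict[str, Any] = {}
    known_top = {"seed", "stages", "axes", "exclude", "log_level", *_SECTION_TYPES}
    for key in data:
        if key not in known_top:
            errors.append(f"unknown config key: {key!r}")

    for section, cls in _SECTION_TYPES.items():
        block = data.get(section, {})
        if not isinstance(block, Mapping):
            errors.append(f"{section}: must be a mapping")
            continue
        valid_fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(block) - valid_fields
        errors.extend(f"{section}: unknown key {k!r}" for k in sorted(unknown))
        try:
            kwargs[section] = cls(**{k: v for k, v in block.items() if k in valid_fields})
        except (ValueError, TypeError) as exc:
            errors.append(f"{section}: {exc}")

    if "stages" in data:
        stages = {s: True for s in _STAGES}
        if not isinstance(data["stages"], Mapping):
            errors.append("stages: must be a mapping of stage -> bool")
        else:
            for k, v in data["stages"].items():
                if k not in _STAGES:
                    errors.append(f"stages: unknown stage {k!r}")
                else:
                    stages[k] = bool(v)
        kwargs["stages"] = stages
    for key in ("seed", "axes"):
        if key in data:
            try:
                kwargs[key] = int(data[key])
            except (TypeError, ValueError):
                errors.append(f"{key}: must be an integer")
    if "exclude" in data:
        kwargs["exclude"] = [str(x) for x in data["exclude"]]
    if "log_level" in data:
        kwargs["log_level"] = str(data["log_level"])
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    cfg = RunConfig(**kwargs)
    # a top-level seed propagates to the simulator unless explicitly set there
    if "seed" in data and "seed" not in data.get("sim", {}):
        cfg.sim.seed = cfg.seed
    return cfg


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(cfg: RunConfig, outdir: Path) -> Path:
    """Execute the enabled stages into ``outdir``; idempotent under a
    fixed seed.  Stage failures abort with the failing stage named."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": config_hash(cfg),
        "stages_run": [],
        "outputs": {},
    }
    summary: dict[str, Any] = {}

    state: dict[str, Any] = {}
    try:
        if cfg.stages.get("simulate", True):
            _stage_simulate(cfg, outdir, state, manifest)
        if cfg.stages.get("genotype", True):
            _stage_genotype(cfg, outdir, state, manifest, summary)
        if cfg.stages.get("ordinate", True):
            _stage_ordinate(cfg, outdir, state, manifest, summary)
        if cfg.stages.get("origin", True):
            _stage_origin(cfg, outdir, state, manifest, summary)
        if cfg.stages.get("ks", True):
            _stage_ks(cfg, outdir, state, manifest, summary)
        if cfg.stages.get("kmer_tree", True):
            _stage_kmer_tree(cfg, outdir, state, manifest, summary)
    except Exception as exc:
        stage = manifest["stages_run"][-1] if manifest["stages_run"] else "setup"
        raise RuntimeError(f"pipeline failed during stage {stage!r}: {exc}") from exc
    finally:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return outdir


def _record(manifest: dict, stage: str, paths: Mapping[str, Path]) -> None:
    manifest["stages_run"].append(stage)
    manifest["outputs"].update({k: str(v) for k, v in paths.items()})


def _stage_simulate(cfg, outdir, state, manifest) -> None:
    manifest["stages_run"].append("simulate")
    founders = simulate_founders(cfg.sim)
    accessions = simulate_accessions(founders, cfg.sim)
    depths = simulate_allele_depths(accessions, cfg.sim)
    paths = write_fixture(founders, accessions, depths, outdir / "fixture", cfg.sim)
    state.update(founders=founders, accessions=accessions, depths=depths, paths=paths)
    manifest["outputs"].update({k: str(v) for k, v in paths.items()})
    logger.info("simulated %d variant sites, %d accessions",
                len(accessions.variants), len(accessions.accessions))


def _stage_genotype(cfg, outdir, state, manifest, summary) -> None:
    vcf_path = state["paths"]["vcf"] if "paths" in state else outdir / "fixture" / "variants.vcf"
    records, refs, alts, deps, samples = read_vcf(vcf_path)
    gm = call_matrix(
        refs, alts, deps, cfg.calling,
        site_ids=[r.site_id for r in records], sample_ids=samples,
    )
    out = outdir / "genotypes.tsv"
    gm.to_tsv(out)
    state["gm"] = gm
    _record(manifest, "genotype", {"genotypes": out})
    counts = {
        "sites": len(gm.site_ids),
        "present": int((gm.calls == 1).sum().sum()),
        "absent": int((gm.calls == 0).sum().sum()),
        "missing": int((gm.calls == -1).sum().sum()),
    }
    summary["genotype_counts"] = counts
    logger.info("genotype calls: %s", counts)


def _stage_ordinate(cfg, outdir, state, manifest, summary) -> None:
    gm = state["gm"]
    meta = pd.read_csv(state["paths"]["metadata"], sep="\t").set_index("accession_id")
    dism = snp_dissimilarity(gm)
    ord_res = pcoa(dism, m=cfg.axes)
    flagged = flag_intermediates(ord_res, meta["pool"])
    paths = {
        "dissimilarity": outdir / "dissimilarity.tsv",
        "coordinates": outdir / "coordinates.tsv",
        "eigenvalues": outdir / "eigenvalues.tsv",
        "flagged": outdir / "flagged_hybrids.txt",
    }
    dism.d.to_csv(paths["dissimilarity"], sep="\t")
    ord_res.coordinates.to_csv(paths["coordinates"], sep="\t", index_label="accession_id")
    pd.DataFrame(
        {"eigenvalue": ord_res.eigvals.values,
         "proportion": ord_res.proportion_explained.values}
    ).to_csv(paths["eigenvalues"], sep="\t", index=False)
    paths["flagged"].write_text("\n".join(flagged) + ("\n" if flagged else ""))
    state["flagged"] = flagged
    state["meta"] = meta
    _record(manifest, "ordinate", paths)
    summary["flagged_hybrids"] = flagged
    logger.info("flagged %d candidate hybrids", len(flagged))


def _stage_origin(cfg, outdir, state, manifest, summary) -> None:
    gm = state["gm"]
    meta = state.get("meta")
    if meta is None:
        meta = pd.read_csv(state["paths"]["metadata"], sep="\t").set_index("accession_id")
    panel = HaplotypePanel.from_tsv(state["paths"]["panel"])
    exclude = set(cfg.exclude) | set(state.get("flagged", []))
    pools = apply_exclusions(meta["pool"], exclude)

    group_df = find_group_specific_snps(panel, cfg.specificity)
    group_df, table2 = assign_group_snp_origin(group_df, gm, pools, cfg.specificity)
    pool_df = find_pool_specific_snps(gm, pools, cfg.specificity)
    pool_df, table3 = map_pool_snps_to_haplotypes(pool_df, panel)
    verdicts = infer_group_origin(table2, table3, cfg.specificity)

    paths = {
        "group_snps": outdir / "group_specific_snps.tsv",
        "pool_snps": outdir / "pool_specific_snps.tsv",
        "table_groups_by_pool": outdir / "table_groups_by_pool.tsv",
        "table_pools_by_group": outdir / "table_pools_by_group.tsv",
        "verdicts": outdir / "verdicts.json",
    }
    group_df.to_csv(paths["group_snps"], sep="\t")
    pool_df.to_csv(paths["pool_snps"], sep="\t")
    table2.to_csv(paths["table_groups_by_pool"], sep="\t")
    table3.to_csv(paths["table_pools_by_group"], sep="\t")
    paths["verdicts"].write_text(json.dumps(verdicts, indent=2))
    _record(manifest, "origin", paths)
    summary["verdicts"] = {g: v["verdict"] for g, v in verdicts.items()}
    summary["table_groups_by_pool"] = table2.to_dict()
    summary["table_pools_by_group"] = table3.to_dict()
    logger.info("origin verdicts: %s", summary["verdicts"])


def _stage_ks(cfg, outdir, state, manifest, summary) -> None:
    genes = simulate_gene_families(cfg.sim)
    rows = []
    for gid, per_lin in genes.items():
        for pair, label in ((("A", "B"), "A-B"), (("A", "C"), "A-C"), (("B", "C"), "B-C")):
            res = ks_pairwise(CodonAlignment.build(per_lin[pair[0]], per_lin[pair[1]]))
            rows.append(
                {"gene": gid, "label": label, "region": "sim", "S": res.S, "N": res.N,
                 "Sd": res.Sd, "Nd": res.Nd, "ps": res.ps, "ks": res.ks}
            )
    records = pd.DataFrame(rows)
    means = group_mean_ks(records)
    pooled = means[means["region"] == "pooled"].copy()
    pooled["mya"] = [divergence_time(v, cfg.dating) for v in pooled["mean_ks"]]
    paths = {"ks_pairs": outdir / "ks_pairs.tsv", "ks_summary": outdir / "ks_summary.tsv"}
    records.to_csv(paths["ks_pairs"], sep="\t", index=False)
    pooled.to_csv(paths["ks_summary"], sep="\t", index=False)
    _record(manifest, "ks", paths)
    summary["divergence_mya"] = dict(zip(pooled["label"], pooled["mya"]))
    logger.info("divergence times (Mya): %s", summary["divergence_mya"])


def _stage_kmer_tree(cfg, outdir, state, manifest, summary) -> None:
    founders = state.get("founders")
    if founders is None:
        founders = simulate_founders(cfg.sim)
    segments = simulate_haplotype_segments(founders, cfg.sim)
    profiles = [build_profile(seq, cfg.kmer, source_id=hid) for hid, _, seq in segments]
    dm = distance_matrix(profiles)
    tree = nj_tree(dm)
    paths = {"kmer_distances": outdir / "kmer_distances.tsv", "tree": outdir / "tree.nwk"}
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        paths["kmer_distances"], sep="\t"
    )
    write_newick(tree, paths["tree"])
    _record(manifest, "kmer_tree", paths)
    summary["tree_newick"] = paths["tree"].read_text().strip()
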