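"""End-to-end pipeline: synthetic community -> ANI lineages -> read
quantification -> strain enrichment -> KO rule -> orthogroup diversity ->
consensus differential abundance -> framework intersection.

A :class:`PipelineConfig` resolves every stage parameter (paper-style
defaults: tau=97, KO rule thresholds 2/4, alpha=0.05) and a run writes every
stage's tables plus a manifest JSON whose hash covers the resolved
parameters and the SHA-256 of every output file, so identical (config,
seed) runs have identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ani as ani_mod
from . import da as da_mod
from . import io as io_mod
from .community import (
    AbundanceModel,
    CommunityConfig,
    LineageSpec,
    PlantedFeature,
    build_community,
    generate_host_decoy,
    make_design,
    simulate_reads,
)
from .diversity import alpha_diversity, bray_curtis, compare_alpha, nmds, permanova
from .enrichment import classify_strategies, strain_enrichment, write_enrichment_tsv
from .ko import enriched_ko_set, ko_enrichment_rule, lineage_presence, write_ko_tsv
from .quant import (
    CountMatrix,
    aggregate_orthogroups,
    assign_reads,
    build_index,
    count_matrix,
    cpm_normalize,
    filter_host_reads,
)

log = logging.getLogger("defcom")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Resolved parameters for a full synthetic run."""

    seed: int = 0
    outdir: str = "defcom_run"
    # community
    genome_length: int = 500_000
    gc: float = 0.6
    n_genes: int = 450
    gene_length: int = 900
    ko_fraction: float = 0.6
    lineage_sizes: tuple[int, ...] = (3, 3, 2, 1, 1)
    within_divergence: float = 0.004
    founder_divergence: float = 0.04
    n_private_genes: int = 3
    n_deleted_genes: int = 5
    planted: tuple[dict, ...] = (
        {"ko": "K90001", "orthogroup": "OGX0001", "lineages": (0, 3), "endosphere": True},
        {"ko": "K90002", "orthogroup": "OGX0002", "lineages": (0, 3), "endosphere": True},
        {"ko": "K90003", "orthogroup": "OGX0003", "lineages": (0, 3), "endosphere": True},
        {"ko": "K90010", "orthogroup": "OGX0010", "lineages": (1,), "endosphere": False},
    )
    # design + abundance model
    n_endosphere: int = 7
    n_rhizosphere: int = 8
    base_log_mean: float = 0.0
    base_log_sd: float = 0.35
    compartment_effects: dict = field(
        default_factory=lambda: {
            "S00": 2.5, "S01": 2.0, "S02": 2.0, "S08": 2.5,
            "S03": -2.0, "S04": -2.0, "S05": -2.0, "S06": -2.0, "S07": -2.0, "S09": -2.0,
        }
    )
    host_effects: dict = field(
        default_factory=lambda: {("S08", "speciesB"): 1.5, ("S00", "speciesA"): 1.0}
    )
    depth: int = 50_000
    host_read_fraction: float = 0.1
    error_rate: float = 0.005
    read_length: int = 150
    host_decoy_length: int = 100_000
    # ANI / lineages
    ani_k: int = 16
    ani_fragment: int = 3000
    ani_min_jaccard: float = 0.01
    tau: float = 97.0
    # read quantification
    assign_k: int = 31
    min_score_fraction: float = 0.25
    host_match_floor: float = 0.5
    mapping_mode: str = "unique"
    per_copy: bool = False
    # statistics
    alpha: float = 0.05
    abundance_quantile: float = 0.5
    min_endo: int = 2
    max_non: int = 4
    n_perm: int = 999
    nmds_starts: int = 20
    nmds_max_iter: int = 300
    css_quantile: float = 0.5
    min_detect: int = 1

    def validate(self) -> None:
        if not 0 < self.tau <= 100:
            raise ValueError("tau must be in (0, 100]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.mapping_mode not in ("unique", "fractional"):
            raise ValueError("mapping_mode must be 'unique' or 'fractional'")
        if min(self.lineage_sizes, default=0) < 1:
            raise ValueError("lineage sizes must be positive")
        if self.depth <= 0 or self.n_endosphere < 2 or self.n_rhizosphere < 2:
            raise ValueError("need positive depth and >= 2 replicates per compartment")

    def community_config(self) -> CommunityConfig:
        return CommunityConfig(
            lineages=[LineageSpec(n, self.within_divergence) for n in self.lineage_sizes],
            genome_length=self.genome_length,
            gc=self.gc,
            n_genes=self.n_genes,
            gene_length=self.gene_length,
            ko_fraction=self.ko_fraction,
            founder_divergence=self.founder_divergence,
            planted=[PlantedFeature(ko=p.get("ko"), orthogroup=p["orthogroup"],
                                    lineages=tuple(p["lineages"]),
                                    endosphere=bool(p.get("endosphere", True)))
                     for p in self.planted],
            n_private_genes=self.n_private_genes,
            n_deleted_genes=self.n_deleted_genes,
        )

    def abundance_model(self) -> AbundanceModel:
        host_eff = {tuple(k) if not isinstance(k, tuple) else k: v
                    for k, v in self.host_effects.items()}
        return AbundanceModel(
            base_log_mean=self.base_log_mean,
            base_log_sd=self.base_log_sd,
            compartment_effects=dict(self.compartment_effects),
            host_effects=host_eff,
            depth=self.depth,
            host_read_fraction=self.host_read_fraction,
            error_rate=self.error_rate,
            read_length=self.read_length,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted"] = [dict(p, lineages=list(p["lineages"])) for p in self.planted]
        d["host_effects"] = {f"{k[0]}|{k[1]}": v for k, v in self.host_effects.items()}
        d["lineage_sizes"] = list(self.lineage_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "host_effects" in d:
            d["host_effects"] = {
                tuple(k.split("|")): v for k, v in d["host_effects"].items()
            }
        if "lineage_sizes" in d:
            d["lineage_sizes"] = tuple(d["lineage_sizes"])
        if "planted" in d:
            d["planted"] = tuple(dict(p, lineages=tuple(p["lineages"])) for p in d["planted"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _seed_for(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory.

    Any stage failure is re-raised as :class:`StageError` naming the stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    summary: dict = {"stages": {}}

    def record(name: str, path: Path):
        outputs[name] = str(path.relative_to(outdir))

    # --- stage: generate ---------------------------------------------------
    stage = "generate"
    try:
        community = build_community(config.community_config(), _seed_for(config.seed, "community"))
        design = make_design(config.n_endosphere, config.n_rhizosphere)
        model = config.abundance_model()
        host_seq = generate_host_decoy(config.host_decoy_length, config.gc,
                                       _seed_for(config.seed, "host"))
        readsets, abund = simulate_reads(
            community, design, model, _seed_for(config.seed, "reads"), host_seq=host_seq
        )
        paths = io_mod.write_community(community, outdir / "community")
        for k, p in paths.items():
            record(k, Path(p))
        io_mod.write_design_tsv(design, outdir / "design.tsv")
        record("design", outdir / "design.tsv")
        rdir = outdir / "reads"
        rdir.mkdir(exist_ok=True)
        for sid, rs in readsets.items():
            p = rdir / f"{sid}.fastq.gz"
            io_mod.write_fastq_gz(rs, p)
            record(f"reads:{sid}", p)
        summary["stages"][stage] = {
            "n_strains": len(community.genomes),
            "n_samples": len(design),
            "depth": config.depth,
        }
        log.info("generate: %d strains, %d samples", len(community.genomes), len(design))
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- stage: ani --------------------------------------------------------
    stage = "ani"
    try:
        ani = ani_mod.ani_matrix(
            community.genomes, k=config.ani_k, fragment=config.ani_fragment,
            min_jaccard=config.ani_min_jaccard,
        )
        lm = ani_mod.cluster_lineages(ani, tau=config.tau)
        ani_mod.write_ani_tsv(ani, outdir / "ani_matrix.tsv")
        record("ani_matrix", outdir / "ani_matrix.tsv")
        summary["stages"][stage] = {"n_lineages": len(set(lm.assignment.values())), "tau": config.tau}
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- stage: quantify ---------------------------------------------------
    stage = "quantify"
    try:
        host_index = build_index({"host": host_seq}, k=config.assign_k)
        index = build_index(community.genomes, k=config.assign_k)
        assignments = {}
        n_host_removed = {}
        for sid, rs in readsets.items():
            kept = filter_host_reads(rs, host_index, config.host_match_floor)
            n_host_removed[sid] = len(rs) - len(kept)
            assignments[sid] = assign_reads(
                kept, index, mode=config.mapping_mode,
                min_score_fraction=config.min_score_fraction,
            )
        strain_cm = count_matrix(assignments, "strain", design=design,
                                 strain_ids=community.strain_ids)
        gene_cm = count_matrix(assignments, "gene", design=design,
                               annotations=community.annotations,
                               read_length=config.read_length)
        og_cm = aggregate_orthogroups(gene_cm, community.annotations, per_copy=False)
        strain_cm.counts.to_csv(outdir / "counts_strain.tsv", sep="\t")
        gene_cm.counts.to_csv(outdir / "counts_gene.tsv", sep="\t")
        og_cm.counts.to_csv(outdir / "counts_orthogroup.tsv", sep="\t")
        cpm_normalize(og_cm).to_csv(outdir / "cpm_orthogroup.tsv", sep="\t", float_format="%.4f")
        for n in ("counts_strain", "counts_gene", "counts_orthogroup", "cpm_orthogroup"):
            record(n, outdir / f"{n}.tsv")
        side = {
            "mode": config.mapping_mode,
            "host_reads_removed": n_host_removed,
            "discarded_multi": strain_cm.meta["discarded_multi"],
            "below_floor": strain_cm.meta["below_floor"],
            "gene_ties": gene_cm.meta["gene_ties"],
        }
        (outdir / "quantify_stats.json").write_text(json.dumps(side, indent=1, sort_keys=True))
        record("quantify_stats", outdir / "quantify_stats.json")
        summary["stages"][stage] = {
            "host_reads_removed": int(sum(n_host_removed.values())),
            "multi_discarded": int(sum(side["discarded_multi"].values())),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- stage: strain enrichment -------------------------------------------
    stage = "enrich-strains"
    try:
        table = strain_enrichment(strain_cm, alpha=config.alpha)
        strategies = classify_strategies(table, alpha=config.alpha,
                                         abundance_quantile=config.abundance_quantile)
        write_enrichment_tsv(table, outdir / "strain_enrichment.tsv", strategies)
        record("strain_enrichment", outdir / "strain_enrichment.tsv")
        dominant = set(strategies.index[strategies == "strong_colonizer"])
        lm = ani_mod.label_endosphere_lineages(lm, dominant)
        ani_mod.write_lineages_tsv(lm, outdir / "lineages.tsv")
        record("lineages", outdir / "lineages.tsv")
        summary["stages"][stage] = {
            "dominant_strains": sorted(dominant),
            "endosphere_lineages": sorted(lm.endosphere_associated),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- stage: KO rule ------------------------------------------------------
    stage = "enrich-kos"
    try:
        presence = lineage_presence(community.annotations, lm)
        ko_table = ko_enrichment_rule(presence, lm.endosphere_associated,
                                      min_endo=config.min_endo, max_non=config.max_non)
        write_ko_tsv(ko_table, outdir / "ko_enrichment.tsv")
        record("ko_enrichment", outdir / "ko_enrichment.tsv")
        summary["stages"][stage] = {"n_enriched_kos": int(ko_table["enriched"].sum())}
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- stage: diversity ----------------------------------------------------
    stage = "diversity"
    try:
        og_cpm = cpm_normalize(og_cm)
        adiv = alpha_diversity(og_cpm)
        adiv.to_csv(outdir / "alpha_diversity.tsv", sep="\t", float_format="%.6g")
        record("alpha_diversity", outdir / "alpha_diversity.tsv")
        alpha_tests = {
            metric: compare_alpha(adiv[metric], design["compartment"])
            for metric in ("richness", "shannon")
        }
        bc = bray_curtis(og_cpm)
        bc.to_csv(outdir / "bray_curtis.tsv", sep="\t", float_format="%.6g")
        record("bray_curtis", outdir / "bray_curtis.tsv")
        ord_res = nmds(bc, n_starts=config.nmds_starts, max_iter=config.nmds_max_iter,
                       seed=_seed_for(config.seed, "nmds"))
        ord_res.coords.to_csv(outdir / "nmds_coords.tsv", sep="\t", float_format="%.6g")
        record("nmds_coords", outdir / "nmds_coords.tsv")
        perm = permanova(bc, design, ["compartment", "host"], n_perm=config.n_perm,
                         seed=_seed_for(config.seed, "permanova"))
        perm.table.to_csv(outdir / "permanova.tsv", sep="\t", float_format="%.6g")
        record("permanova", outdir / "permanova.tsv")
        summary["stages"][stage] = {
            "alpha_tests": alpha_tests,
            "nmds_stress": ord_res.stress,
            "permanova_R2": {
                t: float(perm.table.loc[t, "R2"]) for t in ("compartment", "host")
            },
            "permanova_p": {
                t: float(perm.table.loc[t, "p"]) for t in ("compartment", "host")
            },
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- stage: consensus DA ---------------------------------------------------
    stage = "da"
    try:
        results = da_mod.run_three_methods(og_cm, alpha=config.alpha)
        for r in results:
            r.table.to_csv(outdir / f"da_{r.method}.tsv", sep="\t", float_format="%.6g")
            record(f"da_{r.method}", outdir / f"da_{r.method}.tsv")
        cons = da_mod.consensus(results, alpha=config.alpha, direction=1)
        pd.Series(sorted(cons), name="orthogroup").to_csv(
            outdir / "consensus_orthogroups.tsv", sep="\t", index=False
        )
        record("consensus_orthogroups", outdir / "consensus_orthogroups.tsv")
        ph = da_mod.per_host_enrichment(og_cm, alpha=config.alpha, min_detect=config.min_detect)
        ph_rows = [
            {"set": k, "size": v} for k, v in ph["upset"].items()
        ]
        pd.DataFrame(ph_rows).to_csv(outdir / "per_host_upset.tsv", sep="\t", index=False)
        record("per_host_upset", outdir / "per_host_upset.tsv")
        presence = lineage_presence(community.annotations, lm)
        ko_table = ko_enrichment_rule(presence, lm.endosphere_associated,
                                      min_endo=config.min_endo, max_non=config.max_non)
        inter = da_mod.intersect_frameworks(cons, community.annotations, enriched_ko_set(ko_table))
        (outdir / "framework_intersection.json").write_text(
            json.dumps({"kos": sorted(inter)}, indent=1)
        )
        record("framework_intersection", outdir / "framework_intersection.json")
        summary["stages"][stage] = {
            "significant_per_method": {
                r.method: int(r.table["significant"].sum()) for r in results
            },
            "n_consensus": len(cons),
            "per_host_upset": ph["upset"],
            "n_intersection_kos": len(inter),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- manifest ---------------------------------------------------------------
    resolved = config.to_dict()
    file_hashes = {name: _sha256(outdir / rel) for name, rel in sorted(outputs.items())}
    hashed_params = {k: v for k, v in resolved.items() if k != "outdir"}
    manifest_src = json.dumps({"params": hashed_params, "files": file_hashes}, sort_keys=True)
    manifest = {
        "parameters": resolved,
        "files": file_hashes,
        "summary": summary,
        "manifest_hash": hashlib.sha256(manifest_src.encode()).hexdigest(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    for name, rel in outputs.items():
        p = outdir / rel
        if not p.exists() or p.stat().st_size == 0:
            raise StageError("manifest", RuntimeError(f"declared output missing or empty: {rel}"))
    log.info("pipeline complete: %s", outdir)
    return outdir
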