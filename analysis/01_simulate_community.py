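#!/usr/bin/env python
"""Simulate the 28-strain defined community and its metagenomes.

Writes genomes, annotations, ground truth and per-sample reads under
scratch/analysis/ (bulky, regenerable) and the design plus a community
summary under results/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import DOMINANT, RESULTS, SCRATCH, study_config

from defcom import io as io_mod
from defcom.community import build_community, generate_host_decoy, make_design, simulate_reads
from defcom.pipeline import _seed_for


def main() -> None:
    cfg = study_config()
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    community = build_community(cfg.community_config(), _seed_for(cfg.seed, "community"))
    design = make_design(cfg.n_endosphere, cfg.n_rhizosphere)
    host = generate_host_decoy(cfg.host_decoy_length, cfg.gc, _seed_for(cfg.seed, "host"))
    readsets, abund = simulate_reads(
        community, design, cfg.abundance_model(), _seed_for(cfg.seed, "reads"), host_seq=host
    )

    io_mod.write_community(community, SCRATCH / "community")
    io_mod.write_genome_fasta("host_decoy", host, SCRATCH / "community" / "host_decoy.fasta")
    io_mod.write_design_tsv(design, RESULTS / "design.tsv")
    (SCRATCH / "reads").mkdir(exist_ok=True)
    for sid, rs in readsets.items():
        io_mod.write_fastq_gz(rs, SCRATCH / "reads" / f"{sid}.fastq.gz")
    abund.round(6).to_csv(RESULTS / "true_abundance.tsv", sep="\t")

    gt = community.ground_truth
    n_lineages = len(set(gt.lineage_assignment.values()))
    summary = {
        "n_strains": len(community.genomes),
        "n_lineages": n_lineages,
        "dominant_colonizers": list(DOMINANT),
        "planted_endosphere_kos": sorted(gt.planted_enriched_kos),
        "planted_endosphere_orthogroups": sorted(gt.planted_enriched_ogs),
        "n_samples": len(design),
        "reads_per_sample": cfg.depth,
    }
    (RESULTS / "community_summary.json").write_text(json.dumps(summary, indent=1))
    print(f"Simulated {summary['n_strains']} strains in {n_lineages} lineages, "
          f"{len(design)} samples x {cfg.depth} reads.")
    print(f"Dominant colonizers (planted): {', '.join(DOMINANT)}")
    print(f"Planted endosphere KOs: {', '.join(summary['planted_endosphere_kos'])}")


if __name__ == "__main__":
    main()
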