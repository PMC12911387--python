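"""Shared study definition for the numbered analysis scripts.

A DefCom-scale synthetic community: 28 strains in 15 ANI lineages (sizes
3,3,3,3,2,2,2,2,2,1,1,1,1,1,1), with six dominant endosphere colonizers —
one full 3-strain lineage (S00-S02) plus three singletons (S25-S27) — so the
community partitions into 4 endosphere-associated and 11 non-endosphere
lineages. Three endosphere marker KOs/orthogroups are planted in the
colonizer lineages; one decoy marker sits in a non-colonizer lineage.
Genomes are 100 kb (a desk-scale stand-in for real ~7 Mb genomes);
15 samples (7 endosphere / 8 rhizosphere across two host species) at 20k
single-end 150 bp reads with 10% host contamination.
"""

from pathlib import Path

from defcom.pipeline import PipelineConfig

SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "analysis"
RESULTS = Path(__file__).resolve().parent.parent / "results"

LINEAGE_SIZES = (3, 3, 3, 3, 2, 2, 2, 2, 2, 1, 1, 1, 1, 1, 1)
DOMINANT = ("S00", "S01", "S02", "S25", "S26", "S27")


def study_config(seed: int = 7) -> PipelineConfig:
    effects = {s: -1.5 for s in (f"S{i:02d}" for i in range(28))}
    for s in DOMINANT:
        effects[s] = 2.0
    effects["S00"] = 2.5
    return PipelineConfig(
        seed=seed,
        outdir=str(SCRATCH / "run"),
        genome_length=100_000,
        n_genes=90,
        gene_length=900,
        lineage_sizes=LINEAGE_SIZES,
        within_divergence=0.004,
        founder_divergence=0.04,
        n_private_genes=2,
        n_deleted_genes=3,
        planted=(
            {"ko": "K90001", "orthogroup": "OGX0001", "lineages": (0, 12, 13, 14), "endosphere": True},
            {"ko": "K90002", "orthogroup": "OGX0002", "lineages": (0, 13), "endosphere": True},
            {"ko": "K90003", "orthogroup": "OGX0003", "lineages": (0, 12, 14), "endosphere": True},
            {"ko": "K90010", "orthogroup": "OGX0010", "lineages": (2, 5), "endosphere": False},
        ),
        compartment_effects=effects,
        host_effects={("S25", "speciesA"): 1.5, ("S27", "speciesB"): 1.5},
        depth=20_000,
        host_read_fraction=0.10,
        error_rate=0.005,
        host_decoy_length=100_000,
    )
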