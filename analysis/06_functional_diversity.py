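#!/usr/bin/env python
"""Orthogroup functional diversity: alpha diversity, Bray-Curtis NMDS, and
PERMANOVA variance partitioning by compartment and host species."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import RESULTS, study_config

from defcom.diversity import alpha_diversity, bray_curtis, compare_alpha, nmds, permanova
from defcom.io import read_design_tsv
from defcom.pipeline import _seed_for


def main() -> None:
    cfg = study_config()
    design = read_design_tsv(RESULTS / "design.tsv")
    cpm = pd.read_csv(RESULTS / "cpm_orthogroup.tsv", sep="\t", index_col=0)[list(design.index)]
    # re-normalize after the rounding applied when the table was written
    cpm = cpm / cpm.sum() * 1e6

    adiv = alpha_diversity(cpm)
    adiv.round(4).to_csv(RESULTS / "alpha_diversity.tsv", sep="\t")
    comp = design["compartment"]
    for metric in ("richness", "shannon"):
        tests = compare_alpha(adiv[metric], comp)
        means = adiv.groupby(comp.to_numpy())[metric].mean()
        print(f"{metric}: endosphere {means['endosphere']:.2f} vs rhizosphere "
              f"{means['rhizosphere']:.2f} (Wilcoxon p={tests['wilcoxon_p']:.2g}, "
              f"ANOVA p={tests['anova_p']:.2g})")

    bc = bray_curtis(cpm)
    bc.round(5).to_csv(RESULTS / "bray_curtis.tsv", sep="\t")
    ordn = nmds(bc, n_starts=cfg.nmds_starts, max_iter=cfg.nmds_max_iter,
                seed=_seed_for(cfg.seed, "nmds"))
    coords = ordn.coords.join(design[["host", "compartment"]])
    coords.round(5).to_csv(RESULTS / "nmds_coords.tsv", sep="\t")
    print(f"NMDS stress-1: {ordn.stress:.4f}")

    perm = permanova(bc, design, ["compartment", "host"], n_perm=cfg.n_perm,
                     seed=_seed_for(cfg.seed, "permanova"))
    perm.table.round(5).to_csv(RESULTS / "permanova.tsv", sep="\t")
    for term in ("compartment", "host"):
        row = perm.table.loc[term]
        print(f"PERMANOVA {term}: R2 = {100 * row['R2']:.1f}% "
              f"(F = {row['F']:.2f}, p = {row['p']:.4g})")


if __name__ == "__main__":
    main()
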