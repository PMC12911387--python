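#!/usr/bin/env python
"""Strain-level compartment enrichment and colonization strategies.

TMM + voom + moderated t on the endosphere-vs-rhizosphere contrast, strategy
classification, and labeling of endosphere-associated lineages from the
detected dominant colonizers.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import DOMINANT, RESULTS, study_config

from defcom.ani import LineageMap, label_endosphere_lineages, write_lineages_tsv
from defcom.enrichment import classify_strategies, strain_enrichment, write_enrichment_tsv
from defcom.io import read_design_tsv
from defcom.quant import CountMatrix


def main() -> None:
    cfg = study_config()
    design = read_design_tsv(RESULTS / "design.tsv")
    counts = pd.read_csv(RESULTS / "counts_strain_unique.tsv", sep="\t", index_col=0)
    cm = CountMatrix(counts[list(design.index)], "strain", design)

    table = strain_enrichment(cm, alpha=cfg.alpha)
    strategies = classify_strategies(table, alpha=cfg.alpha,
                                     abundance_quantile=cfg.abundance_quantile)
    write_enrichment_tsv(table, RESULTS / "strain_enrichment.tsv", strategies)

    detected = set(strategies.index[strategies == "strong_colonizer"])
    print("Strategy counts:", strategies.value_counts().to_dict())
    print(f"Detected dominant colonizers: {sorted(detected)}")
    print(f"Planted dominant colonizers:  {sorted(DOMINANT)}")
    print(f"Exact recovery: {detected == set(DOMINANT)}")

    lin = pd.read_csv(RESULTS / "lineages_unlabeled.tsv", sep="\t")
    lm = LineageMap(assignment=dict(zip(lin["strain"], lin["lineage"])), tau=cfg.tau)
    lm = label_endosphere_lineages(lm, detected)
    write_lineages_tsv(lm, RESULTS / "lineages.tsv")
    n_endo = len(lm.endosphere_associated)
    n_non = len(set(lm.assignment.values())) - n_endo
    print(f"Endosphere-associated lineages: {n_endo}; non-endosphere: {n_non}")


if __name__ == "__main__":
    main()
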