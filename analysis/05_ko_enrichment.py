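#!/usr/bin/env python
"""Lineage-level KO frequencies and the dual-threshold enrichment rule.

Scores each KO as present/absent per ANI lineage (any-genome rule) and calls
a KO endosphere-enriched if it occurs in >= 2 endosphere-associated lineages
and <= 4 of the non-endosphere lineages.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import RESULTS, SCRATCH, study_config

from defcom.ani import LineageMap
from defcom.io import read_annotations_tsv
from defcom.ko import enriched_ko_set, ko_enrichment_rule, lineage_presence, write_ko_tsv


def main() -> None:
    cfg = study_config()
    annotations = read_annotations_tsv(SCRATCH / "community" / "annotations.tsv")
    lin = pd.read_csv(RESULTS / "lineages.tsv", sep="\t")
    lm = LineageMap(
        assignment=dict(zip(lin["strain"], lin["lineage"])),
        tau=cfg.tau,
        endosphere_associated=set(lin.loc[lin["endosphere_flag"] == 1, "lineage"]),
    )
    presence = lineage_presence(annotations, lm)
    table = ko_enrichment_rule(presence, lm.endosphere_associated,
                               min_endo=cfg.min_endo, max_non=cfg.max_non)
    write_ko_tsv(table, RESULTS / "ko_enrichment.tsv")

    enriched = enriched_ko_set(table)
    truth = json.loads((SCRATCH / "community" / "ground_truth.json").read_text())
    planted = set(truth["planted_enriched_kos"])
    print(f"{len(enriched)} of {table.shape[0]} KOs enriched "
          f"(>= {cfg.min_endo} endosphere, <= {cfg.max_non} non-endosphere lineages)")
    print(f"Planted endosphere KOs recovered: {sorted(planted & enriched)} "
          f"of {sorted(planted)}")
    core_like = table[(table["endo_freq"] == 1.0) & (table["non_endo_freq"] == 1.0)]
    print(f"{len(core_like)} KOs are core (all lineages) and correctly not enriched: "
          f"{bool((~core_like['enriched']).all())}")


if __name__ == "__main__":
    main()
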