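"""Lineage-level KO presence/absence and the dual-threshold enrichment rule.

A KO is present in a lineage if any member genome carries at least one gene
with that KO. A KO is endosphere-enriched if it is present in at least
``min_endo`` endosphere-associated lineages and in no more than ``max_non``
non-endosphere lineages (defaults 2 and 4, matching a community partitioned
into 4 endosphere and 11 non-endosphere lineages).
"""

from __future__ import annotations

import pandas as pd

from .ani import LineageMap


def lineage_presence(annotations: pd.DataFrame, lm: LineageMap) -> pd.DataFrame:
    """Binary lineage x KO presence matrix (any-genome rule)."""
    ann = annotations.dropna(subset=["ko"])
    strains = set(annotations["strain_id"].unique())
    unassigned = strains - set(lm.assignment)
    if unassigned:
        raise ValueError(f"strains without lineage assignment: {sorted(unassigned)}")
    lineages = sorted(set(lm.assignment.values()))
    kos = sorted(ann["ko"].unique())
    mat = pd.DataFrame(0, index=lineages, columns=kos, dtype=int)
    lin_of = ann["strain_id"].map(lm.assignment)
    for (lin, ko), _ in ann.groupby([lin_of, "ko"]):
        mat.loc[lin, ko] = 1
    return mat


def ko_enrichment_rule(
    presence: pd.DataFrame,
    endosphere_lineages: set[str],
    min_endo: int = 2,
    max_non: int = 4,
) -> pd.DataFrame:
    """Dual-threshold enrichment over lineage presence counts.

    Returns one row per KO with counts, per-group frequencies (proportion of
    lineages in the group containing the KO) and the enriched flag.
    """
    endo = [l for l in presence.index if l in endosphere_lineages]
    non = [l for l in presence.index if l not in endosphere_lineages]
    if not endo or not non:
        raise ValueError("both endosphere and non-endosphere lineage groups must be non-empty")
    if min_endo > len(endo):
        raise ValueError(
            f"min_endo={min_endo} exceeds number of endosphere lineages ({len(endo)})"
        )
    endo_count = presence.loc[endo].sum(axis=0)
    non_count = presence.loc[non].sum(axis=0)
    out = pd.DataFrame(
        {
            "endo_count": endo_count,
            "non_endo_count": non_count,
            "endo_freq": endo_count / len(endo),
            "non_endo_freq": non_count / len(non),
            "enriched": (endo_count >= min_endo) & (non_count <= max_non),
        }
    )
    out.index.name = "ko"
    return out


def enriched_ko_set(rule_table: pd.DataFrame) -> set[str]:
    return set(rule_table.index[rule_table["enriched"]])


def write_ko_tsv(rule_table: pd.DataFrame, path) -> None:
    rule_table.to_csv(path, sep="\t", float_format="%.4f")
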