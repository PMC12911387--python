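"""Strain-level compartment enrichment and colonization-strategy labels.

Counts are TMM-normalized, voom-transformed, and fit with a moderated t on
the endosphere-vs-rhizosphere contrast (positive log2FC = endosphere
enrichment). Strains are then classified into colonization strategies from
the significance call and their mean CPM in each compartment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .linmodel import build_design, contrast_vector, moderated_fit, voom_transform
from .quant import CountMatrix, cpm_normalize, tmm_factors

STRATEGIES = (
    "strong_colonizer",
    "niche_specialist",
    "generalist",
    "rhizosphere_associated",
    "unclassified",
)


def strain_enrichment(
    cm: CountMatrix,
    alpha: float = 0.05,
    host: bool | None = None,
    interaction: bool = False,
    log2fc_from: str = "fit",
) -> pd.DataFrame:
    """Endosphere-vs-rhizosphere enrichment table for every feature.

    ``log2fc_from`` selects the reported fold change: "fit" (the moderated
    model coefficient, default) or "cpm" (log2 ratio of compartment mean
    CPM). Columns: log2fc, mean_cpm, t, p, q, significant.
    """
    design = cm.design
    if design is None:
        raise ValueError("count matrix carries no sample design")
    if host is None:
        host = design["host"].nunique() > 1
    factors = tmm_factors(cm)
    X = build_design(design, compartment=True, host=host, interaction=interaction)
    logcpm, weights = voom_transform(cm.counts, factors, X)
    res = moderated_fit(logcpm, weights, X, contrast_vector(X, "compartment"))
    table = res.table.copy()

    cpm = cpm_normalize(cm)
    endo = design.index[design["compartment"] == "endosphere"]
    rhizo = design.index[design["compartment"] == "rhizosphere"]
    table["mean_cpm"] = cpm.mean(axis=1)
    table["mean_cpm_endosphere"] = cpm[endo].mean(axis=1)
    table["mean_cpm_rhizosphere"] = cpm[rhizo].mean(axis=1)
    if log2fc_from == "cpm":
        table["log2fc"] = np.log2(
            (table["mean_cpm_endosphere"] + 0.5) / (table["mean_cpm_rhizosphere"] + 0.5)
        )
    elif log2fc_from != "fit":
        raise ValueError("log2fc_from must be 'fit' or 'cpm'")
    table["significant"] = table["q"] < alpha
    return table


def classify_strategies(
    table: pd.DataFrame,
    alpha: float = 0.05,
    abundance_quantile: float = 0.5,
) -> pd.Series:
    """Rule-based colonization strategy per strain.

    strong_colonizer: significant endosphere enrichment at moderate-to-high
    endosphere abundance; niche_specialist: significant enrichment below the
    abundance threshold; generalist: no compartment signal but high abundance
    in both compartments; rhizosphere_associated: significant depletion.
    """
    if not 0 < abundance_quantile < 1:
        raise ValueError("abundance_quantile must be in (0, 1)")
    endo = table["mean_cpm_endosphere"]
    rhizo = table["mean_cpm_rhizosphere"]
    thr_endo = endo.quantile(abundance_quantile)
    thr_rhizo = rhizo.quantile(abundance_quantile)
    sig = table["q"] < alpha
    up = sig & (table["log2fc"] > 0)
    down = sig & (table["log2fc"] < 0)
    labels = pd.Series("unclassified", index=table.index, name="strategy")
    labels[up & (endo >= thr_endo)] = "strong_colonizer"
    labels[up & (endo < thr_endo)] = "niche_specialist"
    labels[~sig & (endo >= thr_endo) & (rhizo >= thr_rhizo)] = "generalist"
    labels[down] = "rhizosphere_associated"
    return labels


def write_enrichment_tsv(table: pd.DataFrame, path, strategies: pd.Series | None = None) -> None:
    out = table.copy()
    if strategies is not None:
        out["strategy"] = strategies
    out.index.name = "feature"
    out.to_csv(path, sep="\t", float_format="%.6g")
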