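# defcom

Strain-resolved colonization analysis for defined bacterial communities
(DefComs): which strains of a synthetic consortium successfully colonize the
root endosphere versus the rhizosphere, and which gene functions travel with
them.

The package implements, as one tested pipeline, the analysis chain used in
strain-resolved root-microbiome studies where a community of closely related,
fully sequenced strains (here, *Variovorax*-like genomes sharing up to ≥98.5%
average nucleotide identity) is inoculated onto plants and profiled by shotgun
metagenomics:

1. **Synthetic community generator** — genomes descended from a common
   ancestor with controlled ANI structure, gene annotations (KO / COG /
   orthogroup), planted endosphere marker functions, log-normal strain
   abundances with compartment and host effects, and simulated reads whose
   names carry their true strain of origin. Every downstream claim is tested
   against this planted ground truth.
2. **ANI lineages** — pairwise ANI estimated from fragment-wise k-mer
   containment via the Mash distance relation, single-linkage clustering at a
   threshold τ (default 97%), and endosphere-association labels for lineages
   containing a dominant colonizer.
3. **Read quantification** — host-read filtering against a decoy genome, then
   competitive k-mer pseudo-mapping against all member genomes with either
   *unique* counting (reads tied between strains are discarded, preventing
   double-counting among near-identical genomes) or *fractional* counting
   (weight 1/n per tied strain); counts at strain, gene and orthogroup level
   with CPM and TMM normalization.
4. **Strain enrichment** — voom-transformed, precision-weighted linear models
   with empirical-Bayes moderated t statistics on the endosphere-vs-
   rhizosphere contrast (positive log₂FC = endosphere-enriched), BH-corrected,
   plus rule-based colonization-strategy labels (strong colonizer, niche
   specialist, generalist, rhizosphere-associated).
5. **KO frequency rule** — a KO is endosphere-enriched if present in ≥2
   endosphere-associated lineages and ≤4 non-endosphere lineages
   (presence = any genome in the lineage carries it).
6. **Functional diversity** — orthogroup richness and Shannon H, Bray–Curtis
   dissimilarity, non-metric multidimensional scaling (Kruskal stress-1), and
   sequential PERMANOVA partitioning variance between compartment and host.
7. **Consensus differential abundance** — three independent count-model
   procedures (negative-binomial Wald with median-of-ratios size factors;
   TMM + voom + moderated t; cumulative-sum scaling with zero-inflation
   weights), a consensus set requiring FDR < 0.05 agreement in all three with
   consistent direction, per-host analyses with set intersections, and the
   final intersection of consensus-orthogroup KOs with the lineage-level
   enriched KO set.

The statistical procedures are deliberately lightweight reimplementations of
the standard count-model families; the contract is calibrated error control
and a conservative consensus, not numerical identity with any external
package.

## Worked example

The numbered scripts under `analysis/` run a DefCom-scale study: 28 strains
in 15 ANI lineages with six planted dominant colonizers (one 3-strain lineage
plus three singletons), three planted endosphere marker KOs, 15 samples
(7 endosphere / 8 rhizosphere across two host species) at 20,000 reads each.

```bash
python analysis/01_simulate_community.py
python analysis/02_ani_lineages.py
python analysis/03_quantify_reads.py
python analysis/04_strain_enrichment.py
python analysis/05_ko_enrichment.py
python analysis/06_functional_diversity.py
python analysis/07_consensus_da.py
```

Output (abridged; tables land in `results/`):

```
k-mer ANI vs exact bookkeeping: max |error| = 0.608 percentage points (mean 0.392) over 378 pairs
tau=97.0: 15 lineages; exact recovery of planted partition: True
Assignment accuracy on non-discarded reads: 99.902%
Detected dominant colonizers: ['S00', 'S01', 'S02', 'S25', 'S26', 'S27']
Exact recovery: True
Endosphere-associated lineages: 4; non-endosphere: 11
3 of 60 KOs enriched (>= 2 endosphere, <= 4 non-endosphere lineages)
Planted endosphere KOs recovered: ['K90001', 'K90002', 'K90003'] of ['K90001', 'K90002', 'K90003']
richness: endosphere 138.57 vs rhizosphere 149.75 (Wilcoxon p=0.00099, ANOVA p=5.3e-07)
PERMANOVA compartment: R2 = 33.6% (F = 7.21, p = 0.001)
PERMANOVA host: R2 = 10.4% (F = 2.22, p = 0.036)
Consensus (all three methods, endosphere-enriched): 13 orthogroups; planted markers recovered: ['OGX0001', 'OGX0002', 'OGX0003']
Framework intersection: 3 KOs ... planted markers among them: ['K90001', 'K90002', 'K90003']
```

Reading this: the k-mer ANI estimator tracks the generator's exact
substitution bookkeeping to well under a percentage point; clustering at
τ = 97% recovers the planted 15-lineage partition exactly; the six planted
colonizers are the six strains classified `strong_colonizer`, which labels 4
of 15 lineages endosphere-associated; the lineage-level KO rule and the
orthogroup-level consensus each recover exactly the planted endosphere marker
functions and nothing else at the core; compartment explains the largest
share of orthogroup compositional variance, with a smaller host-species
contribution; and the endosphere shows the expected strain-bottleneck drop in
functional richness.

There is also a subcommand CLI over the same library (`defcom run-all`,
`defcom ani`, `defcom quantify`, `defcom enrich-strains`, `defcom enrich-kos`,
`defcom diversity`, `defcom da`), configured by YAML (`--config`, `--outdir`,
`--seed`); `defcom run-all` writes a manifest whose hash is identical across
reruns with the same configuration and seed.

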