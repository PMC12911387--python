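"""Host filtering, competitive read assignment, and count matrices.

Reads are pseudo-mapped by exact k-mer scoring (default k=31) against every
member genome: a read's score against a strain is the number of its k-mers
present in that strain's k-mer index. The best-scoring strains form the
read's candidate set; under the unique policy reads tied between strains are
discarded (no double-counting of near-identical genomes), under the
fractional policy each tied strain receives weight 1/|ties|. Counting is
unstranded and coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import Genome, ReadSet
from .kmers import kmer_codes_2d, kmer_index


@dataclass
class GenomeIndex:
    """k-mer postings for one or more strains.

    Per strain: sorted unique k-mer codes with leftmost positions. A merged
    sorted array with per-strain ownership bitmasks makes community-wide
    membership a single binary search per read batch.
    """

    k: int
    strain_ids: list[str]
    kmers: list[np.ndarray]      # sorted unique k-mer codes per strain
    positions: list[np.ndarray]  # leftmost position of each k-mer
    lengths: list[int]
    merged: np.ndarray = None    # sorted union of all strains' k-mers
    owners: np.ndarray = None    # uint64 bitmask per merged k-mer


def build_index(genomes: list[Genome] | dict[str, np.ndarray], k: int = 31) -> GenomeIndex:
    if isinstance(genomes, dict):
        items = [(sid, np.asarray(c, dtype=np.uint8)) for sid, c in genomes.items()]
    else:
        items = [(g.strain_id, g.seq) for g in genomes]
    if len(items) > 64:
        raise ValueError("GenomeIndex supports at most 64 strains")
    ids, kms, poss, lens = [], [], [], []
    for sid, codes in items:
        uniq, first = kmer_index(codes, k)
        ids.append(sid)
        kms.append(uniq)
        poss.append(first)
        lens.append(int(codes.size))
    merged = np.unique(np.concatenate(kms)) if kms else np.empty(0, np.uint64)
    owners = np.zeros(merged.size, dtype=np.uint64)
    for s, km in enumerate(kms):
        owners[np.searchsorted(merged, km)] |= np.uint64(1 << s)
    return GenomeIndex(
        k=k, strain_ids=ids, kmers=kms, positions=poss, lengths=lens,
        merged=merged, owners=owners,
    )


@dataclass
class AssignmentResult:
    """Per-read competitive assignment for one sample.

    ``table`` holds one row per (read, strain) assignment with columns
    read_idx, strain, pos, weight; discarded reads have no rows.
    """

    sample_id: str
    mode: str
    n_reads: int
    table: pd.DataFrame
    read_names: list[str]
    n_discarded_multi: int = 0
    n_below_floor: int = 0

    @property
    def total_weight(self) -> float:
        return float(self.table["weight"].sum())


def _read_kmer_membership(read_kmers: np.ndarray, index: GenomeIndex):
    """Membership masks of read k-mers against each strain.

    One binary search against the merged union array; per-strain masks are
    peeled off the ownership bitmasks.
    """
    flat = read_kmers.ravel()
    merged = index.merged
    if merged.size == 0:
        return [np.zeros(read_kmers.shape, bool) for _ in index.strain_ids]
    idx = np.searchsorted(merged, flat)
    idx[idx == merged.size] = merged.size - 1
    hit = merged[idx] == flat
    owner = np.where(hit, index.owners[idx], np.uint64(0))
    return [
        ((owner >> np.uint64(s)) & np.uint64(1)).astype(bool).reshape(read_kmers.shape)
        for s in range(len(index.strain_ids))
    ]


def filter_host_reads(
    reads: ReadSet, host_index: GenomeIndex, host_match_floor: float = 0.5
) -> ReadSet:
    """Drop reads whose k-mer match fraction to the host decoy >= the floor."""
    rk = kmer_codes_2d(reads.seqs, host_index.k)
    (mask,) = _read_kmer_membership(rk, host_index)
    frac = mask.mean(axis=1)
    keep = frac < host_match_floor
    return ReadSet(
        sample_id=reads.sample_id,
        names=[n for n, kf in zip(reads.names, keep) if kf],
        seqs=reads.seqs[keep],
    )


def assign_reads(
    reads: ReadSet,
    index: GenomeIndex,
    mode: str = "unique",
    min_score_fraction: float = 0.25,
) -> AssignmentResult:
    """Competitively assign reads to strains by shared k-mer count.

    A strain is a candidate if it achieves the maximum score and that score
    is at least ``min_score_fraction`` of the read's k-mers. Position is the
    leftmost anchoring k-mer match projected back to the read start.
    """
    if mode not in ("unique", "fractional"):
        raise ValueError(f"unknown mode {mode!r}")
    L = reads.seqs.shape[1]
    if L < index.k:
        raise ValueError(f"read length {L} shorter than index k={index.k}")
    rk = kmer_codes_2d(reads.seqs, index.k)
    n, m = rk.shape
    min_score = max(1, math.ceil(min_score_fraction * m))
    masks = _read_kmer_membership(rk, index)
    scores = np.stack([mk.sum(axis=1) for mk in masks], axis=1)  # (reads, strains)

    best = scores.max(axis=1)
    passed = best >= min_score
    is_best = (scores == best[:, None]) & passed[:, None]
    n_best = is_best.sum(axis=1)

    if mode == "unique":
        assigned = passed & (n_best == 1)
        n_discarded_multi = int((passed & (n_best > 1)).sum())
    else:
        assigned = passed
        n_discarded_multi = 0
    n_below_floor = int((~passed).sum())

    rows_r, rows_s, rows_p, rows_w = [], [], [], []
    offsets = np.arange(m)
    for s, (mk, km, pos_arr) in enumerate(zip(masks, index.kmers, index.positions)):
        sel = np.flatnonzero(assigned & is_best[:, s])
        if not sel.size:
            continue
        sub = mk[sel]
        first_off = sub.argmax(axis=1)  # first True column; scores >= 1 here
        anchor = rk[sel, first_off]
        idx = np.searchsorted(km, anchor)
        start = pos_arr[idx] - first_off
        rows_r.append(sel)
        rows_s.append(np.full(sel.size, s))
        rows_p.append(start)
        rows_w.append(np.where(n_best[sel] > 1, 1.0 / n_best[sel], 1.0))
    if rows_r:
        table = pd.DataFrame(
            {
                "read_idx": np.concatenate(rows_r),
                "strain": pd.Categorical.from_codes(
                    np.concatenate(rows_s), categories=index.strain_ids
                ),
                "pos": np.concatenate(rows_p),
                "weight": np.concatenate(rows_w),
            }
        ).sort_values("read_idx", kind="stable", ignore_index=True)
    else:
        table = pd.DataFrame(
            {
                "read_idx": np.empty(0, int),
                "strain": pd.Categorical([], categories=index.strain_ids),
                "pos": np.empty(0, int),
                "weight": np.empty(0, float),
            }
        )
    return AssignmentResult(
        sample_id=reads.sample_id,
        mode=mode,
        n_reads=n,
        table=table,
        read_names=reads.names,
        n_discarded_multi=n_discarded_multi,
        n_below_floor=n_below_floor,
    )


@dataclass
class CountMatrix:
    """Features x samples counts with the sample design attached."""

    counts: pd.DataFrame
    level: str
    design: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def with_counts(self, counts: pd.DataFrame, level: str | None = None) -> "CountMatrix":
        return CountMatrix(counts=counts, level=level or self.level, design=self.design, meta=dict(self.meta))


def _gene_of_reads(
    assign: AssignmentResult,
    annotations: pd.DataFrame,
    read_length: int,
) -> tuple[pd.DataFrame, int]:
    """Resolve each assignment row to a gene by largest overlap.

    Rows overlapping no gene, or tied between genes, are dropped (tie count
    returned for logging). Genes within a strain are assumed non-overlapping,
    so at most a handful of consecutive genes can overlap a read.
    """
    tbl = assign.table
    out_gene = np.full(len(tbl), -1, dtype=np.int64)  # positional row in `annotations`
    n_ties = 0
    gene_ids_all = annotations["gene_id"].to_numpy()
    for strain, grp in tbl.groupby("strain", observed=True):
        ann = annotations[annotations["strain_id"] == strain].sort_values("start")
        if ann.empty:
            continue
        starts = ann["start"].to_numpy()
        ends = ann["end"].to_numpy()
        gidx = ann.index.to_numpy()
        rows = grp.index.to_numpy()
        rs = grp["pos"].to_numpy()
        re = rs + read_length
        i0 = np.searchsorted(ends, rs, side="right")
        i1 = np.searchsorted(starts, re, side="left")
        n_cand = i1 - i0
        kmax = int(n_cand.max(initial=0))
        if kmax <= 0:
            continue
        cand = i0[:, None] + np.arange(kmax)[None, :]
        valid = cand < i1[:, None]
        cand_c = np.minimum(cand, len(starts) - 1)
        ov = np.minimum(ends[cand_c], re[:, None]) - np.maximum(starts[cand_c], rs[:, None])
        ov = np.where(valid, ov, -1)
        best = ov.max(axis=1)
        hit = best > 0
        winners = (ov == best[:, None]).sum(axis=1)
        tie = hit & (winners > 1)
        n_ties += int(tie.sum())
        ok = hit & ~tie
        choice = ov.argmax(axis=1)
        out_gene[rows[ok]] = gidx[np.minimum(i0[ok] + choice[ok], len(starts) - 1)]
    tbl = tbl.copy()
    tbl["gene"] = [gene_ids_all[i] if i >= 0 else None for i in out_gene]
    return tbl, n_ties


def count_matrix(
    assignments: dict[str, AssignmentResult],
    level: str,
    design: pd.DataFrame | None = None,
    annotations: pd.DataFrame | None = None,
    strain_ids: list[str] | None = None,
    read_length: int | None = None,
) -> CountMatrix:
    """Sum assignment weights into a strain- or gene-level count matrix."""
    if level not in ("strain", "gene"):
        raise ValueError("level must be 'strain' or 'gene'")
    if design is not None:
        missing = set(design.index) - set(assignments)
        if missing:
            raise ValueError(f"no assignments for samples: {sorted(missing)}")
    samples = list(assignments)
    meta: dict = {"discarded_multi": {}, "below_floor": {}, "gene_ties": {}}
    cols = {}
    if level == "strain":
        for sid, asg in assignments.items():
            cols[sid] = asg.table.groupby("strain", observed=False)["weight"].sum()
            meta["discarded_multi"][sid] = asg.n_discarded_multi
            meta["below_floor"][sid] = asg.n_below_floor
        counts = pd.DataFrame(cols)
        if strain_ids:
            counts = counts.reindex(strain_ids, fill_value=0.0)
    else:
        if annotations is None:
            raise ValueError("gene-level counting requires annotations")
        if read_length is None:
            raise ValueError("gene-level counting requires read_length")
        ann = annotations.reset_index(drop=True)
        for sid, asg in assignments.items():
            tbl, ties = _gene_of_reads(asg, ann, read_length)
            meta["gene_ties"][sid] = ties
            meta["discarded_multi"][sid] = asg.n_discarded_multi
            meta["below_floor"][sid] = asg.n_below_floor
            cols[sid] = tbl.dropna(subset=["gene"]).groupby("gene")["weight"].sum()
        counts = pd.DataFrame(cols).reindex(ann["gene_id"].unique(), fill_value=0.0)
    counts = counts.fillna(0.0)[samples]
    if design is not None:
        counts = counts[list(design.index)]
    return CountMatrix(counts=counts, level=level, design=design, meta=meta)


def aggregate_orthogroups(
    gene_counts: CountMatrix, annotations: pd.DataFrame, per_copy: bool = False
) -> CountMatrix:
    """Sum gene counts into orthogroups (optionally per gene copy).

    The per-copy denominator is the orthogroup's total gene-copy number
    across all community genomes (a constant per orthogroup).
    """
    pairs = annotations[["gene_id", "orthogroup"]].drop_duplicates()
    if pairs["gene_id"].duplicated().any():
        dup = pairs.loc[pairs["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"gene ids map to multiple orthogroups: {dup[:10]}")
    og_of = pairs.set_index("gene_id")["orthogroup"]
    missing = [g for g in gene_counts.counts.index if g not in og_of.index]
    if missing:
        raise ValueError(f"genes without orthogroup annotation: {missing[:10]}")
    ogs = og_of.loc[gene_counts.counts.index]
    agg = gene_counts.counts.groupby(ogs.to_numpy()).sum()
    all_ogs = sorted(annotations["orthogroup"].unique())
    agg = agg.reindex(all_ogs, fill_value=0.0)
    if per_copy:
        copies = annotations.groupby("orthogroup")["gene_id"].count().reindex(all_ogs)
        agg = agg.div(copies, axis=0)
    out = gene_counts.with_counts(agg, level="orthogroup")
    out.meta["per_copy"] = per_copy
    return out


def cpm_normalize(m: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts per million: cpm[f, s] = counts[f, s] / colsum(s) * 1e6."""
    counts = m.counts if isinstance(m, CountMatrix) else m
    colsum = counts.sum(axis=0)
    zero = colsum[colsum <= 0]
    if len(zero):
        raise ValueError(f"zero column sum for sample(s): {list(zero.index)}")
    return counts.div(colsum, axis=1) * 1e6


def tmm_factors(
    m: CountMatrix | pd.DataFrame,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, rescaled to geometric mean 1.

    The reference sample is the one whose upper-quartile/library-size ratio
    is closest to the mean of those ratios. M and A are computed over
    doubly-nonzero features; 30% of each M tail and 5% of each A tail are
    trimmed; the factor is 2 to the precision-weighted mean M (delta-method
    binomial weights).
    """
    counts = (m.counts if isinstance(m, CountMatrix) else m).to_numpy(dtype=float)
    samples = list((m.counts if isinstance(m, CountMatrix) else m).columns)
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    lib = counts.sum(axis=0)
    f75 = np.array([np.quantile(counts[:, i] / lib[i], 0.75) for i in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(counts.shape[1])
    for i in range(counts.shape[1]):
        factors[i] = _tmm_pair(
            counts[:, i], counts[:, ref], lib[i], lib[ref], logratio_trim, sum_trim
        )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=samples, name="tmm_factor")


def _tmm_pair(obs, ref, n_obs, n_ref, logratio_trim, sum_trim) -> float:
    from scipy.stats import rankdata

    both = (obs > 0) & (ref > 0)
    o, r = obs[both], ref[both]
    if o.size == 0:
        return 1.0
    logR = np.log2((o / n_obs) / (r / n_ref))
    absE = (np.log2(o / n_obs) + np.log2(r / n_ref)) / 2
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(logR)) < 1e-6:
        return 1.0
    n = o.size
    loL = np.floor(n * logratio_trim) + 1
    hiL = n + 1 - loL
    loS = np.floor(n * sum_trim) + 1
    hiS = n + 1 - loS
    rL = rankdata(logR)
    rS = rankdata(absE)
    keep = (rL >= loL) & (rL <= hiL) & (rS >= loS) & (rS <= hiS)
    if not keep.any():
        return 1.0
    f = np.sum(logR[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)
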