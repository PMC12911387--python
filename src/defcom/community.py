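"""Synthetic defined-community (DefCom) generator.

Builds a community of bacterial strains descended from a common synthetic
ancestor, with controlled average nucleotide identity (ANI) structure:
strains inside a lineage differ by a small substitution rate, lineages are
separated by a larger one. Gene content varies through whole-gene accessory
deletions and insertions, which is how endosphere-associated functions (KO /
orthogroup labels) are planted into chosen lineages. Read sets are simulated
under a log-normal strain-abundance model with compartment (endosphere vs
rhizosphere) and host effects, optional host-read contamination, and i.i.d.
substitution sequencing errors.

Design notes
------------
* Divergence is substitution-only on the shared (core) backbone; indels are
  confined to whole-gene accessory edits. Every strain therefore stays
  colinear with the root ancestor and the true ANI of any pair is an exact
  integer computation from the recorded substitution bookkeeping.
* Read names carry provenance tags (strain of origin, start position, host
  flag) so downstream assignment accuracy is directly measurable.
* Randomness: each operation consumes its own child of a
  ``numpy.random.SeedSequence``, so identical (config, seed) pairs give
  byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kmers import decode_sequence

_COG_LETTERS = "CEFGHIJKLMNOPQTUV"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """A strain genome, tracked relative to its root ancestor.

    ``sub_pos``/``sub_base`` record substitutions in root-ancestor
    coordinates; ``deleted_genes`` and ``inserted`` record whole-gene
    accessory edits. ``seq`` is the emitted sequence (core with deletions
    excised, accessory genes appended).
    """

    strain_id: str
    seq: np.ndarray
    ancestor_id: str
    sub_pos: np.ndarray
    sub_base: np.ndarray
    deleted_genes: frozenset = frozenset()
    inserted: tuple = ()  # tuple of (annotation row dict, seq codes)
    root_seq: np.ndarray | None = None
    root_annot: pd.DataFrame | None = None

    @property
    def sequence(self) -> str:
        return decode_sequence(self.seq)

    @property
    def substitution_positions(self) -> set[int]:
        return set(int(p) for p in self.sub_pos)

    def __len__(self) -> int:
        return int(self.seq.size)


@dataclass
class GroundTruth:
    """Planted truth emitted by the generator, for recovery testing."""

    true_ani: pd.DataFrame
    lineage_assignment: dict[str, str]
    planted_enriched_kos: set[str]
    planted_enriched_ogs: set[str]
    true_abundance: pd.DataFrame | None = None  # samples x strains


@dataclass
class Community:
    genomes: list[Genome]
    annotations: pd.DataFrame
    ground_truth: GroundTruth
    ancestor: Genome

    @property
    def strain_ids(self) -> list[str]:
        return [g.strain_id for g in self.genomes]

    def genome(self, strain_id: str) -> Genome:
        for g in self.genomes:
            if g.strain_id == strain_id:
                return g
        raise KeyError(strain_id)


@dataclass
class LineageSpec:
    """One ANI lineage: ``divergence`` is each member's substitution rate
    from the (hidden) lineage founder, so expected within-lineage pairwise
    divergence is ~2x this value."""

    n_strains: int
    divergence: float = 0.004


@dataclass
class PlantedFeature:
    """A functional marker gene inserted into every strain of the carrier
    lineages (0-based lineage indices into the config's lineage list)."""

    ko: str | None
    orthogroup: str
    lineages: tuple[int, ...]
    endosphere: bool = True
    gene_length: int = 900


@dataclass
class CommunityConfig:
    lineages: list[LineageSpec]
    genome_length: int = 500_000
    gc: float = 0.6
    n_genes: int = 450
    gene_length: int = 900
    ko_fraction: float = 0.6
    founder_divergence: float = 0.04  # each founder vs root; pairwise ~2x
    planted: list[PlantedFeature] = field(default_factory=list)
    n_private_genes: int = 3
    n_deleted_genes: int = 5
    private_gene_length: int = 900
    ani_within_min: float = 98.5
    ani_between_max: float = 95.0

    @property
    def n_strains(self) -> int:
        return sum(l.n_strains for l in self.lineages)


@dataclass
class AbundanceModel:
    """Log-normal strain abundances with compartment / host log2 effects."""

    base_log_mean: float = 0.0
    base_log_sd: float = 0.35
    compartment_effects: dict[str, float] = field(default_factory=dict)
    host_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    depth: int = 50_000
    host_read_fraction: float = 0.0
    error_rate: float = 0.005
    read_length: int = 150

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.error_rate < 0.05:
            raise ValueError("error_rate must be in [0, 0.05)")
        if not 0 <= self.host_read_fraction < 1:
            raise ValueError("host_read_fraction must be in [0, 1)")
        for v in self.compartment_effects.values():
            if not np.isfinite(v):
                raise ValueError("compartment effects must be finite")


@dataclass
class ReadSet:
    """Fixed-length single-end reads for one sample."""

    sample_id: str
    names: list[str]
    seqs: np.ndarray  # (n_reads, read_length) uint8 codes

    def __len__(self) -> int:
        return int(self.seqs.shape[0])


def make_design(
    n_endosphere: int = 7,
    n_rhizosphere: int = 8,
    hosts: tuple[str, str] = ("speciesA", "speciesB"),
) -> pd.DataFrame:
    """Sample design table: compartments split across two host species.

    The default 7 endosphere / 8 rhizosphere samples alternate hosts so every
    host x compartment cell keeps at least 3 replicates.
    """
    rows = []
    for comp, n in (("endosphere", n_endosphere), ("rhizosphere", n_rhizosphere)):
        for i in range(n):
            host = hosts[i % 2]
            rows.append((comp, host, i // 2 + 1))
    df = pd.DataFrame(rows, columns=["compartment", "host", "replicate"])
    df["sample_id"] = [
        f"{r.host[-1]}_{r.compartment[:4]}_{r.replicate}" for r in df.itertuples()
    ]
    return df.set_index("sample_id")[["host", "compartment", "replicate"]]


# ---------------------------------------------------------------------------
# ancestor and strain derivation
# ---------------------------------------------------------------------------

def generate_ancestor(
    length: int,
    gc: float,
    n_genes: int,
    gene_length: int,
    seed: int,
    ko_fraction: float = 0.6,
    strain_id: str = "ancestor",
) -> tuple[Genome, pd.DataFrame]:
    """Random ancestor genome with non-overlapping genes.

    Genes each get a unique orthogroup; a ``ko_fraction`` subset also gets a
    KO id and a COG category letter. Raises if the genes cannot be packed
    into 90% of the genome.
    """
    if n_genes * gene_length > 0.9 * length:
        raise ValueError(
            f"infeasible packing: {n_genes} genes x {gene_length} bp exceed "
            f"90% of genome length {length}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(4, size=length, p=p).astype(np.uint8)

    free = length - n_genes * gene_length
    cuts = np.sort(rng.integers(0, free + 1, size=n_genes))
    starts = cuts + np.arange(n_genes) * gene_length
    strands = rng.choice(np.array(["+", "-"]), size=n_genes)
    has_ko = rng.random(n_genes) < ko_fraction
    kos = [f"K{10000 + i:05d}" if h else None for i, h in enumerate(has_ko)]
    cogs = [
        _COG_LETTERS[rng.integers(len(_COG_LETTERS))] if h else None for h in has_ko
    ]
    annot = pd.DataFrame(
        {
            "gene_id": [f"g{i:04d}" for i in range(n_genes)],
            "strain_id": strain_id,
            "start": starts,
            "end": starts + gene_length,
            "strand": strands,
            "ko": kos,
            "cog": cogs,
            "orthogroup": [f"OG{i:05d}" for i in range(n_genes)],
        }
    )
    genome = Genome(
        strain_id=strain_id,
        seq=seq,
        ancestor_id=strain_id,
        sub_pos=np.empty(0, dtype=np.int64),
        sub_base=np.empty(0, dtype=np.uint8),
        root_seq=seq,
        root_annot=annot,
    )
    return genome, annot


def _deleted_intervals(genome: Genome) -> np.ndarray:
    """(n, 2) array of deleted root-coordinate intervals, sorted, disjoint."""
    if not genome.deleted_genes:
        return np.empty((0, 2), dtype=np.int64)
    ra = genome.root_annot
    rows = ra[ra.gene_id.isin(genome.deleted_genes)].sort_values("start")
    return rows[["start", "end"]].to_numpy(dtype=np.int64)


def _emit(genome: Genome) -> Genome:
    """Materialize ``seq`` from root sequence + subs + deletions + insertions."""
    seq = genome.root_seq.copy()
    seq[genome.sub_pos] = genome.sub_base
    ivals = _deleted_intervals(genome)
    if len(ivals):
        keep = np.ones(seq.size, dtype=bool)
        for s, e in ivals:
            keep[s:e] = False
        seq = seq[keep]
    if genome.inserted:
        seq = np.concatenate([seq] + [s for _, s in genome.inserted])
    genome.seq = seq
    return genome


def strain_annotation(genome: Genome) -> pd.DataFrame:
    """Gene annotation of a derived strain in its own emitted coordinates."""
    ra = genome.root_annot
    keep = ra[~ra.gene_id.isin(genome.deleted_genes)].copy()
    ivals = _deleted_intervals(genome)
    if len(ivals):
        # shift = total deleted length left of each gene start
        del_starts = ivals[:, 0]
        del_lens = (ivals[:, 1] - ivals[:, 0]).cumsum()
        idx = np.searchsorted(del_starts, keep["start"].to_numpy(), side="right")
        shift = np.where(idx > 0, del_lens[idx - 1], 0)
        keep["start"] = keep["start"].to_numpy() - shift
        keep["end"] = keep["end"].to_numpy() - shift
    keep["strain_id"] = genome.strain_id
    offset = int(genome.root_seq.size - (ivals[:, 1] - ivals[:, 0]).sum() if len(ivals) else genome.root_seq.size)
    rows = []
    for rec, seqcodes in genome.inserted:
        rec = dict(rec)
        rec.update(
            strain_id=genome.strain_id,
            start=offset,
            end=offset + len(seqcodes),
            strand="+",
        )
        offset += len(seqcodes)
        rows.append(rec)
    if rows:
        keep = pd.concat([keep, pd.DataFrame(rows)], ignore_index=True)
    return keep.reset_index(drop=True)


def derive_strain(
    parent: Genome,
    target_divergence: float,
    seed: int,
    strain_id: str | None = None,
    delete_genes: tuple[str, ...] = (),
    insert_genes: tuple[dict, ...] = (),
    gc: float = 0.5,
) -> tuple[Genome, pd.DataFrame]:
    """Derive a strain by substitutions plus whole-gene accessory edits.

    Substitutions are placed i.i.d. at rate ``target_divergence`` over the
    parent's core backbone (root coordinates outside deleted genes); each
    substituted base is guaranteed to differ from the parent base, so the
    realized divergence from the parent equals the substituted fraction
    exactly. ``insert_genes`` entries are dicts with keys gene_id, ko, cog,
    orthogroup and optional length (default 900); their sequence is random at
    the given GC.
    """
    if not 0 <= target_divergence <= 0.2:
        raise ValueError("target_divergence must be in [0, 0.2]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    root_len = parent.root_seq.size
    core_mask = np.ones(root_len, dtype=bool)
    for s, e in _deleted_intervals(parent):
        core_mask[s:e] = False
    core_positions = np.flatnonzero(core_mask)

    hit = rng.random(core_positions.size) < target_divergence
    new_pos = core_positions[hit]
    parent_base = parent.root_seq[new_pos].copy()
    if parent.sub_pos.size:
        inherit = np.searchsorted(parent.sub_pos, new_pos)
        inherit[inherit == parent.sub_pos.size] = parent.sub_pos.size - 1
        m = parent.sub_pos[inherit] == new_pos
        parent_base[m] = parent.sub_base[inherit[m]]
    # new base differs from the parent's base at that position
    new_base = ((parent_base + rng.integers(1, 4, size=new_pos.size)) % 4).astype(np.uint8)

    pos = np.concatenate([parent.sub_pos, new_pos])
    base = np.concatenate([parent.sub_base, new_base])
    order = np.argsort(pos, kind="stable")
    pos, base = pos[order], base[order]
    # overwrite inherited substitutions that were re-hit (keep the last)
    keep = np.ones(pos.size, dtype=bool)
    keep[:-1] = pos[1:] != pos[:-1]
    # stable sort puts inherited first; keep marks the last occurrence
    pos, base = pos[keep], base[keep]
    # drop substitutions that revert to the root base (possible on re-hit)
    differs = parent.root_seq[pos] != base
    pos, base = pos[differs], base[differs]

    current = strain_annotation(parent)
    for gid in delete_genes:
        if gid not in set(current.gene_id):
            raise ValueError(f"accessory gene {gid!r} absent from parent annotation")
    root_ids = set(parent.root_annot.gene_id)
    extra_inherited = []
    deletions = set(parent.deleted_genes)
    inherited_inserts = list(parent.inserted)
    for gid in delete_genes:
        if gid in root_ids:
            deletions.add(gid)
        else:
            inherited_inserts = [(r, s) for r, s in inherited_inserts if r["gene_id"] != gid]

    new_inserts = []
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    for spec in insert_genes:
        spec = dict(spec)
        glen = int(spec.pop("length", 900))
        master = spec.pop("sequence", None)
        mrate = float(spec.pop("mutate_rate", 0.0))
        if master is not None:
            # homologous copy of a shared gene, diverged per strain
            gseq = np.asarray(master, dtype=np.uint8).copy()
            if mrate > 0:
                hitm = rng.random(gseq.size) < mrate
                gseq[hitm] = (gseq[hitm] + rng.integers(1, 4, int(hitm.sum()))) % 4
        else:
            gseq = rng.choice(4, size=glen, p=p).astype(np.uint8)
        rec = {
            "gene_id": spec["gene_id"],
            "strain_id": "",
            "start": 0,
            "end": glen,
            "strand": "+",
            "ko": spec.get("ko"),
            "cog": spec.get("cog"),
            "orthogroup": spec["orthogroup"],
        }
        new_inserts.append((rec, gseq))

    child = Genome(
        strain_id=strain_id or f"{parent.strain_id}.d",
        seq=np.empty(0, dtype=np.uint8),
        ancestor_id=parent.ancestor_id,
        sub_pos=pos,
        sub_base=base,
        deleted_genes=frozenset(deletions),
        inserted=tuple(inherited_inserts + extra_inherited + new_inserts),
        root_seq=parent.root_seq,
        root_annot=parent.root_annot,
    )
    _emit(child)
    return child, strain_annotation(child)


def true_ani(a: Genome, b: Genome) -> float:
    """Exact ANI over the shared core backbone, from substitution records."""
    if a.ancestor_id != b.ancestor_id:
        raise ValueError("genomes do not share a root ancestor")
    del_union = {*a.deleted_genes, *b.deleted_genes}
    ra = a.root_annot
    root_len = a.root_seq.size
    if del_union:
        rows = ra[ra.gene_id.isin(del_union)]
        shared_len = root_len - int((rows.end - rows.start).sum())
        ivals = rows.sort_values("start")[["start", "end"]].to_numpy(dtype=np.int64)
    else:
        shared_len = root_len
        ivals = np.empty((0, 2), dtype=np.int64)

    def in_core(pos):
        if not len(ivals) or not pos.size:
            return np.ones(pos.size, dtype=bool)
        idx = np.searchsorted(ivals[:, 0], pos, side="right")
        inside = (idx > 0) & (pos < ivals[np.maximum(idx - 1, 0), 1])
        return ~inside

    pa, ba = a.sub_pos[in_core(a.sub_pos)], a.sub_base[in_core(a.sub_pos)]
    pb, bb = b.sub_pos[in_core(b.sub_pos)], b.sub_base[in_core(b.sub_pos)]
    common, ia, ib = np.intersect1d(pa, pb, return_indices=True)
    diff = (pa.size - common.size) + (pb.size - common.size)
    diff += int((ba[ia] != bb[ib]).sum())
    return 100.0 * (1.0 - diff / shared_len)


# ---------------------------------------------------------------------------
# community assembly
# ---------------------------------------------------------------------------

def build_community(config: CommunityConfig, seed: int) -> Community:
    """Assemble genomes, annotations and ground truth from a config.

    Raises if the realized true ANI violates the configured within/between
    thresholds (infeasible divergence settings).
    """
    ss = np.random.SeedSequence(seed)
    seeds = iter(s.generate_state(1)[0] % (2**31) for s in ss.spawn(4096))
    ancestor, _ = generate_ancestor(
        config.genome_length,
        config.gc,
        config.n_genes,
        config.gene_length,
        seed=int(next(seeds)),
        ko_fraction=config.ko_fraction,
    )
    rng = np.random.default_rng(np.random.SeedSequence(int(next(seeds))))
    root_gene_ids = list(ancestor.root_annot.gene_id)
    planted_by_lineage: dict[int, list[PlantedFeature]] = {}
    for f in config.planted:
        for li in f.lineages:
            planted_by_lineage.setdefault(li, []).append(f)
    # one master sequence per planted feature; carriers receive diverged copies
    p_nt = np.array([(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2])
    master_seq = {
        f.orthogroup: rng.choice(4, size=f.gene_length, p=p_nt).astype(np.uint8)
        for f in config.planted
    }

    genomes: list[Genome] = []
    annots: list[pd.DataFrame] = []
    lineage_members: list[list[str]] = []
    idx = 0
    for li, lin in enumerate(config.lineages):
        founder, _ = derive_strain(
            ancestor,
            config.founder_divergence,
            seed=int(next(seeds)),
            strain_id=f"F{li}",
            gc=config.gc,
        )
        members = []
        for _m in range(lin.n_strains):
            sid = f"S{idx:02d}"
            idx += 1
            deleted = tuple(
                rng.choice(root_gene_ids, size=config.n_deleted_genes, replace=False)
            ) if config.n_deleted_genes else ()
            inserts = [
                {
                    "gene_id": f"{sid}_p{j}",
                    "orthogroup": f"OGP_{sid}_{j}",
                    "ko": None,
                    "cog": None,
                    "length": config.private_gene_length,
                }
                for j in range(config.n_private_genes)
            ]
            for feat in planted_by_lineage.get(li, []):
                inserts.append(
                    {
                        "gene_id": f"{sid}_{feat.orthogroup}",
                        "orthogroup": feat.orthogroup,
                        "ko": feat.ko,
                        "cog": None,
                        "length": feat.gene_length,
                        "sequence": master_seq[feat.orthogroup],
                        "mutate_rate": lin.divergence + config.founder_divergence / 2,
                    }
                )
            g, a = derive_strain(
                founder,
                lin.divergence,
                seed=int(next(seeds)),
                strain_id=sid,
                delete_genes=deleted,
                insert_genes=tuple(inserts),
                gc=config.gc,
            )
            genomes.append(g)
            annots.append(a)
            members.append(sid)
        lineage_members.append(members)

    strain_ids = [g.strain_id for g in genomes]
    n = len(strain_ids)
    ani = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ani[i, j] = ani[j, i] = true_ani(genomes[i], genomes[j])
    ani_df = pd.DataFrame(ani, index=strain_ids, columns=strain_ids)

    lineage_of = {}
    for members in lineage_members:
        lid = min(members)
        for m in members:
            lineage_of[m] = lid
    # validate configured thresholds against realized ANI
    for i in range(n):
        for j in range(i + 1, n):
            same = lineage_of[strain_ids[i]] == lineage_of[strain_ids[j]]
            if same and ani[i, j] < config.ani_within_min:
                raise ValueError(
                    f"within-lineage ANI {ani[i, j]:.2f} below configured "
                    f"minimum {config.ani_within_min}: thresholds infeasible"
                )
            if not same and ani[i, j] > config.ani_between_max:
                raise ValueError(
                    f"between-lineage ANI {ani[i, j]:.2f} above configured "
                    f"maximum {config.ani_between_max}: thresholds infeasible"
                )

    gt = GroundTruth(
        true_ani=ani_df,
        lineage_assignment=lineage_of,
        planted_enriched_kos={f.ko for f in config.planted if f.endosphere and f.ko},
        planted_enriched_ogs={f.orthogroup for f in config.planted if f.endosphere},
    )
    annotations = pd.concat(annots, ignore_index=True)
    return Community(genomes=genomes, annotations=annotations, ground_truth=gt, ancestor=ancestor)


# ---------------------------------------------------------------------------
# abundance and read simulation
# ---------------------------------------------------------------------------

def sample_abundances(
    design: pd.DataFrame, model: AbundanceModel, strain_ids: list[str], seed: int
) -> pd.DataFrame:
    """True per-sample strain proportions (samples x strains, rows sum to 1)."""
    if design.empty:
        raise ValueError("empty sample design")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = np.zeros((len(design), len(strain_ids)))
    comp_eff = np.array([model.compartment_effects.get(s, 0.0) for s in strain_ids])
    for r, (sid, row) in enumerate(design.iterrows()):
        base = np.exp(rng.normal(model.base_log_mean, model.base_log_sd, len(strain_ids)))
        host_eff = np.array(
            [model.host_effects.get((s, row.host), 0.0) for s in strain_ids]
        )
        w = base * np.exp2(host_eff)
        if row.compartment == "endosphere":
            w = w * np.exp2(comp_eff)
        out[r] = w / w.sum()
    return pd.DataFrame(out, index=design.index, columns=strain_ids)


def simulate_strain_counts(
    design: pd.DataFrame, model: AbundanceModel, strain_ids: list[str], seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multinomial strain read counts at the model depth (strains x samples).

    A read-level shortcut for statistical simulations: equivalent to
    simulating reads and assigning them without error or ties.
    """
    ss = np.random.SeedSequence(seed)
    s_ab, s_cnt = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    abund = sample_abundances(design, model, strain_ids, s_ab)
    rng = np.random.default_rng(np.random.SeedSequence(s_cnt))
    counts = np.vstack(
        [rng.multinomial(model.depth, abund.loc[s].to_numpy()) for s in design.index]
    ).T
    return pd.DataFrame(counts, index=strain_ids, columns=design.index), abund


def generate_host_decoy(length: int, gc: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _apply_errors(reads: np.ndarray, error_rate: float, rng) -> np.ndarray:
    if error_rate <= 0:
        return reads
    mask = rng.random(reads.shape) < error_rate
    shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
    reads[mask] = (reads[mask] + shift) % 4
    return reads


def simulate_reads(
    community: Community,
    design: pd.DataFrame,
    model: AbundanceModel,
    seed: int,
    host_seq: np.ndarray | None = None,
) -> tuple[dict[str, ReadSet], pd.DataFrame]:
    """Simulate single-end read sets for every sample in the design.

    Returns the per-sample ReadSets and the true strain proportions (also
    stored on the community's ground truth). Read names carry
    ``strain=<id>|pos=<start>|host=<0/1>`` provenance tags.
    """
    if design.empty:
        raise ValueError("empty sample design")
    L = model.read_length
    for g in community.genomes:
        if len(g) < L:
            raise ValueError(f"read length {L} exceeds genome {g.strain_id}")
    if model.host_read_fraction > 0 and host_seq is None:
        raise ValueError("host_read_fraction > 0 requires a host decoy sequence")
    ss = np.random.SeedSequence(seed)
    s_ab, s_reads = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    strain_ids = community.strain_ids
    abund = sample_abundances(design, model, strain_ids, s_ab)
    rng = np.random.default_rng(np.random.SeedSequence(s_reads))

    readsets: dict[str, ReadSet] = {}
    for sid in design.index:
        p = abund.loc[sid].to_numpy()
        is_host = rng.random(model.depth) < model.host_read_fraction
        n_host = int(is_host.sum())
        n_comm = model.depth - n_host
        strain_idx = rng.choice(len(strain_ids), size=n_comm, p=p)
        seqs = np.empty((model.depth, L), dtype=np.uint8)
        names: list[str] = [""] * model.depth
        comm_rows = np.flatnonzero(~is_host)
        host_rows = np.flatnonzero(is_host)
        for k, g in enumerate(community.genomes):
            rows = comm_rows[strain_idx == k]
            if not rows.size:
                continue
            starts = rng.integers(0, len(g) - L + 1, size=rows.size)
            seqs[rows] = g.seq[starts[:, None] + np.arange(L)[None, :]]
            for r, st in zip(rows, starts):
                names[r] = f"{sid}_r{r}|strain={strain_ids[k]}|pos={st}|host=0"
        if n_host:
            starts = rng.integers(0, host_seq.size - L + 1, size=n_host)
            seqs[host_rows] = host_seq[starts[:, None] + np.arange(L)[None, :]]
            for r, st in zip(host_rows, starts):
                names[r] = f"{sid}_r{r}|strain=host|pos={st}|host=1"
        seqs = _apply_errors(seqs, model.error_rate, rng)
        readsets[sid] = ReadSet(sample_id=sid, names=names, seqs=seqs)

    community.ground_truth.true_abundance = abund
    return readsets, abund


# ---------------------------------------------------------------------------
# feature-level count simulation (orthogroup differential-abundance studies)
# ---------------------------------------------------------------------------

def simulate_feature_counts(
    n_features: int,
    design: pd.DataFrame,
    seed: int,
    planted: dict[str, float] | None = None,
    base_log_mean: float = 4.0,
    base_log_sd: float = 1.2,
    dispersion: float = 0.1,
    depth: int = 200_000,
    libsize_sd: float = 0.25,
) -> tuple[pd.DataFrame, set[str]]:
    """Negative-binomial feature counts with planted endosphere log2 effects.

    Features are named F0000..; ``planted`` maps feature name -> log2 fold
    change applied in endosphere samples, on top of an unchanged baseline
    (library size varies log-normally, so normalization is exercised). Counts
    are NB with the given dispersion. Returns (features x samples counts,
    planted feature set).
    """
    planted = planted or {}
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    feats = [f"F{i:04d}" for i in range(n_features)]
    base = np.exp(rng.normal(base_log_mean, base_log_sd, n_features))
    base = base / base.sum()
    eff = np.array([planted.get(f, 0.0) for f in feats])
    lib = depth * np.exp(rng.normal(0.0, libsize_sd, len(design)))
    is_endo = (design["compartment"] == "endosphere").to_numpy()
    mu = lib[None, :] * base[:, None] * np.exp2(eff[:, None] * is_endo[None, :])
    if dispersion > 0:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam)
    return (
        pd.DataFrame(counts, index=feats, columns=design.index),
        set(planted),
    )
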