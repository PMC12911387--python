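"""File formats: FASTA genomes, gzip FASTQ reads, TSV tables, JSON truth.

FASTA and FASTQ go through Biopython; gzip members are written with a fixed
mtime so identical runs produce byte-identical archives.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .community import Community, GroundTruth, ReadSet
from .kmers import decode_sequence, encode_sequence

ANNOT_COLUMNS = ["gene_id", "strain_id", "start", "end", "strand", "ko", "cog", "orthogroup"]


def write_genome_fasta(strain_id: str, codes: np.ndarray, path: Path) -> None:
    rec = SeqRecord(Seq(decode_sequence(codes)), id=strain_id, description="")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")


def read_genome_fasta(path: Path) -> dict[str, np.ndarray]:
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = encode_sequence(str(rec.seq))
    return out


def write_annotations_tsv(annotations: pd.DataFrame, path: Path) -> None:
    annotations[ANNOT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotations_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"ko": "string", "cog": "string"})
    df["ko"] = df["ko"].astype(object).where(df["ko"].notna(), None)
    df["cog"] = df["cog"].astype(object).where(df["cog"].notna(), None)
    return df


def write_design_tsv(design: pd.DataFrame, path: Path) -> None:
    design.to_csv(path, sep="\t")


def read_design_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_fastq_gz(reads: ReadSet, path: Path, quality_char: str = "I") -> None:
    raw = gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0, compresslevel=4)
    with raw:
        L = reads.seqs.shape[1]
        qual = quality_char * L
        lines = []
        for name, row in zip(reads.names, reads.seqs):
            lines.append(f"@{name}\n{decode_sequence(row)}\n+\n{qual}\n")
        raw.write("".join(lines).encode("ascii"))


def read_fastq_gz(path: Path, sample_id: str | None = None) -> ReadSet:
    names, rows = [], []
    with gzip.open(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            names.append(rec.description)
            rows.append(encode_sequence(str(rec.seq)))
    lengths = {r.size for r in rows}
    if len(lengths) > 1:
        raise ValueError("variable-length reads are not supported")
    seqs = np.vstack(rows) if rows else np.empty((0, 0), dtype=np.uint8)
    return ReadSet(sample_id=sample_id or Path(path).stem, names=names, seqs=seqs)


def write_ground_truth_json(gt: GroundTruth, path: Path) -> None:
    payload = {
        "true_ani": gt.true_ani.round(6).to_dict(),
        "lineage_assignment": gt.lineage_assignment,
        "planted_enriched_kos": sorted(gt.planted_enriched_kos),
        "planted_enriched_ogs": sorted(gt.planted_enriched_ogs),
        "true_abundance": None
        if gt.true_abundance is None
        else gt.true_abundance.round(8).to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_community(community: Community, outdir: Path) -> dict[str, str]:
    """Write genomes, annotations and ground truth; returns a path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    gdir = outdir / "genomes"
    gdir.mkdir(exist_ok=True)
    for g in community.genomes:
        p = gdir / f"{g.strain_id}.fasta"
        write_genome_fasta(g.strain_id, g.seq, p)
        paths[f"genome:{g.strain_id}"] = str(p)
    ap = outdir / "annotations.tsv"
    write_annotations_tsv(community.annotations, ap)
    paths["annotations"] = str(ap)
    tp = outdir / "ground_truth.json"
    write_ground_truth_json(community.ground_truth, tp)
    paths["ground_truth"] = str(tp)
    return paths
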