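"""k-mer average nucleotide identity (ANI) and lineage clustering.

ANI is estimated fragment-wise, in the spirit of fragment-mapping ANI tools:
the query genome is split into non-overlapping fragments, each fragment's
k-mer containment in the reference genome's full k-mer set is converted to a
per-fragment identity through the Mash distance relation, fragments below a
mapping floor (non-homologous / accessory regions) are discarded, and the
two directed estimates are averaged. Lineages are single-linkage connected
components of the ANI graph thresholded at tau (default 97%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .community import Genome
from .kmers import kmer_codes, member_mask


class NoOrthologousFraction(ValueError):
    """No fragment passed the mapping floor: the genomes share no
    detectable orthologous fraction at this k."""


@dataclass
class LineageMap:
    assignment: dict[str, str]
    tau: float
    endosphere_associated: set[str] = field(default_factory=set)

    @property
    def lineage_ids(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def members(self, lineage_id: str) -> list[str]:
        return sorted(s for s, l in self.assignment.items() if l == lineage_id)


def _as_codes(g) -> np.ndarray:
    return g.seq if isinstance(g, Genome) else np.asarray(g, dtype=np.uint8)


def _directed_ani(
    query: np.ndarray,
    ref_kmers_sorted: np.ndarray,
    k: int,
    fragment: int,
    min_jaccard: float,
) -> float:
    n_frag = query.size // fragment
    if n_frag == 0:
        raise ValueError(f"query shorter than one fragment ({fragment} bp)")
    identities = []
    for f in range(n_frag):
        frag = query[f * fragment : (f + 1) * fragment]
        km = np.unique(kmer_codes(frag, k))
        c = member_mask(km, ref_kmers_sorted).mean()
        j = c / (2.0 - c)  # Jaccard of two equal-size sets with containment c
        if j < min_jaccard:
            continue
        # Mash relation: 2J/(1+J) = c ; d = -(1/k) ln c ; identity = e^{-d}
        identities.append(100.0 * c ** (1.0 / k))
    if not identities:
        raise NoOrthologousFraction(
            "no orthologous fraction: no fragment passed the mapping floor"
        )
    return float(np.mean(identities))


def kmer_ani(
    a,
    b,
    k: int = 16,
    fragment: int = 3000,
    min_jaccard: float = 0.01,
) -> float:
    """Symmetric k-mer ANI (percent) between two genomes.

    Mean of the two directed fragment estimates. Raises
    :class:`NoOrthologousFraction` if either direction retains no fragment.
    """
    if not 11 <= k <= 31:
        raise ValueError("k must be in [11, 31]")
    ca, cb = _as_codes(a), _as_codes(b)
    if min(ca.size, cb.size) < fragment:
        raise ValueError("both sequences must be at least one fragment long")
    ka = np.unique(kmer_codes(ca, k))
    kb = np.unique(kmer_codes(cb, k))
    ab = _directed_ani(ca, kb, k, fragment, min_jaccard)
    ba = _directed_ani(cb, ka, k, fragment, min_jaccard)
    return 0.5 * (ab + ba)


def ani_matrix(
    genomes: list[Genome],
    k: int = 16,
    fragment: int = 3000,
    min_jaccard: float = 0.01,
) -> pd.DataFrame:
    """All-pairs symmetric ANI matrix (percent), diagonal 100."""
    ids = [g.strain_id for g in genomes]
    codes = [_as_codes(g) for g in genomes]
    kmers = [np.unique(kmer_codes(c, k)) for c in codes]
    n = len(ids)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ij = _directed_ani(codes[i], kmers[j], k, fragment, min_jaccard)
            ji = _directed_ani(codes[j], kmers[i], k, fragment, min_jaccard)
            m[i, j] = m[j, i] = 0.5 * (ij + ji)
    return pd.DataFrame(m, index=ids, columns=ids)


def cluster_lineages(ani: pd.DataFrame, tau: float = 97.0) -> LineageMap:
    """Single-linkage lineages: connected components of the ANI >= tau graph.

    Lineage ids are deterministic — the lexicographically smallest member
    strain id. Singletons are legitimate lineages.
    """
    if not 0 < tau <= 100:
        raise ValueError("tau must be in (0, 100]")
    ids = list(ani.index)
    adj = (ani.to_numpy() >= tau).astype(np.int8)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    assignment: dict[str, str] = {}
    for comp in range(n_comp):
        members = [ids[i] for i in np.flatnonzero(labels == comp)]
        lid = min(members)
        for mbr in members:
            assignment[mbr] = lid
    return LineageMap(assignment=assignment, tau=tau)


def label_endosphere_lineages(lm: LineageMap, dominant_strains: set[str]) -> LineageMap:
    """Flag lineages containing at least one dominant endosphere colonizer."""
    unknown = set(dominant_strains) - set(lm.assignment)
    if unknown:
        raise ValueError(f"unknown strain ids: {sorted(unknown)}")
    flagged = {lm.assignment[s] for s in dominant_strains}
    return LineageMap(assignment=dict(lm.assignment), tau=lm.tau, endosphere_associated=flagged)


def write_ani_tsv(ani: pd.DataFrame, path) -> None:
    ani.to_csv(path, sep="\t", float_format="%.4f")


def write_lineages_tsv(lm: LineageMap, path) -> None:
    rows = [
        (s, l, int(l in lm.endosphere_associated))
        for s, l in sorted(lm.assignment.items())
    ]
    pd.DataFrame(rows, columns=["strain", "lineage", "endosphere_flag"]).to_csv(
        path, sep="\t", index=False
    )
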