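"""Host filtering, competitive assignment policies, counting, and
normalization."""

import numpy as np
import pandas as pd
import pytest

from defcom.community import ReadSet
from defcom.quant import (
    CountMatrix,
    aggregate_orthogroups,
    assign_reads,
    build_index,
    count_matrix,
    cpm_normalize,
    filter_host_reads,
    tmm_factors,
)


def _reads_from(codes, starts, L, sample="s", tag="x"):
    seqs = np.stack([codes[s : s + L] for s in starts])
    names = [f"{sample}_r{i}|strain={tag}|pos={s}|host=0" for i, s in enumerate(starts)]
    return ReadSet(sample_id=sample, names=names, seqs=seqs)


@pytest.fixture(scope="module")
def two_strain_fixture():
    """Strain A and B identical on [0, 10kb), divergent (2%) on [10kb, 20kb)."""
    rng = np.random.default_rng(1)
    a = rng.integers(0, 4, 20_000).astype(np.uint8)
    b = a.copy()
    pos = 10_000 + np.flatnonzero(rng.random(10_000) < 0.02)
    b[pos] = (b[pos] + rng.integers(1, 4, pos.size)) % 4
    return a, b


class TestHostFilter:
    def test_decoy_read_removed_strain_read_kept(self, two_strain_fixture):
        a, _ = two_strain_fixture
        rng = np.random.default_rng(2)
        host = rng.integers(0, 4, 30_000).astype(np.uint8)
        hidx = build_index({"host": host}, k=31)
        host_reads = _reads_from(host, [100, 5000, 200], 150, tag="host")
        strain_reads = _reads_from(a, [100, 5000, 200], 150, tag="A")
        assert len(filter_host_reads(host_reads, hidx)) == 0
        assert len(filter_host_reads(strain_reads, hidx)) == 3

    def test_removed_count_binomial_band(self, two_strain_fixture):
        a, _ = two_strain_fixture
        rng = np.random.default_rng(3)
        host = rng.integers(0, 4, 30_000).astype(np.uint8)
        hidx = build_index({"host": host}, k=31)
        n = 1000
        is_host = rng.random(n) < 0.3
        starts = rng.integers(0, 20_000 - 150, n)
        seqs = np.stack([
            (host if h else a)[s : s + 150] for h, s in zip(is_host, starts)
        ])
        rs = ReadSet("s", [f"r{i}" for i in range(n)], seqs)
        removed = n - len(filter_host_reads(rs, hidx))
        sd = np.sqrt(n * 0.3 * 0.7)
        # error-free decoy reads are removed exactly; band covers the draw of is_host
        assert removed == is_host.sum()
        assert abs(removed - 300) < 2.6 * sd


class TestAssignReads:
    def test_unique_region_correct_strain(self, two_strain_fixture):
        a, b = two_strain_fixture
        idx = build_index({"A": a, "B": b}, k=31)
        starts = [s for s in range(12_000, 18_000, 500)
                  if (a[s : s + 150] != b[s : s + 150]).any()]
        reads = _reads_from(a, starts, 150, tag="A")
        res = assign_reads(reads, idx, mode="unique")
        assert set(res.table["strain"].astype(str)) == {"A"}
        assert len(res.table) == len(reads)

    def test_shared_segment_tie_semantics(self, two_strain_fixture):
        """Reads from the identical 10 kb segment tie between A and B:
        discarded under unique, split 0.5/0.5 under fractional."""
        a, b = two_strain_fixture
        idx = build_index({"A": a, "B": b}, k=31)
        reads = _reads_from(a, list(range(0, 9_000, 300)), 150, tag="A")
        uniq = assign_reads(reads, idx, mode="unique")
        assert len(uniq.table) == 0
        assert uniq.n_discarded_multi == len(reads)
        frac = assign_reads(reads, idx, mode="fractional")
        assert (frac.table["weight"] == 0.5).all()
        per_read = frac.table.groupby("read_idx")["weight"].sum()
        assert np.allclose(per_read, 1.0)

    def test_positions_match_provenance(self, two_strain_fixture):
        a, b = two_strain_fixture
        idx = build_index({"A": a, "B": b}, k=31)
        starts = list(range(11_000, 19_000, 777))
        res = assign_reads(_reads_from(a, starts, 150, tag="A"), idx)
        got = res.table.sort_values("read_idx")["pos"].tolist()
        assert got == starts

    def test_read_shorter_than_k_raises(self, two_strain_fixture):
        a, b = two_strain_fixture
        idx = build_index({"A": a}, k=31)
        rs = ReadSet("s", ["r0"], a[:20][None, :])
        with pytest.raises(ValueError, match="shorter"):
            assign_reads(rs, idx)


@pytest.fixture(scope="module")
def annotated_strain():
    rng = np.random.default_rng(4)
    codes = rng.integers(0, 4, 5_000).astype(np.uint8)
    ann = pd.DataFrame(
        {
            "gene_id": ["g1", "g2"],
            "strain_id": "A",
            "start": [1000, 2000],
            "end": [2000, 2600],
            "strand": ["+", "-"],
            "ko": ["K1", None],
            "cog": ["E", None],
            "orthogroup": ["OG1", "OG2"],
        }
    )
    return codes, ann


class TestCounting:

    def test_strain_level_counts(self, annotated_strain):
        codes, ann = annotated_strain
        idx = build_index({"A": codes}, k=31)
        res = assign_reads(_reads_from(codes, list(range(0, 1000, 100)), 150), idx)
        cm = count_matrix({"s": res}, "strain")
        assert cm.counts.loc["A", "s"] == 10

    def test_gene_max_overlap_rule(self, annotated_strain):
        """A read overlapping g1 by 80 bp and g2 by 20 bp counts to g1 only;
        the midpoint read overlapping both genes >=1 bp goes to the larger."""
        codes, ann = annotated_strain
        idx = build_index({"A": codes}, k=31)
        # read [1920, 2070): 80 bp in g1, 70 bp in g2
        res = assign_reads(_reads_from(codes, [1920], 150), idx)
        cm = count_matrix({"s": res}, "gene", annotations=ann, read_length=150)
        assert cm.counts.loc["g1", "s"] == 1
        assert cm.counts.loc["g2", "s"] == 0

    def test_gene_tie_dropped_and_logged(self, annotated_strain):
        codes, ann = annotated_strain
        ann2 = ann.copy()
        ann2.loc[1, ["start", "end"]] = [2000, 3000]  # same length as g1
        idx = build_index({"A": codes}, k=31)
        # read [1925, 2075): 75 bp in each gene -> tie -> dropped
        res = assign_reads(_reads_from(codes, [1925], 150), idx)
        cm = count_matrix({"s": res}, "gene", annotations=ann2, read_length=150)
        assert cm.counts["s"].sum() == 0
        assert cm.meta["gene_ties"]["s"] == 1

    def test_fractional_weights_conserved(self, two_strain_fixture):
        a, b = two_strain_fixture
        idx = build_index({"A": a, "B": b}, k=31)
        reads = _reads_from(a, list(range(0, 18_000, 450)), 150, tag="A")
        res = assign_reads(reads, idx, mode="fractional")
        cm = count_matrix({"s": res}, "strain")
        assert cm.counts["s"].sum() == pytest.approx(len(reads))


class TestAggregation:
    def _gene_cm(self):
        counts = pd.DataFrame(
            {"s1": [3.0, 4.0, 0.0], "s2": [1.0, 2.0, 5.0]}, index=["g1", "g2", "g3"]
        )
        ann = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3", "g4"],
                "strain_id": ["A", "A", "B", "B"],
                "start": [0, 100, 0, 100],
                "end": [50, 150, 50, 150],
                "strand": "+",
                "ko": None,
                "cog": None,
                "orthogroup": ["OG1", "OG1", "OG2", "OG3"],
            }
        )
        return CountMatrix(counts, "gene"), ann

    def test_sum_and_per_copy(self):
        cm, ann = self._gene_cm()
        agg = aggregate_orthogroups(cm, ann)
        assert agg.counts.loc["OG1", "s1"] == 7.0
        per = aggregate_orthogroups(cm, ann, per_copy=True)
        assert per.counts.loc["OG1", "s1"] == 3.5  # two gene copies of OG1

    def test_empty_orthogroup_row_retained(self):
        cm, ann = self._gene_cm()
        agg = aggregate_orthogroups(cm, ann)
        assert "OG3" in agg.counts.index
        assert (agg.counts.loc["OG3"] == 0).all()

    def test_column_sums_conserved(self):
        cm, ann = self._gene_cm()
        agg = aggregate_orthogroups(cm, ann)
        assert np.allclose(agg.counts.sum(), cm.counts.sum())

    def test_unannotated_gene_raises(self):
        cm, ann = self._gene_cm()
        with pytest.raises(ValueError, match="orthogroup"):
            aggregate_orthogroups(
                CountMatrix(cm.counts.rename(index={"g1": "gX"}), "gene"), ann
            )


class TestCPM:
    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.poisson(10, (30, 4)) + 0.0)
        assert np.allclose(cpm_normalize(m).sum(), 1e6)

    def test_single_feature_is_million(self):
        m = pd.DataFrame({"s": [123.0]})
        assert cpm_normalize(m).iloc[0, 0] == 1e6

    def test_zero_column_raises(self):
        m = pd.DataFrame({"good": [1.0], "bad": [0.0]})
        with pytest.raises(ValueError, match="bad"):
            cpm_normalize(m)


class TestTMM:
    def test_identical_columns_unit_factors(self):
        col = np.random.default_rng(7).poisson(20, 100).astype(float)
        m = pd.DataFrame({f"s{i}": col for i in range(4)})
        assert np.allclose(tmm_factors(m), 1.0)

    def test_pure_depth_difference_unit_factors(self):
        col = np.random.default_rng(8).poisson(50, 200).astype(float) + 1
        m = pd.DataFrame({"a": col, "b": col * 2})
        assert np.allclose(tmm_factors(m), 1.0, atol=1e-6)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.negative_binomial(5, 0.1, (150, 5)) + 0.0)
        f = tmm_factors(m)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_matches_edger_reference(self, tmp_path):
        """Cross-check against the reference TMM implementation in edgeR."""
        import subprocess

        rng = np.random.default_rng(10)
        m = pd.DataFrame(
            rng.negative_binomial(5, 0.1, (200, 6)),
            columns=[f"s{i}" for i in range(6)],
        )
        p = tmp_path / "m.tsv"
        m.to_csv(p, sep="\t")
        r = subprocess.run(
            ["Rscript", "-e",
             f'suppressMessages(library(edgeR)); x<-as.matrix(read.delim("{p}", row.names=1)); '
             'cat(calcNormFactors(x, method="TMM"), sep="\\n")'],
            capture_output=True, text=True, check=True,
        )
        ref = np.array([float(v) for v in r.stdout.split()])
        assert np.allclose(tmm_factors(m).to_numpy(), ref, atol=1e-6)

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            tmm_factors(pd.DataFrame({"s": [1.0, 2.0]}))


class TestPolicyConsistency:
    def test_unique_depressed_for_close_relatives_only(self, small_community, small_readsets):
        """Strains in a >=99% ANI lineage lose tied reads under unique mode;
        singleton strains agree between modes within 1%."""
        readsets, _, host, model = small_readsets
        hidx = build_index({"host": host}, k=31)
        idx = build_index(small_community.genomes, k=31)
        kept = {s: filter_host_reads(r, hidx) for s, r in readsets.items()}
        uni = {s: assign_reads(r, idx, mode="unique") for s, r in kept.items()}
        fra = {s: assign_reads(r, idx, mode="fractional") for s, r in kept.items()}
        cu = count_matrix(uni, "strain", strain_ids=small_community.strain_ids).counts.sum(1)
        cf = count_matrix(fra, "strain", strain_ids=small_community.strain_ids).counts.sum(1)
        lineage_of = small_community.ground_truth.lineage_assignment
        sizes = pd.Series(lineage_of).value_counts()
        for s in small_community.strain_ids:
            if sizes[lineage_of[s]] > 1:
                assert cu[s] < cf[s] * 0.95
            else:
                assert cu[s] == pytest.approx(cf[s], rel=0.01)

    def test_total_weight_bounded_by_reads(self, small_community, small_readsets):
        readsets, _, host, model = small_readsets
        hidx = build_index({"host": host}, k=31)
        idx = build_index(small_community.genomes, k=31)
        for s, r in readsets.items():
            kept = filter_host_reads(r, hidx)
            res = assign_reads(kept, idx, mode="fractional")
            assert res.total_weight <= len(kept) + 1e-9

    def test_gene_counts_bounded_by_strain_counts(self, small_community, small_readsets):
        readsets, _, host, model = small_readsets
        hidx = build_index({"host": host}, k=31)
        idx = build_index(small_community.genomes, k=31)
        asg = {s: assign_reads(filter_host_reads(r, hidx), idx) for s, r in readsets.items()}
        sc = count_matrix(asg, "strain", strain_ids=small_community.strain_ids)
        gc = count_matrix(asg, "gene", annotations=small_community.annotations,
                          read_length=model.read_length)
        assert (gc.counts.sum(0) <= sc.counts.sum(0) + 1e-9).all()
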