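"""Three differential-abundance procedures, their consensus, per-host
analyses, and the cross-framework KO intersection."""

import numpy as np
import pandas as pd
import pytest

from defcom.community import make_design, simulate_feature_counts
from defcom.da import (
    DAResult,
    _nb_irls,
    consensus,
    css_scales,
    css_zig_da,
    intersect_frameworks,
    nb_wald_da,
    per_host_enrichment,
    run_three_methods,
    size_factors_median_of_ratios,
    voom_da,
    zig_weights,
)
from defcom.linmodel import build_design, contrast_vector, moderated_fit, voom_transform
from defcom.quant import CountMatrix, tmm_factors


class TestSizeFactors:
    def test_scalar_multiple_columns(self):
        """Median-of-ratios on exact scalar multiples returns the scalars
        (up to the common geometric normalization)."""
        rng = np.random.default_rng(0)
        base = rng.poisson(50, 100).astype(float) + 1
        m = pd.DataFrame({"a": base, "b": base * 3, "c": base * 0.5})
        sf = size_factors_median_of_ratios(m)
        assert sf["b"] / sf["a"] == pytest.approx(3.0, rel=1e-12)
        assert sf["c"] / sf["a"] == pytest.approx(0.5, rel=1e-12)

    def test_all_zero_feature_rows_excluded(self):
        m = pd.DataFrame({"a": [10.0, 0.0], "b": [20.0, 5.0]})
        sf = size_factors_median_of_ratios(m)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)


class TestNBWald:
    def test_dispersion_zero_matches_poisson_glm(self):
        """With dispersion pinned to ~0 the NB IRLS equals a Poisson GLM."""
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        design = make_design(4, 4)
        X = build_design(design)
        y = rng.poisson(30, (5, 8)).astype(float)
        offset = np.zeros(8)
        beta, cov = _nb_irls(y, X.to_numpy(), offset, np.full(5, 1e-12))
        for f in range(5):
            fit = sm.GLM(y[f], X.to_numpy(), family=sm.families.Poisson()).fit()
            assert np.allclose(beta[f], fit.params, atol=1e-6)
            assert np.allclose(np.sqrt(np.diag(cov[f])), fit.bse, rtol=1e-4)

    def test_null_type_one_error_band(self):
        design = make_design(7, 8)
        rates = []
        for seed in range(20):
            counts, _ = simulate_feature_counts(300, design, seed=seed)
            r = nb_wald_da(CountMatrix(counts, "orthogroup", design))
            rates.append((r.table["p"] < 0.05).mean())
        assert 0.03 <= np.mean(rates) <= 0.08

    def test_all_zero_feature_p_one_flagged(self):
        design = make_design(3, 3)
        counts, _ = simulate_feature_counts(20, design, seed=2)
        counts.iloc[0] = 0
        r = nb_wald_da(CountMatrix(counts, "orthogroup", design))
        assert r.table.iloc[0]["p"] == 1.0
        assert bool(r.table.iloc[0]["all_zero"])

    def test_non_integer_counts_raise(self):
        design = make_design(3, 3)
        counts = pd.DataFrame(np.full((4, 6), 1.5), columns=design.index)
        with pytest.raises(ValueError, match="integer"):
            nb_wald_da(CountMatrix(counts, "orthogroup", design))


class TestVoomDA:
    def test_identical_to_direct_voom_path(self):
        """voom_da must reproduce the voom + moderated-t numbers computed
        through the strain-enrichment machinery on the same fixture."""
        design = make_design(5, 5)
        counts, _ = simulate_feature_counts(100, design, seed=3)
        cm = CountMatrix(counts, "orthogroup", design)
        res = voom_da(cm)
        X = build_design(design, compartment=True, host=True)
        f = tmm_factors(counts)
        logcpm, w = voom_transform(counts, f, X)
        ref = moderated_fit(logcpm, w, X, contrast_vector(X, "compartment"))
        assert np.allclose(res.table["p"], ref.table["p"], atol=1e-12)
        assert np.allclose(res.table["log2fc"], ref.table["log2fc"], atol=1e-12)

    def test_planted_effect_power(self):
        """4x planted orthogroups at n=7/8: detected (q<0.05) for >=80% of
        planted features over 20 seeds."""
        design = make_design(7, 8)
        hits, total = 0, 0
        for seed in range(20):
            planted = {f"F{i:04d}": 2.0 for i in range(20)}
            counts, pset = simulate_feature_counts(320, design, seed=seed, planted=planted)
            r = voom_da(CountMatrix(counts, "orthogroup", design))
            hits += (r.table.loc[sorted(pset), "q"] < 0.05).sum()
            total += len(pset)
        assert hits / total >= 0.8

    def test_fractional_counts_rounded_and_logged(self):
        design = make_design(3, 3)
        counts, _ = simulate_feature_counts(50, design, seed=4)
        r = voom_da(CountMatrix(counts / 2.0, "orthogroup", design))
        assert r.params["rounded_pseudo_counts"]


class TestCssZig:
    def test_identical_samples_identical_scales(self):
        rng = np.random.default_rng(5)
        col = rng.poisson(5, 100).astype(float)
        m = pd.DataFrame({"a": col, "b": col})
        s = css_scales(m)
        assert s["a"] == s["b"]

    def test_too_few_nonzero_raises(self):
        m = pd.DataFrame({"a": [1.0] * 5 + [0.0] * 20, "b": [2.0] * 25})
        with pytest.raises(ValueError, match="nonzero"):
            css_scales(m)

    def test_no_zeros_reduces_to_weighted_t_with_unit_weights(self):
        design = make_design(4, 4)
        counts, _ = simulate_feature_counts(60, design, seed=6)
        counts = counts + 1  # remove zeros
        r = css_zig_da(CountMatrix(counts, "orthogroup", design))
        assert r.params["em"].get("note", "").startswith("no zeros")

    def test_null_type_one_error_band(self):
        design = make_design(7, 8)
        rates = []
        for seed in range(20):
            counts, _ = simulate_feature_counts(300, design, seed=seed)
            r = css_zig_da(CountMatrix(counts, "orthogroup", design))
            rates.append((r.table["p"] < 0.05).mean())
        assert 0.03 <= np.mean(rates) <= 0.08

    def test_em_recovers_structural_zero_membership(self):
        """Labeled mixture: rare features produce detection dropouts, robust
        features suffer structural knockouts; EM posterior classifies the
        zeros with >= 0.8 accuracy."""
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            F, n = 300, 15
            libsize = np.exp(rng.normal(10, 0.7, n))
            mu_f = np.where(rng.random(F) < 0.4,
                            rng.uniform(0.3, 1.0, F), rng.uniform(3.5, 6.0, F))
            lat = rng.normal(mu_f[:, None], 1.0, (F, n))
            sampling_zero = lat <= 0
            struct = rng.random((F, n)) < 0.08
            y = np.where(struct, 0.0, np.maximum(lat, 0.0))
            iz = y == 0
            truth = struct & ~sampling_zero
            w, diag = zig_weights(pd.DataFrame(y), pd.Series(libsize), iz)
            assert diag["converged"]
            pred = (1 - w.to_numpy()) > 0.5
            accs.append((pred[iz] == truth[iz]).mean())
        assert np.mean(accs) >= 0.8


def _fake_result(method, fc, q):
    tab = pd.DataFrame({"log2fc": fc, "p": q, "q": q}, index=[f"F{i}" for i in range(len(fc))])
    tab["significant"] = tab["q"] < 0.05
    return DAResult(method=method, table=tab)


class TestConsensus:
    def test_two_of_three_excluded(self):
        r1 = _fake_result("a", [2.0], [0.01])
        r2 = _fake_result("b", [2.0], [0.01])
        r3 = _fake_result("c", [2.0], [0.50])
        assert consensus([r1, r2, r3]) == set()

    def test_opposite_signs_excluded(self):
        r1 = _fake_result("a", [2.0], [0.01])
        r2 = _fake_result("b", [-2.0], [0.01])
        r3 = _fake_result("c", [2.0], [0.01])
        assert consensus([r1, r2, r3]) == set()

    def test_direction_filter(self):
        r = [_fake_result(m, [-2.0], [0.01]) for m in "abc"]
        assert consensus(r, direction=1) == set()
        assert consensus(r, direction=-1) == {"F0"}

    def test_consensus_subset_of_each_method(self):
        design = make_design(6, 6)
        planted = {f"F{i:04d}": 2.0 for i in range(15)}
        counts, _ = simulate_feature_counts(200, design, seed=7, planted=planted)
        results = run_three_methods(CountMatrix(counts, "orthogroup", design))
        cons = consensus(results, direction=1)
        for r in results:
            assert cons <= r.significant_set(0.05)

    def test_universe_mismatch_raises(self):
        r1 = _fake_result("a", [1.0, 1.0], [0.01, 0.01])
        r2 = _fake_result("b", [1.0], [0.01])
        with pytest.raises(ValueError, match="universe"):
            consensus([r1, r2, r1])

    def test_determinism_same_seed_same_q(self):
        design = make_design(5, 5)
        counts, _ = simulate_feature_counts(100, design, seed=8)
        cm = CountMatrix(counts, "orthogroup", design)
        a = run_three_methods(cm)
        b = run_three_methods(cm)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.table["q"].to_numpy(), rb.table["q"].to_numpy())


class TestPerHost:
    def _host_counts(self, seed, effect_a=0.0, effect_b=0.0, shared=0.0):
        design = make_design(8, 8)
        a = design[design["host"] == "speciesA"]
        b = design[design["host"] == "speciesB"]
        planted_a = {f"F{i:04d}": effect_a for i in range(5)} if effect_a else {}
        planted_b = {f"F{i:04d}": effect_b for i in range(5)} if effect_b else {}
        shared_p = {f"F{i:04d}": shared for i in range(10, 15)} if shared else {}
        ca, _ = simulate_feature_counts(200, a, seed=seed, planted={**planted_a, **shared_p})
        cb, _ = simulate_feature_counts(200, b, seed=seed + 1, planted={**planted_b, **shared_p})
        counts = pd.concat([ca, cb], axis=1)[list(design.index)]
        return CountMatrix(counts, "orthogroup", design)

    def test_host_specific_effect_in_one_set_only(self):
        cm = self._host_counts(seed=10, effect_a=2.5)
        out = per_host_enrichment(cm)
        a_set = out["significant"]["speciesA"]
        b_set = out["significant"]["speciesB"]
        planted = {f"F{i:04d}" for i in range(5)}
        assert len(planted & a_set) >= 4
        assert len(planted & b_set) <= 1
        assert not (planted & out["shared"]) or len(planted & b_set) > 0

    def test_shared_effect_in_intersection(self):
        cm = self._host_counts(seed=20, shared=2.5)
        out = per_host_enrichment(cm)
        planted = {f"F{i:04d}" for i in range(10, 15)}
        assert len(planted & out["shared"]) >= 4

    def test_upset_cardinalities_partition_union(self):
        cm = self._host_counts(seed=30, effect_a=2.0, shared=2.0)
        out = per_host_enrichment(cm)
        union = out["significant"]["speciesA"] | out["significant"]["speciesB"]
        assert sum(out["upset"].values()) == len(union)

    def test_missing_design_cell_raises(self):
        cm = self._host_counts(seed=40)
        keep = [s for s in cm.design.index
                if not (cm.design.loc[s, "host"] == "speciesB"
                        and cm.design.loc[s, "compartment"] == "endosphere")]
        sub = CountMatrix(cm.counts[keep], "orthogroup", cm.design.loc[keep])
        with pytest.raises(ValueError, match="replicates"):
            per_host_enrichment(sub)


class TestIntersectFrameworks:
    def test_disjoint_inputs_empty(self):
        assert intersect_frameworks({"OG1"}, {"OG1": {"K1"}}, {"K2"}) == set()

    def test_planted_ko_in_both_frameworks_present(self):
        og_to_ko = {"OG1": {"K1", "K2"}, "OG2": {"K3"}}
        out = intersect_frameworks({"OG1"}, og_to_ko, {"K2", "K3"})
        assert out == {"K2"}

    def test_output_subset_of_lineage_kos(self):
        rng = np.random.default_rng(11)
        ogs = {f"OG{i}" for i in range(20)}
        og_to_ko = {f"OG{i}": {f"K{rng.integers(10)}"} for i in range(20)}
        lineage = {f"K{i}" for i in range(5)}
        out = intersect_frameworks(ogs, og_to_ko, lineage)
        assert out <= lineage

    def test_annotation_frame_accepted(self):
        ann = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "strain_id": "A", "start": 0, "end": 1,
             "strand": "+", "ko": ["K1", None], "cog": None,
             "orthogroup": ["OG1", "OG2"]}
        )
        assert intersect_frameworks({"OG1", "OG2"}, ann, {"K1"}) == {"K1"}
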