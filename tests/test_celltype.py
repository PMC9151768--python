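import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import editscape as es
from _oracles import brute_force_bh, brute_force_hypergeom_tail


class TestCohensD:
    def test_identical_groups(self):
        assert es.cohens_d([0.4, 0.6], [0.4, 0.6]) == 0.0

    def test_shift_case(self):
        b = np.array([0.1, 0.2, 0.3, 0.4])
        d = es.cohens_d(b + 0.1, b)
        assert d == pytest.approx(0.1 / b.std(ddof=1))
        assert d > 0

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0.4, 0.1, 12), rng.normal(0.3, 0.2, 9)
        na, nb = len(a), len(b)
        pooled = np.sqrt(((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2))
        assert es.cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / pooled, abs=1e-12)

    def test_zero_pooled_sd_raises(self):
        with pytest.raises(ValueError, match="zero"):
            es.cohens_d([0.3, 0.3], [0.3, 0.3])


class TestBH:
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_step_up(self, pvals):
        p = np.array(pvals)
        assert np.allclose(es.bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_fdr_never_below_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=1000)
        assert (es.bh_adjust(p) >= p - 1e-15).all()


class TestDifferentialEditing:
    def test_identical_groups_are_degenerate(self):
        meta = pd.DataFrame(
            {"cell_type": ["A"] * 3 + ["B"] * 3, "donor": ["D1", "D2", "D3"] * 2,
             "age": [50.0] * 6, "PMI": [20.0] * 6},
            index=[f"S{i}" for i in range(6)],
        )
        lv = pd.DataFrame([[0.3] * 6], index=["s1"], columns=meta.index)
        ones = lv.notna().astype(int)
        sm = es.SiteMatrix(sites=pd.DataFrame(index=lv.index), levels=lv,
                           coverage=ones, edited=ones, samples=meta)
        res = es.differential_editing(sm, ("A", "B"), donor_handling="none")
        assert res.iloc[0]["degenerate"]
        assert res.iloc[0]["p"] == 1.0 and res.iloc[0]["delta"] == 0.0
        assert not res.iloc[0]["significant"]

    def test_power_and_fdp_on_planted_effects(self, two_group_matrix):
        res = es.differential_editing(two_group_matrix, ("A", "B"))
        sig = res["significant"].reindex(two_group_matrix.levels.index)
        power = sig.iloc[:200].mean()
        fdp = sig.iloc[200:].sum() / max(int(sig.sum()), 1)
        assert power >= 0.8
        assert fdp <= 0.1

    def test_delta_and_d_share_sign(self, two_group_matrix):
        res = es.differential_editing(two_group_matrix, ("A", "B"))
        nz = res[(res["delta"].abs() > 1e-9) & ~res["degenerate"]]
        assert (np.sign(nz["delta"]) == np.sign(nz["cohens_d"])).all()

    def test_small_group_raises(self, two_group_matrix):
        sm = two_group_matrix.subset_samples(list(two_group_matrix.samples.index[:4]))
        with pytest.raises(ValueError, match=">= 3 samples"):
            es.differential_editing(sm, ("A", "B"))


class TestClassifySpecificity:
    requery = pd.DataFrame(
        {"site_id": ["s1", "s1"], "cell_type": ["MGE-GABA", "GLU"],
         "label": ["covered-unedited", "covered-unedited"]}
    )

    def _diff(self, fdr, delta):
        return pd.DataFrame({"fdr": [fdr], "delta": [delta]}, index=["s2"])

    def test_unique_with_zero_coverage_evidence_is_specific(self):
        detected = {"MGE-GABA": set(), "GLU": set(), "OLIG": {"s1"}}
        out = es.classify_specificity(detected, self.requery, {})
        assert out.loc["s1", "label"] == "specific:OLIG"

    def test_significant_contrast_wins_enrichment(self):
        detected = {ct: {"s2"} for ct in ("MGE-GABA", "GLU", "OLIG")}
        diffs = {("MGE-GABA", "GLU"): self._diff(0.001, +0.2)}
        out = es.classify_specificity(detected, pd.DataFrame(columns=self.requery.columns), diffs)
        assert out.loc["s2", "label"] == "enriched:MGE-GABA"

    def test_no_significant_contrast_is_shared(self):
        detected = {ct: {"s2"} for ct in ("MGE-GABA", "GLU", "OLIG")}
        diffs = {("MGE-GABA", "GLU"): self._diff(0.5, +0.2)}
        out = es.classify_specificity(detected, pd.DataFrame(columns=self.requery.columns), diffs)
        assert out.loc["s2", "label"] == "shared"

    def test_missing_requery_evidence_raises(self):
        detected = {"MGE-GABA": set(), "GLU": set(), "OLIG": {"sX"}}
        with pytest.raises(ValueError, match="re-query"):
            es.classify_specificity(detected, pd.DataFrame(columns=self.requery.columns), {})

    def test_labels_partition_sites(self, genome, truth, fans_samples):
        from editscape.pipeline import discover_and_classify

        labels, _, _ = discover_and_classify(fans_samples, genome)
        assert labels.index.is_unique
        assert labels["label"].notna().all()


def _factor_frame(rng, n=9):
    donors = [f"D{i}" for i in range(n)]
    idx = [f"{d}_{c}" for c in ("A", "B", "C") for d in donors]
    return pd.DataFrame(
        {
            "cell_type": ["A"] * n + ["B"] * n + ["C"] * n,
            "donor": donors * 3,
            "age": list(rng.uniform(25, 90, n)) * 3,
            "pH": list(rng.uniform(6, 7, n)) * 3,
            "PMI": list(rng.uniform(5, 40, n)) * 3,
            "ADAR1": rng.uniform(10, 50, 3 * n),
            "ADAR2": rng.uniform(10, 50, 3 * n),
            "ADAR3": rng.uniform(1, 10, 3 * n),
        },
        index=idx,
    )


class TestVariancePartition:
    def test_pure_cell_type_signal(self):
        fac = _factor_frame(np.random.default_rng(1))
        means = {"A": 0.2, "B": 0.5, "C": 0.8}
        lv = pd.DataFrame([[means[c] for c in fac["cell_type"]]], index=["s1"], columns=fac.index)
        vp = es.variance_partition(lv, fac)
        assert vp.loc["s1", "cell_type"] == pytest.approx(1.0)

    def test_null_sites_attribute_nothing_to_cell_type(self):
        rng = np.random.default_rng(2)
        fac = _factor_frame(rng)
        lv = pd.DataFrame(rng.normal(0.5, 0.05, (500, 27)), columns=fac.index)
        lv.index = [f"x{i}" for i in range(500)]
        vp = es.variance_partition(lv, fac)
        assert vp["cell_type"].median() <= 0.05
        assert np.allclose(vp.sum(axis=1), 1.0, atol=1e-6)

    def test_age_fraction_recovered(self):
        rng = np.random.default_rng(3)
        fac = _factor_frame(rng)
        age = fac["age"].to_numpy()
        signal = 0.05 * (age - age.mean()) / age.std()  # ~50% of total variance
        lv = pd.DataFrame(0.5 + signal[None, :] + rng.normal(0, 0.05, (200, 27)), columns=fac.index)
        lv.index = [f"a{i}" for i in range(200)]
        vp = es.variance_partition(lv, fac)
        assert abs(vp["age"].mean() - 0.5) <= 0.1

    def test_affine_invariance_of_continuous_factors(self):
        rng = np.random.default_rng(4)
        fac = _factor_frame(rng)
        lv = pd.DataFrame(rng.normal(0.5, 0.05, (50, 27)), columns=fac.index)
        lv.index = [f"z{i}" for i in range(50)]
        fac2 = fac.copy()
        fac2["age"] = fac2["age"] * 10 + 5
        fac2["PMI"] = -fac2["PMI"] / 3
        assert np.allclose(es.variance_partition(lv, fac), es.variance_partition(lv, fac2))

    def test_collinear_factors_raise(self):
        rng = np.random.default_rng(5)
        fac = _factor_frame(rng)
        fac["ADAR2"] = 2 * fac["ADAR1"]
        lv = pd.DataFrame(rng.normal(0.5, 0.05, (5, 27)), columns=fac.index)
        with pytest.raises(ValueError, match="collinear"):
            es.variance_partition(lv, fac)


class TestAdarAssociation:
    def test_slope_recovery(self):
        rng = np.random.default_rng(6)
        fac = _factor_frame(rng)
        expr = pd.Series(rng.uniform(10, 50, 27), index=fac.index)
        lv = pd.DataFrame(
            0.01 * expr.to_numpy()[None, :] + rng.normal(0, 0.001, (50, 27)), columns=fac.index
        )
        lv.index = [f"z{i}" for i in range(50)]
        res = es.adar_association(lv, expr, fac["donor"])
        assert abs(res["slope"].mean() - 0.01) <= 0.001

    def test_permuted_expression_rarely_significant(self):
        rng = np.random.default_rng(7)
        fac = _factor_frame(rng)
        expr = pd.Series(rng.uniform(10, 50, 27), index=fac.index)
        lv = pd.DataFrame(rng.normal(0.5, 0.05, (300, 27)), columns=fac.index)
        lv.index = [f"z{i}" for i in range(300)]
        res = es.adar_association(lv, expr, fac["donor"])
        assert res["significant"].mean() <= 0.07

    def test_constant_site_degenerate(self):
        rng = np.random.default_rng(8)
        fac = _factor_frame(rng)
        expr = pd.Series(rng.uniform(10, 50, 27), index=fac.index)
        lv = pd.DataFrame([[0.4] * 27], index=["flat"], columns=fac.index)
        res = es.adar_association(lv, expr, fac["donor"])
        assert res.loc["flat", "degenerate"] and res.loc["flat", "p"] == 1.0

    def test_constant_expression_raises(self):
        fac = _factor_frame(np.random.default_rng(9))
        expr = pd.Series(5.0, index=fac.index)
        lv = pd.DataFrame([[0.4] * 27], columns=fac.index)
        with pytest.raises(ValueError, match="constant"):
            es.adar_association(lv, expr, fac["donor"])


class TestGeneDensity:
    def test_arithmetic(self):
        genes = pd.DataFrame({"gene_id": ["g1"], "length": [1023]})
        sites = pd.DataFrame({"gene_id": ["g1"] * 31})
        out = es.gene_editing_density(sites, genes)
        assert out.loc["g1", "density"] == pytest.approx(3.1)

    def test_zero_sites(self):
        genes = pd.DataFrame({"gene_id": ["g1"], "length": [1000]})
        out = es.gene_editing_density(pd.DataFrame({"gene_id": []}), genes)
        assert out.loc["g1", "density"] == 0.0

    def test_extreme_gene_flagged_outlier(self):
        rng = np.random.default_rng(10)
        genes = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(1000)], "length": [1023] * 1000}
        )
        counts = rng.poisson(5, 999).tolist() + [500]
        sites = pd.DataFrame({"gene_id": np.repeat(genes["gene_id"], counts)})
        out = es.gene_editing_density(sites, genes)
        assert bool(out.loc["g999", "outlier"])
        assert out["outlier"].iloc[:999].mean() < 0.05

    def test_zero_length_raises(self):
        genes = pd.DataFrame({"gene_id": ["g1"], "length": [0]})
        with pytest.raises(ValueError, match="positive"):
            es.gene_editing_density(pd.DataFrame({"gene_id": []}), genes)


class TestOverlapEnrichment:
    def test_p_matches_exhaustive_hypergeometric(self):
        bg = set(range(10_000))
        a = set(range(100))
        b = set(range(70, 270))
        orat, p = es.overlap_enrichment(a, b, bg)
        assert p == pytest.approx(brute_force_hypergeom_tail(30, 70, 170, 9_730), abs=1e-10)

    def test_independence_gives_or_near_one(self):
        bg = set(range(1_000))
        a = set(range(100))  # 10% of background
        b = set(range(90, 100)) | set(range(100, 190))  # 10% overlap with a: 10 of 100
        orat, _ = es.overlap_enrichment(a, b, bg)
        assert 0.5 < orat < 2.0

    def test_identical_half_background_caps_or(self):
        bg = set(range(100))
        a = b = set(range(50))
        orat, p = es.overlap_enrichment(a, b, bg)
        assert orat == 1e6
        assert p == pytest.approx(brute_force_hypergeom_tail(50, 0, 0, 50), abs=1e-12)

    def test_empty_background_raises(self):
        with pytest.raises(ValueError, match="empty"):
            es.overlap_enrichment(set(), set(), set())


class TestPermutationOverlap:
    lengths = {"g": 100_000}

    def _regions(self, rng, n, lo=50, hi=300):
        start = rng.integers(1, 99_000, n)
        return pd.DataFrame({"chrom": "g", "start": start, "end": start + rng.integers(lo, hi, n)})

    def test_identity_query_is_maximally_significant(self):
        rng = np.random.default_rng(11)
        q = self._regions(rng, 25)
        res = es.permutation_region_overlap(q, q, self.lengths, n_perm=1000, seed=1)
        assert res["p"] == pytest.approx(1 / 1001)
        assert res["z"] > 3

    def test_genome_wide_target_ties_every_permutation(self):
        rng = np.random.default_rng(12)
        q = self._regions(rng, 10)
        target = pd.DataFrame({"chrom": ["g"], "start": [1], "end": [100_000]})
        res = es.permutation_region_overlap(q, target, self.lengths, n_perm=200, seed=2)
        assert res["p"] == 1.0

    def test_oversized_region_raises(self):
        q = pd.DataFrame({"chrom": ["g"], "start": [1], "end": [200_000]})
        with pytest.raises(ValueError, match="longer than"):
            es.permutation_region_overlap(q, q, self.lengths, n_perm=10, seed=3)
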