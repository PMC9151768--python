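import numpy as np
import pandas as pd
import pytest

import editscape as es
from editscape.genome import GenomeBundle
from editscape.simulate import SimulatedSample

from _oracles import brute_force_cascade, make_toy_genome


def _sample(pileup_rows, sample_id="S1", cell_type="CT1", donor="D1"):
    return SimulatedSample(
        sample_id=sample_id,
        cell_type=cell_type,
        donor=donor,
        covariates={},
        pileup=pd.DataFrame(pileup_rows),
        mapped_bases=1_000_000,
    )


def _row(pos, a, c, g, t, ref="A", strand="+", chrom="toy"):
    return {
        "chrom": chrom, "pos": pos, "strand": strand, "ref": ref,
        "A": a, "C": c, "G": g, "T": t, "coverage": a + c + g + t,
    }


class TestQuantifySupervised:
    sites = pd.DataFrame(
        {"chrom": ["toy"] * 3, "pos": [10, 20, 30], "strand": ["+"] * 3}
    )

    def test_threshold_rules_per_sample(self):
        s = _sample([
            _row(10, 4, 0, 5, 0),       # coverage 9, edited 5: below 10-read minimum
            _row(20, 40, 0, 0, 0),      # coverage 40, edited 0: no editing call
            _row(30, 10, 0, 10, 0),     # coverage 20, edited 10: level 0.5
        ])
        sm = es.quantify_supervised(s, self.sites)
        lv = sm.levels["S1"]
        assert np.isnan(lv.iloc[0]) and np.isnan(lv.iloc[1])
        assert lv.iloc[2] == 0.5
        # coverage stays recorded even when the call is missing (re-query input)
        assert sm.coverage["S1"].iloc[1] == 40

    def test_minus_strand_uses_complement_counts(self):
        sites = pd.DataFrame({"chrom": ["toy"], "pos": [10], "strand": ["-"]})
        s = _sample([_row(10, 0, 6, 0, 14, ref="T", strand="-")])
        sm = es.quantify_supervised(s, sites)
        assert sm.levels["S1"].iloc[0] == 0.3

    def test_site_outside_genome_raises(self, genome):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [10**9], "strand": ["+"]})
        s = _sample([_row(10, 5, 0, 5, 0)])
        with pytest.raises(ValueError, match="outside the genome"):
            es.quantify_supervised(s, sites, genome=genome)


class TestCallDenovo:
    def test_candidate_ratio_and_type(self):
        s = _sample([_row(10, 45, 0, 5, 0)])
        cand = es.call_denovo(s)
        assert len(cand) == 1
        assert cand.iloc[0]["substitution"] == "A>G"
        assert cand.iloc[0]["ratio"] == pytest.approx(0.10)

    def test_multi_allelic_flagged(self):
        s = _sample([_row(10, 30, 4, 5, 0)])
        cand = es.call_denovo(s)
        assert bool(cand.iloc[0]["multi_allelic"])

    def test_error_level_position_not_a_candidate(self):
        s = _sample([_row(10, 99, 0, 1, 0)])
        assert es.call_denovo(s).empty

    def test_all_twelve_substitution_types_possible(self):
        rows = [_row(10, 0, 3, 45, 0, ref="G")]
        cand = es.call_denovo(_sample(rows))
        assert cand.iloc[0]["substitution"] == "G>C"


class TestFilterCascade:
    def test_matches_brute_force_oracle_exactly(self):
        genome, cand, attrs = make_toy_genome(n_sites=200, seed=7)
        sm, report = es.apply_filter_cascade(cand, genome, k=8, n=9)
        expected_retained, expected_removed = brute_force_cascade(attrs, k=8)
        got = {(r["chrom"], r["pos"], r["strand"]) for _, r in sm.sites.iterrows()}
        assert got == expected_retained
        assert dict(report.removed) == expected_removed

    def test_report_conserves_counts(self):
        genome, cand, _ = make_toy_genome(n_sites=100, seed=8)
        _, report = es.apply_filter_cascade(cand, genome)
        report.check_conservation()
        assert report.input_count == 100

    def test_detection_rule_boundary(self):
        genome, cand, attrs = make_toy_genome(n_sites=300, seed=9)
        sm, _ = es.apply_filter_cascade(cand, genome, k=8, n=9)
        seven = attrs[
            (attrs["n_detect"] == 7) & ~attrs["multi"]
            & (attrs["coverage"] >= 10) & (attrs["edited"] >= 3) & (attrs["ratio"] >= 0.05)
            & ~attrs["in_blacklist"] & ~attrs["in_homopolymer"]
            & ~(attrs["maf"] > 0.05) & ~((attrs["splice_dist"] > 0) & (attrs["splice_dist"] <= 5))
        ]
        assert len(seven) > 0
        retained_pos = set(sm.sites["pos"])
        assert all(p not in retained_pos for p in seven["pos"])

    def test_k_exceeding_n_raises(self):
        genome, cand, _ = make_toy_genome(n_sites=5, seed=1)
        with pytest.raises(ValueError, match="exceeds"):
            es.apply_filter_cascade(cand, genome, k=10, n=9)


class TestRequery:
    def _three_celltype_samples(self, cov_edited_by_ct):
        sites_rows = lambda cov, ed: [_row(10, cov - ed, 0, ed, 0)]
        return [
            _sample(sites_rows(*cov_edited_by_ct[ct]), sample_id=f"S_{ct}", cell_type=ct, donor="D1")
            for ct in cov_edited_by_ct
        ]

    @pytest.mark.parametrize(
        "cov,edited,expected",
        [
            (50, 0, "covered-unedited"),
            (4, 0, "insufficient-coverage"),
            (12, 2, "covered-unedited"),
        ],
    )
    def test_zero_class_labels(self, cov, edited, expected):
        samples = self._three_celltype_samples({"GLU": (cov, edited)})
        sites = pd.DataFrame({"chrom": ["toy"], "pos": [10], "strand": ["+"]})
        req = es.requery_other_celltypes(sites, samples)
        assert req.set_index("cell_type").loc["GLU", "label"] == expected


class TestImputation:
    def _matrix(self, values):
        meta = pd.DataFrame(
            {"cell_type": ["A"] * len(values), "donor": [f"D{i}" for i in range(len(values))]},
            index=[f"S{i}" for i in range(len(values))],
        )
        lv = pd.DataFrame([values], index=["site1"], columns=meta.index, dtype=float)
        ones = lv.notna().astype(int)
        return es.SiteMatrix(sites=pd.DataFrame(index=lv.index), levels=lv,
                             coverage=ones, edited=ones, samples=meta)

    def test_median_not_mean(self):
        sm = self._matrix([0.1, 0.2, 0.9, np.nan])
        out = es.impute_missing_median(sm, "A")
        assert out.levels.iloc[0, 3] == 0.2

    def test_two_observed(self):
        sm = self._matrix([0.1, 0.3, np.nan])
        out = es.impute_missing_median(sm, "A")
        assert out.levels.iloc[0, 2] == pytest.approx(0.2)

    def test_no_missing_is_identity(self):
        sm = self._matrix([0.1, 0.3, 0.5])
        out = es.impute_missing_median(sm, "A")
        pd.testing.assert_frame_equal(out.levels, sm.levels)

    def test_imputation_preserves_group_median(self):
        sm = self._matrix([0.1, 0.2, 0.4, 0.8, np.nan, np.nan])
        out = es.impute_missing_median(sm, "A")
        assert out.levels.iloc[0].median() == sm.levels.iloc[0].median()

    def test_all_missing_raises(self):
        sm = self._matrix([np.nan, np.nan])
        with pytest.raises(ValueError, match="cannot be imputed"):
            es.impute_missing_median(sm, "A")


def _annotation_genome():
    seq = list("C" * 5_000)
    for pos, base in [(131, "A"), (132, "A"), (133, "A"), (134, "G"), (135, "C"), (136, "A")]:
        seq[pos - 1] = base
    for pos in (110, 150, 250, 203, 660, 90, 4_000):
        if seq[pos - 1] == "C":
            seq[pos - 1] = "A"
    gene = es.Gene(
        gene_id="g1", chrom="m", strand="+", tss=101,
        exons=((101, 200), (301, 400), (501, 700)),
        cds=((131, 200), (301, 400), (501, 640)),
        utr5=((101, 130),), utr3=((641, 700),),
    )
    return GenomeBundle(
        chromosomes={"m": "".join(seq)},
        genes=[gene],
        alu_intervals={"m": [(240, 260, "+")]},
        l1_intervals={"m": []},
        blacklist_intervals={"m": []},
        homopolymer_intervals={"m": []},
        splice_sites={"m": sorted(gene.splice_sites())},
        snp_positions=[],
    )


class TestAnnotation:
    genome = _annotation_genome()

    @pytest.mark.parametrize(
        "pos,region",
        [
            (150, "CDS"),
            (110, "5'UTR"),
            (660, "3'UTR"),
            (250, "intron"),
            (203, "splice-adjacent"),
            (90, "downstream-TSS"),
            (4_000, "intergenic"),
        ],
    )
    def test_genic_region_precedence(self, pos, region):
        sites = pd.DataFrame({"chrom": ["m"], "pos": [pos], "strand": ["+"]})
        out = es.annotate_sites(sites, self.genome)
        assert out.iloc[0]["genic_region"] == region

    def test_intron_and_alu_are_independent_axes(self):
        sites = pd.DataFrame({"chrom": ["m"], "pos": [250], "strand": ["+"]})
        out = es.annotate_sites(sites, self.genome)
        assert out.iloc[0]["genic_region"] == "intron"
        assert out.iloc[0]["repeat_class"] == "Alu"

    def test_catalog_exact_match(self):
        sites = pd.DataFrame({"chrom": ["m", "m"], "pos": [150, 151], "strand": ["+", "+"]})
        out = es.annotate_sites(sites, self.genome, catalog={("m", 150, "+")})
        assert list(out["catalog_status"]) == ["known", "not-in-catalog"]

    def test_recoding_flag_via_codon_table(self):
        # codon AAA (Lys) -> AGA (Arg): recoding; GCA (Ala) -> GCG (Ala): silent
        sites = pd.DataFrame({"chrom": ["m", "m"], "pos": [132, 136], "strand": ["+", "+"]})
        out = es.annotate_sites(sites, self.genome)
        assert list(out["recoding"]) == [True, False]

    def test_provisional_substitutions_tagged(self):
        sites = pd.DataFrame(
            {"chrom": ["m", "m"], "pos": [150, 150], "strand": ["+", "+"],
             "substitution": ["A>G", "C>T"]}
        )
        out = es.annotate_sites(sites, self.genome)
        assert list(out["provisional"]) == [False, True]


class TestCascadeRecovery:
    def test_default_design_recovers_planted_sites(self, genome):
        """At the default depth (mean coverage 100, error 0.001), >= 95% of
        planted sites with rate >= 0.1 survive the cascade in their true
        cell type, and no error-only position survives."""
        truth = es.simulate_editing_truth(genome, n_sites=200, seed=50)
        samples = es.simulate_pileups(truth, genome, seed=51, n_background=200)
        cand = es.call_denovo(samples, genome)
        sm, _ = es.apply_filter_cascade(cand, genome)
        rates = truth.sites[[f"rate_{ct}" for ct in es.CELL_TYPES]].max(axis=1)
        detectable = truth.sites.loc[rates >= 0.1, "site_id"]
        assert len(detectable) > 0
        survived = detectable.isin(sm.sites.index).mean()
        assert survived >= 0.95
        null_ids = set(truth.sites.loc[truth.sites["class_label"] == "null", "site_id"])
        assert not (set(sm.sites.index) & null_ids)
        # surviving sites are detected (8 of 9) in a cell type that truly edits them
        ref = truth.sites.set_index("site_id")
        for sid in set(sm.sites.index) & set(detectable):
            by_ct = {
                ct: sm.levels.loc[sid, sm.samples.index[sm.samples["cell_type"] == ct]].notna().sum()
                for ct in es.CELL_TYPES
            }
            winners = [ct for ct, n in by_ct.items() if n >= 8]
            assert any(ref.loc[sid, f"rate_{ct}"] > 0 for ct in winners)
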