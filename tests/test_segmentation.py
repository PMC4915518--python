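"""Segmentation analyses: BED conversion, state enrichment, metagenes,
boundary alignment, gene-set splits, class tests, transitions, periodicity."""

import numpy as np
import pandas as pd
import pytest

import polstate as ps
from polstate.genome import Gene, GenomeModel
from polstate.segmentation import (BED_COLUMNS, anchors_from_genes,
                                   boundary_alignment, class_compare,
                                   match_expression, metagene_signal,
                                   metagene_states, nucleosome_boundaries_bed,
                                   path_to_segments, periodicity,
                                   periodicity_of_profile, segments_to_path,
                                   split_by_exon1, state_enrichment,
                                   state_transition_positions)
from polstate.tracks import CoverageTrack, StatePath


def simple_path(states, n_states=3, strand="+", chrom="c"):
    return StatePath(data={(chrom, strand): np.asarray(states, dtype=np.int64)},
                     n_states=n_states)


LABELS3 = {0: "A", 1: "B", 2: "C"}


class TestPathToSegments:
    def test_run_length_encoding_example(self):
        seg = path_to_segments(simple_path([0, 0, 1]), {0: "state1", 1: "state2"})
        assert seg[["start", "end", "name"]].values.tolist() == \
            [[0, 40, "state1"], [40, 60, "state2"]]

    def test_constant_path_single_interval(self):
        seg = path_to_segments(simple_path([1] * 7), LABELS3)
        assert len(seg) == 1 and seg.iloc[0]["end"] == 140

    def test_roundtrip_identity(self, default_fit, default_sim):
        genome, _ = default_sim
        _, res = default_fit
        path = res.decode()
        seg = path_to_segments(path, res.labels)
        back = segments_to_path(seg, res.labels, genome.chrom_sizes)
        for k in path.keys():
            np.testing.assert_array_equal(back.data[k], path.data[k])
        # adjacent intervals always change state
        for (_, _), grp in seg.groupby(["chrom", "strand"]):
            assert (grp["name"].shift() != grp["name"]).all()


class TestStateEnrichment:
    def test_whole_genome_window_all_ratios_one(self):
        path = simple_path([0, 0, 1, 2, 1, 0])
        windows = pd.DataFrame([("c", 0, 120, ".", 0, "+")], columns=BED_COLUMNS)
        res = state_enrichment(path, windows)
        np.testing.assert_allclose(res["ratio"], 1.0)

    def test_worked_ratio_example(self):
        # genome 100 bins, 25 of state 1; window of 10 bins contains 5
        z = np.zeros(100, dtype=int)
        z[:25] = 1
        path = simple_path(z, n_states=2)
        win_bins = np.r_[20:25, 50:55]  # 5 state-1 bins + 5 state-0 bins
        windows = pd.DataFrame([("c", int(b) * 20, int(b) * 20 + 20, ".", 0, "+")
                                for b in win_bins], columns=BED_COLUMNS)
        res = state_enrichment(path, windows)
        assert res.loc[1, "ratio"] == pytest.approx(5 / 2.5)

    def test_expected_weighted_mean_ratio_is_one(self, rng):
        z = rng.integers(0, 4, size=400)
        path = simple_path(z, n_states=4)
        windows = pd.DataFrame([("c", 100, 1500, ".", 0, "+")], columns=BED_COLUMNS)
        res = state_enrichment(path, windows)
        ok = res["n_exp"] > 0
        mean = np.average(res.loc[ok, "ratio"], weights=res.loc[ok, "n_exp"])
        assert mean == pytest.approx(1.0)

    def test_absent_state_reported(self):
        path = simple_path([0, 0, 1], n_states=3)
        windows = pd.DataFrame([("c", 0, 60, ".", 0, "+")], columns=BED_COLUMNS)
        res = state_enrichment(path, windows)
        assert bool(res.loc[2, "absent"]) and np.isnan(res.loc[2, "ratio"])


class TestMetageneStates:
    def test_frequencies_sum_to_one_everywhere(self, default_fit, default_sim):
        genome, truth = default_sim
        prof = metagene_states(truth.path, genome.genes_of_class("mRNA"),
                               labeling=truth.labeling)
        sums = prof.values.sum(axis=1).to_numpy()
        np.testing.assert_allclose(sums[prof.counts > 0], 1.0)

    def test_i1_dominates_at_tss_and_cuts_lack_ee(self, default_sim):
        genome, truth = default_sim
        mrna_prof = metagene_states(truth.path, genome.genes_of_class("mRNA"),
                                    labeling=truth.labeling, flank=200)
        at10 = mrna_prof.values.iloc[np.searchsorted(mrna_prof.positions, 0)]
        assert at10["I1"] > 0.9
        cut_prof = metagene_states(truth.path, genome.genes_of_class("CUT"),
                                   labeling=truth.labeling, ten_bins=True)
        assert (cut_prof.values["EE"] < 0.1).all()

    def test_ten_bins_mode_has_ten_rows(self, default_sim):
        genome, truth = default_sim
        prof = metagene_states(truth.path, genome.genes, ten_bins=True,
                               labeling=truth.labeling)
        assert prof.values.shape[0] == 10

    def test_no_anchors_raises(self, default_sim):
        _, truth = default_sim
        with pytest.raises(ValueError, match="no anchor genes"):
            metagene_states(truth.path, [])

    def test_strand_mirroring_leaves_profiles_unchanged(self):
        # same layout on opposite strands must give identical metagenes
        z = [0] * 5 + [1] * 10 + [2] * 5
        path = StatePath(data={("c", "+"): np.array(z, dtype=np.int64),
                               ("c", "-"): np.array(z[::-1], dtype=np.int64)},
                         n_states=3)
        g_plus = Gene("gp", "c", 0, 400, "+", "mRNA")
        g_minus = Gene("gm", "c", 0, 400, "-", "mRNA")
        p1 = metagene_states(path, [g_plus], flank=200)
        p2 = metagene_states(path, [g_minus], flank=200)
        pd.testing.assert_frame_equal(p1.values, p2.values)


class TestMetageneSignal:
    def test_constant_track_flat_profile(self):
        t = CoverageTrack.zeros({"c": 2000}, units="rpm")
        t.get("c", "+")[:] = 4.0
        anchors = pd.DataFrame([("c", 1000, 1001, "a", 0, "+")],
                               columns=BED_COLUMNS)
        prof = metagene_signal(t, anchors, flank=300)
        np.testing.assert_allclose(prof.values["signal"], 4.0)

    def test_max_mrna_normalization_bounds_profile(self):
        t = CoverageTrack.zeros({"c": 2000}, units="rpm")
        t.get("c", "+")[:] = np.linspace(0, 10, 2000)
        genes = [Gene("m", "c", 100, 1900, "+", "mRNA")]
        anchors = anchors_from_genes(genes, "tss")
        prof = metagene_signal(t, anchors, flank=90, norm="max_mrna_gt500",
                               mrna_gt500=genes)
        assert prof.values["signal"].max() <= 1.0

    def test_ser5_profile_signs_match_reference_layout(self, default_sim):
        genome, truth = default_sim
        X = truth.enrichment_matrix()
        mrna = [g for g in genome.genes_of_class("mRNA") if g.length > 600]
        anchors = anchors_from_genes(mrna, "tss")
        prof = metagene_signal(X, anchors, flank=500, mark="Ser5")
        pos = prof.positions
        vals = prof.values["Ser5"].to_numpy()
        assert vals[(pos >= 0) & (pos < 150)].mean() > 0.3   # I1 region
        assert vals[(pos >= 300) & (pos < 500)].mean() < 0.0  # EE region

    def test_flank_truncation_uses_count_weighting(self):
        t = CoverageTrack.zeros({"c": 100}, units="rpm")
        t.get("c", "+")[:] = 1.0
        anchors = pd.DataFrame([("c", 10, 11, "a", 0, "+")], columns=BED_COLUMNS)
        prof = metagene_signal(t, anchors, flank=50)
        assert np.isnan(prof.values["signal"].iloc[0])  # off-chromosome
        assert prof.values["signal"].iloc[-1] == 1.0


class TestBoundaryAlignment:
    def test_constructed_layout_mode_zero(self, default_sim, default_fit):
        genome, truth = default_sim
        seg = path_to_segments(truth.path, truth.labeling)
        mrna = [g for g in genome.genes_of_class("mRNA") if not g.has_intron]
        res = boundary_alignment(seg, mrna, genome, state="I1",
                                 state_edge="3p", nucleosome_index=1,
                                 nucleosome_edge="3p")
        assert res.mode == 0

    def test_empty_segmentation_all_skipped(self, default_sim):
        genome, _ = default_sim
        seg = pd.DataFrame(columns=BED_COLUMNS)
        genes = genome.genes_of_class("mRNA")
        res = boundary_alignment(seg, genes, genome)
        assert res.offsets.size == 0 and res.n_skipped == len(genes)

    def test_translation_equivariance(self, default_sim):
        genome, truth = default_sim
        seg = path_to_segments(truth.path, truth.labeling)
        mrna = [g for g in genome.genes_of_class("mRNA") if not g.has_intron]
        base = boundary_alignment(seg, mrna, genome)
        shifted = {g.name: [(s + 40, e + 40) for s, e in
                            genome.nucleosomes_for_gene(g)] for g in mrna}
        # shifting boundaries +40 nt in transcript orientation
        shifted = {g.name: [((s + 40, e + 40) if g.strand == "+"
                             else (s - 40, e - 40)) for s, e in
                            genome.nucleosomes_for_gene(g)] for g in mrna}
        res = boundary_alignment(seg, mrna, genome, nucleosomes=shifted)
        assert res.mode == base.mode - 40


class TestGeneSetSplits:
    def _genes(self):
        gs = []
        for i, (exon1, expr) in enumerate([(None, 10), (None, 5), (None, 2),
                                           (None, 1), (80, 3), (100, 3),
                                           (99, 3), (140, 3)]):
            if exon1 is None:
                gs.append(Gene(f"g{i}", "c", i * 2000, i * 2000 + 1000, "+",
                               "mRNA", expression=expr))
            else:
                start = i * 2000
                exons = ((start, start + exon1), (start + exon1 + 300, start + 1000))
                gs.append(Gene(f"g{i}", "c", start, start + 1000, "+", "mRNA",
                               exons=exons, expression=expr))
        return gs

    def test_threshold_and_tie_rule(self):
        split = split_by_exon1(self._genes())
        names = {k: {g.name for g in v} for k, v in split.items()}
        assert names["exon1_lt100"] == {"g4", "g6"}   # 80 and 99 nt
        assert names["exon1_ge100"] == {"g5", "g7"}   # 100 goes to long
        assert names["intronless_topQ"] == {"g0"}     # top 25% of 4 by density

    def test_match_expression_self_match_is_exact(self):
        genes = self._genes()
        matched = match_expression(genes, "mRNA", ("mRNA",))
        assert [g.name for g in matched["mRNA"]] == \
               [g.name for g in list(matched.values())[0]]

    def test_match_expression_sizes_and_balance(self, default_sim):
        genome, _ = default_sim
        matched = match_expression(genome.genes, "SUT", ("mRNA", "CUT"))
        n = len(matched["SUT"])
        assert len(matched["mRNA"]) == n and len(matched["CUT"]) == n
        from scipy.stats import mannwhitneyu
        ref = np.log([g.expression for g in matched["SUT"]])
        for c in ("mRNA", "CUT"):
            other = np.log([g.expression for g in matched[c]])
            assert mannwhitneyu(ref, other).pvalue > 0.05

    def test_match_expression_small_pool_raises(self):
        genes = [Gene("a", "c", 0, 100, "+", "SUT", expression=1.0)]
        with pytest.raises(ValueError, match="candidates"):
            match_expression(genes, "SUT", ("mRNA",))


class TestClassCompare:
    def test_identical_distributions_not_significant(self, rng):
        from polstate.tracks import EnrichmentMatrix
        n = 400
        X = EnrichmentMatrix(data={("c", "+"): rng.normal(size=(n, 5))})
        genes = [Gene(f"g{i}", "c", i * 80, i * 80 + 80, "+",
                      "mRNA" if i % 2 else "CUT") for i in range(60)]
        df = class_compare(X, genes, classes=("mRNA", "CUT"))
        assert not df["significant"].any()
        # Bonferroni factor = marks x pairs
        np.testing.assert_allclose(df["p_bonferroni"],
                                   np.minimum(df["p_raw"] * len(df), 1.0))

    def test_cut_thr4_below_mrna_with_significance(self, default_sim):
        genome, truth = default_sim
        X = truth.enrichment_matrix()
        df = class_compare(X, genome.genes, classes=("mRNA", "CUT"))
        row = df[(df["mark"] == "Thr4")].iloc[0]
        assert row["median_b"] < row["median_a"]  # CUT below mRNA
        assert row["significant"]

    def test_small_class_skipped_with_warning(self, default_sim, rng):
        from polstate.tracks import EnrichmentMatrix
        X = EnrichmentMatrix(data={("c", "+"): rng.normal(size=(100, 5))})
        genes = [Gene("a", "c", 0, 100, "+", "mRNA", expression=1.0),
                 Gene("b", "c", 200, 300, "+", "mRNA", expression=1.0)]
        with pytest.warns(UserWarning, match="skipped"):
            df = class_compare(X, genes, classes=("mRNA", "CUT"))
        assert df.empty


class TestTransitions:
    def test_synthetic_mrna_exit_matches_layout(self, default_sim):
        genome, truth = default_sim
        mrna = [g for g in genome.genes_of_class("mRNA") if not g.has_intron]
        res = state_transition_positions(truth.path, mrna, truth.labeling)
        assert abs(res.median_i1_exit - 150) <= 20  # one bin of the +150 switch
        assert res.median_ee_entry == res.median_i1_exit

    def test_cuts_stay_censored(self, default_sim):
        genome, truth = default_sim
        cuts = genome.genes_of_class("CUT")
        res = state_transition_positions(truth.path, cuts, truth.labeling)
        assert res.censored_i1 >= 0.9

    def test_all_i1_path_fully_censored(self):
        path = simple_path([0] * 50, n_states=2)
        g = Gene("g", "c", 0, 1000, "+", "mRNA")
        res = state_transition_positions(path, [g], {0: "I1", 1: "EE"})
        assert res.censored_i1 == 1.0 and res.median_i1_exit is None

    def test_gene_without_i1_at_tss_excluded(self):
        path = simple_path([1] * 50, n_states=2)
        g = Gene("g", "c", 0, 1000, "+", "mRNA")
        res = state_transition_positions(path, [g], {0: "I1", 1: "EE"})
        assert res.no_i1 == 1 and len(res.table) == 0


class TestPeriodicity:
    @pytest.mark.parametrize("period", [150, 165])
    def test_pure_cosine_recovers_period(self, period):
        x = np.cos(2 * np.pi * np.arange(901) / period)
        assert periodicity_of_profile(x).period == period

    def test_flat_profile_has_no_period(self):
        res = periodicity_of_profile(np.ones(900))
        assert res.period is None and not res.reliable

    def test_white_noise_flagged_unreliable(self, rng):
        res = periodicity_of_profile(rng.normal(size=901))
        assert (res.period is None) or (not res.reliable)

    def test_simulated_coverage_periodicity_near_150(self, default_sim,
                                                     default_tracks):
        genome, _ = default_sim
        total, _ = default_tracks
        res = periodicity(total.to_rpm(), nucleosome_boundaries_bed(genome))
        assert res.reliable and abs(res.period - 150) <= 20
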