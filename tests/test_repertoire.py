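import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_clones, hill_numeric_limit, partitions_equal
from conftest import make_heavy_records
from gcoutput.reference import DEFAULT_REGION_LAYOUT, GERMLINE_300NT
from gcoutput.repertoire import (
    CloneSet,
    RecordError,
    assign_clones,
    clone_size_bins,
    diversity_profile,
    filter_contigs,
    gene_usage,
    hill_diversity,
    isotype_fractions,
    mutation_profile,
    mutation_table,
    strip_allele,
)


def record(seq, germ, seq_id="s1", layout=None):
    return {
        "sequence_id": seq_id,
        "sequence_alignment": seq,
        "germline_alignment": germ,
    }


def heavy_df(rows):
    return pd.DataFrame(rows)


class TestAssignClones:
    def two_cells(self, j1, j2, v2="IGHV1-1*01", j_call2="IGHJ1*01"):
        return heavy_df([
            {"sequence_id": "a", "cell_id": "a", "chain": "heavy",
             "v_call": "IGHV1-1*01", "j_call": "IGHJ1*01", "junction": j1},
            {"sequence_id": "b", "cell_id": "b", "chain": "heavy",
             "v_call": v2, "j_call": j_call2, "junction": j2},
        ])

    def test_identical_records_one_clone(self):
        cs = assign_clones(self.two_cells("TGTGCAAGATGG", "TGTGCAAGATGG"))
        assert cs.assignments["clone_id"].nunique() == 1

    def test_length_partition_absolute(self):
        # junction lengths 45 and 48 never share a clone
        cs = assign_clones(self.two_cells("A" * 45, "A" * 48))
        assert cs.assignments["clone_id"].nunique() == 2

    def test_different_v_gene_separates(self):
        cs = assign_clones(self.two_cells("TGTGCAAGATGG", "TGTGCAAGATGG",
                                          v2="IGHV2-1*01"))
        assert cs.assignments["clone_id"].nunique() == 2

    def test_allele_stripped_before_comparison(self):
        cs = assign_clones(self.two_cells("TGTGCAAGATGG", "TGTGCAAGATGG",
                                          v2="IGHV1-1*02"))
        assert cs.assignments["clone_id"].nunique() == 1

    def test_missing_v_call_rejected_with_id(self):
        df = self.two_cells("TGTGCAAGATGG", "TGTGCAAGATGG")
        df.loc[1, "v_call"] = ""
        with pytest.raises(RecordError, match="b"):
            assign_clones(df)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            df = make_heavy_records(rng, int(rng.integers(2, 40)))
            cs = assign_clones(df, 0.15)
            got = cs.assignments.set_index("sequence_id")["clone_id"]
            oracle = brute_force_clones(df, 0.15)
            assert partitions_equal(
                [got[s] for s in df["sequence_id"]], oracle)

    def test_stable_under_reordering(self):
        rng = np.random.default_rng(7)
        df = make_heavy_records(rng, 30)
        a = assign_clones(df).assignments
        b = assign_clones(df.sample(frac=1, random_state=1)).assignments
        pd.testing.assert_frame_equal(a, b)

    def test_threshold_zero_requires_identity(self):
        cs = assign_clones(self.two_cells("TGTGCAAGATGG", "TGTGCAAGATGC"), 0.0)
        assert cs.assignments["clone_id"].nunique() == 2


class TestMutationProfile:
    def test_identical_pair_all_zero(self):
        prof = mutation_profile(record(GERMLINE_300NT, GERMLINE_300NT))
        assert prof.total == 0
        assert prof.frequency == 0.0
        assert prof.denominator == 300

    def test_silent_vs_replacement_genetic_code(self):
        # GAT->GAC (Asp->Asp) silent; GAT->GAA (Asp->Glu) replacement
        germ = "GAT" * 100
        silent = "GAC" + germ[3:]
        repl = "GAA" + germ[3:]
        p_s = mutation_profile(record(silent, germ))
        assert sum(p_s.s_counts.values()) == 1
        assert sum(p_s.r_counts.values()) == 0
        p_r = mutation_profile(record(repl, germ))
        assert sum(p_r.r_counts.values()) == 1
        assert sum(p_r.s_counts.values()) == 0

    def test_frequency_worked_example(self):
        # 300-nt alignment, 6 mismatches, no gaps -> 0.02
        germ = GERMLINE_300NT
        seq = list(germ)
        for pos in (10, 60, 120, 180, 240, 290):
            seq[pos] = "A" if germ[pos] != "A" else "C"
        prof = mutation_profile(record("".join(seq), germ))
        assert prof.total == 6
        assert prof.frequency == pytest.approx(6 / 300)

    def test_mutation_assigned_to_containing_region(self):
        germ = GERMLINE_300NT
        lo, hi = DEFAULT_REGION_LAYOUT["CDR2"]
        pos = lo + 1
        seq = germ[:pos] + ("A" if germ[pos] != "A" else "C") + germ[pos + 1:]
        prof = mutation_profile(record(seq, germ))
        assert prof.r_counts["CDR2"] + prof.s_counts["CDR2"] == 1

    def test_gap_positions_excluded_from_denominator(self):
        germ = GERMLINE_300NT[:30]
        seq = "-" * 3 + germ[3:]
        prof = mutation_profile(record(seq, germ), region_layout={"FWR1": (0, 30)})
        assert prof.denominator == 27

    def test_length_mismatch_errors(self):
        with pytest.raises(RecordError, match="length"):
            mutation_profile(record("ACGT", "ACG"))

    def test_all_gaps_errors(self):
        with pytest.raises(RecordError):
            mutation_profile(record("-" * 300, GERMLINE_300NT))

    def test_exclude_cdr3_option_shrinks_denominator(self):
        prof = mutation_profile(record(GERMLINE_300NT, GERMLINE_300NT),
                                include_cdr3=False)
        lo, hi = DEFAULT_REGION_LAYOUT["CDR3"]
        assert prof.denominator == 300 - (hi - lo)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_rs_sum_equals_hamming_mismatches(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT-N"))
        germ = rng.choice(np.array(list("ACGT")), 300)
        seq = germ.copy()
        n_mut = int(rng.integers(0, 40))
        for pos in rng.choice(300, n_mut, replace=False):
            seq[pos] = rng.choice(bases)
        obs, g = "".join(seq), "".join(germ)
        prof = mutation_profile(record(obs, g))
        expected = sum(
            1 for a, b in zip(obs, g)
            if a in "ACGT" and b in "ACGT" and a != b
        )
        assert prof.total == expected
        assert sum(prof.r_counts.values()) + sum(prof.s_counts.values()) == expected


class TestDiversity:
    def test_uniform_two_clones(self):
        for q in (0.0, 0.5, 1.0, 2.0, 4.0):
            assert hill_diversity(np.array([0.5, 0.5]), q) == pytest.approx(2.0)

    def test_single_clone(self):
        for q in (0.0, 1.0, 3.0):
            assert hill_diversity(np.array([1.0]), q) == pytest.approx(1.0)

    def test_closed_forms(self):
        p = np.array([0.5, 0.25, 0.25])
        assert hill_diversity(p, 0.0) == pytest.approx(3.0, abs=1e-9)
        assert hill_diversity(p, 1.0) == pytest.approx(2 ** 1.5, abs=1e-9)
        assert hill_diversity(p, 2.0) == pytest.approx(8 / 3, abs=1e-9)

    def test_shannon_limit_agrees_numerically(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.dirichlet(np.ones(int(rng.integers(2, 15))))
            d1 = hill_diversity(p, 1.0)
            assert d1 == pytest.approx(hill_numeric_limit(p), rel=1e-6)

    def test_profile_non_increasing(self):
        rng = np.random.default_rng(3)
        labels = pd.Series(rng.integers(0, 20, 200).astype(str))
        prof = diversity_profile(labels, np.linspace(0, 4, 17), n_boot=0)
        assert (np.diff(prof.d) <= 1e-9).all()

    def test_d0_is_richness_and_band_brackets(self):
        rng = np.random.default_rng(4)
        labels = pd.Series(rng.integers(0, 10, 100).astype(str))
        prof = diversity_profile(labels, [0, 1, 2], n_boot=100, seed=1)
        assert prof.d[0] == labels.nunique()
        assert (prof.ci_low <= prof.ci_high).all()

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            diversity_profile(pd.Series([], dtype=str), [0, 1])


class TestGeneUsage:
    def usage_df(self, calls, chain="heavy", group="g1"):
        return heavy_df([
            {"sequence_id": f"s{i}", "cell_id": f"c{i}", "chain": chain,
             "group": group, "v_call": call}
            for i, call in enumerate(calls)
        ])

    def test_single_gene_frequency_one(self):
        usage, _ = gene_usage(self.usage_df(["IGHV3-30*01"] * 5), min_freq=0.0)
        assert usage["frequency"].tolist() == [1.0]
        assert usage["gene"].tolist() == ["IGHV3-30"]

    def test_counts_to_frequencies(self):
        calls = ["IGHV1-2*01"] * 5 + ["IGHV3-30*01"] * 3 + ["IGHV4-34*01"] * 2
        usage, _ = gene_usage(self.usage_df(calls), min_freq=0.0)
        freqs = usage.set_index("gene")["frequency"]
        assert freqs["IGHV1-2"] == pytest.approx(0.5)
        assert freqs["IGHV3-30"] == pytest.approx(0.3)
        assert freqs["IGHV4-34"] == pytest.approx(0.2)

    def test_min_freq_filter(self):
        calls = ["IGHV1-2*01"] * 98 + ["IGHV3-30*01"] * 2  # 2% < 3%
        usage, _ = gene_usage(self.usage_df(calls), min_freq=0.03)
        assert "IGHV3-30" not in usage["gene"].tolist()

    def test_alleles_collapse_but_d_gene_distinct(self):
        calls = ["IGHV1-69*01", "IGHV1-69*02", "IGHV1-69D*01"]
        usage, _ = gene_usage(self.usage_df(calls), min_freq=0.0)
        freqs = usage.set_index("gene")["frequency"]
        assert freqs["IGHV1-69"] == pytest.approx(2 / 3)
        assert freqs["IGHV1-69D"] == pytest.approx(1 / 3)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            gene_usage(self.usage_df([]))

    def test_paired_table(self, small_repertoire):
        filtered, _ = filter_contigs(small_repertoire)
        usage, pairs = gene_usage(filtered, min_freq=0.0)
        assert set(pairs.columns) == {"group", "gene_heavy", "gene_light", "n_cells"}
        per_group_cells = pairs.groupby("group")["n_cells"].sum()
        heavy_cells = (filtered[filtered["chain"] == "heavy"]
                       .groupby("group")["cell_id"].nunique())
        assert (per_group_cells == heavy_cells.loc[per_group_cells.index]).all()


class TestCloneBinsAndIsotypes:
    def clone_set(self, sizes):
        rows = []
        cell = 0
        for i, size in enumerate(sizes):
            for _ in range(size):
                rows.append({"sequence_id": f"s{cell}", "cell_id": f"c{cell}",
                             "clone_id": f"C{i}", "subject": "p1",
                             "timepoint": "t1"})
                cell += 1
        return CloneSet(assignments=pd.DataFrame(rows), threshold=0.15)

    def test_all_singletons(self):
        bins = clone_size_bins(self.clone_set([1, 1, 1]))
        assert bins["rare"].iloc[0] == pytest.approx(1.0)

    def test_cell_weighted_fractions(self):
        bins = clone_size_bins(self.clone_set([1, 2, 5, 10]))
        row = bins.iloc[0]
        assert row["rare"] == pytest.approx(1 / 18)
        assert row["small"] == pytest.approx(2 / 18)
        assert row["medium"] == pytest.approx(5 / 18)
        assert row["large"] == pytest.approx(10 / 18)

    def test_clone_of_three_is_medium(self):
        bins = clone_size_bins(self.clone_set([3]))
        assert bins["medium"].iloc[0] == pytest.approx(1.0)

    def test_oversize_clone_reported_larger(self):
        bins = clone_size_bins(self.clone_set([12]))
        assert bins["larger"].iloc[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self):
        bins = clone_size_bins(self.clone_set([1, 2, 3, 7, 11]))
        total = sum(bins.iloc[0][["rare", "small", "medium", "large", "larger"]])
        assert total == pytest.approx(1.0)

    def iso_df(self, isotypes, group="g1"):
        return heavy_df([
            {"sequence_id": f"s{i}", "cell_id": f"c{i}", "chain": "heavy",
             "group": group, "c_call": iso}
            for i, iso in enumerate(isotypes)
        ])

    def test_all_ighm(self):
        fr = isotype_fractions(self.iso_df(["IGHM"] * 4))
        assert fr["IGHM"].iloc[0] == pytest.approx(1.0)
        assert fr["switched"].iloc[0] == pytest.approx(0.0)

    def test_switched_aggregate(self):
        fr = isotype_fractions(self.iso_df(["IGHG1"] * 3 + ["IGHM"]))
        assert fr["switched"].iloc[0] == pytest.approx(0.75)

    def test_unknown_isotype_warns_other(self):
        with pytest.warns(UserWarning):
            fr = isotype_fractions(self.iso_df(["IGHM", "IGXX"]))
        assert fr["other"].iloc[0] == pytest.approx(0.5)

    def test_empty_group_absent_not_zero(self):
        df = pd.concat([self.iso_df(["IGHM"], group="g1")])
        fr = isotype_fractions(df, group_by=("group",))
        assert fr["group"].tolist() == ["g1"]  # no phantom rows for g2


class TestFilterContigs:
    def test_multi_heavy_cells_removed(self, small_cohort):
        from gcoutput.config import RepertoireConfig
        from gcoutput.synthetic import gen_repertoire
        rep = RepertoireConfig(cells_per_subject=30, multi_heavy_rate=0.3)
        records = gen_repertoire(small_cohort, rep)
        filtered, tally = filter_contigs(records)
        assert tally["cells_multiple_heavy"] > 0
        heavy_counts = (filtered[filtered["chain"] == "heavy"]
                        .groupby("cell_id").size())
        assert (heavy_counts == 1).all()

    def test_nonproductive_removed(self, small_repertoire):
        df = small_repertoire.copy()
        df.loc[df.index[:5], "productive"] = False
        filtered, tally = filter_contigs(df)
        assert tally["nonproductive"] == 5


def test_strip_allele():
    assert strip_allele("IGHV1-69*01") == "IGHV1-69"
    assert strip_allele("IGHV1-69D") == "IGHV1-69D"


def test_group_shm_separation_parameter_recovery():
    """Rank test on per-cell SHM frequencies: 0.045 vs 0.025 detected,
    equal rates not over-rejected (reduced-n version of the full check)."""
    from scipy.stats import mannwhitneyu

    from gcoutput.config import CohortConfig, RepertoireConfig
    from gcoutput.synthetic import gen_repertoire

    rejections_alt, rejections_null = 0, 0
    n_sim = 20
    for seed in range(n_sim):
        cohort = CohortConfig(groups=("healthy", "anti-TNF"),
                              subjects_per_group=5, timepoints=("t2",),
                              seed=seed)
        rep_alt = RepertoireConfig(
            cells_per_subject=30, include_light_chain=False,
            shm_rate={"healthy": 0.045, "anti-TNF": 0.025})
        rec = gen_repertoire(cohort, rep_alt)
        shm = mutation_table(rec)
        a = shm[shm["group"] == "healthy"]["frequency"]
        b = shm[shm["group"] == "anti-TNF"]["frequency"]
        if mannwhitneyu(a, b).pvalue < 0.05:
            rejections_alt += 1
        rep_null = RepertoireConfig(
            cells_per_subject=30, include_light_chain=False, shm_rate=0.035)
        rec0 = gen_repertoire(cohort, rep_null)
        shm0 = mutation_table(rec0)
        a0 = shm0[shm0["group"] == "healthy"]["frequency"]
        b0 = shm0[shm0["group"] == "anti-TNF"]["frequency"]
        if mannwhitneyu(a0, b0).pvalue < 0.05:
            rejections_null += 1
    assert rejections_alt == n_sim
    assert rejections_null <= 3
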