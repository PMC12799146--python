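import numpy as np
import pytest
from scipy import stats

from csdscan.genotypes import Call
from csdscan.intervals import Interval
from csdscan.sex_contrast import (
    binomial_two_tailed,
    find_discordant_interval,
    homozygote_proportions,
    scan_sex_contrast,
    two_proportion_z,
)

from conftest import build_matrix, build_samples


def cohort(calls_by_sample, females, males):
    """calls_by_sample: dict name -> list of calls (one per site)."""
    names = list(calls_by_sample)
    calls = np.array([calls_by_sample[n] for n in names]).T
    n_sites = calls.shape[0]
    gm = build_matrix(np.arange(1, n_sites + 1) * 100, calls, samples=names)
    st = build_samples(females=females, diploid_males=males)
    return gm, st


class TestProportions:
    def test_all_het_females(self):
        gm, st = cohort(
            {**{f"F{i}": [Call.HET] for i in range(10)}, "M1": [Call.HOM_REF]},
            females=[f"F{i}" for i in range(10)],
            males=["M1"],
        )
        p = homozygote_proportions(gm, st)
        assert p.loc[0, "p_hom_female"] == 0.0
        assert p.loc[0, "n_female"] == 10

    def test_missing_excluded_from_denominator(self):
        males = {f"M{i}": [Call.HOM_ALT] for i in range(4)}
        males["M4"] = [Call.MISSING]
        gm, st = cohort(
            {"F1": [Call.HET], **males}, females=["F1"], males=list(males)
        )
        p = homozygote_proportions(gm, st)
        assert p.loc[0, "p_hom_male"] == 1.0
        assert p.loc[0, "n_male"] == 4

    def test_mixed_proportion(self):
        fem = {f"F{i}": [Call.HOM_REF if i < 3 else Call.HET] for i in range(10)}
        gm, st = cohort({**fem, "M1": [Call.HOM_REF]}, females=list(fem), males=["M1"])
        p = homozygote_proportions(gm, st)
        assert p.loc[0, "p_hom_female"] == pytest.approx(0.3)


class TestTwoProportionZ:
    def test_equal_proportions_give_zero(self):
        z, p = two_proportion_z(0.4, 17, 0.4, 9)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # p1=0.2, n1=10, p2=0.8, n2=10: pooled 0.5, z = -0.6/sqrt(0.25*0.2)
        z, p = two_proportion_z(0.2, 10, 0.8, 10)
        assert z == pytest.approx(-2.6833, abs=1e-4)
        assert p == pytest.approx(0.00729, abs=1e-5)

    def test_antisymmetry(self):
        z1, p1 = two_proportion_z(0.2, 10, 0.8, 10)
        z2, p2 = two_proportion_z(0.8, 10, 0.2, 10)
        assert z1 == -z2 and p1 == p2

    def test_degenerate_pooled_proportion(self):
        assert two_proportion_z(0.0, 5, 0.0, 7) == (0.0, 1.0)
        assert two_proportion_z(1.0, 5, 1.0, 7) == (0.0, 1.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_z(0.5, 0, 0.5, 10)

    @pytest.mark.parametrize("seed", range(4))
    def test_z_squared_equals_chisquare(self, seed):
        # z^2 must equal the uncorrected 2x2 chi-square on the same counts
        rng = np.random.default_rng(seed)
        for _ in range(250):
            n1, n2 = rng.integers(2, 60, size=2)
            k1, k2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            if (k1 + k2) in (0, n1 + n2):
                continue
            z, _ = two_proportion_z(k1 / n1, n1, k2 / n2, n2)
            table = [[k1, n1 - k1], [k2, n2 - k2]]
            chi2 = stats.chi2_contingency(table, correction=False).statistic
            assert z**2 == pytest.approx(chi2, abs=1e-9)


class TestScan:
    def test_monomorphic_site_flagged_degenerate(self):
        gm, st = cohort(
            {"F1": [Call.HOM_REF], "F2": [Call.HOM_REF], "M1": [Call.HOM_REF]},
            females=["F1", "F2"],
            males=["M1"],
        )
        df = scan_sex_contrast(gm, st)
        assert df["degenerate"].iloc[0]
        assert df["p_value"].iloc[0] == 1.0

    def test_identical_groups_give_p_one(self):
        gm, st = cohort(
            {"F1": [Call.HET] * 3, "F2": [Call.HET] * 3, "M1": [Call.HET] * 3, "M2": [Call.HET] * 3},
            females=["F1", "F2"],
            males=["M1", "M2"],
        )
        df = scan_sex_contrast(gm, st)
        assert (df["p_value"] == 1.0).all()

    def test_sample_order_invariance(self, default_cohort):
        _, gm, st, _, _ = default_cohort
        df1 = scan_sex_contrast(gm, st)
        perm = np.random.default_rng(0).permutation(len(gm.samples))
        gm2 = build_matrix(
            gm.sites["pos"][gm.chrom_mask("chr1")],
            gm.calls[gm.chrom_mask("chr1")][:, perm],
            samples=[gm.samples[i] for i in perm],
        )
        # restrict to chr1 for both
        df1c = df1[df1["chrom"] == "chr1"].reset_index(drop=True)
        df2 = scan_sex_contrast(gm2, st)
        assert np.allclose(df1c["p_value"], df2["p_value"])

    def test_minimum_p_inside_true_locus(self, default_cohort):
        _, gm, st, _, truth = default_cohort
        df = scan_sex_contrast(gm, st)
        top = df.loc[df["p_value"].idxmin()]
        assert truth.locus.start <= top["pos"] <= truth.locus.end
        assert top["chrom"] == truth.locus.chrom

    def test_full_separation_power(self):
        # 30 vs 30 with complete separation: p below the 1e-12 tail bound
        fem = {f"F{i}": [Call.HET] for i in range(30)}
        mal = {f"M{i}": [Call.HOM_REF] for i in range(30)}
        gm, st = cohort({**fem, **mal}, females=list(fem), males=list(mal))
        df = scan_sex_contrast(gm, st)
        assert df["p_value"].iloc[0] < 1e-12


class TestBinomial:
    def test_crossing_design_value(self):
        # 18 early-male-producing queens of 30 against a 50% expectation
        p = binomial_two_tailed(18, 30, 0.5)
        assert round(p, 2) == 0.36
        assert p == pytest.approx(0.3616, abs=5e-5)

    def test_modal_outcome_is_one(self):
        assert binomial_two_tailed(15, 30, 0.5) == 1.0

    def test_extreme_outcome_enumeration(self):
        assert binomial_two_tailed(5, 5, 0.5) == pytest.approx(0.0625)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            binomial_two_tailed(6, 5, 0.5)
        with pytest.raises(ValueError):
            binomial_two_tailed(2, 5, 1.0)


class TestDiscordantInterval:
    def test_run_construction(self):
        # discordant at 100, 200, 300 (F het, M hom); 400 breaks the pattern
        gm, st = cohort(
            {
                "F1": [Call.HET, Call.HET, Call.HET, Call.HOM_REF],
                "M1": [Call.HOM_REF, Call.HOM_ALT, Call.HOM_REF, Call.HOM_REF],
            },
            females=["F1"],
            males=["M1"],
        )
        ivs = find_discordant_interval(gm, st)
        assert ivs[0] == Interval("chr1", 100, 300)

    def test_no_consistent_het_female_site(self):
        gm, st = cohort(
            {"F1": [Call.HOM_REF] * 3, "M1": [Call.HOM_REF] * 3},
            females=["F1"],
            males=["M1"],
        )
        assert find_discordant_interval(gm, st) == []

    def test_gap_tolerance_merges_runs(self):
        calls_f = [Call.HET, Call.HOM_REF, Call.HET]
        gm, st = cohort(
            {"F1": calls_f, "M1": [Call.HOM_REF] * 3}, females=["F1"], males=["M1"]
        )
        assert find_discordant_interval(gm, st, max_gap_snps=0)[0].length == 1
        assert find_discordant_interval(gm, st, max_gap_snps=1)[0] == Interval("chr1", 100, 300)

    def test_synthetic_interval_within_locus_snps(self, default_cohort):
        _, gm, st, _, truth = default_cohort
        ivs = find_discordant_interval(gm, st, min_frac_het_female=0.5, max_gap_snps=10)
        assert ivs
        lo, hi = truth.locus_positions[0], truth.locus_positions[-1]
        assert lo <= ivs[0].start <= ivs[0].end <= hi

    def test_contains_universally_heterozygous_sites(self):
        # every truth-locus SNP at which all female pairs differ must be inside;
        # with k=2 every female carries both haplotypes, so every locus SNP
        # (all polymorphic between the two) qualifies
        from csdscan.synthetic import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(k_haplotypes=2, n_females=8, seed=21)
        gm, st, _, truth = simulate_cohort(cfg)
        seqs = truth.haplotype_sequences
        pairs = [truth.haplotype_labels[f] for f in st.females()]
        all_diff = np.all([seqs[a] != seqs[b] for a, b in pairs], axis=0)
        ivs = find_discordant_interval(gm, st, min_frac_het_female=1.0)
        covered = set()
        for iv in ivs:
            covered.update(
                p for p in truth.locus_positions if iv.start <= p <= iv.end
            )
        for p in truth.locus_positions[all_diff]:
            assert p in covered
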