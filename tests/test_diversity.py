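import itertools

import numpy as np
import pytest

from csdscan.diversity import (
    HaplotypePool,
    MISS,
    build_haplotype_pool,
    hamming_matrix,
    haplogroup_clusters,
    infer_novel_haplotype,
    phase_female,
    pi_windows,
    pool_to_fasta,
    top_percentile_region,
)
from csdscan.genotypes import Call
from csdscan.intervals import Interval, MaskTrack

from conftest import build_matrix


def brute_force_pi(alleles_per_site):
    """Average pairwise difference per site, enumerating all sequence pairs."""
    out = []
    for alleles in alleles_per_site:
        alleles = [a for a in alleles if a is not None]
        pairs = list(itertools.combinations(alleles, 2))
        if not pairs:
            out.append(0.0)
            continue
        out.append(sum(a != b for a, b in pairs) / len(pairs))
    return out


def make_pool(seq_strings, region=None, positions=None):
    seqs = np.array(
        [[-1 if c == "N" else int(c) for c in s] for s in seq_strings], dtype=np.int8
    )
    n = seqs.shape[1]
    positions = positions if positions is not None else np.arange(1, n + 1) * 10
    region = region or Interval("chr1", 1, int(max(positions)) + 10)
    return HaplotypePool(region, positions, seqs)


class TestPiWindows:
    def test_identical_haploids_give_zero(self):
        calls = np.full((5, 2), Call.HAP_REF)
        gm = build_matrix(np.arange(1, 6) * 100, calls)
        track = pi_windows(gm, ["S1", "S2"])
        assert (track.values == 0).all()

    def test_four_haplotypes_split_site(self):
        # alleles A,A,T,T at one site: 4 differing pairs of 6 -> 2/3
        calls = np.array([[Call.HAP_REF, Call.HAP_REF, Call.HAP_ALT, Call.HAP_ALT]])
        gm = build_matrix([500], calls)
        track = pi_windows(gm, ["S1", "S2", "S3", "S4"], w=1000, step=1000)
        assert track.values[0] == pytest.approx(4 / 6)

    def test_single_het_diploid(self):
        gm = build_matrix([500], [[Call.HET]])
        track = pi_windows(gm, ["S1"], w=1000, step=1000)
        assert track.values[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed,haploid", [(0, True), (1, True), (2, False), (3, False)])
    def test_matches_bruteforce_oracle(self, seed, haploid):
        rng = np.random.default_rng(seed)
        n_samples, n_sites = 10, 200
        pos = np.sort(rng.choice(5000, size=n_sites, replace=False)) + 1
        if haploid:
            codes = [Call.HAP_REF, Call.HAP_ALT, Call.MISSING]
        else:
            codes = [Call.HOM_REF, Call.HET, Call.HOM_ALT, Call.MISSING]
        calls = rng.choice(codes, size=(n_sites, n_samples))
        gm = build_matrix(pos, calls, chrom_length=5000)
        track = pi_windows(gm, gm.samples, w=1000, step=400)
        # expand each call into its allele multiset
        expand = {
            Call.HAP_REF: [0], Call.HAP_ALT: [1],
            Call.HOM_REF: [0, 0], Call.HET: [0, 1], Call.HOM_ALT: [1, 1],
            Call.MISSING: [],
        }
        per_site = brute_force_pi(
            [sum((expand[Call(c)] for c in row), []) for row in calls]
        )
        for row in track.windows.itertuples():
            expected = sum(
                v for p, v in zip(pos, per_site) if row.start <= p <= row.end
            )
            assert row.value == pytest.approx(expected, abs=1e-12)

    def test_sequence_order_and_allele_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        calls = rng.choice([Call.HAP_REF, Call.HAP_ALT], size=(50, 6))
        pos = np.arange(1, 51) * 37
        gm = build_matrix(pos, calls)
        t1 = pi_windows(gm, gm.samples)
        t2 = pi_windows(gm, gm.samples[::-1])
        swapped = np.where(calls == Call.HAP_REF, Call.HAP_ALT, Call.HAP_REF)
        t3 = pi_windows(build_matrix(pos, swapped), gm.samples)
        assert np.allclose(t1.values, t2.values)
        assert np.allclose(t1.values, t3.values)

    def test_mixed_ploidy_rejected(self):
        calls = np.array([[Call.HET, Call.HAP_REF]])
        gm = build_matrix([100], calls)
        with pytest.raises(ValueError, match="all haploid or all diploid"):
            pi_windows(gm, gm.samples)

    def test_masked_sites_excluded(self):
        calls = np.array([[Call.HAP_REF, Call.HAP_ALT]] * 2)
        gm = build_matrix([100, 300], calls)
        mask = MaskTrack.from_intervals([Interval("chr1", 250, 350)])
        track = pi_windows(gm, gm.samples, mask=mask, w=1000, step=1000)
        assert track.values[0] == pytest.approx(1.0)


class TestTopPercentileRegion:
    def test_uniform_track_is_degenerate(self):
        from test_het_scan import track_from_counts

        track = track_from_counts(np.full(200, 4.0), w=1000, s=800)
        assert top_percentile_region(track, q=0.01) is None

    def test_single_spike_recovered(self):
        from test_het_scan import track_from_counts

        values = np.zeros(500)
        values[250] = 9.0
        track = track_from_counts(values, w=1000, s=800)
        region = top_percentile_region(track, q=0.01)
        assert region == track.intervals()[250]

    def test_consecutive_run_spans_min_to_max(self):
        from test_het_scan import track_from_counts

        values = np.zeros(500)
        values[100:105] = [5, 6, 7, 6, 5]
        track = track_from_counts(values, w=1000, s=800)
        region = top_percentile_region(track, q=0.01)
        iv0, iv4 = track.intervals()[100], track.intervals()[104]
        assert region == Interval("chr1", iv0.start, iv4.end)

    def test_synthetic_locus_delineation(self, default_cohort):
        from csdscan.intervals import jaccard

        cfg, gm, st, mask, truth = default_cohort
        track = pi_windows(gm, st.haploid_males(), mask)
        search = Interval(truth.locus.chrom, truth.locus.start - 10000, truth.locus.end + 10000)
        region = top_percentile_region(track, q=0.01, search=search)
        assert region is not None
        assert jaccard(region, truth.locus) >= 0.5


class TestPhaseFemale:
    POOL = make_pool(["0000", "1111", "0011"])

    def test_unique_fully_heterozygous_pair(self):
        g = np.array([Call.HET] * 4, dtype=np.int8)
        hapA, hapB, status = phase_female(g, self.POOL)
        assert status == "unique"
        assert {hapA.tobytes(), hapB.tobytes()} == {
            self.POOL.sequences[0].tobytes(),
            self.POOL.sequences[1].tobytes(),
        }

    def test_unique_mixed_genotype_pair(self):
        g = np.array([Call.HOM_REF, Call.HOM_REF, Call.HET, Call.HET], dtype=np.int8)
        hapA, hapB, status = phase_female(g, self.POOL)
        assert status == "unique"
        assert {hapA.tobytes(), hapB.tobytes()} == {
            self.POOL.sequences[0].tobytes(),
            self.POOL.sequences[2].tobytes(),
        }

    def test_ambiguous_solutions_masked(self):
        pool = make_pool(["00", "11", "01", "10"])
        g = np.array([Call.HET, Call.HET], dtype=np.int8)
        hapA, hapB, status = phase_female(g, pool)
        assert status == "ambiguous"
        assert (hapA == MISS).all() and (hapB == MISS).all()

    def test_inconsistent_genotype_unphased(self):
        pool = make_pool(["0000", "1111"])
        g = np.array([Call.HOM_ALT, Call.HOM_REF, Call.HET, Call.HET], dtype=np.int8)
        hapA, hapB, status = phase_female(g, pool)
        assert status == "unphased"
        assert (hapA == MISS).all()

    def test_duplicate_pool_sequences_still_unique(self):
        pool = make_pool(["0000", "0000", "1111", "1111"])
        g = np.array([Call.HET] * 4, dtype=np.int8)
        _, _, status = phase_female(g, pool)
        assert status == "unique"

    def test_empty_pool_rejected(self):
        pool = make_pool(["00"])
        with pytest.raises(ValueError):
            phase_female(np.array([Call.HET, Call.HET], dtype=np.int8), HaplotypePool(pool.region, pool.snp_positions, np.empty((0, 2), np.int8)))

    def test_truth_recovery_on_synthetic_females(self, default_cohort):
        cfg, gm, st, _, truth = default_cohort
        pool = HaplotypePool(
            truth.locus, truth.locus_positions, truth.haplotype_sequences
        )
        on = gm.chrom_mask(truth.locus.chrom)
        pos = gm.sites.loc[on, "pos"].to_numpy()
        rows = np.flatnonzero(on)[np.isin(pos, truth.locus_positions)]
        for f in st.females()[:10]:
            g = gm.calls[rows, gm.sample_index(f)]
            hapA, hapB, status = phase_female(g, pool)
            assert status == "unique"
            a, b = truth.haplotype_labels[f]
            expect = {
                truth.haplotype_sequences[a].tobytes(),
                truth.haplotype_sequences[b].tobytes(),
            }
            assert {hapA.tobytes(), hapB.tobytes()} == expect


class TestNovelInference:
    def test_complement_derived_from_single_partner(self):
        # female carries pool haplotype 0000 plus an unseen partner:
        # partner allele is 1 at het sites, the called allele at hom sites
        pool = make_pool(["0000"])
        g = np.array([Call.HET, Call.HOM_REF, Call.HET, Call.HOM_REF], dtype=np.int8)
        novel = infer_novel_haplotype(g, pool)
        assert novel is not None
        assert list(novel) == [1, 0, 1, 0]

    def test_ambiguous_partners_return_none(self):
        pool = make_pool(["000", "011"])
        g = np.array([Call.HET, Call.HET, Call.HET], dtype=np.int8)
        assert infer_novel_haplotype(g, pool) is None


class TestHaplogroups:
    def test_identical_sequences_one_cluster(self):
        pool = make_pool(["0101"] * 5)
        assert haplogroup_clusters(pool).max() == 0

    def test_two_blocks_at_half_distance(self):
        pool = make_pool(["0000", "0000", "1111", "1111"])
        labels = haplogroup_clusters(pool, max_within_dist=0.02)
        assert labels.tolist() == [0, 0, 1, 1]

    def test_zero_overlap_pair_unlinked(self):
        pool = make_pool(["01NN", "NN01"])
        d = hamming_matrix(pool.sequences)
        assert np.isnan(d[0, 1])
        labels = haplogroup_clusters(pool)
        assert labels.tolist() == [0, 1]

    def test_synthetic_pool_recovers_k_groups(self, default_cohort):
        cfg, gm, st, _, truth = default_cohort
        ivs = Interval(truth.locus.chrom, truth.locus.start, truth.locus.end)
        pool, status = build_haplotype_pool(gm, st, ivs)
        labels = haplogroup_clusters(pool)
        assert labels.max() + 1 == cfg.k_haplotypes
        # members of one cluster all carry the same truth haplotype
        hm = st.haploid_males()
        by_label = {}
        for name, lab in zip(pool.names, labels):
            if name in hm:
                by_label.setdefault(lab, set()).add(truth.haplotype_labels[name][0])
        for members in by_label.values():
            assert len(members) == 1


class TestPoolFasta:
    def test_nucleotide_and_missing_encoding(self, tmp_path):
        pool = make_pool(["01N"])
        pool.ref = np.array(["A", "G", "C"])
        pool.alt = np.array(["C", "T", "A"])
        path = tmp_path / "p.fa"
        pool_to_fasta(pool, path)
        assert path.read_text() == ">hap1\nATN\n"

    def test_round_trip_count_and_length(self, tmp_path):
        pool = make_pool(["0101", "1N10", "0000"])
        path = tmp_path / "p.fa"
        pool_to_fasta(pool, path)
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        assert len(fa.keys()) == 3
        assert all(len(fa[k][:]) == 4 for k in fa.keys())
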