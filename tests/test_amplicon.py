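"""Read merging, filtering, denoising, clustering and abundance matrices."""

import numpy as np
import pandas as pd
import pytest

from gliamp import amplicon as amp
from gliamp import synthetic_data as sd
from gliamp.synthetic_data import ReadPair, revcomp


def make_pair(amplicon: str, read_len: int = 300, q: int = 30) -> ReadPair:
    qual = chr(q + 33) * read_len
    return ReadPair(
        id="p", fwd=amplicon[:read_len], fwd_qual=qual,
        rev=revcomp(amplicon[-read_len:]), rev_qual=qual,
    )


def random_amplicon(rng, n=420) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


class TestMerge:
    def test_error_free_pair_merges_to_full_amplicon(self):
        rng = np.random.default_rng(0)
        amplicon = random_amplicon(rng, 420)
        merged = amp.merge_pairs(make_pair(amplicon))
        assert isinstance(merged, amp.MergedRead)
        assert len(merged.seq) == 420
        assert merged.seq == amplicon

    def test_agreement_raises_posterior_quality_capped(self):
        rng = np.random.default_rng(1)
        amplicon = random_amplicon(rng, 420)
        merged = amp.merge_pairs(make_pair(amplicon, q=30))
        overlap = 300 + 300 - 420
        assert (merged.quals[300 - overlap : 300] == 45).all()  # min(30+30, 45)
        assert (merged.quals[: 300 - overlap] == 30).all()

    def test_no_overlap_candidates_rejected(self):
        rng = np.random.default_rng(2)
        a = ReadPair(
            id="x", fwd=random_amplicon(rng, 100), fwd_qual="I" * 100,
            rev=random_amplicon(rng, 100), rev_qual="I" * 100,
        )
        res = amp.merge_pairs(a)
        assert isinstance(res, str)

    @pytest.mark.parametrize("error", [0.005, 1e-4])
    def test_simulated_pairs_merge_accurately(self, family, error):
        """Merge rate >= 99% on simulated pairs; the exact-merge fraction
        matches a binomial oracle (a merged read is exact unless an error
        survives: always in single-coverage bases, with probability ~1/2 at
        equal-quality overlap mismatches)."""
        cfg = sd.ReadSimConfig(depth_per_sample=2000, per_base_error=error, chimera_rate=0.0, seed=4)
        freqs = family.truth["dna_frequency"].to_dict()
        pairs = sd.simulate_reads(family.records, {"s": freqs}, cfg)["s"]
        merged = amp.merge_pairs_batch(pairs)
        ok = [m for m in merged if isinstance(m, amp.MergedRead)]
        assert len(ok) / len(pairs) >= 0.99
        truth = family.sequences
        exact = np.mean(
            [
                m.seq == truth[p.truth]
                for m, p in zip(merged, pairs)
                if isinstance(m, amp.MergedRead)
            ]
        )
        lengths = [len(truth[p.truth]) for p in pairs]
        expected = np.mean(
            [
                (1 - error) ** (2 * L - 600)  # single-coverage bases
                * (1 - error) ** (600 - L)  # surviving overlap errors (rate ~ error)
                for L in lengths
            ]
        )
        sigma = np.sqrt(expected * (1 - expected) / len(ok))
        assert abs(exact - expected) < 5 * sigma + 0.01
        if error <= 1e-4:
            assert exact >= 0.95


class TestExpectedErrors:
    @pytest.mark.parametrize(
        "quals,expected",
        [([20] * 10, 0.1), ([2] * 100, 100 * 10 ** -0.2), ([], 0.0), ([30] * 200, 0.2)],
    )
    def test_closed_form(self, quals, expected):
        assert amp.expected_errors(quals) == pytest.approx(expected)

    def test_negative_phred_rejected(self):
        with pytest.raises(ValueError):
            amp.expected_errors([-1, 20])


class TestFilterReads:
    def test_length_threshold_is_inclusive(self):
        reads = [
            amp.MergedRead("A" * n, np.full(n, 40)) for n in (150, 159, 160, 161, 300)
        ]
        kept = amp.filter_reads(reads, amp.PipelineParams())
        assert [len(r.seq) for r in kept] == [160, 161, 300]

    def test_ee_boundary_inclusive_and_q30_read_kept(self):
        r200 = amp.MergedRead("A" * 200, np.full(200, 30))  # EE = 0.2
        # 200 bases at p = 1/200 each: EE exactly 1.0, at the inclusive limit
        r_exact = amp.MergedRead("A" * 200, np.full(200, 10 * np.log10(200)))
        kept = amp.filter_reads([r200, r_exact], amp.PipelineParams())
        assert len(kept) == 2

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        reads = [
            amp.MergedRead(
                "".join(rng.choice(list("ACGT"), size=n)), rng.integers(2, 41, size=n)
            )
            for n in rng.integers(100, 400, size=50)
        ]
        base = {r.seq for r in amp.filter_reads(reads, amp.PipelineParams())}
        looser = amp.PipelineParams(min_merged_len=120, max_expected_errors=2.0)
        assert base <= {r.seq for r in amp.filter_reads(reads, looser)}

    def test_n_bases_penalized(self):
        seq = "A" * 150 + "N" * 20 + "A" * 30
        r = amp.MergedRead(seq, np.full(200, 40))
        assert amp.filter_reads([r], amp.PipelineParams()) == []


class TestDereplicate:
    def test_single_sequence(self):
        u = amp.dereplicate({"s": ["ACGT"] * 100})
        assert len(u) == 1 and u.sizes[0] == 100

    def test_conservation_property(self):
        rng = np.random.default_rng(5)
        reads = {
            f"s{i}": ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(rng.integers(5, 50))]
            for i in range(4)
        }
        u = amp.dereplicate(reads)
        assert int(u.sizes.sum()) == sum(len(v) for v in reads.values())
        assert (u.sample_counts.sum(axis=0).to_numpy() == [len(reads[s]) for s in reads]).all()
        assert list(u.sizes) == sorted(u.sizes, reverse=True)

    def test_single_base_difference_stays_separate(self):
        u = amp.dereplicate({"s": ["ACGTACGT", "ACGTACGA"]})
        assert len(u) == 2


class TestDenoise:
    def test_satellite_absorbed_by_abundance_skew(self):
        seq = "ACGT" * 50
        sat = "T" + seq[1:]
        u = amp.dereplicate({"s": [seq] * 1000 + [sat] * 50})
        d = amp.denoise(u, alpha=2.0)
        # beta(1) = 1/8; 50/1000 = 0.05 <= 1/8 -> merged
        assert d.seqs == [seq] and d.sizes[0] == 1050

    def test_equal_sizes_remain_separate(self):
        rng = np.random.default_rng(6)
        a = random_amplicon(rng, 200)
        b = list(a)
        for i in (10, 50, 90, 130, 170):
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        b = "".join(b)
        u = amp.dereplicate({"s": [a] * 300 + [b] * 300})
        d = amp.denoise(u)
        assert len(d) == 2

    def test_chimera_of_abundant_parents_removed(self):
        rng = np.random.default_rng(7)
        a = random_amplicon(rng, 300)
        b = random_amplicon(rng, 300)
        chi = a[:150] + b[150:]
        u = amp.dereplicate({"s": [a] * 500 + [b] * 400 + [chi] * 5})
        d = amp.denoise(u)
        assert chi not in d.seqs
        assert {a, b} == set(d.seqs)

    def test_singletons_discarded_by_default(self):
        rng = np.random.default_rng(8)
        a = random_amplicon(rng, 200)
        u = amp.dereplicate({"s": [a] * 10 + [random_amplicon(rng, 200)]})
        assert amp.denoise(u).seqs == [a]


class TestCluster:
    def test_one_difference_in_200_joins(self):
        a = "ACGT" * 50
        b = "C" + a[1:]
        u = amp.dereplicate({"s": [a] * 10 + [b] * 5})
        c = amp.cluster_centroids(u, 0.99)
        assert len(c) == 1  # identity 199/200 = 0.995

    def test_three_differences_in_200_split(self):
        a = "ACGT" * 50
        b = list(a)
        for i in (0, 100, 199):
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        u = amp.dereplicate({"s": [a] * 10 + ["".join(b)] * 5})
        c = amp.cluster_centroids(u, 0.99)
        assert len(c) == 2  # identity 197/200 = 0.985

    def test_identical_sequences_one_cluster(self):
        u = amp.dereplicate({"s": ["ACGT" * 50] * 20})
        assert len(amp.cluster_centroids(u, 0.99)) == 1

    def test_identity_one_equals_dereplication(self):
        rng = np.random.default_rng(9)
        seqs = [random_amplicon(rng, 50) for _ in range(10)]
        reads = {"s": [seqs[i] for i in rng.integers(0, 10, size=200)]}
        u = amp.dereplicate(reads)
        c = amp.cluster_centroids(u, 1.0)
        assert sorted(c.seqs) == sorted(u.seqs)
        assert int(c.sizes.sum()) == int(u.sizes.sum())


class TestMapToDatabase:
    def test_error_free_reads_fully_assigned(self, family):
        cfg = sd.ReadSimConfig(depth_per_sample=500, per_base_error=0.0, chimera_rate=0.0, seed=1)
        freqs = family.truth["dna_frequency"].to_dict()
        pairs = sd.simulate_reads(family.records, {"s": freqs}, cfg)["s"]
        merged = [m.seq for m in amp.merge_pairs_batch(pairs)]
        u = amp.dereplicate({"s": merged})
        m = amp.map_to_database(u, family.records)
        assert int(m.sum().sum()) == 500
        truth_counts = pd.Series([p.truth for p in pairs]).value_counts()
        for vid, n in truth_counts.items():
            assert m.loc[vid, "s"] == n

    def test_equidistant_read_tie_breaks_to_earlier_entry(self):
        log = amp.StageLog()
        a = "ACGT" * 50
        b = "T" + a[1:-1] + "A"
        query = "T" + a[1:]  # distance 1 to both a and b
        u = amp.dereplicate({"s": [query] * 7})
        m = amp.map_to_database(u, [("first", a), ("second", b)], 0.99, log)
        assert m.loc["first", "s"] == 7 and m.loc["second", "s"] == 0
        assert log.counts.get("ties", 0) >= 1

    def test_empty_database_raises(self):
        u = amp.dereplicate({"s": ["ACGT"]})
        with pytest.raises(ValueError):
            amp.map_to_database(u, [])


class TestHighConfidenceFilter:
    @pytest.mark.parametrize(
        "row,kept",
        [
            ([80, 80, 80, 0], True),
            ([74, 200, 200, 200], True),
            ([74, 74, 200, 200], False),
            ([75, 75, 75], True),
        ],
    )
    def test_examples(self, row, kept):
        m = pd.DataFrame([row], index=["v"], columns=[f"s{i}" for i in range(len(row))])
        filtered, dropped = amp.high_confidence_filter(m)
        assert (len(filtered) == 1) is kept
        assert (dropped == ["v"]) is not kept

    def test_equivalent_to_row_scan_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            m = pd.DataFrame(
                rng.integers(0, 200, size=(30, 6)),
                index=[f"v{i}" for i in range(30)],
            )
            filtered, _ = amp.high_confidence_filter(m, 75, 3)
            oracle = [
                vid
                for vid, row in m.iterrows()
                if sum(1 for x in row if x >= 75) >= 3
            ]
            assert list(filtered.index) == oracle


class TestNormalizeCounts:
    def test_identity_when_equal_totals_and_unit_factors(self):
        m = pd.DataFrame({"s1": [10, 90], "s2": [40, 60]}, index=["a", "b"])
        ones = pd.Series(1.0, index=m.columns)
        out, prov = amp.normalize_counts(m, ones, ones)
        pd.testing.assert_frame_equal(out, m.astype(float))
        assert prov == ["raw", "rarefied_to_smallest_sample", "dilution_adjusted", "nf_adjusted"]

    def test_rarefaction_halves_larger_sample(self):
        m = pd.DataFrame({"s1": [1000], "s2": [2000]}, index=["a"])
        out, _ = amp.normalize_counts(m)
        assert out.loc["a", "s1"] == 1000 and out.loc["a", "s2"] == 1000

    def test_nf_divides(self):
        m = pd.DataFrame({"s1": [100], "s2": [100]}, index=["a"])
        nf = pd.Series({"s1": 1.0, "s2": 2.0})
        out, _ = amp.normalize_counts(m, nf=nf)
        assert out.loc["a", "s2"] == pytest.approx(out.loc["a", "s1"] / 2)

    def test_dilution_multiplies(self):
        m = pd.DataFrame({"s1": [100], "s2": [100]}, index=["a"])
        dil = pd.Series({"s1": 1.0, "s2": 3.0})
        out, _ = amp.normalize_counts(m, dilution=dil)
        assert out.loc["a", "s2"] == pytest.approx(300.0)

    def test_zero_total_sample_raises_with_name(self):
        m = pd.DataFrame({"good": [10], "empty": [0]}, index=["a"])
        with pytest.raises(ValueError, match="empty"):
            amp.normalize_counts(m)
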