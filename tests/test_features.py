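"""Feature-level coverage, junction-spanning reads and the statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from dsbsirna.features import (
    compare_features,
    count_feature_reads,
    count_spliced_junction_reads,
    enrichment_test,
)
from dsbsirna.locus import GeneModel, derive_features
from dsbsirna.reads import AlignedRead, RawRead, reverse_complement

from conftest import make_library, random_sequence, uniform_reads


class TestCountFeatureReads:
    def test_junction_spanning_rules(self, two_exon_gene):
        fs = derive_features(two_exon_gene)
        spanning = make_library([AlignedRead(95, 21, "+", "a")])       # 5 + 16 flank
        touching = make_library([AlignedRead(100, 21, "+", "b")])      # 0 left of 100
        fc1 = count_feature_reads(spanning, fs, two_exon_gene)
        fc2 = count_feature_reads(touching, fs, two_exon_gene)
        # junction between exon1 end (200) needs flank on both sides of 200;
        # read [95,116) spans nothing at 200 but read [190,211) would.
        assert fc1.counts["exon1"] == 1
        read_at_junction = make_library([AlignedRead(195, 21, "+", "c")])
        fc3 = count_feature_reads(read_at_junction, fs, two_exon_gene)
        assert fc3.counts["exon1_intron1_5p"] == 1
        no_overhang = make_library([AlignedRead(200, 21, "+", "d")])
        fc4 = count_feature_reads(no_overhang, fs, two_exon_gene)
        assert fc4.counts["exon1_intron1_5p"] == 0
        assert fc2.counts["exon1"] == 1  # intersects exon1 at base 100? no:
        # read [100,121) lies inside exon1 [100,200) entirely
        assert fc2.counts["intron1"] == 0

    def test_uniform_tiling_junction_count_and_density(self, two_exon_gene):
        """Tiling every start once: a genomic junction collects L-1 = 20
        spanning reads at o=1 and its normalized density equals the exon
        density."""
        fs = derive_features(two_exon_gene, read_length=21, min_overhang=1)
        lib = make_library(uniform_reads(100, 500, 21))  # tile from the TSS
        fc = count_feature_reads(lib, fs, two_exon_gene)
        assert fc.counts["exon1_intron1_5p"] == 20
        assert fc.counts["intron1_exon2_3p"] == 20
        # exon1 starts at the tiling boundary: 100 reads over 100 bases,
        # exactly the junction's 20 reads over size 20
        assert fc.normalized["exon1_intron1_5p"] == pytest.approx(
            fc.normalized["exon1"]
        )

    def test_matches_brute_force(self, four_exon_gene, rng):
        fs = derive_features(four_exon_gene, min_overhang=3)
        reads = [
            AlignedRead(int(rng.integers(0, 680)), 21, "+", f"r{i}")
            for i in range(400)
        ]
        fc = count_feature_reads(make_library(reads), fs, four_exon_gene, min_overhang=3)
        for f in fs:
            if f.kind in ("exon", "intron"):
                a, b = f.interval
                want = sum(1 for r in reads if r.start < b and r.start + 21 > a)
            elif f.junction.kind == "exon_exon":
                continue
            else:
                p = f.junction.position
                want = sum(
                    1 for r in reads if r.start <= p - 3 and r.start + 21 >= p + 3
                )
            assert fc.counts[f.label] == want, f.label

    def test_uniform_placement_matches_expected_rates(self, four_exon_gene, rng):
        """Uniform random starts: every feature's count matches its
        expected spanning-start rate within binomial sampling error.

        An interval feature of size s is intersected by s + L - 1 start
        positions, a junction at overhang o by L - 2o + 1 (its size), so
        after edge correction all features see the same per-start rate.
        """
        L, n = 21, 40000
        fs = derive_features(four_exon_gene)
        n_starts = 680  # starts 0..679 keep reads inside [0, 700)
        starts = rng.integers(0, n_starts, size=n)
        reads = [AlignedRead(int(s), L, "+", f"r{i}") for i, s in enumerate(starts)]
        fc = count_feature_reads(make_library(reads), fs, four_exon_gene)
        for f in fs:
            if f.kind == "junction":
                if f.junction.kind == "exon_exon":
                    continue
                eligible = L - 1  # o = 1
            else:
                a, b = f.interval
                eligible = min(b, n_starts) - max(a - L + 1, 0)
            expect = n * eligible / n_starts
            sd = np.sqrt(expect)
            assert abs(fc.counts[f.label] - expect) < 5 * sd, f.label


class TestSplicedJunctionReads:
    def _setup(self, rng):
        ref = random_sequence(rng, 500)
        g = GeneModel("g", "c", "+", 100, 400, ((100, 200), (300, 400)))
        return ref, g

    def test_spliced_read_counted_once(self, rng):
        ref, g = self._setup(rng)
        cdna = g.spliced_sequence(ref)
        # read straddling the exon-exon boundary (position 100 on the cDNA)
        read = RawRead("sp", cdna[90:111])
        counts = count_spliced_junction_reads([read], g, ref)
        assert counts == {"exon1_exon2_ee": 1}

    def test_exonic_read_excluded_as_genomic(self, rng):
        ref, g = self._setup(rng)
        read = RawRead("ex", ref[120:141])  # wholly inside exon1: maps to both axes
        counts = count_spliced_junction_reads([read], g, ref)
        assert counts["exon1_exon2_ee"] == 0

    def test_exclusion_never_increases_counts(self, rng):
        ref, g = self._setup(rng)
        cdna = g.spliced_sequence(ref)
        reads = [RawRead(f"r{i}", cdna[s : s + 21]) for i, s in enumerate(range(80, 120))]
        with_excl = count_spliced_junction_reads(reads, g, ref, exclude_genomic=True)
        without = count_spliced_junction_reads(reads, g, ref, exclude_genomic=False)
        assert with_excl["exon1_exon2_ee"] <= without["exon1_exon2_ee"]

    def test_antisense_spliced_read_counts(self, rng):
        ref, g = self._setup(rng)
        cdna = g.spliced_sequence(ref)
        read = RawRead("as", reverse_complement(cdna[95:116]))
        counts = count_spliced_junction_reads([read], g, ref)
        assert counts["exon1_exon2_ee"] == 1


class TestCompareFeatures:
    def _fc(self, values, rep):
        from dsbsirna.features import FeatureCoverage

        return FeatureCoverage(
            f"rep{rep}", {k: 0 for k in values}, dict(values), 10**6
        )

    def test_identical_replicates_degenerate(self):
        reps = [self._fc({"a": 2.0, "b": 1.0}, i) for i in range(4)]
        res = compare_features(reps, "a", "b")
        assert res.degenerate and res.p_value is None
        assert res.mean_difference == pytest.approx(1.0)

    def test_matches_closed_form_paired_t(self, rng):
        a = 2.0 + rng.normal(0, 0.3, size=4)
        b = 1.0 + rng.normal(0, 0.3, size=4)
        reps = [self._fc({"a": a[i], "b": b[i]}, i) for i in range(4)]
        res = compare_features(reps, "a", "b")
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(4))
        p = 2 * sps.t.sf(abs(t), df=3)
        assert res.p_value == pytest.approx(p)

    def test_depressed_intron_detected(self, rng):
        """An intron at half the exon density across 4 replicates is
        significant at 0.05."""
        reps = []
        for i in range(4):
            e = 1.0 * (1 + rng.normal(0, 0.05))
            reps.append(self._fc({"exon": e, "intron": e / 2 * (1 + rng.normal(0, 0.05))}, i))
        res = compare_features(reps, "exon", "intron")
        assert res.p_value < 0.05

    def test_group_averaging(self):
        reps = [self._fc({"e1": 2.0 + i, "e2": 4.0 + i, "i1": 1.0 + i}, i) for i in range(3)]
        res = compare_features(reps, ["e1", "e2"], "i1")
        assert res.mean_difference == pytest.approx(2.0)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            compare_features([self._fc({"a": 1, "b": 2}, 0)], "a", "b")


class TestEnrichmentTest:
    def test_equal_proportions_null(self):
        chi2, p = enrichment_test([[10, 90], [20, 180]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_independent_chi2_oracle(self, rng):
        """Closed-form Pearson statistic + chi2 survival function."""
        for _ in range(20):
            t = rng.integers(1, 60, size=(2, 2)).astype(float)
            chi2, p = enrichment_test(t)
            n = t.sum()
            row, col = t.sum(axis=1), t.sum(axis=0)
            expect = np.outer(row, col) / n
            stat = ((t - expect) ** 2 / expect).sum()
            assert chi2 == pytest.approx(stat, rel=1e-10)
            assert p == pytest.approx(float(sps.chi2.sf(stat, df=1)), rel=1e-10)

    def test_yates_correction_reduces_statistic(self):
        plain, _ = enrichment_test([[8, 8], [18, 104]], correction="none")
        corrected, _ = enrichment_test([[8, 8], [18, 104]], correction="yates")
        assert corrected < plain

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test([[0, 0], [5, 10]])

    def test_shape_validated(self):
        with pytest.raises(ValueError):
            enrichment_test([[1, 2, 3], [4, 5, 6]])
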