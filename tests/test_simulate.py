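"""Read simulator: per-step distributions, liftover, extraction, errors."""

import numpy as np
import pytest

import chipdesign as cd
from chipdesign.genome import DensityProfile, MaternalProbTrack
from chipdesign.simulate import (
    array_to_qual,
    insert_errors,
    lift_to_allele,
    qual_to_array,
    sample_fragment_length,
    sample_midpoint,
)

# closed-form moments of round(100 + 600*Beta(2,5))
BETA_MEAN = 100 + 600 * 2 / 7          # 1900/7 ~ 271.43
BETA_SD = np.sqrt(600**2 * 10 / 392)   # ~ 95.83


class TestFragmentLength:
    def test_range_and_moments(self, rng):
        draws = sample_fragment_length(rng, size=100_000)
        assert draws.min() >= 100 and draws.max() <= 700
        se_mean = BETA_SD / np.sqrt(len(draws))
        assert abs(draws.mean() - BETA_MEAN) < 3 * se_mean
        assert abs(draws.std() - BETA_SD) / BETA_SD < 0.03

    def test_scalar_draw(self, rng):
        val = sample_fragment_length(rng)
        assert isinstance(val, int) and 100 <= val <= 700


class TestMidpoint:
    def test_point_mass(self, rng):
        w = np.zeros(100)
        w[37] = 1.0
        d = DensityProfile(weights=w)
        assert all(sample_midpoint(d, rng) == 37 for _ in range(20))

    def test_two_bin_frequencies(self, rng):
        w = np.array([0.9, 0.1])
        d = DensityProfile(weights=w)
        draws = sample_midpoint(d, rng, size=10_000)
        frac0 = np.mean(draws == 0)
        se = np.sqrt(0.9 * 0.1 / 10_000)
        assert abs(frac0 - 0.9) < 3 * se

    def test_uniform_frequencies_within_multinomial_ci(self, rng):
        n_bins, n = 20, 100_000
        d = DensityProfile(weights=np.ones(n_bins))
        draws = sample_midpoint(d, rng, size=n)
        counts = np.bincount(draws, minlength=n_bins)
        p = 1 / n_bins
        se = np.sqrt(n * p * (1 - p))
        assert (np.abs(counts - n * p) < 4 * se).all()

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError):
            DensityProfile(weights=np.zeros(10))


class TestAssignAllele:
    def test_background_is_fair_coin(self, rng):
        track = MaternalProbTrack(components=[])
        draws = [cd.assign_allele(5, track, rng) for _ in range(10_000)]
        frac = np.mean([a == "maternal" for a in draws])
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_component_probability_recovered(self, rng):
        track = MaternalProbTrack(components=[(0, 100, 0.9)])
        draws = [cd.assign_allele(50, track, rng) for _ in range(10_000)]
        frac = np.mean([a == "maternal" for a in draws])
        assert abs(frac - 0.9) < 3 * np.sqrt(0.9 * 0.1 / 10_000)

    def test_ordering_preserved(self, rng):
        track = MaternalProbTrack(components=[(0, 100, 0.1), (200, 300, 0.9)])
        lo = np.mean([cd.assign_allele(50, track, rng) == "maternal"
                      for _ in range(3000)])
        hi = np.mean([cd.assign_allele(250, track, rng) == "maternal"
                      for _ in range(3000)])
        assert lo < hi


class TestLiftover:
    def test_identity_on_snp_only_genome(self, snp_genome):
        for z in (0, 1234, 9999):
            assert lift_to_allele(z, snp_genome, "maternal") == z
            assert lift_to_allele(z, snp_genome, "paternal") == z

    def test_offset_beyond_deletion(self, indel_genome):
        g = indel_genome
        dels = [
            v for v in g.variants
            if len(v.ref_allele) > len(v.maternal_allele)
        ]
        v = dels[0]
        width = len(v.ref_allele) - 1
        z = v.pos + len(v.ref_allele) + 5  # safely beyond the deletion
        assert lift_to_allele(z, g, "maternal") == g.ref_to_mat[z] == z - sum(
            len(u.ref_allele) - len(u.maternal_allele)
            for u in g.variants
            if u.pos < z and len(u.ref_allele) > len(u.maternal_allele)
        ) + sum(
            len(u.maternal_allele) - len(u.ref_allele)
            for u in g.variants
            if u.pos < z and len(u.maternal_allele) > len(u.ref_allele)
        )

    def test_perturbation_matches_exhaustive_search(self, indel_genome):
        """Inside a deletion, the lifted position is the nearest defined
        neighbor's map, lower coordinate first on ties."""
        g = indel_genome
        m = g.ref_to_mat
        undefined = np.flatnonzero(m == -1)
        assert len(undefined)
        for z in undefined:
            got = lift_to_allele(int(z), g, "maternal", max_perturb=10)
            # exhaustive oracle
            best = None
            for d in range(1, 11):
                for p in (z - d, z + d):
                    if 0 <= p < len(m) and m[p] >= 0:
                        best = int(m[p])
                        break
                if best is not None:
                    break
            assert got == best

    def test_error_past_max_perturb(self, snp_genome):
        with pytest.raises(ValueError):
            lift_to_allele(20_000, snp_genome, "maternal")


class TestExtractReadPair:
    def test_toy_plus_strand(self):
        m1, m2 = cd.extract_read_pair("ACGTACGTAC", 0, 10, 4, "+")
        assert m1 == "ACGT"
        assert m2 == "GTAC"  # revcomp("GTAC") == "GTAC"

    def test_fully_overlapping_mates_are_revcomp(self, plain_genome):
        s = plain_genome.ref_seq
        m1, m2 = cd.extract_read_pair(s, 100, 36, 36, "+")
        assert m2 == cd.revcomp(m1)

    def test_strand_swaps_mates(self, plain_genome):
        s = plain_genome.ref_seq
        p1, p2 = cd.extract_read_pair(s, 500, 200, 36, "+")
        n1, n2 = cd.extract_read_pair(s, 500, 200, 36, "-")
        assert (p1, p2) == (n2, n1)

    def test_out_of_bounds_rejected(self, plain_genome):
        with pytest.raises(ValueError):
            cd.extract_read_pair(plain_genome.ref_seq, -5, 100, 36, "+")
        with pytest.raises(ValueError):
            cd.extract_read_pair(plain_genome.ref_seq, 9950, 100, 36, "+")


class TestInsertErrors:
    def test_q41_rarely_changes_short_read(self, rng):
        seq = "ACGT" * 9
        qual = array_to_qual(np.full(36, 41))
        changed = sum(
            insert_errors(seq, qual, rng) != seq for _ in range(100)
        )
        # per-read error prob ~ 36 * 7.9e-5 ~ 0.003
        assert changed <= 3

    def test_phred_rate_calibration(self, rng):
        n = 100_000
        seq = "A" * n
        qual = array_to_qual(np.full(n, 20))
        mutated = insert_errors(seq, qual, rng)
        rate = sum(a != b for a, b in zip(seq, mutated)) / n
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(rate - 0.01) < 3 * se

    def test_degenerate_substitution_matrix(self, rng):
        sub = np.zeros((4, 4))
        sub[0, 1] = 1.0  # A -> C only
        sub[1, 0] = sub[2, 0] = sub[3, 0] = 1.0
        seq = "A" * 10_000
        qual = array_to_qual(np.full(10_000, 3))  # ~50% error rate
        mutated = insert_errors(seq, qual, rng, substitution_matrix=sub)
        assert set(mutated) <= {"A", "C"}
        assert "C" in mutated

    def test_invalid_quality_rejected(self, rng):
        with pytest.raises(ValueError):
            insert_errors("ACGT", "!!" + chr(130) * 2, rng)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            insert_errors("ACGT", "III", rng)


@pytest.fixture()
def sim(snp_genome):
    density = cd.build_density(snp_genome, 2, enrichment=5, seed=2)
    track = cd.assign_maternal_probs(snp_genome, seed=2)
    qm = cd.QualityModel.parametric()
    return snp_genome, density, track, qm


class TestSimulateReads:

    def test_determinism(self, sim):
        g, d, t, qm = sim
        a = cd.simulate_reads(g, d, t, qm, 10, 36, seed=99)
        b = cd.simulate_reads(g, d, t, qm, 10, 36, seed=99)
        assert a[0] == b[0]
        assert a[1].equals(b[1])

    def test_counts_and_schema(self, sim):
        g, d, t, qm = sim
        pairs, truth = cd.simulate_reads(g, d, t, qm, 50, 36, seed=4)
        assert len(pairs) == len(truth) == 50
        assert all(len(p.mate1_seq) == len(p.mate1_qual) == 36 for p in pairs)
        assert set(truth["allele"]) <= {"maternal", "paternal"}
        assert ((truth["length"] >= 100) & (truth["length"] <= 700)).all()

    def test_error_free_mate1_occurs_in_genome(self, plain_genome):
        d = cd.build_density(plain_genome, 0, seed=1)
        t = cd.assign_maternal_probs(plain_genome, seed=1)
        qm = cd.QualityModel.constant(41)
        pairs, truth = cd.simulate_reads(
            plain_genome, d, t, qm, 30, 36, seed=5, apply_errors=False
        )
        ref = plain_genome.ref_seq
        for p in pairs:
            assert p.mate1_seq in ref or cd.revcomp(p.mate1_seq) in ref

    def test_maternal_fraction_recovers_track_probability(self, plain_genome):
        track = MaternalProbTrack(components=[(0, 10_000, 0.9)])
        d = cd.build_density(plain_genome, 0, seed=1)
        qm = cd.QualityModel.constant(41)
        _, truth = cd.simulate_reads(
            plain_genome, d, track, qm, 10_000, 36, seed=6, apply_errors=False
        )
        frac = (truth["allele"] == "maternal").mean()
        assert abs(frac - 0.9) < 3 * np.sqrt(0.9 * 0.1 / 10_000)

    def test_quality_model_modes(self, rng):
        par = cd.QualityModel.parametric(q_start=38, q_slope=0.1, q_noise_sd=0)
        q = par.sample(101, rng)
        assert q[0] == 38 and q[-1] < q[0]  # declining profile
        emp = cd.QualityModel.empirical(["IIIIHHHH", "IIIIIIII"])
        q2 = emp.sample(8, rng)
        assert len(q2) == 8
        with pytest.raises(ValueError):
            emp.sample(50, rng)

    def test_qual_string_roundtrip(self):
        arr = np.array([2, 20, 41])
        assert (qual_to_array(array_to_qual(arr)) == arr).all()
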