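"""Profile HMM: construction, glocal scoring, calibration, E-values, scanning."""

import math

import numpy as np
import pytest
from scipy import stats

from acdscan.core_io import AMINO_ACIDS, Alignment, SeedAnnotation, SequenceRecord
from acdscan.profile_hmm import (
    GumbelFit,
    ProfileHMM,
    build_profile,
    calibrate,
    determine_match_columns,
    evalue,
    fit_gumbel,
    forward,
    scan,
    viterbi,
    viterbi_score,
)
from acdscan.synthetic import sample_acd

from .oracles import enumerate_glocal, random_tiny_profile

UNIFORM = np.full(20, 0.05)


class TestMatchColumns:
    def test_gap_fractions_below_half_are_match(self):
        aln = Alignment([("a", "AC-"), ("b", "A-G"), ("c", "ACG")])
        assert determine_match_columns(aln, 0.5).tolist() == [True, True, True]

    def test_majority_gap_column_is_insert(self):
        aln = Alignment([("a", "A-"), ("b", "A-"), ("c", "AG")])
        assert determine_match_columns(aln, 0.5).tolist() == [True, False]

    def test_all_gapped_rejected(self):
        aln = Alignment([("a", "-"), ("b", "-")])
        with pytest.raises(ValueError):
            determine_match_columns(aln, 0.5)


class TestBuildProfile:
    ANN2 = SeedAnnotation({1: "b2", 2: "b2"})

    def test_vanishing_pseudocount_limit(self):
        aln = Alignment([("a", "AA"), ("b", "AA")])
        p = build_profile(aln, self.ANN2, pseudocount_weight=1e-9,
                          background=UNIFORM)
        assert p.M == 2
        assert p.match_emit[0, AMINO_ACIDS.index("A")] == pytest.approx(1.0)

    def test_pseudocount_mixture_hand_value(self):
        # two observed A's, weight 20, uniform background: (2 + 20*0.05)/(2+20)
        aln = Alignment([("a", "AA"), ("b", "AA")])
        p = build_profile(aln, self.ANN2, pseudocount_weight=20.0,
                          background=UNIFORM)
        assert p.match_emit[0, AMINO_ACIDS.index("A")] == pytest.approx(3 / 22)

    def test_insert_column_counts_feed_mi_transition(self):
        # column 2 is gap-majority -> insert; one row uses it
        aln = Alignment([("a", "A-C"), ("b", "AGC"), ("c", "A-C")])
        ann = SeedAnnotation({1: "b2", 2: "b2", 3: "b3"})
        p = build_profile(aln, ann, background=UNIFORM)
        assert p.M == 2
        # one observed M->I against zero M->D: insert usage must dominate
        assert p.t_mi[0] > p.t_md[0]

    def test_unlabeled_match_column_rejected(self):
        aln = Alignment([("a", "AA"), ("b", "AA")])
        with pytest.raises(ValueError, match="landmark"):
            build_profile(aln, SeedAnnotation({1: "b2"}), background=UNIFORM)

    def test_normalization_invariants(self, seed_profile):
        p = seed_profile
        assert np.allclose(p.match_emit.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(p.t_mm + p.t_mi + p.t_md, 1.0, atol=1e-9)
        assert np.allclose(p.t_im + p.t_ii, 1.0, atol=1e-9)
        assert np.allclose(p.t_dm + p.t_dd, 1.0, atol=1e-9)
        assert sorted(p.landmark_of_column) == list(range(1, p.M + 1))


def single_state_delta_profile():
    emit = np.zeros((1, 20))
    emit[0, AMINO_ACIDS.index("A")] = 1.0
    z = np.zeros(0)
    return ProfileHMM(
        match_emit=emit, insert_emit=np.tile(UNIFORM, (2, 1)),
        t_mm=z, t_mi=z, t_md=z, t_im=z, t_ii=z, t_dm=z, t_dd=z,
        entry_m=1.0, entry_d=0.0, background=UNIFORM,
    )


class TestScoring:
    def test_single_column_closed_form(self):
        p = single_state_delta_profile()
        score, path = viterbi(p, "A")
        assert score == pytest.approx(math.log2(20))
        assert path.column_map == (1,)
        # only one path exists, so the sums coincide
        assert forward(p, "A") == pytest.approx(score)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            p = random_tiny_profile(rng)
            s = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(1, 7)))
            vb_oracle, fw_oracle = enumerate_glocal(p, s)
            assert viterbi_score(p, s) == pytest.approx(vb_oracle, abs=1e-9)
            assert forward(p, s) == pytest.approx(fw_oracle, abs=1e-9)

    def test_forward_dominates_viterbi(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = random_tiny_profile(rng)
            s = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(1, 9)))
            assert forward(p, s) >= viterbi_score(p, s) - 1e-9

    def test_consensus_outscores_its_reversal(self, gen_profile):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s, _ = sample_acd(gen_profile, rng)
            assert viterbi_score(gen_profile, s) >= viterbi_score(
                gen_profile, s[::-1]
            )

    def test_traceback_envelope_consistency(self, gen_profile):
        rng = np.random.default_rng(4)
        flank = "".join(rng.choice(list(AMINO_ACIDS), size=40))
        acd, _ = sample_acd(gen_profile, rng)
        _, path = viterbi(gen_profile, flank + acd + flank)
        matched = [t for t in path.column_map if t is not None]
        assert matched == sorted(matched)
        span = path.end - path.start + 1
        assert span == len(matched) + sum(path.insert_counts)

    def test_x_scores_as_background(self):
        p = single_state_delta_profile()
        assert viterbi_score(p, "X") == pytest.approx(0.0)


class TestCalibration:
    def test_gumbel_parameter_recovery(self):
        rng = np.random.default_rng(11)
        scores = stats.gumbel_r.rvs(loc=10.0, scale=1 / 0.7, size=10_000,
                                    random_state=rng)
        fit = fit_gumbel(scores)
        assert fit.mu == pytest.approx(10.0, abs=0.2)
        assert fit.lam == pytest.approx(0.7, abs=0.05)

    def test_minimum_sample_size_enforced(self, seed_profile):
        with pytest.raises(ValueError, match="100"):
            calibrate(seed_profile, n=99)
        with pytest.raises(ValueError):
            GumbelFit(mu=0.0, lam=0.5, n_samples=99, sample_length=10, seed=0)

    def test_same_seed_reproduces_fit(self, seed_profile):
        f1 = calibrate(seed_profile, n=120, length=80, seed=5)
        f2 = calibrate(seed_profile, n=120, length=80, seed=5)
        assert (f1.mu, f1.lam) == (f2.mu, f2.lam)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_gumbel(np.zeros(200))


class TestEvalue:
    FIT = GumbelFit(mu=10.0, lam=0.7, n_samples=1000, sample_length=100, seed=0)

    def test_score_at_mu(self):
        assert evalue(10.0, self.FIT, 1000) == pytest.approx(
            1000 * (1 - math.exp(-1))
        )

    def test_closed_form_value(self):
        assert evalue(20.0, self.FIT, 1000) == pytest.approx(
            1000 * (1 - math.exp(-math.exp(-7))), rel=1e-9
        )
        assert evalue(20.0, self.FIT, 1000) == pytest.approx(0.911466, abs=1e-4)

    def test_monotone_decreasing_in_score(self):
        scores = np.linspace(-10, 60, 50)
        es = [evalue(s, self.FIT, 100) for s in scores]
        assert all(a >= b for a, b in zip(es, es[1:]))
        assert es[-1] < 1e-10


class TestScan:
    def test_planted_sequences_found_without_decoys(self, seed_profile, gen_profile):
        rng = np.random.default_rng(6)
        p = seed_profile
        p.calibration = calibrate(p, n=200, length=150, seed=6)
        db = []
        for i in range(5):
            acd, _ = sample_acd(gen_profile, rng)
            db.append(SequenceRecord(f"POS{i}", acd))
        for i in range(5):
            s = "".join(rng.choice(list(AMINO_ACIDS), size=120))
            db.append(SequenceRecord(f"NEG{i}", s))
        hits = scan(p, db, 1e-3)
        assert {h.accession for h in hits} == {f"POS{i}" for i in range(5)}

    def test_empty_db_and_zero_threshold(self, seed_profile):
        p = seed_profile
        p.calibration = calibrate(p, n=100, length=100, seed=7)
        assert scan(p, [], 1e-3) == []
        rec = SequenceRecord("A", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
        assert scan(p, [rec], 0.0) == []

    def test_uncalibrated_profile_rejected(self, gen_profile):
        gen_profile.calibration = None
        with pytest.raises(ValueError, match="calibrat"):
            scan(gen_profile, [], 1e-3)

    def test_seed_members_detected(self, seed_alignment, seed_profile):
        """The degapped seed rows themselves must be confident hits."""
        aln, _ = seed_alignment
        p = seed_profile
        p.calibration = calibrate(p, n=200, length=100, seed=8)
        db = [SequenceRecord(acc, row.replace("-", "")) for acc, row in aln.rows]
        hits = scan(p, db, 1e-3)
        assert len(hits) == len(db)
        assert all(h.e_value <= 1e-3 for h in hits)


class TestSerialization:
    def test_json_round_trip(self, seed_profile, tmp_path):
        p = seed_profile
        p.calibration = GumbelFit(mu=-20.0, lam=0.3, n_samples=200,
                                  sample_length=150, seed=1)
        path = tmp_path / "profile.json"
        p.to_json(path)
        q = ProfileHMM.from_json(path)
        assert q.M == p.M
        np.testing.assert_allclose(q.match_emit, p.match_emit, atol=1e-12)
        np.testing.assert_allclose(q.t_mm, p.t_mm, atol=1e-12)
        assert q.landmark_of_column == p.landmark_of_column
        assert q.calibration.mu == p.calibration.mu
        s = "MKTAYIAKQRQISFVKSHFSRQ"
        assert viterbi_score(q, s) == pytest.approx(viterbi_score(p, s), abs=1e-9)
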