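"""Numt screening: translation, hard flags, codon-ratio test, clock."""

import math

import numpy as np
import pytest

from barcodegap.pseudogene_qc import (
    ClockParams,
    best_frame,
    consensus_record,
    divergence_time,
    exact_multinomial_test,
    insertion_scan,
    screen,
    screen_alignment,
    strip_insertions,
    translate,
)
from barcodegap.seq_io import BarcodeAlignment, BarcodeRecord
from barcodegap.synthetic_data import SimulationConfig, inject_numts, simulate_community


class TestTranslate:
    @pytest.mark.parametrize(
        "seq,frame,expected",
        [
            ("ATGTAA", 0, "M*"),
            ("AGAAGG", 0, "SS"),    # AGA/AGG are Ser under the invertebrate mito code
            ("TGATGG", 0, "WW"),    # TGA is Trp, never stop
            ("ATGGCC", 0, "MA"),
            ("AATGGCC", 1, "MA"),   # frame shift
            ("ATGGC", 0, "M"),      # trailing incomplete codon dropped
            ("ATNGGC", 0, "XG"),    # ambiguity -> X
        ],
    )
    def test_examples(self, seq, frame, expected):
        assert translate(seq, frame) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            translate("", 0)

    def test_bad_frame_rejected(self):
        with pytest.raises(ValueError):
            translate("ATG", 3)


def test_best_frame_minimises_stops():
    # in-frame clean ORF: frame 0 has no stops
    seq = "ATGGCCATTGTAATGGGC"
    assert best_frame(seq) == 0
    # shifting by one puts stops in frame 0; best frame becomes 1
    shifted = "C" + seq
    assert translate(shifted, 1).count("*") == 0


class TestScreen:
    def setup_method(self):
        self.ref = BarcodeRecord("ref", "ATGGCCATTGTAATGGGCACCTTA")

    def test_identity_passes(self):
        rec = BarcodeRecord("q", self.ref.sequence)
        rep = screen(rec, self.ref)
        assert rep.verdict == "pass"
        assert not rep.has_internal_stop and not rep.has_indel
        assert rep.codon_ratio == (0, 0, 0)
        assert rep.protein_diffs == 0
        assert rep.k2p_to_reference == 0.0

    def test_internal_stop_fails(self):
        # mutate codon 2 (GCC) to TAA
        seq = self.ref.sequence[:3] + "TAA" + self.ref.sequence[6:]
        rep = screen(BarcodeRecord("q", seq), self.ref)
        assert rep.has_internal_stop and rep.verdict == "fail"
        assert rep.first_stop_codon == 2

    def test_terminal_stop_is_not_internal(self):
        seq = self.ref.sequence[:-3] + "TAA"
        rep = screen(BarcodeRecord("q", seq), self.ref)
        assert not rep.has_internal_stop

    def test_gap_mismatch_fails(self):
        seq = self.ref.sequence[:5] + "-" + self.ref.sequence[6:]
        rep = screen(BarcodeRecord("q", seq), self.ref)
        assert rep.has_indel and rep.verdict == "fail"

    def test_length_mod3_fails(self):
        rec = BarcodeRecord("q", "ATGGCCAT")
        ref = BarcodeRecord("r", "ATGGCCAT")
        rep = screen(rec, ref)
        assert rep.has_indel and rep.verdict == "fail"

    def test_codon_ratio_sums_to_mismatches(self, community_aln):
        ref = consensus_record(community_aln)
        rec = community_aln.records[-1]
        rep = screen(rec, ref)
        from barcodegap.distances import count_pair

        c = count_pair(rec, ref)
        assert sum(rep.codon_ratio) == c.n_ts + c.n_tv

    def test_anomalous_position_profile_is_suspect(self):
        # 25 mismatches spread 1:2:2 across codon positions vs the expected
        # 5:1:18 profile of functional COI
        rng = np.random.default_rng(1)
        n_codons = 100
        codons = ["ATT"] * n_codons
        ref = BarcodeRecord("ref", "".join(codons))
        arr = list(ref.sequence)
        hit = {0: 5, 1: 10, 2: 10}
        k = 0
        for pos_in_codon, n in hit.items():
            for _ in range(n):
                col = 3 * k + pos_in_codon
                cur = arr[col]
                arr[col] = {"A": "C", "T": "G", "C": "A", "G": "T"}[cur]
                k += 2
                if 3 * k >= len(arr):
                    k = 1
        seq = "".join(arr)
        if translate(seq).count("*"):  # keep the example stop-free
            seq = seq.replace("TAA", "TCA").replace("TAG", "TCG")
        rep = screen(BarcodeRecord("q", seq), ref)
        assert rep.verdict == "suspect"
        assert rep.suspect_p < 0.01

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            screen(BarcodeRecord("q", "ATG"), BarcodeRecord("r", "ATGGCC"))


class TestExactMultinomial:
    def test_perfect_fit_p_one(self):
        assert exact_multinomial_test([5, 1, 18], [5, 1, 18]) == pytest.approx(1.0, abs=0.1)

    def test_extreme_misfit_small_p(self):
        p = exact_multinomial_test([10, 10, 5], [5, 1, 18])
        assert p < 1e-6

    def test_zero_draws(self):
        assert exact_multinomial_test([0, 0, 0], [5, 1, 18]) == 1.0

    def test_matches_simulation(self):
        """Exact p agrees with a Monte-Carlo estimate of the same tail."""
        probs = np.array([0.2, 0.3, 0.5])
        obs = np.array([8, 2, 5])
        n = obs.sum()
        rng = np.random.default_rng(0)
        sims = rng.multinomial(n, probs, size=20000)
        from scipy.stats import multinomial

        p_obs = multinomial.pmf(obs, n, probs)
        sim_p = multinomial.pmf(sims, n, probs)
        mc = (sim_p <= p_obs + 1e-12).mean()
        exact = exact_multinomial_test(obs, probs)
        assert exact == pytest.approx(mc, abs=0.02)

    def test_large_n_falls_back_to_chisquare(self):
        p = exact_multinomial_test([150, 160, 300], [0.25, 0.25, 0.5])
        assert 0 < p < 1


class TestInsertionScan:
    def test_reports_one_based_column(self):
        ref_seq = "A" * 53 + "-" + "A" * 6
        rec_seq = "A" * 60
        hits = insertion_scan(BarcodeRecord("q", rec_seq), BarcodeRecord("r", ref_seq))
        assert hits == [54]

    def test_no_gaps_empty(self):
        hits = insertion_scan(BarcodeRecord("q", "ACGT"), BarcodeRecord("r", "ACGT"))
        assert hits == []

    def test_strip_insertions_restores_pass(self, community):
        """Deleting the reported insertion de-flags a synthetic frameshift numt."""
        aln, truth = community
        rng = np.random.default_rng(12)
        target = aln.seq_ids[5]
        aln2, truth2 = inject_numts(
            aln, truth, [(target, "insert", 54)], rng, background_d=0.0
        )
        ref = consensus_record(aln2)
        rec = aln2.get(target)
        assert insertion_scan(rec, ref) == [54]
        assert screen(rec, ref).verdict == "fail"
        fixed = strip_insertions(rec, ref)
        assert screen(fixed, ref).verdict in ("pass", "suspect")
        assert not screen(fixed, ref).has_indel


class TestScreenAlignment:
    def test_injected_numts_all_fail_clean_all_pass(self, community):
        aln, truth = community
        rng = np.random.default_rng(3)
        lesions = [
            (aln.seq_ids[0], "stop"),
            (aln.seq_ids[21], "insert"),
            (aln.seq_ids[42], "delete"),
        ]
        aln2, truth2 = inject_numts(aln, truth, lesions, rng)
        reports = screen_alignment(aln2)
        verdicts = {r.seq_id: r.verdict for r in reports}
        assert {sid for sid, v in verdicts.items() if v == "fail"} == truth2.numt_ids()

    def test_per_species_reference(self, community):
        aln, truth = community
        reports = screen_alignment(aln, grouping=truth.species)
        assert all(r.verdict != "fail" for r in reports)
        # conspecific mismatch counts are tiny
        assert np.median([sum(r.codon_ratio) for r in reports]) <= 4


class TestDivergenceTime:
    def test_zero_distance_zero_time(self):
        params = ClockParams(1e-9, 1e-9)
        assert divergence_time(0.0, params) == 0.0

    def test_linear_in_distance(self):
        params = ClockParams(1e-9, 1.5e-9)
        assert divergence_time(0.2, params) == pytest.approx(
            2 * divergence_time(0.1, params)
        )

    def test_back_solved_total_rate(self):
        """d = 10.93% at a 2.186e-10/site/yr total rate dates to 500 My."""
        params = ClockParams(1.093e-10, 1.093e-10)
        assert divergence_time(0.1093, params) == pytest.approx(5.0e8, rel=1e-6)

    def test_nan_propagates(self):
        params = ClockParams(1e-9, 1e-9)
        assert math.isnan(divergence_time(float("nan"), params))

    def test_rates_validated(self):
        with pytest.raises(ValueError):
            ClockParams(0.0, 1e-9)
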