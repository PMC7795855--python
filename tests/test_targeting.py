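"""Duplex alignment, cleavage scoring, target-mimic rules and scanning."""

import numpy as np
import pytest

from cernet.io_formats import reverse_complement
from cernet.targeting import (
    Bulge,
    DuplexAlignment,
    PairingRules,
    align_duplex,
    check_mimic,
    scan_transcript,
    score_cleavage,
)

MIRNA = "UGGAGAAGCAGGGCACGUGCA"  # 21 nt


# --- independent brute-force oracle -----------------------------------------

def oracle_state(m, t):
    if (m, t) in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}:
        return "WC"
    if (m, t) in {("G", "U"), ("U", "G")}:
        return "GU"
    return "MM"


def oracle_align(mirna, window, mode):
    """Exhaustive enumeration of admissible antiparallel pairings."""
    L, Lw = len(mirna), len(window)
    if mode == "cleavage":
        if Lw != L:
            return None
        states = [oracle_state(mirna[i], window[L - 1 - i]) for i in range(L)]
        return states, None, None
    k = Lw - L
    if k == 0:
        states = [oracle_state(mirna[i], window[L - 1 - i]) for i in range(L)]
        return states, None, None
    if not 1 <= k <= 4:
        return None
    best = None
    for j in (9, 10):  # middle insertion points for middle = (9, 11)
        # remove the k bulged target bases sitting opposite the j/j+1 boundary
        kept = window[: Lw - j - k] + window[Lw - j :]
        states = [oracle_state(mirna[i], kept[L - 1 - i]) for i in range(L)]
        pen = sum({"WC": 0.0, "GU": 0.5, "MM": 1.0}[s] for s in states)
        if best is None or pen < best[0]:
            best = (pen, j, states)
    return best[2], best[1], k


class TestAlignDuplex:
    def test_exact_complement_all_wc_score_zero(self):
        d = align_duplex(MIRNA, reverse_complement(MIRNA), "cleavage")
        assert set(d.pair_states) == {"WC"}
        assert d.score == 0.0

    def test_single_substitution_marks_position(self):
        w = list(reverse_complement(MIRNA))
        # target base paired to miRNA nt 3 sits at window index L-3
        w[len(MIRNA) - 3] = "A" if w[len(MIRNA) - 3] != "A" else "G"
        d = align_duplex(MIRNA, "".join(w), "cleavage")
        assert d.pair_states[2] != "WC"
        assert [s for i, s in enumerate(d.pair_states, 1) if i != 3] == ["WC"] * 20

    def test_mimic_bulge_between_10_and_11(self):
        w = reverse_complement(MIRNA[10:]) + "CUA" + reverse_complement(MIRNA[:10])
        d = align_duplex(MIRNA, w, "mimic")
        assert set(d.pair_states) == {"WC"}
        assert d.bulges == [Bulge(10, "target", 3)]

    def test_inadmissible_window_length_raises(self):
        with pytest.raises(ValueError, match="admissible"):
            align_duplex(MIRNA, "ACGU" * 10, "cleavage")

    def test_non_rna_alphabet_rejected(self):
        with pytest.raises(ValueError):
            align_duplex("UGGAXGAAG" + "U" * 12, "A" * 21, "cleavage")

    def test_matches_bruteforce_enumeration(self, rng):
        """Oracle equivalence on 100 random miRNA/window pairs."""
        pen = {"WC": 0.0, "GU": 0.5, "MM": 1.0}
        for _ in range(100):
            L = int(rng.integers(18, 26))
            mirna = "".join(rng.choice(list("ACGU"), size=L))
            k = int(rng.integers(0, 5))
            window = "".join(rng.choice(list("ACGU"), size=L + k))
            mode = "cleavage" if k == 0 and rng.random() < 0.5 else "mimic"
            got = align_duplex(mirna, window, mode)
            want = oracle_align(mirna, window, mode)
            assert got is not None and want is not None
            states, j, length = want
            # penalties must agree exactly; states may differ only on ties
            assert sum(pen[s] for s in got.pair_states) == pytest.approx(
                sum(pen[s] for s in states)
            )
            if mode == "mimic" and k > 0:
                assert got.bulges[0].side == "target"
                assert got.bulges[0].length == length
                assert got.bulges[0].after == j


class TestScoreCleavage:
    def duplex(self, states):
        return DuplexAlignment("m", "t", (1, len(states)), list(states), [], "cleavage")

    def test_perfect_complement_accepted_at_zero(self):
        assert score_cleavage(self.duplex(["WC"] * 21)) == (0.0, True)

    def test_core_mismatch_costs_double(self):
        states = ["WC"] * 21
        states[4] = "MM"  # position 5, inside the doubled 2-13 core
        score, accept = score_cleavage(self.duplex(states))
        assert (score, accept) == (2.0, True)

    def test_scissile_site_mismatch_rejected_regardless_of_score(self):
        states = ["WC"] * 21
        states[9] = "MM"  # position 10
        _, accept = score_cleavage(self.duplex(states))
        assert not accept

    def test_score_exceeding_cutoff_rejected(self):
        states = ["WC"] * 21
        for i in (1, 2, 3):  # three core MMs -> score 6
            states[i] = "MM"
        score, accept = score_cleavage(self.duplex(states))
        assert score == 6.0 and not accept

    def test_monotone_in_added_mismatches(self, rng):
        for _ in range(50):
            states = list(rng.choice(["WC", "GU", "MM"], size=21))
            base, _ = score_cleavage(self.duplex(states))
            wc_positions = [i for i, s in enumerate(states) if s == "WC"]
            if not wc_positions:
                continue
            states[int(rng.choice(wc_positions))] = "MM"
            worse, _ = score_cleavage(self.duplex(states))
            assert worse >= base

    def test_mimic_mode_input_is_error(self):
        d = DuplexAlignment("m", "t", (1, 21), ["WC"] * 21, [], "mimic")
        with pytest.raises(ValueError, match="cleavage"):
            score_cleavage(d)


class TestCheckMimic:
    def duplex(self, states, bulges):
        return DuplexAlignment("m", "t", (1, 24), list(states), bulges, "mimic")

    def test_middle_bulge_no_mismatch_accepted(self):
        ok, reasons = check_mimic(self.duplex(["WC"] * 21, [Bulge(10, "target", 3)]))
        assert ok and reasons == []

    def test_five_mismatches_outside_middle_rejected(self):
        states = ["WC"] * 21
        for i in (0, 2, 4, 6, 13):
            states[i] = "MM"
        ok, reasons = check_mimic(self.duplex(states, [Bulge(10, "target", 3)]))
        assert not ok and any(r.startswith("II") for r in reasons)

    def test_three_consecutive_mismatches_rejected(self):
        states = ["WC"] * 21
        for i in (3, 4, 5):  # positions 4-6
            states[i] = "MM"
        ok, reasons = check_mimic(self.duplex(states, [Bulge(10, "target", 3)]))
        assert not ok and any("consecutive" in r for r in reasons)

    def test_gu_neither_counts_as_run_nor_extends_one(self):
        states = ["WC"] * 21
        states[3], states[4], states[5] = "MM", "GU", "MM"
        ok, _ = check_mimic(self.duplex(states, [Bulge(10, "target", 3)]))
        assert ok

    def test_missing_or_misplaced_bulge_rejected(self):
        ok, reasons = check_mimic(self.duplex(["WC"] * 21, []))
        assert not ok and any(r.startswith("I") for r in reasons)
        ok, reasons = check_mimic(self.duplex(["WC"] * 21, [Bulge(4, "target", 2)]))
        assert not ok
        ok, reasons = check_mimic(
            self.duplex(["WC"] * 21, [Bulge(10, "target", 3), Bulge(2, "target", 1)])
        )
        assert not ok and any(r.startswith("III") for r in reasons)

    def test_cleavage_mode_input_is_error(self):
        d = DuplexAlignment("m", "t", (1, 21), ["WC"] * 21, [], "cleavage")
        with pytest.raises(ValueError, match="mimic"):
            check_mimic(d)

    def test_invariant_under_wc_preserving_substitution(self):
        """Acceptance depends on pair states, not which WC pair realizes them."""
        states = ["WC"] * 21
        states[2] = "MM"
        d1 = self.duplex(states, [Bulge(9, "target", 2)])
        d2 = self.duplex(list(states), [Bulge(9, "target", 2)])
        assert check_mimic(d1)[0] == check_mimic(d2)[0]


class TestScanTranscript:
    def test_planted_perfect_site_found_once(self, rng):
        t = "".join(rng.choice(list("ACGU"), size=400))
        site = reverse_complement(MIRNA)
        t = t[:100] + site + t[100 + len(site):]
        hits = scan_transcript(MIRNA, t, "cleavage")
        assert len(hits) == 1
        assert hits[0].cleavage_position == 101 + 21 - 10

    def test_circular_site_across_junction_found(self, rng):
        site = reverse_complement(MIRNA)
        t = site[10:] + "".join(rng.choice(list("ACGU"), size=150)) + site[:10]
        assert scan_transcript(MIRNA, t, "cleavage") == []
        hits = scan_transcript(MIRNA, t, "cleavage", circular=True)
        assert len(hits) == 1

    def test_planted_mimic_found_by_scan(self, rng):
        w = reverse_complement(MIRNA[10:]) + "GU" + reverse_complement(MIRNA[:10])
        t = "".join(rng.choice(list("ACGU"), size=120)) + w + "ACGUACGU"
        hits = scan_transcript(MIRNA, t, "mimic")
        assert any(h.duplex.target_window == (121, 121 + len(w) - 1) for h in hits)

    def test_random_false_positive_rate_is_tiny(self, rng):
        """Monte-Carlo calibration: random 2-kb transcripts vs random 21-mers."""
        total = 0
        for _ in range(60):
            t = "".join(rng.choice(list("ACGU"), size=2000))
            m = "U" + "".join(rng.choice(list("ACGU"), size=20))
            total += len(scan_transcript(m, t, "cleavage"))
        assert total / 60 < 0.05

    def test_scan_agrees_with_align_duplex_per_window(self, rng):
        t = "".join(rng.choice(list("ACGU"), size=300))
        site = reverse_complement(MIRNA)
        t = t[:50] + site + t[50 + len(site):]
        for hit in scan_transcript(MIRNA, t, "cleavage"):
            s, e = hit.duplex.target_window
            d = align_duplex(MIRNA, t[s - 1 : e], "cleavage")
            assert d.pair_states == hit.duplex.pair_states
            assert d.score == hit.duplex.score
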