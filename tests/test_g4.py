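import itertools
from collections import Counter

import pytest
from hypothesis import given
from hypothesis import strategies as st

from selexg4.aptamers import (
    G2_CONSENSUS,
    G4_APTAMERS,
    MUTRF001,
    RF001,
    SCR50,
)
from selexg4.g4 import (
    count_g_doublets,
    enumerate_gqs,
    g_score,
    match_g2_consensus,
    max_g_score,
)

g_rich = st.text(alphabet=["G", "G", "A", "C", "T"], min_size=0, max_size=50)


def linear_scan_doublets(seq):
    """Independent oracle: scan for maximal runs of >= 2 G."""
    seq = seq.upper().replace("U", "T")
    n, i, runs = len(seq), 0, 0
    while i < n:
        if seq[i] == "G":
            j = i
            while j < n and seq[j] == "G":
                j += 1
            if j - i >= 2:
                runs += 1
            i = j
        else:
            i += 1
    return runs


class TestGDoublets:
    def test_consensus_has_eight(self):
        assert count_g_doublets(G2_CONSENSUS) == 8

    def test_alternating_has_none(self):
        assert count_g_doublets("GAGAGA") == 0

    def test_rf001_matches_linear_scan_oracle(self):
        assert count_g_doublets(RF001) == linear_scan_doublets(RF001) == 10

    @given(st.integers(1, 30))
    def test_single_run_counts_once(self, n):
        assert count_g_doublets("G" * n) == (1 if n >= 2 else 0)

    @given(g_rich)
    def test_agrees_with_oracle(self, seq):
        assert count_g_doublets(seq) == linear_scan_doublets(seq)


class TestEnumerate:
    def test_aptamer_dichotomy(self):
        for name, seq in G4_APTAMERS.items():
            assert enumerate_gqs(seq), f"{name} should form a candidate"
        assert enumerate_gqs(SCR50) == []
        assert enumerate_gqs(MUTRF001) == []

    def test_minimal_construction(self):
        cands = enumerate_gqs("GGAGGAGGAGG")
        assert any(c.loops == (1, 1, 1) and c.tetrads == 2 for c in cands)

    def test_candidates_respect_max_len(self):
        for c in enumerate_gqs(RF001, max_len=30):
            assert c.total_len <= 30

    def test_max_len_too_small_errors(self):
        with pytest.raises(ValueError):
            enumerate_gqs("GGGG", max_len=10, min_run=2)

    @given(g_rich)
    def test_u_t_invariance(self, seq):
        assert enumerate_gqs(seq) == enumerate_gqs(seq.replace("T", "U"))


class TestGScore:
    def test_consensus_anchor_is_21(self):
        assert max_g_score(G2_CONSENSUS) == 21

    def test_more_tetrads_score_strictly_higher(self):
        assert g_score(3, (1, 1, 1)) > g_score(2, (1, 1, 1))

    def test_even_loops_score_at_least_as_high(self):
        assert g_score(2, (1, 1, 1)) >= g_score(2, (3, 0, 0))

    @given(st.tuples(st.integers(0, 7), st.integers(0, 7), st.integers(0, 7)))
    def test_non_increasing_in_total_loop(self, loops):
        longer = (loops[0] + 1, loops[1] + 1, loops[2] + 1)  # evenness preserved
        assert g_score(2, longer) <= g_score(2, loops)


class TestMaxGScore:
    def test_mutant_and_control_have_no_score(self):
        assert max_g_score(MUTRF001) is None
        assert max_g_score("AAAA") is None

    def test_every_g2_rich_aptamer_scores(self):
        for seq in G4_APTAMERS.values():
            assert max_g_score(seq) is not None


def consensus_oracle(seq):
    """Naive backtracking oracle: try every spacer-length combination."""
    seq = seq.upper().replace("U", "T")
    spacer_ranges = [(1, 4), (1, 3), (1, 3), (1, 2), (0, 1), (1, 3), (0, 2)]
    anchors = [None, None, None, "A", "AT", None, "A"]  # prefix before free spacer
    spans = []
    combos = list(itertools.product(*[range(lo, hi + 1) for lo, hi in spacer_ranges]))
    for start in range(len(seq)):
        if seq[start : start + 2] != "GG":
            continue
        best = None
        for lens in combos:
            pos = start
            ok = True
            for block in range(8):
                if seq[pos : pos + 2] != "GG":
                    ok = False
                    break
                pos += 2
                if block == 7:
                    break
                anchor = anchors[block]
                if anchor == "A":
                    if seq[pos : pos + 1] != "A":
                        ok = False
                        break
                    pos += 1
                elif anchor == "AT":
                    # fixed A, then 0-1 T taken from the spacer budget
                    if seq[pos : pos + 1] != "A":
                        ok = False
                        break
                    pos += 1
                    if lens[block] and seq[pos : pos + 1] != "T":
                        ok = False
                        break
                    pos += lens[block]
                    continue
                if pos + lens[block] > len(seq):
                    ok = False
                    break
                pos += lens[block]
            if ok and (best is None or pos > best):
                best = pos
        if best is not None:
            spans.append((start, best))
    return spans


class TestConsensusMatcher:
    def test_pattern_instance_matches_full_span(self):
        instance = G2_CONSENSUS.replace("N", "U")
        assert match_g2_consensus(instance) == [(0, len(instance))]

    def test_poly_a_has_no_match(self):
        assert match_g2_consensus("A" * 50) == []

    def test_rf001_contains_the_consensus(self):
        assert match_g2_consensus(RF001)

    def random_instance(self, rng):
        """A random realization of the pattern: random spacer lengths/bases."""
        spacer_ranges = [(1, 4), (1, 3), (1, 3), (1, 2), (0, 1), (1, 3), (0, 2)]
        anchors = [None, None, None, "A", "AT", None, "A"]
        parts = []
        for (lo, hi), anchor in zip(spacer_ranges, anchors):
            parts.append("GG")
            n = int(rng.integers(lo, hi + 1))
            if anchor == "A":
                parts.append("A")
            elif anchor == "AT":
                parts.append("A" + "T" * n)
                continue
            parts.append("".join("ACGT"[b] for b in rng.integers(0, 4, n)))
        parts.append("GG")
        return "".join(parts)

    def test_agrees_with_backtracking_oracle(self, rng):
        # mutated pattern instances embedded in random context, so the
        # comparison sees real matches, near-misses and non-matches
        hits = 0
        for _ in range(40):
            inst = list(self.random_instance(rng))
            for _ in range(rng.integers(0, 3)):  # up to 2 point mutations
                inst[rng.integers(0, len(inst))] = "ACGT"[rng.integers(0, 4)]
            pad = "".join("ACGT"[b] for b in rng.integers(0, 4, 6))
            seq = pad + "".join(inst) + pad
            got = match_g2_consensus(seq)
            assert got == consensus_oracle(seq)
            hits += bool(got)
        assert hits > 0  # the comparison exercised real matches


def test_rf001_and_mutant_share_base_composition():
    assert Counter(RF001) == Counter(MUTRF001)
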