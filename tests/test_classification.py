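"""Alignment, event classification, and spectrum summaries.

The exhaustive window test enumerates every 4-nt substitution window and
every single-nucleotide deletion and checks the classifier against a
direct rule-table oracle: positions where the window differs from the
accurate window are either lesion-opposite (middle two) or flanking
(outer two); opposite-only is targeted, flank-only semi-targeted, both
mixed.
"""

import random
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tlskit.classification import (
    DELETION_MARK,
    Category,
    align_read,
    classify_event,
    classify_read,
    summarize_spectrum,
)
from tlskit.constructs import CloneRead


def _rule_table_oracle(window: str, accurate: str) -> Category:
    """Direct category lookup for a substituted/deleted 4-nt window.

    ``window`` uses "-" for a deleted position; everything outside the
    window is assumed accurate.
    """
    diffs = set()
    for i in range(4):
        if window[i] == "-" or window[i] != accurate[i]:
            diffs.add(i)
    if not diffs:
        return Category.ACCURATE
    opp, flank = diffs & {1, 2}, diffs & {0, 3}
    if opp and flank:
        return Category.MIXED
    return Category.TARGETED if opp else Category.SEMI_TARGETED


def test_identity_read_has_no_edits(tt_cpd, aligner):
    read = CloneRead("c", "x", "r", tt_cpd.reference)
    aln = align_read(read, tt_cpd, aligner)
    assert aln.edits == []
    assert aln.anchor_identity == 1.0
    assert classify_event(aln, tt_cpd).category is Category.ACCURATE


def test_single_substitution_yields_one_sub_edit(tt_cpd, aligner):
    ws = tt_cpd.window_start
    seq = list(tt_cpd.reference)
    seq[ws + 1] = "G"  # A->G at the first lesion-opposite position
    aln = align_read(CloneRead("c", "x", "r", "".join(seq)), tt_cpd, aligner)
    assert len(aln.edits) == 1
    (edit,) = aln.edits
    assert (edit.ref_pos, edit.kind, edit.ref, edit.alt) == (ws + 1, "SUB", "A", "G")


def test_random_reads_are_unscorable(tt_cpd, aligner):
    rng = random.Random(42)
    for _ in range(50):
        seq = "".join(rng.choice("ACGT") for _ in range(100))
        ev = classify_read(CloneRead("c", "x", "r", seq), tt_cpd, aligner)
        assert ev.category is Category.UNSCORABLE
        assert ev.anchor_identity < 0.8


def test_random_dna_anchor_identity_near_quarter(tt_cpd):
    # expected per-position identity of random DNA against an anchor is 1/4
    rng = random.Random(7)
    anchors = tt_cpd.anchor5 + tt_cpd.anchor3
    idents = []
    for _ in range(2000):
        probe = "".join(rng.choice("ACGT") for _ in range(len(anchors)))
        idents.append(sum(a == b for a, b in zip(anchors, probe)) / len(anchors))
    mean = np.mean(idents)
    se = np.std(idents, ddof=1) / np.sqrt(len(idents))
    assert abs(mean - 0.25) < 4 * se + 1e-9


@pytest.mark.parametrize("construct_id", ["TT_CPD", "TT_64PP", "CISPT_GG"])
def test_exhaustive_windows_match_rule_table(
    constructs, aligner, read_with_window, construct_id
):
    """All 256 substitution windows plus 4 single-nt deletions."""
    c = constructs[construct_id]
    windows = ["".join(w) for w in __import__("itertools").product("ACGT", repeat=4)]
    windows += [
        c.accurate_window[:i] + "-" + c.accurate_window[i + 1 :] for i in range(4)
    ]
    for w in windows:
        ev = classify_read(read_with_window(construct_id, w), c, aligner)
        expected = _rule_table_oracle(w, c.accurate_window)
        assert ev.category is expected, f"window {w!r}: {ev.category} != {expected}"
        assert ev.is_tls


def test_deleted_opposite_base_reported_with_delta(tt_cpd, aligner, read_with_window):
    ev = classify_read(read_with_window("TT_CPD", "CA-C"), tt_cpd, aligner)
    assert ev.category is Category.TARGETED
    assert ev.is_tls
    assert DELETION_MARK in ev.observed_window


def test_large_deletion_spanning_window_is_non_tls(tt_cpd, aligner):
    ws = tt_cpd.window_start
    seq = tt_cpd.reference[: ws - 15] + tt_cpd.reference[ws + 15 :]  # 30-nt deletion
    ev = classify_read(CloneRead("c", "x", "r", seq), tt_cpd, aligner)
    assert ev.category is Category.NON_TLS
    assert not ev.is_tls


def test_insertion_is_non_tls(tt_cpd, aligner):
    ws = tt_cpd.window_start
    seq = tt_cpd.reference[:ws] + "GTGTGT" + tt_cpd.reference[ws:]
    ev = classify_read(CloneRead("c", "x", "r", seq), tt_cpd, aligner)
    assert ev.category is Category.NON_TLS


def test_single_deletion_outside_window_is_non_tls(tt_cpd, aligner):
    pos = tt_cpd.window_start - 40
    seq = tt_cpd.reference[:pos] + tt_cpd.reference[pos + 1 :]
    ev = classify_read(CloneRead("c", "x", "r", seq), tt_cpd, aligner)
    assert ev.category is Category.NON_TLS


def test_n_in_window_is_unscorable_but_elsewhere_tolerated(tt_cpd, aligner):
    ws = tt_cpd.window_start
    seq = list(tt_cpd.reference)
    seq[ws + 1] = "N"
    ev = classify_read(CloneRead("c", "x", "r", "".join(seq)), tt_cpd, aligner)
    assert ev.category is Category.UNSCORABLE

    seq = list(tt_cpd.reference)
    seq[5] = "N"
    ev = classify_read(CloneRead("c", "x", "r", "".join(seq)), tt_cpd, aligner)
    assert ev.category is Category.ACCURATE


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    pad5=st.text(alphabet="ACGT", min_size=10, max_size=40),
    pad3=st.text(alphabet="ACGT", min_size=10, max_size=40),
    window=st.text(alphabet="ACGT", min_size=4, max_size=4),
)
def test_padding_invariance(constructs, aligner, pad5, pad3, window):
    """Vector sequence beyond the construct changes no classification."""
    c = constructs["TT_64PP"]
    ws = c.window_start
    core = c.reference[:ws] + window + c.reference[ws + 4 :]
    bare = classify_read(CloneRead("c", "x", "r", core), c, aligner)
    padded = classify_read(CloneRead("c", "x", "r", pad5 + core + pad3), c, aligner)
    assert padded.category is bare.category
    assert padded.observed_window == bare.observed_window


def test_homopolymer_deletion_left_aligned(tt_cpd, aligner):
    """Deleting either A of the CAAC run gives one stable placement."""
    ws = tt_cpd.window_start
    del_first = tt_cpd.reference[: ws + 1] + tt_cpd.reference[ws + 2 :]
    del_second = tt_cpd.reference[: ws + 2] + tt_cpd.reference[ws + 3 :]
    assert del_first == del_second  # same molecule
    ev1 = classify_read(CloneRead("a", "x", "r", del_first), tt_cpd, aligner)
    ev2 = classify_read(CloneRead("b", "x", "r", del_second), tt_cpd, aligner)
    assert ev1.category is ev2.category is Category.TARGETED
    assert ev1.observed_window == ev2.observed_window == "C" + DELETION_MARK + "AC"


def test_determinism(tt_cpd, aligner, read_with_window):
    read = read_with_window("TT_CPD", "TAGC")
    first = classify_read(read, tt_cpd, aligner)
    for _ in range(3):
        assert classify_read(read, tt_cpd, aligner) == first


# -- spectrum summaries --------------------------------------------------


def _event(category, window="CAAC", clone="c", rep="rep1"):
    from tlskit.classification import EventClassification

    return EventClassification(
        clone_id=clone,
        category=category,
        is_tls=category.is_tls,
        observed_window=window,
        edit_summary="",
        anchor_identity=1.0,
        condition_id="cond",
        replicate_id=rep,
    )


def test_spectrum_fraction_and_mutagenic_pct():
    events = (
        [_event(Category.ACCURATE)] * 98
        + [_event(Category.TARGETED, "CAGC")] * 2
        + [_event(Category.NON_TLS, "????")] * 5
    )
    s = summarize_spectrum(events)
    assert s.fraction_tls == pytest.approx(100 / 105)
    assert s.mutagenic_pct == pytest.approx(2.0)
    assert sum(s.category_counts.values()) == len(events)


def test_all_accurate_gives_zero_mutagenic():
    s = summarize_spectrum([_event(Category.ACCURATE)] * 10)
    assert s.mutagenic_pct == 0.0
    assert s.fraction_tls == 1.0


def test_zero_tls_flagged_undefined():
    s = summarize_spectrum([_event(Category.NON_TLS)] * 4)
    assert s.undefined
    assert s.mutagenic_pct is None and s.tls_category_pct is None


def test_spectrum_matches_brute_force_recount():
    rng = np.random.default_rng(123)
    cats = [Category.ACCURATE, Category.TARGETED, Category.SEMI_TARGETED,
            Category.MIXED, Category.NON_TLS, Category.UNSCORABLE]
    draw = rng.multinomial(500, [0.5, 0.15, 0.1, 0.05, 0.15, 0.05])
    events = [e for cat, k in zip(cats, draw) for e in [_event(cat)] * int(k)]
    s = summarize_spectrum(events)
    # independent tally
    tally = Counter(e.category for e in events)
    n_tls = sum(v for c, v in tally.items() if c.is_tls)
    assert s.n_scored == len(events) - tally[Category.UNSCORABLE]
    assert s.fraction_tls == pytest.approx(n_tls / s.n_scored)
    assert s.mutagenic_pct == pytest.approx(
        100 * (n_tls - tally[Category.ACCURATE]) / n_tls
    )
    for cat in ("ACCURATE", "TARGETED", "SEMI_TARGETED", "MIXED"):
        assert s.tls_category_pct[cat] == pytest.approx(
            100 * tally[Category(cat)] / n_tls
        )
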