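"""Grammar structure, sampling constraints and melody invariants."""

import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melgram.grammar import (
    DEGREES,
    RESERVED_PAIRS,
    DeadEndError,
    apply_accent,
    classify_contour,
    default_grammar,
    generate_exposure_melody,
    generate_test_melody,
    grammar_from_json,
    grammar_to_json,
    make_agrammatical_variant,
    matched_test_variant,
    sample_cell,
    validate_grammar,
    validate_melody,
)


# ---------------------------------------------------------------------------
# validation

def test_default_grammar_self_validates(spec):
    assert validate_grammar(spec) == []


def test_reserved_pair_outside_ic_cell_is_reported(spec):
    bad_row = {6: 0.5, 4: 0.5}  # 5->4 is reserved outside IC cells (and 5->6 too)
    start = spec.cells["start"]
    tables = dict(start.transition_table)
    tables[5] = bad_row
    cells = dict(spec.cells)
    cells["start"] = dataclasses.replace(start, transition_table=tables)
    bad = dataclasses.replace(spec, cells=cells)
    report = validate_grammar(bad)
    assert any("reserved pair" in v for v in report)


def test_non_stochastic_row_is_reported(spec):
    start = spec.cells["start"]
    tables = dict(start.transition_table)
    tables[1] = {2: 0.5, 5: 0.4}  # sums to 0.9
    cells = dict(spec.cells)
    cells["start"] = dataclasses.replace(start, transition_table=tables)
    report = validate_grammar(dataclasses.replace(spec, cells=cells))
    assert any("not stochastic" in v for v in report)


def test_malformed_probabilities_are_violations_not_exceptions(spec):
    start = spec.cells["start"]
    tables = dict(start.transition_table)
    tables[1] = {2: -0.5, 5: 1.5}
    cells = dict(spec.cells)
    cells["start"] = dataclasses.replace(start, transition_table=tables)
    report = validate_grammar(dataclasses.replace(spec, cells=cells))
    assert any("malformed probability" in v for v in report)


def test_grammar_json_round_trip(spec):
    again = grammar_from_json(grammar_to_json(spec))
    assert again == spec


# ---------------------------------------------------------------------------
# cell sampling

def test_ic_cells_return_printed_context_target_pairs(spec, rng):
    assert sample_cell(spec.cells["ic_beta"], None, rng, forced_branch="low") == [5, 4]
    assert sample_cell(spec.cells["ic_beta"], None, rng, forced_branch="high") == [5, 6]
    assert sample_cell(spec.cells["ic_alpha"], None, rng, forced_branch="low") == [3, 4]
    assert sample_cell(spec.cells["ic_alpha"], None, rng, forced_branch="high") == [3, 2]


@pytest.mark.parametrize("cell_name", ["ic_alpha", "ic_beta"])
def test_ic_branch_rate_matches_binomial(spec, cell_name):
    """The 0.95 branch is taken at its nominal rate (within 3 binomial SE)."""
    rng = np.random.default_rng(99)
    cell = spec.cells[cell_name]
    n = 10_000
    hits = sum(
        sample_cell(cell, None, rng)[1] == cell.ic_params.high_prob_target
        for _ in range(n)
    )
    p = cell.ic_params.p_high
    se = np.sqrt(p * (1 - p) / n)
    assert abs(hits / n - p) < 3 * se


def test_entry_degree_restricts_initial_distribution(spec, rng):
    # after degree 3, the IC-alpha context 3 would be a repeat: dead end
    with pytest.raises(DeadEndError):
        sample_cell(spec.cells["ic_alpha"], 3, rng)


def test_cell_length_within_declared_range(spec, rng):
    for _ in range(200):
        seq = sample_cell(spec.cells["intermediate"], None, rng)
        lo, hi = spec.cells["intermediate"].length_range
        assert lo <= len(seq) <= hi


# ---------------------------------------------------------------------------
# exposure melodies

def test_exposure_melody_passes_all_invariants(spec, rng):
    rec = generate_exposure_melody(spec, rng)
    assert validate_melody(rec, spec) == []
    assert len(rec.targets) == 2


def test_exposure_corpus_constraint_suite(spec, exposure_corpus):
    """Degree range, no repeats, max step, reserved pairs, lengths: 100%."""
    for rec in exposure_corpus:
        assert validate_melody(rec, spec) == [], rec
    lengths = [len(m) for m in exposure_corpus]
    assert min(lengths) >= 9 and max(lengths) <= 14


def test_both_module_orders_occur_evenly(exposure_corpus):
    first_ic = [next(name for name, a, b in m.cell_spans if name.startswith("ic"))
                for m in exposure_corpus]
    frac_alpha = np.mean([f == "ic_alpha" for f in first_ic])
    se = np.sqrt(0.25 / len(exposure_corpus))
    assert abs(frac_alpha - 0.5) < 4 * se


def test_target_annotations_follow_their_context(exposure_corpus):
    for m in exposure_corpus[:500]:
        for t in m.targets:
            assert m.degrees[t.position - 1] == t.context_degree
            assert abs(m.degrees[t.position] - t.context_degree) == 1


# ---------------------------------------------------------------------------
# forced-choice melodies

def test_test_melody_has_requested_single_target(spec):
    rng = np.random.default_rng(7)
    rec = generate_test_melody(spec, "high", rng)
    assert len(rec.targets) == 1
    assert rec.targets[0].ic_condition == "high"


def test_test_corpus_constraint_suite(spec, test_corpus):
    for rec in test_corpus:
        assert validate_melody(rec, spec) == [], rec
    lengths = [len(m) for m in test_corpus]
    assert min(lengths) >= 7 and max(lengths) <= 9


def test_target_sits_in_middle_third(test_corpus):
    for rec in test_corpus:
        n = len(rec.degrees)
        pos = rec.targets[0].position
        assert n / 3 <= pos <= 2 * n / 3


@pytest.mark.parametrize("seed", range(20))
def test_matched_pair_differs_at_exactly_one_position(spec, seed):
    rng = np.random.default_rng(seed)
    high = generate_test_melody(spec, "high", rng)
    low = matched_test_variant(high, spec)
    diffs = [i for i, (a, b) in enumerate(zip(high.degrees, low.degrees)) if a != b]
    assert diffs == [high.targets[0].position]
    assert low.targets[0].ic_condition == "low"
    assert validate_melody(low, spec) == []
    # flipping twice restores the original
    assert matched_test_variant(low, spec) == high


# ---------------------------------------------------------------------------
# contour classification

def _contour_oracle(prev, target, nxt):
    above = [prev > target, nxt > target]
    if above == [False, False]:
        return "peak"
    if above == [True, True]:
        return "valley"
    return "ascending" if nxt > target else "descending"


def test_contour_examples():
    assert classify_contour(5, 6, 5) == "peak"
    assert classify_contour(5, 4, 5) == "valley"
    assert classify_contour(3, 4, 6) == "ascending"
    assert classify_contour(7, 6, 2) == "descending"


def test_contour_classifier_equals_oracle_on_all_legal_triples():
    for prev, target, nxt in itertools.product(DEGREES, repeat=3):
        if prev == target or nxt == target:
            with pytest.raises(ValueError):
                classify_contour(prev, target, nxt)
        else:
            assert classify_contour(prev, target, nxt) == _contour_oracle(prev, target, nxt)


@given(st.integers(1, 7), st.integers(1, 7), st.integers(1, 7))
@settings(max_examples=200, derandomize=True)
def test_contour_symmetric_under_pitch_reflection(prev, target, nxt):
    """Reflecting pitches maps peak<->valley and ascending<->descending."""
    if prev == target or nxt == target:
        return
    swap = {"peak": "valley", "valley": "peak",
            "ascending": "descending", "descending": "ascending"}
    direct = classify_contour(prev, target, nxt)
    reflected = classify_contour(8 - prev, 8 - target, 8 - nxt)
    assert reflected == swap[direct]


# ---------------------------------------------------------------------------
# accenting and agrammatical variants

def test_accent_is_an_involution(spec, rng):
    rec = generate_test_melody(spec, "low", rng)
    pos = rec.targets[0].position
    accented = apply_accent(rec, pos)
    assert accented.degrees == rec.degrees
    assert accented.targets[0].accented
    assert apply_accent(accented, pos, accented=False) == rec


def test_accent_at_non_target_index_raises(spec, rng):
    rec = generate_test_melody(spec, "low", rng)
    with pytest.raises(ValueError):
        apply_accent(rec, 0)


def test_agrammatical_variant_keeps_degrees(spec, rng):
    rec = generate_exposure_melody(spec, rng)
    ag = make_agrammatical_variant(rec)
    assert ag.degrees == rec.degrees
    assert ag.variant == "agrammatical"
    with pytest.raises(ValueError):
        make_agrammatical_variant(ag)
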