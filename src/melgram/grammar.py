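"""First-order Markov grammar for artificial melodies with controlled surprisal.

Melodies are built from a sequence of short "cells", each a first-order
Markov chain over scale degrees 1-7 (degree 7 is degree 1 one octave up).
Two special two-note *IC cells* embed a context note followed by one of two
target notes: one target occurs with high probability (low information
content, IC) and the other with low probability (high IC).  Filler cells
(start, intermediate, end) pad the melody while never producing the four
reserved context->target pairs, so the corpus-level conditional probability
of each target -- and hence its surprisal, ``-log2 p(target | context)`` --
is controlled by the grammar alone.

Global melodic constraints (enforced everywhere, including across cell
boundaries):

* no immediate repeats (``x -> x`` is forbidden);
* steps never exceed four scale degrees;
* the reserved pairs 5->4, 5->6, 3->4 and 3->2 occur only inside IC cells.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "DEGREES",
    "RESERVED_PAIRS",
    "ICParams",
    "CellSpec",
    "GrammarSpec",
    "TargetAnnotation",
    "MelodyRecord",
    "DeadEndError",
    "GenerationError",
    "default_grammar",
    "validate_grammar",
    "validate_melody",
    "sample_cell",
    "generate_exposure_melody",
    "generate_test_melody",
    "generate_corpus",
    "matched_test_variant",
    "classify_contour",
    "apply_accent",
    "make_agrammatical_variant",
    "grammar_to_json",
    "grammar_from_json",
]

DEGREES = tuple(range(1, 8))

#: context -> target pairs that may only occur inside IC cells
RESERVED_PAIRS = frozenset({(5, 4), (5, 6), (3, 4), (3, 2)})

Contour = Literal["peak", "valley", "ascending", "descending"]


class DeadEndError(RuntimeError):
    """Raised when a cell has no legal continuation given its entry degree."""

    def __init__(self, degree: int, cell: str):
        self.degree = degree
        self.cell = cell
        super().__init__(f"no legal continuation from degree {degree} into cell {cell!r}")


class GenerationError(RuntimeError):
    """Raised when repeated resampling fails to produce a legal melody."""


@dataclass(frozen=True)
class ICParams:
    """Branch parameters of an IC cell.

    The high-probability target is the *low*-IC outcome; the low-probability
    target is the *high*-IC outcome.
    """

    context_degree: int
    high_prob_target: int
    low_prob_target: int
    p_high: float = 0.95


@dataclass(frozen=True)
class CellSpec:
    name: str
    length_range: tuple[int, int]
    initial_distribution: dict[int, float]
    transition_table: dict[int, dict[int, float]]
    ic_params: ICParams | None = None

    @property
    def is_ic(self) -> bool:
        return self.ic_params is not None


@dataclass(frozen=True)
class GrammarSpec:
    """The full melody grammar: five cells plus global constraints.

    ``module_orders`` lists the two admissible exposure cell orderings; the
    forced-choice (test) variant drops the intermediate cell and one IC cell
    and uses the shorter ``fc_*`` length ranges for its filler cells.
    """

    cells: dict[str, CellSpec]
    module_orders: tuple[tuple[str, ...], tuple[str, ...]] = (
        ("start", "ic_alpha", "intermediate", "ic_beta", "end"),
        ("start", "ic_beta", "intermediate", "ic_alpha", "end"),
    )
    max_step: int = 4
    exposure_length: tuple[int, int] = (9, 14)
    fc_length: tuple[int, int] = (7, 9)
    fc_start_length: tuple[int, int] = (2, 3)
    fc_end_length: tuple[int, int] = (3, 4)
    max_retries: int = 100

    @property
    def reserved_pairs(self) -> frozenset[tuple[int, int]]:
        return RESERVED_PAIRS


@dataclass(frozen=True)
class TargetAnnotation:
    position: int  # 0-based index into degrees
    ic_condition: Literal["high", "low"]
    context_degree: int
    contour: Contour
    accented: bool = False


@dataclass(frozen=True)
class MelodyRecord:
    degrees: tuple[int, ...]
    cell_spans: tuple[tuple[str, int, int], ...]  # (cell name, start, end) inclusive
    targets: tuple[TargetAnnotation, ...]
    phase: Literal["exposure", "attention_long", "test"] = "exposure"
    variant: Literal["grammatical", "agrammatical"] = "grammatical"
    seed_tag: str = ""

    def __len__(self) -> int:
        return len(self.degrees)


# ---------------------------------------------------------------------------
# legality helpers

def legal_pair(a: int, b: int, *, max_step: int = 4, allow_reserved: bool = False) -> bool:
    """Whether degree ``b`` may immediately follow degree ``a`` outside IC cells."""
    if a == b:
        return False
    if abs(a - b) > max_step:
        return False
    if not allow_reserved and (a, b) in RESERVED_PAIRS:
        return False
    return True


def classify_contour(prev: int, target: int, nxt: int) -> Contour:
    """Local contour class of ``target`` given its neighbours.

    peak: both neighbours lower; valley: both higher; ascending: prev lower
    and next higher; descending: prev higher and next lower.
    """
    if prev == target or nxt == target:
        raise ValueError(f"adjacent repeated degrees in contour triple ({prev},{target},{nxt})")
    if prev < target and nxt < target:
        return "peak"
    if prev > target and nxt > target:
        return "valley"
    if prev < target < nxt:
        return "ascending"
    return "descending"


# ---------------------------------------------------------------------------
# default grammar

def _norm(d: dict[int, float]) -> dict[int, float]:
    s = sum(d.values())
    return {k: v / s for k, v in d.items()}


def default_grammar() -> GrammarSpec:
    """The calibrated default grammar.

    Filler tables are chosen so that (a) every global constraint holds by
    construction and (b) degrees 3 and 5 occur as contexts outside the IC
    cells about as often as inside them, which places the corpus-level IC of
    the 0.95 branches near 1 bit and of the 0.05 branches near 5-6 bits,
    while keeping the overall frequencies of the target degrees 2, 4 and 6
    within a few percentage points of each other.
    """
    # shared filler chain; rows exclude repeats, steps > 4 and reserved pairs,
    # and route enough traffic through degrees 3 and 5 to dilute the IC-cell
    # conditionals to the intended corpus-level values
    filler = {
        1: _norm({2: 0.20, 5: 0.50, 3: 0.30}),
        2: _norm({1: 0.15, 6: 0.40, 5: 0.45}),
        3: _norm({1: 0.25, 5: 0.20, 6: 0.30, 7: 0.25}),
        5: _norm({1: 0.25, 2: 0.45, 7: 0.30}),
        6: _norm({2: 0.35, 3: 0.40, 7: 0.25}),
        7: _norm({3: 0.45, 6: 0.35, 5: 0.20}),
    }
    start = CellSpec(
        name="start",
        length_range=(1, 3),
        initial_distribution=_norm({1: 0.25, 2: 0.25, 6: 0.25, 7: 0.25}),
        transition_table=filler,
    )
    intermediate = CellSpec(
        name="intermediate",
        length_range=(2, 4),
        initial_distribution=_norm({1: 0.25, 2: 0.20, 6: 0.25, 7: 0.30}),
        transition_table=filler,
    )
    end = CellSpec(
        name="end",
        length_range=(2, 3),
        initial_distribution=_norm({1: 0.25, 2: 0.20, 6: 0.25, 7: 0.30}),
        transition_table=filler,
    )
    ic_alpha = CellSpec(
        name="ic_alpha",
        length_range=(2, 2),
        initial_distribution={3: 1.0},
        transition_table={3: {4: 0.95, 2: 0.05}},
        ic_params=ICParams(context_degree=3, high_prob_target=4, low_prob_target=2),
    )
    ic_beta = CellSpec(
        name="ic_beta",
        length_range=(2, 2),
        initial_distribution={5: 1.0},
        transition_table={5: {4: 0.95, 6: 0.05}},
        ic_params=ICParams(context_degree=5, high_prob_target=4, low_prob_target=6),
    )
    return GrammarSpec(
        cells={c.name: c for c in (start, ic_alpha, intermediate, ic_beta, end)}
    )


# ---------------------------------------------------------------------------
# validation

_EXPECTED_IC = {
    "ic_alpha": ICParams(context_degree=3, high_prob_target=4, low_prob_target=2),
    "ic_beta": ICParams(context_degree=5, high_prob_target=4, low_prob_target=6),
}


def validate_grammar(spec: GrammarSpec) -> list[str]:
    """Check every structural invariant; return a list of violation messages.

    An empty list means the grammar is valid.  Malformed probability rows
    (negative entries, NaN, sums away from 1) are reported as violations
    rather than raised.
    """
    out: list[str] = []
    expected_names = {"start", "ic_alpha", "ic_beta", "intermediate", "end"}
    missing = expected_names - set(spec.cells)
    for name in sorted(missing):
        out.append(f"missing cell {name!r}")

    for name, cell in spec.cells.items():
        lo, hi = cell.length_range
        if not (1 <= lo <= hi):
            out.append(f"{name}: bad length_range {cell.length_range}")
        for label, rows in (("initial", {None: cell.initial_distribution}),
                            ("transition", cell.transition_table)):
            for ctx, row in rows.items():
                where = f"{name}/{label}" + ("" if ctx is None else f" row {ctx}")
                s = 0.0
                for deg, p in row.items():
                    if deg not in DEGREES:
                        out.append(f"{where}: degree {deg} outside 1-7")
                    if not np.isfinite(p) or p < 0:
                        out.append(f"{where}: malformed probability {p} for degree {deg}")
                        continue
                    s += p
                    if label == "transition" and p > 0:
                        if ctx == deg:
                            out.append(f"{where}: repeat {ctx}->{deg} at p>0")
                        elif abs(ctx - deg) > spec.max_step:
                            out.append(f"{where}: step {ctx}->{deg} exceeds {spec.max_step}")
                        if (not cell.is_ic and (ctx, deg) in RESERVED_PAIRS):
                            out.append(f"{where}: reserved pair {ctx}->{deg} outside IC cell")
                if abs(s - 1.0) > 1e-9:
                    out.append(f"{where}: row not stochastic (sums to {s:.6g})")

        if cell.is_ic:
            ic = cell.ic_params
            if cell.length_range != (2, 2):
                out.append(f"{name}: IC cell length must be exactly 2")
            if abs(ic.p_high - 0.95) > 1e-12 and not (0 < ic.p_high < 1):
                out.append(f"{name}: p_high {ic.p_high} not in (0,1)")
            want = _EXPECTED_IC.get(name)
            if want is not None:
                got = (ic.context_degree, ic.high_prob_target, ic.low_prob_target)
                exp = (want.context_degree, want.high_prob_target, want.low_prob_target)
                if got != exp:
                    out.append(f"{name}: context/targets {got} do not match {exp}")
            row = cell.transition_table.get(ic.context_degree, {})
            p_hi = row.get(ic.high_prob_target, 0.0)
            p_lo = row.get(ic.low_prob_target, 0.0)
            if abs(p_hi - ic.p_high) > 1e-9 or abs(p_hi + p_lo - 1.0) > 1e-9:
                out.append(f"{name}: branch probabilities ({p_hi}, {p_lo}) inconsistent "
                           f"with p_high={ic.p_high}")
            if abs(ic.context_degree - ic.high_prob_target) != 1 or \
               abs(ic.context_degree - ic.low_prob_target) != 1:
                out.append(f"{name}: target not one scale degree from context")
    for order in spec.module_orders:
        if missing:
            break
        if set(order) != expected_names:
            out.append(f"module order {order} does not use all five cells once")
    return out


def validate_melody(rec: MelodyRecord, spec: GrammarSpec) -> list[str]:
    """Check a generated melody against every record-level invariant."""
    out: list[str] = []
    n = len(rec.degrees)
    lo, hi = spec.exposure_length if rec.phase != "test" else spec.fc_length
    if rec.phase == "attention_long":
        lo = max(lo, 12)
    if not (lo <= n <= hi):
        out.append(f"length {n} outside [{lo},{hi}]")
    for d in rec.degrees:
        if d not in DEGREES:
            out.append(f"degree {d} outside 1-7")
    ic_positions = set()
    for name, a, b in rec.cell_spans:
        if spec.cells[name].is_ic:
            ic_positions.add(a)  # context->target pair starts at the context
    for i in range(n - 1):
        a, b = rec.degrees[i], rec.degrees[i + 1]
        if a == b:
            out.append(f"repeat {a}->{b} at {i}")
        if abs(a - b) > spec.max_step:
            out.append(f"step {a}->{b} at {i} exceeds {spec.max_step}")
        if (a, b) in RESERVED_PAIRS and i not in ic_positions:
            out.append(f"reserved pair {a}->{b} outside IC cell at {i}")
    want_targets = 2 if rec.phase in ("exposure", "attention_long") else 1
    if len(rec.targets) != want_targets:
        out.append(f"expected {want_targets} targets, found {len(rec.targets)}")
    for t in rec.targets:
        if not (0 < t.position < n - 1):
            out.append(f"target position {t.position} at melody edge")
            continue
        prev, deg, nxt = rec.degrees[t.position - 1], rec.degrees[t.position], rec.degrees[t.position + 1]
        if prev != t.context_degree:
            out.append(f"target at {t.position} not preceded by its context {t.context_degree}")
        if abs(prev - deg) != 1:
            out.append(f"context-target interval |{prev}-{deg}| != 1")
        if classify_contour(prev, deg, nxt) != t.contour:
            out.append(f"target contour annotation {t.contour} inconsistent at {t.position}")
    return out


# ---------------------------------------------------------------------------
# sampling

def _draw(row: dict[int, float], rng: np.random.Generator) -> int:
    degs = list(row)
    p = np.asarray([row[d] for d in degs], dtype=float)
    return int(degs[rng.choice(len(degs), p=p / p.sum())])


def _restrict(dist: dict[int, float], entry: int | None, max_step: int) -> dict[int, float]:
    if entry is None:
        return dict(dist)
    kept = {d: p for d, p in dist.items()
            if p > 0 and legal_pair(entry, d, max_step=max_step)}
    return kept


def sample_cell(
    cell: CellSpec,
    entry_degree: int | None,
    rng: np.random.Generator,
    *,
    length_range: tuple[int, int] | None = None,
    max_step: int = 4,
    forced_branch: Literal["high", "low"] | None = None,
) -> list[int]:
    """Sample one cell as a degree sequence.

    ``entry_degree`` is the last degree of the preceding cell; the cell's
    initial distribution is restricted to degrees that are legal after it
    (no repeat, step <= ``max_step``, no reserved pair).  IC cells return
    ``[context, target]`` with the high-probability target drawn with
    probability ``p_high`` unless ``forced_branch`` pins the outcome.

    Raises
    ------
    DeadEndError
        If no initial degree is legal after ``entry_degree``.
    """
    lo, hi = length_range or cell.length_range
    if cell.is_ic:
        ic = cell.ic_params
        if entry_degree is not None and not legal_pair(entry_degree, ic.context_degree, max_step=max_step):
            raise DeadEndError(entry_degree, cell.name)
        if forced_branch is None:
            branch = "low" if rng.random() < ic.p_high else "high"  # low IC = likely
        else:
            branch = forced_branch
        target = ic.high_prob_target if branch == "low" else ic.low_prob_target
        return [ic.context_degree, target]

    length = int(rng.integers(lo, hi + 1))
    init = _restrict(cell.initial_distribution, entry_degree, max_step)
    if not init:
        raise DeadEndError(entry_degree, cell.name)
    seq = [_draw(init, rng)]
    for _ in range(length - 1):
        row = cell.transition_table.get(seq[-1])
        if not row:
            raise DeadEndError(seq[-1], cell.name)
        seq.append(_draw(row, rng))
    return seq


def _assemble(
    spec: GrammarSpec,
    order: Sequence[str],
    rng: np.random.Generator,
    *,
    length_overrides: dict[str, tuple[int, int]] | None = None,
    forced_branches: dict[str, Literal["high", "low"]] | None = None,
    end_entry_filter: "callable | None" = None,
) -> tuple[list[int], list[tuple[str, int, int]], dict[str, Literal["high", "low"]]]:
    """Sample the cells of ``order`` in sequence, joining them legally."""
    degrees: list[int] = []
    spans: list[tuple[str, int, int]] = []
    branches: dict[str, Literal["high", "low"]] = {}
    for name in order:
        cell = spec.cells[name]
        entry = degrees[-1] if degrees else None
        lr = (length_overrides or {}).get(name)
        fb = (forced_branches or {}).get(name)
        if name == "end" and end_entry_filter is not None:
            # restrict the end cell's first note beyond plain legality
            init = _restrict(cell.initial_distribution, entry, spec.max_step)
            init = {d: p for d, p in init.items() if end_entry_filter(d)}
            if not init:
                raise DeadEndError(entry, name)
            cell = replace(cell, initial_distribution=_norm(init))
        seq = sample_cell(cell, entry, rng, length_range=lr,
                          max_step=spec.max_step, forced_branch=fb)
        if spec.cells[name].is_ic:
            branches[name] = fb or ("low" if seq[1] == spec.cells[name].ic_params.high_prob_target else "high")
        spans.append((name, len(degrees), len(degrees) + len(seq) - 1))
        degrees.extend(seq)
    return degrees, spans, branches


def _annotate_targets(
    degrees: Sequence[int],
    spans: Sequence[tuple[str, int, int]],
    branches: dict[str, Literal["high", "low"]],
    cells: dict[str, CellSpec],
) -> tuple[TargetAnnotation, ...]:
    targets = []
    for name, a, b in spans:
        if cells[name].is_ic:
            pos = a + 1
            targets.append(TargetAnnotation(
                position=pos,
                ic_condition=branches[name],
                context_degree=cells[name].ic_params.context_degree,
                contour=classify_contour(degrees[pos - 1], degrees[pos], degrees[pos + 1]),
            ))
    return tuple(targets)


def generate_exposure_melody(
    spec: GrammarSpec,
    rng: np.random.Generator,
    *,
    min_length: int | None = None,
    seed_tag: str = "",
    phase: Literal["exposure", "attention_long"] = "exposure",
) -> MelodyRecord:
    """Draw one exposure melody: 9-14 notes, both IC cells, order randomised.

    ``min_length`` conditions on total length (rejection sampling), used for
    the long attention-trial melodies (12-14 notes) that reuse this grammar.
    """
    last_err: Exception | None = None
    for _ in range(spec.max_retries):
        order = spec.module_orders[int(rng.integers(0, 2))]
        try:
            degrees, spans, branches = _assemble(spec, order, rng)
        except DeadEndError as err:
            last_err = err
            continue
        lo, hi = spec.exposure_length
        if not (max(lo, min_length or lo) <= len(degrees) <= hi):
            continue
        rec = MelodyRecord(
            degrees=tuple(degrees),
            cell_spans=tuple(spans),
            targets=_annotate_targets(degrees, spans, branches, spec.cells),
            phase=phase,
            seed_tag=seed_tag,
        )
        return rec
    raise GenerationError(
        f"failed to generate an exposure melody after {spec.max_retries} attempts"
        + (f" (last dead end: {last_err})" if last_err else "")
    )


_CONTOUR_SIGN = {"peak": -1, "ascending": +1, "valley": +1, "descending": -1}


def generate_test_melody(
    spec: GrammarSpec,
    ic_condition: Literal["high", "low"],
    rng: np.random.Generator,
    *,
    ic_cell: Literal["ic_alpha", "ic_beta"] | None = None,
    contour: Contour | None = None,
    seed_tag: str = "",
) -> MelodyRecord:
    """Draw one forced-choice melody: 7-9 notes, a single IC cell, no intermediate.

    The target sits near the middle of the melody, and the filler notes are
    drawn so that the matched variant with the opposite ``ic_condition`` and
    identical flanking notes is always legal (see :func:`matched_test_variant`).
    ``contour`` optionally pins the target's contour class by restricting the
    note that follows the target.
    """
    last_err: Exception | None = None
    for _ in range(spec.max_retries):
        cell_name = ic_cell or ("ic_alpha", "ic_beta")[int(rng.integers(0, 2))]
        ic = spec.cells[cell_name].ic_params
        both = (ic.high_prob_target, ic.low_prob_target)
        target = ic.high_prob_target if ic_condition == "low" else ic.low_prob_target

        def end_ok(d: int, _both=both, _target=target) -> bool:
            # the end cell's first note must legally follow either target
            if not all(legal_pair(t, d, max_step=spec.max_step) for t in _both):
                return False
            if contour is not None:
                want = _CONTOUR_SIGN[contour]
                if (d - _target) * want <= 0:
                    return False
                # contour also depends on the context side; check it matches
                prev = ic.context_degree
                if classify_contour(prev, _target, d) != contour:
                    return False
            return True

        order = ("start", cell_name, "end")
        try:
            degrees, spans, _ = _assemble(
                spec, order, rng,
                length_overrides={"start": spec.fc_start_length, "end": spec.fc_end_length},
                forced_branches={cell_name: ic_condition},
                end_entry_filter=end_ok,
            )
        except DeadEndError as err:
            last_err = err
            continue
        lo, hi = spec.fc_length
        if not (lo <= len(degrees) <= hi):
            continue
        branches = {cell_name: ic_condition}
        rec = MelodyRecord(
            degrees=tuple(degrees),
            cell_spans=tuple(spans),
            targets=_annotate_targets(degrees, spans, branches, spec.cells),
            phase="test",
            seed_tag=seed_tag,
        )
        return rec
    raise GenerationError(
        f"failed to generate a test melody ({ic_condition}, contour={contour}) "
        f"after {spec.max_retries} attempts"
        + (f" (last dead end: {last_err})" if last_err else "")
    )


def matched_test_variant(rec: MelodyRecord, spec: GrammarSpec) -> MelodyRecord:
    """The matched forced-choice partner: identical except at the target note.

    Swaps the target degree for the other branch of the same IC cell and
    flips the annotated ``ic_condition``; every other note is untouched.
    """
    if rec.phase != "test" or len(rec.targets) != 1:
        raise ValueError("matched variants are defined for single-target test melodies")
    (t,) = rec.targets
    cell_name = next(name for name, a, b in rec.cell_spans if spec.cells[name].is_ic)
    ic = spec.cells[cell_name].ic_params
    new_cond: Literal["high", "low"] = "low" if t.ic_condition == "high" else "high"
    new_deg = ic.high_prob_target if new_cond == "low" else ic.low_prob_target
    degrees = list(rec.degrees)
    degrees[t.position] = new_deg
    new_t = replace(
        t,
        ic_condition=new_cond,
        contour=classify_contour(degrees[t.position - 1], new_deg, degrees[t.position + 1]),
    )
    return replace(rec, degrees=tuple(degrees), targets=(new_t,))


def generate_corpus(
    spec: GrammarSpec,
    n: int,
    seed: int,
    *,
    kind: Literal["exposure", "test"] = "exposure",
) -> list[MelodyRecord]:
    """Generate ``n`` melodies with per-melody derived substreams.

    Each melody's RNG stream is spawned from ``SeedSequence(seed)`` and its
    provenance recorded in ``seed_tag`` as ``"<seed>:<index>"`` so any single
    melody can be regenerated bit-exactly.
    """
    children = np.random.SeedSequence(seed).spawn(n)
    out = []
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        tag = f"{seed}:{i}"
        if kind == "exposure":
            out.append(generate_exposure_melody(spec, rng, seed_tag=tag))
        else:
            cond: Literal["high", "low"] = ("high", "low")[i % 2]
            out.append(generate_test_melody(spec, cond, rng, seed_tag=tag))
    return out


# ---------------------------------------------------------------------------
# record surgery

def apply_accent(rec: MelodyRecord, target_index: int, accented: bool = True) -> MelodyRecord:
    """Return a copy with the accent flag of the target at ``target_index`` set.

    Only the flag changes; the degree content is untouched.  Calling with
    ``accented=False`` undoes the accent, so the operation is an involution.
    """
    hit = [t for t in rec.targets if t.position == target_index]
    if not hit:
        raise ValueError(f"index {target_index} is not an annotated target")
    new_targets = tuple(
        replace(t, accented=accented) if t.position == target_index else t
        for t in rec.targets
    )
    return replace(rec, targets=new_targets)


def make_agrammatical_variant(rec: MelodyRecord) -> MelodyRecord:
    """Flag a melody as agrammatical: degrees 5 and 6 swap *rendered* pitches.

    The degree content is unchanged; the pitch-mapping layer performs the
    swap when rendering.  Applying the swap twice at render time restores the
    grammatical pitches, so re-flagging is the only state carried here.
    """
    if rec.variant != "grammatical":
        raise ValueError("variant is already agrammatical")
    return replace(rec, variant="agrammatical")


# ---------------------------------------------------------------------------
# (de)serialisation

def grammar_to_json(spec: GrammarSpec) -> str:
    def cell_dict(c: CellSpec) -> dict:
        d = {
            "name": c.name,
            "length_range": list(c.length_range),
            "initial_distribution": {str(k): v for k, v in c.initial_distribution.items()},
            "transition_table": {str(k): {str(kk): vv for kk, vv in row.items()}
                                 for k, row in c.transition_table.items()},
        }
        if c.ic_params:
            d["ic_params"] = {
                "context_degree": c.ic_params.context_degree,
                "high_prob_target": c.ic_params.high_prob_target,
                "low_prob_target": c.ic_params.low_prob_target,
                "p_high": c.ic_params.p_high,
            }
        return d

    return json.dumps({
        "cells": {name: cell_dict(c) for name, c in spec.cells.items()},
        "module_orders": [list(o) for o in spec.module_orders],
        "max_step": spec.max_step,
        "exposure_length": list(spec.exposure_length),
        "fc_length": list(spec.fc_length),
        "fc_start_length": list(spec.fc_start_length),
        "fc_end_length": list(spec.fc_end_length),
        "max_retries": spec.max_retries,
    }, indent=2)


def grammar_from_json(text: str) -> GrammarSpec:
    """Load a grammar document; the result is re-validated by the caller."""
    raw = json.loads(text)

    def cell(d: dict) -> CellSpec:
        ic = None
        if "ic_params" in d:
            ic = ICParams(**d["ic_params"])
        return CellSpec(
            name=d["name"],
            length_range=tuple(d["length_range"]),
            initial_distribution={int(k): v for k, v in d["initial_distribution"].items()},
            transition_table={int(k): {int(kk): vv for kk, vv in row.items()}
                              for k, row in d["transition_table"].items()},
            ic_params=ic,
        )

    return GrammarSpec(
        cells={name: cell(c) for name, c in raw["cells"].items()},
        module_orders=tuple(tuple(o) for o in raw["module_orders"]),
        max_step=raw["max_step"],
        exposure_length=tuple(raw["exposure_length"]),
        fc_length=tuple(raw["fc_length"]),
        fc_start_length=tuple(raw["fc_start_length"]),
        fc_end_length=tuple(raw["fc_end_length"]),
        max_retries=raw["max_retries"],
    )
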