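"""Assembly of the full listening-experiment protocol.

The protocol has four phases:

* **exposure** -- 45 passive trials of four grammar melodies each (180
  melodies total), randomly interleaved with active trials (attention and
  liking) at an average rate of one active trial per two passive trials;
* **learning** -- 16 single-melody similarity-rating trials, 8 grammatical
  (drawn from the exposure pool) and 8 agrammatical (same construction, the
  rendered pitches of degrees 5 and 6 swapped);
* **fc_accent** -- 16 two-alternative items pairing an accented and a plain
  rendering of the same melody (8 high-IC targets, 8 low-IC), with all four
  target contour classes represented;
* **fc_ic** -- 16 two-alternative items pairing matched melodies that differ
  only at the target note (high vs low IC), 8 with both members accented.

Schedules are fully determined by their master seed and serialise
losslessly to JSON; a JSON-lines trial manifest is also provided.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .grammar import (
    GrammarSpec,
    MelodyRecord,
    TargetAnnotation,
    apply_accent,
    generate_exposure_melody,
    generate_test_melody,
    make_agrammatical_variant,
    matched_test_variant,
    validate_grammar,
)
from .midi import RenderConfig, render_midi
from .pitch import PitchMapping

__all__ = [
    "Trial",
    "TrialSchedule",
    "ATTENTION_LENGTHS",
    "build_exposure_schedule",
    "build_learning_test",
    "build_accent_preference_test",
    "build_ic_preference_test",
    "build_full_schedule",
    "render_schedule",
]

TrialKind = Literal["passive", "attention", "liking", "learning", "fc_accent", "fc_ic"]

#: attention-trial difficulty -> (short melody notes, long melody notes)
ATTENTION_LENGTHS = {"easy": (7, 14), "intermediate": (7, 9), "hard": (12, 14)}

_STIMULI_PER_TRIAL = {"passive": 4, "attention": 2, "liking": 1,
                      "learning": 1, "fc_accent": 2, "fc_ic": 2}


@dataclass(frozen=True)
class Trial:
    kind: TrialKind
    stimuli: tuple[str, ...]  # stimulus ids, in presentation order
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        want = _STIMULI_PER_TRIAL[self.kind]
        if len(self.stimuli) != want:
            raise ValueError(f"{self.kind} trial needs {want} stimuli, got {len(self.stimuli)}")


@dataclass
class TrialSchedule:
    phases: dict[str, tuple[Trial, ...]]
    stimuli: dict[str, MelodyRecord]
    tonic_condition: int
    seed: int

    # -- counting helpers -------------------------------------------------
    def n_passive_melodies(self) -> int:
        return sum(len(t.stimuli) for t in self.phases.get("exposure", ())
                   if t.kind == "passive")

    # -- serialisation ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "tonic_condition": self.tonic_condition,
            "seed": self.seed,
            "phases": {ph: [dataclasses.asdict(t) for t in trials]
                       for ph, trials in self.phases.items()},
            "stimuli": {sid: _melody_to_dict(m) for sid, m in self.stimuli.items()},
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TrialSchedule":
        raw = json.loads(text)
        phases = {
            ph: tuple(Trial(kind=t["kind"], stimuli=tuple(t["stimuli"]), info=t["info"])
                      for t in trials)
            for ph, trials in raw["phases"].items()
        }
        stimuli = {sid: _melody_from_dict(d) for sid, d in raw["stimuli"].items()}
        return cls(phases=phases, stimuli=stimuli,
                   tonic_condition=raw["tonic_condition"], seed=raw["seed"])

    def trials_jsonl(self) -> str:
        """One JSON object per trial, in protocol order, for delivery systems."""
        lines = []
        for ph in self.phases:
            for i, t in enumerate(self.phases[ph]):
                lines.append(json.dumps({
                    "phase": ph, "index": i, "kind": t.kind,
                    "stimuli": [f"{s}.mid" for s in t.stimuli], **t.info,
                }))
        return "\n".join(lines) + "\n"


def _melody_to_dict(m: MelodyRecord) -> dict:
    return {
        "degrees": " ".join(map(str, m.degrees)),
        "cell_spans": [list(s) for s in m.cell_spans],
        "targets": [dataclasses.asdict(t) for t in m.targets],
        "phase": m.phase,
        "variant": m.variant,
        "seed_tag": m.seed_tag,
    }


def _melody_from_dict(d: dict) -> MelodyRecord:
    return MelodyRecord(
        degrees=tuple(int(x) for x in d["degrees"].split()),
        cell_spans=tuple((s[0], int(s[1]), int(s[2])) for s in d["cell_spans"]),
        targets=tuple(TargetAnnotation(**t) for t in d["targets"]),
        phase=d["phase"],
        variant=d["variant"],
        seed_tag=d["seed_tag"],
    )


# ---------------------------------------------------------------------------
# generation helpers

def _exposure_with_length(spec, rng, length, *, phase="exposure", tries=5000):
    for _ in range(tries):
        m = generate_exposure_melody(spec, rng, phase=phase)
        if len(m) == length:
            return dataclasses.replace(m, phase=phase)
    raise RuntimeError(f"could not draw an exposure melody of length {length}")


def _test_with_length(spec, rng, length, *, tries=5000):
    for _ in range(tries):
        cond = ("high", "low")[int(rng.integers(0, 2))]
        m = generate_test_melody(spec, cond, rng)
        if len(m) == length:
            return m
    raise RuntimeError(f"could not draw a test melody of length {length}")


def _interleave_positions(n_passive: int, n_active: int, rng: np.random.Generator) -> list[int]:
    """Slots (0..n_passive) after which an active trial is inserted.

    Active trials never precede the first passive trial and are never
    adjacent to one another, i.e. at most one active trial per slot and
    slot 0 is excluded.
    """
    if n_active > n_passive:
        raise ValueError("cannot interleave without adjacent active trials")
    slots = rng.choice(np.arange(1, n_passive + 1), size=n_active, replace=False)
    return sorted(int(s) for s in slots)


# ---------------------------------------------------------------------------
# phase builders

def build_exposure_schedule(
    spec: GrammarSpec,
    rng: np.random.Generator,
    *,
    n_passive_trials: int = 45,
    melodies_per_trial: int = 4,
    n_attention: int = 15,
    n_liking: int = 7,
) -> tuple[tuple[Trial, ...], dict[str, MelodyRecord]]:
    """Exposure phase: passive trials with randomly interleaved active trials.

    Defaults give 180 passive melodies and 22 active trials (2:1 attention
    to liking), one active trial per two passive trials on average.
    """
    stimuli: dict[str, MelodyRecord] = {}

    passive_trials = []
    for i in range(n_passive_trials):
        ids = []
        for j in range(melodies_per_trial):
            sid = f"exp_{i:02d}_{j}"
            stimuli[sid] = generate_exposure_melody(spec, rng)
            ids.append(sid)
        passive_trials.append(Trial(kind="passive", stimuli=tuple(ids)))

    difficulties = [d for d in ATTENTION_LENGTHS for _ in range(n_attention // 3)]
    difficulties += ["easy", "intermediate", "hard"][: n_attention - len(difficulties)]
    active_trials: list[Trial] = []
    for k, diff in enumerate(difficulties):
        short_len, long_len = ATTENTION_LENGTHS[diff]
        short = (_test_with_length(spec, rng, short_len) if short_len <= spec.fc_length[1]
                 else _exposure_with_length(spec, rng, short_len, phase="attention_long"))
        long = _exposure_with_length(spec, rng, long_len, phase="attention_long")
        sid_s, sid_l = f"att_{k:02d}_short", f"att_{k:02d}_long"
        stimuli[sid_s], stimuli[sid_l] = short, long
        order = int(rng.integers(0, 2))  # 0: short first
        pair = (sid_s, sid_l) if order == 0 else (sid_l, sid_s)
        active_trials.append(Trial(
            kind="attention", stimuli=pair,
            info={"difficulty": diff, "correct_answer": pair.index(sid_s)},
        ))
    for k in range(n_liking):
        sid = f"lik_{k:02d}"
        stimuli[sid] = generate_exposure_melody(spec, rng)
        active_trials.append(Trial(kind="liking", stimuli=(sid,)))
    order = rng.permutation(len(active_trials))
    active_trials = [active_trials[i] for i in order]

    slots = _interleave_positions(n_passive_trials, len(active_trials), rng)
    trials: list[Trial] = []
    ai = 0
    for i, pt in enumerate(passive_trials):
        trials.append(pt)
        while ai < len(slots) and slots[ai] == i + 1:
            trials.append(active_trials[ai])
            ai += 1
    return tuple(trials), stimuli


def build_learning_test(
    spec: GrammarSpec,
    rng: np.random.Generator,
    exposure_pool: Sequence[MelodyRecord],
    *,
    n_grammatical: int = 8,
    n_agrammatical: int = 8,
) -> tuple[tuple[Trial, ...], dict[str, MelodyRecord]]:
    """Grammar-learning test: similarity ratings for 8 + 8 melodies.

    Grammatical items are drawn (without replacement) from the exposure
    pool; agrammatical items are fresh draws from the same grammar flagged
    so rendering swaps the pitches of degrees 5 and 6.
    """
    if len(exposure_pool) < n_grammatical:
        raise ValueError("exposure pool too small")
    stimuli: dict[str, MelodyRecord] = {}
    trials: list[Trial] = []
    picks = rng.choice(len(exposure_pool), size=n_grammatical, replace=False)
    for k, idx in enumerate(picks):
        sid = f"learn_g_{k:02d}"
        stimuli[sid] = dataclasses.replace(exposure_pool[int(idx)], phase="exposure")
        trials.append(Trial(kind="learning", stimuli=(sid,), info={"variant": "grammatical"}))
    for k in range(n_agrammatical):
        sid = f"learn_a_{k:02d}"
        stimuli[sid] = make_agrammatical_variant(generate_exposure_melody(spec, rng))
        trials.append(Trial(kind="learning", stimuli=(sid,), info={"variant": "agrammatical"}))
    order = rng.permutation(len(trials))
    return tuple(trials[i] for i in order), stimuli


#: which IC cell realises each (contour, ic_condition) combination
_CONTOUR_CELL = {
    ("peak", "low"): "ic_alpha", ("peak", "high"): "ic_beta",
    ("ascending", "low"): "ic_alpha", ("ascending", "high"): "ic_beta",
    ("valley", "high"): "ic_alpha", ("valley", "low"): "ic_beta",
    ("descending", "high"): "ic_alpha", ("descending", "low"): "ic_beta",
}


def build_accent_preference_test(
    spec: GrammarSpec,
    rng: np.random.Generator,
    *,
    n_items: int = 16,
) -> tuple[tuple[Trial, ...], dict[str, MelodyRecord]]:
    """Accent-preference 2AFC: accented vs plain rendering of one melody.

    Items cross the four contour classes with the two IC conditions as
    evenly as parity allows (16 items = 2 per contour x IC combination);
    presentation order within each pair is randomised and recorded.
    """
    if n_items % 8:
        raise ValueError("item count must be a multiple of 8 to balance contour x IC")
    combos = [(c, ic) for c in ("peak", "valley", "ascending", "descending")
              for ic in ("high", "low")] * (n_items // 8)
    stimuli: dict[str, MelodyRecord] = {}
    trials: list[Trial] = []
    for k, (contour, ic) in enumerate(combos):
        cell = _CONTOUR_CELL[(contour, ic)]
        mel = generate_test_melody(spec, ic, rng, ic_cell=cell, contour=contour)
        (target,) = mel.targets
        accented = apply_accent(mel, target.position)
        sid_a, sid_p = f"fca_{k:02d}_acc", f"fca_{k:02d}_plain"
        stimuli[sid_a], stimuli[sid_p] = accented, mel
        first = int(rng.integers(0, 2))  # 0: accented first
        pair = (sid_a, sid_p) if first == 0 else (sid_p, sid_a)
        trials.append(Trial(
            kind="fc_accent", stimuli=pair,
            info={"ic_condition": ic, "contour": contour,
                  "accented_position": pair.index(sid_a)},
        ))
    order = rng.permutation(len(trials))
    return tuple(trials[i] for i in order), stimuli


def build_ic_preference_test(
    spec: GrammarSpec,
    rng: np.random.Generator,
    *,
    n_items: int = 16,
) -> tuple[tuple[Trial, ...], dict[str, MelodyRecord]]:
    """IC-preference 2AFC: matched pair differing only at the target note.

    Half the items have both members accented at the target, half neither;
    the high-IC member's contour cycles through all four classes.
    """
    if n_items % 2:
        raise ValueError("item count must be even to balance the accent arm")
    contours = ("peak", "valley", "ascending", "descending")
    stimuli: dict[str, MelodyRecord] = {}
    trials: list[Trial] = []
    for k in range(n_items):
        contour = contours[k % 4]
        accent_arm = k < n_items // 2
        cell = _CONTOUR_CELL[(contour, "high")]
        high = generate_test_melody(spec, "high", rng, ic_cell=cell, contour=contour)
        low = matched_test_variant(high, spec)
        if accent_arm:
            high = apply_accent(high, high.targets[0].position)
            low = apply_accent(low, low.targets[0].position)
        sid_h, sid_l = f"fci_{k:02d}_high", f"fci_{k:02d}_low"
        stimuli[sid_h], stimuli[sid_l] = high, low
        first = int(rng.integers(0, 2))  # 0: high-IC first
        pair = (sid_h, sid_l) if first == 0 else (sid_l, sid_h)
        trials.append(Trial(
            kind="fc_ic", stimuli=pair,
            info={"accented": accent_arm,
                  "contour_high": high.targets[0].contour,
                  "contour_low": low.targets[0].contour,
                  "high_position": pair.index(sid_h)},
        ))
    order = rng.permutation(len(trials))
    return tuple(trials[i] for i in order), stimuli


def build_full_schedule(
    spec: GrammarSpec,
    seed: int,
    *,
    tonic_condition: int = 0,
) -> TrialSchedule:
    """Build the complete four-phase protocol from one master seed."""
    problems = validate_grammar(spec)
    if problems:
        raise ValueError("grammar does not validate: " + "; ".join(problems))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    phases: dict[str, tuple[Trial, ...]] = {}
    stimuli: dict[str, MelodyRecord] = {}

    exp_trials, exp_stim = build_exposure_schedule(spec, rng)
    phases["exposure"] = exp_trials
    stimuli.update(exp_stim)

    pool = [exp_stim[s] for t in exp_trials if t.kind == "passive" for s in t.stimuli]
    for builder, name in ((build_learning_test, "learning"),
                          (build_accent_preference_test, "fc_accent"),
                          (build_ic_preference_test, "fc_ic")):
        if name == "learning":
            trials, stim = builder(spec, rng, pool)
        else:
            trials, stim = builder(spec, rng)
        phases[name] = trials
        stimuli.update(stim)
    return TrialSchedule(phases=phases, stimuli=stimuli,
                         tonic_condition=tonic_condition, seed=seed)


def render_schedule(
    schedule: TrialSchedule,
    mapping: PitchMapping,
    out_dir: str | Path,
    cfg: RenderConfig | None = None,
) -> list[Path]:
    """Write every stimulus as a MIDI file named by its id; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for sid, mel in schedule.stimuli.items():
        p = out / f"{sid}.mid"
        p.write_bytes(render_midi(mel, mapping, cfg))
        paths.append(p)
    return paths
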