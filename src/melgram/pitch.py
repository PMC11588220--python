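"""Scale-degree to pitch assignment via an asymmetric hexascale.

The pitch material is a six-note scale whose semitone interval pattern sums
to an octave and has no nonzero rotational symmetry.  The scale repeats
across octaves, forming a pitch lattice; a six-position *sliding window*
selects which lattice position is scale degree 1 (the tonic).  Degrees 1-6
are then six consecutive lattice pitches and degree 7 repeats degree 1 one
octave higher.  Because the scale is asymmetric, the six window positions
give six distinct interval profiles -- the per-participant tonic conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HexascaleSpec", "PitchMapping", "build_pitch_mapping", "DEFAULT_HEXASCALE"]


@dataclass(frozen=True)
class HexascaleSpec:
    """Interval pattern (semitones, summing to 12) anchored at a MIDI pitch."""

    interval_pattern: tuple[int, int, int, int, int, int]
    anchor_pitch: int = 60

    def validate(self) -> list[str]:
        out = []
        pat = self.interval_pattern
        if len(pat) != 6:
            out.append("interval pattern must have 6 entries")
            return out
        if any(i < 1 for i in pat):
            out.append("all intervals must be >= 1 semitone")
        if sum(pat) != 12:
            out.append(f"intervals sum to {sum(pat)}, not 12")
        for k in range(1, 6):
            if tuple(pat[k:] + pat[:k]) == tuple(pat):
                out.append(f"pattern is rotationally symmetric (period {k})")
                break
        if not (0 <= self.anchor_pitch <= 127):
            out.append("anchor pitch outside MIDI range")
        return out


DEFAULT_HEXASCALE = HexascaleSpec(interval_pattern=(1, 2, 2, 1, 3, 3), anchor_pitch=60)


@dataclass(frozen=True)
class PitchMapping:
    tonic_lattice_index: int
    degree_to_pitch: dict[int, int]

    def pitch(self, degree: int, *, agrammatical: bool = False) -> int:
        """MIDI pitch of a scale degree; agrammatical swaps degrees 5 and 6."""
        if agrammatical and degree in (5, 6):
            degree = 11 - degree
        return self.degree_to_pitch[degree]

    @property
    def gap_vector(self) -> tuple[int, ...]:
        p = [self.degree_to_pitch[d] for d in range(1, 8)]
        return tuple(b - a for a, b in zip(p, p[1:]))


def build_pitch_mapping(scale: HexascaleSpec, tonic_lattice_index: int) -> PitchMapping:
    """Place the sliding window at ``tonic_lattice_index`` (0-5).

    Degree ``d`` (1-6) is the lattice pitch ``index + d - 1``; degree 7 is
    degree 1 plus an octave, so consecutive-degree gaps are the rotated
    interval pattern and ``pitch(7) - pitch(1) == 12``.
    """
    problems = scale.validate()
    if problems:
        raise ValueError("invalid hexascale: " + "; ".join(problems))
    if not (0 <= tonic_lattice_index <= 5):
        raise ValueError(f"tonic lattice index {tonic_lattice_index} outside 0-5")
    pat = scale.interval_pattern
    offsets = np.concatenate([[0], np.cumsum(pat)])  # lattice pitch offsets, 0..12
    mapping = {}
    for d in range(1, 8):
        pos = tonic_lattice_index + (d - 1)
        octave, idx = divmod(pos, 6)
        mapping[d] = int(scale.anchor_pitch + 12 * octave + offsets[idx])
    return PitchMapping(tonic_lattice_index=tonic_lattice_index, degree_to_pitch=mapping)
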