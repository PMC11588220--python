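"""Standard MIDI file writing for isochronous single-track melodies.

Only the tiny subset of the SMF format these stimuli need is implemented:
a type-0 file with one track holding a tempo event, a program change, and
one note-on/note-off pair per melody note at a fixed inter-onset interval.
Output is byte-deterministic for identical inputs.  A matching reader
recovers (pitch, velocity, onset-tick, duration-tick) tuples for round-trip
verification.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

from .grammar import MelodyRecord
from .pitch import PitchMapping

__all__ = ["RenderConfig", "render_midi", "read_midi_notes"]

_TICKS_PER_QUARTER = 480


@dataclass(frozen=True)
class RenderConfig:
    """Timing, dynamics and instrument settings for rendering.

    The default is a 500 ms inter-onset interval with 450 ms sounding notes
    on a piano sound, base velocity 80 and an accent increment of 32 --
    clearly audible but below the MIDI velocity ceiling.
    """

    inter_onset_ms: int = 500
    duration_ms: int = 450
    velocity: int = 80
    accent_delta: int = 32
    program: int = 0  # acoustic grand piano
    channel: int = 0


def _var_len(value: int) -> bytes:
    """MIDI variable-length quantity encoding."""
    if value < 0:
        raise ValueError("negative delta time")
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(chunks))


def render_midi(rec: MelodyRecord, mapping: PitchMapping, cfg: RenderConfig | None = None) -> bytes:
    """Render a melody as type-0 SMF bytes.

    One note per degree, equal onsets and durations (the stimuli are
    isochronous); accented targets get velocity ``base + accent_delta``;
    agrammatical variants have the pitches of degrees 5 and 6 swapped at
    this stage.
    """
    cfg = cfg or RenderConfig()
    # with tempo fixed at 120 bpm one quarter note = 500 ms
    tempo_us = 500_000
    ticks_per_ms = _TICKS_PER_QUARTER / (tempo_us / 1000)
    ioi = round(cfg.inter_onset_ms * ticks_per_ms)
    dur = round(cfg.duration_ms * ticks_per_ms)
    if dur >= ioi:
        raise ValueError("note duration must be shorter than the inter-onset interval")

    accented = {t.position for t in rec.targets if t.accented}
    swap = rec.variant == "agrammatical"
    pitches = [mapping.pitch(d, agrammatical=swap) for d in rec.degrees]
    for p in pitches:
        if not (0 <= p <= 127):
            raise ValueError(f"pitch {p} outside MIDI range 0-127")

    track = bytearray()
    track += _var_len(0) + bytes([0xFF, 0x51, 0x03]) + struct.pack(">I", tempo_us)[1:]
    track += _var_len(0) + bytes([0xC0 | cfg.channel, cfg.program])
    for i, p in enumerate(pitches):
        vel = cfg.velocity + (cfg.accent_delta if i in accented else 0)
        if not (1 <= vel <= 127):
            raise ValueError(f"velocity {vel} outside MIDI range 1-127")
        gap = 0 if i == 0 else ioi - dur
        track += _var_len(gap) + bytes([0x90 | cfg.channel, p, vel])
        track += _var_len(dur) + bytes([0x80 | cfg.channel, p, 0])
    track += _var_len(0) + bytes([0xFF, 0x2F, 0x00])  # end of track

    header = b"MThd" + struct.pack(">IHHH", 6, 0, 1, _TICKS_PER_QUARTER)
    return bytes(header + b"MTrk" + struct.pack(">I", len(track)) + track)


def _read_var_len(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        b = data[pos]
        pos += 1
        value = (value << 7) | (b & 0x7F)
        if not (b & 0x80):
            return value, pos


def read_midi_notes(data: bytes) -> list[tuple[int, int, int, int]]:
    """Parse SMF bytes into (pitch, velocity, onset_ticks, duration_ticks).

    Supports exactly the event vocabulary :func:`render_midi` emits.
    """
    if data[:4] != b"MThd":
        raise ValueError("not a standard MIDI file")
    (hlen,) = struct.unpack(">I", data[4:8])
    pos = 8 + hlen
    if data[pos:pos + 4] != b"MTrk":
        raise ValueError("missing track chunk")
    (tlen,) = struct.unpack(">I", data[pos + 4:pos + 8])
    pos += 8
    end = pos + tlen
    time = 0
    open_notes: dict[int, tuple[int, int]] = {}
    notes = []
    while pos < end:
        delta, pos = _read_var_len(data, pos)
        time += delta
        status = data[pos]
        pos += 1
        if status == 0xFF:
            pos += 1  # meta type
            length, pos = _read_var_len(data, pos)
            pos += length
        elif status & 0xF0 == 0xC0:
            pos += 1
        elif status & 0xF0 == 0x90 and data[pos + 1] > 0:
            open_notes[data[pos]] = (data[pos + 1], time)
            pos += 2
        elif status & 0xF0 in (0x80, 0x90):
            pitch = data[pos]
            vel, onset = open_notes.pop(pitch)
            notes.append((pitch, vel, onset, time - onset))
            pos += 2
        else:
            raise ValueError(f"unsupported MIDI status byte 0x{status:02X}")
    notes.sort(key=lambda n: n[2])
    return notes
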