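"""Minimal Standard MIDI File (SMF) support: note-on events with velocities.

Covers what the pipeline needs from performance captures: reading note-on
times (ms) with key velocities from type 0/1 files, and writing a type-0
file.  Written files use division=2000 ticks/quarter with a 1 s/quarter
tempo, i.e. a 0.5 ms tick, so onset times round-trip to within 0.5 ms.

The finger assignment (1..5) is carried on the MIDI channel (channel =
finger - 1), a file-format convention of this package; channels above 4 map
to finger 0 (unknown).
"""

from __future__ import annotations

import struct

__all__ = ["read_note_ons", "write_note_ons", "TICKS_PER_QUARTER", "TEMPO_US"]

TICKS_PER_QUARTER = 2000
TEMPO_US = 1_000_000  # 1 s per quarter note -> 0.5 ms per tick


def _read_vlq(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        b = data[pos]
        pos += 1
        value = (value << 7) | (b & 0x7F)
        if not b & 0x80:
            return value, pos


def _write_vlq(value: int) -> bytes:
    if value < 0:
        raise ValueError("negative delta time")
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append((value & 0x7F) | 0x80)
        value >>= 7
    return bytes(reversed(chunks))


def read_note_ons(path) -> list[tuple[float, int, int, int]]:
    """Parse an SMF file; return [(onset_ms, pitch, velocity, channel), ...].

    Note-ons with velocity 0 (running-status note-offs) are ignored.  Tempo
    meta events are honored; multiple tracks (type 1) are merged on a common
    tick clock, assuming tempo changes live before the first note.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != b"MThd":
        raise ValueError(f"{path}: not a Standard MIDI File")
    hlen = struct.unpack(">I", data[4:8])[0]
    fmt, ntrk, division = struct.unpack(">HHH", data[8:14])
    if fmt not in (0, 1):
        raise ValueError(f"{path}: unsupported SMF type {fmt}")
    if division & 0x8000:
        raise ValueError(f"{path}: SMPTE time division not supported")
    pos = 8 + hlen
    tempo_us = 500_000  # SMF default
    tempo_map: list[tuple[int, int]] = []  # (tick, tempo)
    events: list[tuple[int, int, int, int]] = []  # (tick, pitch, vel, chan)
    for _ in range(ntrk):
        if data[pos : pos + 4] != b"MTrk":
            raise ValueError(f"{path}: malformed track chunk")
        tlen = struct.unpack(">I", data[pos + 4 : pos + 8])[0]
        p, end = pos + 8, pos + 8 + tlen
        tick = 0
        status = 0
        while p < end:
            delta, p = _read_vlq(data, p)
            tick += delta
            b = data[p]
            if b & 0x80:
                status = b
                p += 1
            if status == 0xFF:  # meta
                mtype = data[p]
                mlen, p2 = _read_vlq(data, p + 1)
                body = data[p2 : p2 + mlen]
                if mtype == 0x51:
                    tempo_map.append((tick, int.from_bytes(body, "big")))
                p = p2 + mlen
            elif status in (0xF0, 0xF7):  # sysex
                mlen, p2 = _read_vlq(data, p)
                p = p2 + mlen
            else:
                kind = status & 0xF0
                nargs = 1 if kind in (0xC0, 0xD0) else 2
                args = data[p : p + nargs]
                p += nargs
                if kind == 0x90 and args[1] > 0:
                    events.append((tick, args[0], args[1], status & 0x0F))
        pos = end
    tempo_map.sort()

    def tick_to_ms(t: int) -> float:
        ms, last_tick, tempo = 0.0, 0, 500_000
        for tt, tp in tempo_map:
            if tt >= t:
                break
            ms += (tt - last_tick) * tempo / (division * 1000.0)
            last_tick, tempo = tt, tp
        ms += (t - last_tick) * tempo / (division * 1000.0)
        return ms

    events.sort()
    return [(tick_to_ms(t), pitch, vel, chan) for t, pitch, vel, chan in events]


def write_note_ons(path, events) -> None:
    """Write [(onset_ms, pitch, velocity, channel), ...] as a type-0 SMF.

    Each note-on is paired with a note-off 80% of the way to the next onset
    (or 100 ms after the last), purely so players render something sensible.
    """
    evs = sorted(events)
    msgs: list[tuple[int, bytes]] = []  # (tick, raw message)
    ms_per_tick = TEMPO_US / (TICKS_PER_QUARTER * 1000.0)
    onsets = [e[0] for e in evs]
    for i, (ms, pitch, vel, chan) in enumerate(evs):
        if not 0 <= vel <= 127:
            raise ValueError(f"velocity {vel} outside 0..127")
        on_tick = round(ms / ms_per_tick)
        gap = (onsets[i + 1] - ms) * 0.8 if i + 1 < len(evs) else 100.0
        off_tick = on_tick + max(1, round(gap / ms_per_tick))
        msgs.append((on_tick, bytes([0x90 | chan, pitch, vel])))
        msgs.append((off_tick, bytes([0x80 | chan, pitch, 0])))
    msgs.sort(key=lambda m: m[0])
    body = bytearray()
    body += _write_vlq(0) + bytes([0xFF, 0x51, 0x03]) + TEMPO_US.to_bytes(3, "big")
    last = 0
    for tick, raw in msgs:
        body += _write_vlq(tick - last) + raw
        last = tick
    body += _write_vlq(0) + bytes([0xFF, 0x2F, 0x00])
    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, TICKS_PER_QUARTER))
        fh.write(b"MTrk" + struct.pack(">I", len(body)) + bytes(body))
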