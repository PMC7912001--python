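"""Synthetic tonal syllable trains at 48 kHz.

Each syllable is a pure tone at its fundamental frequency shaped by a
Tukey window (short onset/offset ramps, so energy is concentrated in
the stated interval without clicks).  Silence everywhere else.  The
ground-truth table carries onset, offset and f0 per syllable plus the
call grouping implied by the >25 ms gap rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import windows

#: gap (s) strictly above which two syllables belong to separate calls
CALL_GAP_S = 0.025


@dataclass(frozen=True)
class SyllablePlan:
    """List of (onset_s, duration_s, f0_hz, amplitude) syllables."""

    syllables: tuple = field(default=())
    sample_rate_hz: int = 48000
    duration_s: float | None = None  # total horizon; default: end of last syllable

    def __post_init__(self):
        prev_end = -np.inf
        prev_onset = -np.inf
        for onset, dur, f0, amp in self.syllables:
            if onset <= prev_onset:
                raise ValueError("syllable onsets must be strictly increasing")
            if onset < prev_end:
                raise ValueError(
                    f"syllable at {onset} s overlaps the previous one"
                )
            if dur <= 0:
                raise ValueError("syllable duration must be > 0")
            if not (0 < f0 < self.sample_rate_hz / 2):
                raise ValueError("f0 must lie inside the analysis band (0, fs/2)")
            prev_onset, prev_end = onset, onset + dur

    @property
    def horizon_s(self) -> float:
        if self.duration_s is not None:
            return self.duration_s
        if not self.syllables:
            return 1.0
        last = self.syllables[-1]
        return last[0] + last[1] + 0.1


def synthesise_audio(plan: SyllablePlan) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a plan to a float waveform in [-1, 1] plus its truth table.

    Returns ``(waveform, truth)`` where truth has columns
    ``onset_s, offset_s, f0_hz, amplitude, call_id``.
    """
    fs = plan.sample_rate_hz
    n = int(round(plan.horizon_s * fs))
    wave = np.zeros(n)
    rows = []
    for onset, dur, f0, amp in plan.syllables:
        i0 = int(round(onset * fs))
        i1 = min(int(round((onset + dur) * fs)), n)
        m = i1 - i0
        if m <= 0:
            continue
        t = np.arange(m) / fs
        ramp = min(0.005, dur / 4)  # 5 ms edge ramps
        env = windows.tukey(m, alpha=min(1.0, 2 * ramp / dur))
        wave[i0:i1] += amp * env * np.sin(2 * np.pi * f0 * t)
        rows.append({"onset_s": onset, "offset_s": onset + dur,
                     "f0_hz": f0, "amplitude": amp})
    truth = pd.DataFrame(rows, columns=["onset_s", "offset_s", "f0_hz", "amplitude"])
    call_id = []
    current = -1
    prev_off = None
    for _, r in truth.iterrows():
        if prev_off is None or r["onset_s"] - prev_off > CALL_GAP_S:
            current += 1
        call_id.append(current)
        prev_off = r["offset_s"]
    truth["call_id"] = call_id
    return wave, truth


def write_wav(path: str, waveform: np.ndarray, sample_rate_hz: int = 48000) -> None:
    """Write a float waveform as 16-bit PCM mono WAV."""
    scaled = np.clip(waveform, -1.0, 1.0)
    wavfile.write(path, sample_rate_hz, (scaled * 32767).astype(np.int16))


def read_wav(path: str) -> tuple[np.ndarray, int]:
    """Read a mono WAV to float waveform in [-1, 1] plus its sample rate."""
    fs, data = wavfile.read(path)
    if data.ndim > 1:
        raise ValueError("expected mono audio")
    if data.dtype == np.int16:
        data = data / 32768.0
    elif data.dtype == np.int32:
        data = data / 2147483648.0
    elif data.dtype == np.uint8:
        data = (data.astype(np.float64) - 128) / 128.0
    return np.asarray(data, dtype=np.float64), int(fs)
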