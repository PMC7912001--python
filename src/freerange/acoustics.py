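"""Spectrographic syllable measures of hen vocalisations.

Spectrograms use the bioacoustic settings of the study's measurement
protocol: 48-kHz audio, 1792-sample Hann window, 8192-sample DFT and a
200-sample hop, giving a 48000/8192 ~ 5.86 Hz frequency grid and
(1 - 200/1792) ~ 88.8% frame overlap.

Syllables are contiguous runs of frames whose in-band energy exceeds a
threshold; each syllable's fundamental band is the contiguous frequency
extent around its spectral peak.  Syllables separated by gaps of more
than 25 ms belong to separate calls.  Ten measures are taken per
syllable on the fundamental: the 5/25/50/75/95% energy-quantile
frequencies, their derived interquartile range and 90% bandwidth, the
peak frequency, and the frequency/time extents of the selection box.
Selection boxes can also be supplied externally (a Raven-style
selection table) and re-measured with the same math.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import ShortTimeFFT, windows


@dataclass(frozen=True)
class SpectrogramParams:
    """Short-time analysis settings (defaults: the study protocol)."""

    sample_rate_hz: int = 48000
    window_samples: int = 1792
    dft_size: int = 8192
    hop_samples: int = 200

    def __post_init__(self):
        if self.hop_samples > self.window_samples:
            raise ValueError("hop must not exceed the window length")
        if self.dft_size < self.window_samples:
            raise ValueError("DFT size must be >= window length")

    @property
    def freq_resolution_hz(self) -> float:
        """Frequency grid spacing (sample_rate / DFT size)."""
        return self.sample_rate_hz / self.dft_size

    @property
    def overlap_fraction(self) -> float:
        return 1.0 - self.hop_samples / self.window_samples


@dataclass
class Spectrogram:
    times_s: np.ndarray
    freqs_hz: np.ndarray
    power: np.ndarray      # shape (n_freqs, n_times), magnitude squared
    params: SpectrogramParams


@dataclass(frozen=True)
class Syllable:
    """A time-frequency selection on the fundamental of one sound."""

    onset_s: float
    offset_s: float
    f_low_hz: float
    f_high_hz: float

    def __post_init__(self):
        if self.offset_s <= self.onset_s:
            raise ValueError("offset must follow onset")
        if self.f_high_hz <= self.f_low_hz:
            raise ValueError("f_high must exceed f_low")


@dataclass
class Call:
    """A gap-grouped run of syllables (gaps <= 25 ms within a call)."""

    syllables: list

    @property
    def n_syllables(self) -> int:
        return len(self.syllables)

    @property
    def onset_s(self) -> float:
        return self.syllables[0].onset_s

    @property
    def offset_s(self) -> float:
        return self.syllables[-1].offset_s


@dataclass(frozen=True)
class SyllableMetrics:
    """The ten per-syllable spectral measures on the fundamental."""

    centre_freq_hz: float
    freq25_hz: float
    freq75_hz: float
    iqr_freq_hz: float
    freq5_hz: float
    freq95_hz: float
    bandwidth90_hz: float
    delta_freq_hz: float
    peak_freq_hz: float
    delta_time_s: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "centre_freq_hz", "freq25_hz", "freq75_hz", "iqr_freq_hz",
            "freq5_hz", "freq95_hz", "bandwidth90_hz", "delta_freq_hz",
            "peak_freq_hz", "delta_time_s")}


def compute_spectrogram(waveform: np.ndarray,
                        params: SpectrogramParams | None = None) -> Spectrogram:
    """Magnitude-squared short-time transform at the stated settings."""
    params = params or SpectrogramParams()
    x = np.asarray(waveform, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("expected mono waveform")
    if x.size < params.window_samples:
        raise ValueError(
            f"waveform shorter than one analysis window "
            f"({x.size} < {params.window_samples} samples)"
        )
    win = windows.hann(params.window_samples, sym=False)
    sft = ShortTimeFFT(win, hop=params.hop_samples,
                       fs=params.sample_rate_hz, mfft=params.dft_size)
    S = sft.stft(x)
    power = (S.real ** 2 + S.imag ** 2)
    times = sft.t(x.size)
    return Spectrogram(times_s=times, freqs_hz=sft.f, power=power, params=params)


def segment_syllables(spec: Spectrogram,
                      band_hz: tuple = (200.0, 2000.0),
                      energy_threshold: float | None = None,
                      band_rel_threshold: float = 0.1) -> list[Syllable]:
    """Threshold-based syllable segmentation within a frequency band.

    A frame is voiced when its summed in-band power exceeds
    ``energy_threshold`` (default: half the maximum in-band frame
    energy, so weak indistinct sounds fall below threshold and are not
    segmented).  Contiguous voiced frames form a syllable; its
    fundamental band is the contiguous extent of bins above
    ``band_rel_threshold`` x peak around the peak of the mean syllable
    spectrum.
    """
    flo, fhi = band_hz
    if flo < spec.freqs_hz[0] or fhi > spec.freqs_hz[-1]:
        raise ValueError("band outside spectrogram support")
    in_band = (spec.freqs_hz >= flo) & (spec.freqs_hz <= fhi)
    frame_energy = spec.power[in_band].sum(axis=0)
    if frame_energy.max() <= 0:
        return []
    thr = energy_threshold if energy_threshold is not None else 0.5 * frame_energy.max()
    voiced = frame_energy > thr
    syllables = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], voiced.view(np.int8), [0]))))
    band_freqs = spec.freqs_hz[in_band]
    for start, stop in zip(edges[::2], edges[1::2]):
        seg_spec = spec.power[in_band, start:stop].mean(axis=1)
        peak = int(np.argmax(seg_spec))
        keep = seg_spec >= band_rel_threshold * seg_spec[peak]
        lo = peak
        while lo > 0 and keep[lo - 1]:
            lo -= 1
        hi = peak
        while hi < keep.size - 1 and keep[hi + 1]:
            hi += 1
        syllables.append(
            Syllable(
                onset_s=float(spec.times_s[start]),
                offset_s=float(spec.times_s[stop - 1]
                               + spec.params.hop_samples / spec.params.sample_rate_hz),
                f_low_hz=float(band_freqs[lo]),
                f_high_hz=float(band_freqs[hi]),
            )
        )
    return syllables


def group_calls(syllables: list[Syllable], gap_ms: float = 25.0) -> list[Call]:
    """Chain syllables into calls; a gap strictly over 25 ms splits."""
    onsets = [s.onset_s for s in syllables]
    if onsets != sorted(onsets):
        raise ValueError("syllables must be time-sorted")
    calls: list[Call] = []
    for syl in syllables:
        if calls and (syl.onset_s - calls[-1].offset_s) * 1000.0 <= gap_ms:
            calls[-1].syllables.append(syl)
        else:
            calls.append(Call([syl]))
    return calls


def call_summary(calls: list[Call]) -> dict:
    """Per-test call counts: number of calls, syllables per call."""
    n_syll = [c.n_syllables for c in calls]
    return {
        "n_calls": len(calls),
        "n_syllables_total": int(sum(n_syll)),
        "mean_syllables_per_call": float(np.mean(n_syll)) if n_syll else 0.0,
    }


def syllable_metrics(syllable: Syllable, spec: Spectrogram,
                     use_db: bool = False) -> SyllableMetrics:
    """The ten spectral measures of one syllable selection.

    Energy per frequency bin is power summed over the syllable's frames
    within the fundamental band; the q% quantile frequency is the first
    bin where the cumulative energy reaches q% of the total (left-bin
    convention).  ``use_db`` switches the quantile weights to a dB
    scale (floored 60 dB below peak) instead of linear power.
    """
    t_in = (spec.times_s >= syllable.onset_s) & (spec.times_s <= syllable.offset_s)
    f_in = (spec.freqs_hz >= syllable.f_low_hz) & (spec.freqs_hz <= syllable.f_high_hz)
    if not t_in.any() or not f_in.any():
        raise ValueError("syllable box contains no spectrogram cells")
    box = spec.power[np.ix_(f_in, t_in)]
    energy = box.sum(axis=1)
    if energy.sum() <= 0:
        raise ValueError("zero energy inside the syllable box")
    if use_db:
        peak_power = energy.max()
        db = 10.0 * np.log10(np.maximum(energy, peak_power * 1e-6) / peak_power)
        weights = db + 60.0  # floor at 0
    else:
        weights = energy
    freqs = spec.freqs_hz[f_in]
    cum = np.cumsum(weights)
    total = cum[-1]

    def quantile(q: float) -> float:
        return float(freqs[int(np.searchsorted(cum, q * total))])

    f5, f25, f50, f75, f95 = (quantile(q) for q in (0.05, 0.25, 0.50, 0.75, 0.95))
    return SyllableMetrics(
        centre_freq_hz=f50,
        freq25_hz=f25,
        freq75_hz=f75,
        iqr_freq_hz=f75 - f25,
        freq5_hz=f5,
        freq95_hz=f95,
        bandwidth90_hz=f95 - f5,
        delta_freq_hz=syllable.f_high_hz - syllable.f_low_hz,
        peak_freq_hz=float(freqs[int(np.argmax(energy))]),
        delta_time_s=syllable.offset_s - syllable.onset_s,
    )


def measure_syllables(spec: Spectrogram, syllables: list[Syllable],
                      use_db: bool = False) -> pd.DataFrame:
    """Tabulate the ten measures for a list of syllables."""
    rows = []
    for syl in syllables:
        row = {"onset_s": syl.onset_s, "offset_s": syl.offset_s,
               "f_low_hz": syl.f_low_hz, "f_high_hz": syl.f_high_hz}
        row.update(syllable_metrics(syl, spec, use_db=use_db).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def read_selection_table(path: str) -> list[Syllable]:
    """Load externally drawn selection boxes (onset_s, offset_s, f_low_hz, f_high_hz)."""
    df = pd.read_csv(path)
    required = {"onset_s", "offset_s", "f_low_hz", "f_high_hz"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"selection table missing columns: {sorted(missing)}")
    return [
        Syllable(r.onset_s, r.offset_s, r.f_low_hz, r.f_high_hz)
        for r in df.itertuples()
    ]
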