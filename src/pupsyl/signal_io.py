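"""Audio input, syllable detection, spectrograms and contour extraction.

The analysis chain mirrors a standard bioacoustics workflow for ultrasonic
recordings: an amplitude envelope threshold marks syllables, a short-time
Fourier transform with a Hamming window provides the time-frequency image,
and the dominant frequency (magnitude argmax within the analysis band) is
read off at nine evenly spaced time points per syllable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import get_window

from . import features as _feat

__all__ = [
    "Recording",
    "SpectrogramParams",
    "Spectrogram",
    "SyllableSegment",
    "FrequencyContour",
    "read_wav",
    "write_wav",
    "detect_syllables",
    "compute_spectrogram",
    "extract_contour",
    "process_recording",
]


@dataclass
class Recording:
    """A mono recording with samples normalized to ``[-1, 1]``."""

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Recording.samples must be one-dimensional")
        if self.samples.size == 0:
            raise ValueError("Recording.samples must be non-empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Recording.samples contain non-finite values")
        if int(self.sample_rate) <= 0:
            raise ValueError("sample_rate must be a positive integer")
        self.sample_rate = int(self.sample_rate)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class SpectrogramParams:
    """Short-time Fourier transform settings.

    Defaults correspond to a 1024-point Hamming-windowed FFT with 98.43 %
    overlap (16-sample hop at 500 kHz) and an analysis band of 40-130 kHz.
    """

    window: str = "hamming"
    fft_length: int = 1024
    overlap_fraction: float = 0.9843
    freq_min_khz: float = 40.0
    freq_max_khz: float = 130.0

    def __post_init__(self) -> None:
        n = self.fft_length
        if n < 16 or (n & (n - 1)) != 0:
            raise ValueError("fft_length must be a power of two >= 16")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if not self.freq_min_khz < self.freq_max_khz:
            raise ValueError("freq_min_khz must be below freq_max_khz")

    @property
    def hop(self) -> int:
        """Hop length in samples (at least 1)."""
        return max(1, round(self.fft_length * (1.0 - self.overlap_fraction)))


@dataclass
class Spectrogram:
    """Linear-magnitude time-frequency matrix restricted to the analysis band."""

    magnitudes: np.ndarray  # shape (n_frames, n_bins)
    frame_times: np.ndarray  # seconds, frame centers
    bin_freqs_khz: np.ndarray  # kHz, strictly increasing


@dataclass(frozen=True)
class SyllableSegment:
    """A detected interval of vocal energy."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("segment end must be after start")

    @property
    def duration_ms(self) -> float:
        return 1000.0 * (self.end_s - self.start_s)


@dataclass(frozen=True)
class FrequencyContour:
    """Nine-point dominant-frequency track of one syllable, kHz."""

    raw_khz: np.ndarray
    filtered_khz: np.ndarray


def read_wav(path: str | Path, source_id: str | None = None) -> Recording:
    """Read a PCM or float WAV file into a normalized mono :class:`Recording`.

    Integer PCM is scaled by its full-scale value; for multichannel files the
    first channel is taken with a warning.
    """
    path = Path(path)
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        warnings.warn(f"{path.name}: multichannel WAV, taking first channel", stacklevel=2)
        data = data[:, 0]
    if data.dtype.kind == "i":
        scale = float(np.iinfo(data.dtype).max) + 1.0
        samples = data.astype(float) / scale
    elif data.dtype.kind == "u":  # 8-bit WAV is unsigned
        info = np.iinfo(data.dtype)
        samples = (data.astype(float) - (info.max + 1) / 2.0) / ((info.max + 1) / 2.0)
    else:
        samples = data.astype(float)
    return Recording(samples, rate, source_id=source_id or path.stem)


def write_wav(path: str | Path, rec: Recording) -> None:
    """Write a recording as 16-bit PCM WAV."""
    clipped = np.clip(rec.samples, -1.0, 1.0)
    wavfile.write(Path(path), rec.sample_rate, (clipped * 32767).astype(np.int16))


def _frame_rms(samples: np.ndarray, frame_len: int) -> np.ndarray:
    n_frames = samples.size // frame_len
    if n_frames == 0:
        return np.empty(0)
    trimmed = samples[: n_frames * frame_len]
    frames = trimmed.reshape(n_frames, frame_len)
    return np.sqrt(np.mean(frames**2, axis=1))


def detect_syllables(
    rec: Recording,
    threshold_db: float = 10.0,
    hold_ms: float = 5.0,
    frame_ms: float = 0.5,
    noise_percentile: float = 50.0,
) -> list[SyllableSegment]:
    """Detect syllables as supra-threshold runs of the short-time envelope.

    The envelope is the RMS of consecutive non-overlapping ``frame_ms``
    frames.  The noise floor is the ``noise_percentile``-th percentile of
    the frame RMS (the median by default, robust when vocal activity is
    sparse; lower it for recordings that are mostly voiced) and a frame is
    active when its RMS exceeds the floor by more than ``threshold_db``.  Active runs separated by a sub-threshold
    gap shorter than ``hold_ms`` are merged, accommodating brief
    low-intensity stretches inside a syllable.  No minimum syllable duration
    is enforced.

    Returns segments sorted by start time; an empty list for silent input.
    """
    if threshold_db <= 0:
        raise ValueError("threshold_db must be positive")
    if hold_ms < 0:
        raise ValueError("hold_ms must be non-negative")
    frame_len = max(1, round(frame_ms * 1e-3 * rec.sample_rate))
    rms = _frame_rms(rec.samples, frame_len)
    if rms.size == 0:
        return []
    noise_floor = float(np.percentile(rms, noise_percentile))
    threshold = noise_floor * 10.0 ** (threshold_db / 20.0)
    active = rms > threshold
    if not active.any():
        return []

    # Runs of active frames.
    padded = np.concatenate([[False], active, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]  # frame indices, end exclusive

    # Merge runs separated by gaps shorter than hold_ms.
    frame_s = frame_len / rec.sample_rate
    hold_frames = hold_ms * 1e-3 / frame_s
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < hold_frames:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    return [SyllableSegment(s * frame_s, e * frame_s) for s, e in merged]


def compute_spectrogram(
    rec: Recording,
    params: SpectrogramParams | None = None,
    _chunk_frames: int = 4096,
) -> Spectrogram:
    """Compute a linear-magnitude spectrogram restricted to the analysis band.

    Frames start every ``hop = round(fft_length * (1 - overlap_fraction))``
    samples (at least 1); frame ``i`` covers samples ``[i*hop, i*hop +
    fft_length)`` and its timestamp is the frame center.  The frequency axis
    is truncated to ``[freq_min_khz, freq_max_khz]``.
    """
    params = params or SpectrogramParams()
    n = rec.samples.size
    if n < params.fft_length:
        raise ValueError(
            f"recording has {n} samples but at least fft_length = "
            f"{params.fft_length} are required"
        )
    hop = params.hop
    n_frames = (n - params.fft_length) // hop + 1
    win = get_window(params.window, params.fft_length, fftbins=True)
    freqs_khz = np.fft.rfftfreq(params.fft_length, 1.0 / rec.sample_rate) / 1000.0
    band = (freqs_khz >= params.freq_min_khz) & (freqs_khz <= params.freq_max_khz)
    if not band.any():
        raise ValueError("analysis band contains no FFT bins at this sample rate")

    view = np.lib.stride_tricks.sliding_window_view(rec.samples, params.fft_length)[::hop]
    mags = np.empty((n_frames, int(band.sum())))
    for i0 in range(0, n_frames, _chunk_frames):  # chunked to bound memory
        chunk = view[i0 : i0 + _chunk_frames]
        spec = np.abs(np.fft.rfft(chunk * win, axis=1))
        mags[i0 : i0 + chunk.shape[0]] = spec[:, band]
    frame_times = (np.arange(n_frames) * hop + params.fft_length / 2.0) / rec.sample_rate
    return Spectrogram(mags, frame_times, freqs_khz[band])


def _measurement_times(seg: SyllableSegment, n_points: int, placement: str) -> np.ndarray:
    dur = seg.end_s - seg.start_s
    if placement == "midpoint":
        return seg.start_s + (np.arange(n_points) + 0.5) / n_points * dur
    if placement == "endpoint":
        return seg.start_s + np.arange(n_points) / (n_points - 1) * dur
    raise ValueError(f"unknown placement {placement!r}")


def extract_contour(
    spec: Spectrogram,
    seg: SyllableSegment,
    n_points: int = _feat.N_CONTOUR_POINTS,
    placement: str = "midpoint",
    band_low_khz: float = _feat.BAND_LOW_KHZ,
    band_high_khz: float = _feat.BAND_HIGH_KHZ,
) -> FrequencyContour:
    """Extract the dominant-frequency contour of one syllable.

    Measurement times are placed at the interior midpoints
    ``start + (i + 0.5)/n * duration`` (``placement='midpoint'``, the
    default, which avoids the low-amplitude onset/offset frames) or at
    endpoint-inclusive positions ``start + i/(n-1) * duration``
    (``placement='endpoint'``).  Each raw value is the bin frequency of the
    magnitude argmax in the frame whose center is nearest the measurement
    time (ties broken toward the lower frequency).  The filtered contour
    applies the band replacement rule of
    :func:`pupsyl.features.bandpass_replace`.

    Raises
    ------
    ValueError
        If the segment lies outside the spectrogram's time span, or is
        shorter than one frame hop.
    AllOutOfBandError
        If every raw value is out of band (propagated from the filter).
    """
    times = spec.frame_times
    frame_dt = times[1] - times[0] if times.size > 1 else 0.0
    # The first frame center sits half a window into the recording; allow a
    # full window of margin so segments touching the recording edges pass.
    margin = 2.0 * times[0] + frame_dt
    if seg.start_s < times[0] - margin or seg.end_s > times[-1] + margin:
        raise ValueError(
            f"segment [{seg.start_s:.4f}, {seg.end_s:.4f}] s lies outside the "
            f"spectrogram span [{times[0]:.4f}, {times[-1]:.4f}] s"
        )
    if frame_dt > 0 and (seg.end_s - seg.start_s) < frame_dt:
        raise ValueError(
            "segment is shorter than one spectrogram frame hop "
            f"({frame_dt * 1e3:.3f} ms); recompute with a smaller hop "
            "(higher overlap_fraction)"
        )
    tm = _measurement_times(seg, n_points, placement)
    idx = np.clip(np.searchsorted(times, tm), 1, times.size - 1)
    nearest = np.where(tm - times[idx - 1] <= times[idx] - tm, idx - 1, idx)
    # np.argmax returns the first maximum: the lower-frequency bin on ties.
    raw = spec.bin_freqs_khz[np.argmax(spec.magnitudes[nearest], axis=1)]
    filtered = _feat.bandpass_replace(raw, low=band_low_khz, high=band_high_khz)
    return FrequencyContour(raw_khz=raw, filtered_khz=filtered)


def process_recording(
    rec: Recording,
    params: SpectrogramParams | None = None,
    threshold_db: float = 10.0,
    hold_ms: float = 5.0,
    placement: str = "midpoint",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detect syllables and extract contours from one recording.

    Returns ``(segments, contours)`` tables.  ``segments`` has columns
    ``source_id, start_s, end_s, duration_ms``; ``contours`` follows the
    interchange layout ``source_id, syllable_index, duration_ms, f1..f9,
    f1_raw..f9_raw`` with one row per detected syllable.  Syllables whose
    contour is entirely out of band are dropped with a warning.
    """
    params = params or SpectrogramParams()
    segments = detect_syllables(rec, threshold_db=threshold_db, hold_ms=hold_ms)
    seg_rows = [
        {
            "source_id": rec.source_id,
            "start_s": s.start_s,
            "end_s": s.end_s,
            "duration_ms": s.duration_ms,
        }
        for s in segments
    ]
    seg_df = pd.DataFrame(seg_rows, columns=["source_id", "start_s", "end_s", "duration_ms"])

    contour_rows = []
    if segments:
        spec = compute_spectrogram(rec, params)
        for i, seg in enumerate(segments):
            try:
                contour = extract_contour(spec, seg, placement=placement)
            except _feat.AllOutOfBandError:
                warnings.warn(
                    f"{rec.source_id}: syllable {i} entirely out of band, skipped",
                    stacklevel=2,
                )
                continue
            except ValueError as exc:
                warnings.warn(f"{rec.source_id}: syllable {i} skipped ({exc})", stacklevel=2)
                continue
            row: dict[str, object] = {
                "source_id": rec.source_id,
                "syllable_index": i,
                "duration_ms": seg.duration_ms,
            }
            row.update(zip(_feat.CONTOUR_COLUMNS, contour.filtered_khz))
            row.update(zip(_feat.RAW_CONTOUR_COLUMNS, contour.raw_khz))
            contour_rows.append(row)
    contour_df = pd.DataFrame(
        contour_rows,
        columns=["source_id", "syllable_index", "duration_ms"]
        + _feat.CONTOUR_COLUMNS
        + _feat.RAW_CONTOUR_COLUMNS,
    )
    return seg_df, contour_df
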