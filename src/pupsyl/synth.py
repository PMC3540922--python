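"""Synthetic syllable repertoires with known ground truth.

Generates nine-point contour tables (and optionally audio) whose
statistical structure matches what is observed in mouse pup isolation
calls: two frequency bands for non-stepped syllables, a bimodal
distribution of adjacent-point transitions once stepped syllables are
included, a one-step category that transitions upward toward the end of the
syllable, and a multi-step category with two discontinuous jumps.  The
generator parameters are chosen so that truth labels are unambiguous with
respect to the 20 kHz step criterion: smooth within-contour transitions are
capped strictly below the threshold while step magnitudes are floored
strictly above it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import features as _feat
from .signal_io import Recording

__all__ = ["RepertoireSpec", "generate_repertoire", "synthesize_audio", "DEFAULT_SPEC"]

#: Bounds for random-walk contours, keeping every value inside the analysis
#: band and leaving headroom for a >= 25 kHz jump from the low band.
_LOW_WALK_RANGE = (45.0, 95.0)
_HIGH_WALK_RANGE = (85.0, 125.0)


@dataclass(frozen=True)
class RepertoireSpec:
    """Parameters of a synthetic repertoire.

    ``category_mix`` gives proportions over the four syllable categories and
    must sum to 1.  ``smooth_sd_range`` is the per-syllable range of the
    standard deviation of smooth adjacent-point transitions (drawing the
    scale per syllable yields the leptokurtic, unimodal directional-FM
    distribution seen in real non-stepped syllables); individual smooth
    deltas are capped at ``smooth_cap_khz`` which must stay below the
    20 kHz step criterion.  Step magnitudes are N(mean, sd) floored at
    ``step_floor_khz`` which must exceed the criterion.
    """

    n_syllables: int = 4000
    category_mix: dict = field(
        default_factory=lambda: {
            "low": 0.25,
            "high": 0.25,
            "one_step": 0.25,
            "multi_step": 0.25,
        }
    )
    low_band_mean_khz: float = 70.0
    low_band_sd_khz: float = 4.0
    high_band_mean_khz: float = 100.0
    high_band_sd_khz: float = 5.0
    smooth_sd_range: tuple[float, float] = (0.5, 4.0)
    smooth_cap_khz: float = 15.0
    step_mean_khz: float = 40.0
    step_sd_khz: float = 8.0
    step_floor_khz: float = 25.0
    duration_ms_range: tuple[float, float] = (20.0, 120.0)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_mix must sum to 1, got {total}")
        unknown = set(self.category_mix) - {"low", "high", "one_step", "multi_step"}
        if unknown:
            raise ValueError(f"unknown categories in mix: {sorted(unknown)}")
        if any(p < 0 for p in self.category_mix.values()):
            raise ValueError("category_mix proportions must be non-negative")
        if self.smooth_cap_khz >= _feat.STEP_THRESHOLD_KHZ:
            raise ValueError("smooth_cap_khz must stay below the 20 kHz step criterion")
        if self.step_floor_khz <= _feat.STEP_THRESHOLD_KHZ:
            raise ValueError("step_floor_khz must exceed the 20 kHz step criterion")
        if self.n_syllables < 1:
            raise ValueError("n_syllables must be positive")


DEFAULT_SPEC = RepertoireSpec()


def _smooth_walk(
    rng: np.random.Generator,
    start: float,
    n_deltas: int,
    sd: float,
    cap: float,
    bounds: tuple[float, float],
) -> np.ndarray:
    """Random walk with capped increments, clipped into ``bounds``."""
    values = [start]
    for _ in range(n_deltas):
        d = np.clip(rng.normal(0.0, sd), -cap, cap)
        values.append(float(np.clip(values[-1] + d, bounds[0], bounds[1])))
    return np.asarray(values)


def _one_syllable(rng: np.random.Generator, category: str, spec: RepertoireSpec) -> np.ndarray:
    sd = rng.uniform(*spec.smooth_sd_range)
    cap = spec.smooth_cap_khz
    if category in ("low", "high"):
        if category == "low":
            start = rng.normal(spec.low_band_mean_khz, spec.low_band_sd_khz)
            band = _LOW_WALK_RANGE
        else:
            start = rng.normal(spec.high_band_mean_khz, spec.high_band_sd_khz)
            band = _HIGH_WALK_RANGE
        start = float(np.clip(start, band[0], band[1]))
        return _smooth_walk(rng, start, 8, sd, cap, band)

    low_start = float(
        np.clip(rng.normal(spec.low_band_mean_khz, spec.low_band_sd_khz), *_LOW_WALK_RANGE)
    )
    if category == "one_step":
        # Upward jump toward the end of the syllable (transition index 4-7),
        # so start and middle stay in the low band.
        jump_at = int(rng.integers(4, 8))
        head = _smooth_walk(rng, low_start, jump_at, sd, cap, _LOW_WALK_RANGE)
        mag = float(np.clip(rng.normal(spec.step_mean_khz, spec.step_sd_khz),
                            spec.step_floor_khz, _HIGH_WALK_RANGE[1] - head[-1]))
        after = float(head[-1] + mag)
        tail = _smooth_walk(rng, after, 8 - jump_at - 1, sd, cap, _HIGH_WALK_RANGE)
        return np.concatenate([head, tail])
    if category == "multi_step":
        # Up early (transition 0-2), down late (transition 5-7): the middle
        # point sits in the high band, start and end in the low band.
        up_at = int(rng.integers(0, 3))
        down_at = int(rng.integers(5, 8))
        head = _smooth_walk(rng, low_start, up_at, sd, cap, _LOW_WALK_RANGE)
        up_mag = float(np.clip(rng.normal(spec.step_mean_khz, spec.step_sd_khz),
                               spec.step_floor_khz, _HIGH_WALK_RANGE[1] - head[-1]))
        mid = _smooth_walk(rng, head[-1] + up_mag, down_at - up_at - 1, sd, cap, _HIGH_WALK_RANGE)
        down_mag = float(np.clip(rng.normal(spec.step_mean_khz, spec.step_sd_khz),
                                 spec.step_floor_khz, mid[-1] - _LOW_WALK_RANGE[0]))
        tail = _smooth_walk(rng, mid[-1] - down_mag, 8 - down_at - 1, sd, cap, _LOW_WALK_RANGE)
        return np.concatenate([head, mid, tail])
    raise ValueError(f"unknown category {category!r}")


def generate_repertoire(spec: RepertoireSpec | None = None, **overrides) -> pd.DataFrame:
    """Generate a synthetic contour table with truth labels.

    Returns a DataFrame in the contour interchange layout (``source_id,
    syllable_index, duration_ms, f1..f9, f1_raw..f9_raw``) plus a
    ``true_label`` column.  All generated contours are in band, so the
    filtered and raw contours are identical.  Output is reproducible per
    seed (byte-identical CSV for identical spec).
    """
    spec = replace(spec or DEFAULT_SPEC, **overrides) if overrides else (spec or DEFAULT_SPEC)
    rng = np.random.default_rng(spec.seed)
    cats = sorted(spec.category_mix)
    probs = np.array([spec.category_mix[c] for c in cats])
    drawn = rng.choice(len(cats), size=spec.n_syllables, p=probs)
    rows = []
    for i, ci in enumerate(drawn):
        category = cats[int(ci)]
        contour = _one_syllable(rng, category, spec)
        duration = float(rng.uniform(*spec.duration_ms_range))
        row: dict[str, object] = {
            "source_id": f"synthetic_seed{spec.seed}",
            "syllable_index": i,
            "duration_ms": round(duration, 3),
            "true_label": category,
        }
        contour = np.round(contour, 4)
        row.update(zip(_feat.CONTOUR_COLUMNS, contour))
        row.update(zip(_feat.RAW_CONTOUR_COLUMNS, contour))
        rows.append(row)
    cols = (
        ["source_id", "syllable_index", "duration_ms"]
        + _feat.CONTOUR_COLUMNS
        + _feat.RAW_CONTOUR_COLUMNS
        + ["true_label"]
    )
    return pd.DataFrame(rows)[cols]


def synthesize_audio(
    contour: np.ndarray,
    duration_ms: float,
    sample_rate: int = 500_000,
    amplitude: float = 0.5,
    ramp_ms: float = 5.0,
    pad_ms: float | None = None,
    step_threshold_khz: float = _feat.STEP_THRESHOLD_KHZ,
    source_id: str = "synthetic",
) -> Recording:
    """Render a nine-point contour as a frequency-modulated tone burst.

    Instantaneous frequency is piecewise linear through the contour points
    within jump-free spans and switches discontinuously midway between the
    two measurement points of any transition larger than
    ``step_threshold_khz`` (a true spectro-temporal discontinuity, not a
    glide).  The phase is integrated cumulatively so instantaneous frequency
    is exact; amplitude has ``ramp_ms`` linear onset/offset ramps, and the
    burst is embedded in ``pad_ms`` of silence on both sides (default: the
    larger of 25 ms and 1.25x the syllable duration, which keeps the voiced
    fraction below half so a median-based noise floor stays on the silence).
    """
    if pad_ms is None:
        pad_ms = max(25.0, 1.25 * duration_ms)
    contour = np.asarray(contour, dtype=float)
    if contour.shape != (_feat.N_CONTOUR_POINTS,):
        raise ValueError(f"contour must have {_feat.N_CONTOUR_POINTS} points")
    if contour.min() < _feat.BAND_LOW_KHZ or contour.max() > _feat.BAND_HIGH_KHZ:
        raise ValueError(
            f"contour must lie within [{_feat.BAND_LOW_KHZ}, {_feat.BAND_HIGH_KHZ}] kHz"
        )
    dur_s = duration_ms * 1e-3
    n = max(1, round(dur_s * sample_rate))
    t = np.arange(n) / sample_rate
    # Measurement times at interior midpoints, matching contour extraction.
    tm = (np.arange(_feat.N_CONTOUR_POINTS) + 0.5) / _feat.N_CONTOUR_POINTS * dur_s

    freq = np.empty(n)
    deltas = np.diff(contour)
    jumps = np.abs(deltas) > step_threshold_khz
    freq[t < tm[0]] = contour[0]
    freq[t >= tm[-1]] = contour[-1]
    for i in range(len(deltas)):
        mask = (t >= tm[i]) & (t < tm[i + 1])
        if not mask.any():
            continue
        if jumps[i]:
            switch = 0.5 * (tm[i] + tm[i + 1])
            freq[mask] = np.where(t[mask] < switch, contour[i], contour[i + 1])
        else:
            frac = (t[mask] - tm[i]) / (tm[i + 1] - tm[i])
            freq[mask] = contour[i] + frac * deltas[i]

    phase = 2.0 * np.pi * np.cumsum(freq * 1000.0) / sample_rate
    sig = amplitude * np.sin(phase)
    ramp_n = min(n // 2, max(1, round(ramp_ms * 1e-3 * sample_rate)))
    env = np.ones(n)
    env[:ramp_n] = np.linspace(0.0, 1.0, ramp_n, endpoint=False)
    env[n - ramp_n :] = np.linspace(1.0, 0.0, ramp_n)
    pad = np.zeros(max(1, round(pad_ms * 1e-3 * sample_rate)))
    samples = np.concatenate([pad, sig * env, pad])
    return Recording(samples, sample_rate, source_id=source_id)
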