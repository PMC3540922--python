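"""Per-syllable derived quantities and distribution diagnostics.

A syllable is represented downstream of spectral analysis by its nine-point
dominant-frequency contour (kHz).  This module turns a contour into the
handful of scalar features consumed by the classifier and the clustering
stage (start / middle / end / mean frequency, bandwidth, step count,
directional frequency modulation), and provides the moment-based bimodality
coefficient used to justify every classification boundary, plus a histogram
helper that proposes a boundary between two frequency bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig
from scipy import stats as _stats

#: Analysis band limits applied to raw contour values, kHz.
BAND_LOW_KHZ = 41.0
BAND_HIGH_KHZ = 129.0

#: Adjacent-point frequency transition above which a contour is considered
#: discontinuous ("frequency step"), kHz.
STEP_THRESHOLD_KHZ = 20.0

#: Number of measurement points per contour.
N_CONTOUR_POINTS = 9

#: Reference value of the bimodality coefficient for a uniform distribution;
#: values above it indicate departure from unimodality.
BIMODALITY_REFERENCE = 5.0 / 9.0


class AllOutOfBandError(ValueError):
    """Every contour value falls outside the analysis band.

    Such a syllable carries no usable frequency information and must be
    flagged and excluded downstream rather than silently repaired.
    """


def bandpass_replace(
    raw: Sequence[float],
    low: float = BAND_LOW_KHZ,
    high: float = BAND_HIGH_KHZ,
) -> np.ndarray:
    """Replace out-of-band contour values with the previous in-band value.

    Values outside ``[low, high]`` kHz are treated as spurious measurements
    (typically taken during low-amplitude portions of a syllable) and are
    replaced by the nearest preceding value that is in band or has already
    been replaced.  A leading run of out-of-band values is back-filled from
    the first in-band value, so the output never contains an out-of-band
    frequency.  The operation is idempotent.

    Parameters
    ----------
    raw : sequence of float
        Exactly nine contour values, kHz.
    low, high : float
        Band limits, kHz.

    Returns
    -------
    numpy.ndarray
        Nine filtered values, all within ``[low, high]``.

    Raises
    ------
    AllOutOfBandError
        If no value lies within the band.
    ValueError
        If the input does not have exactly nine finite values.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.shape != (N_CONTOUR_POINTS,):
        raise ValueError(
            f"contour must have exactly {N_CONTOUR_POINTS} values, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("contour contains non-finite values")
    in_band = (arr >= low) & (arr <= high)
    if not in_band.any():
        raise AllOutOfBandError(
            f"all {N_CONTOUR_POINTS} contour values outside [{low}, {high}] kHz"
        )
    out = arr.copy()
    first = int(np.argmax(in_band))
    out[:first] = arr[first]  # back-fill the leading out-of-band run
    for i in range(first + 1, N_CONTOUR_POINTS):
        if not in_band[i]:
            out[i] = out[i - 1]
    return out


def transitions(contour: Sequence[float]) -> np.ndarray:
    """Signed adjacent-point frequency deltas of a nine-point contour (8 values)."""
    arr = np.asarray(contour, dtype=float)
    if arr.shape != (N_CONTOUR_POINTS,):
        raise ValueError(f"contour must have {N_CONTOUR_POINTS} points")
    return np.diff(arr)


def count_steps(
    contour: Sequence[float],
    step_threshold_khz: float = STEP_THRESHOLD_KHZ,
    inclusive: bool = False,
) -> int:
    """Count discontinuous frequency steps in a contour.

    A step is an adjacent-point transition whose magnitude strictly exceeds
    ``step_threshold_khz`` (set ``inclusive=True`` to count transitions equal
    to the threshold as well).
    """
    deltas = np.abs(transitions(contour))
    if not np.all(np.isfinite(deltas)):
        raise ValueError("contour contains non-finite values")
    if inclusive:
        return int(np.count_nonzero(deltas >= step_threshold_khz))
    return int(np.count_nonzero(deltas > step_threshold_khz))


@dataclass(frozen=True)
class SyllableFeatures:
    """Scalar features of one syllable, derived from its filtered contour."""

    start_khz: float
    middle_khz: float
    end_khz: float
    mean_khz: float
    bandwidth_khz: float
    n_steps: int
    duration_ms: float
    directional_fm_khz: float


def summarize(
    filtered_contour: Sequence[float],
    duration_ms: float,
    step_threshold_khz: float = STEP_THRESHOLD_KHZ,
) -> SyllableFeatures:
    """Derive :class:`SyllableFeatures` from a filtered nine-point contour.

    ``start``/``middle``/``end`` are contour points 1, 5 and 9; ``mean`` and
    ``bandwidth`` are computed over all nine points; the step count uses the
    filtered contour so that spurious out-of-band excursions never register
    as steps.
    """
    arr = np.asarray(filtered_contour, dtype=float)
    if arr.shape != (N_CONTOUR_POINTS,):
        raise ValueError(f"contour must have {N_CONTOUR_POINTS} points")
    if not np.all(np.isfinite(arr)):
        raise ValueError("contour contains non-finite values")
    return SyllableFeatures(
        start_khz=float(arr[0]),
        middle_khz=float(arr[4]),
        end_khz=float(arr[8]),
        mean_khz=float(arr.mean()),
        bandwidth_khz=float(arr.max() - arr.min()),
        n_steps=count_steps(arr, step_threshold_khz),
        duration_ms=float(duration_ms),
        directional_fm_khz=float(arr[8] - arr[0]),
    )


# ---------------------------------------------------------------------------
# Contour-table plumbing

CONTOUR_COLUMNS = [f"f{i}" for i in range(1, 10)]
RAW_CONTOUR_COLUMNS = [f"f{i}_raw" for i in range(1, 10)]

FEATURE_COLUMNS = [
    "start_khz",
    "middle_khz",
    "end_khz",
    "mean_khz",
    "bandwidth_khz",
    "n_steps",
    "duration_ms",
    "directional_fm_khz",
]


def features_from_table(
    contours: pd.DataFrame,
    step_threshold_khz: float = STEP_THRESHOLD_KHZ,
    low: float = BAND_LOW_KHZ,
    high: float = BAND_HIGH_KHZ,
) -> pd.DataFrame:
    """Build a features table from a contour table.

    The contour table must carry columns ``f1..f9`` (filtered values are
    accepted as-is when already in band; otherwise the band-replacement rule
    is applied).  Rows whose nine values are all out of band are kept but
    flagged ``valid == False`` with NaN features, so that downstream callers
    can report rather than silently drop them.

    Returns a copy of the identifying columns plus the feature columns and a
    boolean ``valid`` column.
    """
    missing = [c for c in CONTOUR_COLUMNS if c not in contours.columns]
    if missing:
        raise ValueError(f"contour table is missing columns: {missing}")
    if "duration_ms" not in contours.columns:
        raise ValueError("contour table is missing column: duration_ms")

    id_cols = [c for c in ("source_id", "syllable_index", "true_label") if c in contours.columns]
    rows = []
    n_invalid = 0
    for _, row in contours.iterrows():
        raw = row[CONTOUR_COLUMNS].to_numpy(dtype=float)
        rec = {c: row[c] for c in id_cols}
        rec["duration_ms"] = float(row["duration_ms"])
        try:
            filt = bandpass_replace(raw, low=low, high=high)
        except AllOutOfBandError:
            n_invalid += 1
            rec.update({c: np.nan for c in FEATURE_COLUMNS if c != "duration_ms"})
            rec["valid"] = False
            rows.append(rec)
            continue
        feats = summarize(filt, row["duration_ms"], step_threshold_khz)
        rec.update(
            start_khz=feats.start_khz,
            middle_khz=feats.middle_khz,
            end_khz=feats.end_khz,
            mean_khz=feats.mean_khz,
            bandwidth_khz=feats.bandwidth_khz,
            n_steps=feats.n_steps,
            directional_fm_khz=feats.directional_fm_khz,
            valid=True,
        )
        rows.append(rec)
    if n_invalid:
        warnings.warn(
            f"{n_invalid} syllable(s) had all nine contour values out of band "
            f"[{low}, {high}] kHz and were flagged invalid",
            stacklevel=2,
        )
    out = pd.DataFrame(rows)
    return out[id_cols + FEATURE_COLUMNS + ["valid"]]


# ---------------------------------------------------------------------------
# Bimodality machinery


@dataclass(frozen=True)
class BimodalityResult:
    """Sample bimodality coefficient together with its ingredients."""

    b: float
    skewness: float
    kurtosis: float
    n: int


def bimodality_coefficient(samples: Sequence[float]) -> BimodalityResult:
    """Moment-based bimodality coefficient of a sample.

    Computed as ``b = (g1^2 + 1) / (g2 + 3 (n-1)^2 / ((n-2)(n-3)))`` where
    ``g1`` is the bias-corrected sample skewness and ``g2`` the
    bias-corrected sample excess kurtosis.  In the large-sample limit a
    uniform distribution gives 5/9 (~0.556) and a normal distribution 1/3;
    values above 5/9 indicate more than one mode.

    Raises
    ------
    ValueError
        If fewer than four samples, non-finite values, or zero variance.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    n = x.size
    if n < 4:
        raise ValueError(f"bimodality coefficient requires n >= 4, got n = {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples contain non-finite values")
    if np.var(x) == 0.0:
        raise ValueError("samples have zero variance")
    g1 = float(_stats.skew(x, bias=False))
    g2 = float(_stats.kurtosis(x, fisher=True, bias=False))
    corr = 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    b = (g1**2 + 1.0) / (g2 + corr)
    return BimodalityResult(b=float(b), skewness=g1, kurtosis=g2, n=n)


@dataclass(frozen=True)
class BoundarySuggestion:
    """Outcome of a data-driven boundary search between two modes."""

    boundary_khz: float | None
    bin_edges: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    peak_centers: tuple[float, float] | None
    bimodality: BimodalityResult
    warning: str | None = None


def suggest_boundary(
    values: Sequence[float],
    mode: str = "midway_peaks",
    bin_khz: float = 2.0,
    min_peak_separation_bins: int = 3,
) -> BoundarySuggestion:
    """Propose a boundary between the two modes of a frequency sample.

    ``mode='midway_peaks'`` returns the mean of the two highest-count
    histogram peak centers (peaks at least ``min_peak_separation_bins`` bins
    apart); ``mode='histogram_valley'`` returns the center of the
    minimum-count bin between those peaks.  If the sample shows no evidence
    of two modes (bimodality coefficient at or below 5/9, or fewer than two
    separated peaks) no boundary is returned and a warning message is set.

    The histogram (edges and counts) is always returned for inspection.
    """
    if mode not in ("midway_peaks", "histogram_valley"):
        raise ValueError(f"unknown mode {mode!r}")
    x = np.asarray(values, dtype=float)
    if x.size < 50:
        raise ValueError(f"boundary suggestion requires n >= 50, got n = {x.size}")
    lo = np.floor(x.min() / bin_khz) * bin_khz
    hi = np.ceil(x.max() / bin_khz) * bin_khz
    edges = np.arange(lo, hi + bin_khz, bin_khz)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_khz])
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    bim = bimodality_coefficient(x)
    if bim.b <= BIMODALITY_REFERENCE:
        return BoundarySuggestion(
            boundary_khz=None,
            bin_edges=edges,
            counts=counts,
            peak_centers=None,
            bimodality=bim,
            warning=(
                f"no evidence of two modes (bimodality b = {bim.b:.3f} <= "
                f"{BIMODALITY_REFERENCE:.3f}); boundary not suggested"
            ),
        )

    # Zero-pad so maxima in the first/last bin register as peaks.
    padded = np.concatenate([[0], counts, [0]])
    peak_idx, _ = _sig.find_peaks(padded, distance=min_peak_separation_bins)
    peak_idx = peak_idx - 1
    if peak_idx.size < 2:
        return BoundarySuggestion(
            boundary_khz=None,
            bin_edges=edges,
            counts=counts,
            peak_centers=None,
            bimodality=bim,
            warning="fewer than two separated histogram peaks found",
        )
    order = np.argsort(counts[peak_idx])[::-1]
    top2 = np.sort(peak_idx[order[:2]])
    p_lo, p_hi = centers[top2[0]], centers[top2[1]]
    if mode == "midway_peaks":
        boundary = 0.5 * (p_lo + p_hi)
    else:
        between = slice(top2[0] + 1, top2[1])
        valley_rel = int(np.argmin(counts[between]))
        boundary = float(centers[between][valley_rel])
    return BoundarySuggestion(
        boundary_khz=float(boundary),
        bin_edges=edges,
        counts=counts,
        peak_centers=(float(p_lo), float(p_hi)),
        bimodality=bim,
    )
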