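"""Rule-based syllable classification with strain-adjustable boundaries.

Maps per-syllable features onto four categories derived from the cluster
structure of pup isolation-call repertoires:

* ``one_step``   — exactly one discontinuous frequency step;
* ``multi_step`` — more than one frequency step;
* ``low``        — no steps, mean contour frequency below the boundary;
* ``high``       — no steps, mean contour frequency at or above the boundary.

The high/low boundary is strain specific (85 kHz for CBA/CaJ, 73 kHz for
IRW, 70 kHz for C57BL/6 presets); the step threshold defaults to 20 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .features import SyllableFeatures

LABELS = ("low", "high", "one_step", "multi_step")

#: Strain presets: (step threshold kHz, high/low boundary kHz).
STRAIN_PRESETS = {
    "CBA/CaJ": (20.0, 85.0),
    "IRW": (20.0, 73.0),
    "C57BL/6": (20.0, 70.0),
}


@dataclass(frozen=True)
class StrainThresholds:
    """Classification boundaries for one mouse strain."""

    step_threshold_khz: float = 20.0
    high_low_boundary_khz: float = 85.0
    strain_name: str = ""

    def __post_init__(self) -> None:
        if self.step_threshold_khz <= 0 or self.high_low_boundary_khz <= 0:
            raise ValueError("thresholds must be positive")
        if not 41.0 <= self.high_low_boundary_khz <= 129.0:
            raise ValueError("high_low_boundary_khz must lie within [41, 129] kHz")


def strain_preset(name: str) -> StrainThresholds:
    """Return preset thresholds for a known strain name."""
    if name not in STRAIN_PRESETS:
        raise KeyError(
            f"unknown strain {name!r}; presets: {sorted(STRAIN_PRESETS)} "
            "(supply explicit thresholds for other strains)"
        )
    step, boundary = STRAIN_PRESETS[name]
    return StrainThresholds(step, boundary, strain_name=name)


def classify(features: SyllableFeatures, thresholds: StrainThresholds) -> str:
    """Classify one syllable. Total and deterministic.

    More than one step -> ``multi_step``; exactly one -> ``one_step``;
    otherwise ``low`` if the mean frequency is strictly below the boundary,
    ``high`` if at or above it.
    """
    if features.n_steps > 1:
        return "multi_step"
    if features.n_steps == 1:
        return "one_step"
    if features.mean_khz < thresholds.high_low_boundary_khz:
        return "low"
    return "high"


def classify_table(
    features: pd.DataFrame, thresholds: StrainThresholds
) -> tuple[pd.Series, dict[str, float], pd.DataFrame]:
    """Classify a features table.

    Returns ``(labels, proportions, flagged)``: one label per valid row,
    per-category proportions over the valid rows (summing to 1), and the
    rows flagged invalid upstream (``valid == False``), which are reported
    rather than silently dropped.
    """
    if len(features) == 0:
        raise ValueError("empty features table")
    for col in ("n_steps", "mean_khz"):
        if col not in features.columns:
            raise ValueError(f"features table is missing column: {col}")
    valid_mask = features["valid"].astype(bool) if "valid" in features.columns else pd.Series(True, index=features.index)
    flagged = features.loc[~valid_mask]
    valid = features.loc[valid_mask]
    if len(valid) == 0:
        raise ValueError("no valid rows to classify")
    n_steps = valid["n_steps"].to_numpy(dtype=float)
    mean = valid["mean_khz"].to_numpy(dtype=float)
    labels = np.where(
        n_steps > 1,
        "multi_step",
        np.where(
            n_steps == 1,
            "one_step",
            np.where(mean < thresholds.high_low_boundary_khz, "low", "high"),
        ),
    )
    labels = pd.Series(labels, index=valid.index, name="label")
    proportions = {lab: float((labels == lab).mean()) for lab in LABELS}
    return labels, proportions, flagged


@dataclass
class AgreementReport:
    """Percent agreement between two labelings after label alignment."""

    coherence_pct: float
    confusion: pd.DataFrame
    mapping: dict


def _optimal_mapping(confusion: np.ndarray) -> list[tuple[int, int]]:
    # Hungarian assignment maximizing the matched mass; exact, and for the
    # <= 4x4 tables arising here equivalent to exhaustive permutation search.
    r, c = linear_sum_assignment(-confusion)
    return list(zip(r.tolist(), c.tolist()))


def agreement(labels_a, labels_b) -> AgreementReport:
    """Percent of identically labeled syllables after optimal label mapping.

    The two labelings may use different alphabets (e.g., calculator category
    names vs. cluster indices); a one-to-one mapping between alphabets
    maximizing total agreement is found first, and the confusion table is
    reported in the mapped space with rows indexed by the first labeling's
    alphabet.
    """
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length ({len(a)} vs {len(b)})")
    if len(a) == 0:
        raise ValueError("empty label vectors")
    cats_a = sorted(a.unique(), key=str)
    cats_b = sorted(b.unique(), key=str)
    C = np.zeros((len(cats_a), len(cats_b)))
    ia = {v: i for i, v in enumerate(cats_a)}
    ib = {v: i for i, v in enumerate(cats_b)}
    for va, vb in zip(a, b):
        C[ia[va], ib[vb]] += 1
    pairs = _optimal_mapping(C)
    matched = sum(C[i, j] for i, j in pairs)
    mapping = {cats_b[j]: cats_a[i] for i, j in pairs}
    b_mapped = b.map(lambda v: mapping.get(v, v))
    confusion = pd.crosstab(
        a.rename("labels_a"), b_mapped.rename("labels_b"), dropna=False
    )
    return AgreementReport(
        coherence_pct=100.0 * matched / len(a),
        confusion=confusion,
        mapping=mapping,
    )


def agreement_bruteforce(labels_a, labels_b) -> float:
    """Exhaustive-permutation coherence, for validation on small alphabets."""
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    cats_a = sorted(a.unique(), key=str)
    cats_b = sorted(b.unique(), key=str)
    small, large = (cats_a, cats_b) if len(cats_a) <= len(cats_b) else (cats_b, cats_a)
    swap = len(cats_a) > len(cats_b)
    best = 0
    for perm in permutations(large, len(small)):
        m = dict(zip(small, perm))
        if swap:  # map b's alphabet onto a's
            n_match = sum(1 for va, vb in zip(a, b) if m.get(vb) == va)
        else:  # map a's alphabet onto b's
            n_match = sum(1 for va, vb in zip(a, b) if m.get(va) == vb)
        best = max(best, n_match)
    return 100.0 * best / len(a)
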