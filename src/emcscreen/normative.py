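"""Normative references and modified Z-scores.

A normative cohort is summarised per feature by its median and median
absolute deviation (MAD); new feature vectors are scored with the
modified Z-score ``M = (x − median) / (1.486 · MAD)``, a robust
alternative to the standard Z-score that is insensitive to cohort
outliers.  Features whose |M| exceeds a ±2 bound are flagged as
outliers with respect to the normative population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np

from .stp import FEATURE_NAMES, STPFeatures

__all__ = [
    "MAD_SCALE",
    "NormativeReference",
    "ZScoreProfile",
    "UndefinedScoreError",
    "mad",
    "build_reference",
    "modified_zscore",
    "score_profile",
]

MAD_SCALE = 1.486  # multiplies the MAD in the modified Z denominator
DEFAULT_BOUND = 2.0


class UndefinedScoreError(ValueError):
    """The modified Z-score is undefined (zero MAD in the reference)."""


@dataclass
class NormativeReference:
    """Per-feature median and MAD of a control cohort."""

    medians: Dict[str, float]
    mads: Dict[str, float]
    n: int

    def __post_init__(self) -> None:
        if set(self.medians) != set(self.mads):
            raise ValueError("median and MAD entries must match")
        for name, m in self.mads.items():
            if m < 0:
                raise ValueError(f"negative MAD for {name}")


@dataclass
class ZScoreProfile:
    """Modified Z-scores of one feature vector against a reference."""

    z: Dict[str, float]
    flags: Dict[str, bool]
    bound: float
    undefined: List[str] = field(default_factory=list)

    @property
    def n_outliers(self) -> int:
        return sum(self.flags.values())


def mad(values: Iterable[float]) -> float:
    """Median absolute deviation: ``median(|Y_i − median(Y)|)``."""
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("need at least one finite value")
    return float(np.median(np.abs(arr - np.median(arr))))


def build_reference(cohort: Sequence[STPFeatures]) -> NormativeReference:
    """Summarise a control cohort into a normative reference.

    Non-finite entries (failed fits) are ignored per feature.
    """
    if not cohort:
        raise ValueError("empty cohort")
    medians: Dict[str, float] = {}
    mads: Dict[str, float] = {}
    for name in FEATURE_NAMES:
        col = np.array([f[name] for f in cohort], dtype=float)
        col = col[np.isfinite(col)]
        if col.size == 0:
            raise ValueError(f"no finite values for feature {name}")
        medians[name] = float(np.median(col))
        mads[name] = mad(col)
    return NormativeReference(medians=medians, mads=mads, n=len(cohort))


def modified_zscore(
    x: float, reference: NormativeReference, feature: str
) -> float:
    """``M = (x − median) / (1.486 · MAD)`` for one feature."""
    if feature not in reference.medians:
        raise KeyError(f"feature {feature!r} not in reference")
    m = reference.mads[feature]
    if m == 0.0:
        raise UndefinedScoreError(
            f"MAD is zero for {feature!r}: modified Z undefined"
        )
    return (x - reference.medians[feature]) / (MAD_SCALE * m)


def score_profile(
    features: STPFeatures,
    reference: NormativeReference,
    bound: float = DEFAULT_BOUND,
) -> ZScoreProfile:
    """Score all 40 features; flag |M| > bound as outliers.

    Matching is by feature name, so the result is invariant to the
    ordering of the input.  Zero-MAD features are reported in
    ``undefined`` (score NaN, no flag) rather than silently dropped.
    """
    missing = [n for n in FEATURE_NAMES if n not in reference.medians]
    if missing:
        raise ValueError(f"reference lacks features: {missing}")
    z: Dict[str, float] = {}
    flags: Dict[str, bool] = {}
    undefined: List[str] = []
    for name in FEATURE_NAMES:
        try:
            score = modified_zscore(features[name], reference, name)
        except UndefinedScoreError:
            undefined.append(name)
            z[name] = float("nan")
            flags[name] = False
            continue
        z[name] = score
        flags[name] = bool(abs(score) > bound)
    return ZScoreProfile(z=z, flags=flags, bound=bound, undefined=undefined)
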