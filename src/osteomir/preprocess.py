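"""Normalization and group-wise presence filtering of expression matrices.

Intensity matrices are log2 transformed and quantile normalized across all
samples jointly, so tumour-derived and normal samples end up on one common
scale.  Features are then retained only if they carry a detection call in at
least a given fraction of one group and/or of another (default: 75% of the
bone samples and/or 25% of the cell lines, which keeps features expressed in
only a subgroup of the cell lines).  Fractions convert to integer count
thresholds by ceiling, matching "at least" semantics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import (
    DetectionMatrix,
    ExpressionMatrix,
    SampleAnnotation,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PresenceRule:
    """Two-group presence rule: keep a feature if it is detected in at least
    ``frac_a`` of ``group_a`` samples and/or (per ``combine``) ``frac_b`` of
    ``group_b`` samples."""

    group_a: str = "bone"
    frac_a: float = 0.75
    group_b: str = "cell_line"
    frac_b: float = 0.25
    combine: str = "or"

    def __post_init__(self) -> None:
        for frac in (self.frac_a, self.frac_b):
            if not (0.0 <= frac <= 1.0):
                raise ValidationError(f"presence fraction {frac} outside [0, 1]")
        if self.combine not in ("or", "and"):
            raise ValidationError(f"combine must be 'or' or 'and', got {self.combine!r}")


def log2_transform(m: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """log2(value + offset) on a raw-scale matrix; NaN entries stay NaN."""
    if m.scale != "raw":
        raise ValidationError("log2_transform expects a raw-scale matrix")
    if offset < 0:
        raise ValidationError("offset must be non-negative")
    shifted = m.values + offset
    bad = np.argwhere(np.nan_to_num(shifted, nan=1.0) <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"non-positive value {m.values[i, j]!r} at feature "
            f"{m.feature_ids[i]!r}, sample {m.sample_ids[j]!r} with offset {offset}"
        )
    return ExpressionMatrix(
        feature_ids=list(m.feature_ids),
        sample_ids=list(m.sample_ids),
        values=np.log2(shifted),
        scale="log2",
    )


def _tie_aware_assign(column: np.ndarray, rank_means: np.ndarray) -> np.ndarray:
    """Assign cross-column rank means to one column; each tie group receives
    the mean of the rank-mean values over its tied positions."""
    order = np.argsort(column, kind="stable")
    out = np.empty_like(rank_means)
    sorted_vals = column[order]
    n = column.size
    start = 0
    while start < n:
        stop = start + 1
        while stop < n and sorted_vals[stop] == sorted_vals[start]:
            stop += 1
        out[order[start:stop]] = rank_means[start:stop].mean()
        start = stop
    return out


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the cross-column rank-mean distribution.

    After the transform every column holds the same multiset of values (up to
    tie averaging) while within-column ordering is preserved.  The operation
    is idempotent.  Missing values are not allowed: impute or drop first, by
    explicit caller choice.
    """
    if m.scale != "log2":
        raise ValidationError("quantile_normalize expects a log2-scale matrix")
    if np.isnan(m.values).any():
        raise ValidationError(
            "matrix contains missing values; impute or drop rows before normalizing"
        )
    if m.n_samples == 1:
        logger.info("quantile_normalize: single-column matrix returned unchanged")
        return ExpressionMatrix(
            list(m.feature_ids), list(m.sample_ids), m.values.copy(), scale="log2"
        )
    rank_means = np.sort(m.values, axis=0).mean(axis=1)
    out = np.empty_like(m.values)
    for j in range(m.n_samples):
        out[:, j] = _tie_aware_assign(m.values[:, j], rank_means)
    return ExpressionMatrix(list(m.feature_ids), list(m.sample_ids), out, scale="log2")


def presence_threshold(frac: float, n: int) -> int:
    """'at least frac of n' as an integer count: ceil(frac * n), guarded
    against float round-up artefacts."""
    return int(math.ceil(frac * n - 1e-9))


def presence_filter(
    d: DetectionMatrix, ann: SampleAnnotation, rule: PresenceRule
) -> list[str]:
    """Return feature ids (in input order) passing the two-group presence rule."""
    counts = {}
    thresholds = {}
    for group, frac in ((rule.group_a, rule.frac_a), (rule.group_b, rule.frac_b)):
        samples = [s for s in ann.samples_in_group(group) if s in d.sample_ids]
        if not samples:
            raise ValidationError(f"presence rule group {group!r} has no samples in matrix")
        idx = [d.sample_ids.index(s) for s in samples]
        counts[group] = d.values[:, idx].sum(axis=1)
        thresholds[group] = presence_threshold(frac, len(samples))
    pass_a = counts[rule.group_a] >= thresholds[rule.group_a]
    pass_b = counts[rule.group_b] >= thresholds[rule.group_b]
    keep = (pass_a | pass_b) if rule.combine == "or" else (pass_a & pass_b)
    return [f for f, k in zip(d.feature_ids, keep) if k]


def detection_from_intensity(
    m: ExpressionMatrix, quantile: float = 0.25
) -> DetectionMatrix:
    """Fallback detection calls when vendor flags are unavailable: a feature
    is called detected in a sample when its intensity exceeds the given
    global quantile of all (finite) intensities in the matrix."""
    if not (0.0 <= quantile <= 1.0):
        raise ValidationError(f"quantile {quantile} outside [0, 1]")
    finite = m.values[np.isfinite(m.values)]
    if finite.size == 0:
        raise ValidationError("matrix has no finite values")
    threshold = float(np.quantile(finite, quantile))
    detected = np.nan_to_num(m.values, nan=-np.inf) > threshold
    return DetectionMatrix(list(m.feature_ids), list(m.sample_ids), detected)


def detection_counts(
    d: DetectionMatrix, ann: SampleAnnotation, group: str
) -> np.ndarray:
    """Per-feature detected-sample count within one annotation group."""
    samples = [s for s in ann.samples_in_group(group) if s in d.sample_ids]
    idx = [d.sample_ids.index(s) for s in samples]
    return d.values[:, idx].sum(axis=1)
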