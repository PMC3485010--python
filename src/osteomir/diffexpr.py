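"""Two-group differential expression on log2 intensities.

Per feature: a two-sided t-test (Welch by default, robust to the unequal
variances expected between a large heterogeneous tumour panel and a few
normal samples; pooled-variance variant behind a flag), Benjamini-Hochberg
FDR adjustment over the presence-filtered feature set, a signed fold change
on the ratio scale (2^d for a log2 mean difference d >= 0, -2^-d below),
and per-group detection counts.  Features undetected in one group keep their
fold change but are flagged as potentially overestimated.

Hits are annotated with miRNA family and genomic-cluster membership, with a
summary of how many hits belong to conserved families and how many share a
family or cluster with at least one other hit (co-regulated groups).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import (
    DetectionMatrix,
    ExpressionMatrix,
    MirnaAnnotation,
    SampleAnnotation,
    ValidationError,
)
from .preprocess import PresenceRule, detection_from_intensity, presence_filter

RECORD_COLUMNS = [
    "feature_id",
    "t_stat",
    "p_raw",
    "p_adj",
    "log2_mean_a",
    "log2_mean_b",
    "fold_change",
    "presence_a",
    "presence_b",
    "significant",
    "twofold",
    "overestimated",
]


def _group_values(
    m: ExpressionMatrix, ann: SampleAnnotation, group: str
) -> np.ndarray:
    samples = [s for s in ann.samples_in_group(group) if s in m.sample_ids]
    if len(samples) < 2:
        raise ValidationError(f"group {group!r} needs >= 2 samples, has {len(samples)}")
    idx = [m.sample_ids.index(s) for s in samples]
    return m.values[:, idx]


def group_t_test(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    group_a: str,
    group_b: str,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-feature two-sided t-test between two annotation groups.

    Welch's unequal-variance form by default.  Degenerate features (zero
    variance in both groups) get p = 1 when the means agree, so downstream
    FDR adjustment stays well defined, and p = 0 on exact separation.
    """
    a = _group_values(m, ann, group_a)
    b = _group_values(m, ann, group_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_raw = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    t_stat = np.asarray(t_stat, dtype=float)
    p_raw = np.asarray(p_raw, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    both = degenerate & equal_means
    t_stat[both] = 0.0
    p_raw[both] = 1.0
    sep = degenerate & ~equal_means
    t_stat[sep] = np.sign(a.mean(axis=1) - b.mean(axis=1))[sep] * np.inf
    p_raw[sep] = 0.0
    bad = ~np.isfinite(p_raw)
    p_raw[bad] = 1.0
    t_stat[bad & ~np.isfinite(t_stat)] = 0.0
    return pd.DataFrame(
        {"feature_id": m.feature_ids, "t_stat": t_stat, "p_raw": p_raw}
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(
    m: ExpressionMatrix, ann: SampleAnnotation, group_a: str, group_b: str
) -> pd.DataFrame:
    """Signed ratio-scale fold change of group_a over group_b.

    For a log2 mean difference d: 2^d when d >= 0 and -2^-d when d < 0, so
    |fold change| >= 1 always and equality of means yields +1.
    """
    a = _group_values(m, ann, group_a).mean(axis=1)
    b = _group_values(m, ann, group_b).mean(axis=1)
    delta = a - b
    fc = np.where(delta >= 0, 2.0**delta, -(2.0 ** (-delta)))
    return pd.DataFrame(
        {
            "feature_id": m.feature_ids,
            "log2_mean_a": a,
            "log2_mean_b": b,
            "fold_change": fc,
        }
    )


def differential_features(
    m: ExpressionMatrix,
    d: DetectionMatrix | None,
    ann: SampleAnnotation,
    rule: PresenceRule | None,
    group_a: str = "cell_line",
    group_b: str = "bone",
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
    equal_var: bool = False,
    detection_quantile: float = 0.25,
) -> pd.DataFrame:
    """Presence filter, per-feature t-tests, BH adjustment and fold changes.

    ``rule=None`` skips presence filtering (every feature is tested).  When a
    rule is given but no detection matrix, calls are derived from intensity
    above a global quantile.  BH runs over the filtered set only, mirroring a
    filter-before-test design.  ``significant`` is p_adj <= alpha;
    ``twofold`` is |fold change| > fc_threshold.
    """
    if rule is not None:
        if d is None:
            d = detection_from_intensity(m, quantile=detection_quantile)
        if not d.matches(m):
            raise ValidationError("detection matrix axes do not match the expression matrix")
        retained = presence_filter(d, ann, rule)
        sub = m.subset_features(retained)
    else:
        sub = m
        retained = list(m.feature_ids)

    tests = group_t_test(sub, ann, group_a, group_b, equal_var=equal_var)
    fc = fold_change(sub, ann, group_a, group_b)
    out = tests.merge(fc, on="feature_id")
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())

    if d is not None:
        dsub = pd.DataFrame(d.values, index=d.feature_ids, columns=d.sample_ids).loc[retained]
        sa = [s for s in ann.samples_in_group(group_a) if s in d.sample_ids]
        sb = [s for s in ann.samples_in_group(group_b) if s in d.sample_ids]
        out["presence_a"] = dsub[sa].sum(axis=1).to_numpy()
        out["presence_b"] = dsub[sb].sum(axis=1).to_numpy()
    else:
        na = len([s for s in ann.samples_in_group(group_a) if s in m.sample_ids])
        nb = len([s for s in ann.samples_in_group(group_b) if s in m.sample_ids])
        out["presence_a"] = na
        out["presence_b"] = nb
    out["significant"] = out["p_adj"] <= alpha
    out["twofold"] = out["fold_change"].abs() > fc_threshold
    # fold changes computed on a group where the feature was never detected
    # rest on background-level intensities and can be overestimated
    out["overestimated"] = (out["presence_a"] == 0) | (out["presence_b"] == 0)
    return out[RECORD_COLUMNS]


def annotate_families(
    records: pd.DataFrame, mirna_annotation: list[MirnaAnnotation]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Attach family/cluster tags to DE records and summarize co-regulation.

    Summary counts are computed over significant records only:
    ``n_in_family`` — hits carrying any family annotation;
    ``n_shared_family_or_cluster`` — hits whose family or cluster contains at
    least one other significant hit.
    """
    ann_map = {a.mirna_id: a for a in mirna_annotation}
    out = records.copy()
    out["family_id"] = [
        (ann_map[f].family_id if f in ann_map else None) for f in out["feature_id"]
    ]
    out["cluster_id"] = [
        (ann_map[f].cluster_id if f in ann_map else None) for f in out["feature_id"]
    ]
    hits = out[out["significant"]]
    n_in_family = int(hits["family_id"].notna().sum())
    fam_counts = hits["family_id"].dropna().value_counts()
    clu_counts = hits["cluster_id"].dropna().value_counts()
    shared = 0
    for _, row in hits.iterrows():
        fam_ok = row["family_id"] is not None and fam_counts.get(row["family_id"], 0) >= 2
        clu_ok = row["cluster_id"] is not None and clu_counts.get(row["cluster_id"], 0) >= 2
        if fam_ok or clu_ok:
            shared += 1
    summary = {
        "n_significant": int(len(hits)),
        "n_in_family": n_in_family,
        "n_shared_family_or_cluster": shared,
    }
    return out, summary
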