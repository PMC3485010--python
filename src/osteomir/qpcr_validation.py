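"""qRT-PCR validation arm: comparative-threshold-cycle (2^-ddCt)
quantification against dual endogenous references, undetected-well
imputation, and Mann-Whitney group comparison with a significance/trend
banding convention.

The quantification model is the standard comparative Ct method: for each
sample, dCt = Ct(target) - mean Ct over the reference assays; ddCt subtracts
the mean dCt of a calibrator group (normal bone by default), and the
relative quantity is RQ = 2^-ddCt, i.e. expression relative to the mean
level of the calibrator group.  Because both references enter as an
arithmetic mean on the Ct scale, any per-sample additive shift applied
jointly to target and reference wells cancels exactly.

Group comparisons use the Mann-Whitney U test: the exact permutation
distribution when both groups are small (min(n, m) <= 8) and the data are
tie-free, otherwise the normal approximation with tie and continuity
corrections; the method used is recorded in each result.  P-values below
0.05 are called significant and values in the closed band [0.05, 0.15] a
trend, with no multiplicity adjustment across assays by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class QpcrError(ValueError):
    pass


@dataclass
class QpcrTable:
    """Well-level Ct measurements in long format.

    ``frame`` columns: sample_id, assay_id, ct (float cycles, NaN when
    undetected), undetected (bool).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "assay_id", "ct", "undetected"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise QpcrError(f"qPCR table missing columns {missing}")
        self.frame = self.frame[required].copy()
        self.frame["ct"] = self.frame["ct"].astype(float)
        self.frame["undetected"] = self.frame["undetected"].astype(bool)
        numeric = self.frame.loc[~self.frame["undetected"], "ct"]
        if (numeric < 0).any():
            raise QpcrError("negative Ct values are invalid")

    @property
    def assay_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["assay_id"]))

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["sample_id"]))

    def n_undetected(self) -> int:
        return int(self.frame["undetected"].sum())


@dataclass(frozen=True)
class GroupTestResult:
    assay_id: str
    group_a: str
    group_b: str
    u_stat: float
    p: float
    method: str
    band: str  # significant | trend | ns


def impute_undetected(table: QpcrTable, ceiling: float = 40.0) -> QpcrTable:
    """Replace undetected wells by the cycle ceiling (Ct = 40 by default).

    The number of imputed wells is logged per assay; the returned table has
    no undetected flags left set.
    """
    frame = table.frame.copy()
    mask = frame["undetected"]
    if mask.any():
        per_assay = frame.loc[mask, "assay_id"].value_counts()
        for assay, n in per_assay.items():
            logger.info("assay %s: imputed %d undetected well(s) to Ct=%s", assay, n, ceiling)
    frame.loc[mask, "ct"] = float(ceiling)
    frame["undetected"] = False
    return QpcrTable(frame)


def _average_replicates(frame: pd.DataFrame) -> pd.DataFrame:
    # technical replicates are averaged on the Ct scale before any dCt
    return (
        frame.groupby(["sample_id", "assay_id"], sort=False, as_index=False)["ct"].mean()
    )


def ddct(
    table: QpcrTable,
    reference_assays: list[str],
    calibrator_group: str,
    ann,
) -> pd.DataFrame:
    """Comparative-Ct relative quantification.

    Returns one row per (sample, target assay) with columns sample_id,
    assay_id, delta_ct, ddct, rq.  Undetected wells must be imputed first;
    every sample needs a numeric Ct for every reference assay.  The mean
    ddCt of the calibrator group is zero by construction, so calibrator
    samples average RQ = 1 on the log scale.
    """
    if not reference_assays:
        raise QpcrError("at least one reference assay is required")
    if table.frame["undetected"].any():
        raise QpcrError("undetected wells present; run impute_undetected first")
    wide = _average_replicates(table.frame).pivot(
        index="sample_id", columns="assay_id", values="ct"
    )
    for ref in reference_assays:
        if ref not in wide.columns:
            raise QpcrError(f"reference assay {ref!r} absent from the table")
        bad = wide.index[wide[ref].isna()].tolist()
        if bad:
            raise QpcrError(f"missing reference well: assay {ref!r}, sample(s) {bad}")
    calibrator_samples = [s for s in ann.samples_in_group(calibrator_group) if s in wide.index]
    if not calibrator_samples:
        raise QpcrError(f"calibrator group {calibrator_group!r} has no measured samples")

    ref_mean = wide[reference_assays].mean(axis=1)
    targets = [a for a in wide.columns if a not in reference_assays]
    rows = []
    for assay in targets:
        dct = wide[assay] - ref_mean
        calib_mean = dct.loc[calibrator_samples].mean()
        for sample in wide.index:
            if np.isnan(wide.loc[sample, assay]):
                continue
            dd = dct.loc[sample] - calib_mean
            rows.append(
                {
                    "sample_id": sample,
                    "assay_id": assay,
                    "delta_ct": float(dct.loc[sample]),
                    "ddct": float(dd),
                    "rq": float(2.0 ** (-dd)),
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "assay_id", "delta_ct", "ddct", "rq"])


def mann_whitney(a, b) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test.

    Returns (U statistic of the first group, p-value, method).  The exact
    permutation distribution is used when min(n, m) <= 8 and there are no
    ties across the pooled data; otherwise the normal approximation with tie
    and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise QpcrError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and min(a.size, b.size) <= 8:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0)), method


def band(p: float, sig: float = 0.05, trend_hi: float = 0.15) -> str:
    """Banding convention: p < sig is significant, the closed interval
    [sig, trend_hi] a trend towards significance, anything larger ns."""
    if p < sig:
        return "significant"
    if p <= trend_hi:
        return "trend"
    return "ns"


def group_tests(
    rel: pd.DataFrame,
    ann,
    group_a: str,
    group_b: str,
    value: str = "rq",
    sig: float = 0.05,
    trend_hi: float = 0.15,
) -> list[GroupTestResult]:
    """Per-assay Mann-Whitney comparison of two sample groups on relative
    quantities (``value="rq"``) or reference-adjusted Ct (``value="delta_ct"``)."""
    if value not in ("rq", "delta_ct"):
        raise QpcrError(f"unknown test value {value!r}")
    samples_a = set(ann.samples_in_group(group_a))
    samples_b = set(ann.samples_in_group(group_b))
    results = []
    for assay in dict.fromkeys(rel["assay_id"]):
        sub = rel[rel["assay_id"] == assay]
        va = sub.loc[sub["sample_id"].isin(samples_a), value].to_numpy()
        vb = sub.loc[sub["sample_id"].isin(samples_b), value].to_numpy()
        u, p, method = mann_whitney(va, vb)
        results.append(
            GroupTestResult(
                assay_id=assay,
                group_a=group_a,
                group_b=group_b,
                u_stat=u,
                p=p,
                method=method,
                band=band(p, sig=sig, trend_hi=trend_hi),
            )
        )
    return results


def band_results(
    results: list[GroupTestResult], sig: float = 0.05, trend_hi: float = 0.15
) -> list[GroupTestResult]:
    """Re-band a list of test results with new thresholds."""
    return [
        GroupTestResult(
            assay_id=r.assay_id,
            group_a=r.group_a,
            group_b=r.group_b,
            u_stat=r.u_stat,
            p=r.p,
            method=r.method,
            band=band(r.p, sig=sig, trend_hi=trend_hi),
        )
        for r in results
    ]


def results_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "assay_id": r.assay_id,
                "group_a": r.group_a,
                "group_b": r.group_b,
                "u_stat": r.u_stat,
                "p": r.p,
                "method": r.method,
                "band": r.band,
            }
            for r in results
        ]
    )
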