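"""Anti-correlation screening of predicted miRNA targets.

The cascade takes differentially expressed miRNAs, intersects their
predicted targets with genes significant in both the cell-line and the
clinical cohort (guarding against in-vitro artefacts), computes the Pearson
correlation of each surviving pair across the cell-line samples, keeps pairs
with r strictly below -0.5, and finally removes pairs whose conservation
score P_CT falls below 0.4 — except star-strand miRNAs, which have no P_CT
and are retained.  Genes anti-correlated with at least two distinct miRNAs
are grouped into a multi-miRNA target table.  Each stage only ever shrinks
the pair set, and stage counts are reported for audit.

Set overlap between two differential gene lists is tested with an upper-tail
hypergeometric probability accumulated in log space via the log-gamma
function, so p-values far below double-precision underflow (the interesting
regime for genome-scale overlaps) remain representable as log10(p).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .io_formats import ExpressionMatrix, TargetPrediction, ValidationError

STAGES = ("predicted", "cohort_confirmed", "anticorrelated", "conserved", "multi_mirna")


@dataclass(frozen=True)
class PairRecord:
    """One evaluated miRNA/mRNA pair with its screening state."""

    mirna_id: str
    gene_symbol: str
    transcript_id: str
    pct: float | None
    star_strand: bool
    r: float | None = None
    probe_id: str | None = None
    stage_flags: frozenset = frozenset()

    def with_flags(self, *flags: str) -> "PairRecord":
        return replace(self, stage_flags=self.stage_flags | frozenset(flags))


@dataclass(frozen=True)
class OverlapResult:
    n_universe: int
    n_set_a: int
    n_set_b: int
    n_overlap: int
    log10_p: float

    @property
    def p(self) -> float:
        return float(10.0**self.log10_p)


def candidate_pairs(
    de_mirnas: Sequence[str],
    predictions: Sequence[TargetPrediction],
    de_mrnas_cl: Sequence[str],
    de_mrnas_clin: Sequence[str],
) -> list[PairRecord]:
    """Predicted pairs whose miRNA is differentially expressed and whose
    target gene is significant in both cohorts."""
    import logging

    if not predictions:
        logging.getLogger(__name__).warning("empty prediction table: no candidate pairs")
        return []
    de_set = set(de_mirnas)
    confirmed = set(de_mrnas_cl) & set(de_mrnas_clin)
    out = []
    seen = set()
    for p in predictions:
        key = (p.mirna_id, p.gene_symbol)
        if key in seen:
            continue
        if p.mirna_id in de_set and p.gene_symbol in confirmed:
            seen.add(key)
            out.append(
                PairRecord(
                    mirna_id=p.mirna_id,
                    gene_symbol=p.gene_symbol,
                    transcript_id=p.transcript_id,
                    pct=p.pct,
                    star_strand=p.star_strand,
                    stage_flags=frozenset({"predicted", "cohort_confirmed"}),
                )
            )
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    if denom == 0:
        raise ValidationError("zero-variance vector in correlation")
    return float(np.clip((x * y).sum() / denom, -1.0, 1.0))


def pair_correlations(
    pairs: Sequence[PairRecord],
    mirna_m: ExpressionMatrix,
    mrna_m: ExpressionMatrix,
    sample_subset: Sequence[str],
    gene_to_probes: dict[str, list[str]] | None = None,
    require_all_probes: bool = False,
) -> list[PairRecord]:
    """Fill in the Pearson r of every pair over a sample subset (the
    cell-line samples by default in the pipeline).

    When a gene maps to several mRNA probes the most anti-correlated probe
    represents the gene (most favourable to detection); with
    ``require_all_probes`` the least anti-correlated one does, so that every
    probe must pass any downstream threshold.
    """
    subset = list(sample_subset)
    if len(subset) < 3:
        raise ValidationError("need >= 3 overlapping samples for correlation")
    mir = mirna_m.subset_samples(subset)
    mr = mrna_m.subset_samples(subset)
    mir_idx = {f: i for i, f in enumerate(mir.feature_ids)}
    mr_idx = {f: i for i, f in enumerate(mr.feature_ids)}
    out = []
    for pair in pairs:
        if pair.mirna_id not in mir_idx:
            raise ValidationError(f"miRNA {pair.mirna_id!r} absent from the miRNA matrix")
        probes = (
            gene_to_probes.get(pair.gene_symbol, [pair.gene_symbol])
            if gene_to_probes
            else [pair.gene_symbol]
        )
        missing = [p for p in probes if p not in mr_idx]
        if missing:
            raise ValidationError(f"probe(s) {missing} absent from the mRNA matrix")
        x = mir.values[mir_idx[pair.mirna_id]]
        rs = {p: _pearson(x, mr.values[mr_idx[p]]) for p in probes}
        pick = max(rs, key=rs.get) if require_all_probes else min(rs, key=rs.get)
        out.append(replace(pair, r=rs[pick], probe_id=pick))
    return out


def anticorrelation_filter(
    pairs: Sequence[PairRecord], r_threshold: float = -0.5
) -> list[PairRecord]:
    """Keep pairs with r strictly below the threshold (r = -0.5 itself is
    dropped)."""
    out = []
    for p in pairs:
        if p.r is None:
            raise ValidationError(f"pair {p.mirna_id}/{p.gene_symbol} has no r; run pair_correlations")
        if p.r < r_threshold:
            out.append(p.with_flags("anticorrelated"))
    return out


def conservation_filter(
    pairs: Sequence[PairRecord], pct_threshold: float = 0.4
) -> list[PairRecord]:
    """Drop pairs with P_CT below the threshold; P_CT equal to the threshold
    is kept, and pairs with no P_CT (star strands) are retained."""
    out = []
    for p in pairs:
        if p.pct is None or p.pct >= pct_threshold:
            out.append(p.with_flags("conserved"))
    return out


def multi_mirna_targets(
    pairs: Sequence[PairRecord], min_mirnas: int = 2
) -> dict[str, list[str]]:
    """Genes targeted by at least ``min_mirnas`` distinct miRNAs, as an
    ordered gene -> sorted miRNA-list mapping (gene symbols ascending)."""
    by_gene: dict[str, set[str]] = {}
    for p in pairs:
        by_gene.setdefault(p.gene_symbol, set()).add(p.mirna_id)
    return {
        gene: sorted(mirnas)
        for gene, mirnas in sorted(by_gene.items())
        if len(mirnas) >= min_mirnas
    }


def hypergeometric_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """Upper-tail hypergeometric overlap test, P(X >= observed overlap).

    Accumulated in log space (log-gamma pmf terms combined by logsumexp), so
    overlaps whose p-value underflows a double — e.g. below 1e-1000 — still
    yield a finite log10_p.
    """
    universe = set(universe)
    set_a = set(set_a)
    set_b = set(set_b)
    if not set_a <= universe or not set_b <= universe:
        raise ValidationError("both sets must be subsets of the universe")
    N, K, n = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    k_max = min(K, n)
    terms = [stats.hypergeom.logpmf(x, N, K, n) for x in range(k, k_max + 1)]
    log_p = float(logsumexp(terms)) if terms else -np.inf
    log_p = min(log_p, 0.0)
    return OverlapResult(
        n_universe=N,
        n_set_a=K,
        n_set_b=n,
        n_overlap=k,
        log10_p=log_p / np.log(10.0),
    )


def correlate_features(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    id_pairs: Sequence[tuple[str, str]],
    sample_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Generic paired Pearson correlation between features of two matrices
    over their shared samples (e.g. intronic miRNA clusters against their
    host genes, or guide against star strands)."""
    if sample_subset is None:
        sample_subset = [s for s in matrix_a.sample_ids if s in set(matrix_b.sample_ids)]
    subset = list(sample_subset)
    if len(subset) < 3:
        raise ValidationError("need >= 3 shared samples for correlation")
    a = matrix_a.subset_samples(subset)
    b = matrix_b.subset_samples(subset)
    a_idx = {f: i for i, f in enumerate(a.feature_ids)}
    b_idx = {f: i for i, f in enumerate(b.feature_ids)}
    rows = []
    for fa, fb in id_pairs:
        if fa not in a_idx or fb not in b_idx:
            raise ValidationError(f"feature pair ({fa!r}, {fb!r}) not present in both matrices")
        rows.append(
            {"feature_a": fa, "feature_b": fb, "r": _pearson(a.values[a_idx[fa]], b.values[b_idx[fb]])}
        )
    return pd.DataFrame(rows, columns=["feature_a", "feature_b", "r"])


@dataclass
class CascadeResult:
    pairs: list[PairRecord]
    audit: list[tuple[str, int, int, dict]]
    multi_targets: dict[str, list[str]]


def run_cascade(
    de_mirnas: Sequence[str],
    predictions: Sequence[TargetPrediction],
    de_mrnas_cl: Sequence[str],
    de_mrnas_clin: Sequence[str],
    mirna_m: ExpressionMatrix,
    mrna_m: ExpressionMatrix,
    sample_subset: Sequence[str],
    r_threshold: float = -0.5,
    pct_threshold: float = 0.4,
    min_mirnas: int = 2,
    gene_to_probes: dict[str, list[str]] | None = None,
) -> CascadeResult:
    """Run the whole screening cascade and record an audit of stage counts.

    The pair set is checked to shrink (or stay equal) at every stage.
    """
    audit: list[tuple[str, int, int, dict]] = []
    n_pred = len(predictions)
    cands = candidate_pairs(de_mirnas, predictions, de_mrnas_cl, de_mrnas_clin)
    audit.append(("candidate_pairs", n_pred, len(cands), {"n_de_mirnas": len(set(de_mirnas))}))
    if cands:
        withr = pair_correlations(cands, mirna_m, mrna_m, sample_subset, gene_to_probes)
    else:
        withr = []
    anti = anticorrelation_filter(withr, r_threshold=r_threshold)
    audit.append(("anticorrelation", len(withr), len(anti), {"r_threshold": r_threshold}))
    cons = conservation_filter(anti, pct_threshold=pct_threshold)
    audit.append(("conservation", len(anti), len(cons), {"pct_threshold": pct_threshold}))
    multi = multi_mirna_targets(cons, min_mirnas=min_mirnas)
    n_multi_pairs = sum(len(v) for v in multi.values())
    audit.append(("multi_mirna", len(cons), n_multi_pairs, {"min_mirnas": min_mirnas}))
    for (_, n_in, n_out, _params) in audit:
        if n_out > n_in:
            raise AssertionError("filter cascade grew a pair set; this is a bug")
    return CascadeResult(pairs=cons, audit=audit, multi_targets=multi)


def pairs_frame(pairs: Sequence[PairRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": p.mirna_id,
                "gene_symbol": p.gene_symbol,
                "transcript_id": p.transcript_id,
                "probe_id": p.probe_id,
                "r": p.r,
                "pct": np.nan if p.pct is None else p.pct,
                "star_strand": p.star_strand,
                "stage_flags": ",".join(sorted(p.stage_flags)),
            }
            for p in pairs
        ],
        columns=[
            "mirna_id",
            "gene_symbol",
            "transcript_id",
            "probe_id",
            "r",
            "pct",
            "star_strand",
            "stage_flags",
        ],
    )
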