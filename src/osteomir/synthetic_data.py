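"""Seeded synthetic cohorts with the statistical structure the analysis
assumes, plus a ground-truth manifest for parameter-recovery testing.

The generative model works on the log2 intensity scale.  Every expressed
feature has a per-feature baseline; tumour-derived samples (cell lines,
clinical tumours) add a per-sample latent biological deviation with a larger
spread than normal samples (bone, osteoblasts), and measurement noise is
Gaussian on top.  Latent deviations are centred within each sample group, so
with zero measurement noise group means — and hence fold changes — are exact.

Planted structure:

* differentially expressed miRNAs are shifted by +-de_log2_effect in cell
  lines (and osteoblast-like arms); the clinical arm gets half the shift,
  encoding the intermediate-expression gradient of tumours between
  undifferentiated and fully differentiated tissue as a generative
  assumption for testing, not a biological claim;
* miRNAs sharing a genomic cluster share one latent expression factor and
  one effect sign (polycistronic co-transcription), and each cluster has an
  mRNA host gene coupled positively to the same factor;
* each true miRNA->target pair couples the target mRNA to the miRNA's full
  (effect + latent) deviation through a negative slope, so true pairs are
  anti-correlated across cell lines and their targets inherit differential
  expression in both cohorts; decoy predictions have zero coupling;
* a fraction of miRNAs are star strands (id suffix ``*``) whose predictions
  carry no conservation score; a fraction of non-planted miRNAs sit at
  background level and should fall to the presence filter;
* detection calls are intensity above a configured quantile of the global
  null (background) distribution.

``simulate_qpcr`` emits a reference-anchored Ct table for the validation
arm: two reference assays with group-invariant means, per-group Ct offsets
of -log2(relative expression) for the planted assays, a per-sample pipetting
shift that cancels in dCt, and a configurable fraction of the
lowest-expression wells emitted as undetected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    DetectionMatrix,
    ExpressionMatrix,
    MirnaAnnotation,
    SampleAnnotation,
    TargetPrediction,
    ValidationError,
    write_annotation,
    write_detection_matrix,
    write_expression_matrix,
    write_mirna_annotation,
    write_qpcr_table,
    write_table,
    write_targetscan_predictions,
)
from .qpcr_validation import QpcrTable

TUMOR_GROUPS = ("cell_line", "clinical")


@dataclass
class SimulationConfig:
    """Study design and planted-signal parameters (all effects in log2 units).

    Defaults encode the emulated study design: 19 osteosarcoma cell lines
    against 4 normal bones on the arrays, a 12-sample clinical arm, 5
    osteoblast cultures, strong planted effects (3 log2 units, conservative
    relative to the fold changes such panels report), unit-negative
    miRNA->target coupling, and five decoy predictions per true pair.
    """

    n_cell_lines: int = 19
    n_bone: int = 4
    n_clinical: int = 12
    n_osteoblast: int = 5
    n_mirna: int = 200
    n_mrna: int = 400
    n_de_mirna: int = 20
    de_log2_effect: float = 3.0
    n_true_pairs: int = 20
    coupling_slope: float = -1.0
    noise_sd: float = 0.3
    n_de_mrna: int = 60
    n_decoy_predictions: int = 120
    pct_true_range: tuple[float, float] = (0.5, 1.0)
    pct_decoy_range: tuple[float, float] = (0.0, 1.0)
    frac_star: float = 0.2
    tumor_sd: float = 0.8
    normal_sd: float = 0.2
    frac_unexpressed: float = 0.15
    n_clusters: int = 3
    cluster_size: int = 3
    baseline_range: tuple[float, float] = (7.0, 12.0)
    detection_background: float = 4.0
    detection_quantile: float = 0.99
    n_qpcr_assays: int = 15
    frac_undetected: float = 0.05
    qpcr_sample_shift_sd: float = 0.2
    ct_base_range: tuple[float, float] = (25.0, 31.0)
    reference_ct: tuple[float, float] = (24.0, 26.0)
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_cell_lines": self.n_cell_lines,
            "n_bone": self.n_bone,
            "n_clinical": self.n_clinical,
            "n_osteoblast": self.n_osteoblast,
            "n_mirna": self.n_mirna,
            "n_mrna": self.n_mrna,
            "n_de_mirna": self.n_de_mirna,
            "n_true_pairs": self.n_true_pairs,
            "n_de_mrna": self.n_de_mrna,
            "n_decoy_predictions": self.n_decoy_predictions,
            "n_qpcr_assays": self.n_qpcr_assays,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value}")
        if self.n_de_mirna > self.n_mirna:
            raise ValidationError("n_de_mirna cannot exceed n_mirna")
        if self.n_true_pairs > self.n_de_mirna * self.n_mrna:
            raise ValidationError("n_true_pairs cannot exceed n_de_mirna * n_mrna")
        if self.n_true_pairs > 0 and self.coupling_slope >= 0:
            raise ValidationError("coupling_slope must be negative when planting pairs")
        for name, frac in (("frac_star", self.frac_star), ("frac_unexpressed", self.frac_unexpressed), ("frac_undetected", self.frac_undetected)):
            if not (0.0 <= frac <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {frac}")
        if self.n_clusters * self.cluster_size > max(self.n_de_mirna, 0):
            raise ValidationError("cluster assignment requires n_clusters * cluster_size <= n_de_mirna")
        if self.n_qpcr_assays > self.n_de_mirna:
            raise ValidationError("n_qpcr_assays cannot exceed n_de_mirna")
        if self.noise_sd < 0 or self.tumor_sd < 0 or self.normal_sd < 0:
            raise ValidationError("standard deviations must be non-negative")


@dataclass
class GroundTruthManifest:
    """What was planted, for recovery scoring downstream."""

    de_mirna: list[tuple[str, int]]  # (mirna_id, effect sign)
    true_pairs: list[tuple[str, str]]  # (mirna_id, gene_symbol)
    de_mrna_ids: list[str]
    clusters: dict[str, list[str]]
    host_genes: dict[str, str]  # cluster_id -> gene symbol
    groups: dict[str, list[str]]  # group -> sample ids
    qpcr_assays: list[str]
    qpcr_log2_rel: dict[str, dict[str, float]]  # assay -> group -> log2 RE vs bone

    @property
    def de_mirna_ids(self) -> list[str]:
        return [m for m, _ in self.de_mirna]


@dataclass
class Cohort:
    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    detection: DetectionMatrix
    annotation: SampleAnnotation
    predictions: list[TargetPrediction]
    mirna_annotation: list[MirnaAnnotation]
    truth: GroundTruthManifest


def _sample_ids(config: SimulationConfig) -> dict[str, list[str]]:
    return {
        "cell_line": [f"CL{i + 1:02d}" for i in range(config.n_cell_lines)],
        "bone": [f"BO{i + 1:02d}" for i in range(config.n_bone)],
        "clinical": [f"TU{i + 1:02d}" for i in range(config.n_clinical)],
        "osteoblast": [f"OB{i + 1:02d}" for i in range(config.n_osteoblast)],
    }


def _group_effect(sign: int, effect: float) -> dict[str, float]:
    # cell lines and osteoblast-like arms take the full shift, the clinical
    # arm half of it (intermediate expression), bone is the reference level
    return {
        "cell_line": sign * effect,
        "bone": 0.0,
        "clinical": sign * effect / 2.0,
        "osteoblast": sign * effect,
    }


def _centered_latent(
    rng: np.random.Generator,
    group_of: list[str],
    tumor_sd: float,
    normal_sd: float,
) -> np.ndarray:
    sds = np.array([tumor_sd if g in TUMOR_GROUPS else normal_sd for g in group_of])
    latent = rng.normal(0.0, 1.0, size=len(group_of)) * sds
    for g in set(group_of):
        idx = [i for i, gg in enumerate(group_of) if gg == g]
        latent[idx] -= latent[idx].mean()
    return latent


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate miRNA/mRNA matrices, detection calls, annotations, a
    prediction table and the ground-truth manifest, deterministically for a
    fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    groups = _sample_ids(config)
    sample_ids = [s for g in ("cell_line", "bone", "clinical", "osteoblast") for s in groups[g]]
    group_of = [g for g in ("cell_line", "bone", "clinical", "osteoblast") for _ in groups[g]]
    cohort_tag = {
        "cell_line": "cell_panel",
        "bone": "normal_bone",
        "clinical": "clinical_cohort",
        "osteoblast": "osteoblast_culture",
    }
    annotation = SampleAnnotation.from_mapping(
        dict(zip(sample_ids, group_of)),
        {s: cohort_tag[g] for s, g in zip(sample_ids, group_of)},
    )
    n_samples = len(sample_ids)

    # --- miRNA panel -------------------------------------------------------
    star_count = int(round(config.frac_star * config.n_mirna))
    star_idx = set(rng.choice(config.n_mirna, size=star_count, replace=False).tolist())
    mirna_ids = [
        f"miR-{i + 1:04d}*" if i in star_idx else f"miR-{i + 1:04d}"
        for i in range(config.n_mirna)
    ]
    de_idx = sorted(rng.choice(config.n_mirna, size=config.n_de_mirna, replace=False).tolist())
    de_ids = [mirna_ids[i] for i in de_idx]

    # clusters over the first planted miRNAs, one effect sign per cluster
    clusters: dict[str, list[str]] = {}
    cluster_of: dict[str, str] = {}
    pos = 0
    for c in range(config.n_clusters):
        cid = f"clu-{c + 1}"
        members = de_ids[pos : pos + config.cluster_size]
        clusters[cid] = members
        for m in members:
            cluster_of[m] = cid
        pos += config.cluster_size
    signs: dict[str, int] = {}
    flip = 1
    for cid, members in clusters.items():
        for m in members:
            signs[m] = flip
        flip = -flip
    for m in de_ids[pos:]:
        signs[m] = flip
        flip = -flip

    # families: clusters are families; pair up some singleton hits
    family_of: dict[str, str] = {}
    for cid, members in clusters.items():
        for m in members:
            family_of[m] = f"fam-{cid}"
    singles = de_ids[pos:]
    for k in range(0, max(len(singles) - 1, 0), 4):
        pair = singles[k : k + 2]
        if len(pair) == 2:
            for m in pair:
                family_of[m] = f"fam-s{k // 4 + 1}"

    # unexpressed (background) miRNAs among the non-planted ones
    non_de = [i for i in range(config.n_mirna) if i not in set(de_idx)]
    n_unexpr = int(round(config.frac_unexpressed * config.n_mirna))
    n_unexpr = min(n_unexpr, len(non_de))
    unexpr_idx = set(rng.choice(non_de, size=n_unexpr, replace=False).tolist()) if n_unexpr else set()

    baselines_mir = rng.uniform(*config.baseline_range, size=config.n_mirna)
    for i in unexpr_idx:
        baselines_mir[i] = config.detection_background

    cluster_latent = {
        cid: _centered_latent(rng, group_of, config.tumor_sd, config.normal_sd)
        for cid in clusters
    }
    mirna_dev = np.zeros((config.n_mirna, n_samples))
    for i, mid in enumerate(mirna_ids):
        if i in unexpr_idx:
            continue
        if mid in cluster_of:
            latent = cluster_latent[cluster_of[mid]]
        else:
            latent = _centered_latent(rng, group_of, config.tumor_sd, config.normal_sd)
        eff = _group_effect(signs.get(mid, 0), config.de_log2_effect if mid in signs else 0.0)
        mirna_dev[i] = latent + np.array([eff[g] for g in group_of])
    mirna_values = (
        baselines_mir[:, None]
        + mirna_dev
        + rng.normal(0.0, 1.0, size=(config.n_mirna, n_samples)) * config.noise_sd
    )

    # --- mRNA panel --------------------------------------------------------
    gene_ids = [f"GENE{i + 1:04d}" for i in range(config.n_mrna)]
    baselines_gene = rng.uniform(*config.baseline_range, size=config.n_mrna)

    # true pairs: a few genes take two miRNAs (cluster/family mates where
    # possible), the rest one each
    n_multi = config.n_true_pairs // 4
    mate_pool: list[tuple[str, str]] = []
    for members in clusters.values():
        for a, b in zip(members, members[1:]):
            mate_pool.append((a, b))
    fam_groups: dict[str, list[str]] = {}
    for m, f in family_of.items():
        if m not in cluster_of:
            fam_groups.setdefault(f, []).append(m)
    for members in fam_groups.values():
        for a, b in zip(members, members[1:]):
            mate_pool.append((a, b))

    gene_pool = rng.permutation(config.n_mrna).tolist()
    true_pairs: list[tuple[str, str]] = []
    target_mirnas: dict[str, list[str]] = {}
    gi = 0
    for k in range(n_multi):
        if len(true_pairs) + 2 > config.n_true_pairs:
            break
        gene = gene_ids[gene_pool[gi]]
        gi += 1
        a, b = mate_pool[k % len(mate_pool)] if mate_pool else (de_ids[0], de_ids[1 % len(de_ids)])
        target_mirnas[gene] = [a, b]
        true_pairs.extend([(a, gene), (b, gene)])
    mi = 0
    while len(true_pairs) < config.n_true_pairs:
        gene = gene_ids[gene_pool[gi]]
        gi += 1
        m = de_ids[mi % len(de_ids)]
        mi += 1
        if (m, gene) in true_pairs:
            continue
        target_mirnas[gene] = [m]
        true_pairs.append((m, gene))
    target_genes = list(target_mirnas)

    # independently differentially expressed genes (no miRNA coupling)
    remaining = [gene_ids[i] for i in gene_pool[gi:]]
    de_mrna_ids = remaining[: config.n_de_mrna]
    remaining = remaining[config.n_de_mrna :]
    gene_signs = {g: (1 if k % 2 == 0 else -1) for k, g in enumerate(de_mrna_ids)}

    # host genes: one per cluster, positively coupled to the cluster factor
    host_genes: dict[str, str] = {}
    for cid in clusters:
        if not remaining:
            break
        host_genes[cid] = remaining.pop(0)

    mir_index = {m: i for i, m in enumerate(mirna_ids)}
    mrna_values = np.empty((config.n_mrna, n_samples))
    effect_cache = {
        s: np.array([_group_effect(s, config.de_log2_effect)[g] for g in group_of])
        for s in (-1, 1)
    }
    zero_eff = np.zeros(n_samples)
    host_of_gene = {g: cid for cid, g in host_genes.items()}
    for i, gene in enumerate(gene_ids):
        if gene in target_mirnas:
            devs = np.mean(
                [mirna_dev[mir_index[m]] for m in target_mirnas[gene]], axis=0
            )
            signal = config.coupling_slope * devs
        elif gene in host_of_gene:
            cid = host_of_gene[gene]
            sign = signs[clusters[cid][0]]
            signal = cluster_latent[cid] + effect_cache[sign]
        elif gene in gene_signs:
            latent = _centered_latent(rng, group_of, config.tumor_sd, config.normal_sd)
            signal = latent + effect_cache[gene_signs[gene]]
        else:
            signal = _centered_latent(rng, group_of, config.tumor_sd, config.normal_sd)
        mrna_values[i] = baselines_gene[i] + signal
    mrna_values += rng.normal(0.0, 1.0, size=mrna_values.shape) * config.noise_sd

    # --- detection calls ---------------------------------------------------
    threshold = stats.norm.ppf(config.detection_quantile, loc=config.detection_background, scale=1.0)
    detection = DetectionMatrix(
        list(mirna_ids), list(sample_ids), mirna_values > threshold
    )

    # --- prediction table --------------------------------------------------
    def _pred(mid: str, gene: str, pct_range: tuple[float, float]) -> TargetPrediction:
        star = mid.endswith("*")
        pct = None if star else float(rng.uniform(*pct_range))
        fam = family_of.get(mid, mid)
        return TargetPrediction(
            mirna_id=mid,
            family_id=fam,
            gene_symbol=gene,
            transcript_id=f"NM_{gene_ids.index(gene) + 1:06d}.1",
            pct=pct,
            star_strand=star,
        )

    predictions = [_pred(m, g, config.pct_true_range) for m, g in true_pairs]
    taken = set(true_pairs)
    expressed_non_de = [mirna_ids[i] for i in non_de if i not in unexpr_idx]
    non_target_genes = [g for g in gene_ids if g not in target_mirnas]
    n_hard = config.n_decoy_predictions // 2
    made = 0
    guard = 0
    while made < config.n_decoy_predictions and guard < 50 * max(config.n_decoy_predictions, 1):
        guard += 1
        if made < n_hard and de_ids and de_mrna_ids:
            m = de_ids[int(rng.integers(len(de_ids)))]
            g = de_mrna_ids[int(rng.integers(len(de_mrna_ids)))]
        elif expressed_non_de and non_target_genes:
            if rng.random() < 0.5 and expressed_non_de:
                m = expressed_non_de[int(rng.integers(len(expressed_non_de)))]
                g = gene_ids[int(rng.integers(len(gene_ids)))]
            else:
                m = de_ids[int(rng.integers(len(de_ids)))] if de_ids else expressed_non_de[0]
                g = non_target_genes[int(rng.integers(len(non_target_genes)))]
        else:
            break
        if (m, g) in taken:
            continue
        taken.add((m, g))
        predictions.append(_pred(m, g, config.pct_decoy_range))
        made += 1

    mirna_ann = [
        MirnaAnnotation(
            mirna_id=m,
            family_id=family_of.get(m),
            cluster_id=cluster_of.get(m),
            host_gene=host_genes.get(cluster_of.get(m, ""), None),
        )
        for m in mirna_ids
    ]

    # --- qPCR truth --------------------------------------------------------
    qpcr_assays = de_ids[: config.n_qpcr_assays]
    qpcr_log2_rel = {
        a: {
            g: _group_effect(signs[a], config.de_log2_effect)[g]
            for g in ("bone", "clinical", "osteoblast")
        }
        for a in qpcr_assays
    }

    truth = GroundTruthManifest(
        de_mirna=[(m, signs[m]) for m in de_ids],
        true_pairs=true_pairs,
        de_mrna_ids=list(de_mrna_ids),
        clusters=clusters,
        host_genes=host_genes,
        groups=groups,
        qpcr_assays=qpcr_assays,
        qpcr_log2_rel=qpcr_log2_rel,
    )
    _check_manifest(truth, mirna_ids, gene_ids)

    return Cohort(
        mirna=ExpressionMatrix(list(mirna_ids), list(sample_ids), mirna_values, scale="log2"),
        mrna=ExpressionMatrix(list(gene_ids), list(sample_ids), mrna_values, scale="log2"),
        detection=detection,
        annotation=annotation,
        predictions=predictions,
        mirna_annotation=mirna_ann,
        truth=truth,
    )


def _check_manifest(truth: GroundTruthManifest, mirna_ids: list[str], gene_ids: list[str]) -> None:
    mir = set(mirna_ids)
    genes = set(gene_ids)
    for m, _ in truth.de_mirna:
        if m not in mir:
            raise ValidationError(f"manifest DE miRNA {m!r} not in emitted matrix")
    for m, g in truth.true_pairs:
        if m not in mir or g not in genes:
            raise ValidationError(f"manifest pair ({m!r}, {g!r}) not in emitted matrices")
    for g in truth.de_mrna_ids:
        if g not in genes:
            raise ValidationError(f"manifest DE gene {g!r} not in emitted matrix")


def simulate_qpcr(config: SimulationConfig, truth: GroundTruthManifest) -> QpcrTable:
    """Ct table for the validation arm (clinical + bone + osteoblast samples,
    planted assays plus RNU44/RNU6B references)."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if config.seed < 2**31 - 1 else 0)
    samples = [s for g in ("clinical", "bone", "osteoblast") for s in truth.groups[g]]
    group_of = {s: g for g in ("clinical", "bone", "osteoblast") for s in truth.groups[g]}
    shifts = {s: rng.normal(0.0, 1.0) * config.qpcr_sample_shift_sd for s in samples}
    ref_levels = {"RNU44": config.reference_ct[0], "RNU6B": config.reference_ct[1]}
    rows = []
    for ref, level in ref_levels.items():
        for s in samples:
            ct = level + shifts[s] + rng.normal(0.0, 1.0) * config.noise_sd
            rows.append((s, ref, ct, False))
    target_rows = []
    for assay in truth.qpcr_assays:
        base = float(rng.uniform(*config.ct_base_range))
        for s in samples:
            log2_rel = truth.qpcr_log2_rel[assay][group_of[s]]
            ct = base - log2_rel + shifts[s] + rng.normal(0.0, 1.0) * config.noise_sd
            target_rows.append((s, assay, ct, False))
    if config.frac_undetected > 0 and target_rows:
        cts = np.array([r[2] for r in target_rows])
        cut = float(np.quantile(cts, 1.0 - config.frac_undetected))
        target_rows = [
            (s, a, (np.nan if ct > cut else ct), ct > cut) for s, a, ct, _ in target_rows
        ]
    frame = pd.DataFrame(
        rows + target_rows, columns=["sample_id", "assay_id", "ct", "undetected"]
    )
    return QpcrTable(frame)


# ---------------------------------------------------------------------------
# on-disk emission
# ---------------------------------------------------------------------------


def write_truth(truth: GroundTruthManifest, outdir: Path | str) -> None:
    outdir = Path(outdir)
    write_table(
        pd.DataFrame(truth.de_mirna, columns=["mirna_id", "sign"]),
        outdir / "truth_de_mirna.tsv",
    )
    write_table(
        pd.DataFrame(truth.true_pairs, columns=["mirna_id", "gene_symbol"]),
        outdir / "truth_pairs.tsv",
    )
    write_table(
        pd.DataFrame({"gene_symbol": truth.de_mrna_ids}), outdir / "truth_de_mrna.tsv"
    )
    qpcr_rows = [
        {"assay_id": a, "group": g, "log2_rel": v}
        for a, per_group in truth.qpcr_log2_rel.items()
        for g, v in per_group.items()
    ]
    write_table(
        pd.DataFrame(qpcr_rows, columns=["assay_id", "group", "log2_rel"]),
        outdir / "truth_qpcr.tsv",
    )


def write_cohort(
    cohort: Cohort, outdir: Path | str, qpcr: QpcrTable | None = None
) -> dict[str, Path]:
    """Write every canonical TSV plus the truth manifest; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna": outdir / "mirna.tsv",
        "mrna": outdir / "mrna.tsv",
        "detection": outdir / "detection.tsv",
        "annotation": outdir / "annotation.tsv",
        "predictions": outdir / "predictions.tsv",
        "mirna_annotation": outdir / "mirna_annotation.tsv",
    }
    write_expression_matrix(cohort.mirna, paths["mirna"])
    write_expression_matrix(cohort.mrna, paths["mrna"])
    write_detection_matrix(cohort.detection, paths["detection"])
    write_annotation(cohort.annotation, paths["annotation"])
    write_targetscan_predictions(cohort.predictions, paths["predictions"])
    write_mirna_annotation(cohort.mirna_annotation, paths["mirna_annotation"])
    write_truth(cohort.truth, outdir)
    if qpcr is not None:
        paths["qpcr"] = outdir / "qpcr.tsv"
        write_qpcr_table(qpcr, paths["qpcr"])
    return paths
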