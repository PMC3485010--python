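"""Readers and writers for every on-disk artifact the pipeline touches.

The canonical dialect is UTF-8 tab-separated text with '.' as the decimal
separator.  Matrix files carry a header row whose first cell is the literal
``feature_id`` followed by sample identifiers; each subsequent row is a
feature identifier followed by numeric cells (an empty cell encodes a
missing value).  Detection matrices use the same layout with 0/1 cells.
Long-format tables (annotations, target predictions, qPCR plates) carry a
named header row.  A read -> write -> read round trip is the identity, and
write(read(f)) reproduces a canonical file byte for byte.

A GEO series-matrix reader is provided as an optional convenience for the
accession-based reproduction path; the pipeline itself only depends on the
canonical dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

GROUPS = ("cell_line", "bone", "clinical", "osteoblast")

_MISSING = ""
_QPCR_UNDETECTED = "Undetermined"


class ParseError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Feature-by-sample intensity matrix.

    ``scale`` is ``"raw"`` for linear intensities and ``"log2"`` after log
    transformation.  Missing entries are NaN and remain explicit: parsers and
    writers never coerce them to zero.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "log2"

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.feature_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scale: str = "log2") -> "ExpressionMatrix":
        return cls(
            feature_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            scale=scale,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx],
            scale=self.scale,
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return ExpressionMatrix(
            feature_ids=[self.feature_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx, :],
            scale=self.scale,
        )


@dataclass
class DetectionMatrix:
    """Boolean detected/not-detected calls on the same axes as a companion
    expression matrix."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError("detection matrix shape does not match its axes")
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.feature_ids), columns=list(self.sample_ids)
        )

    def matches(self, m: ExpressionMatrix) -> bool:
        return self.feature_ids == m.feature_ids and self.sample_ids == m.sample_ids


@dataclass
class SampleAnnotation:
    """Sample-to-group assignment (cell_line | bone | clinical | osteoblast)
    plus a free-text cohort tag."""

    frame: pd.DataFrame  # columns: sample_id, group, cohort

    def __post_init__(self) -> None:
        required = ["sample_id", "group", "cohort"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"annotation missing columns {missing}")
        self.frame = self.frame[required].copy()
        self.frame["sample_id"] = self.frame["sample_id"].astype(str)
        _check_unique(list(self.frame["sample_id"]), "sample")
        bad = sorted(set(self.frame["group"]) - set(GROUPS))
        if bad:
            raise ValidationError(f"unknown group labels {bad}; expected one of {GROUPS}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def group_of(self, sample_id: str) -> str:
        row = self.frame[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample {sample_id!r} has no annotation")
        return row["group"].iloc[0]

    def samples_in_group(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}")
        return list(self.frame.loc[self.frame["group"] == group, "sample_id"])

    @classmethod
    def from_mapping(cls, groups: dict[str, str], cohorts: dict[str, str] | None = None) -> "SampleAnnotation":
        cohorts = cohorts or {}
        frame = pd.DataFrame(
            {
                "sample_id": list(groups),
                "group": [groups[s] for s in groups],
                "cohort": [cohorts.get(s, groups[s]) for s in groups],
            }
        )
        return cls(frame)


@dataclass(frozen=True)
class TargetPrediction:
    """One predicted miRNA -> transcript interaction with its conservation
    score.

    ``pct`` is the probability of preferentially conserved targeting; star
    strands (passenger strands, id suffix ``*``) have no conservation score
    and carry ``pct=None``.
    """

    mirna_id: str
    family_id: str
    gene_symbol: str
    transcript_id: str
    pct: float | None
    star_strand: bool = False

    def __post_init__(self) -> None:
        if self.pct is not None and not (0.0 <= self.pct <= 1.0):
            raise ValidationError(
                f"P_CT for {self.mirna_id}->{self.gene_symbol} is {self.pct}; "
                "must lie in [0, 1]"
            )


@dataclass(frozen=True)
class MirnaAnnotation:
    """Family, genomic-cluster and host-gene annotation for one miRNA."""

    mirna_id: str
    family_id: str | None = None
    cluster_id: str | None = None
    host_gene: str | None = None


# ---------------------------------------------------------------------------
# low-level canonical-dialect helpers
# ---------------------------------------------------------------------------


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(i for i, n in seen.items() if n > 1)
    if dups:
        raise ValidationError(f"duplicate {what} ids: {dups}")


def _read_rows(path: Path | str) -> list[list[str]]:
    """Split a canonical-dialect file into cell rows, enforcing a rectangular
    shape.  Ragged rows raise a ParseError naming the 1-based line number."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines = lines[:-1]
    if not lines:
        raise ParseError(f"{path}: file is empty")
    rows = [line.split("\t") for line in lines]
    width = len(rows[0])
    for lineno, row in enumerate(rows, start=1):
        if len(row) != width:
            raise ParseError(
                f"{path}: line {lineno} has {len(row)} fields, expected {width}"
            )
    return rows


def _parse_cell(cell: str, path: Path | str, lineno: int, colname: str) -> float:
    if cell == _MISSING:
        return np.nan
    try:
        return float(cell)
    except ValueError as exc:
        raise ParseError(
            f"{path}: line {lineno}, column {colname!r}: "
            f"cannot parse {cell!r} as a number"
        ) from exc


def _fmt(x: float) -> str:
    if isinstance(x, float) and np.isnan(x):
        return _MISSING
    return repr(float(x))


# ---------------------------------------------------------------------------
# matrix io
# ---------------------------------------------------------------------------


def read_expression_matrix(path: Path | str, scale_hint: str = "log2") -> ExpressionMatrix:
    """Read a canonical-dialect feature-by-sample matrix.

    Row and column order are preserved exactly; duplicate feature or sample
    identifiers are rejected.
    """
    rows = _read_rows(path)
    header = rows[0]
    sample_ids = header[1:]
    feature_ids = [r[0] for r in rows[1:]]
    values = np.empty((len(feature_ids), len(sample_ids)), dtype=float)
    for i, row in enumerate(rows[1:], start=2):
        for j, cell in enumerate(row[1:]):
            values[i - 2, j] = _parse_cell(cell, path, i, sample_ids[j])
    return ExpressionMatrix(feature_ids, sample_ids, values, scale=scale_hint)


def write_expression_matrix(m: ExpressionMatrix, path: Path | str) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(m.sample_ids) + "\n")
        for i, fid in enumerate(m.feature_ids):
            fh.write(fid + "\t" + "\t".join(_fmt(v) for v in m.values[i]) + "\n")


def read_detection_matrix(path: Path | str) -> DetectionMatrix:
    rows = _read_rows(path)
    sample_ids = rows[0][1:]
    feature_ids = [r[0] for r in rows[1:]]
    values = np.empty((len(feature_ids), len(sample_ids)), dtype=bool)
    for i, row in enumerate(rows[1:], start=2):
        for j, cell in enumerate(row[1:]):
            if cell not in ("0", "1"):
                raise ParseError(
                    f"{path}: line {i}: detection cell must be 0 or 1, got {cell!r}"
                )
            values[i - 2, j] = cell == "1"
    return DetectionMatrix(feature_ids, sample_ids, values)


def write_detection_matrix(d: DetectionMatrix, path: Path | str) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(d.sample_ids) + "\n")
        for i, fid in enumerate(d.feature_ids):
            fh.write(fid + "\t" + "\t".join("1" if v else "0" for v in d.values[i]) + "\n")


# ---------------------------------------------------------------------------
# long-format tables
# ---------------------------------------------------------------------------


def _read_table(path: Path | str, required: Sequence[str]) -> pd.DataFrame:
    rows = _read_rows(path)
    header = rows[0]
    missing = [c for c in required if c not in header]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    frame = pd.DataFrame(rows[1:], columns=header)
    return frame


def read_annotation(path: Path | str) -> SampleAnnotation:
    frame = _read_table(path, ["sample_id", "group", "cohort"])
    return SampleAnnotation(frame)


def write_annotation(ann: SampleAnnotation, path: Path | str) -> None:
    _write_frame(ann.frame, path)


def read_targetscan_predictions(path: Path | str) -> list[TargetPrediction]:
    """Read a TargetScan-style prediction table.

    Columns: ``mirna_id``, ``family_id``, ``gene_symbol``, ``transcript_id``,
    ``pct``.  An empty ``pct`` cell becomes a missing value (the convention
    for star strands, which have no conservation score); any numeric value
    must lie in [0, 1].
    """
    frame = _read_table(path, ["mirna_id", "family_id", "gene_symbol", "transcript_id", "pct"])
    preds = []
    for lineno, row in enumerate(frame.itertuples(index=False), start=2):
        pct = None if row.pct == _MISSING else _parse_cell(row.pct, path, lineno, "pct")
        preds.append(
            TargetPrediction(
                mirna_id=row.mirna_id,
                family_id=row.family_id,
                gene_symbol=row.gene_symbol,
                transcript_id=row.transcript_id,
                pct=pct,
                star_strand=row.mirna_id.endswith("*"),
            )
        )
    return preds


def write_targetscan_predictions(preds: Sequence[TargetPrediction], path: Path | str) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("mirna_id\tfamily_id\tgene_symbol\ttranscript_id\tpct\n")
        for p in preds:
            pct = _MISSING if p.pct is None else _fmt(p.pct)
            fh.write(f"{p.mirna_id}\t{p.family_id}\t{p.gene_symbol}\t{p.transcript_id}\t{pct}\n")


def read_mirna_annotation(path: Path | str) -> list[MirnaAnnotation]:
    frame = _read_table(path, ["mirna_id", "family_id", "cluster_id", "host_gene"])
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            MirnaAnnotation(
                mirna_id=row.mirna_id,
                family_id=row.family_id or None,
                cluster_id=row.cluster_id or None,
                host_gene=row.host_gene or None,
            )
        )
    _check_unique([a.mirna_id for a in out], "miRNA")
    return out


def write_mirna_annotation(anns: Sequence[MirnaAnnotation], path: Path | str) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("mirna_id\tfamily_id\tcluster_id\thost_gene\n")
        for a in anns:
            fh.write(
                f"{a.mirna_id}\t{a.family_id or ''}\t{a.cluster_id or ''}\t{a.host_gene or ''}\n"
            )


def read_qpcr_table(path: Path | str):
    """Read a long-format qPCR plate: sample_id, assay_id, ct.

    The sentinel ``Undetermined`` marks an undetected well and is parsed as
    an explicit flag, never as a number; imputation to the Ct ceiling happens
    downstream.  Negative Ct values are rejected.
    """
    from .qpcr_validation import QpcrTable

    frame = _read_table(path, ["sample_id", "assay_id", "ct"])
    records = []
    for lineno, row in enumerate(frame.itertuples(index=False), start=2):
        if row.ct == _QPCR_UNDETECTED:
            records.append((row.sample_id, row.assay_id, np.nan, True))
            continue
        ct = _parse_cell(row.ct, path, lineno, "ct")
        if ct < 0:
            raise ValidationError(
                f"{path}: line {lineno}: negative Ct {ct} for "
                f"sample {row.sample_id!r}, assay {row.assay_id!r}"
            )
        records.append((row.sample_id, row.assay_id, ct, False))
    frame = pd.DataFrame(records, columns=["sample_id", "assay_id", "ct", "undetected"])
    return QpcrTable(frame)


def write_qpcr_table(table, path: Path | str) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("sample_id\tassay_id\tct\n")
        for row in table.frame.itertuples(index=False):
            ct = _QPCR_UNDETECTED if row.undetected else _fmt(row.ct)
            fh.write(f"{row.sample_id}\t{row.assay_id}\t{ct}\n")


def _write_frame(frame: pd.DataFrame, path: Path | str) -> None:
    """Write any result table in the canonical dialect (floats via repr, so a
    round trip is exact)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(str(c) for c in frame.columns) + "\n")
        for row in frame.itertuples(index=False):
            cells = []
            for v in row:
                if isinstance(v, float):
                    cells.append(_fmt(v))
                elif isinstance(v, (bool, np.bool_)):
                    cells.append("1" if v else "0")
                elif v is None:
                    cells.append(_MISSING)
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


write_table = _write_frame


# ---------------------------------------------------------------------------
# GEO series-matrix (optional, accession-based reproduction path)
# ---------------------------------------------------------------------------


def read_series_matrix(path: Path | str) -> ExpressionMatrix:
    """Parse a GEO series-matrix text file into an ExpressionMatrix.

    The body between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` is read at full printed precision; sample
    titles from the ``!Sample_title`` header line are used as sample ids when
    present, otherwise the body's own column headers.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").split("\n")
    titles: list[str] | None = None
    begin = end = None
    for i, line in enumerate(lines):
        if line.startswith("!Sample_title"):
            cells = line.split("\t")[1:]
            titles = [c.strip('"') for c in cells]
        elif line.startswith("!series_matrix_table_begin"):
            begin = i
        elif line.startswith("!series_matrix_table_end"):
            end = i
    if begin is None or end is None:
        raise ParseError(f"{path}: series-matrix table delimiters not found")
    body = [line.split("\t") for line in lines[begin + 1 : end] if line]
    if not body:
        raise ParseError(f"{path}: series-matrix table is empty")
    header = [c.strip('"') for c in body[0]]
    sample_ids = titles if titles is not None else header[1:]
    if len(sample_ids) != len(header) - 1:
        raise ParseError(
            f"{path}: {len(sample_ids)} sample titles for {len(header) - 1} data columns"
        )
    feature_ids = [r[0].strip('"') for r in body[1:]]
    values = np.empty((len(feature_ids), len(sample_ids)), dtype=float)
    for i, row in enumerate(body[1:]):
        if len(row) != len(header):
            raise ParseError(f"{path}: ragged series-matrix row for feature {row[0]!r}")
        for j, cell in enumerate(row[1:]):
            values[i, j] = np.nan if cell in ("", "null", "NULL") else float(cell)
    return ExpressionMatrix(feature_ids, sample_ids, values, scale="log2")
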