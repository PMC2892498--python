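"""Readers and writers for expression matrices, bicluster lists and reports.

Two open bicluster dialects are supported as the ingestion contract for
outputs of external biclustering tools (whose native formats are versioned
and undocumented):

- JSON: ``{"dataset": str, "biclusters": [{"id", "source_algorithm",
  "source_rank", "genes": [...], "conditions": [...]}]}``
- two-line text: per record, line 1 = tab-separated gene ids, line 2 =
  tab-separated condition ids; records separated by blank lines; source
  rank is the record's 1-based position.

All writers are deterministic: stable column order and 6-significant-digit
float formatting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import DataError
from .matrix import Bicluster, ExpressionMatrix
from .model import impute_additive
from .ranking import BiclusterCollection, RankedAssessments
from .scoring import BiclusterAssessment
from .simulate import ImplantSpec, SyntheticDataset

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_bicluster_list",
    "write_bicluster_list",
    "write_assessments_tsv",
    "write_ranked_tsv",
    "write_report_json",
    "write_truth_json",
    "read_truth_json",
    "read_config",
]

PathLike = Union[str, Path]

_NA_TOKENS = {"", "NA", "NaN", "nan", "null", "NULL"}


def _fmt(x: float) -> str:
    return format(x, ".6g")


def read_expression_matrix(path: PathLike, missing: str = "error") -> ExpressionMatrix:
    """Read a gene x condition log-expression TSV.

    Layout: header row of condition ids (first cell ignored), then one row
    per gene: gene id followed by tab-separated values.

    ``missing="error"`` (default) rejects any non-numeric/missing cell;
    ``missing="impute"`` fills missing cells with the additive-model
    prediction (row mean + column mean - grand mean over observed cells).
    """
    if missing not in ("error", "impute"):
        raise ValueError(f"missing policy must be 'error' or 'impute', got {missing!r}")
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        condition_ids = header[1:]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(condition_ids) + 1:
                raise DataError(
                    f"{path.name}:{lineno}: expected {len(condition_ids) + 1} "
                    f"columns, found {len(cells)}"
                )
            gene = cells[0]
            if gene in gene_ids:
                raise DataError(f"{path.name}:{lineno}: duplicate gene id {gene!r}")
            vals = []
            for col, cell in enumerate(cells[1:], start=2):
                token = cell.strip()
                if token in _NA_TOKENS:
                    vals.append(np.nan)
                    continue
                try:
                    vals.append(float(token))
                except ValueError:
                    raise DataError(
                        f"{path.name}:{lineno}: non-numeric cell {cell!r} in column {col}"
                    ) from None
            gene_ids.append(gene)
            rows.append(vals)
    if not gene_ids:
        raise DataError(f"{path.name}: no data rows")
    if len(set(condition_ids)) != len(condition_ids):
        raise DataError(f"{path.name}:1: duplicate condition ids in header")
    values = np.asarray(rows, dtype=float)
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        if missing == "error":
            i, j = np.argwhere(np.isnan(values))[0]
            raise DataError(
                f"{path.name}: missing value at gene {gene_ids[i]!r}, "
                f"condition {condition_ids[j]!r} (policy=error)"
            )
        values = impute_additive(values)
        logger.info("imputed %d missing cell(s) with the additive-model fill", n_missing)
    return ExpressionMatrix(values, gene_ids, condition_ids)


def write_expression_matrix(matrix: ExpressionMatrix, path: PathLike) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.condition_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            fh.write(g + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_bicluster_list(
    path: PathLike,
    format: str = "json",
    source_algorithm: Optional[str] = None,
    dataset_label: str = "",
) -> BiclusterCollection:
    """Load a bicluster list in the JSON or two-line-text dialect.

    Records with an empty gene or condition list are skipped with a logged
    count rather than aborting the load.
    """
    path = Path(path)
    if format == "json":
        return _read_biclusters_json(path, source_algorithm, dataset_label)
    if format in ("two-line-text", "text"):
        return _read_biclusters_text(path, source_algorithm, dataset_label)
    raise ValueError(f"unknown bicluster format {format!r}")


def _read_biclusters_json(
    path: Path, source_algorithm: Optional[str], dataset_label: str
) -> BiclusterCollection:
    with path.open("r", encoding="utf-8") as fh:
        doc = json.load(fh)
    records = doc.get("biclusters", []) if isinstance(doc, dict) else doc
    label = dataset_label or (doc.get("dataset", "") if isinstance(doc, dict) else "")
    biclusters: list[Bicluster] = []
    skipped = 0
    for k, rec in enumerate(records, start=1):
        genes = rec.get("genes", [])
        conds = rec.get("conditions", [])
        if not genes or not conds:
            skipped += 1
            logger.warning("%s: record %d has an empty gene or condition list; skipped", path.name, k)
            continue
        biclusters.append(
            Bicluster(
                gene_ids=frozenset(map(str, genes)),
                condition_ids=frozenset(map(str, conds)),
                source_algorithm=str(
                    rec.get("source_algorithm") or source_algorithm or "unknown"
                ),
                source_rank=int(rec["source_rank"]) if rec.get("source_rank") else k,
                id=str(rec["id"]) if rec.get("id") else None,
            )
        )
    if skipped:
        logger.info("%s: skipped %d empty record(s)", path.name, skipped)
    return BiclusterCollection(biclusters, label)


def _read_biclusters_text(
    path: Path, source_algorithm: Optional[str], dataset_label: str
) -> BiclusterCollection:
    blocks: list[list[str]] = [[]]
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.strip():
            blocks[-1].append(line)
        elif blocks[-1]:
            blocks.append([])
    if blocks and not blocks[-1]:
        blocks.pop()
    biclusters: list[Bicluster] = []
    skipped = 0
    for k, block in enumerate(blocks, start=1):
        if len(block) != 2:
            raise DataError(
                f"{path.name}: record {k} has {len(block)} line(s); expected 2 "
                "(gene ids line then condition ids line)"
            )
        genes = [g for g in block[0].split("\t") if g]
        conds = [c for c in block[1].split("\t") if c]
        if not genes or not conds:
            skipped += 1
            logger.warning("%s: record %d empty; skipped", path.name, k)
            continue
        biclusters.append(
            Bicluster(
                gene_ids=frozenset(genes),
                condition_ids=frozenset(conds),
                source_algorithm=source_algorithm or "unknown",
                source_rank=k,
            )
        )
    if skipped:
        logger.info("%s: skipped %d empty record(s)", path.name, skipped)
    return BiclusterCollection(biclusters, dataset_label)


def write_bicluster_list(collection: BiclusterCollection, path: PathLike) -> None:
    """Write the JSON dialect (sorted id lists for byte-stable round trips)."""
    doc = {
        "dataset": collection.dataset_label,
        "biclusters": [
            {
                "id": b.label,
                "source_algorithm": b.source_algorithm,
                "source_rank": b.source_rank,
                "genes": sorted(b.gene_ids),
                "conditions": sorted(b.condition_ids),
            }
            for b in collection.biclusters
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


_ASSESS_COLUMNS = [
    "bicluster_id",
    "source_algorithm",
    "source_rank",
    "n_genes",
    "n_conditions",
    "T1",
    "B1",
    "E1",
    "T2",
    "B2",
    "E2",
    "SB",
    "TS",
    "group_used",
    "type",
]


def _assessment_row(asmt: BiclusterAssessment) -> list[str]:
    b = asmt.bicluster
    c1, c2 = asmt.components_g1, asmt.components_g2
    return [
        b.label,
        b.source_algorithm,
        str(b.source_rank) if b.source_rank is not None else "",
        str(b.n_genes),
        str(b.n_conditions),
        _fmt(c1.T),
        _fmt(c1.B),
        _fmt(c1.E),
        _fmt(c2.T),
        _fmt(c2.B),
        _fmt(c2.E),
        _fmt(asmt.SB),
        _fmt(asmt.TS),
        str(asmt.group_used),
        asmt.coexpression_type,
    ]


def write_assessments_tsv(assessments: list[BiclusterAssessment], path: PathLike) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_ASSESS_COLUMNS) + "\n")
        for asmt in assessments:
            fh.write("\t".join(_assessment_row(asmt)) + "\n")


def write_ranked_tsv(ranked: RankedAssessments, path: PathLike) -> None:
    cols = ["unified_rank"] + _ASSESS_COLUMNS
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for rank, asmt in zip(ranked.unified_ranks, ranked.entries):
            fh.write("\t".join([str(rank)] + _assessment_row(asmt)) + "\n")


def read_ranked_tsv(path: PathLike) -> pd.DataFrame:
    """Load a ranked TSV back as a DataFrame (for the report subcommand)."""
    return pd.read_csv(path, sep="\t")


def write_report_json(report: dict, path: PathLike) -> None:
    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_jsonify) + "\n",
        encoding="utf-8",
    )


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_truth_json(dataset: SyntheticDataset, path: PathLike) -> None:
    doc = [
        {
            "bicluster": {
                "genes": sorted(b.gene_ids),
                "conditions": sorted(b.condition_ids),
                "source_algorithm": b.source_algorithm,
            },
            "spec": asdict(spec),
        }
        for b, spec in dataset.truth
    ]
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_truth_json(path: PathLike) -> list[tuple[Bicluster, ImplantSpec]]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    out = []
    for rec in doc:
        b = rec["bicluster"]
        out.append(
            (
                Bicluster(
                    gene_ids=frozenset(b["genes"]),
                    condition_ids=frozenset(b["conditions"]),
                    source_algorithm=b.get("source_algorithm", "truth"),
                ),
                ImplantSpec(**rec["spec"]),
            )
        )
    return out


def read_config(path: PathLike) -> dict[str, str]:
    """Parse a simple ``key = value`` config file; '#' starts a comment."""
    config: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise DataError(f"config line {lineno}: expected 'key = value', got {line!r}")
        key, value = stripped.split("=", 1)
        config[key.strip()] = value.strip()
    return config
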