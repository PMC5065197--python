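"""Readers and writers for the delimited formats the tool touches.

Expression matrices are genes-in-rows delimited text (TSV/CSV) with gene ids
in the first column and sample ids in the header row; the GCT 1.2 dialect
("#1.2" header, dimensions line, Name/Description columns) is read-only.
Labels are two-column files (sample_id, label).  Matrices are written with
full double precision so a write/read round trip is exact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import ClusterAssignment, ConsensusMatrix
from .evaluation import ExperimentResult
from .filtering import FilterReport
from .nmf import ExpressionMatrix

logger = logging.getLogger("nmfpost")

#: full-precision float format; repr-roundtrips doubles
FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """Malformed input file; the message names the offending location."""


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of a run, emitted alongside every output."""

    command: str
    input: str | None = None
    k: int | None = None
    k_range: list[int] | None = None
    scheme: str | None = "max"
    filter_kind: str | None = None
    T: float = 0.5
    seed: int = 0
    n_runs: int | None = None
    nloop: int | None = None
    out: str | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _detect_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".tsv", ".txt"):
        return "tsv"
    if suffix == ".csv":
        return "csv"
    if suffix == ".gct":
        return "gct"
    raise ParseError(
        f"cannot infer format from extension {suffix!r}; pass format explicitly"
    )


def _validate_frame(df: pd.DataFrame, path) -> ExpressionMatrix:
    bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        col = bad[0]
        row = df.index[df[col].map(lambda x: not _is_number(x))][0]
        raise ParseError(f"{path}: non-numeric cell at gene {row!r}, sample {col!r}")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ParseError(
            f"{path}: missing value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ParseError(
            f"{path}: negative value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    return ExpressionMatrix(values, [str(g) for g in df.index], [str(s) for s in df.columns])


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def read_expression(path: str | Path, fmt: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples expression matrix from TSV, CSV or GCT 1.2."""
    fmt = _detect_format(path, fmt)
    if fmt in ("tsv", "csv"):
        df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",", index_col=0,
                         float_precision="round_trip")
        return _validate_frame(df, path)
    if fmt == "gct":
        return _read_gct(path)
    raise ParseError(f"unknown format {fmt!r}")


def _read_gct(path: str | Path) -> ExpressionMatrix:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ParseError(f"{path}: expected '#1.2' header, got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ParseError(f"{path}: malformed dimensions line")
        n, m = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
    if "Description" in df.columns:
        df = df.drop(columns="Description")
    else:
        df = df.drop(columns=df.columns[0])  # second annotation column
    if df.shape != (n, m):
        raise ParseError(
            f"{path}: dimensions line says {n} x {m} but table is "
            f"{df.shape[0]} x {df.shape[1]}"
        )
    return _validate_frame(df, path)


def write_expression(A: ExpressionMatrix, path: str | Path, fmt: str | None = None) -> None:
    fmt = _detect_format(path, fmt)
    if fmt == "gct":
        raise ParseError("GCT output is not supported; write TSV or CSV")
    sep = "\t" if fmt == "tsv" else ","
    df = pd.DataFrame(A.values, index=A.gene_ids, columns=A.sample_ids)
    df.to_csv(path, sep=sep, float_format=FLOAT_FMT, index_label="gene_id")


def read_labels(
    path: str | Path, sample_ids: list[str] | None = None
) -> ClusterAssignment:
    """Read a two-column (sample_id, label) file; labels re-encoded to 1..k.

    Encoding preserves first-appearance order of the raw labels.  When
    ``sample_ids`` is given the rows are aligned to that order and every
    sample must be present.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str,
                     comment="#", skip_blank_lines=True)
    if df.shape[1] != 2:
        # a header line like "sample_id<TAB>label" is tolerated
        raise ParseError(f"{path}: expected two columns, got {df.shape[1]}")
    if list(df.iloc[0]) == ["sample_id", "label"]:
        df = df.iloc[1:]
    ids = df.iloc[:, 0].tolist()
    raw = df.iloc[:, 1].tolist()
    if sample_ids is not None:
        lookup = dict(zip(ids, raw))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise ParseError(f"{path}: labels missing for samples {missing}")
        unknown = [s for s in ids if s not in set(sample_ids)]
        if unknown:
            raise ParseError(f"{path}: unknown sample ids {unknown}")
        raw = [lookup[s] for s in sample_ids]
    codes: dict[str, int] = {}
    labels = []
    for r in raw:
        if r not in codes:
            codes[r] = len(codes) + 1
        labels.append(codes[r])
    return ClusterAssignment(np.array(labels), len(codes))


def write_labels(assignment: ClusterAssignment, sample_ids: list[str],
                 path: str | Path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "label": assignment.labels}).to_csv(
        path, sep="\t", index=False
    )


def write_assignment(
    assignment: ClusterAssignment,
    H2: np.ndarray,
    sample_ids: list[str],
    path: str | Path,
) -> None:
    """Write sample_id, 1-based cluster, and the winning H' value (strength)."""
    strength = H2[assignment.labels - 1, np.arange(len(sample_ids))]
    pd.DataFrame(
        {"sample_id": sample_ids, "cluster": assignment.labels, "strength": strength}
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_matrix(M: np.ndarray, path: str | Path, index=None, columns=None) -> None:
    df = pd.DataFrame(M, index=index, columns=columns)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT,
              index=index is not None, header=columns is not None)


def write_consensus(C: ConsensusMatrix, sample_ids: list[str], path: str | Path) -> None:
    write_matrix(C.C, path, index=sample_ids, columns=sample_ids)


def write_filter_report(report: FilterReport, path: str | Path) -> None:
    rows = [(g, "kept") for g in report.kept_gene_ids] + [
        (g, "discarded") for g in report.discarded_gene_ids
    ]
    pd.DataFrame(rows, columns=["gene_id", "status"]).to_csv(path, sep="\t", index=False)


def write_experiment_table(results: list[ExperimentResult],
                           pvalues: list[float | None], path: str | Path) -> None:
    """Delimited table: method, mean accuracy, SEM, p-value vs the first row."""
    pd.DataFrame(
        {
            "method": [r.method_id for r in results],
            "mean_accuracy": [r.mean for r in results],
            "sem": [r.sem for r in results],
            "p_vs_baseline": ["" if p is None else p for p in pvalues],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
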