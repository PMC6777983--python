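"""Tabular I/O: connectivity matrices in CSV/TSV and result bundles.

Matrices are stored with region labels in the first row and column; a
file without labels gets synthetic labels ``R01, R02, ...``. Both wide
(source x target matrix) and long (source,target,count) layouts are read.
Result bundles serialize to one JSON manifest plus one CSV per table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Connectome, RawTracing

__all__ = [
    "ResultBundle",
    "read_matrix_csv",
    "read_tracing_csv",
    "read_connectome_csv",
    "write_connectome_csv",
    "write_report",
    "read_report",
]


def _read_table(path, header: bool | None = None) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, index_col=0, header=0 if header in (None, True) else None)
    if header is False:
        df = pd.read_csv(path, sep=sep, header=None)
        df.index = [f"R{i + 1:02d}" for i in range(len(df))]
        df.columns = [f"R{j + 1:02d}" for j in range(df.shape[1])]
    return df


def _validate_labels(labels, what: str):
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate {what} labels in file")
    return labels


def read_matrix_csv(path, orientation: str = "source_rows", header: bool | None = None):
    """Read a labeled connectivity table as a :class:`RawTracing`.

    A three-column long layout (source, target, count) is detected by its
    header; anything else is treated as a wide source x target matrix.
    ``orientation="target_rows"`` transposes a wide file into the package's
    canonical rows = source convention. Non-numeric or NaN cells error.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    probe = pd.read_csv(path, sep=sep, nrows=1)
    cols = [str(c).strip().lower() for c in probe.columns]
    if len(cols) == 3 and cols[0] in ("source", "src") and cols[1] in ("target", "tgt"):
        long = pd.read_csv(path, sep=sep)
        long.columns = ["source", "target", "count"]
        if long["count"].isna().any():
            raise ValueError("NaN counts in long-format file")
        sources = _validate_labels(pd.unique(long["source"]), "source")
        targets = _validate_labels(pd.unique(long["target"]), "target")
        counts = np.zeros((len(sources), len(targets)))
        si = {s: i for i, s in enumerate(sources)}
        ti = {t: j for j, t in enumerate(targets)}
        for _, row in long.iterrows():
            counts[si[str(row["source"])], ti[str(row["target"])]] += row["count"]
        return RawTracing(sources=sources, targets=targets, counts=counts)

    if header in (None, True):
        # pandas mangles duplicate header labels; validate the raw line
        with open(path) as fh:
            head_cells = [c.strip() for c in fh.readline().rstrip("\n").split(sep)[1:]]
        _validate_labels([c for c in head_cells if c], "column")
    df = _read_table(path, header=header)
    values = df.to_numpy(dtype=float)  # raises on non-numeric cells
    if np.isnan(values).any():
        raise ValueError("NaN cells in matrix file")
    rows = _validate_labels(df.index, "row")
    cols = _validate_labels(df.columns, "column")
    if orientation == "target_rows":
        values, rows, cols = values.T, cols, rows
    elif orientation != "source_rows":
        raise ValueError(f"unknown orientation: {orientation!r}")
    return RawTracing(sources=rows, targets=cols, counts=values)


def read_tracing_csv(path, **kw) -> RawTracing:
    """Alias of :func:`read_matrix_csv` returning the raw tracing table."""
    return read_matrix_csv(path, **kw)


def read_connectome_csv(path, orientation: str = "source_rows", header: bool | None = None) -> Connectome:
    """Read a square weighted matrix directly as a :class:`Connectome`.

    The stored values are taken as final weights (support = nonzero);
    the extended in-degree defaults to the internal in-degree. Self-loops
    on the diagonal are stripped.
    """
    raw = read_matrix_csv(path, orientation=orientation, header=header)
    if raw.sources != raw.targets:
        raise ValueError("connectome file must be square with matching labels")
    W = raw.counts.astype(float).copy()
    np.fill_diagonal(W, 0.0)
    A = (W > 0).astype(np.int8)
    return Connectome(
        labels=list(raw.targets), A=A, W=W, k_in_ext=A.sum(axis=0),
        meta={"path": str(path)},
    )


def write_connectome_csv(c: Connectome, path) -> None:
    """Write the weight matrix with labels, canonical orientation."""
    pd.DataFrame(c.W, index=c.labels, columns=c.labels).to_csv(path)


@dataclass
class ResultBundle:
    """Everything one pipeline run produced, ready to serialize.

    ``metrics`` holds scalar results; ``null_summaries`` maps a metric
    name to (null mean, null sd, empirical p); ``tables`` holds the
    tabular outputs (rich-club curve, morphospace trace, coupling sweep,
    partitions) as DataFrames.
    """

    metrics: dict = field(default_factory=dict)
    null_summaries: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def write_report(bundle: ResultBundle, path) -> Path:
    """Write one JSON manifest plus a CSV per table into a directory."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "metrics": _jsonable(bundle.metrics),
        "null_summaries": _jsonable(bundle.null_summaries),
        "config": _jsonable(bundle.config),
        "seeds": _jsonable(bundle.seeds),
        "tables": sorted(bundle.tables),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    for name, table in bundle.tables.items():
        table.to_csv(out / f"{name}.csv", index=False)
    return out


def read_report(path) -> ResultBundle:
    """Round-trip reader for :func:`write_report` output."""
    out = Path(path)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    tables = {
        name: pd.read_csv(out / f"{name}.csv") for name in manifest.get("tables", [])
    }
    return ResultBundle(
        metrics=manifest["metrics"],
        null_summaries=manifest["null_summaries"],
        tables=tables,
        config=manifest["config"],
        seeds=manifest["seeds"],
    )
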