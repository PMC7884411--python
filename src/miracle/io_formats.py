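"""Readers and writers for the plain-text formats the pipeline touches.

Expression and mutation matrices are TSV/CSV with genes in rows (first
column the gene symbol, header row the sample identifiers); clinical tables
are CSV with one row per sample; gene signatures use the standard GMT layout
(set name, description, member genes, tab-separated). All readers validate
into the domain types of :mod:`miracle.types` and log what they dropped.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ParseError, SchemaError
from .types import CLINICAL_OPTIONAL, ClinicalTable, ExpressionMatrix, GeneSet, MutationMatrix, normalise_symbol

logger = logging.getLogger(__name__)


def _separator(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path, sep: str | None = None, transpose: bool = False) -> ExpressionMatrix:
    """Read a gene-by-sample expression matrix from TSV/CSV.

    Duplicate gene symbols (after upper-casing) are collapsed by keeping the
    row with the highest mean expression; rows containing missing values are
    dropped. Both actions are logged.

    Parameters
    ----------
    path : file path; ``.csv`` implies comma separation, anything else tab.
    sep : explicit field separator, overriding the extension heuristic.
    transpose : set when the file stores samples in rows.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(
            path, sep=_separator(path, sep), index_col=0, float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse table: {exc}") from exc
    if raw.columns.size == 0 or raw.index.size == 0:
        raise EmptyInputError(f"{path}: no genes or samples found")
    if transpose:
        raw = raw.T

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {raw.iat[i, j]!r} at gene {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r}"
        )

    n_missing = int(numeric.isna().any(axis=1).sum())
    if n_missing:
        logger.info("%s: dropped %d gene rows with missing values", path, n_missing)
        numeric = numeric.dropna(axis=0)

    numeric.index = [normalise_symbol(g) for g in numeric.index]
    if numeric.index.duplicated().any():
        means = numeric.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        deduped = numeric.iloc[order]
        dup_names = sorted(set(deduped.index[deduped.index.duplicated()]))
        logger.info("%s: collapsed duplicate gene symbols (kept highest mean): %s", path, dup_names)
        deduped = deduped[~deduped.index.duplicated(keep="first")]
        numeric = deduped.loc[[g for g in dict.fromkeys(numeric.index)]]

    if numeric.shape[0] == 0 or numeric.shape[1] == 0:
        raise EmptyInputError(f"{path}: matrix empty after validation")
    return ExpressionMatrix.from_frame(numeric)


def write_expression(matrix: ExpressionMatrix, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    frame = matrix.to_frame()
    frame.index.name = "gene"
    # default float formatting = shortest round-trippable repr
    frame.to_csv(path, sep=_separator(path, sep))


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file into one :class:`GeneSet` per non-empty line."""
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
        name, _description, *genes = fields
        genes = [g for g in genes if g.strip()]
        if not genes:
            raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
        sets.append(GeneSet(name=name, genes=tuple(genes)))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path, description: str = "na") -> None:
    lines = ["\t".join([s.name, description, *s.genes]) for s in sets]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_clinical(path: str | Path, sep: str | None = None) -> ClinicalTable:
    """Read a per-sample clinical CSV into a validated :class:`ClinicalTable`.

    Rows with missing survival time or event are dropped (counted in the
    log); optional ``age``/``gender``/``stage`` columns are carried through
    when present.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_separator(path, ",") if sep is None else sep)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = ["sample_id", "cohort", "time", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required clinical columns: {missing}")
    n_before = len(df)
    df = df.dropna(subset=["time", "event"])
    dropped = n_before - len(df)
    if dropped:
        logger.info("%s: dropped %d rows with missing time/event", path, dropped)
    keep = required + [c for c in CLINICAL_OPTIONAL if c in df.columns]
    return ClinicalTable(df[keep])


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def read_mutations(path: str | Path, sep: str | None = None) -> MutationMatrix:
    """Read a binary gene-by-sample mutation matrix from TSV/CSV."""
    path = Path(path)
    df = pd.read_csv(path, sep=_separator(path, sep), index_col=0)
    values = df.to_numpy()
    return MutationMatrix(list(df.index), list(df.columns), values)


def write_mutations(matrix: MutationMatrix, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    frame = matrix.to_frame()
    frame.index.name = "gene"
    frame.to_csv(path, sep=_separator(path, sep))


def write_json(obj: object, path: str | Path) -> None:
    """Serialise a result object (dataclass-free dict structure) as JSON."""

    def _default(o: object) -> object:
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, GeneSet):
            return {"name": o.name, "genes": list(o.genes)}
        raise TypeError(f"cannot serialise {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
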