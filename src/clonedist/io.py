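"""Reading and writing AIRR-style rearrangement tables.

Supports two TSV dialects of the same four core columns:

* ``airr``    — lowercase AIRR Rearrangement schema names
  (``sequence_id``, ``v_call``, ``j_call``, ``junction``; clones written to
  ``clone_id``).
* ``changeo`` — uppercase Change-O names
  (``SEQUENCE_ID``, ``V_CALL``, ``J_CALL``, ``JUNCTION``; clones written to
  ``CLONE``).

Only the four required columns are interpreted; everything else in the file
is ignored on read. Rows with an empty junction or missing gene calls are
excluded from analysis and counted in the dataset's load report.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConsistencyError, FormatError

__all__ = [
    "SequenceRecord",
    "Dataset",
    "read_rearrangements",
    "write_rearrangements",
    "write_clones",
    "write_distances",
    "collapse_gene_call",
]

#: Column names for each dialect: (sequence_id, v_call, j_call, junction, clone)
_DIALECT_COLUMNS = {
    "airr": ("sequence_id", "v_call", "j_call", "junction", "clone_id"),
    "changeo": ("SEQUENCE_ID", "V_CALL", "J_CALL", "JUNCTION", "CLONE"),
}

_ALLELE_SUFFIX = re.compile(r"\*[0-9]+$")


@dataclass(frozen=True)
class SequenceRecord:
    """One rearrangement row: id, V/J gene calls and junction nucleotides.

    ``junction_length`` is derived from the junction string, so the
    length == len(junction) invariant holds by construction.
    """

    sequence_id: str
    v_call: str
    j_call: str
    junction: str

    @property
    def junction_length(self) -> int:
        return len(self.junction)


@dataclass
class Dataset:
    """Ordered collection of sequence records plus provenance metadata."""

    records: list[SequenceRecord]
    dialect: str = "airr"
    provenance: str = ""
    #: counts from read_rearrangements: total / admitted / excluded
    load_report: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.sequence_id for r in self.records]

    def junctions(self) -> dict[str, str]:
        """Mapping sequence_id -> junction nucleotide string."""
        return {r.sequence_id: r.junction for r in self.records}


def _detect_dialect(columns: list[str]) -> str:
    cols = set(columns)
    for dialect, names in _DIALECT_COLUMNS.items():
        if set(names[:4]) <= cols:
            return dialect
    missing_airr = [c for c in _DIALECT_COLUMNS["airr"][:4] if c not in cols]
    missing_changeo = [c for c in _DIALECT_COLUMNS["changeo"][:4] if c not in cols]
    raise FormatError(
        "header matches neither dialect: missing AIRR column(s) "
        f"{missing_airr} and Change-O column(s) {missing_changeo}"
    )


def read_rearrangements(path: str | Path, dialect: str = "auto") -> Dataset:
    """Read an AIRR/Change-O rearrangement TSV into a :class:`Dataset`.

    Parameters
    ----------
    path:
        TSV file with a header row.
    dialect:
        ``"airr"``, ``"changeo"`` or ``"auto"`` (detect from the header).

    Rows with an empty junction or a missing V/J call are excluded and
    counted in ``Dataset.load_report``. Junctions are upper-cased.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except OSError as exc:
        raise OSError(f"cannot read rearrangement file {path}: {exc}") from exc

    columns = list(table.columns)
    if dialect == "auto":
        dialect = _detect_dialect(columns)
    elif dialect in _DIALECT_COLUMNS:
        missing = [c for c in _DIALECT_COLUMNS[dialect][:4] if c not in columns]
        if missing:
            raise FormatError(
                f"missing required {dialect} column(s): {', '.join(missing)}"
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    id_col, v_col, j_col, jx_col, _ = _DIALECT_COLUMNS[dialect]
    records: list[SequenceRecord] = []
    excluded = {"empty_junction": 0, "missing_v_call": 0, "missing_j_call": 0}
    seen: set[str] = set()
    for row in table.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(columns, row))
        junction = str(row[jx_col]).strip().upper()
        v_call = str(row[v_col]).strip()
        j_call = str(row[j_col]).strip()
        if not junction or junction.upper() in ("NA", "NONE", "NAN"):
            excluded["empty_junction"] += 1
            continue
        if not v_call or v_call.upper() in ("NA", "NONE", "NAN"):
            excluded["missing_v_call"] += 1
            continue
        if not j_call or j_call.upper() in ("NA", "NONE", "NAN"):
            excluded["missing_j_call"] += 1
            continue
        sid = str(row[id_col]).strip()
        if sid in seen:
            raise FormatError(f"duplicate sequence_id {sid!r}")
        seen.add(sid)
        records.append(SequenceRecord(sid, v_call, j_call, junction))

    n_total = len(table)
    n_excluded = sum(excluded.values())
    report = {
        "total": n_total,
        "admitted": n_total - n_excluded,
        "excluded": n_excluded,
        "excluded_reasons": excluded,
    }
    return Dataset(records, dialect=dialect, provenance=str(path), load_report=report)


def _core_frame(dataset: Dataset, dialect: str) -> pd.DataFrame:
    id_col, v_col, j_col, jx_col, _ = _DIALECT_COLUMNS[dialect]
    length_col = "junction_length" if dialect == "airr" else "JUNCTION_LENGTH"
    return pd.DataFrame(
        {
            id_col: [r.sequence_id for r in dataset],
            v_col: [r.v_call for r in dataset],
            j_col: [r.j_call for r in dataset],
            jx_col: [r.junction for r in dataset],
            length_col: [r.junction_length for r in dataset],
        }
    )


def write_rearrangements(dataset: Dataset, path: str | Path, dialect: str | None = None) -> None:
    """Write the four core columns (plus junction length) as a TSV."""
    dialect = dialect or dataset.dialect
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    _core_frame(dataset, dialect).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_clones(dataset: Dataset, partition, path: str | Path, dialect: str | None = None) -> None:
    """Write the dataset with an appended clone column in input row order.

    Raises :class:`ConsistencyError` if any sequence lacks a clone
    assignment.
    """
    dialect = dialect or dataset.dialect
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    assignment = partition.assignment if hasattr(partition, "assignment") else partition
    missing = [r.sequence_id for r in dataset if r.sequence_id not in assignment]
    if missing:
        raise ConsistencyError(
            f"{len(missing)} sequence(s) without clone assignment, e.g. {missing[0]!r}"
        )
    frame = _core_frame(dataset, dialect)
    clone_col = _DIALECT_COLUMNS[dialect][4]
    frame[clone_col] = [assignment[r.sequence_id] for r in dataset]
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_distances(dataset: Dataset, dtn, path: str | Path, dialect: str | None = None) -> None:
    """Write the dataset with a ``dist_nearest`` column (empty if undefined)."""
    dialect = dialect or dataset.dialect
    frame = _core_frame(dataset, dialect)
    values = dtn.values if hasattr(dtn, "values") else dtn
    frame["dist_nearest"] = [
        "" if values.get(r.sequence_id) is None else repr(values[r.sequence_id])
        for r in dataset
    ]
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def collapse_gene_call(call: str, level: str = "gene") -> str:
    """Canonicalize an IMGT-style gene call for grouping.

    ``level="gene"`` strips the ``*NN`` allele suffix from each
    comma-separated assignment; multi-assignments are deduplicated and
    sorted into a canonical comma-joined key. ``level="allele"`` keeps
    allele suffixes but still canonicalizes multi-assignments.

    >>> collapse_gene_call("IGHV1-2*02,IGHV1-2*04", "gene")
    'IGHV1-2'
    """
    if not call or not call.strip():
        raise ValueError("empty gene call")
    if level not in ("gene", "allele"):
        raise ValueError(f"unknown collapse level {level!r}")
    parts = [p.strip() for p in call.split(",") if p.strip()]
    if level == "gene":
        parts = [_ALLELE_SUFFIX.sub("", p) for p in parts]
    return ",".join(sorted(set(parts)))
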