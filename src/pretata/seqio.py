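"""Reading and writing of sequence records and feature tables.

Handles FASTA (amino-acid and H/E/C secondary-structure alphabets), PSIPRED
``.ss2`` (VFORMAT) and ``.horiz`` output files, and labeled feature tables in
CSV/TSV/ARFF. Records are validated on ingest: an amino-acid sequence may use
only the 20 standard residue letters and a secondary-structure string only
{H, E, C}; anything else raises :class:`ValidationError` rather than being
silently coerced.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
SS_ALPHABET = "HEC"

LABEL_POSITIVE = "positive"
LABEL_NEGATIVE = "negative"


class ParseError(ValueError):
    """A file could not be parsed in its declared format."""


class ValidationError(ValueError):
    """A record violates an alphabet or consistency constraint."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence over the 20 standard residues."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - set(AMINO_ALPHABET)
        if bad:
            raise ValidationError(
                f"record {self.id!r}: invalid amino-acid character(s) "
                f"{sorted(bad)!r}"
            )


@dataclass(frozen=True)
class SSRecord:
    """An identified secondary-structure string over {H, E, C}."""

    id: str
    ss: str

    def __post_init__(self) -> None:
        if not self.ss:
            raise ValidationError(f"record {self.id!r}: empty structure string")
        bad = set(self.ss) - set(SS_ALPHABET)
        if bad:
            raise ValidationError(
                f"record {self.id!r}: invalid secondary-structure "
                f"character(s) {sorted(bad)!r}"
            )


@dataclass
class FeatureTable:
    """A named feature matrix with per-row identifiers and optional labels.

    ``values`` is an (n_rows, n_features) float array; ``labels``, when
    present, holds ``"positive"`` / ``"negative"`` per row.
    """

    row_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            self.values = self.values.reshape(len(self.row_ids), -1)
        if self.values.shape[0] != len(self.row_ids):
            raise ValidationError(
                f"{self.values.shape[0]} value rows but {len(self.row_ids)} ids"
            )
        if self.values.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"{self.values.shape[1]} value columns but "
                f"{len(self.feature_names)} feature names"
            )
        if self.labels is not None:
            if len(self.labels) != len(self.row_ids):
                raise ValidationError("labels length does not match row count")
            bad = set(self.labels) - {LABEL_POSITIVE, LABEL_NEGATIVE}
            if bad:
                raise ValidationError(f"unknown label value(s) {sorted(bad)!r}")

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def y(self) -> np.ndarray:
        """Binary label vector (positive=1, negative=0)."""
        if self.labels is None:
            raise ValidationError("table has no labels")
        return np.array([1 if l == LABEL_POSITIVE else 0 for l in self.labels])

    def select_features(self, indices: Sequence[int]) -> "FeatureTable":
        idx = list(indices)
        return FeatureTable(
            row_ids=list(self.row_ids),
            feature_names=[self.feature_names[i] for i in idx],
            values=self.values[:, idx].copy(),
            labels=list(self.labels) if self.labels is not None else None,
        )

    def select_rows(self, indices: Sequence[int]) -> "FeatureTable":
        idx = list(indices)
        return FeatureTable(
            row_ids=[self.row_ids[i] for i in idx],
            feature_names=list(self.feature_names),
            values=self.values[idx, :].copy(),
            labels=[self.labels[i] for i in idx] if self.labels is not None else None,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "id", self.row_ids)
        if self.labels is not None:
            df["label"] = self.labels
        return df

    def equals(self, other: "FeatureTable", rtol: float = 1e-12) -> bool:
        return (
            self.row_ids == other.row_ids
            and self.feature_names == other.feature_names
            and self.labels == other.labels
            and self.values.shape == other.values.shape
            and bool(np.allclose(self.values, other.values, rtol=rtol, atol=0))
        )


def concat_rows(pos: FeatureTable, neg: FeatureTable) -> FeatureTable:
    """Stack two tables with identical feature columns."""
    if pos.feature_names != neg.feature_names:
        raise ValidationError("feature name mismatch between tables")
    labels = None
    if pos.labels is not None and neg.labels is not None:
        labels = list(pos.labels) + list(neg.labels)
    return FeatureTable(
        row_ids=list(pos.row_ids) + list(neg.row_ids),
        feature_names=list(pos.feature_names),
        values=np.vstack([pos.values, neg.values]),
        labels=labels,
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: Literal["amino", "ss"] = "amino"):
    """Read a FASTA file into validated records, preserving file order.

    ``alphabet="amino"`` yields :class:`ProteinRecord`; ``alphabet="ss"``
    yields :class:`SSRecord` over {H, E, C}. Sequences are uppercased and
    whitespace-stripped; invalid characters raise :class:`ValidationError`
    naming the record and offending letters.
    """
    path = Path(path)
    if alphabet not in ("amino", "ss"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    with open(path) as fh:
        first = fh.readline()
        while first and not first.strip():
            first = fh.readline()
        if not first.startswith(">"):
            raise ParseError(
                f"{path}:1: not a FASTA file (first non-blank line does not "
                f"start with '>')"
            )
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "").replace("\t", "")
        if alphabet == "amino":
            records.append(ProteinRecord(id=rec.id, seq=seq))
        else:
            records.append(SSRecord(id=rec.id, ss=seq))
    return records


def write_fasta(records, path: str | Path) -> None:
    """Write protein or secondary-structure records as FASTA (60-char lines)."""
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.seq if isinstance(rec, ProteinRecord) else rec.ss
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def sanitize_records(records: list[ProteinRecord] | list[dict], logger=None):
    """Drop records containing non-standard residues, with a warning each.

    Accepts raw (id, seq) pairs so that records rejected at construction can
    be filtered before validation.
    """
    kept = []
    for item in records:
        if isinstance(item, ProteinRecord):
            kept.append(item)
            continue
        rid, seq = item["id"], item["seq"].upper()
        bad = set(seq) - set(AMINO_ALPHABET)
        if bad:
            if logger is not None:
                logger.warning(
                    "dropping record %r: non-standard residue(s) %s",
                    rid, sorted(bad),
                )
            continue
        kept.append(ProteinRecord(id=rid, seq=seq))
    return kept


# ---------------------------------------------------------------------------
# PSIPRED output
# ---------------------------------------------------------------------------

def parse_psipred_ss2(path: str | Path, id: str | None = None) -> SSRecord:
    """Parse a PSIPRED VFORMAT ``.ss2`` file into one :class:`SSRecord`.

    Data rows carry: residue index, residue letter, state letter (C/H/E),
    and three state probabilities. Indices must be consecutive from 1.
    """
    path = Path(path)
    states: list[str] = []
    expected = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: malformed ss2 row {stripped!r}")
            try:
                idx = int(parts[0])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer residue index {parts[0]!r}"
                ) from exc
            if idx != expected:
                raise ParseError(
                    f"{path}:{lineno}: non-consecutive residue index "
                    f"{idx} (expected {expected})"
                )
            state = parts[2]
            if state not in SS_ALPHABET:
                raise ParseError(
                    f"{path}:{lineno}: unknown secondary-structure state "
                    f"{state!r} (expected one of H, E, C)"
                )
            states.append(state)
            expected += 1
    if not states:
        raise ParseError(f"{path}: no data rows found")
    return SSRecord(id=id if id is not None else path.stem, ss="".join(states))


def parse_psipred_horiz(path: str | Path, id: str | None = None) -> SSRecord:
    """Parse a PSIPRED ``.horiz`` file: concatenate the ``Pred:`` lines."""
    path = Path(path)
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("Pred:"):
                continue
            chunk = line[len("Pred:"):].strip()
            bad = set(chunk) - set(SS_ALPHABET)
            if bad:
                raise ParseError(
                    f"{path}:{lineno}: unknown state letter(s) {sorted(bad)!r}"
                )
            chunks.append(chunk)
    if not chunks:
        raise ParseError(f"{path}: no 'Pred:' lines found")
    return SSRecord(id=id if id is not None else path.stem, ss="".join(chunks))


# ---------------------------------------------------------------------------
# Feature tables (CSV / TSV / ARFF)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"  # 12 significant digits round-trip contract


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    format: Literal["csv", "tsv", "arff"] | None = None,
) -> None:
    """Write a feature table; the format defaults from the file suffix.

    CSV/TSV carry a header ``id,<feature...>[,label]``. ARFF declares every
    feature ``numeric`` and, for labeled tables, a nominal class attribute
    ``{positive,negative}`` (Weka-compatible).
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".arff": "arff"}.get(
            path.suffix.lower(), "csv"
        )
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = table.to_dataframe()
        df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
    elif format == "arff":
        _write_arff(table, path)
    else:
        raise ValueError(f"unknown feature-table format {format!r}")


def _write_arff(table: FeatureTable, path: Path) -> None:
    buf = io.StringIO()
    buf.write("@RELATION features\n\n")
    buf.write("@ATTRIBUTE id STRING\n")
    for name in table.feature_names:
        buf.write(f"@ATTRIBUTE {_arff_quote(name)} NUMERIC\n")
    if table.labels is not None:
        buf.write("@ATTRIBUTE class {positive,negative}\n")
    buf.write("\n@DATA\n")
    for i in range(table.n_rows):
        cells = [_arff_quote(table.row_ids[i])]
        cells += [_FLOAT_FMT % v for v in table.values[i]]
        if table.labels is not None:
            cells.append(table.labels[i])
        buf.write(",".join(cells) + "\n")
    path.write_text(buf.getvalue())


def _arff_quote(token: str) -> str:
    if any(c in token for c in " ,{}%'\"\t"):
        return "'" + token.replace("'", "\\'") + "'"
    return token


def read_feature_table(
    path: str | Path,
    format: Literal["csv", "tsv", "arff"] | None = None,
) -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`."""
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".arff": "arff"}.get(
            path.suffix.lower(), "csv"
        )
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, dtype={"id": str})
        if "id" not in df.columns:
            raise ParseError(f"{path}: missing 'id' column")
        labels = None
        feat_cols = [c for c in df.columns if c not in ("id", "label")]
        if "label" in df.columns:
            labels = [str(x) for x in df["label"]]
        return FeatureTable(
            row_ids=[str(x) for x in df["id"]],
            feature_names=feat_cols,
            values=df[feat_cols].to_numpy(dtype=float)
            if len(df) else np.empty((0, len(feat_cols))),
            labels=labels,
        )
    if format == "arff":
        return _read_arff(path)
    raise ValueError(f"unknown feature-table format {format!r}")


def _read_arff(path: Path) -> FeatureTable:
    attrs: list[tuple[str, str]] = []
    data_rows: list[list[str]] = []
    in_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if low.startswith("@relation"):
                continue
            if low.startswith("@attribute"):
                rest = line.split(None, 1)[1]
                name, typ = _parse_arff_attribute(rest, path, lineno)
                attrs.append((name, typ))
            elif low.startswith("@data"):
                in_data = True
            elif in_data:
                data_rows.append(_split_arff_row(line))
    if not attrs:
        raise ParseError(f"{path}: no @ATTRIBUTE declarations")
    names = [a[0] for a in attrs]
    has_id = names and names[0] == "id"
    has_class = names and names[-1] == "class"
    feat_names = names[(1 if has_id else 0): (len(names) - 1 if has_class else len(names))]
    row_ids, labels, values = [], [], []
    for row in data_rows:
        if len(row) != len(attrs):
            raise ParseError(f"{path}: data row has {len(row)} cells, expected {len(attrs)}")
        i = 0
        if has_id:
            row_ids.append(row[0])
            i = 1
        vals = row[i: i + len(feat_names)]
        values.append([float(v) for v in vals])
        if has_class:
            labels.append(row[-1])
    if not has_id:
        row_ids = [str(i) for i in range(len(data_rows))]
    return FeatureTable(
        row_ids=row_ids,
        feature_names=feat_names,
        values=np.array(values, dtype=float)
        if values else np.empty((0, len(feat_names))),
        labels=labels if has_class else None,
    )


def _parse_arff_attribute(rest: str, path: Path, lineno: int) -> tuple[str, str]:
    rest = rest.strip()
    if rest.startswith("'"):
        end = rest.index("'", 1)
        name = rest[1:end]
        typ = rest[end + 1:].strip()
    else:
        parts = rest.split(None, 1)
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: malformed @ATTRIBUTE")
        name, typ = parts
    return name, typ


def _split_arff_row(line: str) -> list[str]:
    cells, cur, in_q = [], [], False
    for ch in line:
        if ch == "'" :
            in_q = not in_q
        elif ch == "," and not in_q:
            cells.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    cells.append("".join(cur))
    return [c.strip() for c in cells]
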