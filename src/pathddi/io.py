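"""Readers and writers for the external formats the pipeline touches.

* knowledge-graph triples: tab-separated ``head<TAB>relation<TAB>tail`` lines
  with ``Family::identifier`` entity prefixes;
* drug and interaction tables: delimited text with a header row, the
  delimiter (comma or tab) auto-detected from the header line;
* embedding stores: whitespace-delimited text, one identifier followed by its
  vector per line;
* drug subgraphs: JSON (see :class:`pathddi.kg.DrugSubgraph`).

Validation is strict: duplicate drug identifiers, non-integer labels, ragged
embedding rows, and malformed triple lines are reported with positions rather
than silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# triples


@dataclass
class TripleFile:
    triples: list[tuple[str, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.triples)


def read_triples(path) -> TripleFile:
    path = Path(path)
    triples = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            triples.append((fields[0], fields[1], fields[2]))
    return TripleFile(triples)


def write_triples(tf: TripleFile, path) -> None:
    with open(path, "w") as fh:
        for h, r, t in tf.triples:
            fh.write(f"{h}\t{r}\t{t}\n")


# ---------------------------------------------------------------------------
# delimited tables


@dataclass
class DrugTable:
    """(drug_id, smiles) records; IDs unique, SMILES non-empty."""

    records: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for drug_id, smiles in self.records:
            if drug_id in seen:
                raise FormatError(f"duplicate drug_id {drug_id!r}")
            seen.add(drug_id)
            if not smiles.strip():
                raise FormatError(f"empty SMILES for drug {drug_id!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def drug_ids(self) -> list[str]:
        return [d for d, _ in self.records]

    def smiles_of(self, drug_id: str) -> str:
        for d, s in self.records:
            if d == drug_id:
                return s
        raise KeyError(drug_id)


@dataclass
class DDITable:
    """(drug_a, drug_b, label) records with integer class labels >= 0."""

    records: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self):
        for a, b, label in self.records:
            if not isinstance(label, (int, np.integer)) or label < 0:
                raise FormatError(
                    f"label for pair ({a!r}, {b!r}) must be a non-negative "
                    f"integer, got {label!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([l for _, _, l in self.records], dtype=np.int64)

    def drugs(self) -> set[str]:
        out = set()
        for a, b, _ in self.records:
            out.add(a)
            out.add(b)
        return out


def _detect_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def _read_rows(path, expected_columns: int):
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: missing header row")
    delim = _detect_delimiter(lines[0])
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split(delim)
        if len(fields) < expected_columns:
            raise FormatError(
                f"{path}:{lineno}: expected {expected_columns} fields, "
                f"got {len(fields)}"
            )
        rows.append([f.strip() for f in fields])
    return rows


def read_drug_table(path) -> DrugTable:
    rows = _read_rows(path, 2)
    return DrugTable([(r[0], r[1]) for r in rows])


def write_drug_table(table: DrugTable, path, delimiter: str = ",") -> None:
    with open(path, "w") as fh:
        fh.write(delimiter.join(["drug_id", "smiles"]) + "\n")
        for drug_id, smiles in table.records:
            fh.write(delimiter.join([drug_id, smiles]) + "\n")


def read_ddi_table(path) -> DDITable:
    rows = _read_rows(path, 3)
    records = []
    for r in rows:
        try:
            label = int(r[2])
        except ValueError:
            raise FormatError(
                f"label {r[2]!r} for pair ({r[0]!r}, {r[1]!r}) "
                "is not an integer"
            ) from None
        records.append((r[0], r[1], label))
    return DDITable(records)


def write_ddi_table(table: DDITable, path, delimiter: str = ",") -> None:
    with open(path, "w") as fh:
        fh.write(delimiter.join(["drug_a", "drug_b", "label"]) + "\n")
        for a, b, label in table.records:
            fh.write(delimiter.join([a, b, str(label)]) + "\n")


# ---------------------------------------------------------------------------
# embedding stores


class EmbeddingStore:
    """Identifier -> fixed-width vector table; unknown lookups raise."""

    def __init__(self, table: dict[str, np.ndarray]):
        self.table = {}
        self.dim: int | None = None
        for key, vec in table.items():
            self._insert(key, vec)

    def _insert(self, key: str, vec) -> None:
        vec = np.asarray(vec, dtype=np.float64)
        if vec.ndim != 1:
            raise FormatError(f"embedding for {key!r} is not a vector")
        if self.dim is None:
            self.dim = vec.shape[0]
        elif vec.shape[0] != self.dim:
            raise FormatError(
                f"ragged embedding row for {key!r}: dimension "
                f"{vec.shape[0]} != {self.dim}"
            )
        self.table[key] = vec

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, key: str) -> bool:
        return key in self.table

    def lookup(self, key: str) -> np.ndarray:
        if key not in self.table:
            raise KeyError(f"identifier {key!r} missing from embedding store")
        return self.table[key]


def read_embeddings(path) -> EmbeddingStore:
    path = Path(path)
    table: dict[str, np.ndarray] = {}
    store = EmbeddingStore({})
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: identifier without vector")
            try:
                vec = np.array([float(x) for x in fields[1:]])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric embedding entry"
                ) from None
            try:
                store._insert(fields[0], vec)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return store


def write_embeddings(store: EmbeddingStore, path) -> None:
    with open(path, "w") as fh:
        for key in store.table:
            vec = " ".join(f"{x:.10g}" for x in store.table[key])
            fh.write(f"{key} {vec}\n")
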