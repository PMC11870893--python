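"""Prescription records: reading, validation, filtering and binary encoding.

A multicomponent prescription is one transaction in a market-basket sense:
it carries one or more disease labels (what the prescription treats) and one
or more medicinal-material labels (what goes into it).  Disease and material
labels live in disjoint namespaces.  The whole database is encoded as a
binary presence/absence matrix — one row per prescription, one column per
catalog item — which is what the rule miner consumes.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")

REQUIRED_COLUMNS = ("prescription_id", "diseases", "materials")

#: delimiter for multi-valued cells; ";" round-trips botanical authority
#: strings that contain commas, e.g. "Calpurnia aurea (Ait.) Benth."
CELL_DELIMITER = ";"


class FormatError(ValueError):
    """The input file does not have the expected tabular structure."""


class ValidationError(ValueError):
    """A row violates the prescription data model."""


class NamespaceError(ValidationError):
    """A label appears both as a disease and as a material."""


class EmptyResultError(ValueError):
    """An operation removed every prescription."""


def normalize_label(label: str) -> str:
    """Trim and collapse internal whitespace.  No case folding: botanical
    names are case-sensitive by convention."""
    return _WS.sub(" ", label.strip())


@dataclass(frozen=True)
class Prescription:
    """One prescription: an id, ≥1 disease label, ≥1 material label."""

    prescription_id: str
    diseases: frozenset[str]
    materials: frozenset[str]

    def __post_init__(self) -> None:
        if not self.diseases:
            raise ValidationError(
                f"prescription {self.prescription_id!r}: empty disease set"
            )
        if not self.materials:
            raise ValidationError(
                f"prescription {self.prescription_id!r}: empty material set"
            )
        overlap = self.diseases & self.materials
        if overlap:
            raise NamespaceError(
                f"prescription {self.prescription_id!r}: labels used as both "
                f"disease and material: {sorted(overlap)}"
            )

    @property
    def items(self) -> frozenset[str]:
        return self.diseases | self.materials


@dataclass
class TransactionDB:
    """An ordered collection of prescriptions plus item catalogs.

    Catalogs are ordered and unique; every label occurring in any
    prescription appears in exactly one of them.
    """

    prescriptions: list[Prescription]
    disease_catalog: list[str] = field(default_factory=list)
    material_catalog: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.disease_catalog and not self.material_catalog:
            self._rebuild_catalogs()
        self._validate()

    def _rebuild_catalogs(self) -> None:
        dseen: dict[str, None] = {}
        mseen: dict[str, None] = {}
        for p in self.prescriptions:
            for d in sorted(p.diseases):
                dseen.setdefault(d)
            for m in sorted(p.materials):
                mseen.setdefault(m)
        self.disease_catalog = list(dseen)
        self.material_catalog = list(mseen)

    def _validate(self) -> None:
        dset, mset = set(self.disease_catalog), set(self.material_catalog)
        if len(dset) != len(self.disease_catalog):
            raise ValidationError("duplicate labels in disease catalog")
        if len(mset) != len(self.material_catalog):
            raise ValidationError("duplicate labels in material catalog")
        both = dset & mset
        if both:
            raise NamespaceError(f"labels in both catalogs: {sorted(both)}")
        for p in self.prescriptions:
            missing_d = p.diseases - dset
            missing_m = p.materials - mset
            if missing_d or missing_m:
                raise ValidationError(
                    f"prescription {p.prescription_id!r} uses labels missing "
                    f"from the catalogs: {sorted(missing_d | missing_m)}"
                )

    def __len__(self) -> int:
        return len(self.prescriptions)

    def disease_counts(self) -> dict[str, int]:
        """Number of prescriptions each disease occurs in."""
        counts = {d: 0 for d in self.disease_catalog}
        for p in self.prescriptions:
            for d in p.diseases:
                counts[d] += 1
        return counts

    def material_counts(self) -> dict[str, int]:
        counts = {m: 0 for m in self.material_catalog}
        for p in self.prescriptions:
            for m in p.materials:
                counts[m] += 1
        return counts


@dataclass
class BinaryMatrix:
    """Presence/absence encoding of a TransactionDB.

    Columns are the disease catalog followed by the material catalog;
    ``column_kinds`` records which side each column belongs to.
    """

    values: np.ndarray  # (n_rows, n_cols) uint8 in {0,1}
    row_ids: list[str]
    column_labels: list[str]
    column_kinds: list[str]  # "disease" | "material"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")

    @property
    def disease_columns(self) -> list[int]:
        return [j for j, k in enumerate(self.column_kinds) if k == "disease"]

    @property
    def material_columns(self) -> list[int]:
        return [j for j, k in enumerate(self.column_kinds) if k == "material"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_ids, columns=self.column_labels
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "prescription_id"
        df.to_csv(path, sep="\t")


def _split_cell(cell: str) -> frozenset[str]:
    parts = (normalize_label(tok) for tok in str(cell).split(CELL_DELIMITER))
    return frozenset(p for p in parts if p)


def read_prescriptions(path: str | Path) -> TransactionDB:
    """Read a prescriptions TSV into a validated :class:`TransactionDB`.

    Expected header columns: ``prescription_id``, ``diseases``,
    ``materials``; multi-valued cells are ";"-delimited.  Labels are
    whitespace-normalized and duplicates within a cell collapsed.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    prescriptions: list[Prescription] = []
    for i, row in df.iterrows():
        diseases = _split_cell(row["diseases"])
        materials = _split_cell(row["materials"])
        if not diseases:
            raise ValidationError(f"{path}: row {i + 1}: empty disease cell")
        if not materials:
            raise ValidationError(f"{path}: row {i + 1}: empty material cell")
        prescriptions.append(
            Prescription(normalize_label(row["prescription_id"]), diseases, materials)
        )
    return TransactionDB(prescriptions)


def write_prescriptions(db: TransactionDB, path: str | Path) -> None:
    """Inverse of :func:`read_prescriptions` (modulo catalog order)."""
    rows = [
        {
            "prescription_id": p.prescription_id,
            "diseases": CELL_DELIMITER.join(sorted(p.diseases)),
            "materials": CELL_DELIMITER.join(sorted(p.materials)),
        }
        for p in db.prescriptions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_diseases(db: TransactionDB, min_prescriptions: int = 3) -> TransactionDB:
    """Drop diseases occurring in fewer than ``min_prescriptions``
    prescriptions; prescriptions left with no disease are dropped too.

    Rare diseases carry too few co-occurrences to support rule mining.
    Idempotent at a fixed threshold.
    """
    if min_prescriptions < 1:
        raise ValueError("min_prescriptions must be ≥ 1")
    counts = db.disease_counts()
    keep = {d for d, c in counts.items() if c >= min_prescriptions}
    removed = sorted(set(counts) - keep)
    if removed:
        logger.info(
            "filter_diseases: removed %d disease(s) below %d prescriptions: %s",
            len(removed), min_prescriptions, removed,
        )
    survivors: list[Prescription] = []
    for p in db.prescriptions:
        diseases = p.diseases & keep
        if diseases:
            survivors.append(Prescription(p.prescription_id, frozenset(diseases), p.materials))
    if not survivors:
        raise EmptyResultError(
            f"filtering at min_prescriptions={min_prescriptions} removed every prescription"
        )
    dropped = len(db) - len(survivors)
    if dropped:
        logger.info("filter_diseases: dropped %d prescription(s) left without a disease", dropped)
    return TransactionDB(survivors)


def encode_matrix(db: TransactionDB) -> BinaryMatrix:
    """Encode the database as a 0/1 matrix over disease ∥ material columns."""
    labels = db.disease_catalog + db.material_catalog
    kinds = ["disease"] * len(db.disease_catalog) + ["material"] * len(db.material_catalog)
    col_index = {lab: j for j, lab in enumerate(labels)}
    values = np.zeros((len(db), len(labels)), dtype=np.uint8)
    for i, p in enumerate(db.prescriptions):
        for item in p.items:
            values[i, col_index[item]] = 1
    return BinaryMatrix(
        values=values,
        row_ids=[p.prescription_id for p in db.prescriptions],
        column_labels=labels,
        column_kinds=kinds,
    )


def decode_matrix(matrix: BinaryMatrix) -> TransactionDB:
    """Invert :func:`encode_matrix`; ``decode(encode(db)) == db``."""
    dcols = matrix.disease_columns
    mcols = matrix.material_columns
    prescriptions = []
    for i, rid in enumerate(matrix.row_ids):
        row = matrix.values[i]
        diseases = frozenset(matrix.column_labels[j] for j in dcols if row[j])
        materials = frozenset(matrix.column_labels[j] for j in mcols if row[j])
        prescriptions.append(Prescription(rid, diseases, materials))
    return TransactionDB(
        prescriptions,
        disease_catalog=[matrix.column_labels[j] for j in dcols],
        material_catalog=[matrix.column_labels[j] for j in mcols],
    )


def summarize(db: TransactionDB) -> dict:
    """Per-disease prescription counts (descending) plus dataset totals."""
    counts = db.disease_counts()
    ranking = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return {
        "n_prescriptions": len(db),
        "n_diseases": len(db.disease_catalog),
        "n_materials": len(db.material_catalog),
        "disease_ranking": [
            {"disease": d, "n_prescriptions": c} for d, c in ranking
        ],
    }


def write_summary(db: TransactionDB, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summarize(db), indent=2) + "\n")
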