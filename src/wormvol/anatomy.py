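"""Cell-to-tissue mapping, syncytial nuclei counts, and ploidy.

The anatomy table is a CSV with columns ``cell,tissue,somatic,nuclei,
ploidy_c``.  ``nuclei`` is the number of nuclei in the (possibly
syncytial) cell; ``ploidy_c`` is the DNA content per nucleus as a
C-value (2 = diploid, 32 = young-adult intestine).  Diploid-genome
equivalents are computed, never stored:

    genome_equivalents = nuclei * ploidy_c / 2

so a 139-nucleus diploid syncytium carries 139 genome equivalents and a
mononucleate 32C nucleus carries 16.

A literature-derived fixture table for young-adult C. elegans is bundled
as package data (``load_bundled_anatomy``); the germline (rachis plus
germ-cell nuclei) is carried as a single non-somatic pseudo-record, and
the extracellular cuticle as a zero-nuclei record.

Regrouping rules rewrite source collection labels into canonical tissue
labels (e.g. splitting cuticle out of a hypodermis collection, or
rachis/germ cells out of a gonad collection) without touching volumes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from wormvol.volumetrics import VolumeMeasurement

__all__ = [
    "CANONICAL_TISSUES",
    "CellRecord",
    "RegroupRules",
    "AnatomySchemaError",
    "genome_equivalents",
    "load_anatomy",
    "load_bundled_anatomy",
    "load_regroup_rules",
    "regroup",
]

#: Canonical tissue vocabulary; free-text labels are rejected unless
#: declared explicitly, to prevent silent aggregation splits.
CANONICAL_TISSUES = frozenset(
    {
        "intestine",
        "hypodermis",
        "cuticle",
        "body wall muscle",
        "pharynx",
        "neurons",
        "somatic gonad",
        "germline",
        "other",
    }
)

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


class AnatomySchemaError(ValueError):
    """Raised when an anatomy CSV violates the schema; names the row."""


@dataclass(frozen=True)
class CellRecord:
    """One anatomy-table row.

    ``nuclei == 0`` is permitted only for non-cellular structures (the
    cuticle); nucleated cells must have ``ploidy_c >= 2``.
    """

    cell: str
    tissue: str
    somatic: bool
    nuclei: int
    ploidy_c: float

    def __post_init__(self) -> None:
        if self.nuclei < 0:
            raise ValueError(f"{self.cell}: negative nuclei count")
        if self.nuclei > 0 and self.ploidy_c < 2:
            raise ValueError(
                f"{self.cell}: ploidy_c {self.ploidy_c} < 2 for a nucleated cell"
            )


def genome_equivalents(record: CellRecord) -> float:
    """Diploid genome copies in the cell: nuclei * ploidy_c / 2."""
    return record.nuclei * record.ploidy_c / 2.0


def _parse_bool(token: str, where: str) -> bool:
    t = token.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise AnatomySchemaError(f"{where}: bad boolean {token!r}")


_REQUIRED = ("cell", "tissue", "somatic", "nuclei", "ploidy_c")


def load_anatomy(
    path: str | Path,
    extra_tissues: Iterable[str] = (),
) -> list[CellRecord]:
    """Load and validate an anatomy CSV.

    Lines starting with ``#`` are treated as provenance comments.
    Unknown tissue labels are rejected unless listed in
    ``extra_tissues``.
    """
    path = Path(path)
    allowed = CANONICAL_TISSUES | set(extra_tissues)
    records: list[CellRecord] = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        rows = [r for r in fh if not r.lstrip().startswith("#")]
    reader = csv.DictReader(rows)
    if reader.fieldnames is None:
        raise AnatomySchemaError(f"{path}: empty file")
    missing = [c for c in _REQUIRED if c not in reader.fieldnames]
    if missing:
        raise AnatomySchemaError(f"{path}: missing columns {missing}")
    for rowno, row in enumerate(reader, start=2):
        where = f"{path}:row {rowno}"
        cell = (row["cell"] or "").strip()
        if not cell:
            raise AnatomySchemaError(f"{where}: empty cell name")
        if cell in seen:
            raise AnatomySchemaError(f"{where}: duplicate cell {cell!r}")
        seen.add(cell)
        tissue = (row["tissue"] or "").strip()
        if tissue not in allowed:
            raise AnatomySchemaError(
                f"{where}: unknown tissue {tissue!r}; declare it via "
                "extra_tissues or use a canonical label"
            )
        try:
            nuclei = int(row["nuclei"])
        except (TypeError, ValueError):
            raise AnatomySchemaError(
                f"{where}: bad nuclei count {row['nuclei']!r}"
            ) from None
        if nuclei < 0:
            raise AnatomySchemaError(f"{where}: negative nuclei count {nuclei}")
        try:
            ploidy = float(row["ploidy_c"])
        except (TypeError, ValueError):
            raise AnatomySchemaError(
                f"{where}: bad ploidy_c {row['ploidy_c']!r}"
            ) from None
        if nuclei > 0 and ploidy < 2:
            raise AnatomySchemaError(
                f"{where}: ploidy_c {ploidy} < 2 for nucleated cell {cell!r}"
            )
        records.append(
            CellRecord(
                cell=cell,
                tissue=tissue,
                somatic=_parse_bool(row["somatic"], where),
                nuclei=nuclei,
                ploidy_c=ploidy,
            )
        )
    if not records:
        raise AnatomySchemaError(f"{path}: no data rows")
    return records


def load_bundled_anatomy() -> list[CellRecord]:
    """Load the fixture anatomy table shipped with the package."""
    ref = resources.files("wormvol").joinpath("data/anatomy.csv")
    with resources.as_file(ref) as path:
        return load_anatomy(path)


@dataclass(frozen=True)
class RegroupRules:
    """Collection-label rewriting: per-collection map plus per-cell
    overrides.

    Rules must be total over the input collections; per-cell overrides
    win over the collection map.
    """

    collection_map: Mapping[str, str]
    cell_overrides: Mapping[str, str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "collection_map", dict(self.collection_map))
        object.__setattr__(
            self, "cell_overrides", dict(self.cell_overrides or {})
        )

    @classmethod
    def identity(cls, collections: Iterable[str]) -> "RegroupRules":
        return cls({c: c for c in collections})

    def target(self, cell: str, collection: str) -> str:
        if cell in self.cell_overrides:
            return self.cell_overrides[cell]
        if collection not in self.collection_map:
            raise KeyError(collection)
        return self.collection_map[collection]


def load_regroup_rules(path: str | Path) -> RegroupRules:
    """Load regroup rules from YAML: ``collections: {src: dst}`` and
    optional ``cells: {cell: dst}``."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    return RegroupRules(
        collection_map=doc.get("collections", {}),
        cell_overrides=doc.get("cells", {}),
    )


def regroup(
    measurements: Sequence[VolumeMeasurement],
    rules: RegroupRules,
) -> list[VolumeMeasurement]:
    """Rewrite tissue labels on measurements; volumes are untouched.

    Raises
    ------
    ValueError
        If any measurement's collection is not covered by the rules.
    """
    uncovered = sorted(
        {
            m.collection or ""
            for m in measurements
            if m.cell not in rules.cell_overrides
            and (m.collection or "") not in rules.collection_map
        }
    )
    if uncovered:
        raise ValueError(
            f"regroup rules do not cover collections: {uncovered}"
        )
    return [
        replace(m, collection=rules.target(m.cell, m.collection or ""))
        for m in measurements
    ]
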