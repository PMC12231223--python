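"""Domain types, validation and delimited-text I/O for diet datasets.

A diet study dataset is two tables: one row per captured specimen
(id, sex/age group, snout-vent length, mouth width, body mass) and one row
per prey item recovered by stomach flushing (owning specimen, prey
category, maximum length and width, and a derived prolate-spheroid
volume).  This module defines the validated record types, the
:class:`Dataset` container with referential integrity, and CSV/TSV readers
and writers for the two tables.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GROUPS",
    "SPECIMEN_COLUMNS",
    "PREY_COLUMNS",
    "GeckodietError",
    "SchemaError",
    "RowError",
    "ValidationError",
    "WidthExceedsLengthWarning",
    "Specimen",
    "PreyItem",
    "Dataset",
    "read_specimen_table",
    "read_prey_table",
    "write_specimen_table",
    "write_prey_table",
    "assemble_dataset",
]

#: Allowed sex/age group labels.  "juvenile" is permitted by the schema
#: even though typical samples contain none.
GROUPS = ("male", "female", "subadult", "juvenile")

SPECIMEN_COLUMNS = ("specimen_id", "group", "svl_mm", "mw_mm", "bm_g")
PREY_COLUMNS = ("specimen_id", "category", "taxon_class", "length_mm", "width_mm")


class GeckodietError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(GeckodietError):
    """A table is missing a required column or has an unusable header."""


class RowError(GeckodietError):
    """A single table row is malformed; carries the 1-based file line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class ValidationError(GeckodietError):
    """A record or dataset violates a domain invariant."""


class WidthExceedsLengthWarning(UserWarning):
    """A prey item was measured wider than long (kept; curled prey can do this)."""


@dataclass(frozen=True)
class Specimen:
    """One captured individual.

    Parameters
    ----------
    specimen_id : unique identifier.
    group : one of ``male``, ``female``, ``subadult``, ``juvenile``.
    svl : snout-vent length, mm.
    mw : mouth width, mm.
    bm : body mass, g.
    """

    specimen_id: str
    group: str
    svl: float
    mw: float
    bm: float

    def __post_init__(self):
        if not self.specimen_id:
            raise ValidationError("specimen_id must be a non-empty string")
        if self.group not in GROUPS:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: group {self.group!r} not in {GROUPS}"
            )
        for name in ("svl", "mw", "bm"):
            value = getattr(self, name)
            if not value > 0:
                raise ValidationError(
                    f"specimen {self.specimen_id!r}: {name} must be > 0, got {value!r}"
                )
        if not self.mw < self.svl:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: mouth width {self.mw} must be "
                f"smaller than snout-vent length {self.svl}"
            )


@dataclass(frozen=True)
class PreyItem:
    """One measured food item recovered from a stomach.

    ``volume_mm3`` is the derived prolate-spheroid volume and is ``None``
    until computed (see :func:`geckodiet.composition.compute_volumes`).
    A width exceeding the length triggers :class:`WidthExceedsLengthWarning`
    but is kept: maximum width of a curled item can exceed its length, and
    discarding measured items silently would bias composition counts.
    """

    specimen_id: str
    category: str
    length_mm: float
    width_mm: float
    taxon_class: str | None = None
    volume_mm3: float | None = None

    def __post_init__(self):
        if not self.specimen_id:
            raise ValidationError("prey item: specimen_id must be non-empty")
        if not self.category:
            raise ValidationError("prey item: category must be non-empty")
        if not self.length_mm > 0:
            raise ValidationError(
                f"prey item ({self.specimen_id!r}, {self.category!r}): "
                f"length_mm must be > 0, got {self.length_mm!r}"
            )
        if not self.width_mm > 0:
            raise ValidationError(
                f"prey item ({self.specimen_id!r}, {self.category!r}): "
                f"width_mm must be > 0, got {self.width_mm!r}"
            )
        if self.volume_mm3 is not None and not self.volume_mm3 > 0:
            raise ValidationError(
                f"prey item ({self.specimen_id!r}, {self.category!r}): "
                f"volume_mm3 must be > 0 when present"
            )
        if self.width_mm > self.length_mm:
            warnings.warn(
                f"prey item ({self.specimen_id!r}, {self.category!r}): width "
                f"{self.width_mm} mm exceeds length {self.length_mm} mm",
                WidthExceedsLengthWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class Dataset:
    """Specimens plus their prey items, with referential integrity enforced."""

    specimens: tuple[Specimen, ...]
    prey_items: tuple[PreyItem, ...]

    def __post_init__(self):
        object.__setattr__(self, "specimens", tuple(self.specimens))
        object.__setattr__(self, "prey_items", tuple(self.prey_items))
        ids = [s.specimen_id for s in self.specimens]
        seen: set[str] = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})
        if dupes:
            raise ValidationError(f"duplicate specimen ids: {dupes}")
        known = set(ids)
        orphans = sorted({p.specimen_id for p in self.prey_items} - known)
        if orphans:
            raise ValidationError(
                f"prey items reference unknown specimen ids: {orphans}"
            )

    def __len__(self) -> int:
        return len(self.specimens)

    def specimen_frame(self) -> pd.DataFrame:
        """Specimens as a DataFrame with columns ``specimen_id, group, svl, mw, bm``."""
        return pd.DataFrame(
            [(s.specimen_id, s.group, s.svl, s.mw, s.bm) for s in self.specimens],
            columns=["specimen_id", "group", "svl", "mw", "bm"],
        )

    def prey_frame(self) -> pd.DataFrame:
        """Prey items as a DataFrame; ``volume_mm3`` is NaN where not yet computed."""
        return pd.DataFrame(
            [
                (p.specimen_id, p.category, p.taxon_class, p.length_mm, p.width_mm,
                 p.volume_mm3)
                for p in self.prey_items
            ],
            columns=["specimen_id", "category", "taxon_class", "length_mm",
                     "width_mm", "volume_mm3"],
        )

    def group_of(self, specimen_id: str) -> str:
        for s in self.specimens:
            if s.specimen_id == specimen_id:
                return s.group
        raise KeyError(specimen_id)

    def subset(self, groups: Iterable[str]) -> "Dataset":
        """Restrict to specimens (and their items) in the given groups."""
        groups = set(groups)
        keep = tuple(s for s in self.specimens if s.group in groups)
        ids = {s.specimen_id for s in keep}
        return Dataset(keep, tuple(p for p in self.prey_items if p.specimen_id in ids))


def _open_reader(path: str | Path, delimiter: str):
    handle = open(path, newline="", encoding="utf-8")
    return handle, csv.DictReader(handle, delimiter=delimiter)


def _require_columns(reader: csv.DictReader, required: Sequence[str], path) -> None:
    header = reader.fieldnames or []
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; header was {header}"
        )


def _parse_float(raw: str, column: str, line: int) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise RowError(line, f"column {column!r}: non-numeric value {raw!r}") from None


def read_specimen_table(
    path: str | Path,
    delimiter: str = ",",
    column_map: dict[str, str] | None = None,
) -> list[Specimen]:
    """Read a specimen CSV/TSV into validated :class:`Specimen` records.

    Expected columns: ``specimen_id, group, svl_mm, mw_mm, bm_g``
    (remappable via ``column_map`` {canonical: actual}).  Row order is
    preserved.  Malformed rows raise :class:`RowError` with the 1-based
    file line; duplicate ids raise :class:`ValidationError`.
    """
    cmap = {c: c for c in SPECIMEN_COLUMNS}
    cmap.update(column_map or {})
    handle, reader = _open_reader(path, delimiter)
    with handle:
        _require_columns(reader, list(cmap.values()), path)
        out: list[Specimen] = []
        seen: set[str] = set()
        for row in reader:
            line = reader.line_num
            try:
                spec = Specimen(
                    specimen_id=(row[cmap["specimen_id"]] or "").strip(),
                    group=(row[cmap["group"]] or "").strip().lower(),
                    svl=_parse_float(row[cmap["svl_mm"]], cmap["svl_mm"], line),
                    mw=_parse_float(row[cmap["mw_mm"]], cmap["mw_mm"], line),
                    bm=_parse_float(row[cmap["bm_g"]], cmap["bm_g"], line),
                )
            except ValidationError as exc:
                raise RowError(line, str(exc)) from exc
            if spec.specimen_id in seen:
                raise ValidationError(
                    f"{path}: duplicate specimen_id {spec.specimen_id!r} at line {line}"
                )
            seen.add(spec.specimen_id)
            out.append(spec)
        return out


def read_prey_table(
    path: str | Path,
    delimiter: str = ",",
    column_map: dict[str, str] | None = None,
) -> list[PreyItem]:
    """Read a prey-item CSV/TSV into validated :class:`PreyItem` records.

    Expected columns: ``specimen_id, category, taxon_class, length_mm,
    width_mm``; ``taxon_class`` may be empty.  Volumes are left unset.
    Unknown specimen ids are only detected at :func:`assemble_dataset`.
    """
    cmap = {c: c for c in PREY_COLUMNS}
    cmap.update(column_map or {})
    required = [cmap[c] for c in PREY_COLUMNS if c != "taxon_class"]
    handle, reader = _open_reader(path, delimiter)
    with handle:
        _require_columns(reader, required, path)
        out: list[PreyItem] = []
        for row in reader:
            line = reader.line_num
            taxon = (row.get(cmap["taxon_class"]) or "").strip() or None
            try:
                item = PreyItem(
                    specimen_id=(row[cmap["specimen_id"]] or "").strip(),
                    category=(row[cmap["category"]] or "").strip(),
                    taxon_class=taxon,
                    length_mm=_parse_float(row[cmap["length_mm"]], cmap["length_mm"], line),
                    width_mm=_parse_float(row[cmap["width_mm"]], cmap["width_mm"], line),
                )
            except ValidationError as exc:
                raise RowError(line, str(exc)) from exc
            out.append(item)
        return out


def assemble_dataset(
    specimens: Iterable[Specimen], prey_items: Iterable[PreyItem]
) -> Dataset:
    """Combine the two record collections, enforcing referential integrity.

    Raises :class:`ValidationError` listing any prey items whose
    ``specimen_id`` is absent from the specimen table.
    """
    return Dataset(tuple(specimens), tuple(prey_items))


def write_specimen_table(
    specimens: Iterable[Specimen], path: str | Path, delimiter: str = ","
) -> None:
    """Write specimens in the canonical column order (lengths to 0.1 mm, mass 0.1 g)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(SPECIMEN_COLUMNS)
        for s in specimens:
            w.writerow([s.specimen_id, s.group, f"{s.svl:.1f}", f"{s.mw:.1f}",
                        f"{s.bm:.1f}"])


def write_prey_table(
    prey_items: Iterable[PreyItem], path: str | Path, delimiter: str = ","
) -> None:
    """Write prey items in the canonical column order (dimensions to 0.1 mm)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(PREY_COLUMNS)
        for p in prey_items:
            w.writerow([p.specimen_id, p.category, p.taxon_class or "",
                        f"{p.length_mm:.1f}", f"{p.width_mm:.1f}"])
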