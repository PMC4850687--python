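"""Data model and readers/writers for worm-sorter screen data.

The canonical interchange formats are plain UTF-8, tab-delimited text:

* **event TSV** -- one row per worm with columns
  ``plate, well, clone, condition, round, replicate, tof, ext, gfp, dsred``;
* **clone library TSV** -- ``clone_id, source, targets, flags`` where
  ``targets`` is a ``;``-separated list of ``gene`` or ``gene:score`` entries
  and ``flags`` a ``;``-separated subset of gene-family flags (``his``,
  ``msp``);
* **GMT** -- ``id <TAB> label <TAB> gene1 <TAB> gene2 ...`` for annotation
  classes and protein complexes.

Lines starting with ``#`` are ignored everywhere.  Readers validate the type
invariants (positive TOF, nonempty gene lists, unique clone ids) and refuse
files that violate them; writers emit files their readers accept unchanged.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class ScreenDataError(ValueError):
    """Base class for malformed or invariant-violating screen data."""


class ParseError(ScreenDataError):
    """Structurally malformed input (wrong column count, bad numbers)."""


class ValidationError(ScreenDataError):
    """Well-formed input whose values violate a type invariant."""


#: assay conditions understood by the pipeline
CONDITIONS = ("infected", "noninfected", "osmotic", "gpa12star", "irg1")

#: screening rounds; 1 and 2 are the duplicate / quadruplicate sorter rounds
ROUNDS = (1, 2, "adhesion", "epistasis")

EVENT_COLUMNS = (
    "plate", "well", "clone", "condition", "round",
    "replicate", "tof", "ext", "gfp", "dsred",
)


@dataclass(frozen=True, slots=True)
class WormEvent:
    """One sorter record (size + fluorescence) for a single worm.

    ``tof`` (time of flight) is the axial-length proxy used as the size
    denominator of all fluorescence ratios and must be strictly positive.
    """

    plate_id: str
    well_id: str
    tof: float
    ext: float
    gfp: float
    dsred: float

    def __post_init__(self) -> None:
        if not self.tof > 0:
            raise ValidationError(f"tof must be > 0, got {self.tof}")
        if self.gfp < 0 or self.dsred < 0 or self.ext < 0:
            raise ValidationError("fluorescence and extension must be >= 0")


@dataclass(slots=True)
class WellRecord:
    """All events of one well of one assay (plate, condition, round, replicate)."""

    plate_id: str
    well_id: str
    clone_id: str
    condition: str
    round: int | str
    replicate_index: int
    events: list[WormEvent]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.round not in ROUNDS:
            raise ValidationError(f"unknown round {self.round!r}")
        if self.replicate_index < 1:
            raise ValidationError("replicate_index must be >= 1")
        if not self.events:
            raise ValidationError(f"well {self.plate_id}/{self.well_id} has no events")
        for ev in self.events:
            if (ev.plate_id, ev.well_id) != (self.plate_id, self.well_id):
                raise ValidationError("all events of a well must share plate/well ids")


@dataclass(slots=True)
class CloneRecord:
    """An RNAi clone: its source library and predicted target genes.

    ``targets`` may be empty for sequence-ambiguous clones.  ``family_flags``
    marks clones touching large near-identical gene families (histone ``his``,
    major sperm protein ``msp``) whose many-to-many clone/gene mapping
    confounds gene-level statistics.
    """

    clone_id: str
    source_library: str
    targets: list[tuple[str, float]] = field(default_factory=list)
    family_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.source_library not in ("ahringer", "vidal"):
            raise ValidationError(
                f"clone {self.clone_id}: unknown source library "
                f"{self.source_library!r}"
            )
        unknown = set(self.family_flags) - {"his", "msp"}
        if unknown:
            raise ValidationError(f"clone {self.clone_id}: unknown flags {unknown}")

    @property
    def target_genes(self) -> set[str]:
        return {g for g, _ in self.targets}


@dataclass(slots=True)
class AnnotationClass:
    """A named functional gene class (one GMT line)."""

    class_id: str
    label: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"class {self.class_id} has an empty gene list")


@dataclass(slots=True)
class ComplexRecord:
    """A predicted protein complex given by its member genes."""

    complex_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"complex {self.complex_id} has no members")


# ---------------------------------------------------------------------------
# event TSV
# ---------------------------------------------------------------------------

def _parse_round(token: str) -> int | str:
    if token in ("1", "2"):
        return int(token)
    return token


def _iter_tsv(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, newline="", encoding="utf-8") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            yield lineno, row


def read_events(path: str | Path) -> list[WellRecord]:
    """Read an event TSV and group rows into :class:`WellRecord` objects.

    Rows are grouped by ``(plate, well, condition, round, replicate)`` in
    first-appearance order.  Malformed rows raise :class:`ParseError` naming
    the line number; invariant violations raise :class:`ValidationError`.
    """
    wells: dict[tuple, WellRecord] = {}
    header_seen = False
    for lineno, row in _iter_tsv(path):
        if not header_seen:
            if tuple(row) != EVENT_COLUMNS:
                raise ParseError(
                    f"{path}:{lineno}: expected header {'|'.join(EVENT_COLUMNS)}"
                )
            header_seen = True
            continue
        if len(row) != len(EVENT_COLUMNS):
            raise ParseError(f"{path}:{lineno}: expected {len(EVENT_COLUMNS)} columns")
        plate, well, clone, condition, rnd, rep, tof, ext, gfp, dsred = row
        try:
            replicate = int(rep)
            values = (float(tof), float(ext), float(gfp), float(dsred))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        try:
            event = WormEvent(plate, well, *values)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        key = (plate, well, condition, _parse_round(rnd), replicate)
        rec = wells.get(key)
        if rec is None:
            wells[key] = WellRecord(
                plate_id=plate, well_id=well, clone_id=clone,
                condition=condition, round=_parse_round(rnd),
                replicate_index=replicate, events=[event],
            )
        else:
            if rec.clone_id != clone:
                raise ValidationError(
                    f"{path}:{lineno}: well {plate}/{well} maps to two clones"
                )
            rec.events.append(event)
    return list(wells.values())


def write_events(records: Sequence[WellRecord], path: str | Path) -> None:
    """Write well records as an event TSV (inverse of :func:`read_events`)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(EVENT_COLUMNS)
        for rec in records:
            for ev in rec.events:
                writer.writerow(
                    (
                        rec.plate_id, rec.well_id, rec.clone_id, rec.condition,
                        rec.round, rec.replicate_index,
                        repr(ev.tof), repr(ev.ext), repr(ev.gfp), repr(ev.dsred),
                    )
                )


# ---------------------------------------------------------------------------
# clone library TSV
# ---------------------------------------------------------------------------

def _parse_targets(token: str) -> list[tuple[str, float]]:
    targets: list[tuple[str, float]] = []
    if not token:
        return targets
    for entry in token.split(";"):
        entry = entry.strip()
        if not entry:
            continue
        gene, _, score = entry.partition(":")
        targets.append((gene, float(score) if score else 1.0))
    return targets


def read_library(path: str | Path) -> list[CloneRecord]:
    """Read a clone library TSV (``clone_id, source, targets, flags``)."""
    clones: dict[str, CloneRecord] = {}
    header_seen = False
    for lineno, row in _iter_tsv(path):
        if not header_seen and row[0] == "clone_id":
            header_seen = True
            continue
        if len(row) < 2:
            raise ParseError(f"{path}:{lineno}: expected >= 2 columns")
        clone_id, source = row[0], row[1]
        targets = _parse_targets(row[2]) if len(row) > 2 else []
        flags = frozenset(
            f for f in (row[3].split(";") if len(row) > 3 and row[3] else []) if f
        )
        if clone_id in clones:
            raise ValidationError(f"{path}:{lineno}: duplicate clone id {clone_id}")
        try:
            clones[clone_id] = CloneRecord(clone_id, source, targets, flags)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return list(clones.values())


def write_library(clones: Sequence[CloneRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(("clone_id", "source", "targets", "flags"))
        for clone in clones:
            targets = ";".join(f"{g}:{s:g}" for g, s in clone.targets)
            writer.writerow(
                (clone.clone_id, clone.source_library, targets,
                 ";".join(sorted(clone.family_flags)))
            )


# ---------------------------------------------------------------------------
# GMT (classes and complexes)
# ---------------------------------------------------------------------------

def _read_gmt(path: str | Path) -> list[tuple[str, str, frozenset[str], int]]:
    rows = []
    for lineno, row in _iter_tsv(path):
        if len(row) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT lines need id, label and >= 1 gene"
            )
        genes = frozenset(g for g in row[2:] if g)
        rows.append((row[0], row[1], genes, lineno))
    return rows


def read_classes(path: str | Path) -> list[AnnotationClass]:
    """Read annotation classes from a GMT file."""
    classes = []
    seen: set[str] = set()
    for class_id, label, genes, lineno in _read_gmt(path):
        if class_id in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate class id {class_id}")
        seen.add(class_id)
        if not genes:
            raise ValidationError(f"{path}:{lineno}: class {class_id} has no genes")
        classes.append(AnnotationClass(class_id, label, genes))
    return classes


def read_complexes(path: str | Path) -> list[ComplexRecord]:
    """Read protein complexes from a GMT file (the label column is ignored)."""
    complexes = []
    seen: set[str] = set()
    for complex_id, _label, genes, lineno in _read_gmt(path):
        if complex_id in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate complex id {complex_id}")
        seen.add(complex_id)
        if not genes:
            raise ValidationError(f"{path}:{lineno}: complex {complex_id} is empty")
        complexes.append(ComplexRecord(complex_id, genes))
    return complexes


def write_gmt(entries: Iterable[tuple[str, str, Iterable[str]]], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for entry_id, label, genes in entries:
            writer.writerow((entry_id, label, *sorted(genes)))
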