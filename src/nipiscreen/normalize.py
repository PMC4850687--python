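"""Per-worm ratios, per-well means and per-plate truncated-mean normalization.

Raw sorter fluorescence is confounded by worm size and by plate-to-plate
variation in culture and detector conditions.  The screen's unit of decision
is therefore the *well*, summarized in three steps:

1. per worm, fluorescence is divided by TOF (size), giving GFP/TOF and
   dsRed/TOF ratios;
2. per well, the arithmetic mean of the worm ratios (and of raw TOF) is taken;
3. per plate, every well mean is divided by the plate's truncated mean of
   that quantity (default: discard the 25 % lowest and 25 % highest well
   values), yielding normalized values ``ngfp``, ``nred`` and ``ntof`` that
   are comparable across plates.

The truncated mean is robust to the handful of genuine hits expected on any
plate, so a plate of mostly unremarkable wells normalizes to values near 1.
Normalization is exactly invariant to multiplying a whole plate by a
constant, which is the formal content of "across-plate comparison".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .screen_io import ValidationError, WellRecord, WormEvent

#: typical per-well worm yield; wells below this are flagged, not dropped
DEFAULT_MIN_WORMS = 80

#: fraction of well values discarded from each tail of the plate normalizer
DEFAULT_TRIM_FRACTION = 0.25


@dataclass(slots=True)
class WellSummary:
    """Per-well means of the worm-level ratios."""

    plate_id: str
    well_id: str
    clone_id: str
    condition: str
    round: int | str
    replicate_index: int
    n_worms: int
    mean_gfp_tof: float
    mean_red_tof: float
    mean_tof: float
    qc_low_count: bool


@dataclass(slots=True)
class NormalizedWell(WellSummary):
    """Well summary scaled by the plate truncated means (``ngfp, nred, ntof``)."""

    ngfp: float = math.nan
    nred: float = math.nan
    ntof: float = math.nan


def worm_ratios(event: WormEvent) -> tuple[float, float]:
    """Return the per-worm size-corrected ratios ``(gfp/tof, dsred/tof)``."""
    if not event.tof > 0:
        raise ValidationError(f"tof must be > 0, got {event.tof}")
    return event.gfp / event.tof, event.dsred / event.tof


def summarize_well(rec: WellRecord, min_worms: int = DEFAULT_MIN_WORMS) -> WellSummary:
    """Arithmetic means of the worm ratios; flags sparse wells (< min_worms)."""
    if not rec.events:
        raise ValidationError(f"well {rec.plate_id}/{rec.well_id} is empty")
    ratios = [worm_ratios(ev) for ev in rec.events]
    n = len(ratios)
    return WellSummary(
        plate_id=rec.plate_id,
        well_id=rec.well_id,
        clone_id=rec.clone_id,
        condition=rec.condition,
        round=rec.round,
        replicate_index=rec.replicate_index,
        n_worms=n,
        mean_gfp_tof=sum(g for g, _ in ratios) / n,
        mean_red_tof=sum(r for _, r in ratios) / n,
        mean_tof=sum(ev.tof for ev in rec.events) / n,
        qc_low_count=n < min_worms,
    )


def truncated_mean(values: Sequence[float], trim_fraction: float) -> float:
    """Mean after discarding ``floor(trim_fraction * n)`` values per tail.

    Count-based trimming degrades gracefully: when the floor is 0 this is the
    plain mean.  ``trim_fraction`` must lie in ``[0, 0.5)``.
    """
    if not 0 <= trim_fraction < 0.5:
        raise ValueError(f"trim_fraction must be in [0, 0.5), got {trim_fraction}")
    if len(values) == 0:
        raise ValueError("cannot take the truncated mean of an empty list")
    return float(stats.trim_mean(list(values), trim_fraction))


def normalize_plate(
    summaries: Sequence[WellSummary],
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
) -> list[NormalizedWell]:
    """Divide each well mean by the plate truncated mean, per channel.

    QC-flagged (low-count) wells are excluded from the truncated-mean
    computation but are still normalized and keep their flag.  A truncated
    mean of 0 in any channel marks a degenerate plate and is an error.
    """
    if not summaries:
        raise ValueError("normalize_plate needs at least one well")
    reference = [s for s in summaries if not s.qc_low_count]
    if not reference:
        raise ValidationError(
            f"plate {summaries[0].plate_id}: every well is QC-flagged; "
            "no reference wells for the plate normalizer"
        )
    norms = {
        "gfp": truncated_mean([s.mean_gfp_tof for s in reference], trim_fraction),
        "red": truncated_mean([s.mean_red_tof for s in reference], trim_fraction),
        "tof": truncated_mean([s.mean_tof for s in reference], trim_fraction),
    }
    for channel, value in norms.items():
        if value <= 0:
            raise ValidationError(
                f"plate {summaries[0].plate_id}: degenerate plate, "
                f"truncated mean of {channel} is {value}"
            )
    return [
        NormalizedWell(
            **{f: getattr(s, f) for f in (
                "plate_id", "well_id", "clone_id", "condition", "round",
                "replicate_index", "n_worms", "mean_gfp_tof", "mean_red_tof",
                "mean_tof", "qc_low_count",
            )},
            ngfp=s.mean_gfp_tof / norms["gfp"],
            nred=s.mean_red_tof / norms["red"],
            ntof=s.mean_tof / norms["tof"],
        )
        for s in summaries
    ]


def normalize_screen(
    records: Iterable[WellRecord],
    min_worms: int = DEFAULT_MIN_WORMS,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
) -> list[NormalizedWell]:
    """Summarize every well and normalize plate by plate.

    Wells are grouped by ``plate_id``; each physical plate is assumed to hold
    a single assay condition, as produced by the screen protocol.
    """
    by_plate: dict[str, list[WellSummary]] = {}
    order: list[str] = []
    for rec in records:
        summary = summarize_well(rec, min_worms=min_worms)
        if summary.plate_id not in by_plate:
            order.append(summary.plate_id)
            by_plate[summary.plate_id] = []
        by_plate[summary.plate_id].append(summary)
    normalized: list[NormalizedWell] = []
    for plate_id in order:
        normalized.extend(normalize_plate(by_plate[plate_id], trim_fraction))
    return normalized


NORMALIZED_COLUMNS = (
    "plate", "well", "clone", "condition", "round", "replicate", "n_worms",
    "mean_gfp_tof", "mean_red_tof", "mean_tof", "ngfp", "nred", "ntof",
    "qc_low_count",
)


def write_normalized(wells: Sequence[NormalizedWell], path) -> None:
    """Write normalized wells as a TSV (inverse of :func:`read_normalized`)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(NORMALIZED_COLUMNS) + "\n")
        for w in wells:
            handle.write(
                f"{w.plate_id}\t{w.well_id}\t{w.clone_id}\t{w.condition}\t"
                f"{w.round}\t{w.replicate_index}\t{w.n_worms}\t"
                f"{w.mean_gfp_tof!r}\t{w.mean_red_tof!r}\t{w.mean_tof!r}\t"
                f"{w.ngfp!r}\t{w.nred!r}\t{w.ntof!r}\t{int(w.qc_low_count)}\n"
            )


def read_normalized(path) -> list[NormalizedWell]:
    wells = []
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != NORMALIZED_COLUMNS:
            raise ValidationError(f"{path}: unexpected normalized-well header")
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            (plate, well, clone, condition, rnd, rep, n, mg, mr, mt,
             ngfp, nred, ntof, qc) = line.rstrip("\n").split("\t")
            wells.append(
                NormalizedWell(
                    plate_id=plate, well_id=well, clone_id=clone,
                    condition=condition,
                    round=int(rnd) if rnd in ("1", "2") else rnd,
                    replicate_index=int(rep), n_worms=int(n),
                    mean_gfp_tof=float(mg), mean_red_tof=float(mr),
                    mean_tof=float(mt), qc_low_count=bool(int(qc)),
                    ngfp=float(ngfp), nred=float(nred), ntof=float(ntof),
                )
            )
    return wells
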