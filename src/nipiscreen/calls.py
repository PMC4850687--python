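"""Clone classification rules: Nipi/Hipi/Peni calling, developmental
exclusion, epistasis flags and spore-adhesion scoring.

All rules operate on plate-normalized well values (``ngfp``, ``nred``,
``ntof``), so every call is invariant to constant plate factors.  The
vocabulary:

* **Nipi** -- knock-down abolishes infection-induced reporter expression:
  >= 20 % reduction of normalized GFP in *both* first-round duplicates,
  without tripping the control-reporter or size guards, confirmed in
  quadruplicate in round 2.
* **enhancer candidates** -- mean normalized GFP increased by >= 30 % without
  a comparable increase of the red control reporter or of worm size.
* **Peni** -- elevated reporter expression even without infection; the
  cut-off is anchored midway between the positive (fasn-1/pan-1-like) and
  negative (sta-1-like) controls, so it captures all positives and no
  negatives by construction.
* **Hipi** -- exaggerated induction only upon infection (mutually exclusive
  with Peni, which takes precedence).
* **developmental** -- pronounced size or control-reporter phenotype in the
  quantitative round-2 data; such clones are excluded from the final list.
* **G / O / I clones** -- respectively abrogate constitutive GPA-12* driven
  expression, block osmotic-stress induction, or induce the intestinal
  irg-1 reporter; each flag is tri-state (absent when the assay is missing).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .normalize import NormalizedWell
from .screen_io import ValidationError


class ControlsNotSeparable(ValueError):
    """Positive and negative control distributions overlap: assay failure."""


@dataclass(slots=True)
class Thresholds:
    """All tunable decision parameters of the callers.

    Fractions are relative changes of normalized GFP (0.20 = 20 %).
    ``dev_ntof=None`` anchors the developmental size cut to the rack-1-like
    size control when such wells exist (falling back to 0.7).
    """

    nipi_reduction: float = 0.20
    enhancer_increase: float = 0.30
    guard_increase: float = 0.30
    round2_min_hits: int = 3
    g_abrogation: float = 0.50
    o_block: float = 0.50
    i_fold: float = 2.0
    dev_ntof: float | None = None
    dev_nred: float = 0.7
    hipi_cutoff: float = 1.3

    def __post_init__(self) -> None:
        for name in ("nipi_reduction", "enhancer_increase", "guard_increase",
                     "g_abrogation", "o_block", "dev_nred"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not self.i_fold > 1:
            raise ValueError("i_fold must be > 1")
        if not 1 <= self.round2_min_hits <= 4:
            raise ValueError("round2_min_hits must be in [1, 4]")


@dataclass(slots=True)
class EpistasisFlags:
    """Tri-state epistasis calls: ``None`` means the assay was not run."""

    g: bool | None = None
    o: bool | None = None
    i: bool | None = None


@dataclass(slots=True)
class PhenotypeCall:
    """Per-clone decision record with the evidence behind every true flag."""

    clone_id: str
    round1_nipi: bool = False
    round1_enhancer: bool = False
    round2_nipi: bool = False
    peni: bool = False
    hipi: bool = False
    developmental: bool = False
    g_clone: bool | None = None
    o_clone: bool | None = None
    i_clone: bool | None = None
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.peni and self.hipi:
            raise ValidationError("peni and hipi are mutually exclusive")
        if self.round2_nipi and not self.round1_nipi:
            raise ValidationError("round-2 Nipi requires the round-1 flag")

    @property
    def final_nipi(self) -> bool:
        """Retained Nipi call: robust in round 2 and not developmental."""
        return self.round2_nipi and not self.developmental


@dataclass(slots=True)
class AdhesionResult:
    """Spore-adhesion scoring of one clone."""

    clone_id: str
    gfp_score: int
    spore_category: int
    adhesion_index: float

    def __post_init__(self) -> None:
        if self.gfp_score not in (0, 1, 2) or self.spore_category not in (0, 1, 2):
            raise ValidationError("scores must be 0, 1 or 2")
        if not 0 <= self.adhesion_index <= 1:
            raise ValidationError("adhesion_index must be in [0, 1]")


def _mean(values: Sequence[float]) -> float:
    return sum(values) / len(values)


def _rack1_ntof(rack1_controls: Sequence[NormalizedWell]) -> float:
    if not rack1_controls:
        raise ValidationError("no rack-1-like size-control wells supplied")
    return _mean([w.ntof for w in rack1_controls])


def call_nipi_round1(
    duplicates: Sequence[NormalizedWell],
    rack1_controls: Sequence[NormalizedWell],
    th: Thresholds,
) -> bool:
    """First-round Nipi rule on infected duplicates.

    True iff normalized GFP is reduced by at least ``nipi_reduction`` in
    *both* replicates, the red control reporter is not increased beyond the
    guard band, and the worms are not smaller on average than the rack-1-like
    size control.  The red guard is one-sided (increases only): a *reduced*
    control reporter signals a sick or delayed worm population, which is the
    round-2 developmental filter's job to remove.
    """
    if len(duplicates) != 2:
        raise ValidationError(f"round 1 needs 2 replicates, got {len(duplicates)}")
    cutoff = 1.0 - th.nipi_reduction
    if not all(w.ngfp <= cutoff for w in duplicates):
        return False
    if _mean([w.nred for w in duplicates]) >= 1.0 + th.guard_increase:
        return False
    return _mean([w.ntof for w in duplicates]) >= _rack1_ntof(rack1_controls)


def call_enhancer_round1(
    duplicates: Sequence[NormalizedWell],
    th: Thresholds,
) -> bool:
    """First-round enhancer rule: mean normalized GFP up by >= 30 %, with
    neither the red reporter nor worm size increased by that much."""
    if len(duplicates) != 2:
        raise ValidationError(f"round 1 needs 2 replicates, got {len(duplicates)}")
    if _mean([w.ngfp for w in duplicates]) < 1.0 + th.enhancer_increase:
        return False
    if _mean([w.nred for w in duplicates]) >= 1.0 + th.guard_increase:
        return False
    return _mean([w.ntof for w in duplicates]) < 1.0 + th.guard_increase


def anchor_cutoff(positives: Sequence[float], negatives: Sequence[float]) -> float:
    """Midpoint between the highest negative and the lowest positive control.

    Classifying at the returned value captures all positive controls and none
    of the negatives.  Overlapping control distributions signal assay failure
    and raise :class:`ControlsNotSeparable`.
    """
    if not positives or not negatives:
        raise ValidationError("both control sets must be nonempty")
    lo, hi = max(negatives), min(positives)
    if not hi > lo:
        raise ControlsNotSeparable(
            f"controls not separable: max(negatives)={lo} >= min(positives)={hi}"
        )
    return 0.5 * (lo + hi)


def call_peni_hipi(
    quads_infected: Sequence[NormalizedWell],
    quads_uninfected: Sequence[NormalizedWell],
    peni_cutoff: float,
    hipi_cutoff: float,
    min_hits: int = 3,
) -> tuple[bool, bool]:
    """Discriminate constitutive (Peni) from infection-only (Hipi) elevation.

    Peni: uninfected normalized GFP at or above the anchored cut-off in at
    least ``min_hits`` of 4 replicates.  Hipi: not Peni, and infected
    normalized GFP at or above ``hipi_cutoff`` in at least ``min_hits`` of 4.
    """
    if len(quads_infected) != 4 or len(quads_uninfected) != 4:
        raise ValidationError("peni/hipi calling needs 4 + 4 replicates")
    if not (peni_cutoff > 1 and hipi_cutoff > 1):
        raise ValueError("cutoffs must be > 1")
    peni = sum(w.ngfp >= peni_cutoff for w in quads_uninfected) >= min_hits
    hipi = (not peni) and (
        sum(w.ngfp >= hipi_cutoff for w in quads_infected) >= min_hits
    )
    return peni, hipi


def call_nipi_round2(
    quads_infected: Sequence[NormalizedWell],
    rack1_controls: Sequence[NormalizedWell],
    th: Thresholds,
) -> bool:
    """Reproducibility-weighted round-2 Nipi rule on infected quadruplicates.

    Requires at least ``round2_min_hits`` of 4 replicates at >= 20 %
    reduction AND a median reduction of >= 20 %, with the round-1 guards
    re-applied to the replicate medians.
    """
    if len(quads_infected) != 4:
        raise ValidationError("round 2 needs 4 infected replicates")
    cutoff = 1.0 - th.nipi_reduction
    hits = sum(w.ngfp <= cutoff for w in quads_infected)
    if hits < th.round2_min_hits:
        return False
    if statistics.median([w.ngfp for w in quads_infected]) > cutoff:
        return False
    if statistics.median([w.nred for w in quads_infected]) >= 1.0 + th.guard_increase:
        return False
    med_ntof = statistics.median([w.ntof for w in quads_infected])
    return med_ntof >= _rack1_ntof(rack1_controls)


def flag_developmental(
    quadruplicates: Sequence[NormalizedWell],
    th: Thresholds,
    rack1_controls: Sequence[NormalizedWell] | None = None,
) -> bool:
    """Pronounced developmental phenotype in round-2 quantitative data.

    True iff the median normalized size falls below the cut (anchored to the
    rack-1-like control when available, else ``dev_ntof``/0.7) or the median
    control reporter falls below ``dev_nred``.
    """
    if not quadruplicates:
        raise ValidationError("no round-2 wells supplied")
    if th.dev_ntof is not None:
        dev_ntof = th.dev_ntof
    elif rack1_controls:
        dev_ntof = _rack1_ntof(rack1_controls)
    else:
        dev_ntof = 0.7
    med_ntof = statistics.median([w.ntof for w in quadruplicates])
    med_nred = statistics.median([w.nred for w in quadruplicates])
    return med_ntof < dev_ntof or med_nred < th.dev_nred


def classify_epistasis(
    gpa12star_wells: Sequence[NormalizedWell] | None,
    osmotic_wells: Sequence[NormalizedWell] | None,
    irg1_wells: Sequence[NormalizedWell] | None,
    controls: Mapping[str, Sequence[NormalizedWell]],
    th: Thresholds,
) -> EpistasisFlags:
    """G/O/I flags relative to the negative controls of each assay.

    A missing assay leaves the corresponding flag ``None``.  Normalized GFP is
    the induction proxy: with a shared baseline, the clone/control ratio of
    normalized expression equals the ratio of inductions.
    """
    flags = EpistasisFlags()

    def _ratio(wells: Sequence[NormalizedWell], condition: str) -> float:
        ctrl = controls.get(condition)
        if not ctrl:
            raise ValidationError(f"no control wells for condition {condition!r}")
        return _mean([w.ngfp for w in wells]) / _mean([w.ngfp for w in ctrl])

    if gpa12star_wells:
        flags.g = _ratio(gpa12star_wells, "gpa12star") <= 1.0 - th.g_abrogation
    if osmotic_wells:
        flags.o = _ratio(osmotic_wells, "osmotic") <= 1.0 - th.o_block
    if irg1_wells:
        flags.i = _ratio(irg1_wells, "irg1") >= th.i_fold
    return flags


# ---------------------------------------------------------------------------
# spore adhesion
# ---------------------------------------------------------------------------

def adhesion_category(spores_per_worm: float) -> int:
    """Bin mean spore counts: 0 = 1-10 (control-like), 1 = 10-25, 2 = > 25.

    The printed intervals share their endpoints; exactly 10 or 25 spores go
    to the lower bin.
    """
    if spores_per_worm < 0:
        raise ValueError(f"spore count must be >= 0, got {spores_per_worm}")
    if spores_per_worm <= 10:
        return 0
    if spores_per_worm <= 25:
        return 1
    return 2


def adhesion_index(n_mouth: int, n_vulva: int, n_total: int) -> float:
    """Fraction of adhesion sites occupied:
    ``(worms with > 1 spore at mouth + worms with > 1 spore at vulva) /
    (2 x total worms)``, in [0, 1]."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not (0 <= n_mouth <= n_total and 0 <= n_vulva <= n_total):
        raise ValueError("site counts must lie in [0, n_total]")
    return (n_mouth + n_vulva) / (2 * n_total)


def select_adhesion_nipi(
    index_by_clone: Mapping[str, Sequence[float]],
    control_indices: Sequence[float],
    gfp_reduction_by_clone: Mapping[str, Sequence[float]],
    min_reduction: float = 0.50,
) -> set[str]:
    """Clones with reduced spore adhesion *and* a > 50 % reporter reduction.

    A clone is retained iff in BOTH duplicate tests its adhesion index lies
    below every control clone's index and its reporter reduction exceeds
    ``min_reduction``.
    """
    if not control_indices:
        raise ValidationError("no control adhesion indices supplied")
    control_min = min(control_indices)
    selected = set()
    for clone_id, indices in index_by_clone.items():
        reductions = gfp_reduction_by_clone.get(clone_id)
        if reductions is None or len(indices) != 2 or len(reductions) != 2:
            raise ValidationError(
                f"clone {clone_id}: both duplicate tests are required"
            )
        if all(i < control_min for i in indices) and all(
            r > min_reduction for r in reductions
        ):
            selected.add(clone_id)
    return selected
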