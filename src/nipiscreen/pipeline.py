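"""End-to-end two-round screen driver: simulate, normalize, call, account.

The screen design is adaptive: round 1 tests every clone in duplicate under
infection; clones passing the round-1 Nipi or enhancer rule are retested in
quadruplicate with and without infection, and the round-2 quantitative data
both confirms the calls and removes clones with pronounced developmental
phenotypes.  This module wires the synthetic generator, the normalization
and the callers together so a whole screen with known ground truth runs in
one call, and produces the per-step clone accounting (clones in / clones out
for every selection step).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import synthetic
from .calls import (
    PhenotypeCall,
    Thresholds,
    anchor_cutoff,
    call_enhancer_round1,
    call_nipi_round1,
    call_nipi_round2,
    call_peni_hipi,
    classify_epistasis,
    flag_developmental,
)
from .normalize import NormalizedWell, normalize_screen
from .screen_io import CloneRecord
from .synthetic import (
    EffectSpec,
    GeneratorConfig,
    NEGATIVE_CONTROLS,
    PENI_CONTROLS,
    SIZE_CONTROL,
    TruthTable,
)


@dataclass(slots=True)
class ScreenResult:
    """Calls, anchored cut-offs and per-step accounting of one screen run."""

    calls: dict[str, PhenotypeCall]
    peni_cutoff: float | None
    accounting: list[tuple[str, int]] = field(default_factory=list)

    def clones_with(self, flag: str, value: bool = True) -> set[str]:
        return {c for c, call in self.calls.items()
                if getattr(call, flag) is value}

    @property
    def final_nipi_clones(self) -> set[str]:
        return {c for c, call in self.calls.items() if call.final_nipi}


def _wells_by_clone(
    wells: Iterable[NormalizedWell],
    condition: str | None = None,
    round_label: int | str | None = None,
) -> dict[str, list[NormalizedWell]]:
    grouped: dict[str, list[NormalizedWell]] = defaultdict(list)
    for w in wells:
        if condition is not None and w.condition != condition:
            continue
        if round_label is not None and w.round != round_label:
            continue
        grouped[w.clone_id].append(w)
    for group in grouped.values():
        group.sort(key=lambda w: (w.replicate_index, w.plate_id, w.well_id))
    return grouped


def call_round1(
    normalized: Sequence[NormalizedWell],
    clone_ids: Sequence[str],
    th: Thresholds,
) -> dict[str, tuple[bool, bool]]:
    """Round-1 Nipi and enhancer flags for every clone, from its duplicates."""
    by_clone = _wells_by_clone(normalized, condition="infected", round_label=1)
    rack1 = by_clone.get(SIZE_CONTROL, [])
    flags = {}
    for clone_id in clone_ids:
        duplicates = by_clone.get(clone_id, [])[:2]
        nipi = call_nipi_round1(duplicates, rack1, th)
        enhancer = call_enhancer_round1(duplicates, th)
        flags[clone_id] = (nipi, enhancer)
    return flags


def anchor_peni_cutoff(normalized: Sequence[NormalizedWell]) -> float:
    """Anchor the Peni cut-off from the uninfected round-2 control wells."""
    by_clone = _wells_by_clone(normalized, condition="noninfected", round_label=2)
    positives = [w.ngfp for c in PENI_CONTROLS for w in by_clone.get(c, [])]
    negatives = [w.ngfp for c in NEGATIVE_CONTROLS for w in by_clone.get(c, [])]
    return anchor_cutoff(positives, negatives)


def call_round2(
    normalized: Sequence[NormalizedWell],
    round1_flags: Mapping[str, tuple[bool, bool]],
    th: Thresholds,
) -> tuple[dict[str, PhenotypeCall], float | None]:
    """Round-2 confirmation calls for every round-1 candidate clone.

    Clones without a complete quadruplicate retest keep their round-1 flags
    but remain unconfirmed.  Returns the calls and the anchored Peni cut-off
    (``None`` when no enhancer candidate was retested).
    """
    inf = _wells_by_clone(normalized, condition="infected", round_label=2)
    uninf = _wells_by_clone(normalized, condition="noninfected", round_label=2)
    rack1 = inf.get(SIZE_CONTROL, [])
    enhancer_candidates = [c for c, (_, e) in round1_flags.items() if e]
    peni_cutoff = anchor_peni_cutoff(normalized) if enhancer_candidates and uninf else None

    calls: dict[str, PhenotypeCall] = {}
    for clone_id, (r1_nipi, r1_enh) in round1_flags.items():
        call = PhenotypeCall(clone_id, round1_nipi=r1_nipi, round1_enhancer=r1_enh)
        quads_inf = inf.get(clone_id, [])
        quads_uninf = uninf.get(clone_id, [])
        if r1_nipi and len(quads_inf) == 4:
            call.round2_nipi = call_nipi_round2(quads_inf, rack1, th)
            call.developmental = flag_developmental(quads_inf, th, rack1)
            call.evidence["round2"] = {
                "ngfp": [w.ngfp for w in quads_inf],
                "nred": [w.nred for w in quads_inf],
                "ntof": [w.ntof for w in quads_inf],
            }
        if r1_enh and peni_cutoff is not None and len(quads_inf) == 4 \
                and len(quads_uninf) == 4:
            call.peni, call.hipi = call_peni_hipi(
                quads_inf, quads_uninf, peni_cutoff, th.hipi_cutoff,
                th.round2_min_hits,
            )
            call.evidence["peni_hipi"] = {
                "uninfected_ngfp": [w.ngfp for w in quads_uninf],
                "infected_ngfp": [w.ngfp for w in quads_inf],
                "peni_cutoff": peni_cutoff,
                "hipi_cutoff": th.hipi_cutoff,
            }
        calls[clone_id] = call
    return calls, peni_cutoff


def add_epistasis_calls(
    calls: Mapping[str, PhenotypeCall],
    normalized: Sequence[NormalizedWell],
    th: Thresholds,
) -> None:
    """Attach tri-state G/O/I flags from the epistasis assay wells."""
    by_condition: dict[str, dict[str, list[NormalizedWell]]] = {
        cond: _wells_by_clone(normalized, condition=cond, round_label="epistasis")
        for cond in ("gpa12star", "osmotic", "irg1")
    }
    controls = {
        cond: [w for c in NEGATIVE_CONTROLS for w in groups.get(c, [])]
        for cond, groups in by_condition.items()
    }
    for clone_id, call in calls.items():
        g = by_condition["gpa12star"].get(clone_id)
        o = by_condition["osmotic"].get(clone_id)
        i = by_condition["irg1"].get(clone_id)
        if not (g or o or i):
            continue
        flags = classify_epistasis(g, o, i, controls, th)
        call.g_clone, call.o_clone, call.i_clone = flags.g, flags.o, flags.i


def run_two_round_screen(
    library: Sequence[CloneRecord],
    truth: Sequence[EffectSpec],
    cfg: GeneratorConfig,
    th: Thresholds | None = None,
    with_epistasis: bool = False,
    min_worms: int = 80,
    trim_fraction: float = 0.25,
) -> ScreenResult:
    """Simulate and analyze a full adaptive two-round screen.

    Round-2 wells are generated for exactly the clones that passed round 1
    (true and false positives alike), mirroring the real screen flow; the
    epistasis assays, when requested, run on the final retained Nipi clones.
    """
    th = th or Thresholds()
    effects = {e.clone_id: e for e in truth}
    clone_ids = [c.clone_id for c in library]
    root = np.random.SeedSequence(cfg.seed)
    rng1, rng2, rng3 = (np.random.default_rng(s) for s in root.spawn(3))

    round1_wells = synthetic.generate_round1(library, effects, cfg, rng1)
    norm1 = normalize_screen(round1_wells, min_worms, trim_fraction)
    round1_flags = call_round1(norm1, clone_ids, th)
    candidates = [c for c in clone_ids if any(round1_flags[c])]

    norm2: list[NormalizedWell] = []
    if candidates:
        round2_wells = synthetic.generate_round2(candidates, effects, cfg, rng2)
        norm2 = normalize_screen(round2_wells, min_worms, trim_fraction)
    calls, peni_cutoff = call_round2(
        norm2, {c: round1_flags[c] for c in clone_ids}, th
    )

    if with_epistasis:
        retained = sorted(c for c, call in calls.items() if call.final_nipi)
        if retained:
            ep_wells = synthetic.generate_epistasis(retained, effects, cfg, rng3)
            norm_ep = normalize_screen(ep_wells, min_worms, trim_fraction)
            add_epistasis_calls(calls, norm_ep, th)

    n_r1_nipi = sum(1 for c in clone_ids if round1_flags[c][0])
    n_r1_enh = sum(1 for c in clone_ids if round1_flags[c][1])
    n_r2_nipi = sum(1 for c in calls.values() if c.round2_nipi)
    n_dev = sum(1 for c in calls.values() if c.round2_nipi and c.developmental)
    accounting = [
        ("library", len(clone_ids)),
        ("round1_nipi_candidates", n_r1_nipi),
        ("round1_enhancer_candidates", n_r1_enh),
        ("round2_nipi", n_r2_nipi),
        ("pronounced_developmental", n_dev),
        ("retained_nipi", n_r2_nipi - n_dev),
        ("peni", sum(1 for c in calls.values() if c.peni)),
        ("hipi", sum(1 for c in calls.values() if c.hipi)),
    ]
    return ScreenResult(calls=calls, peni_cutoff=peni_cutoff, accounting=accounting)


def generate_and_write_screen(
    library: Sequence[CloneRecord],
    truth: Sequence[EffectSpec],
    cfg: GeneratorConfig,
) -> tuple[synthetic.ScreenDataset, TruthTable]:
    """Non-adaptive dataset for file-based stage-by-stage processing:
    round 2 covers the ground-truth effect clones, epistasis the final list's
    usual suspects (all non-null clones)."""
    non_null = [e.clone_id for e in truth if e.class_label != "null"]
    return synthetic.generate_screen(
        library, truth, cfg, retest_clones=non_null, epistasis_clones=non_null
    )
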