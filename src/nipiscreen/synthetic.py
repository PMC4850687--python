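"""Synthetic worm-sorter screens with known ground truth.

The generator emulates the statistical structure of per-worm reporter data
from a large-particle flow sorter:

* strictly positive, heavy-right-tailed worm-to-worm variation, modeled as
  independent multiplicative lognormal noise on TOF and on the two per-worm
  fluorescence ratios (GFP/TOF, dsRed/TOF);
* a multiplicative lognormal *plate effect* shared by every well of a plate,
  applied to TOF and to both fluorescence ratios -- exactly the nuisance the
  truncated-mean plate normalization removes;
* strong infection-dependent induction of the GFP reporter in wild-type
  worms (default 10-fold), with a saturating Hill-type dependence on the
  spore dose;
* a mostly-null clone population with sparse planted effects (Nipi, Hipi,
  Peni, developmental, epistasis classes), each encoded as multipliers on
  the induced GFP level, the uninfected baseline, the red control reporter
  and worm size.

Every simulated plate carries control wells mirroring the screen design: two
negative controls (``ctrl_sta1``, ``ctrl_k04g11``), a small-worm size control
(``ctrl_rack1``) anchoring the size guard, a strong positive Nipi control
(``ctrl_dcar1``) and -- on retest plates -- two constitutive high-expression
controls (``ctrl_fasn1``, ``ctrl_pan1``) used to anchor the Peni cut-off.
Retest plates are padded with null filler wells so that most wells on any
plate remain unremarkable and the truncated-mean normalizer stays anchored.

All randomness flows from a single integer seed; identical seeds give
byte-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .screen_io import (
    CONDITIONS,
    CloneRecord,
    WellRecord,
    WormEvent,
    write_events,
)


class ConfigurationError(ValueError):
    """Invalid generator configuration or condition name."""


#: phenotype classes the generator can plant
EFFECT_CLASSES = (
    "null", "nipi", "hipi", "peni", "developmental",
    "g_suppressor", "o_suppressor", "i_inducer",
)

# control clone ids placed on every simulated plate
NEGATIVE_CONTROLS = ("ctrl_sta1", "ctrl_k04g11")
SIZE_CONTROL = "ctrl_rack1"
NIPI_CONTROL = "ctrl_dcar1"
PENI_CONTROLS = ("ctrl_fasn1", "ctrl_pan1")
PAD_CLONE = "pad_null"


@dataclass(frozen=True, slots=True)
class EffectSpec:
    """Generative parameters of one clone's planted phenotype.

    All multipliers are relative to wild type (1.0).  ``gfp_induction_multiplier``
    scales the induced GFP level (infection, osmotic stress or constitutive
    GPA-12* signaling, according to ``class_label``); ``baseline_gfp_multiplier``
    scales uninfected GFP; ``red_multiplier`` and ``tof_multiplier`` scale the
    control reporter and worm size.
    """

    clone_id: str
    class_label: str = "null"
    gfp_induction_multiplier: float = 1.0
    baseline_gfp_multiplier: float = 1.0
    red_multiplier: float = 1.0
    tof_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.class_label not in EFFECT_CLASSES:
            raise ConfigurationError(f"unknown class_label {self.class_label!r}")
        for name in ("gfp_induction_multiplier", "baseline_gfp_multiplier",
                     "red_multiplier", "tof_multiplier"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.class_label == "null":
            if any(getattr(self, name) != 1.0 for name in (
                    "gfp_induction_multiplier", "baseline_gfp_multiplier",
                    "red_multiplier", "tof_multiplier")):
                raise ConfigurationError("null effects must have unit multipliers")


@dataclass(slots=True)
class GeneratorConfig:
    """Study conditions of a simulated screen.

    ``worm_cv`` is the lognormal coefficient of variation of the per-worm
    multiplicative noise; ``plate_effect_sd`` the log-scale SD of the per-plate
    factor.  ``wt_induction_fold`` is the infection-induced GFP fold-change in
    wild type at saturating spore dose; ``dose_ec50``/``dose_hill`` parametrize
    the Hill-type spore-dose response and ``spore_dose`` is the dose used for
    infected wells (default: 10x EC50, i.e. near saturation).
    """

    n_worms_per_well: int = 100
    worm_cv: float = 0.2
    plate_effect_sd: float = 0.3
    wt_induction_fold: float = 10.0
    dose_ec50: float = 1.0
    dose_hill: float = 2.0
    spore_dose: float = 10.0
    seed: int = 0
    # arbitrary-unit baselines of the measured channels
    base_tof: float = 100.0
    base_gfp_ratio: float = 1.0
    base_red_ratio: float = 2.0
    # induction folds of the non-infection assay conditions
    osmotic_fold: float = 5.0
    gpa12_fold: float = 8.0
    irg1_baseline: float = 0.3
    # plate layout
    wells_per_plate: int = 96
    retest_clones_per_plate: int = 8
    epistasis_clones_per_plate: int = 8

    def __post_init__(self) -> None:
        if self.n_worms_per_well < 1:
            raise ConfigurationError("n_worms_per_well must be >= 1")
        if not 0 <= self.worm_cv < 1:
            raise ConfigurationError("worm_cv must be in [0, 1)")
        if self.plate_effect_sd < 0:
            raise ConfigurationError("plate_effect_sd must be >= 0")
        if not self.wt_induction_fold > 1:
            raise ConfigurationError("wt_induction_fold must be > 1")
        if not (self.dose_ec50 > 0 and self.dose_hill > 0):
            raise ConfigurationError("dose_ec50 and dose_hill must be > 0")
        if not 8 <= self.wells_per_plate <= 96:
            raise ConfigurationError("wells_per_plate must be in [8, 96]")


@dataclass(slots=True)
class TruthTable:
    """Planted ground truth: one :class:`EffectSpec` per library clone."""

    effects: dict[str, EffectSpec]

    def class_of(self, clone_id: str) -> str:
        return self.effects[clone_id].class_label

    def clones_with_class(self, *labels: str) -> set[str]:
        return {c for c, e in self.effects.items() if e.class_label in labels}

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(
                "clone_id\tclass_label\tgfp_induction_multiplier\t"
                "baseline_gfp_multiplier\tred_multiplier\ttof_multiplier\n"
            )
            for clone_id in sorted(self.effects):
                e = self.effects[clone_id]
                handle.write(
                    f"{e.clone_id}\t{e.class_label}\t{e.gfp_induction_multiplier:g}\t"
                    f"{e.baseline_gfp_multiplier:g}\t{e.red_multiplier:g}\t"
                    f"{e.tof_multiplier:g}\n"
                )

    @classmethod
    def read(cls, path: str | Path) -> "TruthTable":
        effects: dict[str, EffectSpec] = {}
        with open(path, encoding="utf-8") as handle:
            next(handle)
            for line in handle:
                cid, label, gi, bg, rm, tm = line.rstrip("\n").split("\t")
                effects[cid] = EffectSpec(
                    cid, label, float(gi), float(bg), float(rm), float(tm)
                )
        return cls(effects)


@dataclass(slots=True)
class ScreenDataset:
    """All generated wells of a simulated screen."""

    wells: list[WellRecord]

    def write(self, path: str | Path) -> None:
        write_events(self.wells, path)


#: generative parameters of the per-plate control clones
CONTROL_EFFECTS: Mapping[str, EffectSpec] = {
    NEGATIVE_CONTROLS[0]: EffectSpec(NEGATIVE_CONTROLS[0], "null"),
    NEGATIVE_CONTROLS[1]: EffectSpec(NEGATIVE_CONTROLS[1], "null"),
    # rack-1 knock-down: known signaling component whose loss also makes the
    # worms markedly smaller; anchors the size guard and the developmental cut
    SIZE_CONTROL: EffectSpec(
        SIZE_CONTROL, "nipi", gfp_induction_multiplier=0.6, tof_multiplier=0.8
    ),
    # dcar-1-like receptor knock-down: strong positive Nipi control
    NIPI_CONTROL: EffectSpec(NIPI_CONTROL, "nipi", gfp_induction_multiplier=0.2),
    # fasn-1 / pan-1-like: constitutive reporter expression without infection
    PENI_CONTROLS[0]: EffectSpec(
        PENI_CONTROLS[0], "peni", baseline_gfp_multiplier=3.0
    ),
    PENI_CONTROLS[1]: EffectSpec(
        PENI_CONTROLS[1], "peni", baseline_gfp_multiplier=3.0
    ),
    PAD_CLONE: EffectSpec(PAD_CLONE, "null"),
}


def dose_response(spore_dose: float, cfg: GeneratorConfig) -> float:
    """Hill-type induction scaling in [0, 1]: 0 at dose 0, 0.5 at the EC50."""
    if spore_dose < 0:
        raise ConfigurationError(f"spore dose must be >= 0, got {spore_dose}")
    if spore_dose == 0:
        return 0.0
    d = spore_dose ** cfg.dose_hill
    return d / (d + cfg.dose_ec50 ** cfg.dose_hill)


def expected_ratios(
    effect: EffectSpec, condition: str, cfg: GeneratorConfig
) -> tuple[float, float, float]:
    """Noise-free expectations ``(gfp/tof, dsred/tof, tof)`` at plate factor 1.

    The induction multiplier applies to the condition it targets: every
    effect class modulates infection-induced GFP, while the epistasis classes
    additionally (``g_suppressor``, ``o_suppressor``) or exclusively
    (``i_inducer``) modulate their own assay condition.
    """
    if condition not in CONDITIONS:
        raise ConfigurationError(f"unknown condition {condition!r}")
    base = cfg.base_gfp_ratio * effect.baseline_gfp_multiplier
    induction = effect.gfp_induction_multiplier
    if condition == "noninfected":
        gfp = base
    elif condition == "infected":
        fold = 1.0 + (cfg.wt_induction_fold - 1.0) * dose_response(cfg.spore_dose, cfg)
        gfp = base * fold * induction
    elif condition == "osmotic":
        mult = induction if effect.class_label == "o_suppressor" else 1.0
        gfp = base * cfg.osmotic_fold * mult
    elif condition == "gpa12star":
        mult = induction if effect.class_label == "g_suppressor" else 1.0
        gfp = base * cfg.gpa12_fold * mult
    else:  # irg1 reporter strain
        mult = induction if effect.class_label == "i_inducer" else 1.0
        gfp = cfg.irg1_baseline * mult
    red = cfg.base_red_ratio * effect.red_multiplier
    tof = cfg.base_tof * effect.tof_multiplier
    return gfp, red, tof


def wt_infected_baseline(cfg: GeneratorConfig) -> float:
    """Expected GFP/TOF of a wild-type infected well at plate factor 1."""
    return expected_ratios(EffectSpec("wt"), "infected", cfg)[0]


def _lognormal_multipliers(
    rng: np.random.Generator, cv: float, n: int, k: int
) -> np.ndarray:
    """k x n unit-mean lognormal multipliers with coefficient of variation cv."""
    if cv == 0:
        return np.ones((k, n))
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=(k, n))


def generate_well(
    effect: EffectSpec,
    condition: str,
    cfg: GeneratorConfig,
    plate_factor: float,
    plate_id: str = "P001",
    well_id: str = "A01",
    rng: np.random.Generator | None = None,
) -> list[WormEvent]:
    """Simulate the worm events of one well.

    The plate factor multiplies TOF and both per-worm fluorescence ratios, so
    all three normalized channels carry it and the plate normalization removes
    it.  With ``worm_cv == 0`` every event's GFP/TOF equals the configured
    expectation exactly.
    """
    if not plate_factor > 0:
        raise ConfigurationError(f"plate_factor must be > 0, got {plate_factor}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    gfp_ratio, red_ratio, tof = expected_ratios(effect, condition, cfg)
    n = cfg.n_worms_per_well
    noise = _lognormal_multipliers(rng, cfg.worm_cv, n, 3)
    tofs = tof * plate_factor * noise[0]
    gfps = gfp_ratio * plate_factor * noise[1] * tofs
    reds = red_ratio * plate_factor * noise[2] * tofs
    exts = 0.5 * tofs
    return [
        WormEvent(plate_id, well_id, float(tofs[i]), float(exts[i]),
                  float(gfps[i]), float(reds[i]))
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# plate assembly
# ---------------------------------------------------------------------------

def _well_ids(n: int) -> list[str]:
    ids = [f"{row}{col:02d}" for row in "ABCDEFGH" for col in range(1, 13)]
    return ids[:n]


def _plate_factor(rng: np.random.Generator, sd: float) -> float:
    if sd == 0:
        return 1.0
    return float(rng.lognormal(mean=-0.5 * sd * sd, sigma=sd))


def _chunk(seq: Sequence, size: int) -> list[list]:
    return [list(seq[i:i + size]) for i in range(0, len(seq), size)]


def _build_plate(
    plate_id: str,
    layout: Sequence[tuple[str, str, int]],
    effects: Mapping[str, EffectSpec],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    round_label: int | str,
) -> list[WellRecord]:
    """One plate: ``layout`` is a list of (clone_id, condition, replicate)."""
    factor = _plate_factor(rng, cfg.plate_effect_sd)
    wells = []
    for well_id, (clone_id, condition, replicate) in zip(_well_ids(len(layout)), layout):
        effect = effects.get(clone_id) or CONTROL_EFFECTS[clone_id]
        events = generate_well(
            effect, condition, cfg, factor,
            plate_id=plate_id, well_id=well_id, rng=rng,
        )
        wells.append(
            WellRecord(plate_id, well_id, clone_id, condition,
                       round_label, replicate, events)
        )
    return wells


def generate_round1(
    library: Sequence[CloneRecord],
    effects: Mapping[str, EffectSpec],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> list[WellRecord]:
    """Duplicate infected wells for every library clone, plus plate controls."""
    controls = [*NEGATIVE_CONTROLS, SIZE_CONTROL, NIPI_CONTROL]
    per_plate = cfg.wells_per_plate - len(controls)
    wells: list[WellRecord] = []
    plate_no = 0
    for replicate in (1, 2):
        for chunk in _chunk([c.clone_id for c in library], per_plate):
            plate_no += 1
            layout = [(cid, "infected", 1) for cid in controls]
            layout += [(cid, "infected", replicate) for cid in chunk]
            wells.extend(
                _build_plate(f"R1P{plate_no:04d}", layout, effects, cfg, rng, 1)
            )
    return wells


def generate_round2(
    clone_ids: Sequence[str],
    effects: Mapping[str, EffectSpec],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> list[WellRecord]:
    """Quadruplicate wells, with and without infection, for retested clones.

    Each retest plate carries the full control block (including the Peni
    positive controls used for cut-off anchoring) and is padded to a full
    plate with null filler wells so the plate normalizer stays anchored near
    the unremarkable level.
    """
    controls = [*NEGATIVE_CONTROLS, SIZE_CONTROL, NIPI_CONTROL, *PENI_CONTROLS]
    wells: list[WellRecord] = []
    plate_no = 0
    for chunk in _chunk(list(clone_ids), cfg.retest_clones_per_plate):
        for condition in ("infected", "noninfected"):
            plate_no += 1
            layout = [(cid, condition, 1) for cid in controls]
            for cid in chunk:
                layout += [(cid, condition, rep) for rep in (1, 2, 3, 4)]
            n_pad = cfg.wells_per_plate - len(layout)
            layout += [(PAD_CLONE, condition, i + 1) for i in range(max(n_pad, 0))]
            wells.extend(
                _build_plate(f"R2P{plate_no:04d}", layout, effects, cfg, rng, 2)
            )
    return wells


def generate_epistasis(
    clone_ids: Sequence[str],
    effects: Mapping[str, EffectSpec],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> list[WellRecord]:
    """Duplicate wells per clone in the GPA-12*, osmotic and irg-1 assays."""
    controls = [*NEGATIVE_CONTROLS]
    wells: list[WellRecord] = []
    plate_no = 0
    for chunk in _chunk(list(clone_ids), cfg.epistasis_clones_per_plate):
        for condition in ("gpa12star", "osmotic", "irg1"):
            plate_no += 1
            layout = [(cid, condition, 1) for cid in controls]
            for cid in chunk:
                layout += [(cid, condition, rep) for rep in (1, 2)]
            n_pad = cfg.wells_per_plate - len(layout)
            layout += [(PAD_CLONE, condition, i + 1) for i in range(max(n_pad, 0))]
            wells.extend(
                _build_plate(f"EPP{plate_no:04d}", layout, effects, cfg, rng,
                             "epistasis")
            )
    return wells


def generate_screen(
    library: Sequence[CloneRecord],
    truth: Sequence[EffectSpec],
    cfg: GeneratorConfig,
    retest_clones: Iterable[str] | None = None,
    epistasis_clones: Iterable[str] | None = None,
) -> tuple[ScreenDataset, TruthTable]:
    """Simulate a whole two-round screen.

    Every library clone must have exactly one :class:`EffectSpec` in
    ``truth``.  Round 1 contains duplicate infected wells per clone; clones
    in ``retest_clones`` (default: every clone with a non-null planted class)
    additionally receive quadruplicate wells with and without infection in
    round 2.  ``epistasis_clones`` optionally adds the three epistasis assays.
    """
    effects = {e.clone_id: e for e in truth}
    library_ids = [c.clone_id for c in library]
    missing = set(library_ids) - set(effects)
    extra = set(effects) - set(library_ids)
    if missing or extra:
        raise ConfigurationError(
            f"library/truth mismatch: {len(missing)} clones without an effect, "
            f"{len(extra)} effects without a clone"
        )
    if retest_clones is None:
        retest_clones = [c for c in library_ids if effects[c].class_label != "null"]
    else:
        retest_clones = [c for c in library_ids if c in set(retest_clones)]

    root = np.random.SeedSequence(cfg.seed)
    rng1, rng2, rng3 = (np.random.default_rng(s) for s in root.spawn(3))
    wells = generate_round1(library, effects, cfg, rng1)
    wells += generate_round2(retest_clones, effects, cfg, rng2)
    if epistasis_clones is not None:
        epistasis = [c for c in library_ids if c in set(epistasis_clones)]
        wells += generate_epistasis(epistasis, effects, cfg, rng3)
    return ScreenDataset(wells), TruthTable(effects)


# ---------------------------------------------------------------------------
# demo libraries with planted effects
# ---------------------------------------------------------------------------

#: default planted-effect parameters, per class
PLANTED_EFFECTS = {
    "nipi": dict(gfp_induction_multiplier=0.4),
    "hipi": dict(gfp_induction_multiplier=2.0),
    "peni": dict(baseline_gfp_multiplier=3.0),
    "developmental": dict(gfp_induction_multiplier=0.4, red_multiplier=0.5),
    "g_suppressor": dict(gfp_induction_multiplier=0.4),
    "o_suppressor": dict(gfp_induction_multiplier=0.4),
    "i_inducer": dict(gfp_induction_multiplier=3.0),
}


def make_planted_library(
    n_clones: int,
    planted: Mapping[str, int],
    seed: int = 0,
    effect_overrides: Mapping[str, Mapping[str, float]] | None = None,
) -> tuple[list[CloneRecord], list[EffectSpec]]:
    """A clone library with ``planted[class] = count`` non-null effects.

    Planted clones are spread deterministically (but shuffled by ``seed``)
    across the library so no plate is dominated by effects.  Each clone
    targets one synthetic gene ``g_<clone index>``.
    """
    total_planted = sum(planted.values())
    if total_planted > n_clones:
        raise ConfigurationError("more planted effects than clones")
    labels = ["null"] * (n_clones - total_planted)
    for label, count in sorted(planted.items()):
        if label not in EFFECT_CLASSES or label == "null":
            raise ConfigurationError(f"cannot plant class {label!r}")
        labels += [label] * count
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)

    overrides = dict(PLANTED_EFFECTS)
    for label, params in (effect_overrides or {}).items():
        overrides[label] = {**overrides.get(label, {}), **params}

    library, truth = [], []
    for i, label in enumerate(labels):
        clone_id = f"sjj_SIM{i:05d}"
        library.append(CloneRecord(clone_id, "ahringer", [(f"g_{i:05d}", 1.0)]))
        params = overrides[label] if label != "null" else {}
        truth.append(EffectSpec(clone_id, label, **params))
    return library, truth


def zero_noise(cfg: GeneratorConfig) -> GeneratorConfig:
    """A copy of ``cfg`` with all stochastic components switched off."""
    return replace(cfg, worm_cv=0.0, plate_effect_sd=0.0)


def config_fields() -> tuple[str, ...]:
    return tuple(f.name for f in fields(GeneratorConfig))
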