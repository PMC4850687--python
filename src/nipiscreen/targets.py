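"""Clone-to-gene target mapping, gene-family filtering and screen accounting.

An RNAi clone can target zero genes (sequence-ambiguous), one gene, or many
near-identical paralogs (histone ``his`` and major sperm protein ``msp``
families).  Gene-level statistics therefore need an explicit clone-gene
bipartite map, and family-confounded clones/genes are removed as a block:
a clone is dropped only when *all* its predicted targets belong to flagged
families; otherwise the clone is kept and only its family genes are dropped.

Also here: the screen's bookkeeping arithmetic (library assembly, screen
efficiency from sibling clones, printed-precision percentages) and the
ortholog-selection rule used when mapping annotation catalogs from other
species (keep the best candidate only when its score beats the runner-up by
a clear gap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .screen_io import CloneRecord


@dataclass(slots=True)
class TargetSummary:
    """Clone/gene accounting of a clone set.

    ``ambiguous_clones`` are retained in clone-level statistics but excluded
    from gene-level ones (they have no predicted target).  The
    ``family_filtered_*`` sets record what :func:`filter_families` removed
    and are always subsets of the originally retained sets.
    """

    retained_clones: set[str] = field(default_factory=set)
    retained_genes: set[str] = field(default_factory=set)
    multihit_genes: dict[str, int] = field(default_factory=dict)
    ambiguous_clones: set[str] = field(default_factory=set)
    family_filtered_clones: set[str] = field(default_factory=set)
    family_filtered_genes: set[str] = field(default_factory=set)
    clone_targets: dict[str, frozenset[str]] = field(default_factory=dict)


def map_targets(clones: Sequence[CloneRecord]) -> TargetSummary:
    """Union of predicted targets with per-gene clone multiplicity."""
    summary = TargetSummary()
    counts: dict[str, int] = {}
    for clone in clones:
        summary.retained_clones.add(clone.clone_id)
        genes = clone.target_genes
        summary.clone_targets[clone.clone_id] = frozenset(genes)
        if not genes:
            summary.ambiguous_clones.add(clone.clone_id)
            continue
        for gene in genes:
            counts[gene] = counts.get(gene, 0) + 1
    summary.retained_genes = set(counts)
    summary.multihit_genes = {g: c for g, c in counts.items() if c > 1}
    return summary


def filter_families(summary: TargetSummary, family_genes: Iterable[str]) -> TargetSummary:
    """Remove family-confounded clones and genes.

    ``family_genes`` is the explicit membership list of the flagged families
    (supplied as data, never inferred from gene names).  Clones whose targets
    are *exclusively* family genes are dropped; all other clones are kept and
    family genes are removed from the gene set.  Idempotent.
    """
    family = set(family_genes)
    dropped_clones = {
        cid for cid, genes in summary.clone_targets.items()
        if genes and genes <= family
    }
    kept_targets = {
        cid: frozenset(genes - family)
        for cid, genes in summary.clone_targets.items()
        if cid not in dropped_clones
    }
    counts: dict[str, int] = {}
    for genes in kept_targets.values():
        for gene in genes:
            counts[gene] = counts.get(gene, 0) + 1
    return TargetSummary(
        retained_clones=summary.retained_clones - dropped_clones,
        retained_genes=set(counts),
        multihit_genes={g: c for g, c in counts.items() if c > 1},
        ambiguous_clones=summary.ambiguous_clones - dropped_clones,
        family_filtered_clones=summary.family_filtered_clones | dropped_clones,
        family_filtered_genes=summary.family_filtered_genes
        | (summary.retained_genes & family),
        clone_targets=kept_targets,
    )


def screen_efficiency(
    retained: Iterable[str], sibling_missed: Iterable[str]
) -> float:
    """Fraction of clones hitting the identified targets that were retained.

    ``sibling_missed`` are the other library clones predicted to hit the same
    target genes; if the retained clones are true positives these siblings
    should have been retained too, so this fraction measures the screen's
    sensitivity.
    """
    retained, sibling_missed = set(retained), set(sibling_missed)
    if retained & sibling_missed:
        raise ValueError("retained and sibling_missed must be disjoint")
    total = len(retained) + len(sibling_missed)
    if total == 0:
        raise ValueError("both clone sets are empty")
    return len(retained) / total


def library_accounting(
    ahringer_total: int,
    ahringer_failed: int,
    vidal_picked: int,
    vidal_failed: int,
    duplicated_clones: int = 0,
) -> tuple[int, int]:
    """Library assembly arithmetic: ``(clone count, well count)``.

    The well count exceeds the clone count by the number of clones present in
    two wells.
    """
    for name, value in (
        ("ahringer_total", ahringer_total), ("ahringer_failed", ahringer_failed),
        ("vidal_picked", vidal_picked), ("vidal_failed", vidal_failed),
        ("duplicated_clones", duplicated_clones),
    ):
        if value < 0:
            raise ValueError(f"{name} must be >= 0")
    ahringer = ahringer_total - ahringer_failed
    vidal = vidal_picked - vidal_failed
    if ahringer < 0 or vidal < 0:
        raise ValueError("more failed clones than clones")
    clone_count = ahringer + vidal
    return clone_count, clone_count + duplicated_clones


def select_ortholog(
    candidate_scores: Mapping[str, int], mode: str = "strict"
) -> list[str]:
    """Pick putative orthologs from integer prediction scores (0-10).

    ``strict``: keep the best candidate only if it beats the runner-up by a
    score gap >= 2, else keep none.  ``top_two``: keep the best if the gap is
    > 2, else keep the top two.  A single candidate is always kept.  Ties are
    broken by gene id for determinism.
    """
    if mode not in ("strict", "top_two"):
        raise ValueError(f"unknown mode {mode!r}")
    if not candidate_scores:
        raise ValueError("empty candidate score map")
    for gene, score in candidate_scores.items():
        if not 0 <= score <= 10:
            raise ValueError(f"score for {gene} outside [0, 10]")
    ranked = sorted(candidate_scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) == 1:
        return [ranked[0][0]]
    (best, s1), (second, s2) = ranked[0], ranked[1]
    gap = s1 - s2
    if mode == "strict":
        return [best] if gap >= 2 else []
    return [best] if gap > 2 else [best, second]


def percent(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """Percentage rounded half-up to the printed precision."""
    if denominator == 0:
        raise ValueError("denominator is 0")
    value = Decimal(100 * numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-ndigits)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))
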