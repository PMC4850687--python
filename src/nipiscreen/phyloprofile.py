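"""Phylogenetic profiling from best-hit bit scores across species.

For each query protein ``i`` and species ``j``, ``C_ij`` is the best bit
score among that species' reported alignments (0 when the species has no
hit).  Because bit scores grow with protein length, each row is normalized
by the query's self-alignment score ``C_ii``, giving values in which the
query's own species sits at 1.0 and a value near 0 means no detectable
homolog.  Alignments arrive as standard 12-column tabular files (query,
subject, identity, ..., bit score); the aligner itself is never executed
here.

Profiles are clustered over genes (1 - Pearson distance, average linkage),
while species are clustered *within* their taxon group only, the groups kept
in a fixed order, so the display never mixes, say, fungi with vertebrates.
Conservation classes: a gene is an *orphan* when no species besides its own
reaches the presence threshold, *clade-restricted* when every species above
threshold lies within the focal clade, and *broadly conserved* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .enrichment import correlation_linkage
from .screen_io import ValidationError

#: fixed display order of the taxon groups
TAXON_GROUPS = ("fungi", "invertebrates", "vertebrates", "plants", "protists")

#: a homolog is called present when C_ij / C_ii reaches this value
DEFAULT_PRESENCE_THRESHOLD = 0.25

#: 12-column tabular alignment format; only query, subject and bit score are used
BLAST_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

RESTRICTION_LABELS = ("orphan", "clade_restricted", "broadly_conserved")


@dataclass(slots=True)
class BitScoreMatrix:
    """Genes x species best-hit bit scores plus per-gene self scores."""

    scores: pd.DataFrame
    groups: dict[str, str]
    self_scores: pd.Series
    self_species: str

    def __post_init__(self) -> None:
        if (self.scores.to_numpy() < 0).any():
            raise ValidationError("bit scores must be >= 0")
        if (self.self_scores <= 0).any():
            missing = list(self.self_scores.index[self.self_scores <= 0])
            raise ValidationError(f"nonpositive self scores for {missing}")
        unknown = set(self.groups.values()) - set(TAXON_GROUPS)
        if unknown:
            raise ValidationError(f"unknown taxon groups {unknown}")


@dataclass(slots=True)
class NormalizedProfile:
    """Self-normalized profile: values ``C_ij / C_ii`` in [0, ~1]."""

    values: pd.DataFrame
    groups: dict[str, str]
    self_species: str


def read_best_hits(path: str | Path) -> pd.Series:
    """Best (maximum) bit score per query in one tabular alignment file."""
    frame = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=BLAST_COLUMNS,
    )
    if frame.empty:
        return pd.Series(dtype=float)
    return frame.groupby("qseqid")["bitscore"].max()


def best_hit_matrix(
    blast_tabular_paths: Mapping[str, str | Path],
    queries: Sequence[str],
    self_species: str,
    groups: Mapping[str, str],
) -> BitScoreMatrix:
    """Assemble the genes x species best-hit matrix from per-species files.

    ``blast_tabular_paths`` maps species id to its tabular alignment file;
    one of the species must be the queries' own (``self_species``), whose
    query-vs-self alignments provide the self scores ``C_ii``.  A query
    without a self alignment cannot be normalized and is an error.
    """
    if self_species not in blast_tabular_paths:
        raise ValidationError(
            f"self species {self_species!r} has no alignment file"
        )
    columns = {}
    for species, path in blast_tabular_paths.items():
        hits = read_best_hits(path)
        columns[species] = [float(hits.get(q, 0.0)) for q in queries]
    scores = pd.DataFrame(columns, index=list(queries))

    self_frame = pd.read_csv(
        blast_tabular_paths[self_species], sep="\t", header=None,
        comment="#", names=BLAST_COLUMNS,
    )
    self_hits = self_frame[self_frame["qseqid"] == self_frame["sseqid"]]
    self_best = self_hits.groupby("qseqid")["bitscore"].max()
    missing = [q for q in queries if q not in self_best.index]
    if missing:
        raise ValidationError(f"no self score for queries {missing}")
    self_scores = pd.Series([float(self_best[q]) for q in queries],
                            index=list(queries))
    return BitScoreMatrix(scores, dict(groups), self_scores, self_species)


def normalize_profiles(m: BitScoreMatrix) -> NormalizedProfile:
    """Divide each row by its self score (``C_ij -> C_ij / C_ii``)."""
    values = m.scores.div(m.self_scores, axis=0)
    return NormalizedProfile(values, dict(m.groups), m.self_species)


def cluster_profiles(p: NormalizedProfile) -> tuple[list[str], list[str]]:
    """Order genes by global clustering; order species within taxon groups.

    Gene clustering uses the whole profile; species are clustered
    independently inside each taxon group (1 - Pearson over genes, average
    linkage) and the groups are concatenated in the fixed
    fungi/invertebrates/vertebrates/plants/protists order, so species orders
    never cross group boundaries.  A single gene yields identity ordering.
    """
    values = p.values
    if values.shape[0] < 2:
        gene_order = list(values.index)
    else:
        linkage = correlation_linkage(values.to_numpy(dtype=float))
        gene_order = [values.index[i] for i in hierarchy.leaves_list(linkage)]

    species_order: list[str] = []
    for group in TAXON_GROUPS:
        members = [s for s in values.columns if p.groups.get(s) == group]
        if len(members) < 2:
            species_order.extend(members)
            continue
        sub = values[members].to_numpy(dtype=float).T
        linkage = correlation_linkage(sub)
        species_order.extend(members[i] for i in hierarchy.leaves_list(linkage))
    # species with no group annotation keep their input position at the end
    species_order.extend(s for s in values.columns if p.groups.get(s) not in TAXON_GROUPS)
    return gene_order, species_order


def classify_restriction(
    profile_row: pd.Series,
    presence_threshold: float,
    focal_clade: Iterable[str],
    self_species: str,
) -> str:
    """Conservation class of one gene's normalized profile.

    ``orphan``: no species other than the gene's own reaches the presence
    threshold.  ``clade_restricted``: every species at or above threshold
    lies within the focal clade.  Otherwise ``broadly_conserved``.  Raising
    the threshold can only move a gene toward the more restricted classes.
    """
    if not 0 < presence_threshold < 1:
        raise ValueError("presence_threshold must be in (0, 1)")
    present = {s for s, v in profile_row.items() if v >= presence_threshold}
    others = present - {self_species}
    if not others:
        return "orphan"
    if others <= set(focal_clade):
        return "clade_restricted"
    return "broadly_conserved"


def classify_all(
    p: NormalizedProfile,
    focal_clade: Iterable[str],
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> pd.Series:
    """Conservation class for every gene in the profile."""
    focal = set(focal_clade)
    return pd.Series(
        {
            gene: classify_restriction(
                p.values.loc[gene], presence_threshold, focal, p.self_species
            )
            for gene in p.values.index
        }
    )


# ---------------------------------------------------------------------------
# synthetic tabular alignment fixtures
# ---------------------------------------------------------------------------

def make_synthetic_hit_files(
    out_dir: str | Path,
    truth: Mapping[str, str],
    species: Mapping[str, str],
    focal_clade: Iterable[str],
    self_species: str,
    seed: int = 0,
) -> dict[str, Path]:
    """Write synthetic 12-column tabular alignment files for a designed truth.

    ``truth`` maps each query gene to a conservation class (``orphan``,
    ``clade_restricted`` or ``broadly_conserved``); ``species`` maps species
    ids to taxon groups.  Homologous hits get normalized scores in
    [0.4, 0.9]; non-homologous species either lack a hit line or carry a
    spurious low-scoring one (< 0.15 of self), so classification at the
    default 0.25 threshold reproduces the designed truth exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    focal = set(focal_clade) | {self_species}
    rng = np.random.default_rng(seed)
    unknown = set(truth.values()) - set(RESTRICTION_LABELS)
    if unknown:
        raise ValueError(f"unknown truth labels {unknown}")

    # one synthetic protein per gene; self score scales with a fake length
    self_scores = {
        gene: float(rng.integers(200, 900)) for gene in sorted(truth)
    }
    paths: dict[str, Path] = {}
    for sp in species:
        lines = []
        for gene, label in sorted(truth.items()):
            cii = self_scores[gene]
            if sp == self_species:
                # the self alignment (query == subject) plus a weaker paralog hit
                lines.append(_hit_line(gene, gene, cii))
                lines.append(_hit_line(gene, f"{gene}_paralog", 0.3 * cii))
                continue
            if label == "orphan":
                homolog = False
            elif label == "clade_restricted":
                homolog = sp in focal
            else:
                homolog = True
            if homolog:
                ratio = float(rng.uniform(0.4, 0.9))
                lines.append(_hit_line(gene, f"{sp}_{gene}", ratio * cii))
            elif rng.random() < 0.3:
                # spurious low-scoring alignment well below the threshold
                ratio = float(rng.uniform(0.02, 0.15))
                lines.append(_hit_line(gene, f"{sp}_junk", ratio * cii))
        path = out_dir / f"{sp}.blast.tsv"
        path.write_text("".join(lines), encoding="utf-8")
        paths[sp] = path
    return paths


def _hit_line(query: str, subject: str, bitscore: float) -> str:
    fields = (
        query, subject, "35.0", "100", "50", "3",
        "1", "100", "1", "100", "1e-10", f"{bitscore:.1f}",
    )
    return "\t".join(fields) + "\n"
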