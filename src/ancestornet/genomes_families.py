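"""Genome selection, taxonomic grouping and protein-family construction.

The entry point of the pipeline: starting from genome metadata, homology
hits against an oxygen-reductase reference set, and an all-vs-all global
identity edge list, this module

* classifies genomes as aerobic/anaerobic and keeps the anaerobes with
  enough protein-coding genes,
* assigns each genome to a major taxonomic group (phylum, or class for
  the two over-represented phyla, with a residual "Other Bacteria" bin),
* builds the thresholded similarity graph and clusters it into protein
  families with Markov clustering (MCL),
* filters families by species/genome spread and tabulates per-group
  presence, from which universal (present-in-every-group) families are
  selected,
* annotates families by majority vote over per-sequence best hits.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OTHER_BACTERIA = "Other Bacteria"
#: Phyla split into classes because of their over-representation.
SPLIT_PHYLA = frozenset({"Firmicutes", "Proteobacteria"})


@dataclass(frozen=True)
class GenomeRecord:
    """Metadata for one genome."""

    genome_id: str
    phylum: str
    class_name: str = ""
    species: str = ""
    protein_count: int = 0
    oxygen_class: str = "unclassified"

    def __post_init__(self) -> None:
        if self.protein_count < 0:
            raise ValueError(f"protein_count < 0 for {self.genome_id}")


@dataclass(frozen=True)
class HomologyHit:
    """One BLAST-style hit of a query sequence against a reference."""

    query_id: str
    subject_id: str
    percent_identity: float
    e_value: float
    aligned_length_aa: int = 0
    query_coverage: float = 0.0
    length_ratio: float = 1.0
    category: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")


@dataclass(frozen=True)
class SimilarityEdge:
    """Undirected global-identity edge between two sequences."""

    seq_a: str
    seq_b: str
    global_identity: float
    e_value: float

    def __post_init__(self) -> None:
        if self.seq_a == self.seq_b:
            raise ValueError(f"self-edge on {self.seq_a}")


@dataclass
class ProteinFamily:
    """A cluster of homologous sequences, each tagged with its genome."""

    family_id: str
    members: dict[str, str]  # sequence_id -> genome_id
    category_annotations: set[str] = field(default_factory=set)

    @property
    def genomes(self) -> set[str]:
        return set(self.members.values())

    def __len__(self) -> int:
        return len(self.members)


class PresenceMatrix:
    """Per-family, per-group genome presence counts.

    Cell (family, group) stores how many genomes of the group contain at
    least one member sequence of the family; the per-group genome totals
    are constant across families.
    """

    def __init__(self, counts: pd.DataFrame, group_sizes: pd.Series):
        if (group_sizes <= 0).any():
            bad = group_sizes.index[group_sizes <= 0].tolist()
            raise ValueError(f"groups with 0 genomes: {bad}")
        self.counts = counts.loc[:, group_sizes.index]
        self.group_sizes = group_sizes

    @property
    def family_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def groups(self) -> list[str]:
        return list(self.counts.columns)

    def coverage(self) -> pd.DataFrame:
        """Fraction of each group's genomes containing the family."""
        return self.counts.div(self.group_sizes, axis=1)


# ---------------------------------------------------------------------------
# genome selection and grouping


def classify_oxygen(
    records: Sequence[GenomeRecord],
    hco_nor_hits: Iterable[HomologyHit],
    *,
    min_identity: float = 25.0,
    max_e: float = 1e-10,
    min_aligned_aa: int = 300,
) -> list[GenomeRecord]:
    """Classify genomes as aerobic or anaerobic from oxygen-reductase hits.

    A genome is aerobic iff it has at least one hit against the
    heme-copper oxygen reductase / NO reductase reference set with
    identity strictly above ``min_identity``, e-value strictly below
    ``max_e`` and an alignment of at least ``min_aligned_aa`` residues.
    """
    known = {r.genome_id for r in records}
    aerobic: set[str] = set()
    unknown: list[str] = []
    for hit in hco_nor_hits:
        if hit.query_id not in known:
            unknown.append(hit.query_id)
            continue
        if (
            hit.percent_identity > min_identity
            and hit.e_value < max_e
            and hit.aligned_length_aa >= min_aligned_aa
        ):
            aerobic.add(hit.query_id)
    if unknown:
        raise ValueError(
            f"hits reference unknown genome ids: {sorted(set(unknown))}"
        )
    out = []
    for r in records:
        cls = "aerobic" if r.genome_id in aerobic else "anaerobic"
        out.append(
            GenomeRecord(
                r.genome_id, r.phylum, r.class_name, r.species,
                r.protein_count, cls,
            )
        )
    return out


def classify_and_select_genomes(
    records: Sequence[GenomeRecord],
    hco_nor_hits: Iterable[HomologyHit],
    min_proteins: int = 1000,
) -> list[GenomeRecord]:
    """Keep non-aerobic genomes with more than ``min_proteins`` proteins.

    The protein-count floor excludes reduced genomes of energy parasites,
    whose gene losses would otherwise distort universality statistics.
    Input order is preserved.
    """
    if min_proteins < 0:
        raise ValueError("min_proteins must be >= 0")
    classified = classify_oxygen(records, hco_nor_hits)
    kept = [
        r for r in classified
        if r.oxygen_class != "aerobic" and r.protein_count > min_proteins
    ]
    logger.info(
        "genome selection: %d input, %d retained (anaerobic, >%d proteins)",
        len(records), len(kept), min_proteins,
    )
    return kept


def assign_group(
    record: GenomeRecord, species_count_per_phylum: Mapping[str, int]
) -> str:
    """Map a genome to its major taxonomic group label.

    Firmicutes and Proteobacteria are split into classes; other phyla
    with at least 5 species keep the phylum label; smaller phyla are
    pooled into "Other Bacteria".
    """
    if record.phylum in SPLIT_PHYLA:
        if not record.class_name:
            raise ValueError(
                f"genome {record.genome_id}: phylum {record.phylum} "
                "requires a class name"
            )
        return record.class_name
    if species_count_per_phylum.get(record.phylum, 0) >= 5:
        return record.phylum
    return OTHER_BACTERIA


def assign_groups(records: Sequence[GenomeRecord]) -> dict[str, str]:
    """Group labels for a whole dataset (genome_id -> group)."""
    species_per_phylum: dict[str, set[str]] = defaultdict(set)
    for r in records:
        species_per_phylum[r.phylum].add(r.species or r.genome_id)
    counts = {p: len(s) for p, s in species_per_phylum.items()}
    return {r.genome_id: assign_group(r, counts) for r in records}


# ---------------------------------------------------------------------------
# similarity graph and Markov clustering


def build_similarity_graph(
    edges: Iterable[SimilarityEdge],
    min_identity: float = 25.0,
    max_e: float = 1e-10,
) -> nx.Graph:
    """Thresholded undirected similarity graph.

    Every sequence seen in the edge list becomes a node; an edge is
    retained iff global identity >= ``min_identity`` and
    e-value <= ``max_e``. Edge weight is the global identity; duplicate
    pairs collapse to the maximum identity.
    """
    g = nx.Graph()
    for i, e in enumerate(edges):
        if not 0.0 <= e.global_identity <= 100.0:
            raise ValueError(
                f"row {i}: identity {e.global_identity} outside [0, 100]"
            )
        g.add_node(e.seq_a)
        g.add_node(e.seq_b)
        if e.global_identity >= min_identity and e.e_value <= max_e:
            prev = g.get_edge_data(e.seq_a, e.seq_b)
            if prev is None or prev["weight"] < e.global_identity:
                g.add_edge(e.seq_a, e.seq_b, weight=e.global_identity)
    return g


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 200,
    tol: float = 1e-6,
    sequence_genomes: Mapping[str, str] | None = None,
) -> list[ProteinFamily]:
    """Markov clustering of a weighted similarity graph.

    Alternates expansion (matrix squaring) with inflation (entrywise
    power ``inflation`` followed by column renormalisation) on the
    column-stochastic transition matrix until the matrix change drops
    below ``tol``. Self-loops are added with the node's maximum incident
    edge weight before normalisation, which damps oscillations.

    Clusters are read off the converged matrix as connected attractor
    systems. The result is deterministic: nodes are processed in sorted
    order and family ids are assigned by decreasing size, ties by the
    smallest member id.

    ``sequence_genomes`` maps sequence id to genome id for the resulting
    :class:`ProteinFamily` objects; if omitted each sequence is treated
    as its own genome.
    """
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes)
    if not nodes:
        return []
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[idx[a], idx[b]] = w
        m[idx[b], idx[a]] = w
    # self-loops: max incident weight (1.0 for isolated nodes)
    loops = m.max(axis=0)
    loops[loops == 0.0] = 1.0
    np.fill_diagonal(m, loops)
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = m
        m = m @ m
        m = np.power(m, inflation)
        m[m < 1e-12] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0.0] = 1.0
        m /= colsum
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations", max_iter)

    # connected components of the attractor structure
    attract = nx.Graph()
    attract.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > 1e-9)
    attract.add_edges_from(zip(rows.tolist(), cols.tolist()))
    comps = [sorted(c) for c in nx.connected_components(attract)]
    comps.sort(key=lambda c: (-len(c), nodes[c[0]]))

    genome_of = sequence_genomes or {}
    families = []
    width = max(4, len(str(len(comps))))
    for k, comp in enumerate(comps, start=1):
        members = {
            nodes[i]: genome_of.get(nodes[i], nodes[i]) for i in comp
        }
        families.append(ProteinFamily(f"F{k:0{width}d}", members))
    if not converged:
        for fam in families:
            fam.category_annotations.add("__mcl_unconverged__")
    return families


# ---------------------------------------------------------------------------
# family filtering, presence and universality


def filter_and_presence(
    families: Sequence[ProteinFamily],
    genome_groups: Mapping[str, str],
    genome_species: Mapping[str, str],
    min_species: int = 3,
    min_genomes: int = 4,
) -> tuple[list[ProteinFamily], PresenceMatrix]:
    """Drop narrow families and tabulate per-group genome presence.

    A family is kept iff its members span at least ``min_species``
    distinct species and at least ``min_genomes`` distinct genomes.
    """
    group_members: dict[str, set[str]] = defaultdict(set)
    for gid, grp in genome_groups.items():
        group_members[grp].add(gid)
    groups = sorted(group_members)
    sizes = pd.Series({g: len(group_members[g]) for g in groups})

    kept: list[ProteinFamily] = []
    rows: list[list[int]] = []
    for fam in families:
        genomes = fam.genomes
        missing = [g for g in genomes if g not in genome_groups]
        if missing:
            raise ValueError(
                f"family {fam.family_id}: genomes without group: "
                f"{sorted(missing)}"
            )
        species = {genome_species.get(g, g) for g in genomes}
        if len(species) < min_species or len(genomes) < min_genomes:
            continue
        kept.append(fam)
        rows.append(
            [len(genomes & group_members[g]) for g in groups]
        )
    counts = pd.DataFrame(
        rows, index=[f.family_id for f in kept], columns=groups, dtype=int
    )
    logger.info(
        "family filter: %d -> %d (>=%d species, >=%d genomes)",
        len(families), len(kept), min_species, min_genomes,
    )
    return kept, PresenceMatrix(counts, sizes)


def select_universal_and_coverage(
    matrix: PresenceMatrix, coverage_threshold: float = 0.9
) -> tuple[list[str], pd.Series, int]:
    """Universal families and their mean per-group genome coverage.

    A family is universal when it is present (>= 1 genome) in every
    group. Mean coverage is the unweighted mean over groups of the
    fraction of the group's genomes containing the family. Also returns
    how many universal families reach ``coverage_threshold`` mean
    coverage.
    """
    if matrix.counts.empty:
        raise ValueError("empty presence matrix")
    universal_mask = (matrix.counts >= 1).all(axis=1)
    universal = matrix.counts.index[universal_mask].tolist()
    mean_cov = matrix.coverage().mean(axis=1)
    n_high = int((mean_cov[universal] >= coverage_threshold).sum())
    return universal, mean_cov, n_high


# ---------------------------------------------------------------------------
# functional annotation


def _best_hit(hits: Sequence[HomologyHit]) -> HomologyHit:
    # lowest e-value, then highest coverage, then highest identity,
    # then lexicographic subject id for full determinism
    return min(
        hits,
        key=lambda h: (
            h.e_value, -h.query_coverage, -h.percent_identity, h.subject_id
        ),
    )


def annotate_family(
    family: ProteinFamily,
    per_sequence_hits: Mapping[str, Sequence[HomologyHit]],
    min_qcov: float = 0.8,
    max_e: float = 1e-10,
    ratio_bounds: tuple[float, float] = (0.7, 1.3),
) -> set[str]:
    """Majority-vote functional categories for a family.

    Each member sequence contributes the category of its best passing
    hit (query coverage >= ``min_qcov``, e-value <= ``max_e``, length
    ratio within ``ratio_bounds``). The family is annotated with the
    most frequent category; equally frequent categories are all kept.
    """
    lo, hi = ratio_bounds
    votes: Counter[str] = Counter()
    for seq_id in family.members:
        passing = [
            h for h in per_sequence_hits.get(seq_id, ())
            if h.query_coverage >= min_qcov
            and h.e_value <= max_e
            and lo <= h.length_ratio <= hi
        ]
        if passing:
            votes[_best_hit(passing).category] += 1
    if not votes:
        return set()
    top = max(votes.values())
    return {cat for cat, c in votes.items() if c == top}
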