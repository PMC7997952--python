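"""Tab-separated and Newick readers/writers for all pipeline artifacts.

Every tabular format is plain TSV with a header row, UTF-8. Trees are
Newick with branch lengths, one or many per file.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import networkx as nx
import pandas as pd

from .expansion_reduction import TargetSet
from .genomes_families import (
    GenomeRecord,
    HomologyHit,
    PresenceMatrix,
    ProteinFamily,
    SimilarityEdge,
)
from .metabolic_network import Reaction
from .tree_analysis import GeneTree


def read_genomes(path: str | Path) -> list[GenomeRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        GenomeRecord(
            genome_id=r["genome_id"],
            phylum=r["phylum"],
            class_name=r.get("class", ""),
            species=r.get("species", ""),
            protein_count=int(r.get("protein_count", 0) or 0),
        )
        for _, r in df.iterrows()
    ]


def write_genomes(records: Sequence[GenomeRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "genome_id": r.genome_id,
                "phylum": r.phylum,
                "class": r.class_name,
                "species": r.species,
                "protein_count": r.protein_count,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_hits(path: str | Path) -> list[HomologyHit]:
    df = pd.read_csv(path, sep="\t")
    hits = []
    for _, r in df.iterrows():
        hits.append(
            HomologyHit(
                query_id=str(r["query_id"]),
                subject_id=str(r["subject_id"]),
                percent_identity=float(r["percent_identity"]),
                e_value=float(r["e_value"]),
                aligned_length_aa=int(r.get("aligned_length_aa", 0)),
                query_coverage=float(r.get("query_coverage", 0.0)),
                length_ratio=float(r.get("length_ratio", 1.0)),
                category=str(r.get("category", "") or ""),
            )
        )
    return hits


def read_edges(path: str | Path) -> list[SimilarityEdge]:
    df = pd.read_csv(path, sep="\t")
    return [
        SimilarityEdge(
            str(r["seq_a"]), str(r["seq_b"]),
            float(r["global_identity"]), float(r["e_value"]),
        )
        for _, r in df.iterrows()
    ]


def write_edges(
    edges: Sequence[SimilarityEdge], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "seq_a": e.seq_a,
                "seq_b": e.seq_b,
                "global_identity": e.global_identity,
                "e_value": e.e_value,
            }
            for e in edges
        ]
    ).to_csv(path, sep="\t", index=False)


def write_families(
    families: Sequence[ProteinFamily], path: str | Path
) -> None:
    rows = [
        {"family_id": f.family_id, "sequence_id": s, "genome_id": g}
        for f in families
        for s, g in sorted(f.members.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_families(path: str | Path) -> list[ProteinFamily]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    fams: dict[str, dict[str, str]] = {}
    for _, r in df.iterrows():
        fams.setdefault(r["family_id"], {})[r["sequence_id"]] = r["genome_id"]
    return [ProteinFamily(fid, members) for fid, members in fams.items()]


def write_presence_matrix(
    matrix: PresenceMatrix, path: str | Path
) -> None:
    out = matrix.counts.copy()
    out.loc["__group_size__"] = matrix.group_sizes
    out.to_csv(path, sep="\t", index_label="family_id")


def read_presence_matrix(path: str | Path) -> PresenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="family_id")
    sizes = df.loc["__group_size__"]
    counts = df.drop(index="__group_size__").astype(int)
    return PresenceMatrix(counts, sizes.astype(int))


def read_reaction_table(
    path: str | Path,
) -> list[tuple[str, str, set[str]]]:
    """Rows of (reaction_id, equation, KO set)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, r in df.iterrows():
        kos = {k for k in str(r.get("kos", "")).split(";") if k}
        out.append((r["reaction_id"], r["equation"], kos))
    return out


def write_reaction_table(
    rows: Iterable[tuple[str, str, set[str]]], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {"reaction_id": rid, "equation": eq, "kos": ";".join(sorted(kos))}
            for rid, eq, kos in rows
        ]
    ).to_csv(path, sep="\t", index=False)


def read_reversibility(path: str | Path) -> dict[str, bool]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(r["reaction_id"]): bool(int(r["reversible"]))
        for _, r in df.iterrows()
    }


def read_targets(path: str | Path) -> TargetSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return TargetSet(
        {r["compound_id"]: r.get("category", "") for _, r in df.iterrows()}
    )


def write_targets(targets: TargetSet, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"compound_id": c, "category": cat}
            for c, cat in sorted(targets.categories.items())
        ]
    ).to_csv(path, sep="\t", index=False)


def write_network_edgelist(
    graph: nx.DiGraph, path: str | Path
) -> None:
    pd.DataFrame(
        [{"source": u, "target": v} for u, v in graph.edges()]
    ).to_csv(path, sep="\t", index=False)


def write_network_graphml(graph: nx.DiGraph, path: str | Path) -> None:
    nx.write_graphml(graph, path)


def read_gene_trees(path: str | Path) -> list[GeneTree]:
    """Read one or more Newick trees from a file."""
    trees = dendropy.TreeList.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    stem = Path(path).stem
    return [
        GeneTree(tree_id=f"{stem}_{i}", tree=t)
        for i, t in enumerate(trees)
    ]


def write_newick(newicks: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for nwk in newicks:
            fh.write(nwk.rstrip("\n") + "\n")


def write_verticality(
    table: Mapping[str, float], path: str | Path
) -> None:
    pd.DataFrame(
        [{"family_id": f, "verticality": v} for f, v in sorted(table.items())]
    ).to_csv(path, sep="\t", index=False)


def read_verticality(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(r["family_id"]): float(r["verticality"]) for _, r in df.iterrows()
    }
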