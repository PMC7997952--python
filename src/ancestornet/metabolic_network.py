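"""Reaction parsing and the bipartite metabolite-reaction network.

Reactions come in as KEGG-style equation strings ("C00031 + C00002 <=>
C00092 + C00008"). Equations with symbolic stoichiometry (the polymer
coefficients ``n``/``m``) or malformed compound tokens are rejected, as
are transport-like equations with the same compound on both sides.
Reversibility is not encoded in the equation arrow but assigned from a
separate table; reactions absent from the table default to irreversible.

The network itself is a directed bipartite graph with metabolite and
reaction nodes: substrate -> reaction and reaction -> product edges,
both orientations for reversible reactions. Connectivity questions
(components, degrees) are answered on the undirected skeleton.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .genomes_families import PresenceMatrix

_COMPOUND_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_\-]*$")
_AMBIGUOUS_COEFF_RE = re.compile(r"^\(?[0-9]*[nm](\+[0-9]+|\-[0-9]+)?\)?$")


class ReactionRejection(ValueError):
    """Raised when an equation cannot be turned into a Reaction."""

    def __init__(self, reaction_id: str, reason: str, position: int = -1):
        self.reaction_id = reaction_id
        self.reason = reason
        self.position = position
        msg = f"{reaction_id}: {reason}"
        if position >= 0:
            msg += f" (at token {position})"
        super().__init__(msg)


@dataclass
class Reaction:
    """A stoichiometric reaction over compound ids."""

    reaction_id: str
    substrates: dict[str, int]
    products: dict[str, int]
    reversible: bool = False
    encoding_families: set[str] = field(default_factory=set)
    group_count: int = 0

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValueError(
                f"reaction {self.reaction_id}: empty substrate or "
                "product side"
            )

    @property
    def compounds(self) -> set[str]:
        return set(self.substrates) | set(self.products)

    def equation(self) -> str:
        """Canonical equation string (round-trips through the parser)."""

        def side(d: dict[str, int]) -> str:
            return " + ".join(
                (f"{c}" if k == 1 else f"{k} {c}")
                for c, k in sorted(d.items())
            )

        arrow = "<=>" if self.reversible else "=>"
        return f"{side(self.substrates)} {arrow} {side(self.products)}"


def _parse_side(
    reaction_id: str, text: str, offset: int
) -> dict[str, int]:
    out: dict[str, int] = {}
    terms = [t.strip() for t in text.split(" + ")]
    for pos, term in enumerate(terms, start=offset):
        if not term:
            raise ReactionRejection(reaction_id, "empty term", pos)
        bits = term.split()
        if len(bits) == 1:
            coeff_s, compound = "1", bits[0]
        elif len(bits) == 2:
            coeff_s, compound = bits
        else:
            raise ReactionRejection(reaction_id, f"malformed term {term!r}", pos)
        if _AMBIGUOUS_COEFF_RE.match(coeff_s):
            raise ReactionRejection(
                reaction_id, "ambiguous stoichiometry", pos
            )
        try:
            coeff = int(coeff_s)
        except ValueError:
            raise ReactionRejection(
                reaction_id, f"non-integer coefficient {coeff_s!r}", pos
            ) from None
        if coeff <= 0:
            raise ReactionRejection(
                reaction_id, f"non-positive coefficient {coeff}", pos
            )
        if not _COMPOUND_RE.match(compound):
            raise ReactionRejection(
                reaction_id, f"malformed compound id {compound!r}", pos
            )
        out[compound] = out.get(compound, 0) + coeff
    return out


def parse_reaction_equation(
    reaction_id: str,
    equation_text: str,
    allow_transport: bool = False,
) -> Reaction:
    """Parse a KEGG-dialect equation into a :class:`Reaction`.

    Raises :class:`ReactionRejection` for ambiguous stoichiometry
    (symbolic ``n``/``m`` coefficients), malformed compound tokens, or
    (by default) compounds appearing on both sides — the transport-like
    and polymer-growth cases the analysis discards.
    """
    for arrow in ("<=>", "=>"):
        if arrow in equation_text:
            left, _, right = equation_text.partition(arrow)
            break
    else:
        raise ReactionRejection(reaction_id, "no reaction arrow found")
    subs = _parse_side(reaction_id, left.strip(), 0)
    prods = _parse_side(reaction_id, right.strip(), len(subs))
    if not allow_transport:
        both = set(subs) & set(prods)
        if both:
            raise ReactionRejection(
                reaction_id,
                f"compound(s) on both sides: {sorted(both)}",
            )
    return Reaction(reaction_id, subs, prods)


def parse_reaction_table(
    rows: Iterable[tuple[str, str]], allow_transport: bool = False
) -> tuple[list[Reaction], list[ReactionRejection]]:
    """Parse (reaction_id, equation) rows, collecting rejections."""
    reactions, rejected = [], []
    for rid, eq in rows:
        try:
            reactions.append(
                parse_reaction_equation(rid, eq, allow_transport)
            )
        except ReactionRejection as exc:
            rejected.append(exc)
    return reactions, rejected


def assign_reversibility(
    reaction: Reaction, reversibility_table: Mapping[str, bool]
) -> Reaction:
    """Set the reversibility flag from the table; absent ids are
    irreversible."""
    reaction.reversible = bool(
        reversibility_table.get(reaction.reaction_id, False)
    )
    return reaction


def families_to_reactions(
    family_annotations: Mapping[str, set[str]],
    ko_reaction_table: Mapping[str, set[str]],
    reactions: Mapping[str, Reaction] | None = None,
) -> tuple[dict[str, set[str]], dict]:
    """Join families to reactions through their KO annotations.

    Returns the family -> reaction-id mapping and a summary dict with
    the raw (with KO multiplicity) and deduplicated reaction counts and
    the KOs that had no reaction. When ``reactions`` is given, each
    reaction's ``encoding_families`` is filled in place.
    """
    fam_to_rxn: dict[str, set[str]] = {}
    unmapped_kos: set[str] = set()
    raw = 0
    for fam, kos in family_annotations.items():
        rxns: set[str] = set()
        for ko in kos:
            hit = ko_reaction_table.get(ko)
            if hit is None:
                unmapped_kos.add(ko)
            else:
                raw += len(hit)
                rxns |= hit
        fam_to_rxn[fam] = rxns
    if reactions is not None:
        for fam, rxns in fam_to_rxn.items():
            for rid in rxns:
                if rid in reactions:
                    reactions[rid].encoding_families.add(fam)
    all_rxns = set().union(*fam_to_rxn.values()) if fam_to_rxn else set()
    summary = {
        "raw_reaction_links": raw,
        "unique_reactions": len(all_rxns),
        "kos_without_reaction": sorted(unmapped_kos),
    }
    return fam_to_rxn, summary


# ---------------------------------------------------------------------------
# the bipartite graph


def build_bipartite_network(
    reactions: Iterable[Reaction],
) -> tuple[nx.DiGraph, dict[str, int], list[list[str]]]:
    """Directed bipartite metabolite-reaction graph.

    Returns the graph, the per-node degree on the undirected skeleton,
    and the connected components (node lists, sorted by size
    descending, ties by smallest node id; nodes sorted within each).
    """
    g = nx.DiGraph()
    for rxn in reactions:
        rnode = rxn.reaction_id
        g.add_node(rnode, bipartite="reaction")
        for c in rxn.substrates:
            g.add_node(c, bipartite="metabolite")
            g.add_edge(c, rnode)
            if rxn.reversible:
                g.add_edge(rnode, c)
        for c in rxn.products:
            g.add_node(c, bipartite="metabolite")
            g.add_edge(rnode, c)
            if rxn.reversible:
                g.add_edge(c, rnode)
    skeleton = g.to_undirected(as_view=True)
    degrees = dict(skeleton.degree())
    comps = [sorted(c) for c in nx.connected_components(skeleton)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return g, degrees, comps


def score_reaction_distribution(
    reaction: Reaction, presence: PresenceMatrix
) -> int:
    """Number of taxonomic groups in which some encoding family occurs.

    The score orders candidate reactions during network reduction:
    narrowly distributed reactions score low and are removed first.
    """
    if not reaction.encoding_families:
        raise ValueError(
            f"reaction {reaction.reaction_id} has no encoding families"
        )
    fams = [
        f for f in reaction.encoding_families if f in presence.counts.index
    ]
    if not fams:
        return 0
    present = (presence.counts.loc[fams] >= 1).any(axis=0)
    return int(present.sum())
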