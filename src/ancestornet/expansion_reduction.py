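"""Network expansion (scope) and score-ordered greedy reduction.

Scope is the least fixed point of reaction firing: starting from a seed
compound set, any reaction whose substrates are all producible adds its
products (a reversible reaction fires from either side). The greedy
reduction asks the converse question: given a conserved core network and
a pool of candidate reactions, which candidates are indispensable for
producing a set of universally essential target metabolites? Candidates
are visited in increasing taxonomic-distribution score; a candidate is
removed permanently whenever all targets stay producible without it, and
full passes repeat until nothing more can be removed. The surviving
candidate set is 1-minimal: dropping any single retained candidate
breaks at least one target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from .metabolic_network import Reaction

logger = logging.getLogger(__name__)

Mode = Literal["produced_by_any", "scope_from_seeds"]


@dataclass(frozen=True)
class TargetSet:
    """Target metabolites with category labels (amino acid, base, ...)."""

    categories: Mapping[str, str]  # compound_id -> category

    @property
    def compounds(self) -> frozenset[str]:
        return frozenset(self.categories)

    def __len__(self) -> int:
        return len(self.categories)


@dataclass
class ReductionResult:
    retained_candidates: list[str]
    removed_reactions: list[tuple[str, int]]  # (reaction_id, step index)
    producible_before: set[str]
    producible_after: set[str]
    completing_genes: set[str] = field(default_factory=set)


def compute_scope(
    seeds: Iterable[str], reactions: Iterable[Reaction]
) -> set[str]:
    """Producible compound set: least fixed point of reaction firing.

    An irreversible reaction fires when every substrate is in the set,
    adding the products; a reversible reaction fires from either side.
    Unknown seed ids are allowed (they simply seed the set) and the
    result is independent of reaction order.
    """
    scope = set(seeds)
    rxns = list(reactions)
    # (precondition side, addition side) pairs for each direction
    rules: list[tuple[frozenset[str], frozenset[str]]] = []
    for r in rxns:
        subs, prods = frozenset(r.substrates), frozenset(r.products)
        rules.append((subs, prods))
        if r.reversible:
            rules.append((prods, subs))
    pending = list(range(len(rules)))
    changed = True
    while changed:
        changed = False
        still = []
        for i in pending:
            pre, add = rules[i]
            if pre <= scope:
                if not add <= scope:
                    scope |= add
                    changed = True
            else:
                still.append(i)
        pending = still
    return scope


def producible_targets(
    network: Iterable[Reaction],
    targets: TargetSet,
    mode: Mode = "produced_by_any",
    seeds: Iterable[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Which targets can the network make? Returns (producible, missing).

    ``produced_by_any``: a target counts as producible when some
    reaction has it as a product (either side for reversible
    reactions). ``scope_from_seeds``: a target must lie in the scope of
    the seed set. Both lists come back sorted.
    """
    rxns = list(network)
    if mode == "produced_by_any":
        producible_pool: set[str] = set()
        for r in rxns:
            producible_pool |= set(r.products)
            if r.reversible:
                producible_pool |= set(r.substrates)
    elif mode == "scope_from_seeds":
        if seeds is None:
            raise ValueError("scope_from_seeds mode requires seeds")
        producible_pool = compute_scope(seeds, rxns)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    prod = sorted(targets.compounds & producible_pool)
    missing = sorted(targets.compounds - producible_pool)
    return prod, missing


def default_seeds(reactions: Iterable[Reaction]) -> set[str]:
    """Compounds appearing only as substrates: the external inputs."""
    subs: set[str] = set()
    prods: set[str] = set()
    for r in reactions:
        if r.reversible:
            subs |= r.compounds
            prods |= r.compounds
        else:
            subs |= set(r.substrates)
            prods |= set(r.products)
    return subs - prods


def reduce_network(
    core: Sequence[Reaction],
    candidates: Sequence[Reaction],
    targets: TargetSet,
    scores: Mapping[str, int],
    mode: Mode = "produced_by_any",
    seeds: Iterable[str] | None = None,
) -> ReductionResult:
    """Greedy score-ordered reduction of the candidate reaction pool.

    Core reactions are never removal candidates. Candidates are visited
    in increasing score (ties by reaction id); each is removed
    temporarily, the removal is kept iff every target remains
    producible, and passes repeat until a whole pass removes nothing.
    """
    core_ids = {r.reaction_id for r in core}
    overlap = core_ids & {r.reaction_id for r in candidates}
    if overlap:
        raise ValueError(f"reactions in both core and candidates: {sorted(overlap)}")
    seeds = set(seeds) if seeds is not None else None

    def ok(rxns: list[Reaction]) -> bool:
        _, missing = producible_targets(rxns, targets, mode, seeds)
        return not missing

    full = list(core) + list(candidates)
    prod_before, missing = producible_targets(full, targets, mode, seeds)
    if missing:
        raise ValueError(
            "targets unreachable even with all candidates: "
            f"{missing}"
        )

    order = sorted(
        candidates, key=lambda r: (scores.get(r.reaction_id, 0), r.reaction_id)
    )
    retained = {r.reaction_id: r for r in order}
    removed: list[tuple[str, int]] = []
    step = 0
    while True:
        removed_this_pass = 0
        for rxn in order:
            rid = rxn.reaction_id
            if rid not in retained:
                continue
            trial = list(core) + [
                r for r in retained.values() if r.reaction_id != rid
            ]
            step += 1
            if ok(trial):
                del retained[rid]
                removed.append((rid, step))
                removed_this_pass += 1
        if removed_this_pass == 0:
            break

    kept = list(core) + list(retained.values())
    prod_after, _ = producible_targets(kept, targets, mode, seeds)
    # post-hoc 1-minimality check
    for rid in retained:
        trial = list(core) + [
            r for r in retained.values() if r.reaction_id != rid
        ]
        if ok(trial):  # pragma: no cover - violated contract
            raise AssertionError(
                f"reduction not 1-minimal: {rid} is removable"
            )
    genes: set[str] = set()
    for r in retained.values():
        genes |= r.encoding_families
    logger.info(
        "reduction: %d candidates -> %d retained (%d removal checks)",
        len(candidates), len(retained), step,
    )
    return ReductionResult(
        retained_candidates=[r.reaction_id for r in order if r.reaction_id in retained],
        removed_reactions=removed,
        producible_before=set(prod_before),
        producible_after=set(prod_after),
        completing_genes=genes,
    )
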