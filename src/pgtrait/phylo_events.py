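"""Rooted phylogenies, gain-penalizing parsimony, and gain/loss event lists.

The evolutionary history of a binary character (a gene family's presence, the
complete 3-gene set, or peptidoglycan itself) is reconstructed on a rooted
species tree by minimum-cost parsimony with asymmetric transition costs:
a gain (0 -> 1) costs more than a loss (1 -> 0), so the reconstruction
minimizes the detection of gain events.  This is the classic Sankoff dynamic
programme generalized to polytomies; branch lengths are ignored (parsimony is
topology-only).  Every branch whose endpoints differ yields a gain or loss
``Event``; a branch is identified by its child node id (the root carries no
event).

Default costs are gain 2, loss 1 — the smallest integer asymmetry.  With
gain_cost == loss_cost the reconstruction reduces to classical Fitch/Sankoff
parsimony.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy

from .annotation_io import Cohort, ValidationError, binarize
from .geneset_classifier import GeneSetRule, has_minimal_set

__all__ = [
    "Phylogeny",
    "CostScheme",
    "AncestralAssignment",
    "Event",
    "read_newick",
    "parse_newick",
    "ancestral_parsimony",
    "extract_events",
    "character_from_cohort",
]

_INF = float("inf")


class NewickError(ValueError):
    """Malformed Newick input."""


@dataclass(frozen=True)
class CostScheme:
    """Transition costs: gain (0->1) and loss (1->0)."""

    gain_cost: float = 2.0
    loss_cost: float = 1.0

    def __post_init__(self) -> None:
        if self.gain_cost <= 0 or self.loss_cost <= 0:
            raise ValidationError("costs must be positive")

    def cost(self, parent_state: int, child_state: int) -> float:
        if parent_state == child_state:
            return 0.0
        return self.gain_cost if child_state == 1 else self.loss_cost


class Phylogeny:
    """A rooted tree with stable integer node ids and named tips.

    Node ids are assigned in preorder at construction (root = 0) and never
    change.  Polytomies are allowed; unary (single-child) internal nodes are
    collapsed on reading.  Branch lengths are optional and non-negative.
    """

    def __init__(self, dtree: dendropy.Tree):
        dtree.suppress_unifurcations()
        self._dtree = dtree
        self.parent: list[int | None] = []
        self.children: list[list[int]] = []
        self.labels: list[str | None] = []
        self.lengths: list[float | None] = []
        self._node_of_id: list[dendropy.Node] = []

        for i, nd in enumerate(dtree.preorder_node_iter()):
            nd._pg_id = i
            self._node_of_id.append(nd)
            self.parent.append(None if nd.parent_node is None else nd.parent_node._pg_id)
            self.children.append([])
            if nd.parent_node is not None:
                self.children[nd.parent_node._pg_id].append(i)
            label = None
            if nd.taxon is not None and nd.taxon.label:
                label = nd.taxon.label
            elif nd.label:
                label = nd.label
            self.labels.append(label)
            length = nd.edge.length
            if length is not None and length < 0:
                raise NewickError(f"negative branch length {length} above node {i}")
            self.lengths.append(length)

        self.root = 0
        self.n_nodes = len(self.parent)
        self.tip_ids = [i for i in range(self.n_nodes) if not self.children[i]]
        tips = {}
        for i in self.tip_ids:
            lab = self.labels[i]
            if lab is None:
                raise NewickError(f"unlabeled tip (node {i})")
            if lab in tips:
                raise NewickError(f"duplicate tip label {lab!r}")
            tips[lab] = i
        self.tip_id_of = tips
        # postorder: children always before parents
        self.postorder: list[int] = [nd._pg_id for nd in dtree.postorder_node_iter()]

    # -- basic queries ------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    def is_tip(self, node_id: int) -> bool:
        return not self.children[node_id]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_ids]

    def branch_lengths(self, default: float = 1.0):
        """Per-node length of the branch above each node (root gets 0).

        Missing lengths are replaced by ``default``; the species trees used for
        the comparative analysis are often cladogram-like, so unit lengths are
        the documented convention for length-free input.
        """
        out = []
        for i in range(self.n_nodes):
            if i == self.root:
                out.append(0.0)
            else:
                ln = self.lengths[i]
                out.append(default if ln is None else ln)
        return out

    def has_branch_lengths(self) -> bool:
        return all(self.lengths[i] is not None for i in range(self.n_nodes) if i != self.root)

    # -- I/O and editing ----------------------------------------------------

    def to_newick(self) -> str:
        s = self._dtree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        )
        return s.strip() + ("\n" if not s.endswith("\n") else "")

    def write_newick(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick())

    def prune_to(self, keep_labels: Sequence[str]) -> "Phylogeny":
        """A new phylogeny retaining only the named tips (ids re-assigned)."""
        keep = set(keep_labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValidationError(f"labels not in tree: {sorted(missing)}")
        clone = self._dtree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(keep))
        return Phylogeny(clone)

    def __repr__(self) -> str:
        return f"Phylogeny(n_tips={self.n_tips}, n_nodes={self.n_nodes})"


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick tree from a string."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"could not parse Newick: {exc}") from exc
    return Phylogeny(dtree)


def read_newick(path) -> Phylogeny:
    """Read a single rooted Newick tree from a file."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


@dataclass
class AncestralAssignment:
    """Minimum-cost ancestral states for one binary character.

    ``states[i]`` is the state at node id ``i``; ``ambiguous[i]`` flags nodes
    where an equally optimal alternative state existed at backtracking time
    (the documented tie-break chose one deterministically).  ``total_cost`` is
    the global minimum of the summed per-branch transition costs.
    """

    character: str
    states: list[int]
    total_cost: float
    ambiguous: list[bool]
    costs: CostScheme


def ancestral_parsimony(
    tree: Phylogeny,
    tip_states: Mapping[str, int],
    costs: CostScheme | None = None,
    character: str = "trait",
) -> AncestralAssignment:
    """Asymmetric-cost Sankoff reconstruction of a binary character.

    Tie-breaks, both deterministic: at the root an equal-cost tie is resolved
    toward state 1 (presence — the ancestral-presence parsimony reading); below
    the root a tie is resolved toward the parent's state, which delays state
    changes toward the tips.
    """
    costs = costs or CostScheme()
    missing = [lab for lab in tree.tip_labels if lab not in tip_states]
    if missing:
        raise ValidationError(f"no state for tip(s): {missing}")

    n = tree.n_nodes
    # cost[v][s]: minimal cost of the subtree rooted at v given state s at v
    cost = [[0.0, 0.0] for _ in range(n)]
    for v in tree.postorder:
        if tree.is_tip(v):
            s = int(tip_states[tree.labels[v]])
            if s not in (0, 1):
                raise ValidationError(
                    f"tip {tree.labels[v]!r}: state must be 0 or 1, got {s}"
                )
            cost[v][0] = 0.0 if s == 0 else _INF
            cost[v][1] = 0.0 if s == 1 else _INF
        else:
            for s in (0, 1):
                total = 0.0
                for c in tree.children[v]:
                    total += min(
                        costs.cost(s, t) + cost[c][t] for t in (0, 1)
                    )
                cost[v][s] = total

    states = [0] * n
    ambiguous = [False] * n
    root = tree.root
    if cost[root][1] <= cost[root][0]:
        states[root] = 1
        ambiguous[root] = cost[root][1] == cost[root][0]
    else:
        states[root] = 0
    total_cost = min(cost[root])

    # preorder backtrack (ids are preorder, so ascending order works)
    for v in range(n):
        if v == root:
            continue
        s = states[tree.parent[v]]
        c0 = costs.cost(s, 0) + cost[v][0]
        c1 = costs.cost(s, 1) + cost[v][1]
        if c0 == c1:
            states[v] = s  # tie: keep the parent's state, delaying the change
            ambiguous[v] = True
        else:
            states[v] = 0 if c0 < c1 else 1
    return AncestralAssignment(
        character=character,
        states=states,
        total_cost=total_cost,
        ambiguous=ambiguous,
        costs=costs,
    )


@dataclass(frozen=True)
class Event:
    """A state change on a branch: the branch is named by its child node id."""

    character: str
    type: str  # "gain" or "loss"
    parent_id: int
    child_id: int

    @property
    def branch(self) -> int:
        return self.child_id


def extract_events(
    assignment: AncestralAssignment, tree: Phylogeny
) -> tuple[list[Event], dict[str, int]]:
    """List every branch whose endpoints differ, with counts by type."""
    if len(assignment.states) != tree.n_nodes:
        raise ValidationError("assignment does not cover every node of the tree")
    events: list[Event] = []
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        p = tree.parent[v]
        sp, sv = assignment.states[p], assignment.states[v]
        if sp != sv:
            events.append(
                Event(
                    character=assignment.character,
                    type="gain" if sv == 1 else "loss",
                    parent_id=p,
                    child_id=v,
                )
            )
    counts = {
        "gain": sum(e.type == "gain" for e in events),
        "loss": sum(e.type == "loss" for e in events),
    }
    return events, counts


@dataclass
class TipCharacter:
    """Binary states for tree tips plus the tips excluded for unknown status."""

    states: dict[str, int]
    excluded_tips: list[str]


def character_from_cohort(
    cohort: Cohort,
    what: str,
    tree: Phylogeny,
    rule: GeneSetRule | None = None,
) -> TipCharacter:
    """Binary tip states for ``what`` over the tree's tips.

    ``what`` is a family name (presence of that family), ``"set"`` (complete
    3-gene set under ``rule``) or ``"pg"`` (literature PG status).  For
    ``"pg"``, unknown-status genomes are excluded and listed — the caller
    prunes the tree with :meth:`Phylogeny.prune_to` before reconstruction.
    """
    by_id = cohort.by_id()
    missing = [lab for lab in tree.tip_labels if lab not in by_id]
    if missing:
        raise ValidationError(f"tree tips absent from cohort: {missing}")
    states: dict[str, int] = {}
    excluded: list[str] = []
    for lab in tree.tip_labels:
        rec = by_id[lab]
        if what == "pg":
            if rec.pg_status == "unknown":
                excluded.append(lab)
            else:
                states[lab] = 1 if rec.pg_status == "present" else 0
        elif what == "set":
            states[lab] = int(has_minimal_set(binarize(rec), rule))
        else:
            if what not in rec.family_counts:
                raise ValidationError(f"unknown character {what!r}")
            states[lab] = int(rec.family_counts[what] >= 1)
    return TipCharacter(states=states, excluded_tips=excluded)
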