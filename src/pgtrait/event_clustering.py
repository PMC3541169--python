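"""Clustering of gain/loss events across characters, with Pagel verification.

Two complementary groupings of the events produced by the parsimony
reconstruction:

* **by date** — a "date" is a branch (framed by two speciation events).  Every
  branch carrying two or more events pools its (character, event-type) pairs;
  maximal pools that recur on at least two branches become clusters, with
  ``n_dates`` the number of branches on which *all* members co-occur.
* **by feature** — characters (gene families or PG) are grouped by the
  similarity of their event-branch profiles; by default only identical
  profiles group (Jaccard threshold 1.0), merged single-linkage for lower
  thresholds.

Clusters are verified with the Pagel correlated-evolution test applied to
every pair of distinct characters in the cluster; a cluster is flagged
supported when all pairwise error percentages are at or below 5%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

from .annotation_io import Cohort, ValidationError
from .correlated_evolution import PagelResult, pagel_test
from .geneset_classifier import GeneSetRule
from .phylo_events import Event, Phylogeny, character_from_cohort

__all__ = [
    "EventCluster",
    "ClusterReport",
    "cluster_by_date",
    "cluster_by_feature",
    "verify_clusters",
]

#: A cluster member: (character name, "gain" | "loss").
Member = tuple[str, str]


@dataclass
class EventCluster:
    """A set of co-occurring (character, event-type) pairs and their dates."""

    members: frozenset[Member]
    dates: frozenset[int]  # branch ids (child node ids) shared by all members
    verification: dict[tuple[str, str], PagelResult] = field(default_factory=dict)
    supported: bool | None = None
    note: str = ""

    @property
    def n_dates(self) -> int:
        return len(self.dates)

    def characters(self) -> set[str]:
        return {char for char, _ in self.members}


@dataclass
class ClusterReport:
    """Clusters plus the events that joined none (nothing silently dropped)."""

    clusters: list[EventCluster]
    unclustered: list[Event]


def _branch_pools(events: Sequence[Event]) -> dict[int, frozenset[Member]]:
    pools: dict[int, set[Member]] = {}
    for e in events:
        pools.setdefault(e.child_id, set()).add((e.character, e.type))
    return {b: frozenset(m) for b, m in pools.items()}


def _support(member_set: frozenset[Member], pools: Mapping[int, frozenset[Member]]) -> frozenset[int]:
    return frozenset(b for b, pool in pools.items() if member_set <= pool)


def cluster_by_date(events: Sequence[Event], min_dates: int = 2) -> ClusterReport:
    """Cluster events that co-occur on shared branches.

    Candidate member sets are the closed intersections of the per-branch event
    pools (restricted to branches carrying >= 2 events); a candidate of >= 2
    members recurring on >= ``min_dates`` branches becomes a cluster, keeping
    only maximal sets (no cluster is a subset of another with the same dates).
    """
    pools = _branch_pools(events)
    multi = {b: p for b, p in pools.items() if len(p) >= 2}

    # closure of the pool family under pairwise intersection
    candidates: set[frozenset[Member]] = set(multi.values())
    frontier = list(candidates)
    while frontier:
        nxt = []
        for s in frontier:
            for t in list(candidates):
                inter = s & t
                if len(inter) >= 2 and inter not in candidates:
                    candidates.add(inter)
                    nxt.append(inter)
        frontier = nxt

    clusters = []
    for cand in candidates:
        dates = _support(cand, multi)
        if len(dates) >= min_dates:
            clusters.append(EventCluster(members=cand, dates=dates))
    # drop non-maximal candidates: a strict subset with identical dates is noise
    maximal = []
    for c in clusters:
        if not any(
            c.members < other.members and c.dates == other.dates for other in clusters
        ):
            maximal.append(c)
    maximal.sort(key=lambda c: (-c.n_dates, sorted(c.members)))

    def covered(e: Event) -> bool:
        return any(
            (e.character, e.type) in c.members and e.child_id in c.dates
            for c in maximal
        )

    unclustered = [e for e in events if not covered(e)]
    return ClusterReport(clusters=maximal, unclustered=unclustered)


def cluster_by_feature(events: Sequence[Event], jaccard_threshold: float = 1.0) -> ClusterReport:
    """Group characters whose event-branch profiles are similar.

    Each (character, event-type) pair has a profile: the set of branches on
    which it occurs.  Pairs with Jaccard similarity >= ``jaccard_threshold``
    are merged single-linkage; the default threshold 1.0 groups identical
    profiles only.  Singleton groups are reported as singleton clusters.
    """
    if not 0.0 < jaccard_threshold <= 1.0:
        raise ValidationError("jaccard_threshold must be in (0, 1]")
    profiles: dict[Member, set[int]] = {}
    for e in events:
        profiles.setdefault((e.character, e.type), set()).add(e.child_id)
    members = sorted(profiles)

    parent = {m: m for m in members}

    def find(m):
        while parent[m] != m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m

    for m1, m2 in combinations(members, 2):
        p1, p2 = profiles[m1], profiles[m2]
        jac = len(p1 & p2) / len(p1 | p2)
        if jac >= jaccard_threshold:
            parent[find(m1)] = find(m2)

    groups: dict[Member, list[Member]] = {}
    for m in members:
        groups.setdefault(find(m), []).append(m)

    clusters = []
    for group in groups.values():
        shared = set.intersection(*(profiles[m] for m in group))
        dates = frozenset(shared) if shared else frozenset(profiles[group[0]])
        clusters.append(EventCluster(members=frozenset(group), dates=dates))
    clusters.sort(key=lambda c: (-len(c.members), sorted(c.members)))
    return ClusterReport(clusters=clusters, unclustered=[])


def verify_clusters(
    report: ClusterReport,
    tree: Phylogeny,
    cohort: Cohort,
    n_sim: int = 99,
    seed: int = 0,
    rule: GeneSetRule | None = None,
    support_cutoff: float = 5.0,
) -> ClusterReport:
    """Attach a Pagel test to every character pair of every cluster.

    Characters are resolved against the cohort (a family name, ``"set"`` or
    ``"pg"``); tips with unknown PG status are pruned when PG is involved.  A
    cluster is ``supported`` when every pairwise error percentage is at or
    below ``support_cutoff`` (default 5%, the conventional cut-off).
    Single-character clusters are skipped with a note.
    """
    for ci, cluster in enumerate(report.clusters):
        chars = sorted(cluster.characters())
        if len(chars) < 2:
            cluster.note = "single character; pairwise verification not applicable"
            cluster.supported = None
            continue
        all_ok = True
        for pi, (ca, cb) in enumerate(combinations(chars, 2)):
            char_a = character_from_cohort(cohort, ca, tree, rule)
            char_b = character_from_cohort(cohort, cb, tree, rule)
            excluded = set(char_a.excluded_tips) | set(char_b.excluded_tips)
            pair_tree = tree
            if excluded:
                keep = [lab for lab in tree.tip_labels if lab not in excluded]
                pair_tree = tree.prune_to(keep)
            result = pagel_test(
                pair_tree,
                {lab: char_a.states[lab] for lab in pair_tree.tip_labels},
                {lab: char_b.states[lab] for lab in pair_tree.tip_labels},
                n_sim=n_sim,
                seed=seed + 1000 * ci + pi,
            )
            cluster.verification[(ca, cb)] = result
            if result.error_percentage > support_cutoff:
                all_ok = False
        cluster.supported = all_ok
    return report
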