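"""Generators for every input the pipeline needs; no downloads required.

Three families of synthetic input:

* pure-birth (Yule) trees with exponential branch lengths;
* binary character histories evolved tip-ward by exact continuous-time Markov
  chain sampling, with every node state and every transition recorded, so
  parsimony reconstructions can be scored against the true history (multiple
  hits on one branch are recorded faithfully; parsimony is expected to
  undercount them);
* annotation cohorts with configurable confusion structure (set prevalence,
  PG rates given set status, unknown fractions), whose gene counts are drawn
  consistently with the set label.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so every fixture is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .annotation_io import FAMILIES, Cohort, GenomeRecord, ValidationError
from .correlated_evolution import JOINT_STATES, RateModel
from .phylo_events import Event, Phylogeny, parse_newick

__all__ = [
    "CohortSpec",
    "SimulatedHistory",
    "simulate_tree",
    "simulate_characters",
    "simulate_binary_history",
    "generate_cohort",
    "generate_covariate_cohort",
    "fixture_gt51_tree",
]

FOCAL_GH = ("GH23", "GH73", "GH102", "GH103", "GH104")


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """A Yule (pure-birth) tree with ``n_tips`` tips.

    Waiting times between speciations are exponential with rate
    ``k * birth_rate`` while ``k`` lineages are extant; after the last
    speciation the tree grows for one more exponential interval, so pendant
    edges are positive and the tree is ultrametric.  Expected root-to-tip
    depth is ``sum_{k=2..n} 1 / (k * birth_rate)``.
    """
    if n_tips < 3:
        raise ValidationError("n_tips must be >= 3")
    if birth_rate <= 0:
        raise ValidationError("birth_rate must be positive")
    rng = np.random.default_rng(seed)

    tree = dendropy.Tree()
    root = tree.seed_node
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = root.new_child()
        active.append((child, t))
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(k))
        node, start = active.pop(idx)
        node.edge.length = t - start
        for _ in range(2):
            active.append((node.new_child(), t))
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    for i, (node, start) in enumerate(active):
        node.edge.length = t - start
        node.taxon = tree.taxon_namespace.new_taxon(label=f"t{i + 1}")
    root.edge.length = 0.0
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# Character histories
# ---------------------------------------------------------------------------


@dataclass
class SimulatedHistory:
    """A simulated character history with full truth recorded."""

    tree: Phylogeny
    characters: tuple[str, ...]
    node_states: list[tuple[int, ...]]  # per node id, one state per character
    tip_states: dict[str, tuple[int, ...]]
    true_events: list[Event]

    def events_for(self, character: str) -> list[Event]:
        return [e for e in self.true_events if e.character == character]

    def replay(self) -> dict[str, tuple[int, ...]]:
        """Re-derive tip states from the root state and the event list.

        Raising on mismatch would hide bugs; this returns the replayed tip
        states so tests can assert equality with :attr:`tip_states`.
        """
        tree = self.tree
        nchar = len(self.characters)
        char_idx = {c: i for i, c in enumerate(self.characters)}
        events_by_branch: dict[int, list[Event]] = {}
        for e in self.true_events:
            events_by_branch.setdefault(e.child_id, []).append(e)
        states = [None] * tree.n_nodes
        states[tree.root] = list(self.node_states[tree.root])
        for v in range(tree.n_nodes):  # preorder by id
            if v == tree.root:
                continue
            s = list(states[tree.parent[v]])
            for e in events_by_branch.get(v, []):
                s[char_idx[e.character]] = 1 if e.type == "gain" else 0
            states[v] = s
        return {
            lab: tuple(states[tid]) for lab, tid in tree.tip_id_of.items()
        }


def _evolve_branch(
    state: int,
    length: float,
    Q: np.ndarray,
    rng: np.random.Generator,
) -> tuple[int, list[int]]:
    """Exact CTMC path over one branch; returns final state and visited states."""
    path = []
    t = 0.0
    cur = state
    while True:
        rate = -Q[cur, cur]
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= length:
            break
        probs = Q[cur].copy()
        probs[cur] = 0.0
        probs /= probs.sum()
        cur = int(rng.choice(len(probs), p=probs))
        path.append(cur)
    return cur, path


def simulate_characters(
    tree: Phylogeny,
    model: RateModel,
    seed: int = 0,
    root_state: tuple[int, int] | None = None,
    characters: tuple[str, str] = ("A", "B"),
    default_length: float = 1.0,
) -> SimulatedHistory:
    """Evolve two joint binary characters down the tree by exact CTMC sampling.

    The root state is drawn uniformly over the four joint states unless given.
    Every transition is recorded as a gain or loss event of the character that
    changed, on the branch where it happened.
    """
    rng = np.random.default_rng(seed)
    Q = model.generator()
    lengths = tree.branch_lengths(default_length)

    if root_state is None:
        joint_root = int(rng.integers(4))
    else:
        a, b = root_state
        joint_root = 2 * int(a) + int(b)

    joint = [0] * tree.n_nodes
    joint[tree.root] = joint_root
    events: list[Event] = []
    for v in range(tree.n_nodes):  # preorder by id: parents first
        if v == tree.root:
            continue
        parent_state = joint[tree.parent[v]]
        final, path = _evolve_branch(parent_state, lengths[v], Q, rng)
        joint[v] = final
        prev = parent_state
        for s in path:
            pa, pb = JOINT_STATES[prev]
            na, nb = JOINT_STATES[s]
            if na != pa:
                events.append(
                    Event(characters[0], "gain" if na else "loss", tree.parent[v], v)
                )
            if nb != pb:
                events.append(
                    Event(characters[1], "gain" if nb else "loss", tree.parent[v], v)
                )
            prev = s

    node_states = [JOINT_STATES[s] for s in joint]
    tip_states = {lab: node_states[tid] for lab, tid in tree.tip_id_of.items()}
    return SimulatedHistory(
        tree=tree,
        characters=characters,
        node_states=node_states,
        tip_states=tip_states,
        true_events=events,
    )


def simulate_binary_history(
    tree: Phylogeny,
    gain_rate: float,
    loss_rate: float,
    seed: int = 0,
    root_state: int = 1,
    character: str = "trait",
    default_length: float = 1.0,
) -> SimulatedHistory:
    """Evolve a single binary character by exact CTMC sampling."""
    rng = np.random.default_rng(seed)
    Q = np.array([[-gain_rate, gain_rate], [loss_rate, -loss_rate]], dtype=float)
    lengths = tree.branch_lengths(default_length)
    states = [0] * tree.n_nodes
    states[tree.root] = int(root_state)
    events: list[Event] = []
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        final, path = _evolve_branch(states[tree.parent[v]], lengths[v], Q, rng)
        states[v] = final
        for s in path:
            events.append(
                Event(character, "gain" if s == 1 else "loss", tree.parent[v], v)
            )
    node_states = [(s,) for s in states]
    return SimulatedHistory(
        tree=tree,
        characters=(character,),
        node_states=node_states,
        tip_states={lab: (states[tid],) for lab, tid in tree.tip_id_of.items()},
        true_events=events,
    )


# ---------------------------------------------------------------------------
# Annotation cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Target confusion structure of a generated bacterial cohort.

    ``set_prevalence`` is the probability a genome carries the complete 3-gene
    set; ``pg_given_set`` the probability PG is present given the set;
    ``pg_absent_given_noset`` the probability PG is absent given no set (among
    known-status genomes); ``unknown_fraction_noset`` / ``unknown_fraction_set``
    the probability the literature PG status is unknown in each arm.
    Defaults reproduce the published screening's structure: prevalence
    1260/1398, PPV 1 (every set-positive genome PG-present), 84/108 of known
    set-negatives PG-less, and 30/138 of set-negatives unknown.
    """

    n_bacteria: int = 1398
    set_prevalence: float = 1260 / 1398
    pg_given_set: float = 1.0
    pg_absent_given_noset: float = 84 / 108
    unknown_fraction_noset: float = 30 / 138
    unknown_fraction_set: float = 0.0

    def __post_init__(self) -> None:
        if self.n_bacteria < 1:
            raise ValidationError("n_bacteria must be >= 1")
        for name in (
            "set_prevalence",
            "pg_given_set",
            "pg_absent_given_noset",
            "unknown_fraction_noset",
            "unknown_fraction_set",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")


_SIM_PHYLA = (
    "Proteobacteria",
    "Firmicutes",
    "Actinobacteria",
    "Bacteroides-Chlorobi",
    "Cyanobacteria",
)


def _positive_counts(rng: np.random.Generator) -> dict[str, int]:
    """Counts satisfying the rule: GT28 >= 1, GT51 >= 1, >= 1 focal GH."""
    counts = {f: 0 for f in FAMILIES}
    counts["GT28"] = 1 + int(rng.poisson(1.0))
    counts["GT51"] = 1 + int(rng.poisson(1.0))
    present = rng.random(len(FOCAL_GH)) < 0.6
    if not present.any():
        present[int(rng.integers(len(FOCAL_GH)))] = True
    for gh, p in zip(FOCAL_GH, present):
        if p:
            counts[gh] = 1 + int(rng.poisson(1.0))
    if rng.random() < 0.3:
        counts["GH25"] = 1 + int(rng.poisson(1.0))
    return counts


def _negative_counts(rng: np.random.Generator, pg_absent: bool) -> dict[str, int]:
    """Counts violating the rule; PG-less genomes always lack GT51."""
    counts = _positive_counts(rng)
    if pg_absent:
        mode = "gt51"
    else:
        mode = ("gt51", "gt28", "gh")[int(rng.integers(3))]
    if mode == "gt51":
        counts["GT51"] = 0
    elif mode == "gt28":
        counts["GT28"] = 0
    else:
        for gh in FOCAL_GH:
            counts[gh] = 0
    return counts


def generate_cohort(spec: CohortSpec | None = None, seed: int = 0) -> Cohort:
    """A bacterial cohort whose confusion structure follows ``spec`` in expectation.

    Arms with probability exactly 0 or 1 (e.g. the default ``pg_given_set=1``)
    are deterministic, so the corresponding metric (here PPV = 1) is exact,
    not merely expected.  Identical seeds give identical cohorts.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    records = []
    for i in range(spec.n_bacteria):
        has_set = rng.random() < spec.set_prevalence
        if has_set:
            if rng.random() < spec.unknown_fraction_set:
                pg = "unknown"
            else:
                pg = "present" if rng.random() < spec.pg_given_set else "absent"
            counts = _positive_counts(rng)
        else:
            if rng.random() < spec.unknown_fraction_noset:
                pg = "unknown"
                counts = _negative_counts(rng, pg_absent=bool(rng.random() < 0.5))
            else:
                pg = "absent" if rng.random() < spec.pg_absent_given_noset else "present"
                counts = _negative_counts(rng, pg_absent=(pg == "absent"))
        records.append(
            GenomeRecord(
                genome_id=f"SIM{i:05d}",
                domain="Bacteria",
                phylum=_SIM_PHYLA[i % len(_SIM_PHYLA)],
                family_counts=counts,
                pg_status=pg,
            )
        )
    return Cohort(records, provenance=f"generate_cohort(seed={seed})")


def generate_covariate_cohort(
    n: int = 2000,
    odds_ratios: tuple[float, float, float] = (7.7, 80.0, 19.5),
    predictor_prevalence: tuple[float, float, float] = (0.5, 0.15, 0.15),
    baseline_logodds: float = -4.0,
    seed: int = 0,
) -> Cohort:
    """A cohort for the PG-absence logistic regression, with known truth.

    The three binary predictors — GC content below 50%, genome size below
    1.5 Mb, obligate intracellular lifestyle — are drawn independently with
    the given prevalences, and PG absence follows a logistic model with the
    given odds ratios (defaults are the published point estimates).  The
    numeric covariates are set consistently with their binarized values
    (GC 40/60%, size 1.0/3.0 Mb).
    """
    rng = np.random.default_rng(seed)
    betas = np.log(np.asarray(odds_ratios, dtype=float))
    records = []
    counts = {f: 1 if f != "GH25" else 0 for f in FAMILIES}
    for i in range(n):
        x = (rng.random(3) < np.asarray(predictor_prevalence)).astype(float)
        logit = baseline_logodds + float(betas @ x)
        p_absent = 1.0 / (1.0 + np.exp(-logit))
        pg = "absent" if rng.random() < p_absent else "present"
        records.append(
            GenomeRecord(
                genome_id=f"COV{i:05d}",
                domain="Bacteria",
                phylum=_SIM_PHYLA[i % len(_SIM_PHYLA)],
                family_counts=counts,
                pg_status=pg,
                lifestyle="obligate_intracellular" if x[2] else "free_living",
                gc_percent=40.0 if x[0] else 60.0,
                genome_size_mb=1.0 if x[1] else 3.0,
            )
        )
    return Cohort(records, provenance=f"generate_covariate_cohort(seed={seed})")


# ---------------------------------------------------------------------------
# The GT51 stand-in tree
# ---------------------------------------------------------------------------

# A synthetic bacteria-only cladogram assembled from the lineages the published
# screening names as GT51 loss/gain events.  It is NOT the (undeposited)
# 1,114-taxon 16S tree; it is a stand-in that encodes the reported qualitative
# history: GT51-less Rickettsiales, Thermobaculum, two non-sister
# Prochlorococcus strains, Ruminococcus torques / Coprococcus, Dehalococcoides,
# Tenericutes and the PVC superphylum, with Akkermansia muciniphila carrying
# GT51 deep inside the otherwise GT51-less PVC clade.
_GT51_FIXTURE_NEWICK = """
(
 (Aquifex_aeolicus,Thermotoga_maritima),
 (
  (Deinococcus_radiodurans,
   (Chloroflexus_aurantiacus,Roseiflexus_castenholzii,Thermobaculum_terrenum,
    (Dehalococcoides_ethenogenes,Dehalococcoides_CBDB1))),
  (
   ((Synechococcus_elongatus,
     (Prochlorococcus_MED4,Prochlorococcus_NATL1A)),
    (Prochlorococcus_MIT9313,Prochlorococcus_NATL2A)),
   (
    (Mycobacterium_tuberculosis,Streptomyces_coelicolor),
    (
     ((Bacillus_subtilis,Staphylococcus_aureus,Clostridium_difficile,
       (Ruminococcus_torques,Coprococcus_ART55)),
      (Mycoplasma_pneumoniae,Mycoplasma_genitalium,Ureaplasma_parvum)),
     (
      (Escherichia_coli,Caulobacter_crescentus,
       (Orientia_tsutsugamushi,Wolbachia_pipientis,Ehrlichia_chaffeensis,
        Anaplasma_phagocytophilum)),
      (
       ((Rhodopirellula_baltica,Pirellula_staleyi),
        (Chlamydia_trachomatis,Chlamydophila_pneumoniae),
        (Verrucomicrobium_spinosum,
         (Opitutus_terrae,
          (Akkermansia_muciniphila,Methylacidiphilum_infernorum)))),
       (Bacteroides_fragilis,Treponema_pallidum)
      )
     )
    )
   )
  )
 )
);
"""

_GT51_ABSENT = {
    "Orientia_tsutsugamushi",
    "Wolbachia_pipientis",
    "Ehrlichia_chaffeensis",
    "Anaplasma_phagocytophilum",
    "Thermobaculum_terrenum",
    "Dehalococcoides_ethenogenes",
    "Dehalococcoides_CBDB1",
    "Prochlorococcus_NATL1A",
    "Prochlorococcus_NATL2A",
    "Ruminococcus_torques",
    "Coprococcus_ART55",
    "Mycoplasma_pneumoniae",
    "Mycoplasma_genitalium",
    "Ureaplasma_parvum",
    "Rhodopirellula_baltica",
    "Pirellula_staleyi",
    "Chlamydia_trachomatis",
    "Chlamydophila_pneumoniae",
    "Verrucomicrobium_spinosum",
    "Opitutus_terrae",
    "Methylacidiphilum_infernorum",
}

# PG-less lineages among the above: the reduced intracellular groups and the
# PVC superphylum (except Akkermansia); Thermobaculum, the two Prochlorococcus
# strains and Ruminococcus/Coprococcus are PG producers despite lacking GT51.
_PG_ABSENT = {
    "Orientia_tsutsugamushi",
    "Wolbachia_pipientis",
    "Ehrlichia_chaffeensis",
    "Anaplasma_phagocytophilum",
    "Dehalococcoides_ethenogenes",
    "Dehalococcoides_CBDB1",
    "Mycoplasma_pneumoniae",
    "Mycoplasma_genitalium",
    "Ureaplasma_parvum",
    "Rhodopirellula_baltica",
    "Pirellula_staleyi",
    "Chlamydia_trachomatis",
    "Chlamydophila_pneumoniae",
    "Verrucomicrobium_spinosum",
    "Opitutus_terrae",
    "Methylacidiphilum_infernorum",
}


def fixture_gt51_tree() -> tuple[Phylogeny, dict[str, int], dict[str, int]]:
    """Synthetic stand-in tree with GT51 and PG tip states.

    Returns ``(tree, gt51_states, pg_states)``.  Gain-penalizing parsimony on
    ``gt51_states`` yields a GT51-bearing bacterial ancestor with eight loss
    events and a single gain (Akkermansia), mirroring the published
    qualitative history; ``pg_states`` loses PG on four of the same branches.
    """
    tree = parse_newick(_GT51_FIXTURE_NEWICK)
    gt51 = {lab: 0 if lab in _GT51_ABSENT else 1 for lab in tree.tip_labels}
    pg = {lab: 0 if lab in _PG_ABSENT else 1 for lab in tree.tip_labels}
    return tree, gt51, pg
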