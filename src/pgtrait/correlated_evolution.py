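"""Pagel's correlated-evolution test for two binary characters on a phylogeny.

Two binary characters (say, presence of the GT51 gene and presence of
peptidoglycan) evolve along a rooted tree with branch lengths under a
continuous-time Markov chain over the four joint states {00, 01, 10, 11}.
Under the *independent* model each character has its own gain and loss rate
(four free rates); under the *dependent* model each single-character
transition rate may depend on the current state of the other character
(eight free rates).  Simultaneous double transitions have rate zero in both.

The test statistic ("score") is the likelihood-ratio statistic
``2 (lnL_dep - lnL_indep)`` between the two maximum-likelihood fits, and the
"error percentage" is a parametric-bootstrap Monte-Carlo p-value times 100:
traits are re-simulated under the fitted independent model on the same tree
and both models refitted to each replicate.  The ``(1 + #exceed)/(n_sim + 1)``
correction keeps the error percentage strictly positive.

Likelihoods are computed by Felsenstein pruning with per-branch transition
probabilities from the matrix exponential of the generator; the root uses a
flat prior over the joint states.  Trees without branch lengths are given
unit lengths (configurable), the convention for cladogram-like input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .annotation_io import ValidationError
from .phylo_events import Phylogeny

__all__ = [
    "RateModel",
    "PagelResult",
    "mk_loglik",
    "fit",
    "pagel_test",
]

#: Joint-state order: index = 2 * state_A + state_B.
JOINT_STATES = ((0, 0), (0, 1), (1, 0), (1, 1))

#: Dependent-model rate order (single-character transitions among joint states).
DEPENDENT_TRANSITIONS = (
    (0, 1),  # 00 -> 01 : B gained while A absent
    (0, 2),  # 00 -> 10 : A gained while B absent
    (1, 0),  # 01 -> 00 : B lost while A absent
    (1, 3),  # 01 -> 11 : A gained while B present
    (2, 0),  # 10 -> 00 : A lost while B absent
    (2, 3),  # 10 -> 11 : B gained while A present
    (3, 1),  # 11 -> 01 : A lost while B present
    (3, 2),  # 11 -> 10 : B lost while A present
)

RATE_LOWER = 1e-6
RATE_UPPER = 1e3
_LOG_BOUNDS = (math.log(RATE_LOWER), math.log(RATE_UPPER))


def _dependent_generator(rates) -> np.ndarray:
    """4x4 generator from the 8 dependent-model rates (no validation)."""
    Q = np.zeros((4, 4))
    for (i, j), r in zip(DEPENDENT_TRANSITIONS, rates):
        Q[i, j] = r
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


@dataclass(frozen=True)
class RateModel:
    """A 2-character Markov model, either independent (4 rates) or dependent (8).

    Independent rates are ordered ``(qA01, qA10, qB01, qB10)``; dependent rates
    follow :data:`DEPENDENT_TRANSITIONS`.
    """

    kind: str
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("independent", "dependent"):
            raise ValidationError(f"unknown model kind {self.kind!r}")
        expected = 4 if self.kind == "independent" else 8
        if len(self.rates) != expected:
            raise ValidationError(
                f"{self.kind} model needs {expected} rates, got {len(self.rates)}"
            )
        for r in self.rates:
            if not np.isfinite(r) or r < 0:
                raise ValidationError(f"rates must be finite and >= 0, got {r!r}")
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))

    @classmethod
    def independent(cls, qa01: float, qa10: float, qb01: float, qb10: float) -> "RateModel":
        return cls("independent", (qa01, qa10, qb01, qb10))

    @classmethod
    def dependent(cls, rates: Sequence[float]) -> "RateModel":
        return cls("dependent", tuple(rates))

    def generator(self) -> np.ndarray:
        """The 4x4 generator over joint states (rows sum to zero)."""
        return _dependent_generator(self.as_dependent_rates())

    def as_dependent_rates(self) -> tuple[float, ...]:
        """The 8 dependent-model rates realizing this model exactly."""
        if self.kind == "dependent":
            return self.rates
        qa01, qa10, qb01, qb10 = self.rates
        return (qb01, qa01, qb10, qa01, qa10, qb01, qa10, qb10)


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@_njit(cache=True)
def _prune_kernel(P, partial, post_internal, children_flat, child_offsets, root):
    """Felsenstein pruning with per-node rescaling; returns log-likelihood.

    ``partial`` is modified in place; tip rows must be pre-filled, internal
    rows are overwritten.  ``P[c]`` is the transition matrix of the branch
    above node ``c``.  Root prior is flat over the k states.  Small-matrix
    products are explicit loops so the JIT emits straight-line code.
    """
    k = partial.shape[1]
    logscale = 0.0
    for idx in range(post_internal.shape[0]):
        v = post_internal[idx]
        acc = np.ones(k)
        for j in range(child_offsets[idx], child_offsets[idx + 1]):
            c = children_flat[j]
            for s in range(k):
                m = 0.0
                for t in range(k):
                    m += P[c, s, t] * partial[c, t]
                acc[s] *= m
        m = acc.max()
        if m <= 0.0:
            return -np.inf
        logscale += np.log(m)
        for s in range(k):
            partial[v, s] = acc[s] / m
    total = 0.0
    for s in range(k):
        total += partial[root, s]
    total /= k
    if total <= 0.0:
        return -np.inf
    return np.log(total) + logscale


@_njit(cache=True)
def _pmats_expm_kernel(Q, lengths):
    """Per-branch transition matrices ``exp(Q * t)`` by scaling-and-squaring.

    Order-10 Taylor after scaling the norm below 0.1: error far below the
    1e-8 tolerances used against the matrix-exponential oracle.
    """
    n_edges = lengths.shape[0]
    k = Q.shape[0]
    P = np.empty((n_edges, k, k))
    A = np.empty((k, k))
    M = np.empty((k, k))
    T = np.empty((k, k))
    W = np.empty((k, k))
    for e in range(n_edges):
        nrm = 0.0
        for i in range(k):
            row = 0.0
            for j in range(k):
                A[i, j] = Q[i, j] * lengths[e]
                row += abs(A[i, j])
            if row > nrm:
                nrm = row
        s = 0
        while nrm > 0.1:
            nrm *= 0.5
            s += 1
        scale = 1.0 / (2.0**s)
        for i in range(k):
            for j in range(k):
                A[i, j] *= scale
                T[i, j] = A[i, j]
                M[i, j] = A[i, j] + (1.0 if i == j else 0.0)
        for order in range(2, 11):
            inv = 1.0 / order
            for i in range(k):
                for j in range(k):
                    acc = 0.0
                    for l in range(k):
                        acc += T[i, l] * A[l, j]
                    W[i, j] = acc * inv
            for i in range(k):
                for j in range(k):
                    T[i, j] = W[i, j]
                    M[i, j] += W[i, j]
        for _ in range(s):
            for i in range(k):
                for j in range(k):
                    acc = 0.0
                    for l in range(k):
                        acc += M[i, l] * M[l, j]
                    W[i, j] = acc
            for i in range(k):
                for j in range(k):
                    M[i, j] = W[i, j]
        for i in range(k):
            for j in range(k):
                P[e, i, j] = M[i, j] if M[i, j] > 0.0 else 0.0
    return P


class _TreeWork:
    """Flattened traversal arrays for fast repeated likelihood evaluation."""

    def __init__(self, tree: Phylogeny, default_length: float):
        self.tree = tree
        self.n_nodes = tree.n_nodes
        self.root = tree.root
        self.lengths = np.asarray(tree.branch_lengths(default_length))
        internal = [v for v in tree.postorder if not tree.is_tip(v)]
        self.post_internal = np.asarray(internal, dtype=np.int64)
        flat: list[int] = []
        offsets = [0]
        for v in internal:
            flat.extend(tree.children[v])
            offsets.append(len(flat))
        self.children_flat = np.asarray(flat, dtype=np.int64)
        self.child_offsets = np.asarray(offsets, dtype=np.int64)

    def tip_partials_joint(self, tip_states: Mapping[str, tuple]) -> np.ndarray:
        """(n_nodes, 4) tip likelihoods; missing components are ambiguous."""
        partial = np.ones((self.n_nodes, 4))
        tree = self.tree
        for lab, tid in tree.tip_id_of.items():
            if lab not in tip_states:
                raise ValidationError(f"no joint state for tip {lab!r}")
            a, b = tip_states[lab]
            row = np.ones(4)
            if a is not None:
                for s in range(4):
                    if JOINT_STATES[s][0] != a:
                        row[s] = 0.0
            if b is not None:
                for s in range(4):
                    if JOINT_STATES[s][1] != b:
                        row[s] = 0.0
            partial[tid] = row
        return partial

    def tip_partials_single(self, states: Mapping[str, int | None]) -> np.ndarray:
        partial = np.ones((self.n_nodes, 2))
        for lab, tid in self.tree.tip_id_of.items():
            s = states.get(lab)
            if s is not None:
                partial[tid, 1 - int(s)] = 0.0
        return partial

    def loglik(self, P: np.ndarray, tip_partial: np.ndarray) -> float:
        return float(
            _prune_kernel(
                P,
                tip_partial.copy(),
                self.post_internal,
                self.children_flat,
                self.child_offsets,
                self.root,
            )
        )


@_njit(cache=True)
def _pmats_eig_kernel(w, V, Vinv, lengths):
    """Per-branch ``exp(Q t) = V exp(w t) V^-1`` from a spectral decomposition."""
    n_edges = lengths.shape[0]
    k = w.shape[0]
    P = np.empty((n_edges, k, k))
    VS = np.empty((k, k), dtype=np.complex128)
    for e in range(n_edges):
        t = lengths[e]
        for j in range(k):
            ew = np.exp(w[j] * t)
            for i in range(k):
                VS[i, j] = V[i, j] * ew
        for i in range(k):
            for j in range(k):
                acc = 0.0 + 0.0j
                for l in range(k):
                    acc += VS[i, l] * Vinv[l, j]
                re = acc.real
                P[e, i, j] = re if re > 0.0 else 0.0
    return P


def _edge_pmats(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Transition matrices for every branch (matrix exponential per edge).

    Eigendecomposition is done once per generator and reused across branches;
    near-defective generators fall back to scaling-and-squaring (or scipy's
    ``expm`` without the JIT).
    """
    if _HAVE_NUMBA:
        try:
            w, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            # spectral reconstruction must reproduce Q, else Q is near-defective
            err = np.abs((V * w) @ Vinv - Q).max()
            scale = max(1.0, np.abs(Q).max())
            if np.isfinite(err) and err < 1e-9 * scale:
                return _pmats_eig_kernel(w, V, Vinv, lengths)
        except np.linalg.LinAlgError:
            pass
        return _pmats_expm_kernel(np.ascontiguousarray(Q, dtype=float), lengths)
    k = Q.shape[0]
    P = np.empty((len(lengths), k, k))
    for i, t in enumerate(lengths):
        P[i] = expm(Q * t)
    np.clip(P, 0.0, 1.0, out=P)
    return P


def _pmats_2state(q01: float, q10: float, lengths: np.ndarray) -> np.ndarray:
    """Closed-form 2-state transition matrices for every branch."""
    P = np.empty((len(lengths), 2, 2))
    q = q01 + q10
    if q <= 0:
        P[:] = np.eye(2)
        return P
    pi1 = q01 / q
    pi0 = q10 / q
    e = np.exp(-q * lengths)
    P[:, 0, 0] = pi0 + pi1 * e
    P[:, 0, 1] = pi1 * (1.0 - e)
    P[:, 1, 0] = pi0 * (1.0 - e)
    P[:, 1, 1] = pi1 + pi0 * e
    return P


def mk_loglik(
    tree: Phylogeny,
    tip_states: Mapping[str, tuple],
    model: RateModel,
    default_length: float = 1.0,
) -> float:
    """Pruning log-likelihood of joint tip states under a rate model.

    ``tip_states`` maps each tip label to an ``(a, b)`` pair in {0, 1}; either
    component may be ``None`` (treated as ambiguous).  Branches without
    lengths use ``default_length``.
    """
    work = _TreeWork(tree, default_length)
    P = _edge_pmats(model.generator(), work.lengths)
    return work.loglik(P, work.tip_partials_joint(tip_states))


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    model: RateModel
    loglik: float


def _fit_single_char(
    work: _TreeWork, tip_partial: np.ndarray, starts: np.ndarray, maxiter: int
) -> tuple[np.ndarray, float]:
    """ML (q01, q10) for one character; returns (rates, loglik)."""

    def nll(logq: np.ndarray) -> float:
        q01, q10 = np.exp(logq)
        P = _pmats_2state(q01, q10, work.lengths)
        ll = work.loglik(P, tip_partial)
        return -ll if np.isfinite(ll) else 1e12

    best_x, best_f = None, np.inf
    for x0 in starts:
        res = minimize(
            nll,
            np.clip(x0, *_LOG_BOUNDS),
            method="L-BFGS-B",
            bounds=[_LOG_BOUNDS] * 2,
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
    return np.exp(best_x), -best_f


def _fit_dependent(
    work: _TreeWork, tip_partial: np.ndarray, starts: np.ndarray, maxiter: int
) -> tuple[np.ndarray, float]:
    def nll(logr: np.ndarray) -> float:
        P = _edge_pmats(_dependent_generator(np.exp(logr)), work.lengths)
        ll = work.loglik(P, tip_partial)
        return -ll if np.isfinite(ll) else 1e12

    best_x, best_f = None, np.inf
    for x0 in starts:
        res = minimize(
            nll,
            np.clip(x0, *_LOG_BOUNDS),
            method="L-BFGS-B",
            bounds=[_LOG_BOUNDS] * 8,
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
    return np.exp(best_x), -best_f


def _split_traits(tip_states: Mapping[str, tuple]) -> tuple[dict, dict]:
    a = {lab: (None if ab[0] is None else int(ab[0])) for lab, ab in tip_states.items()}
    b = {lab: (None if ab[1] is None else int(ab[1])) for lab, ab in tip_states.items()}
    return a, b


def _char_varies(states: Mapping[str, int | None]) -> bool:
    seen = {s for s in states.values() if s is not None}
    return len(seen) > 1


def _fit_core(
    work: _TreeWork,
    tip_states: Mapping[str, tuple],
    kind: str,
    n_starts: int,
    rng: np.random.Generator,
    maxiter: int,
    indep: "FitResult | None" = None,
) -> FitResult:
    trait_a, trait_b = _split_traits(tip_states)
    n_random = max(0, n_starts - 1)
    if kind == "independent":
        # The joint likelihood factorizes over characters under the flat root
        # prior, so each character is fitted by its own 2-parameter problem.
        rates = []
        total_ll = 0.0
        for trait in (trait_a, trait_b):
            partial = work.tip_partials_single(trait)
            base = np.log(np.full(2, 0.5))
            starts = [base]
            for _ in range(n_random):
                starts.append(base + rng.normal(0.0, 1.5, size=2))
            q, ll = _fit_single_char(work, partial, np.asarray(starts), maxiter)
            rates.extend(q)
            total_ll += ll
        model = RateModel.independent(rates[0], rates[1], rates[2], rates[3])
        return FitResult(model, total_ll)

    # Dependent fit: always seed from the independent optimum (the dependent
    # model nests it exactly), which also enforces lnL_dep >= lnL_indep.
    if indep is None:
        indep = _fit_core(work, tip_states, "independent", n_starts, rng, maxiter)
    base = np.log(np.clip(indep.model.as_dependent_rates(), RATE_LOWER, RATE_UPPER))
    starts = [base]
    for _ in range(n_random):
        starts.append(base + rng.normal(0.0, 1.0, size=8))
    partial = work.tip_partials_joint(tip_states)
    r, ll = _fit_dependent(work, partial, np.asarray(starts), maxiter)
    if ll < indep.loglik:
        # optimizer stalled below its own starting point's optimum: keep the
        # nested solution
        r, ll = np.asarray(indep.model.as_dependent_rates()), indep.loglik
    return FitResult(RateModel.dependent(r), ll)


def fit(
    tree: Phylogeny,
    tip_states: Mapping[str, tuple],
    kind: str,
    n_starts: int = 5,
    seed: int = 0,
    maxiter: int = 200,
    default_length: float = 1.0,
) -> FitResult:
    """ML fit of the independent or dependent model by multi-start L-BFGS-B.

    Rates are optimized on the log scale within ``[1e-6, 1e3]``; the first
    start is deterministic (flat rates, or the independent optimum for the
    dependent model) and the remaining ``n_starts - 1`` are seeded
    perturbations, so refits with the same seed are identical.
    """
    if kind not in ("independent", "dependent"):
        raise ValidationError(f"unknown model kind {kind!r}")
    trait_a, trait_b = _split_traits(tip_states)
    observed = [s for s in tip_states.values() if s[0] is not None and s[1] is not None]
    if len(observed) < 4:
        raise ValidationError("need at least 4 tips with both characters observed")
    if not _char_varies(trait_a) or not _char_varies(trait_b):
        raise ValidationError(
            "a character does not vary across tips; the correlation test is undefined"
        )
    work = _TreeWork(tree, default_length)
    rng = np.random.default_rng(seed)
    return _fit_core(work, tip_states, kind, n_starts, rng, maxiter)


# ---------------------------------------------------------------------------
# The Pagel test
# ---------------------------------------------------------------------------


@dataclass
class PagelResult:
    """Likelihood-ratio score and Monte-Carlo error percentage."""

    loglik_independent: float
    loglik_dependent: float
    score: float
    error_percentage: float
    n_simulations: int
    seed: int
    independent_model: RateModel
    dependent_model: RateModel

    def as_dict(self) -> dict:
        return {
            "loglik_independent": self.loglik_independent,
            "loglik_dependent": self.loglik_dependent,
            "score": self.score,
            "error_percentage": self.error_percentage,
            "n_simulations": self.n_simulations,
            "seed": self.seed,
            "independent_rates": list(self.independent_model.rates),
            "dependent_rates": list(self.dependent_model.rates),
        }


def _simulate_tips_2state(
    work: _TreeWork, q01: float, q10: float, n_sim: int, rng: np.random.Generator
) -> np.ndarray:
    """Tip states for ``n_sim`` replicates of one character (root flat prior)."""
    tree = work.tree
    states = np.zeros((n_sim, work.n_nodes), dtype=np.int8)
    P = _pmats_2state(q01, q10, work.lengths)
    states[:, tree.root] = rng.random(n_sim) < 0.5
    for v in range(work.n_nodes):  # preorder: ids ascend from the root
        if v == tree.root:
            continue
        p = states[:, tree.parent[v]]
        p1 = P[v][p, 1]
        states[:, v] = rng.random(n_sim) < p1
    return states


def _score_from_fits(
    work: _TreeWork,
    tip_states: Mapping[str, tuple],
    n_starts: int,
    rng: np.random.Generator,
    maxiter: int,
) -> tuple[FitResult, FitResult, float]:
    indep = _fit_core(work, tip_states, "independent", n_starts, rng, maxiter)
    dep = _fit_core(work, tip_states, "dependent", n_starts, rng, maxiter, indep=indep)
    score = max(0.0, 2.0 * (dep.loglik - indep.loglik))
    return indep, dep, score


def pagel_test(
    tree: Phylogeny,
    trait_a: Mapping[str, int],
    trait_b: Mapping[str, int],
    n_sim: int = 99,
    seed: int = 0,
    n_starts: int = 2,
    maxiter: int = 60,
    default_length: float = 1.0,
) -> PagelResult:
    """Correlated-evolution test of two binary traits on one tree.

    Returns the two maximized log-likelihoods, the score ``2 dlnL`` (clamped at
    zero) and the parametric-bootstrap error percentage
    ``100 (1 + #{simulated score >= observed}) / (n_sim + 1)``.

    The observed data and every bootstrap replicate are fitted with identical
    optimizer settings (``n_starts`` starts, the first being the nested
    independent optimum), which keeps the Monte-Carlo p-value exchangeable.
    ``n_sim`` must be at least 19 (resolution 5%).
    """
    if n_sim < 19:
        raise ValidationError("n_sim must be >= 19 for a usable error percentage")
    labels = tree.tip_labels
    missing = [lab for lab in labels if lab not in trait_a or lab not in trait_b]
    if missing:
        raise ValidationError(f"traits missing for tip(s): {missing}")
    tip_states = {lab: (trait_a[lab], trait_b[lab]) for lab in labels}
    observed = [s for s in tip_states.values() if s[0] is not None and s[1] is not None]
    if len(observed) < 4:
        raise ValidationError("need at least 4 tips with both characters observed")
    ta, tb = _split_traits(tip_states)
    if not _char_varies(ta) or not _char_varies(tb):
        raise ValidationError(
            "a character does not vary across tips; the correlation test is undefined"
        )

    work = _TreeWork(tree, default_length)
    rng = np.random.default_rng(seed)
    indep, dep, obs_score = _score_from_fits(work, tip_states, n_starts, rng, maxiter)

    qa01, qa10, qb01, qb10 = indep.model.rates
    sim_a = _simulate_tips_2state(work, qa01, qa10, n_sim, rng)
    sim_b = _simulate_tips_2state(work, qb01, qb10, n_sim, rng)
    tip_idx = {lab: tid for lab, tid in tree.tip_id_of.items()}

    n_exceed = 0
    for i in range(n_sim):
        sim_states = {
            lab: (int(sim_a[i, tid]), int(sim_b[i, tid])) for lab, tid in tip_idx.items()
        }
        sa, sb = _split_traits(sim_states)
        if not _char_varies(sa) or not _char_varies(sb):
            # a monomorphic replicate carries no evidence of dependence
            sim_score = 0.0
        else:
            _, _, sim_score = _score_from_fits(work, sim_states, n_starts, rng, maxiter)
        if sim_score >= obs_score:
            n_exceed += 1

    error_percentage = 100.0 * (1 + n_exceed) / (n_sim + 1)
    return PagelResult(
        loglik_independent=indep.loglik,
        loglik_dependent=dep.loglik,
        score=obs_score,
        error_percentage=error_percentage,
        n_simulations=n_sim,
        seed=seed,
        independent_model=indep.model,
        dependent_model=dep.model,
    )
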