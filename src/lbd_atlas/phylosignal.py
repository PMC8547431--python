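"""Phylogenetic signal of a binary presence/absence trait on a species tree.

The question: does the set of species carrying an LBD cluster form
phylogenetically coherent groups, or is it scattered over the tree as
lifestyle-driven selection would produce?

Model and statistic
-------------------
Presence/absence evolves under a symmetric two-state Mk model with a single
rate ``q`` (per unit branch length); the stay probability along a branch of
length ``t`` is ``(1 + exp(-2 q t)) / 2``. The rate is fitted by maximum
likelihood (Felsenstein pruning, flat root prior), and marginal posterior
state probabilities are reconstructed at every internal node by the
standard two-pass algorithm. Each node's Shannon entropy ``H_i`` (natural
log) measures reconstruction uncertainty; the signal statistic is the
entropy ratio

    delta = m * ln(2) / sum_i max(H_i, h_min)

over the ``m`` internal nodes, i.e. the factor by which ancestral states
are more certain than coin flips. delta = 1 under total uncertainty and
grows without bound (capped by ``h_min``) as reconstructions sharpen.

Significance comes from a tip-permutation null: tip states are shuffled
(preserving the number of present species), the rate is re-fitted and delta
recomputed each time, and the add-one p-value ``(1 + #{delta_r >=
delta_obs}) / (1 + n_perm)`` is reported; signal is declared at p < 0.05.
Because the null is rank-based, the p-value is invariant under any strictly
increasing transform of the statistic.

Traits are tested on the MRCA subtree of the species carrying the cluster;
subtrees below the minimum leaf count (default 20, where the statistic has
poor sensitivity) and invariant traits are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import numpy as np

#: Replacement for zero-length or missing branch lengths.
BRANCH_EPSILON = 1e-8

#: Floor on per-node entropies in the delta denominator.
H_MIN = 1e-6

#: Bounds for the ML rate search (per unit branch length).
Q_BOUNDS = (1e-8, 1e3)

DEFAULT_MIN_LEAVES = 20
DEFAULT_N_PERM = 100
ALPHA = 0.05

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# Tree preparation

class TreeArrays:
    """A rooted binary (sub)tree flattened to arrays for fast pruning.

    Nodes are indexed in postorder; leaves first carry their labels.
    Zero-length or missing branches are replaced by ``BRANCH_EPSILON``.
    """

    def __init__(self, root: dendropy.Node):
        postorder = list(root.postorder_iter())
        self.n_nodes = len(postorder)
        index = {id(node): i for i, node in enumerate(postorder)}
        self.children: list = [None] * self.n_nodes
        self.edge_len = np.full(self.n_nodes, BRANCH_EPSILON)
        self.leaf_labels: list = []
        self.leaf_indices: list = []
        for i, node in enumerate(postorder):
            kids = node.child_nodes()
            if node is not root:
                el = node.edge.length
                self.edge_len[i] = el if el and el > 0 else BRANCH_EPSILON
            if kids:
                if len(kids) != 2:
                    raise ValueError(
                        "tree must be binary; resolve polytomies first"
                    )
                self.children[i] = (index[id(kids[0])], index[id(kids[1])])
            else:
                self.leaf_labels.append(node.taxon.label)
                self.leaf_indices.append(i)
        self.leaf_indices = np.asarray(self.leaf_indices)
        self.internal_indices = np.asarray(
            [i for i in range(self.n_nodes) if self.children[i] is not None]
        )
        self.root_index = self.n_nodes - 1

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices)

    @property
    def n_internal(self) -> int:
        return len(self.internal_indices)


def prepare_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Root (at the seed node) and resolve polytomies (epsilon branches) in
    place; returns the tree."""
    tree.is_rooted = True
    tree.resolve_polytomies()
    for edge in tree.preorder_edge_iter():
        if edge.length is None or edge.length <= 0:
            edge.length = BRANCH_EPSILON
    return tree


def states_for(arrays: TreeArrays, present: Iterable[str]) -> np.ndarray:
    """0/1 state vector over ``arrays.leaf_labels`` for a presence set."""
    present = set(present)
    return np.array([1 if lab in present else 0 for lab in arrays.leaf_labels])


# ---------------------------------------------------------------------------
# Mk likelihood machinery

def _stay_prob(q, t):
    return 0.5 * (1.0 + np.exp(-2.0 * np.multiply.outer(q, t)))


def _up_pass_multi(arrays: TreeArrays, states: np.ndarray, qs: np.ndarray):
    """Pruning pass vectorized over rates.

    Returns normalized per-node partial likelihoods of shape
    ``(n_nodes, n_q, 2)``, the per-rate log scale, and the per-edge stay
    probabilities ``(n_q, n_nodes)``.
    """
    a = _stay_prob(qs, arrays.edge_len)  # (n_q, n_nodes)
    n_q = len(qs)
    partial = np.zeros((arrays.n_nodes, n_q, 2))
    for leaf_pos, i in enumerate(arrays.leaf_indices):
        partial[i, :, states[leaf_pos]] = 1.0
    log_scale = np.zeros(n_q)
    for i in range(arrays.n_nodes):
        kids = arrays.children[i]
        if kids is None:
            continue
        prod = np.ones((n_q, 2))
        for c in kids:
            ac = a[:, c]
            lc = partial[c]
            # contribution[:, i_state] = sum_j P(i->j) * L_c[:, j]
            prod[:, 0] *= ac * lc[:, 0] + (1 - ac) * lc[:, 1]
            prod[:, 1] *= (1 - ac) * lc[:, 0] + ac * lc[:, 1]
        mx = prod.max(axis=1)
        if np.any(mx <= 0) or not np.all(np.isfinite(mx)):
            raise FloatingPointError("non-finite intermediate in pruning")
        partial[i] = prod / mx[:, None]
        log_scale += np.log(mx)
    return partial, log_scale, a


def _loglik_multi(arrays: TreeArrays, states: np.ndarray, qs: np.ndarray) -> np.ndarray:
    partial, log_scale, _ = _up_pass_multi(arrays, states, qs)
    root_like = 0.5 * partial[arrays.root_index].sum(axis=1)
    return np.log(root_like) + log_scale


def mk_loglik(arrays: TreeArrays, states: np.ndarray, q: float) -> float:
    """Ln-likelihood of the tip states under the symmetric 2-state model."""
    if q <= 0:
        raise ValueError("rate q must be positive")
    return float(_loglik_multi(arrays, states, np.asarray([float(q)]))[0])


@dataclass(frozen=True)
class MkFit:
    q: float
    loglik: float
    bounds: tuple
    converged: bool


_GRID_POINTS = 33
_LOG_TOL = 1e-6


def fit_mk(arrays: TreeArrays, states: np.ndarray) -> MkFit:
    """ML estimate of the transition rate.

    The likelihood is nearly flat in q over most of the bounded interval (a
    saturation plateau), so a local search from an arbitrary start can
    stall; instead the search is an iteratively refined log-spaced grid
    (vectorized pruning over all grid points) zoomed around the best point
    until the bracket is below 1e-6 on log10(q). Deterministic.
    """
    lo, hi = np.log10(Q_BOUNDS[0]), np.log10(Q_BOUNDS[1])
    best_q = None
    best_ll = -np.inf
    while True:
        qs = np.logspace(lo, hi, _GRID_POINTS)
        ll = _loglik_multi(arrays, states, qs)
        if not np.all(np.isfinite(ll)):
            raise RuntimeError("non-finite likelihood during rate search")
        b = int(np.argmax(ll))
        if ll[b] > best_ll:
            best_ll, best_q = float(ll[b]), float(qs[b])
        if hi - lo <= _LOG_TOL:
            break
        lo, hi = np.log10(qs[max(b - 1, 0)]), np.log10(qs[min(b + 1, _GRID_POINTS - 1)])
    return MkFit(q=best_q, loglik=best_ll, bounds=Q_BOUNDS, converged=True)


def ancestral_posteriors(
    arrays: TreeArrays, states: np.ndarray, q: float
) -> dict:
    """Marginal posterior state probabilities at every internal node.

    Standard two-pass algorithm: the up pass collects within-subtree
    partials, the down pass propagates the likelihood of the rest of the
    tree; the root prior is flat. Returns
    ``{"posteriors": (n_internal, 2), "entropies": (n_internal,)}`` ordered
    like ``arrays.internal_indices``.
    """
    partial_multi, _, a_multi = _up_pass_multi(
        arrays, states, np.asarray([float(q)])
    )
    partial = partial_multi[:, 0, :]
    a = a_multi[0]

    down = np.zeros((arrays.n_nodes, 2))
    down[arrays.root_index] = (0.5, 0.5)
    for i in range(arrays.n_nodes - 1, -1, -1):
        kids = arrays.children[i]
        if kids is None:
            continue
        c1, c2 = kids
        for c, sib in ((c1, c2), (c2, c1)):
            asib = a[sib]
            lsib = partial[sib]
            # S[i_state] = sum_k P(i->k, t_sib) * L_sib[k]
            s = np.array(
                [
                    asib * lsib[0] + (1 - asib) * lsib[1],
                    (1 - asib) * lsib[0] + asib * lsib[1],
                ]
            )
            base = down[i] * s
            ac = a[c]
            d = np.array(
                [
                    ac * base[0] + (1 - ac) * base[1],
                    (1 - ac) * base[0] + ac * base[1],
                ]
            )
            tot = d.sum()
            if tot <= 0 or not np.isfinite(tot):
                raise FloatingPointError("non-finite intermediate in down pass")
            down[c] = d / tot

    idx = arrays.internal_indices
    joint = partial[idx] * down[idx]
    post = joint / joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(post > 0, post * np.log(post), 0.0)
    entropies = -terms.sum(axis=1)
    return {"posteriors": post, "entropies": entropies}


# ---------------------------------------------------------------------------
# Delta statistic and permutation test

def delta_from_entropies(entropies: np.ndarray) -> float:
    """Entropy-ratio statistic over internal-node entropies."""
    m = len(entropies)
    return m * LN2 / float(np.maximum(entropies, H_MIN).sum())


def compute_delta(arrays: TreeArrays, states: np.ndarray) -> float:
    """Fit the Mk rate, reconstruct ancestors and return delta."""
    fit = fit_mk(arrays, states)
    post = ancestral_posteriors(arrays, states, fit.q)
    return delta_from_entropies(post["entropies"])


def negative_entropy_sum(arrays: TreeArrays, states: np.ndarray) -> float:
    """Alternative signal statistic: minus the summed ancestral entropy.

    A strictly increasing transform of delta up to the entropy floor; used
    to check the rank-invariance of the permutation p-value.
    """
    fit = fit_mk(arrays, states)
    post = ancestral_posteriors(arrays, states, fit.q)
    return -float(np.maximum(post["entropies"], H_MIN).sum())


@dataclass(frozen=True)
class DeltaResult:
    cluster_id: object
    delta: float
    p_value: float
    n_leaves: int
    n_permutations: int
    status: str  # tested | skipped_small_subtree | skipped_invariant_trait
    signal: bool


@dataclass(frozen=True)
class TraitVector:
    """Presence/absence states on the leaves of an MRCA subtree."""

    arrays: TreeArrays
    states: np.ndarray

    @property
    def n_leaves(self) -> int:
        return self.arrays.n_leaves


def build_trait(
    cluster_species: Iterable[str],
    tree: dendropy.Tree,
    min_leaves: int = DEFAULT_MIN_LEAVES,
):
    """Map a cluster's species onto the tree as a testable trait.

    Returns ``("tested", TraitVector)`` or ``(skip_status, None)``. The
    trait lives on the MRCA subtree of the cluster's species: present
    species are state 1, every other subtree leaf state 0.
    """
    species = sorted(set(cluster_species))
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [s for s in species if s not in leaf_labels]
    if missing:
        raise KeyError(f"cluster species absent from tree: {missing}")
    mrca = tree.mrca(taxon_labels=species)
    arrays = TreeArrays(mrca)
    if arrays.n_leaves < min_leaves:
        return "skipped_small_subtree", None
    states = states_for(arrays, species)
    if states.all() or not states.any():
        return "skipped_invariant_trait", None
    return "tested", TraitVector(arrays=arrays, states=states)


def permutation_test(
    trait: TraitVector,
    n_perm: int = DEFAULT_N_PERM,
    seed=None,
    stat: Callable = compute_delta,
    cluster_id=None,
) -> DeltaResult:
    """Tip-permutation significance test of the signal statistic.

    Permutations shuffle tip states without replacement (the count of
    present species is preserved); the statistic — including the rate fit —
    is recomputed per permutation. Reproducible for a fixed *seed*; the
    shuffle is drawn over tips sorted by label, so isomorphic trees (child
    rotations, order-preserving relabelings) reproduce the same null
    sequence.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = stat(trait.arrays, trait.states)
    order = np.argsort(np.asarray(trait.arrays.leaf_labels))
    base = trait.states[order]
    n_ge = 0
    perm_states = np.empty_like(trait.states)
    for _ in range(n_perm):
        perm_states[order] = rng.permutation(base)
        if stat(trait.arrays, perm_states) >= observed:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    return DeltaResult(
        cluster_id=cluster_id,
        delta=observed if stat is compute_delta else float("nan"),
        p_value=p,
        n_leaves=trait.n_leaves,
        n_permutations=n_perm,
        status="tested",
        signal=p < ALPHA,
    )


def restrict_tree(tree: dendropy.Tree, keep_species: Iterable[str]) -> dendropy.Tree:
    """Alternative reference phylogeny: only the given species (e.g. those
    with at least one chemoreceptor)."""
    keep = set(keep_species)
    sub = tree.extract_tree_with_taxa_labels(labels=keep)
    return prepare_tree(sub)


def screen_clusters(
    cluster_species: Mapping[object, Iterable[str]],
    tree: dendropy.Tree,
    min_leaves: int = DEFAULT_MIN_LEAVES,
    n_perm: int = DEFAULT_N_PERM,
    seed=None,
) -> tuple:
    """Run the signal test over a set of clusters.

    *cluster_species* maps cluster id → member species (typically the
    high-DPS clusters). Returns ``(results, summary)`` where summary holds
    the fractions of tested clusters with and without signal (``None`` when
    nothing was testable). Skipped clusters appear in results but are
    excluded from the fractions.
    """
    rng = np.random.default_rng(seed)
    results = []
    for cid in sorted(cluster_species, key=str):
        status, trait = build_trait(cluster_species[cid], tree, min_leaves)
        if status != "tested":
            results.append(
                DeltaResult(
                    cluster_id=cid,
                    delta=float("nan"),
                    p_value=float("nan"),
                    n_leaves=0,
                    n_permutations=0,
                    status=status,
                    signal=False,
                )
            )
            continue
        results.append(
            permutation_test(trait, n_perm=n_perm, seed=rng, cluster_id=cid)
        )
    tested = [r for r in results if r.status == "tested"]
    if tested:
        frac_signal = sum(r.signal for r in tested) / len(tested)
        summary = {
            "n_tested": len(tested),
            "n_skipped": len(results) - len(tested),
            "frac_signal": frac_signal,
            "frac_no_signal": 1.0 - frac_signal,
        }
    else:
        summary = {
            "n_tested": 0,
            "n_skipped": len(results),
            "frac_signal": None,
            "frac_no_signal": None,
        }
    return results, summary
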