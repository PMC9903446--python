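"""Maximum-likelihood phylogeny under the HKY85 substitution model.

The HKY85 model has unequal stationary base frequencies pi and a
transition/transversion rate ratio kappa. The rate matrix is scaled so the
mean substitution rate is 1, making branch lengths expected substitutions
per site. Likelihoods are computed by Felsenstein pruning over site
patterns, with transition probabilities from a symmetrized eigendecomposition
(exact for any reversible model). The tree search starts from a
neighbor-joining tree and alternates per-edge branch-length optimization,
kappa optimization, and nearest-neighbor-interchange (NNI) moves, accepting
the best improving move until no move gains more than a fixed tolerance.

Trees are unrooted, represented with an arbitrary trifurcating root; the
likelihood is invariant to the choice of root for a reversible model.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import skbio
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar

from .amova import DistanceMatrix

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: search tolerances: scalar optimizations converge to BRENT_TOL; the outer
#: loop stops when one full round improves the log-likelihood by <= STOP_TOL
BRENT_TOL = 1e-6
STOP_TOL = 1e-8
MIN_BRANCH = 1e-9
MAX_BRANCH = 20.0


@dataclass
class PhyloModel:
    """HKY85 parameters: kappa > 0 and base frequencies (piA, piC, piG, piT)."""

    kappa: float = 4.0
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,) or np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("freqs must be 4 positive values summing to 1")
        if not self.kappa > 0:
            raise ValueError("kappa must be positive")
        self.freqs = tuple(float(x) for x in f)


@dataclass
class Node:
    name: str | None = None
    length: float | None = None  # branch to parent (None for the root)
    children: list["Node"] = field(default_factory=list)
    support: float | None = None

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    @property
    def leaves(self) -> list["Node"]:
        return [n for n in self.walk() if not n.children]


@dataclass
class PhyloTree:
    """Unrooted tree (trifurcating root node), model and fit diagnostics."""

    root: Node
    model: PhyloModel | None = None
    loglik: float | None = None

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves]

    def copy(self) -> "PhyloTree":
        return PhyloTree(copy.deepcopy(self.root), self.model, self.loglik)

    def bipartitions(self) -> set[frozenset]:
        """Leaf bipartitions of internal edges, canonicalized by the side
        not containing the alphabetically first leaf."""
        anchor = min(self.leaf_names)
        all_leaves = frozenset(self.leaf_names)
        splits = set()
        for node in self.root.walk():
            if node is self.root or not node.children:
                continue
            below = frozenset(l.name for l in node.leaves)
            side = below if anchor not in below else all_leaves - below
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(side)
        return splits


# ---------------------------------------------------------------------------
# HKY85 transition probabilities
# ---------------------------------------------------------------------------


def rate_matrix(model: PhyloModel) -> np.ndarray:
    """HKY85 rate matrix scaled to mean rate 1 (A, C, G, T order)."""
    pi = np.asarray(model.freqs)
    kappa = model.kappa
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.sum(pi * np.diag(Q)))
    return Q / mu


def _eigensystem(model: PhyloModel):
    pi = np.asarray(model.freqs)
    Q = rate_matrix(model)
    sqrt_pi = np.sqrt(pi)
    # D^(1/2) Q D^(-1/2) is symmetric for a reversible Q (detailed balance)
    S = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
    w, U = eigh((S + S.T) / 2.0)
    return w, U, sqrt_pi


def prob_matrix(model: PhyloModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for the scaled HKY85 rate matrix."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    w, U, sqrt_pi = _eigensystem(model)
    M = (U * np.exp(w * t)) @ U.T
    P = M * (sqrt_pi[None, :] / sqrt_pi[:, None])
    return np.clip(P, 0.0, None)


# ---------------------------------------------------------------------------
# Felsenstein pruning
# ---------------------------------------------------------------------------


def _encode_alignment(alignment: dict[str, str]):
    """Site-pattern compression: unique columns + multiplicities.

    Characters outside ACGT (gaps, N, ?) are missing: their conditional
    likelihood is 1 for every state.
    """
    labels = list(alignment)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must have equal lengths")
    mat = np.array(
        [[_BASE_INDEX.get(c, -1) for c in alignment[l].upper()] for l in labels],
        dtype=np.int8,
    )
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return labels, patterns, counts.astype(float)


def _leaf_partials(codes: np.ndarray) -> np.ndarray:
    L = np.zeros((4, codes.size))
    obs = codes >= 0
    L[:, ~obs] = 1.0
    L[codes[obs], np.flatnonzero(obs)] = 1.0
    return L


class _Pruner:
    """Reusable pruning engine bound to one alignment."""

    def __init__(self, alignment: dict[str, str]):
        self.labels, self.patterns, self.counts = _encode_alignment(alignment)
        self.index = {l: i for i, l in enumerate(self.labels)}
        self.n_sites = int(self.counts.sum())

    def loglik(self, tree: PhyloTree, model: PhyloModel) -> float:
        seen = sorted(n.name for n in tree.root.leaves)
        if seen != sorted(self.labels):
            raise ValueError("tree leaves do not match alignment labels")
        eig = _eigensystem(model)
        pi = np.asarray(model.freqs)

        def P(t: float) -> np.ndarray:
            w, U, sqrt_pi = eig
            M = (U * np.exp(w * t)) @ U.T
            return np.clip(M * (sqrt_pi[None, :] / sqrt_pi[:, None]), 0.0, None)

        def partial(node: Node) -> np.ndarray:
            if not node.children:
                return _leaf_partials(self.patterns[self.index[node.name]])
            L = np.ones((4, self.patterns.shape[1]))
            for child in node.children:
                L *= P(child.length) @ partial(child)
            return L

        site_l = pi @ partial(tree.root)
        if np.any(site_l <= 0):
            return -np.inf
        return float(self.counts @ np.log(site_l))


def hky85_loglik(tree: PhyloTree, alignment: dict[str, str], model: PhyloModel) -> float:
    """Log-likelihood of an alignment on a tree under HKY85.

    Sites are independent; missing states (gaps, N, ?) are marginalized
    over all four bases.
    """
    return _Pruner(alignment).loglik(tree, model)


def empirical_frequencies(alignment: dict[str, str], floor: float = 1e-8) -> tuple:
    """Base frequencies from alignment counts, missing states excluded."""
    counts = np.zeros(4)
    for seq in alignment.values():
        for c in seq.upper():
            i = _BASE_INDEX.get(c)
            if i is not None:
                counts[i] += 1
    if counts.sum() == 0:
        raise ValueError("alignment contains no unambiguous bases")
    freqs = np.maximum(counts / counts.sum(), floor)
    return tuple(freqs / freqs.sum())


# ---------------------------------------------------------------------------
# Neighbor joining (scikit-bio backed)
# ---------------------------------------------------------------------------


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree from a (plain, not squared) distance matrix.

    Labels are processed in sorted order for deterministic tie-breaking;
    negative branch lengths are clamped to zero.
    """
    if d.n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    order = np.argsort(np.array(d.labels, dtype=object))
    labels = [d.labels[i] for i in order]
    values = d.values[np.ix_(order, order)]
    sk = skbio.tree.nj(skbio.DistanceMatrix(values, labels))

    def convert(tn) -> Node:
        node = Node(
            name=tn.name if tn.is_tip() else None,
            length=max(0.0, float(tn.length or 0.0)),
            children=[convert(c) for c in tn.children],
        )
        return node

    root = Node(children=[convert(c) for c in sk.children])
    # ensure a trifurcating root for >=3 taxa (merge a degree-2 root)
    while len(root.children) == 2:
        a, b = root.children
        expand = a if a.children else b
        if not expand.children:
            break
        keep = b if expand is a else a
        keep.length = max(0.0, (keep.length or 0.0) + (expand.length or 0.0))
        root = Node(children=[keep] + expand.children)
    return PhyloTree(root)


def jc_distance_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    """Jukes-Cantor corrected pairwise distances (missing sites ignored)."""
    labels = list(alignment)
    n = len(labels)
    codes = {
        l: np.array([_BASE_INDEX.get(c, -1) for c in alignment[l].upper()])
        for l in labels
    }
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[labels[i]], codes[labels[j]]
            ok = (a >= 0) & (b >= 0)
            if not ok.any():
                p = 0.0
            else:
                p = float(np.mean(a[ok] != b[ok]))
            p = min(p, 0.749)
            dist = -0.75 * np.log(1.0 - 4.0 * p / 3.0) if p > 0 else 0.0
            dm[i, j] = dm[j, i] = dist
    return DistanceMatrix(labels, dm)


# ---------------------------------------------------------------------------
# ML search: branch lengths, kappa, NNI
# ---------------------------------------------------------------------------


def _optimize_branch_lengths(tree: PhyloTree, pruner: _Pruner, model: PhyloModel) -> float:
    best = pruner.loglik(tree, model)
    for node in list(tree.root.walk()):
        if node is tree.root:
            continue

        def neg(t: float, node=node) -> float:
            node.length = t
            return -pruner.loglik(tree, model)

        keep = node.length
        res = minimize_scalar(
            neg, bounds=(MIN_BRANCH, MAX_BRANCH), method="bounded",
            options={"xatol": BRENT_TOL},
        )
        if -res.fun > best:
            node.length = float(res.x)
            best = -res.fun
        else:
            node.length = keep
    return best


def _optimize_kappa(tree: PhyloTree, pruner: _Pruner, model: PhyloModel) -> tuple[PhyloModel, float]:
    best = pruner.loglik(tree, model)

    def neg(k: float) -> float:
        return -pruner.loglik(tree, PhyloModel(k, model.freqs))

    res = minimize_scalar(
        neg, bounds=(0.05, 100.0), method="bounded", options={"xatol": BRENT_TOL}
    )
    if -res.fun > best:
        return PhyloModel(float(res.x), model.freqs), -res.fun
    return model, best


def _nni_candidates(tree: PhyloTree):
    """Yield (tree copy, description) for all NNI rearrangements.

    For each internal edge parent-child there are two alternative quartet
    topologies, obtained by swapping each child subtree of the lower node
    with one fixed sibling subtree of the upper node.
    """
    paths: list[tuple[int, ...]] = []

    def collect(node: Node, path: tuple[int, ...]):
        for i, child in enumerate(node.children):
            if child.children:  # internal child => internal edge
                paths.append(path + (i,))
            collect(child, path + (i,))

    collect(tree.root, ())
    for path in paths:
        for which in (0, 1):
            cand = tree.copy()
            parent = cand.root
            for i in path[:-1]:
                parent = parent.children[i]
            v = parent.children[path[-1]]
            sibling_idx = next(i for i in range(len(parent.children)) if i != path[-1])
            parent.children[sibling_idx], v.children[which] = (
                v.children[which],
                parent.children[sibling_idx],
            )
            yield cand


def ml_search(
    alignment: dict[str, str],
    start: PhyloTree,
    optimize: tuple[str, ...] = ("bl", "kappa", "nni"),
    model: PhyloModel | None = None,
    max_rounds: int = 50,
) -> PhyloTree:
    """Hill-climbing ML tree search under HKY85.

    Each round optimizes every branch length (bounded Brent), then kappa,
    then evaluates all NNI rearrangements and accepts the best improving
    one. Stops when a full round improves the log-likelihood by less than
    the stopping tolerance. The log-likelihood never decreases.
    """
    pruner = _Pruner(alignment)
    if model is None:
        model = PhyloModel(4.0, empirical_frequencies(alignment))
    tree = start.copy()
    for node in tree.root.walk():
        if node is not tree.root and (node.length is None or node.length < MIN_BRANCH):
            node.length = max(MIN_BRANCH, node.length or 0.0)
    best = pruner.loglik(tree, model)

    for _ in range(max_rounds):
        round_start = best
        if "bl" in optimize:
            best = _optimize_branch_lengths(tree, pruner, model)
        if "kappa" in optimize:
            model, best = _optimize_kappa(tree, pruner, model)
        if "nni" in optimize:
            best_cand, best_cand_ll = None, best
            for cand in _nni_candidates(tree):
                ll = pruner.loglik(cand, model)
                if ll > best_cand_ll + STOP_TOL:
                    best_cand, best_cand_ll = cand, ll
            if best_cand is not None:
                tree, best = best_cand, best_cand_ll
        if best - round_start <= STOP_TOL:
            break

    tree.model = model
    tree.loglik = best
    return tree


def bootstrap_supports(
    alignment: dict[str, str],
    n_reps: int,
    seed: int | None = None,
    point_tree: PhyloTree | None = None,
) -> tuple[PhyloTree, dict[frozenset, float]]:
    """Nonparametric bootstrap supports for the point-estimate tree.

    Sites are resampled with replacement; each replicate is run through
    neighbor joining plus a branch-length-only ML polish. Supports are the
    fraction of replicate trees containing each internal bipartition of the
    point tree. Returns (point tree with supports attached, split -> support).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    if point_tree is None:
        point_tree = ml_search(alignment, nj_tree(jc_distance_matrix(alignment)))
    splits = point_tree.bipartitions()
    tally = {s: 0 for s in splits}
    labels = list(alignment)
    length = len(alignment[labels[0]])
    for _ in range(n_reps):
        idx = rng.integers(0, length, size=length)
        rep = {l: "".join(alignment[l][i] for i in idx) for l in labels}
        rep_tree = ml_search(rep, nj_tree(jc_distance_matrix(rep)), optimize=("bl",))
        rep_splits = rep_tree.bipartitions()
        for s in splits:
            if s in rep_splits:
                tally[s] += 1
    supports = {s: tally[s] / n_reps for s in splits}

    out = point_tree.copy()
    anchor = min(out.leaf_names)
    all_leaves = frozenset(out.leaf_names)
    for node in out.root.walk():
        if node is out.root or not node.children:
            continue
        below = frozenset(l.name for l in node.leaves)
        side = below if anchor not in below else all_leaves - below
        if side in supports:
            node.support = supports[side]
    return out, supports
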