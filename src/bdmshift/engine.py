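"""Phylogenetic likelihood engine.

Felsenstein pruning over a fixed topology with discrete-Gamma rate mixing,
per-site log-scaling against underflow, coordinate-wise branch-length
optimization, pairwise ML protein distances, neighbor joining, and
column-resampling bootstrap support.

The inside ("down") partial at a node is the likelihood of the data in its
subtree conditional on the node's state; the outside ("up") partial is the
likelihood of everything else.  Both are carried per rate category with
per-site log scale factors, so reported log-likelihoods are exact regardless
of taxon count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .io import AA_INDEX, Node, Phylogeny, ProteinAlignment, TreeError
from .models import N_STATES, GammaRates, SubstModel

MAX_BRANCH_LENGTH = 20.0
MAX_PAIR_DISTANCE = 20.0


class LikelihoodError(ValueError):
    pass


def encode_states(aln: ProteinAlignment) -> dict[str, np.ndarray]:
    """Map each sequence to integer states; gap/'X' become -1 (missing)."""
    out = {}
    for name, row in zip(aln.names, aln.rows):
        out[name] = np.array([AA_INDEX.get(ch, -1) for ch in row], dtype=np.int64)
    return out


def _leaf_partial(states: np.ndarray, k: int) -> np.ndarray:
    L = states.shape[0]
    F = np.zeros((L, N_STATES))
    observed = states >= 0
    F[observed, states[observed]] = 1.0
    F[~observed, :] = 1.0  # missing data: all states equally compatible
    return np.broadcast_to(F, (k, L, N_STATES)).copy()


def _transition_stack(model: SubstModel, t: float, rates: GammaRates) -> np.ndarray:
    return np.stack([model.transition_matrix(t, r) for r in rates.rates])


def _rescale(F: np.ndarray, logs: np.ndarray) -> None:
    """In-place per-(category, site) max rescaling; accumulates into logs."""
    m = F.max(axis=2)
    if np.any(m <= 0):
        raise LikelihoodError("zero partial likelihood: numerical underflow")
    F /= m[:, :, None]
    logs += np.log(m)


class PruningContext:
    """Holds the inside/outside partials for one (alignment, tree, model) fit."""

    def __init__(
        self,
        aln: ProteinAlignment,
        tree: Phylogeny,
        model: SubstModel,
        rates: GammaRates,
    ):
        tree.bind(aln)
        self.aln = aln
        self.tree = tree
        self.model = model
        self.rates = rates
        self.states = encode_states(aln)
        self.L = aln.L
        self.k = rates.k
        self.F: dict[int, np.ndarray] = {}
        self.logsF: dict[int, np.ndarray] = {}
        self.U: dict[int, np.ndarray] = {}
        self.logsU: dict[int, np.ndarray] = {}

    # -- inside (down) pass ------------------------------------------------

    def _message(self, child: Node) -> tuple[np.ndarray, np.ndarray]:
        """Child's contribution to its parent: M(i) = sum_s P_is F_child(s)."""
        P = _transition_stack(self.model, child.length, self.rates)
        F_c = self.F[child.index]
        M = np.einsum("kis,kls->kli", P, F_c)
        return M, self.logsF[child.index]

    def down(self) -> None:
        for node in self.tree.postorder():
            if node.is_leaf:
                self.F[node.index] = _leaf_partial(self.states[node.name], self.k)
                self.logsF[node.index] = np.zeros((self.k, self.L))
            else:
                F = np.ones((self.k, self.L, N_STATES))
                logs = np.zeros((self.k, self.L))
                for child in node.children:
                    M, logs_c = self._message(child)
                    F *= M
                    logs += logs_c
                _rescale(F, logs)
                self.F[node.index] = F
                self.logsF[node.index] = logs

    # -- outside (up) pass -------------------------------------------------

    def up(self) -> None:
        root = self.tree.root
        self.U[root.index] = np.ones((self.k, self.L, N_STATES))
        self.logsU[root.index] = np.zeros((self.k, self.L))
        for node in self.tree.preorder():
            if node.is_leaf:
                continue
            messages = {c.index: self._message(c) for c in node.children}
            for child in node.children:
                E = self.U[node.index].copy()
                logsE = self.logsU[node.index].copy()
                for other in node.children:
                    if other is child:
                        continue
                    M, logs_o = messages[other.index]
                    E *= M
                    logsE += logs_o
                # U_child(j) = sum_i P_ji(t) E(i): reversibility turns the
                # parent-side conditional into a forward transition
                P = _transition_stack(self.model, child.length, self.rates)
                U = np.einsum("kji,kli->klj", P, E)
                _rescale(U, logsE)
                self.U[child.index] = U
                self.logsU[child.index] = logsE

    # -- likelihood --------------------------------------------------------

    def site_log_likelihoods(self) -> np.ndarray:
        """Per-site log-likelihoods, mixed over rate categories."""
        if not self.F:
            self.down()
        root = self.tree.root.index
        site_cat = self.F[root] @ self.model.pi  # (k, L)
        log_cat = np.log(site_cat) + self.logsF[root] + np.log(1.0 / self.k)
        return logsumexp(log_cat, axis=0)

    def log_likelihood(self) -> float:
        return float(self.site_log_likelihoods().sum())

    def node_posteriors(self, node_index: int) -> np.ndarray:
        """Marginal posterior P(state | data) per site at one node, (L, 20).

        Per-category posteriors are mixed by the per-site posterior weight of
        each rate category (empirical-Bayes weighting).
        """
        if not self.F:
            self.down()
        if not self.U:
            self.up()
        F = self.F[node_index]
        U = self.U[node_index]
        joint = self.model.pi[None, None, :] * F * U  # (k, L, 20)
        site_cat = joint.sum(axis=2)  # (k, L)
        log_cat = (
            np.log(site_cat)
            + self.logsF[node_index]
            + self.logsU[node_index]
            + np.log(1.0 / self.k)
        )
        log_w = log_cat - logsumexp(log_cat, axis=0, keepdims=True)
        post_cat = joint / site_cat[:, :, None]
        return np.einsum("kl,kls->ls", np.exp(log_w), post_cat)


def site_log_likelihood(
    aln: ProteinAlignment, tree: Phylogeny, model: SubstModel, rates: GammaRates
) -> tuple[np.ndarray, float]:
    """Per-site log-likelihoods and the total alignment log-likelihood."""
    ctx = PruningContext(aln, tree, model, rates)
    per_site = ctx.site_log_likelihoods()
    return per_site, float(per_site.sum())


# ---------------------------------------------------------------------------
# branch-length optimization


def _edge_log_likelihood(
    F_child: np.ndarray,
    logs_child: np.ndarray,
    E: np.ndarray,
    logsE: np.ndarray,
    model: SubstModel,
    rates: GammaRates,
    t: float,
) -> float:
    """lnL as a function of one branch length, all other partials fixed."""
    P = _transition_stack(model, t, rates)
    # site likelihood = sum_i pi_i E(i) (F_child @ P^T)(i)
    M = np.einsum("kis,kls->kli", P, F_child)
    site_cat = np.einsum("kli,kli,i->kl", E, M, model.pi)
    log_cat = np.log(site_cat) + logs_child + logsE + np.log(1.0 / rates.k)
    return float(logsumexp(log_cat, axis=0).sum())


@dataclass
class BranchFit:
    tree: Phylogeny
    lnL: float
    converged: bool


def optimize_branch_lengths(
    aln: ProteinAlignment,
    tree: Phylogeny,
    model: SubstModel,
    rates: GammaRates,
    tol: float = 1e-6,
    max_cycles: int = 25,
    max_length: float = MAX_BRANCH_LENGTH,
) -> tuple[Phylogeny, float, bool]:
    """Optimize every branch length on the fixed topology.

    Coordinate-wise bounded scalar optimization in pre-order sweeps; each
    one-dimensional step maximizes the exact current likelihood, so the total
    log-likelihood is non-decreasing.  Returns (tree copy, lnL, converged);
    non-convergence after ``max_cycles`` sweeps sets the flag and warns
    rather than raising.
    """
    tree = tree.copy()
    ctx = PruningContext(aln, tree, model, rates)
    ctx.down()
    lnL = ctx.log_likelihood()
    converged = False
    for _ in range(max_cycles):
        ctx.F.clear()
        ctx.logsF.clear()
        ctx.down()
        U: dict[int, np.ndarray] = {
            tree.root.index: np.ones((ctx.k, ctx.L, N_STATES))
        }
        logsU: dict[int, np.ndarray] = {tree.root.index: np.zeros((ctx.k, ctx.L))}
        for node in tree.preorder():
            if node.is_leaf:
                continue
            for child in node.children:
                E = U[node.index].copy()
                logsE = logsU[node.index].copy()
                for other in node.children:
                    if other is child:
                        continue
                    M, logs_o = ctx._message(other)
                    E *= M
                    logsE += logs_o
                F_c = ctx.F[child.index]
                logs_c = ctx.logsF[child.index]

                def objective(t: float) -> float:
                    return -_edge_log_likelihood(
                        F_c, logs_c, E, logsE, model, rates, t
                    )

                res = minimize_scalar(
                    objective,
                    bounds=(0.0, max_length),
                    method="bounded",
                    options={"xatol": 1e-10},
                )
                if -res.fun > -objective(child.length):
                    child.length = float(res.x)
                # outside partial for the child under the accepted length
                P = _transition_stack(model, child.length, rates)
                U_c = np.einsum("kji,kli->klj", P, E)
                _rescale(U_c, logsE)
                U[child.index] = U_c
                logsU[child.index] = logsE
        ctx.F.clear()
        ctx.logsF.clear()
        new_lnL = PruningContext(aln, tree, model, rates).log_likelihood()
        if abs(new_lnL - lnL) < tol:
            lnL = new_lnL
            converged = True
            break
        lnL = new_lnL
    if not converged:
        warnings.warn("branch-length optimization did not converge", stacklevel=2)
    return tree, lnL, converged


# ---------------------------------------------------------------------------
# pairwise ML distances


@dataclass
class DistanceMatrix:
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.names), len(self.names)):
            raise ValueError("distance matrix shape does not match names")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.names.index(a), self.names.index(b)])


def _pair_distance(
    counts: np.ndarray, model: SubstModel, rates: GammaRates
) -> float:
    """ML distance from a 20x20 matrix of aligned residue-pair counts."""

    def neg_lnL(t: float) -> float:
        mix = np.zeros((N_STATES, N_STATES))
        for r, w in zip(rates.rates, rates.weights):
            mix += w * model.transition_matrix(t, r)
        joint = model.pi[:, None] * mix
        with np.errstate(divide="ignore"):
            logj = np.log(joint)
        return -float(np.sum(counts * np.where(counts > 0, logj, 0.0)))

    res = minimize_scalar(
        neg_lnL, bounds=(0.0, MAX_PAIR_DISTANCE), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x) if neg_lnL(0.0) > res.fun else 0.0


def protein_distance(
    aln: ProteinAlignment,
    model: SubstModel,
    rates: GammaRates,
    gap_mode: str = "pairwise",
) -> DistanceMatrix:
    """Pairwise ML distances under model+Gamma.

    ``gap_mode='pairwise'`` drops, per pair, sites where either sequence has
    a gap or 'X'; ``'complete'`` drops such columns for all pairs.  Pairs
    with no comparable sites get the configured maximum distance and a
    warning.
    """
    if aln.N < 2:
        raise ValueError("need at least 2 sequences")
    states = encode_states(aln)
    arr = np.stack([states[n] for n in aln.names])
    if gap_mode == "complete":
        keep = np.all(arr >= 0, axis=0)
        arr = arr[:, keep]
    elif gap_mode != "pairwise":
        raise ValueError(f"unknown gap mode {gap_mode!r}")
    n = aln.N
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] >= 0) & (arr[j] >= 0)
            if not np.any(ok):
                warnings.warn(
                    f"no comparable sites between {aln.names[i]!r} and "
                    f"{aln.names[j]!r}; distance set to maximum",
                    stacklevel=2,
                )
                D[i, j] = D[j, i] = MAX_PAIR_DISTANCE
                continue
            pairs = arr[i][ok] * N_STATES + arr[j][ok]
            counts = np.bincount(pairs, minlength=N_STATES * N_STATES).reshape(
                N_STATES, N_STATES
            )
            D[i, j] = D[j, i] = _pair_distance(counts.astype(float), model, rates)
    return DistanceMatrix(list(aln.names), D)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dist: DistanceMatrix, offset: int = 0) -> Phylogeny:
    """Classic Saitou–Nei neighbor joining.

    Negative intermediate branch lengths are clamped to 0 with the excess
    transferred to the sibling branch, so output lengths are nonnegative and
    the pair's path length is preserved.  The result is an unrooted tree
    represented with a trifurcating root.
    """
    n = len(dist.names)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dist.values.copy()
    nodes: list[Node] = [Node(index=-1, name=name) for name in dist.names]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(q), q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = d_ij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = Node(index=-1)
        for child, length in ((nodes[i], li), (nodes[j], lj)):
            child.length = max(length, 0.0)
            child.parent = parent
            parent.children.append(child)
        new = len(nodes)
        nodes.append(parent)
        D = np.pad(D, ((0, 1), (0, 1)))
        for x in active:
            if x in (i, j):
                continue
            D[new, x] = D[x, new] = 0.5 * (D[i, x] + D[j, x] - d_ij)
        active = [x for x in active if x not in (i, j)] + [new]
    # resolve the final three around an unrooted center
    a, b, c = active
    root = Node(index=-1)
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(length, 0.0)
        nodes[idx].parent = root
        root.children.append(nodes[idx])
    renumber_postorder(root, offset)
    return Phylogeny(root)


def renumber_postorder(root: Node, offset: int = 0) -> None:
    counter = offset
    stack: list[tuple[Node, bool]] = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            node.index = counter
            counter += 1
        else:
            stack.append((node, True))
            for child in reversed(node.children):
                stack.append((child, False))


# ---------------------------------------------------------------------------
# bootstrap support


def leaf_splits(tree: Phylogeny) -> dict[int, frozenset[str]]:
    """Nontrivial leaf bipartitions keyed by the child node of each edge.

    Splits are canonicalized as the side not containing the alphabetically
    first leaf, so they compare equal across rootings.
    """
    all_leaves = frozenset(tree.leaf_names)
    anchor = min(all_leaves)
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[node.index] = frozenset([node.name])
        else:
            below[node.index] = frozenset().union(
                *(below[c.index] for c in node.children)
            )
    splits = {}
    for parent, child in tree.branches():
        side = below[child.index]
        if len(side) <= 1 or len(all_leaves - side) <= 1:
            continue
        if anchor in side:
            side = all_leaves - side
        splits[child.index] = side
    return splits


def bootstrap_support(
    aln: ProteinAlignment,
    model: SubstModel,
    rates: GammaRates,
    B: int,
    seed: int,
    tree: Phylogeny | None = None,
    gap_mode: str = "pairwise",
) -> dict[int, float]:
    """Column-resampling bootstrap support for NJ internal edges.

    Returns support percentages keyed by the child node id of each internal
    edge of the reference tree (the NJ tree on the full alignment unless a
    tree is supplied).
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    if tree is None:
        tree = nj_tree(protein_distance(aln, model, rates, gap_mode))
    reference = leaf_splits(tree)
    counts = {k: 0 for k in reference}
    rng = np.random.default_rng(seed)
    for _ in range(B):
        cols = rng.integers(0, aln.L, size=aln.L)
        rows = ["".join(row[c] for c in cols) for row in aln.rows]
        rep_aln = ProteinAlignment(list(aln.names), rows)
        rep_tree = nj_tree(protein_distance(rep_aln, model, rates, gap_mode))
        rep_splits = set(leaf_splits(rep_tree).values())
        for key, split in reference.items():
            if split in rep_splits:
                counts[key] += 1
    return {k: 100.0 * v / B for k, v in counts.items()}
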