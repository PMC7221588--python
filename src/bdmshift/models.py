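"""Empirical amino-acid substitution models and rate heterogeneity.

Provides the WAG and JTT replacement models as time-reversible rate matrices
(Q_ij = S_ij * pi_j, scaled to one expected substitution per unit time at
equilibrium), discrete-Gamma among-site rate variation, transition
probability matrices via spectral decomposition, and BIC-based model
selection.  BLOSUM62 is exposed as an integer score matrix for the
replacement-difference measure built on top of it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .io import AMINO_ACIDS, ProteinAlignment, Phylogeny

N_STATES = 20


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class SubstModel:
    """Time-reversible amino-acid substitution model.

    ``S`` is the symmetric exchangeability matrix, ``pi`` the stationary
    frequencies and ``Q`` the rate matrix, scaled so that the expected rate
    at equilibrium is exactly 1 substitution/site/unit time.
    """

    name: str
    S: np.ndarray
    pi: np.ndarray
    Q: np.ndarray
    # spectral decomposition of the pi-symmetrized rate matrix, cached for
    # fast transition-matrix evaluation
    _evals: np.ndarray
    _left: np.ndarray
    _right: np.ndarray

    @classmethod
    def from_exchangeabilities(
        cls, name: str, S: np.ndarray, pi: np.ndarray
    ) -> "SubstModel":
        S = np.asarray(S, dtype=float)
        pi = np.asarray(pi, dtype=float)
        if S.shape != (N_STATES, N_STATES) or not np.allclose(S, S.T):
            raise ModelError("exchangeability matrix must be symmetric 20x20")
        if pi.shape != (N_STATES,) or np.any(pi <= 0):
            raise ModelError("stationary frequencies must be 20 positive values")
        pi = pi / pi.sum()
        Q = S * pi[np.newaxis, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(pi @ np.diag(Q))
        Q = Q / mu
        # B = D^1/2 Q D^-1/2 is symmetric for reversible Q: real spectrum
        sqrt_pi = np.sqrt(pi)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        evals, U = np.linalg.eigh((B + B.T) / 2.0)
        right = (1.0 / sqrt_pi)[:, None] * U
        left = U.T * sqrt_pi[None, :]
        return cls(name, S, pi, Q, evals, left, right)

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(rt) = exp(Q * rate * t); rows sum to 1."""
        if t < 0:
            raise ModelError(f"branch length must be >= 0, got {t}")
        if rate <= 0:
            raise ModelError(f"rate must be > 0, got {rate}")
        P = (self._right * np.exp(self._evals * (t * rate))) @ self._left
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


@dataclass(frozen=True)
class GammaRates:
    """Discrete Gamma(alpha) rate categories with equal weights and mean 1."""

    alpha: float
    k: int
    rates: np.ndarray

    @property
    def weights(self) -> np.ndarray:
        return np.full(self.k, 1.0 / self.k)


def discretize_gamma(alpha: float, k: int, method: str = "mean") -> GammaRates:
    """Discretize Gamma(alpha, mean 1) into ``k`` equiprobable categories.

    ``method='mean'`` uses the conditional mean of each quantile bin, which
    preserves an overall mean of exactly 1; ``method='median'`` uses the bin
    medians rescaled to mean 1 (matching tools that discretize that way).
    """
    if alpha <= 0:
        raise ModelError(f"gamma shape must be > 0, got {alpha}")
    if k < 1:
        raise ModelError(f"category count must be >= 1, got {k}")
    if k == 1:
        return GammaRates(alpha, 1, np.array([1.0]))
    if method == "mean":
        # bin boundaries at quantiles i/k of Gamma(alpha, scale=1/alpha);
        # conditional mean of bin i follows from the regularized incomplete
        # gamma of shape alpha+1 (Yang's mean-of-bin construction)
        bounds = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
        upper = np.concatenate([gammainc(alpha + 1.0, alpha * bounds), [1.0]])
        lower = np.concatenate([[0.0], gammainc(alpha + 1.0, alpha * bounds)])
        rates = k * (upper - lower)
    elif method == "median":
        rates = gamma_dist.ppf((2 * np.arange(k) + 1) / (2 * k), a=alpha, scale=1.0 / alpha)
    else:
        raise ModelError(f"unknown discretization method {method!r}")
    rates = rates / rates.mean()
    return GammaRates(alpha, k, rates)


UNIFORM_RATES = GammaRates(alpha=float("inf"), k=1, rates=np.array([1.0]))


# ---------------------------------------------------------------------------
# bundled model tables (PAML dat layout: 19 lower-triangle rows, blank line,
# stationary frequencies)


def _read_dat(text: str) -> tuple[np.ndarray, np.ndarray]:
    chunks = [ln.split() for ln in text.splitlines() if ln.strip()]
    S = np.zeros((N_STATES, N_STATES))
    for i in range(1, N_STATES):
        row = [float(x) for x in chunks[i - 1]]
        if len(row) != i:
            raise ModelError(f"malformed dat file: row {i} has {len(row)} entries")
        S[i, :i] = row
        S[:i, i] = row
    pi = np.array([float(x) for x in chunks[N_STATES - 1]])
    if pi.shape != (N_STATES,):
        raise ModelError("malformed dat file: frequency line")
    return S, pi


def load_model(name: str) -> SubstModel:
    """Load a bundled empirical model ('WAG' or 'JTT') or a dat-file path."""
    key = name.upper()
    if key in ("WAG", "JTT"):
        text = (
            resources.files("bdmshift.data").joinpath(f"{key.lower()}.dat").read_text()
        )
    else:
        with open(name) as fh:
            text = fh.read()
        key = name
    S, pi = _read_dat(text)
    return SubstModel.from_exchangeabilities(key, S, pi)


def load_model_with_frequencies(name: str, aln: ProteinAlignment) -> SubstModel:
    """Empirical (+F) variant: model exchangeabilities with observed frequencies."""
    base = load_model(name)
    counts = np.zeros(N_STATES)
    for row in aln.rows:
        for ch in row:
            idx = AMINO_ACIDS.find(ch)
            if idx >= 0:
                counts[idx] += 1
    if counts.sum() == 0:
        raise ModelError("alignment has no residues to estimate frequencies from")
    counts = np.maximum(counts, 0.5)  # pseudocount avoids zero frequencies
    return SubstModel.from_exchangeabilities(base.name + "+F", base.S, counts / counts.sum())


# ---------------------------------------------------------------------------
# BLOSUM62 score matrix


@dataclass(frozen=True)
class ScoreMatrix:
    """Symmetric integer substitution score matrix over the 20 amino acids."""

    labels: str
    scores: np.ndarray

    def score(self, a: str, b: str) -> int:
        return int(self.scores[self.labels.index(a), self.labels.index(b)])


def load_blosum62() -> ScoreMatrix:
    raw = substitution_matrices.load("BLOSUM62")
    scores = np.zeros((N_STATES, N_STATES), dtype=int)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            scores[i, j] = int(raw[a, b])
    return ScoreMatrix(AMINO_ACIDS, scores)


def read_score_matrix(path) -> ScoreMatrix:
    """Read an NCBI-format substitution matrix text file (e.g. BLOSUM62)."""
    with open(path) as fh:
        lines = [ln.rstrip() for ln in fh if ln.strip() and not ln.startswith("#")]
    header = lines[0].split()
    cols = {label: i for i, label in enumerate(header)}
    missing = [a for a in AMINO_ACIDS if a not in cols]
    if missing:
        raise ModelError(f"matrix file lacks columns for {missing}")
    table: dict[str, list[str]] = {}
    for ln in lines[1:]:
        parts = ln.split()
        table[parts[0]] = parts[1:]
    scores = np.zeros((N_STATES, N_STATES), dtype=int)
    for i, a in enumerate(AMINO_ACIDS):
        if a not in table:
            raise ModelError(f"matrix file lacks a row for {a}")
        for j, b in enumerate(AMINO_ACIDS):
            scores[i, j] = int(table[a][cols[b]])
    if not np.array_equal(scores, scores.T):
        raise ModelError("score matrix is not symmetric")
    return ScoreMatrix(AMINO_ACIDS, scores)


# ---------------------------------------------------------------------------
# model selection


def model_select(
    aln: ProteinAlignment,
    tree: Phylogeny,
    candidates: list[tuple[str, bool]],
    gamma_alpha: float = 1.1990,
    gamma_cats: int = 2,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """Rank substitution-model candidates by BIC on a fixed topology.

    Each candidate is ``(model name, gamma on/off)``.  Branch lengths are
    re-optimized per candidate; the Gamma shape is profiled over a coarse
    grid when the +G flag is set.  BIC = -2 lnL + p ln(n) with n = alignment
    columns and p = free parameters (branch lengths, plus alpha under +G).
    """
    from .engine import optimize_branch_lengths

    if not candidates:
        raise ModelError("candidate list is empty")
    n_branches = sum(1 for node in tree.postorder() if node.parent is not None)
    n_cols = aln.L
    rows = []
    for name, with_gamma in candidates:
        model = load_model(name)
        if with_gamma:
            best = None
            for alpha in (0.3, 0.6, gamma_alpha, 2.0, 5.0):
                rates = discretize_gamma(alpha, gamma_cats)
                fit_tree, lnL, _ = optimize_branch_lengths(
                    aln, tree.copy(), model, rates, tol=tol
                )
                if best is None or lnL > best[0]:
                    best = (lnL, alpha)
            lnL, alpha = best
            p = n_branches + 1
            label = f"{name}+G"
        else:
            _, lnL, _ = optimize_branch_lengths(
                aln, tree.copy(), model, UNIFORM_RATES, tol=tol
            )
            p = n_branches
            alpha = math.nan
            label = name
        rows.append(
            {
                "model": label,
                "lnL": lnL,
                "alpha": alpha,
                "params": p,
                "BIC": -2.0 * lnL + p * math.log(n_cols),
            }
        )
    return (
        pd.DataFrame(rows).sort_values("BIC", kind="stable").reset_index(drop=True)
    )


def bic(lnL: float, n_params: int, n_obs: int) -> float:
    """Bayesian Information Criterion: -2 lnL + p ln(n)."""
    return -2.0 * lnL + n_params * math.log(n_obs)
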