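"""Shared continuous-time Markov chain machinery on trees.

Felsenstein pruning and marginal (up–down) ancestral reconstruction for
an arbitrary dense generator over a finite state space. Transition
matrices exp(Q·b) come from a spectral decomposition of Q computed once
per likelihood evaluation (with a scaling-and-squaring fallback when the
eigenbasis is ill-conditioned), cached per branch length.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .trees import Node, Phylogeny

__all__ = ["Propagator", "pruning_loglik", "marginal_ancestral"]

_EIG_COND_MAX = 1e10
_TINY = 1e-300


class Propagator:
    """exp(Q·t) provider for a fixed generator Q."""

    def __init__(self, Q: np.ndarray):
        Q = np.asarray(Q, dtype=float)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
            raise ValueError("Q must be square")
        if np.abs(Q.sum(axis=1)).max() > 1e-8:
            raise ValueError("generator rows must sum to 0")
        self.Q = Q
        self.n_states = Q.shape[0]
        self._cache: dict[float, np.ndarray] = {}
        self._eig = None
        try:
            d, V = linalg.eig(Q)
            if np.linalg.cond(V) < _EIG_COND_MAX:
                Vinv = linalg.inv(V)
                # accept the spectral basis only if it reproduces Q
                err = np.abs(np.real((V * d) @ Vinv) - Q).max()
                scale = max(np.abs(Q).max(), 1.0)
                if err <= 1e-9 * scale:
                    self._eig = (d, V, Vinv)
        except linalg.LinAlgError:
            pass

    def _finalize(self, P: np.ndarray, t: float) -> np.ndarray:
        np.clip(P, 0.0, None, out=P)
        rows = P.sum(axis=1, keepdims=True)
        if np.abs(rows - 1.0).max() > 1e-6:
            # spectral route degraded; fall back to expm for this t
            P = linalg.expm(self.Q * t)
            np.clip(P, 0.0, None, out=P)
            rows = P.sum(axis=1, keepdims=True)
        P /= rows
        return P

    def __call__(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("negative branch length")
        P = self._cache.get(t)
        if P is None:
            if t == 0.0:
                P = np.eye(self.n_states)
            elif self._eig is not None:
                d, V, Vinv = self._eig
                P = np.real((V * np.exp(d * t)) @ Vinv)
            else:
                P = linalg.expm(self.Q * t)
            P = self._finalize(P, t)
            self._cache[t] = P
        return P

    def matvec(self, t: float, v: np.ndarray) -> np.ndarray:
        """exp(Q·t) @ v in O(k²) via the spectral basis (exact up to the
        decomposition; tiny negative entries are clipped)."""
        if self._eig is None or t == 0.0:
            return self(t) @ v
        d, V, Vinv = self._eig
        out = np.real(V @ (np.exp(d * t) * (Vinv @ v)))
        return np.clip(out, 0.0, None)

    def vecmat(self, t: float, v: np.ndarray) -> np.ndarray:
        """v @ exp(Q·t) in O(k²) via the spectral basis."""
        if self._eig is None or t == 0.0:
            return v @ self(t)
        d, V, Vinv = self._eig
        out = np.real(((v @ V) * np.exp(d * t)) @ Vinv)
        return np.clip(out, 0.0, None)

    def precompute(self, ts) -> None:
        """Batch-fill the cache for many branch lengths at once (one
        einsum over the spectral basis instead of a matmul per t)."""
        ts = [t for t in set(float(t) for t in ts)
              if t not in self._cache and t > 0]
        if not ts or self._eig is None:
            return
        d, V, Vinv = self._eig
        expdt = np.exp(np.multiply.outer(np.asarray(ts), d))  # (T, k)
        Ps = np.real(np.einsum("ij,tj,jk->tik", V, expdt, Vinv,
                               optimize=True))
        for t, P in zip(ts, Ps):
            self._cache[t] = self._finalize(P, t)


def _tip_vector(n_states: int, state_idx: int) -> np.ndarray:
    v = np.zeros(n_states)
    v[state_idx] = 1.0
    return v


def _downpass(tree: Phylogeny, tip_idx: dict[str, int], prop: Propagator
              ) -> tuple[dict[Node, np.ndarray], dict[Node, np.ndarray], float]:
    """Scaled conditional likelihoods D_v(j) = P(data below v | v = j).

    Returns (D, child messages M_v(i) = Σ_j P_v[i,j] D_v(j), total log
    scale factor).
    """
    k = prop.n_states
    D: dict[Node, np.ndarray] = {}
    M: dict[Node, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder():
        if node.is_leaf:
            if node.name not in tip_idx:
                raise ValueError(f"no state for tip {node.name!r}")
            d = _tip_vector(k, tip_idx[node.name])
        else:
            d = np.ones(k)
            for c in node.children:
                d = d * M[c]
            s = d.max()
            if s <= 0:
                # data impossible under this model
                D[node] = d
                return D, M, -np.inf
            d = d / s
            log_scale += np.log(s)
        D[node] = d
        if node is not tree.root:
            M[node] = prop.matvec(node.length, d)
    return D, M, log_scale


def pruning_loglik(tree: Phylogeny, tip_states: dict[str, int],
                   Q: np.ndarray | Propagator,
                   root_prior: np.ndarray | None = None) -> float:
    """Felsenstein pruning log-likelihood of discrete tip states.

    ``tip_states`` maps tip labels to state indices into Q's state
    space; ``root_prior`` defaults to uniform.
    """
    prop = Q if isinstance(Q, Propagator) else Propagator(Q)
    prior = _root_prior(prop.n_states, root_prior)
    D, _, log_scale = _downpass(tree, tip_states, prop)
    if not np.isfinite(log_scale):
        return -np.inf
    like = float(prior @ D[tree.root])
    if like <= 0:
        return -np.inf
    return np.log(like) + log_scale


def marginal_ancestral(tree: Phylogeny, tip_states: dict[str, int],
                       Q: np.ndarray | Propagator,
                       root_prior: np.ndarray | None = None
                       ) -> dict[Node, np.ndarray]:
    """Marginal posterior state distribution at every internal node,
    by the standard up–down (inside–outside) recursion."""
    prop = Q if isinstance(Q, Propagator) else Propagator(Q)
    prior = _root_prior(prop.n_states, root_prior)
    D, M, log_scale = _downpass(tree, tip_states, prop)
    if not np.isfinite(log_scale):
        raise ValueError("zero-probability data under this model")

    out: dict[Node, np.ndarray] = {tree.root: prior.copy()}
    marginals: dict[Node, np.ndarray] = {}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        post = out[node] * D[node]
        total = post.sum()
        if total <= 0:
            raise ValueError("zero-probability data at an internal node")
        marginals[node] = post / total
        for c in node.children:
            sib = out[node].copy()
            for s in node.children:
                if s is not c:
                    sib *= M[s]
            oc = prop.vecmat(c.length, sib)
            s = oc.sum()
            out[c] = oc / s if s > 0 else oc
    return marginals


def _root_prior(n_states: int, root_prior: np.ndarray | None) -> np.ndarray:
    if root_prior is None:
        return np.full(n_states, 1.0 / n_states)
    prior = np.asarray(root_prior, dtype=float)
    if prior.shape != (n_states,):
        raise ValueError("root prior has wrong length")
    if not np.isclose(prior.sum(), 1.0):
        raise ValueError("root prior must sum to 1")
    return prior
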