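"""Greedy detection of clade-level Brownian rate shifts.

A one-rate BM fit is compared with two-rate models in which every branch
of a candidate clade (stem branch included) evolves at a multiplicative
rate scalar. The search is greedy-forward: at each step the best
candidate node is accepted if it improves AICc by more than a cut-off
(defaults 4, with 9 as the conservative alternative), and its clade's
rate becomes part of the background for later steps. Branches keep the
rate of their nearest enclosing accepted shift, so later, more inclusive
shifts do not overwrite earlier nested ones.

Each accepted shift adds two parameters by default (rate scalar + shift
location, the MEDUSA convention); set ``shift_k=1`` to count only the
scalar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .trait_models import aicc, gls_fit
from .trees import Node, Phylogeny

__all__ = ["Shift", "ShiftModel", "ShiftScan", "scan_shifts"]

_LOG10_RATE_BOUND = 4.0  # rate scalars searched in [1e-4, 1e4]


@dataclass(frozen=True)
class Shift:
    node: Node
    rate: float
    clade_id: tuple[str, str]  # smallest tip of each child subtree


@dataclass
class ShiftModel:
    shifts: list[Shift]
    sigma2: float
    root_state: float
    lnl: float
    k: int
    n: int

    @property
    def aicc(self) -> float:
        return aicc(self.lnl, self.k, self.n)


@dataclass
class ShiftScan:
    """Sequence of nested models from the greedy search; ``models[0]``
    is the one-rate BM fit and each later entry adds one accepted
    shift."""
    models: list[ShiftModel]
    steps: list[dict] = field(default_factory=list)

    @property
    def best(self) -> ShiftModel:
        return self.models[-1]


class _BranchSystem:
    """Branch-indexed representation: C(w) = Uᵀ diag(w ∘ len) U, where
    row b of U flags the tips below branch b."""

    def __init__(self, tree: Phylogeny):
        if not tree.is_binary():
            raise ValueError("rate-shift scan requires a binary tree "
                             "(resolve polytomies first)")
        self.tree = tree
        tips = tree.tips()
        tip_index = {t: i for i, t in enumerate(tips)}
        self.n = len(tips)
        branches = [n for n in tree.postorder() if n is not tree.root]
        self.branches = branches
        self.branch_index = {node: b for b, node in enumerate(branches)}
        self.lengths = np.array([n.length for n in branches])
        U = np.zeros((len(branches), self.n))
        below: dict[Node, list[int]] = {}
        for node in tree.postorder():
            if node.is_leaf:
                below[node] = [tip_index[node]]
            else:
                below[node] = [i for c in node.children for i in below[c]]
            if node is not tree.root:
                U[self.branch_index[node], below[node]] = 1.0
        self.U = U
        self.below = below
        # branch indices of each internal node's clade, stem included
        self.clade_branches: dict[Node, np.ndarray] = {}
        for node in tree.internal_nodes(exclude_root=True):
            idx = [self.branch_index[node]]
            stack = list(node.children)
            while stack:
                x = stack.pop()
                idx.append(self.branch_index[x])
                stack.extend(x.children)
            self.clade_branches[node] = np.array(sorted(idx))

    def cov(self, w: np.ndarray) -> np.ndarray:
        M = self.U.T * (w * self.lengths)
        return M @ self.U

    def rate_vector(self, shifts: list[Shift]) -> np.ndarray:
        """Per-branch rates: each branch takes the rate of its nearest
        enclosing shift (most tipward wins), background rate 1."""
        w = np.ones(len(self.branches))
        governed = np.zeros(len(self.branches), dtype=bool)
        inner_first = sorted(shifts,
                             key=lambda s: self.clade_branches[s.node].size)
        for shift in inner_first:
            idx = self.clade_branches[shift.node]
            free = idx[~governed[idx]]
            w[free] = shift.rate
            governed[free] = True
        return w


def _clade_id(node: Node) -> tuple[str, str]:
    def min_tip(x: Node) -> str:
        return min(t.name for t in _tips_of(x))
    return tuple(sorted(min_tip(c) for c in node.children[:2]))


def _tips_of(node: Node):
    stack, out = [node], []
    while stack:
        x = stack.pop()
        if x.is_leaf:
            out.append(x)
        else:
            stack.extend(x.children)
    return out


def _fit(system: _BranchSystem, y: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    try:
        return gls_fit(system.cov(w), y)
    except (np.linalg.LinAlgError, ValueError):
        return np.nan, np.nan, -np.inf


def scan_shifts(tree: Phylogeny, y: np.ndarray, cutoff: float = 4.0,
                max_shifts: int | None = None, shift_k: int = 2,
                min_clade_tips: int = 5) -> ShiftScan:
    """Greedy forward search for clade rate shifts.

    Returns the nested model sequence; ``steps`` records, per iteration,
    the best candidate and whether it cleared the AICc cut-off.
    ``min_clade_tips`` excludes very small clades from the candidate
    set: a near-zero rate fitted to a cherry or triplet of similar tips
    collapses the clade's variance and clears any fixed AICc cut-off
    far too easily, so tiny clades are not scanned by default (set 1
    for an exhaustive scan).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    y = np.asarray(y, dtype=float)
    system = _BranchSystem(tree)
    n = system.n
    if n < 4:
        raise ValueError("need at least 4 tips")
    if max_shifts is None:
        max_shifts = max(1, n // 10)

    root_state, sigma2, lnl = _fit(system, y, np.ones(len(system.branches)))
    base = ShiftModel([], sigma2, root_state, lnl, k=2, n=n)
    scan = ShiftScan([base])
    candidates = [
        node for node in system.clade_branches
        if (system.clade_branches[node].size + 1) // 2 >= min_clade_tips
    ]

    while len(scan.best.shifts) < max_shifts:
        current = scan.best
        w_cur = system.rate_vector(current.shifts)
        taken = {s.node for s in current.shifts}

        best = None  # (aicc, order, node, rate, lnl)
        for order, node in enumerate(candidates):
            if node in taken:
                continue
            idx = system.clade_branches[node]
            # branches already governed by a shift nested inside this
            # candidate keep their own rate (most tipward wins)
            nested = np.zeros(len(system.branches), dtype=bool)
            clade_set = set(idx.tolist())
            for s in current.shifts:
                if system.branch_index[s.node] in clade_set:
                    nested[system.clade_branches[s.node]] = True
            free = idx[~nested[idx]]
            if free.size == 0:
                continue

            def neg_lnl(log10_r: float) -> float:
                w = w_cur.copy()
                w[free] = 10.0 ** log10_r
                return -_fit(system, y, w)[2]

            res = optimize.minimize_scalar(
                neg_lnl, bounds=(-_LOG10_RATE_BOUND, _LOG10_RATE_BOUND),
                method="bounded", options={"xatol": 1e-4})
            cand_lnl = -res.fun
            cand_aicc = aicc(cand_lnl, current.k + shift_k, n)
            key = (cand_aicc, order)
            if best is None or key < best[0]:
                best = (key, node, 10.0 ** float(res.x), cand_lnl)

        if best is None:
            break
        (best_aicc, _), node, rate, cand_lnl = best
        accepted = best_aicc < current.aicc - cutoff
        scan.steps.append({
            "step": len(scan.steps) + 1,
            "node": _clade_id(node),
            "rate": rate,
            "lnl": cand_lnl,
            "aicc": best_aicc,
            "accepted": accepted,
        })
        if not accepted:
            break

        shifts = current.shifts + [Shift(node, rate, _clade_id(node))]
        shifts = _refine(system, y, shifts)
        w = system.rate_vector(shifts)
        root_state, sigma2, lnl = _fit(system, y, w)
        scan.models.append(
            ShiftModel(shifts, sigma2, root_state, lnl,
                       k=2 + shift_k * len(shifts), n=n))
    return scan


def _refine(system: _BranchSystem, y: np.ndarray,
            shifts: list[Shift]) -> list[Shift]:
    """Joint re-optimization of all accepted rate scalars."""
    if not shifts:
        return shifts
    x0 = np.log10([s.rate for s in shifts])

    def neg_lnl(x: np.ndarray) -> float:
        x = np.clip(x, -_LOG10_RATE_BOUND, _LOG10_RATE_BOUND)
        trial = [Shift(s.node, 10.0 ** xi, s.clade_id)
                 for s, xi in zip(shifts, x)]
        return -_fit(system, y, system.rate_vector(trial))[2]

    res = optimize.minimize(neg_lnl, x0, method="Nelder-Mead",
                            options={"xatol": 1e-5, "fatol": 1e-8,
                                     "maxiter": 400 * len(shifts)})
    x = np.clip(res.x, -_LOG10_RATE_BOUND, _LOG10_RATE_BOUND)
    return [Shift(s.node, 10.0 ** xi, s.clade_id) for s, xi in zip(shifts, x)]
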