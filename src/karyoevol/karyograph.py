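"""Bidimensional karyotype evolution on the karyograph.

A karyotype is summarized by the haploid chromosome number ``y`` and the
haploid arm count ``x`` (the fundamental number divided by two). Every
chromosome has one arm (telocentric) or two (meta-/submeta-/
subtelocentric), so valid states satisfy ``y ≤ x ≤ 2y``: there are
``2y − x`` uni-armed and ``x − y`` bi-armed chromosomes. Karyotype
change is a walk on this grid:

* Robertsonian **fusion** of two uni-armed chromosomes, (y, x) → (y−1, x),
  rate ``k1 · (2y − x)`` (needs at least two uni-armed);
* centric **fission** of a bi-armed chromosome, (y, x) → (y+1, x),
  rate ``k2 · (x − y)``;
* **telo→meta transition** (arm gain, e.g. pericentric inversion /
  heterochromatin growth), (y, x) → (y, x+1), rate ``k3 · (2y − x)``;
* **meta→telo transition** (arm loss), (y, x) → (y, x−1), rate
  ``k4 · (x − y)``;
* **polyploidization** (y, x) → (2y, 2x), rate ``k5`` (model M2 only;
  M1 omits the parameter structurally).

The rate laws scale with the number of eligible chromosomes; pass
``multiplier="constant"`` for per-karyotype-constant rates instead.

The chain is embedded in a multi-state speciation–extinction (SSE)
likelihood with speciation rate λ and extinction rate μ shared by all
states. Because λ and μ are state-independent, the SSE branch equations
factorize exactly into the plain CTMC propagator times a closed-form
birth–death factor; that factorized likelihood is the default
(``method="exact"``), with an adaptive Runge–Kutta integration of the
full FitzJohn D/E system available as ``method="ode"`` for
cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from ._ctmc import Propagator, marginal_ancestral, pruning_loglik
from .chromevol import AncestralReconstruction
from .trees import Node, Phylogeny

__all__ = [
    "SseParams",
    "SseFit",
    "LrtResult",
    "enumerate_states",
    "build_q",
    "musse_loglik",
    "lrt_statistic",
    "fit_m1_m2",
    "fit_sse",
    "ancestral_karyograph",
    "ancestral_summary",
    "default_y_max",
]


@dataclass(frozen=True)
class SseParams:
    """Karyograph SSE rates. ``k5=None`` marks the polyploidy-free M1
    model (the parameter is structurally absent, not merely zero)."""

    k1: float = 0.0   # fusion
    k2: float = 0.0   # fission
    k3: float = 0.0   # telo -> meta (arm gain)
    k4: float = 0.0   # meta -> telo (arm loss)
    k5: float | None = None  # polyploidization (M2 only)
    lam: float = 0.0  # speciation
    mu: float = 0.0   # extinction

    def __post_init__(self):
        for name in ("k1", "k2", "k3", "k4", "lam", "mu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.k5 is not None and self.k5 < 0:
            raise ValueError("k5 must be non-negative")

    @property
    def n_free(self) -> int:
        return 6 + (self.k5 is not None)


def enumerate_states(y_max: int) -> list[tuple[int, int]]:
    """All (y, x) with 1 ≤ y ≤ y_max and y ≤ x ≤ 2y, ordered by y then x."""
    if y_max < 1:
        raise ValueError("y_max must be at least 1")
    return [(y, x) for y in range(1, y_max + 1) for x in range(y, 2 * y + 1)]


def default_y_max(tip_states: dict[str, tuple[int, int]]) -> int:
    """2×max observed y + 2: one polyploidization from the largest
    observed chromosome number stays representable."""
    return 2 * max(y for y, _ in tip_states.values()) + 2


from functools import lru_cache


@lru_cache(maxsize=8)
def _q_basis(y_max: int, multiplier: str) -> tuple[np.ndarray, ...]:
    """Structure matrices B1..B5 with Q = Σ k_i · B_i (diagonal-free);
    Q is linear in the rate coefficients so these are computed once per
    state space."""
    if multiplier not in ("per_chromosome", "constant"):
        raise ValueError("multiplier must be 'per_chromosome' or 'constant'")
    states = enumerate_states(y_max)
    index = {s: i for i, s in enumerate(states)}
    k = len(states)
    B = [np.zeros((k, k)) for _ in range(5)]

    def mult(count: int) -> float:
        return float(count) if multiplier == "per_chromosome" \
            else float(count > 0)

    for i, (y, x) in enumerate(states):
        uni, bi = 2 * y - x, x - y
        moves = []
        if uni >= 2:
            moves.append((0, (y - 1, x), mult(uni)))
        if bi >= 1:
            moves.append((1, (y + 1, x), mult(bi)))
        if uni >= 1:
            moves.append((2, (y, x + 1), mult(uni)))
        if bi >= 1:
            moves.append((3, (y, x - 1), mult(bi)))
        moves.append((4, (2 * y, 2 * x), 1.0))
        for which, target, weight in moves:
            j = index.get(target)
            if j is not None and weight > 0:
                B[which][i, j] += weight
    return tuple(B)


def build_q(states: list[tuple[int, int]], params: SseParams,
            multiplier: str = "per_chromosome") -> np.ndarray:
    """Dense generator on the karyograph state list (as produced by
    :func:`enumerate_states`); transitions leaving the enumerated grid
    are dropped."""
    y_max = max(y for y, _ in states)
    if states != enumerate_states(y_max):
        raise ValueError("states must be a full enumerate_states() grid")
    B = _q_basis(y_max, multiplier)
    rates = (params.k1, params.k2, params.k3, params.k4,
             params.k5 if params.k5 is not None else 0.0)
    Q = sum(r * b for r, b in zip(rates, B) if r > 0)
    if np.isscalar(Q):  # all rates zero
        Q = np.zeros_like(B[0])
    else:
        Q = Q.copy()
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


# ---------------------------------------------------------------------------
# birth–death scalar factors (state-independent lambda, mu)

def _extinction_prob(t: float, lam: float, mu: float) -> float:
    """P(a single lineage alive at time t before present leaves no
    sampled descendants), complete sampling."""
    if t == 0 or (lam == 0 and mu == 0):
        return 0.0
    if math.isclose(lam, mu, rel_tol=1e-12):
        return lam * t / (1.0 + lam * t)
    r = lam - mu
    if r > 0:
        return 1.0 - r / (lam - mu * math.exp(-r * t))
    # declining process: rearrange so the exponential argument is <= 0
    return 1.0 - r * math.exp(r * t) / (lam * math.exp(r * t) - mu)


def _int_one_minus_e(t: float, lam: float, mu: float) -> float:
    """∫_0^t (1 − E(s)) ds, closed form."""
    if lam == 0 and mu == 0:
        return t
    if lam == 0:
        return (1.0 - math.exp(-mu * t)) / mu
    if math.isclose(lam, mu, rel_tol=1e-12):
        return math.log1p(lam * t) / lam
    r = lam - mu
    if r > 0:
        return (r * t + math.log((lam - mu * math.exp(-r * t)) / r)) / lam
    # equivalent form stable when extinction exceeds speciation
    return math.log((lam * math.exp(r * t) - mu) / r) / lam


def _log_branch_factor(t0: float, t1: float, lam: float, mu: float) -> float:
    """log of the scalar multiplying exp(Q·b)·D along a branch spanning
    heights [t0, t1] above the present: exp(∫ 2λE − (λ+μ) ds)."""
    def phi(t: float) -> float:
        return 2.0 * lam * (t - _int_one_minus_e(t, lam, mu)) - (lam + mu) * t
    return phi(t1) - phi(t0)


# ---------------------------------------------------------------------------
# likelihood

def _tip_state_indices(states: list[tuple[int, int]],
                       tip_states: dict[str, tuple[int, int]]) -> dict[str, int]:
    index = {s: i for i, s in enumerate(states)}
    out = {}
    for name, (y, x) in tip_states.items():
        if not (y <= x <= 2 * y):
            raise ValueError(f"{name}: ({y}, {x}) violates y <= x <= 2y")
        if (y, x) not in index:
            raise ValueError(f"{name}: state ({y}, {x}) outside the "
                             "enumerated karyograph")
        out[name] = index[(y, x)]
    return out


def _root_lnl(D: np.ndarray, log_scale: float, root: str) -> float:
    total = D.sum()
    if total <= 0 or not np.isfinite(log_scale):
        return -np.inf
    if root == "fitzjohn":
        like = float((D ** 2).sum() / total)
    elif root == "flat":
        like = float(D.mean())
    else:
        raise ValueError("root must be 'fitzjohn' or 'flat'")
    return math.log(like) + log_scale if like > 0 else -np.inf


def _exact_downpass(tree: Phylogeny, tip_idx: dict[str, int],
                    prop: Propagator, lam: float, mu: float
                    ) -> tuple[dict[Node, np.ndarray], float]:
    """D vectors at nodes via exp(Q·b) times the closed-form scalar
    birth–death factor; returns root D (scaled) and the log scale."""
    height = tree.height()
    depth = tree.depths()
    k = prop.n_states
    D: dict[Node, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder():
        if node.is_leaf:
            d = np.zeros(k)
            d[tip_idx[node.name]] = 1.0
        else:
            d = np.ones(k)
            for c in node.children:
                d = d * D[c]
            if lam > 0:  # at lam = 0 the process is a pure CTMC
                d = d * lam ** (len(node.children) - 1)
        if node is not tree.root:
            t0 = height - depth[node]            # child-end height
            t1 = height - depth[node.parent]     # parent-end height
            d = prop.matvec(node.length, d)
            log_scale += _log_branch_factor(t0, t1, lam, mu)
        s = d.max()
        if s <= 0:
            return D, -np.inf
        d /= s
        log_scale += math.log(s)
        D[node] = d
    return D, log_scale


def _ode_downpass(tree: Phylogeny, tip_idx: dict[str, int], Q: np.ndarray,
                  lam: float, mu: float, rtol: float = 1e-8
                  ) -> tuple[dict[Node, np.ndarray], float]:
    """Full FitzJohn integration of the coupled E/D system per branch."""
    k = Q.shape[0]
    height = tree.height()
    depth = tree.depths()
    def rhs(_t, z):
        E, D = z[:k], z[k:]
        # Q rows sum to 0, so Q @ E bundles the -Σq_ij E_i outflow with
        # the Σ q_ij E_j inflow of the FitzJohn equations
        dE = mu - (lam + mu) * E + Q @ E + lam * E ** 2
        dD = -(lam + mu) * D + Q @ D + 2.0 * lam * E * D
        return np.concatenate([dE, dD])

    D: dict[Node, np.ndarray] = {}
    E: dict[Node, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder():
        if node.is_leaf:
            d = np.zeros(k)
            d[tip_idx[node.name]] = 1.0
            e = np.zeros(k)
        else:
            d = np.ones(k)
            for c in node.children:
                d = d * D[c]
            if lam > 0:
                d = d * lam ** (len(node.children) - 1)
            e = E[node.children[0]]
        if node is not tree.root:
            t0 = height - depth[node]
            t1 = height - depth[node.parent]
            if t1 > t0:
                sol = integrate.solve_ivp(
                    rhs, (t0, t1), np.concatenate([e, d]),
                    method="RK45", rtol=rtol, atol=1e-12)
                if not sol.success:
                    raise RuntimeError(
                        f"SSE integration failed on branch above "
                        f"{node.name or 'an internal node'}: {sol.message}")
                z = sol.y[:, -1]
                e, d = z[:k], z[k:]
                if np.any(e < -1e-6) or np.any(e > 1 + 1e-6) or np.any(d < -1e-9):
                    raise RuntimeError("SSE integration left the valid "
                                       "E in [0,1], D >= 0 region")
                e = np.clip(e, 0.0, 1.0)
                d = np.clip(d, 0.0, None)
        s = d.max()
        if s <= 0:
            return D, -np.inf
        d /= s
        log_scale += math.log(s)
        D[node] = d
        E[node] = e
    return D, log_scale


def musse_loglik(tree: Phylogeny, tip_states: dict[str, tuple[int, int]],
                 params: SseParams, y_max: int | None = None,
                 root: str = "fitzjohn", method: str = "exact",
                 multiplier: str = "per_chromosome") -> float:
    """SSE log-likelihood of the tree plus karyograph tip states.

    ``root="fitzjohn"`` weights root states by their own likelihood
    contribution (D_i / ΣD_j); ``root="flat"`` averages uniformly, which
    at λ = μ = 0 reduces the likelihood to CTMC pruning with a uniform
    root prior. No survival conditioning is applied.
    """
    if y_max is None:
        y_max = default_y_max(tip_states)
    states = enumerate_states(y_max)
    tip_idx = _tip_state_indices(states, tip_states)
    Q = build_q(states, params, multiplier)
    if method == "exact":
        D, log_scale = _exact_downpass(tree, tip_idx, Propagator(Q),
                                       params.lam, params.mu)
    elif method == "ode":
        D, log_scale = _ode_downpass(tree, tip_idx, Q, params.lam, params.mu)
    else:
        raise ValueError("method must be 'exact' or 'ode'")
    if not np.isfinite(log_scale):
        return -np.inf
    return _root_lnl(D[tree.root], log_scale, root)


# ---------------------------------------------------------------------------
# fitting and model comparison

def lrt_statistic(lnl_smaller: float, lnl_larger: float) -> float:
    """Likelihood-ratio statistic 2·(lnL_larger − lnL_smaller)."""
    return 2.0 * (lnl_larger - lnl_smaller)


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    df: int
    p_value: float
    p_value_boundary: float  # halved: k5 = 0 sits on the boundary

    @classmethod
    def from_lnls(cls, lnl_smaller: float, lnl_larger: float,
                  df: int = 1) -> "LrtResult":
        stat = lrt_statistic(lnl_smaller, lnl_larger)
        p = float(stats.chi2.sf(max(stat, 0.0), df=df)) if stat > 0 else 1.0
        return cls(stat, df, p, p / 2.0 if stat > 0 else 1.0)


@dataclass
class SseFit:
    params: SseParams
    lnl: float
    model: str  # "M1" | "M2"
    converged: bool

    @property
    def k(self) -> int:
        return self.params.n_free


_PARAM_NAMES_M1 = ("k1", "k2", "k3", "k4", "lam", "mu")
_PARAM_NAMES_M2 = ("k1", "k2", "k3", "k4", "k5", "lam", "mu")


def fit_sse(tree: Phylogeny, tip_states: dict[str, tuple[int, int]],
            with_polyploidy: bool, y_max: int | None = None,
            root: str = "fitzjohn", multiplier: str = "per_chromosome",
            n_starts: int = 3, seed: int = 0, maxiter: int = 250,
            x0_extra: np.ndarray | None = None) -> SseFit:
    """ML fit of one karyograph SSE model (Nelder–Mead on log-rates)."""
    if tree.n_tips < 4:
        raise ValueError("need at least 4 tips")
    names = _PARAM_NAMES_M2 if with_polyploidy else _PARAM_NAMES_M1
    if y_max is None:
        y_max = default_y_max(tip_states)

    def unpack(x: np.ndarray) -> SseParams:
        vals = dict(zip(names, np.exp(np.clip(x, -30.0, 8.0))))
        if not with_polyploidy:
            vals["k5"] = None
        return SseParams(**vals)

    def neg_lnl(x: np.ndarray) -> float:
        try:
            val = musse_loglik(tree, tip_states, unpack(x), y_max=y_max,
                               root=root, multiplier=multiplier)
        except (ValueError, RuntimeError, FloatingPointError):
            return np.inf
        return np.inf if not np.isfinite(val) else -val

    total_len = max(tree.total_length(), 1e-9)
    height = max(tree.height(), 1e-9)
    k0 = math.log(max(tree.n_tips / total_len, 1e-4))
    lam0 = math.log(max(math.log(max(tree.n_tips, 3)) / height, 1e-4))
    base = {"k1": k0, "k2": k0, "k3": k0, "k4": k0, "k5": k0 - 2.0,
            "lam": lam0, "mu": lam0 - 2.0}
    rng = np.random.default_rng(seed)
    starts = []
    if x0_extra is not None:
        starts.append(np.asarray(x0_extra, dtype=float))
    starts.append(np.array([base[n] for n in names]))
    while len(starts) < n_starts + (x0_extra is not None):
        starts.append(np.array([base[n] for n in names])
                      + rng.normal(scale=1.2, size=len(names)))

    best = None
    for x0 in starts:
        res = optimize.minimize(neg_lnl, x0, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-6,
                                         "maxiter": maxiter * len(names)})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("SSE fit found no finite likelihood")
    return SseFit(params=unpack(best.x), lnl=-float(best.fun),
                  model="M2" if with_polyploidy else "M1",
                  converged=bool(best.success))


def fit_m1_m2(tree: Phylogeny, tip_states: dict[str, tuple[int, int]],
              y_max: int | None = None, root: str = "fitzjohn",
              multiplier: str = "per_chromosome", n_starts: int = 3,
              seed: int = 0, maxiter: int = 250
              ) -> tuple[SseFit, SseFit, LrtResult]:
    """Fit M1 (no polyploidy) and M2 (with k5) and compare them by a
    likelihood-ratio test with 1 df.

    M2 is additionally started from the M1 optimum with a tiny k5, so
    the nesting lnL(M2) ≥ lnL(M1) holds up to optimizer tolerance; a
    violation beyond 1e-6 flags non-convergence on the M2 fit.
    """
    m1 = fit_sse(tree, tip_states, with_polyploidy=False, y_max=y_max,
                 root=root, multiplier=multiplier, n_starts=n_starts,
                 seed=seed, maxiter=maxiter)
    p = m1.params
    x0 = np.log(np.clip([p.k1, p.k2, p.k3, p.k4, 1e-8, p.lam, p.mu],
                        1e-12, None))
    m2 = fit_sse(tree, tip_states, with_polyploidy=True, y_max=y_max,
                 root=root, multiplier=multiplier, n_starts=n_starts,
                 seed=seed, maxiter=maxiter, x0_extra=x0)
    if m2.lnl < m1.lnl - 1e-6:
        m2.converged = False  # nested model cannot beat its superset
        m2.lnl = max(m2.lnl, m1.lnl)
    return m1, m2, LrtResult.from_lnls(m1.lnl, m2.lnl, df=1)


# ---------------------------------------------------------------------------
# ancestral reconstruction

def ancestral_karyograph(tree: Phylogeny,
                         tip_states: dict[str, tuple[int, int]],
                         params: SseParams, y_max: int | None = None,
                         root: str = "fitzjohn",
                         multiplier: str = "per_chromosome"
                         ) -> AncestralReconstruction:
    """Marginal per-node posteriors over karyograph states.

    With state-independent λ and μ the SSE branch factors are scalar and
    cancel in every normalized posterior, so the marginals equal the
    embedded CTMC's up–down reconstruction; the root prior is uniform
    under ``root="flat"`` and proportional to the root partial
    likelihoods under ``root="fitzjohn"``.
    """
    if y_max is None:
        y_max = default_y_max(tip_states)
    states = enumerate_states(y_max)
    tip_idx = _tip_state_indices(states, tip_states)
    Q = build_q(states, params, multiplier)
    prop = Propagator(Q)
    if root == "fitzjohn":
        D, log_scale = _exact_downpass(tree, tip_idx, prop,
                                       params.lam, params.mu)
        if not np.isfinite(log_scale):
            raise ValueError("zero-probability tip data")
        prior = D[tree.root] / D[tree.root].sum()
    elif root == "flat":
        prior = None
    else:
        raise ValueError("root must be 'fitzjohn' or 'flat'")
    probs = marginal_ancestral(tree, tip_idx, prop, prior)
    recon = AncestralReconstruction(
        states=np.arange(len(states)), probs=probs, method="marginal",
        meta={"states": states, "root": root})
    return recon


def state_frequency_table(tip_states: dict[str, tuple[int, int]]
                          ) -> pd.DataFrame:
    """Observed karyograph occupancy: one row per distinct (y, x) state
    with its species count — the scatter behind a karyograph plot."""
    counts: dict[tuple[int, int], int] = {}
    for y, x in tip_states.values():
        counts[(y, x)] = counts.get((y, x), 0) + 1
    rows = [{"y": y, "x": x, "n_species": c,
             "uni_armed": 2 * y - x, "bi_armed": x - y}
            for (y, x), c in sorted(counts.items())]
    return pd.DataFrame(rows)


def ancestral_summary(tree: Phylogeny,
                      recon: AncestralReconstruction) -> pd.DataFrame:
    """Per-internal-node posterior mean chromosome number and arm
    number, plus the most probable state (heat-map quantities)."""
    states = recon.meta["states"]
    ys = np.array([y for y, _ in states], dtype=float)
    xs = np.array([x for _, x in states], dtype=float)
    rows = []
    for i, node in enumerate(tree.internal_nodes()):
        p = recon.probs[node]
        j = int(np.argmax(p))
        rows.append({
            "node": i,
            "is_root": node is tree.root,
            "mean_y": float(ys @ p),
            "mean_x": float(xs @ p),
            "map_y": states[j][0],
            "map_x": states[j][1],
            "map_prob": float(p[j]),
        })
    return pd.DataFrame(rows)
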