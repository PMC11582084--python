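"""Chromosome-number evolution as a CTMC over haploid counts.

The state space is the integer haploid number n on [n_min, n_max]. Rate
events: single-chromosome gain (ascending dysploidy / fission) and loss
(fusion), whole-set duplication (polyploidy, n → 2n) and
demi-duplication (n → 1.5n; for odd n the probability splits equally
between the two flanking integers). Gain and loss rates may depend
linearly on the current number. Transitions that would leave the state
bounds are dropped, not absorbed, so the top state is not inflated.

Fitting is ML over the enabled rates via multi-start Nelder–Mead on
log-rates; model families are compared by AIC with k = number of free
rates. Ancestral states are marginal posteriors under the fitted model
(uniform root prior by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from ._ctmc import Propagator, marginal_ancestral, pruning_loglik
from .trees import Node, Phylogeny

__all__ = [
    "ChromModel",
    "ChromFit",
    "AncestralReconstruction",
    "FAMILIES",
    "build_q",
    "likelihood",
    "fit",
    "fit_family_table",
    "ancestral_marginal",
    "default_bounds",
]

# model families: which rates are free (linear terms are real-valued,
# base rates positive)
FAMILIES: dict[str, tuple[str, ...]] = {
    "dysploidy": ("gain", "loss"),
    "dysploidy_demi": ("gain", "loss", "demi"),
    "dysploidy_dupl": ("gain", "loss", "dupl"),
    "dysploidy_dupl_demi": ("gain", "loss", "dupl", "demi"),
    "linear_dysploidy": ("gain", "loss", "gain_linear", "loss_linear"),
    "linear_dysploidy_dupl": ("gain", "loss", "gain_linear", "loss_linear",
                              "dupl"),
}

_BASE_RATES = ("gain", "loss", "dupl", "demi")


@dataclass(frozen=True)
class ChromModel:
    """Rate parameterization; a rate of ``None`` is structurally absent."""

    gain: float | None = 0.0
    loss: float | None = 0.0
    dupl: float | None = None
    demi: float | None = None
    gain_linear: float | None = None
    loss_linear: float | None = None
    n_min: int = 1
    n_max: int = 50
    root_prior: str = "uniform"  # uniform | stationary

    @property
    def states(self) -> np.ndarray:
        return np.arange(self.n_min, self.n_max + 1)

    def state_index(self, n: int) -> int:
        if not (self.n_min <= n <= self.n_max):
            raise ValueError(f"haploid number {n} outside [{self.n_min}, "
                             f"{self.n_max}]")
        return int(n - self.n_min)

    @property
    def free_rates(self) -> tuple[str, ...]:
        return tuple(r for r in
                     ("gain", "loss", "dupl", "demi", "gain_linear",
                      "loss_linear")
                     if getattr(self, r) is not None)


def default_bounds(tip_states: dict[str, int]) -> tuple[int, int]:
    """n_min = 1, n_max = 2×max observed + 2, so one duplication from
    the largest observed number stays representable."""
    m = max(tip_states.values())
    return 1, 2 * m + 2


def build_q(model: ChromModel) -> np.ndarray:
    """Dense generator over the haploid-number states."""
    states = model.states
    k = states.size
    if k < 2:
        raise ValueError("state space needs at least two states")
    Q = np.zeros((k, k))
    clamped = False

    def effective(base: float | None, linear: float | None, s: int) -> float:
        if base is None:
            return 0.0
        rate = base + (linear or 0.0) * (s - model.n_min)
        return max(rate, 0.0)

    for i, s in enumerate(states):
        g = effective(model.gain, model.gain_linear, s)
        li = effective(model.loss, model.loss_linear, s)
        if model.gain is not None and (model.gain_linear or 0.0) != 0.0 \
                and model.gain + model.gain_linear * (s - model.n_min) < 0:
            clamped = True
        if s + 1 <= model.n_max:
            Q[i, i + 1] += g
        if s - 1 >= model.n_min:
            Q[i, i - 1] += li
        if model.dupl is not None and 2 * s <= model.n_max:
            Q[i, model.state_index(2 * s)] += model.dupl
        if model.demi is not None:
            t = 1.5 * s
            if t == int(t):
                targets = [(int(t), model.demi)]
            else:
                targets = [(int(np.floor(t)), model.demi / 2),
                           (int(np.ceil(t)), model.demi / 2)]
            for tgt, rate in targets:
                if model.n_min <= tgt <= model.n_max and tgt != s:
                    Q[i, model.state_index(tgt)] += rate
    if clamped:
        warnings.warn("linear rate term produced negative rates; clamped to 0")
    if model.dupl is not None and 2 * model.n_min > model.n_max:
        warnings.warn("n_max too small for any duplication event")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _root_prior_vector(model: ChromModel, Q: np.ndarray) -> np.ndarray | None:
    if model.root_prior == "uniform":
        return None
    if model.root_prior == "stationary":
        # left null vector of Q
        w, v = np.linalg.eig(Q.T)
        i = int(np.argmin(np.abs(w)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()
    raise ValueError(f"unknown root prior mode {model.root_prior!r}")


def _tip_indices(model: ChromModel, tip_states: dict[str, int]) -> dict[str, int]:
    return {name: model.state_index(n) for name, n in tip_states.items()}


def likelihood(tree: Phylogeny, tip_states: dict[str, int],
               model: ChromModel) -> float:
    """Pruning log-likelihood of observed haploid numbers at the tips."""
    Q = build_q(model)
    return pruning_loglik(tree, _tip_indices(model, tip_states), Q,
                          _root_prior_vector(model, Q))


@dataclass
class ChromFit:
    model: ChromModel
    lnl: float
    converged: bool
    family: str
    n_restarts: int = 0

    @property
    def k(self) -> int:
        return len(self.model.free_rates)

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.lnl


def fit(tree: Phylogeny, tip_states: dict[str, int],
        family: str = "dysploidy",
        bounds: tuple[int, int] | None = None,
        root_prior: str = "uniform",
        n_starts: int = 3, seed: int = 0,
        maxiter: int = 400) -> ChromFit:
    """ML fit of one model family.

    Base rates are optimized on the log scale from spread random starts;
    linear coefficients (when enabled) on the natural scale.
    """
    if tree.n_tips < 4:
        raise ValueError("need at least 4 tips")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from "
                         f"{sorted(FAMILIES)}")
    params = FAMILIES[family]
    n_min, n_max = bounds if bounds is not None else default_bounds(tip_states)
    template = ChromModel(
        **{r: (0.0 if r in params else None)
           for r in ("gain", "loss", "dupl", "demi", "gain_linear",
                     "loss_linear")},
        n_min=n_min, n_max=n_max, root_prior=root_prior)

    is_linear = [p.endswith("_linear") for p in params]

    def unpack(x: np.ndarray) -> ChromModel:
        vals = {}
        for p, lin, xi in zip(params, is_linear, x):
            vals[p] = float(xi) if lin else float(np.exp(
                np.clip(xi, -30.0, 10.0)))
        return replace(template, **vals)

    def neg_lnl(x: np.ndarray) -> float:
        try:
            val = likelihood(tree, tip_states, unpack(x))
        except (ValueError, FloatingPointError):
            return np.inf
        return np.inf if not np.isfinite(val) else -val

    # scale-aware starting points: one event per unit tree length
    base0 = np.log(max(tree.n_tips / max(tree.total_length(), 1e-9), 1e-3))
    rng = np.random.default_rng(seed)
    best = None
    for start in range(n_starts):
        x0 = np.array([0.0 if lin else base0 for lin in is_linear])
        if start > 0:
            x0 = x0 + rng.normal(scale=1.5, size=x0.size)
        res = optimize.minimize(neg_lnl, x0, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-6,
                                         "maxiter": maxiter * len(params)})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"{family} fit failed: no finite likelihood found")
    return ChromFit(model=unpack(best.x), lnl=-float(best.fun),
                    converged=bool(best.success), family=family,
                    n_restarts=n_starts)


def fit_family_table(tree: Phylogeny, tip_states: dict[str, int],
                     families: tuple[str, ...] | None = None,
                     **kwargs) -> pd.DataFrame:
    """Fit several families and rank them by AIC."""
    families = families or tuple(FAMILIES)
    fits = [fit(tree, tip_states, fam, **kwargs) for fam in families]
    df = pd.DataFrame({
        "family": [f.family for f in fits],
        "k": [f.k for f in fits],
        "lnl": [f.lnl for f in fits],
        "aic": [f.aic for f in fits],
        "converged": [f.converged for f in fits],
    })
    df["delta_aic"] = df["aic"] - df["aic"].min()
    return df.sort_values("aic", ignore_index=True)


@dataclass
class AncestralReconstruction:
    """Per-internal-node posterior distributions over discrete states."""

    states: np.ndarray  # state values, aligned with probability vectors
    probs: dict[Node, np.ndarray]
    method: str = "marginal"
    meta: dict = field(default_factory=dict)

    def ml_state(self, node: Node) -> int:
        return int(self.states[int(np.argmax(self.probs[node]))])

    def mean_state(self, node: Node) -> float:
        return float(self.states @ self.probs[node])

    def credible_set(self, node: Node, mass: float = 0.95) -> list[int]:
        """Smallest set of states whose posterior mass reaches ``mass``."""
        p = self.probs[node]
        order = np.argsort(p)[::-1]
        total, out = 0.0, []
        for i in order:
            out.append(int(self.states[i]))
            total += p[i]
            if total >= mass:
                break
        return out


def ancestral_marginal(tree: Phylogeny, tip_states: dict[str, int],
                       model: ChromModel) -> AncestralReconstruction:
    """Marginal ancestral haploid numbers under a fitted model."""
    Q = build_q(model)
    probs = marginal_ancestral(tree, _tip_indices(model, tip_states),
                               Propagator(Q), _root_prior_vector(model, Q))
    return AncestralReconstruction(states=model.states, probs=probs,
                                   meta={"root_prior": model.root_prior})
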