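"""ML fitting of Brownian motion and tree-transformation models.

A continuous trait evolving by Brownian motion (BM) on a phylogeny is
multivariate normal with mean ``root·1`` and covariance ``σ²·C``, where
``C`` is the shared-path-length matrix of the tips. The four
transformation models reshape ``C`` with one extra parameter each:

* **lambda** — off-diagonal covariances scaled by λ ∈ [0, 1]; λ = 0 is a
  star phylogeny (no phylogenetic covariance), λ = 1 plain BM.
* **delta** — elementwise ``C**δ``; δ < 1 concentrates change early in
  the tree, δ > 1 late.
* **kappa** — branch lengths raised to κ before rebuilding ``C``; κ = 0
  makes change speciational (every branch equal), κ = 1 plain BM.
* **OU** — Ornstein–Uhlenbeck attraction of strength α toward an
  optimum; covariances decay with phylogenetic distance, and α → 0
  recovers BM.

For every model the root state and σ² profile out analytically (GLS), so
each fit is a one-dimensional bounded likelihood search over the
transform parameter. Model choice uses AICc with n = number of tips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .trees import Phylogeny, vcv

__all__ = [
    "MODELS",
    "DEFAULT_BOUNDS",
    "ModelFit",
    "transform_covariance",
    "transformed_vcv",
    "gls_fit",
    "fit_model",
    "model_table",
    "aic",
    "aicc",
]

MODELS = ("BM", "lambda", "delta", "kappa", "OU")

# delta = 5 and alpha = 2 are deliberately attainable boundary values
DEFAULT_BOUNDS = {
    "lambda": (0.0, 1.0),
    "delta": (1e-6, 5.0),
    "kappa": (0.0, 3.0),
    "OU": (0.0, 2.0),
}

_N_STARTS = 5  # spread starting brackets for the scalar search


def aic(lnl: float, k: int) -> float:
    return 2.0 * k - 2.0 * lnl


def aicc(lnl: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return aic(lnl, k) + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class ModelFit:
    """One fitted trait-evolution model."""

    model: str
    theta: float | None  # transform parameter; None for BM
    sigma2: float
    root_state: float
    lnl: float
    k: int
    n: int
    delta_aicc: float | None = field(default=None)

    @property
    def aic(self) -> float:
        return aic(self.lnl, self.k)

    @property
    def aicc(self) -> float:
        return aicc(self.lnl, self.k, self.n)

    @property
    def neg_lnl(self) -> float:
        return -self.lnl


def transform_covariance(C: np.ndarray, model: str, theta: float) -> np.ndarray:
    """Apply the lambda/delta/OU covariance transform to ``C``.

    The kappa transform needs branch lengths, not just ``C``; use
    :func:`transformed_vcv` for it. For OU the tree must be ultrametric
    (constant diagonal ``T``); the variance is scaled so α → 0 recovers
    ``C`` exactly.
    """
    C = np.asarray(C, dtype=float)
    if model == "BM":
        return C.copy()
    if model == "lambda":
        out = C * theta
        np.fill_diagonal(out, np.diag(C))
        return out
    if model == "delta":
        if theta <= 0:
            raise ValueError("delta must be positive")
        return np.power(C, theta)
    if model == "OU":
        alpha = theta
        if alpha < 0:
            raise ValueError("alpha must be non-negative")
        if alpha == 0:
            return C.copy()
        diag = np.diag(C)
        T = diag.max()
        if not np.allclose(diag, T, rtol=1e-6):
            raise ValueError("OU transform requires an ultrametric tree")
        with np.errstate(over="raise"):
            return (1.0 - np.exp(-2.0 * alpha * C)) / (2.0 * alpha) \
                * np.exp(-2.0 * alpha * (T - C))
    raise ValueError(f"unknown model {model!r}")


def transformed_vcv(tree: Phylogeny, model: str, theta: float | None) -> np.ndarray:
    """Tip covariance of ``tree`` under ``model`` at parameter ``theta``."""
    if model == "kappa":
        if theta < 0:
            raise ValueError("kappa must be non-negative")
        scaled = tree.copy()
        for node in scaled.postorder():
            if node is not scaled.root:
                node.length = node.length ** theta if node.length > 0 else 0.0
        return vcv(scaled)[1]
    _, C = vcv(tree)
    return transform_covariance(C, model, theta if theta is not None else 0.0)


def gls_fit(C: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """ML root state, rate and log-likelihood under covariance ``C``.

    root = (1ᵀC⁻¹1)⁻¹ 1ᵀC⁻¹y;  σ̂² = rᵀC⁻¹r / n (ML, not REML);
    lnL is the multivariate-normal log-density at the optimum.
    """
    C = np.asarray(C, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if C.shape != (n, n):
        raise ValueError("dimension mismatch between C and y")
    try:
        cho = linalg.cho_factor(C, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"covariance not positive definite (cond ~ {np.linalg.cond(C):.3g})"
        ) from exc
    ones = np.ones(n)
    Ci_y = linalg.cho_solve(cho, y, check_finite=False)
    Ci_1 = linalg.cho_solve(cho, ones, check_finite=False)
    root = float(ones @ Ci_y) / float(ones @ Ci_1)
    r = y - root
    quad = float(r @ linalg.cho_solve(cho, r, check_finite=False))
    if quad <= 0:
        raise ValueError("degenerate likelihood: residual quadratic form is zero "
                         "(constant trait?)")
    sigma2 = quad / n
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    lnl = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return root, sigma2, lnl


def _profile_lnl(tree: Phylogeny, y: np.ndarray, model: str, theta: float,
                 C0: np.ndarray | None = None) -> float:
    # kappa rescales branch lengths, so the covariance must be rebuilt;
    # the other transforms act on the cached base covariance directly
    if model == "kappa" or C0 is None:
        C = transformed_vcv(tree, model, theta)
    else:
        C = transform_covariance(C0, model, theta)
    try:
        return gls_fit(C, y)[2]
    except (np.linalg.LinAlgError, linalg.LinAlgError, FloatingPointError):
        return -np.inf


def fit_model(tree: Phylogeny, y: np.ndarray, model: str,
              bounds: tuple[float, float] | None = None,
              xtol: float = 1e-8) -> ModelFit:
    """ML fit of one model; the transform parameter is searched by
    bounded Brent minimization restarted on spread sub-brackets."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if model == "BM":
        root, sigma2, lnl = gls_fit(vcv(tree)[1], y)
        return ModelFit("BM", None, sigma2, root, lnl, k=2, n=n)

    lo, hi = bounds if bounds is not None else DEFAULT_BOUNDS[model]
    C0 = None if model == "kappa" else vcv(tree)[1]
    edges = np.linspace(lo, hi, _N_STARTS + 1)
    best_theta, best_lnl = lo, -np.inf
    for a, b in zip(edges[:-1], edges[1:]):
        res = optimize.minimize_scalar(
            lambda t: -_profile_lnl(tree, y, model, t, C0),
            bounds=(a, b), method="bounded",
            options={"xatol": xtol},
        )
        if -res.fun > best_lnl:
            best_lnl, best_theta = -res.fun, float(res.x)
    # the bounds themselves are legitimate optima (e.g. lambda = 1)
    for t in (lo, hi):
        lnl_t = _profile_lnl(tree, y, model, t, C0)
        if lnl_t >= best_lnl:
            best_lnl, best_theta = lnl_t, t
    if not np.isfinite(best_lnl):
        raise RuntimeError(
            f"{model} fit failed to converge in [{lo}, {hi}]; "
            f"last theta {best_theta}")
    C = transformed_vcv(tree, model, best_theta)
    root, sigma2, lnl = gls_fit(C, y)
    return ModelFit(model, best_theta, sigma2, root, lnl, k=3, n=n)


def model_table(tree: Phylogeny, y: np.ndarray,
                models: tuple[str, ...] = MODELS) -> list[ModelFit]:
    """Fit every model and attach ΔAICc relative to the best one."""
    fits = [fit_model(tree, y, m) for m in models]
    best = min(f.aicc for f in fits)
    for f in fits:
        f.delta_aicc = f.aicc - best
    return fits
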