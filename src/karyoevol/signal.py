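"""Phylogenetic-signal statistics with permutation/randomization tests.

Four measures of whether close relatives resemble each other more than
chance: Moran's I with inverse-patristic-distance weights, Abouheif's
C_mean (a Moran statistic with a topology-only proximity), Blomberg's K
(variance-ratio calibrated to 1 under Brownian motion) and Pagel's λ
(an ML branch-length transform tested against λ = 0 by LRT).

Permutation p-values are one-sided (greater), computed as
(1 + #{permuted ≥ observed}) / (1 + n_reps), so ties count as
exceedances and p can never be exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .trait_models import fit_model, gls_fit, transform_covariance
from .trees import Phylogeny, vcv

__all__ = [
    "SignalResult",
    "morans_i",
    "abouheif_cmean",
    "blomberg_k",
    "pagels_lambda_test",
    "abouheif_proximity",
    "signal_table",
]

DEFAULT_N_REPS = 999


@dataclass(frozen=True)
class SignalResult:
    statistic: str
    value: float
    p_value: float
    n_reps: int | None = None
    seed: int | None = None
    detail: dict = field(default_factory=dict)


def _check_trait(tree: Phylogeny, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if tree.n_tips < 3:
        raise ValueError("need at least 3 tips")
    if y.size != tree.n_tips:
        raise ValueError("trait length does not match tip count")
    if np.ptp(y) == 0:
        raise ValueError("trait is constant (zero variance)")
    return y


def _moran_statistic(W: np.ndarray, y: np.ndarray) -> float:
    z = y - y.mean()
    s0 = W.sum()
    return float(y.size / s0 * (z @ W @ z) / (z @ z))


def _permutation_p(observed: float, stat, y: np.ndarray,
                   n_reps: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_reps):
        if stat(rng.permutation(y)) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_reps)


def morans_i(tree: Phylogeny, y: np.ndarray, n_reps: int = DEFAULT_N_REPS,
             seed: int = 0) -> SignalResult:
    """Moran's I with weights w_ij = 1/d_ij (patristic distance),
    zero diagonal; one-sided permutation test over tip relabelings."""
    y = _check_trait(tree, y)
    _, C = vcv(tree)
    d = np.diag(C)[:, None] + np.diag(C)[None, :] - 2.0 * C
    with np.errstate(divide="ignore"):
        W = 1.0 / d
    np.fill_diagonal(W, 0.0)
    if not np.all(np.isfinite(W)):
        raise ValueError("zero patristic distance between distinct tips")
    obs = _moran_statistic(W, y)
    p = _permutation_p(obs, lambda yy: _moran_statistic(W, yy), y, n_reps, seed)
    return SignalResult("morans_i", obs, p, n_reps, seed,
                        {"weights": "1/patristic distance"})


def abouheif_proximity(tree: Phylogeny) -> np.ndarray:
    """Abouheif proximity a_ij: product over the interior nodes on the
    nodal path between tips i and j (MRCA included) of 1/(number of
    direct descendants). Depends on topology only."""
    tips = tree.tips()
    n = len(tips)
    # ancestor chains root -> tip
    chains = []
    for t in tips:
        chain = []
        node = t.parent
        while node is not None:
            chain.append(node)
            node = node.parent
        chains.append(chain[::-1])
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = chains[i], chains[j]
            k = 0
            while k < min(len(ci), len(cj)) and ci[k] is cj[k]:
                k += 1
            # path nodes: MRCA (index k-1) plus everything below it on
            # both sides
            path = [ci[k - 1]] + ci[k:] + cj[k:]
            prod = 1.0
            for node in path:
                prod /= len(node.children)
            A[i, j] = A[j, i] = prod
    return A


def abouheif_cmean(tree: Phylogeny, y: np.ndarray, n_reps: int = DEFAULT_N_REPS,
                   seed: int = 0) -> SignalResult:
    """Abouheif's C_mean: Moran-type autocorrelation with the
    topology-only Abouheif proximity matrix."""
    y = _check_trait(tree, y)
    A = abouheif_proximity(tree)
    obs = _moran_statistic(A, y)
    p = _permutation_p(obs, lambda yy: _moran_statistic(A, yy), y, n_reps, seed)
    return SignalResult("abouheif_cmean", obs, p, n_reps, seed,
                        {"proximity": "nodal path product, MRCA included"})


def _k_statistic(C: np.ndarray, cho, expected: float, y: np.ndarray) -> float:
    n = y.size
    ones = np.ones(n)
    Ci_y = linalg.cho_solve(cho, y, check_finite=False)
    Ci_1 = linalg.cho_solve(cho, ones, check_finite=False)
    root = float(ones @ Ci_y) / float(ones @ Ci_1)
    r = y - root
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ linalg.cho_solve(cho, r, check_finite=False)) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(tree: Phylogeny, y: np.ndarray, n_reps: int = DEFAULT_N_REPS,
               seed: int = 0) -> SignalResult:
    """Blomberg's K: observed MSE0/MSE over its Brownian expectation
    (tr(C) − n/(1ᵀC⁻¹1))/(n − 1); K ≈ 1 under BM, → 0 without signal.
    One-sided (greater) tip-shuffling randomization."""
    y = _check_trait(tree, y)
    _, C = vcv(tree)
    n = y.size
    cho = linalg.cho_factor(C, lower=True, check_finite=False)
    ones = np.ones(n)
    expected = (np.trace(C) - n / float(ones @ linalg.cho_solve(
        cho, ones, check_finite=False))) / (n - 1)
    obs = _k_statistic(C, cho, expected, y)
    p = _permutation_p(obs, lambda yy: _k_statistic(C, cho, expected, yy),
                       y, n_reps, seed)
    return SignalResult("blomberg_k", obs, p, n_reps, seed)


def pagels_lambda_test(tree: Phylogeny, y: np.ndarray) -> SignalResult:
    """ML Pagel's λ on [0, 1] with a likelihood-ratio test against λ = 0
    (star phylogeny), p from χ² with 1 df."""
    y = _check_trait(tree, y)
    fit = fit_model(tree, y, "lambda")
    _, C = vcv(tree)
    lnl0 = gls_fit(transform_covariance(C, "lambda", 0.0), y)[2]
    lrt = max(0.0, 2.0 * (fit.lnl - lnl0))
    p = float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    return SignalResult("pagels_lambda", fit.theta, p,
                        detail={"lrt": lrt, "df": 1, "lnl": fit.lnl,
                                "lnl_lambda0": lnl0})


def signal_table(tree: Phylogeny, traits: pd.DataFrame,
                 n_reps: int = DEFAULT_N_REPS, seed: int = 0) -> pd.DataFrame:
    """All four statistics for every numeric column of ``traits``
    (tip-ordered rows); layout mirrors a trait × (statistic, p) table."""
    rows = []
    for k, col in enumerate(c for c in traits.columns if c != "taxon"):
        y = traits[col].to_numpy(dtype=float)
        mi = morans_i(tree, y, n_reps, seed + 7 * k)
        cm = abouheif_cmean(tree, y, n_reps, seed + 7 * k + 1)
        bk = blomberg_k(tree, y, n_reps, seed + 7 * k + 2)
        pl = pagels_lambda_test(tree, y)
        rows.append({
            "trait": col,
            "morans_I": mi.value, "morans_I_p": mi.p_value,
            "abouheif_cmean": cm.value, "abouheif_cmean_p": cm.p_value,
            "blomberg_K": bk.value, "blomberg_K_p": bk.p_value,
            "pagels_lambda": pl.value, "pagels_lambda_p": pl.p_value,
        })
    return pd.DataFrame(rows)
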