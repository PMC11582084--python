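"""Synthetic data: birth–death trees, continuous traits, discrete
karyotype histories and karyotype tables.

Every generator is a pure function of its arguments and a seed, so any
pipeline input can be regenerated bit-identically. Trees are simulated
forward in time (retrying on whole-tree extinction) and stopped after
the n-th tip with a final exponential waiting time, so under pure birth
the root height has the Yule expectation Σ_{k=2..n} 1/(b·k). Traits
follow the trait-model definitions exactly: BM and OU by their exact
per-branch transition distributions, the lambda/delta/kappa transforms
by sampling the multivariate normal with the transformed covariance.
Discrete histories are Gillespie simulations along branches, returning
the true internal states for parameter- and ancestry-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .karyotypes import format_formula
from .trait_models import transformed_vcv
from .trees import Node, Phylogeny

__all__ = [
    "SimConfig",
    "sim_bd_tree",
    "sim_continuous",
    "sim_discrete",
    "emit_karyotype_table",
]


@dataclass(frozen=True)
class SimConfig:
    """A reproducible simulation request (used by the CLI)."""

    seed: int
    n_tips: int = 30
    birth: float = 1.0
    death: float = 0.0
    trait_model: str = "BM"
    trait_params: dict = field(default_factory=dict)


def sim_bd_tree(n_tips: int, birth: float, death: float = 0.0,
                seed: int = 0, max_retries: int = 1000) -> Phylogeny:
    """Ultrametric tree with exactly ``n_tips`` extant tips under a
    constant-rate birth–death process; extinct lineages are pruned."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    if not (birth > death >= 0):
        raise ValueError("need birth > death >= 0")
    rng = np.random.default_rng(seed)

    for _ in range(max_retries):
        tree = _try_bd(n_tips, birth, death, rng)
        if tree is not None:
            return tree
    raise RuntimeError(f"birth–death simulation went extinct "
                       f"{max_retries} times")


def _try_bd(n_tips: int, birth: float, death: float,
            rng: np.random.Generator) -> Phylogeny | None:
    root = Node()
    start: dict[Node, float] = {}
    alive: list[Node] = []
    for _ in range(2):
        c = root.add_child(Node())
        start[c] = 0.0
        alive.append(c)
    t = 0.0
    extinct_count = 0
    while len(alive) < n_tips:
        total = len(alive) * (birth + death)
        t += rng.exponential(1.0 / total)
        node = alive[rng.integers(len(alive))]
        if rng.random() < birth / (birth + death):
            node.length = t - start[node]
            alive.remove(node)
            for _ in range(2):
                c = node.add_child(Node())
                start[c] = t
                alive.append(c)
        else:
            node.length = t - start[node]
            node.name = f"x{extinct_count}"
            extinct_count += 1
            alive.remove(node)
            if not alive:
                return None
    # stop strictly before the next event so exactly n_tips survive
    t += rng.exponential(1.0 / (len(alive) * (birth + death)))
    for i, node in enumerate(alive):
        node.length = t - start[node]
        node.name = f"t{i + 1}"

    tree = Phylogeny(root)
    if extinct_count:
        from .trees import prune_to_taxa
        tree = prune_to_taxa(tree, [n.name for n in alive])
    return tree


def sim_continuous(tree: Phylogeny, model: str = "BM", seed: int = 0,
                   sigma2: float = 1.0, root_state: float = 0.0,
                   theta: float | None = None,
                   ou_optimum: float | None = None) -> np.ndarray:
    """Tip trait values (in ``tree.tip_labels`` order) under one of the
    five trait models.

    ``theta`` is the transform parameter (λ, δ, κ or the OU α); for OU,
    ``ou_optimum`` defaults to the root state.
    """
    rng = np.random.default_rng(seed)
    tips = tree.tips()
    if model == "BM":
        values = _recursive_bm(tree, rng, sigma2, root_state)
        return np.array([values[t] for t in tips])
    if model == "OU":
        alpha = float(theta if theta is not None else 0.0)
        opt = root_state if ou_optimum is None else ou_optimum
        values = {tree.root: root_state}
        for node in tree.preorder():
            if node is tree.root:
                continue
            parent = values[node.parent]
            b = node.length
            if alpha == 0:
                mean, var = parent, sigma2 * b
            else:
                mean = opt + (parent - opt) * np.exp(-alpha * b)
                var = sigma2 * (1.0 - np.exp(-2.0 * alpha * b)) / (2.0 * alpha)
            values[node] = mean + rng.normal() * np.sqrt(var)
        return np.array([values[t] for t in tips])
    if model in ("lambda", "delta", "kappa"):
        if theta is None:
            raise ValueError(f"{model} simulation needs theta")
        C = transformed_vcv(tree, model, theta)
        L = np.linalg.cholesky(sigma2 * C + 1e-12 * np.eye(len(tips)))
        return root_state + L @ rng.normal(size=len(tips))
    raise ValueError(f"unknown model {model!r}")


def _recursive_bm(tree: Phylogeny, rng: np.random.Generator,
                  sigma2: float, root_state: float) -> dict[Node, float]:
    values = {tree.root: root_state}
    for node in tree.preorder():
        if node is not tree.root:
            values[node] = values[node.parent] + \
                rng.normal() * np.sqrt(sigma2 * node.length)
    return values


def sim_discrete(tree: Phylogeny, Q: np.ndarray, root_state: int,
                 seed: int = 0) -> tuple[dict[str, int], dict[Node, int]]:
    """Gillespie simulation of a CTMC along every branch.

    Returns (tip states by label, true states of all nodes) — the full
    history supports ancestral-recovery coverage tests.
    """
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    if not 0 <= root_state < k:
        raise ValueError("root state outside the state space")
    rng = np.random.default_rng(seed)
    states: dict[Node, int] = {tree.root: int(root_state)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        s = states[node.parent]
        t = 0.0
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t > node.length:
                break
            probs = np.clip(Q[s], 0.0, None)
            probs[s] = 0.0
            s = int(rng.choice(k, p=probs / probs.sum()))
        states[node] = s
    tips = {n.name: states[n] for n in tree.tips()}
    return tips, states


def emit_karyotype_table(tip_states: dict[str, tuple[int, int]],
                         seed: int = 0) -> pd.DataFrame:
    """Karyotype-formula table for simulated karyograph states.

    The ``x − y`` bi-armed chromosomes are spread over m/sm/st by a
    seeded multinomial and the ``2y − x`` uni-armed ones become t;
    counts are doubled to the diploid scale and formatted so the table
    round-trips through the formula parser.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for taxon, (y, x) in tip_states.items():
        if not (y <= x <= 2 * y):
            raise ValueError(f"{taxon}: invalid karyograph state ({y}, {x})")
        bi, uni = x - y, 2 * y - x
        m, sm, st = rng.multinomial(bi, [1 / 3, 1 / 3, 1 / 3])
        counts = {"m": 2 * int(m), "sm": 2 * int(sm), "st": 2 * int(st),
                  "t": 2 * uni}
        rows.append({
            "taxon": taxon,
            "haploid_n": y,
            "diploid_2n": 2 * y,
            "formula": format_formula(counts),
        })
    return pd.DataFrame(rows)
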