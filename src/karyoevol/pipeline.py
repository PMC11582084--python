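"""End-to-end karyotype-evolution analysis from a config.

Stages: prune the tree to taxa with karyotype data, build the six-trait
table, then (1) phylogenetic-signal statistics, (2) trait-model
selection, (3) clade rate-shift scan, (4) chromosome-number CTMC fit
with marginal ancestral numbers, (5) karyograph SSE M1/M2 fit with LRT
and ancestral (y, x) reconstruction. Each stage is skippable and stage
failures are isolated so independent stages still run. All outputs are
TSV/JSON plus annotated Newick; the resolved config and seed are
serialized into the output directory so a run is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromevol, karyograph, karyotypes, rate_shifts, signal
from . import trait_models
from .trees import Phylogeny, normalize_label, prune_to_taxa, read_newick

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger("karyoevol")

ALL_STAGES = ("signal", "fitmodels", "shifts", "chromevol", "karyograph")


@dataclass
class RunConfig:
    tree_path: str
    karyotype_path: str = "fixture"  # packaged table, or a TSV path
    out_dir: str = "karyoevol_out"
    seed: int = 0
    traits: tuple[str, ...] = ("n", "nm", "nsm", "nst", "nt", "fn")
    log_transform: bool = True
    include_outgroups: bool = True
    n_reps: int = 999
    shift_cutoff: float = 4.0
    max_shifts: int = 5
    chromevol_families: tuple[str, ...] = tuple(chromevol.FAMILIES)
    sse_root: str = "fitzjohn"
    sse_multiplier: str = "per_chromosome"
    sse_y_max: int | None = None  # None: 2×max observed y + 2
    sse_maxiter: int = 250
    n_starts: int = 3
    stages: tuple[str, ...] = ALL_STAGES

    def validate(self) -> None:
        bad = set(self.traits) - set(karyotypes.TRAIT_NAMES)
        if bad:
            raise ValueError(f"unknown trait name(s): {sorted(bad)}")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("traits", "chromevol_families", "stages"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _load_records(config: RunConfig) -> list[karyotypes.KaryotypeRecord]:
    if config.karyotype_path == "fixture":
        return karyotypes.load_fixture(
            include_outgroups=config.include_outgroups)
    df = pd.read_csv(config.karyotype_path, sep="\t")
    records = []
    for i, row in df.iterrows():
        records.append(karyotypes.KaryotypeRecord(
            taxon=normalize_label(str(row["taxon"])),
            haploid_n=int(row["haploid_n"]),
            diploid_2n=int(row["diploid_2n"]),
            formula=karyotypes.parse_formula(row["formula"]),
        ))
    return records


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns the JSON-able summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh)

    tree = read_newick(Path(config.tree_path).read_text())
    records = _load_records(config)
    table = karyotypes.trait_table(records, preferred_only=True,
                                   log_transform=False)
    table["taxon"] = table["taxon"].map(normalize_label)

    matched = sorted(set(tree.tip_labels) & set(table["taxon"]))
    unmatched_tree = sorted(set(tree.tip_labels) - set(table["taxon"]))
    unmatched_data = sorted(set(table["taxon"]) - set(tree.tip_labels))
    if len(matched) < 4:
        raise ValueError(
            f"only {len(matched)} taxa matched between tree and karyotype "
            f"table; unmatched tree tips: {unmatched_tree}; unmatched "
            f"karyotype taxa: {unmatched_data}")
    log.info("matched %d taxa; dropping %d tree tips without karyotypes",
             len(matched), len(unmatched_tree))
    tree = prune_to_taxa(tree, matched)
    if not tree.is_binary():
        tree = tree.resolve_polytomies()
    table = table[table["taxon"].isin(matched)]
    table = table.set_index("taxon").loc[tree.tip_labels].reset_index()
    table.to_csv(out / "trait_table.tsv", sep="\t", index=False)

    analysis = table.copy()
    if config.log_transform:
        for c in karyotypes.TRAIT_NAMES:
            analysis[c] = np.log(analysis[c] + 1.0)

    summary: dict = {
        "n_taxa": len(matched),
        "unmatched_tree_tips": unmatched_tree,
        "unmatched_karyotype_taxa": unmatched_data,
        "seed": config.seed,
        "stages": {},
    }
    runners = {
        "signal": lambda: _stage_signal(config, tree, analysis, out),
        "fitmodels": lambda: _stage_fitmodels(config, tree, analysis, out),
        "shifts": lambda: _stage_shifts(config, tree, analysis, out),
        "chromevol": lambda: _stage_chromevol(config, tree, table, out),
        "karyograph": lambda: _stage_karyograph(config, tree, table, out),
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            summary["stages"][stage] = {"status": "skipped"}
            continue
        try:
            result = runners[stage]()
            summary["stages"][stage] = {"status": "ok", **result}
        except Exception as exc:  # isolate stage failures
            log.error("stage %s failed: %s", stage, exc)
            summary["stages"][stage] = {
                "status": "failed", "error": str(exc),
                "traceback": traceback.format_exc(),
            }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float, sort_keys=True)
    return summary


def _traits(config: RunConfig, analysis: pd.DataFrame):
    for name in config.traits:
        yield name, analysis[name].to_numpy(dtype=float)


def _stage_signal(config, tree, analysis, out: Path) -> dict:
    df = signal.signal_table(tree, analysis[["taxon", *config.traits]],
                             n_reps=config.n_reps, seed=config.seed)
    df.to_csv(out / "signal.tsv", sep="\t", index=False, float_format="%.6g")
    return {"table": "signal.tsv"}


def _stage_fitmodels(config, tree, analysis, out: Path) -> dict:
    rows = []
    for name, y in _traits(config, analysis):
        for fit in trait_models.model_table(tree, y):
            rows.append({
                "trait": name, "model": fit.model, "theta": fit.theta,
                "sigma2": fit.sigma2, "neg_lnl": fit.neg_lnl,
                "aic": fit.aic, "aicc": fit.aicc,
                "delta_aicc": fit.delta_aicc,
            })
    pd.DataFrame(rows).to_csv(out / "model_table.tsv", sep="\t",
                              index=False, float_format="%.6g")
    return {"table": "model_table.tsv"}


def _stage_shifts(config, tree, analysis, out: Path) -> dict:
    rows, best = [], {}
    for name, y in _traits(config, analysis):
        scan = rate_shifts.scan_shifts(tree, y, cutoff=config.shift_cutoff,
                                       max_shifts=config.max_shifts)
        for step in scan.steps:
            rows.append({"trait": name, **{k: (str(v) if k == "node" else v)
                                           for k, v in step.items()}})
        best[name] = {"n_shifts": len(scan.best.shifts),
                      "aicc": scan.best.aicc}
        labels = {s.node: f"rate={s.rate:.4g}" for s in scan.best.shifts}
        (out / f"rate_shifts_{name}.nwk").write_text(
            tree.to_newick(node_labels=labels) + "\n")
    pd.DataFrame(rows).to_csv(out / "rate_shifts.tsv", sep="\t", index=False,
                              float_format="%.6g")
    return {"table": "rate_shifts.tsv", "best": best}


def _stage_chromevol(config, tree, table, out: Path) -> dict:
    tip_states = dict(zip(table["taxon"], table["n"].astype(int)))
    families = chromevol.fit_family_table(
        tree, tip_states, config.chromevol_families,
        n_starts=config.n_starts, seed=config.seed)
    families.to_csv(out / "chromevol_models.tsv", sep="\t", index=False,
                    float_format="%.6g")
    best_family = families.iloc[0]["family"]
    best = chromevol.fit(tree, tip_states, best_family,
                         n_starts=config.n_starts, seed=config.seed)
    recon = chromevol.ancestral_marginal(tree, tip_states, best.model)
    _write_ancestral(tree, recon.states, recon.probs,
                     out / "chromevol_ancestral.tsv")
    labels = {node: str(recon.ml_state(node))
              for node in tree.internal_nodes()}
    (out / "chromevol_annotated.nwk").write_text(
        tree.to_newick(node_labels=labels) + "\n")
    root = tree.root
    return {
        "table": "chromevol_models.tsv",
        "best_family": str(best_family),
        "best_aic": float(best.aic),
        "root_ml_n": recon.ml_state(root),
        "root_top2": sorted(
            zip(recon.states.tolist(), recon.probs[root].tolist()),
            key=lambda t: -t[1])[:2],
    }


def _stage_karyograph(config, tree, table, out: Path) -> dict:
    tip_states = {row.taxon: (int(row.n), int(row.fn) // 2)
                  for row in table.itertuples()}
    m1, m2, lrt = karyograph.fit_m1_m2(
        tree, tip_states, y_max=config.sse_y_max, root=config.sse_root,
        multiplier=config.sse_multiplier, n_starts=config.n_starts,
        seed=config.seed, maxiter=config.sse_maxiter)
    recon = karyograph.ancestral_karyograph(
        tree, tip_states, m1.params, y_max=config.sse_y_max,
        root=config.sse_root, multiplier=config.sse_multiplier)
    summary = karyograph.ancestral_summary(tree, recon)
    summary.to_csv(out / "karyograph_ancestral.tsv", sep="\t", index=False,
                   float_format="%.6g")
    karyograph.state_frequency_table(tip_states).to_csv(
        out / "karyograph_states.tsv", sep="\t", index=False)
    report = {
        "M1": {"lnl": m1.lnl, **dataclasses.asdict(m1.params)},
        "M2": {"lnl": m2.lnl, **dataclasses.asdict(m2.params)},
        "lrt": dataclasses.asdict(lrt),
        "root_mean_y": float(summary.loc[summary["is_root"], "mean_y"].iloc[0]),
        "root_mean_x": float(summary.loc[summary["is_root"], "mean_x"].iloc[0]),
    }
    with open(out / "karyograph_fit.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return {"report": "karyograph_fit.json",
            "lrt_statistic": lrt.statistic, "lrt_p": lrt.p_value}


def _write_ancestral(tree, states, probs, path: Path) -> None:
    rows = []
    for i, node in enumerate(tree.internal_nodes()):
        p = probs[node]
        j = int(np.argmax(p))
        rows.append({"node": i, "is_root": node is tree.root,
                     "ml_state": int(states[j]), "ml_prob": float(p[j]),
                     "mean_state": float(np.asarray(states, float) @ p)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.6g")
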