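"""Experiment driver: generation -> construction -> attack -> dynamics.

A single YAML/JSON config (versioned schema) declares which stages run;
every stochastic stage receives a sub-seed derived from one master seed, so
a config re-run reproduces every output byte for byte.  Outputs are TSV
tables whose headers echo the config hash and sub-seed; the manifest lists
every file with its sha256 checksum.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from netres._rng import subseed
from netres import abbm as abbm_mod
from netres.attack import AttackSpec, compare_curves, run_attack
from netres.construct import pearson_corr, signed_threshold_keep_connected, threshold_by_size_density
from netres.io import write_edgelist_tsv, write_table_tsv
from netres.spreading import sa_attack_experiment
from netres.synth import GeneratorSpec, gen_block_timeseries, gen_brain_like, gen_signed_roi_corr

SCHEMA_VERSION = 1

DEFAULT_CONFIG = {
    "version": SCHEMA_VERSION,
    "master_seed": 0,
    "output_dir": "netres_out",
    "n_replicates": 1,
    "stages": {},
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(path_or_dict)
    merged = {**DEFAULT_CONFIG, **cfg}
    if merged.get("version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported config version {merged.get('version')!r}")
    if not isinstance(merged.get("stages"), dict):
        raise ValueError("config must declare a 'stages' mapping")
    return merged


def config_hash(cfg: dict) -> str:
    """Hash of the scientific content of a config (where outputs land is
    excluded, so relocated re-runs reproduce byte-identical tables)."""
    core = {k: v for k, v in cfg.items() if k != "output_dir"}
    return hashlib.sha256(json.dumps(core, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    cfg = load_config(cfg)
    stages = cfg["stages"]
    seed = int(cfg["master_seed"])
    chash = config_hash(cfg)
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    log: list[dict] = []

    def stamp(stage: str, **extra) -> dict:
        return {"config_hash": chash, "stage": stage, **extra}

    def record(stage: str, t0: float, params: dict, outputs: list[Path]) -> None:
        log.append(
            {
                "stage": stage,
                "params": params,
                "seed": subseed(seed, stage),
                "wall_time_s": round(time.perf_counter() - t0, 3),
                "outputs": [str(p) for p in outputs],
            }
        )

    artifacts: dict[str, object] = {}

    if "generate" in stages:
        t0 = time.perf_counter()
        g = stages["generate"] or {}
        outputs = []
        if "binary" in g:
            b = g["binary"]
            net = gen_brain_like(
                n=int(b.get("n", 300)),
                exponent=float(b.get("exponent", 2.0)),
                cutoff=float(b.get("cutoff", 20.0)),
                p_shortcut=float(b.get("p_shortcut", 0.1)),
                seed=subseed(seed, "generate", "binary"),
            )
            net.meta.update(stamp("generate"))
            artifacts["binary_net"] = net
            p = out_dir / "generate" / "binary_net.tsv"
            p.parent.mkdir(parents=True, exist_ok=True)
            write_edgelist_tsv(net, p)
            outputs.append(p)
        if "timeseries" in g:
            tspec = g["timeseries"]
            spec = GeneratorSpec(
                kind="block_timeseries",
                n_nodes=int(tspec.get("n", 200)),
                params=tspec.get("params", {}),
                seed=subseed(seed, "generate", "timeseries"),
            )
            ts = gen_block_timeseries(spec)
            artifacts["corr"] = pearson_corr(ts)
        if "signed_roi" in g:
            r = g["signed_roi"]
            corr = gen_signed_roi_corr(
                n=int(r.get("n", 90)),
                n_blocks=int(r.get("n_blocks", 6)),
                seed=subseed(seed, "generate", "signed_roi"),
            )
            artifacts["roi_net"] = signed_threshold_keep_connected(corr)
        files += outputs
        record("generate", t0, g, outputs)

    if "topology_attack" in stages:
        t0 = time.perf_counter()
        t = stages["topology_attack"] or {}
        net = artifacts.get("binary_net")
        if net is None and "corr" in artifacts:
            net = threshold_by_size_density(artifacts["corr"], float(t.get("rho", 2.5)))
        if net is None:
            raise ValueError("topology_attack requires stage 'generate' (binary or timeseries)")
        results = []
        for strategy in t.get("strategies", ["degree", "random"]):
            reps = int(cfg["n_replicates"]) if strategy == "random" else 1
            for rep in range(reps):
                spec = AttackSpec(
                    strategy=strategy,
                    direction=t.get("direction", "hub"),
                    fraction_per_round=float(t.get("fraction_per_round", 0.05)),
                    seed=subseed(seed, "topology_attack", strategy, rep),
                )
                results.append(run_attack(net, spec))
        table = compare_curves(results)
        p = out_dir / "topology_attack" / "curves.tsv"
        p.parent.mkdir(parents=True, exist_ok=True)
        write_table_tsv(table, p, stamp("topology_attack", seed=subseed(seed, "topology_attack")))
        files.append(p)
        record("topology_attack", t0, t, [p])

    if "sa" in stages:
        t0 = time.perf_counter()
        s = stages["sa"] or {}
        corr = artifacts.get("corr")
        if corr is None:
            raise ValueError("sa requires stage 'generate' with a 'timeseries' block")
        ranking_net = threshold_by_size_density(corr, float(s.get("rho", 2.5)))
        fractions = s.get("fractions", [round(f, 2) for f in np.arange(0.05, 0.81, 0.05)])
        rows = []
        for strategy in s.get("strategies", ["degree", "random"]):
            res = sa_attack_experiment(
                corr,
                ranking_net,
                strategy=strategy,
                fractions=fractions,
                direction=s.get("direction", "hub"),
                n_seeds=int(s.get("n_seeds", 50)),
                alpha=float(s.get("alpha", 1.0)),
                gamma=float(s.get("gamma", 0.96)),
                n_steps=int(s.get("n_steps", 100)),
                seed=subseed(seed, "sa", strategy),
            )
            for (frac, total), phase in zip(res.curve, res.phases):
                rows.append(
                    {
                        "strategy": strategy,
                        "fraction_removed": frac,
                        "final_total_activity": total,
                        "phase": phase,
                    }
                )
        import pandas as pd

        p = out_dir / "sa" / "final_totals.tsv"
        p.parent.mkdir(parents=True, exist_ok=True)
        write_table_tsv(pd.DataFrame(rows), p, stamp("sa", seed=subseed(seed, "sa")))
        files.append(p)
        record("sa", t0, s, [p])

    if "abbm" in stages:
        t0 = time.perf_counter()
        a = stages["abbm"] or {}
        net = artifacts.get("roi_net")
        if net is None:
            raise ValueError("abbm requires stage 'generate' with a 'signed_roi' block")
        ga_cfg = abbm_mod.GAConfig(
            population_size=int(a.get("population_size", 20)),
            n_generations=int(a.get("n_generations", 20)),
            fitness_trials=int(a.get("fitness_trials", 40)),
            seed=subseed(seed, "abbm", "ga"),
        )
        rule, history = abbm_mod.ga_search(net, ga_cfg)
        results = abbm_mod.abbm_attack_experiment(
            net,
            rule,
            trials_per_density=int(a.get("trials_per_density", 30)),
            fraction=float(a.get("fraction", 0.10)),
            seed=subseed(seed, "abbm", "attack"),
        )
        table = abbm_mod.attack_table(results)
        pdir = out_dir / "abbm"
        pdir.mkdir(parents=True, exist_ok=True)
        rule_path = pdir / "rule.json"
        rule_path.write_text(
            json.dumps(
                {"rule_number": rule.rule_number, "tau_pos": rule.tau_pos, "tau_neg": rule.tau_neg}
            )
            + "\n"
        )
        p1 = pdir / "ga_history.tsv"
        p2 = pdir / "accuracy.tsv"
        write_table_tsv(history, p1, stamp("abbm", seed=ga_cfg.seed))
        write_table_tsv(table, p2, stamp("abbm", seed=subseed(seed, "abbm", "attack")))
        files += [rule_path, p1, p2]
        record("abbm", t0, a, [rule_path, p1, p2])

    manifest = {
        "config_hash": chash,
        "master_seed": seed,
        "output_dir": str(out_dir),
        "files": [{"path": str(p.relative_to(out_dir)), "sha256": _sha256(p)} for p in files],
        "log": log,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def report(manifest: dict, fig_dir: str | Path | None = None) -> str:
    """Render figures for every curve table in the manifest and return a
    text summary; an empty manifest yields an empty report."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    out_dir = Path(manifest.get("output_dir", "."))
    fig_dir = Path(fig_dir) if fig_dir else out_dir / "figures"
    lines: list[str] = []
    for entry in manifest.get("files", []):
        path = out_dir / entry["path"]
        if path.suffix != ".tsv":
            continue
        df = pd.read_csv(path, sep="\t", comment="#")
        fig_dir.mkdir(parents=True, exist_ok=True)
        fig, ax = plt.subplots(figsize=(6, 4))
        name = path.stem
        if {"fraction_removed", "metric", "mean"} <= set(df.columns):
            for (strategy, metric), sub in df.groupby(["strategy", "metric"]):
                ax.errorbar(
                    sub["fraction_removed"], sub["mean"], yerr=sub["sd"], label=f"{strategy}:{metric}"
                )
            ax.set_xlabel("fraction removed")
            lines.append(f"{name}: topology curves for {df['strategy'].nunique()} strategies")
        elif "final_total_activity" in df.columns:
            for strategy, sub in df.groupby("strategy"):
                ax.plot(sub["fraction_removed"], sub["final_total_activity"], marker="o", label=strategy)
            ax.set_xlabel("fraction removed")
            ax.set_ylabel("final total activity")
            lines.append(f"{name}: SA final-total-activity curves")
        elif "accuracy" in df.columns and "density" in df.columns:
            for (strategy, direction), sub in df.groupby(["strategy", "direction"]):
                ax.plot(sub["density"], sub["accuracy"], marker=".", label=f"{strategy}/{direction}")
            ax.set_xlabel("initial density")
            ax.set_ylabel("accuracy")
            lines.append(f"{name}: density-classification accuracy curves")
        elif "best" in df.columns:
            ax.plot(df["generation"], df["best"], label="best")
            ax.plot(df["generation"], df["mean"], label="mean")
            ax.set_xlabel("generation")
            ax.set_ylabel("fitness")
            lines.append(f"{name}: GA fitness history")
        else:
            plt.close(fig)
            continue
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(fig_dir / f"{name}.png", dpi=100)
        plt.close(fig)
    return "\n".join(lines)
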