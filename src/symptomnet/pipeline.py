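"""End-to-end orchestration of the full two-wave analysis.

One config drives: descriptives -> a cross-sectional network per wave
with centralities -> congruence and invariance between the waves -> the
cross-lagged network with in-/out-strength -> bootstrap stability
diagnostics.  A master seed deterministically spawns per-stage seeds,
so any stage can be reproduced in isolation, and a manifest recording
config, seeds and versions is written alongside the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .centrality import centrality_table, directed_centrality_table
from .clpn import estimate_clpn
from .comparison import invariance_test
from .ising import estimate_ising
from .panel import (ColumnMap, SymptomPanel, cronbach_alpha, dichotomize,
                    mcnemar, paired_t, prevalence_table, read_panel,
                    score_pgsi, write_panel)
from .simulate import default_scenario, generate_two_wave
from .stability import (StabilityReport, bootstrap_edges, case_dropping_cs,
                        clpn_centrality_fn, difference_tests,
                        ising_centrality_fn, ising_edge_fn)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_full_analysis", "summarize"]


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce a full analysis run."""

    input_path: str | None = None        # CSV panel; or use a scenario
    scenario: str | None = "paper_like"
    n: int | None = None                 # override scenario sample size
    column_template: str = "pg{item}_w{wave}"
    n_items: int = 9
    gamma: float = 0.25
    rule: str = "AND"
    closeness_variant: str = "inverse_sum"
    n_perm: int = 1000
    n_boot: int = 1000
    cs_n_boot: int | None = None         # defaults to n_boot
    cs_proportions: tuple | None = None  # defaults to the full 10-75% grid
    folds: int = 10
    seed: int = 1
    output_dir: str = "symptomnet_out"
    stages: tuple = ("descriptives", "cross_sectional", "comparison",
                     "clpn", "stability")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        d = json.loads(Path(path).read_text())
        d.pop("_comment", None)
        cfg = cls(**d)
        cfg.stages = tuple(cfg.stages)
        if cfg.cs_proportions is not None:
            cfg.cs_proportions = tuple(cfg.cs_proportions)
        return cfg

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["stages"] = list(self.stages)
        if self.cs_proportions is not None:
            d["cs_proportions"] = list(self.cs_proportions)
        Path(path).write_text(json.dumps(d, indent=2))


def _stage_seeds(master: int, names) -> dict:
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(names))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(names, children)}


def _load_panel(cfg: AnalysisConfig, seed: int) -> SymptomPanel:
    if cfg.input_path:
        cmap = ColumnMap(template=cfg.column_template, n_items=cfg.n_items)
        return read_panel(cfg.input_path, cmap).complete_cases()
    ising, clpn_params, n_default = default_scenario(cfg.scenario)
    n = cfg.n or n_default
    return generate_two_wave(ising, clpn_params, n, seed)


def run_full_analysis(config: AnalysisConfig) -> Path:
    """Run the configured stages, writing all outputs under
    ``config.output_dir``.  Returns the output directory.

    A stage failure aborts with a stage-labelled error; outputs of the
    completed stages are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, ("data", "comparison", "clpn",
                                       "boot_w1", "boot_clpn", "cs"))
    config.to_json(out / "config.json")
    stage = "setup"
    results: dict = {"seeds": seeds}
    try:
        stage = "data"
        panel = _load_panel(config, seeds["data"])
        panel.require_complete("pipeline")
        write_panel(panel, out / "panel.csv")
        binary = dichotomize(panel)
        labels = panel.item_labels

        if "descriptives" in config.stages:
            stage = "descriptives"
            prev = prevalence_table(panel)
            prev.to_csv(out / "prevalence.csv", index=False)
            desc = {}
            for w in range(panel.n_waves):
                wave = panel.wave(w)
                desc[f"alpha_wave{w+1}"] = cronbach_alpha(wave)
            if panel.scale == "ordinal0to3" and panel.n_waves >= 2:
                t1 = score_pgsi(panel.wave(0))
                t2 = score_pgsi(panel.wave(1))
                tt = paired_t(t1, t2)
                desc["paired_t"] = {"t": tt.statistic, "df": tt.df,
                                    "p": tt.p_value, "d": tt.effect_size,
                                    **tt.extra}
                mc = mcnemar((t1 > 0).astype(int), (t2 > 0).astype(int))
                desc["mcnemar"] = {"chi2": mc.statistic, "p": mc.p_value,
                                   "g": mc.effect_size, **mc.extra}
            (out / "descriptives.json").write_text(json.dumps(desc, indent=2))
            results["descriptives"] = desc

        nets = []
        if "cross_sectional" in config.stages:
            stage = "cross_sectional"
            for w in range(binary.n_waves):
                net = estimate_ising(binary.wave(w), config.gamma,
                                     config.rule, labels=labels)
                net.to_json(out / f"network_wave{w+1}.json")
                net.edge_list().to_csv(out / f"edges_wave{w+1}.csv", index=False)
                net.to_graphml(out / f"network_wave{w+1}.graphml")
                ct = centrality_table(net.weights, labels,
                                      config.closeness_variant)
                ct.to_csv(out / f"centrality_wave{w+1}.csv", index=False)
                nets.append(net)
            results["cross_sectional"] = [
                {"wave": w + 1, "nonzero_edges": net.nonzero_edges(),
                 "possible_edges": net.n_possible_edges(),
                 "mean_nonzero_weight": net.mean_nonzero_weight()}
                for w, net in enumerate(nets)]

        if "comparison" in config.stages and len(nets) >= 2:
            stage = "comparison"
            comp = invariance_test(
                binary.wave(0), binary.wave(1),
                estimator=lambda d: estimate_ising(
                    d, config.gamma, config.rule).weights,
                n_perm=config.n_perm, seed=seeds["comparison"])
            (out / "comparison.json").write_text(
                json.dumps(comp.to_dict(), indent=2))
            results["comparison"] = comp.to_dict()

        dnet = None
        if "clpn" in config.stages and binary.n_waves >= 2:
            stage = "clpn"
            dnet = estimate_clpn(binary, folds=config.folds,
                                 seed=seeds["clpn"])
            dnet.to_json(out / "clpn.json")
            dnet.edge_list().to_csv(out / "clpn_edges.csv", index=False)
            dnet.to_graphml(out / "clpn.graphml")
            dct = directed_centrality_table(dnet.matrix, labels)
            dct.to_csv(out / "clpn_centrality.csv", index=False)
            results["clpn"] = {"nonzero_edges": dnet.nonzero_edges(),
                               "possible_edges": dnet.n_possible_edges(),
                               "mean_nonzero_weight": dnet.mean_nonzero_weight()}

        if "stability" in config.stages:
            stage = "stability"
            B = config.n_boot
            csB = config.cs_n_boot or B
            from .stability import DEFAULT_DROP_PROPORTIONS
            props = config.cs_proportions or DEFAULT_DROP_PROPORTIONS
            data1 = binary.wave(0)
            rep = StabilityReport()
            rep.edges = bootstrap_edges(
                data1, ising_edge_fn(config.gamma, config.rule),
                B=B, seed=seeds["boot_w1"])
            rep.centrality_differences["strength"] = difference_tests(
                data1, ising_centrality_fn("strength", config.gamma,
                                           config.rule),
                B=B, seed=seeds["boot_w1"])
            for index in ("strength", "closeness", "betweenness"):
                rep.cs[index] = case_dropping_cs(
                    data1,
                    ising_centrality_fn(index, config.gamma, config.rule,
                                        config.closeness_variant),
                    proportions=props, B=csB, seed=seeds["cs"])
            rep.to_json(out / "stability_wave1.json")
            results["stability_wave1"] = {"cs": rep.cs_coefficients()}
            if dnet is not None:
                drep = StabilityReport()
                drep.cs["out_strength"] = case_dropping_cs(
                    binary.responses,
                    clpn_centrality_fn("out_strength", folds=config.folds,
                                       seed=seeds["clpn"]),
                    proportions=props, B=csB, seed=seeds["cs"])
                drep.cs["in_strength"] = case_dropping_cs(
                    binary.responses,
                    clpn_centrality_fn("in_strength", folds=config.folds,
                                       seed=seeds["clpn"]),
                    proportions=props, B=csB, seed=seeds["cs"])
                drep.to_json(out / "stability_clpn.json")
                results["stability_clpn"] = {"cs": drep.cs_coefficients()}
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "symptomnet_version": __version__,
        "config": json.loads((out / "config.json").read_text()),
        "config_sha256": hashlib.sha256(
            (out / "config.json").read_bytes()).hexdigest(),
        "seeds": seeds,
        "results": _jsonable(results),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def summarize(bundle_dir: str | Path) -> str:
    """Human-readable markdown summary of a completed result bundle."""
    out = Path(bundle_dir)
    missing = []
    lines = ["# Symptom network analysis summary", ""]
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(f"symptomnet {manifest['symptomnet_version']}; "
                     f"master seed {manifest['config'].get('seed')}")
        lines.append("")
    else:
        missing.append("manifest.json")
    for w in (1, 2):
        f = out / f"network_wave{w}.json"
        if not f.exists():
            missing.append(f.name)
            continue
        net = json.loads(f.read_text())
        Wm = np.asarray(net["weights"])
        p = Wm.shape[0]
        possible = p * (p - 1) // 2
        nz = int(np.count_nonzero(np.triu(Wm, 1)))
        mean_w = (np.triu(Wm, 1)[np.triu(Wm, 1) != 0].mean()
                  if nz else float("nan"))
        lines.append(f"- Wave {w} network: {nz} ({100*nz/possible:.1f}%) of "
                     f"{possible} possible edges non-zero; mean non-zero "
                     f"weight {mean_w:.2f}")
        cent = out / f"centrality_wave{w}.csv"
        if cent.exists():
            ct = pd.read_csv(cent)
            top = ct.loc[ct["strength_z"].idxmax(), "node"]
            low = ct.loc[ct["strength_z"].idxmin(), "node"]
            lines.append(f"  most central (strength): {top}; least: {low}")
    comp = out / "comparison.json"
    if comp.exists():
        c = json.loads(comp.read_text())
        lines.append(f"- Invariance: M = {c['M']:.2f} (p = {c['M_p']:.2f}), "
                     f"S = {c['S']:.2f} (p = {c['S_p']:.2f}); "
                     f"edge presence phi = {c['phi']:.2f}")
    else:
        missing.append("comparison.json")
    clpn_f = out / "clpn.json"
    if clpn_f.exists():
        d = json.loads(clpn_f.read_text())
        Bm = np.asarray(d["matrix"])
        p = Bm.shape[0]
        nz = int(np.count_nonzero(Bm))
        mean_w = Bm[Bm != 0].mean() if nz else float("nan")
        lines.append(f"- Cross-lagged network: {nz} "
                     f"({100*nz/(p*p):.1f}%) of {p*p} possible directed "
                     f"edges non-zero"
                     + (f"; mean non-zero weight {mean_w:.2f}" if nz else ""))
    else:
        missing.append("clpn.json")
    for name, label in (("stability_wave1.json", "wave-1 network"),
                        ("stability_clpn.json", "cross-lagged network")):
        f = out / name
        if f.exists():
            s = json.loads(f.read_text())
            cs = ", ".join(f"{k}: {v:.2f}"
                           for k, v in s["cs_coefficients"].items())
            lines.append(f"- CS coefficients ({label}): {cs}")
        else:
            missing.append(name)
    if missing:
        lines += ["", "Missing bundle components: " + ", ".join(missing)]
    return "\n".join(lines) + "\n"
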