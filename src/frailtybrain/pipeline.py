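"""End-to-end pipeline orchestration.

``run_pipeline`` executes the full analysis chain from one config:
simulate (or load) a cohort -> binarize/screen items and score the
frailty index (+ the three sensitivity variants) -> group statistics
(ANOVA/Tukey and covariate-adjusted ANCOVA) -> three pairwise
class-weighted classifications -> per-group region and edge association
models -> pairwise subsampling contrasts. All randomness flows from the
single master seed in the config; every stage writes CSV/JSON outputs
and the run is described by a :class:`RunManifest` whose config hash
and seed make re-runs reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassifierConfig, FrailtyClassifier
from .cohort import CohortConfig, GroupSpec, ItemSpec, simulate_cohort
from .contrast import SubsampleConfig, contrast_groups, subsample_t_distribution
from .exceptions import FrailtyBrainError
from .frailty import (HealthItemSpec, SENSITIVITY_VARIANTS, binarize_items,
                      compute_frailty_index, screen_items, variant_index)
from .groupstats import ancova, one_way_anova
from .neuro import fit_edge_models, fit_region_models, node_degree_summary

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline", "default_config", "load_config"]


def default_config(**overrides) -> dict:
    """A scaled-down default pipeline config (full cohort sizes, small
    imaging problem) suitable for demonstration runs."""
    cfg = {
        "seed": 0,
        "cohort": {
            "groups": [
                {"label": "CU", "n": 1924, "mean": 0.14, "sd": 0.065},
                {"label": "AD", "n": 1126, "mean": 0.24, "sd": 0.075},
                {"label": "FTLD", "n": 411, "mean": 0.27, "sd": 0.10},
            ],
            "missing_rate": 0.02,
            "item_frailty_coupling": 1.0,
            "n_regions": 12,
            "n_scanners": 2,
        },
        "frailty": {"variants": True},
        "classify": {"k_folds": 10, "search_iters": 10, "n_init": 5,
                     "variants": False},
        "assoc": {"alpha": 0.05},
        "contrast": {"n_draws": 100, "fraction": 0.8},
    }
    cfg.update(overrides)
    return cfg


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def _cohort_config(cfg: dict) -> CohortConfig:
    c = cfg["cohort"]
    groups = tuple(GroupSpec(g["label"], int(g["n"]), float(g["mean"]),
                             float(g["sd"])) for g in c["groups"])
    return CohortConfig(
        groups=groups,
        missing_rate=float(c.get("missing_rate", 0.0)),
        item_frailty_coupling=float(c.get("item_frailty_coupling", 0.0)),
        n_regions=int(c.get("n_regions", 116)),
        n_scanners=int(c.get("n_scanners", 2)),
        roi_slopes=c.get("roi_slopes"),
        edge_slopes=c.get("edge_slopes"),
        seed=int(cfg.get("seed", 0)),
    )


def specs_for_cohort(config: CohortConfig) -> list[HealthItemSpec]:
    """Identity-rule item specs for a synthetic cohort's (already binary)
    items, with sensitivity tags inferred from the item names."""
    tags = {"mmse": "MMSE", "gad_7": "GAD7", "gds_sf": "GDS_SF"}
    specs = []
    for it in config.items:
        tag = tags.get(it.name)
        if it.name.startswith("cdr"):
            tag = "CDR"
        specs.append(HealthItemSpec(it.name, it.domain, "binary",
                                    {"kind": "identity"}, tag))
    return specs


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    started: float
    finished: float | None = None
    outputs: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "config_hash": self.config_hash, "seed": self.seed,
                "version": self.version, "started": self.started,
                "finished": self.finished, "outputs": self.outputs,
                "stages": self.stages,
            }, fh, indent=1)


def _hash_config(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: dict, outdir) -> RunManifest:
    """Execute the full chain; outputs land under ``outdir``.

    Any stage failure raises with the stage name prefixed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(config_hash=_hash_config(config), seed=seed,
                           version=__version__, started=time.time())
    summary: dict = {"seed": seed}

    def stage(name):
        manifest.stages.append(name)
        logger.info("stage: %s", name)

    try:
        # ---- simulate ------------------------------------------------
        stage("simulate")
        ccfg = _cohort_config(config)
        cohort = simulate_cohort(ccfg)
        manifest.outputs.update(cohort.write(outdir / "cohort"))

        # ---- frailty -------------------------------------------------
        stage("frailty")
        specs = specs_for_cohort(ccfg)
        deficits = binarize_items(cohort.item_table, specs)
        ledger = screen_items(deficits)
        ledger.to_csv(outdir / "screening_ledger.csv")
        manifest.outputs["screening_ledger"] = str(outdir / "screening_ledger.csv")
        retained = ledger.retained
        fi = compute_frailty_index(deficits, retained, variant="full")
        frames = {"full": fi}
        if config.get("frailty", {}).get("variants", True):
            for name, tags in SENSITIVITY_VARIANTS.items():
                frames[name] = variant_index(deficits, specs, tags,
                                             retained=retained, variant=name)
        fi_all = pd.concat(
            {k: v["index"] for k, v in frames.items()}, axis=1)
        fi_all.insert(0, "group", cohort.group)
        fi_all.to_csv(outdir / "frailty_index.csv", index_label="participant")
        manifest.outputs["frailty_index"] = str(outdir / "frailty_index.csv")
        index = fi["index"]

        # ---- group statistics ---------------------------------------
        stage("stats")
        ok = index.notna()
        anova_res = one_way_anova(index[ok], cohort.group[ok])
        stats_out = {
            "anova": {"F": anova_res.statistic, "df": anova_res.df,
                      "p": anova_res.p_value, "n": anova_res.n_used,
                      "direction": anova_res.direction()},
        }
        if cohort.demographics is not None:
            anc = ancova(index[ok], cohort.group[ok],
                         cohort.demographics[ok])
            stats_out["ancova"] = {"F": anc.statistic, "df": anc.df,
                                   "p": anc.p_value, "n": anc.n_used,
                                   "direction": anc.direction()}
        summary["group_stats"] = stats_out

        # ---- classification (three pairwise comparisons) -------------
        stage("classify")
        pairs = list(combinations(ccfg.group_labels, 2))
        clf_cfg = config.get("classify", {})
        summary["classification"] = {}
        for ref, pos in pairs:
            mask = cohort.group.isin([ref, pos]) & index.notna()
            y = (cohort.group[mask] == pos).astype(int).to_numpy()
            for variant, frame in frames.items():
                if variant != "full" and not clf_cfg.get("variants", True):
                    continue
                x = frame.loc[mask, "index"]
                sub_ok = x.notna()
                cc = ClassifierConfig(
                    k_folds=int(clf_cfg.get("k_folds", 10)),
                    search_iters=int(clf_cfg.get("search_iters", 25)),
                    n_init=int(clf_cfg.get("n_init", 8)),
                    seed=seed)
                res = FrailtyClassifier(x[sub_ok].to_frame("frailty"),
                                        y[sub_ok.to_numpy()], cc).fit()
                key = f"{pos}_vs_{ref}"
                summary["classification"].setdefault(key, {})[variant] = {
                    "mean_auc": res.mean_auc, "sd_auc": res.sd_auc,
                    "test_auc": res.test_auc,
                    "balanced_accuracy":
                        res.test_metrics["balanced_accuracy"],
                    "brier": res.test_metrics["brier"],
                }

        # ---- associations per group ----------------------------------
        stage("assoc")
        alpha = float(config.get("assoc", {}).get("alpha", 0.05))
        region_results, edge_results = {}, {}
        for g in ccfg.group_labels:
            mask = ((cohort.group == g) & index.notna()).to_numpy()
            region_results[g] = fit_region_models(
                cohort.roi_volumes, index, cohort.scanner,
                group_mask=mask, alpha=alpha)
            region_results[g].to_csv(outdir / f"assoc_regions_{g}.csv")
            manifest.outputs[f"assoc_regions_{g}"] = str(
                outdir / f"assoc_regions_{g}.csv")
            edge_results[g] = fit_edge_models(
                cohort.connectivity, index, cohort.scanner,
                group_mask=mask, alpha=alpha)
            edge_results[g].to_csv(outdir / f"assoc_edges_{g}.csv")
            manifest.outputs[f"assoc_edges_{g}"] = str(
                outdir / f"assoc_edges_{g}.csv")
            degree = node_degree_summary(edge_results[g])
            degree.to_csv(outdir / f"node_degree_{g}.csv")
            manifest.outputs[f"node_degree_{g}"] = str(
                outdir / f"node_degree_{g}.csv")
        summary["associations"] = {
            g: {"significant_regions": len(region_results[g].significant_units),
                "significant_edges": len(edge_results[g].significant_units)}
            for g in ccfg.group_labels}

        # ---- subsampling contrasts per pair --------------------------
        stage("contrast")
        ctr = config.get("contrast", {})
        sub_cfg = SubsampleConfig(n_draws=int(ctr.get("n_draws", 1000)),
                                  fraction=float(ctr.get("fraction", 0.8)),
                                  seed=seed)
        summary["contrasts"] = {}
        for a, b in pairs:
            restrict = sorted(set(region_results[a].significant_units)
                              | set(region_results[b].significant_units))
            key = f"{a}_vs_{b}"
            if not restrict:
                summary["contrasts"][key] = {"n_units": 0, "significant": 0}
                continue
            t_a = subsample_t_distribution(
                cohort.roi_volumes[restrict], index, cohort.scanner, sub_cfg,
                group_mask=((cohort.group == a) & index.notna()).to_numpy())
            t_b = subsample_t_distribution(
                cohort.roi_volumes[restrict], index, cohort.scanner, sub_cfg,
                group_mask=((cohort.group == b) & index.notna()).to_numpy())
            cres = contrast_groups(t_a, t_b, restrict, group_a=a, group_b=b,
                                   alpha=alpha, fraction=sub_cfg.fraction)
            cres.to_csv(outdir / f"contrast_{key}.csv")
            manifest.outputs[f"contrast_{key}"] = str(
                outdir / f"contrast_{key}.csv")
            summary["contrasts"][key] = {
                "n_units": len(cres.table),
                "significant": len(cres.significant_units)}

        # ---- report --------------------------------------------------
        stage("report")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, default=_json_default)
        manifest.outputs["summary"] = str(outdir / "summary.json")
        _write_markdown(summary, outdir / "summary.md")
        manifest.outputs["summary_md"] = str(outdir / "summary.md")
    except FrailtyBrainError as err:
        raise FrailtyBrainError(
            f"pipeline failed in stage {manifest.stages[-1]!r}: {err}") from err

    manifest.finished = time.time()
    manifest.to_json(outdir / "manifest.json")
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    return str(obj)


def _write_markdown(summary: dict, path) -> None:
    lines = ["# Pipeline summary", ""]
    gs = summary.get("group_stats", {})
    if "anova" in gs:
        a = gs["anova"]
        lines += [f"ANOVA on frailty index: F({a['df'][0]:g}, {a['df'][1]:g}) "
                  f"= {a['F']:.1f}, p = {a['p']:.3g} ({a['direction']})", ""]
    if summary.get("classification"):
        lines += ["## Pairwise classification (mean CV AUC)", ""]
        for pair, variants in summary["classification"].items():
            for variant, m in variants.items():
                lines.append(f"- {pair} [{variant}]: "
                             f"{m['mean_auc']:.3f} +/- {m['sd_auc']:.3f}")
        lines.append("")
    if summary.get("associations"):
        lines += ["## Significant associations", ""]
        for g, m in summary["associations"].items():
            lines.append(f"- {g}: {m['significant_regions']} regions, "
                         f"{m['significant_edges']} edges")
        lines.append("")
    if summary.get("contrasts"):
        lines += ["## Subsampling contrasts", ""]
        for pair, m in summary["contrasts"].items():
            lines.append(f"- {pair}: {m['significant']}/{m['n_units']} "
                         "units significant")
    Path(path).write_text("\n".join(lines) + "\n")
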