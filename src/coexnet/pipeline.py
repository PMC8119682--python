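"""End-to-end orchestration: simulate -> preprocess -> network -> traits
-> hubs -> hgs -> enrich -> cogscore -> clinstats.

A single YAML config drives all stages; every source of randomness flows
from the one ``seed`` key. Each stage writes its plain-text artifacts
(TSV/CSV/JSON) before the next starts, and a run manifest records the
config hash, per-stage counts and tool version so deterministic stages
can be verified byte-identical across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import clinpath, cognitive, enrich, hgs, hubs, network, prep, synth, traitcorr

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "load_config", "run_all", "STAGES"]

STAGES = [
    "simulate", "preprocess", "network", "traits", "hubs",
    "hgs", "enrich", "cogscore", "clinstats",
]

# key -> (type, default); nested dicts are sub-schemas.
_SCHEMA: dict[str, Any] = {
    "seed": (int, 0),
    "simulate": {
        "n_genes": (int, 600),
        "n_samples": (int, 60),
        "module_sizes": (list, [150, 100, 80]),
        "loading_range": (list, [0.7, 0.95]),
        "meta_groups": (list, None),
        "super_factor_weight": (float, 0.0),
        "traits": (list, [
            {"name": "trait_m1", "module": 1, "rho": 0.8, "kind": "continuous"},
            {"name": "grade", "module": 2, "rho": 0.6, "kind": "ordinal", "levels": 4},
        ]),
        "cognitive": (list, [
            {"name": "recall", "domain": "memory", "direction": "higher_better",
             "control_mean": 50.0, "control_sd": 10.0, "patient_shift": 12.0},
            {"name": "naming", "domain": "language", "direction": "higher_better",
             "control_mean": 30.0, "control_sd": 5.0, "patient_shift": 6.0},
            {"name": "stroop_time", "domain": "executive", "direction": "lower_better",
             "control_mean": 60.0, "control_sd": 15.0, "patient_shift": 20.0},
        ]),
        "n_patients": (int, 24),
        "n_controls": (int, 24),
        "flag_rate": (float, 0.02),
        "intensity_offset": (float, 8.0),
    },
    "preprocess": {
        "max_ok_flags": (int, 1),
        "normalize": (bool, True),
    },
    "network": {
        "power": (int, None),
        "r2_min": (float, 0.90),
        "kind": (str, "unsigned"),
        "min_module_size": (int, 30),
        "deep_split": (int, 2),
        "pam_stage": (bool, True),
        "meta_method": (str, "gap"),
        "meta_cut_height": (float, 0.25),
    },
    "selection": {"r_min": (float, 0.50), "p_max": (float, 0.05)},
    "hubs": {"q_high": (float, 0.90), "alpha": (float, 0.05)},
    "hgs": {"gs_min": (float, 0.5), "mm_min": (float, 0.8), "alpha": (float, 0.05)},
    "enrich": {"gmt": (str, None), "alpha": (float, 0.05)},
    "cognitive": {
        "alpha": (float, 0.05),
        "only_significant": (bool, True),
        "by_side": (bool, True),
    },
    "clinstats": {"alpha": (float, 0.05), "pairs": (list, None)},
}

_NUMERIC_OK = {float: (int, float), int: (int,)}


def _validate(node: dict, schema: dict, prefix: str, problems: list[str]) -> dict:
    out = {}
    for key, value in node.items():
        if key not in schema:
            problems.append(f"unknown key: {prefix}{key}")
    for key, spec in schema.items():
        path = f"{prefix}{key}"
        if isinstance(spec, dict):
            sub = node.get(key, {})
            if not isinstance(sub, dict):
                problems.append(f"{path}: expected a mapping")
                sub = {}
            out[key] = _validate(sub, spec, path + ".", problems)
        else:
            typ, default = spec
            if key in node and node[key] is not None:
                value = node[key]
                allowed = _NUMERIC_OK.get(typ, (typ,))
                if typ is float and isinstance(value, bool):
                    problems.append(f"{path}: expected a number")
                elif not isinstance(value, allowed):
                    problems.append(f"{path}: expected {typ.__name__}, got {type(value).__name__}")
                out[key] = value
            else:
                out[key] = default
    return out


@dataclass
class RunConfig:
    data: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_config(source: str | Path | dict) -> tuple[RunConfig | None, list[str]]:
    """Validate a YAML/JSON/dict config; returns (config, problems)."""
    if isinstance(source, (str, Path)):
        try:
            raw = yaml.safe_load(Path(source).read_text())
        except yaml.YAMLError as err:
            return None, [f"parse error: {err}"]
        if raw is None:
            raw = {}
    else:
        raw = source
    problems: list[str] = []
    if not isinstance(raw, dict):
        return None, ["config root must be a mapping"]
    data = _validate(raw, _SCHEMA, "", problems)
    net = data["network"]
    if net["min_module_size"] < 2:
        problems.append("network.min_module_size: must be >= 2")
    if not 0 <= net["deep_split"] <= 4:
        problems.append("network.deep_split: must be in 0..4")
    if problems:
        return None, problems
    return RunConfig(data=data), []


def load_config(source: str | Path | dict) -> RunConfig:
    cfg, problems = validate_config(source)
    if cfg is None:
        raise ValueError("invalid config:\n" + "\n".join(problems))
    return cfg


def _synth_config(cfg: RunConfig) -> synth.SyntheticConfig:
    sim = cfg["simulate"]
    traits = tuple(
        synth.TraitSpec(
            name=t["name"], module=int(t["module"]), rho=float(t["rho"]),
            kind=t.get("kind", "continuous"), levels=int(t.get("levels", 2)),
        )
        for t in sim["traits"]
    )
    cog = tuple(
        synth.CognitiveTestSpec(
            name=c["name"], domain=c["domain"],
            direction=c.get("direction", "higher_better"),
            control_mean=float(c.get("control_mean", 50.0)),
            control_sd=float(c.get("control_sd", 10.0)),
            patient_shift=float(c.get("patient_shift", 10.0)),
        )
        for c in sim["cognitive"]
    )
    meta = sim["meta_groups"]
    return synth.SyntheticConfig(
        n_genes=sim["n_genes"],
        n_samples=sim["n_samples"],
        module_sizes=tuple(sim["module_sizes"]),
        loading_range=tuple(sim["loading_range"]),
        meta_groups=tuple(tuple(g) for g in meta) if meta else None,
        super_factor_weight=sim["super_factor_weight"],
        trait_specs=traits,
        cognitive_specs=cog,
        n_patients=sim["n_patients"],
        n_controls=sim["n_controls"],
        seed=cfg.seed,
    )


def run_all(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages on synthetic inputs; returns the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "coexnet", "version": __version__,
        "config_hash": cfg.digest(), "stages": [],
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"].append({"stage": stage, **counts})
        log.info("stage %s: %s", stage, counts)

    # --- simulate -----------------------------------------------------
    scfg = _synth_config(cfg)
    values, truth = synth.simulate_expression(scfg)
    traits_df = synth.simulate_traits(truth, scfg)
    battery = synth.simulate_cognitive(scfg)
    flags = synth.simulate_flags(
        scfg.n_genes, scfg.n_samples, cfg["simulate"]["flag_rate"], cfg.seed
    )
    gene_sets = synth.simulate_gene_sets(truth, scfg)
    offset = cfg["simulate"]["intensity_offset"]
    intensities = pd.DataFrame(
        np.power(2.0, values.to_numpy() + offset),
        index=values.index, columns=values.columns,
    )
    intensities.to_csv(out / "expression_raw.tsv", sep="\t", index_label="gene_id")
    flags.to_csv(out / "flags.tsv", sep="\t", index_label="gene_id")
    traits_df.to_csv(out / "traits.csv")
    synth.write_truth(truth, out / "truth.json")
    synth.write_gmt(gene_sets, out / "gene_sets.gmt")
    battery.scores.to_csv(out / "battery_scores.csv")
    battery.subjects.to_csv(out / "battery_subjects.csv")
    battery.tests.to_csv(out / "battery_tests.csv")
    record("simulate", genes=scfg.n_genes, samples=scfg.n_samples,
           traits=traits_df.shape[1], tests=battery.tests.shape[0])

    # --- preprocess ---------------------------------------------------
    raw = prep.read_expression(out / "expression_raw.tsv")
    pp = cfg["preprocess"]
    em = prep.preprocess(
        raw, flags=prep.read_flags(out / "flags.tsv"), annotation=gene_sets,
        max_ok_flags=pp["max_ok_flags"], normalize=pp["normalize"],
    )
    em.values.to_csv(out / "expression_preprocessed.tsv", sep="\t", index_label="gene_id")
    record("preprocess", genes_in=raw.values.shape[0], genes_out=em.values.shape[0])

    # --- network ------------------------------------------------------
    ncfg = cfg["network"]
    model = network.build_network(
        em.values, beta=ncfg["power"], r2_min=ncfg["r2_min"], kind=ncfg["kind"],
        min_module_size=ncfg["min_module_size"], deep_split=ncfg["deep_split"],
        pam_stage=ncfg["pam_stage"], meta_cut_height=ncfg["meta_cut_height"],
        meta_method=ncfg["meta_method"],
    )
    model.module_of_gene.to_frame().to_csv(out / "modules.tsv", sep="\t", index_label="gene_id")
    model.eigengenes.eigengenes.to_csv(out / "eigengenes.csv", index_label="module")
    if model.scan is not None:
        model.scan.table.to_csv(out / "soft_threshold_scan.csv", index=False)
    model.meta.meta_module_of.to_frame().to_csv(out / "meta_modules.csv", index_label="module")
    n_modules = model.module_of_gene[model.module_of_gene != network.GREY].nunique()
    record("network", beta=model.beta, modules=n_modules,
           grey=int((model.module_of_gene == network.GREY).sum()))

    # --- traits -------------------------------------------------------
    sel = cfg["selection"]
    gts = traitcorr.gene_significance(em.values, traits_df)
    ms = traitcorr.module_significance(gts, model.module_of_gene)
    mt = traitcorr.module_trait_correlations(
        model.eigengenes.eigengenes, traits_df, r_min=sel["r_min"], p_max=sel["p_max"]
    )
    gts.gs.to_csv(out / "gene_significance.csv", index_label="gene_id")
    ms.to_csv(out / "module_significance.csv", index_label="module")
    mt.r.to_csv(out / "module_trait_r.csv", index_label="module")
    mt.p.to_csv(out / "module_trait_p.csv", index_label="module")
    report = mt.selection_report()
    report.to_json(out / "selection_report.json", orient="records", indent=1)
    record("traits", traits=traits_df.shape[1], selected=int(mt.selected.sum().sum()))

    # --- hubs ---------------------------------------------------------
    hcfg = cfg["hubs"]
    conn = hubs.connectivities(model.adjacency, model.module_of_gene)
    conn = hubs.classify_hubs(conn, q_high=hcfg["q_high"])
    direction = hubs.expression_direction(gts, alpha=hcfg["alpha"])
    hub_table = conn.join(direction.add_prefix("dir_"))
    hub_table.to_csv(out / "hubs.tsv", sep="\t", index_label="gene_id")
    record("hubs", hhub=int((conn["hub_class"] == "HHub").sum()),
           ihub=int((conn["hub_class"] == "iHub").sum()),
           ehub=int((conn["hub_class"] == "eHub").sum()))

    # --- hgs ----------------------------------------------------------
    gcfg = cfg["hgs"]
    membership = hgs.module_membership(em.values, model.eigengenes)
    hgs_table = hgs.select_hgs(
        gts, membership, model.module_of_gene,
        gs_min=gcfg["gs_min"], mm_min=gcfg["mm_min"], alpha=gcfg["alpha"],
        hub_classes=conn["hub_class"],
    )
    hgs_table.to_csv(out / "hgs.tsv", sep="\t", index=False)
    record("hgs", flagged=int(hgs_table["hgs"].sum()))

    # --- enrich -------------------------------------------------------
    ecfg = cfg["enrich"]
    sets = prep.read_gmt(ecfg["gmt"]) if ecfg["gmt"] else gene_sets
    background = set(em.values.index)
    enrich_rows, fractions = [], {}
    for color in model.assignment.module_colors:
        module_genes = set(em.values.index[model.module_of_gene == color])
        res = enrich.enrich_module(module_genes, background, sets, alpha=ecfg["alpha"])
        res.insert(0, "module", color)
        enrich_rows.append(res)
        fractions[color] = enrich.enriched_gene_fraction(
            module_genes, res, alpha=ecfg["alpha"]
        )
    enrich_table = (
        pd.concat(enrich_rows, ignore_index=True) if enrich_rows else pd.DataFrame()
    )
    enrich_table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    Path(out / "enriched_fraction.json").write_text(json.dumps(fractions, indent=1))
    record("enrich", terms=len(sets.sets),
           significant=int(enrich_table["significant"].sum()) if len(enrich_table) else 0)

    # --- cogscore -----------------------------------------------------
    ccfg = cfg["cognitive"]
    profiles = cognitive.score_battery(
        battery, alpha=ccfg["alpha"], only_significant=ccfg["only_significant"],
        by_side=ccfg["by_side"],
    )
    profiles.to_csv(out / "impairment_profiles.csv", index_label="subject_id")
    table, fisher_p = cognitive.laterality_association(
        profiles, battery.subjects["side"]
    )
    Path(out / "laterality.json").write_text(
        json.dumps({"table": table.tolist(), "p": fisher_p}, indent=1)
    )
    record("cogscore", patients=len(profiles),
           severe=int((profiles["severity"] == "severe").sum()),
           laterality_p=round(fisher_p, 4))

    # --- clinstats ----------------------------------------------------
    kcfg = cfg["clinstats"]
    pairs = kcfg["pairs"]
    if pairs is None:
        cols = list(traits_df.columns)
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
    else:
        pairs = [tuple(p) for p in pairs]
    screen = clinpath.correlation_screen(traits_df, pairs, alpha=kcfg["alpha"])
    screen.to_csv(out / "clinpath_screen.csv", index=False)
    freq = clinpath.frequency_summary(
        traits_df, [c for c in traits_df.columns if traits_df[c].nunique() <= 10]
    )
    freq.to_csv(out / "frequency_summary.csv", index=False)
    record("clinstats", pairs=len(pairs),
           significant=int(screen["significant"].sum()) if len(screen) else 0)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
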