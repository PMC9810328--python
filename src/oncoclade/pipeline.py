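"""Configuration-driven orchestration of the comparative-oncology pipeline.

Stages run in dependency order:

    tree -> trait ASR -> cancer risk
    PSL -> ECNC -> binary copy-number ASR -> pathway ORA
    necropsy counts -> prevalence
    doubling times -> effect sizes

``run`` resolves a config (defaults serialised, unknown keys rejected),
executes the requested stages, and writes a manifest recording the config
hash, seed, package version and per-stage row counts. Any stage failure
aborts with a stage-named message and the manifest marks the run
incomplete.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cancer_risk, copy_number_asr, effect_sizes, ora, phylo
from . import prevalence as prevalence_mod
from . import rbhb, simulate, trait_asr

__all__ = ["DEFAULT_CONFIG", "resolve_config", "run", "write_bundle"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "pipeline_out",
    "stages": ["simulate", "asr", "risk", "ecnc", "dup-asr", "ora",
               "prevalence", "stats"],
    "inputs": {
        # defaults point at the simulate stage's own outputs
        "tree": None,
        "life_history": None,
        "copy_number": None,
        "forward_psl": None,
        "reciprocal_psl": None,
        "isoform_map": None,
        "query_sizes": None,
        "gene_sets": None,
        "necropsy_counts": None,
        "doubling_times": None,
    },
    "params": {
        "asr_method": "brownian",       # or heavy_tailed
        "heavy_tail_alpha": 2.0,
        "chain_length": 2000,
        "burn_in": 500,
        "ecnc_min": 1.5,
        "n_loci_min": 2,
        "locus_max_gap": 10000,
        "bpp_min": 0.80,
        "frequency_mode": "empirical",
        "q_max": 0.25,
        "min_set_size": 5,
        "min_foreground": 20,
        "conf_level": 0.95,
        "n_boot": 5000,
        "n_perm": 5000,
        "test_clade": "sloths",
        "fold_change_convention": "literal",
        "n_tips": 30,
        "n_genes": 400,
    },
}


def _deep_merge(base: dict, override: dict, path="") -> dict:
    out = dict(base)
    for key, value in override.items():
        if key not in base:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(base[key], value, path + key + ".")
        else:
            out[key] = value
    return out


def resolve_config(user_config: dict | str | Path | None = None) -> dict:
    """Merge a user config (dict or YAML path) over defaults; reject unknown keys."""
    if user_config is None:
        user_config = {}
    if isinstance(user_config, (str, Path)):
        with open(user_config) as fh:
            user_config = yaml.safe_load(fh) or {}
    return _deep_merge(DEFAULT_CONFIG, user_config)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


# ------------------------------------------------------------------ bundle IO
def write_bundle(outdir: Path, cfg: simulate.SimulationConfig) -> dict[str, int]:
    """Generate and write the full synthetic input bundle; returns row counts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    tree = simulate.simulate_tree(cfg.tree, cfg.seed)
    (outdir / "tree.nwk").write_text(phylo.write_newick(tree) + "\n")
    counts["tree_tips"] = len(tree.tips())

    life, trait_truth = simulate.simulate_traits(tree, cfg.traits, cfg.seed + 1)
    life.to_csv(outdir / "life_history.tsv", sep="\t", index=False)
    counts["life_history"] = len(life)

    matrix, gains, bursts = simulate.simulate_duplications(
        tree, cfg.duplications, cfg.seed + 2
    )
    first_gain = {g: (b[0] if b else None) for g, b in gains.items()}
    long = matrix.reset_index().melt(id_vars="gene", var_name="species",
                                     value_name="state").dropna()
    long["state"] = long["state"].astype(int)
    long.to_csv(outdir / "copy_number.tsv", sep="\t", index=False)
    counts["copy_number"] = len(long)

    bundle = simulate.simulate_psl(cfg.psl, cfg.seed + 3)
    rbhb.write_psl(bundle["forward"], outdir / "forward.psl")
    rbhb.write_psl(bundle["reciprocal"], outdir / "reciprocal.psl")
    pd.DataFrame(
        sorted(bundle["isoform_to_gene"].items()), columns=["isoform", "gene"]
    ).to_csv(outdir / "isoform_map.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(bundle["query_sizes"].items()), columns=["isoform", "length"]
    ).to_csv(outdir / "query_sizes.tsv", sep="\t", index=False)
    counts["forward_psl"] = len(bundle["forward"])

    genes = sorted(matrix.index)
    # plant the enriched pathway around the dominant burst's gene gains
    gains_per_burst = {
        b: [g for g, fb in first_gain.items() if fb == b] for b in bursts
    }
    burst_genes = max(gains_per_burst.values(), key=len)
    sets = simulate.simulate_gene_sets(
        genes, cfg.enrichment, cfg.seed + 4, planted_from=burst_genes
    )
    ora.write_gmt(sets["collection"], outdir / "gene_sets.gmt")
    counts["gene_sets"] = len(sets["collection"])

    records, prev_truth = simulate.simulate_prevalence(cfg.prevalence, cfg.seed + 5)
    pd.DataFrame(
        [(r.taxon, r.n, r.x) for r in records], columns=["taxon", "n", "x"]
    ).to_csv(outdir / "necropsy_counts.tsv", sep="\t", index=False)
    counts["necropsy_counts"] = len(records)

    groups, pheno_truth = simulate.simulate_phenotypes(cfg.phenotypes, cfg.seed + 6)
    rows = [(clade, float(v)) for clade, vals in groups.items() for v in vals]
    pd.DataFrame(rows, columns=["clade", "doubling_time_hr"]).to_csv(
        outdir / "doubling_times.tsv", sep="\t", index=False
    )
    counts["doubling_times"] = len(rows)

    truth = {
        "burst_branches": bursts,
        "first_gain": first_gain,
        "all_gains": gains,
        "trait_root": trait_truth[tree.root.label],
        "psl_truth": bundle["truth"],
        "planted_pathway": sets["planted_id"],
        "prevalence_truth": prev_truth,
        "phenotype_truth": pheno_truth,
        "config": _simcfg_dict(cfg),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, default=str))
    return counts


def _simcfg_dict(cfg: simulate.SimulationConfig) -> dict:
    d = asdict(cfg)
    # JSON keys must be strings
    d["psl"]["copy_number_probs"] = {
        str(k): v for k, v in d["psl"]["copy_number_probs"].items()
    }
    return d


# --------------------------------------------------------------------- stages
def _input_path(config: dict, key: str, default_name: str) -> Path:
    outdir = Path(config["outdir"])
    p = config["inputs"].get(key)
    path = Path(p) if p else outdir / default_name
    if not path.exists():
        raise FileNotFoundError(f"input {key!r}: {path} does not exist")
    return path


def _stage_simulate(config: dict) -> dict[str, int]:
    p = config["params"]
    cfg = simulate.SimulationConfig(seed=config["seed"])
    cfg.tree.n_tips = p["n_tips"]
    cfg.duplications.n_genes = p["n_genes"]
    return write_bundle(Path(config["outdir"]), cfg)


def _stage_asr(config: dict) -> dict[str, int]:
    outdir = Path(config["outdir"])
    p = config["params"]
    tree = phylo.read_newick(_input_path(config, "tree", "tree.nwk").read_text())
    life = pd.read_csv(_input_path(config, "life_history", "life_history.tsv"), sep="\t")
    tips = {r.species: math.log(r.mass_g) for r in life.itertuples()}
    if p["asr_method"] == "heavy_tailed":
        cfg = trait_asr.HeavyTailModelConfig(
            alpha=p["heavy_tail_alpha"], chain_length=p["chain_length"],
            burn_in=p["burn_in"], seed=config["seed"],
        )
        states = trait_asr.heavy_tailed_asr(tree, tips, cfg)
    else:
        states = trait_asr.brownian_asr(tree, tips)
    frame = states.to_frame()
    frame["seed"] = config["seed"]
    frame.to_csv(outdir / "asr_states.tsv", sep="\t", index=False)
    trait_asr.branch_rates(states, tree).to_csv(
        outdir / "branch_rates.tsv", sep="\t", index=False
    )
    return {"asr_states": len(frame)}


def _stage_risk(config: dict) -> dict[str, int]:
    outdir = Path(config["outdir"])
    tree = phylo.read_newick(_input_path(config, "tree", "tree.nwk").read_text())
    life = pd.read_csv(_input_path(config, "life_history", "life_history.tsv"), sep="\t")
    asr = pd.read_csv(outdir / "asr_states.tsv", sep="\t")
    masses_tab = {r.species: float(r.mass_g) for r in life.itertuples()}
    lifespans_tab = {r.species: float(r.lifespan_yr) for r in life.itertuples()}
    fit = cancer_risk.pgls_fit(tree, lifespans_tab, masses_tab)
    ln_mass = dict(zip(asr["node"], asr["estimate"]))
    masses = {n: math.exp(v) for n, v in ln_mass.items()}
    lifespans = {
        n: (lifespans_tab[n] if n in lifespans_tab
            else float(np.exp(fit.predict_ln_lifespan(v))))
        for n, v in ln_mass.items()
    }
    table = cancer_risk.risk_table(
        tree, masses, lifespans, convention=config["params"]["fold_change_convention"]
    )
    table.to_csv(outdir / "risk.tsv", sep="\t", index=False)
    return {"risk": len(table)}


def _stage_ecnc(config: dict) -> dict[str, int]:
    outdir = Path(config["outdir"])
    p = config["params"]
    forward = rbhb.parse_psl(_input_path(config, "forward_psl", "forward.psl"))
    reciprocal = rbhb.parse_psl(_input_path(config, "reciprocal_psl", "reciprocal.psl"))
    iso_map = pd.read_csv(_input_path(config, "isoform_map", "isoform_map.tsv"), sep="\t")
    isoform_to_gene = dict(zip(iso_map["isoform"], iso_map["gene"]))
    sizes = pd.read_csv(_input_path(config, "query_sizes", "query_sizes.tsv"), sep="\t")
    query_sizes = dict(zip(sizes["isoform"], sizes["length"]))

    hits, diags = rbhb.reciprocal_best_hits(
        forward, reciprocal, isoform_to_gene, max_gap=p["locus_max_gap"]
    )
    by_iso: dict[str, list[rbhb.RbhHit]] = {}
    for h in hits:
        by_iso.setdefault(h.query_isoform, []).append(h)
    iso_results = []
    for iso, iso_hits in sorted(by_iso.items()):
        res = rbhb.ecnc(int(query_sizes[iso]), iso_hits, query_isoform=iso)
        iso_results.append((iso, res, len(iso_hits)))
    gene_table, gdiags = rbhb.gene_copy_number(iso_results, isoform_to_gene)
    called = rbhb.binarize_copy_number(
        gene_table, n_loci_min=p["n_loci_min"], ecnc_min=p["ecnc_min"]
    )
    called.to_csv(outdir / "ecnc.tsv", sep="\t", index=False)
    (outdir / "ecnc_diagnostics.json").write_text(
        json.dumps({**diags, **gdiags}, indent=1)
    )
    return {"ecnc_genes": len(called)}


def _stage_dup_asr(config: dict) -> dict[str, int]:
    outdir = Path(config["outdir"])
    p = config["params"]
    tree = phylo.read_newick(_input_path(config, "tree", "tree.nwk").read_text())
    long = pd.read_csv(_input_path(config, "copy_number", "copy_number.tsv"), sep="\t")
    matrix = copy_number_asr.matrix_from_long(long)
    model = copy_number_asr.fit_two_state_model(
        matrix, tree, frequency_mode=p["frequency_mode"]
    )
    recon = copy_number_asr.marginal_asr(matrix, tree, model)
    events = copy_number_asr.call_duplications(recon, tree, bpp_min=p["bpp_min"])
    summary = copy_number_asr.lineage_duplication_summary(events)
    summary.drop(columns="genes").to_csv(outdir / "duplication_events.tsv",
                                         sep="\t", index=False)
    lists_dir = outdir / "branch_gene_lists"
    lists_dir.mkdir(exist_ok=True)
    for row in summary.itertuples():
        (lists_dir / f"{row.branch}.txt").write_text("\n".join(row.genes) + "\n")
    (outdir / "dup_model.json").write_text(json.dumps({
        "q01": model.q01, "q10": model.q10,
        "frequency_mode": model.frequency_mode, "bpp_min": p["bpp_min"],
    }, indent=1))
    return {"duplication_branches": len(summary),
            "duplication_events": int(summary["count"].sum()) if len(summary) else 0}


def _stage_ora(config: dict) -> dict[str, int]:
    outdir = Path(config["outdir"])
    p = config["params"]
    collection = ora.read_gmt(_input_path(config, "gene_sets", "gene_sets.gmt"))
    long = pd.read_csv(_input_path(config, "copy_number", "copy_number.tsv"), sep="\t")
    background = sorted(long["gene"].unique())
    summary = pd.read_csv(outdir / "duplication_events.tsv", sep="\t")
    summary = summary[summary["count"] >= p["min_foreground"]]
    if len(summary) == 0:
        pd.DataFrame().to_csv(outdir / "ora.tsv", sep="\t", index=False)
        return {"ora_branches": 0, "ora_pathways": 0}
    frames = []
    for branch in sorted(summary["branch"]):
        fg = (outdir / "branch_gene_lists" / f"{branch}.txt").read_text().split()
        res = ora.run_ora(fg, background, collection,
                          q_max=p["q_max"], min_set_size=p["min_set_size"])
        res.insert(0, "branch", branch)
        frames.append(res)
    results = pd.concat(frames, ignore_index=True)
    results.to_csv(outdir / "ora.tsv", sep="\t", index=False)
    return {"ora_branches": len(frames), "ora_pathways": len(results)}


def _stage_prevalence(config: dict) -> dict[str, int]:
    outdir = Path(config["outdir"])
    counts = pd.read_csv(
        _input_path(config, "necropsy_counts", "necropsy_counts.tsv"), sep="\t"
    )
    records = [
        prevalence_mod.NecropsyCount(taxon=r.taxon, n=int(r.n), x=int(r.x))
        for r in counts.itertuples()
    ]
    table = prevalence_mod.prevalence_table(
        records, conf=config["params"]["conf_level"]
    )
    table.to_csv(outdir / "prevalence.tsv", sep="\t", index=False)
    return {"prevalence_rows": len(table)}


def _stage_stats(config: dict) -> dict[str, int]:
    outdir = Path(config["outdir"])
    p = config["params"]
    data = pd.read_csv(
        _input_path(config, "doubling_times", "doubling_times.tsv"), sep="\t"
    )
    test_clade = p["test_clade"]
    if test_clade not in set(data["clade"]):
        raise ValueError(f"test clade {test_clade!r} absent from doubling-time table")
    test = data.loc[data["clade"] == test_clade, "doubling_time_hr"].to_numpy()
    control = data.loc[data["clade"] != test_clade, "doubling_time_hr"].to_numpy()
    res = effect_sizes.unpaired_mean_difference(
        control, test, n_boot=p["n_boot"], n_perm=p["n_perm"], seed=config["seed"]
    )
    pd.DataFrame([{
        "test_clade": test_clade, "difference_hr": res.difference,
        "ci_low": res.ci_low, "ci_high": res.ci_high, "p_value": res.p_value,
        "n_control": res.n_control, "n_test": res.n_test,
        "exact_permutations": res.exact, "seed": res.seed,
    }]).to_csv(outdir / "effect_sizes.tsv", sep="\t", index=False)
    return {"effect_size_rows": 1}


_STAGES = {
    "simulate": _stage_simulate,
    "asr": _stage_asr,
    "risk": _stage_risk,
    "ecnc": _stage_ecnc,
    "dup-asr": _stage_dup_asr,
    "ora": _stage_ora,
    "prevalence": _stage_prevalence,
    "stats": _stage_stats,
}

STAGE_ORDER = list(_STAGES)


def run(config: dict | str | Path | None = None, stages: list[str] | None = None) -> dict:
    """Run the requested stages in dependency order; returns the manifest."""
    config = resolve_config(config)
    wanted = stages or config["stages"]
    unknown = [s for s in wanted if s not in _STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    ordered = [s for s in STAGE_ORDER if s in wanted]

    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": config["seed"],
        "version": __version__,
        "stages": {},
        "status": "incomplete",
    }
    manifest_path = outdir / "manifest.json"
    for stage in ordered:
        try:
            manifest["stages"][stage] = _STAGES[stage](config)
        except Exception as exc:
            manifest["status"] = f"failed at stage {stage}"
            manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest["status"] = "complete"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
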