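"""End-to-end orchestration: fixtures -> preprocess -> EWIS variants ->
pathway enrichment -> DMR calling -> over-representation, from one
declarative config, with a JSON run manifest recording counts and seeds.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .dmr import annotate_dmrs, call_dmrs, dmrs_to_frame, smooth_squared_z, satterthwaite_pvalues
from .ewis import ModelSpec, crp_association, run_ewis
from .pathways import assign_cpgs_to_genes, build_pathway_cpg_sets, ora_fisher, wks_enrichment
from .preprocess import apply_detection_mask, control_probe_residualize, filter_probes
from .simulate import SimDesign, generate_genes_and_pathways, generate_manifest, plant_effects, simulate_cohort

log = logging.getLogger(__name__)

DEFAULT_MODELS = [
    {"exposure": "bmi", "adjust": []},
    {"exposure": "bmi", "adjust": ["phys_act"]},
    {"exposure": "bmi", "adjust": ["neutrophils"]},
    {"exposure": "bmi_change", "adjust": []},
    {"exposure": "bmi_change", "adjust": ["phys_act"]},
    {"exposure": "bmi_change", "adjust": ["neutrophils"]},
]

DEFAULT_SYNTHETIC = {
    "n_cpgs": 20_000,
    "n_chroms": 5,
    "cluster_size": 10,
    "cluster_spacing": 20_000,
    "n_genes": 400,
    "n_pathways": 17,
    "genes_per_pathway": 12,
    "plant": {
        "n_causal_pathways": 2,
        "gamma_pathway": 0.5,
        "n_dmr_blocks": 3,
        "dmr_block_size": 10,
        "gamma_dmr": 1.2,
    },
}


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def make_fixtures(synth: dict, seed: int, outdir: Path | None = None):
    """Generate a complete synthetic bundle (optionally writing it to disk)."""
    cfg = copy.deepcopy(DEFAULT_SYNTHETIC)
    plant_cfg = {**cfg.pop("plant"), **(synth.get("plant") or {})}
    cfg.update({k: v for k, v in synth.items() if k != "plant"})
    design_keys = {f.name for f in SimDesign.__dataclass_fields__.values()}

    manifest = generate_manifest(
        cfg["n_cpgs"], cfg["n_chroms"], cfg["cluster_size"], cfg["cluster_spacing"], seed=seed
    )
    genes, pathway_db = generate_genes_and_pathways(
        manifest, cfg["n_genes"], cfg["n_pathways"], cfg["genes_per_pathway"], seed=seed + 1
    )
    gamma, causal_pw, dmr_intervals = plant_effects(
        manifest, genes, pathway_db, seed=seed + 2, **plant_cfg
    )
    design_kwargs = {k: v for k, v in cfg.items() if k in design_keys}
    design = SimDesign(gamma=gamma, seed=seed + 3, **design_kwargs)
    beta, detp, controls, covariates, truth = simulate_cohort(design, manifest, genes, pathway_db)
    truth.causal_pathways = truth.causal_pathways or causal_pw
    bundle = {
        "manifest": manifest,
        "genes": genes,
        "pathway_db": pathway_db,
        "beta": beta,
        "detp": detp,
        "controls": controls,
        "covariates": covariates,
        "truth": truth,
        "design": design,
    }
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_manifest(manifest, outdir / "manifest.tsv")
        io.write_genes(genes, outdir / "genes.tsv")
        io.write_gmt(pathway_db, outdir / "pathways.gmt")
        io.write_matrix(beta, outdir / "beta.tsv")
        io.write_matrix(detp, outdir / "detection_p.tsv", float_format="%.3e")
        io.write_matrix(controls, outdir / "control_probes.tsv")
        io.write_covariates(covariates, outdir / "covariates.tsv")
        (outdir / "mask.txt").write_text("")
    return bundle


def write_table_with_metadata(table: pd.DataFrame, path: Path) -> None:
    """Delimited table preceded by '#'-prefixed metadata header lines."""
    with open(path, "w") as fh:
        for k, v in table.attrs.items():
            fh.write(f"# {k}: {json.dumps(v, default=str)}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: dict) -> dict:
    """Run every stage from one config dict; returns the run manifest.

    The config either names input files (`inputs:` block) or requests a
    synthetic bundle (`synthetic:` block). Stage failure raises with the
    failing stage named; a `<stage>.partial` marker is left in the output
    directory.
    """
    outdir = Path(config.get("output_dir", "ewistk_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest_json: dict = {
        "tool_version": __version__,
        "config_hash": config_hash(config),
        "seed": seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    stage = "fixtures"
    try:
        if "synthetic" in config or "inputs" not in config:
            bundle = make_fixtures(config.get("synthetic") or {}, seed, outdir / "fixtures")
            mani, genes = bundle["manifest"], bundle["genes"]
            pathway_db = bundle["pathway_db"]
            beta, detp, controls = bundle["beta"], bundle["detp"], bundle["controls"]
            covariates = bundle["covariates"]
            mask_list: list[str] = []
        else:
            paths = config["inputs"]
            mani = io.read_manifest(paths["manifest"])
            genes = io.read_genes(paths["genes"])
            pathway_db = io.read_gmt(paths["gmt"]) if paths.get("gmt") else None
            beta = io.read_matrix(paths["beta"])
            detp = io.read_matrix(paths["detection_p"])
            controls = io.read_matrix(paths["control_probes"])
            covariates = io.read_covariates(paths["covariates"])
            mask_list = (
                Path(paths["mask"]).read_text().split() if paths.get("mask") else []
            )
        manifest_json["stages"]["fixtures"] = {
            "n_probes": int(len(beta)),
            "n_samples": int(beta.shape[1]),
            "n_cases": int(covariates["asthma"].sum()),
            "n_controls": int((covariates["asthma"] == 0).sum()),
        }

        stage = "preprocess"
        pp = config.get("preprocess") or {}
        masked = apply_detection_mask(beta, detp, pp.get("detection_threshold", 1e-16))
        filtered, report = filter_probes(masked, mani, mask_list, pp.get("call_rate_min", 0.95))
        resid = control_probe_residualize(filtered, controls, pp.get("n_pcs", 30))
        io.write_matrix(resid.values, outdir / "residuals.tsv")
        pd.DataFrame([{k: v for k, v in report.items() if not isinstance(v, pd.Series)}]).to_csv(
            outdir / "filter_report.tsv", sep="\t", index=False
        )
        manifest_json["stages"]["preprocess"] = {
            **{k: v for k, v in report.items() if isinstance(v, int)},
            "n_pcs_removed": resid.n_components_removed,
        }

        stage = "crp_check"
        if "hs_crp" in covariates.columns and covariates["hs_crp"].notna().sum() >= 20:
            crp = crp_association(covariates)
            (outdir / "crp_association.json").write_text(json.dumps(crp, indent=1))
            manifest_json["stages"]["crp_check"] = crp

        model_cfgs = config.get("models") or DEFAULT_MODELS
        specs = [
            ModelSpec(exposure=m["exposure"], extra_adjust=tuple(m.get("adjust") or ()))
            for m in model_cfgs
        ]
        enr_cfg = config.get("enrichment") or {}
        dmr_cfg = config.get("dmr") or {}
        ora_cfg = config.get("ora") or {}
        # every defaulted parameter, resolved explicitly
        manifest_json["resolved_parameters"] = {
            "preprocess": {"detection_threshold": pp.get("detection_threshold", 1e-16),
                           "call_rate_min": pp.get("call_rate_min", 0.95),
                           "n_pcs": pp.get("n_pcs", 30)},
            "models": [s.label() for s in specs],
            "enrichment": {"flank": enr_cfg.get("flank", 200),
                           "B": enr_cfg.get("B", 10_000)},
            "dmr": {"bandwidth": dmr_cfg.get("bandwidth", 1000),
                    "scaling": dmr_cfg.get("scaling", 2),
                    "fdr": dmr_cfg.get("fdr", 0.05),
                    "gap": dmr_cfg.get("gap", 1000),
                    "promoter_bp": dmr_cfg.get("promoter_bp", 2000)},
            "ora": {"min_genes": ora_cfg.get("min_genes", 25)},
        }
        pairs = assign_cpgs_to_genes(mani, genes, enr_cfg.get("flank", 200)) if pathway_db else None

        enrich_wide = None
        for vi, spec in enumerate(specs):
            label = spec.label()
            stage = f"ewis[{label}]"
            table = run_ewis(resid, covariates, spec)
            write_table_with_metadata(table, outdir / f"ewis_{label}.tsv")
            manifest_json["stages"][stage] = {
                "n_probes": int(len(table)),
                "n_converged": table.attrs["n_converged"],
                "n_samples_used": table.attrs["n_samples_used"],
                "n_significant": int(table["significant"].sum()),
            }

            if pathway_db:
                stage = f"enrichment[{label}]"
                sets = build_pathway_cpg_sets(pairs, pathway_db, table[table["converged"]])
                enr = wks_enrichment(
                    table, sets, B=enr_cfg.get("B", 10_000), seed=seed + 1000 + vi
                )
                write_table_with_metadata(enr, outdir / f"enrichment_{label}.tsv")
                col = enr.set_index("pathway")["mc_p"].rename(label)
                enrich_wide = col.to_frame() if enrich_wide is None else enrich_wide.join(col)
                manifest_json["stages"][stage] = {
                    "n_pathways_tested": int(enr["mc_p"].notna().sum()),
                    "n_enriched": int(enr["enriched"].sum()),
                    "n_universe": enr.attrs["n_universe"],
                    "B": enr.attrs["B"],
                }

            stage = f"dmr[{label}]"
            smoothed = satterthwaite_pvalues(
                smooth_squared_z(
                    table, mani, dmr_cfg.get("bandwidth", 1000), dmr_cfg.get("scaling", 2)
                )
            )
            dmrs = call_dmrs(smoothed, table, dmr_cfg.get("fdr", 0.05), dmr_cfg.get("gap", 1000))
            dmrs = annotate_dmrs(dmrs, genes, dmr_cfg.get("promoter_bp", 2000))
            dmrs_to_frame(dmrs).to_csv(outdir / f"dmrs_{label}.tsv", sep="\t", index=False)
            dmr_genes = sorted({g for r in dmrs for g in r.annotated_genes})
            manifest_json["stages"][stage] = {
                "n_dmrs": len(dmrs),
                "n_unannotated": sum(1 for r in dmrs if not r.annotated_genes),
                "n_annotated_genes": len(dmr_genes),
            }

            stage = f"ora[{label}]"
            min_genes = ora_cfg.get("min_genes", 25)
            if pathway_db and len(dmr_genes) >= min_genes:
                ora = ora_fisher(dmr_genes, set(genes["gene_id"]), pathway_db)
                ora.to_csv(outdir / f"ora_{label}.tsv", sep="\t", index=False)
                manifest_json["stages"][stage] = {
                    "n_genes_tested": len(dmr_genes),
                    "n_pathways": int(len(ora)),
                }
            else:
                manifest_json["stages"][stage] = {
                    "skipped": f"fewer than {min_genes} annotated DMR genes",
                    "n_genes": len(dmr_genes),
                }

        if enrich_wide is not None:
            enrich_wide.to_csv(outdir / "enrichment_by_model.tsv", sep="\t", float_format="%.4g")
    except Exception as exc:
        (outdir / f"{stage.split('[')[0]}.partial").write_text(f"{stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest_json["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "run_manifest.json").write_text(json.dumps(manifest_json, indent=1, default=str))
    return manifest_json
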