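"""Shared fixtures: small synthetic bundles computed once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ewistk import (
    ModelSpec,
    SimDesign,
    apply_detection_mask,
    control_probe_residualize,
    filter_probes,
    generate_manifest,
    run_ewis,
    simulate_cohort,
)
from ewistk.pipeline import make_fixtures


@pytest.fixture(scope="session")
def manifest_small():
    return generate_manifest(
        1000, n_chroms=4, cluster_size=10, cluster_spacing=20_000, seed=11
    )


@pytest.fixture(scope="session")
def bundle_planted():
    """2000-CpG bundle with planted pathway and DMR interaction effects."""
    return make_fixtures(
        {"n_cpgs": 2000, "n_genes": 120, "n_pathways": 6, "genes_per_pathway": 10},
        seed=21,
    )


def _preprocess(bundle, n_pcs=30):
    masked = apply_detection_mask(bundle["beta"], bundle["detp"])
    filtered, report = filter_probes(masked, bundle["manifest"])
    return control_probe_residualize(filtered, bundle["controls"], n_pcs), report


@pytest.fixture(scope="session")
def residuals_planted(bundle_planted):
    resid, _ = _preprocess(bundle_planted)
    return resid


@pytest.fixture(scope="session")
def ewis_planted(bundle_planted, residuals_planted):
    return run_ewis(residuals_planted, bundle_planted["covariates"], ModelSpec())


@pytest.fixture(scope="session")
def null_cohort():
    """Global-null cohort: no planted effects, no batch, no shared cell loadings."""
    manifest = generate_manifest(
        1200, n_chroms=4, cluster_size=10, seed=31, sex_chrom_frac=0.0, masked_frac=0.0
    )
    design = SimDesign(seed=32, batch_sd=0.0, cell_profile_shift={})
    beta, detp, controls, covariates, truth = simulate_cohort(design, manifest)
    return {
        "manifest": manifest, "beta": beta, "detp": detp,
        "controls": controls, "covariates": covariates, "truth": truth,
    }


@pytest.fixture(scope="session")
def ewis_null(null_cohort):
    masked = apply_detection_mask(null_cohort["beta"], null_cohort["detp"])
    filtered, _ = filter_probes(masked, null_cohort["manifest"])
    resid = control_probe_residualize(filtered, null_cohort["controls"], 30)
    return run_ewis(resid, null_cohort["covariates"], ModelSpec())
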