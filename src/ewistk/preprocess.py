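"""Probe filtering and control-probe principal-component residualization.

The analytic methylation variable downstream is not the beta value itself
but its residual after ordinary least squares on the leading principal
components of the array's 220 control probes — a standard way to strip
technical/batch variation while retaining biological signal. Filters applied
first: detection-p masking (beta set to missing where detection p exceeds
1e-16), removal of sex-chromosome probes, externally masked probes
(multi-mapping / SNP-overlapping), and probes with call rate below 0.95.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DETECTION_P_THRESHOLD = 1e-16
CALL_RATE_MIN = 0.95
N_CONTROL_PCS = 30


@dataclass
class ResidualMatrix:
    """Per-CpG residuals of beta on control-probe PCs.

    values: CpG x sample frame (unbounded reals, NaN where beta was missing).
    pc_scores: sample x component PC score matrix actually regressed out.
    """

    values: pd.DataFrame
    n_components_removed: int
    pc_scores: np.ndarray


def apply_detection_mask(
    beta: pd.DataFrame, detection_p: pd.DataFrame, threshold: float = DETECTION_P_THRESHOLD
) -> pd.DataFrame:
    """Set beta to missing wherever the detection p-value exceeds `threshold`."""
    if beta.shape != detection_p.shape:
        raise ValueError(
            f"beta {beta.shape} and detection-p {detection_p.shape} shapes differ"
        )
    return beta.mask(detection_p.to_numpy() > threshold)


def filter_probes(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    mask_list=(),
    call_rate_min: float = CALL_RATE_MIN,
) -> tuple[pd.DataFrame, dict]:
    """Drop sex-chromosome probes, externally masked probes, and probes with
    call rate below `call_rate_min`; survivors keep their input order.

    Returns the filtered matrix and a removal report with counts per class
    (a probe is counted once, in the first class that removes it) plus
    per-sample call rates for reporting.
    """
    mani = manifest.set_index("probe_id").loc[beta.index]
    masked_ids = set(mask_list)
    sex = mani["is_sex_chrom"].to_numpy()
    masked = mani["is_masked"].to_numpy() | beta.index.isin(masked_ids)
    call_rate = beta.notna().mean(axis=1).to_numpy()
    low_call = call_rate < call_rate_min

    drop_sex = sex
    drop_mask = masked & ~sex
    drop_call = low_call & ~sex & ~masked
    keep = ~(sex | masked | low_call)
    report = {
        "n_input": len(beta),
        "n_sex_chrom": int(drop_sex.sum()),
        "n_masked": int(drop_mask.sum()),
        "n_low_call_rate": int(drop_call.sum()),
        "n_kept": int(keep.sum()),
        "call_rate_min": call_rate_min,
        "sample_call_rate": beta.notna().mean(axis=0),
    }
    low_samples = report["sample_call_rate"][report["sample_call_rate"] < call_rate_min]
    report["n_low_call_samples"] = int(len(low_samples))
    if len(low_samples):
        log.warning("%d samples have call rate < %.2f (reported, not dropped)",
                    len(low_samples), call_rate_min)
    if not keep.any():
        raise ValueError("probe filtering removed every probe; check inputs")
    return beta.loc[keep], report


def control_probe_pca(control_matrix: pd.DataFrame, n_components: int) -> np.ndarray:
    """PC scores of the control probes with samples as observations.

    Columns (probes) are centered but not scaled. Returns an
    n_samples x k score matrix with orthogonal columns; near-null components
    (singular value < 1e-10 of the leading one) are dropped.
    """
    if n_components < 0:
        raise ValueError("n_components must be non-negative")
    X = control_matrix.to_numpy().T.astype(float)  # samples x probes
    n_samples, n_probes = X.shape
    k = min(n_components, n_samples - 1, n_probes)
    if k == 0:
        return np.empty((n_samples, 0))
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > 1e-10 * s[0]).sum())
    if rank < k:
        log.warning("control-probe PCA rank %d < requested %d components", rank, k)
        k = rank
    return U[:, :k] * s[:k]


def control_probe_residualize(
    beta: pd.DataFrame,
    control_matrix: pd.DataFrame,
    n_components: int = N_CONTROL_PCS,
) -> ResidualMatrix:
    """Replace each probe's beta values by OLS residuals on an intercept plus
    the first `n_components` control-probe PC scores.

    Missing beta entries are omitted pairwise from each probe's regression
    and remain missing in the residuals. With `n_components=0` this reduces
    to per-probe mean centering.
    """
    if list(beta.columns) != list(control_matrix.columns):
        raise ValueError("beta and control matrix sample ids differ")
    scores = control_probe_pca(control_matrix, n_components)
    k = scores.shape[1]
    B = beta.to_numpy().astype(float)
    missing = ~np.isfinite(B)

    # orthonormal basis of [intercept | scores]; scores are already centered
    # and mutually orthogonal, so normalizing columns suffices
    norms = np.linalg.norm(scores, axis=0)
    Q = scores / norms
    out = np.empty_like(B)

    complete = ~missing.any(axis=1)
    if complete.any():
        Bc = B[complete] - B[complete].mean(axis=1, keepdims=True)
        out[complete] = Bc - (Bc @ Q) @ Q.T
    X_full = np.column_stack([np.ones(B.shape[1]), scores])
    for i in np.flatnonzero(~complete):
        obs = ~missing[i]
        if obs.sum() == 0:
            out[i] = np.nan
            continue
        Xi = X_full[obs]
        coef, *_ = np.linalg.lstsq(Xi, B[i, obs], rcond=None)
        out[i, obs] = B[i, obs] - Xi @ coef
        out[i, ~obs] = np.nan
    values = pd.DataFrame(out, index=beta.index, columns=beta.columns)
    return ResidualMatrix(values=values, n_components_removed=k, pc_scores=scores)
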