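"""Per-CpG logistic effect-modification models.

For each CpG i the model is

    asthma ~ exposure x residual_i + exposure + residual_i + covariates

where `exposure` is BMI (kg/m^2) or 10-year BMI change (additionally
adjusted for the earlier BMI), `residual_i` is the control-probe-PC residual
of the beta value, and covariates are age, sex, education, study area,
pack-years, bench time and six white-blood-cell fractions (B, CD4T, CD8T,
NK, monocytes, eosinophils). Neutrophils are deliberately excluded from the
basic model — in non-atopic disease the immune response may run through
neutrophil proliferation, so adjusting for them could absorb the signal of
interest; a sensitivity variant adds them back, another adds physical
activity. The genome-wide interaction statistic is the Wald z of the product
term; discovery is controlled by Benjamini-Hochberg at FDR 0.1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .simulate import CELL_TYPES, EDUCATION_LEVELS

log = logging.getLogger(__name__)

BASIC_CELLS = ("Bcell", "CD4T", "CD8T", "NK", "Mono", "Eos")  # no Neu in the basic model
MAX_ITER = 100
LL_TOL = 1e-8
SEPARATION_COEF = 15.0
SEPARATION_SE = 1e3


@dataclass
class ModelSpec:
    """One EWIS model variant."""

    exposure: str = "bmi"  # "bmi" or "bmi_change"
    extra_adjust: tuple[str, ...] = ()  # subset of {"phys_act", "neutrophils"}
    fdr_q: float = 0.1

    def __post_init__(self):
        if self.exposure not in ("bmi", "bmi_change"):
            raise ValueError("exposure must be 'bmi' or 'bmi_change'")
        bad = set(self.extra_adjust) - {"phys_act", "neutrophils"}
        if bad:
            raise ValueError(f"unknown adjustment: {sorted(bad)}")

    @property
    def exposure_column(self) -> str:
        return "bmi_s3" if self.exposure == "bmi" else "bmi_change"

    def label(self) -> str:
        return self.exposure + ("+" + "+".join(sorted(self.extra_adjust)) if self.extra_adjust else "")


@dataclass
class CpGResult:
    probe_id: str
    beta_int: float
    se: float
    z: float
    p: float
    converged: bool
    reason: str = ""
    n_used: int = 0


def build_design(
    covariates: pd.DataFrame, spec: ModelSpec, area_levels: tuple[str, ...] | None = None
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Build the shared (CpG-independent) design matrix for one model spec.

    Returns (X, exposure_values, ledger). X contains the intercept, the
    exposure main effect and all adjustment covariates, dummy-coded against
    declared reference levels; the per-CpG residual and product columns are
    appended at fit time. Rows with missing required covariates are dropped
    and counted in the ledger. Declared categorical levels absent from the
    data yield all-zero columns which are then dropped as constant, with a
    warning; both events are recorded in the column ledger.
    """
    cov = covariates.copy()
    required = [
        "asthma", spec.exposure_column, "age", "sex", "education", "area",
        "packyears", "benchtime", *BASIC_CELLS,
    ]
    if spec.exposure == "bmi_change":
        required.append("bmi_s2")
    if "neutrophils" in spec.extra_adjust:
        required.append("Neu")
    if "phys_act" in spec.extra_adjust:
        cov["phys_act"] = cov["phys_act"].replace("NA", np.nan)
        required.append("phys_act")

    keep = cov[required].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropped %d rows with missing required covariates", n_dropped)
    cov = cov.loc[keep]

    X = pd.DataFrame(index=cov.index)
    X["const"] = 1.0
    X[spec.exposure_column] = cov[spec.exposure_column].astype(float)
    if spec.exposure == "bmi_change":
        X["bmi_s2"] = cov["bmi_s2"].astype(float)
    X["age"] = cov["age"].astype(float)
    X["sex_M"] = (cov["sex"] == "M").astype(float)
    ledger: dict[str, str] = {c: "kept" for c in X.columns}

    def add_dummies(col: str, levels: tuple[str, ...]):
        ref = levels[0]
        for lev in levels[1:]:
            name = f"{col}_{lev}"
            X[name] = (cov[col] == lev).astype(float)
            ledger[name] = "kept"
            if not (cov[col] == lev).any():
                ledger[name] = "declared level absent (all-zero)"
                log.warning("level %r of %s absent from data", lev, col)
        ledger[f"{col}[ref={ref}]"] = "reference"

    add_dummies("education", EDUCATION_LEVELS)
    if area_levels is None:
        area_levels = tuple(sorted(cov["area"].astype(str).unique()))
    add_dummies("area", area_levels)

    X["packyears"] = cov["packyears"].astype(float)
    X["benchtime"] = cov["benchtime"].astype(float)
    for ct in BASIC_CELLS:
        X[ct] = cov[ct].astype(float)
    if "neutrophils" in spec.extra_adjust:
        X["Neu"] = cov["Neu"].astype(float)
    if "phys_act" in spec.extra_adjust:
        X["phys_act_insufficient"] = (cov["phys_act"] == "insufficient").astype(float)
    for c in X.columns:
        ledger.setdefault(c, "kept")

    const_cols = [c for c in X.columns if c != "const" and X[c].nunique() <= 1]
    for c in const_cols:
        ledger[c] = ledger.get(c, "kept").replace("kept", "") + " dropped (constant)"
        log.warning("dropping constant design column %r", c)
    X = X.drop(columns=const_cols)

    ledger["_n_dropped_missing"] = str(n_dropped)
    ledger["_exposure"] = spec.exposure_column
    return X, cov[spec.exposure_column].to_numpy(float), ledger


def fit_interaction_model(
    asthma: np.ndarray,
    exposure: np.ndarray,
    residual_i: np.ndarray,
    design: pd.DataFrame | np.ndarray,
    probe_id: str = "",
) -> CpGResult:
    """Maximum-likelihood logistic fit; Wald z/p for the interaction term.

    Rows with missing residual are dropped. Perfect separation or
    non-convergence within the iteration cap yields converged=False with
    missing statistics; a constant residual is flagged as degenerate.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(asthma, dtype=float)
    r = np.asarray(residual_i, dtype=float)
    obs = np.isfinite(r)
    y, e, r, Xo = y[obs], np.asarray(exposure, float)[obs], r[obs], X[obs]
    n_used = int(obs.sum())
    nan = float("nan")
    if n_used == 0 or y.min() == y.max():
        return CpGResult(probe_id, nan, nan, nan, nan, False, "needs >=1 case and >=1 control", n_used)
    if np.ptp(r) == 0:
        return CpGResult(probe_id, nan, nan, nan, nan, False, "degenerate methylation", n_used)
    # Product column built from centered factors: an exact reparametrization
    # (both main effects are in the model) whose interaction coefficient and
    # SE are unchanged, but without the severe r ~ r*e collinearity that an
    # uncentered product has when the exposure's coefficient of variation is
    # small (BMI ~ 25 +/- 4).
    Xfull = np.column_stack([Xo, r, (r - r.mean()) * (e - e.mean())])
    # standardize non-constant columns for conditioning; the Wald z and p of
    # the interaction are invariant, the coefficient back-transforms by the
    # product column's SD
    mean = Xfull.mean(axis=0)
    sd = Xfull.std(axis=0)
    scale_cols = sd > 0
    scale_cols[0] = False  # keep the intercept
    Xs = Xfull.copy()
    Xs[:, scale_cols] = (Xfull[:, scale_cols] - mean[scale_cols]) / sd[scale_cols]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xs).fit(
                method="newton", maxiter=MAX_ITER, tol=LL_TOL, disp=0, warn_convergence=False
            )
            # SE from the analytic information matrix at the final estimate
            # (the optimizer's own covariance can lag one Newton step); tiny
            # ridge guards the inverse when a sparse category level drifts to
            # the boundary (e.g. a dummy with cases or controls only)
            info = -res.model.hessian(res.params)
            cov_params = np.linalg.inv(info + 1e-9 * np.eye(info.shape[0]))
            coef = res.params[-1] / sd[-1]
            se = float(np.sqrt(cov_params[-1, -1])) / sd[-1]
            ok = bool(res.mle_retvals.get("converged", False))
            if not ok:  # the parameter-change criterion can chatter in the
                # last float digits; the score is the authoritative check
                ok = bool(np.abs(res.model.score(res.params)).max() < 1e-6)
        except (np.linalg.LinAlgError, PerfectSeparationError, ValueError):
            return CpGResult(probe_id, nan, nan, nan, nan, False, "separation or singular fit", n_used)
    if not np.isfinite(coef) or not np.isfinite(se):
        return CpGResult(probe_id, nan, nan, nan, nan, False, "non-finite estimate", n_used)
    if abs(coef) > SEPARATION_COEF or se > SEPARATION_SE:
        return CpGResult(probe_id, nan, nan, nan, nan, False, "separation", n_used)
    if not ok:
        return CpGResult(probe_id, nan, nan, nan, nan, False, "not converged", n_used)
    z = coef / se
    return CpGResult(probe_id, float(coef), float(se), float(z), float(2 * norm.sf(abs(z))), True, "", n_used)


def _batched_interaction_fits(
    Xs: np.ndarray,
    exposure: np.ndarray,
    R: np.ndarray,
    y: np.ndarray,
    chunk: int = 512,
) -> pd.DataFrame:
    """Damped-Newton logistic fits for many probes sharing one covariate block.

    Per probe the design is [Xs | r_std | r_std * e_std] with the residual
    and the doubly-centered product standardized per probe over its observed
    samples; the interaction coefficient is back-transformed to raw units
    (log-odds per residual unit per exposure unit). Missing residuals enter
    as zero-weight rows. Numerically equivalent to per-probe maximum
    likelihood (cross-checked against the reference single-probe fit in the
    test suite) but runs as batched BLAS operations.
    """
    m, n = R.shape
    p = Xs.shape[1]
    out = {
        "beta_int": np.full(m, np.nan), "se": np.full(m, np.nan),
        "converged": np.zeros(m, bool), "n_used": np.zeros(m, int),
        "reason": np.array([""] * m, dtype=object),
    }
    eye = np.eye(p + 2)
    for s in range(0, m, chunk):
        Rc = R[s : s + chunk]
        c = Rc.shape[0]
        mask = np.isfinite(Rc)
        cnt = mask.sum(axis=1)
        Rz = np.where(mask, Rc, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rmean = Rz.sum(1) / cnt
            rvar = (Rz * Rz).sum(1) / cnt - rmean**2
            rsd = np.sqrt(np.maximum(rvar, 0.0))
            emean = (exposure * mask).sum(1) / cnt
            evar = (exposure**2 * mask).sum(1) / cnt - emean**2
            esd = np.sqrt(np.maximum(evar, 0.0))
            n1 = (mask * y).sum(1)
            n0 = cnt - n1
        bad = cnt == 0
        degen = (rsd <= 0) & ~bad
        nocase = ((n1 == 0) | (n0 == 0)) & ~bad & ~degen
        fit_ok = ~(bad | degen | nocase)
        out["n_used"][s : s + c] = cnt
        out["reason"][s : s + c][bad | nocase] = "needs >=1 case and >=1 control"
        out["reason"][s : s + c][degen] = "degenerate methylation"
        if not fit_ok.any():
            continue
        idx = np.flatnonzero(fit_ok)
        rs = np.where(mask[idx], (Rc[idx] - rmean[idx, None]) / rsd[idx, None], 0.0)
        ec = (exposure[None, :] - emean[idx, None]) / esd[idx, None]
        Xb = np.empty((len(idx), n, p + 2))
        Xb[:, :, :p] = Xs[None, :, :]
        Xb[:, :, p] = rs
        Xb[:, :, p + 1] = rs * ec
        msk = mask[idx].astype(float)
        ybar = np.clip(n1[idx] / cnt[idx], 1e-3, 1 - 1e-3)
        beta = np.zeros((len(idx), p + 2))
        beta[:, 0] = np.log(ybar / (1 - ybar))
        active = np.ones(len(idx), bool)
        dev_prev = np.full(len(idx), np.inf)
        for _ in range(MAX_ITER):
            a = np.flatnonzero(active)
            if len(a) == 0:
                break
            eta = np.clip((Xb[a] @ beta[a, :, None])[..., 0], -35, 35)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = msk[a] * mu * (1 - mu)
            resid = msk[a] * (y[None, :] - mu)
            score = (Xb[a].transpose(0, 2, 1) @ resid[..., None])[..., 0]
            Ha = Xb[a].transpose(0, 2, 1) * w[:, None, :] @ Xb[a] + 1e-9 * eye
            delta = np.linalg.solve(Ha, score[..., None])[..., 0]
            np.clip(delta, -2.0, 2.0, out=delta)
            beta[a] += delta
            beta[a] = np.clip(beta[a], -30, 30)
            ll = msk[a] * (y[None, :] * eta - np.logaddexp(0.0, eta))
            dev = -2 * ll.sum(1)
            done = (np.abs(score).max(1) < 1e-6) | (np.abs(dev_prev[a] - dev) < LL_TOL)
            dev_prev[a] = dev
            active[a[done]] = False
        # observed information at the final coefficients
        eta = np.clip((Xb @ beta[:, :, None])[..., 0], -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = msk * mu * (1 - mu)
        H = Xb.transpose(0, 2, 1) * w[:, None, :] @ Xb + 1e-9 * eye
        with np.errstate(invalid="ignore"):
            cov = np.linalg.inv(H)
        se_fit = np.sqrt(np.maximum(cov[:, -1, -1], 0.0))
        denom = rsd[idx] * esd[idx]
        coef = beta[:, -1] / denom
        se = se_fit / denom
        sep = (np.abs(beta[:, -1]) >= 29) | (np.abs(coef) > SEPARATION_COEF) | (se > SEPARATION_SE)
        conv = ~active & ~sep & np.isfinite(coef) & np.isfinite(se) & (se > 0)
        rows = s + idx
        out["beta_int"][rows[conv]] = coef[conv]
        out["se"][rows[conv]] = se[conv]
        out["converged"][rows] = conv
        out["reason"][rows[~conv & ~active]] = "separation"
        out["reason"][rows[active]] = "not converged"
    df = pd.DataFrame(out)
    df["z"] = df["beta_int"] / df["se"]
    df["p"] = 2 * norm.sf(np.abs(df["z"]))
    return df


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN entries excluded)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    obs = np.isfinite(p)
    if ((p[obs] < 0) | (p[obs] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if obs.any():
        out[obs] = multipletests(p[obs], method="fdr_bh")[1]
    return out


def run_ewis(
    residuals,
    covariates: pd.DataFrame,
    spec: ModelSpec | None = None,
    engine: str = "batched",
) -> pd.DataFrame:
    """Fit the interaction model at every probe and BH-adjust over converged fits.

    `residuals` is a ResidualMatrix or a CpG x sample DataFrame aligned to
    `covariates` by sample id. Returns a per-probe table with the interaction
    estimate (log-odds per residual unit per exposure unit), its Wald z and
    p, BH q over converged probes, a `significant` flag at `spec.fdr_q`, and
    `effect_per_sd` = estimate x SD(residual_i) over non-missing samples
    (log-odds per exposure unit per 1 SD methylation). Model metadata lives
    in `.attrs`.
    """
    spec = spec or ModelSpec()
    R = residuals if isinstance(residuals, pd.DataFrame) else getattr(residuals, "values", None)
    if not isinstance(R, pd.DataFrame):
        raise TypeError("residuals must be a ResidualMatrix or DataFrame")
    cov = covariates.set_index("sample_id").loc[list(R.columns)].reset_index()
    X, exposure, ledger = build_design(cov, spec)
    row_idx = X.index.to_numpy()
    y = cov.loc[row_idx, "asthma"].to_numpy(float)
    Xmat = X.to_numpy(float)
    Rmat = R.to_numpy(float)[:, row_idx]

    if engine == "batched":
        # standardize the shared covariate block once (intercept kept)
        sd = Xmat.std(axis=0)
        scale = (sd > 0) & (np.arange(Xmat.shape[1]) > 0)
        Xs = Xmat.copy()
        Xs[:, scale] = (Xmat[:, scale] - Xmat.mean(axis=0)[scale]) / sd[scale]
        table = _batched_interaction_fits(Xs, exposure, Rmat, y)
        table.insert(0, "probe_id", R.index.to_numpy())
        reasons = table.pop("reason")
        table = table[["probe_id", "beta_int", "se", "z", "p", "converged", "n_used"]]
    elif engine == "per_probe":
        records = [
            fit_interaction_model(y, exposure, Rmat[i], Xmat, probe_id=probe)
            for i, probe in enumerate(R.index)
        ]
        table = pd.DataFrame([r.__dict__ for r in records]).drop(columns="reason")
        reasons = pd.Series([r.reason for r in records], index=table.index)
    else:
        raise ValueError("engine must be 'batched' or 'per_probe'")
    table["bh_q"] = bh_adjust(table["p"].where(table["converged"]))
    table["significant"] = table["bh_q"] < spec.fdr_q
    sd = np.nanstd(Rmat, axis=1, ddof=1)
    table["effect_per_sd"] = table["beta_int"] * sd
    if not table["converged"].any():
        raise RuntimeError("no probe converged; EWIS table would be empty")
    table.attrs.update(
        {
            "model": spec.label(),
            "exposure": spec.exposure_column,
            "fdr_q": spec.fdr_q,
            "column_ledger": ledger,
            "n_samples_used": int(len(row_idx)),
            "n_converged": int(table["converged"].sum()),
            "n_failed": int((~table["converged"]).sum()),
            "failure_reasons": reasons[~table["converged"]].value_counts().to_dict(),
            "max_iter": MAX_ITER,
            "ll_tol": LL_TOL,
        }
    )
    return table


def crp_association(covariates: pd.DataFrame) -> dict:
    """Linear check that BMI tracks systemic inflammation: regress natural-log
    hs-CRP on BMI (earlier survey) adjusted for age, sex, education, area and
    pack-years. Rows with missing or non-positive hs-CRP are excluded and
    counted. Returns the BMI coefficient with its 95% CI.
    """
    cov = covariates.copy()
    bad = ~(cov["hs_crp"] > 0)
    n_excluded = int(bad.sum())
    cov = cov.loc[~bad]
    if len(cov) < 20:
        raise ValueError(f"need >= 20 samples with positive hs-CRP, have {len(cov)}")
    X = pd.DataFrame(index=cov.index)
    X["const"] = 1.0
    X["bmi_s2"] = cov["bmi_s2"].astype(float)
    X["age"] = cov["age"].astype(float)
    X["sex_M"] = (cov["sex"] == "M").astype(float)
    for lev in EDUCATION_LEVELS[1:]:
        X[f"education_{lev}"] = (cov["education"] == lev).astype(float)
    for lev in sorted(cov["area"].astype(str).unique())[1:]:
        X[f"area_{lev}"] = (cov["area"] == lev).astype(float)
    X["packyears"] = cov["packyears"].astype(float)
    X = X.loc[:, (X.nunique() > 1) | (X.columns == "const")]
    fit = sm.OLS(np.log(cov["hs_crp"].to_numpy(float)), X).fit()
    ci = fit.conf_int().loc["bmi_s2"]
    return {
        "coef": float(fit.params["bmi_s2"]),
        "se": float(fit.bse["bmi_s2"]),
        "ci_low": float(ci[0]),
        "ci_high": float(ci[1]),
        "p": float(fit.pvalues["bmi_s2"]),
        "n_used": int(len(cov)),
        "n_excluded": n_excluded,
    }
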