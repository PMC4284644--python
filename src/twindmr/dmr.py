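"""Per-bin differentially methylated region (DMR) discovery.

The discovery scan regresses normalized per-bin methylation on disease
status plus covariates (age, sex, BMI) with a family random intercept, and
adjusts p-values genome-wide by Benjamini-Hochberg.  Discoveries are
reported at the FDR tiers 5% / 10% / 25%, with the 25% tier as the
suggestive set.  Replication in unrelated case-control samples uses
ordinary least squares with a same-direction + nominal-significance rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ModelError
from .mixedmodel import fit_many
from .quantify import BinnedMethylome, bin_ids

log = logging.getLogger(__name__)

SAMPLE_COLUMNS = ["sample_id", "family_id", "is_case", "age", "sex", "bmi"]
DEFAULT_COVARIATES = ("age", "sex", "bmi")
FDR_TIERS = (0.05, 0.10, 0.25)


def validate_sample_table(samples: pd.DataFrame, methylome: BinnedMethylome | None = None,
                          covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Check required columns, family sizes, and sample/matrix agreement."""
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise DataError(f"sample table missing columns: {missing}")
    sizes = samples.groupby("family_id").size()
    if (sizes > 2).any():
        bad = sizes[sizes > 2].index.tolist()
        raise DataError(f"family groups larger than 2: {bad}")
    for c in covariates:
        if samples[c].isna().any():
            bad = samples.loc[samples[c].isna(), "sample_id"].tolist()
            raise DataError(f"missing covariate {c!r} for samples: {bad}")
    if methylome is not None:
        if list(samples["sample_id"]) != list(methylome.samples):
            raise DataError("sample table does not match methylome sample order")
    return samples


def design_matrix(samples: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> np.ndarray:
    """Fixed-effect design: intercept, disease indicator, then covariates."""
    cols = [np.ones(len(samples)), samples["is_case"].to_numpy(float)]
    cols += [samples[c].to_numpy(float) for c in covariates]
    return np.column_stack(cols)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, float)
    if p.size and (np.min(p) <= 0 or np.max(p) > 1 or np.isnan(p).any()):
        raise DataError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def dmr_scan(methylome: BinnedMethylome, samples: pd.DataFrame,
             covariates=DEFAULT_COVARIATES, df_method: str = "satterthwaite") -> pd.DataFrame:
    """Family mixed-model scan for disease-associated bins.

    Requires a normalized methylome.  Returns one record per tested bin:
    effect estimate (beta), standard error, Wald p, BH q, direction
    ('hyper' for higher methylation in cases) and variance components.
    Constant bins and non-converged fits are excluded; their count is
    logged and stored in ``result.attrs``.
    """
    if methylome.signal_type not in {"normalized", "simulated"}:
        raise DataError("dmr_scan expects a normalized (or generator-scale) methylome")
    validate_sample_table(samples, methylome, covariates)
    X = design_matrix(samples, covariates)
    Y = methylome.values
    sd = Y.std(axis=1)
    testable = sd > 0
    n_constant = int((~testable).sum())
    if not testable.any():
        log.warning("dmr_scan: all %d bins constant across samples; nothing to test", len(sd))
        out = _empty_records()
        out.attrs.update(n_constant=n_constant, n_nonconverged=0)
        return out
    beta, se, z, p, s_f, s_e, conv = fit_many(Y[testable], X, samples["family_id"].to_numpy(),
                                              coef_index=1, df_method=df_method)
    n_nonconv = int((~conv).sum())
    if n_nonconv:
        log.warning("dmr_scan: %d bins did not converge and were excluded", n_nonconv)
    keep = np.where(testable)[0][conv]
    bins = methylome.bins.iloc[keep].reset_index(drop=True)
    out = bins.copy()
    out["bin"] = bin_ids(bins)
    out["beta"] = beta[conv]
    out["se"] = se[conv]
    out["z"] = z[conv]
    out["p"] = np.clip(p[conv], np.finfo(float).tiny, 1.0)
    out["q"] = bh_fdr(out["p"])
    out["direction"] = np.where(out["beta"] > 0, "hyper", np.where(out["beta"] < 0, "hypo", "none"))
    out["sigma_family_sq"] = s_f[conv]
    out["sigma_resid_sq"] = s_e[conv]
    out.attrs.update(n_constant=n_constant, n_nonconverged=n_nonconv,
                     tier_counts={t: int((out["q"] <= t).sum()) for t in FDR_TIERS})
    return out


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(columns=["chrom", "start", "end", "bin", "beta", "se", "z",
                                 "p", "q", "direction"])


def suggestive_set(records: pd.DataFrame, q_threshold: float = 0.25) -> pd.DataFrame:
    return records.loc[records["q"] <= q_threshold].reset_index(drop=True)


def _ols_many(Y: np.ndarray, X: np.ndarray):
    """Per-row OLS of Y rows on shared design X; t-test on column 1."""
    n, p = X.shape
    XtXi = np.linalg.inv(X.T @ X)
    B = Y @ X @ XtXi.T  # rows x p
    resid = Y - B @ X.T
    s2 = (resid**2).sum(axis=1) / (n - p)
    se = np.sqrt(s2 * XtXi[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = B[:, 1] / se
    pvals = 2.0 * stats.t.sf(np.abs(t), n - p)
    return B[:, 1], se, t, pvals


def replicate_dmrs(discovery: pd.DataFrame, methylome: BinnedMethylome,
                   samples: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Test discovery DMRs in unrelated samples by linear regression.

    A DMR is ``same_direction`` when the replication slope agrees in sign
    with the discovery beta, and ``replicated`` when it additionally
    reaches p < alpha.  DMRs absent from the replication matrix are flagged
    missing and excluded from the summary denominators; DMRs with
    discovery beta exactly 0 are flagged ambiguous.
    """
    validate_sample_table(samples, None, covariates)
    if (samples.groupby("family_id").size() > 1).any():
        raise DataError("replication samples must be unrelated (family size 1)")
    rep_ids = pd.Index(methylome.ids)
    X = design_matrix(samples, covariates)
    out = discovery[["chrom", "start", "end", "bin", "beta"]].rename(
        columns={"beta": "discovery_beta"}).copy()
    pos = rep_ids.get_indexer(out["bin"])
    present = pos >= 0
    beta = np.full(len(out), np.nan)
    pv = np.full(len(out), np.nan)
    if present.any():
        b, se, t, p = _ols_many(methylome.values[pos[present]], X)
        beta[present] = b
        pv[present] = p
    out["rep_beta"], out["rep_p"] = beta, pv
    out["missing"] = ~present
    ambiguous = out["discovery_beta"] == 0
    out["ambiguous"] = ambiguous
    out["same_direction"] = present & ~ambiguous & (np.sign(beta) == np.sign(out["discovery_beta"]))
    out["replicated"] = out["same_direction"] & (pv < alpha)
    denom = int((present & ~ambiguous).sum())
    out.attrs.update(
        n_tested=denom,
        n_missing=int((~present).sum()),
        n_same_direction=int(out["same_direction"].sum()),
        n_replicated=int(out["replicated"].sum()),
        frac_same_direction=out["same_direction"].sum() / denom if denom else np.nan,
        frac_replicated=out["replicated"].sum() / denom if denom else np.nan,
    )
    return out


def confounder_check(records: pd.DataFrame, methylome: BinnedMethylome,
                     samples: pd.DataFrame, extra_covariate: str,
                     covariates=DEFAULT_COVARIATES, case_only: bool = False) -> pd.DataFrame:
    """Refit the family mixed model adding one potential confounder.

    For each suggestive DMR, reports the extra covariate's effect p-value
    and the disease p-value after adjustment.  ``case_only`` codes the
    covariate as 0 for controls (e.g. medication use among cases).
    Constant covariates are untestable; collinearity with disease status is
    reported as a model error.
    """
    if extra_covariate not in samples.columns:
        raise DataError(f"sample table has no column {extra_covariate!r}")
    validate_sample_table(samples, methylome, covariates)
    extra = samples[extra_covariate].to_numpy(float)
    if case_only:
        extra = np.where(samples["is_case"].to_numpy(bool), extra, 0.0)
    if np.isnan(extra).any():
        raise DataError(f"missing values in covariate {extra_covariate!r}")
    if np.std(extra) == 0:
        raise ModelError(f"covariate {extra_covariate!r} is constant: untestable")
    X = np.column_stack([design_matrix(samples, covariates), extra])
    ids = pd.Index(methylome.ids)
    pos = ids.get_indexer(records["bin"])
    if (pos < 0).any():
        raise DataError("confounder_check: records contain bins absent from the methylome")
    fam = samples["family_id"].to_numpy()
    Y = methylome.values[pos]
    cb, cse, cz, cp, *_ = fit_many(Y, X, fam, coef_index=X.shape[1] - 1)
    db, dse, dz, dp, *_ = fit_many(Y, X, fam, coef_index=1)
    out = records[["chrom", "start", "end", "bin"]].copy()
    out["covariate"] = extra_covariate
    out["covariate_beta"], out["covariate_p"] = cb, np.clip(cp, np.finfo(float).tiny, 1)
    out["adjusted_disease_beta"], out["adjusted_disease_p"] = db, dp
    out["covariate_q"] = bh_fdr(out["covariate_p"])
    out.attrs["n_covariate_fdr05"] = int((out["covariate_q"] < 0.05).sum())
    return out
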