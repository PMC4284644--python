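"""Methylation QTL scans and the causal inference test (CIT).

Cis mQTL: SNPs within 50 kb of a DMR, ordinary least squares of per-DMR
methylation on dosage with age and sex adjustment; both Bonferroni and BH
adjustments are reported.  Trans mQTL: all remaining (DMR, SNP) pairs.

The CIT asks whether methylation M mediates the effect of a locus L on a
binary trait T.  Four component p-values are combined by their maximum
(omnibus):

  p1: L -> T           (T ~ L + covariates)
  p2: L -> M | T       (M ~ L + T + covariates)
  p3: M -> T | L       (T ~ M + L + covariates)
  p4: equivalence      L independent of T given M, via permutation

For p4 the mediator is permuted within genotype strata, which preserves
the L-M association while severing any M-T link: the permuted F statistics
for L in T ~ M* + L represent "no mediation" datasets in which L keeps its
full marginal effect on T.  Under a causal chain the observed F collapses
once the real M is adjusted for, so F_obs falls in the lower tail and
p4 = (1 + #{F* <= F_obs}) / (B + 1) is small; under independent pleiotropy
adjustment changes little and p4 stays large.  Binary traits are handled
by linear probability models throughout for internal consistency (a
logistic option is exposed for the three parametric components).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import bh_fdr
from .errors import ConfigurationError, DataError
from .quantify import BinnedMethylome, bin_ids
from .simulate import GenotypeMatrix

log = logging.getLogger(__name__)

CIS_WINDOW_BP = 50_000


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of v (vector or columns) on the design Z."""
    coef, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ coef


def _slope_test(y: np.ndarray, x: np.ndarray, Z: np.ndarray) -> tuple[float, float, float]:
    """OLS slope of y on x adjusting for Z; returns (beta, se, two-sided p)."""
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    sxx = float(rx @ rx)
    if sxx <= 0:
        raise DataError("regressor has zero residual variance")
    beta = float(rx @ ry) / sxx
    dof = len(y) - Z.shape[1] - 1
    resid = ry - beta * rx
    s2 = float(resid @ resid) / dof
    se = np.sqrt(s2 / sxx)
    t = beta / se if se > 0 else np.inf
    return beta, se, float(2.0 * stats.t.sf(abs(t), dof))


def _covariate_design(samples: pd.DataFrame, covariates) -> np.ndarray:
    cols = [np.ones(len(samples))]
    cols += [samples[c].to_numpy(float) for c in covariates]
    return np.column_stack(cols)


def cis_pairs(bins: pd.DataFrame, snps: pd.DataFrame,
              window: int = CIS_WINDOW_BP) -> pd.DataFrame:
    """(bin index, snp index) pairs with the SNP inside the half-open cis window.

    A SNP is cis to a bin when its position lies in
    [bin start - window, bin end + window).
    """
    rows = []
    for bi, b in enumerate(bins.itertuples(index=False)):
        sel = ((snps["chrom"] == b.chrom)
               & (snps["pos"] >= b.start - window)
               & (snps["pos"] < b.end + window))
        rows += [(bi, si) for si in np.where(sel.to_numpy())[0]]
    return pd.DataFrame(rows, columns=["bin_index", "snp_index"])


def _pair_scan(methylome: BinnedMethylome, genotypes: GenotypeMatrix,
               samples: pd.DataFrame, pairs: pd.DataFrame, covariates) -> pd.DataFrame:
    Z = _covariate_design(samples, covariates)
    ids = bin_ids(methylome.bins)
    # residualize every bin and SNP on the covariates once; the per-pair
    # slope test then reduces to a closed-form simple regression
    Yr = _residualize(methylome.values.T, Z)
    Gr = _residualize(genotypes.dosage.T, Z)
    dof = len(samples) - Z.shape[1] - 1
    rows = []
    n_skipped = 0
    for bi, si in pairs.itertuples(index=False):
        if np.std(genotypes.dosage[si]) == 0:
            n_skipped += 1
            continue
        rx, ry = Gr[:, si], Yr[:, bi]
        sxx = float(rx @ rx)
        beta = float(rx @ ry) / sxx
        resid = ry - beta * rx
        se = np.sqrt(float(resid @ resid) / dof / sxx)
        t = beta / se if se > 0 else np.inf
        p = float(2.0 * stats.t.sf(abs(t), dof))
        rows.append(dict(bin=ids[bi], snp=genotypes.snps["snp_id"].iloc[si],
                         bin_index=bi, snp_index=si, beta=beta, se=se, p=p))
    if n_skipped:
        log.warning("mQTL scan: %d SNPs with zero variance skipped", n_skipped)
    out = pd.DataFrame(rows, columns=["bin", "snp", "bin_index", "snp_index",
                                      "beta", "se", "p"])
    if len(out):
        out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
        out["q"] = bh_fdr(np.clip(out["p"], np.finfo(float).tiny, 1.0))
    else:
        out["p_bonferroni"] = out["q"] = np.nan
    out.attrs["n_skipped"] = n_skipped
    return out


def cis_mqtl_scan(methylome: BinnedMethylome, genotypes: GenotypeMatrix,
                  samples: pd.DataFrame, window: int = CIS_WINDOW_BP,
                  covariates=("age", "sex")) -> pd.DataFrame:
    """Per-(DMR, cis SNP) dosage regression with age/sex adjustment.

    Returns raw, Bonferroni and BH-adjusted p-values per tested pair;
    ``result.attrs['best_per_bin']`` maps each DMR to its best cis SNP.
    """
    pairs = cis_pairs(methylome.bins, genotypes.snps, window)
    out = _pair_scan(methylome, genotypes, samples, pairs, covariates)
    if len(out):
        best = out.loc[out.groupby("bin")["p"].idxmin(), ["bin", "snp", "beta", "p"]]
        out.attrs["best_per_bin"] = best.reset_index(drop=True).to_dict("records")
    out.attrs["scan"] = "cis"
    return out


def trans_mqtl_scan(methylome: BinnedMethylome, genotypes: GenotypeMatrix,
                    samples: pd.DataFrame, cis_window: int = CIS_WINDOW_BP,
                    covariates=("age", "sex"), fdr: float = 0.05) -> pd.DataFrame:
    """Genome-wide (DMR, SNP) regressions excluding the cis window.

    The cis/trans partition is exact: every tested pair appears in exactly
    one of the two scans.  Pairs with BH q <= ``fdr`` are flagged.
    """
    cis = set(map(tuple, cis_pairs(methylome.bins, genotypes.snps, cis_window)
                  .itertuples(index=False)))
    all_pairs = [(bi, si) for bi in range(methylome.n_bins)
                 for si in range(len(genotypes.snps)) if (bi, si) not in cis]
    pairs = pd.DataFrame(all_pairs, columns=["bin_index", "snp_index"])
    out = _pair_scan(methylome, genotypes, samples, pairs, covariates)
    out["is_trans_mqtl"] = out["q"] <= fdr if len(out) else pd.Series(dtype=bool)
    out.attrs["scan"] = "trans"
    return out


@dataclass
class CitResult:
    """Component and omnibus p-values of the causal inference test."""

    p1: float
    p2: float
    p3: float
    p4: float
    p_omnibus: float
    B: int
    untestable: bool = False
    note: str = ""

    def __post_init__(self):
        if not self.untestable:
            assert abs(self.p_omnibus - max(self.p1, self.p2, self.p3, self.p4)) < 1e-15


def _genotype_strata(L: np.ndarray, max_classes: int = 5) -> np.ndarray:
    """Permutation strata: genotype classes, or deciles for fractional dosage."""
    uniq = np.unique(L)
    if uniq.size <= max_classes:
        return np.searchsorted(uniq, L)
    q = np.quantile(L, np.linspace(0, 1, 11)[1:-1])
    return np.searchsorted(q, L)


def causal_inference_test(L, M, T, covariates: np.ndarray | None = None,
                          B: int = 1000, seed: int = 0,
                          trait_model: str = "linear") -> CitResult:
    """Causal inference test for mediation of a genetic effect by methylation.

    ``L`` is an additive dosage (possibly fractional), ``M`` the mediator
    (methylation), ``T`` the trait (binary case/control, modelled by
    linear probability regression; ``trait_model='logistic'`` switches the
    three parametric components).  ``covariates`` is an optional n x c
    matrix.  Requires >= 30 complete samples and a non-constant locus.
    """
    L = np.asarray(L, float)
    M = np.asarray(M, float)
    T = np.asarray(T, float)
    n = len(L)
    if n < 30:
        raise DataError(f"causal inference test requires >=30 samples, got {n}")
    if np.std(L) == 0:
        raise DataError("locus L is constant")
    if np.std(M) == 0 or np.std(T) == 0:
        return CitResult(np.nan, np.nan, np.nan, np.nan, np.nan, B,
                         untestable=True, note="constant mediator or trait")
    if B < 100:
        log.warning("causal_inference_test: B=%d permutations is low", B)
    C = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, float)])

    def comp(y, x, others):
        Z = np.column_stack([C] + [o[:, None] for o in others])
        if trait_model == "logistic" and set(np.unique(y)) <= {0.0, 1.0}:
            import statsmodels.api as sm
            X = np.column_stack([Z, x])
            fit = sm.Logit(y, X).fit(disp=0)
            return float(fit.pvalues[-1])
        return _slope_test(y, x, Z)[2]

    p1 = comp(T, L, [])
    p2 = comp(M, L, [T])
    p3 = comp(T, M, [L])

    # p4: equivalence component.  Residualize on covariates once, then work
    # with partial correlations; the mediator is permuted within genotype
    # strata to preserve the L-M association while severing M-T.
    l0 = _residualize(L, C)
    m0 = _residualize(M, C)
    t0 = _residualize(T, C)
    l0 = l0 / np.linalg.norm(l0)
    t0n = t0 / np.linalg.norm(t0)
    dof = n - C.shape[1] - 2  # intercept+covs absorbed, minus M and L

    def partial_F(mvec: np.ndarray) -> float:
        mn = mvec / np.linalg.norm(mvec)
        r_lt = float(l0 @ t0n)
        r_lm = float(l0 @ mn)
        r_tm = float(t0n @ mn)
        denom = (1 - r_lm**2) * (1 - r_tm**2)
        if denom <= 0:
            return np.inf
        pr = (r_lt - r_lm * r_tm) / np.sqrt(denom)
        pr = float(np.clip(pr, -0.999999999, 0.999999999))
        return dof * pr**2 / (1 - pr**2)

    F_obs = partial_F(m0)
    rng = np.random.default_rng(seed)
    strata = _genotype_strata(L)
    idx = np.arange(n)
    count = 0
    for _ in range(B):
        perm = idx.copy()
        for s in np.unique(strata):
            sel = np.where(strata == s)[0]
            perm[sel] = sel[rng.permutation(sel.size)]
        if partial_F(m0[perm]) <= F_obs:
            count += 1
    p4 = (1 + count) / (B + 1)
    return CitResult(p1=p1, p2=p2, p3=p3, p4=p4,
                     p_omnibus=max(p1, p2, p3, p4), B=B)


def cit_for_mqtls(mqtl_records: pd.DataFrame, methylome: BinnedMethylome,
                  genotypes: GenotypeMatrix, samples: pd.DataFrame,
                  max_triples: int = 20, B: int = 1000, seed: int = 0,
                  q_threshold: float = 0.05) -> pd.DataFrame:
    """Run the CIT on the strongest mQTL (SNP, DMR, disease) triples."""
    hits = mqtl_records.loc[mqtl_records["q"] <= q_threshold].nsmallest(max_triples, "p")
    covs = samples[["age", "sex"]].to_numpy(float)
    T = samples["is_case"].to_numpy(float)
    rows = []
    for k, (_, rec) in enumerate(hits.iterrows()):
        res = causal_inference_test(genotypes.dosage[int(rec["snp_index"])],
                                    methylome.values[int(rec["bin_index"])],
                                    T, covs, B=B, seed=seed + k)
        rows.append(dict(bin=rec["bin"], snp=rec["snp"], p1=res.p1, p2=res.p2,
                         p3=res.p3, p4=res.p4, p_omnibus=res.p_omnibus,
                         untestable=res.untestable))
    return pd.DataFrame(rows, columns=["bin", "snp", "p1", "p2", "p3", "p4",
                                       "p_omnibus", "untestable"])


def read_dosage_matrix(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["snp_id", "chrom", "pos", "maf"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise DataError(f"dosage matrix missing columns: {missing}")
    samples = [c for c in df.columns if c not in meta_cols]
    return GenotypeMatrix(df[meta_cols].copy(), samples, df[samples].to_numpy(float))
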