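"""Metabolite integration: run-day normalization, within-pair association,
replication, and meta-analysis.

Mass-spectrometry metabolite panels drift between machine runs; values are
first divided by the per-(metabolite, run-day) median and then
standardized per metabolite.  Discovery uses the discordant-twin design: a
Wilcoxon signed-rank test of within-pair (affected - unaffected)
differences.  Metabolites nominally significant at discovery are carried
to a replication regression in unrelated samples, and the two stages are
combined by a direction-signed Stouffer meta-analysis with sqrt(n)
weights, Bonferroni-corrected over the meta-analysed metabolites.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .gidmr import discordant_pairs
from .mqtl import _slope_test
from .dmr import validate_sample_table

log = logging.getLogger(__name__)

MIN_PAIRS = 5
EXACT_WILCOXON_MAX_N = 25


def runday_median_normalize(raw: pd.DataFrame, run_day: pd.Series) -> pd.DataFrame:
    """Divide by per-(metabolite, day) medians, then standardize per metabolite.

    ``raw`` is metabolites x samples; ``run_day`` maps sample -> day label.
    Groups whose values are all missing keep their missing values and are
    logged.  Standardization brings each metabolite to mean 0, sd 1 across
    samples, so day-scale effects cancel by construction.
    """
    if not set(raw.columns) <= set(run_day.index):
        missing = sorted(set(raw.columns) - set(run_day.index))
        raise DataError(f"samples without run-day labels: {missing}")
    out = raw.astype(float).copy()
    days = run_day.loc[out.columns]
    for day in days.unique():
        cols = out.columns[(days == day).to_numpy()]
        med = out[cols].median(axis=1)
        all_missing = out[cols].isna().all(axis=1)
        if all_missing.any():
            log.warning("run-day %s: %d metabolites with no values remain missing",
                        day, int(all_missing.sum()))
        med = med.where(med != 0)
        out.loc[:, cols] = out[cols].div(med, axis=0)
    mean = out.mean(axis=1)
    sd = out.std(axis=1, ddof=1)
    out = out.sub(mean, axis=0).div(sd.where(sd > 0), axis=0)
    return out


def pairwise_wilcoxon(metabolites: pd.DataFrame, samples: pd.DataFrame,
                      min_pairs: int = MIN_PAIRS) -> pd.DataFrame:
    """Wilcoxon signed-rank test of within-pair metabolite differences.

    Differences are oriented affected - unaffected over discordant pairs.
    Zero differences are dropped (standard signed-rank convention, counts
    logged); the exact null distribution is used for n <= 25 usable pairs
    and the normal approximation with continuity correction above.
    Metabolites with fewer than ``min_pairs`` usable pairs are flagged
    untestable.
    """
    validate_sample_table(samples)
    pairs = discordant_pairs(samples)
    if len(pairs) < 2:
        raise DataError("need >=2 discordant pairs")
    aff = metabolites[pairs["affected"]].to_numpy(float)
    una = metabolites[pairs["unaffected"]].to_numpy(float)
    D = aff - una  # metabolites x pairs
    rows = []
    n_zero_dropped = 0
    for i, met in enumerate(metabolites.index):
        d = D[i][~np.isnan(D[i])]
        nz = d[d != 0]
        n_zero_dropped += d.size - nz.size
        if nz.size < min_pairs:
            rows.append(dict(metabolite=met, n_pairs=int(nz.size), statistic=np.nan,
                             p=np.nan, direction="", untestable=True))
            continue
        method = "exact" if nz.size <= EXACT_WILCOXON_MAX_N else "approx"
        res = stats.wilcoxon(nz, zero_method="wilcox", correction=(method == "approx"),
                             alternative="two-sided", method=method)
        # report W+ (rank sum of positive differences); scipy's statistic
        # is min(W+, W-) under the two-sided alternative
        ranks = stats.rankdata(np.abs(nz))
        w_plus = float(ranks[nz > 0].sum())
        mean_diff = float(d.mean())
        rows.append(dict(metabolite=met, n_pairs=int(nz.size),
                         statistic=w_plus, p=float(res.pvalue),
                         direction="up" if mean_diff > 0 else ("down" if mean_diff < 0 else ""),
                         untestable=False))
    if n_zero_dropped:
        log.info("pairwise_wilcoxon: dropped %d zero differences", n_zero_dropped)
    out = pd.DataFrame(rows).set_index("metabolite")
    out.attrs["n_zero_dropped"] = n_zero_dropped
    return out


def pair_difference_correlation(metabolites: pd.DataFrame, methylation: pd.Series,
                                samples: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of within-pair metabolite vs. methylation differences.

    A documented variant of the discovery test that conditions on the
    chosen DMR: both difference vectors are oriented affected - unaffected.
    """
    pairs = discordant_pairs(samples)
    md = (methylation[pairs["affected"]].to_numpy(float)
          - methylation[pairs["unaffected"]].to_numpy(float))
    D = (metabolites[pairs["affected"]].to_numpy(float)
         - metabolites[pairs["unaffected"]].to_numpy(float))
    rows = []
    for i, met in enumerate(metabolites.index):
        ok = ~np.isnan(D[i])
        if ok.sum() < MIN_PAIRS:
            rows.append(dict(metabolite=met, rho=np.nan, p=np.nan, untestable=True))
            continue
        rho, p = stats.spearmanr(D[i][ok], md[ok])
        rows.append(dict(metabolite=met, rho=float(rho), p=float(p), untestable=False))
    return pd.DataFrame(rows).set_index("metabolite")


def replication_regression(metabolites: pd.DataFrame, methylation: pd.Series,
                           samples: pd.DataFrame, discovery: pd.DataFrame | None = None,
                           covariates=("age", "sex", "bmi"),
                           alpha: float = 0.05) -> pd.DataFrame:
    """OLS of each carried-forward metabolite on methylation + covariates.

    When ``discovery`` results are supplied, only metabolites with
    discovery p < alpha are tested (the staged design); with no survivors
    an empty table is returned.  Samples without methylation are dropped
    with a log entry.
    """
    validate_sample_table(samples)
    carried = metabolites.index
    if discovery is not None:
        keep = discovery.loc[~discovery["untestable"] & (discovery["p"] < alpha)].index
        carried = metabolites.index.intersection(keep)
    cols = ["metabolite", "beta", "se", "p", "direction", "n"]
    if len(carried) == 0:
        return pd.DataFrame(columns=cols).set_index("metabolite")
    meth = methylation.reindex(samples["sample_id"])
    usable = ~meth.isna().to_numpy()
    if (~usable).any():
        log.warning("replication_regression: dropped %d samples without methylation",
                    int((~usable).sum()))
    sub = samples.loc[usable]
    Z = np.column_stack([np.ones(len(sub))] + [sub[c].to_numpy(float) for c in covariates])
    x = meth.to_numpy(float)[usable]
    rows = []
    for met in carried:
        y = metabolites.loc[met, sub["sample_id"]].to_numpy(float)
        ok = ~np.isnan(y)
        beta, se, p = _slope_test(y[ok], x[ok], Z[ok])
        rows.append(dict(metabolite=met, beta=beta, se=se, p=p,
                         direction="up" if beta > 0 else ("down" if beta < 0 else ""),
                         n=int(ok.sum())))
    return pd.DataFrame(rows, columns=cols).set_index("metabolite")


def stouffer_meta(p1: float, direction1: str, n1: int,
                  p2: float, direction2: str, n2: int) -> float:
    """Direction-signed Stouffer combination with sqrt(n) weights.

    Each two-sided p is converted to a signed z (positive for 'up'); the
    combined z is (w1 z1 + w2 z2) / sqrt(w1^2 + w2^2) with w = sqrt(n), and
    the meta p is the two-sided normal tail.
    """
    signs = {"up": 1.0, "down": -1.0}
    if direction1 not in signs or direction2 not in signs:
        raise DataError("meta-analysis requires an 'up'/'down' direction for both stages")
    z1 = signs[direction1] * stats.norm.isf(p1 / 2.0)
    z2 = signs[direction2] * stats.norm.isf(p2 / 2.0)
    w1, w2 = np.sqrt(n1), np.sqrt(n2)
    z = (w1 * z1 + w2 * z2) / np.sqrt(w1**2 + w2**2)
    return float(2.0 * stats.norm.sf(abs(z)))


def meta_analyze(discovery: pd.DataFrame, replication: pd.DataFrame) -> pd.DataFrame:
    """Combine discovery and replication per metabolite; Bonferroni flag.

    Expects ``p``, ``direction`` and ``n_pairs``/``n`` columns.  Metabolites
    missing a direction in either stage are excluded and logged.
    """
    both = discovery.index.intersection(replication.index)
    rows = []
    n_excluded = 0
    for met in both:
        d, r = discovery.loc[met], replication.loc[met]
        if d.get("untestable", False) or not d["direction"] or not r["direction"]:
            n_excluded += 1
            continue
        n1 = int(d.get("n_pairs", d.get("n", 0)))
        meta_p = stouffer_meta(d["p"], d["direction"], n1, r["p"], r["direction"], int(r["n"]))
        rows.append(dict(metabolite=met, discovery_p=d["p"], replication_p=r["p"],
                         meta_p=meta_p, same_direction=d["direction"] == r["direction"]))
    if n_excluded:
        log.warning("meta_analyze: %d metabolites excluded (missing direction)", n_excluded)
    out = pd.DataFrame(rows, columns=["metabolite", "discovery_p", "replication_p",
                                      "meta_p", "same_direction"]).set_index("metabolite")
    m = len(out)
    out["meta_p_bonferroni"] = np.minimum(out["meta_p"] * m, 1.0) if m else np.nan
    out["significant"] = out["meta_p_bonferroni"] < 0.05 if m else False
    return out
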