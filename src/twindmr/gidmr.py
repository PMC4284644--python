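"""Genetically independent DMR (giDMR) discovery in discordant MZ pairs.

Monozygotic co-twins share genotype and family environment, so the
within-pair methylation difference (affected minus unaffected co-twin)
cancels every pair-shared additive term — genetic background included.  A
one-sample t-test per bin asks whether the mean within-pair difference is
zero; hits are environmental, stochastic, or disease-consequent by design.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import bh_fdr, validate_sample_table
from .errors import DataError
from .quantify import BinnedMethylome, bin_ids

log = logging.getLogger(__name__)


def discordant_pairs(samples: pd.DataFrame) -> pd.DataFrame:
    """Table of (pair_id, affected sample, unaffected sample).

    Discordance is derived from case labels within each two-member family.
    If the table carries a ``pair_type`` column, a pair labelled
    'discordant' whose members are concordant raises a metadata error.
    """
    rows = []
    for fam, grp in samples.groupby("family_id", sort=False):
        if len(grp) != 2:
            continue
        cases = grp["is_case"].astype(bool)
        labelled = (grp.get("pair_type") == "discordant").any() if "pair_type" in grp else None
        if cases.sum() == 1:
            rows.append((fam,
                         grp.loc[cases, "sample_id"].iloc[0],
                         grp.loc[~cases, "sample_id"].iloc[0]))
        elif labelled:
            raise DataError(
                f"pair {fam!r} is labelled discordant but has {cases.sum()} cases")
    return pd.DataFrame(rows, columns=["pair_id", "affected", "unaffected"])


def pair_differences(methylome: BinnedMethylome, samples: pd.DataFrame) -> pd.DataFrame:
    """Within-pair differences (affected - unaffected), pairs x bins."""
    validate_sample_table(samples, methylome)
    pairs = discordant_pairs(samples)
    if len(pairs) < 2:
        raise DataError(f"need >=2 discordant pairs, found {len(pairs)}")
    frame = methylome.to_frame()
    diff = (frame[pairs["affected"]].to_numpy() - frame[pairs["unaffected"]].to_numpy()).T
    return pd.DataFrame(diff, index=pd.Index(pairs["pair_id"], name="pair_id"),
                        columns=frame.index)


def one_sample_t(differences) -> tuple[float, float]:
    """One-sample t-test that the mean difference is zero.

    t = mean / (sd / sqrt(n)), two-sided p from t with n-1 df.  Zero
    variance is untestable and raises rather than returning p = 0.
    """
    d = np.asarray(differences, float)
    n = d.size
    if n < 2:
        raise DataError("one_sample_t needs >=2 differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DataError("zero variance: untestable")
    t = d.mean() / (sd / np.sqrt(n))
    return float(t), float(2.0 * stats.t.sf(abs(t), n - 1))


def gidmr_scan(methylome: BinnedMethylome, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-bin paired t-test scan restricted to discordant pairs.

    beta is the mean within-pair difference; q-values are BH over all
    tested bins.  Bins with zero difference variance are excluded and
    counted in ``result.attrs``.
    """
    diffs = pair_differences(methylome, samples)
    D = diffs.to_numpy().T  # bins x pairs
    n = D.shape[1]
    sd = D.std(axis=1, ddof=1)
    testable = sd > 0
    n_untestable = int((~testable).sum())
    if n_untestable:
        log.warning("gidmr_scan: %d bins with zero difference variance excluded", n_untestable)
    Dk = D[testable]
    mean = Dk.mean(axis=1)
    t = mean / (sd[testable] / np.sqrt(n))
    p = np.clip(2.0 * stats.t.sf(np.abs(t), n - 1), np.finfo(float).tiny, 1.0)
    bins = methylome.bins.loc[testable].reset_index(drop=True)
    out = bins.copy()
    out["bin"] = bin_ids(bins)
    out["beta"] = mean
    out["se"] = sd[testable] / np.sqrt(n)
    out["t"] = t
    out["p"] = p
    out["q"] = bh_fdr(p)
    out["direction"] = np.where(mean > 0, "hyper", np.where(mean < 0, "hypo", "none"))
    out.attrs.update(n_pairs=n, n_untestable=n_untestable)
    return out


def overlap_report(gidmr_records: pd.DataFrame, dmr_records: pd.DataFrame,
                   q_threshold: float = 0.25) -> pd.DataFrame:
    """Bins suggestive in the giDMR scan, flagged by primary-scan overlap."""
    gi = gidmr_records.loc[gidmr_records["q"] <= q_threshold, ["bin"]].copy()
    primary = set(dmr_records.loc[dmr_records["q"] <= q_threshold, "bin"])
    gi["in_both_scans"] = gi["bin"].isin(primary)
    gi.attrs["n_shared"] = int(gi["in_both_scans"].sum())
    return gi.reset_index(drop=True)
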