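"""Enrichment of DMRs in gene annotations, GWAS loci and candidate gene sets.

Three constructions:

* a TSS-proximity permutation test (observed fraction of DMRs near a
  transcription start site vs. TSS positions relocated uniformly within
  their chromosome);
* one-sided Fisher exact tests for region overlap (bins vs. SNP windows)
  and gene-set overlap, both reduced to hypergeometric tails;
* a rank-resampling test comparing the per-gene DMR p-value ranks of a
  target gene set against randomly drawn gene sets of the same size
  (Wilcoxon rank-sum statistic, add-one empirical p).

Gene annotation is strand-aware: the extended promoter runs 20 kb upstream
of the gene, and a DMR is assigned to every gene whose body or promoter it
overlaps by at least 1 bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import ConfigurationError, DataError

PROMOTER_UPSTREAM_BP = 20_000
GWAS_FLANK_BP = 50_000


@dataclass
class EnrichmentResult:
    """Observed statistic vs. a null summary, with fold and p-value."""

    method: str
    observed: float
    null_mean: float
    null_sd: float
    n_null: int
    fold: float
    p: float
    odds_ratio: float | None = None
    untestable: bool = False
    note: str = ""

    @property
    def excess_percent(self) -> float:
        """The 'x% more than expected by chance' reading: (fold - 1) * 100."""
        return (self.fold - 1.0) * 100.0

    def to_row(self) -> dict:
        return {"method": self.method, "observed": self.observed, "fold": self.fold,
                "p": self.p, "null_mean": self.null_mean, "n_null": self.n_null,
                "untestable": self.untestable}


def validate_genes(genes: pd.DataFrame, chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    need = {"gene_id", "chrom", "strand", "tss", "start", "end"}
    missing = need - set(genes.columns)
    if missing:
        raise DataError(f"gene table missing columns: {sorted(missing)}")
    bad = ~genes["strand"].isin(["+", "-"])
    if bad.any():
        raise DataError(f"invalid strand values: {genes.loc[bad, 'strand'].unique().tolist()}")
    plus = genes["strand"] == "+"
    tss_ok = np.where(plus, genes["tss"] == genes["start"], genes["tss"] == genes["end"] - 1)
    if not np.all(tss_ok):
        raise DataError("tss must equal start (+ strand) or end-1 (- strand)")
    return genes


def promoter_intervals(genes: pd.DataFrame, chrom_sizes: dict[str, int] | None = None,
                       upstream_bp: int = PROMOTER_UPSTREAM_BP) -> pd.DataFrame:
    """Strand-aware extended promoter [upstream_bp upstream of the gene)."""
    plus = (genes["strand"] == "+").to_numpy()
    start = np.where(plus, genes["start"] - upstream_bp, genes["end"])
    end = np.where(plus, genes["start"], genes["end"] + upstream_bp)
    start = np.maximum(start, 0)
    if chrom_sizes:
        lim = genes["chrom"].map(chrom_sizes).to_numpy()
        end = np.minimum(end, lim)
    return pd.DataFrame({"gene_id": genes["gene_id"], "chrom": genes["chrom"],
                         "start": start.astype(int), "end": end.astype(int)})


def _build_trees(df: pd.DataFrame, label_col: str) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        if d["end"] > d["start"]:
            trees.setdefault(d["chrom"], IntervalTree()).addi(d["start"], d["end"], d[label_col])
    return trees


def annotate_dmrs_to_genes(dmrs: pd.DataFrame, genes: pd.DataFrame,
                           chrom_sizes: dict[str, int] | None = None,
                           upstream_bp: int = PROMOTER_UPSTREAM_BP) -> pd.DataFrame:
    """Assign each DMR to overlapping genes with a promoter/gene-body class.

    A DMR is assigned to every gene whose body or extended promoter it
    overlaps (>=1 bp); ``gene_body`` takes precedence over ``promoter``
    when both overlap the same gene.  DMRs overlapping nothing appear once
    with class ``intergenic`` and an empty gene id.  ``result.attrs``
    carries the DMR-level class fractions and the unique DMR gene list.
    """
    validate_genes(genes)
    if genes.empty:
        out = dmrs[["chrom", "start", "end", "bin"]].copy()
        out["gene_id"], out["cls"] = "", "intergenic"
        out.attrs.update(dmr_genes=[], class_fractions={})
        return out
    body_trees = _build_trees(genes[["chrom", "start", "end", "gene_id"]], "gene_id")
    prom = promoter_intervals(genes, chrom_sizes, upstream_bp)
    prom_trees = _build_trees(prom, "gene_id")
    rows = []
    for r in dmrs[["chrom", "start", "end", "bin"]].itertuples(index=False):
        hits: dict[str, str] = {}
        for iv in (prom_trees.get(r.chrom) or IntervalTree()).overlap(r.start, r.end):
            hits[iv.data] = "promoter"
        for iv in (body_trees.get(r.chrom) or IntervalTree()).overlap(r.start, r.end):
            hits[iv.data] = "gene_body"  # body wins over promoter for the same gene
        if hits:
            rows += [dict(chrom=r.chrom, start=r.start, end=r.end, bin=r.bin,
                          gene_id=g, cls=c) for g, c in sorted(hits.items())]
        else:
            rows.append(dict(chrom=r.chrom, start=r.start, end=r.end, bin=r.bin,
                             gene_id="", cls="intergenic"))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "bin", "gene_id", "cls"])
    per_dmr = out.groupby("bin")["cls"].agg(
        lambda s: "gene_body" if (s == "gene_body").any()
        else ("promoter" if (s == "promoter").any() else "intergenic"))
    frac = (per_dmr.value_counts() / len(per_dmr)).to_dict() if len(per_dmr) else {}
    out.attrs.update(dmr_genes=sorted(set(out.loc[out["gene_id"] != "", "gene_id"])),
                     class_fractions=frac)
    return out


def tss_proximity_test(dmrs: pd.DataFrame, genes: pd.DataFrame,
                       chrom_sizes: dict[str, int], window_bp: int = 100,
                       n_perm: int = 20, seed: int = 0) -> EnrichmentResult:
    """Fraction of DMR midpoints within ``window_bp`` of any TSS vs. permuted TSSs.

    The null relocates every TSS uniformly within its own chromosome
    (per-chromosome TSS counts preserved).  Twenty permutations match the
    historical default; below 999 the minimum attainable p is coarse, so a
    warning note is attached.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    if dmrs.empty or genes.empty:
        raise DataError("tss_proximity_test needs >=1 DMR and >=1 gene")
    rng = np.random.default_rng(seed)
    mids = ((dmrs["start"] + dmrs["end"]) // 2).to_numpy()
    chrom_of_dmr = dmrs["chrom"].to_numpy()

    def frac_near(tss_by_chrom: dict[str, np.ndarray]) -> float:
        near = 0
        for c in np.unique(chrom_of_dmr):
            t = np.sort(tss_by_chrom.get(c, np.empty(0)))
            m = mids[chrom_of_dmr == c]
            if t.size == 0:
                continue
            j = np.searchsorted(t, m)
            d = np.minimum(np.abs(m - t[np.clip(j, 0, t.size - 1)]),
                           np.abs(m - t[np.clip(j - 1, 0, t.size - 1)]))
            near += int((d <= window_bp).sum())
        return near / len(mids)

    observed_tss = {c: g["tss"].to_numpy() for c, g in genes.groupby("chrom")}
    observed = frac_near(observed_tss)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = {c: rng.integers(0, chrom_sizes[c], size=len(t))
                for c, t in observed_tss.items()}
        null[b] = frac_near(perm)
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    nm = null.mean()
    return EnrichmentResult(
        method="tss_proximity_permutation", observed=observed, null_mean=nm,
        null_sd=null.std(ddof=1) if n_perm > 1 else 0.0, n_null=n_perm,
        fold=observed / nm if nm > 0 else np.inf, p=p,
        note="" if n_perm >= 999 else f"n_perm={n_perm} < 999: minimum attainable "
                                      f"p is {1 / (n_perm + 1):.4g}")


def _hypergeom_tail(x: int, N: int, K: int, n: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n); one-sided enrichment tail."""
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def region_overlap_fisher(dmr_bins: pd.DataFrame, windows: pd.DataFrame,
                          universe_bins: pd.DataFrame,
                          two_sided: bool = False) -> EnrichmentResult:
    """Fisher test of {bin is DMR} x {bin overlaps any window} over the universe.

    ``windows`` carries chrom/start/end intervals (e.g. GWAS SNPs +-50 kb).
    The one-sided enrichment p is the hypergeometric upper tail.
    """
    if universe_bins.empty:
        raise DataError("empty bin universe")
    from .quantify import bin_ids
    uni_ids = bin_ids(universe_bins)
    dmr_ids = set(bin_ids(dmr_bins))
    if not dmr_ids <= set(uni_ids):
        raise DataError("dmr_bins must be a subset of universe_bins")
    trees = _build_trees(windows.assign(wid=np.arange(len(windows)))[
        ["chrom", "start", "end", "wid"]], "wid") if len(windows) else {}
    in_window = np.array([
        bool((trees.get(r.chrom) or IntervalTree()).overlap(r.start, r.end))
        for r in universe_bins.itertuples(index=False)])
    is_dmr = np.asarray(uni_ids.isin(dmr_ids))
    N, K, n = len(uni_ids), int(is_dmr.sum()), int(in_window.sum())
    x = int((is_dmr & in_window).sum())
    if n in (0, N) or K in (0, N):
        return EnrichmentResult("region_overlap_fisher", x, 0.0, 0.0, 0, np.nan, 1.0,
                                untestable=True, note="degenerate margin")
    expected = K * n / N
    table = np.array([[x, K - x], [n - x, N - K - (n - x)]])
    odds = stats.fisher_exact(table, alternative="greater")[0]
    p = (stats.fisher_exact(table, alternative="two-sided")[1] if two_sided
         else _hypergeom_tail(x, N, K, n))
    return EnrichmentResult("region_overlap_fisher", observed=x, null_mean=expected,
                            null_sd=0.0, n_null=0, fold=x / expected if expected else np.inf,
                            p=p, odds_ratio=odds)


def gene_set_fisher(dmr_genes, target_genes, universe_genes,
                    allow_drop: bool = False, two_sided: bool = False) -> EnrichmentResult:
    """Fisher test of {gene has a DMR} x {gene in target set} over the universe."""
    uni = list(dict.fromkeys(universe_genes))
    uset = set(uni)
    dmr = set(dmr_genes)
    target = set(target_genes)
    outside = sorted((dmr | target) - uset)
    if outside:
        if not allow_drop:
            raise DataError(f"gene ids outside the universe: {outside}")
        dmr &= uset
        target &= uset
    N, K, n = len(uni), len(dmr), len(target)
    x = len(dmr & target)
    if N == 0 or n in (0, N) or K in (0, N):
        return EnrichmentResult("gene_set_fisher", x, 0.0, 0.0, 0, np.nan, 1.0,
                                untestable=True, note="degenerate margin")
    expected = K * n / N
    table = np.array([[x, K - x], [n - x, N - K - (n - x)]])
    odds = stats.fisher_exact(table, alternative="greater")[0]
    p = (stats.fisher_exact(table, alternative="two-sided")[1] if two_sided
         else _hypergeom_tail(x, N, K, n))
    return EnrichmentResult("gene_set_fisher", observed=x, null_mean=expected, null_sd=0.0,
                            n_null=0, fold=x / expected if expected else np.inf,
                            p=p, odds_ratio=odds)


def gene_level_pvalues(annotation: pd.DataFrame, records: pd.DataFrame,
                       summary: str = "min") -> pd.Series:
    """Per-gene summary of DMR p-values (minimum across assigned DMRs).

    ``summary='mean_rank'`` averages the p-values instead; only genes with
    at least one assigned DMR (the covered genes) appear.
    """
    hits = annotation.loc[annotation["gene_id"] != "", ["gene_id", "bin"]]
    merged = hits.merge(records[["bin", "p"]], on="bin", how="inner")
    if merged.empty:
        return pd.Series(dtype=float, name="p")
    agg = "min" if summary == "min" else "mean"
    return merged.groupby("gene_id")["p"].agg(agg).rename("p")


def rank_resampling_test(gene_p: pd.Series, target_set, n_draws: int = 10_000,
                         seed: int = 0) -> EnrichmentResult:
    """Wilcoxon rank-sum of the target genes' p-value ranks vs. random gene sets.

    The observed statistic is the rank-sum of the target set's p-values
    (average ranks for ties); the null resamples gene sets of identical
    size uniformly from the covered genes.  Smaller rank-sums mean the
    target genes rank higher (smaller p); the add-one empirical p counts
    draws at least as extreme toward enrichment.
    """
    target = [g for g in dict.fromkeys(target_set)]
    if len(target) > len(gene_p):
        raise DataError("target set larger than the covered-gene universe")
    missing = sorted(set(target) - set(gene_p.index))
    if missing:
        raise DataError(f"target genes without coverage: {missing}")
    if not target:
        return EnrichmentResult("rank_resampling", np.nan, np.nan, np.nan, 0, np.nan, 1.0,
                                untestable=True, note="empty target set")
    rng = np.random.default_rng(seed)
    ranks = pd.Series(stats.rankdata(gene_p.to_numpy()), index=gene_p.index)
    k = len(target)
    observed = float(ranks.loc[target].sum())
    draws = rng.random((n_draws, len(ranks))).argsort(axis=1)[:, :k]
    null = ranks.to_numpy()[draws].sum(axis=1)
    p = (1 + int((null <= observed).sum())) / (n_draws + 1)
    nm = float(null.mean())
    return EnrichmentResult("rank_resampling", observed=observed, null_mean=nm,
                            null_sd=float(null.std(ddof=1)) if n_draws > 1 else 0.0,
                            n_null=n_draws, fold=nm / observed if observed else np.inf, p=p)


def gwas_windows(gwas: pd.DataFrame, chrom_sizes: dict[str, int],
                 flank_bp: int = GWAS_FLANK_BP) -> pd.DataFrame:
    """SNP +- flank windows, clipped to chromosome bounds."""
    start = np.maximum(gwas["pos"] - flank_bp, 0)
    end = np.minimum(gwas["pos"] + flank_bp, gwas["chrom"].map(chrom_sizes))
    return pd.DataFrame({"locus_id": gwas["locus_id"], "chrom": gwas["chrom"],
                         "start": start.astype(int), "end": end.astype(int)})
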