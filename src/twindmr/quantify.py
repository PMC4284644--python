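"""Genome tiling, per-bin RPM quantification, and bin-level normalization.

MeDIP-seq methylation is quantified as fragment counts in overlapping
sliding-window bins (default 500 bp windows every 250 bp), scaled to reads
per million mapped fragments (RPM).  All coordinates are 0-based half-open
throughout; BED input/output maps onto this convention natively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import ConfigurationError, DataError

BIN_COLUMNS = ["chrom", "start", "end"]


@dataclass(frozen=True)
class BinScheme:
    """Sliding-window tiling scheme: ``bin_size`` bp windows every ``step`` bp."""

    bin_size: int = 500
    step: int = 250

    def __post_init__(self):
        if self.step <= 0 or self.bin_size < self.step:
            raise ConfigurationError(
                f"invalid bin scheme: need 0 < step <= bin_size, "
                f"got bin_size={self.bin_size}, step={self.step}"
            )


def bin_ids(bins: pd.DataFrame) -> pd.Index:
    """Canonical ``chrom:start-end`` identifiers for a bin table."""
    return pd.Index(
        bins["chrom"].astype(str)
        + ":"
        + bins["start"].astype(str)
        + "-"
        + bins["end"].astype(str),
        name="bin",
    )


@dataclass
class BinnedMethylome:
    """A bins x samples methylation signal matrix with genomic coordinates.

    ``signal_type`` records the scale of ``values``: raw ``RPM``, externally
    supplied ``AMS``, model-scale ``simulated`` draws from the generator, or
    ``normalized`` (per-bin mean 0, variance 1).
    """

    bins: pd.DataFrame
    samples: list[str]
    values: np.ndarray
    signal_type: str = "RPM"
    excluded_bins: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=BIN_COLUMNS))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.bins), len(self.samples)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.bins)} bins x {len(self.samples)} samples"
            )
        if self.signal_type not in {"RPM", "AMS", "normalized", "simulated"}:
            raise DataError(f"unknown signal_type {self.signal_type!r}")
        if self.signal_type == "RPM" and self.values.size and self.values.min() < 0:
            raise DataError("RPM values must be nonnegative")
        if self.signal_type == "normalized" and self.values.shape[0]:
            mu = self.values.mean(axis=1)
            if np.abs(mu).max() > 1e-8:
                raise DataError("normalized values must have per-bin mean 0")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def ids(self) -> pd.Index:
        return bin_ids(self.bins)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.samples)

    def subset_samples(self, keep: Sequence[str]) -> "BinnedMethylome":
        idx = [self.samples.index(s) for s in keep]
        return replace(self, samples=list(keep), values=self.values[:, idx])


def tile_genome(chrom_sizes: Mapping[str, int] | Sequence[tuple[str, int]],
                scheme: BinScheme = BinScheme()) -> pd.DataFrame:
    """Tile chromosomes into overlapping bins.

    Per chromosome of length L, windows start at 0, step, 2*step, ... while
    start < L; each window ends at min(start + bin_size, L).  Trailing
    windows shorter than ``step`` are dropped.  Output is sorted by input
    chromosome order, then start.
    """
    items = list(chrom_sizes.items()) if isinstance(chrom_sizes, Mapping) else list(chrom_sizes)
    rows = []
    for chrom, length in items:
        length = int(length)
        if length <= 0:
            raise DataError(f"chromosome {chrom!r} has non-positive length {length}")
        for start in range(0, length, scheme.step):
            end = min(start + scheme.bin_size, length)
            if end - start < scheme.step:
                continue
            rows.append((str(chrom), start, end))
    return pd.DataFrame(rows, columns=BIN_COLUMNS)


def _check_fragments(frags: pd.DataFrame, chrom_sizes: Mapping[str, int]) -> None:
    for _, rec in frags.iterrows():
        L = chrom_sizes.get(rec["chrom"])
        if L is None:
            raise DataError(f"fragment on unknown chromosome: {rec.to_dict()}")
        if rec["start"] < 0 or rec["end"] > L or rec["start"] >= rec["end"]:
            raise DataError(f"fragment outside chromosome bounds: {rec.to_dict()}")


def compute_rpm(fragments: Mapping[str, pd.DataFrame],
                bins: pd.DataFrame,
                totals: Mapping[str, int] | None = None,
                chrom_sizes: Mapping[str, int] | None = None) -> BinnedMethylome:
    """Count fragments per bin (>=1 bp overlap) and scale to per-million.

    ``fragments`` maps sample id -> BED-like frame (chrom/start/end).  A
    fragment overlapping several sliding windows counts once in each.
    ``totals`` gives the per-sample mapped-fragment totals used for the
    per-million scaling; by default the number of supplied fragments.
    """
    samples = list(fragments)
    trees: dict[str, IntervalTree] = {}
    for i, (_, b) in enumerate(bins.iterrows()):
        trees.setdefault(b["chrom"], IntervalTree()).addi(b["start"], b["end"], i)
    counts = np.zeros((len(bins), len(samples)))
    for j, s in enumerate(samples):
        frags = fragments[s]
        if chrom_sizes is not None:
            _check_fragments(frags, chrom_sizes)
        for chrom, start, end in frags[BIN_COLUMNS].itertuples(index=False):
            tree = trees.get(chrom)
            if tree is None:
                continue
            for iv in tree.overlap(start, end):
                counts[iv.data, j] += 1
    if totals is None:
        totals = {s: len(fragments[s]) for s in samples}
    tot = np.array([float(totals[s]) for s in samples])
    if (tot <= 0).any():
        bad = [s for s, t in zip(samples, tot) if t <= 0]
        raise DataError(f"non-positive mapped-fragment totals for samples: {bad}")
    return BinnedMethylome(bins.reset_index(drop=True), samples, counts / (tot / 1e6), "RPM")


def normalize_bins(methylome: BinnedMethylome, method: str = "zscore") -> BinnedMethylome:
    """Normalize each bin across samples to an N(0,1) scale.

    ``zscore`` centres and scales by the n-1 sample standard deviation;
    ``inverse_normal`` maps average ranks through the standard normal
    quantile function with the Blom offset (rank - 3/8) / (n + 1/4).
    Bins with zero variance are excluded and reported in ``excluded_bins``.
    """
    n = len(methylome.samples)
    if n < 3:
        raise DataError(f"normalization requires >=3 samples, got {n}")
    if method not in {"zscore", "inverse_normal"}:
        raise ConfigurationError(f"unknown normalization method {method!r}")
    X = methylome.values
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    Xk = X[keep]
    if method == "zscore":
        out = (Xk - Xk.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    else:
        ranks = np.apply_along_axis(stats.rankdata, 1, Xk)
        out = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
        out = (out - out.mean(axis=1, keepdims=True)) / out.std(axis=1, ddof=1, keepdims=True)
    return BinnedMethylome(
        methylome.bins.loc[keep].reset_index(drop=True),
        list(methylome.samples),
        out,
        "normalized",
        excluded_bins=methylome.bins.loc[~keep].reset_index(drop=True),
    )


def filter_bins(methylome: BinnedMethylome, min_nonzero_fraction: float = 0.0) -> BinnedMethylome:
    """Keep bins with signal > 0 in at least the given fraction of samples.

    The retained bin list defines the coverage universe used by the
    enrichment stage.
    """
    if not 0.0 <= min_nonzero_fraction <= 1.0:
        raise ConfigurationError("min_nonzero_fraction must be in [0, 1]")
    frac = (methylome.values > 0).mean(axis=1)
    keep = frac >= min_nonzero_fraction
    return replace(
        methylome,
        bins=methylome.bins.loc[keep].reset_index(drop=True),
        values=methylome.values[keep],
        excluded_bins=methylome.bins.loc[~keep].reset_index(drop=True),
    )


# ---------------------------------------------------------------- file I/O

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def read_bed3(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2], names=BIN_COLUMNS,
                     dtype={0: str, 1: int, 2: int})
    return df


def write_bed3(df: pd.DataFrame, path: str | Path) -> None:
    df[BIN_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def write_matrix(methylome: BinnedMethylome, path: str | Path) -> None:
    methylome.to_frame().to_csv(path, sep="\t", index_label="bin")


def read_matrix(path: str | Path, signal_type: str = "RPM") -> BinnedMethylome:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = df.index.str.extract(r"(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)")
    if ids.isna().any().any():
        raise DataError("matrix row names must be chrom:start-end bin identifiers")
    bins = pd.DataFrame({
        "chrom": ids["chrom"].values,
        "start": ids["start"].astype(int).values,
        "end": ids["end"].astype(int).values,
    })
    return BinnedMethylome(bins, [str(c) for c in df.columns], df.to_numpy(float), signal_type)
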