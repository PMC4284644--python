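"""Synthetic data generation with planted truth for every pipeline stage.

The generator emulates a discordant-MZ-twin methylation study: per-bin
methylation follows a family random-intercept model with case-control mean
shifts at planted DMR bins and covariate effects; monozygotic co-twins
share genotype, age, sex and the family intercept; SNPs act on methylation
in cis; metabolites couple to a planted DMR within twin pairs.  A
machine-readable :class:`PlantedTruth` records every planted effect so
downstream stages can be scored without external data.

Randomness is hierarchical: one root seed spawns a named child stream per
component (methylome, genotypes, annotations, fragments, metabolites), so
each stage is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .quantify import BinScheme, BinnedMethylome, tile_genome

_COMPONENTS = ("methylome", "genotypes", "annotations", "fragments", "metabolites", "mediation")

DEFAULT_COVARIATE_EFFECTS = {"age": 0.005, "sex": 0.05, "bmi": 0.01}
SCENARIOS = ("causal", "reactive", "independent", "null")


@dataclass
class SimulationConfig:
    """Study-design and effect-size knobs for the generator.

    Defaults follow the emulated twin study: 17 T2D-discordant, 3
    concordant-case and 7 concordant-control MZ pairs in discovery, with 42
    unrelated cases and 221 matched controls for replication; 503 measured
    metabolites.  Effect sizes are on the normalized-methylation scale.
    """

    n_discordant_pairs: int = 17
    n_concordant_case_pairs: int = 3
    n_concordant_control_pairs: int = 7
    n_unrelated_cases: int = 42
    n_unrelated_controls: int = 221
    n_bins: int = 2000
    toy_genome: tuple = (("chr1", 10_000_000), ("chr2", 10_000_000))
    n_planted_dmrs: int = 100
    dmr_effect: float = 0.8
    sigma_family_sq: float = 1.0
    sigma_resid_sq: float = 1.0
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    n_snps: int = 60
    maf_range: tuple = (0.05, 0.5)
    cis_effect: float = 0.5
    mediation_scenario: str = "causal"
    n_metabolites: int = 503
    metabolite_coupling: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_discordant_pairs", "n_concordant_case_pairs",
                     "n_concordant_control_pairs", "n_unrelated_cases",
                     "n_unrelated_controls", "n_bins", "n_planted_dmrs",
                     "n_snps", "n_metabolites"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n_planted_dmrs > self.n_bins:
            raise ConfigurationError("n_planted_dmrs exceeds n_bins")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range bounds must lie in (0, 0.5], got {self.maf_range}")
        if self.sigma_family_sq < 0 or self.sigma_resid_sq <= 0:
            raise ConfigurationError(
                "sigma_family_sq must be >= 0 and sigma_resid_sq > 0, got "
                f"sigma_family_sq={self.sigma_family_sq}, sigma_resid_sq={self.sigma_resid_sq}")
        if self.mediation_scenario not in SCENARIOS:
            raise ConfigurationError(
                f"mediation_scenario must be one of {SCENARIOS}, got {self.mediation_scenario!r}")
        for chrom, length in self.toy_genome:
            if length <= 0:
                raise ConfigurationError(f"toy_genome chromosome {chrom!r} has length {length}")

    def rng(self, component: str) -> np.random.Generator:
        """Child random stream for one named generator component."""
        if component not in _COMPONENTS:
            raise ConfigurationError(f"unknown RNG component {component!r}")
        root = np.random.SeedSequence(self.seed)
        children = root.spawn(len(_COMPONENTS))
        return np.random.default_rng(children[_COMPONENTS.index(component)])

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: int(l) for c, l in self.toy_genome}


@dataclass
class PlantedTruth:
    """Record of everything the generator planted."""

    dmr_bin_indices: list[int] = field(default_factory=list)
    dmr_effect: float = 0.0
    mqtl_assignments: list[tuple[int, int, float]] = field(default_factory=list)
    mediation_scenario: str = "null"
    coupled_metabolite_indices: list[int] = field(default_factory=list)
    anchor_bin_index: int | None = None
    seed: int = 0

    def validate(self, n_bins: int, n_snps: int | None = None,
                 n_metabolites: int | None = None) -> None:
        if any(not 0 <= b < n_bins for b in self.dmr_bin_indices):
            raise DataError("planted DMR index outside the bin matrix")
        if n_snps is not None and any(
                not (0 <= s < n_snps and 0 <= b < n_bins) for s, b, _ in self.mqtl_assignments):
            raise DataError("planted mQTL index outside the generated matrices")
        if n_metabolites is not None and any(
                not 0 <= m < n_metabolites for m in self.coupled_metabolite_indices):
            raise DataError("coupled metabolite index outside the metabolite matrix")

    def save(self, path: str | Path) -> None:
        lines = [
            f"seed={self.seed}",
            f"dmr_effect={self.dmr_effect!r}",
            "dmr_bin_indices=" + ",".join(map(str, self.dmr_bin_indices)),
            "mqtl_assignments=" + ";".join(f"{s},{b},{e!r}" for s, b, e in self.mqtl_assignments),
            f"mediation_scenario={self.mediation_scenario}",
            "coupled_metabolite_indices=" + ",".join(map(str, self.coupled_metabolite_indices)),
            f"anchor_bin_index={self.anchor_bin_index}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PlantedTruth":
        kv = dict(line.split("=", 1) for line in Path(path).read_text().splitlines() if line)
        anchor = kv.get("anchor_bin_index", "None")
        return cls(
            dmr_bin_indices=[int(x) for x in kv["dmr_bin_indices"].split(",") if x],
            dmr_effect=float(kv["dmr_effect"]),
            mqtl_assignments=[
                (int(a), int(b), float(c))
                for a, b, c in (t.split(",") for t in kv["mqtl_assignments"].split(";") if t)],
            mediation_scenario=kv["mediation_scenario"],
            coupled_metabolite_indices=[
                int(x) for x in kv["coupled_metabolite_indices"].split(",") if x],
            anchor_bin_index=None if anchor == "None" else int(anchor),
            seed=int(kv["seed"]),
        )


def _select_bins(config: SimulationConfig) -> pd.DataFrame:
    tiles = tile_genome(config.chrom_sizes, BinScheme())
    if len(tiles) < config.n_bins:
        raise ConfigurationError(
            f"toy_genome yields only {len(tiles)} bins; n_bins={config.n_bins} requested")
    idx = np.unique(np.linspace(0, len(tiles) - 1, config.n_bins).round().astype(int))
    if len(idx) < config.n_bins:  # spacing collapsed duplicates; fall back to a prefix
        idx = np.arange(config.n_bins)
    return tiles.iloc[idx].reset_index(drop=True)


def _sample_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []

    def pair(prefix, k, case_a, case_b, pair_type):
        fid = f"{prefix}{k:03d}"
        age = rng.uniform(40, 80)
        sex = int(rng.random() < 0.5)
        shared = rng.normal()
        for tag, is_case in (("a", case_a), ("b", case_b)):
            bmi = 27.0 + 4.0 * (np.sqrt(0.5) * shared + np.sqrt(0.5) * rng.normal())
            rows.append(dict(sample_id=f"{fid}{tag}", family_id=fid, is_case=int(is_case),
                             age=age, sex=sex, bmi=bmi, pair_type=pair_type,
                             cohort="discovery"))

    for k in range(config.n_discordant_pairs):
        pair("D", k, 1, 0, "discordant")
    for k in range(config.n_concordant_case_pairs):
        pair("C", k, 1, 1, "concordant_case")
    for k in range(config.n_concordant_control_pairs):
        pair("H", k, 0, 0, "concordant_control")

    def unrelated(prefix, k, is_case):
        fid = f"{prefix}{k:03d}"
        rows.append(dict(sample_id=fid, family_id=fid, is_case=is_case,
                         age=rng.uniform(40, 80), sex=int(rng.random() < 0.5),
                         bmi=27.0 + 4.0 * rng.normal(), pair_type="unrelated",
                         cohort="replication"))

    for k in range(config.n_unrelated_cases):
        unrelated("RC", k, 1)
    for k in range(config.n_unrelated_controls):
        unrelated("RU", k, 0)

    df = pd.DataFrame(rows)
    n = len(df)
    df["medication"] = np.where(df["is_case"].astype(bool), (rng.random(n) < 0.5).astype(int), 0)
    df["smoking"] = (rng.random(n) < 0.2).astype(int)
    for cell, mu, sd in (("neutrophils", 4.0, 1.0), ("eosinophils", 0.2, 0.08),
                         ("monocytes", 0.5, 0.15), ("lymphocytes", 2.0, 0.5)):
        df[cell] = np.clip(rng.normal(mu, sd, n), 0.01, None)
    df["total_wbc"] = df[["neutrophils", "eosinophils", "monocytes", "lymphocytes"]].sum(axis=1)
    return df


def simulate_twin_methylome(config: SimulationConfig,
                            shared_env_effect: float = 0.0,
                            ) -> tuple[BinnedMethylome, pd.DataFrame, PlantedTruth]:
    """Generate the binned methylome, sample table, and planted truth.

    Per bin b and sample j in family i,

        y = mu_b + beta_b * case_j + sum_c gamma_c * cov_cj + u_i + e_ij,

    with u_i ~ N(0, sigma_family_sq) shared by co-twins and beta_b equal to
    ``dmr_effect`` at planted bins, 0 elsewhere.  ``shared_env_effect``
    optionally adds a pair-level shift at planted bins to every member of a
    case-containing family — a pair-shared exposure that a within-pair
    (giDMR) analysis cancels by construction.
    """
    rng = config.rng("methylome")
    bins = _select_bins(config)
    samples = _sample_table(config, rng)
    n = len(samples)
    m = len(bins)
    planted = np.sort(rng.choice(m, size=config.n_planted_dmrs, replace=False))
    beta = np.zeros(m)
    beta[planted] = config.dmr_effect

    fam_codes, fam_idx = np.unique(samples["family_id"], return_inverse=True)
    # bin-specific family intercepts: bins are independent given the design
    u = rng.normal(0.0, np.sqrt(config.sigma_family_sq), (m, len(fam_codes)))[:, fam_idx]
    mu = rng.normal(0.0, 1.0, m)
    case = samples["is_case"].to_numpy(float)
    covs = sum((g * samples[c].to_numpy(float)
                for c, g in config.covariate_effects.items()), np.zeros(n))
    e = rng.normal(0.0, np.sqrt(config.sigma_resid_sq), (m, n))
    Y = mu[:, None] + beta[:, None] * case[None, :] + covs[None, :] + u + e
    if shared_env_effect:
        # exposure shared within family, present in every case-containing
        # family: both co-twins of discordant/concordant-case pairs and
        # unrelated cases.  Within-pair differencing cancels it exactly.
        fam_has_case = samples.groupby("family_id")["is_case"].transform("max").to_numpy(float)
        Y[planted] += shared_env_effect * fam_has_case[None, :]
    methylome = BinnedMethylome(bins, samples["sample_id"].tolist(), Y, "simulated")
    truth = PlantedTruth(dmr_bin_indices=planted.tolist(), dmr_effect=config.dmr_effect,
                         mediation_scenario=config.mediation_scenario, seed=config.seed)
    truth.validate(m)
    return methylome, samples, truth


@dataclass
class GenotypeMatrix:
    """SNP dosage matrix (SNPs x samples, additive 0-2 coding)."""

    snps: pd.DataFrame  # snp_id, chrom, pos, maf
    samples: list[str]
    dosage: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.snps), len(self.samples)):
            raise DataError("dosage matrix shape does not match snps x samples")
        if self.dosage.size and (self.dosage.min() < 0 or self.dosage.max() > 2):
            raise DataError("dosages must lie in [0, 2]")
        if self.dosage.size:
            emp = self.dosage.mean(axis=1) / 2.0
            self.snps = self.snps.assign(empirical_maf=np.minimum(emp, 1 - emp))
        else:
            self.snps = self.snps.assign(empirical_maf=np.nan)


def simulate_genotypes(config: SimulationConfig, methylome: BinnedMethylome,
                       samples: pd.DataFrame, truth: PlantedTruth,
                       ) -> tuple[GenotypeMatrix, PlantedTruth]:
    """Draw SNP dosages and plant additive cis effects on methylation.

    Dosages are binomial(2, MAF) per family — monozygotic co-twins share
    dosages exactly.  Up to half of the SNPs are assigned one planted DMR
    bin each and placed within the cis window of that bin; the assigned
    bin's methylation receives ``cis_effect`` per alternate allele (the
    methylome is updated in place).  Assignments are appended to the truth.
    """
    rng = config.rng("genotypes")
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, config.n_snps)
    fam_codes, fam_idx = np.unique(samples["family_id"], return_inverse=True)
    dos = rng.binomial(2, maf[:, None], (config.n_snps, len(fam_codes))).astype(float)
    dosage = dos[:, fam_idx]

    chroms = list(config.chrom_sizes)
    lengths = np.array([config.chrom_sizes[c] for c in chroms], float)
    pos = np.empty(config.n_snps, int)
    chrom = np.empty(config.n_snps, object)
    n_mqtl = min(len(truth.dmr_bin_indices), config.n_snps // 2)
    assigned_bins = list(truth.dmr_bin_indices[:n_mqtl])
    for i in range(config.n_snps):
        if i < n_mqtl:
            b = methylome.bins.iloc[assigned_bins[i]]
            chrom[i] = b["chrom"]
            lo_p = max(0, int(b["start"]) - 40_000)
            hi_p = min(config.chrom_sizes[b["chrom"]], int(b["end"]) + 40_000)
            pos[i] = rng.integers(lo_p, hi_p)
        else:
            ci = rng.choice(len(chroms), p=lengths / lengths.sum())
            chrom[i] = chroms[ci]
            pos[i] = rng.integers(0, int(lengths[ci]))

    for i, b in enumerate(assigned_bins):
        methylome.values[b] += config.cis_effect * dosage[i]
        truth.mqtl_assignments.append((i, int(b), config.cis_effect))

    snps = pd.DataFrame({
        "snp_id": [f"snp{i:04d}" for i in range(config.n_snps)],
        "chrom": chrom.astype(str) if config.n_snps else chrom,
        "pos": pos,
        "maf": maf,
    })
    geno = GenotypeMatrix(snps, list(methylome.samples), dosage)
    truth.validate(methylome.n_bins, config.n_snps)
    return geno, truth


def simulate_annotations(config: SimulationConfig, methylome: BinnedMethylome,
                         truth: PlantedTruth, enrichment_fraction: float = 0.5,
                         n_genes: int = 500, n_gwas_loci: int = 65,
                         n_imprinted: int = 50,
                         ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Place genes, GWAS loci and an imprinted-gene list on the toy genome.

    ``enrichment_fraction`` of GWAS loci are centred on planted DMR bins
    (planting genuine enrichment); the rest, and all genes, are placed
    uniformly.  The imprinted list mixes genes near planted bins with
    random genes in the same proportion.
    """
    if not 0.0 <= enrichment_fraction <= 1.0:
        raise ConfigurationError("enrichment_fraction must be in [0, 1]")
    rng = config.rng("annotations")
    chroms = list(config.chrom_sizes)
    lengths = np.array([config.chrom_sizes[c] for c in chroms], float)

    rows = []
    for g in range(n_genes):
        ci = rng.choice(len(chroms), p=lengths / lengths.sum())
        L = int(lengths[ci])
        size = int(rng.integers(5_000, 100_000))
        if size >= L:
            raise DataError(f"gene of size {size} exceeds chromosome {chroms[ci]} ({L} bp)")
        start = int(rng.integers(0, L - size))
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else start + size - 1
        rows.append(dict(gene_id=f"G{g:04d}", chrom=chroms[ci], strand=strand,
                         tss=tss, start=start, end=start + size))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "start", "end"])

    loci = []
    planted = truth.dmr_bin_indices
    for k in range(n_gwas_loci):
        if planted and rng.random() < enrichment_fraction:
            b = methylome.bins.iloc[planted[int(rng.integers(0, len(planted)))]]
            loci.append(dict(locus_id=f"L{k:03d}", chrom=b["chrom"],
                             pos=int((b["start"] + b["end"]) // 2)))
        else:
            ci = rng.choice(len(chroms), p=lengths / lengths.sum())
            loci.append(dict(locus_id=f"L{k:03d}", chrom=chroms[ci],
                             pos=int(rng.integers(0, int(lengths[ci])))))
    gwas = pd.DataFrame(loci, columns=["locus_id", "chrom", "pos"])

    imprinted: list[str] = []
    if n_genes and n_imprinted:
        near: set[str] = set()
        if planted:
            pb = methylome.bins.iloc[planted]
            for _, g in genes.iterrows():
                hit = ((pb["chrom"] == g["chrom"]) & (pb["start"] < g["end"])
                       & (pb["end"] > g["start"])).any()
                if hit:
                    near.add(g["gene_id"])
        n_near = int(round(enrichment_fraction * n_imprinted))
        near_list = sorted(near)
        picked = list(rng.choice(near_list, size=min(n_near, len(near_list)), replace=False))
        rest = [g for g in genes["gene_id"] if g not in set(picked)]
        picked += list(rng.choice(rest, size=n_imprinted - len(picked), replace=False))
        imprinted = sorted(picked)
    return genes, gwas, imprinted


def simulate_fragments(config: SimulationConfig, bins: pd.DataFrame,
                       rates: np.ndarray, sample_ids: Sequence[str],
                       fragment_length: int = 200,
                       ) -> tuple[dict[str, pd.DataFrame], dict[str, int]]:
    """Draw sequencing-fragment intervals with Poisson counts per bin.

    ``rates`` is a per-bin expected-count vector (shared by all samples) or
    a bins x samples matrix.  Fragment starts are uniform within the bin
    and ends are clipped to the chromosome.
    """
    rng = config.rng("fragments")
    rates = np.asarray(rates, float)
    if (rates < 0).any():
        raise ConfigurationError("fragment rates must be nonnegative")
    if rates.ndim == 1:
        rates = np.tile(rates[:, None], (1, len(sample_ids)))
    if rates.shape != (len(bins), len(sample_ids)):
        raise ConfigurationError("rates must be per-bin or bins x samples")
    sizes = config.chrom_sizes
    out: dict[str, pd.DataFrame] = {}
    for j, s in enumerate(sample_ids):
        counts = rng.poisson(rates[:, j])
        recs = []
        for b, c in zip(bins.itertuples(index=False), counts):
            if c == 0:
                continue
            starts = rng.integers(b.start, b.end, size=c)
            ends = np.minimum(starts + fragment_length, sizes[b.chrom])
            recs.append(pd.DataFrame({"chrom": b.chrom, "start": starts, "end": ends}))
        out[s] = (pd.concat(recs, ignore_index=True) if recs
                  else pd.DataFrame(columns=["chrom", "start", "end"]))
    return out, dict(sizes)


def simulate_metabolites(config: SimulationConfig, methylome: BinnedMethylome,
                         samples: pd.DataFrame, truth: PlantedTruth,
                         n_coupled: int = 7, n_days: int = 5,
                         ) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a metabolite matrix coupled to the top planted DMR.

    ``n_coupled`` metabolites follow baseline + coupling * anchor-bin
    methylation + noise; the rest are pure noise.  Run days are assigned
    round-robin and a multiplicative per-day scale is applied so run-day
    median normalization has real work to do.
    """
    rng = config.rng("metabolites")
    n = len(samples)
    k = config.n_metabolites
    if k == 0:
        return (pd.DataFrame(index=pd.Index([], name="metabolite"),
                             columns=samples["sample_id"]),
                pd.Series(1 + np.arange(n) % n_days, index=samples["sample_id"], name="run_day"))
    if config.metabolite_coupling != 0 and not truth.dmr_bin_indices:
        raise ConfigurationError("metabolite coupling requested but no planted DMRs")
    coupled = sorted(rng.choice(k, size=min(n_coupled, k), replace=False).tolist()) \
        if config.metabolite_coupling != 0 else []
    anchor = truth.dmr_bin_indices[0] if truth.dmr_bin_indices else None
    anchor_vals = methylome.values[anchor] if anchor is not None else np.zeros(n)
    V = 10.0 + rng.normal(0.0, 1.0, (k, n))
    for ci in coupled:
        V[ci] += config.metabolite_coupling * anchor_vals
    day = 1 + np.arange(n) % n_days
    scale = rng.lognormal(0.0, 0.3, n_days)
    V = V * scale[day - 1][None, :]
    truth.coupled_metabolite_indices = list(coupled)
    truth.anchor_bin_index = None if anchor is None else int(anchor)
    truth.validate(methylome.n_bins, None, k)
    mat = pd.DataFrame(V, index=pd.Index([f"met{i:04d}" for i in range(k)], name="metabolite"),
                       columns=samples["sample_id"])
    return mat, pd.Series(day, index=samples["sample_id"], name="run_day")


def simulate_mediation_triple(scenario: str, n_samples: int, rng: np.random.Generator,
                              maf: float = 0.3, locus_effect: float = 1.0,
                              mediator_effect: float = 1.0, direct_effect: float = 1.0,
                              reactive_effect: float = 1.0) -> dict[str, np.ndarray]:
    """One (locus L, mediator M, binary trait T) triple under a wiring scenario.

    causal:      L -> M -> T (no direct edge)
    reactive:    L -> T -> M
    independent: L -> M and L -> T via separate paths
    null:        no edges from L
    The binary trait is thresholded at the median of a Gaussian liability,
    fixing prevalence at one half.
    """
    if scenario not in SCENARIOS:
        raise ConfigurationError(f"unknown mediation scenario {scenario!r}")
    L = rng.binomial(2, maf, n_samples).astype(float)
    eM = rng.normal(0.0, 1.0, n_samples)
    eT = rng.normal(0.0, 1.0, n_samples)
    if scenario == "causal":
        M = locus_effect * L + eM
        liability = mediator_effect * M + eT
        T = (liability > np.median(liability)).astype(float)
    elif scenario == "reactive":
        liability = direct_effect * L + eT
        T = (liability > np.median(liability)).astype(float)
        M = reactive_effect * T + eM
    elif scenario == "independent":
        M = locus_effect * L + eM
        liability = direct_effect * L + eT
        T = (liability > np.median(liability)).astype(float)
    else:
        M = eM
        T = (eT > np.median(eT)).astype(float)
    age = rng.uniform(40, 80, n_samples)
    sex = (rng.random(n_samples) < 0.5).astype(float)
    return {"L": L, "M": M, "T": T, "age": age, "sex": sex}


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def write_gene_table(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def write_dosage_matrix(geno: GenotypeMatrix, path: str | Path) -> None:
    df = pd.concat(
        [geno.snps[["snp_id", "chrom", "pos", "maf"]].reset_index(drop=True),
         pd.DataFrame(geno.dosage, columns=geno.samples)], axis=1)
    df.to_csv(path, sep="\t", index=False)
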