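import numpy as np
import pandas as pd
import pytest

from twindmr.quantify import BinnedMethylome
from twindmr.simulate import SimulationConfig, simulate_twin_methylome


def small_sim_config(**kw) -> SimulationConfig:
    """A fast generator configuration for unit tests (twins only by default)."""
    defaults = dict(seed=0, n_bins=60, n_planted_dmrs=6, n_snps=10,
                    n_metabolites=20, n_unrelated_cases=0, n_unrelated_controls=0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture
def twin_sim():
    cfg = small_sim_config()
    methylome, samples, truth = simulate_twin_methylome(cfg)
    return cfg, methylome, samples, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def toy_methylome(values: np.ndarray, signal_type: str = "simulated",
                  samples: list[str] | None = None) -> BinnedMethylome:
    """Wrap a plain matrix in a methylome with consecutive 500-bp bins."""
    m, n = values.shape
    bins = pd.DataFrame({"chrom": "chr1",
                         "start": np.arange(m) * 500,
                         "end": np.arange(m) * 500 + 500})
    names = samples if samples is not None else [f"s{j}" for j in range(n)]
    return BinnedMethylome(bins, list(names), values, signal_type)


def toy_samples(n_pairs: int, n_discordant: int | None = None) -> pd.DataFrame:
    """Minimal sample table: first ``n_discordant`` pairs discordant, rest control."""
    if n_discordant is None:
        n_discordant = n_pairs
    rows = []
    rng = np.random.default_rng(7)
    for k in range(n_pairs):
        age = rng.uniform(40, 80)
        sex = int(rng.random() < 0.5)
        for tag, case in (("a", 1 if k < n_discordant else 0), ("b", 0)):
            rows.append(dict(sample_id=f"P{k:02d}{tag}", family_id=f"P{k:02d}",
                             is_case=case, age=age, sex=sex,
                             bmi=27 + 4 * rng.normal(),
                             pair_type="discordant" if k < n_discordant else
                             "concordant_control"))
    df = pd.DataFrame(rows)
    df["sample_id"] = df["sample_id"].astype(str)
    return df
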