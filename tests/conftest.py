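import numpy as np
import pandas as pd
import pytest

from liabilityscan import (MarkerPanel, PedigreeTable, SimulationConfig,
                           simulate_genotypes, simulate_pedigree,
                           simulate_phenotypes)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_founder_sires=20, n_generations=2, daughters_per_sire=5,
        n_herds=8, n_year_seasons=3, n_chromosomes=3,
        markers_per_chromosome=20, n_qtl=10, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    ped = simulate_pedigree(small_config)
    panel = simulate_genotypes(ped, small_config)
    phen, truth = simulate_phenotypes(ped, panel, small_config)
    return ped, panel, phen, truth


def random_pedigree(n_founders: int, n_offspring: int, seed: int) -> PedigreeTable:
    """Random mating pedigree: offspring pick any earlier male/female."""
    rng = np.random.default_rng(seed)
    rows = []
    sexes = []
    for i in range(n_founders):
        sex = "M" if i % 2 == 0 else "F"
        rows.append((f"A{i}", "0", "0", sex, 0))
        sexes.append(sex)
    for i in range(n_founders, n_founders + n_offspring):
        males = [j for j in range(i) if sexes[j] == "M"]
        females = [j for j in range(i) if sexes[j] == "F"]
        s = rows[rng.choice(males)][0]
        d = rows[rng.choice(females)][0]
        sex = "M" if rng.random() < 0.5 else "F"
        rows.append((f"A{i}", s, d, sex, 1))
        sexes.append(sex)
    return PedigreeTable(pd.DataFrame(
        rows, columns=["animal", "sire", "dam", "sex", "generation"]))


def panel_from_genotypes(geno, chrom=None, bp=None) -> MarkerPanel:
    """Wrap a raw genotype array in a MarkerPanel with a simple map."""
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom)
    bp = (np.arange(m) * 1000 + 1) if bp is None else np.asarray(bp)
    mm = pd.DataFrame({"marker": [f"m{j}" for j in range(m)],
                       "chrom": chrom, "bp": bp})
    return MarkerPanel(ids=np.array([f"I{i}" for i in range(n)]),
                       genotypes=geno, marker_map=mm)
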