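"""Synthetic pedigree / genotype / phenotype generator.

Emulates the data structure of a national dairy-cattle disease evaluation:
a multi-generation pedigree of AI sires, each with a group of recorded
daughters out of unrelated founder dams; a dense biallelic SNP panel in
linkage on autosomes; and a binary outcome generated from a Gaussian
liability with a fixed threshold.

The liability for daughter *i* of sire *s(i)* is

    lambda_i = ys_{j(i)} + h_{k(i)} + 0.5 * a_{s(i)} + e_i

with year-season effects ys ~ N(0, sigma2_ys), herd-year effects
h ~ N(0, sigma2_h), sire breeding values a with Var(a) = 4 * sigma2_s
(so the transmitted sire effect 0.5*a has variance sigma2_s), and
residual e ~ N(0, sigma2_e).  The binary outcome is y_i = 1 iff
lambda_i > t, where t is the (1 - incidence) quantile of the *analytic*
marginal liability distribution — incidence is a parameter of the
generator, never an artifact of the realized sample.

Breeding values are the sum of a QTL part (marker genotypes times additive
allele-substitution effects, scaled so its expected Hardy-Weinberg variance
is qtl_variance_fraction * 4 * sigma2_s) and an independent polygenic
remainder carrying the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from scipy.stats import norm

__all__ = [
    "MISSING",
    "SimulationConfig",
    "PedigreeTable",
    "MarkerPanel",
    "TrueGeneticModel",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_founder_genotypes",
]

#: sentinel for a missing genotype in the 0/1/2 coding
MISSING = np.int8(-1)

#: reserved null-parent identifier
UNKNOWN_PARENT = "0"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Variance defaults are on the liability scale: sire variance 0.037,
    herd-year variance 0.496, residual fixed at 1, disease incidence
    10.91% — the structure the analysis model assumes.
    """

    n_founder_sires: int = 150
    n_generations: int = 2
    daughters_per_sire: int = 10
    n_herds: int = 30
    n_year_seasons: int = 4
    n_chromosomes: int = 29
    markers_per_chromosome: int = 100
    n_qtl: int = 100
    founder_maf_low: float = 0.05
    founder_maf_high: float = 0.5
    morgans_per_chromosome: float = 1.0
    sigma2_s: float = 0.037
    sigma2_h: float = 0.496
    sigma2_e: float = 1.0
    sigma2_ys: float = 0.1
    qtl_variance_fraction: float = 0.3
    dropout_rate: float = 0.0     # uniform missing-call rate, exercises QC
    incidence: float = 0.1091
    seed: int = 2024

    def __post_init__(self) -> None:
        for name in (
            "n_founder_sires",
            "n_generations",
            "daughters_per_sire",
            "n_herds",
            "n_year_seasons",
            "n_chromosomes",
            "markers_per_chromosome",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not (0.0 < self.founder_maf_low <= self.founder_maf_high <= 0.5):
            raise ValueError(
                "need 0 < founder_maf_low <= founder_maf_high <= 0.5, got "
                f"({self.founder_maf_low}, {self.founder_maf_high})"
            )
        if not (0.0 < self.incidence < 1.0):
            raise ValueError(f"incidence must be in (0, 1), got {self.incidence}")
        if self.n_qtl < 0:
            raise ValueError("n_qtl must be >= 0")
        if not (0.0 <= self.qtl_variance_fraction <= 1.0):
            raise ValueError("qtl_variance_fraction must be in [0, 1]")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        for name in ("sigma2_s", "sigma2_h", "sigma2_e", "sigma2_ys"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with selected fields replaced."""
        return replace(self, **kwargs)


@dataclass
class PedigreeTable:
    """Ordered pedigree records; parents always precede offspring.

    ``records`` has columns animal, sire, dam, sex ('M'/'F'), generation.
    Unknown parents carry the reserved ID '0'.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"animal", "sire", "dam", "sex", "generation"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"pedigree missing columns: {sorted(missing)}")
        ids = self.records["animal"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate animal IDs in pedigree: {dups[:5]}")
        self._index = {a: i for i, a in enumerate(ids)}
        # topological check: every known parent must already be indexed
        for col in ("sire", "dam"):
            parents = self.records[col].to_numpy()
            for i, p in enumerate(parents):
                if p != UNKNOWN_PARENT and self._index.get(p, len(ids)) >= i:
                    raise ValueError(
                        f"pedigree not topologically ordered: {col} {p!r} of "
                        f"{ids.iloc[i]!r} does not precede it"
                    )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def animals(self) -> np.ndarray:
        return self.records["animal"].to_numpy()

    def index_of(self, animal_id: str) -> int:
        return self._index[animal_id]

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Positional sire/dam indices; -1 for unknown parents."""
        out = []
        for col in ("sire", "dam"):
            idx = np.array(
                [self._index.get(p, -1) if p != UNKNOWN_PARENT else -1
                 for p in self.records[col]],
                dtype=np.int64,
            )
            out.append(idx)
        return out[0], out[1]

    def subset_with_ancestors(self, animal_ids) -> "PedigreeTable":
        """Restrict to the given animals plus all their ancestors."""
        keep = set(animal_ids)
        recs = self.records
        sires = recs["sire"].to_numpy()
        dams = recs["dam"].to_numpy()
        ids = recs["animal"].to_numpy()
        for i in range(len(recs) - 1, -1, -1):
            if ids[i] in keep:
                if sires[i] != UNKNOWN_PARENT:
                    keep.add(sires[i])
                if dams[i] != UNKNOWN_PARENT:
                    keep.add(dams[i])
        mask = np.fromiter((a in keep for a in ids), dtype=bool, count=len(ids))
        return PedigreeTable(recs.loc[mask].reset_index(drop=True))


@dataclass
class MarkerPanel:
    """Genotype matrix (individuals x markers, coded 0/1/2, -1 missing)
    with a physical marker map and allele frequencies of the counted allele."""

    ids: np.ndarray                 # individual IDs, aligned with genotype rows
    genotypes: np.ndarray           # int8, n x m
    marker_map: pd.DataFrame        # columns: marker, chrom, bp
    allele_freqs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        n, m = self.genotypes.shape
        if len(self.ids) != n:
            raise ValueError("ID list does not match genotype rows")
        if len(self.marker_map) != m:
            raise ValueError("marker map does not match genotype columns")
        if self.allele_freqs is None:
            self.allele_freqs = self.compute_allele_freqs()

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def compute_allele_freqs(self) -> np.ndarray:
        """Frequency of the allele counted as 2, ignoring missing calls."""
        g = self.genotypes
        obs = g != MISSING
        with np.errstate(invalid="ignore"):
            p = np.where(obs, g, 0).sum(axis=0) / (2.0 * obs.sum(axis=0))
        return p

    def subset_individuals(self, keep_ids) -> "MarkerPanel":
        keep = set(keep_ids)
        mask = np.fromiter((i in keep for i in self.ids), dtype=bool,
                           count=len(self.ids))
        return MarkerPanel(
            ids=self.ids[mask],
            genotypes=self.genotypes[mask],
            marker_map=self.marker_map.copy(),
            allele_freqs=None,
        )

    def subset_markers(self, mask: np.ndarray) -> "MarkerPanel":
        return MarkerPanel(
            ids=self.ids.copy(),
            genotypes=self.genotypes[:, mask],
            marker_map=self.marker_map.loc[mask].reset_index(drop=True),
            allele_freqs=None,
        )


@dataclass
class TrueGeneticModel:
    """Ground truth for parameter-recovery tests."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    true_breeding_values: pd.Series   # indexed by animal ID
    liability_threshold: float


def _marker_map(config: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced markers, 1-based bp, chromosomes 1..n."""
    chroms = np.repeat(np.arange(1, config.n_chromosomes + 1),
                       config.markers_per_chromosome)
    spacing = 100_000
    bp = np.tile(np.arange(config.markers_per_chromosome) * spacing + 1,
                 config.n_chromosomes)
    names = [f"M{c}_{i + 1}" for c, i in
             zip(chroms, np.tile(np.arange(config.markers_per_chromosome),
                                 config.n_chromosomes))]
    return pd.DataFrame({"marker": names, "chrom": chroms, "bp": bp})


def simulate_pedigree(config: SimulationConfig) -> PedigreeTable:
    """Build a sire-line pedigree.

    Generation 0 holds the founder sires (unknown parents).  Each of
    ``n_generations`` daughter generations gives every active sire
    ``daughters_per_sire`` daughters, each out of a unique founder dam.
    After each generation but the last, every sire line is continued by one
    son (sire x new founder dam) who becomes the active sire of the next
    generation.
    """
    rows: list[tuple[str, str, str, str, int]] = []
    active = [f"S{g}_{i}" for g, i in
              zip([0] * config.n_founder_sires, range(config.n_founder_sires))]
    for s in active:
        rows.append((s, UNKNOWN_PARENT, UNKNOWN_PARENT, "M", 0))
    dam_counter = 0
    for gen in range(1, config.n_generations + 1):
        # daughters with records
        for s in active:
            for _ in range(config.daughters_per_sire):
                dam = f"F{dam_counter}"
                dam_counter += 1
                rows.append((dam, UNKNOWN_PARENT, UNKNOWN_PARENT, "F", 0))
                rows.append((f"D{gen}_{len(rows)}", s, dam, "F", gen))
        if gen < config.n_generations:
            new_active = []
            for j, s in enumerate(active):
                dam = f"F{dam_counter}"
                dam_counter += 1
                rows.append((dam, UNKNOWN_PARENT, UNKNOWN_PARENT, "F", 0))
                son = f"S{gen}_{j}"
                rows.append((son, s, dam, "M", gen))
                new_active.append(son)
            active = new_active
    records = pd.DataFrame(rows,
                           columns=["animal", "sire", "dam", "sex", "generation"])
    return PedigreeTable(records)


def simulate_founder_genotypes(n: int, freqs: np.ndarray,
                               rng: np.random.Generator) -> np.ndarray:
    """Hardy-Weinberg founder genotypes: two independent binomial alleles."""
    m = len(freqs)
    h1 = rng.random((n, m)) < freqs
    h2 = rng.random((n, m)) < freqs
    return (h1.astype(np.int8) + h2.astype(np.int8))


def _interval_recomb_fractions(config: SimulationConfig) -> np.ndarray:
    """Haldane recombination fraction between adjacent markers on the same
    chromosome; 0.5 across chromosome boundaries (independent assortment).
    Length n_markers; entry j applies to the interval (j-1, j); entry 0 is
    unused (the first marker's source haplotype is a fair coin)."""
    m = config.n_markers
    per_chrom = config.markers_per_chromosome
    d = config.morgans_per_chromosome / max(per_chrom - 1, 1)
    r = np.full(m, 0.5 * (1.0 - np.exp(-2.0 * d)))
    r[::per_chrom] = 0.5  # chromosome starts: independent
    return r


def _meioses(haps: tuple[np.ndarray, np.ndarray], parent_idx: np.ndarray,
             r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per entry of parent_idx, vectorized.

    The source-haplotype indicator follows a two-state Markov chain along
    the marker order: it starts at a fair coin and switches between
    adjacent markers with the interval's recombination fraction.  Under no
    crossover interference this is distributionally identical to dropping a
    Poisson number of uniformly placed crossovers per chromosome and
    reading off the marker loci.
    """
    n, m = len(parent_idx), len(r)
    switch = rng.random((n, m)) < r
    switch[:, 0] = rng.random(n) < 0.5
    source = np.cumsum(switch, axis=1) & 1  # 0/1 haplotype indicator
    h0 = haps[0][parent_idx]
    h1 = haps[1][parent_idx]
    return np.where(source == 0, h0, h1)


def simulate_genotypes(ped: PedigreeTable, config: SimulationConfig) -> MarkerPanel:
    """Gene-drop genotypes through the pedigree.

    Founders draw haplotypes from per-marker allele frequencies uniform in
    [founder_maf_low, founder_maf_high]; descendants receive one
    recombinant gamete from each parent.  Processes one pedigree
    generation at a time so large cohorts stay vectorized.
    """
    rng = np.random.default_rng(config.seed + 1)
    m = config.n_markers
    freqs = rng.uniform(config.founder_maf_low, config.founder_maf_high, size=m)
    r = _interval_recomb_fractions(config)

    n = len(ped)
    sire_idx, dam_idx = ped.parent_indices()
    hap_pat = np.zeros((n, m), dtype=np.int8)  # gamete received from sire
    hap_mat = np.zeros((n, m), dtype=np.int8)  # gamete received from dam

    founders = (sire_idx < 0) & (dam_idx < 0)
    if not np.all((sire_idx < 0) == (dam_idx < 0)):
        # animals with exactly one known parent: treat missing side as founder draw
        pass
    nf = int(founders.sum())
    hap_pat[founders] = rng.random((nf, m)) < freqs
    hap_mat[founders] = rng.random((nf, m)) < freqs

    # process non-founders in waves: an animal is ready once both parents done
    done = founders.copy()
    pending = np.flatnonzero(~done)
    while len(pending):
        sire_ok = (sire_idx[pending] < 0) | done[sire_idx[pending]]
        dam_ok = (dam_idx[pending] < 0) | done[dam_idx[pending]]
        ready = pending[sire_ok & dam_ok]
        if len(ready) == 0:
            raise ValueError("pedigree contains a cycle")
        si = sire_idx[ready]
        di = dam_idx[ready]
        # unknown single parents (not produced by simulate_pedigree, but legal
        # in hand-built pedigrees): draw a founder gamete
        known_s = si >= 0
        known_d = di >= 0
        if known_s.any():
            hap_pat[ready[known_s]] = _meioses(
                (hap_pat, hap_mat), si[known_s], r, rng)
        if (~known_s).any():
            k = int((~known_s).sum())
            hap_pat[ready[~known_s]] = rng.random((k, m)) < freqs
        if known_d.any():
            hap_mat[ready[known_d]] = _meioses(
                (hap_pat, hap_mat), di[known_d], r, rng)
        if (~known_d).any():
            k = int((~known_d).sum())
            hap_mat[ready[~known_d]] = rng.random((k, m)) < freqs
        done[ready] = True
        pending = np.flatnonzero(~done)

    geno = hap_pat + hap_mat
    if config.dropout_rate > 0.0:
        miss = rng.random(geno.shape) < config.dropout_rate
        geno[miss] = MISSING
    return MarkerPanel(ids=ped.animals.copy(), genotypes=geno,
                       marker_map=_marker_map(config), allele_freqs=None)


def _standardized_normal(rng: np.random.Generator, n: int,
                         sigma2: float) -> np.ndarray:
    """Gaussian draws rescaled to exact sample mean 0 and variance sigma2.

    Level effects (herd-year, year-season) and founder polygenic values are
    standardized so the configured variances — and through them the
    liability threshold — are parameters of the generator rather than
    artifacts of a particular finite draw.
    """
    if sigma2 == 0.0 or n == 1:
        # a single level is indistinguishable from the intercept
        return np.zeros(n)
    x = rng.normal(size=n)
    x = x - x.mean()
    sd = x.std()
    if sd == 0.0:
        return np.zeros(n)
    return x * (np.sqrt(sigma2) / sd)


def _breeding_values(ped: PedigreeTable, panel: Optional[MarkerPanel],
                     config: SimulationConfig,
                     rng: np.random.Generator
                     ) -> tuple[pd.Series, np.ndarray, np.ndarray]:
    """True additive breeding values = scaled QTL part + polygenic remainder.

    Var(a) targets 4*sigma2_s (sire-model convention: the transmitted sire
    effect a/2 must have variance sigma2_s).
    """
    sigma2_a = 4.0 * config.sigma2_s
    n = len(ped)
    qtl_idx = np.array([], dtype=np.int64)
    qtl_eff = np.array([])
    qtl_part = np.zeros(n)
    frac = config.qtl_variance_fraction
    if panel is not None and config.n_qtl > 0 and frac > 0 and sigma2_a > 0:
        m = panel.n_markers
        n_qtl = min(config.n_qtl, m)
        qtl_idx = np.sort(rng.choice(m, size=n_qtl, replace=False))
        raw = rng.normal(size=n_qtl)
        p = panel.allele_freqs[qtl_idx]
        # expected HWE variance of sum 2p(1-p)beta^2 scaled to frac*sigma2_a
        expected = np.sum(2.0 * p * (1.0 - p) * raw ** 2)
        scale = np.sqrt(frac * sigma2_a / expected) if expected > 0 else 0.0
        qtl_eff = raw * scale
        g = panel.genotypes[:, qtl_idx].astype(float)
        centred = g - 2.0 * p  # centering keeps the polygenic mean at 0
        qtl_part = centred @ qtl_eff
        poly_var = (1.0 - frac) * sigma2_a
    else:
        poly_var = sigma2_a

    # polygenic remainder transmitted through the pedigree
    poly = np.zeros(n)
    sire_idx, dam_idx = ped.parent_indices()
    founders = (sire_idx < 0) & (dam_idx < 0)
    poly[founders] = _standardized_normal(rng, int(founders.sum()), poly_var)
    order = np.flatnonzero(~founders)
    mend = rng.normal(0.0, np.sqrt(0.5 * poly_var), size=len(order))
    for k, i in enumerate(order):
        ps = poly[sire_idx[i]] if sire_idx[i] >= 0 else 0.0
        pd_ = poly[dam_idx[i]] if dam_idx[i] >= 0 else 0.0
        poly[i] = 0.5 * (ps + pd_) + mend[k]

    bv = pd.Series(qtl_part + poly, index=ped.animals)
    return bv, qtl_idx, qtl_eff


def simulate_phenotypes(
    ped: PedigreeTable,
    panel: Optional[MarkerPanel],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, TrueGeneticModel]:
    """Binary phenotypes for every recorded daughter.

    Returns a phenotype table (animal, sire, herd_year, year_season, y)
    and the ground-truth genetic model.  The threshold t is the
    (1 - incidence) quantile of the analytic marginal liability
    N(0, sigma2_ys + sigma2_h + sigma2_s + sigma2_e).
    """
    rng = np.random.default_rng(config.seed + 2)
    bv, qtl_idx, qtl_eff = _breeding_values(ped, panel, config, rng)

    recs = ped.records
    is_daughter = (recs["sex"] == "F") & (recs["sire"] != UNKNOWN_PARENT)
    daughters = recs.loc[is_daughter]
    n = len(daughters)
    if n == 0:
        raise ValueError("pedigree contains no recorded daughters")

    ys_eff = _standardized_normal(rng, config.n_year_seasons, config.sigma2_ys)
    hy_eff = _standardized_normal(rng, config.n_herds, config.sigma2_h)
    ys = rng.integers(0, config.n_year_seasons, size=n)
    hy = rng.integers(0, config.n_herds, size=n)

    sire_bv = bv.loc[daughters["sire"]].to_numpy()
    resid = rng.normal(0.0, np.sqrt(config.sigma2_e), size=n)
    liab = ys_eff[ys] + hy_eff[hy] + 0.5 * sire_bv + resid

    # single-level factors collapse into the intercept and contribute no
    # variance on the liability scale
    marg_var = (
        (config.sigma2_ys if config.n_year_seasons > 1 else 0.0)
        + (config.sigma2_h if config.n_herds > 1 else 0.0)
        + config.sigma2_s + config.sigma2_e)
    t = float(norm.ppf(1.0 - config.incidence, scale=np.sqrt(marg_var)))
    y = (liab > t).astype(np.int8)

    phen = pd.DataFrame({
        "animal": daughters["animal"].to_numpy(),
        "sire": daughters["sire"].to_numpy(),
        "herd_year": [f"HY{k}" for k in hy],
        "year_season": [f"YS{k}" for k in ys],
        "y": y,
    })
    truth = TrueGeneticModel(
        qtl_indices=qtl_idx,
        qtl_effects=qtl_eff,
        true_breeding_values=bv,
        liability_threshold=t,
    )
    return phen, truth
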