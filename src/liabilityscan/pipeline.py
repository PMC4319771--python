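"""End-to-end orchestration: simulate/load -> QC -> relationship matrices
-> threshold-model Gibbs fit -> SNP back-solving with iterative
re-weighting -> window ranking and reporting.

A run is driven by a :class:`RunConfig` (YAML on disk), executes the
stages in order with per-stage logging, and leaves behind a posterior
summary, an effects table per re-weighting round, the window table with
its top-10 ranking, a Manhattan TSV/PNG pair and a manifest with record
counts and file checksums.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .qc import QcThresholds, filter_individuals, filter_markers
from .relmat import (build_A22, build_A_inverse, blend_G, build_G,
                     build_H_inverse, initial_weights)
from .simdata import (MarkerPanel, PedigreeTable, SimulationConfig,
                      simulate_genotypes, simulate_pedigree,
                      simulate_phenotypes)
from .snpeffects import iterate_reweighting, top_windows, window_variance
from .thrgibbs import GibbsConfig, build_model_frame, gibbs_fit, summarize_chain

logger = logging.getLogger("liabilityscan")

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "render_manhattan",
           "load_run_config"]


@dataclass
class RunConfig:
    """Inputs are either file paths or a simulation block, never both."""

    output_dir: str = "liabilityscan_run"
    seed: int = 1
    pedigree_path: Optional[str] = None
    genotype_prefix: Optional[str] = None     # PLINK prefix
    phenotype_path: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    qc: QcThresholds = field(default_factory=QcThresholds)
    gibbs: GibbsConfig = field(default_factory=GibbsConfig)
    reweight_rounds: int = 4
    window_size: int = 10
    n_top_windows: int = 10
    blend_alpha: float = 0.05
    breeding_value_scale: float = 1.0   # x2 turns transmitting ability into EBV
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        have_paths = all(p is not None for p in
                         (self.pedigree_path, self.genotype_prefix,
                          self.phenotype_path))
        any_paths = any(p is not None for p in
                        (self.pedigree_path, self.genotype_prefix,
                         self.phenotype_path))
        if self.simulation is not None and any_paths:
            raise ValueError("give either input paths or a simulation block, "
                             "not both")
        if self.simulation is None and not have_paths:
            raise ValueError("either all three input paths or a simulation "
                             "block is required")


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stage_counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)   # filename -> sha256

    def to_dict(self) -> dict:
        return asdict(self)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulation", None)
    qc = raw.pop("qc", None)
    gibbs = raw.pop("gibbs", None)
    cfg = RunConfig(
        simulation=SimulationConfig(**sim) if sim else None,
        qc=QcThresholds(**{**qc, "autosomes": frozenset(
            str(c) for c in qc["autosomes"])}) if qc and "autosomes" in qc
        else (QcThresholds(**qc) if qc else QcThresholds()),
        gibbs=GibbsConfig(**gibbs) if gibbs else GibbsConfig(),
        **raw,
    )
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if isinstance(o, frozenset):
            return sorted(o)
        return str(o)
    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def extract_sire_pedigree(ped: PedigreeTable, phenotypes: pd.DataFrame
                          ) -> PedigreeTable:
    """Pedigree restricted to the sires of recorded daughters and their
    ancestors — the effect structure of the sire model."""
    sires = phenotypes["sire"].astype(str).unique()
    return ped.subset_with_ancestors(sires)


def render_manhattan(table: pd.DataFrame, path) -> pd.DataFrame:
    """Manhattan plot of window variance shares plus its TSV twin.

    One point per window at the window's bp midpoint on a cumulative
    genome axis, chromosomes shaded alternately.  Returns the TSV frame.
    """
    if len(table) == 0:
        raise ValueError("empty window table")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = table.copy()
    offsets = {}
    run = 0
    for c in pd.unique(tab["chrom"]):
        offsets[c] = run
        run += int(tab.loc[tab["chrom"] == c, "stop_bp"].max())
    tab["midpoint_bp"] = (tab["start_bp"] + tab["stop_bp"]) / 2.0
    tab["genome_bp"] = tab.apply(
        lambda r: offsets[r["chrom"]] + r["midpoint_bp"], axis=1)

    fig, ax = plt.subplots(figsize=(10, 3.2))
    for k, c in enumerate(pd.unique(tab["chrom"])):
        sub = tab[tab["chrom"] == c]
        ax.scatter(sub["genome_bp"], sub["variance_share"], s=8,
                   color="tab:blue" if k % 2 == 0 else "tab:gray")
    ax.set_xlabel("genome position")
    ax.set_ylabel("window variance share")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)

    tsv = tab[["chrom", "midpoint_bp", "variance_share"]]
    tsv.to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
    return tsv


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full analysis and return its manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config),
                           version=_version(), seed=config.seed)

    current_stage = ["inputs"]

    def stage(name):
        current_stage[0] = name
        logger.info("=== stage: %s ===", name)

    try:
        stage("inputs")
        if config.simulation is not None:
            sim = config.simulation.with_(seed=config.seed)
            ped = simulate_pedigree(sim)
            panel_all = simulate_genotypes(ped, sim)
            phen, truth = simulate_phenotypes(ped, panel_all, sim)
            # the genotyped set mirrors the study: bulls with recorded
            # daughters, not the recorded cows themselves
            sires = pd.unique(phen["sire"])
            panel = panel_all.subset_individuals(sires)
            lio.write_pedigree(ped, out / "pedigree.csv")
            lio.write_phenotypes(phen, out / "phenotypes.csv")
            lio.write_plink(panel, out / "genotypes")
            lio.write_genotype_lines(panel, out / "genotypes.txt")
            lio.write_truth(truth, {
                "sigma2_s": sim.sigma2_s, "sigma2_h": sim.sigma2_h,
                "sigma2_e": sim.sigma2_e}, out / "truth.json")
        else:
            ped = lio.read_pedigree(config.pedigree_path)
            panel = lio.read_plink(config.genotype_prefix)
            phen = lio.read_phenotypes(config.phenotype_path)
        manifest.stage_counts["inputs"] = {
            "pedigree": len(ped), "records": len(phen),
            "genotyped": panel.n_individuals, "markers": panel.n_markers,
        }

        stage("qc")
        panel, rep_ind = filter_individuals(panel, phen, config.qc)
        panel, rep_mark = filter_markers(panel, config.qc)
        with open(out / "qc_report.json", "w") as fh:
            json.dump({"individuals": rep_ind.to_dict(),
                       "markers": rep_mark.to_dict()}, fh, indent=1)
        manifest.stage_counts["qc"] = {
            "genotyped": panel.n_individuals, "markers": panel.n_markers,
            "removed_individuals": rep_ind.removed,
            "removed_markers": rep_mark.removed,
        }

        stage("relmat")
        sire_ped = extract_sire_pedigree(ped, phen)
        Ainv = build_A_inverse(sire_ped)
        genotyped = [i for i in panel.ids if i in set(sire_ped.animals)]
        panel = panel.subset_individuals(genotyped)
        if panel.n_individuals > 0:
            weights = initial_weights(panel)
            A22 = build_A22(sire_ped, panel.ids)
            G = build_G(panel, weights)
            G_star = blend_G(G, A22, config.blend_alpha)
            Hinv = build_H_inverse(Ainv, sire_ped.animals, G_star, A22)
        else:
            A22 = None
            Hinv = build_H_inverse(Ainv, sire_ped.animals, None, None)
        manifest.stage_counts["relmat"] = {
            "sire_pedigree": len(sire_ped), "genotyped": panel.n_individuals,
        }

        stage("fit")
        frame = build_model_frame(phen, sire_ped)
        gibbs_cfg = GibbsConfig(
            n_iterations=config.gibbs.n_iterations,
            burn_in=config.gibbs.burn_in, thin=config.gibbs.thin,
            seed=config.seed,
            nu_h=config.gibbs.nu_h, s2_h=config.gibbs.s2_h,
            nu_s=config.gibbs.nu_s, s2_s=config.gibbs.s2_s,
        )
        chain = gibbs_fit(frame, Hinv, gibbs_cfg)
        summary = summarize_chain(chain)
        summary.to_csv(out / "posterior_summary.tsv", sep="\t", index=False)
        summary_json = {
            row["parameter"]: {
                "mean": row["mean"], "sd": row["sd"],
                "hpd_low": row["hpd_low"], "hpd_high": row["hpd_high"],
            } for _, row in summary.iterrows()
        }
        with open(out / "posterior_summary.json", "w") as fh:
            json.dump(summary_json, fh, indent=1)
        chain.to_frame().to_csv(out / "chain.tsv", sep="\t", index=False)
        manifest.stage_counts["fit"] = {
            "records": frame.n_records, "retained_samples": chain.n_retained,
        }

        if panel.n_individuals > 0:
            stage("snp-effects")
            sols = chain.sire_solutions()
            a_g = (config.breeding_value_scale
                   * sols.loc[list(panel.ids)].to_numpy())
            rounds = iterate_reweighting(panel, a_g,
                                         n_rounds=config.reweight_rounds,
                                         alpha=config.blend_alpha, A22=A22)
            eff_frames = [e.to_frame(panel) for e in rounds]
            pd.concat(eff_frames).to_csv(out / "snp_effects.tsv", sep="\t",
                                         index=False)

            stage("report")
            wtab = window_variance(rounds[-1], panel,
                                   window_size=config.window_size)
            wtab.to_csv(out / "windows.tsv", sep="\t", index=False)
            top = top_windows(wtab, config.n_top_windows)
            top.to_csv(out / "top_windows.tsv", sep="\t", index=False)
            render_manhattan(wtab, out / "manhattan.png")
            manifest.stage_counts["windows"] = {
                "windows": len(wtab), "top": len(top),
                "top_share_sum": float(top["variance_share"].sum()),
            }
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {current_stage[0]!r} failed: {exc}") from exc

    for f in sorted(out.iterdir()):
        if f.is_file() and f.suffix in {".tsv", ".csv", ".json", ".txt",
                                        ".ped", ".map"}:
            manifest.outputs[f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=1)
    return manifest


def _version() -> str:
    from . import __version__
    return __version__
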