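"""Back-solving marker effects, iterative G re-weighting, window variances.

Marker effects are recovered from the genomic breeding values a_g of the
genotyped individuals through

    u = D Z' G^-1 a_g

with Z the allele-frequency-centred genotype matrix, D the diagonal of
marker weights and G = Z D Z' the (possibly blended) genomic matrix this
D produced.  The variance a marker absorbs is its realized variance
r_i = 2 p_i (1 - p_i) u_i^2.  Re-weighting replaces the expected marker
contributions in D with these realized variances (d_i proportional to
u_i^2, rescaled so sum d_i 2 p_i (1 - p_i) = 1, which keeps G on the
iteration-1 scale), rebuilds G, and solves again; four rounds by default.
Variance is then partitioned into blocks of 10 adjacent SNPs per
chromosome and reported as genome-wide normalized shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional
import warnings

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .relmat import (MarkerWeights, RelationshipMatrix, blend_G, build_G,
                     centered_Z, initial_weights)
from .simdata import MarkerPanel

__all__ = [
    "SnpEffectSet",
    "backsolve_effects",
    "update_weights",
    "iterate_reweighting",
    "window_variance",
    "top_windows",
]


@dataclass
class SnpEffectSet:
    """Per-marker effects and the genomic breeding values they reproduce."""

    u: np.ndarray                  # marker effects
    weights: MarkerWeights         # the D that produced them
    a_g: np.ndarray                # genomic breeding values used
    ids: np.ndarray                # genotyped individual IDs
    iteration: int = 1

    @property
    def realized_variance(self) -> np.ndarray:
        """r_i = 2 p_i (1 - p_i) u_i^2."""
        p = self.weights.allele_freqs
        return 2.0 * p * (1.0 - p) * self.u ** 2

    def to_frame(self, panel: MarkerPanel) -> pd.DataFrame:
        return pd.DataFrame({
            "marker": panel.marker_map["marker"],
            "chrom": panel.marker_map["chrom"],
            "bp": panel.marker_map["bp"],
            "u": self.u,
            "realized_variance": self.realized_variance,
            "weight": self.weights.d,
            "iteration": self.iteration,
        })


def backsolve_effects(panel: MarkerPanel, weights: MarkerWeights,
                      G_star: RelationshipMatrix, a_g: np.ndarray
                      ) -> SnpEffectSet:
    """Solve u = D Z' G*^-1 a_g."""
    a_g = np.asarray(a_g, dtype=float)
    if len(a_g) != panel.n_individuals:
        raise ValueError("a_g length does not match the genotyped set")
    if G_star.values.shape[0] != panel.n_individuals:
        raise ValueError("G dimension does not match the genotyped set")
    try:
        cf = cho_factor(G_star.values)
    except np.linalg.LinAlgError as exc:
        raise ValueError("G* is singular; blend with A22 first") from exc
    ginv_ag = cho_solve(cf, a_g)
    Z = centered_Z(panel)
    u = weights.d * (Z.T @ ginv_ag)
    return SnpEffectSet(u=u, weights=weights, a_g=a_g, ids=panel.ids.copy(),
                        iteration=weights.iteration)


def update_weights(effects: SnpEffectSet, panel: MarkerPanel,
                   floor: float = 1e-8) -> MarkerWeights:
    """Realized-variance re-weighting: d_i proportional to u_i^2, floored
    at ``floor`` times the mean raw weight, then rescaled to the
    sum d_i 2 p_i (1 - p_i) = 1 normalization."""
    u2 = effects.u ** 2
    if not np.any(u2 > 0):
        raise ValueError("all marker effects are zero; cannot re-weight")
    mean_raw = u2.mean()
    raw = np.maximum(u2, floor * mean_raw)
    p = panel.allele_freqs
    het = 2.0 * p * (1.0 - p)
    scale = 1.0 / float(np.sum(raw * het))
    return MarkerWeights(d=raw * scale, allele_freqs=p.copy(),
                         iteration=effects.iteration + 1)


def iterate_reweighting(panel: MarkerPanel, a_g: np.ndarray,
                        n_rounds: int = 4, alpha: float = 0.05,
                        A22: Optional[RelationshipMatrix] = None,
                        floor: float = 1e-8) -> list[SnpEffectSet]:
    """Alternate back-solving and realized-variance re-weighting of G.

    Round 1 uses the expected-variance weights; each later round rebuilds
    G from the updated weights, re-blends and re-solves with a_g held
    fixed.  Returns the effect set of every round.  When no A22 is given
    the identity matrix (the unrelated-genotyped-set limit) is used for
    blending.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    if A22 is None:
        A22 = RelationshipMatrix(np.eye(panel.n_individuals),
                                 panel.ids.copy(), kind="A22")
    weights = initial_weights(panel)
    rounds: list[SnpEffectSet] = []
    for r in range(1, n_rounds + 1):
        G = build_G(panel, weights)
        G_star = blend_G(G, A22, alpha) if alpha > 0 else G
        eff = backsolve_effects(panel, weights, G_star, a_g)
        eff.iteration = r
        rounds.append(eff)
        if r < n_rounds:
            weights = update_weights(eff, panel, floor=floor)
    return rounds


def window_variance(effects: SnpEffectSet, panel: MarkerPanel,
                    window_size: int = 10, sliding: bool = False
                    ) -> pd.DataFrame:
    """Partition realized marker variance into blocks of ``window_size``
    adjacent SNPs per chromosome and normalize to genome-wide shares.

    Windows never span chromosomes; the final partial block of a
    chromosome is retained.  Shares sum to 1.  With ``sliding=True`` an
    overlapping step-1 window mode is produced for comparison; its shares
    are each window's fraction of total variance and do not sum to 1.
    """
    mm = panel.marker_map
    chrom = mm["chrom"].to_numpy()
    bp = mm["bp"].to_numpy()
    for c in np.unique(chrom):
        b = bp[chrom == c]
        if np.any(np.diff(b) < 0):
            raise ValueError(f"marker map not sorted by bp on chromosome {c}")
    r = effects.realized_variance
    total = float(r.sum())
    if total <= 0:
        raise ValueError("total realized variance is zero")

    rows = []
    wid = 0
    for c in pd.unique(pd.Series(chrom)):
        idx = np.flatnonzero(chrom == c)
        if sliding:
            starts = range(0, max(len(idx) - window_size + 1, 1))
        else:
            starts = range(0, len(idx), window_size)
        for s0 in starts:
            wslice = idx[s0: s0 + window_size]
            wid += 1
            rows.append({
                "window_id": wid,
                "chrom": c,
                "start_bp": int(bp[wslice[0]]),
                "stop_bp": int(bp[wslice[-1]]),
                "n_snps": len(wslice),
                "variance_share": float(r[wslice].sum()) / total,
            })
    table = pd.DataFrame(rows)
    if not sliding:
        # exact renormalization guard against accumulated round-off
        table["variance_share"] /= table["variance_share"].sum()
    return table


def top_windows(table: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """The ``n`` windows with the largest variance share, ties broken by
    (chromosome, start_bp) ascending."""
    if len(table) == 0:
        raise ValueError("empty window table")
    if n > len(table):
        warnings.warn(f"requested {n} windows but only {len(table)} exist; "
                      "returning all")
        n = len(table)
    ordered = table.sort_values(
        by=["variance_share", "chrom", "start_bp"],
        ascending=[False, True, True],
        kind="mergesort",
    ).head(n)
    out = ordered[["window_id", "variance_share", "chrom",
                   "start_bp", "stop_bp", "n_snps"]].copy()
    out["variance_pct"] = 100.0 * out["variance_share"]
    return out.reset_index(drop=True)
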