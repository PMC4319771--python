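"""Threshold-liability sire model fitted by Gibbs sampling.

Model on the liability scale, for record i:

    lambda_i = x_i' beta + h_{hy(i)} + s_{sire(i)} + e_i

with fixed year-season effects beta (intercept absorbed, reference level
dropped), herd-year effects h ~ N(0, I sigma2_h), sire effects
s ~ N(0, H sigma2_s) over the whole pedigree, and e ~ N(0, 1).  The
observed binary outcome is y_i = 1{lambda_i > 0}: the threshold is fixed
at 0 and the residual variance at 1, the usual identification of the
probit/threshold model.

Each Gibbs sweep:

1. lambda_i | rest ~ N(fitted_i, 1) truncated to (0, inf) if y_i = 1,
   else (-inf, 0] — inverse-CDF sampling, vectorized;
2. (beta, h, s) | lambda jointly from the Gaussian full conditional of
   the mixed-model equations, via a dense Cholesky of the coefficient
   matrix C = W'W + blockdiag(0, I/sigma2_h, H^-1/sigma2_s);
3. sigma2_h, sigma2_s from scaled-inverse-chi-square full conditionals
   driven by h'h and s' H^-1 s.

Priors: flat on beta; scaled-inverse-chi-square(nu, S2) on the variances,
default nu = -2, S2 = 0 (flat on the variance scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import ndtr, ndtri

import arviz as az

from .relmat import HInverse
from .simdata import PedigreeTable, UNKNOWN_PARENT

__all__ = [
    "ModelFrame",
    "GibbsConfig",
    "VarianceComponents",
    "PosteriorChain",
    "build_model_frame",
    "gibbs_fit",
    "summarize_chain",
    "heritability_from_components",
    "hpd_interval",
]


@dataclass
class ModelFrame:
    """Design structure of the threshold sire model.

    Factor incidence is stored as integer index vectors (record -> level);
    sparse design matrices are materialized on demand.
    """

    y: np.ndarray                 # binary outcomes, n
    X: np.ndarray                 # dense fixed-effect design (intercept + contrasts)
    hy_index: np.ndarray          # record -> herd-year level
    sire_index: np.ndarray        # record -> position in pedigree ID order
    ys_levels: list               # year-season labels (first = reference)
    hy_levels: list
    ped_ids: np.ndarray           # sire-effect order = pedigree order

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_hy(self) -> int:
        return len(self.hy_levels)

    @property
    def n_sires(self) -> int:
        return len(self.ped_ids)

    def design_matrix(self) -> sp.csr_matrix:
        """W = [X | Z_h | Z_s] as one sparse matrix."""
        n = self.n_records
        Zh = sp.csr_matrix(
            (np.ones(n), (np.arange(n), self.hy_index)),
            shape=(n, self.n_hy))
        Zs = sp.csr_matrix(
            (np.ones(n), (np.arange(n), self.sire_index)),
            shape=(n, self.n_sires))
        return sp.hstack([sp.csr_matrix(self.X), Zh, Zs]).tocsr()


@dataclass(frozen=True)
class GibbsConfig:
    n_iterations: int = 120_000
    burn_in: int = 20_000
    thin: int = 10
    seed: int = 0
    nu_h: float = -2.0
    s2_h: float = 0.0
    nu_s: float = -2.0
    s2_s: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("need 0 <= burn_in < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_s: float
    sigma2_h: float
    sigma2_e: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2_s < 0 or self.sigma2_h < 0 or self.sigma2_e <= 0:
            raise ValueError("variance components must be nonnegative "
                             "(residual positive)")


@dataclass
class PosteriorChain:
    """Retained Gibbs samples; one row per retained sweep."""

    beta: np.ndarray              # k x p
    h: np.ndarray                 # k x n_hy
    s: np.ndarray                 # k x n_sires
    sigma2_h: np.ndarray          # k
    sigma2_s: np.ndarray          # k
    sigma2_e: np.ndarray          # k, identically 1
    h2: np.ndarray                # k, per-sample heritability
    iterations: np.ndarray        # sweep index of each retained sample
    frame: Optional[ModelFrame] = None

    @property
    def n_retained(self) -> int:
        return len(self.sigma2_s)

    def sire_solutions(self) -> pd.Series:
        """Posterior means of the sire effects, indexed by pedigree ID."""
        return pd.Series(self.s.mean(axis=0), index=self.frame.ped_ids)

    def to_frame(self) -> pd.DataFrame:
        """Long TSV-ready view of the scalar parameters."""
        return pd.DataFrame({
            "iteration": np.tile(self.iterations, 3),
            "parameter": np.repeat(["sigma2_s", "sigma2_h", "h2"],
                                   self.n_retained),
            "value": np.concatenate([self.sigma2_s, self.sigma2_h, self.h2]),
        })


def build_model_frame(phenotypes: pd.DataFrame, ped: PedigreeTable) -> ModelFrame:
    """Assemble X (intercept + year-season contrasts), herd-year and sire
    incidence from a phenotype table.

    Every record must name a known sire present in the pedigree: the sire
    model has no effect to attach an orphan record to.
    """
    req = {"sire", "herd_year", "year_season", "y"}
    missing = req - set(phenotypes.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    sires = phenotypes["sire"].astype(str)
    if (sires == UNKNOWN_PARENT).any() or sires.isna().any():
        raise ValueError("records with unknown sire are not usable "
                         "in a sire model")
    try:
        sire_index = np.array([ped.index_of(s) for s in sires], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"sire {exc} not found in pedigree") from exc

    ys = pd.Categorical(phenotypes["year_season"].astype(str))
    ys_levels = list(ys.categories)
    n = len(phenotypes)
    # reference level absorbed into the intercept
    X = np.ones((n, len(ys_levels)))
    X[:, 1:] = (ys.codes[:, None] == np.arange(1, len(ys_levels))[None, :])
    X = X[:, : max(1, len(ys_levels))]
    if len(ys_levels) == 1:
        X = np.ones((n, 1))

    hy = pd.Categorical(phenotypes["herd_year"].astype(str))
    return ModelFrame(
        y=phenotypes["y"].to_numpy().astype(np.int8),
        X=X,
        hy_index=hy.codes.astype(np.int64),
        sire_index=sire_index,
        ys_levels=ys_levels,
        hy_levels=list(hy.categories),
        ped_ids=ped.animals.copy(),
    )


def _sample_variance(q: float, n: int, nu: float, s2: float,
                     rng: np.random.Generator) -> float:
    """Scaled-inverse-chi-square full conditional: (q + nu*S2) / chi2_{n+nu}."""
    dof = n + nu
    if dof <= 0:
        raise ValueError("non-positive posterior degrees of freedom; "
                         "use a proper prior or more levels")
    chi2 = rng.chisquare(dof)
    return (q + nu * s2) / chi2


def _truncated_normal(mean: np.ndarray, positive: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-variance normals truncated to (0, inf) where positive, else
    (-inf, 0]; inverse-CDF method."""
    lo = np.where(positive, ndtr(-mean), 0.0)
    hi = np.where(positive, 1.0, ndtr(-mean))
    u = lo + (hi - lo) * rng.random(len(mean))
    u = np.clip(u, 1e-15, 1.0 - 1e-15)
    return mean + ndtri(u)


def gibbs_fit(frame: ModelFrame, Hinv: HInverse, config: GibbsConfig,
              gaussian_response: Optional[np.ndarray] = None,
              fix_variances: Optional[VarianceComponents] = None
              ) -> PosteriorChain:
    """Run the Gibbs sampler and return the retained chain.

    ``gaussian_response`` replaces the latent-liability update with an
    observed continuous response (testing hook: the sampler then reduces
    to a Gaussian mixed model).  ``fix_variances`` clamps the variance
    components instead of sampling them.
    """
    y = frame.y
    if gaussian_response is None and (y.min() == y.max()):
        raise ValueError("response is constant; the threshold is "
                         "unidentifiable")
    if not np.array_equal(np.asarray(Hinv.ids), np.asarray(frame.ped_ids)):
        raise ValueError("H^-1 ID order must match the model frame pedigree")

    rng = np.random.default_rng(config.seed)
    n = frame.n_records
    p = frame.X.shape[1]
    n_hy = frame.n_hy
    n_s = frame.n_sires
    q = p + n_hy + n_s

    W = frame.design_matrix()
    WtW = np.asarray((W.T @ W).todense())
    Hinv_dense = np.asarray(Hinv.matrix.todense())

    h_slice = slice(p, p + n_hy)
    s_slice = slice(p + n_hy, q)

    theta = np.zeros(q)
    sigma2_h = 0.5 if fix_variances is None else fix_variances.sigma2_h
    sigma2_s = 0.05 if fix_variances is None else fix_variances.sigma2_s

    if gaussian_response is not None:
        lam = np.asarray(gaussian_response, dtype=float).copy()
    else:
        lam = np.where(y == 1, 0.5, -0.5).astype(float)
    positive = y == 1

    k = config.n_retained
    out_beta = np.empty((k, p))
    out_h = np.empty((k, n_hy))
    out_s = np.empty((k, n_s))
    out_s2h = np.empty(k)
    out_s2s = np.empty(k)
    out_iter = np.empty(k, dtype=np.int64)
    kept = 0

    for sweep in range(1, config.n_iterations + 1):
        # 1. latent liabilities
        if gaussian_response is None:
            fitted = (frame.X @ theta[:p]
                      + theta[h_slice][frame.hy_index]
                      + theta[s_slice][frame.sire_index])
            lam = _truncated_normal(fitted, positive, rng)

        # 2. joint location sample from N(C^-1 W'lam, C^-1)
        C = WtW.copy()
        C[h_slice, h_slice] += np.eye(n_hy) / sigma2_h
        C[s_slice, s_slice] += Hinv_dense / sigma2_s
        rhs = W.T @ lam
        try:
            cf = cho_factor(C, lower=False)
        except np.linalg.LinAlgError as exc:
            raise ValueError("mixed-model coefficient matrix is not positive "
                             "definite") from exc
        mu = cho_solve(cf, rhs)
        z = rng.standard_normal(q)
        theta = mu + solve_triangular(cf[0], z, lower=False)

        # 3. variance components
        if fix_variances is None:
            h = theta[h_slice]
            s = theta[s_slice]
            sigma2_h = _sample_variance(float(h @ h), n_hy,
                                        config.nu_h, config.s2_h, rng)
            sigma2_s = _sample_variance(float(s @ (Hinv_dense @ s)), n_s,
                                        config.nu_s, config.s2_s, rng)

        if sweep > config.burn_in and (sweep - config.burn_in) % config.thin == 0:
            if kept < k:
                out_beta[kept] = theta[:p]
                out_h[kept] = theta[h_slice]
                out_s[kept] = theta[s_slice]
                out_s2h[kept] = sigma2_h
                out_s2s[kept] = sigma2_s
                out_iter[kept] = sweep
                kept += 1

    h2 = 4.0 * out_s2s / (out_s2s + out_s2h + 1.0)
    return PosteriorChain(
        beta=out_beta, h=out_h, s=out_s,
        sigma2_h=out_s2h, sigma2_s=out_s2s,
        sigma2_e=np.ones(k), h2=h2,
        iterations=out_iter, frame=frame,
    )


def heritability_from_components(vc: VarianceComponents) -> float:
    """Liability-scale heritability under the sire model,
    h2 = 4 sigma2_s / (sigma2_s + sigma2_h + sigma2_e)."""
    total = vc.sigma2_s + vc.sigma2_h + vc.sigma2_e
    if total <= 0:
        raise ValueError("total variance must be positive")
    return 4.0 * vc.sigma2_s / total


def hpd_interval(samples: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    k = max(1, int(np.ceil(prob * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])


def _geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late segment means,
    with ESS-corrected variances."""
    n = len(x)
    a = x[: int(first * n)]
    b = x[int((1.0 - last) * n):]
    if len(a) < 2 or len(b) < 2:
        return np.nan
    va = np.var(a, ddof=1) / max(float(az.ess(np.asarray(a))), 1.0)
    vb = np.var(b, ddof=1) / max(float(az.ess(np.asarray(b))), 1.0)
    denom = np.sqrt(va + vb)
    return float((a.mean() - b.mean()) / denom) if denom > 0 else 0.0


def summarize_chain(chain: PosteriorChain, prob: float = 0.95) -> pd.DataFrame:
    """Posterior mean, SD, HPD interval, ESS and Geweke z per scalar
    parameter (variance components, heritability, fixed effects)."""
    if chain.n_retained < 100:
        raise ValueError("need at least 100 retained samples to summarize")
    params = {
        "sigma2_s": chain.sigma2_s,
        "sigma2_h": chain.sigma2_h,
        "sigma2_e": chain.sigma2_e,
        "h2": chain.h2,
    }
    for j in range(chain.beta.shape[1]):
        params[f"beta_{j}"] = chain.beta[:, j]
    rows = []
    for name, x in params.items():
        x = np.asarray(x, dtype=float)
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        if sd == 0.0:
            lo = hi = float(x[0])
            ess = float(len(x))
            gz = 0.0
        else:
            lo, hi = hpd_interval(x, prob)
            ess = float(az.ess(x))
            gz = _geweke_z(x)
        rows.append({
            "parameter": name,
            "mean": float(np.mean(x)),
            "sd": sd,
            "hpd_low": lo,
            "hpd_high": hi,
            "ess": ess,
            "geweke_z": gz,
        })
    return pd.DataFrame(rows)
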