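"""Differential representation of hairpin counts.

The count model is the standard one for sequencing screens: counts
``y_gk ~ NB(mu_gk, phi_g)`` with ``log mu_gk = x_k' beta_g + o_k``, where
``o_k = log(N_k f_k)`` combines raw library size and a TMM normalisation
factor.  The pipeline is

1. abundance filter: keep hairpins with CPM >= 0.5 in *every* t0 replicate;
2. TMM normalisation factors (weighted trimmed mean of M-values);
3. dispersion estimation by Cox-Reid adjusted profile likelihood (APL):
   a common value maximising the summed APL, and per-hairpin (tagwise)
   values maximising a weighted likelihood that shrinks each hairpin's APL
   toward the mean APL with weight ``prior_df / residual_df``;
4. per-hairpin negative-binomial GLM fits (IRLS with step halving) and
   likelihood-ratio tests of each final-timepoint treatment against t0,
   with p-values from chi-square;
5. Benjamini-Hochberg FDR within each pool x contrast.

Pools are analysed independently and results concatenated.  Reported
log2 fold changes come from a fit with a small prior count added (so zero
counts give finite estimates); the test itself uses raw counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import DesignError, DropscreenError, ValidationError
from .screen_model import CountMatrix, SampleSheet, ShRNALibrary

DEFAULT_CONTRASTS = ("PDS-t0", "PhenDC3-t0", "DMSO-t0")

_PHI_GRID = np.logspace(-4, 1, 41)  # dispersion search grid


# ---------------------------------------------------------------------------
# CPM and filtering
# ---------------------------------------------------------------------------


def cpm(counts: pd.DataFrame | np.ndarray, lib_sizes=None) -> pd.DataFrame | np.ndarray:
    """Counts per million: ``1e6 * y / N`` per sample column."""
    if lib_sizes is None:
        lib_sizes = np.asarray(counts).sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if np.any(lib_sizes <= 0):
        if isinstance(counts, pd.DataFrame):
            bad = list(counts.columns[lib_sizes <= 0])
            raise DropscreenError(f"zero library size for sample(s): {bad}")
        raise DropscreenError("zero library size")
    return counts * (1e6 / lib_sizes)


def filter_low_counts(
    cm: CountMatrix, ss: SampleSheet, threshold: float = 0.5
) -> CountMatrix:
    """Keep hairpins with CPM >= threshold in every t0 sample (inclusive).

    Only initial-timepoint replicates are consulted; treatment columns never
    affect the filter.
    """
    t0 = [s for s in ss.samples_where(timepoint="t0") if s in cm.sample_ids]
    if not t0:
        raise DesignError("no t0 samples available for CPM filtering")
    t0_cpm = cpm(cm.counts[t0])
    keep = (t0_cpm >= threshold).all(axis=1)
    return CountMatrix(cm.counts.loc[keep].copy())


# ---------------------------------------------------------------------------
# TMM normalisation
# ---------------------------------------------------------------------------


@dataclass
class NormFactors:
    """Per-sample TMM factors, rescaled to geometric mean 1."""

    factors: pd.Series
    ref_sample: str

    def __post_init__(self) -> None:
        f = self.factors.to_numpy(dtype=float)
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ValidationError("normalisation factors must be finite and positive")

    def effective_lib_sizes(self, lib_sizes: pd.Series) -> pd.Series:
        return lib_sizes.astype(float) * self.factors.reindex(lib_sizes.index)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """One TMM factor: trimmed, inverse-variance-weighted mean of M values."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    n = obs.size
    if n < 2:
        warnings.warn("fewer than 2 shared non-zero hairpins; TMM factor set to 1")
        return 1.0
    p_o, p_r = obs / n_obs, ref / n_ref
    M = np.log2(p_o / p_r)
    A = 0.5 * np.log2(p_o * p_r)
    # double trim by rank: drop top/bottom trim_m of M and trim_a of A
    rank_m = stats.rankdata(M)
    rank_a = stats.rankdata(A)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n - np.floor(n * trim_m)
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n - np.floor(n * trim_a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep2.sum() < 2:
        warnings.warn("fewer than 2 hairpins survive TMM trimming; factor set to 1")
        return 1.0
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    f = np.sum(M[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    return float(2.0 ** f)


def tmm_factors(
    cm: CountMatrix,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormFactors:
    """Weighted trimmed mean of M-values normalisation factors.

    The reference defaults to the sample whose upper quartile of
    library-scaled counts is closest to the mean upper quartile.  Factors
    are rescaled to geometric mean 1.
    """
    counts = cm.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise DropscreenError("TMM requires at least 2 samples")
    lib_sizes = counts.sum(axis=0)
    samples = cm.sample_ids
    if ref_sample is None:
        uq = np.array(
            [np.quantile(counts[:, j] / lib_sizes[j], 0.75) for j in range(len(samples))]
        )
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_j = samples.index(ref_sample)
    ref = counts[:, ref_j]
    factors = np.ones(len(samples))
    for j in range(len(samples)):
        if j == ref_j:
            continue
        factors[j] = _tmm_pair(
            counts[:, j], ref, lib_sizes[j], lib_sizes[ref_j], trim_m, trim_a
        )
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(pd.Series(factors, index=samples), samples[ref_j])


# ---------------------------------------------------------------------------
# NB GLM machinery (vectorised over hairpins)
# ---------------------------------------------------------------------------


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Row sums of the NB log-likelihood (Poisson branch for phi ~ 0)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-10)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 0:
        phi = np.full(y.shape[0] if y.ndim == 2 else 1, float(phi))
    phi = phi.reshape(-1, 1)
    y2 = y if y.ndim == 2 else y[None, :]
    mu2 = mu if mu.ndim == 2 else mu[None, :]
    out = np.empty(y2.shape[0])
    small = phi[:, 0] < 1e-8
    if small.any():
        ys, ms = y2[small], mu2[small]
        out[small] = np.sum(ys * np.log(ms) - ms - special.gammaln(ys + 1), axis=1)
    if (~small).any():
        ys, ms, r = y2[~small], mu2[~small], 1.0 / phi[~small]
        out[~small] = np.sum(
            special.gammaln(ys + r)
            - special.gammaln(r)
            - special.gammaln(ys + 1)
            + ys * np.log(ms / (ms + r))
            + r * np.log(r / (r + ms)),
            axis=1,
        )
    return out if y.ndim == 2 else out[0]


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Row sums of NB unit deviances, 2*(ll_saturated - ll_fit)."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    mu = np.maximum(np.atleast_2d(np.asarray(mu, dtype=float)), 1e-10)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 0:
        phi = np.full(y.shape[0], float(phi))
    phi = phi.reshape(-1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(y / mu), 0.0)
        small = phi < 1e-8
        pois = ylogy - (y - mu)
        r = 1.0 / np.where(small, 1.0, phi)
        nb = ylogy - (y + r) * np.log((y + r) / (mu + r))
    dev = 2.0 * np.where(small, pois, nb).sum(axis=1)
    return dev


def _irls(
    Y: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray,
    phi: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised IRLS for the log-link NB GLM, one fit per row of Y.

    Returns (beta, mu, deviance, converged).  Step-halving keeps the
    deviance non-increasing; etas are clamped to avoid overflow.
    """
    G, K = Y.shape
    P = X.shape[1]
    phi = np.broadcast_to(np.asarray(phi, dtype=float).reshape(-1), (G,)).copy()
    off = np.broadcast_to(np.asarray(offsets, dtype=float), (G, K))
    mu = np.maximum(Y, 0.5).astype(float)
    eta = np.log(mu) - off
    # initial LS projection of the working response onto the design
    beta = np.linalg.lstsq(X, eta.T, rcond=None)[0].T
    eta = beta @ X.T + off
    mu = np.exp(np.clip(eta, -45, 45))
    dev = nb_deviance(Y, mu, phi)
    converged = np.zeros(G, dtype=bool)
    ridge = 1e-10 * np.eye(P)
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        W = mu[active] / (1.0 + phi[active, None] * mu[active])
        Z = (eta[active] - off[active]) + (Y[active] - mu[active]) / np.maximum(
            mu[active], 1e-10
        )
        XtWX = np.einsum("kp,gk,kq->gpq", X, W, X) + ridge
        XtWZ = np.einsum("kp,gk,gk->gp", X, W, Z)
        beta_new = np.linalg.solve(XtWX, XtWZ[..., None])[..., 0]
        step = beta_new - beta[active]
        old_dev = dev[active]
        frac = np.ones(step.shape[0])
        for _half in range(10):
            cand_beta = beta[active] + frac[:, None] * step
            cand_eta = cand_beta @ X.T + off[active]
            cand_mu = np.exp(np.clip(cand_eta, -45, 45))
            cand_dev = nb_deviance(Y[active], cand_mu, phi[active])
            worse = cand_dev > old_dev + 1e-10
            if not worse.any():
                break
            frac[worse] *= 0.5
        beta[active] = cand_beta
        eta[active] = cand_eta
        mu[active] = cand_mu
        dev_new = dev.copy()
        dev_new[active] = cand_dev
        rel = np.abs(dev_new - dev) / (np.abs(dev) + 1.0)
        converged |= rel < tol
        dev = dev_new
    return beta, mu, dev, converged


def fit_nb_glm(
    y: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray | float = 0.0,
    phi: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit one hairpin's NB GLM; returns (coefficients, fitted means, deviance).

    ``design`` must be full rank; all-zero ``y`` is returned with near-zero
    fitted means (degenerate, coefficients at the clamp floor).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DropscreenError("design matrix is rank deficient")
    off = np.broadcast_to(np.asarray(offsets, dtype=float), y.shape)
    if not np.all(np.isfinite(off)):
        raise DropscreenError("offsets must be finite")
    beta, mu, dev, _ = _irls(y[None, :], X, off[None, :], np.array([phi]))
    return beta[0], mu[0], float(dev[0])


def _cox_reid(X: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """0.5 * log det(X' W X) per row, W the IRLS working weights."""
    W = mu / (1.0 + np.asarray(phi).reshape(-1, 1) * mu)
    XtWX = np.einsum("kp,gk,kq->gpq", X, W, X) + 1e-10 * np.eye(X.shape[1])
    sign, logdet = np.linalg.slogdet(XtWX)
    return 0.5 * logdet


def adjusted_profile_loglik(
    Y: np.ndarray, X: np.ndarray, offsets: np.ndarray, phi: float | np.ndarray
) -> np.ndarray:
    """Cox-Reid APL per hairpin at dispersion ``phi``: ll(mu_hat) - 0.5 logdet I."""
    G = Y.shape[0]
    phi_vec = np.broadcast_to(np.asarray(phi, dtype=float).reshape(-1), (G,))
    _, mu, _, _ = _irls(Y, X, np.broadcast_to(offsets, Y.shape), phi_vec)
    return nb_loglik(Y, mu, phi_vec) - _cox_reid(X, mu, phi_vec)


def _apl_grid(
    Y: np.ndarray, X: np.ndarray, offsets: np.ndarray, grid: np.ndarray = _PHI_GRID
) -> np.ndarray:
    """APL evaluated for every hairpin at every grid dispersion: (G, n_grid)."""
    return np.column_stack(
        [adjusted_profile_loglik(Y, X, offsets, g) for g in grid]
    )


@dataclass
class DispersionEstimates:
    """Common + tagwise NB dispersions with the shrinkage weight used."""

    phi_common: float
    phi_tag: pd.Series | np.ndarray
    prior_df: float

    def __post_init__(self) -> None:
        tag = np.asarray(self.phi_tag, dtype=float)
        if not np.all(np.isfinite(tag)) or np.any(tag < 0):
            raise ValidationError("tagwise dispersions must be finite and >= 0")


def _check_residual_df(X: np.ndarray, n_samples: int) -> int:
    df = n_samples - np.linalg.matrix_rank(X)
    if df < 1:
        raise DropscreenError(
            "residual degrees of freedom are zero; supply a dispersion instead "
            "of estimating one"
        )
    return df


def estimate_common_dispersion(
    cm: CountMatrix | np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray,
    grid: np.ndarray = _PHI_GRID,
    apl_grid: np.ndarray | None = None,
) -> float:
    """Maximise the summed Cox-Reid APL over a log grid, then refine.

    The grid spans [1e-4, 10]; the argmax bracket is refined with a bounded
    scalar search in log10(phi).
    """
    Y = cm.counts.to_numpy(dtype=float) if isinstance(cm, CountMatrix) else np.asarray(cm, float)
    X = np.asarray(design, dtype=float)
    _check_residual_df(X, Y.shape[1])
    if apl_grid is None:
        apl_grid = _apl_grid(Y, X, offsets, grid)
    total = apl_grid.sum(axis=0)
    j = int(np.argmax(total))
    lo = np.log10(grid[max(j - 1, 0)])
    hi = np.log10(grid[min(j + 1, len(grid) - 1)])
    if lo == hi:
        return float(grid[j])
    res = optimize.minimize_scalar(
        lambda lphi: -float(adjusted_profile_loglik(Y, X, offsets, 10.0 ** lphi).sum()),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(10.0 ** res.x)


def estimate_tagwise_dispersion(
    cm: CountMatrix | np.ndarray,
    design: np.ndarray,
    phi_common: float | None = None,
    prior_df: float = 10.0,
    offsets: np.ndarray | None = None,
    grid: np.ndarray = _PHI_GRID,
    apl_grid: np.ndarray | None = None,
) -> DispersionEstimates:
    """Per-hairpin dispersions by weighted-likelihood empirical Bayes.

    Each hairpin maximises ``WL_g(phi) = APL_g(phi) + (prior_df/residual_df)
    * mean_g' APL_g'(phi)``; with ``prior_df -> inf`` every estimate collapses
    to the common maximiser, with ``prior_df = 0`` to the per-hairpin ML
    value.  The maximiser is located on the shared log grid and polished by
    quadratic interpolation in log10(phi).
    """
    is_cm = isinstance(cm, CountMatrix)
    Y = cm.counts.to_numpy(dtype=float) if is_cm else np.asarray(cm, dtype=float)
    X = np.asarray(design, dtype=float)
    if offsets is None:
        offsets = np.log(Y.sum(axis=0))
    res_df = _check_residual_df(X, Y.shape[1])
    if apl_grid is None:
        apl_grid = _apl_grid(Y, X, offsets, grid)
    abar = apl_grid.mean(axis=0)
    weight = min(prior_df / res_df, 1e12)  # guard prior_df = inf
    wl = apl_grid + weight * abar[None, :]
    j = np.argmax(wl, axis=1)
    lgrid = np.log10(grid)
    # quadratic interpolation of the maximiser where it is interior
    jj = np.clip(j, 1, len(grid) - 2)
    y0, y1, y2 = (wl[np.arange(len(j)), jj + k] for k in (-1, 0, 1))
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    step = lgrid[1] - lgrid[0]
    lphi = np.where((j > 0) & (j < len(grid) - 1), lgrid[jj] + shift * step, lgrid[j])
    phi_tag = 10.0 ** lphi
    if phi_common is None:
        phi_common = estimate_common_dispersion(
            Y, X, offsets, grid=grid, apl_grid=apl_grid
        )
    index = cm.counts.index if is_cm else None
    return DispersionEstimates(
        phi_common=float(phi_common),
        phi_tag=pd.Series(phi_tag, index=index) if index is not None else phi_tag,
        prior_df=prior_df,
    )


# ---------------------------------------------------------------------------
# LRT contrasts
# ---------------------------------------------------------------------------


def _assert_nested(X_full: np.ndarray, X_red: np.ndarray) -> int:
    rank_full = np.linalg.matrix_rank(X_full)
    rank_red = np.linalg.matrix_rank(X_red)
    combined = np.linalg.matrix_rank(np.hstack([X_full, X_red]))
    if combined > rank_full or rank_red >= rank_full:
        raise DropscreenError("reduced design is not nested in the full design")
    return rank_full - rank_red


def lrt_matrix(
    Y: np.ndarray,
    X_full: np.ndarray,
    X_red: np.ndarray,
    offsets: np.ndarray,
    phi: np.ndarray | float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised LR statistics (clamped at 0) and chi-square p-values."""
    df = _assert_nested(X_full, X_red)
    off = np.broadcast_to(offsets, Y.shape)
    phi_vec = np.broadcast_to(np.asarray(phi, dtype=float).reshape(-1), (Y.shape[0],))
    _, _, dev_full, _ = _irls(Y, X_full, off, phi_vec)
    _, _, dev_red, _ = _irls(Y, X_red, off, phi_vec)
    lr = np.maximum(dev_red - dev_full, 0.0)
    p = stats.chi2.sf(lr, df)
    return lr, p


def lrt_contrast(
    y: np.ndarray,
    design_full: np.ndarray,
    design_reduced: np.ndarray,
    offsets: np.ndarray | float,
    phi: float,
    treat_col: int | None = None,
    prior_count: float = 0.5,
) -> tuple[float, float, float]:
    """Single-hairpin LRT; returns (LR, p, log2FC).

    The log2FC is taken from a prior-count-augmented fit of the full design
    (coefficient ``treat_col``, which in the group parametrisations used
    here is already the treatment-minus-reference log contrast); the test
    itself uses the raw counts.
    """
    y = np.asarray(y, dtype=float)
    off = np.broadcast_to(np.asarray(offsets, dtype=float), y.shape)
    lr, p = lrt_matrix(y[None, :], design_full, design_reduced, off[None, :], phi)
    log2fc = np.nan
    if treat_col is not None:
        y_aug = y + prior_count * np.exp(off) / np.exp(off).mean()
        beta, _, _ = fit_nb_glm(y_aug, design_full, off, phi)
        log2fc = float(beta[treat_col] / np.log(2.0))
    return float(lr[0]), float(p[0]), log2fc


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------


def bh_adjust(p: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up: adj_i = min_{j>=i} p_(j) m / j, capped at 1.

    NaN entries propagate as NaN (with a warning) and do not count toward m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    nan = np.isnan(p)
    if nan.any():
        warnings.warn("NaN p-values propagated through BH adjustment")
    pv = p[~nan]
    if np.any((pv < 0) | (pv > 1)):
        raise DropscreenError("p-values must lie in [0, 1]")
    m = pv.size
    if m:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        result = np.empty(m)
        result[order] = np.minimum(adj, 1.0)
        out[~nan] = result
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class DiffConfig:
    """Thresholds and priors for :func:`run_differential`."""

    cpm_threshold: float = 0.5
    prior_df: float = 10.0
    prior_count: float = 0.5
    trim_m: float = 0.30
    trim_a: float = 0.05


def _group_design(groups: Sequence[str], levels: Sequence[str]) -> np.ndarray:
    """One-hot group-indicator design (no intercept), columns in ``levels`` order."""
    return np.array([[1.0 if g == lv else 0.0 for lv in levels] for g in groups])


def run_differential(
    cm: CountMatrix,
    ss: SampleSheet,
    lib: ShRNALibrary | None = None,
    contrasts: Sequence[str] | None = None,
    config: DiffConfig | None = None,
) -> pd.DataFrame:
    """Filter -> TMM -> dispersions -> per-hairpin LRT per contrast -> BH.

    Contrasts are ``"<treatment>-t0"`` strings; by default every treatment
    present at the final timepoint of each pool is tested against that
    pool's t0.  Pools are processed independently; BH runs within each
    pool x contrast; results are concatenated long-form.
    """
    config = config or DiffConfig()
    gene_of = lib.gene_of() if lib is not None else None
    results = []
    for pool, pool_tab in ss.table.groupby("pool"):
        samples = [s for s in pool_tab["sample_id"] if s in cm.sample_ids]
        if not samples:
            continue
        sub_ss = SampleSheet(pool_tab[pool_tab["sample_id"].isin(samples)])
        sub_cm = cm.subset_samples(samples)
        filt = filter_low_counts(sub_cm, sub_ss, threshold=config.cpm_threshold)
        if filt.shape[0] == 0:
            warnings.warn(f"pool {pool!r}: no hairpins pass the CPM filter")
            continue
        nf = tmm_factors(filt, trim_m=config.trim_m, trim_a=config.trim_a)
        eff_lib = nf.effective_lib_sizes(filt.lib_sizes)
        offsets = np.log(eff_lib.to_numpy())

        meta = sub_ss.table.set_index("sample_id").loc[filt.sample_ids]
        group = np.where(meta["timepoint"] == "t0", "t0", meta["treatment"])
        levels = ["t0"] + sorted(set(group) - {"t0"})
        X_full = _group_design(group, levels)

        pool_contrasts = contrasts
        if pool_contrasts is None:
            pool_contrasts = [f"{lv}-t0" for lv in levels[1:]]

        Y = filt.counts.to_numpy(dtype=float)
        grid_apl = _apl_grid(Y, X_full, offsets)
        phi_common = estimate_common_dispersion(
            Y, X_full, offsets, apl_grid=grid_apl
        )
        disp = estimate_tagwise_dispersion(
            filt,
            X_full,
            phi_common=phi_common,
            prior_df=config.prior_df,
            offsets=offsets,
            apl_grid=grid_apl,
        )
        phi_tag = np.asarray(disp.phi_tag, dtype=float)

        off2 = np.broadcast_to(offsets, Y.shape)
        _, mu_full, dev_full, conv = _irls(Y, X_full, off2, phi_tag)
        # prior-count-augmented fit for reported fold changes
        prior = config.prior_count * np.exp(offsets) / np.exp(offsets).mean()
        beta_aug, _, _, _ = _irls(Y + prior, X_full, off2, phi_tag)
        mean_log_cpm = np.log2(
            np.mean((Y + 0.5) / np.exp(offsets) * 1e6, axis=1)
        )
        group_zero = {
            lv: (Y[:, np.array(group) == lv].sum(axis=1) == 0) for lv in levels
        }

        for contrast in pool_contrasts:
            treat = contrast.split("-")[0]
            if treat not in levels:
                raise DesignError(f"contrast {contrast!r}: group {treat!r} not in pool {pool!r}")
            merged = ["t0" if lv == treat else lv for lv in levels]
            red_levels = [lv for lv in levels if lv != treat]
            X_red = _group_design(
                ["t0" if g == treat else g for g in group], red_levels
            )
            _, _, dev_red, _ = _irls(Y, X_red, off2, phi_tag)
            lr = np.maximum(dev_red - dev_full, 0.0)
            p = stats.chi2.sf(lr, 1)
            log2fc = (
                beta_aug[:, levels.index(treat)] - beta_aug[:, levels.index("t0")]
            ) / np.log(2.0)
            flag = np.where(
                group_zero[treat] | group_zero["t0"],
                "degenerate",
                np.where(conv, "", "nonconverged"),
            )
            res = pd.DataFrame(
                {
                    "hairpin_id": filt.hairpin_ids,
                    "pool": pool,
                    "contrast": contrast,
                    "log_cpm": mean_log_cpm,
                    "log2fc": log2fc,
                    "lr": lr,
                    "p": p,
                    "fdr": bh_adjust(p),
                    "phi": phi_tag,
                    "flag": flag,
                }
            )
            if gene_of is not None:
                res.insert(1, "gene", gene_of.reindex(res["hairpin_id"]).to_numpy())
            results.append(res)
    if not results:
        raise DesignError("no pools could be analysed")
    return pd.concat(results, ignore_index=True)
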