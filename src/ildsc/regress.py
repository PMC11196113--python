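"""Weighted regression of GWAS chi-square statistics on LD scores.

Fits ``E[chi^2] = intercept + ell * tau + f * theta`` by iteratively
re-weighted least squares with heteroscedasticity weights
``psi_jj = fitted_j^{-2}`` (floored), block-jackknife standard errors, a
two-sided test of ``theta = 0``, stratified multi-annotation fits and
likelihood-weighted model averaging across window sizes.

Regressors are pre-scaled by ``N/J`` (additive) and ``N/M`` (interaction)
so the reported coefficients sit directly on the variance-explained scale;
``tau_hat``/``theta_hat`` are recovered from them by the inverse scaling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ildsc.genio import SumStats
from ildsc.scores import ScoreTable

log = logging.getLogger(__name__)

PSI_FLOOR = 1.0
DEFAULT_N_BLOCKS = 200
DEFAULT_N_ITER = 2


class SingularDesignError(np.linalg.LinAlgError):
    """Regression design is (numerically) collinear."""


@dataclass
class ILDSCFit:
    """Result of an interaction-LD score regression fit."""

    intercept: float
    tau_hat: float | np.ndarray
    theta_hat: float
    se: dict[str, float] = field(default_factory=dict)
    p_theta: float = float("nan")
    pve_add: float = float("nan")
    pve_int: float = float("nan")
    weights: np.ndarray | None = None
    n_blocks: int = 0
    n_iter: int = DEFAULT_N_ITER
    J_used: int = 0
    M_used: int = 0
    N_mean: float = float("nan")
    log_likelihood: float = float("nan")
    window: int | None = None
    snp_ids: tuple[str, ...] = ()
    ell_names: tuple[str, ...] = ("L2",)

    @property
    def pve_total(self) -> float:
        return self.pve_add + self.pve_int

    def to_dict(self) -> dict:
        tau = self.tau_hat
        return {
            "intercept": self.intercept,
            "tau_hat": tau.tolist() if isinstance(tau, np.ndarray) else tau,
            "theta_hat": self.theta_hat,
            "se": self.se,
            "p_theta": self.p_theta,
            "pve_add": self.pve_add,
            "pve_int": self.pve_int,
            "pve_total": self.pve_total,
            "n_blocks": self.n_blocks,
            "n_iter": self.n_iter,
            "J_used": self.J_used,
            "M_used": self.M_used,
            "window": self.window,
            "log_likelihood": self.log_likelihood,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class ModelAverageResult:
    """Likelihood-weighted average over per-window fits."""

    weights: np.ndarray
    tau_avg: float
    theta_avg: float
    per_window: list[ILDSCFit]


# ---------------------------------------------------------------------------
# Design assembly
# ---------------------------------------------------------------------------

def default_max_chisq(n: float) -> float:
    return max(80.0, 0.001 * n)


def _merge(sumstats: SumStats, scores: ScoreTable) -> pd.DataFrame:
    ss = sumstats.table
    merged = ss.merge(scores.df, left_on="snp", right_on="SNP", how="inner")
    if merged["snp"].duplicated().any():
        raise ValueError("duplicated SNP ids after merge")
    # genomic order for contiguous jackknife blocks
    merged = merged.sort_values(["CHR", "BP"], kind="stable").reset_index(drop=True)
    return merged


def build_design(
    sumstats: SumStats,
    scores: ScoreTable,
    window: int,
    *,
    free_intercept: bool = True,
    max_chisq: float | None = None,
    ell_names: tuple[str, ...] = ("L2",),
) -> dict:
    """Merge, filter outliers and assemble the scaled regression design.

    Columns are ``[1?, N*ell_c/J_used ..., N*f/M]`` so fitted coefficients
    are phenotypic-variance proportions.
    """
    merged = _merge(sumstats, scores)
    n = merged["n"].to_numpy(dtype=float)
    if max_chisq is None:
        max_chisq = default_max_chisq(float(np.mean(n)))
    chisq = merged["chisq"].to_numpy(dtype=float)
    keep = chisq <= max_chisq
    n_out = int((~keep).sum())
    if n_out:
        log.info("filtered %d variants with chi^2 > %.3g", n_out, max_chisq)
    merged = merged.loc[keep].reset_index(drop=True)
    if len(merged) == 0:
        raise ValueError("all variants filtered before fitting")
    n = merged["n"].to_numpy(dtype=float)
    chisq = merged["chisq"].to_numpy(dtype=float)
    j_used = len(merged)
    fcol = f"F_W{window}"
    if fcol not in merged.columns:
        raise KeyError(f"score table has no window {window}")
    cnt = merged[f"CNT_W{window}"].to_numpy(dtype=float)
    m_used = float(cnt.sum())
    if m_used <= 0:
        raise ValueError(f"window {window} has no interaction pairs")
    cols: list[np.ndarray] = []
    names: list[str] = []
    if free_intercept:
        cols.append(np.ones(j_used))
        names.append("intercept")
    for name in ell_names:
        cols.append(n * merged[name].to_numpy(dtype=float) / j_used)
        names.append(name)
    cols.append(n * merged[fcol].to_numpy(dtype=float) / m_used)
    names.append(fcol)
    design = np.column_stack(cols)
    ell_raw = merged["L2"].to_numpy(dtype=float)
    for k, name in enumerate(names):
        if name != "intercept" and np.std(design[:, k]) < 1e-14:
            raise SingularDesignError(f"design column {name!r} is constant")
    return {
        "X": design,
        "y": chisq,
        "ell_raw": ell_raw,
        "names": names,
        "free_intercept": free_intercept,
        "J_used": j_used,
        "M_used": int(m_used),
        "N_mean": float(np.mean(n)),
        "snp_ids": tuple(merged["snp"].tolist()),
        "ell_names": tuple(ell_names),
        "window": window,
    }


# ---------------------------------------------------------------------------
# IRLS core
# ---------------------------------------------------------------------------

def _wls_solve(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    Xw = X * w[:, None]
    xtx = X.T @ Xw
    cond = np.linalg.cond(xtx)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularDesignError(f"collinear design (cond={cond:.3g})")
    return np.linalg.solve(xtx, Xw.T @ y)


def irls(
    X: np.ndarray,
    y: np.ndarray,
    *,
    n_iter: int = DEFAULT_N_ITER,
    free_intercept: bool = True,
    psi_floor: float = PSI_FLOOR,
    init_weights: np.ndarray | None = None,
    overcount: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """IRLS with chi^2-scale variance weights; returns (coef, final psi).

    ``overcount`` (typically the additive LD scores, floored at 1) divides
    the weights to counter double-counting of correlated chi^2 statistics.
    """
    offset = 0.0 if free_intercept else 1.0
    oc = np.ones(len(y)) if overcount is None else np.maximum(overcount, 1.0)
    w = (np.ones(len(y)) if init_weights is None else init_weights) / oc
    coef = _wls_solve(X, y - offset, w)
    for _ in range(n_iter):
        fitted = X @ coef + offset
        w = 1.0 / (np.maximum(fitted, psi_floor) ** 2 * oc)
        coef = _wls_solve(X, y - offset, w)
    return coef, w


def _gaussian_pseudo_loglik(X, y, coef, w, offset) -> float:
    resid = y - offset - X @ coef
    # weights are inverse variances of the working Gaussian model
    return float(-0.5 * np.sum(w * resid**2 - np.log(w) + np.log(2 * np.pi)))


def _fit_from_design(design: dict, n_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    coef, w = irls(
        design["X"], design["y"], n_iter=n_iter,
        free_intercept=design["free_intercept"],
        overcount=design.get("overcount"),
    )
    offset = 0.0 if design["free_intercept"] else 1.0
    ll = _gaussian_pseudo_loglik(design["X"], design["y"], coef, w, offset)
    return coef, w, ll


def _unpack(design: dict, coef: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Split a coefficient vector into (intercept, pve per ell column, pve_f)."""
    k = 0
    if design["free_intercept"]:
        intercept = float(coef[0])
        k = 1
    else:
        intercept = 1.0
    n_ell = len(design["ell_names"])
    pve_ell = coef[k:k + n_ell]
    pve_f = float(coef[k + n_ell])
    return intercept, pve_ell, pve_f


# ---------------------------------------------------------------------------
# Jackknife
# ---------------------------------------------------------------------------

def block_bounds(j: int, n_blocks: int) -> list[tuple[int, int]]:
    """Near-equal contiguous blocks covering range(j)."""
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    edges = np.linspace(0, j, n_blocks + 1).astype(int)
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:]) if b > a]


def _jackknife_cov(design: dict, coef_full: np.ndarray, n_blocks: int, n_iter: int):
    """Delete-m_j block jackknife covariance of the coefficient vector."""
    X, y = design["X"], design["y"]
    j = len(y)
    bounds = block_bounds(j, n_blocks)
    g = len(bounds)
    pseudo = np.empty((g, len(coef_full)))
    hfac = np.empty(g)
    for b, (a, z) in enumerate(bounds):
        mask = np.ones(j, dtype=bool)
        mask[a:z] = False
        sub = dict(design, X=X[mask], y=y[mask])
        if design.get("overcount") is not None:
            sub["overcount"] = design["overcount"][mask]
        try:
            coef_del, _, _ = _fit_from_design(sub, n_iter)
        except SingularDesignError as exc:
            raise SingularDesignError(f"deleting block {b} ({a}:{z}): {exc}") from exc
        h = j / (z - a)
        hfac[b] = h
        pseudo[b] = h * coef_full - (h - 1.0) * coef_del
    centred = pseudo - pseudo.mean(axis=0)
    # Busing et al. delete-m_j variance; reduces to the delete-one form for
    # equal blocks
    cov = (centred.T * (1.0 / (hfac - 1.0))) @ centred / g
    return cov, g


def jackknife(
    sumstats: SumStats,
    scores: ScoreTable,
    window: int,
    *,
    n_blocks: int = DEFAULT_N_BLOCKS,
    n_iter: int = DEFAULT_N_ITER,
    free_intercept: bool = True,
    max_chisq: float | None = None,
    ell_names: tuple[str, ...] = ("L2",),
    overcount_weight: bool = False,
) -> tuple[dict[str, float], float]:
    """Block-jackknife SEs for every coefficient and the two-sided theta p-value."""
    design = build_design(
        sumstats, scores, window, free_intercept=free_intercept,
        max_chisq=max_chisq, ell_names=ell_names,
    )
    if overcount_weight:
        design["overcount"] = design["ell_raw"]
    coef, _, _ = _fit_from_design(design, n_iter)
    cov, _ = _jackknife_cov(design, coef, n_blocks, n_iter)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    se_map = dict(zip(design["names"], se))
    p_theta = _p_from_z(coef[-1], se[-1])
    return se_map, p_theta


def _p_from_z(est: float, se: float) -> float:
    if se == 0:
        return 0.0 if est != 0 else 1.0
    return float(2.0 * sps.norm.sf(abs(est) / se))


# ---------------------------------------------------------------------------
# Public fits
# ---------------------------------------------------------------------------

def fit_ildsc(
    sumstats: SumStats,
    scores: ScoreTable,
    window: int,
    *,
    n_iter: int = DEFAULT_N_ITER,
    free_intercept: bool = True,
    max_chisq: float | None = None,
    n_blocks: int = DEFAULT_N_BLOCKS,
    two_stage: bool = False,
    ell_names: tuple[str, ...] = ("L2",),
    overcount_weight: bool = False,
) -> ILDSCFit:
    """Fit the interaction-LD score regression for one window size.

    ``two_stage=True`` first estimates the intercept on variants with
    chi^2 < 30 and then refits all coefficients with it held fixed.
    ``overcount_weight=True`` additionally divides the regression weights by
    the additive LD score (floored at 1) to counter double-counting of
    correlated chi-square statistics.
    """
    design = build_design(
        sumstats, scores, window, free_intercept=free_intercept,
        max_chisq=max_chisq, ell_names=ell_names,
    )
    if overcount_weight:
        design["overcount"] = design["ell_raw"]
    if design["J_used"] < n_blocks + 3:
        raise ValueError(
            f"only {design['J_used']} variants after merge/filtering; "
            f"need >= n_blocks + 3 = {n_blocks + 3}"
        )
    if two_stage and free_intercept:
        low = design["y"] < 30.0
        if low.sum() < design["X"].shape[1] + 1:
            raise ValueError("two-stage fit: too few variants with chi^2 < 30")
        sub = dict(design, X=design["X"][low], y=design["y"][low])
        if design.get("overcount") is not None:
            sub["overcount"] = design["overcount"][low]
        coef0, _, _ = _fit_from_design(sub, n_iter)
        fixed = float(coef0[0])
        d2 = dict(design, X=design["X"][:, 1:], free_intercept=False)
        d2["y"] = design["y"] - (fixed - 1.0)
        coef_rest, w, ll = _fit_from_design(d2, n_iter)
        coef = np.concatenate([[fixed], coef_rest])
    else:
        coef, w, ll = _fit_from_design(design, n_iter)
    cov, g = _jackknife_cov(design, coef, n_blocks, n_iter)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    se_map = dict(zip(design["names"], se))
    intercept, pve_ell, pve_f = _unpack(design, coef)
    n_mean, j_used, m_used = design["N_mean"], design["J_used"], design["M_used"]
    pve_add = float(np.sum(pve_ell))
    tau = pve_ell * n_mean / j_used
    tau_hat = float(tau[0]) if len(tau) == 1 else tau
    return ILDSCFit(
        intercept=intercept,
        tau_hat=tau_hat,
        theta_hat=pve_f * n_mean / m_used,
        se=se_map,
        p_theta=_p_from_z(coef[-1], se[-1]),
        pve_add=pve_add,
        pve_int=pve_f,
        weights=w,
        n_blocks=g,
        n_iter=n_iter,
        J_used=j_used,
        M_used=m_used,
        N_mean=n_mean,
        log_likelihood=ll,
        window=window,
        snp_ids=design["snp_ids"],
        ell_names=design["ell_names"],
    )


def fit_stratified(
    sumstats: SumStats,
    scores: ScoreTable,
    window: int,
    annotation_names: tuple[str, ...] | None = None,
    **options,
) -> ILDSCFit:
    """Multi-annotation fit: one coefficient per ``L2``/``L2_*`` column plus f."""
    if annotation_names is None:
        annotation_names = tuple(scores.ell_columns())
    return fit_ildsc(sumstats, scores, window, ell_names=annotation_names, **options)


def model_average(fits: list[ILDSCFit]) -> ModelAverageResult:
    """Average per-window fits with softmax likelihood weights."""
    if not fits:
        raise ValueError("need at least one fit")
    ids = fits[0].snp_ids
    for f in fits[1:]:
        if f.snp_ids != ids:
            raise ValueError("fits were computed on different variant sets")
    ll = np.array([f.log_likelihood for f in fits])
    w = np.exp(ll - ll.max())
    w /= w.sum()
    tau = float(sum(wi * np.sum(f.tau_hat) for wi, f in zip(w, fits)))
    theta = float(sum(wi * f.theta_hat for wi, f in zip(w, fits)))
    return ModelAverageResult(weights=w, tau_avg=tau, theta_avg=theta, per_window=fits)
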