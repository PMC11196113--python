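"""Synthetic genotype panels, polygenic traits and analytic oracles.

Genotypes come from a Gaussian-copula AR(1) latent field: each of the two
allele draws per sample is thresholded at the variant's MAF quantile, so
marginals are Bin(2, p) under Hardy-Weinberg equilibrium while adjacent
variants share latent correlation ``ld_decay**distance``.

Traits follow ``y = X beta + W theta + Z gamma + (X_D omega) + eps`` with
every component rescaled in-sample (after orthogonalisation of the
component vectors) so that the realised variance decomposition matches the
configured one exactly and ``V[y] = 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ildsc.genio import GenotypePanel, SumStats, standardize

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n: int,
    j: int,
    ld_decay: float | np.ndarray = 0.9,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed: int | np.random.Generator = 0,
    bp_spacing: int = 1000,
    ld_blocks: tuple[float, float, int] | None = None,
) -> GenotypePanel:
    """AR(1) Gaussian-copula panel with Bin(2, p) marginals under HWE.

    ``ld_decay`` may be a scalar or a length-``j`` vector giving the latent
    correlation of each variant with its left neighbour.  ``ld_blocks =
    (lo, hi, size)`` is a convenience that alternates the decay between
    ``lo`` and ``hi`` in runs of ``size`` variants, mimicking haplotype
    blocks separated by recombination hotspots.
    """
    if ld_blocks is not None:
        lo, hi, size = ld_blocks
        blocks = (np.arange(j) // size) % 2
        ld_decay = np.where(blocks == 0, hi, lo)
    decay = np.broadcast_to(np.asarray(ld_decay, dtype=float), (j,)).copy()
    if np.any((decay < 0) | (decay >= 1)):
        raise ValueError("ld_decay must lie in [0, 1)")
    if not 0 <= maf_low < maf_high <= 0.5:
        raise ValueError("need 0 <= maf_low < maf_high <= 0.5")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    maf = rng.uniform(maf_low, maf_high, size=j)
    thresholds = sps.norm.ppf(maf)
    geno = np.zeros((n, j), dtype=np.int8)
    innov_sd = np.sqrt(1.0 - decay**2)
    for _ in range(2):  # two haplotype draws per sample
        z = np.empty((n, j))
        z[:, 0] = rng.standard_normal(n)
        eps = rng.standard_normal((n, j - 1)) if j > 1 else None
        for col in range(1, j):
            z[:, col] = decay[col] * z[:, col - 1] + innov_sd[col] * eps[:, col - 1]
        geno += (z < thresholds).astype(np.int8)
    bp = (np.arange(j) + 1) * bp_spacing
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "id": [f"rs{i}" for i in range(j)],
            "cm": bp * 1e-6,
            "bp": bp,
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypePanel(genotypes=geno, variants=variants)


# ---------------------------------------------------------------------------
# Interaction architecture
# ---------------------------------------------------------------------------

@dataclass
class PairList:
    """Hub/partner interaction pairs (unordered, deduplicated)."""

    pairs: list[tuple[int, int]]
    group1: np.ndarray
    group2: np.ndarray

    @property
    def M(self) -> int:
        return len(self.pairs)


def assign_interactions(
    panel: GenotypePanel,
    group1_frac: float,
    group2_window_kb: float,
    seed: int | np.random.Generator = 0,
) -> PairList:
    """Sample hub variants and pair each with every neighbour within the window."""
    j = panel.J
    n_hubs = int(round(group1_frac * j))
    if n_hubs < 1:
        raise ValueError("group1_frac * J must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    bp = panel.variants["bp"].to_numpy(dtype=float)
    chrom = panel.variants["chrom"].to_numpy()
    dist = group2_window_kb * 1000.0
    available = list(range(j))
    hubs: list[int] = []
    pairs: set[tuple[int, int]] = set()
    while len(hubs) < n_hubs and available:
        pick = int(rng.choice(len(available)))
        hub = available.pop(pick)
        close = np.flatnonzero((np.abs(bp - bp[hub]) <= dist) & (chrom == chrom[hub]))
        partners = close[close != hub]
        if partners.size == 0:
            log.info("assign_interactions: hub %d has no partners, resampling", hub)
            continue
        hubs.append(hub)
        for k in partners:
            pairs.add((min(hub, int(k)), max(hub, int(k))))
    if len(hubs) < n_hubs:
        raise ValueError("could not place the requested number of hubs")
    hubs_arr = np.array(sorted(hubs))
    group2 = np.array(sorted({k for p in pairs for k in p} - set(hubs)))
    return PairList(pairs=sorted(pairs), group1=hubs_arr, group2=group2)


# ---------------------------------------------------------------------------
# Trait generation
# ---------------------------------------------------------------------------

@dataclass
class TraitConfig:
    """Parameters of the generative trait model."""

    h2: float = 0.6
    rho: float = 1.0
    alpha_effects: float = 0.0
    extra: str = "none"  # none | gxe | gxancestry
    gxe_w: float = 1.5
    k_pcs: int = 10
    var_extra: float = 0.0  # share of phenotypic variance, inside h2
    effect_corr: float = 0.0
    include_dominance: bool = False
    var_dom: float = 0.0
    b0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must lie in [0, 1]")
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must lie in [0, 1]")
        if self.extra not in ("none", "gxe", "gxancestry"):
            raise ValueError(f"unknown extra component {self.extra!r}")
        genetic = self.var_extra + (self.var_dom if self.include_dominance else 0.0)
        if genetic > self.h2 + 1e-12:
            raise ValueError("extra/dominance variance shares exceed h2")

    @property
    def var_add(self) -> float:
        core = self.h2 - self.var_extra - (self.var_dom if self.include_dominance else 0.0)
        return self.rho * core

    @property
    def var_int(self) -> float:
        core = self.h2 - self.var_extra - (self.var_dom if self.include_dominance else 0.0)
        return (1.0 - self.rho) * core


@dataclass
class TraitRealization:
    """Simulated phenotype with ground-truth effects and realised variances."""

    y: np.ndarray
    beta: np.ndarray
    theta: dict[tuple[int, int], float]
    omega: np.ndarray | None
    gamma: np.ndarray | None
    eps: np.ndarray
    realized_var: dict[str, float]
    kept: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _scale_to_var(vec: np.ndarray, target: float) -> tuple[np.ndarray, float]:
    """Rescale so the (1/N) sample variance of ``vec`` equals ``target``."""
    if target == 0:
        return np.zeros_like(vec), 0.0
    v = float(np.mean((vec - vec.mean()) ** 2))
    if v <= 0:
        raise ValueError("component has zero variance; cannot hit target")
    s = np.sqrt(target / v)
    return vec * s, s


def _orthogonalise(vec: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    out = vec - vec.mean()
    for b in basis:
        denom = float(b @ b)
        if denom > 0:
            out = out - (out @ b) / denom * b
    return out


def simulate_trait(
    panel: GenotypePanel,
    pairs: PairList | None,
    config: TraitConfig,
) -> TraitRealization:
    """Generate a unit-variance phenotype with an exact variance decomposition.

    Effects are drawn on the allele-count scale with MAF dependence
    ``(2 p q)^(alpha/2)`` and applied to the standardized panel; component
    vectors are orthogonalised (Gram-Schmidt, in draw order add -> int ->
    extra -> dominance) and rescaled in-sample so each realised variance hits
    its configured share exactly.
    """
    rng = np.random.default_rng(config.seed)
    std = standardize(panel, min_maf=0.0)
    x = std.matrix
    n, j = x.shape
    maf = std.maf
    het = 2.0 * maf * (1.0 - maf)

    # additive: count-scale draws mapped to the standardized scale via the
    # in-sample count sd (missing entries mean-imputed, as in standardize)
    from ildsc.genio import MISSING

    counts = panel.genotypes[:, std.kept].astype(float)
    counts[counts == MISSING] = np.nan
    col_mean = np.nanmean(counts, axis=0)
    inds = np.where(np.isnan(counts))
    counts[inds] = col_mean[inds[1]]
    sd_count = np.sqrt(np.mean((counts - col_mean) ** 2, axis=0))
    # realized count variance as the heterozygosity factor (2pq under exact
    # HWE); alpha = -1 then gives unit per-SNP variance on the standardized
    # scale with no HWE sampling distortion
    het = sd_count**2
    beta_raw = rng.standard_normal(j) * het ** (config.alpha_effects / 2.0)
    g_add_raw = x @ (beta_raw * sd_count)

    basis: list[np.ndarray] = []
    realized: dict[str, float] = {}

    g_add = _orthogonalise(g_add_raw, basis)
    g_add, s_add = _scale_to_var(g_add, config.var_add)
    beta = beta_raw * s_add
    if config.var_add > 0:
        basis.append(g_add)
    realized["add"] = config.var_add

    # pairwise interactions
    theta: dict[tuple[int, int], float] = {}
    g_int = np.zeros(n)
    if config.var_int > 0:
        if pairs is None or pairs.M == 0:
            raise ValueError("rho < 1 requires a non-empty pair list")
        src = {int(v): k for k, v in enumerate(std.kept)}
        cols = []
        kept_pairs = []
        for (a, b) in pairs.pairs:
            if a in src and b in src:
                cols.append(x[:, src[a]] * x[:, src[b]])
                kept_pairs.append((a, b))
        if not cols:
            raise ValueError("no interaction pair survives standardization")
        w_mat = np.column_stack(cols)
        # optionally correlate each pair's draw with its hub's additive draw
        z = rng.standard_normal(len(kept_pairs))
        if config.effect_corr != 0.0:
            r = config.effect_corr
            hub_z = np.array([beta_raw[src[a]] for a, _ in kept_pairs])
            hub_z = hub_z / max(np.std(hub_z), 1e-12)
            z = r * hub_z + np.sqrt(max(1 - r**2, 0.0)) * z
        g_int_raw = w_mat @ z
        g_int = _orthogonalise(g_int_raw, basis)
        g_int, s_int = _scale_to_var(g_int, config.var_int)
        theta = {p: float(zz * s_int) for p, zz in zip(kept_pairs, z)}
        basis.append(g_int)
    realized["int"] = config.var_int

    # extra component: G x E amplification or G x Ancestry
    gamma = None
    g_extra = np.zeros(n)
    if config.var_extra > 0:
        if config.extra == "gxe":
            gamma = rng.standard_normal(j)
            amp = np.ones(n)
            amp[n // 2:] = config.gxe_w  # contiguous half split
            g_extra_raw = (x @ gamma) * amp
        elif config.extra == "gxancestry":
            k = min(config.k_pcs, min(n, j) - 1)
            _, _, vt = np.linalg.svd(x, full_matrices=False)
            zmat = x @ vt[:k].T
            gamma = rng.standard_normal(k)
            g_extra_raw = zmat @ gamma
        else:
            raise ValueError("var_extra > 0 requires extra in {gxe, gxancestry}")
        g_extra = _orthogonalise(g_extra_raw, basis)
        g_extra, s_extra = _scale_to_var(g_extra, config.var_extra)
        gamma = gamma * s_extra
        basis.append(g_extra)
    realized["extra"] = config.var_extra

    # dominance, {0,1,1} encoding standardized
    omega = None
    g_dom = np.zeros(n)
    if config.include_dominance and config.var_dom > 0:
        dom = (panel.genotypes[:, std.kept] >= 1).astype(float)
        dom = dom - dom.mean(axis=0)
        sd = np.sqrt(np.mean(dom**2, axis=0))
        ok = sd > 0
        dom[:, ok] /= sd[ok]
        omega = rng.standard_normal(j)
        omega[~ok] = 0.0
        g_dom = _orthogonalise(dom @ omega, basis)
        g_dom, s_dom = _scale_to_var(g_dom, config.var_dom)
        omega = omega * s_dom
        basis.append(g_dom)
    realized["dom"] = config.var_dom if config.include_dominance else 0.0

    noise_share = 1.0 - config.h2
    eps = _orthogonalise(rng.standard_normal(n), basis)
    eps, _ = _scale_to_var(eps, noise_share)
    realized["noise"] = noise_share

    y = config.b0 + g_add + g_int + g_extra + g_dom + eps
    y = y - y.mean() + config.b0
    return TraitRealization(
        y=y, beta=beta, theta=theta, omega=omega, gamma=gamma, eps=eps,
        realized_var=realized, kept=std.kept,
    )


def sparse_architecture_effects(
    panel: GenotypePanel,
    ell: np.ndarray,
    percentile: float,
    side: str = "top",
    h2: float = 0.6,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Additive effects restricted to an LD-score percentile set.

    Returns a per-variant (standardized-scale) effect vector rescaled so the
    realised additive variance equals ``h2``.
    """
    if side not in ("top", "bottom"):
        raise ValueError("side must be 'top' or 'bottom'")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    std = standardize(panel, min_maf=0.0)
    if len(ell) != std.J:
        raise ValueError("ell must be computed on the same (standardized) panel")
    n_caus = max(int(round(percentile / 100.0 * std.J)), 1)
    order = np.argsort(ell, kind="stable")
    chosen = order[-n_caus:] if side == "top" else order[:n_caus]
    if chosen.size == 0:
        raise ValueError("empty causal selection")
    beta = np.zeros(std.J)
    beta[chosen] = rng.standard_normal(n_caus)
    g = std.matrix @ beta
    g, s = _scale_to_var(g, h2)
    return beta * s


# ---------------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------------

def gwas(
    panel: GenotypePanel,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    drop_variants: set[int] | None = None,
) -> SumStats:
    """Marginal per-SNP regression on the standardized panel.

    ``y`` and each genotype column are residualised on the covariates (with
    intercept) first; ``beta_hat = x'y / x'x`` and ``chisq = N beta_hat^2``.
    ``drop_variants`` indexes the source panel (unobserved-variant scenarios).
    """
    std = standardize(panel, min_maf=0.0)
    x = std.matrix.copy()
    n = std.N
    yv = np.asarray(y, dtype=float)
    if covariates is not None:
        c = np.column_stack([np.ones(n), covariates])
        if np.linalg.matrix_rank(c) < c.shape[1]:
            raise ValueError("covariate matrix is rank-deficient")
        q, _ = np.linalg.qr(c)
        yv = yv - q @ (q.T @ yv)
        x = x - q @ (q.T @ x)
    else:
        yv = yv - yv.mean()
    xtx = np.sum(x * x, axis=0)
    beta_hat = (x.T @ yv) / xtx
    chisq = n * beta_hat**2
    keep = np.ones(std.J, dtype=bool)
    if drop_variants:
        keep = ~np.isin(std.kept, list(drop_variants))
    tab = pd.DataFrame(
        {
            "snp": std.variants["id"].to_numpy()[keep],
            "a1": std.variants["a1"].to_numpy()[keep],
            "a2": std.variants["a2"].to_numpy()[keep],
            "n": n,
            "chisq": chisq[keep],
        }
    )
    return SumStats(table=tab)


# ---------------------------------------------------------------------------
# Analytic oracle
# ---------------------------------------------------------------------------

def additive_variance_bound(
    maf: np.ndarray,
    beta: np.ndarray,
    theta: dict[tuple[int, int], float],
) -> tuple[float, np.ndarray]:
    """Average effects and total additive variance under HWE.

    ``eta_j = beta_j + 2 sum_k p_k theta_jk`` and
    ``sigma_A^2(j) = 2 p_j q_j eta_j^2``; effects are on the allele-count
    scale and ``theta`` is keyed by unordered index pairs.
    """
    maf = np.asarray(maf, dtype=float)
    beta = np.asarray(beta, dtype=float)
    j = len(beta)
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("maf must lie in (0, 0.5]")
    eta = beta.copy()
    for (a, b), t in theta.items():
        if not (0 <= a < j and 0 <= b < j):
            raise IndexError(f"pair ({a}, {b}) out of range for J={j}")
        eta[a] += 2.0 * maf[b] * t
        eta[b] += 2.0 * maf[a] * t
    sigma_per = 2.0 * maf * (1.0 - maf) * eta**2
    return float(sigma_per.sum()), eta
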