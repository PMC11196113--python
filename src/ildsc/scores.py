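"""Additive and cis-interaction LD scores.

The additive score of a focal variant sums squared Pearson correlations with
every variant inside a window (self term included).  The cis-interaction
score sums squared correlations between the focal genotype and the centred,
unit-variance Hadamard product of the focal genotype with each window
neighbour.  Both accept an optional small-sample bias correction and a
MAF-dependent per-variant weight ``(2 p q)^(1+alpha)`` (mean-normalised so
``alpha = -1`` reduces to unweighted scores on standardized genotypes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ildsc.genio import GenotypePanel, StandardizedPanel, effective_cm, standardize

log = logging.getLogger(__name__)

# a Hadamard-product column with (1/N-convention) variance below this is
# treated as constant and the pair is skipped
_VAR_EPS = 1e-12


@dataclass(frozen=True)
class WindowSpec:
    """Half-width window in SNP-count, kb or cM units (inclusive distance)."""

    mode: str
    half_width: float

    def __post_init__(self) -> None:
        if self.mode not in ("snps", "kb", "cm"):
            raise ValueError(f"unknown window mode: {self.mode!r}")
        if self.half_width < 0:
            raise ValueError("half_width must be non-negative")

    @property
    def label(self) -> int:
        return int(self.half_width)


@dataclass
class ScoreTable:
    """Per-variant LD scores backed by a data frame.

    Columns: ``CHR SNP BP MAF L2`` plus one ``F_W{w}`` (cis-interaction
    score) and one ``CNT_W{w}`` (pairs used) column per window label, and
    optionally extra ``L2_{name}`` annotation-stratified columns.
    """

    df: pd.DataFrame
    windows: list[int] = field(default_factory=list)
    n_ref: int = 0

    @property
    def J(self) -> int:
        return len(self.df)

    @property
    def ell(self) -> np.ndarray:
        return self.df["L2"].to_numpy(dtype=float)

    def f(self, window: int) -> np.ndarray:
        return self.df[f"F_W{window}"].to_numpy(dtype=float)

    def pair_count(self, window: int) -> np.ndarray:
        return self.df[f"CNT_W{window}"].to_numpy(dtype=int)

    def M(self, window: int) -> int:
        """Total pair count under the once-per-focal-SNP convention."""
        return int(self.pair_count(window).sum())

    def ell_columns(self) -> list[str]:
        return [c for c in self.df.columns if c == "L2" or c.startswith("L2_")]


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def _chrom_bounds(variants: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Start (inclusive) and stop (exclusive) index of each variant's chromosome."""
    chrom = variants["chrom"].to_numpy()
    j = len(chrom)
    starts = np.empty(j, dtype=np.int64)
    stops = np.empty(j, dtype=np.int64)
    i = 0
    while i < j:
        k = i
        while k < j and chrom[k] == chrom[i]:
            k += 1
        starts[i:k] = i
        stops[i:k] = k
        i = k
    return starts, stops


def _check_sorted(variants: pd.DataFrame) -> None:
    for _, grp in variants.groupby("chrom", sort=False):
        if not grp["bp"].is_monotonic_increasing:
            raise ValueError("variants must be sorted by (chrom, bp)")


class _Windower:
    """Precomputed chromosome bounds and positions for repeated window queries."""

    def __init__(self, variants: pd.DataFrame, spec: WindowSpec):
        _check_sorted(variants)
        self.spec = spec
        self.starts, self.stops = _chrom_bounds(variants)
        if spec.mode == "kb":
            self.pos = variants["bp"].to_numpy(dtype=float)
            self.dist = spec.half_width * 1000.0
        elif spec.mode == "cm":
            self.pos = effective_cm(variants)
            self.dist = spec.half_width
        else:
            self.pos = None
            self.dist = None

    def __call__(self, j: int) -> tuple[int, int]:
        lo_chr, hi_chr = int(self.starts[j]), int(self.stops[j])
        if self.spec.mode == "snps":
            h = int(self.spec.half_width)
            return max(j - h, lo_chr), min(j + h + 1, hi_chr)
        seg = self.pos[lo_chr:hi_chr]
        lo = lo_chr + int(np.searchsorted(seg, self.pos[j] - self.dist, side="left"))
        hi = lo_chr + int(np.searchsorted(seg, self.pos[j] + self.dist, side="right"))
        return lo, hi


def window_indices(variants: pd.DataFrame, j: int, spec: WindowSpec) -> tuple[int, int]:
    """Inclusive-distance window around focal index ``j`` as ``(lo, hi)``.

    Returns a half-open index interval ``[lo, hi)`` on the focal variant's
    chromosome whose members lie within ``spec.half_width`` of the focal
    variant in the spec's unit.  SNP-count mode measures index distance.
    """
    return _Windower(variants, spec)(j)


# ---------------------------------------------------------------------------
# Weights and bias correction
# ---------------------------------------------------------------------------

def maf_weights(maf: np.ndarray, alpha: float, *, schoech_exponent: bool = True) -> np.ndarray:
    """Per-variant weight ``(2 p q)^(1+alpha)``, normalised to unit mean.

    ``schoech_exponent=False`` switches to the ``(2 p q)^(1-alpha)``
    compatibility convention.
    """
    expo = (1.0 + alpha) if schoech_exponent else (1.0 - alpha)
    het = 2.0 * maf * (1.0 - maf)
    w = het**expo
    return w / w.mean()


def _bias_correct(sq: np.ndarray, n: int) -> np.ndarray:
    if n <= 2:
        raise ValueError("bias correction needs N > 2")
    return sq - (1.0 - sq) / (n - 2)


# ---------------------------------------------------------------------------
# Additive LD scores
# ---------------------------------------------------------------------------

def additive_ld_scores(
    panel: StandardizedPanel,
    spec: WindowSpec,
    alpha: float = -1.0,
    annotations: pd.DataFrame | None = None,
    bias_correct: bool = True,
    schoech_exponent: bool = True,
) -> pd.DataFrame:
    """Windowed sum of (weighted, optionally bias-corrected) squared correlations.

    Returns a frame with column ``L2`` and, when ``annotations`` is given,
    one ``L2_{name}`` column per annotation category (terms multiplied by the
    neighbour's annotation value).
    """
    x = panel.matrix
    n, j = x.shape
    win = _Windower(panel.variants, spec)
    w = maf_weights(panel.maf, alpha, schoech_exponent=schoech_exponent)
    annot = None
    if annotations is not None:
        if len(annotations) != j:
            raise ValueError("annotation table length must match panel variants")
        annot = annotations.to_numpy(dtype=float)
    out = np.zeros(j)
    out_annot = np.zeros((j, annot.shape[1])) if annot is not None else None
    for jj in range(j):
        lo, hi = win(jj)
        r = x[:, lo:hi].T @ x[:, jj] / n
        r2 = r**2
        if bias_correct:
            r2 = _bias_correct(r2, n)
        terms = w[lo:hi] * r2
        out[jj] = terms.sum()
        if out_annot is not None:
            out_annot[jj] = terms @ annot[lo:hi]
    res = pd.DataFrame({"L2": out})
    if out_annot is not None:
        for c, name in enumerate(annotations.columns):
            res[f"L2_{name}"] = out_annot[:, c]
    return res


# ---------------------------------------------------------------------------
# cis-interaction LD scores
# ---------------------------------------------------------------------------

def cis_interaction_scores(
    panel: StandardizedPanel,
    spec: WindowSpec,
    alpha: float = -1.0,
    include_self: bool = False,
    bias_correct: bool = True,
    product_moment: bool = False,
    schoech_exponent: bool = True,
) -> pd.DataFrame:
    """Fast-path cis-interaction scores via per-focal inner products.

    For focal variant j and neighbour k the squared sample Pearson
    correlation between x_j and the centred, unit-variance product
    x_j * x_k is

        v^2 = (s_j' x_k / N)^2 / (s_j' s_k / N - r_jk^2),   s_j = x_j * x_j,

    exploiting that x_j is mean-zero unit-variance.  ``product_moment=True``
    instead accumulates the uncentred moment ``(s_j' x_k / N)^2``.  Pairs
    whose product column is (numerically) constant are skipped and logged.
    Returns columns ``F`` (score) and ``CNT`` (pairs used).
    """
    x = panel.matrix
    n, j = x.shape
    win = _Windower(panel.variants, spec)
    w = maf_weights(panel.maf, alpha, schoech_exponent=schoech_exponent)
    s = x * x
    out = np.zeros(j)
    cnt = np.zeros(j, dtype=np.int64)
    skipped = 0
    for jj in range(j):
        lo, hi = win(jj)
        xk = x[:, lo:hi]
        num = s[:, jj] @ xk / n
        if product_moment:
            v2 = num**2
            ok = np.ones(v2.shape, dtype=bool)
        else:
            r = x[:, jj] @ xk / n
            prod_var = s[:, jj] @ s[:, lo:hi] / n - r**2
            ok = prod_var > _VAR_EPS
            v2 = np.zeros(hi - lo)
            v2[ok] = num[ok] ** 2 / prod_var[ok]
        if bias_correct:
            v2[ok] = _bias_correct(v2[ok], n)
        skipped += int((hi - lo) - ok.sum())
        if not include_self and lo <= jj < hi:
            ok[jj - lo] = False
        out[jj] = (w[lo:hi][ok] * v2[ok]).sum()
        cnt[jj] = int(ok.sum())
    if skipped > 0:
        log.info("cis_interaction_scores: skipped %d constant-product pairs", skipped)
    return pd.DataFrame({"F": out, "CNT": cnt})


def cis_interaction_scores_bruteforce(
    panel: StandardizedPanel,
    spec: WindowSpec,
    alpha: float = -1.0,
    include_self: bool = False,
    bias_correct: bool = True,
    schoech_exponent: bool = True,
) -> pd.DataFrame:
    """Reference implementation materialising every interaction column.

    Small panels only: explicitly builds each Hadamard product x_j * x_k,
    standardizes it and correlates with x_j.
    """
    x = panel.matrix
    n, j = x.shape
    win = _Windower(panel.variants, spec)
    w = maf_weights(panel.maf, alpha, schoech_exponent=schoech_exponent)
    out = np.zeros(j)
    cnt = np.zeros(j, dtype=np.int64)
    for jj in range(j):
        lo, hi = win(jj)
        total = 0.0
        used = 0
        for kk in range(lo, hi):
            if kk == jj and not include_self:
                continue
            prod = x[:, jj] * x[:, kk]
            prod = prod - prod.mean()
            sd = np.sqrt(np.mean(prod**2))
            if sd <= np.sqrt(_VAR_EPS):
                continue
            v = float(x[:, jj] @ (prod / sd) / n)
            v2 = v * v
            if bias_correct:
                v2 = v2 - (1.0 - v2) / (n - 2)
            total += w[kk] * v2
            used += 1
        out[jj] = total
        cnt[jj] = used
    return pd.DataFrame({"F": out, "CNT": cnt})


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

DEFAULT_F_WINDOWS = (5, 10, 25, 50)


def compute_scores(
    panel: GenotypePanel,
    specs: list[WindowSpec] | None = None,
    ell_spec: WindowSpec | None = None,
    alpha: float = -1.0,
    min_maf: float = 0.01,
    include_self: bool = False,
    bias_correct: bool = True,
    product_moment: bool = False,
    annotations: pd.DataFrame | None = None,
    schoech_exponent: bool = True,
) -> ScoreTable:
    """Standardize a panel and compute its full score table.

    Defaults: additive scores over a 1 cM window, cis-interaction scores for
    SNP-count windows of +/- 5, 10, 25 and 50.
    """
    if specs is None:
        specs = [WindowSpec("snps", wdt) for wdt in DEFAULT_F_WINDOWS]
    if ell_spec is None:
        ell_spec = WindowSpec("cm", 1.0)
    std = standardize(panel, min_maf=min_maf)
    ell = additive_ld_scores(
        std, ell_spec, alpha=alpha, annotations=annotations,
        bias_correct=bias_correct, schoech_exponent=schoech_exponent,
    )
    df = pd.DataFrame(
        {
            "CHR": std.variants["chrom"].to_numpy(),
            "SNP": std.variants["id"].to_numpy(),
            "BP": std.variants["bp"].to_numpy(),
            "MAF": std.maf,
        }
    )
    for col in ell.columns:
        df[col] = ell[col].to_numpy()
    windows = []
    fparts = []
    for spec in specs:
        part = cis_interaction_scores(
            std, spec, alpha=alpha, include_self=include_self,
            bias_correct=bias_correct, product_moment=product_moment,
            schoech_exponent=schoech_exponent,
        )
        windows.append(spec.label)
        fparts.append(part)
    for wlab, part in zip(windows, fparts):
        df[f"F_W{wlab}"] = part["F"].to_numpy()
    for wlab, part in zip(windows, fparts):
        df[f"CNT_W{wlab}"] = part["CNT"].to_numpy()
    return ScoreTable(df=df, windows=windows, n_ref=std.N)
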