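"""Genotype, summary-statistic and score-table I/O.

PLINK 1 binary panels (``.bed``/``.bim``/``.fam``) are read and written
bit-exactly: SNP-major mode, two bits per genotype, least-significant pair
first, with ``00`` coding two copies of the bim A1 allele, ``10`` one copy,
``11`` zero copies and ``01`` missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -9
"""Sentinel for missing genotype calls in :class:`GenotypePanel`."""

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = 0x01

#: dosage value for each 2-bit PLINK code 0b00..0b11
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
#: inverse map, indexed by dosage (missing handled separately)
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11, MISSING: 0b01}


class PlinkFormatError(ValueError):
    """Malformed .bed payload (bad magic bytes, mode, or byte count)."""


@dataclass
class GenotypePanel:
    """Raw allele-count matrix with variant and sample metadata.

    ``genotypes`` is an ``N x J`` int8 matrix of counts of the A1 allele in
    ``{0, 1, 2, MISSING}``.  ``variants`` carries one row per variant with
    columns ``chrom, id, cm, bp, a1, a2``; ``bp`` must be non-decreasing
    within each chromosome.
    """

    genotypes: np.ndarray
    variants: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        n, j = self.genotypes.shape
        if n < 1 or j < 1:
            raise ValueError(f"degenerate panel: N={n}, J={j}")
        if len(self.variants) != j:
            raise ValueError("variant table length does not match genotype columns")
        if not self.samples:
            self.samples = [f"sample_{i}" for i in range(n)]
        valid = np.isin(self.genotypes, [0, 1, 2, MISSING])
        if not valid.all():
            bad = np.unique(self.genotypes[~valid])
            raise ValueError(f"invalid genotype codes: {bad.tolist()}")
        for _, grp in self.variants.groupby("chrom", sort=False):
            if not grp["bp"].is_monotonic_increasing:
                raise ValueError("bp must be non-decreasing within a chromosome")

    @property
    def N(self) -> int:
        return self.genotypes.shape[0]

    @property
    def J(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class StandardizedPanel:
    """Mean-centred, unit-variance genotype matrix plus per-variant MAF.

    Columns use the divide-by-N variance convention so each retained column
    has exactly unit second moment.  Monomorphic and low-MAF columns from the
    source panel are dropped; ``kept`` maps columns back to source indices.
    """

    matrix: np.ndarray
    maf: np.ndarray
    variants: pd.DataFrame
    samples: list[str]
    kept: np.ndarray

    @property
    def N(self) -> int:
        return self.matrix.shape[0]

    @property
    def J(self) -> int:
        return self.matrix.shape[1]


@dataclass
class SumStats:
    """Per-variant GWAS chi-square statistics with sample sizes.

    Backed by a data frame with columns ``snp, a1, a2, n, chisq`` and
    optionally ``z`` (in which case ``chisq == z**2``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"snp", "a1", "a2", "n", "chisq"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"SumStats missing columns: {sorted(missing)}")
        if (self.table["n"] <= 1).any():
            raise ValueError("sample size N must exceed 1")
        if "z" in self.table.columns:
            z2 = self.table["z"].to_numpy(dtype=float) ** 2
            if not np.allclose(z2, self.table["chisq"].to_numpy(dtype=float), atol=1e-6):
                raise ValueError("chisq inconsistent with z**2")

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# PLINK 1 binary
# ---------------------------------------------------------------------------

def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK 1 binary fileset ``prefix.{bed,bim,fam}``."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "bp", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, j = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes")
    if raw[2] != _BED_SNP_MAJOR:
        raise PlinkFormatError(f"{prefix}.bed: not SNP-major (mode byte {raw[2]:#x})")
    bytes_per_variant = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_variant * j:
        raise PlinkFormatError(
            f"{prefix}.bed: expected {bytes_per_variant * j} payload bytes, "
            f"found {payload.size}"
        )
    blocks = payload.reshape(j, bytes_per_variant)
    # unpack 2-bit codes, least-significant pair first
    codes = np.empty((j, bytes_per_variant * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (blocks >> (2 * shift)) & 0b11
    genotypes = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()
    return GenotypePanel(genotypes=genotypes, variants=bim, samples=fam["iid"].tolist())


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write ``panel`` as a PLINK 1 binary fileset (trailing bits zero)."""
    prefix = Path(prefix)
    n, j = panel.N, panel.J
    bytes_per_variant = (n + 3) // 4
    codes = np.zeros((j, bytes_per_variant * 4), dtype=np.uint8)
    geno = panel.genotypes.T  # variant-major
    for dosage, code in _DOSAGE_TO_CODE.items():
        if code:
            codes[:, :n][geno == dosage] = code
    blocks = np.zeros((j, bytes_per_variant), dtype=np.uint8)
    for shift in range(4):
        blocks |= codes[:, shift::4] << (2 * shift)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(bytes([_BED_SNP_MAJOR]))
        fh.write(blocks.tobytes())
    panel.variants.to_csv(
        prefix.with_suffix(".bim"), sep="\t", header=False, index=False,
        columns=["chrom", "id", "cm", "bp", "a1", "a2"],
    )
    fam = pd.DataFrame(
        {
            "fid": panel.samples,
            "iid": panel.samples,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def standardize(panel: GenotypePanel, min_maf: float = 0.01) -> StandardizedPanel:
    """Mean-impute, centre and scale genotype columns; drop MAF < ``min_maf``.

    MAF is computed from non-missing calls; missing entries are imputed with
    the column mean before centring so that N stays constant per column.
    Scaling uses the divide-by-N standard deviation so retained columns have
    unit second moment.
    """
    if not 0 <= min_maf < 0.5:
        raise ValueError("min_maf must lie in [0, 0.5)")
    geno = panel.genotypes
    mat = geno.astype(np.float64)
    miss = geno == MISSING
    mat[miss] = np.nan
    col_mean = np.nanmean(mat, axis=0)
    # frequency of the A1 allele, then folded
    p_a1 = col_mean / 2.0
    maf = np.minimum(p_a1, 1.0 - p_a1)
    inds = np.where(miss)
    mat[inds] = col_mean[inds[1]]
    centred = mat - col_mean
    sd = np.sqrt(np.mean(centred**2, axis=0))
    keep = (sd > 0) & (maf >= min_maf)
    if not keep.any():
        raise ValueError("all columns dropped during standardization")
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("standardize: dropped %d of %d columns", n_drop, panel.J)
    kept = np.flatnonzero(keep)
    out = centred[:, kept] / sd[kept]
    return StandardizedPanel(
        matrix=out,
        maf=maf[kept],
        variants=panel.variants.iloc[kept].reset_index(drop=True),
        samples=list(panel.samples),
        kept=kept,
    )


def effective_cm(variants: pd.DataFrame) -> np.ndarray:
    """Genetic positions; falls back to bp * 1e-6 when the cM column is all zero."""
    cm = variants["cm"].to_numpy(dtype=float)
    if np.all(cm == 0):
        cm = variants["bp"].to_numpy(dtype=float) * 1e-6
    return cm


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

_SUMSTATS_ALIASES = {
    "snp": "snp", "a1": "a1", "a2": "a2", "n": "n", "z": "z", "chisq": "chisq",
}


def read_sumstats(path: str | Path) -> SumStats:
    """Read whitespace/tab-delimited summary statistics.

    Requires header columns SNP, A1, A2, N and at least one of Z or CHISQ
    (case-insensitive).  Rows with negative or non-finite chi-square are
    dropped and the count logged.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={0: str})
    df.columns = [c.lower() for c in df.columns]
    required = {"snp", "a1", "a2", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sumstats missing required columns: {sorted(missing)}")
    if "chisq" not in df.columns:
        if "z" not in df.columns:
            raise ValueError("sumstats need a Z or CHISQ column")
        df["chisq"] = df["z"].astype(float) ** 2
    chisq = df["chisq"].to_numpy(dtype=float)
    bad = ~np.isfinite(chisq) | (chisq < 0)
    if bad.any():
        log.warning("read_sumstats: dropped %d rows with invalid chi-square", int(bad.sum()))
        df = df.loc[~bad].reset_index(drop=True)
    cols = ["snp", "a1", "a2", "n", "chisq"] + (["z"] if "z" in df.columns else [])
    return SumStats(table=df[cols])


def write_sumstats(stats: SumStats, path: str | Path) -> None:
    df = stats.table.rename(columns=str.upper)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Score tables (TSV)
# ---------------------------------------------------------------------------

def write_scores(table: "ScoreTable", path: str | Path) -> None:  # noqa: F821
    """Write a score table as TSV: CHR SNP BP MAF L2 [annot L2s] F_W* [CNT_W*]."""
    table.df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_scores(path: str | Path) -> "ScoreTable":  # noqa: F821
    from ildsc.scores import ScoreTable  # local import avoids a cycle

    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "SNP": str})
    for col in ("CHR", "SNP", "BP", "MAF", "L2"):
        if col not in df.columns:
            raise ValueError(f"score file missing required column {col}")
    if df["SNP"].duplicated().any():
        dup = df.loc[df["SNP"].duplicated(), "SNP"].iloc[0]
        raise ValueError(f"duplicated SNP id in score file: {dup}")
    windows = [int(c[3:]) for c in df.columns if c.startswith("F_W")]
    n_ref = int(df.attrs.get("n_ref", 0))
    return ScoreTable(df=df, windows=windows, n_ref=n_ref)
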