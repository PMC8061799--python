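"""Chromosome-scale outlier detection: contiguous-gene-block permutation
tests for a per-gene statistic, and read-depth copy-number classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import DepthMatrix, LinePanel


@dataclass
class BlockPermutationResult:
    focal_genes: list[int]
    observed_mean: float
    null_means: np.ndarray
    p_value: float
    side: str  # LOWER or UPPER


@dataclass
class GeneCoverageRecord:
    gene_id: str
    mean_std_depth_d: float
    mean_std_depth_dminus: float
    ratio: float | None       # D_MINUS / D; None when excluded
    category: str             # DELETED, NORMAL, DUPLICATED, EXCLUDED


def block_permutation_test(
    per_gene_stat,
    focal_block,
    block_size: int = 8,
    n_perm: int = 500,
    side: str = "LOWER",
    seed: int | None = None,
    exclude_overlap: bool = False,
) -> BlockPermutationResult:
    """Permutation test of a focal contiguous gene block against random blocks.

    The null distribution is the mean statistic of ``n_perm`` uniformly drawn
    contiguous windows of ``block_size`` genes along the chromosome.  The
    focal window itself is never drawn; windows merely overlapping it are
    allowed unless ``exclude_overlap``.  The p-value uses the add-one
    convention p = (1 + #{null <= observed}) / (n_perm + 1) for LOWER
    (mirrored for UPPER), so p is always positive.
    """
    values = np.asarray(per_gene_stat, dtype=float)
    focal = np.asarray(focal_block, dtype=int)
    if side not in ("LOWER", "UPPER"):
        raise ValueError("side must be LOWER or UPPER")
    if len(focal) != block_size:
        raise ValueError("focal block must contain block_size genes")
    if not np.array_equal(np.sort(focal), np.arange(focal.min(), focal.min() + len(focal))):
        raise ValueError("focal block must be contiguous in map order")
    n = values.size
    if block_size >= n:
        raise ValueError("block_size must be smaller than the chromosome")
    focal_start = int(focal.min())
    starts = np.arange(n - block_size + 1)
    if exclude_overlap:
        keep = (starts + block_size <= focal_start) | (starts >= focal_start + block_size)
        starts = starts[keep]
    else:
        starts = starts[starts != focal_start]
    if starts.size == 0:
        raise ValueError("no permissible null windows")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(starts, size=n_perm, replace=True)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    null_means = (csum[chosen + block_size] - csum[chosen]) / block_size
    observed = float(values[focal].mean())
    if side == "LOWER":
        extreme = int((null_means <= observed).sum())
    else:
        extreme = int((null_means >= observed).sum())
    p = (1 + extreme) / (n_perm + 1)
    return BlockPermutationResult(
        focal_genes=list(map(int, focal)), observed_mean=observed,
        null_means=null_means, p_value=p, side=side,
    )


def standardize_depth(d: DepthMatrix) -> pd.DataFrame:
    """Per-gene per-line mean depth after per-line median standardization.

    Each cell is divided by its line's chromosome-wide median exonic depth
    (computed per chromosome), then averaged over each gene's exonic sites.
    Lines whose median depth is zero on a chromosome are excluded there with
    a warning.  Returns a genes x lines frame (NaN for excluded cells).
    """
    genes = pd.unique(d.sites["gene_id"])
    out = pd.DataFrame(np.nan, index=genes, columns=d.line_ids)
    chrom_arr = d.sites["chrom"].to_numpy()
    gene_arr = d.sites["gene_id"].to_numpy()
    for chrom in pd.unique(d.sites["chrom"]):
        cols = np.flatnonzero(chrom_arr == chrom)
        block = d.depth[:, cols].astype(float)
        med = np.median(block, axis=1)
        zero = med == 0
        if zero.any():
            dropped = [d.line_ids[i] for i in np.flatnonzero(zero)]
            warnings.warn(
                f"lines with zero median depth on {chrom} excluded: {dropped}",
                stacklevel=2,
            )
        std = np.full_like(block, np.nan)
        std[~zero] = block[~zero] / med[~zero, None]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            for gid in pd.unique(gene_arr[cols]):
                gcols = np.flatnonzero((gene_arr == gid) & (chrom_arr == chrom))
                sel = np.searchsorted(cols, gcols)
                if len(sel):
                    out.loc[gid, :] = np.nanmean(std[:, sel], axis=1)
    return out


def classify_coverage_ratio(
    std: pd.DataFrame,
    panel: LinePanel,
    d_exclude_lo: float = 0.5,
    d_exclude_hi: float = 3.0,
) -> list[GeneCoverageRecord]:
    """Classify genes as deleted/duplicated from D_MINUS : D coverage ratios.

    Genes whose D-class mean standardized depth falls outside
    [d_exclude_lo, d_exclude_hi] are EXCLUDED as likely misassembled or
    repetitive.  Otherwise ratio = mean(D_MINUS)/mean(D) with bins:
    [0, 0.25] DELETED, (0.25, 1.75) NORMAL, >= 1.75 DUPLICATED (the upper
    bin is open-ended; the display track it derives from is capped at 2).
    """
    d_lines = [l for l in panel.lines_of_class("D") if l in std.columns]
    dm_lines = [l for l in panel.lines_of_class("D_MINUS") if l in std.columns]
    if not d_lines or not dm_lines:
        raise ValueError("both D and D_MINUS classes must be represented")
    records = []
    for gid in std.index:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN class
            mean_d = float(np.nanmean(std.loc[gid, d_lines]))
            mean_dm = float(np.nanmean(std.loc[gid, dm_lines]))
        if not np.isfinite(mean_d) or mean_d < d_exclude_lo or mean_d > d_exclude_hi:
            records.append(
                GeneCoverageRecord(str(gid), mean_d, mean_dm, None, "EXCLUDED")
            )
            continue
        assert mean_d > 0.0  # guaranteed by the exclusion bounds
        ratio = mean_dm / mean_d
        if ratio <= 0.25:
            cat = "DELETED"
        elif ratio < 1.75:
            cat = "NORMAL"
        else:
            cat = "DUPLICATED"
        records.append(GeneCoverageRecord(str(gid), mean_d, mean_dm, ratio, cat))
    return records
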