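"""Per-gene diversity, divergence, linkage disequilibrium, and bootstrap CIs.

All statistics are missing-data aware: per-site sample sizes are recomputed
from non-missing calls everywhere.  Nucleotide diversity pi is Nei's average
pairwise heterozygosity per site; sites with fewer than two called lines
cannot contribute a pair and are excluded from both the numerator and the
per-gene site denominator (their count is reported back as a flag).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import MISSING, GeneAnnotation, GenotypeMatrix


@dataclass
class GeneDiversityRecord:
    gene_id: str
    region: str
    n_lines_used: float   # mean per-site sample size over usable sites
    n_sites: int          # retained sites in the gene
    n_sites_used: int     # sites with n_s >= 2
    S: int                # segregating sites
    pi: float             # per-site nucleotide diversity
    tajima_d: float | None  # None iff S == 0


@dataclass
class GenePairLD:
    gene_a: str
    gene_b: str
    mean_r2: float
    n_pairs: int


@dataclass
class BootstrapCI:
    mean: float
    lo: float
    hi: float
    n_boot: int

    def __post_init__(self) -> None:
        if not (self.lo <= self.mean <= self.hi):
            raise ValueError("bootstrap interval does not bracket the mean")


# ---------------------------------------------------------------------------
# Site-level helpers
# ---------------------------------------------------------------------------

def site_allele_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Counts of reference and alternate alleles per site (missing excluded)."""
    ref = (calls == 0).sum(axis=0)
    alt = (calls == 1).sum(axis=0)
    return ref, alt


def tajima_constants(n: int) -> dict[str, float]:
    """Standard a1, a2, b1, b2, c1, c2, e1, e2 constants for sample size n."""
    if n < 2:
        raise ValueError("Tajima's D requires n >= 2")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(n: int, S: int, pi_total: float) -> float | None:
    """Tajima's D from sample size, segregating sites, and summed pairwise
    diversity (pi summed over sites, not per site).  None when S == 0."""
    if S == 0:
        return None
    k = tajima_constants(n)
    theta_w = S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:  # degenerate at n = 2: the normalizing variance vanishes
        return None
    return (pi_total - theta_w) / math.sqrt(var)


# ---------------------------------------------------------------------------
# Per-gene statistics
# ---------------------------------------------------------------------------

def gene_diversity(
    g: GenotypeMatrix, gene_id: str | None = None, region: str = "OTHER"
) -> GeneDiversityRecord:
    """Diversity summary for a matrix restricted to one gene.

    pi per site uses per-site sample sizes: at a site with a alt / b ref
    alleles over n_s called lines the pairwise-difference fraction is
    a*b / C(n_s, 2).  Tajima's D uses the gene-mean n_s rounded to the
    nearest integer for its constants (flagged via ``n_lines_used``).
    """
    if g.n_sites == 0:
        raise ValueError("gene_diversity requires at least one site")
    if gene_id is None:
        ids = g.sites["gene_id"].unique()
        gene_id = str(ids[0]) if len(ids) == 1 else "<multi>"
    ref, alt = site_allele_counts(g.calls)
    n_s = ref + alt
    usable = n_s >= 2
    het = np.zeros(g.n_sites)
    u = usable
    het[u] = (ref[u] * alt[u]) / (n_s[u] * (n_s[u] - 1) / 2.0)
    pi_total = float(het.sum())
    n_used = int(usable.sum())
    S = int(((ref > 0) & (alt > 0) & usable).sum())
    pi = pi_total / n_used if n_used else 0.0
    mean_n = float(n_s[usable].mean()) if n_used else 0.0
    d = tajimas_d(max(int(round(mean_n)), 2), S, pi_total) if n_used else None
    return GeneDiversityRecord(
        gene_id=gene_id, region=region, n_lines_used=mean_n,
        n_sites=g.n_sites, n_sites_used=n_used, S=S, pi=pi, tajima_d=d,
    )


def dxy_between_classes(gA: GenotypeMatrix, gB: GenotypeMatrix) -> float | None:
    """Mean between-class pairwise difference per site for one gene.

    Per site, the fraction of mismatching cross-class pairs over
    n_A * n_B called pairs; averaged over sites where both classes have at
    least one call.  None (undefined) when no site is jointly covered.
    """
    if gA.n_sites != gB.n_sites:
        raise ValueError("class matrices must cover the same sites")
    refA, altA = site_allele_counts(gA.calls)
    refB, altB = site_allele_counts(gB.calls)
    nA, nB = refA + altA, refB + altB
    ok = (nA > 0) & (nB > 0)
    if not ok.any():
        return None
    mismatch = refA[ok] * altB[ok] + altA[ok] * refB[ok]
    frac = mismatch / (nA[ok] * nB[ok])
    return float(frac.sum() / ok.sum())


def pairwise_r2(x: np.ndarray, y: np.ndarray, min_joint: int = 4) -> float | None:
    """Squared Pearson correlation of haploid 0/1 codes at two sites.

    Restricted to lines called at both sites; None when fewer than
    ``min_joint`` joint calls or either site is monomorphic among them.
    """
    joint = (x != MISSING) & (y != MISSING)
    if joint.sum() < min_joint:
        return None
    xv = x[joint].astype(float)
    yv = y[joint].astype(float)
    if xv.std() == 0 or yv.std() == 0:
        return None
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def gene_pair_ld(
    g: GenotypeMatrix, genes: list[str] | None = None, min_joint: int = 4
) -> list[GenePairLD]:
    """Mean r^2 over all cross-gene SNP pairs for each gene pair.

    Only sites polymorphic among jointly-called lines contribute; skipped
    pairs are not counted in ``n_pairs``.
    """
    if genes is None:
        genes = list(pd.unique(g.sites["gene_id"]))
    cols = {gid: np.flatnonzero((g.sites["gene_id"] == gid).to_numpy()) for gid in genes}
    out = []
    for ga, gb in itertools.combinations(genes, 2):
        vals = []
        for i in cols[ga]:
            for j in cols[gb]:
                r2 = pairwise_r2(g.calls[:, i], g.calls[:, j], min_joint)
                if r2 is not None:
                    vals.append(r2)
        if vals:
            out.append(GenePairLD(ga, gb, float(np.mean(vals)), len(vals)))
    return out


def reference_match_fraction(
    g: GenotypeMatrix, ref_line: str, min_poly: int = 7
) -> pd.DataFrame:
    """Per line x gene fraction of polymorphic sites matching a reference line.

    A gene is scored for a line only when at least ``min_poly`` of its
    polymorphic sites are genotyped in both that line and the reference;
    otherwise the cell is missing (NaN).
    """
    if ref_line not in g.line_ids:
        raise ValueError(f"reference line {ref_line!r} not in panel")
    ref_idx = g.line_index(ref_line)
    refc, altc = site_allele_counts(g.calls)
    poly = (refc > 0) & (altc > 0)
    genes = list(pd.unique(g.sites["gene_id"]))
    result = pd.DataFrame(np.nan, index=g.line_ids, columns=genes)
    gene_arr = g.sites["gene_id"].to_numpy()
    for gid in genes:
        cols = np.flatnonzero((gene_arr == gid) & poly)
        if cols.size == 0:
            continue
        ref_calls = g.calls[ref_idx, cols]
        for li, line in enumerate(g.line_ids):
            line_calls = g.calls[li, cols]
            scored = (line_calls != MISSING) & (ref_calls != MISSING)
            if scored.sum() < min_poly:
                continue
            result.loc[line, gid] = float(
                (line_calls[scored] == ref_calls[scored]).mean()
            )
    return result


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_mean_ci(
    values, n_boot: int = 1000, level: float = 0.95, seed: int | None = None
) -> BootstrapCI:
    """Percentile bootstrap CI for the mean (n-of-n resampling with
    replacement), deterministic given ``seed``."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("bootstrap requires at least one finite value")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    means = v[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    m = float(v.mean())
    return BootstrapCI(mean=m, lo=min(float(lo), m), hi=max(float(hi), m), n_boot=n_boot)


def bootstrap_se(values, n_boot: int = 1000, seed: int | None = None) -> float:
    """Bootstrap SD of the mean (the SE used in region summary tables)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    return float(v[idx].mean(axis=1).std(ddof=1))


# ---------------------------------------------------------------------------
# Table-style summaries
# ---------------------------------------------------------------------------

def diversity_table(
    g: GenotypeMatrix,
    annotation: GeneAnnotation,
    line_classes: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-gene, per-line-class diversity records plus D vs D_MINUS d_xy.

    ``line_classes`` maps class labels (e.g. "D", "D_MINUS") to line ids.
    Returns a tidy frame with one row per gene x class and a d_xy column
    repeated on each gene's rows (NaN when either class is absent).
    """
    rows = []
    genes = list(pd.unique(g.sites["gene_id"]))
    submatrices = {cls: g.subset_lines(lines) for cls, lines in line_classes.items()}
    for gid in genes:
        region = annotation.region_of(gid)
        per_gene = {cls: sub.for_gene(gid) for cls, sub in submatrices.items()}
        dxy = None
        if "D" in per_gene and "D_MINUS" in per_gene:
            dxy = dxy_between_classes(per_gene["D"], per_gene["D_MINUS"])
        for cls, sub in per_gene.items():
            rec = gene_diversity(sub, gene_id=gid, region=region)
            rows.append(
                dict(
                    gene_id=gid, region=region, line_class=cls,
                    n_sites=rec.n_sites, n_sites_used=rec.n_sites_used,
                    n_lines_used=rec.n_lines_used, S=rec.S, pi=rec.pi,
                    tajima_d=np.nan if rec.tajima_d is None else rec.tajima_d,
                    dxy=np.nan if dxy is None else dxy,
                )
            )
    return pd.DataFrame(rows)


def region_summary(
    table: pd.DataFrame, n_boot: int = 1000, seed: int | None = None
) -> pd.DataFrame:
    """Region x class means of pi with bootstrap SE and percentile CI."""
    rows = []
    for (region, cls), sub in table.groupby(["region", "line_class"]):
        vals = sub["pi"].to_numpy()
        ci = bootstrap_mean_ci(vals, n_boot=n_boot, seed=seed)
        rows.append(
            dict(
                region=region, line_class=cls, n_genes=len(sub),
                mean_pi=ci.mean, se_pi=bootstrap_se(vals, n_boot=n_boot, seed=seed),
                ci_lo=ci.lo, ci_hi=ci.hi,
            )
        )
    return pd.DataFrame(rows)
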