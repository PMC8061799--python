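"""Synthetic inputs with the statistical structure the analyses assume.

Three generators cover the pipeline's inputs end to end, each emitting a
truth record sufficient to score parameter recovery without touching
generator internals:

* :func:`simulate_inbred_panel` - an inbred panel (default 34 lines, 14 of
  them carrying the driving haplotype) with a monomorphic swept interval at
  intermediate frequency, high flanking diversity, sprinkled missing data,
  and a read-depth matrix with a zero-coverage deleted interval in the
  non-driving lines.
* :func:`simulate_swept_flank_haplotypes` - long-range haplotype groups
  around a swept focal gene whose shared-segment genetic length is, by
  construction, exponentially distributed with mean 1/t Morgans (1/(2t) per
  side), the exact inverse of the haplotype-length dating formula.
* :func:`simulate_f2_cross` - a three-parent F2 intercross segregating
  DD_MINUS / Dd at the drive locus, with Haldane-map-function recombination
  along each chromosome, optional planted unlinked modifiers of female
  transmission, and selfed-F3 genotype counts per family.

Background polymorphism is site-i.i.d. with a neutral-like frequency
spectrum, P(derived count = i) proportional to 1/i, so that pairwise
diversity and Watterson's estimator agree in expectation (Tajima's D is
centred on zero under the null).  This is a modelling convenience, not a
coalescent simulation: sites are exchangeable and unlinked given the
planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    MISSING,
    DepthMatrix,
    GeneAnnotation,
    GenotypeMatrix,
    LinePanel,
)
from .drive_qtl import F2Panel

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Inbred panel
# ---------------------------------------------------------------------------

@dataclass
class PanelSimConfig:
    n_lines: int = 34
    d_frequency: float = 14 / 34
    n_genes: int = 60
    gene_length: int = 1200          # bp; genes are single-exon spans
    gene_gap: int = 300
    mdl11_gene_fraction: float = 0.2  # contiguous central block of genes
    sweep_age: float = 1000.0         # generations since the D sweep
    mu: float = 1.0e-8                # per site per generation
    diversity: float = 0.01           # background per-site pi target
    missing_rate: float = 0.10
    deleted_gene_fraction: float = 0.12  # of MDL11 genes, zero depth in D-
    depth_mean: float = 30.0
    depth_noise_sd: float = 0.10      # relative Gaussian depth noise
    het_rate: float = 0.0             # residual heterozygous-call rate
    chrom: str = "chr11"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.d_frequency < 1.0):
            raise ValueError("d_frequency must be in (0, 1)")
        if self.sweep_age < 0:
            raise ValueError("sweep_age must be >= 0")
        if not (0.0 <= self.diversity <= 0.5):
            raise ValueError("diversity target must be in [0, 0.5]")


@dataclass
class PanelTruth:
    config: PanelSimConfig
    d_lines: list[str]
    dminus_lines: list[str]
    mdl11_genes: list[str]
    flanking_genes: list[str]
    deleted_genes: list[str]
    L_mdl11: int                      # exonic positions in the swept interval
    private_mutations: dict[str, int]  # per D line
    poly_fraction_full: float          # site polymorphism prob, full panel
    poly_fraction_dminus: float


def _poly_fraction(pi_target: float, n: int) -> float:
    """Per-site polymorphism probability hitting the pi target under the
    1/i spectrum: E[het | polymorphic] = 1/a1(n), hence q = pi * a1(n)."""
    a1 = sum(1.0 / i for i in range(1, n))
    q = pi_target * a1
    if q > 1.0:
        raise ValueError(
            f"diversity target {pi_target} infeasible for n={n} (q={q:.3f} > 1)"
        )
    return q


def _sfs_counts(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    """Derived-allele counts i in 1..n-1 with P(i) proportional to 1/i."""
    i = np.arange(1, n)
    w = 1.0 / i
    return rng.choice(i, size=size, p=w / w.sum())


def simulate_inbred_panel(
    cfg: PanelSimConfig,
) -> tuple[GenotypeMatrix, GeneAnnotation, DepthMatrix, LinePanel, PanelTruth]:
    """Generate genotypes, annotation, depth, and line classes for a panel
    with a planted sweep; see the module docstring for the model."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_lines
    n_d = int(round(cfg.d_frequency * n))
    if not (0 < n_d < n):
        raise ValueError("d_frequency leaves one class empty")
    line_ids = [f"L{i:03d}" for i in range(n)]
    d_idx = np.sort(rng.choice(n, size=n_d, replace=False))
    d_mask = np.zeros(n, dtype=bool)
    d_mask[d_idx] = True
    d_lines = [line_ids[i] for i in np.flatnonzero(d_mask)]
    dm_lines = [line_ids[i] for i in np.flatnonzero(~d_mask)]

    # gene layout: equal single-exon genes separated by gaps, central MDL11 block
    n_mdl = max(int(round(cfg.mdl11_gene_fraction * cfg.n_genes)), 1)
    first_mdl = (cfg.n_genes - n_mdl) // 2
    starts = 1 + np.arange(cfg.n_genes) * (cfg.gene_length + cfg.gene_gap)
    gene_ids = [f"gene{i:04d}" for i in range(cfg.n_genes)]
    regions = [
        "MDL11" if first_mdl <= i < first_mdl + n_mdl else "FLANKING"
        for i in range(cfg.n_genes)
    ]
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": cfg.chrom,
            "start": starts,
            "end": starts + cfg.gene_length - 1,
            "map_order": np.arange(cfg.n_genes),
            "region": regions,
        }
    )
    exons = {g: [(int(s), int(s) + cfg.gene_length - 1)] for g, s in zip(gene_ids, starts)}
    annotation = GeneAnnotation(genes=genes, exons=exons)
    mdl_genes = [g for g, r in zip(gene_ids, regions) if r == "MDL11"]
    flank_genes = [g for g, r in zip(gene_ids, regions) if r == "FLANKING"]

    # site scaffold: every exonic position, monomorphic included
    pos_blocks, gene_of_site = [], []
    for g, s in zip(gene_ids, starts):
        pos_blocks.append(np.arange(s, s + cfg.gene_length))
        gene_of_site.extend([g] * cfg.gene_length)
    pos = np.concatenate(pos_blocks)
    m = pos.size
    gene_of_site = np.asarray(gene_of_site)
    in_mdl = np.isin(gene_of_site, mdl_genes)
    calls = np.zeros((n, m), dtype=np.int8)

    # background polymorphism
    q_full = _poly_fraction(cfg.diversity, n)
    n_dm = n - n_d
    q_dm = _poly_fraction(cfg.diversity, n_dm) if n_dm >= 2 else 0.0
    flank_cols = np.flatnonzero(~in_mdl)
    poly_flank = flank_cols[rng.random(flank_cols.size) < q_full]
    counts = _sfs_counts(rng, n, poly_flank.size)
    for j, c in zip(poly_flank, counts):
        carriers = rng.choice(n, size=c, replace=False)
        calls[carriers, j] = 1
    mdl_cols = np.flatnonzero(in_mdl)
    poly_mdl = mdl_cols[rng.random(mdl_cols.size) < q_dm]
    dm_idx = np.flatnonzero(~d_mask)
    counts = _sfs_counts(rng, n_dm, poly_mdl.size) if n_dm >= 2 else []
    for j, c in zip(poly_mdl, counts):
        carriers = rng.choice(dm_idx, size=c, replace=False)
        calls[carriers, j] = 1

    # private mutations on the swept haplotype (mutation clock)
    L_mdl = int(in_mdl.sum())
    rate = cfg.mu * L_mdl * cfg.sweep_age
    private = {}
    for li in np.flatnonzero(d_mask):
        k = rng.poisson(rate)
        private[line_ids[li]] = int(k)
        if k:
            hit = rng.choice(mdl_cols, size=k, replace=False)
            calls[li, hit] = 1

    het = np.zeros((n, m), dtype=bool)
    if cfg.het_rate > 0:
        het = rng.random((n, m)) < cfg.het_rate
    miss = rng.random((n, m)) < cfg.missing_rate
    calls[miss | het] = MISSING

    refs = rng.choice(4, size=m)
    alts = (refs + rng.integers(1, 4, size=m)) % 4
    sites = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "pos": pos,
            "ref_allele": _BASES[refs],
            "alt_allele": _BASES[alts],
            "gene_id": gene_of_site,
            "exonic": True,
        }
    )
    matrix = GenotypeMatrix(
        line_ids=line_ids, sites=sites, calls=calls, het_flags=het,
        meta={"generator": "simulate_inbred_panel"},
    )

    # depth matrix: relative Gaussian noise; deleted block ~ zero in D-minus
    n_del = int(round(cfg.deleted_gene_fraction * len(mdl_genes)))
    if cfg.deleted_gene_fraction > 0:
        n_del = max(n_del, 1)
    deleted = mdl_genes[:n_del]
    depth = cfg.depth_mean * (1.0 + rng.normal(0.0, cfg.depth_noise_sd, size=(n, m)))
    in_del = np.isin(gene_of_site, deleted)
    if in_del.any():
        dm_rows = np.flatnonzero(~d_mask)
        depth[np.ix_(dm_rows, np.flatnonzero(in_del))] = cfg.depth_mean * np.abs(
            rng.normal(0.0, 0.05, size=(dm_rows.size, int(in_del.sum())))
        )
    depth = np.clip(np.round(depth), 0, None).astype(int)
    depth_matrix = DepthMatrix(
        line_ids=line_ids,
        sites=sites[["chrom", "pos", "gene_id"]].copy(),
        depth=depth,
    )

    panel = LinePanel(
        pd.DataFrame(
            {
                "line_id": line_ids,
                "haplotype_class": np.where(d_mask, "D", "D_MINUS"),
                "population": "SIM",
            }
        )
    )
    truth = PanelTruth(
        config=cfg, d_lines=d_lines, dminus_lines=dm_lines,
        mdl11_genes=mdl_genes, flanking_genes=flank_genes,
        deleted_genes=deleted, L_mdl11=L_mdl, private_mutations=private,
        poly_fraction_full=q_full, poly_fraction_dminus=q_dm,
    )
    return matrix, annotation, depth_matrix, panel, truth


# ---------------------------------------------------------------------------
# Swept-flank haplotypes
# ---------------------------------------------------------------------------

@dataclass
class FlankTruth:
    true_age: float
    kb_per_cM: float
    group_of_line: dict[str, int]
    segments: dict[int, tuple[int, int]]   # group -> (start, end) bp
    lengths_kb: dict[int, float]
    mean_length_kb: float


def simulate_swept_flank_haplotypes(
    n_lines: int,
    focal_pos: int,
    true_age: float,
    kb_per_cM: float,
    marker_grid,
    seed: int | None = None,
    n_groups: int = 7,
    background_freq: float = 0.5,
    chrom: str = "chr14",
) -> tuple[GenotypeMatrix, FlankTruth]:
    """Haplotype groups sharing exponentially-long segments around a swept
    focal position.

    Each group draws an unbroken shared length per side from an exponential
    with mean 1/(2*true_age) Morgans (total expectation 1/t Morgans) and all
    member lines are identical over that segment; outside it every line
    carries independent background alleles.  With a huge ``true_age`` the
    segments collapse toward the marker spacing.
    """
    if true_age <= 0:
        raise ValueError("true_age must be positive")
    rng = np.random.default_rng(seed)
    markers = np.unique(np.asarray(marker_grid, dtype=np.int64))
    if focal_pos not in markers:
        markers = np.sort(np.append(markers, focal_pos))
    m = markers.size
    bp_per_morgan = kb_per_cM * 1000.0 * 100.0
    if bp_per_morgan / (2 * true_age) < 2 * np.median(np.diff(markers)):
        import warnings

        warnings.warn(
            "marker grid too sparse to resolve expected segment lengths",
            stacklevel=2,
        )
    group_of = rng.integers(0, n_groups, size=n_lines)
    line_ids = [f"L{i:03d}" for i in range(n_lines)]
    backgrounds = (rng.random((n_groups, m)) < background_freq).astype(np.int8)
    backgrounds[:, np.searchsorted(markers, focal_pos)] = 0  # shared swept allele
    segments, lengths = {}, {}
    for gidx in range(n_groups):
        left = rng.exponential(1.0 / (2 * true_age)) * bp_per_morgan
        right = rng.exponential(1.0 / (2 * true_age)) * bp_per_morgan
        start = int(max(markers[0], focal_pos - left))
        end = int(min(markers[-1], focal_pos + right))
        segments[gidx] = (start, end)
        lengths[gidx] = (end - start + 1) / 1000.0
    calls = np.empty((n_lines, m), dtype=np.int8)
    for li in range(n_lines):
        gidx = int(group_of[li])
        start, end = segments[gidx]
        inside = (markers >= start) & (markers <= end)
        row = (rng.random(m) < 0.5).astype(np.int8)
        row[inside] = backgrounds[gidx, inside]
        calls[li] = row
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": markers,
            "ref_allele": "A",
            "alt_allele": "T",
            "gene_id": "flank",
            "exonic": True,
        }
    )
    matrix = GenotypeMatrix(
        line_ids=line_ids, sites=sites, calls=calls,
        het_flags=np.zeros_like(calls, dtype=bool),
        meta={"generator": "simulate_swept_flank_haplotypes"},
    )
    truth = FlankTruth(
        true_age=true_age, kb_per_cM=kb_per_cM,
        group_of_line={line_ids[i]: int(group_of[i]) for i in range(n_lines)},
        segments=segments, lengths_kb=lengths,
        mean_length_kb=float(np.mean(list(lengths.values()))),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# F2 cross
# ---------------------------------------------------------------------------

def _default_cross_map() -> dict[str, np.ndarray]:
    return {f"chr{i}": np.arange(0.0, 101.0, 5.0) for i in range(1, 15)}


@dataclass
class CrossSimConfig:
    n_f2: int = 184
    chrom_map: dict = field(default_factory=_default_cross_map)  # chrom -> cM
    f_Dd: float = 0.98
    f_DDminus: float = 0.58
    modifiers: list = field(default_factory=list)  # (chrom, cM, per-allele effect)
    family_range: tuple[int, int] = (12, 16)
    call_noise: float = 0.05
    miss_rate: float = 0.10
    seed: int | None = None

    def __post_init__(self) -> None:
        for f in (self.f_Dd, self.f_DDminus):
            if not (0.0 <= f <= 1.0):
                raise ValueError("transmission rates must be in [0, 1]")
        lo, hi = self.family_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid family size range")


@dataclass
class CrossTruth:
    config: CrossSimConfig
    mdl11: np.ndarray
    true_f: np.ndarray
    genotypes: np.ndarray              # G-allele dosage per F2 x marker
    modifier_markers: list[int]        # marker indices of planted modifiers


def _simulate_gametes(
    rng: np.random.Generator, n: int, cm_positions: np.ndarray
) -> np.ndarray:
    """n haploid gametes along one chromosome under the Haldane map function."""
    m = cm_positions.size
    out = np.empty((n, m), dtype=np.int8)
    out[:, 0] = rng.random(n) < 0.5
    if m > 1:
        d = np.diff(cm_positions)
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        switches = rng.random((n, m - 1)) < r
        for k in range(1, m):
            out[:, k] = out[:, k - 1] ^ switches[:, k - 1]
    return out


def simulate_f2_cross(cfg: CrossSimConfig) -> tuple[F2Panel, CrossTruth]:
    """Simulate the three-parent drive cross and its selfed-F3 phenotypes.

    The heterospecific F1 mother transmits only the driving allele, so each
    F2 is Dd or DD_MINUS with probability 1/2.  Both F1 parents are
    heterozygous at every genome-wide marker; F2 genotypes arise from two
    independent gametes with Haldane-map recombination.  Each F2's true
    female transmission f is its MDL11-class base rate plus
    (dosage - 1) * effect for every planted modifier, clipped to [0, 1];
    F3 counts are multinomial with probabilities (f/2, 1/2, (1-f)/2) over
    (driver homozygote, heterozygote, other homozygote).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_f2
    marker_rows = []
    geno_blocks = []
    for chrom, cms in cfg.chrom_map.items():
        cms = np.asarray(cms, dtype=float)
        g = _simulate_gametes(rng, n, cms) + _simulate_gametes(rng, n, cms)
        geno_blocks.append(g)
        marker_rows.extend(
            (f"{chrom}_{k:03d}", chrom, float(c)) for k, c in enumerate(cms)
        )
    markers = pd.DataFrame(marker_rows, columns=["marker", "chrom", "cM"])
    geno = np.concatenate(geno_blocks, axis=1)  # G-allele dosage 0/1/2

    mdl11 = np.where(rng.random(n) < 0.5, "Dd", "DD_MINUS")
    f_true = np.where(mdl11 == "Dd", cfg.f_Dd, cfg.f_DDminus).astype(float)
    mod_idx = []
    for chrom, cm, effect in cfg.modifiers:
        sub = markers[markers["chrom"] == chrom]
        if sub.empty:
            raise ValueError(f"modifier chromosome {chrom} not in map")
        j = int((sub["cM"] - cm).abs().idxmin())
        mod_idx.append(j)
        f_true = f_true + effect * (geno[:, j] - 1)
    f_true = np.clip(f_true, 0.0, 1.0)

    fam = rng.integers(cfg.family_range[0], cfg.family_range[1] + 1, size=n)
    f3 = np.empty((n, 3), dtype=int)
    for i in range(n):
        probs = [f_true[i] * 0.5, 0.5, (1.0 - f_true[i]) * 0.5]
        f3[i] = rng.multinomial(fam[i], probs)

    eps = cfg.call_noise
    probs = np.empty((n, len(markers), 3))
    noisy = rng.random((n, len(markers))) < cfg.miss_rate
    for c in range(3):  # true class c maps to dosage 2-c under (GG, NG, NN)
        mask = geno == (2 - c)
        for k in range(3):
            probs[..., k][mask] = (1.0 - eps) if k == c else eps / 2.0
        # uncertain calls: peak below the hardening threshold
        unc = mask & noisy
        for k in range(3):
            probs[..., k][unc] = 0.6 if k == c else 0.2
    panel = F2Panel(
        f2_ids=[f"F2_{i:04d}" for i in range(n)],
        mdl11=mdl11,
        markers=markers,
        probs=probs,
        f3_counts=f3,
        meta={"generator": "simulate_f2_cross"},
    )
    truth = CrossTruth(
        config=cfg, mdl11=mdl11, true_f=f_true, genotypes=geno,
        modifier_markers=mod_idx,
    )
    return panel, truth


# ---------------------------------------------------------------------------
# Writers in the dialects core_io reads
# ---------------------------------------------------------------------------

def write_panel_vcf(g: GenotypeMatrix, path, depth: int = 30) -> None:
    """Write the matrix as an uncompressed VCF 4.2 with GT:DP per sample.

    Haploid calls are emitted as homozygous diploid genotypes; flagged het
    cells as 0/1; missing calls as ./. -- so a read_panel round trip is
    lossless.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in pd.unique(g.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.line_ids)
            + "\n"
        )
        order = np.lexsort((g.sites["pos"].to_numpy(), g.sites["chrom"].to_numpy()))
        for j in order:
            site = g.sites.iloc[j]
            cells = []
            for i in range(g.n_lines):
                if g.het_flags[i, j]:
                    gt = "0/1"
                elif g.calls[i, j] == MISSING:
                    gt = "./."
                else:
                    a = int(g.calls[i, j])
                    gt = f"{a}/{a}"
                cells.append(f"{gt}:{depth}")
            fh.write(
                f"{site['chrom']}\t{site['pos']}\t.\t{site['ref_allele']}\t"
                f"{site['alt_allele']}\t.\tPASS\t.\tGT:DP\t" + "\t".join(cells) + "\n"
            )


def write_depth_tsv(d: DepthMatrix, path) -> None:
    df = pd.DataFrame(d.depth.T, columns=d.line_ids)
    df.insert(0, "pos", d.sites["pos"].to_numpy())
    df.insert(0, "chrom", d.sites["chrom"].to_numpy())
    df.to_csv(path, sep="\t", index=False)
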