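"""Dating selective sweeps from mutation accumulation and haplotype decay.

Two complementary clocks are implemented:

* **Mutation accumulation** on a non-recombining swept haplotype: the Thomson
  estimator t = sum(x_i) / (n * mu * L), where x_i are derived-allele counts
  among n sampled lines over L high-confidence positions.  Generations are
  treated as years (annual plant), and that equivalence is propagated in all
  labels.
* **Haplotype-length decay** around a swept focal gene: a shared haplotype of
  genetic length 1/t Morgans is expected t generations after the sweep began,
  so t = 100 * (kb per cM) / (length in kb).

Both are closed-form; uncertainty is expressed by evaluating over grids of
mutation rates or local recombination rates (no averaging across grid points).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import MISSING, GeneAnnotation, GenotypeMatrix


@dataclass
class DerivedVariantTable:
    """Derived-allele counts relative to the inferred common ancestor."""

    variants: pd.DataFrame  # chrom, pos, gene_id, derived_count, ancestral_allele
    n: int                  # focal lines
    L: int                  # retained high-confidence positions

    @property
    def S(self) -> int:
        return len(self.variants)

    @property
    def sum_x(self) -> int:
        return int(self.variants["derived_count"].sum())


@dataclass
class ThomsonEstimate:
    t_hat: float   # generations (= years)
    n: int
    mu: float
    L: int
    sum_x: int


@dataclass
class HaplotypeSegment:
    member_lines: list[str]
    chrom: str
    start: int
    end: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


@dataclass
class HaplotypeAgeEstimate:
    t: float        # generations (= years)
    length_kb: float
    kb_per_cM: float


@dataclass
class HaplotypeGrouping:
    groups: list[HaplotypeSegment]
    singletons: list[str]
    mean_length_kb: float | None = field(default=None)
    median_length_kb: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.groups:
            lengths = [s.length_kb for s in self.groups]
            self.mean_length_kb = float(np.mean(lengths))
            self.median_length_kb = float(statistics.median(lengths))


# ---------------------------------------------------------------------------
# Mutation-accumulation clock
# ---------------------------------------------------------------------------

def count_derived_variants(
    g: GenotypeMatrix,
    annotation: GeneAnnotation,
    max_het_per_gene: int = 5,
    require_fully_called: bool = False,
) -> DerivedVariantTable:
    """Count derived exonic variants among the focal-class lines.

    Restricted to exonic sites; het-flagged sites are excluded, and genes
    with more than ``max_het_per_gene`` heterozygous exon sites are excluded
    entirely (such genes typically reflect stacked copy-number variants or
    misalignment).  ``L`` is the number of retained positions; with
    ``require_fully_called`` only positions called in every focal line count
    (the high-confidence convention that keeps variant detection and L on
    the same footing under missing data, and hence the Thomson clock
    unbiased).  The ancestral allele at each variant is the majority allele
    among the focal lines, ties broken toward the reference allele.
    """
    exonic = g.sites["exonic"].to_numpy(dtype=bool)
    het_site = g.het_flags.any(axis=0)
    gene_ids = g.sites["gene_id"].to_numpy()
    het_exon_per_gene = pd.Series(gene_ids[exonic & het_site]).value_counts()
    bad_genes = set(het_exon_per_gene[het_exon_per_gene > max_het_per_gene].index)
    keep = exonic & ~het_site & ~np.isin(gene_ids, list(bad_genes))
    if require_fully_called:
        keep &= (g.calls != MISSING).all(axis=0)
    sub = g.subset_sites(keep)
    L = sub.n_sites
    if L == 0:
        raise ValueError("no retained exonic sites; cannot date the haplotype")
    ref = (sub.calls == 0).sum(axis=0)
    alt = (sub.calls == 1).sum(axis=0)
    poly = (ref > 0) & (alt > 0)
    rows = []
    for j in np.flatnonzero(poly):
        # majority allele is ancestral; ties go to the reference allele
        anc_is_ref = ref[j] >= alt[j]
        derived = int(ref[j] if not anc_is_ref else alt[j])
        site = sub.sites.iloc[j]
        rows.append(
            dict(
                chrom=site["chrom"], pos=int(site["pos"]),
                gene_id=site["gene_id"], derived_count=derived,
                ancestral_allele=site["ref_allele"] if anc_is_ref else site["alt_allele"],
            )
        )
    variants = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "gene_id", "derived_count", "ancestral_allele"],
    )
    return DerivedVariantTable(variants=variants, n=g.n_lines, L=L)


def thomson_age(
    table: DerivedVariantTable | int,
    n: int,
    mu: float | np.ndarray,
    L: int,
) -> ThomsonEstimate | list[ThomsonEstimate]:
    """Thomson TMRCA estimate t = sum(x)/(n*mu*L), per mutation rate.

    ``table`` may be a :class:`DerivedVariantTable` or a precomputed
    sum of derived-allele counts.  A sequence of mutation rates returns one
    estimate per rate.  The estimator omits the initial spread of the focal
    haplotype to high frequency and therefore leans young.
    """
    sum_x = table.sum_x if isinstance(table, DerivedVariantTable) else int(table)
    if n < 1 or L <= 0:
        raise ValueError("n >= 1 and L > 0 required")
    if np.ndim(mu) > 0:
        return [thomson_age(sum_x, n, float(m), L) for m in np.asarray(mu).ravel()]
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    return ThomsonEstimate(
        t_hat=sum_x / (n * float(mu) * L), n=n, mu=float(mu), L=L, sum_x=sum_x
    )


# ---------------------------------------------------------------------------
# Haplotype-length clock
# ---------------------------------------------------------------------------

def _informative_match(calls: np.ndarray, max_mismatch: int = 0):
    """Per-site status for a set of lines: +1 match, -1 mismatch, 0 uninformative."""
    called = calls != MISSING
    n_called = called.sum(axis=0)
    status = np.zeros(calls.shape[1], dtype=np.int8)
    informative = n_called >= 2
    # all called lines equal <=> no site has both alleles among called lines
    has0 = ((calls == 0) & called).any(axis=0)
    has1 = ((calls == 1) & called).any(axis=0)
    mism = has0 & has1
    status[informative & ~mism] = 1
    status[informative & mism] = -1
    return status


def shared_core_segment(
    g: GenotypeMatrix,
    lines: list[str],
    focal_pos: int,
    chrom: str | None = None,
    max_mismatch: int = 0,
) -> HaplotypeSegment | None:
    """Maximal span around ``focal_pos`` over which the lines are identical.

    Identity is evaluated at informative SNPs (>= 2 of the lines called; all
    called lines equal).  Segment boundaries sit at the midpoint between the
    last matching and the first mismatching SNP; where no mismatch occurs
    before the end of the data, the boundary is the outermost genotyped SNP.
    Returns None when the informative SNP nearest the focal position already
    mismatches (zero-length signal, not an error).
    """
    if len(lines) < 2:
        raise ValueError("need at least two lines")
    sub = g.subset_lines(lines)
    if chrom is not None:
        sub = sub.subset_sites((sub.sites["chrom"] == chrom).to_numpy())
    else:
        chroms = sub.sites["chrom"].unique()
        if len(chroms) != 1:
            raise ValueError("multiple chromosomes present; pass chrom")
        chrom = str(chroms[0])
    order = np.argsort(sub.sites["pos"].to_numpy(), kind="stable")
    sub = sub.subset_sites(order)
    pos = sub.sites["pos"].to_numpy()
    lo, hi = int(pos.min()), int(pos.max())
    if not (lo <= focal_pos <= hi):
        raise ValueError(f"focal position {focal_pos} outside genotyped range")
    status = _informative_match(sub.calls)
    inf_idx = np.flatnonzero(status != 0)
    if inf_idx.size == 0:
        return HaplotypeSegment(list(lines), chrom, lo, hi)
    inf_pos = pos[inf_idx]
    # informative SNP nearest the focal position
    k = int(np.argmin(np.abs(inf_pos - focal_pos)))
    vals = status[inf_idx]
    if vals[k] == -1:
        return None
    budget = max_mismatch
    i = k
    while i - 1 >= 0 and (vals[i - 1] == 1 or budget > 0):
        if vals[i - 1] == -1:
            budget -= 1
        i -= 1
    j = k
    budget = max_mismatch
    while j + 1 < len(vals) and (vals[j + 1] == 1 or budget > 0):
        if vals[j + 1] == -1:
            budget -= 1
        j += 1
    start = lo if i == 0 else int((inf_pos[i - 1] + inf_pos[i]) // 2) + 1
    end = hi if j == len(vals) - 1 else int((inf_pos[j] + inf_pos[j + 1]) // 2)
    return HaplotypeSegment(list(lines), chrom, start, end)


def _pair_span_markers(
    calls_a: np.ndarray, calls_b: np.ndarray, pos: np.ndarray, focal_pos: int
) -> int:
    """Number of contiguous jointly-called matching markers around focal."""
    joint = (calls_a != MISSING) & (calls_b != MISSING)
    idx = np.flatnonzero(joint)
    if idx.size == 0:
        return 0
    match = calls_a[idx] == calls_b[idx]
    k = int(np.argmin(np.abs(pos[idx] - focal_pos)))
    if not match[k]:
        return 0
    i = k
    while i - 1 >= 0 and match[i - 1]:
        i -= 1
    j = k
    while j + 1 < len(match) and match[j + 1]:
        j += 1
    return j - i + 1


def assign_haplotype_groups(
    g: GenotypeMatrix,
    region: tuple[str, int, int] | None,
    focal_pos: int,
    max_mismatch: int = 0,
    min_group: int = 2,
    min_span_markers: int = 10,
    max_span_shrink: int = 6,
) -> HaplotypeGrouping:
    """Greedy long-range haplotype grouping around a focal position.

    Each group is seeded with an unassigned line; remaining lines are tried
    in decreasing order of their pairwise shared span with the seed.  A
    candidate joins only if it matches the group across its current shared
    span: the joint segment must still cover at least ``min_span_markers``
    genotyped SNPs and may not lose more than ``max_span_shrink`` of the
    markers the group already shares (both guards reject chance background
    matches, which extend over short runs only).  Groups smaller than
    ``min_group`` are reported as singletons.  Mean/median group segment
    lengths summarize the grouping.
    """
    sub = g
    if region is not None:
        chrom, start, end = region
        mask = (
            (g.sites["chrom"] == chrom)
            & (g.sites["pos"] >= start)
            & (g.sites["pos"] <= end)
        ).to_numpy()
        sub = g.subset_sites(mask)
    order = np.argsort(sub.sites["pos"].to_numpy(), kind="stable")
    sub = sub.subset_sites(order)
    pos = sub.sites["pos"].to_numpy()
    chrom = str(sub.sites["chrom"].iloc[0])

    unassigned = list(sub.line_ids)
    groups: list[HaplotypeSegment] = []
    singles: list[str] = []
    while unassigned:
        seed = unassigned.pop(0)
        si = sub.line_index(seed)
        spans = []
        for cand in unassigned:
            ci = sub.line_index(cand)
            m = _pair_span_markers(sub.calls[si], sub.calls[ci], pos, focal_pos)
            if m >= min_span_markers:
                spans.append((m, cand))
        spans.sort(key=lambda t: (-t[0], t[1]))
        members = [seed]
        current_markers = None
        for _, cand in spans:
            trial = members + [cand]
            seg = shared_core_segment(
                sub, trial, focal_pos, chrom=chrom, max_mismatch=max_mismatch
            )
            if seg is None:
                continue
            n_markers = int(((pos >= seg.start) & (pos <= seg.end)).sum())
            if n_markers < min_span_markers:
                continue
            if current_markers is not None and n_markers < current_markers - max_span_shrink:
                continue
            members = trial
            current_markers = n_markers
        if len(members) >= max(min_group, 2):
            seg = shared_core_segment(
                sub, members, focal_pos, chrom=chrom, max_mismatch=max_mismatch
            )
            groups.append(
                HaplotypeSegment(members, chrom, seg.start, seg.end)
            )
            for m in members[1:]:
                unassigned.remove(m)
        else:
            singles.append(seed)
    return HaplotypeGrouping(groups=groups, singletons=singles)


def haplotype_age_from_length(
    length_kb: float | np.ndarray, kb_per_cM: float | np.ndarray
) -> HaplotypeAgeEstimate | list[HaplotypeAgeEstimate]:
    """Sweep age t = 100 * (kb per cM) / (length in kb) generations.

    The shared haplotype's genetic length in Morgans is
    length_kb / (kb_per_cM * 100); its reciprocal is the age.  Sequences for
    either argument produce the Cartesian product of estimates.
    """
    if np.ndim(length_kb) > 0 or np.ndim(kb_per_cM) > 0:
        lens = np.atleast_1d(np.asarray(length_kb, dtype=float))
        rates = np.atleast_1d(np.asarray(kb_per_cM, dtype=float))
        return [
            haplotype_age_from_length(float(l), float(r))
            for l in lens for r in rates
        ]
    if length_kb <= 0 or kb_per_cM <= 0:
        raise ValueError("length_kb and kb_per_cM must be positive")
    return HaplotypeAgeEstimate(
        t=100.0 * kb_per_cM / length_kb, length_kb=float(length_kb),
        kb_per_cM=float(kb_per_cM),
    )
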