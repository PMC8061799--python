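"""Readers, containers, and filtering rules for inbred resequencing panels.

The panel model is a set of highly inbred (effectively haploid) lines genotyped
at biallelic SNPs inside annotated genes.  A residual heterozygous diploid call
is not a valid haploid state: it is recorded as a flag and the call itself is
treated as missing, so that downstream site filters can remove het-contaminated
sites entirely.

Coordinates are 1-based inclusive throughout (VCF/GFF convention).  Missing
genotypes are encoded with the sentinel :data:`MISSING` (-1), never NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel genotype code for a missing call.
MISSING: int = -1

#: Valid haplotype classes for panel lines.
HAPLOTYPE_CLASSES = ("D", "D_MINUS", "UNKNOWN")

#: Valid region labels for genes.
REGIONS = ("MDL11", "FLANKING", "OTHER")

SITE_COLUMNS = ["chrom", "pos", "ref_allele", "alt_allele", "gene_id", "exonic"]


class NoSitesError(ValueError):
    """Raised when a filter removes every site from a genotype matrix."""


class MalformedRecordError(ValueError):
    """Raised for an uninterpretable input record; carries its locus."""


@dataclass
class GeneAnnotation:
    """Gene models with exon structure, map order, and region labels.

    Parameters
    ----------
    genes
        One row per gene with columns ``gene_id``, ``chrom``, ``start``,
        ``end`` (1-based inclusive), ``map_order`` (integer rank along the
        re-ordered chromosome), ``region`` (one of :data:`REGIONS`).
    exons
        Mapping ``gene_id -> [(start, end), ...]`` of 1-based inclusive exon
        intervals contained in the gene span.
    """

    genes: pd.DataFrame
    exons: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        g = self.genes
        missing = {"gene_id", "chrom", "start", "end"} - set(g.columns)
        if missing:
            raise ValueError(f"annotation lacks columns: {sorted(missing)}")
        if "map_order" not in g.columns:
            g = g.assign(map_order=np.arange(len(g)))
        if "region" not in g.columns:
            g = g.assign(region="OTHER")
        if (g["start"] > g["end"]).any():
            bad = g.loc[g["start"] > g["end"], "gene_id"].iloc[0]
            raise ValueError(f"gene {bad}: start > end")
        if not g["gene_id"].is_unique:
            raise ValueError("duplicate gene_id in annotation")
        bad_region = set(g["region"]) - set(REGIONS)
        if bad_region:
            raise ValueError(f"unknown region labels: {sorted(bad_region)}")
        for gid, ivals in self.exons.items():
            row = g.loc[g["gene_id"] == gid]
            if row.empty:
                raise ValueError(f"exons listed for unknown gene {gid}")
            lo, hi = int(row["start"].iloc[0]), int(row["end"].iloc[0])
            for s, e in ivals:
                if not (lo <= s <= e <= hi):
                    raise ValueError(f"exon {s}-{e} outside span of {gid}")
        for chrom, sub in g.groupby("chrom"):
            if not sub["map_order"].is_unique:
                raise ValueError(f"map_order not unique on {chrom}")
        self.genes = g.reset_index(drop=True)
        self._build_index()

    def _build_index(self) -> None:
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.genes.groupby("chrom"):
            sub = sub.sort_values("start")
            self._by_chrom[chrom] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["gene_id"].to_numpy(),
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])

    def gene_at(self, chrom: str, pos: int) -> str | None:
        """Return the gene whose span contains ``pos``, or None."""
        if chrom not in self._by_chrom:
            return None
        starts, ends, ids = self._by_chrom[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and ends[i] >= pos:
            return str(ids[i])
        return None

    def is_exonic(self, gene_id: str, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons.get(gene_id, ()))

    def region_of(self, gene_id: str) -> str:
        row = self.genes.loc[self.genes["gene_id"] == gene_id, "region"]
        if row.empty:
            raise KeyError(gene_id)
        return str(row.iloc[0])

    # -- TSV dialect: exons serialized as "start-end;start-end" ------------

    @classmethod
    def from_tsv(cls, path) -> "GeneAnnotation":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        exons = {}
        for _, row in df.iterrows():
            spans = []
            cell = row.get("exons", "")
            if isinstance(cell, str) and cell:
                for part in cell.split(";"):
                    s, e = part.split("-")
                    spans.append((int(s), int(e)))
            else:
                spans.append((int(row["start"]), int(row["end"])))
            exons[row["gene_id"]] = spans
        genes = df.drop(columns=[c for c in ("exons",) if c in df.columns])
        return cls(genes=genes, exons=exons)

    def to_tsv(self, path) -> None:
        df = self.genes.copy()
        df["exons"] = [
            ";".join(f"{s}-{e}" for s, e in self.exons[g]) for g in df["gene_id"]
        ]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_gff3(cls, path, region_map: dict[str, str] | None = None) -> "GeneAnnotation":
        """Import convenience for GFF3 gene/exon features.

        ``region_map`` optionally assigns region labels by gene_id; unlisted
        genes get OTHER.  Map order is the rank of gene start per chromosome.
        """
        rows, exons, parent_of = [], {}, {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9:
                    raise MalformedRecordError(f"bad GFF3 line: {line[:80]}")
                chrom, _, ftype, start, end, _, _, _, attrs = f[:9]
                adict = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                )
                if ftype == "gene":
                    gid = adict.get("ID") or adict.get("Name")
                    rows.append((gid, chrom, int(start), int(end)))
                    exons.setdefault(gid, [])
                elif ftype in ("mRNA", "transcript"):
                    parent_of[adict.get("ID")] = adict.get("Parent")
                elif ftype == "exon":
                    parent = adict.get("Parent")
                    gid = parent_of.get(parent, parent)
                    exons.setdefault(gid, []).append((int(start), int(end)))
        genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
        order = genes.groupby("chrom")["start"].rank(method="first").astype(int)
        genes["map_order"] = order
        region_map = region_map or {}
        genes["region"] = [region_map.get(g, "OTHER") for g in genes["gene_id"]]
        exons_clean = {}
        for gid, _, s, e in rows:
            ivals = sorted(set(exons.get(gid, [])))
            exons_clean[gid] = ivals or [(s, e)]
        return cls(genes=genes, exons=exons_clean)


@dataclass
class GenotypeMatrix:
    """Lines x biallelic sites, effectively haploid, with explicit missingness.

    ``calls`` holds 0 (reference allele), 1 (alternate allele), or
    :data:`MISSING`.  ``het_flags`` records which cells carried an original
    heterozygous diploid call before haploid collapse (those cells are
    MISSING in ``calls``).
    """

    line_ids: list[str]
    sites: pd.DataFrame
    calls: np.ndarray
    het_flags: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.het_flags = np.asarray(self.het_flags, dtype=bool)
        n, m = len(self.line_ids), len(self.sites)
        if self.calls.shape != (n, m) or self.het_flags.shape != (n, m):
            raise ValueError(
                f"shape mismatch: {n} lines x {m} sites vs calls "
                f"{self.calls.shape}, het_flags {self.het_flags.shape}"
            )
        ok = np.isin(self.calls, (0, 1, MISSING))
        if not ok.all():
            raise ValueError("calls must be 0, 1, or MISSING")
        if (self.sites["pos"] < 1).any():
            raise ValueError("positions are 1-based; pos >= 1 required")
        if len(set(self.line_ids)) != n:
            raise ValueError("duplicate line ids")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def line_index(self, line_id: str) -> int:
        return self.line_ids.index(line_id)

    def subset_sites(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            sites=self.sites.iloc[idx],
            calls=self.calls[:, idx],
            het_flags=self.het_flags[:, idx],
            meta=dict(self.meta),
        )

    def subset_lines(self, line_ids) -> "GenotypeMatrix":
        idx = [self.line_index(l) for l in line_ids]
        return replace(
            self,
            line_ids=list(line_ids),
            calls=self.calls[idx],
            het_flags=self.het_flags[idx],
            meta=dict(self.meta),
        )

    def for_gene(self, gene_id: str) -> "GenotypeMatrix":
        return self.subset_sites((self.sites["gene_id"] == gene_id).to_numpy())

    def site_sample_sizes(self) -> np.ndarray:
        """Per-site count of non-missing calls (n_s)."""
        return (self.calls != MISSING).sum(axis=0)


@dataclass
class DepthMatrix:
    """Per-line read depth at exonic sites (CNV path; no depth masking)."""

    line_ids: list[str]
    sites: pd.DataFrame  # chrom, pos, gene_id
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError("negative read depth")
        if self.depth.shape != (len(self.line_ids), len(self.sites)):
            raise ValueError("depth shape mismatch")
        self.sites = self.sites.reset_index(drop=True)


@dataclass
class LinePanel:
    """Line metadata: haplotype class (D / D_MINUS / UNKNOWN) and population."""

    table: pd.DataFrame  # line_id, haplotype_class, population

    def __post_init__(self) -> None:
        t = self.table
        if not t["line_id"].is_unique:
            raise ValueError("duplicate line_id in panel table")
        bad = set(t["haplotype_class"]) - set(HAPLOTYPE_CLASSES)
        if bad:
            raise ValueError(f"unknown haplotype classes: {sorted(bad)}")
        self.table = t.reset_index(drop=True)

    def lines_of_class(self, haplotype_class: str) -> list[str]:
        t = self.table
        return list(t.loc[t["haplotype_class"] == haplotype_class, "line_id"])

    @classmethod
    def from_tsv(cls, path) -> "LinePanel":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _collapse_diploid(a: int, b: int) -> tuple[int, bool]:
    """Collapse a diploid GT to a haploid code; returns (call, is_het)."""
    if a < 0 or b < 0:
        return MISSING, False
    if a != b:
        return MISSING, True
    return (0 if a == 0 else 1), False


def read_panel(vcf_source, annotation: GeneAnnotation, min_depth: int = 3) -> GenotypeMatrix:
    """Read a multi-sample VCF into a haploid genotype matrix.

    Keeps biallelic SNPs inside annotated genes; drops indels and
    multi-allelic records (counted in ``meta``); converts genotypes covered
    by fewer than ``min_depth`` reads to missing data; records original
    heterozygous calls in ``het_flags``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_source))
    line_ids = list(vcf.samples)
    rows, call_cols, het_cols = [], [], []
    dropped = {"indel": 0, "multiallelic": 0, "intergenic": 0, "no_alt": 0}
    for var in vcf:
        locus = f"{var.CHROM}:{var.POS}"
        if var.ALT is None or len(var.ALT) == 0:
            dropped["no_alt"] += 1
            continue
        if len(var.ALT) > 1:
            dropped["multiallelic"] += 1
            continue
        if not var.is_snp:
            dropped["indel"] += 1
            continue
        gene = annotation.gene_at(var.CHROM, var.POS)
        if gene is None:
            dropped["intergenic"] += 1
            continue
        gts = var.genotypes
        if gts is None or len(gts) != len(line_ids):
            raise MalformedRecordError(f"bad genotype block at {locus}")
        dp = var.format("DP")
        depths = (
            dp.reshape(-1) if dp is not None
            else np.full(len(line_ids), -1)
        )  # negative = unknown, passes through unmasked
        calls = np.empty(len(line_ids), dtype=np.int8)
        hets = np.zeros(len(line_ids), dtype=bool)
        for i, gt in enumerate(gts):
            alleles = gt[:-1]
            if len(alleles) == 1:  # haploid record
                a = b = alleles[0]
            else:
                a, b = alleles[0], alleles[1]
            call, is_het = _collapse_diploid(a, b)
            hets[i] = is_het
            if call != MISSING and 0 <= depths[i] < min_depth:
                call = MISSING
            calls[i] = call
        rows.append(
            (var.CHROM, var.POS, var.REF, var.ALT[0], gene,
             annotation.is_exonic(gene, var.POS))
        )
        call_cols.append(calls)
        het_cols.append(hets)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    n_dropped = sum(dropped.values())
    if n_dropped:
        logger.info("read_panel dropped %d records: %s", n_dropped, dropped)
    calls = (
        np.stack(call_cols, axis=1) if call_cols
        else np.empty((len(line_ids), 0), dtype=np.int8)
    )
    hets = (
        np.stack(het_cols, axis=1) if het_cols
        else np.empty((len(line_ids), 0), dtype=bool)
    )
    return GenotypeMatrix(
        line_ids=line_ids, sites=sites, calls=calls, het_flags=hets,
        meta={"dropped": dropped, "min_depth": min_depth},
    )


def apply_inbred_site_filters(g: GenotypeMatrix, min_lines: int = 10) -> GenotypeMatrix:
    """Site-level filters for the inbred panel, in the documented order.

    First removes every site carrying at least one (flagged) heterozygous
    call, then removes sites with fewer than ``min_lines`` non-missing calls.
    Rule attribution in ``meta['filter_log']`` reflects that order: a site
    failing both rules is charged to the het rule.
    """
    het_sites = g.het_flags.any(axis=0)
    n_called = g.site_sample_sizes()
    low_call = (~het_sites) & (n_called < min_lines)
    keep = ~(het_sites | low_call)
    out = g.subset_sites(keep)
    out.meta.setdefault("filter_log", {}).update(
        het_sites_removed=int(het_sites.sum()),
        low_call_sites_removed=int(low_call.sum()),
        min_lines=min_lines,
    )
    if out.n_sites == 0 and g.n_sites > 0:
        raise NoSitesError("no sites survive inbred site filters")
    return out


def apply_gene_filters(
    g: GenotypeMatrix, annotation: GeneAnnotation, min_sites: int = 150
) -> tuple[GenotypeMatrix, pd.Series]:
    """Drop genes with fewer than ``min_sites`` retained sites.

    Returns the filtered matrix and the per-gene retained-site counts of the
    *kept* genes.
    """
    known = set(annotation.gene_ids)
    referenced = set(g.sites["gene_id"])
    unknown = referenced - known
    if unknown:
        raise ValueError(f"sites reference genes absent from annotation: {sorted(unknown)[:5]}")
    counts = g.sites["gene_id"].value_counts()
    kept_genes = counts[counts >= min_sites]
    keep = g.sites["gene_id"].isin(kept_genes.index).to_numpy()
    out = g.subset_sites(keep)
    out.meta.setdefault("filter_log", {}).update(
        genes_dropped=int((counts < min_sites).sum()), min_sites=min_sites
    )
    return out, kept_genes.sort_index()


def read_depth_matrix(depth_source, annotation: GeneAnnotation) -> DepthMatrix:
    """Read a site x line depth TSV, restricted to exonic sites.

    The copy-number path deliberately applies no minimum-depth masking and
    tolerates missing genotype data; depth values pass through verbatim.
    """
    df = (
        depth_source
        if isinstance(depth_source, pd.DataFrame)
        else pd.read_csv(depth_source, sep="\t", dtype={"chrom": str})
    )
    line_cols = [c for c in df.columns if c not in ("chrom", "pos")]
    genes, exonic = [], []
    for chrom, pos in zip(df["chrom"], df["pos"]):
        gid = annotation.gene_at(chrom, int(pos))
        genes.append(gid)
        exonic.append(gid is not None and annotation.is_exonic(gid, int(pos)))
    mask = np.asarray(exonic)
    sites = pd.DataFrame(
        {"chrom": df["chrom"], "pos": df["pos"], "gene_id": genes}
    ).loc[mask]
    depth = df.loc[mask, line_cols].to_numpy().T
    if (depth < 0).any():
        raise ValueError("negative read depth in input")
    return DepthMatrix(line_ids=line_cols, sites=sites, depth=depth)
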