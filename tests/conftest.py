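"""Shared fixtures: tiny annotations, toy VCFs, and matrix builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from centrodrive.core_io import MISSING, GeneAnnotation, GenotypeMatrix


def make_annotation(genes):
    """Annotation from (gene_id, chrom, start, end) tuples; single full-span
    exon per gene unless an exon list is appended as a 5th element."""
    rows, exons = [], {}
    for spec in genes:
        gid, chrom, start, end = spec[:4]
        rows.append((gid, chrom, start, end))
        exons[gid] = spec[4] if len(spec) > 4 else [(start, end)]
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    df["map_order"] = df.groupby("chrom").cumcount()
    df["region"] = "OTHER"
    return GeneAnnotation(genes=df, exons=exons)


def make_matrix(calls, positions=None, chrom="chr1", gene_id="g1",
                het_flags=None, exonic=True, line_ids=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = np.arange(1, m + 1)
    if np.isscalar(gene_id):
        gene_id = [gene_id] * m
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions),
            "ref_allele": "A",
            "alt_allele": "T",
            "gene_id": gene_id,
            "exonic": exonic,
        }
    )
    if het_flags is None:
        het_flags = np.zeros_like(calls, dtype=bool)
    if line_ids is None:
        line_ids = [f"L{i}" for i in range(n)]
    return GenotypeMatrix(
        line_ids=line_ids, sites=sites, calls=calls,
        het_flags=np.asarray(het_flags, dtype=bool),
    )


def write_vcf(path, samples, records):
    """Write a minimal VCF.  Each record is (chrom, pos, ref, alt_field,
    [(gt, dp), ...]) with gt like '0/0', './.', '0/1'."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n')
        chroms = sorted({r[0] for r in records})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for chrom, pos, ref, alt, cells in records:
            body = "\t".join(f"{gt}:{dp}" for gt, dp in cells)
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:DP\t{body}\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def basic_annotation():
    return make_annotation([("g1", "chr1", 1, 1000), ("g2", "chr1", 2001, 3000)])


MISSING_ = MISSING  # re-export convenience
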