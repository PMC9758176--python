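"""VCF / BED / TSV input-output for genotype matrices and IBD segments.

VCF v4.2 is the sole genotype interchange format (read and written with
pysam). Only biallelic SNVs are kept: multiallelic or non-SNV records are
skipped and counted on the returned matrix (``n_skipped``). Unphased "/"
and phased "|" separators are both accepted; phase is discarded. BED
export follows the 0-based half-open convention (bed start = VCF position
- 1)."""

from __future__ import annotations

import logging
from os import PathLike
from typing import Iterable, Sequence

import numpy as np
import pysam

from .ibd import IBDSegment, segment_span_kb
from .matrix import MISSING, GenotypeMatrix

log = logging.getLogger("founderhap")

_CODE_OF = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}


def read_vcf(path: str | PathLike) -> GenotypeMatrix:
    """Read a minimal GT-only VCF into a genotype matrix.

    Multiallelic and non-SNV records are skipped with a logged warning;
    the count is available as ``matrix.n_skipped``.
    """
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        chroms, poss, refs, alts = [], [], [], []
        rows = []
        skipped = 0
        for rec in vf:
            alleles = rec.alts or ()
            if len(alleles) != 1 or len(rec.ref) != 1 or len(alleles[0]) != 1:
                skipped += 1
                log.warning(
                    "skipping non-biallelic-SNV record %s:%s", rec.chrom, rec.pos
                )
                continue
            codes = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT", (None, None))
                if gt is None or None in gt or len(gt) != 2:
                    codes[i] = MISSING
                else:
                    codes[i] = _CODE_OF[tuple(gt)]
            chroms.append(rec.chrom)
            poss.append(rec.pos)
            refs.append(rec.ref)
            alts.append(alleles[0])
            rows.append(codes)
    codes2 = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        samples=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        codes=codes2,
        n_skipped=skipped,
    )


def write_vcf(gm: GenotypeMatrix, path: str | PathLike) -> None:
    """Write a genotype matrix as uncompressed VCF v4.2 (deterministic)."""
    header = pysam.VariantHeader()
    for chromosome in gm.chromosomes():
        sl = gm.chrom_slice(chromosome)
        length = int(gm.pos[sl].max()) + 1000 if sl.stop > sl.start else 1000
        header.contigs.add(chromosome, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in gm.samples:
        header.add_sample(s)
    gt_of = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j in range(gm.n_sites):
            rec = vf.new_record(
                contig=str(gm.chrom[j]),
                start=int(gm.pos[j]) - 1,
                stop=int(gm.pos[j]),
                alleles=(str(gm.ref[j]), str(gm.alt[j])),
            )
            for i, s in enumerate(gm.samples):
                rec.samples[s]["GT"] = gt_of[int(gm.codes[i, j])]
                rec.samples[s].phased = False
            vf.write(rec)


def write_segments_bed(segs: Iterable[IBDSegment], path: str | PathLike) -> None:
    """BED6: chrom, start-1, end, pair name, score = n_markers, strand '.'."""
    with open(path, "w") as fh:
        for s in segs:
            name = "|".join(s.pair)
            fh.write(
                f"{s.chromosome}\t{s.start - 1}\t{s.end}\t{name}\t{s.n_markers}\t.\n"
            )


def write_segments_tsv(segs: Iterable[IBDSegment], path: str | PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(
            "pair\tchromosome\tstart\tend\tspan_bp\tspan_kb\tn_markers\tn_mismatches\n"
        )
        for s in segs:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        "|".join(s.pair),
                        s.chromosome,
                        s.start,
                        s.end,
                        s.span_bp,
                        segment_span_kb(s),
                        s.n_markers,
                        s.n_mismatches,
                    )
                )
                + "\n"
            )


def write_calls_tsv(calls: Sequence, path: str | PathLike) -> None:
    """Haplotype calls as TSV (sample, diplotype, reason)."""
    with open(path, "w") as fh:
        fh.write("sample\tdiplotype\treason\n")
        for c in calls:
            fh.write(f"{c.sample}\t{c.diplotype}\t{c.reason}\n")
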