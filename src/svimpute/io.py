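"""Reading and writing the pipeline's file formats.

VCF 4.2 via pysam/htslib: phased-GT panel files, single-sample evidence
files with log10-scaled GL and/or integer PL triples, and imputed files
with GT and GP.  Coordinates are 1-based inclusive; SV records carry
SVTYPE and END.  Chunk lists, genetic maps and truth tables are
tab-separated text.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .sites import Chunk
from .types import (
    SNV,
    SV_CLASSES,
    HaplotypePanel,
    ImputedRecord,
    SiteLikelihoods,
    TrueGenotypes,
    Variant,
)

_SV_ALT = {cls: f"<{cls}>" for cls in SV_CLASSES}


def _base_header(
    chrom: str, chrom_length: int, seed: Optional[int]
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={chrom},length={chrom_length}>")
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">')
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    if seed is not None:
        header.add_line(f"##svimpute_seed={int(seed)}")
    return header


def _new_record(
    vcf: pysam.VariantFile, v: Variant
) -> pysam.VariantRecord:
    if v.var_class == SNV:
        rec = vcf.new_record(contig=v.chrom, start=v.pos - 1, alleles=("A", "C"), id=v.id)
    else:
        rec = vcf.new_record(
            contig=v.chrom, start=v.pos - 1, alleles=("N", _SV_ALT[v.var_class]), id=v.id
        )
        rec.info["SVTYPE"] = v.var_class
        # END (1-based inclusive) defines the interval; SVLEN is omitted
        # because htslib would re-derive END from it under the END = POS +
        # SVLEN convention, which is not the inclusive-length convention here.
        rec.stop = v.end
    return rec


def write_panel_vcf(
    panel: HaplotypePanel,
    path,
    chrom_length: Optional[int] = None,
    seed: Optional[int] = None,
) -> None:
    """Write a phased reference panel as an uncompressed VCF."""
    chrom = panel.variants[0].chrom if panel.variants else "chr1"
    length = chrom_length or (max(v.end for v in panel.variants) if panel.variants else 1)
    header = _base_header(chrom, length, seed)
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in panel.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for m, v in enumerate(panel.variants):
            rec = _new_record(vcf, v)
            for i, s in enumerate(panel.samples):
                rec.samples[s]["GT"] = (
                    int(panel.haplotypes[2 * i, m]),
                    int(panel.haplotypes[2 * i + 1, m]),
                )
                rec.samples[s].phased = True
            vcf.write(rec)


def _variant_from_record(rec: pysam.VariantRecord) -> Variant:
    where = f"{rec.chrom}:{rec.pos}"
    if rec.alts is None or len(rec.alts) != 1:
        raise ValueError(f"record at {where} is not biallelic")
    alt = rec.alts[0]
    svtype = rec.info.get("SVTYPE")
    if alt.startswith("<") or svtype:
        cls = svtype or alt.strip("<>")
        if cls not in SV_CLASSES:
            raise ValueError(f"record at {where}: unsupported SV class {cls!r}")
        end = rec.stop  # pysam stop is the 1-based inclusive end
        if end <= rec.pos:
            raise ValueError(f"SV record at {where} lacks a usable END")
        return Variant(rec.id or f"{where}", rec.chrom, rec.pos, end, cls)
    return Variant(rec.id or f"{where}", rec.chrom, rec.pos, rec.pos, SNV)


def read_panel_vcf(path) -> HaplotypePanel:
    """Read a phased panel VCF; rejects unphased or multi-allelic records."""
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            v = _variant_from_record(rec)
            col = np.empty(2 * len(samples), dtype=np.uint8)
            for i, s in enumerate(samples):
                call = rec.samples[s]
                gt = call["GT"]
                if gt is None or None in gt or len(gt) != 2 or not call.phased:
                    raise ValueError(
                        f"record at {rec.chrom}:{rec.pos} sample {s}: "
                        "genotype must be phased diploid"
                    )
                col[2 * i], col[2 * i + 1] = gt
            variants.append(v)
            columns.append(col)
    H = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((2 * len(samples), 0), dtype=np.uint8)
    )
    return HaplotypePanel(H, samples, variants)


def write_evidence_vcf(
    evidence: Mapping[str, SiteLikelihoods],
    variants: Sequence[Variant],
    sample: str,
    path,
    chrom_length: Optional[int] = None,
    seed: Optional[int] = None,
) -> None:
    """Write single-sample GL/PL evidence; missing sites keep '.' fields."""
    vlist = [v for v in variants if v.id in evidence]
    chrom = vlist[0].chrom if vlist else "chr1"
    length = chrom_length or (max(v.end for v in vlist) if vlist else 1)
    header = _base_header(chrom, length, seed)
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=GL,Number=G,Type=Float,Description="log10 genotype likelihoods">'
    )
    header.add_line(
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled likelihoods">'
    )
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in vlist:
            site = evidence[v.id]
            rec = _new_record(vcf, v)
            rec.samples[sample]["GT"] = (None, None)
            if not site.missing:
                if site.gl is not None:
                    with np.errstate(divide="ignore"):
                        log10 = np.log10(site.gl / site.gl.max())
                    rec.samples[sample]["GL"] = tuple(
                        float(max(x, -99.0)) for x in log10
                    )
                if site.pl is not None:
                    rec.samples[sample]["PL"] = tuple(int(x) for x in site.pl)
            vcf.write(rec)


def read_evidence_vcf(path) -> tuple[dict[str, SiteLikelihoods], list[Variant]]:
    """Read a single-sample evidence VCF back into likelihood records."""
    out: dict[str, SiteLikelihoods] = {}
    variants: list[Variant] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValueError("evidence VCF must have exactly one sample")
        for rec in vcf:
            v = _variant_from_record(rec)
            variants.append(v)
            call = rec.samples[samples[0]]
            gl = call.get("GL")
            pl = call.get("PL")
            if gl is not None and gl[0] is not None:
                out[v.id] = SiteLikelihoods(
                    v.id, gl=np.power(10.0, np.asarray(gl, dtype=float))
                )
            elif pl is not None and pl[0] is not None:
                out[v.id] = SiteLikelihoods(v.id, pl=np.asarray(pl, dtype=int))
            else:
                out[v.id] = SiteLikelihoods(v.id, missing=True)
    return out, variants


def write_imputed_vcf(
    records: Sequence[ImputedRecord],
    sample: str,
    path,
    chrom_length: Optional[int] = None,
    pp_cutoff: Optional[float] = None,
    seed: Optional[int] = None,
) -> None:
    """Write imputed genotypes with GT and GP; below-cutoff calls are './.'."""
    chrom = records[0].variant.chrom if records else "chr1"
    length = chrom_length or (max(r.variant.end for r in records) if records else 1)
    header = _base_header(chrom, length, seed)
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype posteriors">'
    )
    header.add_line('##FILTER=<ID=LowPP,Description="Posterior below cut-off">')
    header.add_sample(sample)
    gt_of = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in records:
            rec = _new_record(vcf, r.variant)
            low = (pp_cutoff is not None and r.pp < pp_cutoff) or r.missing
            rec.samples[sample]["GT"] = (None, None) if low else gt_of[r.call]
            rec.samples[sample]["GP"] = tuple(float(x) for x in r.gp)
            rec.filter.add("LowPP" if low else "PASS")
            vcf.write(rec)


def read_imputed_vcf(path) -> tuple[list[ImputedRecord], str]:
    """Read an imputed VCF back into records; returns (records, sample)."""
    out: list[ImputedRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValueError("imputed VCF must have exactly one sample")
        for rec in vcf:
            v = _variant_from_record(rec)
            call = rec.samples[samples[0]]
            gp = np.asarray(call["GP"], dtype=float)
            gt = call["GT"]
            out.append(ImputedRecord(v, gp / gp.sum(), missing=None in gt))
    return out, samples[0]


def write_truth_table(truth: TrueGenotypes, path, seed: Optional[int] = None) -> None:
    """Tab-separated truth dosages: sample, variant id, dosage, membership."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={int(seed)}\n")
        fh.write("sample\tvariant_id\ttrue_dosage\tpanel_membership\n")
        for v in truth.variants:
            fh.write(
                f"{truth.sample}\t{v.id}\t{truth.dosage[v.id]}\t"
                f"{int(truth.panel_membership[v.id])}\n"
            )


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_chunks(chunks: Sequence[Chunk], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tbstart\tbend\n")
        for c in chunks:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.bstart}\t{c.bend}\n")


def write_genetic_map(variants: Sequence[Variant], cm: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tcM\n")
        for v, x in zip(variants, cm):
            fh.write(f"{v.chrom}\t{v.pos}\t{x:.6f}\n")
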