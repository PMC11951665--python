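"""Site-level primitives: genotype likelihoods, phred conversion, the
proxy genetic map, genome chunking, SNV filtering and SV interval matching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .types import HaplotypePanel, SiteLikelihoods, Variant, check_sorted


def gl_from_counts(ref_reads: int, alt_reads: int, base_error: float) -> np.ndarray:
    """Linear-scale genotype likelihood triple from pileup read counts.

    Under genotype g (alternate dosage), each read supports the alternate
    allele with probability (g/2)(1-e) + (1-g/2)e, independently.  With no
    reads the triple is uninformative, (1, 1, 1).
    """
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    if not 0 < base_error < 0.5:
        raise ValueError("base_error must be in (0, 0.5)")
    g = np.array([0.0, 1.0, 2.0])
    p_alt = (g / 2) * (1 - base_error) + (1 - g / 2) * base_error
    return p_alt**alt_reads * (1 - p_alt) ** ref_reads


def gl_to_pl(gl: Sequence[float]) -> np.ndarray:
    """Phred-scaled integer likelihoods: round(-10*log10(L/max L)), min 0.

    Rounding is half-away-from-zero ("closest integer").
    """
    gl = np.asarray(gl, dtype=float)
    if gl.shape != (3,):
        raise ValueError("likelihood triple must have 3 entries")
    if (gl < 0).any() or gl.max() <= 0:
        raise ValueError("likelihoods must be non-negative with a positive maximum")
    with np.errstate(divide="ignore"):
        phred = -10.0 * np.log10(gl / gl.max())
    return np.floor(phred + 0.5).astype(int)


def merge_likelihood_sets(
    snv_set: Mapping[str, SiteLikelihoods],
    sv_set: Mapping[str, SiteLikelihoods],
) -> dict[str, SiteLikelihoods]:
    """Union of SNV and SV likelihood records; ids must be disjoint.

    Missing SV records stay in the merged set flagged missing, so the
    GL-supplemented imputation mode can exclude them explicitly.
    """
    dup = set(snv_set) & set(sv_set)
    if dup:
        raise ValueError(f"duplicate variant ids across sets: {sorted(dup)[:5]}")
    merged = dict(snv_set)
    merged.update(sv_set)
    return merged


def extract_variable_sites(panel: HaplotypePanel) -> list[Variant]:
    """Every polymorphic site of every class, SVs included."""
    freq = panel.allele_freq()
    return [v for v, f in zip(panel.variants, freq) if 0.0 < f < 1.0]


def make_genetic_map(variants: Sequence[Variant]) -> np.ndarray:
    """Proxy genetic positions in cM at a constant 1 Mb per cM."""
    check_sorted(variants)
    return np.array([v.pos / 1_000_000 for v in variants])


@dataclass(frozen=True)
class Chunk:
    """A core imputation interval plus its buffered extension (1-based)."""

    chrom: str
    start: int
    end: int
    bstart: int
    bend: int

    def __post_init__(self) -> None:
        if not (self.bstart <= self.start <= self.end <= self.bend):
            raise ValueError("core interval must lie inside the buffered interval")


def chunk_genome(
    chrom_length: int,
    chrom: str = "chr1",
    window: int = 100_000_000,
    buffer: int = 200_000,
) -> list[Chunk]:
    """Tile [1, chrom_length] with cores of ``window`` bp plus buffers.

    Cores partition the chromosome exactly; each buffered interval extends
    the core by ``buffer`` bp on both sides, clipped at the chromosome ends.
    """
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    if not window > 2 * buffer > 0:
        raise ValueError("require window > 2*buffer > 0")
    chunks = []
    start = 1
    while start <= chrom_length:
        end = min(start + window - 1, chrom_length)
        chunks.append(
            Chunk(
                chrom=chrom,
                start=start,
                end=end,
                bstart=max(1, start - buffer),
                bend=min(chrom_length, end + buffer),
            )
        )
        start = end + 1
    return chunks


def reciprocal_overlap_match(a: Variant, b: Variant, threshold: float = 0.90) -> bool:
    """True iff the overlap covers >= threshold of BOTH intervals.

    Different chromosomes or different variant classes never match.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if a.chrom != b.chrom or a.var_class != b.var_class:
        return False
    overlap = min(a.end, b.end) - max(a.pos, b.pos) + 1
    return overlap >= threshold * a.length and overlap >= threshold * b.length


@dataclass
class GenotypeCall:
    """One per-sample genotype in a raw SNV call set, before filtering."""

    dosage: Optional[int]  # None = missing call
    gq: float = 99.0
    dp: int = 99


@dataclass
class SnvSiteRecord:
    """One candidate site in a raw call set, carrying its filter inputs."""

    variant: Variant
    qual: float
    n_alleles: int
    is_indel: bool
    genotypes: list[GenotypeCall] = field(default_factory=list)


def filter_snvs(
    records: Iterable[SnvSiteRecord],
    *,
    min_maf: float = 0.01,
    min_qual: float = 30.0,
    min_call_rate: float = 0.7,
    min_gq: float = 10.0,
    min_dp: int = 4,
) -> list[SnvSiteRecord]:
    """Hard-filter a raw SNV call set.

    Genotypes with GQ < min_gq or DP < min_dp are masked to missing first;
    the site then survives only if it is a biallelic SNV (no indels) with
    QUAL >= min_qual, post-mask call rate >= min_call_rate and post-mask
    minor-allele frequency >= min_maf.  All comparisons are inclusive.
    """
    kept = []
    for rec in records:
        if rec.is_indel or rec.n_alleles != 2 or rec.variant.var_class != "SNV":
            continue
        if rec.qual < min_qual:
            continue
        called = [
            g.dosage
            for g in rec.genotypes
            if g.dosage is not None and g.gq >= min_gq and g.dp >= min_dp
        ]
        if not rec.genotypes:
            continue
        if len(called) / len(rec.genotypes) < min_call_rate:
            continue
        alt = sum(called)
        af = alt / (2 * len(called))
        if min(af, 1 - af) < min_maf:
            continue
        kept.append(rec)
    return kept
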