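"""Core domain containers shared across the package.

The unit of analysis is a biallelic variant: a single-nucleotide variant
(SNV) or a structural variant (SV) of class deletion (DEL), duplication
(DUP) or inversion (INV).  A phased reference panel is a binary
haplotype-by-variant matrix; target samples are diploids described by an
alternate-allele dosage in {0, 1, 2} per variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

SNV = "SNV"
DEL = "DEL"
DUP = "DUP"
INV = "INV"

VAR_CLASSES = (SNV, DEL, DUP, INV)
SV_CLASSES = (DEL, DUP, INV)

#: Minimum structural-variant length considered, in bp.
MIN_SV_LENGTH = 100


@dataclass(frozen=True)
class Variant:
    """One biallelic site with 1-based inclusive coordinates.

    ``end == pos`` for SNVs; for SVs ``length = end - pos + 1``.
    """

    id: str
    chrom: str
    pos: int
    end: int
    var_class: str

    def __post_init__(self) -> None:
        if self.var_class not in VAR_CLASSES:
            raise ValueError(f"unknown var_class {self.var_class!r} for {self.id}")
        if self.end < self.pos:
            raise ValueError(f"variant {self.id}: end {self.end} < pos {self.pos}")
        if self.var_class == SNV and self.end != self.pos:
            raise ValueError(f"SNV {self.id} must have end == pos")
        if self.var_class in SV_CLASSES and self.length < MIN_SV_LENGTH:
            raise ValueError(
                f"SV {self.id}: length {self.length} < minimum {MIN_SV_LENGTH} bp"
            )

    @property
    def length(self) -> int:
        return self.end - self.pos + 1

    @property
    def is_sv(self) -> bool:
        return self.var_class in SV_CLASSES


def check_sorted(variants: Sequence[Variant]) -> None:
    """Raise if variants are not sorted by (chrom, pos)."""
    keys = [(v.chrom, v.pos) for v in variants]
    if keys != sorted(keys):
        raise ValueError("variants are not sorted by (chrom, pos)")


@dataclass
class HaplotypePanel:
    """Phased haplotype-by-variant allele matrix.

    Rows 2i and 2i+1 hold the two haplotypes of ``samples[i]``.  Entries
    are 0 (reference allele) or 1 (alternate allele).
    """

    haplotypes: np.ndarray  # (K, M) uint8
    samples: list[str]
    variants: list[Variant]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        k, m = self.haplotypes.shape
        if k != 2 * len(self.samples):
            raise ValueError(
                f"{k} haplotype rows for {len(self.samples)} samples "
                "(need exactly two rows per sample)"
            )
        if m != len(self.variants):
            raise ValueError(
                f"{m} matrix columns for {len(self.variants)} variants"
            )
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype matrix entries must be 0 or 1")
        check_sorted(self.variants)
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("variant ids are not unique")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def sample_rows(self, sample: str) -> Tuple[int, int]:
        try:
            i = self.samples.index(sample)
        except ValueError:
            raise ValueError(f"sample {sample!r} not in panel") from None
        return 2 * i, 2 * i + 1

    def allele_freq(self) -> np.ndarray:
        """Per-variant alternate-allele frequency."""
        return self.haplotypes.mean(axis=0)


# Uninformative likelihood triple used where a site carries no read data.
UNIFORM_GL = np.ones(3)


@dataclass
class SiteLikelihoods:
    """Genotype likelihood triple L(0), L(1), L(2) for one sample at one site.

    ``gl`` is on a linear scale with arbitrary positive normalisation.
    ``pl`` is the integer phred-scaled form (minimum 0) when it has been
    computed.  ``missing`` marks sites with no evidence record at all —
    e.g. SVs whose genotyper produced nothing at low depth.
    """

    variant_id: str
    gl: Optional[np.ndarray] = None
    pl: Optional[np.ndarray] = None
    missing: bool = False

    def __post_init__(self) -> None:
        if self.gl is not None:
            self.gl = np.asarray(self.gl, dtype=float)
            if self.gl.shape != (3,):
                raise ValueError(f"{self.variant_id}: GL triple must have 3 entries")
            if (self.gl < 0).any() or not (self.gl > 0).any():
                raise ValueError(
                    f"{self.variant_id}: GL must be non-negative with at least one positive entry"
                )
        if self.pl is not None:
            self.pl = np.asarray(self.pl, dtype=int)
            if self.pl.shape != (3,) or self.pl.min() != 0:
                raise ValueError(f"{self.variant_id}: PL triple must have min 0")
        if not self.missing and self.gl is None and self.pl is None:
            raise ValueError(f"{self.variant_id}: non-missing site needs GL or PL")

    def linear(self) -> np.ndarray:
        """Linear-scale likelihood triple, uniform when missing."""
        if self.missing:
            return UNIFORM_GL.copy()
        if self.gl is not None:
            return self.gl.copy()
        return np.power(10.0, -np.asarray(self.pl, dtype=float) / 10.0)


@dataclass
class TrueGenotypes:
    """Ground-truth diploid dosages for one target sample.

    ``variants`` covers panel variants and, for out-panel targets, private
    variants absent from the panel (``panel_membership`` False).  For
    in-panel targets ``hap_pair`` records the two contributing panel rows
    for audit.
    """

    sample: str
    variants: list[Variant]
    dosage: Mapping[str, int]
    panel_membership: Mapping[str, bool]
    mode: str  # "in_panel" or "out_panel"
    hap_pair: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        for v in self.variants:
            g = self.dosage[v.id]
            if g not in (0, 1, 2):
                raise ValueError(f"{v.id}: dosage {g} not in {{0,1,2}}")


@dataclass
class ImputedRecord:
    """One imputed genotype: posterior triple, its max (PP) and argmax call."""

    variant: Variant
    gp: np.ndarray  # posterior triple, sums to 1
    missing: bool = False

    def __post_init__(self) -> None:
        self.gp = np.asarray(self.gp, dtype=float)
        if self.gp.shape != (3,):
            raise ValueError(f"{self.variant.id}: GP triple must have 3 entries")
        if abs(self.gp.sum() - 1.0) > 1e-6:
            raise ValueError(f"{self.variant.id}: GP does not sum to 1")

    @property
    def pp(self) -> float:
        return float(self.gp.max())

    @property
    def call(self) -> int:
        return int(self.gp.argmax())
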