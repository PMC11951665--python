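"""Synthetic data generator.

Stands in for a wild-population WGS resource: a phased reference panel of
SNVs and SVs in linkage disequilibrium, diploid target samples that are
recombinant mosaics of panel haplotypes, and coverage-dependent read
evidence.

The panel is built by founder-mosaic copying: a small set of founder
haplotypes is drawn, and each panel haplotype copies founders in segments
whose boundaries follow a per-Mb switch rate.  Nearby variants therefore
share founder origin and are correlated (LD), including SVs and their
flanking SNVs.  SV columns additionally receive a small per-haplotype
allele-flip noise, emulating residual SV genotyping/phasing error in a
short-read panel; this is what limits purely LD-based SV imputation.

Read evidence per SNV site is depth ~ Poisson(coverage) with alternate
reads ~ Binomial(depth, (g/2)(1-e) + (1-g/2)e).  SV evidence uses the same
count model with class-specific effective depth and error, and each SV
independently lacks evidence altogether with probability
p_miss(c) = exp(-c / lambda_class).  The per-SV dropout draw is keyed by
site and seed only, so the set of SVs with evidence at a lower coverage is
a subset of the set at a higher coverage — as when down-sampling one
sequencing run.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .config import IN_PANEL, OUT_PANEL, SimulationConfig
from .sites import gl_from_counts, gl_to_pl
from .types import (
    DEL,
    DUP,
    INV,
    SNV,
    SV_CLASSES,
    HaplotypePanel,
    SiteLikelihoods,
    TrueGenotypes,
    Variant,
)

# Sub-stream tags so each operation draws from an independent seeded stream.
_TAG_PANEL, _TAG_TARGET, _TAG_SNV_EV, _TAG_SV_EV = 11, 13, 17, 19


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *tags]))


def _draw_variants(config: SimulationConfig, rng: np.random.Generator) -> list[Variant]:
    variants: list[Variant] = []
    pos = rng.choice(config.chrom_length, size=config.n_snvs, replace=False) + 1
    for i, p in enumerate(np.sort(pos)):
        variants.append(Variant(f"snv{i:06d}", config.chrom, int(p), int(p), SNV))
    for cls in SV_CLASSES:
        n = config.n_svs_per_class.get(cls, 0)
        lo, hi = config.sv_length_bounds[cls]
        lengths = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
        for i, ln in enumerate(lengths):
            length = int(min(round(ln), config.chrom_length - 1))
            start = int(rng.integers(1, config.chrom_length - length + 1))
            variants.append(
                Variant(
                    f"{cls.lower()}{i:04d}",
                    config.chrom,
                    start,
                    start + length - 1,
                    cls,
                )
            )
    variants.sort(key=lambda v: (v.chrom, v.pos, v.id))
    return variants


def _ensure_polymorphic(
    H: np.ndarray, founder_path: np.ndarray, rng: np.random.Generator
) -> None:
    """Flip alleles in-place so every column is polymorphic."""
    K, M = H.shape
    for m in np.flatnonzero(~((H.sum(axis=0) > 0) & (H.sum(axis=0) < K))):
        copied = founder_path[:, m]
        # prefer flipping every haplotype that copied one founder, which
        # preserves the founder-determined LD structure at the site
        founders, counts = np.unique(copied, return_counts=True)
        proper = founders[(counts > 0) & (counts < K)]
        if proper.size:
            f = rng.choice(proper)
            H[copied == f, m] ^= 1
        else:  # single founder copied by everyone: flip a random proper subset
            rows = rng.choice(K, size=int(rng.integers(1, K)), replace=False)
            H[rows, m] ^= 1


def simulate_panel(
    config: SimulationConfig,
) -> tuple[HaplotypePanel, list[Variant]]:
    """Generate a phased reference panel of SNVs and SVs in LD.

    Returns the panel and its (sorted) variant list.  Deterministic given
    ``config.seed``; every emitted column is polymorphic.
    """
    rng = _rng(config.seed, _TAG_PANEL)
    variants = _draw_variants(config, rng)
    M = len(variants)
    K, F = config.n_haplotypes, config.n_founders

    # founder haplotypes with per-site allele frequencies away from fixation
    p = rng.uniform(0.1, 0.9, size=M)
    founders = (rng.random((F, M)) < p).astype(np.uint8)

    # mosaic copying: per-gap switch probability from the per-Mb rate
    pos = np.array([v.pos for v in variants], dtype=float)
    gap_mb = np.diff(pos) / 1e6
    s = 1.0 - np.exp(-config.mosaic_switch_rate * gap_mb)
    switch = rng.random((K, M - 1)) < s if M > 1 else np.zeros((K, 0), bool)
    seg = np.concatenate(
        [np.zeros((K, 1), dtype=np.int64), np.cumsum(switch, axis=1)], axis=1
    )
    choices = rng.integers(0, F, size=(K, M))
    founder_path = np.take_along_axis(choices, seg, axis=1)
    H = founders[founder_path, np.arange(M)[None, :]]

    # residual SV genotyping noise in the panel, per class
    for m, v in enumerate(variants):
        if v.is_sv:
            flips = rng.random(K) < config.sv_panel_noise[v.var_class]
            H[:, m] ^= flips.astype(np.uint8)

    _ensure_polymorphic(H, founder_path, rng)
    samples = [f"S{i:04d}" for i in range(K // 2)]
    panel = HaplotypePanel(H, samples, variants)
    return panel, variants


def simulate_target(
    panel: HaplotypePanel,
    config: SimulationConfig,
    sample: Optional[str] = None,
    seed: Optional[int] = None,
) -> TrueGenotypes:
    """Draw one target diploid and its true dosages.

    in_panel: the target IS a panel sample (its two phased haplotypes);
    the caller benchmarks it leave-one-out.  out_panel: the target is a
    fresh recombinant mosaic of panel haplotypes, plus private variants
    absent from the panel at ``private_variant_fraction``.
    """
    if panel.n_variants == 0:
        raise ValueError("panel has no variants")
    seed = config.seed if seed is None else seed
    rng = _rng(seed, _TAG_TARGET)

    if config.target_mode == IN_PANEL:
        name = sample if sample is not None else str(rng.choice(panel.samples))
        r0, r1 = panel.sample_rows(name)
        dosage = (panel.haplotypes[r0] + panel.haplotypes[r1]).astype(int)
        return TrueGenotypes(
            sample=name,
            variants=list(panel.variants),
            dosage={v.id: int(g) for v, g in zip(panel.variants, dosage)},
            panel_membership={v.id: True for v in panel.variants},
            mode=IN_PANEL,
            hap_pair=(r0, r1),
        )

    # out-panel: two new mosaics over the panel's haplotype rows
    K, M = panel.haplotypes.shape
    pos = np.array([v.pos for v in panel.variants], dtype=float)
    s = 1.0 - np.exp(-config.mosaic_switch_rate * np.diff(pos) / 1e6)
    haps = np.empty((2, M), dtype=np.uint8)
    for h in range(2):
        switch = rng.random(M - 1) < s if M > 1 else np.zeros(0, bool)
        seg = np.concatenate([[0], np.cumsum(switch)])
        choices = rng.integers(0, K, size=M)
        rows = choices[seg]
        haps[h] = panel.haplotypes[rows, np.arange(M)]
    dosage = {v.id: int(g) for v, g in zip(panel.variants, haps.sum(axis=0))}
    membership = {v.id: True for v in panel.variants}
    variants = list(panel.variants)

    frac = config.private_variant_fraction
    if frac > 0:
        if M == 0:
            raise ValueError("cannot inject private variants into an empty panel")
        n_priv = int(rng.binomial(M, frac))
        class_counts = {c: sum(v.var_class == c for v in panel.variants)
                        for c in (SNV, *SV_CLASSES)}
        classes = [c for c, n in class_counts.items() if n > 0]
        weights = np.array([class_counts[c] for c in classes], dtype=float)
        weights /= weights.sum()
        for i in range(n_priv):
            cls = str(rng.choice(classes, p=weights))
            if cls == SNV:
                start = int(rng.integers(1, config.chrom_length + 1))
                length = 1
            else:
                lo, hi = config.sv_length_bounds[cls]
                length = int(
                    min(
                        round(math.exp(rng.uniform(math.log(lo), math.log(hi)))),
                        config.chrom_length - 1,
                    )
                )
                start = int(rng.integers(1, config.chrom_length - length + 1))
            v = Variant(f"priv{i:05d}", config.chrom, start, start + length - 1, cls)
            variants.append(v)
            dosage[v.id] = 1 + int(rng.random() < 0.25)
            membership[v.id] = False
        variants.sort(key=lambda v: (v.chrom, v.pos, v.id))

    return TrueGenotypes(
        sample=f"OUT_{seed}",
        variants=variants,
        dosage=dosage,
        panel_membership=membership,
        mode=OUT_PANEL,
        hap_pair=None,
    )


def simulate_snv_evidence(
    truth: TrueGenotypes,
    coverage: float,
    base_error: float,
    seed: int,
) -> dict[str, SiteLikelihoods]:
    """Per-SNV genotype likelihoods from simulated pileup read counts.

    Covers panel-member SNVs only (private variants are never imputed).
    Sites that draw zero reads carry the uninformative (1, 1, 1) triple.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    rng = _rng(seed, _TAG_SNV_EV)
    sites = [v for v in truth.variants
             if v.var_class == SNV and truth.panel_membership[v.id]]
    g = np.array([truth.dosage[v.id] for v in sites], dtype=float)
    depth = rng.poisson(coverage, size=len(sites))
    p_alt = (g / 2) * (1 - base_error) + (1 - g / 2) * base_error
    alt = rng.binomial(depth, p_alt)
    ref = depth - alt
    out = {}
    for v, r, a in zip(sites, ref, alt):
        out[v.id] = SiteLikelihoods(v.id, gl=gl_from_counts(int(r), int(a), base_error))
    return out


def p_miss(coverage: float, dropout_scale: float) -> float:
    """Probability that an SV lacks any genotype-likelihood evidence."""
    return math.exp(-coverage / dropout_scale)


def simulate_sv_evidence(
    truth: TrueGenotypes,
    coverage: float,
    config: SimulationConfig,
    seed: int,
) -> dict[str, SiteLikelihoods]:
    """Per-SV likelihoods with coverage-dependent evidence dropout.

    Each panel SV independently has no evidence with probability
    p_miss(coverage) (returned flagged missing); otherwise a GL triple is
    drawn with class-specific effective depth and error and converted to
    integer PLs.  The dropout draw is shared across coverages under one
    seed, making low-coverage evidence sets nested in high-coverage ones.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    sites = [v for v in truth.variants
             if v.is_sv and truth.panel_membership[v.id]]
    out = {}
    for i, v in enumerate(sites):
        rng = _rng(seed, _TAG_SV_EV, i)
        u = rng.random()
        if u < p_miss(coverage, config.sv_dropout_scale[v.var_class]):
            out[v.id] = SiteLikelihoods(v.id, missing=True)
            continue
        err = config.sv_error[v.var_class]
        eff = coverage * config.sv_depth_scale[v.var_class]
        depth = int(rng.poisson(eff))
        g = truth.dosage[v.id]
        p_alt = (g / 2) * (1 - err) + (1 - g / 2) * err
        alt = int(rng.binomial(depth, p_alt))
        gl = gl_from_counts(depth - alt, alt, err)
        out[v.id] = SiteLikelihoods(v.id, gl=gl, pl=gl_to_pl(gl))
    return out
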