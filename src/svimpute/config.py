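"""Configuration objects and their validation.

Defaults define the desk-scale study conditions used throughout the test
suite and the experiment driver: a 10 Mb chromosome, 100 panel haplotypes
(50 diploid samples), 2,000 SNVs and 130 SVs (100 DEL / 20 DUP / 10 INV),
target coverages of 1–4x and posterior cut-offs 0.60 / 0.75 / 0.90.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence, Tuple

import yaml

from .types import DEL, DUP, INV, SV_CLASSES

IN_PANEL = "in_panel"
OUT_PANEL = "out_panel"

LD_ONLY = "ld_only"
GL_SUPPLEMENTED = "gl_supplemented"
MERGED_LOGICAL = "merged_logical"
MERGED_NON_LOGICAL = "merged_non_logical"
STRATEGIES = (LD_ONLY, GL_SUPPLEMENTED, MERGED_LOGICAL, MERGED_NON_LOGICAL)

#: Posterior-probability cut-offs at which imputed calls are filtered.
DEFAULT_PP_CUTOFFS = (0.60, 0.75, 0.90)

#: Imputation window and buffer sizes in bp.
DEFAULT_WINDOW = 100_000_000
DEFAULT_BUFFER = 200_000


def _default_sv_counts() -> dict:
    return {DEL: 100, DUP: 20, INV: 10}


def _default_sv_length_bounds() -> dict:
    # Log-uniform sampling bounds per class, bp; spans chosen to mirror the
    # observed length ranges of short-read SV call sets (deletions reach
    # hundreds of kb, duplications and inversions tens of kb).
    return {DEL: (100, 400_000), DUP: (140, 30_000), INV: (1_100, 16_000)}


def _default_sv_error() -> dict:
    # Effective per-read mis-evidence rate of the SV genotyper, per class.
    # Duplications and inversions are harder to genotype from short reads
    # than deletions, so their evidence is noisier.
    return {DEL: 0.02, DUP: 0.08, INV: 0.06}


def _default_sv_depth_scale() -> dict:
    # Fraction of the nominal depth that yields informative reads at an SV.
    return {DEL: 1.0, DUP: 0.7, INV: 0.7}


def _default_sv_dropout_scale() -> dict:
    # lambda of p_miss(c) = exp(-c / lambda): probability that an SV has no
    # genotype-likelihood record at coverage c.
    return {DEL: 1.0, DUP: 1.3, INV: 1.3}


def _default_sv_panel_noise() -> dict:
    # Per-haplotype allele-flip rate applied to SV columns of the panel,
    # emulating residual SV genotyping/phasing error in a short-read panel.
    # Deletions are the best-genotyped class.
    return {DEL: 0.04, DUP: 0.10, INV: 0.08}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic panel / target / evidence generator."""

    n_haplotypes: int = 100
    chrom: str = "chr1"
    chrom_length: int = 10_000_000
    n_snvs: int = 2_000
    n_svs_per_class: Mapping[str, int] = field(default_factory=_default_sv_counts)
    sv_length_bounds: Mapping[str, Tuple[int, int]] = field(
        default_factory=_default_sv_length_bounds
    )
    n_founders: int = 8
    mosaic_switch_rate: float = 1.0  # expected ancestor switches per Mb
    target_mode: str = IN_PANEL
    private_variant_fraction: float = 0.45  # used in out_panel mode only
    coverage: float = 1.0  # mean read depth, x
    base_error: float = 0.001  # per-read base error epsilon
    sv_error: Mapping[str, float] = field(default_factory=_default_sv_error)
    sv_depth_scale: Mapping[str, float] = field(default_factory=_default_sv_depth_scale)
    sv_dropout_scale: Mapping[str, float] = field(
        default_factory=_default_sv_dropout_scale
    )
    sv_panel_noise: Mapping[str, float] = field(default_factory=_default_sv_panel_noise)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplotypes < 4 or self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even and >= 4")
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        if self.n_snvs < 0:
            raise ValueError("n_snvs must be >= 0")
        for cls in SV_CLASSES:
            n = self.n_svs_per_class.get(cls, 0)
            if n < 0:
                raise ValueError(f"n_svs_per_class[{cls}] must be >= 0")
            lo, hi = self.sv_length_bounds[cls]
            if not (100 <= lo <= hi <= 2_000_000):
                raise ValueError(
                    f"sv_length_bounds[{cls}] must lie within [100, 2000000] bp"
                )
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if self.mosaic_switch_rate <= 0:
            raise ValueError("mosaic_switch_rate must be positive")
        if self.target_mode not in (IN_PANEL, OUT_PANEL):
            raise ValueError(f"target_mode must be {IN_PANEL!r} or {OUT_PANEL!r}")
        if not 0 <= self.private_variant_fraction < 1:
            raise ValueError("private_variant_fraction must be in [0, 1)")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not 0 < self.base_error < 0.5:
            raise ValueError("base_error must be in (0, 0.5)")
        for cls in SV_CLASSES:
            if not 0 < self.sv_error[cls] < 0.5:
                raise ValueError(f"sv_error[{cls}] must be in (0, 0.5)")
            if self.sv_dropout_scale[cls] <= 0:
                raise ValueError(f"sv_dropout_scale[{cls}] must be positive")
            if not 0 <= self.sv_panel_noise[cls] < 0.5:
                raise ValueError(f"sv_panel_noise[{cls}] must be in [0, 0.5)")


@dataclass
class HMMParams:
    """Haplotype-copying HMM parameters.

    rho is the expected template-switch rate per cM per haplotype;
    mu the copying-error probability per copied allele.
    """

    rho: float = 0.04
    mu: float = 1e-3

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if not 0 <= self.mu < 0.5:
            raise ValueError("mu must be in [0, 0.5)")


@dataclass
class RunSpec:
    """One imputation run: a target sample at a depth under a strategy."""

    sample: str
    depth: float
    strategy: str
    pp_cutoffs: Sequence[float] = DEFAULT_PP_CUTOFFS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        for c in self.pp_cutoffs:
            if not 0 < c < 1:
                raise ValueError("pp_cutoffs must lie in (0, 1)")


@dataclass
class ExperimentConfig:
    """Full leave-one-out experiment grid."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    hmm: HMMParams = field(default_factory=HMMParams)
    n_targets: int = 10
    depths: Sequence[float] = (1.0, 4.0)
    strategies: Sequence[str] = STRATEGIES
    pp_cutoffs: Sequence[float] = DEFAULT_PP_CUTOFFS
    window: int = DEFAULT_WINDOW
    buffer: int = DEFAULT_BUFFER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 1 or not self.depths or not self.strategies:
            raise ValueError("experiment grid must be non-empty")
        if 2 * self.n_targets > self.sim.n_haplotypes:
            raise ValueError("n_targets exceeds number of panel samples")
        for s in self.strategies:
            if s not in STRATEGIES:
                raise ValueError(f"unknown strategy {s!r}")


def _to_plain(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(config: ExperimentConfig, path) -> None:
    """Write an experiment configuration as a YAML key-value file."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def load_config(path) -> ExperimentConfig:
    """Read an experiment configuration from YAML, applying defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        sim = SimulationConfig(**_tupled(raw.pop("sim", {})))
        hmm = HMMParams(**raw.pop("hmm", {}))
        return ExperimentConfig(sim=sim, hmm=hmm, **_tupled(raw))
    except TypeError as exc:
        raise ValueError(f"invalid configuration field: {exc}") from exc


def _tupled(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, dict):
            out[k] = {
                kk: tuple(vv) if isinstance(vv, list) else vv for kk, vv in v.items()
            }
        elif isinstance(v, list):
            out[k] = tuple(v)
        else:
            out[k] = v
    return out
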