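"""Haplotype-copying HMM for diploid genotype imputation.

The target diploid is modelled as an imperfect mosaic of an ordered pair
of reference-panel haplotypes (the Li & Stephens model).  Hidden state at
each site is the pair (j, k) of copied haplotypes; between adjacent sites
each haplotype independently switches template with probability
1 - exp(-rho * d_cM), resampling uniformly over the K panel haplotypes.
Each copied allele is mis-copied with probability mu, and the emission at
a site integrates the genotype likelihood triple over the copying-error
kernel.  Sites with no likelihood record emit uniformly, so their
posterior is driven purely by LD with flanking sites — this realises
LD-only imputation of variants lacking read evidence.

The forward-backward pass is exact over the K^2 ordered-pair state space.
The factorised transition keeps each site O(K^2), which is adequate for
panels of up to a few hundred haplotypes; no PBWT/state-sampling
approximation is used.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Optional, Sequence

import numpy as np

from .config import GL_SUPPLEMENTED, LD_ONLY, HMMParams
from .sites import Chunk, make_genetic_map
from .types import (
    SNV,
    HaplotypePanel,
    ImputedRecord,
    SiteLikelihoods,
    Variant,
)

logger = logging.getLogger(__name__)


def copy_error_kernel(mu: float) -> np.ndarray:
    """P(observed genotype g | copied genotype g*) under independent
    per-haplotype allele flips with probability mu.  Rows index g*."""
    stay, flip = 1 - mu, mu
    return np.array(
        [
            [stay * stay, 2 * stay * flip, flip * flip],
            [stay * flip, stay * stay + flip * flip, stay * flip],
            [flip * flip, 2 * stay * flip, stay * stay],
        ]
    )


def switch_probability(dist_cM: float, rho: float) -> float:
    """Per-haplotype template-switch probability over a map distance."""
    if dist_cM < 0:
        raise ValueError("dist_cM must be >= 0")
    return 1.0 - float(np.exp(-rho * dist_cM))


def transition_matrix(dist_cM: float, rho: float, K: int) -> np.ndarray:
    """Dense K^2 x K^2 diploid transition kernel (for small-K checks).

    The diploid process is the product of two independent per-haplotype
    processes, each (1-s) I + (s/K) 11^T.
    """
    s = switch_probability(dist_cM, rho)
    T1 = (1 - s) * np.eye(K) + (s / K) * np.ones((K, K))
    return np.kron(T1, T1)


def _apply_transition(A: np.ndarray, s: float, K: int) -> np.ndarray:
    """Factorised transition applied to a K x K state table in O(K^2)."""
    stay = 1 - s
    mix = s / K
    # first haplotype index
    B = stay * A + mix * A.sum(axis=0, keepdims=True)
    # second haplotype index
    return stay * B + mix * B.sum(axis=1, keepdims=True)


def _hap_matrix(panel) -> np.ndarray:
    """0/1 haplotype-by-variant matrix from a panel or a raw array."""
    H = panel.haplotypes if isinstance(panel, HaplotypePanel) else np.asarray(panel)
    if H.ndim != 2 or not np.isin(H, (0, 1)).all():
        raise ValueError("haplotypes must be a 2-D 0/1 matrix")
    return H.astype(np.uint8)


def emission(
    panel,
    j: int,
    k: int,
    site: int,
    likelihoods: Optional[SiteLikelihoods],
    mu: float,
) -> float:
    """Emission probability of the evidence at one site from state (j, k)."""
    H = _hap_matrix(panel)
    g_star = int(H[j, site]) + int(H[k, site])
    L = likelihoods.linear() if likelihoods is not None else np.ones(3)
    return float(copy_error_kernel(mu)[g_star] @ L)


def _site_emissions(g_outer: np.ndarray, L: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """K x K emission table from the outer genotype matrix of one site."""
    e_vals = kernel @ L  # emission per copied genotype 0/1/2
    return e_vals[g_outer]


def forward_backward(
    panel,
    likelihoods: np.ndarray,
    gmap: np.ndarray,
    params: HMMParams,
) -> np.ndarray:
    """Exact posterior genotype triples over all sites of one chunk.

    ``panel`` is a :class:`HaplotypePanel` or a raw (K, M) 0/1 haplotype
    matrix.  ``likelihoods`` is (M, 3) on the linear scale (rows of ones
    where a site has no evidence); ``gmap`` the per-site genetic position
    in cM.  Returns an (M, 3) array of normalised posterior triples.  The
    genotype posterior is marginalised through the copying-error kernel:
    p(g) proportional to L(g) * sum_t w_t P(g | t, mu), with w_t the
    posterior mass of states whose copied genotype is t.
    """
    H = _hap_matrix(panel)
    K, M = H.shape
    L = np.asarray(likelihoods, dtype=float)
    if L.shape != (M, 3):
        raise ValueError(f"likelihood track shape {L.shape} != ({M}, 3)")
    if M < 1:
        raise ValueError("need at least one site")
    kernel = copy_error_kernel(params.mu)
    s_gap = 1.0 - np.exp(-params.rho * np.diff(np.asarray(gmap, dtype=float)))
    if (s_gap < -1e-12).any():
        raise ValueError("genetic map must be non-decreasing")
    s_gap = np.clip(s_gap, 0.0, 1.0)

    # forward pass, storing the scaled alpha tables
    alphas = np.empty((M, K, K))
    pred = np.full((K, K), 1.0 / (K * K))
    Hc = H.astype(np.intp)
    for m in range(M):
        if m > 0:
            pred = _apply_transition(alphas[m - 1], float(s_gap[m - 1]), K)
        g_outer = Hc[:, m][:, None] + Hc[:, m][None, :]
        a = pred * _site_emissions(g_outer, L[m], kernel)
        tot = a.sum()
        if tot <= 0:
            raise ValueError(
                f"zero total likelihood at site index {m}: all emissions vanish"
            )
        alphas[m] = a / tot

    # backward pass, accumulating genotype posteriors on the fly
    post = np.empty((M, 3))
    beta = np.ones((K, K))
    for m in range(M - 1, -1, -1):
        pred = (
            _apply_transition(alphas[m - 1], float(s_gap[m - 1]), K)
            if m > 0
            else np.full((K, K), 1.0 / (K * K))
        )
        g_outer = Hc[:, m][:, None] + Hc[:, m][None, :]
        gamma_no_em = pred * beta  # state posterior excluding site-m emission
        w = np.bincount(g_outer.ravel(), weights=gamma_no_em.ravel(), minlength=3)
        p = L[m] * (w @ kernel)
        post[m] = p / p.sum()
        if m > 0:
            e = _site_emissions(g_outer, L[m], kernel)
            b = _apply_transition(beta * e, float(s_gap[m - 1]), K)
            beta = b / b.sum()
    return post


def brute_force_posteriors(
    panel,
    likelihoods: np.ndarray,
    gmap: np.ndarray,
    params: HMMParams,
    max_paths: int = 20_000_000,
) -> np.ndarray:
    """Posterior triples by explicit summation over every hidden path.

    Test oracle with the same output contract as :func:`forward_backward`;
    restricted to small instances (K <= 4 haplotypes, M <= 6 sites).
    """
    H = _hap_matrix(panel)
    K, M = H.shape
    if K > 4 or M > 6:
        raise ValueError("instance too large for brute-force enumeration")
    S = K * K
    if S**M > max_paths:
        raise ValueError("instance too large for brute-force enumeration")
    L = np.asarray(likelihoods, dtype=float)
    kernel = copy_error_kernel(params.mu)
    gmap = np.asarray(gmap, dtype=float)

    # per-site emission vector over flattened states s = j*K + k
    E = np.empty((M, S))
    G = np.empty((M, S), dtype=int)
    for m in range(M):
        g_outer = np.add.outer(H[:, m].astype(int), H[:, m].astype(int)).ravel()
        G[m] = g_outer
        E[m] = (kernel @ L[m])[g_outer]
    T = [
        transition_matrix(float(gmap[m + 1] - gmap[m]), params.rho, K)
        for m in range(M - 1)
    ]

    n_paths = S**M
    weights = np.zeros((M, S))  # total path probability through state s at m
    chunk = 1_000_000
    for start in range(0, n_paths, chunk):
        ids = np.arange(start, min(start + chunk, n_paths), dtype=np.int64)
        states = np.empty((M, ids.size), dtype=np.int64)
        rem = ids
        for m in range(M - 1, -1, -1):
            states[m] = rem % S
            rem = rem // S
        prob = np.full(ids.size, 1.0 / S)
        prob *= E[0, states[0]]
        for m in range(1, M):
            prob *= T[m - 1][states[m - 1], states[m]] * E[m, states[m]]
        for m in range(M):
            np.add.at(weights[m], states[m], prob)

    post = np.empty((M, 3))
    for m in range(M):
        # replace the site's own emission with the genotype-resolved term
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(E[m] > 0, weights[m] / E[m], 0.0)
        w = np.bincount(G[m], weights=a, minlength=3)
        p = L[m] * (w @ kernel)
        post[m] = p / p.sum()
    return post


def impute_sample(
    panel: HaplotypePanel,
    evidence: Mapping[str, SiteLikelihoods],
    chunks: Sequence[Chunk],
    params: HMMParams,
    mode: str,
) -> list[ImputedRecord]:
    """Impute one target across chunks under one strategy.

    ld_only: SV likelihoods are forced missing, so every SV posterior
    rests purely on LD with flanking SNVs; all panel sites are emitted.
    gl_supplemented: SV PL/GL evidence enters the emission, and SVs with
    no evidence record are excluded from the output (they would not appear
    in a genotype-likelihood input file).
    """
    if mode not in (LD_ONLY, GL_SUPPLEMENTED):
        raise ValueError(f"mode must be {LD_ONLY!r} or {GL_SUPPLEMENTED!r}")
    records: list[ImputedRecord] = []
    for chunk in chunks:
        idx = [
            i
            for i, v in enumerate(panel.variants)
            if v.chrom == chunk.chrom and chunk.bstart <= v.pos <= chunk.bend
        ]
        if not idx:
            warnings.warn(
                f"chunk {chunk.chrom}:{chunk.start}-{chunk.end} has no panel sites; skipped"
            )
            continue
        sub_vars = [panel.variants[i] for i in idx]
        sub_panel = HaplotypePanel(
            panel.haplotypes[:, idx], list(panel.samples), sub_vars
        )
        L = np.ones((len(idx), 3))
        excluded: set[str] = set()
        for row, v in enumerate(sub_vars):
            ev = evidence.get(v.id)
            if v.var_class == SNV:
                if ev is not None and not ev.missing:
                    L[row] = ev.linear()
            else:
                if mode == LD_ONLY:
                    continue  # uniform: rely on LD only
                if ev is None or ev.missing:
                    excluded.add(v.id)
                else:
                    L[row] = ev.linear()
        post = forward_backward(sub_panel, L, make_genetic_map(sub_vars), params)
        for row, v in enumerate(sub_vars):
            if chunk.start <= v.pos <= chunk.end and v.id not in excluded:
                records.append(ImputedRecord(v, post[row]))
        logger.info(
            "imputed chunk %s:%d-%d: %d sites, %d SVs excluded (no evidence)",
            chunk.chrom, chunk.start, chunk.end, len(sub_vars), len(excluded),
        )
    return records
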