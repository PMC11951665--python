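"""Haplotype-copying HMM: transitions, emissions, forward-backward vs the
path-enumeration oracle, and chunked sample imputation."""

import warnings

import numpy as np
import pytest

from svimpute.config import GL_SUPPLEMENTED, LD_ONLY, HMMParams
from svimpute.hmm import (
    brute_force_posteriors,
    copy_error_kernel,
    emission,
    forward_backward,
    impute_sample,
    switch_probability,
    transition_matrix,
)
from svimpute.sites import Chunk, chunk_genome
from svimpute.types import HaplotypePanel, SiteLikelihoods, Variant


def _snv(vid, pos):
    return Variant(vid, "chr1", pos, pos, "SNV")


def test_copy_error_kernel_rows_sum_to_one():
    k = copy_error_kernel(0.013)
    np.testing.assert_allclose(k.sum(axis=1), 1.0)
    np.testing.assert_allclose(copy_error_kernel(0.0), np.eye(3))


def test_transition_zero_distance_is_identity():
    assert switch_probability(0.0, 0.04) == 0.0
    np.testing.assert_allclose(transition_matrix(0.0, 0.04, 3), np.eye(9))


def test_transition_large_distance_is_stationary_uniform():
    T = transition_matrix(1e9, 0.04, 4)
    np.testing.assert_allclose(T, np.full((16, 16), 1 / 16), atol=1e-12)


def test_transition_rows_sum_to_one():
    T = transition_matrix(0.7, 0.05, 5)
    np.testing.assert_allclose(T.sum(axis=1), 1.0)


def test_emission_exact_copy_no_error():
    H = np.array([[0, 1], [0, 0]], dtype=np.uint8)
    L = SiteLikelihoods("x", gl=(1.0, 0.0, 0.0))
    assert emission(H, 0, 1, 0, L, mu=0.0) == pytest.approx(1.0)  # g*=0
    H2 = np.array([[1], [0]], dtype=np.uint8)
    assert emission(H2, 0, 1, 0, L, mu=0.0) == pytest.approx(0.0)  # g*=1


def test_emission_missing_likelihoods_uniform_across_states():
    H = np.array([[0, 1], [1, 1], [0, 0]], dtype=np.uint8)
    missing = SiteLikelihoods("x", missing=True)
    vals = {emission(H, j, k, 1, missing, mu=0.01) for j in range(3) for k in range(3)}
    assert len({round(v, 12) for v in vals}) == 1


def test_emission_matches_two_flip_enumeration():
    """mu=0.01, copied genotype 1, L=(0,1,0): enumerate the four flip
    outcomes of the allele pair (1,0) and sum those that emit g=1."""
    mu = 0.01
    expected = 0.0
    for f0 in (0, 1):
        for f1 in (0, 1):
            alleles = (1 ^ f0, 0 ^ f1)
            p = (mu if f0 else 1 - mu) * (mu if f1 else 1 - mu)
            if sum(alleles) == 1:
                expected += p
    H = np.array([[1], [0]], dtype=np.uint8)
    L = SiteLikelihoods("x", gl=(0.0, 1.0, 0.0))
    assert emission(H, 0, 1, 0, L, mu) == pytest.approx(expected)
    assert expected == pytest.approx((1 - mu) ** 2 + mu**2)


def test_identical_allref_panel_no_evidence_gives_p0_one():
    H = np.zeros((2, 5), dtype=np.uint8)
    L = np.ones((5, 3))
    post = forward_backward(H, L, np.linspace(0, 1, 5), HMMParams(rho=0.04, mu=0.0))
    np.testing.assert_allclose(post[:, 0], 1.0)


def test_single_site_posterior_closed_form(rng):
    """At M=1 the posterior is the prior-weighted emission mix, computable
    by direct summation over the K^2 states."""
    K = 4
    H = rng.integers(0, 2, size=(K, 1)).astype(np.uint8)
    L = rng.random((1, 3)) + 0.01
    params = HMMParams(rho=0.3, mu=0.02)
    kernel = copy_error_kernel(params.mu)
    expected = np.zeros(3)
    for j in range(K):
        for k in range(K):
            g_star = int(H[j, 0]) + int(H[k, 0])
            expected += kernel[g_star] * L[0]
    expected /= expected.sum()
    post = forward_backward(H, L, np.array([0.0]), params)
    np.testing.assert_allclose(post[0], expected, atol=1e-12)


def test_forward_backward_matches_path_enumeration(rng):
    """Exact oracle equivalence on 50 random K=3, M=4 instances."""
    params = HMMParams(rho=0.5, mu=0.01)
    for _ in range(50):
        H = rng.integers(0, 2, size=(3, 4)).astype(np.uint8)
        L = rng.random((4, 3)) + 1e-3
        gmap = np.sort(rng.random(4) * 2)
        fb = forward_backward(H, L, gmap, params)
        bf = brute_force_posteriors(H, L, gmap, params)
        assert np.abs(fb - bf).max() < 1e-8


def test_brute_force_single_haplotype_is_emission_posterior(rng):
    H = rng.integers(0, 2, size=(1, 3)).astype(np.uint8)
    L = rng.random((3, 3)) + 0.05
    params = HMMParams(rho=0.1, mu=0.01)
    kernel = copy_error_kernel(params.mu)
    post = brute_force_posteriors(H, L, np.arange(3.0), params)
    for m in range(3):
        expected = kernel[2 * int(H[0, m])] * L[m]
        np.testing.assert_allclose(post[m], expected / expected.sum(), atol=1e-10)


def test_brute_force_rejects_large_instances():
    H = np.zeros((5, 3), dtype=np.uint8)
    with pytest.raises(ValueError, match="too large"):
        brute_force_posteriors(H, np.ones((3, 3)), np.arange(3.0), HMMParams())
    H = np.zeros((2, 7), dtype=np.uint8)
    with pytest.raises(ValueError, match="too large"):
        brute_force_posteriors(H, np.ones((7, 3)), np.arange(7.0), HMMParams())


def test_posteriors_sum_to_one(rng):
    for _ in range(10):
        K, M = int(rng.integers(2, 8)), int(rng.integers(1, 30))
        H = rng.integers(0, 2, size=(K, M)).astype(np.uint8)
        L = rng.random((M, 3)) + 1e-4
        post = forward_backward(H, L, np.sort(rng.random(M) * 5), HMMParams())
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)


def test_zero_likelihood_site_rejected():
    H = np.zeros((2, 2), dtype=np.uint8)  # all copied genotypes are 0
    L = np.array([[1.0, 1.0, 1.0], [0.0, 0.0, 1.0]])  # site 1 demands g=2
    with pytest.raises(ValueError, match="site index 1"):
        forward_backward(H, L, np.array([0.0, 0.1]), HMMParams(mu=0.0))


def _toy_panel():
    vs = [_snv(f"s{i}", 100_000 * (i + 1)) for i in range(8)]
    vs.insert(4, Variant("del0", "chr1", 450_000, 450_199, "DEL"))
    vs.sort(key=lambda v: v.pos)
    rng = np.random.default_rng(0)
    H = rng.integers(0, 2, size=(6, 9)).astype(np.uint8)
    return HaplotypePanel(H, ["a", "b", "c"], vs)


def test_gl_supplemented_excludes_evidence_less_svs():
    panel = _toy_panel()
    ev = {
        v.id: SiteLikelihoods(v.id, gl=(1.0, 0.5, 0.1))
        for v in panel.variants
        if v.var_class == "SNV"
    }
    ev["del0"] = SiteLikelihoods("del0", missing=True)
    chunks = chunk_genome(1_000_000, window=1_000_000, buffer=100_000)
    out_gl = impute_sample(panel, ev, chunks, HMMParams(), GL_SUPPLEMENTED)
    assert all(r.variant.var_class == "SNV" for r in out_gl)
    out_ld = impute_sample(panel, ev, chunks, HMMParams(), LD_ONLY)
    assert {r.variant.id for r in out_ld} == {v.id for v in panel.variants}


def test_imputed_records_unique_across_chunks():
    panel = _toy_panel()
    ev = {}
    chunks = chunk_genome(1_000_000, window=300_000, buffer=50_000)
    out = impute_sample(panel, ev, chunks, HMMParams(), LD_ONLY)
    ids = [r.variant.id for r in out]
    assert len(ids) == len(set(ids)) == len(panel.variants)


def test_empty_chunk_skipped_with_warning():
    panel = _toy_panel()  # sites all below 1 Mb
    chunks = [Chunk("chr1", 2_000_000, 3_000_000, 2_000_000, 3_000_000)]
    with pytest.warns(UserWarning, match="no panel sites"):
        out = impute_sample(panel, {}, chunks, HMMParams(), LD_ONLY)
    assert out == []


def test_ld_only_sv_posterior_invariant_to_sv_evidence():
    panel = _toy_panel()
    chunks = chunk_genome(1_000_000, window=1_000_000, buffer=100_000)
    strong = {"del0": SiteLikelihoods("del0", gl=(1e-6, 1e-6, 1.0))}
    a = impute_sample(panel, {}, chunks, HMMParams(), LD_ONLY)
    b = impute_sample(panel, strong, chunks, HMMParams(), LD_ONLY)
    ga = next(r.gp for r in a if r.variant.id == "del0")
    gb = next(r.gp for r in b if r.variant.id == "del0")
    np.testing.assert_array_equal(ga, gb)


def test_buffer_enlargement_leaves_core_posteriors_unchanged(default_panel):
    """Doubling the buffer beyond the default changes core-site posteriors
    by < 1e-6, justifying the chunked approximation."""
    cfg, panel, _ = default_panel
    sub = HaplotypePanel(panel.haplotypes[:20], panel.samples[:10], panel.variants)
    params = HMMParams()
    outs = []
    for buffer in (200_000, 500_000):
        chunks = chunk_genome(cfg.chrom_length, window=2_000_000, buffer=buffer)
        outs.append(impute_sample(sub, {}, chunks, params, LD_ONLY))
    gps_a = np.array([r.gp for r in outs[0]])
    gps_b = np.array([r.gp for r in outs[1]])
    assert np.abs(gps_a - gps_b).max() < 1e-6
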