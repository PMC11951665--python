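"""Site-level primitives: GL/PL math, maps, chunking, filtering, overlap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from svimpute.sites import (
    GenotypeCall,
    SnvSiteRecord,
    chunk_genome,
    extract_variable_sites,
    filter_snvs,
    gl_from_counts,
    gl_to_pl,
    make_genetic_map,
    merge_likelihood_sets,
    reciprocal_overlap_match,
)
from svimpute.types import HaplotypePanel, SiteLikelihoods, Variant


@pytest.mark.parametrize(
    "ref,alt,eps,expected",
    [
        (2, 0, 0.01, (0.9801, 0.25, 0.0001)),
        (0, 0, 0.01, (1.0, 1.0, 1.0)),
        (1, 1, 0.01, (0.0099, 0.25, 0.0099)),
    ],
)
def test_gl_from_counts_product_formula(ref, alt, eps, expected):
    np.testing.assert_allclose(gl_from_counts(ref, alt, eps), expected, rtol=1e-12)


def test_gl_from_counts_rejects_bad_inputs():
    with pytest.raises(ValueError):
        gl_from_counts(-1, 0, 0.01)
    with pytest.raises(ValueError):
        gl_from_counts(1, 1, 0.7)


@pytest.mark.parametrize(
    "gl,expected",
    [
        ((1.0, 0.1, 0.01), (0, 10, 20)),
        ((0.5, 0.5, 0.5), (0, 0, 0)),
        ((0.02, 0.001, 1e-8), (0, 13, 63)),
    ],
)
def test_gl_to_pl_phred_rounding(gl, expected):
    assert tuple(gl_to_pl(gl)) == expected


def test_gl_to_pl_rejects_all_zero():
    with pytest.raises(ValueError):
        gl_to_pl((0.0, 0.0, 0.0))


@given(
    st.tuples(
        st.floats(1e-6, 1.0), st.floats(1e-6, 1.0), st.floats(1e-6, 1.0)
    )
)
@settings(max_examples=200, derandomize=True)
def test_gl_to_pl_ratio_roundtrip_within_half_phred(gl):
    """Integer PLs reproduce the input likelihood ratios within rounding."""
    gl = np.asarray(gl)
    pl = gl_to_pl(gl)
    exact = -10 * np.log10(gl / gl.max())
    assert np.abs(pl - exact).max() <= 0.5 + 1e-9


def test_merge_likelihood_sets_union_and_missing():
    snvs = {f"s{i}": SiteLikelihoods(f"s{i}", gl=(1, 1, 1)) for i in range(3)}
    svs = {
        "d0": SiteLikelihoods("d0", pl=(0, 10, 20)),
        "d1": SiteLikelihoods("d1", missing=True),
    }
    merged = merge_likelihood_sets(snvs, svs)
    assert len(merged) == 5
    assert merged["d1"].missing
    with pytest.raises(ValueError, match="duplicate"):
        merge_likelihood_sets(snvs, {"s0": SiteLikelihoods("s0", gl=(1, 1, 1))})


def test_extract_variable_sites_drops_fixed_columns():
    vs = [
        Variant("a", "chr1", 100, 100, "SNV"),
        Variant("b", "chr1", 200, 299, "DEL"),
        Variant("c", "chr1", 300, 300, "SNV"),
    ]
    H = np.array([[0, 1, 1], [1, 0, 1], [0, 1, 1], [1, 0, 1]])
    panel = HaplotypePanel(H, ["x", "y"], vs)
    out = extract_variable_sites(panel)
    assert [v.id for v in out] == ["a", "b"]  # fixed column c excluded
    assert {v.var_class for v in out} == {"SNV", "DEL"}
    assert [v.pos for v in out] == sorted(v.pos for v in out)


def test_genetic_map_one_mb_per_cm():
    vs = [
        Variant("a", "chr1", 250_000, 250_000, "SNV"),
        Variant("b", "chr1", 1_000_000, 1_000_000, "SNV"),
    ]
    cm = make_genetic_map(vs)
    np.testing.assert_allclose(cm, [0.25, 1.0])
    assert (np.diff(cm) >= 0).all()
    with pytest.raises(ValueError, match="sorted"):
        make_genetic_map(vs[::-1])


def test_chunk_250mb_default_window_and_buffer():
    chunks = chunk_genome(250_000_000)
    assert [(c.start, c.end) for c in chunks] == [
        (1, 100_000_000),
        (100_000_001, 200_000_000),
        (200_000_001, 250_000_000),
    ]
    assert chunks[0].bend == 100_200_000
    assert chunks[0].bstart == 1
    assert chunks[-1].bend == 250_000_000


def test_chunk_short_chromosome_single_chunk():
    (c,) = chunk_genome(50_000_000)
    assert (c.start, c.end) == (1, 50_000_000)
    assert (c.bstart, c.bend) == (1, 50_000_000)


def test_chunk_custom_window_and_buffer():
    chunks = chunk_genome(10_000_000, window=4_000_000, buffer=500_000)
    assert [(c.start, c.end) for c in chunks] == [
        (1, 4_000_000),
        (4_000_001, 8_000_000),
        (8_000_001, 10_000_000),
    ]


def test_chunk_rejects_bad_inputs():
    with pytest.raises(ValueError):
        chunk_genome(0)
    with pytest.raises(ValueError):
        chunk_genome(100, window=10, buffer=5)


@given(
    st.integers(1, 500_000_000),
    st.integers(1_000_000, 200_000_000),
    st.integers(1, 400_000),
)
@settings(max_examples=100, derandomize=True)
def test_chunk_cores_partition_exactly(length, window, buffer):
    if not window > 2 * buffer:
        window = 2 * buffer + 1
    chunks = chunk_genome(length, window=window, buffer=buffer)
    assert chunks[0].start == 1 and chunks[-1].end == length
    for a, b in zip(chunks, chunks[1:]):
        assert b.start == a.end + 1
    assert sum(c.end - c.start + 1 for c in chunks) == length
    assert all(c.bstart <= c.start and c.bend >= c.end for c in chunks)


def _sv(vid, pos, end, cls="DEL"):
    return Variant(vid, "chr1", pos, end, cls)


def test_reciprocal_overlap_truth_table():
    assert reciprocal_overlap_match(_sv("a", 100, 199), _sv("b", 105, 204))
    assert not reciprocal_overlap_match(_sv("a", 100, 199), _sv("b", 150, 249))
    assert reciprocal_overlap_match(_sv("a", 100, 199), _sv("b", 100, 199))
    # class and chromosome mismatches never match
    assert not reciprocal_overlap_match(_sv("a", 100, 199), _sv("b", 100, 199, "DUP"))
    assert not reciprocal_overlap_match(
        _sv("a", 100, 199), Variant("b", "chr2", 100, 199, "DEL")
    )


@given(
    st.integers(1, 10_000),
    st.integers(100, 5_000),
    st.integers(1, 10_000),
    st.integers(100, 5_000),
)
@settings(max_examples=200, derandomize=True)
def test_reciprocal_overlap_symmetric(pa, la, pb, lb):
    a, b = _sv("a", pa, pa + la - 1), _sv("b", pb, pb + lb - 1)
    assert reciprocal_overlap_match(a, b) == reciprocal_overlap_match(b, a)


def _snv_record(vid, pos=1000, qual=50.0, n_alleles=2, is_indel=False, genotypes=None):
    if genotypes is None:
        # 10 clean calls, MAF 0.25
        genotypes = [GenotypeCall(d) for d in [0, 0, 0, 1, 1, 0, 1, 1, 1, 0]]
    return SnvSiteRecord(
        Variant(vid, "chr1", pos, pos, "SNV"), qual, n_alleles, is_indel, genotypes
    )


def test_filter_snvs_each_rule_removes_one_record():
    failing = [
        _snv_record("low_maf", genotypes=[GenotypeCall(0)] * 99 + [GenotypeCall(1)]),
        _snv_record("low_qual", qual=29.9),
        _snv_record("multi_allelic", n_alleles=3),
        _snv_record("indel", is_indel=True),
        _snv_record(
            "low_gq",  # masking GQ<10 drops call rate below 0.7
            genotypes=[GenotypeCall(1, gq=5.0)] * 4
            + [GenotypeCall(d) for d in [0, 1, 0, 1, 0, 1]],
        ),
        _snv_record(
            "low_dp",  # masking DP<4 drops call rate below 0.7
            genotypes=[GenotypeCall(1, dp=3)] * 4
            + [GenotypeCall(d) for d in [0, 1, 0, 1, 0, 1]],
        ),
    ]
    assert filter_snvs(failing) == []
    passing = _snv_record("clean")
    out = filter_snvs(failing + [passing])
    assert [r.variant.id for r in out] == ["clean"]


def test_filter_snvs_maf_boundary_inclusive():
    # 100 diploid calls: 2 alt alleles -> MAF 0.010 kept, 1 alt -> 0.005 removed
    at_boundary = _snv_record(
        "maf_0.010", genotypes=[GenotypeCall(0)] * 99 + [GenotypeCall(2)]
    )
    below = _snv_record(
        "maf_0.005", genotypes=[GenotypeCall(0)] * 99 + [GenotypeCall(1)]
    )
    assert [r.variant.id for r in filter_snvs([at_boundary, below])] == ["maf_0.010"]


def test_filter_snvs_all_passing_unchanged():
    records = [_snv_record(f"v{i}", pos=1000 + i) for i in range(5)]
    assert filter_snvs(records) == records
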