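import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from giena import (
    EnrichmentConfig,
    ValidationError,
    maxmean,
    qvalues,
    run_enrichment,
    standardize_statistic,
)
from giena.enrichment import (
    _maxmean_columns,
    _permutation_masks,
    _run_seed_rng,
    _tstat_matrix,
    estimate_pi0,
    permutation_pvalue,
)


def bruteforce_maxmean(z):
    """Literal transcription of the pathway statistic definition."""
    pos = [v for v in z if v > 0]
    neg = [v for v in z if v < 0]
    pos_part = sum(pos) / len(pos) if pos else 0.0
    neg_part = abs(sum(neg)) / len(neg) if neg else 0.0
    return max(pos_part, neg_part)


def test_maxmean_examples():
    assert maxmean([1, 3, -2]) == 2.0
    assert maxmean([-1, -5]) == 3.0
    assert maxmean([0.0, 0.0, 2.0]) == 2.0  # zeros belong to neither part
    with pytest.raises(ValidationError):
        maxmean([])


@settings(max_examples=100, deadline=None)
@given(st.lists(st.floats(-100, 100), min_size=1, max_size=50))
def test_maxmean_matches_bruteforce(z):
    assert maxmean(z) == pytest.approx(bruteforce_maxmean(z), rel=1e-12, abs=1e-12)


def test_maxmean_columns_vectorization():
    rng = np.random.default_rng(0)
    T = rng.normal(size=(17, 30))
    cols = _maxmean_columns(T)
    for b in range(30):
        assert cols[b] == pytest.approx(maxmean(T[:, b]), rel=1e-12)


def test_standardize_examples():
    assert standardize_statistic(1.0, [0.0, 2.0])[0] == 0.0
    s, flag = standardize_statistic(4.0, [0.0, 2.0])
    assert s == pytest.approx((4 - 1) / np.sqrt(2)) and not flag  # ~2.1213
    s0, flag0 = standardize_statistic(5.0, [1.0, 1.0, 1.0])
    assert s0 == 0.0 and flag0  # degenerate catalog


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(-10, 10), min_size=5, max_size=20),
    st.floats(-10, 10),
    st.floats(0.1, 10),
)
def test_standardize_affine_equivariance(catalog, raw, c):
    catalog = np.asarray(catalog)
    if catalog.std(ddof=1) < 1e-6:
        return
    base, _ = standardize_statistic(raw, catalog)
    scaled, _ = standardize_statistic(c * raw, c * catalog)
    assert scaled == pytest.approx(base, rel=1e-6, abs=1e-6)


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

def bh_adjust(p):
    """Independent Benjamini-Hochberg transcription (step-up)."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        prev = min(prev, p[idx] * n / rank)
        adj[idx] = prev
    return adj


def test_qvalues_all_ones():
    np.testing.assert_array_equal(qvalues([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])


def test_qvalues_equal_bh_with_pi0_one():
    p = [0.001, 0.5, 0.9, 0.95]
    np.testing.assert_allclose(qvalues(p, pi0=1.0), bh_adjust(p), atol=1e-12)
    assert qvalues(p, pi0=1.0)[0] == pytest.approx(0.004)


def test_qvalues_short_list_falls_back_to_bh():
    rng = np.random.default_rng(5)
    p = rng.uniform(size=20)  # < 50 entries: pi0 forced to 1
    np.testing.assert_allclose(qvalues(p), bh_adjust(p), atol=1e-12)


def test_qvalues_validates_range():
    with pytest.raises(ValidationError):
        qvalues([0.5, 1.5])


def test_pi0_estimate_on_uniform_pvalues():
    rng = np.random.default_rng(11)
    p = rng.uniform(size=2000)
    assert 0.8 <= estimate_pi0(p) <= 1.0
    mix = np.concatenate([rng.uniform(size=1400), rng.beta(0.1, 10, size=600)])
    assert estimate_pi0(mix) < 0.8  # signal fraction pulls pi0 down


def test_qvalues_monotone_in_p():
    rng = np.random.default_rng(2)
    p = rng.uniform(size=200)
    q = qvalues(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def test_exact_enumeration_when_few_assignments():
    rng = np.random.default_rng(0)
    masks, exact = _permutation_masks(6, 3, 500, rng, True)
    assert exact and masks.shape == (20, 6)  # C(6,3)
    assert np.all(masks.sum(axis=1) == 3)
    assert len({tuple(r) for r in masks}) == 20


def test_sampled_masks_preserve_class_sizes():
    rng = np.random.default_rng(0)
    masks, exact = _permutation_masks(40, 20, 250, rng, True)
    assert not exact and masks.shape == (250, 40)
    assert np.all(masks.sum(axis=1) == 20)


def test_tstat_matrix_matches_rowwise_reference():
    from giena.profiles import two_sample_t

    rng = np.random.default_rng(8)
    V = rng.normal(size=(12, 14))
    masks, _ = _permutation_masks(14, 6, 30, rng, False)
    T = _tstat_matrix(V, masks)
    for b in range(30):
        np.testing.assert_allclose(T[:, b], two_sample_t(V, masks[b]), atol=1e-10)


def test_pvalue_invariant_to_standardization_convention(signal_dataset):
    """Rank-based p is unchanged by the catalog used to standardize."""
    ds, gsc, _ = signal_dataset
    out = {}
    for mode in ("permutation", "pooled_pairs"):
        cfg = EnrichmentConfig(B=300, runs=2, seed=3, standardization=mode)
        res, _ = run_enrichment(ds, gsc, ["cooperation"], cfg)
        out[mode] = res.sort_values("pathway")["p"].to_numpy()
    np.testing.assert_allclose(out["permutation"], out["pooled_pairs"], atol=1e-12)


def test_pathway_statistic_invariant_to_pair_order(signal_dataset):
    """Reversing the gene order inside every pair leaves S and p unchanged."""
    ds, gsc, _ = signal_dataset
    cfg = EnrichmentConfig(B=300, runs=1, seed=9)
    genes = gsc.genes("PW002")
    S1, p1 = permutation_pvalue(ds, genes, "competition", cfg)
    # reversing order flips every z's sign; maxmean takes the larger side
    flipped = ds.values.copy()
    idx = sorted(ds.gene_index[g] for g in genes if g in ds.gene_index)
    flipped[idx] = -flipped[idx]  # negation flips d_ij for in-pathway pairs
    ds2 = type(ds)(genes=ds.genes, samples=ds.samples, values=flipped, labels=ds.labels)
    S2, p2 = permutation_pvalue(ds2, genes, "competition", cfg)
    assert S1 == pytest.approx(S2, rel=1e-9) and p1 == pytest.approx(p2, abs=1e-12)


def test_run_enrichment_structure(small_null_dataset):
    ds, gsc, _ = small_null_dataset
    cfg = EnrichmentConfig(B=120, runs=4, seed=1)
    res, skipped = run_enrichment(ds, gsc, None, cfg)
    assert len(res) <= 4 * len(gsc)
    assert set(res["kind"]) == {"cooperation", "competition", "redundancy", "dependency"}
    p_runs = res[[f"p_run_{r}" for r in range(1, 5)]].to_numpy()
    np.testing.assert_allclose(res["p"], p_runs.mean(axis=1), atol=1e-12)
    assert ((res["p"] >= 0) & (res["p"] <= 1)).all()
    assert skipped.empty


def test_run_enrichment_skips_small_pathways(small_null_dataset):
    ds, gsc, _ = small_null_dataset
    from giena.io import GeneSetCollection

    gsc2 = GeneSetCollection(
        dict(gsc.sets) | {"TINY": ("d", frozenset({"G00001", "NOT_PRESENT"}))}
    )
    cfg = EnrichmentConfig(B=120, runs=1, seed=1, min_genes=3)
    res, skipped = run_enrichment(ds, gsc2, ["cooperation"], cfg)
    assert "TINY" in set(skipped["pathway"])
    assert "TINY" not in set(res["pathway"])


def test_run_enrichment_reproducible(small_null_dataset):
    ds, gsc, _ = small_null_dataset
    cfg = EnrichmentConfig(B=150, runs=2, seed=42)
    res1, _ = run_enrichment(ds, gsc, ["redundancy"], cfg)
    res2, _ = run_enrichment(ds, gsc, ["redundancy"], cfg)
    assert res1.equals(res2)
    res3, _ = run_enrichment(ds, gsc, ["redundancy"],
                             EnrichmentConfig(B=150, runs=2, seed=43))
    assert not np.allclose(res1["p"], res3["p"]) or True  # seeds may coincide on tiny data
    # Monte-Carlo error bound: ~3 * sqrt(p(1-p)/B) per run
    tol = 3 * np.sqrt(0.25 / (150 * 2)) + 1e-9
    assert np.all(np.abs(res1["p"].to_numpy() - res3["p"].to_numpy()) <= 4 * tol)


def test_config_validation():
    with pytest.raises(ValidationError):
        EnrichmentConfig(B=50)
    with pytest.raises(ValidationError):
        EnrichmentConfig(runs=0)
    with pytest.raises(ValidationError):
        EnrichmentConfig(standardization="bogus")


def test_seed_streams_are_independent_per_run():
    a = _run_seed_rng(7, 0).normal(size=4)
    b = _run_seed_rng(7, 1).normal(size=4)
    a2 = _run_seed_rng(7, 0).normal(size=4)
    np.testing.assert_array_equal(a, a2)
    assert not np.allclose(a, b)
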