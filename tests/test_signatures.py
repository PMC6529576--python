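import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from exomeburden.contexts import CONTEXT_LABELS, complement
from exomeburden.signatures import (
    SignatureCatalog,
    _em_fit,
    exposure_covariate_correlation,
    fit_exposures,
    select_and_refit,
    spectrum_96,
    spectrum_from_records,
    synthetic_catalog,
)

BASES = "ACGT"


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def test_purine_reference_is_reverse_complemented():
    # G>T with plus-strand context 5'-AGA-3' lands in T[C>A]T
    (idx,) = np.flatnonzero(spectrum_from_records([("G", "T", "A", "A")]))
    assert CONTEXT_LABELS[idx] == "T[C>A]T"


def test_pyrimidine_reference_binned_directly():
    (idx,) = np.flatnonzero(spectrum_from_records([("C", "T", "A", "G")]))
    assert CONTEXT_LABELS[idx] == "A[C>T]G"


@given(
    st.lists(
        st.tuples(
            st.sampled_from(BASES), st.sampled_from(BASES),
            st.sampled_from(BASES), st.sampled_from(BASES),
        ).filter(lambda t: t[0] != t[1]),
        min_size=1, max_size=50,
    )
)
def test_strand_flip_invariance(records):
    """Reverse-complementing every record leaves the spectrum unchanged."""
    flipped = [
        (complement(r), complement(a), complement(t3), complement(t5))
        for r, a, t5, t3 in records
    ]
    assert (spectrum_from_records(records) == spectrum_from_records(flipped)).all()


def test_spectrum_total_conserved(small_exome):
    from exomeburden.dnds import draw_coding_snvs

    draws = draw_coding_snvs(small_exome, 200, seed=1)

    class V:
        def __init__(self, r):
            self.chrom, self.pos, self.ref, self.alt = r.chrom, r.pos, r.ref, r.alt

    spec = spectrum_96([V(r) for r in draws.itertuples()], small_exome)
    assert spec.sum() == 200


def test_spectrum_edge_variant_rejected(small_exome):
    class V:
        chrom, pos, ref, alt = "chr1", 1, None, "A"

    V.ref = small_exome.chromosome_sequences["chr1"][0]
    V.alt = "A" if V.ref != "A" else "C"
    with pytest.raises(ValueError, match="chr1:1"):
        spectrum_96([V], small_exome)


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------


def test_catalog_roundtrip(tmp_path, catalog30):
    catalog30.to_tsv(tmp_path / "cat.tsv")
    back = SignatureCatalog.from_tsv(tmp_path / "cat.tsv")
    assert back.names == catalog30.names
    assert np.allclose(back.matrix, catalog30.matrix)


def test_catalog_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        SignatureCatalog(names=["a"], matrix=np.full((96, 1), 0.5))
    with pytest.raises(ValueError, match="non-negative"):
        m = np.full((96, 1), 1 / 96)
        m[0] = -m[0]
        m[1] += 2 / 96
        SignatureCatalog(names=["a"], matrix=m)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_single_active_signature_recovered(catalog30):
    rng = np.random.default_rng(7)
    spec = rng.multinomial(1000, catalog30.matrix[:, 3])
    est = fit_exposures(spec, catalog30, n_bootstrap=100, seed=1)
    assert est.weights[3] >= 0.95


def test_two_signature_mixture_recovered(catalog30):
    rng = np.random.default_rng(8)
    truth = np.zeros(30)
    truth[[2, 7]] = [0.6, 0.4]
    spec = rng.multinomial(10_000, catalog30.matrix @ truth)
    est = fit_exposures(spec, catalog30, n_bootstrap=100, seed=2)
    assert abs(est.weights[2] - 0.6) < 0.05
    assert abs(est.weights[7] - 0.4) < 0.05


def test_single_signature_catalog_weight_one(catalog30):
    sub = catalog30.subset(["SBS_S04"])
    rng = np.random.default_rng(9)
    spec = rng.multinomial(500, sub.matrix[:, 0])
    est = fit_exposures(spec, sub, n_bootstrap=50, seed=0)
    assert est.weights[0] == 1.0


def test_exposures_stay_on_simplex(catalog30):
    rng = np.random.default_rng(11)
    for _ in range(5):
        spec = rng.multinomial(200, rng.dirichlet(np.ones(96)))
        est = fit_exposures(spec, catalog30, n_bootstrap=20, seed=3)
        assert (est.weights >= 0).all()
        assert abs(est.weights.sum() - 1) < 1e-6


def test_em_likelihood_never_decreases(catalog30):
    """The EM objective is monotone: final fit is at least as good as any
    truncated run, on arbitrary spectra."""
    rng = np.random.default_rng(13)
    for _ in range(5):
        counts = rng.multinomial(300, rng.dirichlet(np.ones(96))).astype(float)
        lls = []
        for iters in (1, 3, 10, 100, 1000):
            _, ll = _em_fit(counts, catalog30.matrix, max_iter=iters)
            lls.append(ll)
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


def test_em_matches_grid_search_on_two_signatures(catalog30):
    """1-D grid search over the two-signature simplex as an independent
    oracle for the EM optimum."""
    sub = catalog30.subset(["SBS_S01", "SBS_S02"])
    rng = np.random.default_rng(17)
    truth = 0.35
    probs = truth * sub.matrix[:, 0] + (1 - truth) * sub.matrix[:, 1]
    counts = rng.multinomial(5000, probs).astype(float)
    grid = np.linspace(0, 1, 2001)
    mix = np.outer(sub.matrix[:, 0], grid) + np.outer(sub.matrix[:, 1], 1 - grid)
    mask = counts > 0
    lls = counts[mask] @ np.log(mix[mask, :])
    best = grid[np.argmax(lls)]
    w, _ = _em_fit(counts, sub.matrix)
    assert abs(w[0] - best) < 2e-3


def test_recovery_degrades_gracefully(catalog30):
    truth = np.zeros(30)
    truth[[0, 4, 11]] = [0.5, 0.3, 0.2]
    probs = catalog30.matrix @ truth

    def recovery_error(n, seed):
        rng = np.random.default_rng(seed)
        spec = rng.multinomial(n, probs)
        est = fit_exposures(spec, catalog30, n_bootstrap=10, seed=seed)
        return np.abs(est.weights - truth).sum()

    small = np.mean([recovery_error(100, s) for s in range(5)])
    large = np.mean([recovery_error(10_000, s) for s in range(5)])
    assert small > large


def test_empty_spectrum_rejected(catalog30):
    with pytest.raises(ValueError, match=">= 1"):
        fit_exposures(np.zeros(96), catalog30, n_bootstrap=10)


def test_dimension_mismatch_rejected(catalog30):
    with pytest.raises(ValueError, match="dimension"):
        fit_exposures(np.ones(95), catalog30, n_bootstrap=10)


# ---------------------------------------------------------------------------
# select-and-refit
# ---------------------------------------------------------------------------


def test_three_of_thirty_selected(catalog30):
    rng = np.random.default_rng(21)
    truth = np.zeros(30)
    truth[[0, 4, 11]] = [0.5, 0.3, 0.2]
    spec = rng.multinomial(10_000, catalog30.matrix @ truth)
    est = select_and_refit(spec, catalog30, n_bootstrap=200, seed=5)
    selected = {n for n, s in zip(est.signatures, est.selected) if s}
    assert selected == {"SBS_S01", "SBS_S05", "SBS_S12"}
    for i, w in [(0, 0.5), (4, 0.3), (11, 0.2)]:
        assert abs(est.weights[i] - w) < 0.05


def test_single_truth_signature_refit_weight_one(catalog30):
    rng = np.random.default_rng(23)
    spec = rng.multinomial(2000, catalog30.matrix[:, 6])
    est = select_and_refit(spec, catalog30, n_bootstrap=100, seed=6)
    assert est.weights[6] == 1.0
    assert est.selected[6]


def test_zero_threshold_keeps_all_confident_signatures():
    cat = synthetic_catalog(2, seed=5)
    rng = np.random.default_rng(25)
    spec = rng.multinomial(20_000, cat.matrix @ np.array([0.5, 0.5]))
    est = select_and_refit(spec, cat, threshold=0.0, n_bootstrap=100, seed=7)
    assert est.selected.all()  # stage 2 catalog equals stage 1


def test_fallback_to_best_signature_when_none_selected(catalog30, caplog):
    rng = np.random.default_rng(27)
    # threshold above any achievable weight forces the fallback path
    spec = rng.multinomial(50, np.full(96, 1 / 96))
    est = select_and_refit(spec, catalog30, threshold=1.1, n_bootstrap=20, seed=8)
    assert est.selected.sum() == 1
    assert est.weights[np.argmax(est.selected)] == 1.0


# ---------------------------------------------------------------------------
# exposure-covariate correlation
# ---------------------------------------------------------------------------


def test_perfectly_monotone_rho_one():
    rho, p = exposure_covariate_correlation([1, 2, 3, 4], [10, 20, 30, 40])
    assert rho == 1.0
    assert p == pytest.approx(2 / 24)  # two of 4! pairings reach |rho|=1


def test_reversed_ranks_rho_minus_one():
    rho, _ = exposure_covariate_correlation([1, 2, 3, 4], [4, 3, 2, 1])
    assert rho == -1.0


def test_exact_permutation_p_matches_brute_force_oracle():
    rng = np.random.default_rng(31)
    x = rng.random(6)
    y = rng.random(6)
    rho_obs, p = exposure_covariate_correlation(x, y)
    # oracle: scipy spearman statistic over every pairing
    count = 0
    total = 0
    for perm in itertools.permutations(y):
        r = stats.spearmanr(x, perm).statistic
        count += abs(r) >= abs(rho_obs) - 1e-12
        total += 1
    assert p == pytest.approx(count / total)


def test_large_n_uses_asymptotic_p():
    rng = np.random.default_rng(33)
    x = rng.random(50)
    y = x + rng.normal(0, 0.3, 50)
    rho, p = exposure_covariate_correlation(x, y)
    ref = stats.spearmanr(x, y)
    assert rho == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)


def test_constant_covariate_rejected():
    with pytest.raises(ValueError, match="constant"):
        exposure_covariate_correlation([1, 2, 3], [5, 5, 5])


def test_too_few_pairs_rejected():
    with pytest.raises(ValueError, match="at least 3"):
        exposure_covariate_correlation([1, 2], [1, 2])
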