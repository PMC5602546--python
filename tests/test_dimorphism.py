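import numpy as np
import pandas as pd
import pytest

from hepadim import dimorphism as dim
from hepadim import simulate as sim
from hepadim.io import CountMatrix, FoldChangeTable, FormatError


def make_cm(counts, sexes):
    counts = np.asarray(counts)
    samples = [f"s{i}" for i in range(counts.shape[1])]
    meta = pd.DataFrame(
        {"sex": sexes, "dose": 0.0, "duration": 28},
        index=pd.Index(samples, name="sample_id"),
    )
    return CountMatrix(
        [f"g{i}" for i in range(counts.shape[0])], samples, counts, meta
    )


def fc_table(rows):
    return FoldChangeTable(
        pd.DataFrame(
            [(g, "c", l, p, 100) for g, l, p in rows],
            columns=["gene_id", "contrast_id", "log2fc", "p1t", "max_reads"],
        )
    )


# ---------------------------------------------------------------------------
# VST and normalization
# ---------------------------------------------------------------------------


def test_vst_maps_zero_to_zero_and_is_monotone():
    cm = make_cm([[0, 10], [5, 0], [100, 1000]], ["male", "female"])
    mat = dim.vst(cm).to_numpy()
    assert mat[0, 0] == 0.0
    assert mat[1, 1] == 0.0
    col = dim.vst(make_cm([[0, 0], [10, 10], [200, 200]], ["male", "female"]))
    assert (np.diff(col.to_numpy()[:, 0]) > 0).all()


def test_vst_rejects_degenerate_input():
    with pytest.raises(FormatError):
        dim.vst(make_cm(np.zeros((3, 2), dtype=int), ["male", "female"]))


def test_size_factor_equivariance_under_sample_scaling(rng):
    counts = rng.integers(1, 2000, size=(300, 6))
    sf = dim.size_factors(counts)
    scaled = counts.copy()
    scaled[:, 2] *= 3
    sf2 = dim.size_factors(scaled)
    # scaling one sample scales its factor relative to every other sample
    np.testing.assert_allclose(
        (sf2[2] / sf2[0]), 3.0 * (sf[2] / sf[0]), rtol=1e-9
    )


def test_vst_flattens_the_mean_variance_trend():
    cm, _ = sim.simulate_counts(
        n_genes=4000, n_per_sex=10, frac_male_biased=0.0, frac_female_biased=0.0,
        dispersion=0.05, seed=8,
    )
    mat = dim.vst(cm).to_numpy()
    mean = np.asarray(cm.counts).mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    order = np.argsort(mean)
    bins = np.array_split(order, 20)
    bm = np.array([np.log(mean[b].mean()) for b in bins])
    bs = np.array([np.log(sd[b].mean()) for b in bins])
    slope = np.polyfit(bm, bs, 1)[0]
    assert -0.25 <= slope <= 0.25


def test_normalize_identity_and_shift_removal(rng):
    mat = pd.DataFrame(rng.normal(5, 1, size=(100, 2)))
    mat[1] = mat[0]
    out = dim.normalize(mat)
    pd.testing.assert_frame_equal(out, mat)

    # columns that differ only by per-sample constant offsets collapse to one
    x = rng.normal(5, 1, size=100)
    offsets = [0.0, -1.2, 3.7, 0.4]
    mat = pd.DataFrame({j: x + c for j, c in enumerate(offsets)})
    out = dim.normalize(mat).to_numpy()
    for j in range(1, 4):
        np.testing.assert_allclose(out[:, j], out[:, 0], atol=1e-9)


def test_normalize_single_sample_is_identity_with_warning(caplog):
    mat = pd.DataFrame({"s": [1.0, 2.0]})
    with caplog.at_level("WARNING", logger="hepadim"):
        out = dim.normalize(mat)
    pd.testing.assert_frame_equal(out, mat)
    assert any("single sample" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# Empirical Bayes
# ---------------------------------------------------------------------------


def test_identical_groups_give_zero_log2fc_exactly(rng):
    x = rng.normal(5, 1, size=(50, 3))
    mat = pd.DataFrame(np.hstack([x, x]))
    table, _ = dim.empirical_bayes_posteriors(
        mat, ["male"] * 3 + ["female"] * 3, groups=("male", "female")
    )
    assert (table.data["log2fc"] == 0.0).all()


def test_label_swap_negates_fc_and_preserves_p1t():
    cm, _ = sim.simulate_counts(n_genes=800, seed=10)
    mat = dim.normalize(dim.vst(cm))
    labels = [cm.sex_of(s) for s in cm.sample_ids]
    t1, _ = dim.empirical_bayes_posteriors(mat, labels, groups=("male", "female"))
    t2, _ = dim.empirical_bayes_posteriors(mat, labels, groups=("female", "male"))
    np.testing.assert_array_equal(
        t1.data["log2fc"].to_numpy(), -t2.data["log2fc"].to_numpy()
    )
    np.testing.assert_array_equal(t1.data["p1t"].to_numpy(), t2.data["p1t"].to_numpy())


def test_em_loglik_is_nondecreasing_and_weights_sum_to_one(rng):
    t = np.concatenate([rng.normal(0, 1, 900), rng.normal(0, 6, 100)])
    fit = dim.fit_scale_mixture(t)
    assert (np.diff(fit.loglik_path) >= -1e-8).all()
    assert fit.pi0 + fit.pi1 == pytest.approx(1.0)
    assert fit.sigma1 >= 2 * fit.sigma0


def test_posteriors_are_calibrated_on_planted_data():
    cm, truth = sim.simulate_counts(n_genes=2000, seed=12)
    table, calls, _ = dim.dimorphism_analysis(cm)
    planted = set(truth.male_biased_ids) | set(truth.female_biased_ids)
    confident = table.data[table.data.p1t >= 0.8]
    tp = confident.gene_id.isin(planted).mean()
    assert tp >= 0.7


def test_groups_need_two_samples_each():
    mat = pd.DataFrame(np.ones((10, 3)))
    with pytest.raises(FormatError):
        dim.empirical_bayes_posteriors(
            mat, ["male", "male", "female"], groups=("male", "female")
        )


# ---------------------------------------------------------------------------
# Threshold calls
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "log2fc,p1t,bias",
    [
        (1.0, 0.8, "male"),      # 2.0-fold at the posterior gate: inclusive
        (3.0, 0.5, "none"),      # large fold blocked by the posterior gate
        (-1.0, 0.8, "female"),
        (np.log2(1.99), 0.99, "none"),
    ],
)
def test_dimorphic_call_boundaries(log2fc, p1t, bias):
    (call,) = dim.call_dimorphic(fc_table([("g", log2fc, p1t)]))
    assert call.bias == bias


@pytest.mark.parametrize(
    "fold,p1t,de,direction",
    [
        (1.5, 0.9, True, "induced"),
        (1.4, 0.99, False, "none"),
        (-3.0, 0.95, True, "repressed"),  # Gstp1-scale repression in males
    ],
)
def test_differential_call_boundaries(fold, p1t, de, direction):
    log2fc = np.sign(fold) * np.log2(abs(fold))
    out = dim.call_differential(fc_table([("g", log2fc, p1t)]))
    assert bool(out.loc[0, "de"]) is de
    assert out.loc[0, "direction"] == direction


def test_all_zero_genes_are_dropped_and_reported():
    counts = np.array([[0, 0, 0, 0], [5, 6, 7, 8], [9, 1, 2, 3]])
    cm = make_cm(counts, ["male", "male", "female", "female"])
    table, _, dropped = dim.dimorphism_analysis(cm)
    assert dropped == ["g0"]
    assert list(table.data.gene_id) == ["g1", "g2"]
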