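"""Negative-binomial differential expression: normalisation, dispersion,
Wald test and BH adjustment."""

import numpy as np
import pandas as pd
import pytest

from cladecompare import (
    CountsTable,
    GroupContrastNB,
    adjust_bh,
    estimate_dispersions,
    filter_core_transcriptome,
    size_factors,
    wald_test,
)
from cladecompare.de import DEError

from oracles import bh_step_up


def _table(data, samples, groups):
    frame = pd.DataFrame(data, columns=samples)
    frame.index = [f"c{i + 1}" for i in range(len(frame))]
    return CountsTable(frame, groups)


GROUPS22 = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}


def test_core_filter_drops_rows_with_zeros():
    table = _table(
        [[5, 0, 3, 1], [1, 1, 1, 1], [2, 3, 4, 5], [9, 9, 0, 9], [7, 8, 9, 10]],
        ["s1", "s2", "s3", "s4"], GROUPS22,
    )
    core = filter_core_transcriptome(table)
    assert list(core.counts.index) == ["c2", "c3", "c5"]
    strict = filter_core_transcriptome(table, min_count=2)
    assert list(strict.counts.index) == ["c3", "c5"]


def test_size_factors_identical_samples_are_one():
    table = _table([[10, 10], [5, 5], [100, 100]], ["s1", "s2"],
                   {"s1": "A", "s2": "B"})
    f = size_factors(table)
    assert np.allclose(f, 1.0)


def test_size_factors_doubled_sample():
    table = _table(
        [[10, 20], [4, 8], [100, 200], [7, 14]],
        ["s1", "s2"], {"s1": "A", "s2": "B"},
    )
    f = size_factors(table)
    assert f["s1"] == pytest.approx(1 / np.sqrt(2), rel=1e-12)
    assert f["s2"] == pytest.approx(np.sqrt(2), rel=1e-12)


def test_size_factors_single_sample_is_one():
    table = _table([[10], [5]], ["s1"], {"s1": "A"})
    assert size_factors(table)["s1"] == pytest.approx(1.0)


def test_size_factors_require_all_positive_gene():
    table = _table([[0, 5], [5, 0]], ["s1", "s2"], {"s1": "A", "s2": "B"})
    with pytest.raises(DEError, match="core"):
        size_factors(table)


def test_dispersion_zero_for_constant_counts():
    data = np.full((3, 6), 50)
    samples = [f"s{i}" for i in range(6)]
    groups = {s: ("A" if i < 3 else "B") for i, s in enumerate(samples)}
    table = _table(data, samples, groups)
    alphas = estimate_dispersions(table, size_factors(table))
    assert np.allclose(alphas, 0.0)


def test_dispersion_poisson_limit_small():
    rng = np.random.default_rng(0)
    samples = [f"s{i}" for i in range(50)]
    groups = {s: ("A" if i < 25 else "B") for i, s in enumerate(samples)}
    data = rng.poisson(500.0, size=(300, 50))
    table = _table(data, samples, groups)
    factors = pd.Series(1.0, index=samples)
    alphas = estimate_dispersions(table, factors)
    assert alphas.mean() <= 0.02


def test_dispersion_recovery_nb():
    rng = np.random.default_rng(1)
    alpha_true, mu = 0.5, 500.0
    n = 1 / alpha_true
    p = n / (n + mu)
    samples = [f"s{i}" for i in range(50)]
    groups = {s: ("A" if i < 25 else "B") for i, s in enumerate(samples)}
    data = rng.negative_binomial(n, p, size=(300, 50))
    table = _table(data, samples, groups)
    alphas = estimate_dispersions(table, pd.Series(1.0, index=samples))
    assert 0.35 <= alphas.mean() <= 0.65


def test_dispersion_requires_two_samples_per_group():
    table = _table([[5, 6, 7]], ["s1", "s2", "s3"],
                   {"s1": "A", "s2": "B", "s3": "B"})
    with pytest.raises(DEError, match="group A"):
        estimate_dispersions(table, pd.Series(1.0, index=["s1", "s2", "s3"]))


def _nb_counts(rng, mu_a, mu_b, alpha, n_per_group, n_clusters):
    samples = [f"a{i}" for i in range(n_per_group)] + [
        f"b{i}" for i in range(n_per_group)
    ]
    groups = {s: ("A" if s.startswith("a") else "B") for s in samples}
    mus = np.concatenate(
        [np.full(n_per_group, mu_a), np.full(n_per_group, mu_b)]
    )
    if alpha == 0:
        data = rng.poisson(mus, size=(n_clusters, len(samples)))
    else:
        n = 1 / alpha
        p = n / (n + mus)
        data = rng.negative_binomial(n, p, size=(n_clusters, len(samples)))
    return _table(data, samples, groups)


def test_wald_label_permutation_flips_sign():
    rng = np.random.default_rng(2)
    table = _nb_counts(rng, 500, 500, 0.2, 5, 40)
    factors = size_factors(table)
    alphas = estimate_dispersions(table, factors)
    res = wald_test(table, factors, alphas)
    flipped_groups = {
        s: ("B" if g == "A" else "A") for s, g in table.sample_group.items()
    }
    flipped = CountsTable(table.counts, flipped_groups)
    res_flipped = wald_test(flipped, factors, alphas)
    assert np.allclose(res["log2fc"], -res_flipped["log2fc"], atol=1e-6)
    assert np.allclose(res["wald"].abs(), res_flipped["wald"].abs(), atol=1e-6)


def test_wald_identical_groups_give_zero_lfc():
    table = _table(
        [[50, 50, 50, 50], [7, 7, 7, 7]], ["s1", "s2", "s3", "s4"], GROUPS22
    )
    factors = size_factors(table)
    alphas = estimate_dispersions(table, factors)
    res = wald_test(table, factors, alphas)
    assert np.allclose(res["log2fc"], 0.0, atol=1e-10)


def test_wald_matches_statsmodels_glm():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(3)
    table = _nb_counts(rng, 400, 800, 0.1, 6, 10)
    factors = size_factors(table)
    alphas = estimate_dispersions(table, factors)
    res = wald_test(table, factors, alphas)
    group = np.array([0] * 6 + [1] * 6)
    X = np.column_stack([np.ones(12), group])
    offset = np.log(factors.to_numpy())
    for cid in list(table.counts.index)[:5]:
        y = table.counts.loc[cid].to_numpy()
        alpha = float(alphas.loc[cid])
        if alpha <= 0:
            continue
        glm = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=alpha),
            offset=offset,
        ).fit()
        assert res.loc[cid, "log2fc"] == pytest.approx(
            glm.params[1] / np.log(2), rel=1e-4, abs=1e-6
        )
        assert res.loc[cid, "se"] == pytest.approx(
            glm.bse[1] / np.log(2), rel=1e-3
        )


def test_bh_worked_example_and_oracle():
    assert np.allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert adjust_bh([0.2]) == pytest.approx([0.2])
    rng = np.random.default_rng(4)
    for _ in range(25):
        p = rng.uniform(size=rng.integers(1, 50))
        assert np.allclose(adjust_bh(p), bh_step_up(p))


def test_bh_monotone_in_sorted_order():
    rng = np.random.default_rng(5)
    p = rng.uniform(size=100)
    q = adjust_bh(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(DEError):
        adjust_bh([0.5, 1.5])


def test_model_results_surface(small_counts):
    res = GroupContrastNB(small_counts).fit()
    t = res.table
    assert {"baseMean", "log2fc", "se", "wald", "p", "padj"} <= set(t.columns)
    ok = t.dropna(subset=["p"])
    assert (ok["padj"] >= ok["p"] - 1e-12).all()
    assert np.allclose(
        t["wald"].to_numpy(), (t["log2fc"] / t["se"]).to_numpy(), rtol=1e-8
    )
    assert "NB group contrast" in res.summary()


def test_scaling_one_sample_scales_its_size_factor():
    rng = np.random.default_rng(6)
    table = _nb_counts(rng, 500, 500, 0.05, 5, 400)
    f0 = size_factors(table)
    scaled_counts = table.counts.copy()
    scaled_counts["a0"] = (scaled_counts["a0"] * 3).astype(int)
    scaled = CountsTable(scaled_counts, table.sample_group)
    f1 = size_factors(scaled)
    # relative to any other sample the factor scales by c (the geometric
    # mean itself absorbs a c**(1/n) share)
    assert (f1["a0"] / f1["b0"]) / (f0["a0"] / f0["b0"]) == pytest.approx(
        3.0, rel=0.02
    )
    assert f1["a0"] / f0["a0"] == pytest.approx(3 ** 0.9, rel=0.02)
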