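"""Signed coexpression network: adjacency, TOM, modules, eigengenes, traits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from painrhythm.network import (
    GREY,
    NetworkConfig,
    build_network_modules,
    detect_modules,
    eigengenes,
    merge_modules,
    module_trait,
    pick_soft_threshold,
    scale_free_fit,
    signed_adjacency,
    tom,
)


def _block_matrix(rng, block_sizes, n_noise, n_samples=40, load=0.9, noise=0.45):
    rows = []
    for size in block_sizes:
        f = rng.normal(size=n_samples)
        rows += [load * f + noise * rng.normal(size=n_samples) for _ in range(size)]
    rows += [rng.normal(size=n_samples) for _ in range(n_noise)]
    return pd.DataFrame(
        rows, index=[f"g{i}" for i in range(len(rows))], columns=[f"s{j}" for j in range(n_samples)]
    )


# ------------------------------------------------------------ adjacency

def test_signed_adjacency_endpoints_and_formula(rng):
    base = rng.normal(size=30)
    vals = pd.DataFrame([base, base, -base], index=list("abc"))
    a = signed_adjacency(vals, 12)
    assert a[0, 1] == pytest.approx(1.0)  # cor +1
    assert a[0, 2] == pytest.approx(0.0, abs=1e-12)  # cor -1
    x, y = rng.normal(size=200), rng.normal(size=200)
    r = np.corrcoef(x, y)[0, 1]
    a2 = signed_adjacency(pd.DataFrame([x, y], index=["u", "v"]), 12)
    assert a2[0, 1] == pytest.approx(((1 + r) / 2) ** 12)


def test_signed_adjacency_contract(rng):
    vals = pd.DataFrame(rng.normal(size=(20, 15)), index=[f"g{i}" for i in range(20)])
    a = signed_adjacency(vals, 6)
    assert np.allclose(a, a.T)
    assert (a >= 0).all() and (a <= 1).all()
    assert np.allclose(np.diag(a), 1.0)


def test_signed_adjacency_constant_row_named(rng):
    vals = pd.DataFrame(rng.normal(size=(5, 10)), index=[f"g{i}" for i in range(5)])
    vals.iloc[2] = 3.14
    with pytest.raises(ValueError, match="g2"):
        signed_adjacency(vals, 6)


# ------------------------------------------------------------------ TOM

def test_tom_identical_neighbourhoods_give_unit_overlap():
    # fully shared neighbourhoods at full strength: maximal overlap
    a = np.ones((4, 4))
    t, d = tom(a)
    assert np.allclose(t, 1.0)
    assert np.allclose(d, 0.0)


def test_tom_matches_scalar_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(3, 8))
        r = rng.random((n, n))
        a = (r + r.T) / 2
        np.fill_diagonal(a, 1.0)
        t, _ = tom(a)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                k_i = sum(a[i, u] for u in range(n) if u != i)
                k_j = sum(a[j, u] for u in range(n) if u != j)
                expected = (l + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
                assert t[i, j] == pytest.approx(expected, abs=1e-12)


def test_tom_bounds_and_symmetry(rng):
    r = rng.random((12, 12))
    a = (r + r.T) / 2
    np.fill_diagonal(a, 1.0)
    t, d = tom(a)
    assert np.allclose(t, t.T)
    assert np.allclose(np.diag(t), 1.0)
    assert ((d >= 0) & (d <= 1)).all()


def test_tom_rejects_asymmetric_input():
    with pytest.raises(ValueError):
        tom(np.array([[1.0, 0.2], [0.9, 1.0]]))


# -------------------------------------------------------- soft threshold

def test_scale_free_fit_reaches_target_on_power_law_degrees(rng):
    u = rng.random(2000)
    k = (1 - u) ** (-1 / 1.5)  # Pareto tail, gamma = 2.5
    assert scale_free_fit(k) >= 0.80


def test_pick_soft_threshold_rule_and_determinism(rng):
    vals = _block_matrix(rng, [30, 30], 60)
    b1, tab1 = pick_soft_threshold(vals, target_r2=0.30)
    b2, tab2 = pick_soft_threshold(vals, target_r2=0.30)
    assert b1 == b2
    assert tab1.equals(tab2)
    eligible = tab1[tab1["mean_k"] >= 2.0]
    qualifying = eligible[eligible["signed_r2"] >= 0.30]
    expected = int(qualifying["beta"].iloc[0]) if len(qualifying) else int(
        eligible.loc[eligible["signed_r2"].idxmax(), "beta"]
    )
    assert b1 == expected
    # connectivity decays monotonically with the soft power
    assert (np.diff(tab1["mean_k"]) < 0).all()


# ------------------------------------------------------ module detection

def test_two_planted_blocks_recovered_exactly(rng):
    vals = _block_matrix(rng, [30, 30], 0)
    a = signed_adjacency(vals, 6)
    _, d = tom(a)
    labels = detect_modules(d, min_size=10)
    first, second = labels[:30], labels[30:]
    assert len(set(first)) == 1 and len(set(second)) == 1
    assert first[0] != 0 and second[0] != 0 and first[0] != second[0]


def test_min_size_beyond_blocks_gives_all_grey(rng):
    vals = _block_matrix(rng, [30, 30], 0)
    _, d = tom(signed_adjacency(vals, 6))
    assert (detect_modules(d, min_size=40) == 0).all()


def test_module_labels_invariant_to_transcript_order(rng):
    vals = _block_matrix(rng, [20, 20], 20)
    _, d = tom(signed_adjacency(vals, 6))
    labels = detect_modules(d, min_size=10)
    perm = rng.permutation(len(vals))
    _, dp = tom(signed_adjacency(vals.iloc[perm], 6))
    labp = detect_modules(dp, min_size=10)
    # same partition after mapping back
    back = np.empty_like(labp)
    back[perm] = labp
    for m in set(labels):
        idx = labels == m
        assert len(set(back[idx])) == 1


# ------------------------------------------------------------ eigengenes

def test_eigengene_of_identical_profiles(rng):
    prof = rng.normal(size=25)
    vals = pd.DataFrame([prof, prof, prof], index=list("abc"))
    labels = pd.Series(["M1"] * 3, index=list("abc"))
    me, ve = eigengenes(vals, labels)
    z = (prof - prof.mean()) / prof.std()
    expected = z / np.linalg.norm(z)
    assert np.allclose(me["M1"].to_numpy(), expected, atol=1e-10)
    assert ve["M1"] == pytest.approx(1.0)


def test_eigengene_orthogonal_pair_splits_variance():
    v1 = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
    v2 = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
    vals = pd.DataFrame([v1, v2], index=["a", "b"])
    _, ve = eigengenes(vals, pd.Series(["M1", "M1"], index=["a", "b"]))
    assert ve["M1"] == pytest.approx(0.5)


def test_eigengene_matches_svd_oracle_with_anchored_sign(rng):
    vals = pd.DataFrame(rng.normal(size=(10, 30)), index=[f"g{i}" for i in range(10)])
    labels = pd.Series(["M1"] * 10, index=vals.index)
    me, _ = eigengenes(vals, labels)
    z = stats.zscore(vals.to_numpy(), axis=1, ddof=0)
    _, _, Vt = np.linalg.svd(z, full_matrices=False)
    v = Vt[0] / np.linalg.norm(Vt[0])
    got = me["M1"].to_numpy()
    assert np.allclose(got, v, atol=1e-8) or np.allclose(got, -v, atol=1e-8)
    assert np.dot(got, z.mean(axis=0)) >= 0  # anchored to the mean profile


# --------------------------------------------------------------- merging

def test_merge_combines_correlated_modules(rng):
    f = rng.normal(size=40)
    rows = [0.9 * f + 0.3 * rng.normal(size=40) for _ in range(20)]
    vals = pd.DataFrame(rows, index=[f"g{i}" for i in range(20)])
    labels = pd.Series(["A"] * 10 + ["B"] * 10, index=vals.index)
    ms = merge_modules(vals, labels)
    assert ms.labels.nunique() == 1


def test_merge_fixed_point_below_threshold(rng):
    f1, f2 = rng.normal(size=60), rng.normal(size=60)
    rows = [0.95 * f1 + 0.1 * rng.normal(size=60) for _ in range(10)]
    rows += [0.95 * f2 + 0.1 * rng.normal(size=60) for _ in range(10)]
    vals = pd.DataFrame(rows, index=[f"g{i}" for i in range(20)])
    labels = pd.Series(["A"] * 10 + ["B"] * 10, index=vals.index)
    if abs(np.corrcoef(f1, f2)[0, 1]) < 0.25:  # guard the construction
        ms = merge_modules(vals, labels)
        assert set(ms.labels) == {"A", "B"}


def test_merge_terminates_below_threshold_on_random_partitions(rng):
    vals = pd.DataFrame(rng.normal(size=(40, 30)), index=[f"g{i}" for i in range(40)])
    labels = pd.Series(rng.choice(["A", "B", "C", "D"], 40), index=vals.index)
    ms = merge_modules(vals, labels)
    if ms.eigengenes.shape[1] >= 2:
        c = np.corrcoef(ms.eigengenes.to_numpy().T)
        off = np.abs(c[~np.eye(c.shape[0], dtype=bool)])
        assert (off < 0.30).all()


# ------------------------------------------------------------ module-trait

def test_module_trait_null_p_uniform(rng):
    ps = []
    for _ in range(150):
        me = pd.DataFrame({"M1": rng.normal(size=60)}, index=[f"s{i}" for i in range(60)])
        ph = pd.Series(
            rng.permutation(["rhythmic_up"] * 12 + ["mixed"] * 48), index=me.index
        )
        ps.append(module_trait(me, ph, "binary")["p"].iloc[0])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_module_trait_constant_eigengene_flagged():
    me = pd.DataFrame({"M1": np.ones(20)}, index=[f"s{i}" for i in range(20)])
    ph = pd.Series(["rhythmic_up"] * 5 + ["mixed"] * 15, index=me.index)
    out = module_trait(me, ph, "binary")
    assert out["constant"].iloc[0]
    assert np.isnan(out["p"].iloc[0])


def test_module_trait_multinomial_contrasts(rng):
    me = pd.DataFrame({"M1": rng.normal(size=60)}, index=[f"s{i}" for i in range(60)])
    ph = pd.Series(
        ["rhythmic_up"] * 15 + ["mixed"] * 15 + ["constant_low"] * 15 + ["constant_high"] * 15,
        index=me.index,
    )
    out = module_trait(me, ph, "multinomial")
    assert len(out) == 3
    assert set(out["contrast"]) == {
        "mixed_vs_rhythmic_up",
        "constant_low_vs_rhythmic_up",
        "constant_high_vs_rhythmic_up",
    }


def test_single_level_phenotype_rejected(rng):
    me = pd.DataFrame({"M1": rng.normal(size=10)}, index=[f"s{i}" for i in range(10)])
    with pytest.raises(ValueError):
        module_trait(me, pd.Series(["mixed"] * 10, index=me.index))


# ----------------------------------------------------------- end to end

def test_build_network_modules_planted_block(rng):
    vals = _block_matrix(rng, [30], 60, load=0.95, noise=0.35)
    ms = build_network_modules(vals, NetworkConfig(min_module_size=10))
    planted = ms.labels.iloc[:30]
    assert (planted != GREY).mean() >= 0.8
    assert planted[planted != GREY].nunique() == 1
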