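import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from germscreen.core_io import DegenerateDataError, InputError
from germscreen.screen import (
    cor_screen,
    correlation_pvalue,
    cv,
    cv_screen,
    dam_screen,
    intersect_screens,
    pearson_r,
)
from germscreen.synthetic import SyntheticConfig, generate

from conftest import build_matrix


# -- pearson_r --------------------------------------------------------------


def brute_force_r(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def test_pearson_exact_linear_relations():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
    assert pearson_r(x, -x) == pytest.approx(-1.0)


def test_pearson_matches_covariance_formula():
    x = np.array([1, 2, 3, 4, 5, 6], dtype=float)
    y = np.array([1, 2, 3, 4, 5, 7], dtype=float)
    assert pearson_r(x, y) == pytest.approx(brute_force_r(x, y), abs=1e-12)


def test_pearson_pairwise_complete_and_degenerate():
    x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
    y = np.array([2.0, 4.0, 6.0, np.nan, 10.0])
    assert pearson_r(x, y) == pytest.approx(1.0)
    with pytest.raises(DegenerateDataError, match="constant"):
        pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(DegenerateDataError, match="3 complete"):
        pearson_r([1.0, np.nan, 3.0], [1.0, 2.0, np.nan])


# -- correlation p-value ----------------------------------------------------


def test_pvalue_worked_examples_match_t_transform():
    assert round(correlation_pvalue(0.94, 6), 3) == 0.005
    assert round(correlation_pvalue(-0.95, 6), 3) == 0.004


def test_pvalue_null_and_degenerate_limits():
    assert correlation_pvalue(0.0, 6) == pytest.approx(1.0)
    assert correlation_pvalue(1.0, 6) == 0.0
    assert correlation_pvalue(-1.0, 6) == 0.0


def test_pvalue_monotone_in_r_and_n():
    rs = np.linspace(0.05, 0.95, 10)
    ps = [correlation_pvalue(r, 6) for r in rs]
    assert all(a > b for a, b in zip(ps, ps[1:]))
    ns = range(4, 40, 3)
    ps = [correlation_pvalue(0.5, n) for n in ns]
    assert all(a > b for a, b in zip(ps, ps[1:]))


def test_pvalue_agrees_with_scipy_cor_test():
    rng = np.random.default_rng(0)
    for n in (5, 8, 20):
        x, y = rng.normal(size=n), rng.normal(size=n)
        ref = stats.pearsonr(x, y)
        assert correlation_pvalue(pearson_r(x, y), n) == pytest.approx(
            ref.pvalue, rel=1e-9
        )


# -- cor_screen -------------------------------------------------------------


def test_cor_screen_planted_versus_flat(noiseless_dataset):
    m, phen, truth = noiseless_dataset
    edges = cor_screen(m, phen)
    fast = edges[edges["variety"] == "fast"].set_index("metabolite_id")
    pos = truth.metabolites[
        truth.metabolites["associated"] & (truth.metabolites["direction"] > 0)
    ].index
    assert fast.loc[pos, "passes"].all()
    assert (fast.loc[pos, "r"] > 0.8).all()
    flat = truth.metabolites[
        ~truth.metabolites["associated"] & (truth.metabolites["archetype"] == "flat")
    ].index
    # zero-noise flat metabolites are constant → excluded, not passed
    assert not set(flat) & set(fast.index)


def test_cor_screen_missing_phenotype_timepoint(noiseless_dataset):
    m, phen, _ = noiseless_dataset
    with pytest.raises(InputError, match="lacks germination rate"):
        cor_screen(m, phen[phen["timepoint_hai"] != 24])


# -- cv ---------------------------------------------------------------------


def test_cv_hand_computed_values():
    assert cv([5.0, 5.0, 5.0]) == 0.0
    assert cv([1.0, 2.0, 3.0]) == pytest.approx(0.5)  # sample SD 1, mean 2


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    vals=st.lists(st.floats(0.1, 1e4, allow_nan=False), min_size=2, max_size=12),
    scale=st.floats(0.01, 1e3, allow_nan=False),
)
def test_cv_scale_invariance(vals, scale):
    v = np.array(vals)
    assert cv(scale * v) == pytest.approx(cv(v), rel=1e-9, abs=1e-12)


def test_cv_undefined_cases():
    with pytest.raises(DegenerateDataError):
        cv([0.0, 0.0])
    with pytest.raises(DegenerateDataError):
        cv([1.0])


def test_cv_screen_flat_versus_doubling(noiseless_dataset):
    m, _, truth = noiseless_dataset
    passing, series = cv_screen(m, "fast")
    flat = truth.metabolites[
        ~truth.metabolites["associated"] & (truth.metabolites["archetype"] == "flat")
    ].index
    assert not set(flat) & passing
    # a metabolite doubling each time point has CV ≫ 0.3 over 8 means
    doubling = build_matrix(
        np.repeat([[2.0**k] for k in range(8)], 3, axis=0),
        varieties=("fast",),
        met_ids=["dbl"],
    )
    dbl_pass, dbl_series = cv_screen(doubling, "fast")
    assert dbl_pass == {"dbl"}
    assert dbl_series["dbl"] > 0.3
    assert cv_screen(m, "fast", threshold=np.inf)[0] == set()


# -- dam_screen -------------------------------------------------------------


def _two_group_matrix(fast_reps, slow_reps, n_met=1):
    vals = np.array([[v] * n_met for v in list(fast_reps) + list(slow_reps)], float)
    return build_matrix(
        vals, varieties=("fast", "slow"), timepoints=(6,), n_replicates=3
    )


def test_dam_identical_groups_not_significant():
    m = _two_group_matrix([5, 5, 5], [5, 5, 5])
    records, dam = dam_screen(m, timepoints=(6,))
    assert records.loc[0, "fold_change"] == pytest.approx(1.0)
    assert records.loc[0, "raw_p"] == 1.0
    assert dam == set()


def test_dam_strong_difference_significant():
    m = _two_group_matrix([1.0, 1.01, 0.99], [10.0, 10.1, 9.9])
    records, dam = dam_screen(m, timepoints=(6,), pseudocount=0.0)
    assert dam == {"met0000"}
    row = records.iloc[0]
    assert row["fold_change"] == pytest.approx(10.0, rel=0.05)
    assert row["direction"] == "slow"
    # cross-check against the closed-form equal-variance t
    t_ref = stats.ttest_ind([1.0, 1.01, 0.99], [10.0, 10.1, 9.9], equal_var=True)
    assert row["raw_p"] == pytest.approx(t_ref.pvalue)


def test_dam_zero_variance_degenerate_cases():
    m = _two_group_matrix([5, 5, 5], [20, 20, 20])
    records, dam = dam_screen(m, timepoints=(6,))
    assert records.loc[0, "degenerate"]
    assert dam == {"met0000"}
    m2 = _two_group_matrix([5, 5, 5], [5, 5, 5])
    records2, _ = dam_screen(m2, timepoints=(6,))
    assert not records2.loc[0, "degenerate"]


def test_dam_symmetric_under_variety_swap():
    cfg = SyntheticConfig(rng_seed=9, n_metabolites=80)
    m, _, _ = generate(cfg)
    rec_a, dam_a = dam_screen(m, varieties=("fast", "slow"))
    rec_b, dam_b = dam_screen(m, varieties=("slow", "fast"))
    assert dam_a == dam_b
    merged = rec_a.merge(rec_b, on=["metabolite_id", "timepoint_hai"])
    assert np.allclose(merged["fold_change_x"], merged["fold_change_y"])
    assert (merged["significant_x"] == merged["significant_y"]).all()
    assert (merged["direction_x"] == merged["direction_y"]).all()  # labels, not slots


def test_dam_requires_two_replicates():
    m = build_matrix(
        [[1.0], [2.0]], varieties=("fast", "slow"), timepoints=(6,), n_replicates=1
    )
    with pytest.raises(InputError, match="2 replicates"):
        dam_screen(m, timepoints=(6,))


# -- Benjamini–Hochberg oracle ----------------------------------------------


def brute_force_bh(p):
    """Textbook step-up: adj_(i) = min_{j ≥ i} min(1, n·p_(j)/j)."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate(
        (n * p[order] / np.arange(1, n + 1))[::-1]
    )[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def test_bh_matches_brute_force_on_random_vectors():
    from germscreen.screen import _bh_adjust

    rng = np.random.default_rng(12)
    for _ in range(50):
        p = rng.uniform(size=rng.integers(2, 100))
        assert np.allclose(_bh_adjust(p), brute_force_bh(p), atol=1e-12)


def test_bh_preserves_order_and_never_lowers():
    from germscreen.screen import _bh_adjust

    rng = np.random.default_rng(13)
    p = rng.uniform(size=60)
    adj = _bh_adjust(p)
    assert (adj >= p - 1e-15).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-15).all()


# -- intersection -----------------------------------------------------------


def _fake_edges(ids, variety="fast", passing=True):
    return pd.DataFrame(
        {
            "metabolite_id": list(ids),
            "variety": variety,
            "r": 0.9,
            "n": 6,
            "t_statistic": 4.0,
            "p": 0.01,
            "passes": passing,
        }
    )


def test_intersection_of_disjoint_sets_empty():
    res = intersect_screens(_fake_edges(["a"]), {"fast": {"b"}}, {"c"})
    assert res.intersection_set == set()


def test_intersection_of_identical_sets_is_the_set():
    ids = {"a", "b", "c"}
    res = intersect_screens(_fake_edges(sorted(ids)), {"fast": ids}, set(ids))
    assert res.intersection_set == ids
    assert res.cor_set == ids and res.cv_set == ids and res.dam_set == ids


def test_union_versus_intersection_modes():
    edges = pd.concat(
        [_fake_edges(["a", "b"], "fast"), _fake_edges(["b", "c"], "slow")]
    )
    cv_sets = {"fast": {"a", "b", "c"}, "slow": {"b", "c"}}
    union = intersect_screens(edges, cv_sets, {"a", "b", "c"}, mode="union")
    assert union.cor_set == {"a", "b", "c"}
    assert union.intersection_set == {"a", "b", "c"} & union.cv_set
    inter = intersect_screens(edges, cv_sets, {"a", "b", "c"}, mode="intersection")
    assert inter.cor_set == {"b"}
    assert inter.intersection_set == {"b"}


def test_universe_mismatch_rejected(default_dataset):
    m, _, _ = default_dataset
    with pytest.raises(InputError, match="outside the annotated universe"):
        intersect_screens(
            _fake_edges(["not-there"]), {}, set(), annotations=m.metabolites
        )


def test_screen_invariant_under_sample_and_metabolite_relabeling():
    """Shuffling metabolite columns and renaming samples leaves every
    method set unchanged."""
    cfg = SyntheticConfig(rng_seed=10, n_metabolites=60)
    m, phen, _ = generate(cfg)

    def run(mat):
        edges = cor_screen(mat, phen)
        cvs = {v: cv_screen(mat, v)[0] for v in mat.varieties}
        _, dam = dam_screen(mat)
        res = intersect_screens(edges, cvs, dam, annotations=mat.metabolites)
        return res.cor_set, res.cv_set, res.dam_set, res.intersection_set

    base = run(m)
    shuffled = m.copy()
    rng = np.random.default_rng(1)
    order = rng.permutation(shuffled.values.columns)
    shuffled.values = shuffled.values[order]
    shuffled.metabolites = shuffled.metabolites.loc[order]
    shuffled.samples = shuffled.samples.rename(index=lambda s: f"x-{s}")
    shuffled.values.index = shuffled.samples.index
    assert run(shuffled) == base
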