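import numpy as np
import pandas as pd
import pytest

from germscreen.core_io import InputError
from germscreen.screen import pearson_r
from germscreen.synthetic import (
    SyntheticConfig,
    SyntheticTruth,
    generate,
    logistic_germination,
    truth_confusion,
)


def test_same_seed_is_bit_identical():
    a, pa, ta = generate(SyntheticConfig(rng_seed=11, n_metabolites=50, n_associated=10))
    b, pb, tb = generate(SyntheticConfig(rng_seed=11, n_metabolites=50, n_associated=10))
    assert a.values.equals(b.values)
    assert pa.equals(pb)
    assert ta.metabolites.equals(tb.metabolites)


def test_different_seeds_differ():
    a, _, _ = generate(SyntheticConfig(rng_seed=1, n_metabolites=50, n_associated=10))
    b, _, _ = generate(SyntheticConfig(rng_seed=2, n_metabolites=50, n_associated=10))
    assert not a.values.equals(b.values)


def test_zero_noise_replicates_identical(noiseless_dataset):
    m, phen, truth = noiseless_dataset
    for (_, _), sids in m.replicate_groups():
        vals = m.values.loc[sids].to_numpy()
        assert (vals == vals[0]).all()
    # phenotype is the noiseless curve: replicates identical too
    per_rep = phen.pivot_table(
        index=["variety", "timepoint_hai"], columns="replicate",
        values="germination_fraction",
    )
    assert per_rep.nunique(axis=1).eq(1).all()


def test_planted_positive_metabolite_tracks_germination(noiseless_dataset):
    """Under the linear link and zero noise, a positively associated
    metabolite's 6–48 HAI means correlate perfectly with germination rate."""
    m, phen, truth = noiseless_dataset
    tps = [6, 9, 12, 24, 36, 48]
    germ = (
        phen[phen["variety"] == "fast"]
        .groupby("timepoint_hai")["germination_fraction"]
        .mean()
        .loc[tps]
    )
    pos = truth.metabolites[
        truth.metabolites["associated"] & (truth.metabolites["direction"] > 0)
    ].index
    means = m.timepoint_means("fast").loc[tps]
    for met in pos[:10]:
        r = pearson_r(means[met], germ)
        assert r == pytest.approx(1.0, abs=1e-9)
        assert r > 0.8


def test_replicate_cv_matches_noise_cv():
    """Pooled log-variance across cells recovers the configured noise CV."""
    cfg = SyntheticConfig(rng_seed=3, n_metabolites=250, noise_cv=0.2)
    m, _, _ = generate(cfg)
    logs = np.log(m.values.to_numpy())
    cell_var = []
    for (_, _), sids in m.replicate_groups():
        lv = logs[[m.values.index.get_loc(s) for s in sids]]
        cell_var.append(lv.var(axis=0, ddof=1))
    sigma2 = float(np.mean(np.concatenate(cell_var)))
    cv_hat = float(np.sqrt(np.expm1(sigma2)))
    assert cv_hat == pytest.approx(0.2, abs=0.01)


def test_slow_variety_trajectories_are_time_shifted(noiseless_dataset):
    m, _, truth = noiseless_dataset  # default lag 9 h
    fast = m.timepoint_means("fast")
    slow = m.timepoint_means("slow")
    assoc = truth.metabolites.index[truth.metabolites["associated"]][0]
    # 12 HAI slow has effective time 3: matches fast at 3 HAI exactly
    assert slow.loc[12, assoc] == pytest.approx(fast.loc[3, assoc], rel=1e-12)


def test_outlier_replicate_is_uncorrelated_with_siblings():
    cfg = SyntheticConfig(rng_seed=4, n_metabolites=200, n_outlier_replicates=1)
    m, _, truth = generate(cfg)
    (sid,) = truth.outlier_samples
    variety, tp = m.samples.loc[sid, ["variety", "timepoint_hai"]]
    sibs = m.samples[
        (m.samples["variety"] == variety) & (m.samples["timepoint_hai"] == tp)
    ].index.drop(sid)
    for sib in sibs:
        r = np.corrcoef(m.values.loc[sid], m.values.loc[sib])[0, 1]
        assert abs(r) < 0.5


def test_bad_proportions_rejected():
    with pytest.raises(InputError, match="sum to 1"):
        generate(SyntheticConfig(class_proportions={"lipids": 0.5, "others": 0.4}))
    with pytest.raises(InputError, match="n_associated"):
        SyntheticConfig(n_metabolites=10, n_associated=20).validate()


def test_germination_curve_is_logistic_with_lag():
    cfg = SyntheticConfig(rng_seed=5, noise_cv=0.0, lag_hours=12.0)
    _, phen, _ = generate(cfg)
    for variety, lag in (("fast", 0.0), ("slow", 12.0)):
        series = (
            phen[phen["variety"] == variety]
            .groupby("timepoint_hai")["germination_fraction"]
            .mean()
        )
        for t, frac in series.items():
            expected = logistic_germination(
                max(t - lag, 0.0), cfg.germination_midpoint, cfg.germination_steepness
            )
            assert frac == pytest.approx(float(expected), abs=1e-12)


# -- truth confusion --------------------------------------------------------


def _toy_truth(n=100, n_assoc=60):
    mets = pd.DataFrame(
        {
            "associated": [i < n_assoc for i in range(n)],
            "direction": 1,
            "archetype": "flat",
            "effect_size": 0.0,
        },
        index=pd.Index([f"met{i:04d}" for i in range(n)], name="metabolite_id"),
    )
    samples = pd.DataFrame({"outlier": []})
    return SyntheticTruth(metabolites=mets, samples=samples, config={}, seed=0)


def test_confusion_perfect_recovery():
    truth = _toy_truth()
    res = truth_confusion(truth.associated_set, truth)
    assert res["sensitivity"] == 1.0 and res["precision"] == 1.0


def test_confusion_disjoint_recovery():
    truth = _toy_truth()
    rest = set(truth.metabolites.index) - truth.associated_set
    assert truth_confusion(rest, truth)["sensitivity"] == 0.0


def test_confusion_partial_counts():
    truth = _toy_truth(n=200, n_assoc=60)
    planted = sorted(truth.associated_set)
    others = sorted(set(truth.metabolites.index) - truth.associated_set)
    recovered = set(planted[:54]) | set(others[:16])  # 70 recovered, 54 planted
    res = truth_confusion(recovered, truth)
    assert res["sensitivity"] == pytest.approx(0.9)
    assert res["precision"] == pytest.approx(54 / 70)
    assert (res["tp"], res["fp"], res["fn"]) == (54, 16, 6)


def test_confusion_universe_mismatch():
    truth = _toy_truth()
    with pytest.raises(InputError, match="unknown metabolites"):
        truth_confusion({"not-a-met"}, truth)
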