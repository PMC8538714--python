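"""Likelihood, pooled fit, MAP estimates, AIC ranking and the group comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from voridial.cohort import StudyDesign, draw_population, generate_dataset
from voridial.estimate import (
    _LikelihoodData,
    aic_compare,
    compare_groups,
    comparisons_frame,
    map_estimate,
    neg2ll,
    pooled_fit,
)


@pytest.fixture(scope="module")
def pooled_data(low_ruv_params, rrt, design):
    """A small IIV-free dataset at the typical values with 5% residual CV."""
    pop = draw_population(6, low_ruv_params, design, 100, include_iiv=False, include_iov=False)
    table, _ = generate_dataset(pop, low_ruv_params, rrt, design, 200)
    weights = {str(i): w for i, w in zip(pop.ids, pop.weights)}
    return table, weights


def _truth(params):
    t = {k: getattr(params, k) for k in ("cl_body", "v1", "q", "v2", "cl_rrt", "f_ads")}
    t.update(ads_max=params.ads_max, rbctp=params.rbctp)
    return t


def test_neg2ll_matches_per_record_evaluation(low_ruv_params, rrt, design, pooled_data):
    """The vectorized likelihood equals a literal per-record sum on a toy table."""
    table, weights = pooled_data
    toy = table[table["time_h"] > 0].head(5)
    theta = _truth(low_ruv_params)
    data = _LikelihoodData(toy, design, rrt, weights, low_ruv_params.ruv_prop)
    preds = data.predictions(theta)
    total = 0.0
    for _, row in toy.iterrows():
        i = data.ids.index(row["id"])
        j = int(np.flatnonzero(np.abs(data.times - row["time_h"]) < 1e-9)[0])
        f = preds[row["stream"]][i, j]
        sig = low_ruv_params.ruv_prop[row["stream"]] / 100.0 * f
        total += -2.0 * stats.norm.logpdf(row["conc_mg_L"], f, sig)
    assert neg2ll(toy, theta, rrt, design, weights, low_ruv_params.ruv_prop) == pytest.approx(
        total, rel=1e-9
    )


def test_neg2ll_invariant_to_record_order_and_monotone_in_residuals(
    low_ruv_params, rrt, design, pooled_data
):
    table, weights = pooled_data
    obs = table[table["time_h"] > 0]
    theta = _truth(low_ruv_params)
    ruv = low_ruv_params.ruv_prop
    base = neg2ll(obs, theta, rrt, design, weights, ruv)
    shuffled = obs.sample(frac=1.0, random_state=1)
    assert neg2ll(shuffled, theta, rrt, design, weights, ruv) == pytest.approx(base, rel=1e-12)
    # halving every residual at fixed ruv can only improve the fit
    data = _LikelihoodData(obs, design, rrt, weights, ruv)
    preds = data.predictions(theta)
    halved = obs.copy()
    for stream in ("pre", "post", "effluent"):
        m = halved["stream"] == stream
        i = [data.ids.index(x) for x in halved.loc[m, "id"]]
        j = [int(np.flatnonzero(np.abs(data.times - t) < 1e-9)[0]) for t in halved.loc[m, "time_h"]]
        f = preds[stream][i, j]
        halved.loc[m, "conc_mg_L"] = f + 0.5 * (halved.loc[m, "conc_mg_L"] - f)
    assert neg2ll(halved, theta, rrt, design, weights, ruv) < base


def test_neg2ll_zero_prediction_is_an_error(low_ruv_params, rrt, design, pooled_data):
    table, weights = pooled_data
    with_baseline = table  # includes the pre-dose t=0 records where C1 = 0
    with pytest.raises(ValueError, match="zero predicted"):
        neg2ll(with_baseline, _truth(low_ruv_params), rrt, design, weights,
               low_ruv_params.ruv_prop)


def test_pooled_fit_from_truth_converges_to_truth(low_ruv_params, rrt, design, pooled_data):
    table, weights = pooled_data
    fit = pooled_fit(table, design, rrt, weights, low_ruv_params.ruv_prop,
                     init=_truth(low_ruv_params), n_starts=1, maxfev=800)
    assert fit.converged
    assert fit.aic == pytest.approx(fit.minus2ll + 2 * fit.n_params)
    for k, v in fit.estimates.items():
        assert v == pytest.approx(getattr(low_ruv_params, k), rel=0.25)


def test_fit_without_filter_streams_flags_flat_adsorption(low_ruv_params, rrt, design, pooled_data):
    """Pre-filter data alone cannot identify the adsorption split."""
    table, weights = pooled_data
    pre_only = table[table["stream"] == "pre"]
    fit = pooled_fit(pre_only, design, rrt, weights, low_ruv_params.ruv_prop,
                     init=_truth(low_ruv_params), n_starts=1, maxfev=600)
    assert "f_ads" in fit.flat_directions


def test_map_estimate_prior_mode_and_shrinkage_limits(params, rrt, design):
    no_obs = pd.DataFrame(columns=["id", "time_h", "stream", "conc_mg_L"])
    ebe = map_estimate(no_obs, params, rrt, design, 80.0)
    assert ebe["cl_body"] == params.cl_body and all(v == 0 for v in ebe["eta"].values())

    pop = draw_population(1, params, design, 21, include_iov=False)
    table, _ = generate_dataset(pop, params, rrt, design, 22)
    frozen = params.with_(iiv_cv={k: 0.0 for k in params.iiv_cv})
    ebe0 = map_estimate(table, frozen, rrt, design, pop.weights[0])
    for k in ("cl_body", "v1", "q", "v2", "cl_rrt", "f_ads"):
        assert ebe0[k] == getattr(params, k)


def test_map_estimate_recovers_individual_on_rich_noise_free_data(params, rrt, rich_design):
    sharp = params.with_(ruv_prop={"pre": 2.0, "post": 2.0, "effluent": 2.0})
    pop = draw_population(1, sharp, rich_design, 7, include_iov=False)
    table, _ = generate_dataset(pop, sharp, rrt, rich_design, 8, include_ruv=False)
    ebe = map_estimate(table, sharp, rrt, rich_design, pop.weights[0], maxfev=3000)
    truth = pop.patients[0].params
    for k in ("cl_body", "v1", "q", "v2", "cl_rrt"):
        assert ebe[k] == pytest.approx(truth[k], rel=0.02)
    # the adsorption fraction is the least identified direction; looser bound
    assert ebe["f_ads"] == pytest.approx(truth["f_ads"], rel=0.05)


def test_aic_duplicate_candidate_identical_and_nesting_bound(
    low_ruv_params, rrt, design, pooled_data
):
    table, weights = pooled_data
    rank = aic_compare(table, design, rrt, weights, low_ruv_params.ruv_prop,
                       candidates=("irreversible", "irreversible"),
                       init=_truth(low_ruv_params), n_starts=1, maxfev=400)
    assert len(rank) == 2
    assert rank["aic"].iloc[0] == rank["aic"].iloc[1]
    assert (rank["delta_aic"] >= 0).all()


def test_compare_groups_identical_copies_and_degenerate(params):
    vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    frame = pd.DataFrame({
        "group": ["ACLF"] * 6 + ["NLF"] * 6,
        "cl_body": np.concatenate([vals, vals]),
        "const": 1.0,
    })
    out = {c.parameter: c for c in compare_groups(frame)}
    assert out["cl_body"].p_value > 0.95
    assert out["const"].test == "skipped"
    table = comparisons_frame(list(out.values()))
    assert set(table["parameter"]) == {"cl_body", "const"}


def test_compare_groups_detects_large_injected_effect(params, design):
    hits = 0
    for rep in range(10):
        pop = draw_population(15, params, design, 3000 + rep, group_effect_cl_body=3.0)
        comp = {c.parameter: c for c in compare_groups(pop.to_frame(), ["cl_body"])}
        hits += comp["cl_body"].p_value < 0.05
    assert hits >= 6  # a 3x clearance shift is detected in the majority of studies


def test_compare_groups_requires_two_groups_and_min_size():
    frame = pd.DataFrame({"group": ["A"] * 6, "x": np.arange(6.0)})
    with pytest.raises(ValueError):
        compare_groups(frame)
    frame2 = pd.DataFrame({"group": ["A", "A", "B", "B"], "x": [1.0, 2, 3, 4]})
    with pytest.raises(ValueError):
        compare_groups(frame2)
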