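"""Parameter set: published defaults, validation, serialization, distributions."""

import copy
import math

import numpy as np
import pytest
from scipy import stats

from vtecea.parameters import (
    Param,
    build_distribution,
    default_paper_parameters,
    get_param,
    iter_params,
    load_parameters,
    parameter_table,
    sample_parameter_draws,
    sample_parameters,
    save_parameters,
    validate_parameters,
)

Z95 = float(stats.norm.ppf(0.975))


def test_published_values_transcribed(paper_params):
    p = paper_params
    assert p.risks["recurrent_vte"].segments[0].prob.value == 0.0171
    assert p.risks["recurrent_vte"].segments[0].prob.ci_low == 0.012
    assert p.relative_effects["extended_vka"].rr_major_bleed.value == 7.7
    assert p.utilities.baseline.value == 0.825
    assert p.risks["crnm_bleed"].segments[0].prob.value == 0.0265
    assert p.costs.apixaban_initial_daily.value == 4.39
    assert p.relative_effects["extended_placebo"].major_bleed_absolute_annual.value == 0.0048
    assert p.population.starting_age == 56.9


def test_defaults_validate_clean(paper_params):
    assert validate_parameters(paper_params) == []


def test_auxiliary_inputs_flagged_as_assumptions(paper_params):
    table = parameter_table(paper_params)
    assumed = set(table.loc[table.source == "assumption", "name"])
    assert "settings.hr_post_vte" in assumed
    assert any(name.startswith("long_term.late_recurrence_schedule") for name in assumed)
    # every published risk is flagged as such
    assert table.loc[table.name == "risks.recurrent_vte.segments[0].prob", "source"].item() == "paper"


def test_round_trip_identity(tmp_path, paper_params):
    path = tmp_path / "params.yaml"
    save_parameters(paper_params, path)
    assert load_parameters(path) == paper_params


def test_single_field_override(tmp_path, paper_params):
    path = tmp_path / "override.yaml"
    path.write_text("settings:\n  wtp_threshold: 30000\n")
    p = load_parameters(path)
    assert p.settings.wtp_threshold == 30000
    p.settings.wtp_threshold = paper_params.settings.wtp_threshold
    assert p == paper_params


def test_unknown_key_rejected(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text("settings:\n  wtp_thresold: 30000\n")
    with pytest.raises(ValueError, match="wtp_thresold"):
        load_parameters(path)


def test_domain_violation_names_the_key(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text(
        "relative_effects:\n  extended_vka:\n    rr_major_bleed:\n      value: -1\n"
        "      kind: rr\n"
    )
    with pytest.raises(ValueError, match="rr_major_bleed"):
        load_parameters(path)


def test_validate_flags_split_and_gap(paper_params):
    p = copy.deepcopy(paper_params)
    p.recurrent_split_on.fraction_dvt.value = 0.30  # sums to 0.9
    violations = validate_parameters(p)
    assert len([v for v in violations if "fractions sum" in v]) == 1

    p = copy.deepcopy(paper_params)
    p.risks["recurrent_vte"].segments[2].start_month = 7  # gap between 6 and 7
    violations = validate_parameters(p)
    assert len([v for v in violations if "contiguous" in v]) == 1


# ----------------------------------------------------------------------
# distributions
# ----------------------------------------------------------------------


def test_beta_distribution_mean_and_percentiles():
    d = build_distribution(0.0171, 0.012, 0.022, "beta")
    assert d.family == "beta"
    assert d.analytic_mean() == pytest.approx(0.0171, rel=1e-6)
    f = d.frozen()
    width = f.ppf(0.975) - f.ppf(0.025)
    assert width == pytest.approx(0.022 - 0.012, rel=1e-6)


def test_gamma_distribution_mean_and_percentiles():
    d = build_distribution(1340.41, 938.29, 1742.54, "gamma")
    assert d.analytic_mean() == pytest.approx(1340.41, rel=1e-6)
    f = d.frozen()
    assert f.ppf(0.975) - f.ppf(0.025) == pytest.approx(1742.54 - 938.29, rel=1e-6)


def test_lognormal_sigma_from_ci_ratio():
    d = build_distribution(3.26, 1.84, 5.79, "lognormal")
    mu, sigma = d.args
    assert sigma == pytest.approx(math.log(5.79 / 1.84) / (2 * Z95), rel=1e-9)
    assert sigma == pytest.approx(0.2924, abs=3e-4)
    assert math.exp(mu) == pytest.approx(3.26)  # median preserved for ratios


def test_fixed_distribution_point_mass():
    d = build_distribution(0.5, 0.5, 0.5, "fixed")
    assert d.family == "fixed"
    rng = np.random.default_rng(0)
    assert d.sample(rng) == 0.5
    assert np.all(d.sample(rng, size=10) == 0.5)


def test_infeasible_beta_raises():
    with pytest.raises(ValueError):
        build_distribution(1.5, 1.0, 2.0, "beta")
    with pytest.raises(ValueError):
        build_distribution(0.5, 0.6, 0.9, "beta")  # mean outside CI


# ----------------------------------------------------------------------
# sampling
# ----------------------------------------------------------------------


def test_sampling_deterministic_for_seed(paper_params):
    a = sample_parameters(paper_params, seed=42)
    b = sample_parameters(paper_params, seed=42)
    assert a == b
    c = sample_parameters(paper_params, seed=43)
    assert c != a


def test_sampled_sets_pass_validation(paper_params):
    for seed in range(5):
        drawn = sample_parameters(paper_params, seed=seed)
        assert validate_parameters(drawn) == []


def test_sample_mean_matches_target_within_mc_error(paper_params):
    """Law-of-large-numbers check on a key beta-distributed risk."""
    n = 10_000
    drawn = sample_parameter_draws(paper_params, seed=11, n_draws=n)
    vals = get_param(drawn, "risks.recurrent_vte.segments[0].prob").value
    assert vals.shape == (n,)
    se = vals.std(ddof=1) / math.sqrt(n)
    assert abs(vals.mean() - 0.0171) < 3 * se


def test_simplex_renormalized_after_sampling(paper_params):
    drawn = sample_parameter_draws(paper_params, seed=3, n_draws=500)
    total = (
        drawn.recurrent_split_on.fraction_vte_death.value
        + drawn.recurrent_split_on.fraction_pe.value
        + drawn.recurrent_split_on.fraction_dvt.value
    )
    np.testing.assert_allclose(total, 1.0, atol=1e-12)


def test_all_fixed_draw_equals_input(paper_params):
    p = copy.deepcopy(paper_params)
    for _, prm in iter_params(p):
        prm.ci_low = prm.ci_high = None
    assert sample_parameters(p, seed=1) == p


def test_iter_params_order_deterministic(paper_params):
    names1 = [path for path, _ in iter_params(paper_params)]
    names2 = [path for path, _ in iter_params(default_paper_parameters())]
    assert names1 == names2
    assert len(names1) == len(set(names1))


def test_param_family_resolution():
    assert Param(0.1, 0.05, 0.2, kind="probability").family == "beta"
    assert Param(100.0, 50.0, 150.0, kind="cost").family == "gamma"
    assert Param(2.0, 1.0, 4.0, kind="rr").family == "lognormal"
    assert Param(2.0, kind="rr").family == "fixed"
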