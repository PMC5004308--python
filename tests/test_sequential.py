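"""The sequential strategy: signature flow, imputation, ordering, contracts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from omicslink import (
    LayeredCohort,
    SequentialConfig,
    Signature,
    SimulationConfig,
    extract_signature,
    fit_linking_model,
    fit_second_level,
    generate_two_layer_cohort,
    run_reference,
    run_sequential,
    selected_features_report,
)

CFG = SequentialConfig(n_steps_max=25, cv_folds=5, seed=3)


def test_zero_offset_equals_reference(small_cohort):
    cohort, _ = small_cohort
    zero_sig = Signature(
        values=pd.Series(0.0, index=cohort.layer_b_ids),
        source=pd.Series("observed", index=cohort.layer_b_ids),
    )
    second = fit_second_level(cohort, zero_sig, CFG)
    reference = run_reference(cohort, CFG)
    np.testing.assert_allclose(second.coef_path, reference.coef_path, atol=1e-10)
    np.testing.assert_allclose(
        second.mandatory_path, reference.mandatory_path, atol=1e-10
    )


def test_signature_is_molecular_linear_predictor(small_cohort):
    cohort, _ = small_cohort
    result = run_sequential(cohort, CFG, fit_reference=False)
    gamma = result.first_fit.coefficients()
    expected = cohort.layer_a[gamma.index].to_numpy() @ gamma.to_numpy()
    obs = result.signature.values.loc[cohort.layer_a_ids].to_numpy()
    np.testing.assert_allclose(obs, expected, atol=1e-12)


def test_signature_with_clinical_part(small_cohort):
    cohort, _ = small_cohort
    result = run_sequential(cohort, CFG, fit_reference=False)
    sig = extract_signature(result.first_fit, cohort, include_clinical=True)
    alpha = result.first_fit.mandatory_coefficients()
    clin_part = (
        cohort.clinical.loc[cohort.layer_a_ids, alpha.index].to_numpy()
        @ alpha.to_numpy()
    )
    base = result.signature.values.loc[cohort.layer_a_ids].to_numpy()
    np.testing.assert_allclose(sig.values.to_numpy(), base + clin_part, atol=1e-12)


def test_imputation_preserves_observed_values(small_cohort):
    cohort, _ = small_cohort
    result = run_sequential(cohort, CFG, fit_reference=False)
    sig = result.signature
    a_ids = cohort.layer_a_ids
    assert (sig.source.loc[a_ids] == "observed").all()
    b_only = cohort.layer_b_ids.difference(a_ids)
    assert (sig.source.loc[b_only] == "imputed").all()
    assert set(sig.values.index) == set(a_ids.union(cohort.layer_b_ids))


def test_imputed_signature_tracks_truth_under_exact_linkage():
    # full-overlap ground truth available: mask layer A for some samples and
    # check the linking model recovers their signature; with linkage 1 the
    # second layer carries exact copies, so only estimation error remains
    cfg = SimulationConfig(
        n_samples=160, k_layer_a=25, q_layer_b=25, n_clinical=2,
        n_true_a=4, n_true_b=0, effect_a=1.0, linkage=1.0,
        overlap_fraction=1.0, layer_a_kind="gaussian", censoring_rate=0.2,
        seed=11,
    )
    full, _ = generate_two_layer_cohort(cfg)
    held = full.sample_ids[100:]
    masked = LayeredCohort(
        clinical=full.clinical,
        layer_a=full.layer_a.iloc[:100],
        layer_b=full.layer_b,
        outcome=full.outcome,
    )
    result = run_sequential(masked, CFG, fit_reference=False)
    gamma = result.first_fit.coefficients()
    truth_sig = full.layer_a.loc[held, gamma.index].to_numpy() @ gamma.to_numpy()
    imputed = result.signature.values.loc[held].to_numpy()
    if truth_sig.std() > 0:
        corr = np.corrcoef(truth_sig, imputed)[0, 1]
        assert corr >= 0.9


def test_order_swap_symmetry(small_cohort):
    cohort, _ = small_cohort
    cfg_b = dataclasses.replace(CFG, order="B_then_A")
    res_swapped = run_sequential(cohort, cfg_b)
    res_direct = run_sequential(cohort.swap_layers(), CFG)
    np.testing.assert_allclose(
        res_swapped.second_fit.coef_path, res_direct.second_fit.coef_path, atol=1e-12
    )
    assert res_swapped.second_fit.selected_step == res_direct.second_fit.selected_step


def test_run_sequential_deterministic(small_cohort):
    cohort, _ = small_cohort
    r1 = run_sequential(cohort, CFG, fit_reference=False)
    r2 = run_sequential(cohort, CFG, fit_reference=False)
    for a, b in ((r1.first_fit, r2.first_fit), (r1.second_fit, r2.second_fit)):
        assert a.selected_step == b.selected_step
        np.testing.assert_array_equal(a.coef_path, b.coef_path)
    pd.testing.assert_series_equal(r1.signature.values, r2.signature.values)


def test_stage_seeds_distinct_and_bounded():
    cfg = SequentialConfig(seed=123)
    seeds = {stage: cfg.stage_config(stage).seed
             for stage in ("first", "link", "second", "reference")}
    assert len(set(seeds.values())) == 4
    assert all(0 <= s < 2**31 for s in seeds.values())


def test_insufficient_overlap_raises(small_cohort):
    cohort, _ = small_cohort
    b_only = cohort.layer_b_ids.difference(cohort.layer_a_ids)
    disjoint = LayeredCohort(
        clinical=cohort.clinical,
        layer_a=cohort.layer_a,
        layer_b=cohort.layer_b.loc[b_only],
        outcome=cohort.outcome,
    )
    sig = Signature(
        values=pd.Series(0.0, index=cohort.layer_a_ids),
        source=pd.Series("observed", index=cohort.layer_a_ids),
    )
    with pytest.raises(ValueError, match="insufficient overlap"):
        fit_linking_model(sig, disjoint, CFG)


def test_small_overlap_warns(small_cohort):
    cohort, _ = small_cohort
    keep_b = cohort.overlap_ids[:4].append(
        cohort.layer_b_ids.difference(cohort.layer_a_ids)
    )
    thin = LayeredCohort(
        clinical=cohort.clinical,
        layer_a=cohort.layer_a,
        layer_b=cohort.layer_b.loc[keep_b],
        outcome=cohort.outcome,
    )
    with pytest.warns(UserWarning, match="overlap"):
        run_sequential(thin, CFG, fit_reference=False)


def test_missing_signature_values_raise(small_cohort):
    cohort, _ = small_cohort
    partial_ids = cohort.layer_b_ids[:5]
    sig = Signature(
        values=pd.Series(0.0, index=partial_ids),
        source=pd.Series("observed", index=partial_ids),
    )
    with pytest.raises(ValueError, match="signature"):
        fit_second_level(cohort, sig, CFG)


def test_selected_features_report_structure(small_cohort):
    cohort, _ = small_cohort
    result = run_sequential(cohort, CFG)
    report = selected_features_report(result)
    assert list(report.columns) == ["stage", "feature", "coefficient"]
    stages = set(report["stage"])
    assert stages <= {"first_level", "linking_model", "second_level", "reference"}
    assert (report["coefficient"] != 0).all()


def test_stage_errors_are_labelled():
    ids = np.array([f"s{i}" for i in range(20)], dtype=object)
    rng = np.random.default_rng(0)
    from omicslink import SurvivalOutcome

    cohort = LayeredCohort(
        clinical=pd.DataFrame({"c": rng.standard_normal(20)}, index=ids),
        layer_a=pd.DataFrame({"a": rng.standard_normal(20)}, index=ids),
        layer_b=pd.DataFrame({"b": rng.standard_normal(20)}, index=ids),
        outcome=SurvivalOutcome(
            time=rng.exponential(1, 20), event=np.zeros(20, int), sample_ids=ids
        ),
    )
    with pytest.raises(ValueError, match=r"\[stage first_level\]"):
        run_sequential(cohort, CFG)
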