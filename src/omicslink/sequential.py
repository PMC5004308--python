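"""The sequential complementary strategy for two molecular layers.

Step 1a fits a Cox boosting model to the first layer (clinical covariates
mandatory) and condenses it into a per-sample molecular signature — the
optional-covariate part of the linear predictor.  Step 1b fits a Gaussian
boosting "linking model" on the overlap samples, predicting that signature
from the second layer, and imputes it for second-layer samples without
first-layer measurements.  Step 2 fits the second-layer Cox boosting model
with the (observed or imputed) signature as a fixed offset, so the second
layer contributes only information complementary to the first.  A reference
fit — the identical second-level model with zero offset — quantifies what
adjustment changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .boosting import fit_cox_boost, fit_gaussian_boost, predict_linear_predictor
from .containers import BoostConfig, BoostFit, LayeredCohort, Signature

__all__ = [
    "SequentialConfig",
    "SequentialResult",
    "fit_first_level",
    "extract_signature",
    "fit_linking_model",
    "impute_signature",
    "fit_second_level",
    "run_sequential",
    "run_reference",
    "selected_features_report",
]

_STAGE_SEEDS = {"first": 0, "link": 1, "second": 2, "reference": 3}


@dataclass
class SequentialConfig:
    """Configuration of the full stepwise procedure.

    ``order`` chooses which layer is modeled first ("A_then_B" analyzes layer
    A and adjusts the layer-B model; "B_then_A" swaps the roles).  Each stage
    consumes an independent sub-seed derived from ``seed``, so fold
    assignments in one stage do not depend on the others.
    ``offset_includes_clinical`` switches the signature passed downstream
    from the molecular part of the first-level linear predictor (default) to
    the full linear predictor including the clinical contribution.
    """

    order: str = "A_then_B"
    n_steps_max: int = 200
    penalty: Optional[float] = None
    penalty_link: Optional[float] = None
    cv_folds: int = 10
    seed: int = 0
    offset_includes_clinical: bool = False
    min_overlap_warn: int = 10

    def __post_init__(self):
        if self.order not in ("A_then_B", "B_then_A"):
            raise ValueError("order must be 'A_then_B' or 'B_then_A'")

    def stage_config(self, stage: str) -> BoostConfig:
        sub = np.random.SeedSequence(self.seed).generate_state(4)
        penalty = self.penalty_link if stage == "link" else self.penalty
        return BoostConfig(
            n_steps_max=self.n_steps_max,
            penalty=penalty,
            cv_folds=self.cv_folds,
            seed=int(sub[_STAGE_SEEDS[stage]] % (2**31)),
        )


@dataclass
class SequentialResult:
    """All fits of one sequential run plus the reference fit."""

    first_fit: BoostFit
    link_fit: BoostFit
    signature: Signature
    second_fit: BoostFit
    reference_fit: BoostFit
    config: SequentialConfig
    order: str


def _stage(name: str):
    class _StageContext:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise type(exc)(f"[stage {name}] {exc}") from exc
            return False

    return _StageContext()


def fit_first_level(cohort: LayeredCohort, config: SequentialConfig) -> BoostFit:
    """Cox boosting fit on the samples with first-layer measurements
    (clinical covariates mandatory, layer features optional)."""
    ids = cohort.layer_a_ids
    outcome = cohort.outcome.subset(ids)
    if outcome.n_events < 2:
        raise ValueError(
            f"only {outcome.n_events} events among first-layer samples; need >= 2"
        )
    return fit_cox_boost(
        mandatory=cohort.clinical.loc[ids],
        optional=cohort.layer_a,
        outcome=outcome,
        config=config.stage_config("first"),
    )


def extract_signature(
    first_fit: BoostFit, cohort: LayeredCohort, include_clinical: bool = False
) -> Signature:
    """Observed signature: the molecular contribution x' gamma-hat of the
    first-level fit at its selected step, for every first-layer sample.

    With ``include_clinical`` the clinical contribution is added; by default
    it is excluded, because downstream models re-estimate clinical effects
    with their own unpenalized parameter vectors.
    """
    ids = cohort.layer_a_ids
    gamma = first_fit.coefficients()
    values = cohort.layer_a[gamma.index].to_numpy(dtype=float) @ gamma.to_numpy()
    if include_clinical:
        alpha = first_fit.mandatory_coefficients()
        values = values + cohort.clinical.loc[ids, alpha.index].to_numpy() @ alpha.to_numpy()
    series = pd.Series(values, index=ids, name="signature")
    return Signature(values=series, source=pd.Series("observed", index=ids))


def fit_linking_model(
    signature_observed: Signature, cohort: LayeredCohort, config: SequentialConfig
) -> BoostFit:
    """Gaussian boosting fit on the overlap samples predicting the observed
    signature from clinical (mandatory) plus second-layer (optional)
    covariates."""
    overlap = cohort.overlap_ids
    if len(overlap) < 2:
        raise ValueError(f"insufficient overlap: {len(overlap)} samples (need >= 2)")
    if len(overlap) < config.min_overlap_warn:
        warnings.warn(
            f"overlap of only {len(overlap)} samples; imputation quality may be poor",
            stacklevel=2,
        )
    stage_cfg = config.stage_config("link")
    stage_cfg.cv_folds = min(stage_cfg.cv_folds, len(overlap))
    return fit_gaussian_boost(
        mandatory=cohort.clinical.loc[overlap],
        optional=cohort.layer_b.loc[overlap],
        response=signature_observed.values.loc[overlap],
        config=stage_cfg,
    )


def impute_signature(
    link_fit: BoostFit, cohort: LayeredCohort, signature_observed: Signature
) -> Signature:
    """Complete signature: observed values for first-layer samples, linking-
    model predictions for the remaining second-layer samples."""
    observed_ids = signature_observed.values.index
    to_impute = cohort.layer_b_ids.difference(observed_ids)
    pieces_v = [signature_observed.values]
    pieces_s = [pd.Series("observed", index=observed_ids)]
    if len(to_impute):
        predicted = predict_linear_predictor(
            link_fit,
            mandatory=cohort.clinical.loc[to_impute],
            optional=cohort.layer_b.loc[to_impute],
        )
        pieces_v.append(predicted)
        pieces_s.append(pd.Series("imputed", index=to_impute))
    values = pd.concat(pieces_v)
    source = pd.concat(pieces_s)
    return Signature(values=values, source=source)


def fit_second_level(
    cohort: LayeredCohort, signature: Signature, config: SequentialConfig
) -> BoostFit:
    """Cox boosting fit on second-layer samples with the signature as a fixed
    offset (clinical mandatory, second-layer features optional)."""
    ids = cohort.layer_b_ids
    missing = ids.difference(signature.values.index)
    if len(missing):
        raise ValueError(f"second-level samples without signature value: {list(missing[:5])}")
    outcome = cohort.outcome.subset(ids)
    if outcome.n_events < 2:
        raise ValueError(
            f"only {outcome.n_events} events among second-layer samples; need >= 2"
        )
    return fit_cox_boost(
        mandatory=cohort.clinical.loc[ids],
        optional=cohort.layer_b,
        outcome=outcome,
        offset=signature.values.loc[ids],
        config=config.stage_config("second"),
    )


def run_reference(cohort: LayeredCohort, config: SequentialConfig) -> BoostFit:
    """Second-level model without adjustment (zero offset): the reference
    against which the sequential strategy is compared."""
    ids = cohort.layer_b_ids
    outcome = cohort.outcome.subset(ids)
    if outcome.n_events < 2:
        raise ValueError(
            f"only {outcome.n_events} events among second-layer samples; need >= 2"
        )
    return fit_cox_boost(
        mandatory=cohort.clinical.loc[ids],
        optional=cohort.layer_b,
        outcome=outcome,
        config=config.stage_config("reference"),
    )


def run_sequential(
    cohort: LayeredCohort, config: Optional[SequentialConfig] = None, fit_reference: bool = True
) -> SequentialResult:
    """Execute the full stepwise procedure on a two-layer cohort.

    Runs first-level fit, signature extraction, linking model, imputation and
    the offset-adjusted second-level fit, plus (optionally) the unadjusted
    reference fit on identical data.  With ``order='B_then_A'`` the roles of
    the two layers are exchanged before fitting.
    """
    config = config or SequentialConfig()
    work = cohort.swap_layers() if config.order == "B_then_A" else cohort

    with _stage("first_level"):
        first_fit = fit_first_level(work, config)
    with _stage("extract_signature"):
        sig_observed = extract_signature(
            first_fit, work, include_clinical=config.offset_includes_clinical
        )
    with _stage("linking_model"):
        link_fit = fit_linking_model(sig_observed, work, config)
    with _stage("impute_signature"):
        signature = impute_signature(link_fit, work, sig_observed)
    with _stage("second_level"):
        second_fit = fit_second_level(work, signature, config)
    reference_fit = None
    if fit_reference:
        with _stage("reference"):
            reference_fit = run_reference(work, config)
    return SequentialResult(
        first_fit=first_fit,
        link_fit=link_fit,
        signature=signature,
        second_fit=second_fit,
        reference_fit=reference_fit,
        config=config,
        order=config.order,
    )


def selected_features_report(result: SequentialResult) -> pd.DataFrame:
    """Tidy table of non-zero coefficients per stage at the selected steps."""
    rows = []
    stages = [
        ("first_level", result.first_fit),
        ("linking_model", result.link_fit),
        ("second_level", result.second_fit),
    ]
    if result.reference_fit is not None:
        stages.append(("reference", result.reference_fit))
    for stage, fit in stages:
        for feature, coef in fit.selected_features().items():
            rows.append({"stage": stage, "feature": feature, "coefficient": coef})
    return pd.DataFrame(rows, columns=["stage", "feature", "coefficient"])
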