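"""Refittable pipeline wrappers binding the sequential strategy to the
resampling-based evaluation machinery.

The .632+ bootstrap and the stability analysis both require retraining the
*entire* model-building procedure — first-level fit, linking model,
imputation and second-level fit, each with its own cross-validated step
selection — inside every resample.  The helpers here package the four
approaches compared throughout (sequential, reference, clinical Cox,
Kaplan-Meier benchmark) as refit-and-predict callables over the second-level
cohort, and run the paired stability analysis.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .boosting import predict_linear_predictor, predict_survival
from .containers import LayeredCohort, Signature, SurvivalOutcome
from .evaluation import (
    PredictionErrorCurve,
    bootstrap_632plus_pec,
    clinical_cox_benchmark,
    default_time_grid,
    km_estimator,
)
from .sequential import (
    SequentialConfig,
    fit_second_level,
    run_reference,
    run_sequential,
)

__all__ = [
    "bootstrap_cohort",
    "sequential_signature_for",
    "evaluate_approaches",
    "stability_frequencies",
]


def _relabel_duplicates(ids: np.ndarray) -> np.ndarray:
    """Make a with-replacement draw of sample ids unique by suffixing
    repeated occurrences (s12, s12@1, s12@2, ...)."""
    seen: dict = {}
    out = np.empty(ids.shape[0], dtype=object)
    for i, s in enumerate(ids):
        k = seen.get(s, 0)
        out[i] = s if k == 0 else f"{s}@{k}"
        seen[s] = k + 1
    return out


def bootstrap_cohort(cohort: LayeredCohort, second_ids: np.ndarray) -> LayeredCohort:
    """Cohort for one resample of the second-level samples.

    ``second_ids`` may contain repeats (bootstrap); repeated samples are
    relabeled.  Samples measured only on the first layer are always kept, so
    the first-level model keeps using all its data.
    """
    second_ids = np.asarray(second_ids, dtype=object)
    new_second = _relabel_duplicates(second_ids)
    a_only = cohort.layer_a_ids.difference(cohort.layer_b_ids)

    def stack(df: pd.DataFrame, ids, new_ids) -> pd.DataFrame:
        out = df.loc[list(ids)]
        out.index = pd.Index(new_ids)
        return out

    clin = pd.concat(
        [cohort.clinical.loc[a_only], stack(cohort.clinical, second_ids, new_second)]
    )
    in_a = np.isin(second_ids, cohort.layer_a_ids)
    layer_a = pd.concat(
        [cohort.layer_a.loc[a_only], stack(cohort.layer_a, second_ids[in_a], new_second[in_a])]
    )
    layer_b = stack(cohort.layer_b, second_ids, new_second)
    ofr = cohort.outcome.to_frame()
    out = pd.concat([ofr.loc[a_only], stack(ofr, second_ids, new_second)])
    return LayeredCohort(
        clinical=clin,
        layer_a=layer_a,
        layer_b=layer_b,
        outcome=SurvivalOutcome.from_frame(out),
    )


def sequential_signature_for(result, cohort: LayeredCohort) -> Signature:
    """Signature values for an arbitrary cohort's second-level samples, using
    the fits of a (possibly resample-trained) sequential result: observed
    via the first-level coefficients where the first layer is measured,
    imputed via the linking model elsewhere."""
    gamma = result.first_fit.coefficients()
    obs_ids = cohort.layer_a_ids
    obs = pd.Series(
        cohort.layer_a[gamma.index].to_numpy(float) @ gamma.to_numpy(), index=obs_ids
    )
    if result.config.offset_includes_clinical:
        alpha = result.first_fit.mandatory_coefficients()
        obs = obs + pd.Series(
            cohort.clinical.loc[obs_ids, alpha.index].to_numpy(float) @ alpha.to_numpy(),
            index=obs_ids,
        )
    to_impute = cohort.layer_b_ids.difference(obs_ids)
    values = [obs]
    sources = [pd.Series("observed", index=obs_ids)]
    if len(to_impute):
        values.append(
            predict_linear_predictor(
                result.link_fit,
                mandatory=cohort.clinical.loc[to_impute],
                optional=cohort.layer_b.loc[to_impute],
            )
        )
        sources.append(pd.Series("imputed", index=to_impute))
    return Signature(values=pd.concat(values), source=pd.concat(sources))


def _draw_seed(base_seed: int, counter: int) -> int:
    return int(np.random.SeedSequence([base_seed, counter]).generate_state(1)[0] % (2**31))


def _make_fit_predict(cohort: LayeredCohort, config: SequentialConfig, times, approach: str):
    """Build the refit-and-predict callable for one approach.

    The returned function accepts positional bootstrap indices into the
    second-level samples (None = full data), refits the approach from
    scratch (fresh CV seed per draw), and predicts survival for all original
    second-level samples.
    """
    eval_ids = np.asarray(cohort.layer_b_ids, dtype=object)
    eval_clin = cohort.clinical.loc[eval_ids]
    eval_b = cohort.layer_b.loc[eval_ids]
    eval_outcome = cohort.outcome.subset(eval_ids)
    times = np.asarray(times, dtype=float)
    state = {"counter": 0}

    def fit_predict(idx):
        if idx is None:
            work = cohort
            seed = config.seed
        else:
            work = bootstrap_cohort(cohort, eval_ids[idx])
            state["counter"] += 1
            seed = _draw_seed(config.seed, state["counter"])
        cfg = SequentialConfig(
            order="A_then_B",  # layers already in role order here
            n_steps_max=config.n_steps_max,
            penalty=config.penalty,
            penalty_link=config.penalty_link,
            cv_folds=config.cv_folds,
            seed=seed,
            offset_includes_clinical=config.offset_includes_clinical,
            min_overlap_warn=config.min_overlap_warn,
        )
        if approach == "sequential":
            result = run_sequential(work, cfg, fit_reference=False)
            sig = sequential_signature_for(result, cohort)
            return predict_survival(
                result.second_fit,
                mandatory=eval_clin,
                optional=eval_b,
                times=times,
                offset=sig.values.loc[eval_ids],
            ).to_numpy()
        if approach == "reference":
            fit = run_reference(work, cfg)
            return predict_survival(
                fit, mandatory=eval_clin, optional=eval_b, times=times
            ).to_numpy()
        if approach == "clinical":
            second = work.layer_b_ids
            fit = clinical_cox_benchmark(
                work.clinical.loc[second], work.outcome.subset(second)
            )
            return predict_survival(fit, mandatory=eval_clin, times=times).to_numpy()
        if approach == "km":
            second = work.layer_b_ids
            km = km_estimator(work.outcome.subset(second))
            return np.tile(km(times), (eval_ids.shape[0], 1))
        raise ValueError(f"unknown approach: {approach}")

    return fit_predict, eval_outcome


APPROACHES = ("sequential", "reference", "clinical", "km")


def evaluate_approaches(
    cohort: LayeredCohort,
    config: Optional[SequentialConfig] = None,
    times=None,
    B: int = 100,
    seed: int = 0,
    approaches=APPROACHES,
) -> dict:
    """.632+ prediction error curves of the compared approaches.

    All approaches are evaluated on the second-level samples with identical
    bootstrap draws (same ``seed``), so comparisons are paired.  Respects
    ``config.order`` by swapping layer roles up front.
    """
    config = config or SequentialConfig()
    work = cohort.swap_layers() if config.order == "B_then_A" else cohort
    if times is None:
        times = default_time_grid(cohort.outcome.subset(work.layer_b_ids))
    curves = {}
    for approach in approaches:
        fit_predict, eval_outcome = _make_fit_predict(work, config, times, approach)
        curves[approach] = bootstrap_632plus_pec(
            fit_predict, eval_outcome, times, B=B, seed=seed, label=approach
        )
    return curves


def stability_frequencies(
    cohort: LayeredCohort,
    config: Optional[SequentialConfig] = None,
    B: int = 100,
    seed: int = 0,
    refit_linking: bool = True,
) -> pd.DataFrame:
    """Paired inclusion frequencies of the second-layer features under the
    sequential strategy and the reference approach.

    Draws B subsamples of size floor(0.632 n) without replacement from the
    second-level samples (first-layer-only samples always retained) and
    reruns both model-building procedures per subsample, cross-validated
    step selection included.  With ``refit_linking=False`` the signature is
    computed once on the full cohort and held fixed inside resamples.
    """
    config = config or SequentialConfig()
    work = cohort.swap_layers() if config.order == "B_then_A" else cohort
    eval_ids = np.asarray(work.layer_b_ids, dtype=object)
    a_only = work.layer_a_ids.difference(work.layer_b_ids)
    n = eval_ids.shape[0]
    size = int(np.floor(0.632 * n))
    rng = np.random.default_rng(seed)
    event_lookup = pd.Series(work.outcome.event, index=work.outcome.sample_ids)

    fixed_signature = None
    if not refit_linking:
        full = run_sequential(work, config, fit_reference=False)
        fixed_signature = full.signature

    features = list(work.layer_b.columns)
    counts = pd.DataFrame(0.0, index=pd.Index(features, name="feature"),
                          columns=["sequential", "reference"])
    for b in range(B):
        for _ in range(100):
            pos = rng.choice(n, size=size, replace=False)
            if event_lookup.loc[eval_ids[pos]].any():
                break
        else:
            raise RuntimeError("could not draw a subsample containing events")
        sub_ids = pd.Index(a_only).append(pd.Index(eval_ids[pos]))
        sub = work.restrict(sub_ids)
        cfg = SequentialConfig(
            order="A_then_B",
            n_steps_max=config.n_steps_max,
            penalty=config.penalty,
            penalty_link=config.penalty_link,
            cv_folds=config.cv_folds,
            seed=_draw_seed(config.seed, b + 1),
            offset_includes_clinical=config.offset_includes_clinical,
            min_overlap_warn=config.min_overlap_warn,
        )
        if refit_linking:
            result = run_sequential(sub, cfg, fit_reference=True)
            seq_selected = result.second_fit.selected_features().index
            ref_selected = result.reference_fit.selected_features().index
        else:
            second = fit_second_level(sub, fixed_signature, cfg)
            seq_selected = second.selected_features().index
            ref_selected = run_reference(sub, cfg).selected_features().index
        counts.loc[seq_selected, "sequential"] += 1.0
        counts.loc[ref_selected, "reference"] += 1.0
    freqs = counts / B
    freqs.attrs["B"] = B
    freqs.attrs["subsample_size"] = size
    return freqs
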