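"""Planted-signal simulation benchmarks for the sequential strategy.

Three study designs exercised by the package's acceptance checks and
reproduction script:

* feature recovery — how reliably does first-level boosting re-find planted
  hazard-driving features across subsamples (inclusion frequencies)?
* approach ordering — do the integrated .632+ prediction errors of the four
  approaches (sequential, reference, clinical Cox, Kaplan-Meier) order as
  expected on informative data?
* overlap-size degradation — does sequential performance decay, and never
  improve, as the sample overlap between the two layers shrinks?

Problem sizes are chosen desk-scale: a few hundred samples and tens to a few
hundred features, so a full benchmark finishes in minutes on one CPU while
preserving the qualitative structure of much larger cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import LayeredCohort
from .evaluation import (
    brier_curve,
    default_time_grid,
    inclusion_frequencies,
    integrated_pec,
)
from .pipelines import evaluate_approaches, sequential_signature_for
from .sequential import SequentialConfig, fit_first_level, run_sequential
from .simulate import SimulationConfig, generate_two_layer_cohort

__all__ = [
    "recovery_benchmark",
    "ordering_benchmark",
    "overlap_benchmark",
]


def _sub_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Feature recovery under subsampling
# ---------------------------------------------------------------------------

def recovery_benchmark(
    seed: int = 0,
    n_samples: int = 300,
    k_features: int = 200,
    n_true: int = 5,
    effect: float = 0.8,
    B: int = 50,
    n_steps_max: int = 100,
    cv_folds: int = 10,
) -> dict:
    """Inclusion-frequency recovery of planted first-layer effects.

    Generates one cohort with ``n_true`` hazard-driving features of strength
    ``effect`` among ``k_features`` Gaussian features, draws ``B`` subsamples
    of size floor(0.632 n) and reruns the full first-level model building
    (including cross-validated step selection) per subsample.  Returns the
    frequencies plus the fraction of true features reaching frequency 0.5.
    """
    cfg = SimulationConfig(
        n_samples=n_samples,
        k_layer_a=k_features,
        q_layer_b=max(2 * n_true, 10),
        n_true_a=n_true,
        n_true_b=0,
        effect_a=effect,
        layer_a_kind="gaussian",
        overlap_fraction=1.0,
        seed=_sub_seed(seed, 0),
    )
    cohort, truth = generate_two_layer_cohort(cfg)

    def select(sub_ids, rep_seed):
        sub = cohort.restrict(sub_ids)
        cfg_rep = SequentialConfig(
            n_steps_max=n_steps_max, cv_folds=cv_folds, seed=rep_seed
        )
        fit = fit_first_level(sub, cfg_rep)
        return fit.selected_features().index

    freqs = inclusion_frequencies(
        select,
        sample_ids=cohort.layer_a_ids,
        feature_ids=cohort.layer_a.columns,
        B=B,
        seed=_sub_seed(seed, 1),
        event=cohort.outcome.subset(cohort.layer_a_ids).event,
    )
    true_freqs = freqs.loc[truth.true_a.index]
    return {
        "frequencies": freqs,
        "true_features": list(truth.true_a.index),
        "recovered_fraction": float((true_freqs >= 0.5).mean()),
    }


# ---------------------------------------------------------------------------
# Shared generator for the prediction benchmarks
# ---------------------------------------------------------------------------

def _informative_config(seed: int, n_samples: int, overlap_fraction: float,
                        n_a_only: int = 0) -> SimulationConfig:
    """Informative two-layer design: strong direct layer-A effects, tight
    A-to-B linkage (so imputation can work), moderate layer-B-specific and
    clinical effects."""
    return SimulationConfig(
        n_samples=n_samples,
        k_layer_a=40,
        q_layer_b=40,
        n_clinical=3,
        n_true_a=4,
        n_true_b=3,
        effect_a=0.7,
        effect_b=0.5,
        clinical_effect=0.7,
        linkage=0.9,
        overlap_fraction=overlap_fraction,
        n_a_only=n_a_only,
        censoring_rate=0.3,
        layer_a_kind="gaussian",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Ordering of the four approaches (integrated .632+ error)
# ---------------------------------------------------------------------------

def ordering_benchmark(
    seed: int = 0,
    n_replicates: int = 20,
    n_samples: int = 160,
    overlap_fraction: float = 0.5,
    B_bootstrap: int = 10,
    n_steps_max: int = 40,
    cv_folds: int = 10,
) -> dict:
    """Median integrated .632+ error per approach over replicates.

    Within each replicate the four approaches share the same cohort and the
    same bootstrap draws, so the comparison is paired.
    """
    per_rep = {a: [] for a in ("sequential", "reference", "clinical", "km")}
    for rep in range(n_replicates):
        rep_seed = _sub_seed(seed, 100, rep)
        cohort, _ = generate_two_layer_cohort(
            _informative_config(rep_seed, n_samples, overlap_fraction)
        )
        cfg = SequentialConfig(
            n_steps_max=n_steps_max, cv_folds=cv_folds, seed=rep_seed
        )
        curves = evaluate_approaches(cohort, cfg, B=B_bootstrap, seed=rep_seed)
        for name, curve in curves.items():
            per_rep[name].append(
                integrated_pec(curve.times, curve.e632plus, curve.times.max())
            )
    medians = {name: float(np.median(v)) for name, v in per_rep.items()}
    return {"per_replicate": per_rep, "medians": medians}


# ---------------------------------------------------------------------------
# Effect of the overlap size
# ---------------------------------------------------------------------------

def _mask_overlap(cohort: LayeredCohort, n_a_only: int, n_overlap: int) -> LayeredCohort:
    """Restrict layer-A availability of a fully-overlapping cohort: the first
    ``n_a_only`` samples keep layer A only, the next ``n_overlap`` keep both,
    and the remaining samples keep layer B only."""
    ids = np.asarray(cohort.sample_ids, dtype=object)
    a_ids = ids[: n_a_only + n_overlap]
    b_ids = ids[n_a_only:]
    return LayeredCohort(
        clinical=cohort.clinical,
        layer_a=cohort.layer_a.loc[a_ids],
        layer_b=cohort.layer_b.loc[b_ids],
        outcome=cohort.outcome,
    )


def overlap_benchmark(
    seed: int = 0,
    overlap_fractions=(1.0, 0.5, 0.15, 0.05),
    n_replicates: int = 40,
    n_second_level: int = 100,
    n_a_only: int = 100,
    n_test: int = 300,
    q_layer_b: int = 120,
    n_steps_max: int = 40,
    cv_folds: int = 10,
) -> dict:
    """Sequential prediction error as the overlap shrinks.

    Each replicate draws one training cohort (``n_a_only`` first-layer-only
    samples plus ``n_second_level`` second-layer samples, fully overlapping)
    and one independent test cohort from the same design.  The first-layer
    availability of the second-level samples is then thinned to each overlap
    fraction — mimicking a study where ever fewer patients were measured on
    both platforms — the whole pipeline is refit, and the integrated IPCW
    Brier score of the sequential model is measured on the test samples,
    which carry second-layer measurements only (signature always imputed).
    Paired across fractions within a replicate.

    The second layer is wider here (``q_layer_b`` candidate features) than in
    the ordering benchmark so that the linking model's quality depends
    materially on how many overlap samples it can train on.
    """
    import dataclasses

    n_train = n_a_only + n_second_level
    results = {f: [] for f in overlap_fractions}
    for rep in range(n_replicates):
        rep_seed = _sub_seed(seed, 200, rep)
        full, _ = generate_two_layer_cohort(
            dataclasses.replace(
                _informative_config(rep_seed, n_train, 1.0), q_layer_b=q_layer_b
            )
        )
        test, _ = generate_two_layer_cohort(
            dataclasses.replace(
                _informative_config(_sub_seed(seed, 201, rep), n_test, 1.0),
                q_layer_b=q_layer_b,
            )
        )
        test_outcome = test.outcome
        times = default_time_grid(test_outcome)
        for f in overlap_fractions:
            n_overlap = max(int(round(f * n_second_level)), 2)
            masked = _mask_overlap(full, n_a_only, n_overlap)
            cfg = SequentialConfig(
                n_steps_max=n_steps_max, cv_folds=cv_folds,
                seed=_sub_seed(rep_seed, 1),
            )
            result = run_sequential(masked, cfg, fit_reference=False)
            # test samples are second-layer only: signature always imputed
            from .boosting import predict_linear_predictor, predict_survival

            sig = predict_linear_predictor(
                result.link_fit, mandatory=test.clinical, optional=test.layer_b
            )
            S = predict_survival(
                result.second_fit,
                mandatory=test.clinical,
                optional=test.layer_b,
                times=times,
                offset=sig,
            )
            curve = brier_curve(S.to_numpy(), test_outcome, times)
            results[f].append(integrated_pec(times, curve, times.max()))
    medians = {f: float(np.median(v)) for f, v in results.items()}
    return {"per_replicate": results, "medians": medians}
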