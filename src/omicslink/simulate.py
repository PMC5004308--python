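"""Seeded generator of two-layer cohorts with partial sample overlap.

The generator emulates the data situation the sequential strategy targets:
two high-dimensional molecular layers measured on partially overlapping
sample sets, a small clinical table available for everyone, sparse true
effects on a proportional-hazards survival endpoint, and independent
censoring.  Information flows from layer A into layer B: a subset of layer-B
features are noisy linear images of the hazard-driving layer-A features, so
layer B carries proxy information about the layer-A signal — the structure
that makes linear-predictor imputation through a linking model possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional
import warnings

import numpy as np
import pandas as pd

from .containers import LayeredCohort, SurvivalOutcome

__all__ = ["SimulationConfig", "TruthRecord", "generate_two_layer_cohort", "application1_fixture"]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Effects are expressed on the standardized feature scale so that
    ``effect_a``/``effect_b`` are log hazard ratios per standard deviation
    regardless of the layer-A coding.  ``linkage`` is the correlation between
    a true layer-A feature and its layer-B proxy (0 = independent layers,
    1 = layer B determines the signature exactly).
    """

    n_samples: int = 200
    k_layer_a: int = 100
    q_layer_b: int = 100
    n_clinical: int = 4
    n_true_a: int = 5
    n_true_b: int = 5
    effect_a: float = 0.8
    effect_b: float = 0.8
    clinical_effect: float = 0.5
    linkage: float = 0.7
    overlap_fraction: float = 0.5
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.3
    layer_a_kind: str = "genotype"  # "genotype" ({0,1,2} allele counts) or "gaussian"
    n_a_only: int = 0
    n_b_only: Optional[int] = None
    event_time: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must lie in (0, 1]")
        if self.overlap_fraction * self.n_samples < 2:
            raise ValueError("overlap_fraction * n_samples must be >= 2")
        if self.n_true_a > self.k_layer_a or self.n_true_b > self.q_layer_b:
            raise ValueError("more true effects than features")
        if self.n_true_a + self.n_true_b > self.q_layer_b:
            raise ValueError("layer B too small for linked plus true features")
        if not 0 <= self.linkage <= 1:
            raise ValueError("linkage must lie in [0, 1]")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.layer_a_kind not in ("genotype", "gaussian"):
            raise ValueError("layer_a_kind must be 'genotype' or 'gaussian'")
        if self.event_time not in ("exponential", "weibull"):
            raise ValueError("event_time must be 'exponential' or 'weibull'")


@dataclass
class TruthRecord:
    """Ground truth of a generated cohort, for parameter-recovery checks."""

    true_a: pd.Series  # coefficient per true layer-A feature (standardized scale)
    true_b: pd.Series  # coefficient per true layer-B feature
    linked_b: list  # layer-B features that are proxies of true layer-A features
    clinical: pd.Series
    eta: pd.Series  # true log relative hazard per sample
    hazard: pd.Series
    a_center: pd.Series  # standardization moments used for layer-A effects
    a_scale: pd.Series
    censoring_rate_achieved: float
    censoring_hazard: float


def calibrate_censoring(event_times: np.ndarray, target: float) -> float:
    """Exponential censoring hazard achieving an expected censoring fraction.

    Given realized event times, the expected fraction censored under
    C ~ Exp(c) is mean(1 - exp(-c * T)); solved for c by bisection.
    """
    if target <= 0:
        return 0.0

    def frac(c):
        return float(np.mean(1.0 - np.exp(-c * event_times)))

    lo, hi = 1e-12, 1.0 / max(event_times.mean(), 1e-12)
    while frac(hi) < target:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("cannot reach censoring target")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _alternating(size: int, magnitude: float) -> np.ndarray:
    signs = np.where(np.arange(size) % 2 == 0, 1.0, -1.0)
    return signs * magnitude


def generate_two_layer_cohort(config: SimulationConfig):
    """Generate one cohort; returns (LayeredCohort, TruthRecord).

    Deterministic given ``config.seed``; independent sub-streams per
    component so that, e.g., enlarging layer B does not change layer A.
    """
    cfg = config
    n = cfg.n_samples
    ss = np.random.SeedSequence(cfg.seed)
    r_clin, r_a, r_b, r_surv, r_cens = [np.random.default_rng(s) for s in ss.spawn(5)]

    sample_ids = np.array([f"s{i:05d}" for i in range(n)], dtype=object)

    # clinical covariates: alternating continuous / binary, emulating e.g.
    # age, WBC and mutation-status predictors
    clin_cols = [f"clin{j + 1}" for j in range(cfg.n_clinical)]
    clin = np.empty((n, cfg.n_clinical))
    for j in range(cfg.n_clinical):
        if j % 2 == 0:
            clin[:, j] = r_clin.standard_normal(n)
        else:
            clin[:, j] = r_clin.binomial(1, 0.4, size=n).astype(float)
    clinical = pd.DataFrame(clin, index=sample_ids, columns=clin_cols)
    alpha = _alternating(cfg.n_clinical, cfg.clinical_effect)

    # layer A
    a_cols = [f"A{j + 1:04d}" for j in range(cfg.k_layer_a)]
    if cfg.layer_a_kind == "genotype":
        maf = r_a.uniform(0.15, 0.5, size=cfg.k_layer_a)
        A = r_a.binomial(2, maf, size=(n, cfg.k_layer_a)).astype(float)
        a_center = 2.0 * maf
        a_scale = np.sqrt(2.0 * maf * (1.0 - maf))
    else:
        A = r_a.standard_normal((n, cfg.k_layer_a))
        a_center = np.zeros(cfg.k_layer_a)
        a_scale = np.ones(cfg.k_layer_a)
    A_std = (A - a_center) / a_scale
    true_a_idx = np.arange(cfg.n_true_a)
    gamma_a = _alternating(cfg.n_true_a, cfg.effect_a)

    # layer B: the first n_true_a features are noisy proxies of the true
    # layer-A features (this is how layer A acts on the hazard "through"
    # layer B); the next n_true_b features carry layer-B-specific effects.
    b_cols = [f"B{j + 1:04d}" for j in range(cfg.q_layer_b)]
    B = r_b.standard_normal((n, cfg.q_layer_b))
    rho = cfg.linkage
    for i, j in enumerate(true_a_idx):
        B[:, i] = rho * A_std[:, j] + np.sqrt(max(1.0 - rho**2, 0.0)) * B[:, i]
    true_b_idx = np.arange(cfg.n_true_a, cfg.n_true_a + cfg.n_true_b)
    beta_b = _alternating(cfg.n_true_b, cfg.effect_b)

    eta = clin @ alpha + A_std[:, true_a_idx] @ gamma_a + B[:, true_b_idx] @ beta_b
    hazard = cfg.baseline_hazard * np.exp(eta)

    # proportional-hazards event times
    e = r_surv.exponential(1.0, size=n)
    if cfg.event_time == "exponential":
        T = e / hazard
    else:  # Weibull: H0(t) = baseline * t^shape
        T = (e / hazard) ** (1.0 / cfg.weibull_shape)

    c_hazard = calibrate_censoring(T, cfg.censoring_rate)
    if c_hazard > 0:
        C = r_cens.exponential(1.0 / c_hazard, size=n)
    else:
        C = np.full(n, np.inf)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    achieved = 1.0 - event.mean()
    if abs(achieved - cfg.censoring_rate) > 0.15:
        warnings.warn(
            f"achieved censoring rate {achieved:.2f} far from target {cfg.censoring_rate:.2f}"
        )

    # availability masks: overlap first, then layer-A-only, then layer-B-only
    n_overlap = int(round(cfg.overlap_fraction * n))
    n_a_only = cfg.n_a_only
    n_b_only = cfg.n_b_only if cfg.n_b_only is not None else n - n_overlap - n_a_only
    if n_overlap + n_a_only + n_b_only != n:
        raise ValueError("overlap + A-only + B-only sample counts must equal n_samples")
    a_ids = sample_ids[: n_overlap + n_a_only]
    b_ids = np.concatenate([sample_ids[:n_overlap], sample_ids[n_overlap + n_a_only :]])

    layer_a = pd.DataFrame(A, index=sample_ids, columns=a_cols).loc[a_ids]
    layer_b = pd.DataFrame(B, index=sample_ids, columns=b_cols).loc[b_ids]
    outcome = SurvivalOutcome(time=time, event=event, sample_ids=sample_ids)
    cohort = LayeredCohort(
        clinical=clinical, layer_a=layer_a, layer_b=layer_b, outcome=outcome
    )
    truth = TruthRecord(
        true_a=pd.Series(gamma_a, index=[a_cols[j] for j in true_a_idx]),
        true_b=pd.Series(beta_b, index=[b_cols[j] for j in true_b_idx]),
        linked_b=[b_cols[i] for i in range(cfg.n_true_a)],
        clinical=pd.Series(alpha, index=clin_cols),
        eta=pd.Series(eta, index=sample_ids),
        hazard=pd.Series(hazard, index=sample_ids),
        a_center=pd.Series(a_center, index=a_cols),
        a_scale=pd.Series(a_scale, index=a_cols),
        censoring_rate_achieved=float(achieved),
        censoring_hazard=float(c_hazard),
    )
    return cohort, truth


def application1_fixture(seed: int = 20160830):
    """Desk-scale analogue of a two-platform leukemia cohort.

    120 samples with SNP-like genotypes (2,000 markers), 130 samples with
    expression-like features (1,500), an overlap of 12 samples, and 5
    clinical covariates.  Layer A ships dummy-coded (two indicator columns
    per marker, distinguishing dominant and recessive effects).
    Returns (LayeredCohort, TruthRecord).
    """
    from .preprocessing import snp_dummy_code

    cfg = SimulationConfig(
        n_samples=238,
        k_layer_a=2000,
        q_layer_b=1500,
        n_clinical=5,
        n_true_a=6,
        n_true_b=6,
        effect_a=0.9,
        effect_b=0.9,
        linkage=0.8,
        overlap_fraction=12 / 238,
        n_a_only=108,
        censoring_rate=0.4,
        layer_a_kind="genotype",
        seed=seed,
    )
    cohort, truth = generate_two_layer_cohort(cfg)
    cohort = LayeredCohort(
        clinical=cohort.clinical,
        layer_a=snp_dummy_code(cohort.layer_a),
        layer_b=cohort.layer_b,
        outcome=cohort.outcome,
    )
    return cohort, truth
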