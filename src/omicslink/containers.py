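"""Core data containers shared across the package.

Covariate matrices are plain :class:`pandas.DataFrame` objects with sample
identifiers as index and feature identifiers as columns; the helpers here
validate them and carry the survival endpoint, the two-layer cohort with its
availability structure, fitted boosting models, and per-sample signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalOutcome",
    "BoostConfig",
    "BoostFit",
    "LayeredCohort",
    "Signature",
    "validate_design_matrix",
]


def validate_design_matrix(df: pd.DataFrame, name: str = "design matrix") -> pd.DataFrame:
    """Check a covariate matrix: finite values, unique sample/feature ids.

    Missingness is expressed at cohort level through availability (row
    presence), never as NaN inside a matrix.
    """
    if not isinstance(df, pd.DataFrame):
        raise TypeError(f"{name} must be a pandas DataFrame")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"{name} has duplicated feature ids: {dup[:5]}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{name} has duplicated sample ids: {dup[:5]}")
    values = df.to_numpy(dtype=float)
    if values.size and not np.isfinite(values).all():
        raise ValueError(f"{name} contains non-finite values")
    return df


@dataclass(frozen=True)
class SurvivalOutcome:
    """Right-censored survival endpoint.

    ``time`` holds the observed time t_i = min(T_i, C_i) and ``event`` the
    indicator delta_i = I(T_i <= C_i) for each sample.
    """

    time: np.ndarray
    event: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=int)
        ids = np.asarray(self.sample_ids, dtype=object)
        if time.ndim != 1 or event.shape != time.shape or ids.shape != time.shape:
            raise ValueError("time, event and sample_ids must be 1-d and aligned")
        if not np.isfinite(time).all() or (time < 0).any():
            raise ValueError("survival times must be finite and non-negative")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "event": self.event},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalOutcome":
        return cls(
            time=df["time"].to_numpy(),
            event=df["event"].to_numpy(),
            sample_ids=np.asarray(df.index, dtype=object),
        )

    def subset(self, ids) -> "SurvivalOutcome":
        """Reorder/restrict to the given sample ids (which must all exist)."""
        frame = self.to_frame()
        missing = [s for s in ids if s not in frame.index]
        if missing:
            raise KeyError(f"samples without outcome: {missing[:5]}")
        sub = frame.loc[list(ids)]
        return SurvivalOutcome.from_frame(sub)


@dataclass
class BoostConfig:
    """Tuning knobs of componentwise likelihood-based boosting.

    The number of boosting steps is the main tuning parameter and is chosen
    by cross-validation over ``step_grid`` (default 0..n_steps_max).  The
    ridge-type penalty on the one-parameter updates matters little as long as
    it is large enough; by default it is set so each update is shrunk by a
    factor of about 0.1 (Cox: 9 x number of events; Gaussian: 9 x n for
    unit-variance covariates).
    """

    n_steps_max: int = 200
    penalty: Optional[float] = None
    cv_folds: int = 10
    step_grid: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_steps_max < 0:
            raise ValueError("n_steps_max must be >= 0")
        if self.penalty is not None and self.penalty < 0:
            raise ValueError("penalty must be non-negative")
        if self.step_grid is not None:
            grid = np.asarray(self.step_grid, dtype=int)
            if grid.size == 0 or grid.min() < 0 or grid.max() > self.n_steps_max:
                raise ValueError("step_grid must be a non-empty subset of 0..n_steps_max")
            self.step_grid = np.unique(grid)

    def resolved_grid(self) -> np.ndarray:
        if self.step_grid is not None:
            return self.step_grid
        return np.arange(self.n_steps_max + 1)


@dataclass
class BoostFit:
    """Result of one componentwise boosting run.

    ``coef_path`` holds the optional-covariate coefficients on the original
    covariate scale, one row per boosting step (row 0 all zeros; at most one
    entry changes between consecutive rows).  ``mandatory_path`` holds the
    unpenalized clinical coefficients refit at every step.  For the Gaussian
    family ``intercept_path`` completes the mean model on the raw scale.
    ``eta_path`` caches the training linear predictor (raw scale, offset
    included) per step, from which the Breslow baseline hazard is derived.
    """

    family: str
    feature_ids: list
    mandatory_ids: list
    coef_path: np.ndarray
    mandatory_path: np.ndarray
    selected_step: int
    offset: np.ndarray
    sample_ids: np.ndarray
    train_criterion_path: np.ndarray
    eta_path: np.ndarray
    intercept_path: Optional[np.ndarray] = None
    outcome: Optional[SurvivalOutcome] = None
    response: Optional[np.ndarray] = None
    cv_scores: Optional[np.ndarray] = None
    config: Optional[BoostConfig] = None

    @property
    def n_steps(self) -> int:
        return self.coef_path.shape[0] - 1

    def coefficients(self, at_step: Optional[int] = None) -> pd.Series:
        """Optional-covariate coefficients (original scale) at a step."""
        step = self.selected_step if at_step is None else at_step
        if not 0 <= step <= self.n_steps:
            raise ValueError(f"step {step} outside fitted range 0..{self.n_steps}")
        return pd.Series(self.coef_path[step], index=self.feature_ids)

    def mandatory_coefficients(self, at_step: Optional[int] = None) -> pd.Series:
        step = self.selected_step if at_step is None else at_step
        if not 0 <= step <= self.n_steps:
            raise ValueError(f"step {step} outside fitted range 0..{self.n_steps}")
        return pd.Series(self.mandatory_path[step], index=self.mandatory_ids)

    def selected_features(self, at_step: Optional[int] = None) -> pd.Series:
        """Non-zero optional coefficients at the (selected) step."""
        coefs = self.coefficients(at_step)
        return coefs[coefs != 0.0]


@dataclass
class LayeredCohort:
    """Clinical table, two feature layers with partial sample overlap, outcome.

    ``clinical`` and ``outcome`` cover every sample; each layer matrix
    contains only the rows of samples for which that layer was measured
    (row presence is the availability mask).
    """

    clinical: pd.DataFrame
    layer_a: pd.DataFrame
    layer_b: pd.DataFrame
    outcome: SurvivalOutcome

    def __post_init__(self):
        validate_design_matrix(self.clinical, "clinical")
        validate_design_matrix(self.layer_a, "layer A")
        validate_design_matrix(self.layer_b, "layer B")
        all_ids = set(self.outcome.sample_ids)
        if set(self.clinical.index) != all_ids:
            raise ValueError("clinical covariates must be available for every sample")
        for name, layer in (("A", self.layer_a), ("B", self.layer_b)):
            extra = set(layer.index) - all_ids
            if extra:
                raise ValueError(
                    f"layer {name} has samples without outcome: {sorted(extra)[:5]}"
                )

    @property
    def sample_ids(self) -> np.ndarray:
        return self.outcome.sample_ids

    @property
    def layer_a_ids(self) -> pd.Index:
        return self.layer_a.index

    @property
    def layer_b_ids(self) -> pd.Index:
        return self.layer_b.index

    @property
    def overlap_ids(self) -> pd.Index:
        return self.layer_a.index.intersection(self.layer_b.index)

    @property
    def n_overlap(self) -> int:
        return len(self.overlap_ids)

    def swap_layers(self) -> "LayeredCohort":
        """Return the cohort with the roles of the two layers exchanged."""
        return LayeredCohort(
            clinical=self.clinical,
            layer_a=self.layer_b,
            layer_b=self.layer_a,
            outcome=self.outcome,
        )

    def restrict(self, ids) -> "LayeredCohort":
        """Sub-cohort with only the given samples (layers restricted too)."""
        ids = pd.Index(ids)
        return LayeredCohort(
            clinical=self.clinical.loc[ids],
            layer_a=self.layer_a.loc[self.layer_a.index.intersection(ids)],
            layer_b=self.layer_b.loc[self.layer_b.index.intersection(ids)],
            outcome=self.outcome.subset(ids),
        )


@dataclass
class Signature:
    """Per-sample molecular risk score carried between models.

    ``values`` is the optional-covariate part of a first-level linear
    predictor; ``source`` records per sample whether the value was computed
    from measured first-layer covariates ("observed") or predicted by the
    linking model ("imputed").
    """

    values: pd.Series
    source: pd.Series

    def __post_init__(self):
        if not self.values.index.equals(self.source.index):
            raise ValueError("values and source must share an index")
        bad = set(self.source.unique()) - {"observed", "imputed"}
        if bad:
            raise ValueError(f"invalid source labels: {bad}")

    @property
    def observed_ids(self) -> pd.Index:
        return self.values.index[self.source == "observed"]

    @property
    def imputed_ids(self) -> pd.Index:
        return self.values.index[self.source == "imputed"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"signature": self.values, "source": self.source})
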