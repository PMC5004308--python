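"""Reading and writing the package's delimited-text formats and artifacts.

Covariate matrices travel as TSV/CSV with samples in rows (first column =
sample id, header row = feature ids); the survival endpoint as a two-column
(time, event) table; fitted boosting models as JSON artifacts storing the
coefficient path sparsely (one update per step).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .containers import BoostConfig, BoostFit, LayeredCohort, Signature, SurvivalOutcome

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_outcome",
    "write_outcome",
    "read_cohort",
    "write_cohort",
    "fit_to_json",
    "fit_from_json",
    "write_signature",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path: Union[str, Path]) -> pd.DataFrame:
    """Read a samples x features matrix (first column sample ids)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: Union[str, Path]) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_outcome(path: Union[str, Path]) -> SurvivalOutcome:
    """Read a (time, event) table indexed by sample id."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"outcome file not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"outcome file {path} lacks required column '{col}'")
    return SurvivalOutcome.from_frame(df)


def write_outcome(outcome: SurvivalOutcome, path: Union[str, Path]) -> None:
    path = Path(path)
    outcome.to_frame().to_csv(path, sep=_sep_for(path), index_label="sample_id")


def write_cohort(cohort: LayeredCohort, directory: Union[str, Path]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_matrix(cohort.clinical, directory / "clinical.tsv")
    write_matrix(cohort.layer_a, directory / "layer_a.tsv")
    write_matrix(cohort.layer_b, directory / "layer_b.tsv")
    write_outcome(cohort.outcome, directory / "outcome.tsv")


def read_cohort(
    clinical: Union[str, Path],
    layer_a: Union[str, Path],
    layer_b: Union[str, Path],
    outcome: Union[str, Path],
) -> LayeredCohort:
    return LayeredCohort(
        clinical=read_matrix(clinical),
        layer_a=read_matrix(layer_a),
        layer_b=read_matrix(layer_b),
        outcome=read_outcome(outcome),
    )


def write_signature(signature: Signature, path: Union[str, Path]) -> None:
    signature.to_frame().to_csv(Path(path), sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Fit serialization
# ---------------------------------------------------------------------------

def _path_updates(coef_path: np.ndarray):
    """Sparse encoding of a boosting path: (step, column, new value) for the
    single coefficient that changed at each step."""
    updates = []
    for step in range(1, coef_path.shape[0]):
        diff = np.nonzero(coef_path[step] != coef_path[step - 1])[0]
        if diff.size == 0:
            continue
        if diff.size > 1:
            raise ValueError("coefficient path changes more than one entry per step")
        j = int(diff[0])
        updates.append([step, j, float(coef_path[step, j])])
    return updates


def fit_to_json(fit: BoostFit, path: Union[str, Path]) -> None:
    """Serialize a fit to a JSON artifact reusable across runs."""
    payload = {
        "family": fit.family,
        "feature_ids": list(map(str, fit.feature_ids)),
        "mandatory_ids": list(map(str, fit.mandatory_ids)),
        "n_steps": fit.n_steps,
        "selected_step": int(fit.selected_step),
        "updates": _path_updates(fit.coef_path),
        "mandatory_path": fit.mandatory_path.tolist(),
        "intercept_path": None if fit.intercept_path is None else fit.intercept_path.tolist(),
        "offset": fit.offset.tolist(),
        "sample_ids": list(map(str, fit.sample_ids)),
        "train_criterion_path": fit.train_criterion_path.tolist(),
        "eta_path": fit.eta_path.tolist(),
        "outcome": None
        if fit.outcome is None
        else {
            "time": fit.outcome.time.tolist(),
            "event": fit.outcome.event.tolist(),
            "sample_ids": list(map(str, fit.outcome.sample_ids)),
        },
        "response": None if fit.response is None else fit.response.tolist(),
        "cv_scores": None if fit.cv_scores is None else np.asarray(fit.cv_scores).tolist(),
        "config": None
        if fit.config is None
        else {
            "n_steps_max": fit.config.n_steps_max,
            "penalty": fit.config.penalty,
            "cv_folds": fit.config.cv_folds,
            "seed": fit.config.seed,
        },
    }
    Path(path).write_text(json.dumps(payload))


def fit_from_json(path: Union[str, Path]) -> BoostFit:
    payload = json.loads(Path(path).read_text())
    q = len(payload["feature_ids"])
    n_steps = payload["n_steps"]
    coef_path = np.zeros((n_steps + 1, q))
    updates = {step: (j, v) for step, j, v in payload["updates"]}
    for step in range(1, n_steps + 1):
        coef_path[step] = coef_path[step - 1]
        if step in updates:
            j, v = updates[step]
            coef_path[step, j] = v
    outcome = None
    if payload["outcome"] is not None:
        o = payload["outcome"]
        outcome = SurvivalOutcome(
            time=np.asarray(o["time"]),
            event=np.asarray(o["event"]),
            sample_ids=np.asarray(o["sample_ids"], dtype=object),
        )
    cfg = None
    if payload["config"] is not None:
        cfg = BoostConfig(**payload["config"])
    return BoostFit(
        family=payload["family"],
        feature_ids=payload["feature_ids"],
        mandatory_ids=payload["mandatory_ids"],
        coef_path=coef_path,
        mandatory_path=np.asarray(payload["mandatory_path"]),
        selected_step=payload["selected_step"],
        offset=np.asarray(payload["offset"]),
        sample_ids=np.asarray(payload["sample_ids"], dtype=object),
        train_criterion_path=np.asarray(payload["train_criterion_path"]),
        eta_path=np.asarray(payload["eta_path"]),
        intercept_path=None
        if payload["intercept_path"] is None
        else np.asarray(payload["intercept_path"]),
        outcome=outcome,
        response=None if payload["response"] is None else np.asarray(payload["response"]),
        cv_scores=None if payload["cv_scores"] is None else np.asarray(payload["cv_scores"]),
        config=cfg,
    )
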