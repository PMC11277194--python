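"""Two-stage hybrid forecaster: symbolic regression plus SVR residual
correction.

Stage one evolves a closed-form expression (GEP) regressing the
numeric outbreak level on the 14 normalized climate features — the
level is ordinal, so treating it as numeric keeps the natural ordering
1 < 2 < 3 and lets a one-level miss cost less than a two-level miss.
Stage two fits an RBF support-vector regressor to the training
residuals of stage one, capturing structure the evolved formula missed.
The final numeric prediction is the exact sum of the two stage outputs,
then discretized to a level with a 0.5 threshold (fractional part above
0.5 rounds to the next level; exactly 0.5 rounds up) and clamped to
[1, 3].

Both stages operate in the feature space min-max normalized on the
training rows only; the normalization constants travel with the model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import (
    FEATURE_COLUMNS,
    LEVEL_COLUMN,
    NormalizationSpec,
    apply_normalizer,
    fit_normalizer,
    terminal_map,
)
from .engine import EngineConfig, FitnessContext, evolve
from .ga import grid_search_cv
from .karva import (
    Chromosome,
    GeneArchitecture,
    evaluate_chromosome,
    parse_kexpression,
    to_kexpression,
)
from .svr import SvrModel, SvrParams, fit_svr, predict_svr

__all__ = [
    "DEFAULT_ARCHITECTURE",
    "HybridModel",
    "default_architecture",
    "fit_hybrid",
    "predict_gep",
    "predict_hybrid",
    "to_level",
    "levels_from_predictions",
    "save_model",
    "load_model",
]

MODEL_FORMAT = "gepcast-model"
MODEL_VERSION = 1

LEVEL_MIN, LEVEL_MAX = 1, 3


def default_architecture(terminals: Sequence[str] | None = None) -> GeneArchitecture:
    """Standard genome shape for this model: head length 6, five genes
    linked by ``+``, the ten-function set, terminals x1..x14."""
    from .data import TERMINAL_NAMES

    return GeneArchitecture(
        head_len=6,
        gene_count=5,
        terminal_set=tuple(terminals) if terminals else TERMINAL_NAMES,
    )


DEFAULT_ARCHITECTURE = default_architecture()


@dataclass
class HybridModel:
    """Fitted two-stage model with its training normalization."""

    gep_best: Chromosome
    svr_residual: SvrModel
    normalization: NormalizationSpec
    feature_columns: tuple[str, ...] = FEATURE_COLUMNS
    history: list[float] | None = None

    @property
    def architecture(self) -> GeneArchitecture:
        return self.gep_best.architecture


def _feature_matrix(df: pd.DataFrame, columns: tuple[str, ...]) -> np.ndarray:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    return df[list(columns)].to_numpy(dtype=float)


def fit_hybrid(
    train_df: pd.DataFrame,
    architecture: GeneArchitecture | None = None,
    engine_config: EngineConfig | None = None,
    svr_params: SvrParams | str = "default",
    gamma_grid: Sequence[float] | None = None,
    c_grid: Sequence[float] | None = None,
    feature_columns: tuple[str, ...] = FEATURE_COLUMNS,
) -> HybridModel:
    """Fit both stages on a training table.

    ``svr_params`` may be an explicit :class:`SvrParams`, ``"default"``
    (the tuned C=10, gamma=0.001), or ``"grid"`` to pick (C, gamma) by
    5-fold cross-validation on the stage-one residuals.
    ``feature_columns`` defaults to the 14 same-year climate columns;
    pass ``FEATURE_COLUMNS + LAGGED_RAIN_COLUMNS`` on a table prepared
    with :func:`gepcast.data.add_lagged_rain` to include previous-year
    summer rainfall as explicit predictors.
    """
    from .data import terminal_names

    if len(train_df) < 8:
        raise ValueError("need at least 8 training rows")
    levels = train_df[LEVEL_COLUMN].to_numpy(dtype=float)
    if np.ptp(levels) == 0 and len(set(train_df[LEVEL_COLUMN])) == 1:
        raise ValueError("training levels are constant; nothing to learn")

    architecture = architecture or default_architecture(
        terminal_names(feature_columns)
    )
    engine_config = engine_config or EngineConfig()

    norm = fit_normalizer(train_df, feature_columns)
    norm_df = apply_normalizer(norm, train_df)
    context = FitnessContext(
        targets=levels,
        case_features=terminal_map(norm_df, feature_columns),
        mode="mse",
    )
    result = evolve(architecture, context, engine_config)

    gep_pred = np.asarray(
        evaluate_chromosome(result.best, context.case_features), dtype=float
    )
    residuals = levels - gep_pred

    X = _feature_matrix(norm_df, feature_columns)
    if isinstance(svr_params, SvrParams):
        params = svr_params
    elif svr_params == "grid":
        gs = grid_search_cv(
            X,
            residuals,
            c_grid=c_grid or (0.25, 1.0, 4.0, 10.0, 64.0, 256.0),
            gamma_grid=gamma_grid or (0.001, 0.01, 0.1, 1.0, 4.0),
            n_folds=5,
            seed=engine_config.rng_seed,
        )
        params = SvrParams(cost=gs.best_c, gamma=gs.best_gamma)
    elif svr_params == "default":
        params = SvrParams()
    else:
        raise ValueError(f"svr_params must be SvrParams, 'default' or 'grid'")
    svr_model = fit_svr(X, residuals, params)

    return HybridModel(
        gep_best=result.best,
        svr_residual=svr_model,
        normalization=norm,
        feature_columns=tuple(feature_columns),
        history=result.history,
    )


def predict_gep(model: HybridModel, df: pd.DataFrame) -> np.ndarray:
    """Stage-one (symbolic expression) predictions only."""
    norm_df = apply_normalizer(model.normalization, df)
    fmap = terminal_map(norm_df, model.feature_columns)
    return np.asarray(evaluate_chromosome(model.gep_best, fmap), dtype=float)


def predict_hybrid(model: HybridModel, df: pd.DataFrame) -> np.ndarray:
    """Final numeric prediction: stage-one output plus the SVR residual
    correction, computed in the stored normalized space."""
    norm_df = apply_normalizer(model.normalization, df)
    gep_pred = np.asarray(
        evaluate_chromosome(
            model.gep_best, terminal_map(norm_df, model.feature_columns)
        ),
        dtype=float,
    )
    X = _feature_matrix(norm_df, model.feature_columns)
    return gep_pred + predict_svr(model.svr_residual, X)


def to_level(prediction: float) -> int:
    """Discretize a numeric prediction to an ordinal level.

    Nearest integer with the 0.5 threshold (exactly .5 rounds up),
    clamped to [1, 3].
    """
    if not np.isfinite(prediction):
        raise ValueError(f"non-finite prediction: {prediction}")
    lvl = int(np.floor(prediction + 0.5))
    return max(LEVEL_MIN, min(LEVEL_MAX, lvl))


def levels_from_predictions(predictions: Sequence[float]) -> np.ndarray:
    return np.array([to_level(p) for p in np.asarray(predictions, dtype=float)])


def save_model(model: HybridModel, path: str | Path) -> None:
    """Serialize to a versioned plain-text (JSON) bundle."""
    arch = model.architecture
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "architecture": {
            "head_len": arch.head_len,
            "gene_count": arch.gene_count,
            "terminal_set": list(arch.terminal_set),
            "function_set": dict(arch.function_set),
            "link_op": arch.link_op,
        },
        "kexpression": to_kexpression(model.gep_best),
        "svr": {
            "params": asdict(model.svr_residual.params),
            "support_points": model.svr_residual.support_points.tolist(),
            "support_coefficients": model.svr_residual.support_coefficients.tolist(),
            "bias": model.svr_residual.bias,
        },
        "normalization": {
            "mins": model.normalization.mins,
            "maxs": model.normalization.maxs,
        },
        "feature_columns": list(model.feature_columns),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_model(path: str | Path) -> HybridModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != MODEL_FORMAT:
        raise ValueError(f"not a {MODEL_FORMAT} file: {path}")
    if payload.get("version") != MODEL_VERSION:
        raise ValueError(f"unsupported model version {payload.get('version')}")
    a = payload["architecture"]
    arch = GeneArchitecture(
        head_len=a["head_len"],
        gene_count=a["gene_count"],
        terminal_set=tuple(a["terminal_set"]),
        function_set=dict(a["function_set"]),
        link_op=a["link_op"],
    )
    chromosome = parse_kexpression(payload["kexpression"], arch)
    s = payload["svr"]
    svr_model = SvrModel(
        support_points=np.asarray(s["support_points"], dtype=float),
        support_coefficients=np.asarray(s["support_coefficients"], dtype=float),
        bias=float(s["bias"]),
        params=SvrParams(**s["params"]),
    )
    norm = NormalizationSpec(
        mins={k: float(v) for k, v in payload["normalization"]["mins"].items()},
        maxs={k: float(v) for k, v in payload["normalization"]["maxs"].items()},
    )
    return HybridModel(
        gep_best=chromosome,
        svr_residual=svr_model,
        normalization=norm,
        feature_columns=tuple(payload["feature_columns"]),
    )
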