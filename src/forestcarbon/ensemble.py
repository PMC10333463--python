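"""Multi-model random-forest ensemble (MMRFE) of process-model carbon fields.

Process-based land models disagree widely on absolute carbon density, but
each carries real spatial signal.  Rather than averaging them (the MMEM
baseline), a random-forest regressor is trained to map the K model values
at a plot's pixel — plus fused NDVI in the historical era — onto the plot's
observed density.  Four independent model objects exist in a full analysis:
{cVeg, cSoil} x {historical (with NDVI), future (no NDVI)}.

Training uses a 75% train / 25% holdout split (optionally a bootstrap
resample of the same size) with a small cross-validated hyperparameter
search; holdout correlation and RMSE are recorded on the fitted object.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV

from .grids import GridCube, ModelStack

__all__ = [
    "TrainingTable",
    "MMRFEConfig",
    "TrainedEnsemble",
    "extract_training_table",
    "train_mmrfe",
    "predict_grid",
    "mmem_mean",
    "total_carbon",
]

logger = logging.getLogger(__name__)

MIN_TRAINING_ROWS = 10
NDVI_FEATURE = "ndvi"


@dataclass
class TrainingTable:
    """Plot-level features and target for one regression problem."""

    frame: pd.DataFrame  # plot_id, row, col, features..., target
    feature_names: list[str]
    target_name: str
    n_dropped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in self.feature_names + [self.target_name] if c not in self.frame]
        if missing:
            raise ValueError(f"table lacks columns: {missing}")
        if self.frame[self.feature_names + [self.target_name]].isna().any().any():
            raise ValueError("retained rows must have no missing features/target")

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.frame[self.target_name].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)


def extract_training_table(
    plots: pd.DataFrame,
    stacks: ModelStack,
    reference_year: int,
    target: str,
    ndvi: np.ndarray | None = None,
) -> TrainingTable:
    """Pull per-plot features from the model grids at the reference year.

    Each plot contributes the value of its containing pixel in every model
    field (and the NDVI grid when given).  Rows with any missing feature or
    target — plots outside the extent or on masked pixels — are dropped and
    counted, not fatal.
    """
    geom = stacks.geometry
    rows, cols = geom.pixel_of(plots["lon"].to_numpy(), plots["lat"].to_numpy())
    inside = rows >= 0
    n_outside = int(np.count_nonzero(~inside))
    if n_outside:
        logger.warning("%d plots fall outside the grid extent; dropped", n_outside)

    grids = stacks.grids_at(reference_year)
    feature_names = list(stacks.names)
    data: dict[str, np.ndarray] = {
        "plot_id": plots["plot_id"].to_numpy(),
        "row": rows,
        "col": cols,
    }
    r_safe = np.where(inside, rows, 0)
    c_safe = np.where(inside, cols, 0)
    for name in feature_names:
        data[name] = np.where(inside, grids[name][r_safe, c_safe], np.nan)
    if ndvi is not None:
        if ndvi.shape != geom.shape:
            raise ValueError("ndvi grid must share the stack geometry")
        data[NDVI_FEATURE] = np.where(inside, ndvi[r_safe, c_safe], np.nan)
        feature_names = [NDVI_FEATURE] + feature_names
    data[target] = plots[target].to_numpy()

    frame = pd.DataFrame(data)
    keep = frame[feature_names + [target]].notna().all(axis=1) & inside
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("extract_training_table: %d rows dropped (missing features)", n_dropped)
    return TrainingTable(
        frame=frame.loc[keep].reset_index(drop=True),
        feature_names=feature_names,
        target_name=target,
        n_dropped=n_dropped,
    )


@dataclass(frozen=True)
class MMRFEConfig:
    """Training configuration.

    ``train_fraction`` rows train, the rest score the fit; with
    ``bootstrap_split=True`` the training set is instead a bootstrap
    resample of that size and out-of-sample rows form the holdout.  The
    hyperparameter grid is deliberately small; forests are insensitive to
    fine tuning at plot-scale sample sizes.
    """

    seed: int = 0
    train_fraction: float = 0.75
    bootstrap_split: bool = False
    n_estimators: int = 200
    param_grid: tuple[tuple[str, tuple], ...] = (
        ("max_features", (0.33, 1.0)),
        ("min_samples_leaf", (1, 4)),
    )
    cv_folds: int = 3

    def grid_dict(self) -> dict[str, list]:
        return {k: list(v) for k, v in self.param_grid}


@dataclass
class TrainedEnsemble:
    """A fitted MMRFE regressor plus everything needed to apply it safely."""

    regressor: RandomForestRegressor
    feature_names: list[str]
    target_name: str
    config: MMRFEConfig
    best_params: dict[str, Any]
    holdout_r: float
    holdout_rmse: float
    train_r2: float
    n_train: int
    n_holdout: int

    @property
    def uses_ndvi(self) -> bool:
        return NDVI_FEATURE in self.feature_names


def train_mmrfe(table: TrainingTable, config: MMRFEConfig = MMRFEConfig()) -> TrainedEnsemble:
    """Fit the random-forest ensemble with a cross-validated grid search.

    Raises on fewer than 10 usable rows or a constant target (the forest
    would be degenerate and the holdout correlation undefined).
    """
    if len(table) < MIN_TRAINING_ROWS:
        raise ValueError(f"need >= {MIN_TRAINING_ROWS} rows, got {len(table)}")
    y = table.y
    if np.ptp(y) == 0:
        raise ValueError("constant target; nothing to learn")

    rng = np.random.default_rng(config.seed)
    n = len(table)
    n_train = max(int(round(config.train_fraction * n)), MIN_TRAINING_ROWS // 2)
    perm = rng.permutation(n)
    if config.bootstrap_split:
        train_idx = rng.choice(n, size=n_train, replace=True)
        hold_idx = np.setdiff1d(np.arange(n), np.unique(train_idx))
    else:
        train_idx, hold_idx = perm[:n_train], perm[n_train:]
    if hold_idx.size < 2:
        raise ValueError("holdout too small to score the fit")

    X, Xh = table.X[train_idx], table.X[hold_idx]
    yt, yh = y[train_idx], y[hold_idx]

    base = RandomForestRegressor(
        n_estimators=config.n_estimators, random_state=int(config.seed) % (2**31)
    )
    grid = config.grid_dict()
    if grid:
        search = GridSearchCV(base, grid, cv=config.cv_folds, n_jobs=1)
        search.fit(X, yt)
        reg, best = search.best_estimator_, dict(search.best_params_)
    else:
        reg, best = base.fit(X, yt), {}

    pred = reg.predict(Xh)
    if np.ptp(pred) == 0 or np.ptp(yh) == 0:
        r = 0.0  # degenerate holdout; correlation undefined, report no skill
    else:
        r = float(np.corrcoef(pred, yh)[0, 1])
    rmse = float(np.sqrt(np.mean((pred - yh) ** 2)))
    return TrainedEnsemble(
        regressor=reg,
        feature_names=list(table.feature_names),
        target_name=table.target_name,
        config=config,
        best_params=best,
        holdout_r=r,
        holdout_rmse=rmse,
        train_r2=float(reg.score(X, yt)),
        n_train=int(train_idx.size),
        n_holdout=int(hold_idx.size),
    )


def predict_grid(
    model: TrainedEnsemble,
    stacks: ModelStack,
    year: int,
    ndvi: np.ndarray | None = None,
) -> np.ndarray:
    """Apply a trained ensemble to one year's model grids.

    Features are assembled by *name* in the training order, so permuting
    the stack changes nothing.  A missing or extra feature is a hard error
    — silently predicting from misaligned columns would corrupt every
    downstream table.  Pixels with any missing feature come out masked;
    negative predictions clip to zero (carbon density is nonnegative).
    """
    grids = stacks.grids_at(year)
    if ndvi is not None:
        if ndvi.shape != stacks.geometry.shape:
            raise ValueError("ndvi grid must share the stack geometry")
        grids = {NDVI_FEATURE: ndvi, **grids}
    missing = [f for f in model.feature_names if f not in grids]
    extra = sorted(set(grids) - set(model.feature_names))
    if missing or extra:
        raise ValueError(
            f"feature mismatch: model needs {model.feature_names}, "
            f"missing {missing}, unexpected {extra}"
        )
    shape = stacks.geometry.shape
    cols = [grids[f].ravel() for f in model.feature_names]
    X = np.column_stack(cols)
    valid = ~np.isnan(X).any(axis=1)
    out = np.full(X.shape[0], np.nan)
    if valid.any():
        out[valid] = np.clip(model.regressor.predict(X[valid]), 0.0, None)
    return out.reshape(shape)


def mmem_mean(stacks: ModelStack) -> GridCube:
    """Multi-model ensemble mean: per-pixel, per-year arithmetic average of
    the raw model fields — the baseline the learned ensemble must beat."""
    if len(stacks) < 1:
        raise ValueError("empty stack")
    data = np.mean(np.stack([c.data for c in stacks.cubes]), axis=0)
    first = stacks.cubes[0]
    return GridCube(first.years, data, first.geometry, units=first.units, name="mmem")


def total_carbon(cveg: np.ndarray, csoil: np.ndarray) -> np.ndarray:
    """Ecosystem carbon density: cVeg + cSoil, masked where either is."""
    if cveg.shape != csoil.shape:
        raise ValueError(f"geometry mismatch: {cveg.shape} vs {csoil.shape}")
    return cveg + csoil
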