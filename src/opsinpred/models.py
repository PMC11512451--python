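"""Cross-validated regression of lambda_max on one-hot sequence features.

The harness trains a pluggable suite of regressors on encoded alignments,
scores them with five metrics (R², MAE, MAPE, MSE, RMSE) under seeded k-fold
cross-validation, ranks them by mean R², and reports per-position relative
importances from the top models.

The default registry covers the families that dominate this kind of
sequence-to-function problem: ridge-type linear models (plain and Bayesian),
random forests, gradient-boosted trees (three implementations), and boosted
stumps.  Each entry is constructed fresh per call with fixed, documented
defaults; all randomness flows from one explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import BayesianRidge, Ridge
from sklearn.model_selection import KFold

from .encode import GAP, Alignment, EncodedMatrix, one_hot

__all__ = [
    "MetricSet",
    "CVReport",
    "FittedModel",
    "compute_metrics",
    "crossvalidate",
    "fit_model",
    "predict_new",
    "importance_report",
    "make_estimator",
    "REGISTRY",
]


@dataclass(frozen=True)
class MetricSet:
    """The five evaluation metrics; wavelengths in nm throughout."""

    r2: float
    mae: float
    mape: float  # percent
    mse: float
    rmse: float

    def as_dict(self) -> dict:
        return {"r2": self.r2, "mae": self.mae, "mape": self.mape, "mse": self.mse, "rmse": self.rmse}


def compute_metrics(y, yhat) -> MetricSet:
    """Evaluate predictions: R², MAE, MAPE (%), MSE, RMSE.

    R² is 1 − SSres/SStot and is undefined (NaN, with a warning) for fewer
    than two observations or a zero-variance truth vector; the error metrics
    are always returned.  MAPE divides by the true values, which is safe for
    wavelengths (lambda_max >= 350 nm in practice).
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    err = y - yhat
    mae = float(np.mean(np.abs(err)))
    mape = float(100.0 * np.mean(np.abs(err) / y))
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    sstot = float(np.sum((y - y.mean()) ** 2))
    if y.size < 2 or sstot == 0.0:
        warnings.warn("R^2 undefined (need >=2 observations with variance)", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = float(1.0 - np.sum(err**2) / sstot)
    return MetricSet(r2=r2, mae=mae, mape=mape, mse=mse, rmse=rmse)


# ---------------------------------------------------------------------------
# estimator registry

def _make_lgbm(seed: int):
    from lightgbm import LGBMRegressor

    return LGBMRegressor(
        n_estimators=100, random_state=seed, verbose=-1, min_child_samples=5
    )


def _make_xgb(seed: int):
    from xgboost import XGBRegressor

    return XGBRegressor(n_estimators=100, random_state=seed, verbosity=0, n_jobs=1)


#: name -> (constructor taking a seed, importance kind)
REGISTRY = {
    "ridge": (lambda seed: Ridge(alpha=1.0), "standardized |coef|"),
    "bayesian_ridge": (lambda seed: BayesianRidge(), "standardized |coef|"),
    "random_forest": (
        lambda seed: RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1),
        "impurity (Gini) importance",
    ),
    "gbr": (
        lambda seed: GradientBoostingRegressor(random_state=seed),
        "impurity (Gini) importance",
    ),
    "adaboost": (
        lambda seed: AdaBoostRegressor(random_state=seed),
        "impurity (Gini) importance",
    ),
    "lgbm": (_make_lgbm, "split count"),
    "xgb": (_make_xgb, "gain"),
}

DEFAULT_ESTIMATORS = tuple(REGISTRY)


def make_estimator(name: str, seed: int = 0):
    try:
        ctor, _ = REGISTRY[name]
    except KeyError:
        raise ValueError(f"unknown estimator {name!r}; known: {sorted(REGISTRY)}") from None
    return ctor(seed)


def _as_matrix(X) -> pd.DataFrame:
    if isinstance(X, EncodedMatrix):
        return X.X
    return pd.DataFrame(X)


@dataclass
class CVReport:
    """Mean cross-validation metrics per estimator, ranked by R²."""

    metrics: pd.DataFrame  # index = estimator name; columns r2, mae, mape, mse, rmse
    ranking: list[str]
    k: int
    seed: int

    @property
    def best(self) -> str:
        return self.ranking[0]

    def to_frame(self) -> pd.DataFrame:
        out = self.metrics.loc[self.ranking].copy()
        out.insert(0, "rank", range(1, len(out) + 1))
        return out


def crossvalidate(X, y, estimators=None, k: int = 10, seed: int = 0) -> CVReport:
    """k-fold cross-validation of the estimator suite on identical folds.

    Folds are a seeded random partition shared by every estimator so the
    ranking compares like with like.  Ranking is by mean R², ties broken by
    lower MAE then name.
    """
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(Xm)
    if y.shape[0] != n:
        raise ValueError("X and y differ in length")
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n samples ({k=} vs {n=})")
    names = list(estimators) if estimators is not None else list(DEFAULT_ESTIMATORS)

    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(Xm))
    Xv = Xm.to_numpy(dtype=float)
    rows = {}
    for name in names:
        per_fold = []
        for train_idx, val_idx in folds:
            est = make_estimator(name, seed)
            est.fit(Xv[train_idx], y[train_idx])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # tiny folds may have zero variance
                per_fold.append(compute_metrics(y[val_idx], est.predict(Xv[val_idx])).as_dict())
        rows[name] = pd.DataFrame(per_fold).mean().to_dict()
    metrics = pd.DataFrame.from_dict(rows, orient="index")[["r2", "mae", "mape", "mse", "rmse"]]
    ranking = sorted(names, key=lambda m: (-metrics.at[m, "r2"], metrics.at[m, "mae"], m))
    return CVReport(metrics=metrics, ranking=ranking, k=k, seed=seed)


@dataclass
class FittedModel:
    """A fitted estimator bundled with the training vocabulary it needs."""

    name: str
    estimator: object
    vocabulary: dict[int, tuple[str, ...]]
    feature_labels: list[str]
    feature_std: np.ndarray  # per-feature std of the training matrix

    def predict_matrix(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_labels:
            raise ValueError("feature labels do not match the training vocabulary")
        return np.asarray(self.estimator.predict(X.to_numpy(dtype=float)), dtype=float)


class _MeanRegressor:
    """Fallback when encoding yields zero features (fully invariant training
    alignment): predicts the training mean."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(len(X), self.mean_)


def fit_model(name: str, X: EncodedMatrix, y, seed: int = 0) -> FittedModel:
    """Fit one registry estimator on a full encoded matrix."""
    Xm = _as_matrix(X)
    if Xm.shape[1] == 0:
        make_estimator(name, seed)  # still validate the estimator name
        warnings.warn("no informative features; falling back to mean prediction", stacklevel=2)
        est = _MeanRegressor()
    else:
        est = make_estimator(name, seed)
    est.fit(Xm.to_numpy(dtype=float), np.asarray(y, dtype=float))
    vocab = X.vocabulary if isinstance(X, EncodedMatrix) else {}
    return FittedModel(
        name=name,
        estimator=est,
        vocabulary=dict(vocab),
        feature_labels=list(Xm.columns),
        feature_std=Xm.to_numpy(dtype=float).std(axis=0),
    )


def fit_on_records(records, estimator: str = "gbr", seed: int = 0):
    """Encode equal-length dataset records and fit one estimator on their
    lambda_max values.  Returns ``(FittedModel, training Alignment)``."""
    from .encode import alignment_from_records

    al = alignment_from_records(records)
    enc = one_hot(al)
    y = [r.lambda_max for r in records]
    return fit_model(estimator, enc, y, seed=seed), al


# ---------------------------------------------------------------------------
# prediction for new (possibly unaligned) sequences

#: global pairwise-alignment scores used to project new sequences onto the
#: training columns (match/mismatch with affine gaps)
PAIRWISE_SCORES = {"match": 2.0, "mismatch": -1.0, "open": -10.0, "extend": -0.5}


def _project_onto_columns(seq: str, al: Alignment, reference_row: str) -> str:
    """Globally align ``seq`` to the training reference and place its residues
    into training-alignment columns; unmatched columns become gaps."""
    from Bio import Align

    ref_aligned = al.row(reference_row)
    ref_cols = [j for j, c in enumerate(ref_aligned) if c != GAP]
    ref_seq = "".join(ref_aligned[j] for j in ref_cols)

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = PAIRWISE_SCORES["match"]
    aligner.mismatch_score = PAIRWISE_SCORES["mismatch"]
    aligner.open_gap_score = PAIRWISE_SCORES["open"]
    aligner.extend_gap_score = PAIRWISE_SCORES["extend"]
    best = aligner.align(ref_seq, seq)[0]

    row = [GAP] * al.n_columns
    for (r_start, r_end), (s_start, s_end) in zip(*best.aligned):
        for offset in range(r_end - r_start):
            row[ref_cols[r_start + offset]] = seq[s_start + offset]
    return "".join(row)


def predict_new(
    model: FittedModel,
    seqs: list[str] | dict[str, str],
    al: Alignment,
    mode: str = "prealigned",
    reference_row: str | None = None,
) -> np.ndarray:
    """Predict lambda_max for new sequences.

    ``prealigned`` expects sequences already in training-column space (same
    length as the training alignment).  ``map_to_reference_pairwise`` takes
    ungapped sequences and places them onto training columns by global
    pairwise alignment to the training reference row.  Either way the
    sequences are then encoded with the *training* vocabulary, so residues
    unseen at a column in training become all-zero blocks — predictions never
    fail on novel residues.
    """
    if isinstance(seqs, dict):
        ids, seq_list = list(seqs), list(seqs.values())
    else:
        seq_list = list(seqs)
        ids = [f"query_{i}" for i in range(len(seq_list))]
    if mode == "prealigned":
        for s in seq_list:
            if len(s) != al.n_columns:
                raise ValueError(
                    f"prealigned sequence length {len(s)} != alignment width {al.n_columns}"
                )
        rows = seq_list
    elif mode == "map_to_reference_pairwise":
        if reference_row is None:
            raise ValueError("pairwise mode needs reference_row")
        rows = [_project_onto_columns(s, al, reference_row) for s in seq_list]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    query = Alignment(ids=ids, rows=rows)
    enc = one_hot(query, vocabulary=model.vocabulary)
    return model.predict_matrix(enc.X)


# ---------------------------------------------------------------------------
# position importance

def _raw_importances(fm: FittedModel) -> np.ndarray | None:
    est = fm.estimator
    if hasattr(est, "feature_importances_"):
        return np.asarray(est.feature_importances_, dtype=float)
    if hasattr(est, "coef_"):
        return np.abs(np.asarray(est.coef_, dtype=float).ravel()) * fm.feature_std
    return None


def importance_report(
    fitted: list[FittedModel],
    pmap=None,
    n: int = 3,
) -> pd.DataFrame:
    """Per-position relative importances from the top ``n`` fitted models.

    Feature importances are summed within each column's indicator block and
    scaled per model so the maximum is 1.0 (a model with all-zero importances
    stays all-zero); the ``mean_relative_importance`` column averages the
    scaled scores of the models used.  When a PositionMap is given, each row
    also carries the reference position and TMD label.
    """
    used: list[tuple[str, dict[int, float]]] = []
    columns: set[int] = set()
    for fm in fitted[:n]:
        raw = _raw_importances(fm)
        if raw is None:
            warnings.warn(f"{fm.name}: no importance capability; skipped", stacklevel=2)
            continue
        per_col: dict[int, float] = {}
        for lab, v in zip(fm.feature_labels, raw):
            col = int(lab.split(":", 1)[0]) - 1
            per_col[col] = per_col.get(col, 0.0) + float(v)
        peak = max(per_col.values(), default=0.0)
        if peak > 0:
            per_col = {c: v / peak for c, v in per_col.items()}
        used.append((fm.name, per_col))
        columns.update(per_col)
    if not used:
        raise ValueError("no fitted model exposes importances")

    cols = sorted(columns)
    data = {"column": [c + 1 for c in cols]}
    if pmap is not None:
        data["ref_pos"] = [pmap.reference_position(c) for c in cols]
        data["tmd"] = [pmap.tmd_labels[c] for c in cols]
    vocab = fitted[0].vocabulary
    data["residues"] = ["".join(vocab.get(c, ())) for c in cols]
    for name, per_col in used:
        data[f"imp_{name}"] = [per_col.get(c, 0.0) for c in cols]
    df = pd.DataFrame(data)
    imp_cols = [f"imp_{name}" for name, _ in used]
    df["mean_relative_importance"] = df[imp_cols].mean(axis=1)
    df.attrs["importance_metrics"] = {
        name: REGISTRY[name][1] if name in REGISTRY else "unknown" for name, _ in used
    }
    return df.sort_values("mean_relative_importance", ascending=False).reset_index(drop=True)
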