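"""Dataset-level protocols: exhaustive hold-out prediction, learning curves
with AIC model selection, residual breakdowns, and the conservation-vs-
importance regression.

The hold-out protocol mirrors how predictive accuracy is measured without a
fixed test set: records are shuffled once, partitioned into groups, and each
group is predicted by a model trained on everything outside it, so every
record is predicted exactly once and never by a model that saw it.

Learning curves relate training-set size to cross-validated R²; their shape is
summarised by least-squares fits of six candidate nonlinear models compared by
AIC (for least squares, ``AIC = n·ln(RSS/n) + 2k`` with k the parameter
count).  Performance typically plateaus, which the reciprocal model
``y = a + b/x`` captures with a negative b.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .encode import alignment_from_records, one_hot
from .models import compute_metrics, crossvalidate, fit_model
from .mutagen import MutationError, parse_mutation_notation
from .seqdata import Dataset, subset

#: residual magnitude (nm) above which a prediction counts as an outlier
OUTLIER_NM = 10.0


def record_tag(record) -> str:
    """wt | single-mutant | multi-mutant | chimera, from type and notation."""
    if record.record_type == "wt":
        return "wt"
    if record.record_type == "chimera":
        return "chimera"
    try:
        n_edits = len(parse_mutation_notation(record.mutation_notation).edits)
    except MutationError:
        n_edits = 2  # unparseable multi-edit notation: bucket conservatively
    return "single-mutant" if n_edits == 1 else "multi-mutant"


@dataclass
class HoldoutResult:
    """One prediction per target record, with residuals and outlier flags."""

    table: pd.DataFrame  # accession, known, predicted, residual, tag, outlier
    group_size: int
    estimator: str
    seed: int

    def metrics(self):
        return compute_metrics(self.table["known"], self.table["predicted"])


def iterative_holdout(
    ds: Dataset,
    group_size: int,
    estimator: str = "gbr",
    seed: int = 0,
    target_filter=None,
) -> HoldoutResult:
    """Predict every target record exactly once by group-wise hold-out.

    Targets (optionally a subset, e.g. mutants only) are shuffled with the
    seed and split into groups of ``group_size`` (the last group may be
    smaller).  For each group a model is trained on *all* other records —
    withheld records take no part in training — and the group is predicted.
    """
    targets = subset(ds, target_filter).records if target_filter is not None else list(ds.records)
    if not 1 <= group_size <= len(targets):
        raise ValueError(f"group_size must be in [1, {len(targets)}]")
    al = alignment_from_records(ds.records)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(targets))
    rows = []
    for start in range(0, len(targets), group_size):
        group = [targets[i] for i in order[start : start + group_size]]
        held = {r.accession for r in group}
        train = [r for r in ds.records if r.accession not in held]
        if not train:
            raise ValueError(
                "a hold-out group covers the whole dataset; nothing to train on "
                "(use a target_filter or a smaller group_size)"
            )
        train_al = al.subset_rows([r.accession for r in train])
        enc = one_hot(train_al)
        fm = fit_model(estimator, enc, [r.lambda_max for r in train], seed=seed)
        group_al = al.subset_rows([r.accession for r in group])
        preds = fm.predict_matrix(one_hot(group_al, vocabulary=fm.vocabulary).X)
        for rec, pred in zip(group, preds):
            resid = pred - rec.lambda_max
            rows.append(
                {
                    "accession": rec.accession,
                    "known": rec.lambda_max,
                    "predicted": float(pred),
                    "residual": float(resid),
                    "tag": record_tag(rec),
                    "outlier": abs(resid) > OUTLIER_NM,
                }
            )
    return HoldoutResult(
        table=pd.DataFrame(rows), group_size=group_size, estimator=estimator, seed=seed
    )


def residual_breakdown(hr: HoldoutResult) -> pd.DataFrame:
    """Per record-type summary: count, median residual, MAE, outlier count.

    The outlier rule is strict: a residual of exactly 10 nm is not an outlier.
    """
    out = []
    for tag, grp in hr.table.groupby("tag"):
        out.append(
            {
                "tag": tag,
                "count": len(grp),
                "median_residual": float(grp["residual"].median()),
                "mae": float(grp["residual"].abs().mean()),
                "outliers": int((grp["residual"].abs() > OUTLIER_NM).sum()),
            }
        )
    return pd.DataFrame(out)


def learning_curve(
    ds: Dataset,
    step: int,
    reps: int = 3,
    estimator: str = "gbr",
    seed: int = 0,
    k: int = 5,
) -> pd.DataFrame:
    """Cross-validated R² as a function of training-set size.

    Each repetition draws a fresh seeded permutation of the records; training
    sets grow by ``step`` records at a time (the full dataset is always the
    last point) and each size is scored by k-fold CV.
    """
    if step < 2:
        raise ValueError("step must be >= 2")
    n = len(ds)
    if n < step:
        raise ValueError(f"dataset ({n} records) smaller than one step ({step})")
    al = alignment_from_records(ds.records)
    sizes = list(range(step, n + 1, step))
    if sizes[-1] != n:
        sizes.append(n)
    rows = []
    rng = np.random.default_rng(seed)
    for rep in range(reps):
        order = rng.permutation(n)
        for size in sizes:
            chosen = [ds.records[i] for i in order[:size]]
            sub_al = al.subset_rows([r.accession for r in chosen])
            enc = one_hot(sub_al)
            rep_seed = int(rng.integers(2**31))
            report = crossvalidate(
                enc,
                [r.lambda_max for r in chosen],
                estimators=[estimator],
                k=min(k, size),
                seed=rep_seed,
            )
            rows.append({"n_train": size, "r2": report.metrics.at[estimator, "r2"], "rep": rep})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nonlinear curve fitting with AIC selection

@dataclass
class CurveFit:
    name: str
    params: dict
    rss: float
    aic: float
    n_params: int
    ok: bool = True
    message: str = ""


def aic_least_squares(rss: float, n: int, k: int) -> float:
    """AIC for a least-squares fit, constant terms dropped: n·ln(RSS/n) + 2k."""
    rss = max(float(rss), 1e-300)  # guard log(0) on exact fits
    return n * float(np.log(rss / n)) + 2 * k


def _fit_linear(x, y, design_cols):
    A = np.column_stack(design_cols)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(np.sum((y - A @ coef) ** 2))
    return coef, rss


def _fit_nonlinear(f, x, y, starts):
    best = None
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(f, x, y, p0=p0, maxfev=20000)
            rss = float(np.sum((y - f(x, *popt)) ** 2))
        except (RuntimeError, TypeError, ValueError):
            continue
        if np.isfinite(rss) and (best is None or rss < best[1]):
            best = (popt, rss)
    if best is None:
        raise RuntimeError("no start converged")
    return best


def _candidates():
    def reciprocal(x, y):
        coef, rss = _fit_linear(x, y, [np.ones_like(x), 1.0 / x])
        return {"a": coef[0], "b": coef[1]}, rss, 2

    def logarithmic(x, y):
        coef, rss = _fit_linear(x, y, [np.ones_like(x), np.log(x)])
        return {"a": coef[0], "b": coef[1]}, rss, 2

    def quadratic(x, y):
        coef, rss = _fit_linear(x, y, [np.ones_like(x), x, x**2])
        return {"a": coef[0], "b": coef[1], "c": coef[2]}, rss, 3

    def power(x, y):
        f = lambda x, a, b: a * np.power(x, b)
        starts = [(float(np.mean(y)), 0.0)]
        if np.all(y > 0):
            b0, loga = np.polyfit(np.log(x), np.log(y), 1)
            starts.insert(0, (float(np.exp(loga)), float(b0)))
        (a, b), rss = _fit_nonlinear(f, x, y, starts)
        return {"a": a, "b": b}, rss, 2

    def saturating(x, y):
        f = lambda x, a, b: a * x / (b + x)
        ymax = float(np.max(np.abs(y))) or 1.0
        starts = [(ymax, xm) for xm in (np.median(x), np.max(x), np.min(x) + 1e-6)]
        (a, b), rss = _fit_nonlinear(f, x, y, starts)
        return {"a": a, "b": b}, rss, 2

    def exp_rise(x, y):
        f = lambda x, a, b, c: a - b * np.exp(-c * x)
        a0 = float(np.max(y))
        b0 = float(np.max(y) - np.min(y)) or 1.0
        starts = [(a0, b0, c0) for c0 in (1e-3, 1e-2, 1e-1, 1.0)]
        (a, b, c), rss = _fit_nonlinear(f, x, y, starts)
        return {"a": a, "b": b, "c": c}, rss, 3

    return {
        "reciprocal": reciprocal,
        "exponential_rise": exp_rise,
        "logarithmic": logarithmic,
        "power": power,
        "saturating": saturating,
        "quadratic": quadratic,
    }


def fit_curves(points, candidates=None) -> list[CurveFit]:
    """Least-squares fit of candidate trend models, sorted ascending by AIC.

    ``points`` is an iterable of (x, y) pairs or a DataFrame with x in the
    first column and y in the second.  A model that fails to converge is
    returned flagged (``ok=False``) and ranked last.
    """
    if isinstance(points, pd.DataFrame):
        x = points.iloc[:, 0].to_numpy(dtype=float)
        y = points.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(points), dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if np.any(x <= 0):
        raise ValueError("x values must be positive (training-set sizes)")
    funcs = _candidates()
    if candidates is not None:
        funcs = {name: funcs[name] for name in candidates}
    if len(x) < min(2 if name != "quadratic" and name != "exponential_rise" else 3
                    for name in funcs):
        raise ValueError(f"too few points ({len(x)}) for every candidate model")
    n = len(x)
    # fits that are exact to numerical precision tie in RSS, so AIC ranks them
    # by parameter count (the tie-break below)
    rss_floor = n * (1e-9 * max(1.0, float(np.abs(y).mean()))) ** 2
    fits = []
    for name, fitter in funcs.items():
        try:
            params, rss, k = fitter(x, y)
        except Exception as exc:  # per-model failure: flag, keep others
            fits.append(
                CurveFit(name=name, params={}, rss=float("inf"), aic=float("inf"),
                         n_params=0, ok=False, message=str(exc))
            )
            continue
        rss = max(rss, rss_floor)
        fits.append(
            CurveFit(name=name, params={k_: float(v) for k_, v in params.items()},
                     rss=rss, aic=aic_least_squares(rss, n, k), n_params=k)
        )
    fits.sort(key=lambda f: (not f.ok, f.aic, f.n_params, f.name))
    return fits


def entropy_importance_regression(profiles, imp: pd.DataFrame) -> float:
    """R² of mean relative importance regressed on relative Shannon entropy.

    Joins column profiles and the importance report on alignment column; a
    value near zero says the model's important positions are not simply the
    variable ones.
    """
    prof = pd.DataFrame(
        {
            "column": [p.column + 1 for p in profiles if not p.all_gap],
            "relative_entropy": [p.relative_entropy for p in profiles if not p.all_gap],
        }
    )
    joined = prof.merge(imp[["column", "mean_relative_importance"]], on="column")
    if len(joined) < 3:
        raise ValueError(f"need >=3 joined columns, got {len(joined)}")
    fit = linregress(joined["relative_entropy"], joined["mean_relative_importance"])
    return float(fit.rvalue**2)
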