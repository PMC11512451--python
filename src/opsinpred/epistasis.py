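"""Intragenic epistasis: additive expectations, case discovery, the
leave-epistatic-out experiment, and paired nonparametric testing.

A multimutant is *decomposable* when its wild-type background and every
single-component mutant have measured phenotypes in the same dataset.  For
such a case the epistasis-free additive mutation value (EAMV) is the
lambda_max expected if single-mutation shifts added up:

    EAMV = wt + sum_i (single_i − wt)

A multimutant deviating from its EAMV by more than 1 nm (strict) is called
epistatic.  The leave-epistatic-out experiment removes all epistatic
multimutants from training (keeping their singles), and compares the model's
predictions of them against a wild-type-only model and against the EAMV
baseline, pairing squared errors per multimutant for a Wilcoxon signed-rank
test with Bonferroni correction.

The Wilcoxon test here is exact for small samples: the two-sided p-value is
computed over all 2^n equally likely sign assignments (via a rank-sum
distribution identical to full enumeration), with midranks for ties; larger
samples use the normal approximation with tie-corrected variance and
continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .encode import alignment_from_records, one_hot
from .models import MetricSet, compute_metrics, fit_model
from .mutagen import MutationError, parse_mutation_notation
from .seqdata import Dataset, OpsinRecord, subset

#: deviation (nm) beyond which a multimutant counts as epistatic (strict >)
EPISTASIS_THRESHOLD_NM = 1.0


def eamv(wt_lambda: float, single_lambdas) -> float:
    """Additive expectation: wild type plus the sum of single-mutant shifts."""
    return float(wt_lambda + sum(s - wt_lambda for s in single_lambdas))


def classify_epistatic(actual: float, expected: float, threshold: float = EPISTASIS_THRESHOLD_NM) -> bool:
    """True iff |actual − expected| exceeds the threshold (strict)."""
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    return abs(actual - expected) > threshold


@dataclass(frozen=True)
class EpistasisCase:
    wt_record: OpsinRecord
    single_records: tuple[OpsinRecord, ...]
    multi_record: OpsinRecord
    eamv: float
    deviation: float
    is_epistatic: bool


def find_decomposable_multimutants(ds: Dataset, threshold: float = EPISTASIS_THRESHOLD_NM) -> list[EpistasisCase]:
    """All multimutants whose wild type and every component single are in ``ds``.

    Components are matched on the *same* parent accession plus the single-edit
    notation; cross-background singles do not count.  Records with
    unparseable notation are skipped with a warning.
    """
    singles: dict[tuple[str, str], OpsinRecord] = {}
    multis: list[tuple[OpsinRecord, list[str]]] = []
    for rec in ds.records:
        if rec.record_type != "mutant":
            continue
        try:
            spec = parse_mutation_notation(rec.mutation_notation)
        except MutationError as exc:
            warnings.warn(f"{rec.accession}: skipping unparseable notation ({exc})", stacklevel=2)
            continue
        tokens = [str(e) for e in spec.edits]
        if len(tokens) == 1:
            singles[(rec.parent_accession, tokens[0])] = rec
        else:
            multis.append((rec, tokens))

    cases = []
    for multi, tokens in multis:
        if multi.parent_accession not in ds:
            continue
        comp = [singles.get((multi.parent_accession, t)) for t in tokens]
        if any(c is None for c in comp):
            continue
        wt = ds[multi.parent_accession]
        expected = eamv(wt.lambda_max, [c.lambda_max for c in comp])
        deviation = abs(multi.lambda_max - expected)
        cases.append(
            EpistasisCase(
                wt_record=wt,
                single_records=tuple(comp),
                multi_record=multi,
                eamv=expected,
                deviation=deviation,
                is_epistatic=classify_epistatic(multi.lambda_max, expected, threshold),
            )
        )
    return cases


def cases_to_frame(cases) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "multi": [c.multi_record.accession for c in cases],
            "wt": [c.wt_record.accession for c in cases],
            "singles": [",".join(s.accession for s in c.single_records) for c in cases],
            "actual": [c.multi_record.lambda_max for c in cases],
            "eamv": [c.eamv for c in cases],
            "deviation": [c.deviation for c in cases],
            "is_epistatic": [c.is_epistatic for c in cases],
        }
    )


@dataclass
class LeaveEpistaticOutResult:
    """Paired predictions of the epistatic multimutants by three routes."""

    table: pd.DataFrame  # accession, actual, pred_minusepi, pred_wt_only, eamv
    metrics: dict[str, MetricSet]

    def squared_errors(self, column: str) -> np.ndarray:
        return (self.table[column].to_numpy() - self.table["actual"].to_numpy()) ** 2


def leave_epistatic_out(ds: Dataset, estimator: str = "gbr", seed: int = 0) -> LeaveEpistaticOutResult:
    """Remove all epistatic multimutants from training and predict them.

    Three prediction routes are paired per multimutant: (a) a model trained
    on everything except the epistatic multimutants themselves (their singles
    stay in), (b) a model trained on wild types only, and (c) the EAMV
    additive baseline from the observed singles.
    """
    cases = find_decomposable_multimutants(ds)
    epi = [c for c in cases if c.is_epistatic]
    if not epi:
        raise ValueError("no epistatic cases in dataset")
    held = {c.multi_record.accession for c in epi}

    al = alignment_from_records(ds.records)
    targets = [c.multi_record for c in epi]
    target_al = al.subset_rows([t.accession for t in targets])

    def train_and_predict(records):
        sub = al.subset_rows([r.accession for r in records])
        fm = fit_model(estimator, one_hot(sub), [r.lambda_max for r in records], seed=seed)
        return fm.predict_matrix(one_hot(target_al, vocabulary=fm.vocabulary).X)

    train_a = [r for r in ds.records if r.accession not in held]
    assert not held & {r.accession for r in train_a}
    pred_a = train_and_predict(train_a)
    pred_b = train_and_predict(subset(ds, "wild_type_only").records)

    table = pd.DataFrame(
        {
            "accession": [t.accession for t in targets],
            "actual": [t.lambda_max for t in targets],
            "pred_minusepi": pred_a,
            "pred_wt_only": pred_b,
            "eamv": [c.eamv for c in epi],
        }
    )
    actual = table["actual"]
    metrics = {
        col: compute_metrics(actual, table[col])
        for col in ("pred_minusepi", "pred_wt_only", "eamv")
    }
    return LeaveEpistaticOutResult(table=table, metrics=metrics)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test

@dataclass(frozen=True)
class PairedTestResult:
    statistic: float  # W+ (sum of positive midranks)
    n_effective: int
    p_two_sided: float
    method: str  # "exact" | "normal-approx"
    p_adjusted: float  # Bonferroni for m tests

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_two_sided <= 1.0


def _exact_two_sided_p(ranks2: np.ndarray, w2: int) -> float:
    """Two-sided tail probability of W+ over all sign assignments.

    ``ranks2`` are midranks doubled to integers; the distribution of the
    doubled statistic is built by dynamic programming, which enumerates the
    same 2^n sign patterns as brute force.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    denom = counts.sum()
    p_le = counts[: w2 + 1].sum() / denom
    p_ge = counts[w2:].sum() / denom
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(d, m: int = 1, exact_cutoff: int = 25) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking; ties get midranks.  With at
    most ``exact_cutoff`` effective pairs the p-value is exact over all sign
    assignments; beyond that a normal approximation with tie-corrected
    variance and continuity correction is used.  ``m`` gives the Bonferroni
    adjustment ``min(1, m·p)``.
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero: test degenerate")
    ranks = rankdata(np.abs(d))  # midranks
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_cutoff:
        ranks2 = np.rint(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        p = _exact_two_sided_p(ranks2, w2)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
        dev = w_plus - mean
        z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)
        p = min(1.0, 2.0 * float(norm.sf(abs(z))))
        method = "normal-approx"
    return PairedTestResult(
        statistic=w_plus,
        n_effective=n,
        p_two_sided=p,
        method=method,
        p_adjusted=min(1.0, m * p),
    )


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: each p becomes min(1, m·p)."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueError("m must be at least the number of p-values")
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in p_values]
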