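"""Brownian-motion imputation of missing tip phenotypes, and the machine
learning vs. imputation comparison harness.

Under Brownian motion with rate sigma² on a rooted tree, tip traits are
jointly normal with covariance ``sigma² · C`` where ``C[i][j]`` is the branch
length shared by the root-to-tip paths of tips i and j.  Imputation is the
conditional normal: with observed block ``o`` and missing block ``m``,

    mu_hat    = (1' C_oo^-1 y) / (1' C_oo^-1 1)          (GLS root estimate)
    E[y_m]    = mu_hat + C_mo C_oo^-1 (y_o − mu_hat·1)
    Var[y_m]  = sigma_hat² · diag(C_mm − C_mo C_oo^-1 C_om)

with sigma² estimated by maximum likelihood on the observed tips.  Trees are
consumed as Newick; inference of the tree itself is external (a
neighbor-joining helper on p-distances exists for synthetic tests only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .encode import Alignment, alignment_from_records, one_hot
from .models import MetricSet, compute_metrics, fit_model


class TreeError(ValueError):
    pass


@dataclass
class PhyloTree:
    """A rooted tree with finite non-negative branch lengths, unique tip labels."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        if self.tree.is_rooted is False:
            raise TreeError("tree must be rooted")
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            raise TreeError("tip labels are not unique")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            length = edge.length
            if length is None:
                raise TreeError("every non-root edge needs a branch length")
            if not np.isfinite(length) or length < 0:
                raise TreeError(f"bad branch length {length!r}")

    @classmethod
    def from_newick(cls, source: str, is_path: bool = False) -> "PhyloTree":
        kwargs = {"path" if is_path else "data": source, "schema": "newick"}
        try:
            tree = dendropy.Tree.get(**kwargs)
        except Exception as exc:  # dendropy's reader errors are not ValueErrors
            raise TreeError(f"could not parse Newick: {exc}") from exc
        return cls(tree)

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def height(self) -> float:
        return max(self.tree.calc_node_root_distances(return_leaf_distances_only=True))


def bm_vcv(tree: PhyloTree) -> tuple[np.ndarray, list[str]]:
    """Shared-path covariance matrix of the tips (root edge ignored).

    ``C[i][j]`` is the root depth of the most recent common ancestor of tips
    i and j; the diagonal holds root-to-tip distances.
    """
    t = tree.tree
    labels = tree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))

    depth: dict = {t.seed_node: 0.0}
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        depth[node] = depth[node.parent_node] + node.edge.length

    def tips_under(node) -> list[int]:
        return [index[leaf.taxon.label] for leaf in node.leaf_iter()]

    for node in t.preorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            C[i, i] = depth[node]
            continue
        children = node.child_nodes()
        groups = [tips_under(c) for c in children]
        d = depth[node]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        C[a, b] = C[b, a] = d
    return C, labels


@dataclass
class ImputationResult:
    means: dict[str, float]  # imputed mean per missing tip (nm)
    variances: dict[str, float]  # conditional variance per missing tip (nm²)
    mu_hat: float  # GLS root estimate
    sigma2_hat: float  # ML Brownian rate estimate

    def to_frame(self) -> pd.DataFrame:
        tips = list(self.means)
        return pd.DataFrame(
            {
                "tip": tips,
                "imputed_mean": [self.means[t] for t in tips],
                "conditional_variance": [self.variances[t] for t in tips],
            }
        )


def impute_bm(
    tree: PhyloTree,
    observed: dict[str, float],
    missing: set[str] | None = None,
    ridge_fraction: float = 1e-8,
) -> ImputationResult:
    """Impute missing tip phenotypes by conditional-normal Brownian motion.

    ``observed`` maps tip labels to known values; ``missing`` defaults to all
    remaining tips and together they must cover the tree exactly.  A singular
    observed covariance block (duplicate zero-length tips) gets a ridge of
    ``ridge_fraction`` × tree height added to its diagonal, with a warning.
    """
    C, labels = bm_vcv(tree)
    tips = set(labels)
    if missing is None:
        missing = tips - set(observed)
    if set(observed) | set(missing) != tips or set(observed) & set(missing):
        raise TreeError("observed and missing tips must partition the tree's tips")
    if not observed:
        raise TreeError("need at least one observed tip")
    obs_labels = [l for l in labels if l in observed]
    mis_labels = [l for l in labels if l in missing]
    o = [labels.index(l) for l in obs_labels]
    mridx = [labels.index(l) for l in mis_labels]
    y = np.array([observed[l] for l in obs_labels], dtype=float)
    Coo = C[np.ix_(o, o)]
    try:
        np.linalg.cholesky(Coo)
    except np.linalg.LinAlgError:
        eps = ridge_fraction * float(C.diagonal().max())
        warnings.warn(f"singular observed covariance; adding ridge {eps:g}", stacklevel=2)
        Coo = Coo + eps * np.eye(len(o))
    Coo_inv = np.linalg.inv(Coo)
    ones = np.ones(len(o))
    mu_hat = float(ones @ Coo_inv @ y) / float(ones @ Coo_inv @ ones)
    resid = y - mu_hat
    sigma2_hat = float(resid @ Coo_inv @ resid) / len(o)

    if not mis_labels:
        return ImputationResult(means={}, variances={}, mu_hat=mu_hat, sigma2_hat=sigma2_hat)
    Cmo = C[np.ix_(mridx, o)]
    Cmm = C[np.ix_(mridx, mridx)]
    cond_mean = mu_hat + Cmo @ Coo_inv @ resid
    cond_cov = Cmm - Cmo @ Coo_inv @ Cmo.T
    cond_var = sigma2_hat * np.clip(np.diag(cond_cov), 0.0, None)
    return ImputationResult(
        means={l: float(v) for l, v in zip(mis_labels, cond_mean)},
        variances={l: float(v) for l, v in zip(mis_labels, cond_var)},
        mu_hat=mu_hat,
        sigma2_hat=sigma2_hat,
    )


def nj_tree_from_alignment(al: Alignment) -> PhyloTree:
    """Neighbor-joining tree on p-distances; a convenience for synthetic
    tests, not a substitute for proper phylogenetic inference."""
    n = len(al)
    taxa = dendropy.TaxonNamespace(al.ids)
    pdm = dendropy.PhylogeneticDistanceMatrix()
    pdm.taxon_namespace = taxa
    dists = {}
    for i in range(n):
        for j in range(n):
            a, b = al.rows[i], al.rows[j]
            diff = sum(1 for x, y in zip(a, b) if x != y and x != "-" and y != "-")
            comp = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
            dists[(taxa[i], taxa[j])] = diff / comp if comp else 0.0
    pdm.compile_from_dict(dists, taxon_namespace=taxa)
    tree = pdm.nj_tree()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0  # NJ can emit small negative branches
    tree.is_rooted = True
    return PhyloTree(tree)


@dataclass
class ComparisonResult:
    table: pd.DataFrame  # accession, actual, pred_ml, pred_imputation
    ml: MetricSet
    imputation: MetricSet


def compare_ml_vs_imputation(
    ds,
    al: Alignment,
    tree: PhyloTree,
    holdout_n: int,
    estimator: str = "gbr",
    seed: int = 0,
) -> ComparisonResult:
    """Hold out tips at random and predict them twice from the same data.

    The regression route trains on all non-held records of the dataset; the
    imputation route conditions the Brownian model on the non-held tip values.
    Both predict the same held-out lambda_max values, paired per tip.
    """
    tips = tree.tip_labels
    offenders = [t for t in tips if t not in ds]
    if offenders:
        raise TreeError(f"tree tips missing from dataset: {offenders}")
    if not 1 <= holdout_n < len(tips):
        raise ValueError(f"holdout_n must be in [1, {len(tips) - 1}]")
    rng = np.random.default_rng(seed)
    held = set(rng.choice(tips, size=holdout_n, replace=False).tolist())

    train = [r for r in ds.records if r.accession not in held]
    train_al = alignment_from_records(train)  # includes mutant records, not just tips
    fm = fit_model(estimator, one_hot(train_al), [r.lambda_max for r in train], seed=seed)
    held_order = [t for t in tips if t in held]
    held_al = al.subset_rows(held_order)
    pred_ml = fm.predict_matrix(one_hot(held_al, vocabulary=fm.vocabulary).X)

    observed = {t: ds[t].lambda_max for t in tips if t not in held}
    imput = impute_bm(tree, observed, missing=held)
    pred_imp = np.array([imput.means[t] for t in held_order])

    actual = np.array([ds[t].lambda_max for t in held_order])
    table = pd.DataFrame(
        {
            "accession": held_order,
            "actual": actual,
            "pred_ml": pred_ml,
            "pred_imputation": pred_imp,
        }
    )
    return ComparisonResult(
        table=table,
        ml=compute_metrics(actual, pred_ml),
        imputation=compute_metrics(actual, pred_imp),
    )
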