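"""The transcriptomic biological-age clock.

Exploratory PC1 axis; a sparse L1-penalized clock trained on age rescaled by
lifespan over the signature genes, with the penalty chosen by
leave-datasets-out cross-validation; projection of expression to biological
age z ~ sum_i a_i (x_i - xbar_i); and the temporal-scaling report comparing
the correlation of predicted biological age with rescaled versus raw age.

The clock predicts rescaled age (dimensionless: ~0 at the L4/adult molt, ~1
at the group mean lifespan), so one model serves cohorts whose lifespans
differ tenfold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso

from ._rng import rng_from
from .normalize import ExpressionStudy, MetaCollection
from .signature import AgingSignature

__all__ = [
    "PC1Result",
    "BiomarkerModel",
    "ScalingReport",
    "pc1_axis",
    "train_sparse_clock",
    "predict_bioage",
    "trajectory_scaling_report",
]


@dataclass(frozen=True)
class PC1Result:
    loadings: pd.Series        # unit-norm, indexed by gene
    scores: pd.Series          # per sample, sign-oriented along age
    age_correlation: float


@dataclass
class BiomarkerModel:
    """Sparse affine clock: z = intercept + sum_i weights_i (x_i - xbar_i)."""

    genes: list
    weights: np.ndarray
    xbar: np.ndarray
    intercept: float
    penalty: float
    cv_table: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(self.weights != 0))

    def save(self, path) -> None:
        payload = {
            "genes": list(map(str, self.genes)),
            "weights": self.weights.tolist(),
            "xbar": self.xbar.tolist(),
            "intercept": self.intercept,
            "penalty": self.penalty,
            "cv_table": None if self.cv_table is None else self.cv_table.to_dict("list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "BiomarkerModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            genes=d["genes"],
            weights=np.asarray(d["weights"]),
            xbar=np.asarray(d["xbar"]),
            intercept=float(d["intercept"]),
            penalty=float(d["penalty"]),
            cv_table=None if d["cv_table"] is None else pd.DataFrame(d["cv_table"]),
        )


@dataclass(frozen=True)
class ScalingReport:
    r_rescaled: float
    r_raw: float
    curves: pd.DataFrame       # binned mean trajectory per group


def pc1_axis(study: ExpressionStudy) -> PC1Result:
    """First principal component of a gene-centered study.

    Loadings are unit norm; the sign is oriented so the score-age correlation
    is non-negative.  On a noise-free one-factor study the loadings coincide
    with the aging direction b.
    """
    if study.n_samples < 3:
        raise ValueError("need at least 3 samples for PCA")
    X = study.values.to_numpy(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = U[:, 0]
    scores = Vt[0, :] * s[0]
    age = study.metadata["age_days"].to_numpy(float)
    r = float(np.corrcoef(scores, age)[0, 1]) if np.ptp(age) > 0 else 0.0
    if r < 0:
        loadings, scores, r = -loadings, -scores, -r
    return PC1Result(
        loadings=pd.Series(loadings, index=study.values.index),
        scores=pd.Series(scores, index=study.values.columns),
        age_correlation=r,
    )


def _group_folds(dataset_ids: np.ndarray, folds: int, seed: int):
    """Assign whole datasets to folds (leave-datasets-out CV)."""
    units = np.unique(dataset_ids)
    rng = rng_from(seed, 60)
    perm = rng.permutation(len(units))
    assignment = {units[j]: int(perm[j] % folds) for j in range(len(units))}
    fold_of = np.array([assignment[d] for d in dataset_ids])
    return fold_of


def train_sparse_clock(
    collection: MetaCollection,
    signature: AgingSignature,
    folds: int = 5,
    penalties: np.ndarray | None = None,
    seed: int = 0,
    penalty_rule: str = "1se",
    allow_null_model: bool = False,
) -> BiomarkerModel:
    """Cross-validated lasso of rescaled age on signature-gene expression.

    Cross-validation is grouped by dataset: each fold holds out whole
    datasets, mirroring validation on experiments never seen during
    training.  ``penalty_rule`` '1se' (default) picks the sparsest penalty
    whose held-out error is within one standard error of the minimum — the
    standard choice when the support matters; 'min' picks the error minimum.
    The model is refitted on all samples at the chosen penalty; reference
    levels xbar are the training-collection gene means.
    """
    if len(signature) == 0:
        raise ValueError("signature is empty")
    genes = list(signature.genes)
    missing = set(genes) - set(collection.gene_ids)
    if missing:
        raise ValueError(f"signature genes absent from collection: {sorted(missing)[:10]}")
    if penalties is None:
        penalties = np.logspace(-4.5, -0.5, 25)
    X = collection.pooled_values().loc[genes].to_numpy(float).T  # samples x genes
    md = collection.pooled_metadata()
    y = md["rescaled_age"].to_numpy(float)
    xbar = X.mean(axis=0)
    Xc = X - xbar
    fold_of = _group_folds(md["dataset_id"].to_numpy(), folds, seed)
    records = []
    for pen in penalties:
        errs = []
        for k in range(folds):
            tr, te = fold_of != k, fold_of == k
            if te.sum() == 0 or tr.sum() == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = Lasso(alpha=pen, max_iter=20000).fit(Xc[tr], y[tr])
            errs.append(float(np.mean((m.predict(Xc[te]) - y[te]) ** 2)))
        records.append({"penalty": float(pen), "cv_mse": float(np.mean(errs)),
                        "cv_se": float(np.std(errs) / np.sqrt(len(errs)))})
    cv_table = pd.DataFrame(records)
    i_min = cv_table["cv_mse"].idxmin()
    if penalty_rule == "min":
        best = cv_table.loc[i_min]
    elif penalty_rule == "1se":
        bound = cv_table.loc[i_min, "cv_mse"] + cv_table.loc[i_min, "cv_se"]
        ok = cv_table[cv_table["cv_mse"] <= bound]
        best = ok.loc[ok["penalty"].idxmax()]
    else:
        raise ValueError("penalty_rule must be 'min' or '1se'")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final = Lasso(alpha=float(best["penalty"]), max_iter=50000).fit(Xc, y)
    weights = np.asarray(final.coef_)
    if np.all(weights == 0) and not allow_null_model:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            all_null = all(
                np.all(Lasso(alpha=p, max_iter=20000).fit(Xc, y).coef_ == 0)
                for p in penalties
            )
        if all_null:
            raise ValueError(
                "lasso solution is all-zero at every penalty; extend the grid "
                "toward smaller penalties (or pass allow_null_model=True for "
                "the intercept-only limit)"
            )
    return BiomarkerModel(
        genes=genes,
        weights=weights,
        xbar=xbar,
        intercept=float(final.intercept_),
        penalty=float(best["penalty"]),
        cv_table=cv_table,
    )


def predict_bioage(model: BiomarkerModel, study: ExpressionStudy) -> pd.DataFrame:
    """Project a study to biological age, z = intercept + a . (x - xbar).

    Returns a per-sample table with columns ``bioage``, ``age_days``,
    ``rescaled_age`` and ``group``.
    """
    missing = [g for g in model.genes if g not in study.values.index]
    if missing:
        raise ValueError(f"study lacks model genes: {missing[:10]}")
    X = study.values.loc[model.genes].to_numpy(float).T
    z = model.intercept + (X - model.xbar) @ model.weights
    return pd.DataFrame(
        {
            "bioage": z,
            "age_days": study.metadata["age_days"].to_numpy(float),
            "rescaled_age": study.rescaled_age().to_numpy(float),
            "group": study.metadata["group"].to_numpy(),
        },
        index=study.values.columns,
    )


def trajectory_scaling_report(traj: pd.DataFrame, n_bins: int = 10) -> ScalingReport:
    """Temporal-scaling contrast for biological-age trajectories.

    Pearson correlation of predicted biological age with rescaled age versus
    raw chronological age, over all samples of all groups, plus per-group
    binned mean trajectories for plotting.  Rescaling by lifespan collapses
    the trajectories of cohorts with different lifespans, so the rescaled
    correlation exceeds the raw one whenever lifespans differ.
    """
    groups = traj["group"].unique()
    lifespans = traj.groupby("group", sort=False).apply(
        lambda g: (g["age_days"] / g["rescaled_age"].replace(0, np.nan)).dropna().iloc[0]
        if (g["rescaled_age"] != 0).any() else np.nan,
        include_groups=False,
    )
    if len(groups) < 2 or lifespans.nunique() < 2:
        warnings.warn("single group (or equal lifespans): raw and rescaled correlations coincide")
    r_rescaled = float(stats.pearsonr(traj["bioage"], traj["rescaled_age"])[0])
    r_raw = float(stats.pearsonr(traj["bioage"], traj["age_days"])[0])
    bins = np.linspace(0, max(traj["rescaled_age"].max(), 1e-9), n_bins + 1)
    curves = (
        traj.assign(bin=pd.cut(traj["rescaled_age"], bins, include_lowest=True))
        .groupby(["group", "bin"], observed=True)["bioage"]
        .mean()
        .reset_index()
    )
    curves["bin_mid"] = curves["bin"].apply(lambda iv: float(iv.mid))
    return ScalingReport(
        r_rescaled=r_rescaled, r_raw=r_raw,
        curves=curves[["group", "bin_mid", "bioage"]],
    )
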