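"""Synthetic expression studies, meta-collections and survival cohorts.

The generator reproduces the statistical structure the analysis assumes:

- one-factor age-driven expression x_i = xbar_i + b_i z + xi_i, with a sparse
  unit-norm loading vector b (a configurable fraction of genes carries
  exactly zero loading);
- a biological-age trajectory z that is a universal function of age rescaled
  by cohort mean lifespan (the temporal-scaling hypothesis): each cohort's
  stiffness is alpha = c / tbar and its noise is scaled so the law of z at
  rescaled age u is cohort-independent;
- per-dataset affine batch effects (one offset vector and one scale per
  dataset) that dominate total variance, emulating a compilation of small
  public studies whose batch differences swamp the aging signal;
- survival cohorts from either closed-form Gompertz mortality or first
  passage of the critical mode.

Every generated object carries a ground-truth channel (true z per sample,
loading support, cohort alpha) for parameter-recovery tests downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import rng_from
from .core_model import GompertzLaw, LangevinParams, first_passage_times
from .events import event_table
from .normalize import ExpressionStudy, MetaCollection, write_study

__all__ = [
    "FactorModelParams",
    "ZTrajectory",
    "CohortSpec",
    "MetaCollectionSpec",
    "generate_survival_cohort",
    "generate_expression_study",
    "generate_meta_collection",
    "cohort_mean_lifespan",
    "variance_explained",
    "write_collection",
]


@dataclass(frozen=True)
class FactorModelParams:
    """One-factor expression model parameters.

    ``xbar``: per-gene baseline (log-scale abundance units); ``b``: unit-norm
    aging loadings, zero outside the support; ``resid_sd``: residual noise;
    ``count_mode``: 'continuous' (default) or 'nb' (negative-binomial counts
    with the given dispersion, means = exp(x)).
    """

    xbar: np.ndarray
    b: np.ndarray
    resid_sd: float = 0.03
    count_mode: str = "continuous"
    nb_dispersion: float = 0.1

    def __post_init__(self) -> None:
        if self.xbar.shape != self.b.shape:
            raise ValueError("xbar and b must have equal length")
        nrm = np.linalg.norm(self.b)
        if nrm > 0 and abs(nrm - 1.0) > 1e-12:
            raise ValueError("b must be unit norm (or identically zero)")
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be >= 0")
        if self.count_mode not in ("continuous", "nb"):
            raise ValueError("count_mode must be 'continuous' or 'nb'")

    @property
    def n_genes(self) -> int:
        return len(self.xbar)

    @property
    def support(self) -> np.ndarray:
        return self.b != 0

    @classmethod
    def random(
        cls,
        G: int = 500,
        support_frac: float = 0.1,
        seed: int = 0,
        baseline_mean: float = 6.0,
        baseline_sd: float = 1.5,
        resid_sd: float = 0.03,
        count_mode: str = "continuous",
    ) -> "FactorModelParams":
        """Random factor model with equal-magnitude +-1/sqrt(k) loadings on a
        random support of ``round(support_frac * G)`` genes.

        Equal magnitudes make every support gene carry the same effect size,
        so the truth channel is meaningful for sensitivity estimates.
        """
        if not (0 <= support_frac <= 1):
            raise ValueError("support_frac must be in [0, 1]")
        rng = rng_from(seed, 10)
        xbar = np.clip(rng.normal(baseline_mean, baseline_sd, G), 1.0, None)
        b = np.zeros(G)
        k = int(round(support_frac * G))
        if k > 0:
            idx = rng.choice(G, size=k, replace=False)
            b[idx] = rng.choice([-1.0, 1.0], size=k) / math.sqrt(k)
        return cls(xbar=xbar, b=b, resid_sd=resid_sd, count_mode=count_mode)


@dataclass(frozen=True)
class ZTrajectory:
    """The cohort-independent law of biological age at rescaled age u = t/tbar.

    With stiffness alpha = c/tbar and noise sigma = noise_scale*sqrt(2*alpha),
    the linear-SDE law of z at age u*tbar depends on u only:
    z ~ N(z0*exp(c*u), noise_scale^2*(exp(2*c*u) - 1)).  Defaults traverse
    z0=0.1 to ~1.1 over one lifespan with ~25% relative noise at u=1.
    """

    c: float = math.log(10.0)
    z0: float = 0.1
    noise_scale: float = 0.025

    def mean(self, u) -> np.ndarray:
        return self.z0 * np.exp(self.c * np.asarray(u, float))

    def sd(self, u) -> np.ndarray:
        return self.noise_scale * np.sqrt(np.expm1(2.0 * self.c * np.asarray(u, float)))

    def sample(self, u, rng: np.random.Generator) -> np.ndarray:
        u = np.asarray(u, float)
        return rng.normal(self.mean(u), self.sd(u))

    def alpha_for(self, tbar: float) -> float:
        return self.c / tbar


@dataclass(frozen=True)
class CohortSpec:
    """A survival cohort: group id, size, mortality law, optional censoring."""

    group: str
    n_animals: int
    mortality: object  # GompertzLaw | LangevinParams
    censor_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if not (0 <= self.censor_prob < 1):
            raise ValueError("censor_prob must be in [0, 1)")
        if not isinstance(self.mortality, (GompertzLaw, LangevinParams)):
            raise ValueError("mortality must be a GompertzLaw or LangevinParams")


def cohort_mean_lifespan(mortality) -> float:
    """Mean lifespan implied by a mortality law.

    Gompertz: numerical integral of S(t).  Langevin: the deterministic
    crossing time ln(z_crit/z0)/alpha (requires z0 > 0).
    """
    if isinstance(mortality, GompertzLaw):
        return mortality.mean_lifespan()
    if isinstance(mortality, LangevinParams):
        if mortality.z0 <= 0:
            raise ValueError("deterministic lifespan needs z0 > 0")
        return math.log(mortality.z_crit / mortality.z0) / mortality.alpha
    raise TypeError(f"unsupported mortality law {type(mortality)!r}")


def generate_survival_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample an event table from the cohort's mortality law.

    Gompertz death times come from the closed-form inverse CDF; Langevin
    cohorts delegate to first-passage simulation.  Random right-censoring is
    applied independently per animal: with probability ``censor_prob`` the
    record is censored at a uniform time before its death.
    """
    rng = rng_from(spec.seed, 20)
    if isinstance(spec.mortality, GompertzLaw):
        times = spec.mortality.sample(spec.n_animals, rng)
        events = np.ones(spec.n_animals, dtype=int)
        table = event_table(times, events, spec.group)
    else:
        table = first_passage_times(spec.mortality, spec.n_animals, group=spec.group)
        table = table.copy()
    if spec.censor_prob > 0:
        cens = rng.uniform(size=len(table)) < spec.censor_prob
        t = table["time_days"].to_numpy(float)
        t[cens] = rng.uniform(0.0, t[cens])
        table["time_days"] = t
        table.loc[cens, "event"] = 0
    return table


def generate_expression_study(
    factor: FactorModelParams,
    cohorts: list[CohortSpec],
    sampling_ages,
    replicates: int = 2,
    seed: int = 0,
    ztraj: ZTrajectory = ZTrajectory(),
    dataset_id: str = "study",
) -> ExpressionStudy:
    """One-factor expression study sampled over cohorts and rescaled ages.

    For each cohort and each sampling age u (a fraction of the cohort mean
    lifespan, in [0, ~1.2]), ``replicates`` animals are drawn: z from the
    cohort's Langevin law at that age, then x = xbar + b z + xi.  The true z
    of every sample is recorded in the truth channel.  In 'nb' count mode the
    log-scale x is exponentiated to means and integer counts are drawn from a
    gamma-Poisson mixture.
    """
    sampling_ages = np.asarray(sampling_ages, float)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if np.any(sampling_ages < 0) or np.any(sampling_ages > 1.25):
        raise ValueError("sampling ages must be fractions of lifespan in [0, ~1.2]")
    rng = rng_from(seed, 30)
    cols, ages, groups, tbars, zs = [], [], [], [], []
    names = []
    alphas = {}
    for spec in cohorts:
        tbar = cohort_mean_lifespan(spec.mortality)
        alphas[spec.group] = ztraj.alpha_for(tbar)
        for u in sampling_ages:
            z_r = ztraj.sample(np.full(replicates, u), rng)
            for r in range(replicates):
                z = z_r[r]
                x = factor.xbar + factor.b * z + rng.normal(0, factor.resid_sd, factor.n_genes)
                cols.append(x)
                ages.append(u * tbar)
                groups.append(spec.group)
                tbars.append(tbar)
                zs.append(z)
                names.append(f"{dataset_id}:{spec.group}:u{u:.3f}:r{r}")
    X = np.column_stack(cols)
    value_kind = "normalized"
    if factor.count_mode == "nb":
        mean = np.exp(X)
        shape = 1.0 / factor.nb_dispersion
        lam = rng.gamma(shape, mean / shape)
        X = rng.poisson(lam).astype(float)
        value_kind = "counts"
    gene_ids = pd.Index([f"g{i:04d}" for i in range(factor.n_genes)], name="gene_id")
    values = pd.DataFrame(X, index=gene_ids, columns=names)
    metadata = pd.DataFrame(
        {
            "age_days": ages,
            "group": groups,
            "group_mean_lifespan_days": tbars,
            "dataset_id": dataset_id,
        },
        index=pd.Index(names, name="sample_id"),
    )
    truth = {
        "z": np.array(zs),
        "support": factor.support.copy(),
        "b": factor.b.copy(),
        "alpha_per_group": alphas,
    }
    return ExpressionStudy(values=values, metadata=metadata, value_kind=value_kind, truth=truth)


@dataclass(frozen=True)
class MetaCollectionSpec:
    """Shape of a multi-dataset compilation of small aging studies.

    Lifespans are drawn log-uniformly over ``lifespan_range`` (default 17-160
    days, a ~10x span); each dataset samples ages in a window of width
    ``age_window_width`` (as a fraction of lifespan) placed randomly inside
    ``age_range``; batch effects are affine per dataset, x -> s_d*x + o_d,
    with per-gene offsets o_d ~ N(0, offset_sd) and a scalar scale drawn from
    ``scale_range``.
    """

    n_datasets: int = 20
    samples_per_dataset: tuple[int, int] = (8, 16)
    offset_sd: float = 0.03
    scale_range: tuple[float, float] = (0.8, 1.25)
    lifespan_range: tuple[float, float] = (17.0, 160.0)
    age_range: tuple[float, float] = (0.05, 1.05)
    age_window_width: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets < 2:
            raise ValueError("n_datasets must be >= 2")
        if self.lifespan_range[0] <= 0 or self.lifespan_range[1] < self.lifespan_range[0]:
            raise ValueError("lifespan range must be positive and ordered")
        if self.age_window_width > self.age_range[1] - self.age_range[0]:
            raise ValueError("age window wider than the age range")


def generate_meta_collection(
    spec: MetaCollectionSpec,
    factor: FactorModelParams,
    ztraj: ZTrajectory = ZTrajectory(),
) -> MetaCollection:
    """Generate a meta-collection with dataset-level batch effects applied."""
    rng = rng_from(spec.seed, 40)
    studies = []
    gene_ids = pd.Index([f"g{i:04d}" for i in range(factor.n_genes)], name="gene_id")
    for d in range(spec.n_datasets):
        ds = f"ds{d:03d}"
        tbar = float(
            np.exp(rng.uniform(*np.log(np.asarray(spec.lifespan_range))))
        )
        n = int(rng.integers(spec.samples_per_dataset[0], spec.samples_per_dataset[1] + 1))
        lo = rng.uniform(spec.age_range[0], spec.age_range[1] - spec.age_window_width)
        u = rng.uniform(lo, lo + spec.age_window_width, size=n)
        z = ztraj.sample(u, rng)
        X = (
            factor.xbar[:, None]
            + factor.b[:, None] * z[None, :]
            + rng.normal(0, factor.resid_sd, (factor.n_genes, n))
        )
        offset = rng.normal(0, spec.offset_sd, factor.n_genes) if spec.offset_sd > 0 else np.zeros(factor.n_genes)
        scale = float(rng.uniform(*spec.scale_range))
        prebatch = X.copy()
        X = scale * X + offset[:, None]
        names = [f"{ds}:s{j:03d}" for j in range(n)]
        values = pd.DataFrame(X, index=gene_ids, columns=names)
        metadata = pd.DataFrame(
            {
                "age_days": u * tbar,
                "group": ds,
                "group_mean_lifespan_days": tbar,
                "dataset_id": ds,
            },
            index=pd.Index(names, name="sample_id"),
        )
        truth = {
            "z": z,
            "support": factor.support.copy(),
            "b": factor.b.copy(),
            "alpha_per_group": {ds: ztraj.alpha_for(tbar)},
            "batch_offset": offset,
            "batch_scale": scale,
            "prebatch": prebatch,
        }
        studies.append(
            ExpressionStudy(values=values, metadata=metadata, value_kind="normalized", truth=truth)
        )
    return MetaCollection(studies)


def variance_explained(collection: MetaCollection) -> dict:
    """Average per-gene variance fractions explained by dataset label vs age.

    Dataset: between-dataset sum of squares over total (eta squared).
    Age: squared correlation with rescaled age.  In a batch-dominated
    compilation the former exceeds the latter.
    """
    X = collection.pooled_values().to_numpy(float)
    md = collection.pooled_metadata()
    labels = pd.Categorical(md["dataset_id"]).codes
    u = md["rescaled_age"].to_numpy(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    tot = (Xc**2).sum(axis=1)
    tot = np.maximum(tot, 1e-300)
    between = np.zeros_like(tot)
    for lab in np.unique(labels):
        m = labels == lab
        between += m.sum() * Xc[:, m].mean(axis=1) ** 2
    uc = (u - u.mean()) / max(u.std(), 1e-300)
    r = (Xc @ uc) / np.sqrt(tot * len(u))
    return {
        "eta2_dataset": float(np.mean(between / tot)),
        "r2_age": float(np.mean(r**2)),
    }


def write_collection(collection: MetaCollection, out_dir) -> None:
    """Write each study as TSV pairs plus a JSON ground-truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, study in enumerate(collection.studies):
        ds = str(study.metadata["dataset_id"].iloc[0])
        write_study(study, out_dir / ds)
        truth = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in study.truth.items()
        }
        with open(out_dir / f"{ds}_truth.json", "w") as fh:
            json.dump(truth, fh, sort_keys=True)
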