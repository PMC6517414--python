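"""Meta-analysis of aging dynamics: the resampled transcriptomic signature.

Single-gene association tests of expression against age rescaled by lifespan,
repeated over an ensemble of random resamples of the dataset collection;
genes significant (after Bonferroni correction over the gene universe) in a
large enough fraction of resamples form the aging signature, with a
direction given by the majority slope sign.  Resampling at the dataset level
is what makes the signature robust to batch effects: a spurious association
driven by a few datasets does not survive resamples that exclude them.

Also provides the Mann-Whitney/AUC enrichment congruence test between a gene
ranking from one study and a signature derived from another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import rng_from
from .normalize import MetaCollection

__all__ = [
    "ResampleConfig",
    "AgingSignature",
    "AssociationResult",
    "EnrichmentResult",
    "gene_age_association",
    "association_matrix",
    "resample_signature",
    "single_split_significant",
    "enrichment_auc",
    "bonferroni_level",
]


@dataclass(frozen=True)
class ResampleConfig:
    """Knobs of the resampling ensemble.

    ``B`` resamples, each drawing ``fraction`` of the units (datasets by
    default) without replacement; per-gene significance at ``level``
    Bonferroni-corrected over the gene universe; genes significant in at
    least ``freq_threshold`` of resamples enter the signature, provided their
    slope sign agrees in at least ``direction_consistency`` of their
    significant resamples.
    """

    B: int = 200
    unit: str = "dataset"
    fraction: float = 0.5
    test: str = "pearson"
    level: float = 0.005
    freq_threshold: float = 0.5
    direction_consistency: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 10:
            raise ValueError("B must be >= 10")
        if not (0 < self.fraction < 1):
            raise ValueError("fraction must be in (0, 1)")
        if not (0 < self.freq_threshold <= 1):
            raise ValueError("freq_threshold must be in (0, 1]")
        if self.unit not in ("dataset", "sample"):
            raise ValueError("unit must be 'dataset' or 'sample'")
        if self.test not in ("pearson", "spearman"):
            raise ValueError("test must be 'pearson' or 'spearman'")


@dataclass(frozen=True)
class AssociationResult:
    sign: int              # +1 up with age, -1 down, 0 undefined
    correlation: float
    p: float
    constant: bool = False # expression was constant; reported non-significant


@dataclass(frozen=True)
class AgingSignature:
    """Genes robustly associated with rescaled age.

    ``table`` carries the full frequency/direction bookkeeping for every gene
    in the universe, signature member or not.
    """

    genes: list
    directions: dict       # gene -> 'up' | 'down'
    frequencies: dict      # gene -> selection frequency in [0, 1]
    table: pd.DataFrame = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class EnrichmentResult:
    auc: float
    se: float
    p: float


def bonferroni_level(level: float, n_genes: int) -> float:
    """Per-gene significance level after Bonferroni correction."""
    return level / n_genes


def gene_age_association(values, rescaled_ages, test: str = "pearson") -> AssociationResult:
    """Two-sided association test of one gene's expression with rescaled age."""
    v = np.asarray(values, float)
    u = np.asarray(rescaled_ages, float)
    if len(v) < 4:
        raise ValueError("need at least 4 samples")
    if np.ptp(u) == 0:
        raise ValueError("ages must not be constant")
    if np.ptp(v) == 0:
        return AssociationResult(sign=0, correlation=0.0, p=1.0, constant=True)
    if test == "pearson":
        r, p = stats.pearsonr(v, u)
    elif test == "spearman":
        r, p = stats.spearmanr(v, u)
    else:
        raise ValueError("test must be 'pearson' or 'spearman'")
    return AssociationResult(sign=int(np.sign(r)), correlation=float(r), p=float(p))


def association_matrix(X: np.ndarray, rescaled_ages: np.ndarray, test: str = "pearson"):
    """Vectorized per-gene correlation and two-sided p over a genes x samples
    block.  Constant genes get r = 0, p = 1."""
    u = np.asarray(rescaled_ages, float)
    n = len(u)
    if n < 4:
        raise ValueError("need at least 4 samples")
    if np.ptp(u) == 0:
        raise ValueError("ages must not be constant")
    X = np.asarray(X, float)
    if test == "spearman":
        X = stats.rankdata(X, axis=1)
        u = stats.rankdata(u)
    Xc = X - X.mean(axis=1, keepdims=True)
    uc = u - u.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    su = np.sqrt((uc**2).sum())
    const = sx == 0
    r = (Xc @ uc) / (np.where(const, 1.0, sx) * su)
    r[const] = 0.0
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[const] = 1.0
    return r, np.minimum(p, 1.0)


def resample_signature(collection: MetaCollection, config: ResampleConfig) -> AgingSignature:
    """Aging signature by exhaustive random resampling with frequency thresholding.

    Each of the B resamples draws the configured fraction of units without
    replacement, pools their samples and tests every gene against rescaled
    age at the Bonferroni-corrected level.  The signature consists of the
    genes significant in at least ``freq_threshold`` of resamples whose slope
    sign is consistent; directions follow the majority sign.
    """
    X = collection.pooled_values().to_numpy(float)
    md = collection.pooled_metadata()
    u = md["rescaled_age"].to_numpy(float)
    genes = collection.gene_ids
    G = len(genes)
    if config.unit == "dataset":
        labels = md["dataset_id"].to_numpy()
        units = np.unique(labels)
        if len(units) < 2:
            raise ValueError("dataset-level resampling needs >= 2 datasets")
    else:
        units = np.arange(len(u))
        labels = units
    n_draw = max(1, int(round(config.fraction * len(units))))
    per_gene_level = bonferroni_level(config.level, G)
    rng = rng_from(config.seed, 50)
    hits = np.zeros(G)
    pos = np.zeros(G)
    for _ in range(config.B):
        chosen = rng.choice(units, size=n_draw, replace=False)
        mask = np.isin(labels, chosen)
        r, p = association_matrix(X[:, mask], u[mask], test=config.test)
        sig = p < per_gene_level
        hits += sig
        pos += sig & (r > 0)
    freq = hits / config.B
    selected = freq >= config.freq_threshold
    table = pd.DataFrame(
        {
            "frequency": freq,
            "n_significant": hits.astype(int),
            "frac_up": np.divide(pos, hits, out=np.full(G, np.nan), where=hits > 0),
        },
        index=genes,
    )
    sig_genes, directions, frequencies = [], {}, {}
    for g, sel, f, h, fp in zip(genes, selected, freq, hits, table["frac_up"]):
        if not sel:
            continue
        consistency = max(fp, 1.0 - fp)
        if consistency < config.direction_consistency:
            continue  # no coherent direction: dropped as inconsistent
        sig_genes.append(g)
        directions[g] = "up" if fp >= 0.5 else "down"
        frequencies[g] = float(f)
    table["selected"] = table.index.isin(sig_genes)
    return AgingSignature(
        genes=sig_genes, directions=directions, frequencies=frequencies, table=table
    )


def single_split_significant(collection: MetaCollection, config: ResampleConfig) -> list:
    """Significant genes from one pooled split (no resampling ensemble).

    The naive comparator to the resampled signature: a single random draw of
    the configured fraction of datasets, one Bonferroni-corrected test per
    gene.  Used to demonstrate why the meta-analysis resamples.
    """
    X = collection.pooled_values().to_numpy(float)
    md = collection.pooled_metadata()
    u = md["rescaled_age"].to_numpy(float)
    labels = md["dataset_id"].to_numpy()
    units = np.unique(labels)
    rng = rng_from(config.seed, 51)
    chosen = rng.choice(units, size=max(1, int(round(config.fraction * len(units)))), replace=False)
    mask = np.isin(labels, chosen)
    r, p = association_matrix(X[:, mask], u[mask], test=config.test)
    sig = p < bonferroni_level(config.level, len(collection.gene_ids))
    return [g for g, s in zip(collection.gene_ids, sig) if s]


def enrichment_auc(ranking: list, gene_set) -> EnrichmentResult:
    """Mann-Whitney enrichment of a gene set in a significance ranking.

    ``ranking`` orders the whole gene universe from most to least significant.
    AUC = U/(n1*n2) is the probability that a set gene outranks a non-set
    gene; the standard error and the two-sided p use the normal approximation
    of the U statistic.
    """
    gene_set = set(gene_set)
    universe = list(ranking)
    if len(set(universe)) != len(universe):
        raise ValueError("ranking contains duplicates")
    if not gene_set.issubset(universe):
        raise ValueError("gene_set must be a subset of the ranking universe")
    n1 = len(gene_set)
    n2 = len(universe) - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("gene_set must be non-empty and a strict subset")
    # rank 1 = most significant; count set-vs-nonset wins
    in_set = np.array([g in gene_set for g in universe])
    # number of non-set genes ranked below each set gene
    nonset_cum = np.cumsum(~in_set)
    wins = np.sum(n2 - nonset_cum[in_set])
    auc = wins / (n1 * n2)
    se = np.sqrt((n1 + n2 + 1) / (12.0 * n1 * n2))
    zstat = (auc - 0.5) / se
    p = 2.0 * stats.norm.sf(abs(zstat))
    return EnrichmentResult(auc=float(auc), se=float(se), p=float(p))


def write_signature(signature: AgingSignature, path) -> None:
    pd.DataFrame(
        {
            "gene_id": signature.genes,
            "direction": [signature.directions[g] for g in signature.genes],
            "frequency": [signature.frequencies[g] for g in signature.genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_signature(path) -> AgingSignature:
    df = pd.read_csv(path, sep="\t")
    return AgingSignature(
        genes=list(df["gene_id"]),
        directions=dict(zip(df["gene_id"], df["direction"])),
        frequencies=dict(zip(df["gene_id"], df["frequency"])),
        table=None,
    )
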