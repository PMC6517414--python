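"""Expression I/O and the normalization chain.

Pipeline for RNA-seq count matrices: drop genes with any zero count,
upper-quartile scaling, RPKM conversion.  Cross-platform meta-collections are
normalized per sample with the YuGene cumulative-proportion transform, which
is invariant to per-sample scaling and therefore comparable across platforms.

The genes x samples matrix lives in an :class:`ExpressionStudy` together with
per-sample metadata (age, group, group mean lifespan, dataset id); a
:class:`MetaCollection` is a list of studies sharing a gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gmean

__all__ = [
    "ExpressionStudy",
    "MetaCollection",
    "filter_zero_genes",
    "upper_quartile_normalize",
    "rpkm",
    "yugene",
    "write_study",
    "read_study",
]

METADATA_COLUMNS = ["age_days", "group", "group_mean_lifespan_days", "dataset_id"]


@dataclass
class ExpressionStudy:
    """Genes x samples expression matrix with per-sample metadata.

    ``values``: DataFrame indexed by gene id, columns = sample ids.
    ``metadata``: DataFrame indexed by sample id with columns ``age_days``,
    ``group``, ``group_mean_lifespan_days``, ``dataset_id``.
    ``value_kind``: 'counts', 'normalized' or 'yugene'.
    ``truth``: optional ground-truth channel written by the synthetic
    generator (true z per sample, loading support, cohort alpha).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    value_kind: str = "normalized"
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if list(self.values.columns) != list(self.metadata.index):
            raise ValueError("metadata index must match sample columns")
        arr = self.values.to_numpy()
        if self.value_kind == "counts":
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be non-negative integers")
        elif self.value_kind == "yugene":
            if (arr < 0).any() or (arr > 1).any():
                raise ValueError("yugene values must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def rescaled_age(self) -> pd.Series:
        """Age divided by the group mean lifespan, per sample."""
        return self.metadata["age_days"] / self.metadata["group_mean_lifespan_days"]


@dataclass
class MetaCollection:
    """A list of expression studies over a common gene universe."""

    studies: list

    def __post_init__(self) -> None:
        if len(self.studies) == 0:
            raise ValueError("empty collection")
        genes = list(self.studies[0].values.index)
        for s in self.studies[1:]:
            if list(s.values.index) != genes:
                raise ValueError("all studies must share the same gene universe")

    @property
    def gene_ids(self) -> pd.Index:
        return self.studies[0].values.index

    def pooled_values(self) -> pd.DataFrame:
        return pd.concat([s.values for s in self.studies], axis=1)

    def pooled_metadata(self) -> pd.DataFrame:
        md = pd.concat([s.metadata for s in self.studies], axis=0)
        md = md.copy()
        md["rescaled_age"] = md["age_days"] / md["group_mean_lifespan_days"]
        return md

    def pooled_truth_z(self) -> np.ndarray | None:
        if any("z" not in s.truth for s in self.studies):
            return None
        return np.concatenate([np.asarray(s.truth["z"], float) for s in self.studies])

    def map(self, fn) -> "MetaCollection":
        return MetaCollection([fn(s) for s in self.studies])


def filter_zero_genes(study: ExpressionStudy) -> ExpressionStudy:
    """Drop low-expressed genes having at least one zero count in any sample."""
    if study.value_kind != "counts":
        raise ValueError("zero-count filter applies to raw counts")
    keep = (study.values > 0).all(axis=1)
    if keep.sum() == 0:
        raise ValueError(
            "no genes survive the zero-count filter: every gene has a zero "
            f"count in at least one of {study.n_samples} samples"
        )
    return replace(study, values=study.values.loc[keep])


def upper_quartile_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Scale each sample by its 75th percentile of nonzero counts.

    The per-sample quartiles are referenced to their geometric mean across
    samples, so relative sample scalings are removed while the overall level
    is preserved.
    """
    if study.value_kind != "counts":
        raise ValueError("upper-quartile normalization applies to raw counts")
    arr = study.values.to_numpy(float)
    q = np.empty(arr.shape[1])
    for j in range(arr.shape[1]):
        nz = arr[:, j][arr[:, j] > 0]
        if nz.size == 0:
            raise ValueError(f"sample {study.values.columns[j]!r} has all-zero counts")
        q[j] = np.percentile(nz, 75)
    scaled = arr / (q / gmean(q))
    return replace(
        study,
        values=pd.DataFrame(scaled, index=study.values.index, columns=study.values.columns),
        value_kind="normalized",
    )


def rpkm(study: ExpressionStudy, gene_lengths: pd.Series) -> ExpressionStudy:
    """Reads per kilobase per million mapped reads.

    RPKM = count / ((length/1e3) * (library size/1e6)); library size is the
    per-sample column total, so uniformly rescaling a sample leaves its RPKM
    values unchanged.
    """
    missing = study.values.index.difference(gene_lengths.index)
    if len(missing) > 0:
        raise ValueError(f"missing gene lengths for: {list(missing[:10])}")
    lengths = gene_lengths.loc[study.values.index].to_numpy(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    arr = study.values.to_numpy(float)
    lib = arr.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("each sample must have positive total counts")
    out = arr / (lengths[:, None] / 1e3) / (lib[None, :] / 1e6)
    return replace(
        study,
        values=pd.DataFrame(out, index=study.values.index, columns=study.values.columns),
        value_kind="normalized",
    )


def _yugene_column(v: np.ndarray) -> np.ndarray:
    tot = v.sum()
    order = np.argsort(-v, kind="stable")
    cum = np.cumsum(v[order])
    sc = np.clip(1.0 - cum / tot, 0.0, 1.0)  # guard the last entry against fp dust
    scores = np.empty_like(sc)
    scores[order] = sc
    # tied values share the mean score of their block
    uniq, inv = np.unique(v, return_inverse=True)
    if len(uniq) < len(v):
        sums = np.bincount(inv, weights=scores)
        counts = np.bincount(inv)
        scores = (sums / counts)[inv]
    return scores


def yugene(study: ExpressionStudy) -> ExpressionStudy:
    """YuGene cumulative-proportion transform, per sample.

    Genes are sorted by decreasing value; a gene's score is one minus the
    inclusive cumulative sum through that gene divided by the sample total.
    Scores lie in [0, 1), preserve ranks, and are invariant to multiplying a
    sample by any positive constant; ties share their block's mean score.
    """
    arr = study.values.to_numpy(float)
    if (arr < 0).any():
        raise ValueError("yugene requires non-negative values")
    if (arr.sum(axis=0) <= 0).any():
        raise ValueError("each sample must have a positive total")
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[:, j] = _yugene_column(arr[:, j])
    return replace(
        study,
        values=pd.DataFrame(out, index=study.values.index, columns=study.values.columns),
        value_kind="yugene",
    )


def write_study(study: ExpressionStudy, prefix) -> None:
    """Write values to ``<prefix>_expression.tsv`` (gene ids in the first
    column) and metadata to ``<prefix>_samples.tsv``."""
    prefix = Path(prefix)
    study.values.rename_axis("gene_id").to_csv(
        prefix.with_name(prefix.name + "_expression.tsv"), sep="\t"
    )
    study.metadata.rename_axis("sample_id").to_csv(
        prefix.with_name(prefix.name + "_samples.tsv"), sep="\t"
    )


def read_study(prefix, value_kind: str = "normalized") -> ExpressionStudy:
    prefix = Path(prefix)
    values = pd.read_csv(
        prefix.with_name(prefix.name + "_expression.tsv"), sep="\t", index_col=0
    )
    metadata = pd.read_csv(
        prefix.with_name(prefix.name + "_samples.tsv"), sep="\t", index_col=0
    )
    metadata.index = metadata.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionStudy(values=values, metadata=metadata, value_kind=value_kind)
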