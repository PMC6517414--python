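#!/usr/bin/env python
"""Meta-analysis: the resampled transcriptomic signature of aging.

Generates the default batch-dominated meta-collection (20 datasets, 10x
lifespan range), YuGene-normalizes it, and extracts the aging signature by
exhaustive random resampling of datasets with Bonferroni-corrected per-gene
tests and frequency thresholding.  Judged against the generator's truth
channel; a congruence check then asks whether the signature from one half of
the datasets is enriched among the most age-associated genes of the other
half (Mann-Whitney AUC).

Writes results/signature/{signature.tsv,frequency_table.tsv} and a summary.
"""

import sys
from pathlib import Path

import numpy as np

from critaging._rng import child_seeds
from critaging.normalize import MetaCollection, yugene
from critaging.signature import (
    ResampleConfig,
    association_matrix,
    enrichment_auc,
    resample_signature,
    write_signature,
)
from critaging.synthetic_data import (
    FactorModelParams,
    MetaCollectionSpec,
    generate_meta_collection,
    variance_explained,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/signature")
OUT.mkdir(parents=True, exist_ok=True)
seeds = child_seeds(SEED + 1, 3)

factor = FactorModelParams.random(G=500, seed=seeds[0])
collection = generate_meta_collection(
    MetaCollectionSpec(n_datasets=20, seed=seeds[1]), factor
).map(yugene)
frac = variance_explained(collection)
print(f"collection: {sum(s.n_samples for s in collection.studies)} samples, "
      f"20 datasets; variance by dataset {frac['eta2_dataset']:.3f} vs by age "
      f"{frac['r2_age']:.3f} (batch-dominated)")

signature = resample_signature(collection, ResampleConfig(B=200, seed=seeds[2]))
selected = np.isin(collection.gene_ids, signature.genes)
support = factor.support
sens = (selected & support).sum() / support.sum()
fpr = (selected & ~support).sum() / (~support).sum()
n_up = sum(1 for g in signature.genes if signature.directions[g] == "up")
print(f"signature: {len(signature)} genes ({n_up} up, {len(signature)-n_up} down); "
      f"sensitivity {sens:.3f}, false-positive rate {fpr:.4f} vs truth channel")

write_signature(signature, OUT / "signature.tsv")
signature.table.to_csv(OUT / "frequency_table.tsv", sep="\t")

# congruence: is the half-A signature enriched among half-B's top genes?
half_a = MetaCollection(collection.studies[:10])
half_b = MetaCollection(collection.studies[10:])
sig_a = resample_signature(half_a, ResampleConfig(B=100, seed=seeds[2] + 1))
Xb = half_b.pooled_values().to_numpy()
ub = half_b.pooled_metadata()["rescaled_age"].to_numpy()
_, p_b = association_matrix(Xb, ub)
ranking = [g for _, g in sorted(zip(p_b, collection.gene_ids))]
if 0 < len(sig_a) < len(ranking):
    res = enrichment_auc(ranking, sig_a.genes)
    print(f"congruence across halves: AUC = {res.auc:.3f} +- {res.se:.3f} "
          f"(p = {res.p:.2e})")
print(f"wrote {OUT}/signature.tsv and frequency_table.tsv")
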