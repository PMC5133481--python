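"""Simulate a family-based imputation study.

Generates pedigrees, founder haplotypes with ancestral-mosaic LD, gene
drops them with recombination, and splits the result into a sparse GWAS
scaffold and a dense sequence panel plus a drifted cosmopolitan
reference.
"""

import numpy as np

from pedimpute import SimConfig, simulate_study

cfg = SimConfig(n_families=8, n_sequence_variants=600, n_gwas_variants=80,
                n_reference=50, seed=42)
study = simulate_study(cfg)

sizes = sorted(len(p) for p in study.pedigrees)
print(f"{len(study.pedigrees)} families, sizes {sizes}")
print(f"truth panel: {study.truth.n_haplotypes} haplotypes x "
      f"{study.truth.n_variants} variants")
print(f"GWAS scaffold: {study.gwas.n_individuals} individuals x "
      f"{study.gwas.n_variants} variants")
print(f"sequence panel: {study.sequence.n_individuals} individuals x "
      f"{study.sequence.n_variants} variants")
print(f"cosmopolitan reference: {study.reference.n_haplotypes} haplotypes")

p = study.truth.genotypes().calls.mean(axis=0) / 2
maf = np.minimum(p, 1 - p)
for lo, hi in [(0, 0.01), (0.01, 0.05), (0.05, 0.5)]:
    print(f"variants with MAF in ({lo}, {hi}]: {((maf > lo) & (maf <= hi)).sum()}")
print("the MAF spectrum places most mass on rare variants, as in a")
print("sequenced family study; missing calls were injected at the QC-")
print(f"relevant rate (observed {np.mean(study.sequence.calls == -1):.3f}).")
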