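"""Family imputation through inferred transmission segments.

Builds the working family subset around a masked individual, infers
which parental haplotype they inherited along the region from scaffold
markers, and copies relatives' dense genotypes through the segments.
"""

import numpy as np

from pedimpute import (
    SimConfig,
    impute_family,
    infer_transmission,
    select_family_subset,
    simulate_study,
)

study = simulate_study(SimConfig(n_families=6, n_sequence_variants=500,
                                 n_gwas_variants=70, n_reference=20, seed=7))

# pick a masked individual with genotyped parents so the paternal
# meiosis below is actually inferable
masked = next(
    i for i in study.both_panel_ids()
    if study.pedigree_of(i).parents_of(i) is not None
)
ped = study.pedigree_of(masked)
subset = select_family_subset(ped, masked)
print(f"masked {masked} in family {ped.family_id} (size {len(ped)}); "
      f"subset = {list(subset.members)}")

scaffold = study.gwas.subset(
    [i for i in subset.members if study.gwas.has_individual(i)], None
)
segs = infer_transmission(subset, scaffold, study.gmap, study.truth, ped)
seg = segs[(masked, 0)]
ivals = seg.intervals()
print(f"paternal meiosis of {masked}: {len(ivals)} segments, "
      f"mean confidence {np.mean([w for *_, w in ivals]):.3f}")

dense = study.sequence.subset(
    [i for i in study.sequence.individuals if i != masked], None
)
gp = impute_family(subset, dense, segs, masked, ped)
truth = study.truth.haplotype(masked, 0) + study.truth.haplotype(masked, 1)
col = {v.vid: j for j, v in enumerate(study.sequence.variants)}
dosages = gp.dosages()[0]
t = np.array([truth[col[v.vid]] for v in gp.variants])
r = np.corrcoef(t, dosages)[0, 1]
print(f"dosage correlation with hidden truth over {len(dosages)} dense "
      f"variants: {r:.3f}")
print("segments carry dense genotypes from sequenced relatives to the")
print("masked individual; accuracy depends on how many relatives are")
print("sequenced and how well the scaffold resolves each meiosis.")
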