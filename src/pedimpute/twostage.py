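"""The combined two-stage imputation method.

Stage 1 imputes the target from a phased reference panel with the
population haplotype-copying HMM.  Confident best-guess genotypes
(posterior strictly above ``prob_threshold``) at sufficiently common
variants (MAF strictly above ``maf_cutoff``) are merged into the GWAS
scaffold — observed calls win at overlaps, and variants that would
introduce a Mendelian inconsistency in the family subset are dropped.
Stage 2 reruns family-based imputation on the augmented scaffold, where
the accepted calls act as direct observations on the target.  Variants
the filter excludes are untouched by stage 1, so their posteriors are
identical to a family-only run by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    GenotypeProbabilities,
    HaplotypePanel,
    Pedigree,
    Variant,
)
from . import famimpute, popimpute
from .qc import VariantStats

__all__ = [
    "CombineConfig",
    "best_guess",
    "best_guess_calls",
    "filter_by_maf",
    "merge_scaffold",
    "run_two_stage",
]


@dataclass(frozen=True)
class CombineConfig:
    """MAF inclusion cutoff (0.01, 0.05, or None for no filter) and the
    posterior floor for accepting a best-guess genotype (strict)."""

    maf_cutoff: float | None = 0.01
    prob_threshold: float = 0.9
    maf_source: str = "local"  # or "reference": which panel's MAF gates entry

    def __post_init__(self):
        if not (1 / 3 < self.prob_threshold <= 1):
            raise ValueError("prob_threshold must be in (1/3, 1]")
        if self.maf_cutoff is not None and not 0 <= self.maf_cutoff <= 0.5:
            raise ValueError("maf_cutoff must be in [0, 0.5] or None")
        if self.maf_source not in ("local", "reference"):
            raise ValueError("maf_source must be 'local' or 'reference'")


def best_guess(p, threshold: float = 0.9) -> int:
    """Argmax genotype iff its posterior is *strictly* above the
    threshold, else ``MISSING``; ties never qualify."""
    p = np.asarray(p, dtype=float)
    if p.shape != (3,) or np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("best_guess needs a normalised genotype 3-vector")
    top = int(p.argmax())
    if p[top] > threshold and np.sum(p == p[top]) == 1:
        return top
    return MISSING


def best_guess_calls(probs: np.ndarray, threshold: float = 0.9) -> np.ndarray:
    """Vectorised ``best_guess`` over a (..., 3) posterior array."""
    probs = np.asarray(probs, dtype=float)
    top = probs.argmax(axis=-1)
    topval = probs.max(axis=-1)
    unique = (probs == topval[..., None]).sum(axis=-1) == 1
    out = np.where((topval > threshold) & unique, top, MISSING)
    return out.astype(np.int8)


def filter_by_maf(
    candidate_vids: list[str],
    cfg: CombineConfig,
    stats: dict[str, VariantStats] | list[VariantStats],
) -> set[str]:
    """Candidate variants whose MAF is strictly above the cutoff
    (all of them when the cutoff is None)."""
    if not isinstance(stats, dict):
        stats = {s.vid: s for s in stats}
    out: set[str] = set()
    for vid in candidate_vids:
        if vid not in stats:
            raise KeyError(f"no MAF statistics for candidate variant {vid!r}")
        if cfg.maf_cutoff is None or stats[vid].maf > cfg.maf_cutoff:
            out.add(vid)
    return out


def merge_scaffold(
    gwas: GenotypeMatrix,
    accepted: dict[str, tuple[Variant, dict[str, int]]],
    mendelian_flags: set[str] = frozenset(),
) -> GenotypeMatrix:
    """Union of the GWAS scaffold and accepted imputed calls.

    ``accepted`` maps variant id to ``(Variant, {iid: call})``.  At
    overlapping variants the observed GWAS call wins; accepted variants
    flagged Mendelian-inconsistent are dropped; allele-code disagreement
    at a shared position is an error.
    """
    gwas_by_vid = {v.vid: v for v in gwas.variants}
    extra: list[tuple[Variant, dict[str, int]]] = []
    for vid, (var, calls) in accepted.items():
        if vid in mendelian_flags:
            continue
        if vid in gwas_by_vid:
            g = gwas_by_vid[vid]
            if (g.pos, g.ref, g.alt) != (var.pos, var.ref, var.alt):
                raise ValueError(
                    f"allele-code disagreement at {vid!r}: "
                    f"scaffold={g!r} imputed={var!r}"
                )
            continue  # observed beats imputed; nothing to add
        if any(v.pos == var.pos for v in gwas.variants):
            clash = next(v for v in gwas.variants if v.pos == var.pos)
            raise ValueError(
                f"allele-code disagreement at position {var.pos}: "
                f"scaffold={clash!r} imputed={var!r}"
            )
        extra.append((var, calls))
    variants = list(gwas.variants) + [v for v, _ in extra]
    order = np.argsort([v.pos for v in variants], kind="stable")
    calls_mat = np.full((gwas.n_individuals, len(variants)), MISSING, dtype=np.int8)
    calls_mat[:, : gwas.n_variants] = gwas.calls
    for j, (_, calls) in enumerate(extra, start=gwas.n_variants):
        for iid, c in calls.items():
            if iid in gwas.individuals:
                calls_mat[gwas.individuals.index(iid), j] = c
    return GenotypeMatrix(
        gwas.individuals,
        [variants[j] for j in order],
        calls_mat[:, order],
    )


class StageError(RuntimeError):
    """Failure annotated with the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage: {stage}] {cause}")
        self.stage = stage
        self.__cause__ = cause


def run_two_stage(
    masked: str,
    gwas: GenotypeMatrix,
    dense: GenotypeMatrix,
    reference: HaplotypePanel,
    ped: Pedigree,
    cfg: CombineConfig,
    gmap: GeneticMap,
    *,
    hmm: popimpute.HmmParams = popimpute.HmmParams(),
    phase: HaplotypePanel | None = None,
    fam_mode: str = "agnostic",
    local_stats: dict[str, VariantStats] | None = None,
) -> GenotypeProbabilities:
    """Population imputation -> best-guess filter -> scaffold merge ->
    family imputation, for one masked individual.

    ``reference`` must cover the dense grid; ``dense`` must not contain
    the masked individual's row.  Returns family-stage posteriors at all
    dense variants, with a per-variant ``provenance`` array on the
    result ('combined' where an accepted stage-1 call was the final
    evidence, 'family' elsewhere).
    """
    if dense.has_individual(masked):
        raise ValueError("dense panel must exclude the masked individual")
    try:
        scaffold_m = gwas.subset([masked], None)
        pop = popimpute.impute_population(
            scaffold_m, reference, gmap, hmm, phase=phase, individuals=[masked]
        )
    except Exception as e:  # noqa: BLE001 - stage labelling is the contract
        raise StageError("popimpute", e)

    try:
        calls = best_guess_calls(pop.probs[0], cfg.prob_threshold)
        dense_vids = {v.vid for v in dense.variants}
        gwas_vids = {v.vid for v in gwas.variants}
        candidates = [
            v.vid
            for j, v in enumerate(pop.variants)
            if calls[j] != MISSING and v.vid in dense_vids and v.vid not in gwas_vids
        ]
        if cfg.maf_source == "reference":
            p = reference.allele_freq()
            stats = {
                v.vid: VariantStats(v.vid, 1.0, float(min(p[j], 1 - p[j])), True)
                for j, v in enumerate(reference.variants)
            }
        elif local_stats is not None:
            stats = local_stats
        else:
            # MAF from the local sequenced panel plus the masked
            # individual's own accepted best-guess call
            dcol = {v.vid: j for j, v in enumerate(dense.variants)}
            pcol = {v.vid: j for j, v in enumerate(pop.variants)}
            stats = {}
            for vid in candidates:
                col_calls = dense.calls[:, dcol[vid]]
                obs = col_calls[col_calls != MISSING]
                n_alt = int(obs.sum()) + int(calls[pcol[vid]])
                n_all = 2 * (len(obs) + 1)
                p = n_alt / n_all
                stats[vid] = VariantStats(vid, 1.0, float(min(p, 1 - p)), 0 < p < 1)
        accepted_vids = filter_by_maf(candidates, cfg, stats)
    except Exception as e:
        raise StageError("filter", e)

    try:
        col = {v.vid: j for j, v in enumerate(pop.variants)}
        accepted = {
            vid: (pop.variants[col[vid]], {masked: int(calls[col[vid]])})
            for vid in accepted_vids
        }
        subset = famimpute.select_family_subset(ped, masked)
        merged = merge_scaffold(gwas.subset([masked], None), accepted)
        # Mendelian screen of accepted calls against the family's dense data
        fam_ids = [i for i in subset.members if dense.has_individual(i)]
        screen_ids = fam_ids + [masked]
        screen_vars = [v for v in merged.variants if v.vid not in gwas_vids]
        if screen_vars and fam_ids:
            dcol = {v.vid: j for j, v in enumerate(dense.variants)}
            rows = []
            for iid in fam_ids:
                rows.append([dense.row(iid)[dcol[v.vid]] for v in screen_vars])
            mcol = {v.vid: j for j, v in enumerate(merged.variants)}
            rows.append([merged.row(masked)[mcol[v.vid]] for v in screen_vars])
            screen = GenotypeMatrix(
                screen_ids, screen_vars, np.array(rows, dtype=np.int8)
            )
            flags = famimpute.detect_mendelian_errors(screen, ped)
        else:
            flags = set()
        if flags:
            merged = merge_scaffold(gwas.subset([masked], None), accepted, flags)
    except Exception as e:
        raise StageError("merge", e)

    try:
        segs = famimpute.infer_transmission(
            subset, gwas.subset([i for i in subset.members if gwas.has_individual(i)], None),
            gmap, phase, ped,
        )
        out = famimpute.impute_family(
            subset,
            dense,
            segs,
            masked,
            ped,
            mode=fam_mode,
            phase=phase,
            observed_calls=merged,
        )
    except Exception as e:
        raise StageError("famimpute", e)

    prov = np.array(
        ["combined" if v.vid in accepted_vids and v.vid not in flags else "family"
         for v in out.variants]
    )
    out.provenance = prov  # type: ignore[attr-defined]
    return out
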