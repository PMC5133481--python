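"""Experiment orchestration: QC, arms, masking loop, summaries, provenance.

An :class:`Experiment` takes one :class:`ExperimentConfig`, simulates the
study, applies QC, builds the configured method arms (population-only,
family-only, combined per MAF cutoff, and an oracle for calibration
checks) and runs the leave-one-out masking loop.  Everything is
deterministic in the single master seed: each stage draws from its own
seed-derived stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import famimpute, formats, popimpute, twostage
from ._rng import stage_rng
from .core import GenotypeMatrix, GenotypeProbabilities, HaplotypePanel
from .evalmetrics import (
    DEFAULT_MAF_BINS,
    MaskingPlan,
    run_masking_experiment,
    summarize_by_maf,
)
from .pedsim import MafSpectrum, SimConfig, StudyData, simulate_study
from .popimpute import HmmParams
from .qc import filter_missingness
from .twostage import CombineConfig

log = logging.getLogger("pedimpute")

__all__ = ["ExperimentConfig", "Experiment", "cmd_simulate", "cmd_run"]


@dataclass
class ExperimentConfig:
    """Everything one reproducible experiment needs."""

    sim: SimConfig = field(default_factory=SimConfig)
    gwas_variant_missing: float = 0.05
    gwas_individual_missing: float = 0.05
    seq_variant_missing: float = 0.10
    seq_individual_missing: float = 0.05
    hmm: HmmParams = field(default_factory=HmmParams)
    combine_cutoffs: tuple[float | None, ...] = (0.01, 0.05)
    prob_threshold: float = 0.9
    arms: tuple[str, ...] = ("population", "family", "combined")
    include_oracle: bool = False
    fam_mode: str = "agnostic"
    n_masked: int = 20

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["maf_spectrum"] = [list(b) for b in self.sim.maf_spectrum.bins]
        d["combine_cutoffs"] = [
            "none" if c is None else c for c in self.combine_cutoffs
        ]
        d["arms"] = list(self.arms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        sim = dict(d.pop("sim", {}))
        if "maf_spectrum" in sim:
            sim["maf_spectrum"] = MafSpectrum(
                tuple(tuple(b) for b in sim.pop("maf_spectrum"))
            )
        if "family_size_counts" in sim:
            sim["family_size_counts"] = {
                int(k): int(v) for k, v in sim["family_size_counts"].items()
            }
        hmm = HmmParams(**d.pop("hmm", {}))
        cut = tuple(
            None if c in ("none", None) else float(c)
            for c in d.pop("combine_cutoffs", (0.01, 0.05))
        )
        arms = tuple(d.pop("arms", ("population", "family", "combined")))
        return cls(sim=SimConfig(**sim), hmm=hmm, combine_cutoffs=cut,
                   arms=arms, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


class Experiment:
    """A prepared experiment: simulated study, QC'd panels, method arms."""

    def __init__(self, cfg: ExperimentConfig, study: StudyData | None = None):
        self.cfg = cfg
        self.study = study if study is not None else simulate_study(cfg.sim)
        self._prepare()

    def _prepare(self) -> None:
        cfg, study = self.cfg, self.study
        self.gwas_qc, self.gwas_report = filter_missingness(
            study.gwas, cfg.gwas_variant_missing, cfg.gwas_individual_missing
        )
        self.seq_qc, self.seq_report = filter_missingness(
            study.sequence, cfg.seq_variant_missing, cfg.seq_individual_missing
        )
        log.info(
            "QC: GWAS %d->%d variants, %d->%d individuals; "
            "sequence %d->%d variants, %d->%d individuals",
            study.gwas.n_variants, self.gwas_qc.n_variants,
            study.gwas.n_individuals, self.gwas_qc.n_individuals,
            study.sequence.n_variants, self.seq_qc.n_variants,
            study.sequence.n_individuals, self.seq_qc.n_individuals,
        )
        # dense working grid = QC'd sequence variants; scaffold restricted
        # to QC survivors present on that grid (GWAS is nested by design)
        seq_vids = {v.vid for v in self.seq_qc.variants}
        keep = [
            j for j, v in enumerate(self.gwas_qc.variants) if v.vid in seq_vids
        ]
        self.scaffold = self.gwas_qc.subset(None, keep)
        truth_col = {v.vid: j for j, v in enumerate(study.truth.variants)}
        self.dense_idx = [truth_col[v.vid] for v in self.seq_qc.variants]
        self.truth_dense = study.truth.subset_variants(self.dense_idx)
        self.ref_dense = study.reference.subset_variants(self.dense_idx)
        self.scaffold_vids = {v.vid for v in self.scaffold.variants}
        # scoring targets: imputed (non-scaffold) dense variants
        self.target_idx = [
            j for j, v in enumerate(self.seq_qc.variants)
            if v.vid not in self.scaffold_vids
        ]
        self.target_variants = [self.seq_qc.variants[j] for j in self.target_idx]
        truth_geno = self.truth_dense.genotypes()
        p = truth_geno.calls.mean(axis=0) / 2.0
        maf_all = np.minimum(p, 1 - p)
        self.true_maf = maf_all[self.target_idx]
        self._truth_geno = truth_geno
        self.eligible = [
            iid for iid in study.truth.individual_ids()
            if study.assignment[iid] == "both"
            and self.scaffold.has_individual(iid)
            and self.seq_qc.has_individual(iid)
        ]

    # -- per-arm method closures ------------------------------------------
    def _local_reference(self, masked: str) -> HaplotypePanel:
        """Phased dense panel: sequenced individuals (minus the masked
        one) plus the cosmopolitan reference."""
        ids = [i for i in self.seq_qc.individuals if i != masked]
        local = self.truth_dense.for_individuals(ids)
        haps = np.vstack([local.haps, self.ref_dense.haps])
        carriers = list(local.carriers) + list(self.ref_dense.carriers)
        return HaplotypePanel(local.variants, haps, carriers)

    def _masked_dense(self, masked: str) -> GenotypeMatrix:
        ids = [i for i in self.seq_qc.individuals if i != masked]
        return self.seq_qc.subset(ids, None)

    def _family_inputs(self, masked: str):
        ped = self.study.pedigree_of(masked)
        subset = famimpute.select_family_subset(ped, masked)
        sub_scaffold = self.scaffold.subset(
            [i for i in subset.members if self.scaffold.has_individual(i)], None
        )
        flags = famimpute.detect_mendelian_errors(sub_scaffold, ped)
        if flags:
            keep = [
                j for j, v in enumerate(sub_scaffold.variants)
                if v.vid not in flags
            ]
            sub_scaffold = sub_scaffold.subset(None, keep)
        return ped, subset, sub_scaffold

    def method_oracle(self, masked: str) -> GenotypeProbabilities:
        g = self._truth_geno.row(masked)
        probs = np.zeros((1, len(g), 3))
        probs[0, np.arange(len(g)), g] = 1.0
        return GenotypeProbabilities([masked], self.seq_qc.variants, probs)

    def method_population(self, masked: str) -> GenotypeProbabilities:
        ref = self._local_reference(masked)
        scaffold_m = self.scaffold.subset([masked], None)
        return popimpute.impute_population(
            scaffold_m, ref, self.study.gmap, self.cfg.hmm,
            phase=self.study.truth, individuals=[masked],
        )

    def method_family(self, masked: str) -> GenotypeProbabilities:
        ped, subset, sub_scaffold = self._family_inputs(masked)
        segs = famimpute.infer_transmission(
            subset, sub_scaffold, self.study.gmap, self.study.truth, ped
        )
        return famimpute.impute_family(
            subset, self._masked_dense(masked), segs, masked, ped,
            mode=self.cfg.fam_mode, phase=self.study.truth,
            observed_calls=sub_scaffold.subset([masked], None)
            if sub_scaffold.has_individual(masked) else None,
        )

    def method_combined(self, cutoff: float | None):
        ccfg = CombineConfig(maf_cutoff=cutoff,
                             prob_threshold=self.cfg.prob_threshold)

        def run(masked: str) -> GenotypeProbabilities:
            ped, subset, sub_scaffold = self._family_inputs(masked)
            return twostage.run_two_stage(
                masked,
                sub_scaffold,
                self._masked_dense(masked),
                self._local_reference(masked),
                ped,
                ccfg,
                self.study.gmap,
                hmm=self.cfg.hmm,
                phase=self.study.truth,
                fam_mode=self.cfg.fam_mode,
            )

        return run

    def methods(self) -> dict:
        out = {}
        for arm in self.cfg.arms:
            if arm == "population":
                out["population"] = self.method_population
            elif arm == "family":
                out["family"] = self.method_family
            elif arm == "combined":
                for c in self.cfg.combine_cutoffs:
                    name = f"combined({'none' if c is None else c})"
                    out[name] = self.method_combined(c)
            else:
                raise ValueError(f"unknown arm {arm!r}")
        if self.cfg.include_oracle:
            out["oracle"] = self.method_oracle
        return out

    # -- the experiment ----------------------------------------------------
    def masking_plan(self, n: int | None = None) -> MaskingPlan:
        n = self.cfg.n_masked if n is None else n
        seed = int(stage_rng(self.cfg.sim.seed, "maskplan").integers(2**31 - 1))
        return MaskingPlan.random(sorted(self.eligible), n, seed)

    def truth_for(self, plan: MaskingPlan) -> dict[str, np.ndarray]:
        return {
            iid: self._truth_geno.row(iid)[self.target_idx] for iid in plan.ids
        }

    def run(self, plan: MaskingPlan | None = None):
        plan = plan if plan is not None else self.masking_plan()
        methods = self.methods()

        def restrict(fn):
            def inner(iid: str) -> GenotypeProbabilities:
                gp = fn(iid)
                col = {v.vid: j for j, v in enumerate(gp.variants)}
                idx = [col[v.vid] for v in self.target_variants if v.vid in col]
                vs = [gp.variants[j] for j in idx]
                return GenotypeProbabilities(
                    gp.individuals, vs, gp.probs[:, idx, :]
                )
            return inner

        methods = {m: restrict(fn) for m, fn in methods.items()}
        records, frame = run_masking_experiment(
            self.truth_for(plan), self.target_variants, self.true_maf,
            methods, plan,
        )
        summary = summarize_by_maf(frame, DEFAULT_MAF_BINS)
        return ExperimentResult(self.cfg, plan, records, frame, summary)


@dataclass
class ExperimentResult:
    cfg: ExperimentConfig
    plan: MaskingPlan
    records: list
    frame: pd.DataFrame
    summary: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cfg.to_yaml(out / "config.yaml")
        self.frame.to_csv(out / "records.tsv", sep="\t", index=False)
        self.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        (out / "plan.json").write_text(
            json.dumps({"ids": list(self.plan.ids), "seed": self.plan.seed})
        )


# ---------------------------------------------------------------------------
# file-producing commands


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def cmd_simulate(cfg: ExperimentConfig, out_dir: str | Path) -> dict:
    """Simulate a study and write all artifacts plus a checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as e:
        raise OSError(f"output directory {out} is not writable: {e}") from e
    study = simulate_study(cfg.sim)
    chrom = cfg.sim.chrom
    files = {
        "truth_vcf": out / "truth.vcf",
        "gwas_vcf": out / "gwas.vcf",
        "sequence_vcf": out / "sequence.vcf",
        "reference_vcf": out / "reference.vcf",
        "fam": out / "study.fam",
        "map": out / "genetic.map",
    }
    formats.write_vcf(study.truth, files["truth_vcf"], chrom)
    formats.write_vcf(study.gwas, files["gwas_vcf"], chrom)
    formats.write_vcf(study.sequence, files["sequence_vcf"], chrom)
    formats.write_vcf(study.reference, files["reference_vcf"], chrom)
    formats.write_fam(study.pedigrees, files["fam"])
    formats.write_impute2_map(study.gmap, files["map"])
    manifest = {
        name: {"path": str(p.name), "sha256": _sha256(p)}
        for name, p in files.items()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    cfg.to_yaml(out / "config.yaml")
    return manifest


def cmd_run(cfg: ExperimentConfig, out_dir: str | Path) -> ExperimentResult:
    """Full pipeline: simulate, QC, masking loop, summaries; writes the
    results tree and returns the result object."""
    exp = Experiment(cfg)
    result = exp.run()
    result.write(out_dir)
    exp.gwas_report.to_csv(Path(out_dir) / "qc_gwas.tsv", sep="\t", index=False)
    exp.seq_report.to_csv(Path(out_dir) / "qc_sequence.tsv", sep="\t", index=False)
    return result
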