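"""Readers and writers for the interchange formats.

VCF (via pysam) for haplotype panels and genotype matrices, Impute2
GEN + SAMPLE for genotype posteriors, PLINK PED/MAP and FAM for study
panels and pedigrees, and the 3-column Impute2 genetic-map dialect.
Every writer round-trips losslessly through the matching reader; GEN
probabilities are written with 4 decimal places and renormalised (with
a warning) on read when a triplet is off by more than 0.01.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .core import (
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    GenotypeProbabilities,
    HaplotypePanel,
    Individual,
    Pedigree,
    Variant,
)

__all__ = [
    "write_vcf",
    "read_vcf_haplotypes",
    "read_vcf_genotypes",
    "write_gen",
    "read_gen",
    "write_ped_map",
    "read_ped_map",
    "write_fam",
    "read_fam",
    "write_impute2_map",
    "read_impute2_map",
]


# ---------------------------------------------------------------------------
# VCF


def _vcf_header(chrom: str, samples: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={chrom}>")
    header.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(
    data: HaplotypePanel | GenotypeMatrix, path: str | Path, chrom: str = "3"
) -> None:
    """Write a panel as VCF: phased ``|`` genotypes for haplotype
    panels, unphased ``/`` (with ``./.`` for missing) for matrices."""
    path = Path(path)
    phased = isinstance(data, HaplotypePanel)
    samples = data.individual_ids() if phased else data.individuals
    header = _vcf_header(chrom, samples)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, var in enumerate(data.variants):
            rec = vcf.new_record(
                contig=chrom, start=var.pos - 1, stop=var.pos,
                alleles=(var.ref, var.alt), id=var.vid,
            )
            for iid in samples:
                if phased:
                    gt = (int(data.haplotype(iid, 0)[j]), int(data.haplotype(iid, 1)[j]))
                    rec.samples[iid]["GT"] = gt
                    rec.samples[iid].phased = True
                else:
                    c = data.row(iid)[j]
                    if c == MISSING:
                        rec.samples[iid]["GT"] = (None, None)
                    else:
                        rec.samples[iid]["GT"] = (min(int(c), 1), max(int(c) - 1, 0))
                    rec.samples[iid].phased = False
            vcf.write(rec)


def _read_vcf(path: str | Path):
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        variants: list[Variant] = []
        rows: list[list] = []
        last = -1
        for rec in vcf:
            if rec.pos <= last:
                raise ValueError(
                    f"{path}: VCF positions not strictly increasing at {rec.pos}"
                )
            last = rec.pos
            variants.append(
                Variant(rec.id or f"{rec.chrom}:{rec.pos}", rec.pos,
                        rec.ref, rec.alts[0])
            )
            rows.append([rec.samples[s]["GT"] for s in samples])
    return samples, variants, rows


def read_vcf_haplotypes(path: str | Path) -> HaplotypePanel:
    samples, variants, rows = _read_vcf(path)
    V = len(variants)
    haps = np.zeros((2 * len(samples), V), dtype=np.int8)
    for j, gts in enumerate(rows):
        for n, gt in enumerate(gts):
            if gt[0] is None or gt[1] is None:
                raise ValueError(f"{path}: missing call in phased panel at column {j}")
            haps[2 * n, j] = gt[0]
            haps[2 * n + 1, j] = gt[1]
    carriers = [(s, k) for s in samples for k in (0, 1)]
    return HaplotypePanel(variants, haps, carriers)


def read_vcf_genotypes(path: str | Path) -> GenotypeMatrix:
    samples, variants, rows = _read_vcf(path)
    calls = np.full((len(samples), len(variants)), MISSING, dtype=np.int8)
    for j, gts in enumerate(rows):
        for n, gt in enumerate(gts):
            if gt[0] is not None and gt[1] is not None:
                calls[n, j] = gt[0] + gt[1]
    return GenotypeMatrix(samples, variants, calls)


# ---------------------------------------------------------------------------
# Impute2 GEN + SAMPLE


def write_gen(
    gp: GenotypeProbabilities, gen_path: str | Path, sample_path: str | Path,
    chrom: str = "3",
) -> None:
    with open(gen_path, "w") as fh:
        for j, var in enumerate(gp.variants):
            cols = [chrom, var.vid, str(var.pos), var.ref, var.alt]
            for n in range(gp.n_individuals):
                cols.extend(f"{p:.4f}" for p in gp.probs[n, j])
            fh.write(" ".join(cols) + "\n")
    with open(sample_path, "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for iid in gp.individuals:
            fh.write(f"{iid} {iid} 0\n")


def read_gen(
    gen_path: str | Path, sample_path: str | Path
) -> GenotypeProbabilities:
    with open(sample_path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    ids = [row[0] for row in lines[2:]]
    variants: list[Variant] = []
    probs: list[np.ndarray] = []
    with open(gen_path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            f = ln.split()
            if len(f) != 5 + 3 * len(ids):
                raise ValueError(
                    f"{gen_path}:{lineno}: expected {5 + 3 * len(ids)} fields, "
                    f"got {len(f)}"
                )
            try:
                pos = int(f[2])
                trip = np.array(f[5:], dtype=float).reshape(len(ids), 3)
            except ValueError as e:
                raise ValueError(f"{gen_path}:{lineno}: {e}") from None
            sums = trip.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 0.01):
                warnings.warn(
                    f"{gen_path}:{lineno}: probabilities renormalised "
                    "(triplet sum off by > 0.01)",
                    stacklevel=2,
                )
            trip = trip / np.where(sums == 0, 1.0, sums)[:, None]
            variants.append(Variant(f[1], pos, f[3], f[4]))
            probs.append(trip)
    return GenotypeProbabilities(ids, variants, np.stack(probs, axis=1))


# ---------------------------------------------------------------------------
# PLINK PED/MAP and FAM


def write_fam(pedigrees: Sequence[Pedigree], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ped in pedigrees:
            for ind in ped.members.values():
                fh.write(
                    f"{ped.family_id} {ind.iid} {ind.father or 0} "
                    f"{ind.mother or 0} {ind.sex} -9\n"
                )


def read_fam(path: str | Path) -> list[Pedigree]:
    fams: dict[str, list[Individual]] = {}
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            f = ln.split()
            if not f:
                continue
            if len(f) < 5:
                raise ValueError(f"{path}:{lineno}: FAM line needs >= 5 fields")
            fid, iid, pat, mat, sex = f[0], f[1], f[2], f[3], f[4]
            fams.setdefault(fid, []).append(
                Individual(
                    iid,
                    None if pat == "0" else pat,
                    None if mat == "0" else mat,
                    int(sex) if sex in ("1", "2") else 0,
                )
            )
    return [Pedigree(fid, inds) for fid, inds in fams.items()]


def write_ped_map(
    g: GenotypeMatrix,
    pedigrees: Sequence[Pedigree],
    ped_path: str | Path,
    map_path: str | Path,
    chrom: str = "3",
    gmap: GeneticMap | None = None,
) -> None:
    by_iid: dict[str, tuple[str, Individual]] = {}
    for ped in pedigrees:
        for ind in ped.members.values():
            by_iid[ind.iid] = (ped.family_id, ind)
    with open(map_path, "w") as fh:
        for var in g.variants:
            cm = float(gmap.cm_at(var.pos)) if gmap else 0.0
            fh.write(f"{chrom} {var.vid} {cm:.6f} {var.pos}\n")
    with open(ped_path, "w") as fh:
        for iid in g.individuals:
            fid, ind = by_iid.get(iid, (iid, Individual(iid)))
            cols = [fid, iid, ind.father or "0", ind.mother or "0",
                    str(ind.sex), "-9"]
            for j, var in enumerate(g.variants):
                c = g.row(iid)[j]
                if c == MISSING:
                    cols.extend(("0", "0"))
                else:
                    a = [var.ref, var.alt]
                    cols.extend((a[1 if c == 2 else 0], a[1 if c >= 1 else 0]))
            fh.write(" ".join(cols) + "\n")


def read_ped_map(
    ped_path: str | Path,
    map_path: str | Path,
    template: Sequence[Variant] | None = None,
) -> tuple[GenotypeMatrix, list[Pedigree]]:
    """Read a PED/MAP pair.

    PED files carry no ref/alt orientation; by default the first allele
    letter seen at a column becomes code 0.  Pass ``template`` (a
    variant list with ref/alt) to fix the orientation — required for a
    lossless round-trip.
    """
    variants: list[Variant] = []
    with open(map_path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            f = ln.split()
            if not f:
                continue
            if len(f) != 4:
                raise ValueError(f"{map_path}:{lineno}: MAP line needs 4 fields")
            variants.append(Variant(f[1], int(f[3])))
    ids: list[str] = []
    fams: dict[str, list[Individual]] = {}
    calls_rows: list[np.ndarray] = []
    allele_codes: list[dict[str, int] | None] = [None] * len(variants)
    raw: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            f = ln.split()
            if not f:
                continue
            if len(f) != 6 + 2 * len(variants):
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * len(variants)} "
                    f"fields, got {len(f)}"
                )
            fid, iid, pat, mat, sex = f[0], f[1], f[2], f[3], f[4]
            ids.append(iid)
            fams.setdefault(fid, []).append(
                Individual(iid, None if pat == "0" else pat,
                           None if mat == "0" else mat,
                           int(sex) if sex in ("1", "2") else 0)
            )
            raw.append(
                [(f[6 + 2 * j], f[7 + 2 * j]) for j in range(len(variants))]
            )
    # first-seen allele = ref, second = alt (codes are arbitrary in PED)
    tmpl = {v.vid: v for v in template} if template else {}
    for j in range(len(variants)):
        if variants[j].vid in tmpl:
            tv = tmpl[variants[j].vid]
            allele_codes[j] = {tv.ref: 0, tv.alt: 1}
            continue
        seen: dict[str, int] = {}
        for row in raw:
            for a in row[j]:
                if a != "0" and a not in seen:
                    seen[a] = len(seen)
        allele_codes[j] = seen
    calls = np.full((len(ids), len(variants)), MISSING, dtype=np.int8)
    for n, row in enumerate(raw):
        for j, (a, b) in enumerate(row):
            if a == "0" or b == "0":
                continue
            calls[n, j] = allele_codes[j][a] + allele_codes[j][b]  # type: ignore[index]
    # rebuild variants with observed allele letters where possible
    rebuilt = []
    for j, var in enumerate(variants):
        codes = sorted(allele_codes[j] or {}, key=allele_codes[j].get)  # type: ignore[union-attr]
        ref = codes[0] if codes else var.ref
        alt = codes[1] if len(codes) > 1 else var.alt
        rebuilt.append(Variant(var.vid, var.pos, ref, alt))
    g = GenotypeMatrix(ids, rebuilt, calls)
    # parents without their own row are treated as unknown (founder-ized)
    peds = []
    for fid, inds in fams.items():
        present = {i.iid for i in inds}
        fixed = [
            ind
            if ind.father in present and ind.mother in present
            else Individual(ind.iid, None, None, ind.sex)
            for ind in inds
        ]
        peds.append(Pedigree(fid, fixed))
    return g, peds


# ---------------------------------------------------------------------------
# Impute2 genetic map (3 columns)


def write_impute2_map(gmap: GeneticMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position COMBINED_rate(cM/Mb) Genetic_Map(cM)\n")
        for i, (bp, cm) in enumerate(zip(gmap.bp, gmap.cm)):
            if i + 1 < len(gmap.bp):
                rate = (gmap.cm[i + 1] - cm) / ((gmap.bp[i + 1] - bp) / 1e6)
            else:
                rate = 0.0
            fh.write(f"{bp} {rate:.8f} {cm:.8f}\n")


def read_impute2_map(path: str | Path) -> GeneticMap:
    bp: list[int] = []
    cm: list[float] = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            f = ln.split()
            if not f or f[0] == "position":
                continue
            if len(f) != 3:
                raise ValueError(f"{path}:{lineno}: map line needs 3 fields")
            bp.append(int(f[0]))
            cm.append(float(f[2]))
    return GeneticMap(bp, cm)
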