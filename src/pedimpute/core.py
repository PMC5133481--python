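"""Core domain containers shared by every stage of the pipeline.

The pipeline moves genotype data through three representations:

* :class:`HaplotypePanel` — phased alleles (0/1) over an ordered variant
  list, one row per haplotype.  Simulated truth and reference panels live
  here.
* :class:`GenotypeMatrix` — unphased alt-allele counts {0, 1, 2} with
  ``-1`` for missing.  Study panels (GWAS scaffold, sequence panel) live
  here.
* :class:`GenotypeProbabilities` — per-individual, per-variant posterior
  3-vectors over the genotype classes.  This is the interchange currency
  between imputation engines and the evaluation metrics.

All variant lists are position-sorted (1-based physical bp, VCF
convention) and all containers validate their invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

MISSING: int = -1

__all__ = [
    "MISSING",
    "Variant",
    "Individual",
    "Pedigree",
    "GeneticMap",
    "HaplotypePanel",
    "GenotypeMatrix",
    "GenotypeProbabilities",
]


@dataclass(frozen=True)
class Variant:
    """A biallelic site: identifier, 1-based physical position, alleles."""

    vid: str
    pos: int
    ref: str = "A"
    alt: str = "G"


def _check_positions(variants: Sequence[Variant]) -> None:
    pos = np.asarray([v.pos for v in variants])
    if len(pos) > 1 and not np.all(np.diff(pos) > 0):
        raise ValueError("variant positions must be strictly increasing")


@dataclass(frozen=True)
class Individual:
    """One pedigree member.  ``father``/``mother`` are ``None`` for founders."""

    iid: str
    father: str | None = None
    mother: str | None = None
    sex: int = 0  # 1 male, 2 female, 0 unknown


class Pedigree:
    """A single family: a directed acyclic graph of parent-child links.

    Invariants checked on construction: every non-founder has *both*
    parents present, the graph is acyclic, and any individual used as a
    father (mother) has male (female) sex where sex is recorded.
    """

    def __init__(self, family_id: str, individuals: Iterable[Individual]):
        self.family_id = family_id
        self.members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.iid in self.members:
                raise ValueError(f"duplicate individual id {ind.iid!r}")
            self.members[ind.iid] = ind
        self._validate()

    def _validate(self) -> None:
        for ind in self.members.values():
            if (ind.father is None) != (ind.mother is None):
                raise ValueError(f"{ind.iid}: non-founders need both parents")
            if ind.father is not None:
                for pid, want_sex in ((ind.father, 1), (ind.mother, 2)):
                    if pid not in self.members:
                        raise ValueError(f"{ind.iid}: parent {pid!r} absent")
                    psex = self.members[pid].sex
                    if psex not in (0, want_sex):
                        raise ValueError(
                            f"{ind.iid}: parent {pid!r} has inconsistent sex"
                        )
        # acyclicity via topological ordering
        self.topological_order()

    # -- structure queries -------------------------------------------------
    def founders(self) -> list[str]:
        return [i.iid for i in self.members.values() if i.father is None]

    def nonfounders(self) -> list[str]:
        return [i.iid for i in self.members.values() if i.father is not None]

    def parents_of(self, iid: str) -> tuple[str, str] | None:
        ind = self.members[iid]
        if ind.father is None:
            return None
        return (ind.father, ind.mother)  # type: ignore[return-value]

    def children_of(self, iid: str) -> list[str]:
        return [
            i.iid
            for i in self.members.values()
            if iid in (i.father, i.mother)
        ]

    def spouses_of(self, iid: str) -> list[str]:
        out: list[str] = []
        for child in self.children_of(iid):
            f, m = self.parents_of(child)  # type: ignore[misc]
            other = m if f == iid else f
            if other not in out:
                out.append(other)
        return out

    def siblings_of(self, iid: str) -> list[str]:
        """Full siblings: individuals sharing both parents."""
        par = self.parents_of(iid)
        if par is None:
            return []
        return [
            i.iid
            for i in self.members.values()
            if i.iid != iid and (i.father, i.mother) == par
        ]

    def topological_order(self) -> list[str]:
        """Founders first; every parent precedes its children."""
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(iid: str) -> None:
            if state.get(iid) == 2:
                return
            if state.get(iid) == 1:
                raise ValueError("pedigree graph contains a cycle")
            state[iid] = 1
            ind = self.members[iid]
            if ind.father is not None:
                visit(ind.father)
                visit(ind.mother)  # type: ignore[arg-type]
            state[iid] = 2
            order.append(iid)

        for iid in self.members:
            visit(iid)
        return order

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, iid: str) -> bool:
        return iid in self.members


class GeneticMap:
    """Piecewise-linear physical-to-genetic coordinate map.

    ``bp`` strictly increasing, ``cm`` non-decreasing.  Positions outside
    the map range are clamped to the end values (constant extrapolation).
    """

    def __init__(self, bp: Sequence[int], cm: Sequence[float]):
        self.bp = np.asarray(bp, dtype=np.int64)
        self.cm = np.asarray(cm, dtype=float)
        if self.bp.ndim != 1 or self.bp.shape != self.cm.shape or len(self.bp) < 1:
            raise ValueError("map needs matching 1-d bp and cM arrays")
        if len(self.bp) > 1 and not np.all(np.diff(self.bp) > 0):
            raise ValueError("physical positions must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("cM positions must be non-decreasing")

    @classmethod
    def uniform(cls, start_bp: int, end_bp: int, cm_per_mb: float = 1.0) -> "GeneticMap":
        span_cm = (end_bp - start_bp) / 1e6 * cm_per_mb
        return cls([start_bp, end_bp], [0.0, span_cm])

    def cm_at(self, pos) -> np.ndarray | float:
        return np.interp(pos, self.bp, self.cm)

    def bp_at(self, cm) -> np.ndarray | float:
        """Inverse interpolation (cM -> bp); flat stretches map to their start."""
        return np.interp(cm, self.cm, self.bp)

    @property
    def length_cm(self) -> float:
        return float(self.cm[-1] - self.cm[0])

    @property
    def length_morgans(self) -> float:
        return self.length_cm / 100.0


class HaplotypePanel:
    """Phased 0/1 alleles: ``haps[h, v]`` for haplotype ``h`` at variant ``v``.

    ``carriers[h] = (individual_id, 0|1)`` labels the diploid owner of each
    row; haplotype index 0 is paternal by the simulator's convention.
    """

    def __init__(
        self,
        variants: Sequence[Variant],
        haps: np.ndarray,
        carriers: Sequence[tuple[str, int]],
    ):
        self.variants = list(variants)
        _check_positions(self.variants)
        self.haps = np.asarray(haps, dtype=np.int8)
        if self.haps.ndim != 2 or self.haps.shape[1] != len(self.variants):
            raise ValueError("haplotype matrix shape does not match variant list")
        if self.haps.size and not np.isin(self.haps, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")
        self.carriers = list(carriers)
        if len(self.carriers) != self.haps.shape[0]:
            raise ValueError("one carrier label per haplotype row required")
        self._row: dict[tuple[str, int], int] = {
            c: i for i, c in enumerate(self.carriers)
        }

    @property
    def n_haplotypes(self) -> int:
        return self.haps.shape[0]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([v.pos for v in self.variants], dtype=np.int64)

    def individual_ids(self) -> list[str]:
        seen: list[str] = []
        for iid, _ in self.carriers:
            if iid not in seen:
                seen.append(iid)
        return seen

    def haplotype(self, iid: str, k: int) -> np.ndarray:
        return self.haps[self._row[(iid, k)]]

    def has_individual(self, iid: str) -> bool:
        return (iid, 0) in self._row

    def allele_freq(self) -> np.ndarray:
        if self.n_haplotypes == 0:
            raise ValueError("empty panel has no allele frequencies")
        return self.haps.mean(axis=0)

    def subset_variants(self, idx: Sequence[int]) -> "HaplotypePanel":
        idx = list(idx)
        return HaplotypePanel(
            [self.variants[i] for i in idx], self.haps[:, idx], self.carriers
        )

    def for_individuals(self, ids: Sequence[str]) -> "HaplotypePanel":
        rows = [self._row[(i, k)] for i in ids for k in (0, 1)]
        return HaplotypePanel(
            self.variants, self.haps[rows], [self.carriers[r] for r in rows]
        )

    def genotypes(self) -> "GenotypeMatrix":
        """Collapse phased haplotypes to unphased dosage-class calls."""
        ids = self.individual_ids()
        calls = np.empty((len(ids), self.n_variants), dtype=np.int8)
        for n, iid in enumerate(ids):
            calls[n] = self.haplotype(iid, 0) + self.haplotype(iid, 1)
        return GenotypeMatrix(ids, self.variants, calls)


class GenotypeMatrix:
    """Unphased calls ``calls[n, v]`` in {0, 1, 2}, ``MISSING`` (-1) when absent."""

    def __init__(
        self,
        individuals: Sequence[str],
        variants: Sequence[Variant],
        calls: np.ndarray,
    ):
        self.individuals = list(individuals)
        self.variants = list(variants)
        _check_positions(self.variants)
        self.calls = np.asarray(calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.variants)):
            raise ValueError("call matrix shape does not match labels")
        if self.calls.size and not np.isin(self.calls, (0, 1, 2, MISSING)).all():
            raise ValueError("calls must be 0/1/2 or MISSING")
        self._irow = {iid: n for n, iid in enumerate(self.individuals)}
        self._vcol = {v.vid: j for j, v in enumerate(self.variants)}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([v.pos for v in self.variants], dtype=np.int64)

    def row(self, iid: str) -> np.ndarray:
        return self.calls[self._irow[iid]]

    def has_individual(self, iid: str) -> bool:
        return iid in self._irow

    def variant_index(self, vid: str) -> int:
        return self._vcol[vid]

    def subset(
        self,
        individuals: Sequence[str] | None = None,
        variant_idx: Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        ids = self.individuals if individuals is None else list(individuals)
        rows = [self._irow[i] for i in ids]
        cols = (
            list(range(self.n_variants)) if variant_idx is None else list(variant_idx)
        )
        return GenotypeMatrix(
            ids, [self.variants[j] for j in cols], self.calls[np.ix_(rows, cols)]
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.individuals, self.variants, self.calls.copy())

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING


class GenotypeProbabilities:
    """Posterior genotype 3-vectors; each sums to 1 within 1e-9."""

    SUM_TOL = 1e-9

    def __init__(
        self,
        individuals: Sequence[str],
        variants: Sequence[Variant],
        probs: np.ndarray,
    ):
        self.individuals = list(individuals)
        self.variants = list(variants)
        _check_positions(self.variants)
        self.probs = np.asarray(probs, dtype=float)
        if self.probs.shape != (len(self.individuals), len(self.variants), 3):
            raise ValueError("probability array must be N x V x 3")
        if self.probs.size:
            if np.any(self.probs < -1e-12):
                raise ValueError("negative genotype probability")
            sums = self.probs.sum(axis=2)
            if np.any(np.abs(sums - 1.0) > self.SUM_TOL):
                raise ValueError("genotype 3-vectors must sum to 1")
        self._irow = {iid: n for n, iid in enumerate(self.individuals)}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def row(self, iid: str) -> np.ndarray:
        return self.probs[self._irow[iid]]

    def dosages(self) -> np.ndarray:
        """Expected alt-allele counts, N x V."""
        return self.probs @ np.array([0.0, 1.0, 2.0])

    def best_guess_calls(self) -> np.ndarray:
        """Plain argmax calls (no confidence threshold), N x V."""
        return self.probs.argmax(axis=2).astype(np.int8)
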