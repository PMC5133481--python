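"""Population-based imputation: a Li-Stephens haplotype-copying HMM.

Each target haplotype is modelled as an imperfect mosaic of the phased
reference haplotypes.  The hidden state at every reference site is the
reference haplotype currently being copied; between adjacent sites the
chain switches with probability ``1 - exp(-rho * d_cM / H)`` (and then
lands uniformly on any of the ``H`` reference haplotypes, including the
current one), and the observed allele differs from the copied one with a
symmetric per-site error ``eps``.  Forward-backward over this chain
gives per-site posterior alternate-allele probabilities for each of the
target's two haplotypes, which are combined independently into genotype
3-vectors.

This is a deliberately transparent functional stand-in for production
population imputation engines (Impute2 and kin), not an emulation of any
of them: no MCMC, no chunking, no internal info score.
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
)

__all__ = ["HmmParams", "haploid_posterior", "impute_individual", "impute_population"]


@dataclass(frozen=True)
class HmmParams:
    """Copying-model parameters.

    ``error_rate`` is the symmetric allele-miscopy probability (must lie
    in (0, 0.5)); ``rho`` scales the switch rate so that the expected
    number of copying switches is about ``rho / H`` per cM — the default
    of 10 gives ~1 switch per 10 cM per 100 reference haplotypes.
    """

    error_rate: float = 0.001
    rho: float = 10.0

    def validate(self) -> None:
        if not 0 < self.error_rate < 0.5:
            raise ValueError("error_rate must be in (0, 0.5)")
        if self.rho <= 0:
            raise ValueError("rho must be positive")


def _switch_probs(
    positions: np.ndarray, gmap: GeneticMap, rho: float, n_haps: int
) -> np.ndarray:
    """Per-gap probability that the copied haplotype is redrawn."""
    cm = np.asarray(gmap.cm_at(positions), dtype=float)
    return 1.0 - np.exp(-rho * np.diff(cm) / n_haps)


def haploid_posterior(
    obs: np.ndarray,
    reference: HaplotypePanel,
    gmap: GeneticMap,
    params: HmmParams,
) -> np.ndarray:
    """Posterior P(alt) per site for one target haplotype.

    ``obs`` holds the target's observed alleles on the reference variant
    grid: 0/1 where scaffolded, ``MISSING`` (-1) elsewhere.  Scaled
    forward-backward; never underflows to silent zeros.
    """
    params.validate()
    H, V = reference.haps.shape
    if H < 2:
        raise ValueError("reference panel needs at least 2 haplotypes")
    if len(obs) != V:
        raise ValueError("observation vector does not match reference grid")
    eps = params.error_rate
    x = reference.haps.astype(float)  # H x V
    # emission[h, v]
    emit = np.ones((H, V))
    seen = obs != MISSING
    if seen.any():
        match = x[:, seen] == obs[seen][None, :]
        emit[:, seen] = np.where(match, 1.0 - eps, eps)
    s = _switch_probs(reference.positions, gmap, params.rho, H)

    fwd = np.empty((H, V))
    a = emit[:, 0] / H
    fwd[:, 0] = a / a.sum()
    for v in range(1, V):
        prev = fwd[:, v - 1]
        a = emit[:, v] * ((1 - s[v - 1]) * prev + s[v - 1] / H)
        fwd[:, v] = a / a.sum()
    bwd = np.empty((H, V))
    bwd[:, -1] = 1.0 / H
    for v in range(V - 2, -1, -1):
        nb = emit[:, v + 1] * bwd[:, v + 1]
        b = (1 - s[v]) * nb + s[v] * nb.sum() / H
        bwd[:, v] = b / b.sum()
    gamma = fwd * bwd
    gamma /= gamma.sum(axis=0, keepdims=True)
    return (gamma * ((1 - eps) * x + eps * (1 - x))).sum(axis=0)


def _project_scaffold(
    scaffold: GenotypeMatrix,
    reference: HaplotypePanel,
) -> np.ndarray:
    """Column indices of scaffold variants on the reference grid; errors
    name any scaffold variant absent from the reference."""
    ref_by_vid = {v.vid: j for j, v in enumerate(reference.variants)}
    idx = np.empty(scaffold.n_variants, dtype=int)
    for j, var in enumerate(scaffold.variants):
        if var.vid not in ref_by_vid:
            raise ValueError(
                f"scaffold variant {var.vid!r} (pos {var.pos}) is absent "
                "from the reference panel"
            )
        idx[j] = ref_by_vid[var.vid]
    return idx


def impute_individual(
    hap0_obs: np.ndarray,
    hap1_obs: np.ndarray,
    reference: HaplotypePanel,
    gmap: GeneticMap,
    params: HmmParams,
) -> np.ndarray:
    """Genotype posteriors (V x 3) from two phased scaffold haplotypes,
    imputed independently (haploid-copying approximation)."""
    p0 = haploid_posterior(np.asarray(hap0_obs), reference, gmap, params)
    p1 = haploid_posterior(np.asarray(hap1_obs), reference, gmap, params)
    out = np.stack(
        [(1 - p0) * (1 - p1), p0 * (1 - p1) + (1 - p0) * p1, p0 * p1], axis=1
    )
    return out / out.sum(axis=1, keepdims=True)


def impute_population(
    scaffold: GenotypeMatrix,
    reference: HaplotypePanel,
    gmap: GeneticMap,
    params: HmmParams = HmmParams(),
    phase: HaplotypePanel | None = None,
    individuals: list[str] | None = None,
) -> GenotypeProbabilities:
    """Impute every requested scaffold individual onto the reference grid.

    ``phase``, when given, supplies each individual's phased scaffold
    haplotypes (the simulator's true phase, or an external pre-phased
    panel); scaffold sites with a missing *observed* call stay
    unobserved even when phase is available.  Without ``phase``,
    homozygous scaffold calls are used as-is on both haplotypes and
    heterozygous sites are left unobserved (a documented, conservative
    unphased mode).
    """
    ids = individuals if individuals is not None else scaffold.individuals
    idx = _project_scaffold(scaffold, reference)
    V = reference.n_variants
    probs = np.empty((len(ids), V, 3))
    for n, iid in enumerate(ids):
        calls = scaffold.row(iid)
        obs0 = np.full(V, MISSING, dtype=np.int8)
        obs1 = np.full(V, MISSING, dtype=np.int8)
        seen = calls != MISSING
        if phase is not None:
            h0 = phase.haplotype(iid, 0)
            h1 = phase.haplotype(iid, 1)
            ph_idx = _project_scaffold(scaffold, phase)  # scaffold on phase grid
            obs0[idx[seen]] = h0[ph_idx[seen]]
            obs1[idx[seen]] = h1[ph_idx[seen]]
        else:
            hom = seen & (calls != 1)
            obs0[idx[hom]] = (calls[hom] // 2).astype(np.int8)
            obs1[idx[hom]] = (calls[hom] // 2).astype(np.int8)
        probs[n] = impute_individual(obs0, obs1, reference, gmap, params)
    return GenotypeProbabilities(ids, reference.variants, probs)
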