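"""Synthetic study generator: pedigrees, founder haplotypes, gene dropping.

Emulates a family-based imputation study design: ~20 extended families,
a sparse "GWAS" scaffold nested inside a dense "sequence" panel over one
genomic region, a minor-allele-frequency spectrum with mass below 0.01
and between 0.01-0.05, a subset of individuals with sequence data, an
external cosmopolitan reference haplotype panel, and missing genotype
calls at QC-relevant rates.

Founder haplotypes are built by mosaic copying among a small set of
ancestral haplotypes, which creates local linkage disequilibrium without
a coalescent simulation.  Each variant draws its carrier count from
Binomial(H, f) and packs the carriers into ancestral clades (the sets of
final haplotypes copying the same ancestor at that site): common
variants fill whole clades and are strongly tagged by their local
ancestral background, while rare variants occupy a small fraction of a
single clade and are only partially tagged — so population
imputability degrades continuously as frequency falls, the way it does
in real panels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ._rng import stage_rng
from .core import (
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    HaplotypePanel,
    Individual,
    Pedigree,
    Variant,
)

__all__ = [
    "FAMILY_SIZE_COUNTS",
    "MafSpectrum",
    "SimConfig",
    "StudyData",
    "simulate_pedigrees",
    "simulate_founder_haplotypes",
    "gene_drop",
    "make_study_panels",
    "inject_missingness",
    "simulate_study",
]

# Empirical family-size distribution of the study pedigree subsets
# (sizes 3..15 with observed counts, n = 100).
FAMILY_SIZE_COUNTS: dict[int, int] = {
    3: 6, 4: 8, 5: 24, 6: 17, 7: 15, 8: 5, 9: 8,
    10: 1, 11: 3, 12: 7, 13: 2, 14: 2, 15: 2,
}


@dataclass(frozen=True)
class MafSpectrum:
    """Mixture of frequency bins: ``(low, high, weight)`` triples.

    Within a chosen bin the target alternate-allele frequency is drawn
    log-uniformly.  Default weights follow the study's variant counts in
    the rare / low-frequency / common bins (0.61 / 0.22 / 0.17).
    """

    bins: tuple[tuple[float, float, float], ...] = (
        (0.002, 0.01, 0.61),
        (0.01, 0.05, 0.22),
        (0.05, 0.4, 0.17),
    )

    def validate(self) -> None:
        total = sum(w for _, _, w in self.bins)
        if not self.bins or total <= 0:
            raise ValueError("MAF spectrum needs positive total weight")
        for lo, hi, w in self.bins:
            if w < 0 or not (0 <= lo <= hi <= 0.5):
                raise ValueError(f"invalid spectrum bin ({lo}, {hi}, {w})")
        if all(hi == 0 for _, hi, _ in self.bins):
            raise ValueError("degenerate spectrum: all mass at frequency 0")

    @classmethod
    def fixed(cls, f: float) -> "MafSpectrum":
        """Force every site to target frequency ``f`` exactly."""
        return cls(bins=((f, f, 1.0),))

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        self.validate()
        w = np.array([b[2] for b in self.bins], dtype=float)
        w /= w.sum()
        which = rng.choice(len(self.bins), size=n, p=w)
        lo = np.array([max(b[0], 1e-4) for b in self.bins])
        hi = np.array([max(b[1], 1e-4) for b in self.bins])
        u = rng.random(n)
        return np.exp(
            np.log(lo[which]) + u * (np.log(hi[which]) - np.log(lo[which]))
        )


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with study-shaped defaults."""

    n_families: int = 20
    family_size_counts: dict[int, int] = field(
        default_factory=lambda: dict(FAMILY_SIZE_COUNTS)
    )
    n_sequence_variants: int = 2000
    n_gwas_variants: int = 200
    chrom: str = "3"
    region_start: int = 46_750_000
    region_end: int = 49_250_000
    cm_per_mb: float = 1.0
    maf_spectrum: MafSpectrum = field(default_factory=MafSpectrum)
    # panel-membership fractions (study: 419/959 both, 495/959 GWAS only,
    # 45/959 sequence only)
    fraction_both: float = 0.437
    fraction_gwas_only: float = 0.516
    fraction_seq_only: float = 0.047
    variant_missing_rate: float = 0.02
    individual_missing_rate: float = 0.02
    n_reference: int = 100          # cosmopolitan reference individuals
    n_ancestors: int = 40           # mosaic-copying ancestral haplotypes
    ancestry_switch_prob: float = 0.002  # per-site mosaic switch probability
    drift_fst: float = 0.05         # Balding-Nichols drift of the reference
    gwas_min_maf: float = 0.05      # array selection prefers common variants
    seed: int = 2016

    def validate(self) -> None:
        if self.n_gwas_variants > self.n_sequence_variants:
            raise ValueError("n_gwas_variants must not exceed n_sequence_variants")
        if self.n_sequence_variants <= 0:
            raise ValueError("n_sequence_variants must be positive (empty panel)")
        for name in (
            "fraction_both",
            "fraction_gwas_only",
            "fraction_seq_only",
            "variant_missing_rate",
            "individual_missing_rate",
            "ancestry_switch_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        tot = self.fraction_both + self.fraction_gwas_only + self.fraction_seq_only
        if abs(tot - 1.0) > 1e-6:
            raise ValueError("panel-membership fractions must sum to 1")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be a fixed integer")
        self.maf_spectrum.validate()

    @property
    def fraction_sequenced(self) -> float:
        return self.fraction_both + self.fraction_seq_only

    def genetic_map(self) -> GeneticMap:
        return GeneticMap.uniform(self.region_start, self.region_end, self.cm_per_mb)

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# pedigrees


def _build_family(fid: str, size: int, rng: np.random.Generator) -> Pedigree:
    """Grow one extended family to ``size`` members.

    Starts from a founder couple with a child and repeatedly either adds a
    child to an existing couple or marries in a founder spouse for a
    member without one (creating a new couple plus their first child),
    which yields multi-generation pedigrees with grandparents and
    grandchildren at realistic rates.
    """
    if size < 3:
        raise ValueError("family size must be at least 3")
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"{fid}_I{counter[0]:02d}"

    inds: dict[str, Individual] = {}
    f0, m0 = new_id(), new_id()
    inds[f0] = Individual(f0, sex=1)
    inds[m0] = Individual(m0, sex=2)
    couples: list[tuple[str, str]] = [(f0, m0)]
    married: set[str] = {f0, m0}

    def add_child(couple: tuple[str, str]) -> str:
        cid = new_id()
        inds[cid] = Individual(
            cid, father=couple[0], mother=couple[1], sex=int(rng.integers(1, 3))
        )
        return cid

    add_child(couples[0])
    while len(inds) < size:
        singles = [i for i in inds.values() if i.iid not in married and i.father]
        marry = singles and (len(inds) + 2 <= size) and rng.random() < 0.45
        if marry:
            person = inds[singles[int(rng.integers(len(singles)))].iid]
            sid = new_id()
            inds[sid] = Individual(sid, sex=2 if person.sex == 1 else 1)
            couple = (
                (person.iid, sid) if person.sex == 1 else (sid, person.iid)
            )
            couples.append(couple)
            married.update(couple)
            add_child(couple)
        else:
            add_child(couples[int(rng.integers(len(couples)))])
    return Pedigree(fid, list(inds.values()))


def simulate_pedigrees(cfg: SimConfig, rng: np.random.Generator | None = None) -> list[Pedigree]:
    """Draw ``cfg.n_families`` pedigrees with sizes from the configured
    empirical family-size distribution."""
    cfg.validate()
    rng = rng if rng is not None else stage_rng(cfg.seed, "pedigrees")
    sizes = np.array(sorted(cfg.family_size_counts), dtype=int)
    weights = np.array([cfg.family_size_counts[s] for s in sizes], dtype=float)
    weights /= weights.sum()
    drawn = rng.choice(sizes, size=cfg.n_families, p=weights)
    return [
        _build_family(f"FAM{k + 1:03d}", int(s), rng) for k, s in enumerate(drawn)
    ]


# ---------------------------------------------------------------------------
# founder / reference haplotypes

_BASES = np.array(list("ACGT"))


def _draw_variants(cfg: SimConfig, rng: np.random.Generator) -> list[Variant]:
    span = cfg.region_end - cfg.region_start
    if span <= cfg.n_sequence_variants:
        raise ValueError("region too small for the requested variant count")
    pos = np.sort(
        rng.choice(span - 1, size=cfg.n_sequence_variants, replace=False)
    ) + cfg.region_start + 1
    refs = rng.integers(0, 4, size=cfg.n_sequence_variants)
    alts = (refs + rng.integers(1, 4, size=cfg.n_sequence_variants)) % 4
    return [
        Variant(f"var{j + 1:05d}", int(p), _BASES[r], _BASES[a])
        for j, (p, r, a) in enumerate(zip(pos, refs, alts))
    ]


def _mosaic_paths(
    n_haps: int, n_sites: int, n_anc: int, switch: float, rng: np.random.Generator
) -> np.ndarray:
    path = np.empty((n_haps, n_sites), dtype=np.int16)
    path[:, 0] = rng.integers(0, n_anc, size=n_haps)
    for v in range(1, n_sites):
        sw = rng.random(n_haps) < switch
        path[:, v] = np.where(sw, rng.integers(0, n_anc, size=n_haps), path[:, v - 1])
    return path


def simulate_founder_haplotypes(
    cfg: SimConfig,
    founder_ids: list[str] | None = None,
    reference_ids: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> HaplotypePanel:
    """Generate phased haplotypes for the pedigree founders plus the
    cosmopolitan reference individuals.

    Returns one panel holding ``2 * (n_founders + n_reference)``
    haplotypes; founder rows come first.  The reference block is drawn
    from a Balding-Nichols drifted copy of the founder allele frequencies
    (Fst = ``cfg.drift_fst``) over the same ancestral haplotype pool, so
    it shares LD structure with the study population but not its exact
    frequencies — and its rare variants are drawn independently,
    mirroring the population-privacy of rare variation.
    """
    cfg.validate()
    rng = rng if rng is not None else stage_rng(cfg.seed, "founders")
    if founder_ids is None:
        founder_ids = [f"F{k + 1:04d}" for k in range(40)]
    if reference_ids is None:
        reference_ids = [f"REF{k + 1:04d}" for k in range(cfg.n_reference)]

    variants = _draw_variants(cfg, rng)
    V = cfg.n_sequence_variants
    K = cfg.n_ancestors
    f = cfg.maf_spectrum.draw(V, rng)

    # drifted frequencies for the cosmopolitan reference (Balding-Nichols)
    with np.errstate(divide="ignore"):
        F = cfg.drift_fst
        alpha = np.clip(f * (1 - F) / F, 1e-3, None)
        beta = np.clip((1 - f) * (1 - F) / F, 1e-3, None)
    f_ref = np.clip(rng.beta(alpha, beta), 1e-5, 1 - 1e-5)

    # per-site ancestor preference order, shared by both blocks so the
    # reference panel tags the same ancestral backgrounds as the founders
    anc_order = np.argsort(rng.random((V, K)), axis=1)

    def _block(ids: list[str], freqs: np.ndarray) -> np.ndarray:
        """Mosaic-copied haplotypes with clade-packed carriers.

        Carrier count per site is Binomial(H, f); carriers fill the
        site's preferred ancestral clades in order, so a variant's
        carriers share local ancestry and the tagging strength scales
        with how much of its clade the variant fills.
        """
        H = 2 * len(ids)
        paths = _mosaic_paths(H, V, K, cfg.ancestry_switch_prob, rng)
        haps = np.zeros((H, V), dtype=np.int8)
        counts = rng.binomial(H, freqs)
        for v in np.flatnonzero(counts):
            c = int(counts[v])
            chosen: list[int] = []
            for k in anc_order[v]:
                clade = np.flatnonzero(paths[:, v] == k)
                if len(clade) >= c - len(chosen):
                    pick = rng.choice(clade, size=c - len(chosen), replace=False)
                    chosen.extend(int(i) for i in pick)
                    break
                chosen.extend(int(i) for i in clade)
            haps[chosen, v] = 1
        return haps

    founder_block = _block(founder_ids, f)
    ref_block = _block(reference_ids, f_ref)
    carriers = [(iid, k) for iid in founder_ids for k in (0, 1)] + [
        (iid, k) for iid in reference_ids for k in (0, 1)
    ]
    return HaplotypePanel(
        variants, np.vstack([founder_block, ref_block]), carriers
    )


# ---------------------------------------------------------------------------
# gene dropping


def meiosis(
    parent_haps: np.ndarray,
    positions: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One recombinant gamete from a phased parent.

    Crossover count is Poisson with mean equal to the map length in
    Morgans; crossover genetic positions are uniform on the cM scale and
    converted to bp by inverse interpolation.  Returns ``(gamete,
    source)`` where ``source[v]`` is the parental haplotype (0/1) the
    allele at site ``v`` was copied from.
    """
    n_x = rng.poisson(gmap.length_morgans)
    start = int(rng.integers(2))
    if n_x == 0:
        source = np.full(len(positions), start, dtype=np.int8)
    else:
        x_cm = np.sort(rng.uniform(gmap.cm[0], gmap.cm[-1], size=n_x))
        x_bp = np.asarray(gmap.bp_at(x_cm))
        flips = np.searchsorted(x_bp, positions, side="left")
        source = ((start + flips) % 2).astype(np.int8)
    return parent_haps[source, np.arange(len(positions))], source


def gene_drop(
    ped: Pedigree,
    founders: HaplotypePanel,
    gmap: GeneticMap,
    rng: np.random.Generator | int,
) -> HaplotypePanel:
    """Drop founder haplotypes through a pedigree with recombination.

    Every non-founder receives one recombinant haplotype per parent
    (row 0 paternal, row 1 maternal).  The returned panel carries true
    phase; the grandparental origin of every transmitted allele is kept
    on the panel as ``panel.origins[(child_id, meiosis)]``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    positions = founders.positions
    haps: dict[tuple[str, int], np.ndarray] = {}
    origins: dict[tuple[str, int], np.ndarray] = {}
    for iid in ped.topological_order():
        par = ped.parents_of(iid)
        if par is None:
            if not founders.has_individual(iid):
                raise ValueError(
                    f"founder {iid!r} has no assigned haplotypes and no parents"
                )
            haps[(iid, 0)] = founders.haplotype(iid, 0).copy()
            haps[(iid, 1)] = founders.haplotype(iid, 1).copy()
        else:
            for k, parent in enumerate(par):
                ph = np.vstack([haps[(parent, 0)], haps[(parent, 1)]])
                gamete, source = meiosis(ph, positions, gmap, rng)
                haps[(iid, k)] = gamete
                origins[(iid, k)] = source
    order = ped.topological_order()
    carriers = [(iid, k) for iid in order for k in (0, 1)]
    panel = HaplotypePanel(
        founders.variants, np.vstack([haps[c] for c in carriers]), carriers
    )
    panel.origins = origins  # type: ignore[attr-defined]
    return panel


# ---------------------------------------------------------------------------
# study panels and missingness


def make_study_panels(
    truth: HaplotypePanel,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, GenotypeMatrix, dict[str, str]]:
    """Split the simulated truth into the two study panels.

    Picks ``cfg.n_gwas_variants`` array sites as a nested subset of the
    sequence variants (restricted to common variants, MAF >
    ``cfg.gwas_min_maf``, mimicking an array design) and assigns each
    individual to ``both`` / ``gwas`` / ``seq`` panel membership by the
    configured fractions.  Returns ``(gwas, sequence, assignment)`` with
    unphased dosage-class calls derived from the truth haplotypes.
    """
    cfg.validate()
    rng = rng if rng is not None else stage_rng(cfg.seed, "panels")
    geno = truth.genotypes()
    p = geno.calls.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    eligible = np.flatnonzero(maf > cfg.gwas_min_maf)
    if len(eligible) < cfg.n_gwas_variants:
        raise ValueError(
            f"only {len(eligible)} variants exceed MAF {cfg.gwas_min_maf}; "
            f"cannot select {cfg.n_gwas_variants} array variants"
        )
    gwas_idx = np.sort(rng.choice(eligible, size=cfg.n_gwas_variants, replace=False))

    groups = np.array(["both", "gwas", "seq"])
    probs = np.array(
        [cfg.fraction_both, cfg.fraction_gwas_only, cfg.fraction_seq_only]
    )
    assignment = {
        iid: str(groups[g])
        for iid, g in zip(
            geno.individuals, rng.choice(3, size=geno.n_individuals, p=probs)
        )
    }
    gwas_ids = [i for i in geno.individuals if assignment[i] in ("both", "gwas")]
    seq_ids = [i for i in geno.individuals if assignment[i] in ("both", "seq")]
    gwas = geno.subset(gwas_ids, list(gwas_idx))
    sequence = geno.subset(seq_ids, None)
    return gwas, sequence, assignment


def inject_missingness(
    g: GenotypeMatrix,
    rate_variantwise: float,
    rate_individualwise: float,
    rng: np.random.Generator | int,
) -> GenotypeMatrix:
    """Mask calls missing-completely-at-random.

    Two independent Bernoulli layers: one at the configured variant-wise
    rate, one at the individual-wise rate; an entry is missing when
    either layer fires, so the overall rate is
    ``1 - (1-rv) * (1-ri)``.
    """
    for r in (rate_variantwise, rate_individualwise):
        if not 0 <= r <= 1:
            raise ValueError(f"missingness rate {r} outside [0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out = g.copy()
    shape = out.calls.shape
    mask = (rng.random(shape) < rate_variantwise) | (
        rng.random(shape) < rate_individualwise
    )
    out.calls[mask] = MISSING
    return out


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class StudyData:
    """Everything one simulated study produces."""

    cfg: SimConfig
    pedigrees: list[Pedigree]
    gmap: GeneticMap
    truth: HaplotypePanel              # all study individuals, phased truth
    reference: HaplotypePanel          # cosmopolitan reference haplotypes
    gwas: GenotypeMatrix               # sparse scaffold panel (with missingness)
    sequence: GenotypeMatrix           # dense panel (with missingness)
    assignment: dict[str, str]         # iid -> both | gwas | seq

    def sequenced_ids(self) -> list[str]:
        return [i for i in self.truth.individual_ids() if self.assignment[i] != "gwas"]

    def both_panel_ids(self) -> list[str]:
        return [i for i in self.truth.individual_ids() if self.assignment[i] == "both"]

    def pedigree_of(self, iid: str) -> Pedigree:
        for ped in self.pedigrees:
            if iid in ped:
                return ped
        raise KeyError(iid)


def simulate_study(cfg: SimConfig) -> StudyData:
    """Run the full generator: pedigrees -> founders -> gene drop ->
    study panels -> missingness.  Deterministic in ``cfg.seed``."""
    cfg.validate()
    peds = simulate_pedigrees(cfg)
    founder_ids = [iid for ped in peds for iid in ped.founders()]
    pool = simulate_founder_haplotypes(cfg, founder_ids=founder_ids)
    ref_ids = [i for i in pool.individual_ids() if i.startswith("REF")]
    founder_panel = pool.for_individuals(founder_ids)
    reference = pool.for_individuals(ref_ids)

    drop_rng = stage_rng(cfg.seed, "genedrop")
    per_family = [gene_drop(ped, founder_panel, cfg.genetic_map(), drop_rng) for ped in peds]
    all_ids: list[str] = []
    rows: list[np.ndarray] = []
    carriers: list[tuple[str, int]] = []
    origins: dict[tuple[str, int], np.ndarray] = {}
    for panel in per_family:
        all_ids.extend(panel.individual_ids())
        rows.append(panel.haps)
        carriers.extend(panel.carriers)
        origins.update(panel.origins)  # type: ignore[attr-defined]
    truth = HaplotypePanel(pool.variants, np.vstack(rows), carriers)
    truth.origins = origins  # type: ignore[attr-defined]

    gwas, sequence, assignment = make_study_panels(truth, cfg)
    miss_rng = stage_rng(cfg.seed, "missingness")
    gwas = inject_missingness(
        gwas, cfg.variant_missing_rate, cfg.individual_missing_rate, miss_rng
    )
    sequence = inject_missingness(
        sequence, cfg.variant_missing_rate, cfg.individual_missing_rate, miss_rng
    )
    return StudyData(
        cfg=cfg,
        pedigrees=peds,
        gmap=cfg.genetic_map(),
        truth=truth,
        reference=reference,
        gwas=gwas,
        sequence=sequence,
        assignment=assignment,
    )
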