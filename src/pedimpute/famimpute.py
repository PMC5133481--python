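"""Family-based imputation through inferred transmission segments.

The engine mirrors the mechanism of pedigree imputation tools in the
Merlin tradition — combine sparse framework markers with dense genotypes
on some relatives to infer unobserved dense genotypes — but replaces the
Lander-Green multipoint likelihood over inheritance vectors with exact,
per-meiosis two-state hidden Markov chains:

1. For every (child, parent) meiosis in the working family subset, a
   2-state HMM over the scaffold markers infers which parental haplotype
   the child inherited on each interval (``infer_transmission``).
2. Dense genotypes of relatives are copied through those segments into
   posterior genotype 3-vectors for the target individual
   (``impute_family``), with evidence combined exactly across the
   target's nuclear family and propagated approximately (per-branch
   independence) from more distant relatives; uninformative sites fall
   back to the subset's Hardy-Weinberg allele-frequency prior.

This per-meiosis factorisation keeps inference exact on nuclear families
and tractable at any family size, at the cost of ignoring joint
constraints between meioses that the full multipoint likelihood would
capture.  Looped (inbred) pedigrees are rejected.
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
)

__all__ = [
    "FamilySubset",
    "TransmissionSegments",
    "select_family_subset",
    "detect_mendelian_errors",
    "infer_transmission",
    "impute_family",
]


@dataclass(frozen=True)
class FamilySubset:
    """The relatives used to impute one masked individual."""

    masked: str
    members: tuple[str, ...]

    def __post_init__(self):
        if self.masked not in self.members:
            raise ValueError("masked individual must be part of the subset")

    def __contains__(self, iid: str) -> bool:
        return iid in self.members


def select_family_subset(ped: Pedigree, masked: str) -> FamilySubset:
    """The masked individual's nuclear family (parents, full siblings,
    spouses, children) plus grandchildren and grandparents — nothing
    else."""
    if masked not in ped:
        raise KeyError(f"{masked!r} is not in pedigree {ped.family_id!r}")
    keep: set[str] = {masked}
    par = ped.parents_of(masked)
    if par:
        keep.update(par)
        for gp in par:
            gpp = ped.parents_of(gp)
            if gpp:
                keep.update(gpp)  # grandparents
    keep.update(ped.siblings_of(masked))
    keep.update(ped.spouses_of(masked))
    children = ped.children_of(masked)
    keep.update(children)
    for c in children:
        keep.update(ped.children_of(c))  # grandchildren
    return FamilySubset(masked, tuple(sorted(keep)))


def _ancestors(ped: Pedigree, iid: str) -> set[str]:
    out: set[str] = set()
    stack = [iid]
    while stack:
        cur = stack.pop()
        par = ped.parents_of(cur)
        if par:
            for p in par:
                if p not in out:
                    out.add(p)
                    stack.append(p)
    return out


def _reject_loops(ped: Pedigree) -> None:
    for iid in ped.nonfounders():
        f, m = ped.parents_of(iid)  # type: ignore[misc]
        common = (_ancestors(ped, f) | {f}) & (_ancestors(ped, m) | {m})
        if common:
            raise ValueError(
                f"pedigree {ped.family_id!r} is looped/inbred (couple "
                f"{f!r} x {m!r} share ancestry {sorted(common)}); "
                "looped pedigrees are not supported"
            )


def detect_mendelian_errors(g: GenotypeMatrix, ped: Pedigree) -> set[str]:
    """Variant ids with at least one impossible duo/trio transmission.

    A child's genotype is consistent iff it can be composed of one
    allele drawable from each parent's genotype; missing genotypes never
    trigger flags (an absent parent contributes alleles {0, 1}).
    """
    calls = g.calls
    lo = np.where(calls == 2, 1, 0)          # min transmissible allele
    hi = np.where((calls >= 1), 1, 0)        # max transmissible allele
    lo = np.where(calls == MISSING, 0, lo)
    hi = np.where(calls == MISSING, 1, hi)
    flagged: set[str] = set()
    bad = np.zeros(g.n_variants, dtype=bool)
    for iid in ped.nonfounders():
        if not g.has_individual(iid):
            continue
        f, m = ped.parents_of(iid)  # type: ignore[misc]
        gc = g.row(iid)
        lo_f, hi_f = _parent_bounds(g, f)
        lo_m, hi_m = _parent_bounds(g, m)
        seen = gc != MISSING
        bad |= seen & ((gc < lo_f + lo_m) | (gc > hi_f + hi_m))
    for j in np.flatnonzero(bad):
        flagged.add(g.variants[j].vid)
    return flagged


def _parent_bounds(g: GenotypeMatrix, iid: str) -> tuple[np.ndarray, np.ndarray]:
    if not g.has_individual(iid):
        return np.zeros(g.n_variants, int), np.ones(g.n_variants, int)
    c = g.row(iid)
    lo = np.where(c == 2, 1, 0)
    hi = np.where(c >= 1, 1, 0)
    lo = np.where(c == MISSING, 0, lo)
    hi = np.where(c == MISSING, 1, hi)
    return lo, hi


# ---------------------------------------------------------------------------
# transmission inference


@dataclass
class TransmissionSegments:
    """Posterior inheritance along one meiosis.

    ``p_hap0[m]`` is the posterior probability that the child's allele
    at scaffold marker ``m`` came from the parent's haplotype 0;
    between markers the posterior is piecewise constant with breakpoints
    at marker midpoints, tiling ``region`` without overlap.
    """

    child: str
    parent_index: int  # 0 = paternal meiosis, 1 = maternal
    marker_pos: np.ndarray
    p_hap0: np.ndarray
    region: tuple[int, int]

    def weights_at(self, positions: np.ndarray) -> np.ndarray:
        """P(haplotype 0 inherited) at arbitrary bp positions."""
        positions = np.asarray(positions)
        if len(self.marker_pos) == 0:
            return np.full(len(positions), 0.5)
        mids = (self.marker_pos[:-1] + self.marker_pos[1:]) / 2.0
        return self.p_hap0[np.searchsorted(mids, positions)]

    def intervals(self) -> list[tuple[int, int, int, float]]:
        """(start_bp, end_bp, inherited haplotype index, confidence)."""
        lo, hi = self.region
        if len(self.marker_pos) == 0:
            return [(lo, hi, 0, 0.5)]
        mids = (self.marker_pos[:-1] + self.marker_pos[1:]) / 2.0
        bounds = [lo, *[int(m) for m in mids], hi]
        out = []
        for m, p in enumerate(self.p_hap0):
            k = 0 if p >= 0.5 else 1
            out.append((bounds[m], bounds[m + 1], k, float(max(p, 1 - p))))
        return out


def _haldane_switch(positions: np.ndarray, gmap: GeneticMap) -> np.ndarray:
    """Recombination fraction between adjacent markers (Haldane)."""
    cm = np.asarray(gmap.cm_at(positions), dtype=float)
    return 0.5 * (1.0 - np.exp(-2.0 * np.diff(cm) / 100.0))


def _chain_posterior(emit: np.ndarray, switch: np.ndarray) -> np.ndarray:
    """Forward-backward on a 2-state chain; returns P(state 0) per step."""
    M = emit.shape[1]
    if M == 0:
        return np.empty(0)
    fwd = np.empty((2, M))
    a = 0.5 * emit[:, 0]
    fwd[:, 0] = a / a.sum() if a.sum() > 0 else [0.5, 0.5]
    for m in range(1, M):
        t = switch[m - 1]
        prev = fwd[:, m - 1]
        trans = np.array(
            [(1 - t) * prev[0] + t * prev[1], t * prev[0] + (1 - t) * prev[1]]
        )
        a = emit[:, m] * trans
        s = a.sum()
        fwd[:, m] = a / s if s > 0 else [0.5, 0.5]
    bwd = np.empty((2, M))
    bwd[:, -1] = 0.5
    for m in range(M - 2, -1, -1):
        t = switch[m]
        nb = emit[:, m + 1] * bwd[:, m + 1]
        b = np.array([(1 - t) * nb[0] + t * nb[1], t * nb[0] + (1 - t) * nb[1]])
        s = b.sum()
        bwd[:, m] = b / s if s > 0 else [0.5, 0.5]
    post = fwd * bwd
    tot = post.sum(axis=0)
    tot[tot == 0] = 1.0
    return post[0] / tot


def _transmit_prob_from_genotype(calls: np.ndarray, freq: np.ndarray) -> np.ndarray:
    """P(parent transmits alt) from an unphased genotype; missing -> freq."""
    p = calls / 2.0
    return np.where(calls == MISSING, freq, p)


def infer_transmission(
    subset: FamilySubset,
    scaffold: GenotypeMatrix,
    gmap: GeneticMap,
    phase: HaplotypePanel | None,
    ped: Pedigree,
) -> dict[tuple[str, int], TransmissionSegments]:
    """Infer inheritance posteriors for every meiosis inside the subset.

    ``phase`` supplies parents' phased scaffold haplotypes (the
    simulator's truth, standing in for pre-phased data).  A marker is
    informative only where the parent is heterozygous and both the
    parent's and the child's scaffold calls are observed; the other
    parent's genotype (or, failing that, the subset allele frequency)
    supplies the probability of the co-transmitted allele.  A meiosis
    with no informative markers gets flat weights of 0.5.
    """
    _reject_loops(ped)
    pos = scaffold.positions
    region = (int(gmap.bp[0]), int(gmap.bp[-1]))
    switch = _haldane_switch(pos, gmap)
    # subset allele frequency per scaffold marker
    sub_rows = [scaffold.row(i) for i in subset.members if scaffold.has_individual(i)]
    if sub_rows:
        mat = np.array(sub_rows)
        with np.errstate(invalid="ignore"):
            freq = np.where(
                (mat != MISSING).sum(0) > 0,
                np.where(mat == MISSING, 0, mat).sum(0)
                / np.maximum(2 * (mat != MISSING).sum(0), 1),
                0.5,
            )
    else:
        freq = np.full(scaffold.n_variants, 0.5)

    out: dict[tuple[str, int], TransmissionSegments] = {}
    if phase is not None:
        phase_col = {v.vid: j for j, v in enumerate(phase.variants)}
        try:
            ph_idx = np.array([phase_col[v.vid] for v in scaffold.variants])
        except KeyError as e:
            raise ValueError(f"scaffold variant {e} missing from the phase panel")
    for iid in subset.members:
        par = ped.parents_of(iid) if iid in ped else None
        if par is None:
            continue
        for k, parent in enumerate(par):
            if parent not in subset:
                continue
            M = scaffold.n_variants
            emit = np.ones((2, M))
            child_obs = (
                scaffold.row(iid)
                if scaffold.has_individual(iid)
                else np.full(M, MISSING, dtype=np.int8)
            )
            if (
                phase is not None
                and scaffold.has_individual(parent)
                and phase.has_individual(parent)
            ):
                p_calls = scaffold.row(parent)
                h0 = phase.haplotype(parent, 0)[ph_idx]
                h1 = phase.haplotype(parent, 1)[ph_idx]
                other = par[1 - k]
                o_calls = (
                    scaffold.row(other)
                    if scaffold.has_individual(other)
                    else np.full(M, MISSING, dtype=np.int8)
                )
                t_other = _transmit_prob_from_genotype(o_calls, freq)
                usable = (child_obs != MISSING) & (p_calls != MISSING)
                for st, hap in ((0, h0), (1, h1)):
                    need = child_obs - hap
                    lik = np.where(
                        need == 0, 1 - t_other, np.where(need == 1, t_other, 0.0)
                    )
                    emit[st] = np.where(usable, lik, 1.0)
                dead = emit.sum(axis=0) == 0  # Mendelian clash: treat as missing
                emit[:, dead] = 1.0
            p0 = _chain_posterior(emit, switch)
            out[(iid, k)] = TransmissionSegments(iid, k, pos.copy(), p0, region)
    return out


# ---------------------------------------------------------------------------
# dense imputation through segments

_COMBO_H0 = np.array([0.0, 0.0, 1.0, 1.0])  # combos 00, 01, 10, 11
_COMBO_H1 = np.array([0.0, 1.0, 0.0, 1.0])


class _FamilyEvidence:
    """Vectorised evidence assembly for one subset at all dense variants."""

    def __init__(
        self,
        subset: FamilySubset,
        dense: GenotypeMatrix,
        segs: dict[tuple[str, int], TransmissionSegments],
        ped: Pedigree,
        mode: str,
        phase: HaplotypePanel | None,
    ):
        if mode not in ("agnostic", "benchmark"):
            raise ValueError("mode must be 'agnostic' or 'benchmark'")
        if mode == "benchmark" and phase is None:
            raise ValueError("benchmark mode needs a phase panel")
        self.subset = subset
        self.ped = ped
        self.mode = mode
        self.phase = phase
        self.segs = segs
        self.V = dense.n_variants
        self.variants = dense.variants
        self.pos = dense.positions
        # masked's own dense data must never leak in
        keep = [
            i for i in dense.individuals if i in subset and i != subset.masked
        ]
        self.dense = dense.subset(keep, None)
        if phase is not None:
            col = {v.vid: j for j, v in enumerate(phase.variants)}
            self.ph_idx = np.array([col[v.vid] for v in self.variants])
        # subset allele frequency with panel-wide fallback
        sub = self.dense.calls
        n_obs = (sub != MISSING).sum(0)
        alt = np.where(sub == MISSING, 0, sub).sum(0)
        pan_obs = (dense.calls != MISSING).sum(0)
        pan_alt = np.where(dense.calls == MISSING, 0, dense.calls).sum(0)
        pan_f = np.where(pan_obs > 0, pan_alt / np.maximum(2 * pan_obs, 1), 0.5)
        self.freq = np.where(n_obs > 0, alt / np.maximum(2 * n_obs, 1), pan_f)
        self.any_observed = n_obs > 0
        self._hap_prior: dict[tuple[str, int], np.ndarray] = {}
        self._hap_post: dict[tuple[str, int], np.ndarray] = {}

    # -- per-haplotype alternate-allele probabilities ----------------------
    def weight(self, child: str, k: int) -> np.ndarray:
        seg = self.segs.get((child, k))
        if seg is None:
            return np.full(self.V, 0.5)
        return np.asarray(seg.weights_at(self.pos), dtype=float)

    def observed(self, iid: str) -> np.ndarray:
        if self.dense.has_individual(iid):
            return self.dense.row(iid) != MISSING
        return np.zeros(self.V, dtype=bool)

    def calls(self, iid: str) -> np.ndarray:
        if self.dense.has_individual(iid):
            return self.dense.row(iid)
        return np.full(self.V, MISSING, dtype=np.int8)

    def hap_prior(self, iid: str, k: int) -> np.ndarray:
        """P(hap k = alt) from ancestry alone (no self observation)."""
        key = (iid, k)
        if key not in self._hap_prior:
            par = self.ped.parents_of(iid) if iid in self.ped else None
            if par is not None and par[k] in self.subset:
                w = self.weight(iid, k)
                val = w * self.hap_post(par[k], 0) + (1 - w) * self.hap_post(par[k], 1)
            else:
                val = self.freq.copy()
            self._hap_prior[key] = val
        return self._hap_prior[key]

    def hap_post(self, iid: str, k: int) -> np.ndarray:
        """P(hap k = alt) including the individual's own dense calls."""
        key = (iid, k)
        if key not in self._hap_post:
            prior = self.hap_prior(iid, k)
            obs = self.observed(iid)
            g = self.calls(iid)
            if self.mode == "benchmark" and self.phase is not None and \
                    self.phase.has_individual(iid):
                truth = self.phase.haplotype(iid, k)[self.ph_idx].astype(float)
                val = np.where(obs, truth, prior)
            else:
                hetval = np.full(self.V, 0.5)
                obs_val = np.where(g == 1, hetval, g / 2.0)
                val = np.where(obs, obs_val, prior)
            self._hap_post[key] = val
        return self._hap_post[key]

    def pair_dist(self, iid: str) -> np.ndarray:
        """(V, 4) distribution over the ordered haplotype pair
        (00, 01, 10, 11)."""
        p0, p1 = self.hap_prior(iid, 0), self.hap_prior(iid, 1)
        ind = np.stack(
            [(1 - p0) * (1 - p1), (1 - p0) * p1, p0 * (1 - p1), p0 * p1], axis=1
        )
        obs = self.observed(iid)
        if not obs.any():
            return ind
        g = self.calls(iid)
        if self.mode == "benchmark" and self.phase is not None and \
                self.phase.has_individual(iid):
            h0 = self.phase.haplotype(iid, 0)[self.ph_idx]
            h1 = self.phase.haplotype(iid, 1)[self.ph_idx]
            hard = np.zeros((self.V, 4))
            hard[np.arange(self.V), 2 * h0 + h1] = 1.0
        else:
            hard = np.zeros((self.V, 4))
            hard[g == 0, 0] = 1.0
            hard[g == 2, 3] = 1.0
            hard[g == 1, 1] = 0.5
            hard[g == 1, 2] = 0.5
        return np.where(obs[:, None], hard, ind)

    def transmit_alt(self, iid: str) -> np.ndarray:
        """P(iid transmits alt) marginalised over phase — used for the
        'other parent' of a descendant."""
        return 0.5 * (self.hap_post(iid, 0) + self.hap_post(iid, 1))

    # -- likelihoods -------------------------------------------------------
    @staticmethod
    def _geno_lik(g: np.ndarray, t: np.ndarray, o: np.ndarray) -> np.ndarray:
        """P(child genotype | focal transmit prob t, other transmit prob o).

        ``t`` has shape (V, *extra); ``g`` and ``o`` are (V,).
        """
        extra = t.ndim - 1
        gx = g.reshape((-1,) + (1,) * extra)
        ox = o.reshape((-1,) + (1,) * extra)
        l0 = (1 - t) * (1 - ox)
        l1 = t * (1 - ox) + (1 - t) * ox
        l2 = t * ox
        out = np.where(gx == 0, l0, np.where(gx == 1, l1, np.where(gx == 2, l2, 1.0)))
        return np.where(gx == MISSING, 1.0, out)

    def descendant_lik(self, c: str, k_focal: int, t: np.ndarray) -> np.ndarray:
        """Likelihood of the dense evidence on ``c`` and c's subset
        descendants, given P(c's haplotype-from-focal-parent = alt) = t.

        Evidence below an observed site is ignored (the genotype screens
        it off to good approximation); branches are treated as
        independent.
        """
        o = self.hap_prior(c, 1 - k_focal)
        g = self.calls(c)
        geno = self._geno_lik(g, t, o)
        obs = self.observed(c)
        desc = np.ones_like(t)
        for gc in self.ped.children_of(c) if c in self.ped else []:
            if gc not in self.subset:
                continue
            par = self.ped.parents_of(gc)
            k_c = 0 if par[0] == c else 1
            u = self.weight(gc, k_c).reshape((-1,) + (1,) * (t.ndim - 1))
            hap_focal = t
            hap_other = o.reshape((-1,) + (1,) * (t.ndim - 1)) * np.ones_like(t)
            h0 = hap_focal if k_focal == 0 else hap_other
            h1 = hap_other if k_focal == 0 else hap_focal
            q = u * h0 + (1 - u) * h1
            desc = desc * self.descendant_lik(gc, k_c, q)
        mask = obs.reshape((-1,) + (1,) * (t.ndim - 1))
        return np.where(mask, geno, desc)


def impute_family(
    subset: FamilySubset,
    dense: GenotypeMatrix,
    segs: dict[tuple[str, int], TransmissionSegments],
    masked: str,
    ped: Pedigree,
    *,
    mode: str = "agnostic",
    phase: HaplotypePanel | None = None,
    observed_calls: GenotypeMatrix | None = None,
) -> GenotypeProbabilities:
    """Posterior genotype 3-vectors for ``masked`` at every dense variant.

    Evidence is combined exactly over the masked individual's nuclear
    family (both parents' haplotype pairs and all siblings jointly) and
    approximately beyond it; sites with no informative relatives fall
    back to the Hardy-Weinberg prior at the subset allele frequency and
    are flagged on the result as ``low_confidence``.

    ``observed_calls``, when given, is a scaffold holding the masked
    individual's own observed (or accepted best-guess) calls: the
    posterior at those sites is the one-hot observed genotype — the
    family stage never contradicts an observed scaffold site.
    """
    if masked != subset.masked:
        raise ValueError("masked id does not match the subset")
    _reject_loops(ped)
    ev = _FamilyEvidence(subset, dense, segs, ped, mode, phase)
    V = ev.V
    f = ev.freq

    par = ped.parents_of(masked)
    if par is not None and all(p in subset for p in par):
        F, M = par
        PF, PM = ev.pair_dist(F), ev.pair_dist(M)  # (V, 4)
        sib_l = np.ones((V, 4, 4))
        for sib in ped.siblings_of(masked):
            if sib not in subset or not ev.observed(sib).any():
                continue
            wf = ev.weight(sib, 0)[:, None]
            wm = ev.weight(sib, 1)[:, None]
            tf = wf * _COMBO_H0[None, :] + (1 - wf) * _COMBO_H1[None, :]  # (V,4)
            tm = wm * _COMBO_H0[None, :] + (1 - wm) * _COMBO_H1[None, :]
            g = ev.calls(sib)[:, None, None]
            tfx, tmx = tf[:, :, None], tm[:, None, :]
            l0 = (1 - tfx) * (1 - tmx)
            l1 = tfx * (1 - tmx) + (1 - tfx) * tmx
            l2 = tfx * tmx
            lg = np.where(g == 0, l0, np.where(g == 1, l1, np.where(g == 2, l2, 1.0)))
            sib_l *= np.where(g == MISSING, 1.0, lg)
        wf_m = ev.weight(masked, 0)[:, None]
        wm_m = ev.weight(masked, 1)[:, None]
        tF = wf_m * _COMBO_H0[None, :] + (1 - wf_m) * _COMBO_H1[None, :]  # (V,4)
        tM = wm_m * _COMBO_H0[None, :] + (1 - wm_m) * _COMBO_H1[None, :]
        aF = np.stack([1 - tF, tF], axis=2)  # (V,4,2): P(aF | comboF)
        aM = np.stack([1 - tM, tM], axis=2)
        joint = (
            PF[:, :, None, None, None]
            * PM[:, None, :, None, None]
            * sib_l[:, :, :, None, None]
            * aF[:, :, None, :, None]
            * aM[:, None, :, None, :]
        )
        pair = joint.sum(axis=(1, 2))  # (V, 2, 2) over (aF, aM)
        pair = _apply_children(ev, masked, pair, from_parents=True)
    else:
        b0 = np.stack([1 - f, f], axis=1)  # (V, 2)
        pair = b0[:, :, None] * b0[:, None, :]
        pair = _apply_children(ev, masked, pair, from_parents=False)

    tot = pair.sum(axis=(1, 2), keepdims=True)
    hw = np.stack(
        [
            np.stack([(1 - f) * (1 - f), (1 - f) * f], axis=1),
            np.stack([f * (1 - f), f * f], axis=1),
        ],
        axis=1,
    )
    pair = np.where(tot > 0, pair / np.maximum(tot, 1e-300), hw)
    probs = np.stack(
        [pair[:, 0, 0], pair[:, 0, 1] + pair[:, 1, 0], pair[:, 1, 1]], axis=1
    )
    probs = probs / probs.sum(axis=1, keepdims=True)

    low_conf = ~ev.any_observed
    if observed_calls is not None and observed_calls.has_individual(masked):
        col = {v.vid: j for j, v in enumerate(dense.variants)}
        row = observed_calls.row(masked)
        for j, var in enumerate(observed_calls.variants):
            if var.vid in col and row[j] != MISSING:
                probs[col[var.vid]] = 0.0
                probs[col[var.vid], row[j]] = 1.0
                low_conf[col[var.vid]] = False
    out = GenotypeProbabilities([masked], dense.variants, probs[None, :, :])
    out.low_confidence = low_conf  # type: ignore[attr-defined]
    return out


def _apply_children(
    ev: _FamilyEvidence, masked: str, pair: np.ndarray, from_parents: bool
) -> np.ndarray:
    """Multiply the masked individual's hap-pair distribution (V, 2, 2)
    by the likelihood of each of their children's branches."""
    ped = ev.ped
    if masked not in ped:
        return pair
    # masked's haplotype alleles on the (aF, aM) grid: h0 = aF, h1 = aM
    grid_h0 = np.array([[0.0, 0.0], [1.0, 1.0]]).reshape(1, 2, 2)
    grid_h1 = np.array([[0.0, 1.0], [0.0, 1.0]]).reshape(1, 2, 2)
    for child in ped.children_of(masked):
        if child not in ev.subset:
            continue
        cf, _cm = ped.parents_of(child)  # type: ignore[misc]
        k_m = 0 if cf == masked else 1
        u = ev.weight(child, k_m)[:, None, None]
        q = u * grid_h0 + (1 - u) * grid_h1
        pair = pair * ev.descendant_lik(child, k_m, q)
    return pair
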