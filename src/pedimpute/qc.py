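"""Quality control and marker-set construction.

Missingness filters (strict "more than" thresholds), per-variant minor
allele frequency, pairwise genotype r-squared, greedy windowed LD
pruning (PLINK ``--indep-pairwise`` semantics), and LD-cluster
definition (each high-r2 pair plus all intervening markers, merged into
maximal intervals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

__all__ = [
    "VariantStats",
    "LDResult",
    "filter_missingness",
    "compute_variant_stats",
    "ld_r2",
    "prune_ld",
    "define_clusters",
]


@dataclass(frozen=True)
class VariantStats:
    vid: str
    call_rate: float
    maf: float
    polymorphic: bool
    defined: bool = True


@dataclass(frozen=True)
class LDResult:
    vid_a: str
    vid_b: str
    r2: float
    defined: bool


def filter_missingness(
    g: GenotypeMatrix,
    max_variant_missing: float = 0.05,
    max_individual_missing: float = 0.05,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove variants, then individuals, whose missing fraction is
    *strictly greater* than the threshold.

    Each pass filters variants first and recomputes individual
    missingness on the variant-filtered matrix; passes repeat until a
    fixed point (removing an individual can push a variant over the
    threshold), which makes the filter idempotent.  Returns the
    filtered matrix and a report of removals
    ``(id, type, missing_fraction, action)``.
    """
    for t in (max_variant_missing, max_individual_missing):
        if not 0 <= t <= 1:
            raise ValueError(f"threshold {t} outside [0, 1]")
    rows: list[dict] = []
    out = g
    while True:
        removed = 0
        miss = out.missing_mask()
        vfrac = miss.mean(axis=0) if out.n_individuals else np.zeros(out.n_variants)
        keep_v = np.flatnonzero(~(vfrac > max_variant_missing))
        for j in np.flatnonzero(vfrac > max_variant_missing):
            rows.append(
                dict(id=out.variants[j].vid, type="variant",
                     missing_fraction=float(vfrac[j]), action="removed")
            )
            removed += 1
        g2 = out.subset(None, list(keep_v))
        ifrac = (
            g2.missing_mask().mean(axis=1)
            if g2.n_variants
            else np.zeros(g2.n_individuals)
        )
        keep_i = [
            iid for n, iid in enumerate(g2.individuals)
            if not ifrac[n] > max_individual_missing
        ]
        for n, iid in enumerate(g2.individuals):
            if ifrac[n] > max_individual_missing:
                rows.append(
                    dict(id=iid, type="individual",
                         missing_fraction=float(ifrac[n]), action="removed")
                )
                removed += 1
        out = g2.subset(keep_i, None)
        if removed == 0:
            break
    report = pd.DataFrame(rows, columns=["id", "type", "missing_fraction", "action"])
    if out.n_variants == 0 or out.n_individuals == 0:
        report.attrs["empty_after_filtering"] = True
    return out, report


def compute_variant_stats(g: GenotypeMatrix) -> list[VariantStats]:
    """Call rate and MAF per variant, from non-missing calls only.

    Monomorphic variants get ``maf = 0`` with ``polymorphic=False``;
    variants with zero non-missing calls are flagged undefined.
    """
    out: list[VariantStats] = []
    for j, var in enumerate(g.variants):
        col = g.calls[:, j]
        obs = col[col != MISSING]
        call_rate = len(obs) / g.n_individuals if g.n_individuals else 0.0
        if len(obs) == 0:
            out.append(VariantStats(var.vid, 0.0, float("nan"), False, defined=False))
            continue
        p = obs.sum() / (2 * len(obs))
        maf = float(min(p, 1 - p))
        out.append(VariantStats(var.vid, call_rate, maf, 0.0 < p < 1.0))
    return out


def _r2_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan"), False
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    if xs.std() == 0 or ys.std() == 0:
        return float("nan"), False
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r), True


def ld_r2(g: GenotypeMatrix, vid_a: str, vid_b: str) -> LDResult:
    """Squared Pearson correlation of genotype dosages over individuals
    complete at both variants (composite r2, PLINK convention).
    Undefined when either variant is monomorphic among complete pairs or
    fewer than 2 complete pairs exist."""
    a, b = g.variant_index(vid_a), g.variant_index(vid_b)
    r2, ok = _r2_pair(g.calls[:, a], g.calls[:, b])
    return LDResult(vid_a, vid_b, r2, ok)


def _pairwise_r2(calls: np.ndarray) -> np.ndarray:
    """All-pairs composite r2 for a call submatrix; NaN where undefined."""
    V = calls.shape[1]
    out = np.full((V, V), np.nan)
    for i in range(V):
        out[i, i] = 1.0 if _r2_pair(calls[:, i], calls[:, i])[1] else np.nan
        for j in range(i + 1, V):
            r2, ok = _r2_pair(calls[:, i], calls[:, j])
            out[i, j] = out[j, i] = r2 if ok else np.nan
    return out


def prune_ld(
    g: GenotypeMatrix,
    r2_threshold: float = 0.2,
    window_size: int = 50,
    step: int = 5,
) -> list[str]:
    """Greedy windowed LD pruning.

    Within each sliding window of ``window_size`` variants (advancing by
    ``step``), repeatedly remove one variant of the worst-offending pair
    with r2 >= threshold — the member with lower MAF, or at equal MAF the
    later position — until no within-window pair violates the threshold.
    Returns the surviving variant ids in position order.
    """
    if window_size < 2:
        raise ValueError("window_size must be at least 2")
    stats = {s.vid: s for s in compute_variant_stats(g)}
    alive = np.ones(g.n_variants, dtype=bool)
    V = g.n_variants
    starts = range(0, max(V - 1, 1), step)
    for start in starts:
        window = [j for j in range(start, min(start + window_size, V)) if alive[j]]
        while True:
            idx = [j for j in window if alive[j]]
            if len(idx) < 2:
                break
            sub = _pairwise_r2(g.calls[:, idx])
            np.fill_diagonal(sub, np.nan)
            if np.all(~(sub >= r2_threshold)):
                break
            flat = np.nanargmax(sub)
            a, b = divmod(flat, len(idx))
            ja, jb = idx[a], idx[b]
            ma = stats[g.variants[ja].vid].maf
            mb = stats[g.variants[jb].vid].maf
            ma = -1.0 if np.isnan(ma) else ma
            mb = -1.0 if np.isnan(mb) else mb
            if ma < mb:
                drop = ja
            elif mb < ma:
                drop = jb
            else:  # equal MAF: drop the later position
                drop = max(ja, jb)
            alive[drop] = False
        if start + window_size >= V:
            break
    return [g.variants[j].vid for j in np.flatnonzero(alive)]


def define_clusters(g: GenotypeMatrix, r2_threshold: float = 0.2) -> list[list[str]]:
    """Partition markers into LD clusters and singletons.

    Every pair with r2 strictly above the threshold seeds an interval
    covering the pair and all physically intervening markers; overlapping
    intervals are merged into maximal runs.  Pairs with undefined r2
    never seed clusters.
    """
    V = g.n_variants
    r2 = _pairwise_r2(g.calls)
    intervals: list[tuple[int, int]] = []
    for i in range(V):
        for j in range(i + 1, V):
            if not np.isnan(r2[i, j]) and r2[i, j] > r2_threshold:
                intervals.append((i, j))
    merged: list[list[int]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    clusters: list[list[str]] = []
    cursor = 0
    for lo, hi in merged:
        for j in range(cursor, lo):
            clusters.append([g.variants[j].vid])
        clusters.append([g.variants[j].vid for j in range(lo, hi + 1)])
        cursor = hi + 1
    for j in range(cursor, V):
        clusters.append([g.variants[j].vid])
    return clusters
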