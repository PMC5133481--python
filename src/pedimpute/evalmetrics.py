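"""Accuracy assessment: IQS, dosage correlation, masking experiments.

The imputation quality score (IQS) is Cohen's Kappa computed on a 3x3
true-by-imputed genotype table whose cells are sums of posterior
probabilities rather than hard counts:

    kappa = (sum_i n_ii / n..  -  sum_i n_i. n_.i / n..^2)
            / (1 - sum_i n_i. n_.i / n..^2)

With degenerate (0/1) posteriors every cell is an integer and IQS equals
classical Kappa exactly.  Because the chance-agreement term grows as
variants get rarer, IQS — unlike concordance — stays honest for rare
variants; it can legally be negative.  Both IQS and the true-vs-imputed
dosage correlation are only meaningful when both the true and the
imputed (best-guess) genotypes are polymorphic, so undefined records are
flagged and excluded from summaries; the per-bin count of variants with
a defined score is reported alongside each mean/variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeProbabilities

__all__ = [
    "ContingencyTable",
    "QualityRecord",
    "MaskingPlan",
    "build_weighted_table",
    "kappa",
    "iqs",
    "dosage",
    "dosage_correlation",
    "run_masking_experiment",
    "summarize_by_maf",
    "DEFAULT_MAF_BINS",
]

DEFAULT_MAF_BINS: tuple[tuple[float, float], ...] = (
    (0.0, 0.01),
    (0.01, 0.05),
    (0.05, 0.4),
)


@dataclass
class ContingencyTable:
    """3x3 table; row = true genotype, column = imputed; real cells."""

    cells: np.ndarray

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.shape != (3, 3):
            raise ValueError("contingency table must be 3x3")
        if np.any(self.cells < 0):
            raise ValueError("contingency table cells must be nonnegative")

    @property
    def row_marginals(self) -> np.ndarray:
        return self.cells.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.cells.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.cells.sum())


def build_weighted_table(
    true_genotypes: Sequence[int], posteriors: np.ndarray
) -> ContingencyTable:
    """Probability-weighted tabulation: cell (i, j) accumulates the
    posterior mass on class j from every individual whose true genotype
    is i.  Individuals with a missing true genotype are excluded."""
    g = np.asarray(true_genotypes)
    p = np.asarray(posteriors, dtype=float)
    if p.shape != (len(g), 3):
        raise ValueError("posteriors must be n x 3 matching true genotypes")
    keep = g != MISSING
    g, p = g[keep], p[keep]
    if len(g) == 0:
        raise ValueError("no individuals with both truth and posterior")
    cells = np.zeros((3, 3))
    for i in range(3):
        cells[i] = p[g == i].sum(axis=0)
    return ContingencyTable(cells)


def kappa(t: ContingencyTable) -> float | None:
    """Cohen's Kappa for a (possibly probability-weighted) table.

    Returns ``None`` (undefined) when the chance-agreement term reaches
    1, which makes the denominator vanish.
    """
    n = t.total
    if n <= 0:
        raise ValueError("contingency table is empty")
    po = np.trace(t.cells) / n
    pe = float(t.row_marginals @ t.col_marginals) / (n * n)
    if abs(1.0 - pe) < 1e-12:
        return None
    return float((po - pe) / (1.0 - pe))


def _maf_of_calls(calls: np.ndarray) -> float:
    obs = calls[calls != MISSING]
    if len(obs) == 0:
        return 0.0
    p = obs.sum() / (2 * len(obs))
    return float(min(p, 1 - p))


def iqs(true_genotypes: Sequence[int], posteriors: np.ndarray) -> float | None:
    """Probability-weighted Kappa; ``None`` when undefined.

    Undefined when either the true or the imputed best-guess genotypes
    are monomorphic (allele frequency 0 or 1) or when chance agreement
    is total.  Equals classical Kappa exactly on degenerate posteriors.
    """
    g = np.asarray(true_genotypes)
    p = np.asarray(posteriors, dtype=float)
    keep = g != MISSING
    g, p = g[keep], p[keep]
    if len(g) == 0:
        return None
    if _maf_of_calls(g) == 0.0:
        return None
    if _maf_of_calls(p.argmax(axis=1)) == 0.0:
        return None
    return kappa(build_weighted_table(g, p))


def dosage(p) -> float:
    """Expected alt-allele count of one genotype 3-vector."""
    p = np.asarray(p, dtype=float)
    if p.shape != (3,) or np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("dosage needs a normalised genotype 3-vector")
    return float(p @ [0.0, 1.0, 2.0])


def dosage_correlation(
    true_genotypes: Sequence[int], posteriors: np.ndarray
) -> float | None:
    """Pearson correlation between true and imputed expected dosages;
    ``None`` when fewer than 2 pairs or either side has zero variance
    (the polymorphism requirement)."""
    g = np.asarray(true_genotypes, dtype=float)
    p = np.asarray(posteriors, dtype=float)
    keep = np.asarray(true_genotypes) != MISSING
    g, p = g[keep], p[keep]
    if len(g) < 2:
        return None
    d = p @ np.array([0.0, 1.0, 2.0])
    if g.std() == 0 or d.std() == 0:
        return None
    return float(np.corrcoef(g, d)[0, 1])


# ---------------------------------------------------------------------------
# masking experiments


@dataclass(frozen=True)
class QualityRecord:
    method: str
    vid: str
    true_maf: float
    iqs: float | None
    correlation: float | None
    valid_iqs: bool
    valid_corr: bool
    n_individuals: int


@dataclass(frozen=True)
class MaskingPlan:
    """Which individuals to mask, one replicate each."""

    ids: tuple[str, ...]
    seed: int

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("masking plan contains duplicate ids")

    @classmethod
    def random(cls, eligible: Sequence[str], n: int, seed: int) -> "MaskingPlan":
        """The study's selection rule: randomly order the eligible ids
        and take the first ``n``."""
        if n > len(eligible):
            raise ValueError(
                f"cannot mask {n} individuals: only {len(eligible)} are "
                "eligible (need both GWAS and sequence data)"
            )
        rng = np.random.default_rng(seed)
        order = list(np.array(eligible)[rng.permutation(len(eligible))])
        return cls(tuple(order[:n]), seed)


MethodFn = Callable[[str], GenotypeProbabilities]
"""A method maps a masked individual id to their genotype posteriors."""


def run_masking_experiment(
    truth_calls: Mapping[str, np.ndarray],
    target_variants: Sequence,
    true_maf: np.ndarray,
    methods: Mapping[str, MethodFn],
    plan: MaskingPlan,
) -> tuple[list[QualityRecord], pd.DataFrame]:
    """Leave-one-out masking loop.

    For each planned individual, each method imputes them with their
    dense data hidden; the posteriors at ``target_variants`` are scored
    against ``truth_calls[iid]`` (the hidden truth).  Individuals are
    pooled across replicates per variant before computing IQS and
    dosage correlation, and each record carries the polymorphism-rule
    validity flags.  ``true_maf`` (per target variant, from the full
    simulated truth) is attached for MAF binning.
    """
    if len(plan.ids) == 0:
        warnings.warn("empty masking plan: no records produced", stacklevel=2)
        return [], _records_frame([])
    tv = list(target_variants)
    pooled: dict[str, tuple[list[list[int]], list[list[np.ndarray]]]] = {
        m: ([[] for _ in tv], [[] for _ in tv]) for m in methods
    }
    for iid in plan.ids:
        truth = np.asarray(truth_calls[iid])
        if len(truth) != len(tv):
            raise ValueError("truth vector does not match target variants")
        for mname, fn in methods.items():
            gp = fn(iid)
            col = {v.vid: j for j, v in enumerate(gp.variants)}
            probs = gp.row(iid)
            gsink, psink = pooled[mname]
            for j, var in enumerate(tv):
                if var.vid not in col:
                    continue
                gsink[j].append(int(truth[j]))
                psink[j].append(probs[col[var.vid]])
    records: list[QualityRecord] = []
    for mname in methods:
        gsink, psink = pooled[mname]
        for j, var in enumerate(tv):
            if not gsink[j]:
                continue
            g = np.array(gsink[j])
            p = np.array(psink[j])
            q = iqs(g, p)
            c = dosage_correlation(g, p)
            records.append(
                QualityRecord(
                    method=mname,
                    vid=var.vid,
                    true_maf=float(true_maf[j]),
                    iqs=q,
                    correlation=c,
                    valid_iqs=q is not None,
                    valid_corr=c is not None,
                    n_individuals=int((g != MISSING).sum()),
                )
            )
    return records, _records_frame(records)


def _records_frame(records: list[QualityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                method=r.method,
                vid=r.vid,
                true_maf=r.true_maf,
                iqs=np.nan if r.iqs is None else r.iqs,
                correlation=np.nan if r.correlation is None else r.correlation,
                valid_iqs=r.valid_iqs,
                valid_corr=r.valid_corr,
                n_individuals=r.n_individuals,
            )
            for r in records
        ],
        columns=[
            "method", "vid", "true_maf", "iqs", "correlation",
            "valid_iqs", "valid_corr", "n_individuals",
        ],
    )


def summarize_by_maf(
    records: pd.DataFrame | list[QualityRecord],
    bins: Sequence[tuple[float, float]] = DEFAULT_MAF_BINS,
) -> pd.DataFrame:
    """Per MAF bin, per method, per metric: count of valid records
    (``n_snp_p``), mean, and variance.

    Bins are half-open ``(low, high]``; a variant whose true MAF falls
    outside every bin is excluded and counted in the ``excluded``
    attribute of the result.
    """
    bins = list(bins)
    for a, b in zip(sorted(bins), sorted(bins)[1:]):
        if a[1] > b[0]:
            raise ValueError(f"overlapping MAF bins: {a} and {b}")
    df = records if isinstance(records, pd.DataFrame) else _records_frame(records)
    rows = []
    excluded = 0
    assigned = np.full(len(df), -1)
    maf = df["true_maf"].to_numpy() if len(df) else np.empty(0)
    for b, (lo, hi) in enumerate(bins):
        assigned[(maf > lo) & (maf <= hi)] = b
    excluded = int((assigned == -1).sum())
    for b, (lo, hi) in enumerate(bins):
        sub = df[assigned == b] if len(df) else df
        for method in sorted(df["method"].unique()) if len(df) else []:
            ms = sub[sub["method"] == method]
            for metric in ("iqs", "correlation"):
                valid_col = "valid_iqs" if metric == "iqs" else "valid_corr"
                vals = ms[ms[valid_col]][metric].to_numpy()
                rows.append(
                    dict(
                        bin_low=lo,
                        bin_high=hi,
                        method=method,
                        metric=metric,
                        n_snp_p=len(vals),
                        mean=float(np.mean(vals)) if len(vals) else np.nan,
                        var=float(np.var(vals, ddof=1)) if len(vals) > 1 else np.nan,
                    )
                )
    out = pd.DataFrame(
        rows,
        columns=["bin_low", "bin_high", "method", "metric", "n_snp_p", "mean", "var"],
    )
    out.attrs["excluded"] = excluded
    return out
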