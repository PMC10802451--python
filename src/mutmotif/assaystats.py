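"""Forward-mutation plate-assay statistics.

A fluctuation-style plating assay measures forward mutation at a
counter-selectable reporter (canavanine resistance via CAN1 loss):
each culture yields a resistant-colony titer and a viable-colony titer,

    mutation frequency = Can^R colonies per ml / viable colonies per ml
    viability (%)      = 100 * treated viable titer / untreated viable titer

Group comparisons are nonparametric: medians with distribution-free
order-statistic confidence intervals, fold-changes as ratios of group
medians, and a one-sided Mann-Whitney U test for the alternative that
treated cultures have higher mutation frequencies.  The exact test
enumerates the permutation distribution of U (with midranks for ties)
whenever the number of group assignments is small enough; otherwise the
tie-corrected normal approximation with continuity correction is used.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from itertools import combinations
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom, norm, rankdata

__all__ = [
    "AssayMeasurement",
    "GroupComparison",
    "MedianCI",
    "mutation_frequency",
    "viability_percent",
    "titer_per_ml",
    "median_with_ci",
    "mann_whitney_one_sided",
    "compare_groups",
    "read_assay_table",
    "write_assay_table",
    "write_comparisons",
]


def mutation_frequency(canr_per_ml: float, viable_per_ml: float) -> float:
    """Can^R titer over viable titer."""
    if canr_per_ml < 0 or viable_per_ml < 0:
        raise ValueError("titers must be non-negative")
    if viable_per_ml == 0:
        raise ZeroDivisionError("viable titer is zero; frequency undefined")
    return canr_per_ml / viable_per_ml


def viability_percent(treated_viable_per_ml: float,
                      untreated_viable_per_ml: float) -> float:
    """100 x treated / untreated viable titer (not clamped at 100)."""
    if treated_viable_per_ml < 0 or untreated_viable_per_ml < 0:
        raise ValueError("titers must be non-negative")
    if untreated_viable_per_ml == 0:
        raise ZeroDivisionError("untreated viable titer is zero")
    return 100.0 * treated_viable_per_ml / untreated_viable_per_ml


def titer_per_ml(colony_count: float, volume_plated_ml: float,
                 dilution_factor: float = 1.0) -> float:
    """Colonies per ml of the original culture from a plate count."""
    if volume_plated_ml <= 0 or dilution_factor <= 0:
        raise ValueError("volume and dilution factor must be positive")
    return colony_count * dilution_factor / volume_plated_ml


@dataclass(frozen=True)
class AssayMeasurement:
    """One culture's plating result."""

    culture: str
    genotype: str
    treatment: str            # e.g. "water" or "acetaldehyde"
    canr_per_ml: float
    viable_per_ml: float
    dose: str = ""

    def __post_init__(self):
        if self.canr_per_ml < 0 or self.viable_per_ml < 0:
            raise ValueError("titers must be non-negative")

    @property
    def frequency(self) -> float:
        return mutation_frequency(self.canr_per_ml, self.viable_per_ml)


class MedianCI(NamedTuple):
    median: float
    lower: float
    upper: float
    coverage: float      # achieved (conservative) coverage of (lower, upper)
    exact: bool          # False when n too small, bounds fell back to min/max


def median_with_ci(values: Sequence[float], level: float = 0.95) -> MedianCI:
    """Sample median with a distribution-free CI from order statistics.

    The interval (x_(k), x_(n-k+1)) with k the largest integer such that
    2 * BinomCDF(k-1; n, 1/2) <= 1 - level has coverage >= level for any
    continuous distribution.  For n < 6 no such interval reaches 95%, so
    (min, max) is returned flagged non-exact.
    """
    if len(values) == 0:
        raise ValueError("empty input")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    med = float(np.median(x))
    alpha = 1.0 - level
    # largest k with 2*BinomCDF(k-1; n, 1/2) <= alpha gives the 1-based
    # interval (x_(k), x_(n-k+1)) with coverage 1 - 2*BinomCDF(k-1)
    k = 0
    while k < (n + 1) // 2 and 2.0 * binom.cdf(k, n, 0.5) <= alpha:
        k += 1
    if k == 0:
        # even (min, max) misses the target level; fall back, flagged
        return MedianCI(med, float(x[0]), float(x[-1]),
                        float(1.0 - 2.0 ** (1 - n)), exact=False)
    coverage = 1.0 - 2.0 * float(binom.cdf(k - 1, n, 0.5))
    return MedianCI(med, float(x[k - 1]), float(x[n - k]), coverage, exact=True)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for the alternative 'y stochastically greater than x'."""
    gt = (y[:, None] > x[None, :]).sum()
    eq = (y[:, None] == x[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_one_sided(x: Sequence[float], y: Sequence[float],
                           max_exact: int = 10 ** 6) -> tuple[float, float]:
    """One-sided Mann-Whitney U test: is ``y`` stochastically greater?

    Returns ``(U, p)`` where U counts pairs with y > x (ties at 1/2).
    When C(n1+n2, n1) <= ``max_exact`` the p-value is exact, from full
    enumeration of the permutation distribution of U over all group
    assignments of the pooled values (midranks handle ties); beyond
    that, the normal approximation with tie-corrected variance and
    continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    u_obs = _u_statistic(x, y)

    if math.comb(n1 + n2, n1) <= max_exact:
        pooled = np.concatenate([x, y])
        ranks = rankdata(pooled)               # midranks
        offset = n2 * (n2 + 1) / 2.0
        n = n1 + n2
        # enumerate the smaller group's index sets
        if n2 <= n1:
            combos = np.fromiter(
                (i for c in combinations(range(n), n2) for i in c),
                dtype=np.intp).reshape(-1, n2)
            u_all = ranks[combos].sum(axis=1) - offset
        else:
            combos = np.fromiter(
                (i for c in combinations(range(n), n1) for i in c),
                dtype=np.intp).reshape(-1, n1)
            # rank sum of y = total - rank sum of x
            u_all = ranks.sum() - ranks[combos].sum(axis=1) - offset
        p = float(np.mean(u_all >= u_obs - 1e-9))
        return u_obs, max(p, 1.0 / len(u_all))

    # normal approximation, tie-corrected variance, continuity correction
    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / (n * (n - 1))
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0
    z = (u_obs - mu - 0.5) / math.sqrt(sigma2)
    return u_obs, float(min(max(norm.sf(z), 5e-324), 1.0))


@dataclass
class GroupComparison:
    genotype: str
    untreated_label: str
    treated_label: str
    untreated_frequencies: list = field(default_factory=list)
    treated_frequencies: list = field(default_factory=list)
    untreated_median: MedianCI | None = None
    treated_median: MedianCI | None = None
    fold_change: float | None = None
    u_statistic: float | None = None
    p: float | None = None
    flags: tuple = ()


def compare_groups(untreated: Sequence[AssayMeasurement],
                   treated: Sequence[AssayMeasurement],
                   fold_method: str = "ratio-of-medians") -> GroupComparison:
    """Treated-vs-untreated mutation-frequency comparison for one
    genotype: medians with CIs, fold-change, one-sided Mann-Whitney p.

    ``fold_method`` is ``ratio-of-medians`` (default: median of treated
    frequencies over median of untreated) or ``median-of-ratios``
    (median of per-culture treated/untreated ratios, paired by order;
    requires equal group sizes).
    """
    untreated = list(untreated)
    treated = list(treated)
    if not untreated or not treated:
        raise ValueError("both groups must be non-empty")
    genotypes = {m.genotype for m in untreated} | {m.genotype for m in treated}
    if len(genotypes) > 1:
        raise ValueError(f"groups mix genotypes: {sorted(genotypes)}")

    fu = [m.frequency for m in untreated]
    ft = [m.frequency for m in treated]
    mu = median_with_ci(fu)
    mt = median_with_ci(ft)

    flags = []
    if fold_method == "ratio-of-medians":
        if mu.median == 0:
            fold = None
            flags.append("untreated_median_zero")
        else:
            fold = mt.median / mu.median
    elif fold_method == "median-of-ratios":
        if len(fu) != len(ft):
            raise ValueError("median-of-ratios requires equal group sizes")
        if any(v == 0 for v in fu):
            fold = None
            flags.append("untreated_frequency_zero")
        else:
            fold = float(np.median([t / u for u, t in zip(fu, ft)]))
    else:
        raise ValueError(f"unknown fold_method {fold_method!r}")

    u_stat, p = mann_whitney_one_sided(fu, ft)
    return GroupComparison(
        genotype=untreated[0].genotype,
        untreated_label=untreated[0].treatment,
        treated_label=treated[0].treatment,
        untreated_frequencies=fu, treated_frequencies=ft,
        untreated_median=mu, treated_median=mt,
        fold_change=fold, u_statistic=u_stat, p=p, flags=tuple(flags))


_ASSAY_COLUMNS = ["culture", "genotype", "treatment", "dose",
                  "canr_per_ml", "viable_per_ml"]


def read_assay_table(path) -> list[AssayMeasurement]:
    """Read a delimited assay table.

    Either provides ``canr_per_ml``/``viable_per_ml`` directly, or raw
    plate counts with dilution bookkeeping (columns ``canr_count``,
    ``viable_count``, ``volume_plated_ml``, ``canr_dilution``,
    ``viable_dilution``), which are converted to titers.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "canr_per_ml" not in df.columns and "canr_count" in df.columns:
        df["canr_per_ml"] = [
            titer_per_ml(r.canr_count, r.volume_plated_ml, r.canr_dilution)
            for r in df.itertuples()]
        df["viable_per_ml"] = [
            titer_per_ml(r.viable_count, r.volume_plated_ml, r.viable_dilution)
            for r in df.itertuples()]
    missing = [c for c in _ASSAY_COLUMNS if c not in df.columns and c != "dose"]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [AssayMeasurement(
        culture=str(r.culture), genotype=str(r.genotype),
        treatment=str(r.treatment),
        dose=str(getattr(r, "dose", "")),
        canr_per_ml=float(r.canr_per_ml),
        viable_per_ml=float(r.viable_per_ml))
        for r in df.itertuples(index=False)]


def write_assay_table(measurements: Sequence[AssayMeasurement], path) -> None:
    pd.DataFrame([(m.culture, m.genotype, m.treatment, m.dose,
                   m.canr_per_ml, m.viable_per_ml) for m in measurements],
                 columns=_ASSAY_COLUMNS).to_csv(path, sep="\t", index=False)


def write_comparisons(comparisons: Sequence[GroupComparison],
                      tsv_path=None, json_path=None) -> None:
    rows = []
    for c in comparisons:
        rows.append({
            "genotype": c.genotype,
            "untreated_median": c.untreated_median.median,
            "untreated_ci_lower": c.untreated_median.lower,
            "untreated_ci_upper": c.untreated_median.upper,
            "treated_median": c.treated_median.median,
            "treated_ci_lower": c.treated_median.lower,
            "treated_ci_upper": c.treated_median.upper,
            "fold_change": c.fold_change,
            "u_statistic": c.u_statistic,
            "p_one_sided": c.p,
            "flags": ";".join(c.flags),
        })
    if tsv_path is not None:
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(rows, indent=2) + "\n")
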