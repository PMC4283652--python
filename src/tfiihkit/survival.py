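"""UV-survival analysis: death rates, odds ratios, simultaneous intervals.

Each fly line contributes a 2x2 table (control vs irradiated arm, dead vs
alive embryos).  UV sensitivity of a line is summarized by the sample odds
ratio of death in the irradiated over the control arm — a sensitive line
sits above 1 — with Wald confidence intervals on the log-odds-ratio scale.
Because many lines are compared at once, the intervals are *simultaneous*:
the per-comparison level is sharpened (Sidak by default, Bonferroni
optionally) so that the probability that every interval in the family
covers its true odds ratio reaches the nominal level.

Zero cells are handled with the Haldane-Anscombe correction (+0.5 to all
four cells, flagged), keeping estimates and standard errors finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SurvivalCounts",
    "OddsRatioResult",
    "UVInducedDeathRate",
    "CoverageResult",
    "death_rate",
    "uv_induced_death_rate",
    "odds_ratio",
    "simultaneous_ci",
    "compare_to_reference",
    "analyze_survival",
    "counts_from_frame",
    "critical_z",
    "coverage_simulation",
]

ARMS = ("control", "irradiated")


@dataclass(frozen=True)
class SurvivalCounts:
    """Embryo counts for one genotype and one arm."""

    genotype: str
    arm: str
    n_total: int
    n_dead: int
    uv_dose: float | None = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0 <= self.n_dead <= self.n_total:
            raise ValueError("need 0 <= n_dead <= n_total")

    @property
    def n_alive(self) -> int:
        return self.n_total - self.n_dead


@dataclass(frozen=True)
class OddsRatioResult:
    """Sample odds ratio of one genotype, optionally with simultaneous CI."""

    genotype: str
    or_hat: float
    log_or: float
    se_log_or: float
    continuity_corrected: bool
    degenerate: bool = False
    ci_low: float | None = None
    ci_high: float | None = None
    family_size: int | None = None
    nominal_level: float | None = None
    method: str | None = None


class UVInducedDeathRate(NamedTuple):
    rate: float
    floored: bool


def death_rate(counts: SurvivalCounts) -> float:
    """Fraction of dead embryos in one arm."""
    return counts.n_dead / counts.n_total


def uv_induced_death_rate(
    control: SurvivalCounts, irradiated: SurvivalCounts
) -> UVInducedDeathRate:
    """Irradiated minus control death rate, floored at 0.

    A negative difference (irradiated arm did better) is floored to 0 and
    flagged rather than reported as protective.
    """
    if control.genotype != irradiated.genotype:
        raise ValueError(
            f"genotype mismatch: {control.genotype!r} vs {irradiated.genotype!r}"
        )
    diff = death_rate(irradiated) - death_rate(control)
    if diff < 0:
        return UVInducedDeathRate(0.0, True)
    return UVInducedDeathRate(diff, False)


def _corrected_cells(a, b, c, d):
    """Haldane-Anscombe: +0.5 to all four cells of any table with a zero cell.

    Works elementwise on arrays; returns (cells..., corrected_mask).
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    half = np.where(zero, 0.5, 0.0)
    return a + half, b + half, c + half, d + half, zero


def odds_ratio(control: SurvivalCounts, irradiated: SurvivalCounts) -> OddsRatioResult:
    """Sample odds ratio of death: irradiated over control.

    OR = (dead_irr * alive_ctrl) / (alive_irr * dead_ctrl); with any zero
    cell all four cells get +0.5 (flagged).  A table that is degenerate even
    after correction — both arms all dead or both all alive — is returned
    flagged, not raised.
    """
    if control.genotype != irradiated.genotype:
        raise ValueError(
            f"genotype mismatch: {control.genotype!r} vs {irradiated.genotype!r}"
        )
    a, b = irradiated.n_dead, irradiated.n_alive
    c, d = control.n_dead, control.n_alive
    degenerate = (b == 0 and d == 0) or (a == 0 and c == 0)
    ac, bc_, cc, dc, zero = _corrected_cells(a, b, c, d)
    or_hat = float((ac * dc) / (bc_ * cc))
    log_or = math.log(or_hat)
    se = float(np.sqrt(1 / ac + 1 / bc_ + 1 / cc + 1 / dc))
    return OddsRatioResult(
        genotype=control.genotype,
        or_hat=or_hat,
        log_or=log_or,
        se_log_or=se,
        continuity_corrected=bool(zero),
        degenerate=degenerate,
    )


def critical_z(nominal_level: float, family_size: int, method: str = "sidak") -> float:
    """Two-sided critical value for simultaneous Wald intervals.

    Sidak sharpens the per-comparison level to ``level**(1/k)``
    (equivalently alpha' = 1 - (1-alpha)^(1/k)); Bonferroni uses alpha/k.
    Both reduce to the unadjusted z for a family of one.
    """
    if not 0 < nominal_level < 1:
        raise ValueError("nominal_level must be in (0, 1)")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    alpha = 1.0 - nominal_level
    if method == "sidak":
        alpha_pc = 1.0 - nominal_level ** (1.0 / family_size)
    elif method == "bonferroni":
        alpha_pc = alpha / family_size
    else:
        raise ValueError("method must be 'sidak' or 'bonferroni'")
    return float(norm.ppf(1.0 - alpha_pc / 2.0))


def simultaneous_ci(
    results: Sequence[OddsRatioResult],
    nominal_level: float = 0.95,
    method: str = "sidak",
) -> list[OddsRatioResult]:
    """Attach simultaneous Wald interval bounds to a family of odds ratios.

    Intervals are computed on the log-OR scale with the family-adjusted
    critical value and exponentiated; each contains its point estimate and
    is never narrower than the unadjusted interval.
    """
    k = len(results)
    z = critical_z(nominal_level, k, method)
    out = []
    for r in results:
        lo = math.exp(r.log_or - z * r.se_log_or)
        hi = math.exp(r.log_or + z * r.se_log_or)
        out.append(
            replace(
                r, ci_low=lo, ci_high=hi, family_size=k,
                nominal_level=nominal_level, method=method,
            )
        )
    return out


def compare_to_reference(
    results: Sequence[OddsRatioResult], reference_genotype: str
) -> pd.DataFrame:
    """Each genotype's OR relative to a reference line's OR.

    Reports the OR ratio and whether the genotype's simultaneous interval
    excludes the reference point estimate (a conservative screen for lines
    more UV-sensitive than the reference).
    """
    by_geno = {r.genotype: r for r in results}
    if reference_genotype not in by_geno:
        raise ValueError(f"reference genotype {reference_genotype!r} missing")
    ref = by_geno[reference_genotype]
    rows = []
    for r in results:
        excludes = None
        if r.ci_low is not None and r.ci_high is not None:
            excludes = not (r.ci_low <= ref.or_hat <= r.ci_high)
        rows.append((r.genotype, r.or_hat / ref.or_hat, excludes))
    return pd.DataFrame(
        rows, columns=["genotype", "or_ratio_vs_reference", "ci_excludes_reference"]
    )


def counts_from_frame(df: pd.DataFrame) -> dict[str, dict[str, SurvivalCounts]]:
    """Group a counts table into {genotype: {arm: SurvivalCounts}}."""
    out: dict[str, dict[str, SurvivalCounts]] = {}
    for row in df.itertuples(index=False):
        uv = getattr(row, "uv_dose", None)
        c = SurvivalCounts(
            genotype=str(row.genotype), arm=str(row.arm),
            n_total=int(row.n_total), n_dead=int(row.n_dead),
            uv_dose=None if uv is None or pd.isna(uv) else float(uv),
        )
        out.setdefault(c.genotype, {})[c.arm] = c
    for g, arms in out.items():
        missing = set(ARMS) - set(arms)
        if missing:
            raise ValueError(f"genotype {g!r} missing arm(s): {sorted(missing)}")
    return out


def analyze_survival(
    counts: pd.DataFrame,
    nominal_level: float = 0.95,
    method: str = "sidak",
    reference_genotype: str | None = None,
) -> pd.DataFrame:
    """Full per-genotype survival analysis from a long counts table.

    Returns one row per genotype with death rates, UV-induced death rate,
    the sample odds ratio and its simultaneous confidence interval, plus —
    when a reference line is given — the comparison against it.
    """
    grouped = counts_from_frame(counts)
    results = [odds_ratio(arms["control"], arms["irradiated"])
               for arms in grouped.values()]
    results = simultaneous_ci(results, nominal_level, method)
    rows = []
    for (genotype, arms), r in zip(grouped.items(), results):
        rate_c = death_rate(arms["control"])
        rate_i = death_rate(arms["irradiated"])
        induced = uv_induced_death_rate(arms["control"], arms["irradiated"])
        rows.append(
            {
                "genotype": genotype,
                "death_rate_control": rate_c,
                "death_rate_irradiated": rate_i,
                "uv_induced_death_rate": induced.rate,
                "uv_induced_floored": induced.floored,
                "or_hat": r.or_hat,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "corrected": r.continuity_corrected,
                "degenerate": r.degenerate,
            }
        )
    out = pd.DataFrame(rows)
    if reference_genotype is not None:
        cmp = compare_to_reference(results, reference_genotype)
        out = out.merge(cmp, on="genotype", how="left")
    return out


@dataclass(frozen=True)
class CoverageResult:
    """Joint-coverage estimate of the simultaneous-CI procedure."""

    coverage: float
    n_families: int
    n_covered: int
    family_size: int
    nominal_level: float
    method: str


def log_or_and_se(a, b, c, d):
    """Vectorized log odds ratio and Wald SE with Haldane-Anscombe correction.

    Cell layout: a = dead irradiated, b = alive irradiated, c = dead
    control, d = alive control.  This is the same arithmetic as
    :func:`odds_ratio`, exposed in array form for simulation studies.
    """
    ac, bc_, cc, dc, corrected = _corrected_cells(a, b, c, d)
    log_or = np.log((ac * dc) / (bc_ * cc))
    se = np.sqrt(1 / ac + 1 / bc_ + 1 / cc + 1 / dc)
    return log_or, se, corrected


def coverage_simulation(
    true_ors: Iterable[float],
    baseline_p: float = 0.115,
    n_per_arm: int = 100,
    n_families: int = 2000,
    nominal_level: float = 0.95,
    method: str = "sidak",
    seed: int = 0,
) -> CoverageResult:
    """Estimate joint coverage of the simultaneous intervals by simulation.

    For each replicate family, one 2x2 table per genotype is drawn with the
    control arm's death probability at ``baseline_p`` and the irradiated
    arm's odds multiplied by the genotype's true odds ratio; the family's
    simultaneous intervals are computed and the family counts as covered
    only if *every* interval contains its true odds ratio.
    """
    true_ors = np.asarray(list(true_ors), dtype=float)
    if (true_ors <= 0).any():
        raise ValueError("true odds ratios must be positive")
    k = true_ors.size
    odds0 = baseline_p / (1.0 - baseline_p)
    p_irr = (odds0 * true_ors) / (1.0 + odds0 * true_ors)
    rng = np.random.default_rng(seed)
    dead_ctrl = rng.binomial(n_per_arm, baseline_p, size=(n_families, k))
    dead_irr = rng.binomial(n_per_arm, p_irr, size=(n_families, k))
    a, b = dead_irr, n_per_arm - dead_irr
    c, d = dead_ctrl, n_per_arm - dead_ctrl
    log_or, se, _ = log_or_and_se(a, b, c, d)
    z = critical_z(nominal_level, k, method)
    true_log = np.log(true_ors)[None, :]
    covered = np.abs(log_or - true_log) <= z * se
    family_covered = covered.all(axis=1)
    n_cov = int(family_covered.sum())
    return CoverageResult(
        coverage=n_cov / n_families,
        n_families=n_families,
        n_covered=n_cov,
        family_size=k,
        nominal_level=nominal_level,
        method=method,
    )
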