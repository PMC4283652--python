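"""Scoring of syncytial-embryo cell-cycle defects and mitotic-wave geometry.

During nuclear cycles 10-13 of the early fly embryo thousands of nuclei
divide in near synchrony, normally as two metachronous waves starting at
both poles and meeting in the middle.  Live imaging of mutant embryos
yields time-stamped defect events per nucleus (chromatin bridges, loss of
nuclei with free centrosomes) or per embryo (asynchronous mitotic waves).

Scoring follows a first-event rule: a defect is counted only when it
arises in a nucleus that previously showed no defect, and each embryo is
summarized by the category of its earliest counted event.  Frequencies are
reported with Wilson score intervals, which behave well at the small
per-genotype embryo counts typical of live-imaging experiments.

:func:`classify_wave` decides, from division-onset times along the
anterior-posterior axis, whether the mitotic wave was bidirectional (the
wild-type tent profile, onset latest at mid-embryo) or unidirectional (a
single wave crossing from one pole), by least-squares model competition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .synthetic import DEFECT_CATEGORIES

__all__ = [
    "CATEGORY_PRECEDENCE",
    "WaveClassification",
    "first_defect_reduction",
    "defect_frequencies",
    "classify_wave",
    "classify_waves_frame",
]

#: Tie-break order when two categories share the exact same onset time.
CATEGORY_PRECEDENCE: Mapping[str, int] = {
    "async_wave": 0,
    "chromatin_bridge": 1,
    "nucleus_loss_free_centrosome": 2,
}


def first_defect_reduction(events: pd.DataFrame) -> pd.DataFrame:
    """Reduce an event stream to one first-defect assignment per embryo.

    Two-stage reduction: per nucleus only the earliest event survives
    (later events in an already-defective nucleus are never counted); per
    embryo the earliest surviving event — embryo-level asynchronous-wave
    events compete by time alongside the per-nucleus survivors — sets the
    embryo's first-defect category.  Exact simultaneous ties are broken by
    the fixed precedence :data:`CATEGORY_PRECEDENCE` and flagged.

    Exact duplicate records are dropped with a warning.  Embryos without
    events simply do not appear in the output.

    Returns a frame with columns ``genotype, embryo_id, category, time_s,
    tie_broken``.
    """
    required = {"genotype", "embryo_id", "nucleus_id", "time_s", "category"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    if events.empty:
        return pd.DataFrame(
            columns=["genotype", "embryo_id", "category", "time_s", "tie_broken"]
        )
    ev = events.copy()
    if (ev["time_s"] < 0).any():
        raise ValueError("event times must be >= 0")
    bad = set(ev["category"]) - set(DEFECT_CATEGORIES)
    if bad:
        raise ValueError(f"unknown defect categories: {sorted(bad)}")

    dup_key = ["genotype", "embryo_id", "nucleus_id", "time_s", "category"]
    n_dup = int(ev.duplicated(subset=dup_key).sum())
    if n_dup:
        warnings.warn(f"dropping {n_dup} duplicate defect event(s)", stacklevel=2)
        ev = ev.drop_duplicates(subset=dup_key)

    ev["_prec"] = ev["category"].map(CATEGORY_PRECEDENCE)
    ev = ev.sort_values(["time_s", "_prec"], kind="stable")

    nucleus_level = ev["nucleus_id"].notna()
    per_nucleus = (
        ev[nucleus_level]
        .groupby(["genotype", "embryo_id", "nucleus_id"], sort=False)
        .head(1)
    )
    survivors = pd.concat([per_nucleus, ev[~nucleus_level]], ignore_index=True)
    survivors = survivors.sort_values(["time_s", "_prec"], kind="stable")
    first = survivors.groupby(["genotype", "embryo_id"], sort=False).head(1)

    min_times = survivors.groupby(["genotype", "embryo_id"], sort=False).agg(
        _tmin=("time_s", "min")
    )
    at_min = survivors.merge(min_times, on=["genotype", "embryo_id"])
    at_min = at_min[at_min["time_s"] == at_min["_tmin"]]
    ties = (
        at_min.groupby(["genotype", "embryo_id"], sort=False)["category"]
        .nunique()
        .rename("_ncat")
    )
    out = first.merge(ties, on=["genotype", "embryo_id"])
    out["tie_broken"] = out["_ncat"] > 1
    return out[["genotype", "embryo_id", "category", "time_s", "tie_broken"]].reset_index(
        drop=True
    )


def defect_frequencies(
    assignments: pd.DataFrame,
    n_embryos_analyzed: Mapping[str, int],
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-genotype fraction of embryos whose first defect is each category.

    Denominators are the numbers of embryos analyzed per genotype (an input
    of the experiment, since defect-free embryos leave no events).  Wilson
    score intervals at ``level`` are attached per category.

    Returns one row per genotype x category, including zero-count rows.
    """
    counts = (
        assignments.groupby(["genotype", "category"], sort=False)
        .size()
        .rename("n_first")
    )
    rows = []
    for genotype, n in n_embryos_analyzed.items():
        assigned = int(
            assignments.loc[assignments["genotype"] == genotype, "embryo_id"].nunique()
        )
        if n < assigned:
            raise ValueError(
                f"{genotype!r}: {assigned} embryos with defects exceeds "
                f"n_embryos_analyzed={n}"
            )
        for category in DEFECT_CATEGORIES:
            k = int(counts.get((genotype, category), 0))
            lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
            rows.append(
                {
                    "genotype": genotype,
                    "category": category,
                    "n_embryos_analyzed": n,
                    "n_first": k,
                    "fraction": k / n,
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WaveClassification:
    """Outcome of the tent-vs-line model competition for one embryo."""

    classification: str  # bidirectional | unidirectional | indeterminate
    origin_pole: str | None
    wave_speed: float | None
    rss: Mapping[str, float]


def _fit_line(x: np.ndarray, t: np.ndarray, clip_nonneg: bool) -> tuple[float, float, float]:
    """Least-squares fit t ~ c + k*x; returns (c, k, rss)."""
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, t, rcond=None)
    c, k = float(beta[0]), float(beta[1])
    if clip_nonneg and k < 0:
        c, k = float(t.mean()), 0.0
    rss = float(np.sum((t - (c + k * x)) ** 2))
    return c, k, rss


def classify_wave(
    positions: np.ndarray, onset_times: np.ndarray, min_points: int = 5
) -> WaveClassification:
    """Classify a mitotic wave as bidirectional or unidirectional.

    Fits two onset-time models over normalized axis position x in [0, 1]:
    the tent ``c + k*min(x, 1-x)`` (two waves from both poles meeting
    mid-embryo; slope constrained non-negative) and the line ``c + k*x``
    (one wave crossing the embryo; the slope's sign gives the origin pole,
    so the mirror model needs no separate fit).  The model with the lower
    residual sum of squares wins; all RSS values and the fitted wave speed
    (seconds per egg length) are reported.  All-equal onset times are
    classified indeterminate.
    """
    x = np.asarray(positions, dtype=float)
    t = np.asarray(onset_times, dtype=float)
    if x.shape != t.shape or x.ndim != 1:
        raise ValueError("positions and onset_times must be 1-D and equal length")
    if x.size < min_points:
        raise ValueError(f"need at least {min_points} observations, got {x.size}")
    if np.allclose(t, t[0]):
        return WaveClassification(
            classification="indeterminate", origin_pole=None, wave_speed=None,
            rss={"bidirectional": 0.0, "unidirectional": 0.0},
        )
    _, k_tent, rss_tent = _fit_line(np.minimum(x, 1.0 - x), t, clip_nonneg=True)
    _, k_line, rss_line = _fit_line(x, t, clip_nonneg=False)
    rss = {"bidirectional": rss_tent, "unidirectional": rss_line}
    if rss_tent < rss_line:
        return WaveClassification(
            classification="bidirectional", origin_pole=None,
            wave_speed=k_tent, rss=rss,
        )
    return WaveClassification(
        classification="unidirectional",
        origin_pole="anterior" if k_line > 0 else "posterior",
        wave_speed=abs(k_line), rss=rss,
    )


def classify_waves_frame(onsets: pd.DataFrame, min_points: int = 5) -> pd.DataFrame:
    """Apply :func:`classify_wave` per (genotype, embryo_id) of an onsets table.

    Expects columns ``genotype, embryo_id, position, onset_time_s``.
    """
    rows = []
    for (genotype, embryo_id), grp in onsets.groupby(
        ["genotype", "embryo_id"], sort=False
    ):
        w = classify_wave(
            grp["position"].to_numpy(), grp["onset_time_s"].to_numpy(), min_points
        )
        rows.append(
            {
                "genotype": genotype,
                "embryo_id": embryo_id,
                "classification": w.classification,
                "origin_pole": w.origin_pole,
                "wave_speed": w.wave_speed,
                "rss_bidirectional": w.rss["bidirectional"],
                "rss_unidirectional": w.rss["unidirectional"],
            }
        )
    return pd.DataFrame(rows)
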