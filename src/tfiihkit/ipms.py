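"""Bait-normalized stoichiometry of TFIIH subcomplexes from targeted IP-MS.

The pipeline mirrors targeted-proteomics practice for pulldown
stoichiometry:

1. :func:`compute_peptide_cv` — per (genotype, peptide) replicate-injection
   means and coefficients of variation; a peptide quantification is
   accepted only when its CV over the injections is below a threshold
   (default 50%).
2. :func:`aggregate_protein` — per protein, the sum of the accepted
   peptides' injection sums.
3. :func:`bait_normalize` — each protein expressed relative to the
   immunoprecipitated bait (Cdk7) within the same pulldown, cancelling
   IP efficiency and load.
4. :func:`fold_reduction` — mutant vs wild-type comparison of the
   bait-normalized ratios.
5. :func:`classify_interactions` — labels each genotype with interaction
   defects: reduced or enhanced Xpd-CAK binding (Xpd:bait ratio vs wild
   type), and reduced Xpd-core binding, strong or weak (geometric mean of
   core:Xpd ratios vs wild type).
6. :func:`cak_stoichiometry_qc` — checks that the CycH:bait and Mat1:bait
   ratios are constant across genotypes, the internal control that the
   trimeric CAK itself is untouched by the mutations.

:func:`loading_control_normalize` is the small western-blot companion:
target band intensities normalized to a loading-control band and expressed
as percent of a reference sample, with mean +/- s.e.m. over replicate
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PEPTIDE_KEY",
    "CakQcReport",
    "compute_peptide_cv",
    "aggregate_protein",
    "bait_normalize",
    "fold_reduction",
    "classify_interactions",
    "cak_stoichiometry_qc",
    "loading_control_normalize",
]

#: Columns identifying one targeted peptide within one genotype's pulldown.
PEPTIDE_KEY = ["genotype", "protein_id", "peptide_sequence", "charge_state"]


def compute_peptide_cv(records: pd.DataFrame, cv_threshold: float = 0.5) -> pd.DataFrame:
    """Replicate-injection summary and CV acceptance per peptide.

    CV is the sample (ddof=1) standard deviation over the observed
    injections divided by their mean.  A peptide quantification is accepted
    iff at least two injections were observed, the mean is positive and
    CV < ``cv_threshold``; otherwise the CV is undefined or too large and
    the peptide is rejected.

    Parameters
    ----------
    records
        Long-format table with columns ``genotype, protein_id,
        peptide_sequence, charge_state, injection, intensity``; missing
        intensities are NaN/blank.
    cv_threshold
        Acceptance threshold in (0, 1], default 0.5 (CV below 50%).
    """
    if not 0 < cv_threshold <= 1:
        raise ValueError("cv_threshold must be in (0, 1]")
    intensity = records["intensity"]
    if (intensity.dropna() < 0).any():
        raise ValueError("negative intensities in records")

    grouped = records.groupby(PEPTIDE_KEY, sort=False)["intensity"]
    out = grouped.agg(
        mean_intensity="mean",
        _sd=lambda s: s.std(ddof=1),
        n_injections_observed="count",
    ).reset_index()
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = out["_sd"] / out["mean_intensity"]
    cv = cv.where((out["n_injections_observed"] >= 2) & (out["mean_intensity"] > 0))
    out["cv"] = cv
    out["accepted"] = cv.notna() & (cv < cv_threshold)
    return out.drop(columns="_sd")


def aggregate_protein(quants: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Per-protein summed intensity over accepted peptides.

    Each accepted peptide contributes the sum of its observed injection
    intensities; the protein value is the sum over its accepted peptides.
    Proteins whose peptides were all rejected are reported with a missing
    sum and ``n_peptides_used = 0``.  Single-peptide proteins are flagged
    because their estimate has no internal peptide-level replication.
    """
    merged = records.merge(
        quants.loc[quants["accepted"], PEPTIDE_KEY], on=PEPTIDE_KEY, how="inner"
    )
    sums = (
        merged.groupby(["genotype", "protein_id"], sort=False)
        .agg(
            summed_intensity=("intensity", "sum"),
            n_peptides_used=("peptide_sequence", "nunique"),
        )
        .reset_index()
    )
    # Every (genotype, protein) present in the records appears in the output,
    # including all-rejected ones.
    universe = records[["genotype", "protein_id"]].drop_duplicates()
    out = universe.merge(sums, on=["genotype", "protein_id"], how="left")
    out["n_peptides_used"] = out["n_peptides_used"].fillna(0).astype(int)
    out["single_peptide_flag"] = out["n_peptides_used"] == 1
    return out


def bait_normalize(proteins: pd.DataFrame, bait_id: str = "Cdk7") -> pd.DataFrame:
    """Express each protein's summed intensity relative to the bait.

    The bait's self-ratio is exactly 1 in every genotype.  Scale invariant:
    multiplying all of one genotype's intensities by a constant leaves the
    profile unchanged.

    Raises
    ------
    ValueError
        If the bait is absent, rejected or non-positive in any genotype
        (the error names the genotype).
    """
    out_frames = []
    for genotype, grp in proteins.groupby("genotype", sort=False):
        bait = grp.loc[grp["protein_id"] == bait_id, "summed_intensity"]
        if bait.empty or pd.isna(bait.iloc[0]) or bait.iloc[0] <= 0:
            raise ValueError(
                f"bait {bait_id!r} missing or non-positive in genotype {genotype!r}"
            )
        g = grp.copy()
        g["ratio_to_bait"] = g["summed_intensity"] / bait.iloc[0]
        out_frames.append(g)
    out = pd.concat(out_frames, ignore_index=True)
    out["bait_id"] = bait_id
    return out[
        ["genotype", "protein_id", "ratio_to_bait", "n_peptides_used",
         "single_peptide_flag", "bait_id"]
    ]


def fold_reduction(profiles: pd.DataFrame, wildtype: str = "xpd_wt") -> pd.DataFrame:
    """Fold table: each genotype's bait ratios against wild type.

    ``fold_vs_bait`` is the "times less abundant than the bait" scale
    (1/ratio_to_bait, infinite when the protein was undetected, flagged);
    ``fold_vs_wildtype`` is the mutant's ratio_to_bait divided by the
    wild-type ratio_to_bait, 0 when the mutant ratio is 0.

    Raises
    ------
    ValueError
        If the wild-type genotype is absent or protein sets differ between
        genotypes.
    """
    genotypes = profiles["genotype"].unique()
    if wildtype not in genotypes:
        raise ValueError(f"wild-type genotype {wildtype!r} not in profiles")
    by_geno = {g: set(grp["protein_id"]) for g, grp in profiles.groupby("genotype")}
    wt_set = by_geno[wildtype]
    for g, s in by_geno.items():
        if s != wt_set:
            raise ValueError(
                f"protein set of {g!r} differs from wild type: "
                f"{sorted(s ^ wt_set)}"
            )
    wt = (
        profiles.loc[profiles["genotype"] == wildtype, ["protein_id", "ratio_to_bait"]]
        .rename(columns={"ratio_to_bait": "ratio_wildtype"})
    )
    out = profiles.merge(wt, on="protein_id", how="left")
    ratio = out["ratio_to_bait"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["fold_vs_bait"] = np.where(ratio > 0, 1.0 / ratio, np.inf)
        out["fold_vs_wildtype"] = np.where(
            ratio > 0,
            ratio / out["ratio_wildtype"],
            np.where(out["ratio_wildtype"] > 0, 0.0, np.nan),
        )
    out["undetected_flag"] = ~(ratio > 0)
    return out


def _geometric_mean(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if (values <= 0).any() or np.isnan(values).any():
        # a zero/undetected core subunit drives the statistic to 0
        return 0.0 if (values == 0).any() else float("nan")
    return float(np.exp(np.mean(np.log(values))))


def classify_interactions(
    table: pd.DataFrame,
    down_threshold: float = 1.5,
    strong_threshold: float = 3.0,
    up_threshold: float = 1.5,
    xpd_id: str = "Xpd",
    core_ids: Sequence[str] = ("Hay", "Mrn"),
    wildtype: str = "xpd_wt",
) -> pd.DataFrame:
    """Interaction-defect labels per genotype from a fold-reduction table.

    Labels (may co-occur):

    - ``reduced_xpd_cak``: Xpd fold_vs_wildtype <= 1/down_threshold —
      less Xpd recovered per bait, i.e. impaired Xpd-CAK binding.
    - ``enhanced_xpd_cak``: Xpd fold_vs_wildtype >= up_threshold.
    - ``reduced_xpd_core_strong`` / ``_weak``: the geometric mean of
      core-subunit:Xpd ratios, relative to the same statistic in wild
      type, is <= 1/down_threshold (strong when <= 1/strong_threshold) —
      core subunits underrepresented relative to Xpd, i.e. impaired
      Xpd-core binding.
    - ``none`` when no label fires.

    Returns one row per genotype with the two test statistics and the label
    tuple.
    """
    if not (down_threshold > 1 and strong_threshold > 1 and up_threshold > 1):
        raise ValueError("classification thresholds must be > 1")
    if strong_threshold < down_threshold:
        raise ValueError("strong_threshold must be >= down_threshold")

    def core_vs_xpd(grp: pd.DataFrame) -> float:
        ratios = grp.set_index("protein_id")["ratio_to_bait"]
        xpd = ratios.get(xpd_id, np.nan)
        if not xpd or np.isnan(xpd):
            return float("inf") if any(ratios.get(c, 0) > 0 for c in core_ids) else float("nan")
        return _geometric_mean(np.array([ratios.get(c, np.nan) for c in core_ids]) / xpd)

    per_geno = table.groupby("genotype", sort=False)
    stats = {g: core_vs_xpd(grp) for g, grp in per_geno}
    wt_core = stats[wildtype]
    rows = []
    for genotype, grp in per_geno:
        xpd_fold = float(
            grp.loc[grp["protein_id"] == xpd_id, "fold_vs_wildtype"].iloc[0]
        )
        core_fold = stats[genotype] / wt_core if wt_core > 0 else float("nan")
        labels = []
        if xpd_fold <= 1.0 / down_threshold:
            labels.append("reduced_xpd_cak")
        if xpd_fold >= up_threshold:
            labels.append("enhanced_xpd_cak")
        if not np.isnan(core_fold) and core_fold <= 1.0 / down_threshold:
            labels.append(
                "reduced_xpd_core_strong"
                if core_fold <= 1.0 / strong_threshold
                else "reduced_xpd_core_weak"
            )
        rows.append(
            (genotype, xpd_fold, core_fold, tuple(labels) or ("none",))
        )
    return pd.DataFrame(
        rows,
        columns=["genotype", "xpd_fold_vs_wildtype", "core_vs_xpd_fold_vs_wildtype",
                 "labels"],
    )


@dataclass(frozen=True)
class CakQcReport:
    """Constancy check of the CAK-internal stoichiometry across genotypes."""

    cv_by_protein: Mapping[str, float]
    max_cv: float
    tolerance: float
    passed: bool


def cak_stoichiometry_qc(
    profiles: pd.DataFrame,
    cak_ids: Sequence[str] = ("CycH", "Mat1"),
    tolerance: float = 0.2,
) -> CakQcReport:
    """Check that CycH:bait and Mat1:bait ratios are constant across genotypes.

    An anti-Cdk7 pulldown recovering intact trimeric CAK must show the same
    CycH:Cdk7 and Mat1:Cdk7 ratios whatever the xpd genotype; a drift
    signals a technical problem or a destabilized trimer.  Reports the
    coefficient of variation of each ratio across genotypes and passes when
    all are below ``tolerance``.
    """
    if profiles["genotype"].nunique() < 2:
        raise ValueError("QC needs at least two genotypes")
    cvs: dict[str, float] = {}
    for protein in cak_ids:
        ratios = profiles.loc[
            profiles["protein_id"] == protein, "ratio_to_bait"
        ].astype(float)
        cvs[protein] = float(ratios.std(ddof=1) / ratios.mean())
    max_cv = max(cvs.values())
    return CakQcReport(
        cv_by_protein=cvs, max_cv=max_cv, tolerance=tolerance,
        passed=max_cv < tolerance,
    )


def loading_control_normalize(
    bands: pd.DataFrame, reference_sample: str
) -> pd.DataFrame:
    """Western-blot quantification as percent of a reference sample.

    Per replicate experiment, the target:loading-control band ratio of each
    sample is divided by the same ratio of ``reference_sample`` and scaled
    to percent; the output gives each sample's mean and s.e.m. over the
    replicates (the reference is 100% in every replicate by construction).

    Parameters
    ----------
    bands
        Columns ``sample, replicate, target_intensity, control_intensity``.
    """
    if (bands["control_intensity"] <= 0).any():
        raise ValueError("loading-control intensities must be positive")
    if reference_sample not in set(bands["sample"]):
        raise ValueError(f"reference sample {reference_sample!r} missing")
    b = bands.copy()
    b["ratio"] = b["target_intensity"] / b["control_intensity"]
    ref = b.loc[b["sample"] == reference_sample, ["replicate", "ratio"]].rename(
        columns={"ratio": "ref_ratio"}
    )
    b = b.merge(ref, on="replicate", how="left")
    if b["ref_ratio"].isna().any():
        missing = sorted(b.loc[b["ref_ratio"].isna(), "replicate"].unique())
        raise ValueError(f"reference sample missing in replicates: {missing}")
    b["percent_of_reference"] = b["ratio"] / b["ref_ratio"] * 100.0
    out = (
        b.groupby("sample", sort=False)["percent_of_reference"]
        .agg(
            mean_percent="mean",
            sem_percent=lambda s: s.std(ddof=1) / np.sqrt(len(s)),
            n_replicates="count",
        )
        .reset_index()
    )
    return out
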