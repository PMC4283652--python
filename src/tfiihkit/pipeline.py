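"""End-to-end pipeline stages: file in, report files out.

Each ``run_*`` function is the library form of one CLI subcommand: read
the TSV inputs, run the corresponding analysis chain, and write a TSV
table plus a JSON report carrying the thresholds used and a provenance
block (package version + config hash), so any output can be traced to its
exact configuration.  All stages are deterministic given inputs + config.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import defects, io, ipms, survival, synthetic
from .config import RunConfig

__all__ = ["run_ipms", "run_survival", "run_cellcycle", "simulate_all"]


def _jsonable(x: Any) -> Any:
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and not np.isfinite(x):
        return repr(x)
    return x


def run_ipms(
    config: RunConfig,
    intensities_path: str | Path,
    peptides_path: str | Path | None,
    out_dir: str | Path,
) -> dict[str, Any]:
    """CV filter -> protein sums -> bait normalization -> folds -> labels -> QC."""
    out_dir = Path(out_dir)
    records = io.read_intensities(intensities_path)
    if peptides_path is not None:
        inventory = io.read_peptide_inventory(peptides_path)
        known = set(map(tuple, inventory[["protein_id", "peptide_sequence"]].values))
        seen = set(map(tuple, records[["protein_id", "peptide_sequence"]].values))
        stray = sorted(seen - known)
        if stray:
            raise ValueError(f"intensity records not in peptide inventory: {stray[:5]}")
    quants = ipms.compute_peptide_cv(records, config.cv_threshold)
    proteins = ipms.aggregate_protein(quants, records)
    profiles = ipms.bait_normalize(proteins, config.bait_id)
    folds = ipms.fold_reduction(profiles, config.wildtype_genotype)
    labels = ipms.classify_interactions(
        folds,
        down_threshold=config.down_threshold,
        strong_threshold=config.strong_threshold,
        up_threshold=config.up_threshold,
        wildtype=config.wildtype_genotype,
    )
    qc = ipms.cak_stoichiometry_qc(profiles, tolerance=config.cak_qc_tolerance)

    io.write_tsv(folds, out_dir / "fold_reduction.tsv")
    report = {
        "provenance": io.provenance(config.to_dict()),
        "thresholds": {
            "cv_threshold": config.cv_threshold,
            "down_threshold": config.down_threshold,
            "strong_threshold": config.strong_threshold,
            "up_threshold": config.up_threshold,
        },
        "bait_id": config.bait_id,
        "classification": {
            row.genotype: {
                "labels": list(row.labels),
                "xpd_fold_vs_wildtype": _jsonable(row.xpd_fold_vs_wildtype),
                "core_vs_xpd_fold_vs_wildtype": _jsonable(
                    row.core_vs_xpd_fold_vs_wildtype
                ),
            }
            for row in labels.itertuples(index=False)
        },
        "cak_qc": {
            "cv_by_protein": {k: _jsonable(v) for k, v in qc.cv_by_protein.items()},
            "max_cv": _jsonable(qc.max_cv),
            "tolerance": qc.tolerance,
            "passed": qc.passed,
        },
    }
    io.write_json(report, out_dir / "ipms_report.json")
    return report


def run_survival(
    config: RunConfig, counts_path: str | Path, out_dir: str | Path
) -> pd.DataFrame:
    """Death rates, odds ratios and simultaneous CIs for every genotype."""
    out_dir = Path(out_dir)
    counts = io.read_survival_counts(counts_path)
    table = survival.analyze_survival(
        counts,
        nominal_level=config.nominal_level,
        method=config.multiplicity,
        reference_genotype=config.reference_genotype,
    )
    io.write_tsv(table, out_dir / "survival_report.tsv")
    io.write_json(
        {
            "provenance": io.provenance(config.to_dict()),
            "nominal_level": config.nominal_level,
            "multiplicity": config.multiplicity,
            "family_size": int(table.shape[0]),
            "genotypes": {
                row.genotype: {
                    "or_hat": _jsonable(row.or_hat),
                    "ci_low": _jsonable(row.ci_low),
                    "ci_high": _jsonable(row.ci_high),
                    "corrected": bool(row.corrected),
                }
                for row in table.itertuples(index=False)
            },
        },
        out_dir / "survival_report.json",
    )
    return table


def run_cellcycle(
    config: RunConfig,
    events_path: str | Path,
    onsets_path: str | Path | None,
    out_dir: str | Path,
    n_embryos_analyzed: dict[str, int] | None = None,
) -> pd.DataFrame:
    """First-defect frequencies (+ wave classes when onsets are given).

    When ``n_embryos_analyzed`` is not supplied, the denominator of each
    genotype defaults to the number of distinct embryo ids appearing in the
    event or onset tables for that genotype.
    """
    out_dir = Path(out_dir)
    events = io.read_defect_events(events_path)
    assignments = defects.first_defect_reduction(events)
    onsets = io.read_wave_onsets(onsets_path) if onsets_path is not None else None
    if n_embryos_analyzed is None:
        n_embryos_analyzed = {}
        sources = [events[["genotype", "embryo_id"]]]
        if onsets is not None:
            sources.append(onsets[["genotype", "embryo_id"]])
        all_ids = pd.concat(sources, ignore_index=True)
        for g, grp in all_ids.groupby("genotype", sort=False):
            n_embryos_analyzed[str(g)] = int(grp["embryo_id"].nunique())
    summary = defects.defect_frequencies(
        assignments, n_embryos_analyzed, level=config.nominal_level
    )
    io.write_tsv(summary, out_dir / "defect_summary.tsv")
    report: dict[str, Any] = {
        "provenance": io.provenance(config.to_dict()),
        "n_embryos_analyzed": n_embryos_analyzed,
        "frequencies": {
            f"{row.genotype}/{row.category}": {
                "fraction": _jsonable(row.fraction),
                "ci_low": _jsonable(row.ci_low),
                "ci_high": _jsonable(row.ci_high),
            }
            for row in summary.itertuples(index=False)
        },
    }
    if onsets is not None:
        waves = defects.classify_waves_frame(onsets)
        io.write_tsv(waves, out_dir / "wave_classes.tsv")
        report["wave_classes"] = {
            f"{row.genotype}/{row.embryo_id}": row.classification
            for row in waves.itertuples(index=False)
        }
    io.write_json(report, out_dir / "cellcycle_report.json")
    return summary


def simulate_all(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write one synthetic input set (all three experiments) plus ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    models = synthetic.default_genotype_models()
    peptides = synthetic.default_peptide_inventory()
    records = synthetic.simulate_ip_intensities(models, peptides, seed=seed)
    sparams = synthetic.default_survival_params()
    counts = synthetic.simulate_survival(sparams, seed=seed + 1)
    probs = synthetic.default_defect_probs()
    sim = synthetic.simulate_defect_events(probs, n_embryos=30, seed=seed + 2)
    onset_frames = []
    wave_rng = np.random.default_rng(seed + 3)
    for genotype, p_async in ((g, probs[g]["async_wave"]) for g in probs):
        for e in range(5):
            mode = "unidirectional" if wave_rng.random() < p_async else "bidirectional"
            params = synthetic.WaveSimParams(
                mode=mode, wave_speed=60.0, onset_noise_sd=3.0,
                origin_pole="posterior" if wave_rng.random() < 0.5 else "anterior",
            )
            onsets = synthetic.simulate_wave_onsets(
                params, seed=int(wave_rng.integers(2**31))
            )
            onsets.insert(0, "genotype", genotype)
            onsets.insert(1, "embryo_id", f"{genotype}_w{e:02d}")
            onset_frames.append(onsets)

    paths = {
        "peptides": out_dir / "peptides.tsv",
        "intensities": out_dir / "intensities.tsv",
        "survival_counts": out_dir / "survival_counts.tsv",
        "defect_events": out_dir / "defect_events.tsv",
        "wave_onsets": out_dir / "wave_onsets.tsv",
        "ground_truth": out_dir / "ground_truth.json",
    }
    io.write_tsv(peptides, paths["peptides"])
    io.write_tsv(records, paths["intensities"])
    io.write_tsv(counts, paths["survival_counts"])
    io.write_tsv(sim.events, paths["defect_events"])
    io.write_tsv(pd.concat(onset_frames, ignore_index=True), paths["wave_onsets"])
    io.write_json(
        {
            "seed": seed,
            "pool_models": {
                g: {"k_xpd_cak": m.k_xpd_cak, "k_xpd_core": m.k_xpd_core,
                    "noise_sigma": m.noise_sigma}
                for g, m in models.items()
            },
            "survival": {
                "n_per_arm": sparams.n_per_arm,
                "baseline_death_prob": dict(sparams.baseline_death_prob),
                "uv_log_odds_effect": dict(sparams.uv_log_odds_effect),
            },
            "defect_probs": probs,
            "true_first_defects": {
                f"{row.genotype}/{row.embryo_id}": row.category
                for row in sim.true_first_defects.itertuples(index=False)
            },
        },
        paths["ground_truth"],
    )
    return paths
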