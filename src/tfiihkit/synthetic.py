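"""Synthetic-data generators with known ground truth.

Three experiment types are emulated, each at the level the analysis code
consumes (no raw spectra, images or chromatograms):

1. **Targeted IP-qMS/MS peptide intensities.** An anti-Cdk7 pulldown
   recovers Cdk7 together with whatever is bound to it: the trimeric CAK
   kinase (Cdk7/CycH/Mat1), the tetrameric CAK (CAK + Xpd), and holo-TFIIH
   (tetrameric CAK bridged by Xpd to the core subunits Hay/Xpb and
   Mrn/p52).  :class:`ComplexPoolModel` partitions the Cdk7 pool among the
   three species via two effective binding parameters and produces expected
   peptide intensities with multiplicative lognormal injection noise.

2. **UV-survival counts.** Per genotype, a control and an irradiated arm of
   embryos; deaths are binomial with a genotype-specific UV effect acting
   additively on the log-odds of death.

3. **Syncytial cell-cycle defects.** Per-embryo first-defect categories
   (asynchronous mitotic wave, chromatin bridge, nucleus loss with free
   centrosomes) plus later secondary events that exercise the
   first-defect-only scoring rule, and division-onset times along the
   anterior-posterior axis for mitotic-wave classification.

All generators are deterministic given a seed and return the long-format
:mod:`pandas` tables the analysis modules read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CAK_PROTEINS",
    "CORE_PROTEINS",
    "XPD",
    "DEFAULT_PROTEINS",
    "DEFECT_CATEGORIES",
    "ComplexPoolModel",
    "SurvivalSimParams",
    "WaveSimParams",
    "DefectSimulation",
    "default_peptide_inventory",
    "default_genotype_models",
    "default_survival_params",
    "default_defect_probs",
    "simulate_ip_intensities",
    "simulate_survival",
    "simulate_defect_events",
    "simulate_wave_onsets",
]

#: The three subunits of the trimeric Cdk-activating kinase (CAK).
CAK_PROTEINS: tuple[str, ...] = ("Cdk7", "CycH", "Mat1")
#: The bridging helicase: CAK + Xpd = tetrameric CAK.
XPD: str = "Xpd"
#: Core-TFIIH subunits quantified in the pulldown (Drosophila Xpb and p52).
CORE_PROTEINS: tuple[str, ...] = ("Hay", "Mrn")
DEFAULT_PROTEINS: tuple[str, ...] = CAK_PROTEINS + (XPD,) + CORE_PROTEINS

#: Per-protein multiplicative unit response (arbitrary).  Different peptides
#: ionize with different efficiency, so equal molar amounts of two proteins
#: need not give equal summed intensities; these defaults are synthetic.
DEFAULT_IONIZATION: Mapping[str, float] = {
    "Cdk7": 1.0,
    "CycH": 0.8,
    "Mat1": 1.3,
    "Xpd": 0.6,
    "Hay": 0.9,
    "Mrn": 1.1,
}

DEFECT_CATEGORIES: tuple[str, ...] = (
    "async_wave",
    "chromatin_bridge",
    "nucleus_loss_free_centrosome",
)


@dataclass(frozen=True)
class ComplexPoolModel:
    """Generative partition of the Cdk7 pool among its three complexes.

    ``k_xpd_cak`` is the effective fraction of CAK recovered with Xpd bound
    (tetrameric CAK or holo-TFIIH) relative to a fully assembled wild type;
    ``k_xpd_core`` is, of the Xpd-bound CAK, the effective fraction further
    bound to core TFIIH.  Wild type corresponds to ``k = 1`` ("all pools
    bound"); values above 1 model enhanced recovery of the interaction,
    values below 1 a binding defect.  Expected recovered abundance scales
    linearly in the k's, so halving ``k_xpd_core`` exactly halves the
    expected core:bait ratio — the property parameter-recovery tests rely
    on.

    CAK integrity is built in: CycH and Mat1 are always locked 1:1 to Cdk7,
    since xpd mutations leave the trimer itself intact; genotypes differ
    only via ``k_xpd_cak`` and ``k_xpd_core``.
    """

    total_cdk7: float = 1000.0
    k_xpd_cak: float = 1.0
    k_xpd_core: float = 1.0
    ip_efficiency: float = 0.5
    noise_sigma: float = 0.15
    ionization: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IONIZATION)
    )

    def __post_init__(self) -> None:
        if not self.total_cdk7 > 0:
            raise ValueError("total_cdk7 must be positive")
        if self.k_xpd_cak < 0 or self.k_xpd_core < 0:
            raise ValueError("binding propensities must be non-negative")
        if not 0 < self.ip_efficiency <= 1:
            raise ValueError("ip_efficiency must be in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if any(v <= 0 for v in self.ionization.values()):
            raise ValueError("ionization factors must be positive")

    def pool_fractions(self) -> dict[str, float]:
        """Fractions of the Cdk7 pool in each species (sum to 1).

        Occupancies are clipped to [0, 1] here so the accounting stays a
        proper partition even when a ``k`` above 1 models enhanced recovery.
        """
        q_cak = min(self.k_xpd_cak, 1.0)
        q_core = min(self.k_xpd_core, 1.0)
        return {
            "free_cak3": 1.0 - q_cak,
            "cak4": q_cak * (1.0 - q_core),
            "holo_tfiih": q_cak * q_core,
        }

    def expected_abundance(self) -> dict[str, float]:
        """Expected recovered protein abundance (arbitrary units) per subunit."""
        base = self.total_cdk7 * self.ip_efficiency
        out = {p: base for p in CAK_PROTEINS}
        out[XPD] = base * self.k_xpd_cak
        for p in CORE_PROTEINS:
            out[p] = base * self.k_xpd_cak * self.k_xpd_core
        return out

    def perturbed(self, cak_factor: float = 1.0, core_factor: float = 1.0) -> "ComplexPoolModel":
        """Return a copy with the binding parameters multiplied by the factors."""
        return replace(
            self,
            k_xpd_cak=self.k_xpd_cak * cak_factor,
            k_xpd_core=self.k_xpd_core * core_factor,
        )


# Synthetic tryptic-peptide inventory.  The sequences are plausible-looking
# placeholders (uppercase amino acids ending in K/R), not the published
# transition list; the analysis only keys on (protein, sequence, charge).
_DEFAULT_PEPTIDES: tuple[tuple[str, str, int], ...] = (
    ("Cdk7", "LGEGTYAVVYK", 2),
    ("Cdk7", "DLKPQNLLINR", 2),
    ("Cdk7", "AFSLAK", 1),
    ("CycH", "LSQEAILLGSK", 2),
    ("CycH", "VQAIYLTQEHER", 3),
    ("CycH", "FILEVGAK", 2),
    ("Mat1", "EALEQLQLDR", 2),
    ("Mat1", "TGGAYDPAEFEK", 2),
    ("Mat1", "SVNQLIDLK", 2),
    ("Xpd", "LVITDEAHNIDNVCR", 3),
    ("Xpd", "GAILLSVAR", 2),
    ("Xpd", "YQEQFPNPVR", 2),
    ("Hay", "NLEGLDQIVEEK", 2),
    ("Mrn", "ITPLELFSGR", 2),
)


def default_peptide_inventory() -> pd.DataFrame:
    """Synthetic peptide inventory mirroring the targeted-MS design.

    Three peptides per subunit except Hay and Mrn, which are covered by a
    single peptide each (their protein estimates are therefore flagged as
    single-peptide downstream).
    """
    return pd.DataFrame(
        _DEFAULT_PEPTIDES, columns=["protein_id", "peptide_sequence", "charge_state"]
    )


def default_genotype_models(
    base: ComplexPoolModel | None = None,
) -> dict[str, ComplexPoolModel]:
    """Synthetic genotype panel for end-to-end runs.

    The k-factors encode the qualitative interaction classes of the xpd
    point mutants (reduced or enhanced Xpd-CAK binding, reduced Xpd-core
    binding), not measured stoichiometries.
    """
    base = base or ComplexPoolModel()
    factors: dict[str, tuple[float, float]] = {
        "xpd_wt": (1.0, 1.0),
        "D234N": (0.35, 1.0),
        "S541R": (1.0, 1.0),
        "G47R": (1.0, 0.9),
        "G675R": (1.6, 0.9),
        "R112H": (0.5, 0.55),
        "R601L": (1.7, 0.3),
        "R658C": (1.0, 0.65),
        "R683W": (1.6, 0.5),
        "R722W": (1.0, 0.3),
    }
    return {g: base.perturbed(c, k) for g, (c, k) in factors.items()}


def _as_models(
    model: ComplexPoolModel | Mapping[str, ComplexPoolModel],
    genotypes: Sequence[str] | None,
) -> dict[str, ComplexPoolModel]:
    if isinstance(model, ComplexPoolModel):
        if genotypes is None:
            genotypes = ["wt"]
        return {g: model for g in genotypes}
    models = dict(model)
    if genotypes is not None:
        missing = [g for g in genotypes if g not in models]
        if missing:
            raise KeyError(f"no model for genotypes: {missing}")
        models = {g: models[g] for g in genotypes}
    return models


def simulate_ip_intensities(
    model: ComplexPoolModel | Mapping[str, ComplexPoolModel],
    peptides: pd.DataFrame,
    genotypes: Sequence[str] | None = None,
    n_injections: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate replicate-injection peptide intensities from a pulldown.

    Each peptide's intensity is the expected recovered abundance of its
    parent protein times the protein's ionization factor times lognormal
    noise ``exp(N(0, noise_sigma))`` drawn independently per peptide and
    injection.  Deterministic given ``seed``.

    Parameters
    ----------
    model
        A single :class:`ComplexPoolModel` (applied to every genotype) or a
        mapping genotype -> model.
    peptides
        Inventory with columns ``protein_id, peptide_sequence, charge_state``.
    """
    if n_injections < 1:
        raise ValueError("n_injections must be >= 1")
    models = _as_models(model, genotypes)
    rng = np.random.default_rng(seed)
    frames = []
    for genotype, m in models.items():
        abundance = m.expected_abundance()
        unknown = sorted(set(peptides["protein_id"]) - set(abundance) )
        if unknown:
            raise ValueError(f"peptides reference unknown proteins: {unknown}")
        expected = np.array(
            [abundance[p] * m.ionization[p] for p in peptides["protein_id"]]
        )
        noise = (
            np.exp(rng.normal(0.0, m.noise_sigma, size=(len(peptides), n_injections)))
            if m.noise_sigma > 0
            else np.ones((len(peptides), n_injections))
        )
        intensity = expected[:, None] * noise
        rep = peptides.loc[peptides.index.repeat(n_injections)].reset_index(drop=True)
        rep.insert(0, "genotype", genotype)
        rep["injection"] = np.tile(np.arange(1, n_injections + 1), len(peptides))
        rep["intensity"] = intensity.ravel()
        frames.append(rep)
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class SurvivalSimParams:
    """Per-genotype binomial death model for the UV-survival experiment.

    ``uv_log_odds_effect`` shifts the log-odds of death in the irradiated
    arm, so the population odds ratio of a genotype is
    ``exp(uv_log_odds_effect)``.  ``uv_dose`` is carried as metadata only.
    """

    baseline_death_prob: Mapping[str, float]
    uv_log_odds_effect: Mapping[str, float]
    n_per_arm: int = 100
    uv_dose: float = 100.0

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        for g, p in self.baseline_death_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"baseline death probability out of [0,1] for {g}")
        missing = set(self.baseline_death_prob) ^ set(self.uv_log_odds_effect)
        if missing:
            raise ValueError(f"genotype sets differ between fields: {sorted(missing)}")

    def irradiated_death_prob(self, genotype: str) -> float:
        p = self.baseline_death_prob[genotype]
        if p in (0.0, 1.0):
            return p
        odds = p / (1 - p) * math.exp(self.uv_log_odds_effect[genotype])
        return odds / (1 + odds)


def default_survival_params(n_per_arm: int = 100) -> SurvivalSimParams:
    """Synthetic survival panel: wild-type-like baseline with class-graded UV effects.

    Baseline death probability 0.115 for every line (the wild-type
    unirradiated rate scale); log-odds effects grade from roughly twofold
    odds of death after irradiation in the wild type up to strong effects
    for the XP/CS-class alleles.
    """
    effects = {
        "y_w": math.log(1.6),
        "xpd_wt": math.log(2.26),
        "D234N": math.log(8.0),
        "S541R": math.log(3.0),
        "G47R": math.log(12.0),
        "G675R": math.log(10.0),
        "R112H": math.log(4.0),
        "R601L": math.log(3.0),
        "R658C": math.log(1.0),
        "R683W": math.log(3.5),
        "R722W": math.log(4.5),
    }
    return SurvivalSimParams(
        baseline_death_prob={g: 0.115 for g in effects},
        uv_log_odds_effect=effects,
        n_per_arm=n_per_arm,
    )


def simulate_survival(params: SurvivalSimParams, seed: int = 0) -> pd.DataFrame:
    """Draw per-arm death counts; returns one row per genotype x arm."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in params.baseline_death_prob:
        p0 = params.baseline_death_prob[g]
        p1 = params.irradiated_death_prob(g)
        dead0 = int(rng.binomial(params.n_per_arm, p0))
        dead1 = int(rng.binomial(params.n_per_arm, p1))
        rows.append((g, "control", params.n_per_arm, dead0, params.uv_dose))
        rows.append((g, "irradiated", params.n_per_arm, dead1, params.uv_dose))
    return pd.DataFrame(
        rows, columns=["genotype", "arm", "n_total", "n_dead", "uv_dose"]
    )


@dataclass(frozen=True)
class DefectSimulation:
    """Events plus the ground-truth first-defect draw they were built from."""

    events: pd.DataFrame
    true_first_defects: pd.DataFrame


def default_defect_probs() -> dict[str, dict[str, float]]:
    """Synthetic per-genotype first-defect probabilities.

    Patterned on the qualitative ordering of the reported phenotype
    frequencies (asynchronous waves most frequent in the XP/CS and
    TTD-class alleles, nucleus loss in a subset); not measured values.
    """
    return {
        "xpd_wt": {"async_wave": 0.05, "chromatin_bridge": 0.02,
                   "nucleus_loss_free_centrosome": 0.0},
        "D234N": {"async_wave": 0.02, "chromatin_bridge": 0.10,
                  "nucleus_loss_free_centrosome": 0.05},
        "G47R": {"async_wave": 0.45, "chromatin_bridge": 0.10,
                 "nucleus_loss_free_centrosome": 0.25},
        "G675R": {"async_wave": 0.50, "chromatin_bridge": 0.10,
                  "nucleus_loss_free_centrosome": 0.25},
        "R112H": {"async_wave": 0.40, "chromatin_bridge": 0.10,
                  "nucleus_loss_free_centrosome": 0.25},
        "R601L": {"async_wave": 0.40, "chromatin_bridge": 0.15,
                  "nucleus_loss_free_centrosome": 0.10},
        "R658C": {"async_wave": 0.10, "chromatin_bridge": 0.05,
                  "nucleus_loss_free_centrosome": 0.05},
        "R683W": {"async_wave": 0.40, "chromatin_bridge": 0.15,
                  "nucleus_loss_free_centrosome": 0.20},
        "R722W": {"async_wave": 0.55, "chromatin_bridge": 0.10,
                  "nucleus_loss_free_centrosome": 0.15},
    }


def simulate_defect_events(
    defect_probs: Mapping[str, Mapping[str, float]],
    n_embryos: int,
    nuclei_per_embryo: int = 40,
    seed: int = 0,
    secondary_prob: float = 0.5,
    cycle: int = 13,
) -> DefectSimulation:
    """Simulate per-embryo first defects with optional later secondary events.

    Each embryo draws at most one *first* defect category; the remainder of
    the probability mass is "no defect".  For nucleus-level first defects,
    a later second event may be added in the same nucleus (which the
    first-defect scoring rule must discard) and in another nucleus (which
    survives the per-nucleus reduction but loses the per-embryo earliest
    competition).  Asynchronous-wave events are embryo-level and carry no
    nucleus id.
    """
    if n_embryos < 0:
        raise ValueError("n_embryos must be >= 0")
    rng = np.random.default_rng(seed)
    nucleus_cats = [c for c in DEFECT_CATEGORIES if c != "async_wave"]
    event_rows = []
    truth_rows = []
    for genotype, probs in defect_probs.items():
        unknown = sorted(set(probs) - set(DEFECT_CATEGORIES))
        if unknown:
            raise ValueError(f"unknown defect categories: {unknown}")
        p = np.array([probs.get(c, 0.0) for c in DEFECT_CATEGORIES])
        if (p < 0).any():
            raise ValueError("defect probabilities must be non-negative")
        if p.sum() > 1 + 1e-12:
            raise ValueError(
                f"defect probabilities for {genotype} sum to {p.sum():.3f} > 1"
            )
        pk = np.append(p, max(0.0, 1.0 - p.sum()))
        pk = pk / pk.sum()
        for e in range(n_embryos):
            embryo_id = f"{genotype}_e{e:04d}"
            k = rng.choice(len(pk), p=pk)
            if k == len(DEFECT_CATEGORIES):
                truth_rows.append((genotype, embryo_id, "none"))
                continue
            category = DEFECT_CATEGORIES[k]
            truth_rows.append((genotype, embryo_id, category))
            t0 = float(rng.uniform(100.0, 400.0))
            if category == "async_wave":
                event_rows.append((genotype, embryo_id, pd.NA, cycle, t0, category))
                continue
            nucleus = int(rng.integers(nuclei_per_embryo))
            event_rows.append(
                (genotype, embryo_id, f"n{nucleus:03d}", cycle, t0, category)
            )
            if rng.random() < secondary_prob:  # later event, same nucleus
                cat2 = nucleus_cats[int(rng.integers(len(nucleus_cats)))]
                event_rows.append(
                    (genotype, embryo_id, f"n{nucleus:03d}", cycle,
                     t0 + float(rng.uniform(30.0, 120.0)), cat2)
                )
            if rng.random() < secondary_prob:  # later event, other nucleus
                other = int((nucleus + 1 + rng.integers(nuclei_per_embryo - 1))
                            % nuclei_per_embryo)
                cat2 = nucleus_cats[int(rng.integers(len(nucleus_cats)))]
                event_rows.append(
                    (genotype, embryo_id, f"n{other:03d}", cycle,
                     t0 + float(rng.uniform(30.0, 120.0)), cat2)
                )
    events = pd.DataFrame(
        event_rows,
        columns=["genotype", "embryo_id", "nucleus_id", "cycle", "time_s", "category"],
    )
    truth = pd.DataFrame(truth_rows, columns=["genotype", "embryo_id", "category"])
    return DefectSimulation(events=events, true_first_defects=truth)


@dataclass(frozen=True)
class WaveSimParams:
    """Mitotic-wave onset model along the normalized anterior-posterior axis.

    Positions live on [0, 1] (0 = anterior pole).  In the bidirectional
    (wild-type) mode two metachronous waves start at both poles and meet in
    the middle: onset(x) = base + speed * min(x, 1-x).  In the
    unidirectional (mutant) mode a single wave crosses the embryo from
    ``origin_pole``: onset(x) = base + speed * x (or 1-x).  ``wave_speed``
    is in seconds per egg length.
    """

    mode: str = "bidirectional"
    wave_speed: float = 10.0
    onset_noise_sd: float = 0.0
    n_positions: int = 12
    origin_pole: str = "posterior"
    base_time: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("bidirectional", "unidirectional"):
            raise ValueError("mode must be 'bidirectional' or 'unidirectional'")
        if self.origin_pole not in ("anterior", "posterior"):
            raise ValueError("origin_pole must be 'anterior' or 'posterior'")
        if not self.wave_speed > 0:
            raise ValueError("wave_speed must be positive")
        if self.onset_noise_sd < 0:
            raise ValueError("onset_noise_sd must be non-negative")
        if self.n_positions < 3:
            raise ValueError("n_positions must be >= 3")


def simulate_wave_onsets(params: WaveSimParams, seed: int = 0) -> pd.DataFrame:
    """Division-onset times at equally spaced axis positions."""
    x = np.linspace(0.0, 1.0, params.n_positions)
    if params.mode == "bidirectional":
        t = params.base_time + params.wave_speed * np.minimum(x, 1.0 - x)
    elif params.origin_pole == "anterior":
        t = params.base_time + params.wave_speed * x
    else:
        t = params.base_time + params.wave_speed * (1.0 - x)
    if params.onset_noise_sd > 0:
        rng = np.random.default_rng(seed)
        t = t + rng.normal(0.0, params.onset_noise_sd, size=x.shape)
    return pd.DataFrame({"position": x, "onset_time_s": t})
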