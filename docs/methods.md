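# Methods

## The biological setting

TFIIH is a ten-subunit transcription/repair factor. Its Cdk-activating
kinase module (CAK: Cdk7, Cyclin H, Mat1) exists in three states inside a
cell: free trimeric CAK, tetrameric CAK (trimer + Xpd), and holo-TFIIH
(tetrameric CAK bridged by Xpd to the core subunits, among them Hay/Xpb
and Mrn/p52). An anti-Cdk7 immunoprecipitation therefore recovers a
mixture of the three species, and the relative abundance of Xpd and of
core subunits per unit Cdk7 reads out how well a given Xpd variant binds
CAK and core TFIIH. The package quantifies that readout, plus two
organism-level phenotypes of xpd mutant embryos: UV-induced lethality and
loss of mitotic synchrony in the syncytial blastoderm.

## Pool model and generator (`tfiihkit.synthetic`)

`ComplexPoolModel` carries two effective binding parameters:
`k_xpd_cak`, the fraction of recovered CAK that carries Xpd, and
`k_xpd_core`, the fraction of Xpd-bound CAK further bound to core.
Expected recovered abundance is **linear** in both:

- Cdk7, CycH, Mat1: `total_cdk7 * ip_efficiency` (the trimer is always
  intact — CycH and Mat1 are locked 1:1 to Cdk7, because xpd mutations do
  not destabilize CAK itself; genotypes differ only in the two k's),
- Xpd: `... * k_xpd_cak`,
- Hay, Mrn: `... * k_xpd_cak * k_xpd_core`.

Wild type is `k = 1` (fully assembled); values above 1 model enhanced
recovery of an interaction, as seen for some alleles. The linearity is
deliberate: it makes every downstream bait-normalized fold change equal
to the simulated k-factor exactly at zero noise, which is what the
parameter-recovery tests assert. `pool_fractions()` reports the
free-CAK3/CAK4/holo partition with occupancies clipped to [0, 1] so the
fractions always sum to 1.

Peptide intensity = expected protein abundance × per-protein ionization
factor × `exp(N(0, noise_sigma))`, independent per peptide and injection.
Defaults: `noise_sigma = 0.15` (the scale of typical repeat-injection
variability in targeted LC-MS; the 50% CV acceptance filter is an outlier
cut, not the typical spread), `ip_efficiency = 0.5` (cancels in all
bait-normalized statistics; sets only the absolute intensity scale).
The default inventory has three peptides per subunit except Hay and Mrn
(one each, flagged single-peptide downstream); sequences are synthetic
placeholders.

The survival generator draws deaths per arm as
`Binomial(n_per_arm, p)` with the irradiated arm's odds multiplied by
`exp(uv_log_odds_effect)`, so a genotype's population odds ratio is
exactly `exp(effect)`. The defect generator draws one first-defect
category per embryo (remaining mass = no defect) and, with probability
`secondary_prob`, later events in the same and in another nucleus — these
exist solely to exercise the first-defect scoring rule. Wave onsets
follow the tent (`c + k·min(x, 1−x)`) or line (`c + k·x`) model on the
normalized anterior→posterior axis [0, 1] plus Gaussian onset noise.

What the generator does **not** emulate: missing peptides and
interference-driven (non-lognormal, correlated) intensity errors, batch
effects between pulldowns, overdispersed embryo mortality, spatial
nucleus structure, or detection failure of subtle defects. Passing
recovery tests therefore show the chains are correct and well calibrated
under the stated noise model, not that real data meet that model.

## Stoichiometry chain (`tfiihkit.ipms`)

- **CV filter**: CV = sample (n−1) SD over observed injections / mean;
  accept iff ≥ 2 injections observed, mean > 0, CV < threshold (default
  0.5). One observation gives no dispersion estimate and is rejected.
- **Protein sums** use accepted peptides only (whether rejected-CV
  peptides should ever be included is not decidable from the experiment
  description; excluding them is this package's rule and is stated in the
  output via the thresholds block).
- **Bait normalization** divides by the bait's summed intensity within
  the same genotype; the chain is invariant to any per-genotype rescaling
  of raw intensities (tested as a property).
- **Classification** thresholds default to down 1.5×, strong 3×, up 1.5×.
  The underlying colour scheme being reproduced is qualitative, so the
  thresholds are explicit config, reported in every JSON report. The
  core-binding statistic is the geometric mean of core:Xpd ratios
  (multiplicative data; robust to one noisy subunit), compared against
  the same statistic in wild type. The reduced-Xpd–CAK label conditions
  on the Xpd:bait fold only: under the pool model, core recovery is
  proportional to Xpd-bound CAK, so a separate core condition would be
  redundant and noise-sensitive.
- **CAK QC** reports the across-genotype CV of CycH:bait and Mat1:bait
  and passes below a tolerance (default 20%).

## Survival chain (`tfiihkit.survival`)

OR orientation: odds of death in the irradiated over the control arm, so
UV sensitivity gives OR > 1. Zero cells: Haldane–Anscombe +0.5 on all
four cells, flagged; tables degenerate even after correction (both arms
all dead or all alive) are flagged, not raised. The UV-induced death rate
is the arithmetic difference of arm death rates, floored at 0 with a flag
(a ratio variant would change units, and the derived-from-counts reading
supports a difference).

Simultaneous intervals: Wald on log-OR with the per-comparison level
Šidák-sharpened, `α' = 1 − (1 − α)^(1/k)` (Bonferroni `α/k` via config).
Šidák is exact under independence of lines — satisfied here, since lines
are separate experiments — and conservative-safe otherwise. For k = 1
both reduce to the unadjusted interval. `coverage_simulation` verifies
joint coverage by simulation; it shares the cell-correction and
critical-value code with the scalar estimator, and a test pins the
vectorized path to `odds_ratio` table-by-table. With k = 11, n = 100 per
arm and baseline death probability 0.115, empirical joint coverage of the
nominal-95% procedure is ≈ 98% (the Wald-plus-Šidák construction is
mildly conservative at these cell counts).

## Cell-cycle chain (`tfiihkit.defects`)

First-defect reduction runs nucleus-first (earliest event per nucleus),
then embryo-first (earliest surviving event, embryo-level asynchronous
waves competing by time), so one event stream yields the per-embryo
category frequencies directly. Exact time ties are broken by the fixed
precedence async_wave > chromatin_bridge > nucleus_loss and flagged;
exact duplicate records are dropped with a warning. Frequencies use the
number of embryos analyzed as denominator (an experiment-level input —
defect-free embryos leave no events) and Wilson score intervals, which
behave well at small n and at proportions near 0 or 1.

Wave classification is model competition, not an asymmetry threshold:
fit tent and line by least squares (the line's slope sign identifies the
origin pole, so no mirror fit is needed; the tent slope is constrained
non-negative, since a negative tent would mean a biologically
uninterpretable center-origin wave) and pick the lower RSS. Both models
have two parameters, so RSS comparison is fair. All-equal onset times are
classified indeterminate. The classifier is exact on noise-free model
data, symmetric under the anterior/posterior mirror, and ≥ 95% correct at
onset noise equal to 10% of the onset range (tested at 200 embryos per
mode, 12 positions).

## Orchestration and determinism

`pipeline.run_*` functions (and the thin CLI over them) read the TSV
interfaces, run one chain, and write a TSV table plus a JSON report that
embeds the thresholds used and a provenance block (package version,
SHA-256 of the canonical config). Reports are byte-identical across
repeat runs with the same inputs, config and seed; JSON keys are sorted
and floats are written at fixed precision to keep that guarantee.

## Problem sizes used in validation

Recovery and coverage studies run at the scales the experimental design
implies: 2000 simulated families of 11 genotypes at 100 embryos per arm
for CI coverage; 200 synthetic pulldown datasets per perturbation
scenario (wild type + mutant, 14 peptides, 3 injections) for
classification recovery; 200 embryos per mode for the wave classifier;
200 panels for the CAK QC rate. These sizes give binomial standard errors
well below the margins being asserted.

## Known limitations

- The interaction-defect thresholds are conventions, not fitted cut
  points; borderline alleles near a threshold can flip label under noise
  (the two statistics are always reported alongside the labels).
- Wald log-OR intervals rely on cell counts of moderate size; at very
  small n or extreme probabilities an exact or score method would be
  preferable to the corrected Wald construction.
- Single-peptide proteins (Hay, Mrn) carry no internal replication at the
  peptide level; their estimates are flagged but not down-weighted.
- The wave classifier assumes a single recording per embryo covering the
  whole axis; partial spatial coverage biases the model competition
  toward the line.
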