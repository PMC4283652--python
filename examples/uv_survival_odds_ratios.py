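"""UV-survival odds ratios with simultaneous confidence intervals.

Simulates control/irradiated embryo counts for a panel of fly lines (100
embryos per arm; baseline death probability 0.115 with line-specific UV
log-odds effects), then computes per-line death rates, UV-induced death
rates, sample odds ratios and Sidak-adjusted simultaneous 95% intervals.
"""

import math

from tfiihkit import survival as sv, synthetic as syn

params = syn.default_survival_params(n_per_arm=100)
counts = syn.simulate_survival(params, seed=2)
table = sv.analyze_survival(
    counts, nominal_level=0.95, method="sidak", reference_genotype="xpd_wt"
)

cols = ["genotype", "death_rate_control", "death_rate_irradiated",
        "uv_induced_death_rate", "or_hat", "ci_low", "ci_high"]
print(table[cols].round(3).to_string(index=False))
print(
    "\nOR > 1 means higher odds of death after irradiation; an interval "
    "excluding 1 flags a UV-sensitive line at the simultaneous 95% level "
    f"(family of {len(table)} lines). True ORs ranged from "
    f"{math.exp(min(params.uv_log_odds_effect.values())):.1f} to "
    f"{math.exp(max(params.uv_log_odds_effect.values())):.1f}."
)
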