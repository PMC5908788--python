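"""Detect diurnal rhythms in a simulated TF DNA-binding-activity study.

Generates a two-cycle (ZT0..ZT45, 3-h sampling) study in which half of 40
TFs oscillate with a 24-h period, normalizes the raw abundances
(FOT -> per-cycle z-score), runs the rank-based rhythm test over the
20-28 h period grid, and compares the calls with the planted truth.
"""

from circatf import (
    RunConfig,
    StudyConfig,
    ibaq_to_fot,
    jtk_cycle,
    simulate_study,
    zscore_per_cycle,
)

bundle = simulate_study(StudyConfig(n_tfs=40, frac_rhythmic=0.5, snr=4.0, seed=1))
dba = bundle.matrices["tf_dba"]

fot = ibaq_to_fot(dba)          # per-column fraction-of-total
z = zscore_per_cycle(fot)       # per-feature, per-cycle standardisation

config = RunConfig(seed=1)
table = jtk_cycle(z, config, alpha=config.alpha_proteome)

planted = set(bundle.truth.rhythmic_tf_ids)
called = set(table[table.rhythmic].feature_id) & set(bundle.truth.tf_ids)

print(f"features tested:      {len(table)}")
print(f"planted rhythmic TFs: {len(planted)}")
print(f"called rhythmic TFs:  {len(called)}  (adjusted p < {config.alpha_proteome})")
print(f"recovered:            {len(called & planted)}")
print(f"false calls:          {len(called - planted)}")
best = table[table.rhythmic].nsmallest(3, "p_adj")
print("\nstrongest rhythms (period in h, peak ZT, adjusted p):")
for _, r in best.iterrows():
    print(f"  {r.feature_id}: period {r.best_period_h:.0f}, "
          f"peak ZT{r.best_lag_h:.1f}, p_adj {r.p_adj:.2e}")
# A recovered/false-call split near 20/0 shows the test detects every
# planted oscillator at this signal-to-noise without inflating the calls.
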