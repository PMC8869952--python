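"""Match subtype solutions from the two morphological measures.

Fits the mixture-of-experts independently on the density table and the
thickness table, pairs the resulting subtypes by maximum subject overlap
(optimal assignment on the 4 x 4 contingency table), and reports the Dice
score of each matched pair.
"""

from admoe import (
    MOEConfig,
    concordance_report,
    fit_moe,
    generate_cohort,
    hard_assign,
    match_subtypes,
    residualize_pipeline,
)

density, ct, truth, _ = generate_cohort(n_cn=200, n_ad=180, kappa=0.8, seed=42)

solutions = {}
for table in (density, ct):
    residuals, _ = residualize_pipeline(table)
    model = fit_moe(residuals, MOEConfig(seed=0))
    solutions[table.modality] = hard_assign(model)

match = match_subtypes(solutions["density"], solutions["ct"])
report = concordance_report(
    match, solutions["density"], solutions["ct"], truth=truth
)

print("subtype pairing (density -> ct):", match.mapping)
for k, dice in enumerate(match.dice, start=1):
    print(f"  matched pair {k}: Dice = {100 * dice:.1f}%")
print(f"mean Dice {100 * report['dice_mean']:.1f}% "
      f"(range {100 * report['dice_min']:.1f}-{100 * report['dice_max']:.1f}%)")
print(f"ARI vs truth: density {report['ari_a']:.3f}, ct {report['ari_b']:.3f}")
# With kappa = 0.8, one AD subject in five expresses a different subtype in
# the thickness table, so matched Dice sits near 80% even at perfect
# clustering — mirroring the imperfect overlap seen with real cohorts.
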