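"""Score a small (C, t) grid with the three selection indicators.

Each cell reports stratified 10-fold cross-validated diagnostic accuracy
(ACC), the Bezdek partition coefficient (BPC, membership crispness) and
the maximum pairwise expert cosine (W_r, expert redundancy), and a
deterministic lexicographic rule picks the operating point.  The full
14 x 14 powers-of-two grid works the same way, just longer; a 2 x 2
sub-grid keeps this example quick.
"""

from admoe import (
    MOEConfig,
    generate_cohort,
    grid_search,
    residualize_pipeline,
    select_parameters,
)

density, _, _, _ = generate_cohort(n_cn=100, n_ad=100, seed=42)
residuals, _ = residualize_pipeline(density)

grid = grid_search(
    residuals,
    c_values=[2.0**-3, 2.0**0],
    t_values=[2.0**-2, 2.0**1],
    config=MOEConfig(seed=0),
    n_folds=5,
    seed=7,
)
C_star, t_star, ranked = select_parameters(grid)

print(ranked.round(3).to_string(index=False))
print(f"\nselected C = {C_star}, t = {t_star} "
      "(max ACC; ties within 0.5% broken by higher BPC, then lower W_r)")
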