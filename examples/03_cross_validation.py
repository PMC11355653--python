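"""Validate a top-6 model by exhaustive leave-one-out and leave-two-out CV.

The six highest-VIP variables feed a second (validation) PLS model that is
refitted once per fold.  Continuous predictions are called trichotomously:
above +0.1 fitting, below -0.1 non-fitting, the middle band unknown.
Leave-two-out makes n(n-1) = 210 predictions for 15 participants (each is
predicted once per possible co-held-out partner), shown as a heatmap.
"""

from pessaryfit import (
    auto_components,
    build_design_matrix,
    default_effect_profile,
    fit_pls,
    generate_cohort,
    leave_one_out_cv,
    leave_two_out_cv,
    render_heatmap_text,
    select_top_k,
    vip_scores,
)

cohort = generate_cohort(9, 6, default_effect_profile(), seed=1)
design = build_design_matrix(cohort)
vip = vip_scores(fit_pls(design, auto_components(design)))
selected = select_top_k(vip, 6)

for name, runner in [("leave-one-out", leave_one_out_cv),
                     ("leave-two-out", leave_two_out_cv)]:
    report = runner(cohort, selected)
    t, pct = report.tallies, report.percentages()
    print(f"{name}: {t['n_correct']}/{t['n_total']} correct"
          f" ({pct['correct_pct']}%), {pct['incorrect_pct']}% incorrect,"
          f" {pct['unknown_pct']}% unknown")

lto = leave_two_out_cv(cohort, selected)
print("\nheatmap (+ correct, x incorrect, ? unknown, . diagonal);")
print("rows = predicted participant, columns = co-held-out participant:\n")
print(render_heatmap_text(lto).split("\n\ncoded values:")[0])
# A row full of x marks a participant the model systematically mispredicts
# regardless of which partner is held out with them.
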