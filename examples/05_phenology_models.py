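"""Fit the event-time and proportion models on a synthetic study.

Cox proportional hazards (Efron ties, sequential likelihood-ratio tests)
for flowering and brood onset, the proportion GLMs, the height mixed
model, the weight-change model, and Tukey-adjusted contrasts.
"""

from phenobee.detect import analyze_colony, build_survival_records
from phenobee.phenostats import (
    fit_cross_species_cox,
    fit_flowering_cox,
    fit_height_lmm,
    fit_onset_cox,
    fit_weight_model,
    summarize_proportions,
    weight_status_means,
)
from phenobee.scenario import EXPERIMENT_END, EXPERIMENT_START
from phenobee.synthetic import SimulationConfig, generate_study

bundle = generate_study(SimulationConfig(seed=1))

onsets, deaths = {}, {}
for cid, samples in bundle.telemetry.groupby("colony_id"):
    r = analyze_colony(samples)
    onsets[cid], deaths[cid] = r["onset"], r["death"]
survival = build_survival_records(
    onsets, deaths, EXPERIMENT_START, EXPERIMENT_END, bundle.colonies
)

for res in (
    fit_flowering_cox(bundle.flowering),
    fit_onset_cox(survival),
    fit_height_lmm(bundle.heights),
    fit_weight_model(weight_status_means(bundle.weights, bundle.colonies)),
):
    print(f"== {res.name} ==")
    print(res.anova.to_string(index=False))
    print()

cross = fit_cross_species_cox(bundle.flowering, survival, "current")
print("== cross-species (current regime), Tukey cell contrasts ==")
print(cross.contrasts[["cell_a", "cell_b", "estimate", "p_tukey"]]
      .round(3).to_string(index=False))

mean, sd = summarize_proportions([(4, 4), (4, 4), (4, 4), (3, 4)])
print(f"\nper-pot open-flower proportion for a 15-of-16 cell: {mean} +- {sd}")
print("Small p-values on temperature/photoperiod terms reflect the effects "
      "the generator encodes; brood onset is patternless by construction.")
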