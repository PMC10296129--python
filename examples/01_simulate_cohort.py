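"""Generate a synthetic control population and stroke cohort.

The control population feeds the normative model; the stroke cohort gets
trial-level APM sessions at two weeks and six months, clinical scores and
lesion masks, with a latent severity linking all modalities.  The realised
six-month impairment fraction is calibrated against the fitted normative
model (~36% by default).
"""

from propriokit import fit_normative_model
from propriokit.synthetic import (
    SyntheticConfig,
    control_observations,
    generate_control_cohort,
    generate_stroke_cohort,
)

config = SyntheticConfig(n_controls=300, n_stroke=133, seed=42)

controls = generate_control_cohort(config)
print(f"controls: {len(controls.demographics)} subjects, {len(controls.sessions)} APM sessions")

model = fit_normative_model(control_observations(controls))
stroke = generate_stroke_cohort(config, model)

prevalence = stroke.scores["impaired_6mo"].mean()
print(f"stroke cohort: {len(stroke.demographics)} participants, "
      f"{len(stroke.sessions)} sessions, {len(stroke.lesions)} lesion masks")
print(f"severity scale after calibration: {stroke.severity_scale:.3f} "
      f"({stroke.calibration_iterations} evaluations)")
print(f"impaired at six months: {stroke.scores['impaired_6mo'].sum()} "
      f"({100 * prevalence:.1f}% — target {100 * config.prop_impaired_6mo:.1f}%)")
print(f"mean Task Score: {stroke.scores['task_score_2wk'].mean():.2f} at two weeks, "
      f"{stroke.scores['task_score_6mo'].mean():.2f} at six months")
print(f"latent severity falls with recovery: {stroke.severity['s_2wk'].mean():.2f} -> "
      f"{stroke.severity['s_6mo'].mean():.2f} (population mean; Task Scores follow on average)")
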