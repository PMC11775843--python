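"""Apply a frozen endotyping model to a new cohort (no re-fitting).

Mirrors the second validation pathway: the development model's normalizer,
encoder weights and mixture are reused verbatim on data from a different
population (here: the critically-ill parameter set), yielding per-point
posterior endotype probabilities.
"""

import endotyper as et
from endotyper.autoencoder import AutoencoderConfig
from endotyper.clustering import GMMConfig
from endotyper.endotyping import assign, rollup_episodes
from endotyper.episodes import extract_cohort_points
from endotyper.pipeline import PipelineConfig, run_pipeline
from endotyper.synth import SECOND_VALIDATION_SPECS

# develop on the surgical parameter set ...
dev = et.generate_cohort(et.CohortConfig(n_patients=50, points_per_patient=200, seed=4))
config = PipelineConfig(
    autoencoder=AutoencoderConfig(epochs=60), gmm=GMMConfig(n_restarts=4),
    k_range=(4, 4), seed=21,
)
_, model = run_pipeline(dev.frame, config)

# ... apply frozen to a critically-ill cohort
icu = et.generate_cohort(
    et.CohortConfig(n_patients=30, points_per_patient=200,
                    endotype_specs=SECOND_VALIDATION_SPECS, seed=5)
)
points = extract_cohort_points(icu.frame)
result = assign(model, points)

print(f"assigned {len(result.frame)} points from the new cohort")
print("\nhard-label shares (probability-weighted membership is also available):")
print(result.labels.value_counts(normalize=True).round(3).to_string())
print("\nfirst rows of per-point posterior probabilities:")
print(result.frame.head(5).round(3).to_string(index=False))
episodes = rollup_episodes(result)
print(f"\nepisode-level roll-up: {len(episodes)} episodes; a row's probabilities")
print("are the mean posterior over the episode's points.")
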