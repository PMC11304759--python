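"""Generate a synthetic cohort and inspect how well the observation streams
track the latent mood ground truth."""

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from moodpulse import CohortConfig, simulate_cohort

bundle = simulate_cohort(CohortConfig(n_users=100, n_days=14, seed=42))

print(f"users: {bundle.n_users}, 3-hour slots per user: {bundle.n_slots}")
print(f"ESM annotations: {len(bundle.annotations)} "
      f"(7-level Likert, ~6 prompts/day, 50% answered)")
print(f"sensor frames:  {len(bundle.sensor_frames)}")
print(f"query events:   {len(bundle.queries)}")

# fidelity of the Likert discretization: annotations should track latent mood
ann = bundle.annotations
slots = ((pd.to_datetime(ann["timestamp"]) - bundle.slot_starts[0])
         .dt.total_seconds() // (3 * 3600)).astype(int)
latent_at_ann = bundle.latent[ann["user_id"].to_numpy(), slots.to_numpy()]
rho = spearmanr(latent_at_ann, ann["likert"]).statistic
print(f"Spearman(latent mood, Likert answer) = {rho:.3f}")
print("-> the self-reports are a noisy but faithful discretization of the")
print("   latent mood the models are later asked to recover")

# population mood carries the weekly cycle the rhythm analysis looks for
daily = bundle.daily_population_mood()
by_weekday = daily.groupby(daily.index.day_name()).mean()
print("\nmean population mood by weekday:")
print(by_weekday.reindex(["Monday", "Wednesday", "Friday", "Saturday",
                          "Sunday"]).round(3).to_string())
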