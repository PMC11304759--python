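"""Weekly mood rhythm: for each weekday, how often is the national daily
score at or above the previous day's?

The generator's weekly cycle peaks on Sunday and sags midweek, so Mondays
should almost always fall below the preceding Sunday while weekend days rise.
"""

from moodpulse.studies import weekly_rhythm_study

table = weekly_rhythm_study(n_users=250, n_days=26 * 7, seed=0)
print("fraction of days with score >= yesterday (half a simulated year):")
print(table.round(1).to_string())
print("\n-> Monday ~0% 'up', Saturday/Sunday close to 100%: the aggregate")
print("   score exposes the population's weekly mood cycle.")
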