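"""Harmonizing mixed trial results onto one benefit-positive SMD scale.

A pain trial (continuous, lower score is better -> harm direction) and a
healing trial (binary, event is good -> benefit direction) end up directly
comparable after conversion and direction harmonization.
"""

from metaconstancy import harmonize_direction, smd_binary, smd_continuous

# Continuous pain-intensity outcome: active mean 3.1 vs placebo 4.0 (0-10 scale)
pain = smd_continuous(
    active_mean=3.1, active_sd=2.0, active_n=60,
    placebo_mean=4.0, placebo_sd=2.1, placebo_n=58,
)
pain_harmonized = harmonize_direction(pain, "harm")

# Binary healing outcome: 42/90 healed on active vs 28/88 on placebo
healing = smd_binary(active_events=42, active_n=90, placebo_events=28, placebo_n=88)
healing_harmonized = harmonize_direction(healing, "benefit")

for label, e in [("pain (harm outcome)", pain_harmonized),
                 ("healing (benefit outcome)", healing_harmonized)]:
    print(f"{label}: SMD = {e.smd:+.3f}  (95% CI {e.ci_low:+.3f} to {e.ci_high:+.3f})")

print(
    "\nBoth SMDs are now positive when the active arm does clinically better:\n"
    "the raw pain effect was negative (lower score), the flip makes it comparable\n"
    "with the healing effect on one scale."
)
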