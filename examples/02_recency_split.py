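"""Splitting a meta-analysis into its historical and most recent parts.

For a simulated review, pool all trials, the trials before the latest
publication year (the historical meta-analysis), and the latest trial(s)
separately — the triple that drives the constancy question: does the
historical pooled effect predict the newest trial?
"""

from metaconstancy import SimulationConfig, recency_split, simulate_corpus

reviews, truth = simulate_corpus(SimulationConfig(n_reviews=5, seed=12))
review = max(reviews, key=len)
split = recency_split(review)

print(f"review {split.review_id}: {split.k_all} trials, "
      f"{split.first_year}-{split.year_of_last}")
print(f"  pooled SMD, all trials     : {split.smd_all.smd:+.3f} "
      f"(I2 = {split.smd_all.i2:.0f}%, tau2 = {split.smd_all.tau2:.3f})")
print(f"  historical (last deleted)  : {split.smd_dl.smd:+.3f} "
      f"from {split.smd_dl.k} trials, n = {split.smd_dl.n_total}")
print(f"  most recent trial(s)       : {split.smd_lt.smd:+.3f} "
      f"from {split.k_last} trial(s) in {split.year_of_last}")
print(f"  eligible for regression    : {split.eligible}")

theta = truth.reviews.set_index("review_id").loc[split.review_id, "theta"]
print(f"\nGenerator's true review effect: {theta:+.3f} — the pooled estimates "
      "scatter around it with sampling noise and heterogeneity.")
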