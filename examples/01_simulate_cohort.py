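"""Simulate the study cohort: 1000 virtual respondents to the 30-item
skin-cancer risk questionnaire.

Abilities are drawn from N(0, 1) logits, item responses from the partial
credit model at each respondent's true ability, and the binary cancer
label is assigned where the true ability reaches the 0.88-logit cutoff.
"""

from scipy import stats

from sccat import SimulationConfig, generate_cohort, packaged_bank

bank = packaged_bank()
config = SimulationConfig(n=1000, ability_mean=0.0, ability_sd=1.0, cutoff=0.88, seed=42)
cohort = generate_cohort(bank, config)

print(f"cohort: {cohort.n} respondents x {cohort.n_items} items")
print(f"positive (cancer) labels: {cohort.labels.sum()} "
      f"({cohort.labels.mean():.1%} of the cohort)")
print(f"expected from the normal tail beyond 0.88 logits: {stats.norm.sf(0.88):.1%}")
print(f"ability range: {cohort.thetas.min():.2f} to {cohort.thetas.max():.2f} logits")
print("first respondent's responses:", cohort.responses[0])

# The positive fraction tracks P(theta >= 0.88) for a standard normal
# (~18.9%); each response is an integer category 0..K for its item.
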