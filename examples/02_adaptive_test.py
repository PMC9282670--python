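"""Run one adaptive test for a simulated respondent and inspect the
session: item-by-item ability trajectory, stopping, fit diagnostics,
expected-value imputation, and final classification.
"""

from sccat import (
    SimulationConfig,
    SimulatedResponder,
    StopRule,
    generate_cohort,
    packaged_bank,
    run_cat,
)
from sccat.cat import fit_statistics
from sccat.classify import odds, predict_proba, train

bank = packaged_bank()

# a respondent with elevated true risk (1.2 logits)
session = run_cat(bank, SimulatedResponder(1.2, rng=7), rule=StopRule(), seed=7)

print(f"administered {session.n_administered} of {len(bank)} items "
      f"({session.items_saved_fraction:.0%} saved); stopped: {session.stopped_because}")
for step, ((iid, obs), th, se) in enumerate(
    zip(session.administered, session.theta_trajectory, session.se_trajectory), 1
):
    print(f"  step {step}: item {iid:2d} response {obs:.0f} -> theta {th:+.2f} (SE {se:.2f})")
print(f"final theta {session.final_theta:.2f} logits, SE {session.final_se:.3f} "
      f"(stop threshold 0.469 = 1.0 x sqrt(1 - .78))")

fit = fit_statistics(session)
print(f"fit: infit MNSQ {fit.infit_mnsq:.2f}, outfit MNSQ {fit.outfit_mnsq:.2f}, "
      f"v {fit.v:.3f}, t {fit.t_statistic:.2f} (outfit > 2 would flag aberrance)")

# classify from the imputed 30-item vector with a logistic model trained
# on a simulated cohort
cohort = generate_cohort(bank, SimulationConfig(seed=1))
model = train("lr", cohort.responses, cohort.labels)
p = float(predict_proba(model, session.imputed_vector)[0])
print(f"P(cancer) = {p:.2f}, odds = {odds(p):.2f} -> {'SC+' if p >= 0.5 else 'SC-'}")
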