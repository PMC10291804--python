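"""Trace one adaptive administration step by step.

Items are chosen by the determinant rule (maximize the determinant of the
posterior information matrix), traits re-estimated by MAP after every
response, and the run stops when the general-factor SE drops below 0.32.
"""

import numpy as np

import bifcat as bc

bank = bc.generate_item_bank(bc.BankSpec(seed=3))
thetas = bc.generate_thetas(5, bank.D, seed=11)
responses = bc.simulate_responses(thetas, bank, seed=12)

policy = bc.factorial_design()["sim3"]   # SE(general) < 0.32, no other rules
respondent = 2
record = bc.administer_respondent(responses[respondent], bank, policy,
                                  respondent=respondent)

print(f"true general trait: {thetas[respondent, 0]:+.3f}")
print(f"{'step':>4} {'item':<22} {'resp':>4} {'theta_hat_0':>11} {'SE_0':>6}")
x = np.full(bank.n_items, -1)
for step, (iid, resp) in enumerate(zip(record.item_ids, record.responses), 1):
    x[bank.index_of(iid)] = resp
    th = record.theta_history[step - 1]
    se = bc.standard_errors(bc.posterior_information(th, x, bank))
    print(f"{step:>4} {iid:<22} {resp:>4} {th[0]:>+11.3f} {se[0]:>6.3f}")

print(f"stopped after {record.n_items} of {bank.n_items} items "
      f"({record.stop_reason}); final estimate {record.theta_hat[0]:+.3f} "
      f"vs truth {thetas[respondent, 0]:+.3f}")
print("Each response tightens the posterior; the SE column shows the",
      "general-factor precision crossing the 0.32 stopping threshold.")
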