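"""Build a synthetic bifactor item bank and simulate responses from it.

The bank mimics a 44-item health-related quality-of-life instrument:
one general factor, ten group factors (3-6 items each), three
general-only items, and mixed 2- to 6-point response formats.
"""

import numpy as np

import bifcat as bc

bank = bc.generate_item_bank(bc.BankSpec(seed=3))
print(f"bank: {bank.n_items} items, {bank.G} group factors, D = {bank.D}")

a_gen = [it.a_general for it in bank.items]
a_grp = [it.a_group for it in bank.items if it.group_index > 0]
print(f"general slopes span [{min(a_gen):.2f}, {max(a_gen):.2f}], "
      f"group slopes span [{min(a_grp):.2f}, {max(a_grp):.2f}]")

thetas = bc.generate_thetas(1000, bank.D, seed=11)
responses = bc.simulate_responses(thetas, bank, seed=12)
print(f"responses: {responses.shape[0]} persons x {responses.shape[1]} items, "
      f"categories 0..{responses.max()}")

# empirical category distribution of the first item vs its model curve at theta=0
item = bank.items[0]
p0 = bc.category_probabilities(item, np.zeros(bank.D))
print(f"{item.item_id}: model P(x|theta=0) = {np.round(p0, 3)}")
print("Slopes are discriminations in logit units per trait SD; the response",
      "matrix is the raw material for calibration and adaptive simulation.")
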