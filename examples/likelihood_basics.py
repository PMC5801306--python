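"""The diffusion likelihood in numbers.

Builds one parameter cell, prints the closed-form choice probability,
the first-passage density at a few response times, and the lapse-mixture
likelihood used for fitting.
"""

import numpy as np

from switchddm import ChoiceRT, DDMParams, choice_probability, \
    fpt_density, fpt_mass_within, lapse_likelihood, observed_accuracy

# the non-switch block-1 group-level cell
p = DDMParams(v=2.58, a=2.00, t0=0.3, lapse=0.10)

print(f"P(correct | diffusion)  = {choice_probability(p):.5f}"
      "   # logistic identity 1/(1+exp(-v*a))")
print(f"expected accuracy       = {observed_accuracy(p):.5f}"
      "   # with the 10% uniform-lapse mixture")
print(f"mass resolved by 2 s    = {fpt_mass_within(p, 2.0):.5f}"
      "   # rest are omissions at the deadline")
print()
print("first-passage density (correct boundary):")
for t in (0.35, 0.5, 0.8, 1.5):
    print(f"  f({t:.2f} s) = {fpt_density(t, 'upper', p):8.4f}")
print()
like = lapse_likelihood(ChoiceRT("upper", 0.5), p, deadline=2.0)
print(f"lapse-mixture likelihood of a correct 0.5-s response = {like:.4f}")
print("  # (1 - lapse) * density + lapse / (2 * deadline)")
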