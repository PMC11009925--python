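"""Code raw consumption values as none + tertiles of positive consumption.

Dietary intake per food group is typically a nonnegative amount with many
exact zeros. The standard categorisation keeps "never consumed" as its own
level and splits the consumers into tertiles, giving 4 ordinal levels per
food that the latent class model treats as categorical.
"""

import numpy as np

from surveylca import discretize_none_plus_tertiles

rng = np.random.default_rng(0)
# grams of some food group for 12 subjects; a third consume none
intake = np.where(rng.random(12) < 0.33, 0.0, rng.gamma(2.0, 40.0, 12)).round(1)

levels = discretize_none_plus_tertiles(intake)

print("intake (g):", intake)
print("levels    :", levels)
print()
print("level 1 = no consumption; levels 2-4 = lower/middle/upper tertile")
print("of the positive amounts (values on a cut point take the lower level)")
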