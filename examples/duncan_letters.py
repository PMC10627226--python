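"""Duncan's multiple range test with a compact letter display.

Five treatment means with a known error variance: means sharing a letter
are not significantly different at the 5% protection level; "a" always
sits on the largest mean, matching agronomy table conventions.
"""

from ojip import duncan_mrt, one_way_anova, star_code

import numpy as np

rng = np.random.default_rng(3)
levels = {"22/14": 0.74, "26/18": 0.84, "30/22": 0.83, "34/26": 0.77, "40/32": 0.76}
n = 5

# five replicate observations per level around each mean
values, labels = [], []
for lv, mu in levels.items():
    values.extend(rng.normal(mu, 0.015, n))
    labels.extend([lv] * n)

res = one_way_anova(values, labels)
letters = duncan_mrt(
    {lv: float(np.mean([v for v, l in zip(values, labels) if l == lv]))
     for lv in levels},
    n, res.mse, res.df_error, alpha=0.05,
)

print(f"ANOVA: F = {res.f_stat:.2f}, p = {res.p_value:.2g} "
      f"({star_code(res.p_value)})")
for lv in levels:
    mean = np.mean([v for v, l in zip(values, labels) if l == lv])
    print(f"  {lv:>6}: mean = {mean:.3f}  {letters[lv]}")
print("\nLevels sharing a letter are statistically indistinguishable under "
      "Duncan's range test; distinct letters mark significant differences.")
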