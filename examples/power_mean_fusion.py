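"""The power mean as a family of decision-fusion rules.

Fuses one vector of base-classifier scores at several exponents, showing
the sweep from min-like to max-like behavior.
"""

import numpy as np

from elapmc import pmc_fuse

scores = np.array([0.15, 0.55, 0.70, 0.92])
print(f"base scores: {scores}")
for alpha, name in [(-20, "~min"), (-1, "harmonic"), (0, "geometric"),
                    (1, "arithmetic"), (20, "~max")]:
    print(f"  alpha={alpha:+4d} ({name:10s}) -> {pmc_fuse(scores, alpha):.4f}")
# Lower exponents weight small scores more (a single sceptical base learner
# can veto), higher exponents let a single confident learner dominate; the
# ensemble picks the exponent that minimizes out-of-bag error.
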