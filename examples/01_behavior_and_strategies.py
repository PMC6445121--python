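"""Simulate prototypical Trustees in the Hidden Multiplier Trust Game.

Builds the standard 80-trial schedule and simulates four parameterizations
of the Moral Strategy Model that express the four moral strategies. The
printed table shows mean returned tokens by multiplier condition: guilt
aversion is flat across conditions (it honors the Investor's fixed belief),
inequity aversion scales with the true pot, moral opportunism follows
whichever moral rule is cheaper, and greed returns (almost) nothing.
"""

import numpy as np

from hmtg import MSParams, build_schedule, simulate_behavior

schedule = build_schedule(seed=0)
examples = {
    "inequity aversion (theta=.05, phi=+.08)": MSParams(0.05, 0.08),
    "guilt aversion    (theta=.05, phi=-.08)": MSParams(0.05, -0.08),
    "moral opportunism (theta=.05, phi= .00)": MSParams(0.05, 0.0),
    "greed             (theta=.48, phi= .00)": MSParams(0.48, 0.0),
}

print(f"{'strategy':44s}  x2    x4    x6")
for name, params in examples.items():
    data = simulate_behavior("MS", params, schedule)
    means = []
    for m in (2, 4, 6):
        mask = (schedule.multipliers == m) & (schedule.investments > 0)
        means.append(np.mean(data.returned[mask]))
    print(f"{name:44s}  " + "  ".join(f"{v:4.1f}" for v in means))
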