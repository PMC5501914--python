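"""Observer-agreement statistics on simulated repeated readings.

Simulates three raters each reading the same 200 beats twice (with
within-rater and between-rater noise), then reports Bland-Altman agreement
of each rater against the leave-one-out consensus and the intra-/inter-
operator variance split.
"""
import numpy as np
import pandas as pd

import tdiquant as tq

rng = np.random.default_rng(0)
n_beats, raters = 200, 3
truth = rng.normal(8.0, 2.0, n_beats)            # true per-beat s' (cm/s)
sigma_intra, sigma_inter = 0.7, 0.35             # within- / between-rater SD

readings = []
per_rater = np.empty((raters, n_beats))
for r in range(raters):
    rater_effect = rng.normal(0.0, sigma_inter, n_beats)
    for reading in (1, 2):
        values = truth + rater_effect + rng.normal(0.0, sigma_intra, n_beats)
        if reading == 1:
            per_rater[r] = values
        readings.append(pd.DataFrame({"rater": f"expert{r + 1}",
                                      "reading": reading,
                                      "beat": np.arange(n_beats),
                                      "value_cm_s": values}))

consensus, loo = tq.consensus(per_rater)
print("each expert vs the consensus of the others (first readings):")
for r in range(raters):
    st = tq.bland_altman(per_rater[r], loo[r])
    print(f"  expert{r + 1}: bias {st.bias:+.3f} cm/s, "
          f"95% LoA +/-{st.loa_half:.3f}, R^2 {st.r_squared:.3f} (n={st.n})")

intra, inter, frac = tq.variance_components(pd.concat(readings))
print(f"\nvariance split: intra-operator SD {intra:.2f} cm/s, "
      f"inter-operator SD {inter:.2f} cm/s")
print(f"{100 * frac:.0f}% of measurement variance is within-rater — "
      "reread the same trace and most of the disagreement comes back")
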