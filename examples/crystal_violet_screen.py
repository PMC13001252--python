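"""Hit-calling for a crystal-violet biofilm screen plate.

Builds three replicate plates where most wells sit at the plate-average
biofilm signal, plants one well with increased and one with decreased
staining, and calls hits with the 1.5-fold rule followed by an unpaired
t-test against control wells.
"""

import numpy as np
import pandas as pd

import tnarray as tn

rows, cols = list("ABCDEFGH"), list(range(1, 13))
rng = np.random.default_rng(5)

plates = []
for rep in range(3):
    signal = rng.normal(1.0, 0.05, size=(8, 12))
    signal[0, 0] = rng.normal(2.0, 0.05)   # A1: strong biofilm former
    signal[0, 1] = rng.normal(0.4, 0.03)   # A2: attachment-defective
    od660 = pd.DataFrame(rng.uniform(0.4, 0.6, size=(8, 12)), index=rows, columns=cols)
    od540 = od660 * signal  # so OD540/OD660 equals the intended signal
    plates.append(tn.ScreenPlate("plate1", f"rep{rep + 1}", od540, od660))

hits = tn.call_fold_hits(plates, fold=1.5)
called = hits[hits["direction"] != "none"]
print(called[["well_row", "well_col", "mean_signal", "fold_change", "direction"]])

control = [tn.normalize_plate(p).loc["H", 12] for p in plates]
for _, hit in called.iterrows():
    values = [tn.normalize_plate(p).loc[hit.well_row, hit.well_col] for p in plates]
    t, p_val = tn.ttest_vs_control(values, control)
    print(f"{hit.well_row}{hit.well_col}: t={t:.2f}, p={p_val:.4f}")
# A well is a hit when its replicate-mean OD540/OD660 departs from the plate
# mean by >= 1.5x; the t-test then quantifies confidence vs a control well.
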