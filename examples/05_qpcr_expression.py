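"""qPCR relative expression: standard curve, 2^-ddCt, significance stars.

Simulates a salt/osmotic stress panel (triplicates, actin reference,
untreated calibrator) with a known 6-fold salt induction, then recovers
the fold changes and significance, and fits a primer standard curve.
"""

import math

from genefam.qpcr import expression_table, primer_efficiency
from genefam.simulate import paper_stress_design, simulate_ct_data

samples, calibrator = paper_stress_design()
true_folds = {"control": 1.0, "PEG_4h": 0.5, "PEG_8h": 0.4, "NaCl_4h": 6.0, "NaCl_8h": 6.5}
data = simulate_ct_data(true_folds, ct_noise_sd=0.15, seed=20130524, genes=("GeneX",))

table = expression_table(data)
print(table[["sample", "fold_change", "p_value", "star"]].round(3).to_string(index=False))
print("(fold_change = 2^-ddCt vs untreated control; stars: * <0.05, ** <0.01, *** <0.001)")

# Dilution series: a slope of -log2(10) cycles per 10-fold dilution means
# perfect doubling per cycle, i.e. 100% primer efficiency.
points = [(-i, 20.0 + i * math.log2(10)) for i in range(5)]
curve = primer_efficiency(points)
print(f"\nstandard curve slope {curve.slope:.3f} -> efficiency E = {curve.efficiency:.3f}")
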