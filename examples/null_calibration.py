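"""Null-model calibration: the selection must stay empty on noise.

Runs the full pipeline on null datasets (1000 samples x 100 sites,
mutation probability 0.005, random case/control labels) and reports how
often a dataset is declared significant.  A calibrated selector yields a
rate far below the nominal 5% level, because selecting case-enriched
sites and then testing them would otherwise inflate the false-positive
rate enormously.
"""

from burdenmrf import run_null_battery

res = run_null_battery(n_datasets=200, seed=99)
print(f"null datasets analyzed: {res['n_datasets']}")
print(f"declared significant: {res['n_significant']} "
      f"({res['significant_fraction'] * 100:.2f}%)")
print(f"mean variants selected per dataset: {res['mean_selected']:.2f}")
print("\nA near-zero selection size is the mechanism: with nothing"
      "\nselected the collapsed test returns p = 1, so chance patterns"
      "\nnever reach the association stage.")
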