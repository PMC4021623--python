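"""Derive analysis-ready phenotypes from longitudinal EMR-style records.

Quantitative labs measured many times per person collapse to a single
value by the median-of-yearly-medians rule (one observation suffices).
Hypertension is dichotomized from blood-pressure readings and medication
flags; BMI is range-cleaned first to drop unit-conversion artefacts.
"""

import numpy as np
import pandas as pd

from mtphewas import median_of_yearly_medians, dichotomize_hypertension
from mtphewas.phenotypes import aggregate_quantitative

# longitudinal cholesterol records for one person
years = [2008, 2008, 2009, 2011, 2011, 2011]
chol = [182.0, 176.0, 190.0, 171.0, 169.0, 200.0]
value = median_of_yearly_medians(years, chol)
print(f"cholesterol records {chol} over years {sorted(set(years))}")
print(f"median-of-yearly-medians: {value}")   # medians 179, 190, 171 -> 179

# hypertension dichotomization
print("SBP 140 once, no meds          ->",
      dichotomize_hypertension([140], [78]))             # case (>=140 rule)
print("SBP 128/DBP 82, prior meds     ->",
      dichotomize_hypertension([128], [82], med_history=True))  # excluded
print("SBP 122/DBP 74, clean history  ->",
      dichotomize_hypertension([122], [74]))              # control

# a small table end to end, with a BMI artefact removed
records = pd.DataFrame({
    "sample_id": ["p1"] * 4 + ["p2"] * 2,
    "trait": ["bmi", "bmi", "chol", "chol", "bmi", "chol"],
    "year": [2010, 2010, 2010, 2012, 2011, 2011],
    "value": [28.8, 2880.0, 180.0, 176.0, 24.0, 210.0],  # 2880 = unit error
    "age": [44, 44, 44, 46, 61, 61],
})
wide = aggregate_quantitative(records)
print("\nper-sample phenotype table:")
print(wide.round(1).to_string())
assert np.isclose(wide.loc["p1", "bmi"], 28.8)  # the artefact did not bias it
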