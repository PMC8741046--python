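"""Simulate a small synthetic cohort and summarize its behavior and clinics.

Builds 6 healthy controls, 4 early-stage patients and 3 established patients
at a reduced trial count, then prints the metadata table and the Go/No-Go
behavior summary of the first control. RT statistics are in milliseconds;
accuracy, omission and commission rates in percent.
"""

import pandas as pd

from erpmarker import CohortDesign, iter_cohort, summarize_behavior
from erpmarker.io import records_to_frame

design = CohortDesign().scaled(0.25)  # 100-trial tasks, proportions kept
records, behaviors = [], []
for record, epoch_sets in iter_cohort(6, 4, 3, design=design, seed=7):
    records.append(record)
    go = next(e for e in epoch_sets
              if e.condition == "Go" and e.lock == "stimulus")
    behaviors.append(summarize_behavior(go))

print("Cohort metadata (mUPDRS/LEDD exist for patients only):")
print(records_to_frame(records).to_string())

print("\nGo-condition behavior per subject:")
frame = pd.DataFrame(behaviors, index=[r.id for r in records])
print(frame.round(1).to_string())
print("\nMedian RT ~420 ms and accuracy >90% mirror typical task behavior;")
print("patients show slightly lower accuracy by design.")
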