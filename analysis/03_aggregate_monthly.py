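"""Aggregate the planted cohort into the monthly modelling table.

Reads the windows/clinical tables written by 01, applies the 720/480
month-exclusion and >= 18 h day rules, and writes analysis_table.csv under
results/analysis/planted/.  Prints the filter counts.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from phenolmm.aggregate import aggregate_months, build_analysis_table, write_analysis_table

BASE = Path(__file__).resolve().parents[1] / "results" / "analysis" / "planted"


def main():
    windows = pd.read_csv(BASE / "windows.csv", parse_dates=["window_start"])
    clinical = pd.read_csv(BASE / "clinical.csv", parse_dates=["enrollment_date"])
    enrollment = clinical.drop_duplicates("patient_id").set_index("patient_id")["enrollment_date"].to_dict()

    months = aggregate_months(windows, enrollment=enrollment)
    table = build_analysis_table(months, clinical)
    months.to_csv(BASE / "patient_months.csv", index=False)
    write_analysis_table(table, BASE / "analysis_table.csv")

    print(f"patient-months with any data: {len(months)}")
    print(f"excluded by the 720-wake/480-sleep rule: {int((~months['included']).sum())}")
    print(f"modelling rows after joining monthly ratings: {len(table)}")
    print(f"mean follow-up across patients: "
          f"{table.groupby('patient_id')['month_index'].max().mean():.1f} months")


if __name__ == "__main__":
    main()
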