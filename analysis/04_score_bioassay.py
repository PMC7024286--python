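"""Score the antimicrobial screen from the OD620 plate readings.

Computes percent growth inhibition per replicate, summarises each extract x
pathogen combination as mean ± SEM over triplicates, calls activity at the
strict >50% threshold, and renders the activity table (inactive cells shown
as "n.a."). Writes results/bioassay/activity.csv and compares the recovered
means with the planted inhibition values.
"""

from pathlib import Path

import pandas as pd

from cyanoprospect.bioassay import activity_table, read_plate_csv, summarize

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    inputs = ROOT / "results" / "inputs"
    outdir = ROOT / "results" / "bioassay"
    outdir.mkdir(parents=True, exist_ok=True)

    readings = read_plate_csv(inputs / "plates.csv")
    results = [summarize(r) for r in readings]
    table = activity_table(results)
    table.to_csv(outdir / "activity.csv")

    truth = pd.read_csv(inputs / "truth_plates.csv").set_index(
        ["extract_id", "pathogen_id"])
    print(f"{len(results)} extract x pathogen combinations (triplicates)")
    for r in sorted(results, key=lambda r: (r.extract_id, r.pathogen_id)):
        planted = truth.at[(r.extract_id, r.pathogen_id), "true_inhibition"]
        flag = "ACTIVE" if r.active else "n.a."
        print(f"  {r.extract_id} vs {r.pathogen_id:12s} "
              f"{r.mean_inhibition:6.2f} ± {r.sem:.2f} % "
              f"(planted {planted:5.1f}) -> {flag}")
    print("\nactivity table:")
    print(table.to_string())
    print(f"\nreport in {outdir}")


if __name__ == "__main__":
    main()
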