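"""Generate a synthetic corpus and run the full pipeline on it.

The generator plants ground truth (who uses, who is documented, which
diagnosis codes exist), so the pipeline's outputs can be scored exactly:
screening confusion vs. gold, patient statuses, the yearly trend table,
and the diagnostic-code cross-check.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from cannascreen import io as cio
from cannascreen.synth import SimConfig, generate_cohort, gold_confusion


def main() -> None:
    config = SimConfig(n_patients=400, seed=11)
    sim = generate_cohort(config)
    print(f"generated {len(sim.notes)} notes for {len(sim.patients)} patients, "
          f"{len(sim.diagnoses)} diagnosis records")

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        cio.write_notes(sim.notes, tmp / "notes.jsonl")
        cio.write_patients(sim.patients, tmp / "patients.csv")
        cio.write_diagnoses(sim.diagnoses, tmp / "diagnoses.csv")

        manifest = cio.run_pipeline(
            tmp / "notes.jsonl", tmp / "patients.csv", tmp / "out",
            diagnoses_path=tmp / "diagnoses.csv",
        )
        print("\nstage tallies:")
        print(json.dumps(manifest.stage_tallies, indent=2, sort_keys=True))

        # score the screening stage against the planted gold labels
        decisions = {}
        for line in (tmp / "out" / "decisions.jsonl").read_text().splitlines():
            o = json.loads(line)
            decisions[o["note_id"]] = o["status"]
        print("\nscreening confusion (gold status x pipeline decision):")
        print(gold_confusion(decisions, sim.gold))

        trends = pd.read_csv(tmp / "out" / "trend_table.csv")
        cols = ["year", "n_notes", "pct_documented_all_notes",
                "pct_positive_all_notes", "n_new_positive_patients"]
        print("\ntrend table (last 8 years):")
        print(trends[cols].tail(8).to_string(index=False,
                                             float_format=lambda v: f"{v:.2f}"))

        cross = tmp / "out" / "crosscheck.json"
        if cross.exists():
            print("\ndiagnostic-code cross-check:", cross.read_text().strip())


if __name__ == "__main__":
    main()
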