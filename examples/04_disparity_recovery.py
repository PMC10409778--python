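"""Plant disparity odds ratios and recover them with the logistic model.

Simulates a patient-level cohort where positive use depends on sex, race,
and the Social Vulnerability Index with known odds ratios, then fits the
adjusted model and compares the estimates to the planted values.
"""

import math

from cannascreen.disparity import build_design, fit_disparity_model
from cannascreen.synth import plant_patient_outcomes

PLANTED = {
    "female": 0.96,
    "race_black": 3.22,
    "race_hispanic": 2.13,
    "svi_per_001": 1.002,
}


def main() -> None:
    effects = {k: math.log(v) for k, v in PLANTED.items()}
    patients, statuses = plant_patient_outcomes(
        20000, effects, base_logodds=-1.0, seed=7
    )
    n_pos = sum(s.status == "positive" for s in statuses)
    print(f"simulated {len(patients)} patients, {n_pos} positive")

    y, X = build_design(patients, statuses, "positive_use")
    results = fit_disparity_model(y, X, setting="positive_use")

    print(f"\n{'covariate':<16}{'planted':>9}{'aOR':>8}{'95% CI':>18}{'p':>10}")
    for r in results:
        planted = PLANTED.get(r.covariate)
        planted_s = f"{planted:.3f}" if planted is not None else "1.000"
        print(f"{r.covariate:<16}{planted_s:>9}{r.aOR:>8.3f}"
              f"   ({r.ci_low:6.3f}, {r.ci_high:6.3f}){r.p_value:>10.2g}")


if __name__ == "__main__":
    main()
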