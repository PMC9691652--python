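"""Calibrate the unpublished model inputs to the reported lifetime outcomes.

The post-30-day NYHA distributions and the per-state monthly
HF-hospitalization probabilities are not published. Starting from the trial
cohort's baseline NYHA shares and a severity-increasing hospitalization
profile anchored to the reported lifetime event counts, this script fits
(a) each arm's post-30-day NYHA simplex and (b) one hospitalization scale
factor per arm, against nine reported outcomes: life-years (3.72/2.90),
hospitalizations (1.16/1.51), QALYs (2.32/1.80), lifetime costs
(423,817/28,369 CNY) and the ICER (754,410 CNY/QALY).

Writes results/calibration.json (fit report) and
results/calibrated_config.yaml, and checks the fitted values against the
defaults shipped in the package config.
"""

from pathlib import Path

import numpy as np

from teer_cea import default_parameters
from teer_cea.parameters import load_parameters, to_document
from teer_cea.report import cmd_calibrate

RESULTS = Path(__file__).resolve().parents[1] / "results"

TARGETS = {
    "life_years.mitraclip": 3.72,
    "life_years.omt": 2.90,
    "hospitalizations.mitraclip": 1.16,
    "hospitalizations.omt": 1.51,
    "qaly.mitraclip": 2.32,
    "qaly.omt": 1.80,
    "lifetime_cost.mitraclip": 423_817.0,
    "lifetime_cost.omt": 28_369.0,
    "icer": 754_410.0,
}
FREE = ["initial.mitraclip", "initial.omt", "hosp_scale.mitraclip", "hosp_scale.omt"]

# pre-calibration starting point: MitraClip shifted toward NYHA II (the
# procedure improves functional class by 30 days), OMT near the baseline
# II/III mix; hospitalization profiles doubling with each severity step,
# anchored so lifetime event counts start near the reported 1.16/1.51
START = {
    "initial_nyha_distribution": {
        "mitraclip": [0.01, 0.93, 0.05, 0.01],
        "omt": [0.01, 0.45, 0.52, 0.02],
    },
    "hospitalization": {
        "mitraclip": {"nyha1": 0.009, "nyha2": 0.018, "nyha3": 0.036, "nyha4": 0.055},
        "omt": {"nyha1": 0.011, "nyha2": 0.027, "nyha3": 0.054, "nyha4": 0.108},
    },
}


def main() -> None:
    doc = to_document(default_parameters())
    doc["decision_tree"]["initial_nyha_distribution"] = START["initial_nyha_distribution"]
    doc["transitions"]["hospitalization"] = START["hospitalization"]
    start = load_parameters(doc)

    report = cmd_calibrate(start, TARGETS, FREE, RESULTS)

    print(f"calibration {'succeeded' if report['success'] else 'FAILED'}: "
          f"{report['message']} ({report['n_evaluations']} model evaluations)")
    for name, target in TARGETS.items():
        print(f"  {name:28s} target {target:>12,.2f}  achieved "
              f"{report['achieved'][name]:>12,.2f}  "
              f"({report['relative_residuals'][name]:+.2%})")
    print(f"max |relative residual| = {report['max_abs_relative_residual']:.2%} "
          f"(all reported outcomes matched within 2%)"
          if report["max_abs_relative_residual"] < 0.02
          else f"max |relative residual| = {report['max_abs_relative_residual']:.2%}")

    # the shipped defaults are these fitted values (rounded); confirm they agree
    fitted = load_parameters(RESULTS / "calibrated_config.yaml")
    shipped = default_parameters()
    for arm in ("mitraclip", "omt"):
        d = np.abs(
            np.array(fitted.decision_tree.initial_nyha_distribution[arm])
            - np.array(shipped.decision_tree.initial_nyha_distribution[arm])
        ).max()
        print(f"shipped vs fitted initial distribution ({arm}): max diff {d:.2e}")


if __name__ == "__main__":
    main()
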