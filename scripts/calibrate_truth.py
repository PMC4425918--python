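"""One-off calibration of the simulator's baseline-hazard scales.

The generating coefficient tables pin down every parameter of the synthetic
cohort except the two Weibull baseline scales, which are not published
anywhere.  This script searches for scales such that a default cohort
averages ~15% deaths and ~48% interventions under first-event-wins
follow-up, and prints the constants that are frozen into
``bnpjm/simulate.py``.

Run from the repository root:  python scripts/calibrate_truth.py
"""

import numpy as np

from bnpjm import simulate as sim
from bnpjm.joint import WeibullBaseline

TARGETS = {"death": 0.15, "intervention": 0.48}
N = 8000
ROUNDS = 8
SEED = 20150507  # fixed; calibration is a one-off


def fractions(scale_death, scale_int, seed):
    truth = sim.default_truth()
    truth.params_death.baseline = WeibullBaseline(
        truth.params_death.baseline.shape, scale_death)
    truth.params_intervention.baseline = WeibullBaseline(
        truth.params_intervention.baseline.shape, scale_int)
    coh = sim.simulate_cohort(truth, N, seed=seed)
    return sim.event_fractions(coh)


def main():
    truth = sim.default_truth()
    s_d = truth.params_death.baseline.scale
    s_i = truth.params_intervention.baseline.scale
    k_d = truth.params_death.baseline.shape
    k_i = truth.params_intervention.baseline.shape
    for r in range(ROUNDS):
        fr = fractions(s_d, s_i, SEED + r)
        print(f"round {r}: scale_death={s_d:.1f} scale_int={s_i:.3f} -> {fr}")
        # multiplicative update: events scale roughly like scale^-shape
        s_d *= (fr["death"] / TARGETS["death"]) ** (1.0 / k_d)
        s_i *= (fr["intervention"] / TARGETS["intervention"]) ** (1.0 / k_i)
    fr = fractions(s_d, s_i, SEED + ROUNDS)
    print(f"final: scale_death={s_d:.1f} scale_int={s_i:.3f} -> {fr}")
    print(f"freeze: _DEATH_BASELINE = WeibullBaseline(shape={k_d}, "
          f"scale={s_d:.1f})")
    print(f"freeze: _INTERVENTION_BASELINE = WeibullBaseline(shape={k_i}, "
          f"scale={s_i:.2f})")


if __name__ == "__main__":
    main()
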