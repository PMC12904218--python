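"""Recompute the listener-population calibration anchor.

The simulated cohort's 50%-point on the STOI axis is anchored to the mean
STOI of the synthetic sentence corpus reverberated at RT60 = 1.0 s, so
that the cohort's median RT60_50% comes out at ~1.0 s.  This script
recomputes that anchor from scratch; the resulting number is the
``S50_POPULATION_MEAN`` constant in ``ciderev.study``.

Usage:  python scripts/calibrate_listeners.py [--n 20]
"""

import argparse

import numpy as np

from ciderev.room import simulate_rir, study_room
from ciderev.stimuli import apply_protocol, generate_pseudo_sentence
from ciderev.stoi import compute_stoi
from ciderev.study import TITRATION_SEED_BASE


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=20,
                    help="number of sentences to average over")
    ap.add_argument("--rt60", type=float, default=1.0)
    args = ap.parse_args()

    ir = simulate_rir(study_room(args.rt60), "left")
    values = []
    for i in range(args.n):
        s = generate_pseudo_sentence(TITRATION_SEED_BASE + i)
        trial = apply_protocol(s, ir, "none", rt60=args.rt60)
        values.append(compute_stoi(s.samples, trial.audio,
                                   s.sample_rate).value)
    values = np.asarray(values)
    print(f"mean STOI of reverberated sentences at RT60={args.rt60} s "
          f"(n={args.n}): {values.mean():.3f} (SD {values.std(ddof=1):.3f})")
    print("-> set ciderev.study.S50_POPULATION_MEAN to the mean above")


if __name__ == "__main__":
    main()
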