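#!/usr/bin/env python
"""Regenerate the shipped end-diastolic steady-state snapshots.

Run after any change to the baseline parameter set:

    python scripts/make_snapshots.py [--quick]
"""

import argparse
import pathlib
import time

from myocyte import build_parameters, run_to_steady_state
from myocyte.signaling import set_bars
from myocyte.states import save_state
from myocyte.snapshots import steady_state

DATA = pathlib.Path(__file__).resolve().parents[1] / "src/myocyte/data"


def make(name, p, rate, max_beats, y0=None):
    t0 = time.time()
    res = run_to_steady_state(p, rate, max_beats=max_beats, tol=2e-4,
                              y0=y0, check_every=20)
    save_state(res.state, DATA / f"{name}.json")
    print(f"{name}: beats={res.n_beats} converged={res.converged} "
          f"alternans={res.alternans} apd90={res.apd90:.1f} "
          f"({time.time()-t0:.0f}s)")
    return res.state


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--quick", action="store_true",
                    help="shorter pacing (for iteration during development)")
    args = ap.parse_args()
    nmax = 300 if args.quick else 1000

    male = build_parameters("male")
    female = build_parameters("female")

    y1 = make("steady_male_1hz", male, 1.0, nmax)
    for rate in (0.5, 1.5, 2.0, 2.5, 3.0):
        make(f"steady_male_{rate:g}hz", male, rate, nmax, y0=y1.copy())
    make("steady_male_1hz_bars", set_bars(male, True), 1.0, nmax,
         y0=y1.copy())
    make("steady_female_1hz", female, 1.0, nmax, y0=y1.copy())


if __name__ == "__main__":
    main()
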