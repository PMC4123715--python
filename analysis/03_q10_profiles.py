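#!/usr/bin/env python
"""Voltage-resolved temperature sensitivity of the reference channels.

Computes noiseless model Q10 profiles for the four headline channel types
and, for the Kv-type channels, the corresponding measured profiles
(synthetic G-V pairs through the full pipeline). The headline bounds:

    TRP-type pore:        Q10 > 20 everywhere on −100…+150 mV (36.6→46.0 °C)
    coupled Kv:           mean Q10 ≤ 4 on the activated range (22.4→27.7 °C)
    decoupled (ILT-like): peak Q10 > 20 (25→35 °C)
    sign-flipped (V2):    Q10 < 1 where open (25→35 °C) — heat deactivation
"""

import warnings
from pathlib import Path

import numpy as np

from kvtherm.analysis_runs import pipeline_q10_profile
from kvtherm.presets_api import load_preset
from kvtherm.reproduce import (ilt_peak_q10, shaker_mean_q10, trp_min_q10,
                               v2_q10_heat_deactivation)
from kvtherm.thermo import model_q10_profile

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

PROFILES = [
    ("trpv1_like", 36.6, 46.0, np.arange(-100.0, 151.0, 1.0)),
    ("shaker_like", 22.4, 27.7, np.arange(-100.0, 51.0, 1.0)),
    ("ilt_like", 25.0, 35.0, np.arange(-100.0, 101.0, 1.0)),
    ("v2_like", 25.0, 35.0, np.arange(-100.0, 101.0, 1.0)),
]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    prof_path = RESULTS / "03_q10_profiles.tsv"
    with open(prof_path, "w") as fh:
        fh.write("channel\tsource\tt1_C\tt2_C\tvoltage_mV\tq10\n")
        for name, t1, t2, grid in PROFILES:
            model = model_q10_profile(load_preset(name).model, t1, t2, grid)
            for v, q in zip(model.voltages, model.q10):
                fh.write(f"{name}\tmodel\t{t1}\t{t2}\t{v:g}\t{q:.6g}\n")
            if name in ("shaker_like", "ilt_like"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    meas = pipeline_q10_profile(name, t1, t2, seed=9)
                for v, q in zip(meas.voltages, meas.q10):
                    fh.write(f"{name}\tmeasured\t{t1}\t{t2}\t{v:g}\t{q:.6g}\n")

    summary = RESULTS / "03_q10_summary.tsv"
    rows = [
        ("trp_min_q10", *trp_min_q10(), "minimum over -100..+150 mV, 36.6->46.0 C"),
        ("shaker_mean_q10", *shaker_mean_q10(), "mean over -40..+50 mV, 22.4->27.7 C"),
        ("ilt_peak_q10", *ilt_peak_q10(), "maximum over -100..+100 mV, 25->35 C"),
        ("v2_q10", *v2_q10_heat_deactivation(), "at the ~60%-open voltage, 25->35 C"),
    ]
    with open(summary, "w") as fh:
        fh.write("quantity\tvalue\tn\tdefinition\n")
        for name, value, n, desc in rows:
            fh.write(f"{name}\t{value:.6g}\t{n}\t{desc}\n")
            print(f"{name:>18s} = {value:.4g}  ({desc})")
    print(f"profiles: {prof_path}\nsummary:  {summary}")


if __name__ == "__main__":
    main()
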