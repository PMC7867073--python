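"""Prediction outside the calibrated concentration range.

Trains WA-KPLS on nitrate bands with a raised lower edge (4-80, 6-80, 8-80,
10-80 umol/L) and predicts samples below the band and in the 90-100 umol/L
band.  Predictions a few umol/L below the training range remain accurate;
10+ umol/L above it they fail completely -- the kernel model cannot
extrapolate, so field deployments must cover the expected range during
calibration.
"""

from nitrauv.workflows import run_extrapolation_study

result = run_extrapolation_study(seed=1)

print(f"{'train band':>12s}   {'test band':>12s}   within +/-2 umol/L")
for band in result["bands"]:
    lo, hi = band["train_band"]
    for side in ("low", "high"):
        b = band[side]
        print(f"{lo:5.0f}-{hi:3.0f}      {b['band'][0]:5.0f}-{b['band'][1]:3.0f}"
              f"        {b['frac_within']:10.1%}")
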