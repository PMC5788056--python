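#!/usr/bin/env python
"""Frequency-response predictions and their spectral measurement.

Computes the predicted hand amplitude per frequency under the gain
(1.15) and mechanical (tau = 0.2 s) representations for a 2 cm target,
in cm and dB, for both a flat and a frequency-growing baseline; then
verifies that the Hann/zero-padded periodogram pipeline measures these
amplitudes from simulated 120 s sinusoid-mixture tracking.

Writes results/frequency_response.csv and results/mixture_measured.csv.

Expected picture: in dB difference the gain model is flat across
frequency while the mechanical model grows - and that distinction is
baseline-free, which is why the analysis works in dB.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from delayrep import TrackSpec, frequency_response_prediction, \
    periodogram_amplitude, simulate_blind_tracking
from delayrep.models import RepresentationParams, taylor_params
from delayrep.tasksim import MIXTURE_FREQS

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    freqs = np.sort(np.asarray(MIXTURE_FREQS))
    b, m = taylor_params(0.2)
    models = {
        "gain": RepresentationParams("gain", g_hat=1.15),
        "mechanical": RepresentationParams("mechanical", b_over_k=b,
                                           m_over_k=m),
    }
    rows = []
    for baseline_name, At in (("flat", np.full(len(freqs), 2.0)),
                              ("growing", 2.0 + 0.1 * (2 * np.pi * freqs) ** 2)):
        for name, params in models.items():
            resp, diff = frequency_response_prediction(params, freqs, At)
            for f, a, d in zip(freqs, resp.amp_cm, diff):
                rows.append({"baseline": baseline_name, "model": name,
                             "freq_hz": f, "amp_cm": a, "db_diff": d})
    pred = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    pred.to_csv(OUT / "frequency_response.csv", index=False)

    # measure the same effect from simulated mixture tracking
    spec = TrackSpec(path_kind="sinusoid_mixture", A=2.0, duration=120.0)
    meas_rows = []
    for name, params in [("none", RepresentationParams("none"))] + list(
            models.items()):
        _, hand = simulate_blind_tracking(spec, params, baseline_lag=0.2)
        resp = periodogram_amplitude(hand.y, hand.rate,
                                     probe_freqs=MIXTURE_FREQS)
        for f, a in zip(resp.freqs, resp.amp_cm):
            meas_rows.append({"model": name, "freq_hz": f,
                              "measured_amp_cm": a})
    meas = pd.DataFrame(meas_rows)
    meas.to_csv(OUT / "mixture_measured.csv", index=False)

    flat = pred[pred.baseline == "flat"]
    slopes = flat.groupby("model").apply(
        lambda g: np.polyfit(g.freq_hz, g.db_diff, 1)[0],
        include_groups=False)
    print("Predicted dB-difference slopes (flat baseline):")
    print(slopes.to_string(float_format=lambda v: f"{v:.3f} dB/Hz"))
    wide = meas.pivot(index="freq_hz", columns="model",
                      values="measured_amp_cm")
    print("\nMeasured component amplitudes (cm):")
    print(wide.to_string(float_format=lambda v: f"{v:.3f}"))
    print("\nGain scales every component by 1.15; the mechanical gain "
          "grows from ~1.00 at 0.23 Hz to ~1.06 at 0.67 Hz.")


if __name__ == "__main__":
    sys.exit(main())
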