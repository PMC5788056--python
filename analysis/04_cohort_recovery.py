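#!/usr/bin/env python
"""Closed loop on synthetic cohorts: generate -> analyze -> recover.

Generates delay and control cohorts (reaching, gain ground truth 1.2,
endpoint noise 1 cm), measures the session amplitude change, then runs
per-participant model recovery on tracking cohorts, the noise
robustness curve, and the gain-vs-mechanical identifiability study.

Writes results/cohort_amplitudes.csv, results/recovery_noise.csv and
results/identifiability.json.

Expected picture: the delay cohort overshoots by ~2 cm while the
control cohort stays at baseline; the generator parameter recovers
exactly without noise and degrades gracefully with it; the flatness
statistic separates gain from mechanical generators in >= 95% of
replicates.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from delayrep import CohortSpec, generate_cohort, recover_parameters
from delayrep.models import RepresentationParams
from delayrep.synthetic import frequency_flatness_study

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 11


def session_amplitude(sess) -> float:
    return float(np.mean(np.linalg.norm(sess.endpoints, axis=1)))


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for group in ("delay", "control"):
        spec = CohortSpec(n_participants=8, group=group, seed=SEED,
                          true_model=RepresentationParams("gain", g_hat=1.2))
        for pre, post in generate_cohort(spec):
            rows.append({"group": group, "participant": pre.participant,
                         "pre_amp_cm": session_amplitude(pre),
                         "post_amp_cm": session_amplitude(post)})
    amps = pd.DataFrame(rows)
    amps["diff_cm"] = amps.post_amp_cm - amps.pre_amp_cm
    amps.to_csv(OUT / "cohort_amplitudes.csv", index=False)
    print(amps.groupby("group").diff_cm.agg(["mean", "std"]).to_string(
        float_format=lambda v: f"{v:.3f}"))

    noise_rows = []
    for noise in (0.0, 0.1, 0.5, 1.0):
        errs = []
        for rep in range(20):
            spec = CohortSpec(n_participants=1, task="figure_eight",
                              trials_per_session=1,
                              true_model=RepresentationParams("gain",
                                                              g_hat=1.2),
                              tracking_noise_sd=noise, param_jitter_sd=0.0,
                              seed=SEED * 1000 + rep)
            pre, post = generate_cohort(spec)[0]
            fit = recover_parameters(pre, post,
                                     candidate_variants=("gain",)).fits["gain"]
            errs.append(fit - 1.2)
        noise_rows.append({"tracking_noise_sd_cm": noise,
                           "gain_rmse": float(np.sqrt(np.mean(
                               np.square(errs))))})
    noise_df = pd.DataFrame(noise_rows)
    noise_df.to_csv(OUT / "recovery_noise.csv", index=False)
    print("\nGain-recovery RMSE vs tracking noise:")
    print(noise_df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

    study = frequency_flatness_study(n_replicates=100, seed=SEED,
                                     tracking_noise_sd=0.1)
    out = {"separation_rate": study["separation_rate"],
           "threshold_db_per_hz": study["threshold"],
           "mean_slope_gain": float(np.mean(study["slopes_gain"])),
           "mean_slope_mechanical": float(np.mean(
               study["slopes_mechanical"]))}
    (OUT / "identifiability.json").write_text(json.dumps(out, indent=2))
    print(f"\nGain vs mechanical separation: "
          f"{100 * out['separation_rate']:.0f}% of 100 replicates "
          f"(threshold {out['threshold_db_per_hz']:.2f} dB/Hz).")


if __name__ == "__main__":
    sys.exit(main())
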