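#!/usr/bin/env python
"""Run the calibration and recovery studies and summarize them.

These are the package's statistical self-checks: clusterer-vs-oracle
agreement, 4C false-call control and sensitivity, end-to-end driver
recovery, null uniformity of the log-rank and dosage-ANOVA p-values, and
the Bliss identity. The same computations back scripts/acceptance.py;
this driver writes a readable summary table.
"""

import os

from crcprior import io
from crcprior.calibration import (
    anova_null_pvalues,
    bliss_identity_study,
    clustering_oracle_agreement,
    driver_recovery_rate,
    fourc_null_false_call_rate,
    fourc_recovery_rate,
    ks_uniformity_p,
    logrank_null_pvalues,
)

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 20180


def main() -> None:
    import pandas as pd

    rows = []

    agree = clustering_oracle_agreement(n_instances=1000, max_n=200, seed=SEED)
    rows.append(("clustering_oracle_agreement", agree, "fraction of 1000 instances"))
    print(f"clustering vs closure oracle: {agree:.3f}")

    null_rate = fourc_null_false_call_rate(n_tracks=200, seed=SEED)
    rows.append(("fourc_null_false_call_rate", null_rate, "fraction of windows, 200 tracks"))
    print(f"4C null false-call rate at FDR 1%: {null_rate:.5f}")

    rec = fourc_recovery_rate(n_tracks=100, seed=SEED)
    rows.append(("fourc_planted_recovery", rec, "fraction of 100 tracks"))
    print(f"4C planted-window recovery: {rec:.2f}")

    drv = driver_recovery_rate(n_runs=50, seed=SEED)
    rows.append(("driver_recovery", drv, "fraction of 50 landscape+cohort runs"))
    print(f"planted-driver recovery: {drv:.2f}")

    lr = ks_uniformity_p(logrank_null_pvalues(n_reps=2000, seed=SEED))
    rows.append(("logrank_null_ks_p", lr, "KS vs Uniform(0,1), 2000 reps"))
    an = ks_uniformity_p(anova_null_pvalues(n_reps=2000, seed=SEED))
    rows.append(("anova_null_ks_p", an, "KS vs Uniform(0,1), 2000 reps"))
    print(f"null uniformity KS p: log-rank {lr:.3f}, ANOVA {an:.3f}")

    bliss = bliss_identity_study(n_reps=100, seed=SEED)
    rows.append(("bliss_noiseless_max_abs_eob", bliss["noiseless_max_abs_eob"], "exact identity"))
    rows.append(("bliss_noisy_mean_eob", bliss["noisy_mean_eob"], "100 noisy boards"))
    print(f"Bliss identity: noiseless max |EoB| {bliss['noiseless_max_abs_eob']:.2e}, "
          f"noisy mean EoB {bliss['noisy_mean_eob']:.4f}")

    table = pd.DataFrame(rows, columns=["study", "value", "conditions"])
    out_path = os.path.join(OUT, "calibration_summary.tsv")
    io.write_table(table, out_path)
    print(f"summary -> {out_path}")


if __name__ == "__main__":
    main()
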