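#!/usr/bin/env python
"""Generate one synthetic study's worth of inputs.

Writes per-cell-line SE calls (BED), the tumor cohort (expression,
survival, copy-number segments, stage), a 4C fragment track with three
planted interaction windows, and a checkerboard with planted synergy,
all under scratch/simdata/, together with their truth records.
"""

import json
import os

import numpy as np

from crcprior import io
from crcprior.simulate import (
    CheckerboardSpec,
    CohortSpec,
    FourCSpec,
    LandscapeSpec,
    gen_checkerboard,
    gen_cohort,
    gen_fourc,
    gen_se_landscape,
)

SEED = 20180
OUT = os.path.join(os.path.dirname(__file__), "..", "scratch", "simdata")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)

    se_tables, genes, tss_peaks, truth = gen_se_landscape(LandscapeSpec(seed=SEED))
    se_dir = os.path.join(OUT, "se_calls")
    os.makedirs(se_dir, exist_ok=True)
    for sid, table in se_tables.items():
        io.write_bed(table, os.path.join(se_dir, f"{sid}.bed"))
    print(f"wrote SE calls for {len(se_tables)} cell lines "
          f"(driver cluster #{truth['driver_cluster']}, gene {truth['driver_gene_id']})")

    expression, survival, segments, stage, ctruth = gen_cohort(
        CohortSpec(seed=SEED + 1),
        gene_ids=[g.gene_id for g in genes],
        driver_gene_id=truth["driver_gene_id"],
    )
    io.write_matrix(expression, os.path.join(OUT, "expression.tsv"))
    io.write_survival(survival, os.path.join(OUT, "survival.tsv"))
    with open(os.path.join(OUT, "segments.tsv"), "w") as fh:
        for sid, segs in segments.items():
            for s in segs:
                fh.write(f"{sid}\t{s.chrom}\t{s.start}\t{s.end}\t{s.log2_ratio:.4f}\n")
    n_gained = sum(ctruth["gained"].values())
    print(f"wrote cohort: {expression.shape[0]} genes x {expression.shape[1]} tumors, "
          f"{n_gained} with 17q gain")

    track, ftruth = gen_fourc(
        FourCSpec(
            seed=SEED + 2,
            planted_windows=[(1000, 100, 0.5), (2500, 100, 0.5), (4000, 100, 0.5)],
            viewpoint_index=2450,
        )
    )
    with open(os.path.join(OUT, "fourc_fragments.bedgraph"), "w") as fh:
        for i, count in enumerate(track.counts):
            fh.write(f"{track.chrom}\t{track.fragment_starts[i]}\t"
                     f"{track.fragment_end(i)}\t{count}\n")
    print(f"wrote 4C track: {len(track)} fragments, "
          f"{len(ftruth['planted_windows'])} planted windows")

    board, btruth = gen_checkerboard(
        CheckerboardSpec(seed=SEED + 3, synergy_term=0.15, emax_a=0.6, emax_b=0.55,
                         noise_sd=0.02)
    )
    import pandas as pd
    pd.DataFrame(board.viability, index=board.doses_a, columns=board.doses_b).to_csv(
        os.path.join(OUT, "checkerboard.tsv"), sep="\t"
    )
    print("wrote checkerboard with planted synergy 0.15 on combination cells")

    with open(os.path.join(OUT, "truth.json"), "w") as fh:
        json.dump(
            {
                "landscape": {
                    "driver_cluster": truth["driver_cluster"],
                    "driver_gene_id": truth["driver_gene_id"],
                    "recurrences": {str(k): v for k, v in truth["recurrences"].items()},
                },
                "fourc": ftruth,
                "checkerboard_planted_eob": np.asarray(
                    btruth["planted_eob"]
                ).tolist(),
            },
            fh,
            indent=1,
        )


if __name__ == "__main__":
    main()
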