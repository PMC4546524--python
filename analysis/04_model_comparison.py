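#!/usr/bin/env python
"""Trimmed repeated two-fold cross-validation of all prediction models.

For each contrast (recurrence, fast recurrence, lethal) evaluates the four
single-modality models (L = LSR, N = nomogram, F = fusion status,
G = Gleason grade) and the LDA combinations L+N+F and L+N+F+G under the
protocol: 14 random equal splits, drop the 2 best and 2 worst by summed
AUC, average the remaining 10.  Writes one metric table per contrast.
"""

from pathlib import Path

from lsrcnv import segment_io as sio
from lsrcnv.evaluation import build_contrast, summary_table, trimmed_cv

BASE = Path(__file__).resolve().parent.parent / "results"
MODEL_SETS = ["L", "N", "F", "G", "L,N,F", "L,N,F,G"]
SEED = 7


def main() -> None:
    segments = sio.read_segments(BASE / "cohort" / "segments.tsv")
    records = sio.read_clinical(BASE / "cohort" / "clinical.csv")
    profiles = sio.build_profiles(sio.filter_segments(segments))

    for contrast in ("recurrence", "fast_recurrence", "lethal"):
        data = build_contrast(records, profiles, contrast)
        results = {}
        for mods in MODEL_SETS:
            results[mods.replace(",", "+")] = trimmed_cv(
                data, mods.split(","), n_repeats=14, trim=2, seed=SEED
            )
        table = summary_table(results)
        out = BASE / f"cv_metrics_{contrast}.csv"
        table.to_csv(out, index=False)
        print(f"\n{contrast} ({len(data.labels)} samples, {data.labels.sum()} positive):")
        test = table[table.role == "test"][
            ["model", "accuracy", "sensitivity", "specificity", "auc"]
        ]
        print(test.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        print(f"-> {out}")


if __name__ == "__main__":
    main()
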