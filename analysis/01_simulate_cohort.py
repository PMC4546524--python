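#!/usr/bin/env python
"""Simulate the study-design cohort and write its raw tables.

Generates 143 patients (35 non-recurrent with >= 90 months of follow-up,
55 fast-recurrent with PSADT <= 4 months, 53 slow-recurrent with
PSADT >= 15 months) with ~152 CNV fragments per genome and a 3.2-fold
larger mean fragment size in the recurrent arms, then writes the segment
TSV and clinical CSV consumed by every later step.
"""

from pathlib import Path

import numpy as np

from lsrcnv import segment_io as sio
from lsrcnv.synthetic_cohort import CohortSpec, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(seed=SEED)
    segments, records = generate_cohort(spec)
    sio.write_segments(segments, OUT / "segments.tsv")
    sio.write_clinical(records, OUT / "clinical.csv")

    n_rec = sum(r.recurrent for r in records)
    sizes = np.array([s.size for s in segments])
    print(f"cohort: {len(records)} patients ({n_rec} recurrent), seed {SEED}")
    print(f"segments written: {len(segments)} (pre-filter), mean size {sizes.mean():,.0f} bp")
    print(f"outputs: {OUT / 'segments.tsv'}, {OUT / 'clinical.csv'}")


if __name__ == "__main__":
    main()
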