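"""Encoding of the three clinical modalities and feature-matrix assembly.

Modalities are named by single letters throughout: L = leukocyte-CNV LSR,
N = nomogram, F = fusion-transcript status, G = Gleason grade.  All encoded
features are oriented so that higher = more likely recurrent; in particular
the nomogram's 7-year progression-free probability (higher = better
prognosis) is flipped to a risk score 1 - prob.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .segment_io import ClinicalRecord

log = logging.getLogger(__name__)

MODALITIES = ("L", "N", "F", "G")

#: column name per modality in an assembled feature matrix
MODALITY_COLUMNS = {"L": "lsr", "N": "nomogram_risk", "F": "fusion_bin", "G": "gleason_bin"}


def encode_gleason(score: int) -> int:
    """Binary Gleason grade: 1 iff score > 7."""
    if not (2 <= score <= 10):
        raise ValueError(f"Gleason score {score} outside [2, 10]")
    return int(score > 7)


def encode_fusion(fusion_count: int) -> int:
    """Binary fusion status: 1 iff at least one of the 8 transcripts detected."""
    if fusion_count < 0:
        raise ValueError("fusion count must be non-negative")
    if fusion_count > 8:
        raise ValueError("fusion count exceeds the 8 assayed transcripts")
    return int(fusion_count >= 1)


def nomogram_risk(nomogram_prob: float) -> float:
    """Orient the nomogram probability as a risk score (higher = worse)."""
    if not (0.0 <= nomogram_prob <= 1.0):
        raise ValueError("nomogram probability outside [0, 1]")
    return 1.0 - nomogram_prob


def assemble_features(
    records: Sequence[ClinicalRecord],
    lsr_scores: Mapping[str, float] | None,
    modalities: Iterable[str],
) -> pd.DataFrame:
    """One feature row per sample restricted to the requested modalities.

    ``lsr_scores`` maps sample_id -> LSR and is only consulted when "L" is
    requested.  Samples missing a requested modality are excluded with a
    logged count rather than imputed.  Returns a DataFrame indexed by
    sample_id whose columns follow MODALITY_COLUMNS order.
    """
    mods = tuple(modalities)
    unknown = set(mods) - set(MODALITIES)
    if unknown:
        raise ValueError(f"unknown modalities: {sorted(unknown)}")
    if not mods:
        raise ValueError("at least one modality is required")

    rows, dropped = {}, 0
    for r in records:
        row = {}
        if "L" in mods:
            if lsr_scores is None or r.sample_id not in lsr_scores:
                dropped += 1
                continue
            row["lsr"] = float(lsr_scores[r.sample_id])
        if "N" in mods:
            row["nomogram_risk"] = nomogram_risk(r.nomogram_prob)
        if "F" in mods:
            row["fusion_bin"] = float(encode_fusion(r.fusion_positive_count))
        if "G" in mods:
            row["gleason_bin"] = float(encode_gleason(r.gleason))
        rows[r.sample_id] = row
    if dropped:
        log.info("assemble_features: excluded %d sample(s) lacking LSR", dropped)
    if not rows:
        raise ValueError("no samples carry all requested modalities")
    cols = [MODALITY_COLUMNS[m] for m in MODALITIES if m in mods]
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample"
    return df[cols]
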