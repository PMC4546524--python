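"""Reading, validation and filtering of CNV segment tables and clinical tables.

Segment tables are the shape of SNP-array segmentation output: one row per
called copy-number interval with marker support, gain/loss state and a call
p-value.  Coordinates are stored 0-based half-open internally; two input
dialects are supported ("bed": 0-based half-open, "partek": 1-based
inclusive).  Chromosome names are kept verbatim and compared case-sensitively.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "markers", "state", "pvalue"]
CLINICAL_COLUMNS = [
    "sample",
    "recurrent",
    "followup_months",
    "psadt_months",
    "gleason",
    "nomogram_prob",
    "fusion_count",
]

#: Default segment retention thresholds: size >= 2 kb (inclusive),
#: >= 10 supporting markers, call p-value < 0.001 (strict).
MIN_SIZE_BP = 2000
MIN_MARKERS = 10
MAX_P = 0.001

#: Minimum recurrence-free follow-up (months) for a sample to be eligible
#: as a "non-recurrent" control.
NONRECURRENT_FOLLOWUP_MONTHS = 90.0


class SegmentFormatError(ValueError):
    """Structural problem with a segment or clinical table."""


class SegmentRowError(ValueError):
    """A row that violates the segment invariants; carries the row index."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class CNVSegment:
    """One called copy-number interval (coordinates 0-based half-open)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_markers: int
    state: str  # "loss" | "gain"
    p_value: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")
        if self.state not in ("loss", "gain"):
            raise ValueError(f"state must be 'loss' or 'gain', got {self.state!r}")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class SampleProfile:
    """A sample's post-filter segment-size multiset with burden summaries."""

    sample_id: str
    sizes: np.ndarray  # bp, one entry per retained segment

    def __post_init__(self):
        self.sizes = np.asarray(self.sizes, dtype=float)

    @property
    def n_segments(self) -> int:
        return int(self.sizes.size)

    @property
    def mean_size(self) -> float:
        if self.n_segments == 0:
            raise ValueError(f"sample {self.sample_id}: no segments, mean undefined")
        return float(self.sizes.mean())


@dataclass
class ClinicalRecord:
    """Outcome labels, follow-up and the three clinical covariates.

    ``followup_months`` is the recurrence time for recurrent patients and
    the recurrence-free observation time otherwise.  ``nomogram_prob`` is
    the externally computed 7-year progression-free probability (higher =
    lower risk); ``fusion_positive_count`` counts detected fusion
    transcripts out of the eight assayed.
    """

    sample_id: str
    recurrent: bool
    followup_months: float
    psadt_months: float | None
    gleason: int
    nomogram_prob: float
    fusion_positive_count: int

    def __post_init__(self):
        if self.followup_months < 0:
            raise ValueError("followup_months must be non-negative")
        if self.psadt_months is not None and not self.recurrent:
            raise ValueError(
                f"sample {self.sample_id}: PSADT given for a non-recurrent sample"
            )
        if self.psadt_months is not None and self.psadt_months <= 0:
            raise ValueError("psadt_months must be positive")
        if not (2 <= self.gleason <= 10):
            raise ValueError(f"gleason score {self.gleason} outside [2, 10]")
        if not (0.0 <= self.nomogram_prob <= 1.0):
            raise ValueError("nomogram_prob must lie in [0, 1]")
        if self.fusion_positive_count < 0:
            raise ValueError("fusion_positive_count must be non-negative")

    @property
    def eligible_nonrecurrent(self) -> bool:
        """Usable as a non-recurrent control: recurrence-free >= 90 months."""
        return (not self.recurrent) and (
            self.followup_months >= NONRECURRENT_FOLLOWUP_MONTHS
        )


def read_segments(path: str | Path | io.IOBase, dialect: str = "bed") -> list[CNVSegment]:
    """Read a TSV segment table, normalizing coordinates to 0-based half-open.

    dialect "bed" takes (start, end) as 0-based half-open; "partek" takes
    them as 1-based inclusive (start-1 is stored, end kept, so a 1-based
    (101, 200) row becomes (100, 200), size 100).
    """
    if dialect not in ("bed", "partek"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SegmentFormatError(f"missing required column(s): {', '.join(missing)}")

    segments: list[CNVSegment] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            start = int(row.start)
            end = int(row.end)
            markers = int(row.markers)
            pvalue = float(row.pvalue)
        except (TypeError, ValueError) as exc:
            raise SegmentRowError(idx, f"non-numeric field ({exc})") from exc
        if dialect == "partek":
            start -= 1
        try:
            segments.append(
                CNVSegment(
                    sample_id=str(row.sample),
                    chrom=str(row.chrom),
                    start=start,
                    end=end,
                    n_markers=markers,
                    state=str(row.state),
                    p_value=pvalue,
                )
            )
        except ValueError as exc:
            raise SegmentRowError(idx, str(exc)) from exc
    return segments


def write_segments(segments: Iterable[CNVSegment], path: str | Path) -> None:
    """Write segments in the canonical TSV dialect (0-based half-open)."""
    rows = [
        (s.sample_id, s.chrom, s.start, s.end, s.n_markers, s.state, s.p_value)
        for s in segments
    ]
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def filter_segments(
    segments: Sequence[CNVSegment],
    min_size: int = MIN_SIZE_BP,
    min_markers: int = MIN_MARKERS,
    max_p: float = MAX_P,
) -> list[CNVSegment]:
    """Keep segments with size >= min_size, markers >= min_markers and p < max_p.

    Order is preserved; the operation is idempotent.
    """
    if min_size <= 0 or min_markers <= 0 or max_p <= 0:
        raise ValueError("thresholds must be positive")
    return [
        s
        for s in segments
        if s.size >= min_size and s.n_markers >= min_markers and s.p_value < max_p
    ]


def build_profiles(
    segments: Sequence[CNVSegment], states: Sequence[str] = ("loss", "gain")
) -> list[SampleProfile]:
    """Group (already filtered) segments into one size profile per sample.

    Gains and losses are pooled by default; pass ``states=("loss",)`` or
    ``("gain",)`` to restrict.  Profiles come back ordered by first
    appearance of each sample in the input.
    """
    order: dict[str, list[float]] = {}
    for s in segments:
        if s.state not in states:
            continue
        order.setdefault(s.sample_id, []).append(float(s.size))
    return [SampleProfile(sample_id=sid, sizes=np.array(sz)) for sid, sz in order.items()]


def read_clinical(path: str | Path | io.IOBase) -> list[ClinicalRecord]:
    """Read the clinical covariate CSV; samples failing the non-recurrent
    eligibility rule are kept (flagged via ``eligible_nonrecurrent``), not
    silently dropped."""
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SegmentFormatError(f"missing required column(s): {', '.join(missing)}")

    records: list[ClinicalRecord] = []
    for idx, row in df.iterrows():
        psadt = row["psadt_months"]
        psadt = None if pd.isna(psadt) else float(psadt)
        try:
            records.append(
                ClinicalRecord(
                    sample_id=str(row["sample"]),
                    recurrent=_parse_bool(row["recurrent"]),
                    followup_months=float(row["followup_months"]),
                    psadt_months=psadt,
                    gleason=int(row["gleason"]),
                    nomogram_prob=float(row["nomogram_prob"]),
                    fusion_positive_count=int(row["fusion_count"]),
                )
            )
        except ValueError as exc:
            raise SegmentRowError(int(idx), str(exc)) from exc
    return records


def write_clinical(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    rows = [
        (
            r.sample_id,
            r.recurrent,
            r.followup_months,
            "" if r.psadt_months is None else r.psadt_months,
            r.gleason,
            r.nomogram_prob,
            r.fusion_positive_count,
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, index=False)


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file of gene intervals (chrom, start, end, name)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"],
    )
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise SegmentFormatError(f"BED row {bad[0]}: end <= start")
    return df
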