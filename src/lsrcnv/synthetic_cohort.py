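"""Synthetic cohorts with the reported leukocyte-CNV and clinical structure.

The generator emulates the published cohort at the level the downstream
statistics consume: per-sample CNV fragment counts (negative binomial,
mean 152), log-normal fragment sizes with a heavier upper tail in
recurrent patients (arm mean-size ratio calibrated analytically, default
3.2-fold), class-dependent clinical covariates (Gleason, nomogram
probability, fusion transcripts), and class-consistent recurrence /
censoring times.  It does not attempt marker-level intensities or
realistic chromosomal placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .segment_io import CNVSegment, ClinicalRecord, SampleProfile

LN10 = math.log(10.0)

#: Published cohort bookkeeping used for defaults: 273 genomes carrying
#: 24213 deletion + 17376 amplification fragments after filtering.
STUDY_N_SAMPLES = 273
STUDY_N_DELETIONS = 24213
STUDY_N_AMPLIFICATIONS = 17376
STUDY_TOTAL_FRAGMENTS = STUDY_N_DELETIONS + STUDY_N_AMPLIFICATIONS

#: approximate autosome lengths (bp), enough for placement plausibility
_CHROM_LENGTHS = {
    f"chr{i}": length
    for i, length in enumerate(
        [249, 243, 198, 191, 181, 171, 159, 146, 141, 136, 135, 134,
         115, 107, 102, 90, 81, 78, 59, 63, 48, 51],
        start=1,
    )
}
_CHROM_LENGTHS = {k: v * 1_000_000 for k, v in _CHROM_LENGTHS.items()}

CLASSES = ("nonrec", "slow", "fast")


@dataclass
class ClassCovariates:
    """Covariate distribution of one outcome class."""

    gleason_high_prob: float  # P(Gleason > 7)
    nomogram_mean: float      # mean 7-year progression-free probability
    fusion_prob: float        # P(>= 1 fusion transcript detected)
    nomogram_concentration: float = 12.0


@dataclass
class CovariateEffects:
    nonrec: ClassCovariates = field(
        default_factory=lambda: ClassCovariates(0.12, 0.80, 0.05)
    )
    slow: ClassCovariates = field(
        default_factory=lambda: ClassCovariates(0.28, 0.68, 0.18)
    )
    fast: ClassCovariates = field(
        default_factory=lambda: ClassCovariates(0.45, 0.52, 0.40)
    )

    @staticmethod
    def null() -> "CovariateEffects":
        """Identical covariate distributions in every class."""
        c = ClassCovariates(0.25, 0.70, 0.15)
        return CovariateEffects(nonrec=c, slow=replace(c), fast=replace(c))


@dataclass
class CohortSpec:
    """Full description of a simulated cohort.

    The default class sizes follow the published design: 35 non-recurrent
    (>= 90 months), 55 fast-recurrent (PSADT <= 4 months) and 53
    slow-recurrent (PSADT >= 15 months).  Size model: fragment sizes are
    log-normal (log10 mean/sd of the non-recurrent arm given directly);
    recurrent samples draw each fragment from a two-component mixture
    whose upper-tail component is placed analytically so the recurrent /
    non-recurrent arm mean-size ratio equals ``size_fold_recurrent``.
    """

    n_nonrecurrent: int = 35
    n_recurrent_fast: int = 55
    n_recurrent_slow: int = 53

    mean_fragments_per_sample: float = float(
        round(STUDY_TOTAL_FRAGMENTS / STUDY_N_SAMPLES)
    )  # = 152
    fragment_dispersion: float = 20.0  # NB size parameter; var = mu + mu^2/k

    size_log10_mean_nonrec: float = 4.5
    size_log10_sd: float = 0.5
    size_fold_recurrent: float = 3.2
    tail_weight: float = 0.25  # mixture weight of the large-size component
    tail_log10_mean: float | None = None  # None -> calibrated from the fold
    tail_log10_sd: float | None = None    # None -> same as base sd

    # between-sample heterogeneity: a per-sample location shift of the size
    # distribution (same law in every class, so arm mean ratios are
    # unchanged in expectation) and per-sample variation of the recurrent
    # tail weight around ``tail_weight``
    sample_log10_jitter_sd: float = 0.12
    tail_weight_sd: float = 0.10

    loss_fraction: float = STUDY_N_DELETIONS / STUDY_TOTAL_FRAGMENTS
    noise_fragment_fraction: float = 0.08  # sub-threshold rows, removed by filtering

    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)

    # survival structure (months)
    fast_event_scale: float = 13.0   # exponential scale; median ~9 months
    slow_event_scale: float = 65.0   # median ~45 months
    censor_time: float = 90.0        # minimum non-recurrent follow-up
    max_extra_followup: float = 60.0

    seed: int = 0

    def __post_init__(self):
        if min(self.n_nonrecurrent, self.n_recurrent_fast, self.n_recurrent_slow) < 0:
            raise ValueError("class counts must be non-negative")
        if self.size_fold_recurrent < 1:
            raise ValueError("size_fold_recurrent must be >= 1")
        if not (0.0 < self.tail_weight <= 1.0):
            raise ValueError("tail_weight must lie in (0, 1]")

    # ---- analytic size moments -------------------------------------------

    @property
    def base_mean_size(self) -> float:
        """E[size] of the non-recurrent log-normal component (bp)."""
        m = self.size_log10_mean_nonrec * LN10
        s = self.size_log10_sd * LN10
        return math.exp(m + s * s / 2.0)

    @property
    def tail_params(self) -> tuple[float, float]:
        """(log10 mean, log10 sd) of the recurrent upper-tail component.

        When not given explicitly, the component mean is solved from
        E[size | recurrent] = fold * E[size | non-recurrent] with the
        mixture weight fixed, i.e. the component mean ratio is
        r = (fold - 1) / weight + 1.
        """
        s10 = self.tail_log10_sd if self.tail_log10_sd is not None else self.size_log10_sd
        if self.tail_log10_mean is not None:
            return float(self.tail_log10_mean), float(s10)
        r = (self.size_fold_recurrent - 1.0) / self.tail_weight + 1.0
        s2 = s10 * LN10
        m2 = math.log(r * self.base_mean_size) - s2 * s2 / 2.0
        return m2 / LN10, float(s10)

    @property
    def recurrent_mean_size(self) -> float:
        m2_10, s2_10 = self.tail_params
        comp_mean = math.exp(m2_10 * LN10 + (s2_10 * LN10) ** 2 / 2.0)
        return (1.0 - self.tail_weight) * self.base_mean_size + self.tail_weight * comp_mean

    @property
    def n_samples(self) -> int:
        return self.n_nonrecurrent + self.n_recurrent_fast + self.n_recurrent_slow


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[CNVSegment], list[ClinicalRecord]]:
    """Draw a full cohort (segment rows + clinical rows), reproducible from
    ``spec.seed``; each sample has its own random sub-stream."""
    if spec.n_samples == 0:
        raise ValueError("cohort must contain at least one sample")
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(spec.n_samples)

    classes = (
        ["nonrec"] * spec.n_nonrecurrent
        + ["fast"] * spec.n_recurrent_fast
        + ["slow"] * spec.n_recurrent_slow
    )
    chrom_names = list(_CHROM_LENGTHS)
    chrom_lengths = np.array([_CHROM_LENGTHS[c] for c in chrom_names], dtype=float)

    segments: list[CNVSegment] = []
    records: list[ClinicalRecord] = []
    for i, (cls, stream) in enumerate(zip(classes, streams)):
        rng = np.random.default_rng(stream)
        sid = f"S{i:04d}"
        segments.extend(
            _sample_segments(sid, cls, spec, rng, chrom_names, chrom_lengths)
        )
        records.append(_sample_clinical(sid, cls, spec, rng))
    return segments, records


def _draw_sizes(n: int, cls: str, spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    # per-sample location shift (drawn once per call = once per sample)
    jitter = rng.normal(0.0, spec.sample_log10_jitter_sd) if spec.sample_log10_jitter_sd else 0.0
    m, s = spec.size_log10_mean_nonrec, spec.size_log10_sd
    log10_sizes = rng.normal(m + jitter, s, n)
    if cls != "nonrec":
        m2, s2 = spec.tail_params
        w = spec.tail_weight
        if spec.tail_weight_sd:
            # Beta with mean tail_weight and the requested sd
            var = min(spec.tail_weight_sd**2, w * (1 - w) * 0.99)
            c = w * (1 - w) / var - 1.0
            w = rng.beta(w * c, (1 - w) * c)
        from_tail = rng.random(n) < w
        k = int(from_tail.sum())
        log10_sizes[from_tail] = rng.normal(m2 + jitter, s2, k)
    return np.maximum(np.round(10.0 ** log10_sizes), 2000.0)


def _sample_segments(
    sid: str,
    cls: str,
    spec: CohortSpec,
    rng: np.random.Generator,
    chrom_names: list[str],
    chrom_lengths: np.ndarray,
) -> list[CNVSegment]:
    mu, k = spec.mean_fragments_per_sample, spec.fragment_dispersion
    n = max(1, int(rng.negative_binomial(k, k / (k + mu))))
    sizes = _draw_sizes(n, cls, spec, rng)
    n_noise = rng.binomial(n, spec.noise_fragment_fraction)

    out: list[CNVSegment] = []
    for j in range(n + n_noise):
        is_noise = j >= n
        if is_noise:
            size = float(rng.integers(200, 2000))
            markers = int(rng.integers(1, 10))
            pval = float(rng.uniform(0.001, 1.0))
            # noise rows break one rule at least; may break several
            kind = rng.integers(3)
            if kind == 0:
                size = float(np.round(10.0 ** rng.normal(4.5, 0.5)))
                markers = max(10, int(size / 1500))
            elif kind == 1:
                pval = float(rng.uniform(0.0, 0.001))
                markers = max(10, int(size / 150))
        else:
            size = sizes[j]
            markers = max(10, int(rng.poisson(size / 1500.0)))
            pval = float(rng.uniform(0.0, 0.001))
        ci = int(rng.integers(len(chrom_names)))
        start = int(rng.integers(0, max(1, int(chrom_lengths[ci] - size))))
        state = "loss" if rng.random() < spec.loss_fraction else "gain"
        out.append(
            CNVSegment(
                sample_id=sid,
                chrom=chrom_names[ci],
                start=start,
                end=start + int(size),
                n_markers=markers,
                state=state,
                p_value=min(pval, 1.0),
            )
        )
    return out


def _sample_clinical(
    sid: str, cls: str, spec: CohortSpec, rng: np.random.Generator
) -> ClinicalRecord:
    cov: ClassCovariates = getattr(spec.covariate_effects, cls)
    high = rng.random() < cov.gleason_high_prob
    gleason = int(rng.choice([8, 9, 10], p=[0.6, 0.3, 0.1])) if high else int(
        rng.choice([6, 7], p=[0.45, 0.55])
    )
    a = cov.nomogram_mean * cov.nomogram_concentration
    b = (1.0 - cov.nomogram_mean) * cov.nomogram_concentration
    nomogram = float(np.clip(rng.beta(a, b), 0.0, 1.0))
    fusion = int(1 + rng.binomial(7, 0.1)) if rng.random() < cov.fusion_prob else 0

    if cls == "nonrec":
        return ClinicalRecord(
            sample_id=sid,
            recurrent=False,
            followup_months=float(
                np.round(spec.censor_time + rng.uniform(0, spec.max_extra_followup), 2)
            ),
            psadt_months=None,
            gleason=gleason,
            nomogram_prob=nomogram,
            fusion_positive_count=fusion,
        )
    scale = spec.fast_event_scale if cls == "fast" else spec.slow_event_scale
    event_time = float(np.round(max(0.5, rng.exponential(scale)), 2))
    psadt = (
        float(np.round(rng.uniform(1.0, 4.0), 2))
        if cls == "fast"
        else float(np.round(rng.uniform(15.0, 60.0), 2))
    )
    return ClinicalRecord(
        sample_id=sid,
        recurrent=True,
        followup_months=event_time,
        psadt_months=psadt,
        gleason=gleason,
        nomogram_prob=nomogram,
        fusion_positive_count=fusion,
    )


# ---------------------------------------------------------------------------
# Fixed worked example

#: Large-size threshold of the worked example (bp): 10^4.5 rounded down.
WORKED_EXAMPLE_DELTA = 31622


def worked_example_profile() -> SampleProfile:
    """The documented 7-fragment example: exactly 3 fragments at or above
    the 31622-bp threshold, so LSR = 3/7 = 0.43."""
    sizes = np.array([2400.0, 5600.0, 11000.0, 18000.0, 45000.0, 160000.0, 610000.0])
    return SampleProfile(sample_id="worked-example", sizes=sizes)
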