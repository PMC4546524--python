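"""ROC machinery, LDA score fusion, and trimmed repeated two-fold CV.

The evaluation protocol mirrors the study design: samples are randomly and
equally split in two; the LSR size threshold delta, the LDA weights and the
decision cutoff are fitted on one half and applied to the other, then the
halves swap roles.  The whole procedure is repeated (default 14 times), the
top-2 and bottom-2 repeats by summed AUC are discarded, and the remaining
repeats (default 10) are averaged.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .covariates import assemble_features
from .lsr_model import (
    DEFAULT_DELTA_GRID,
    compute_lsr,
    fit_lsr_cutoff,
    optimize_delta,
)
from .segment_io import ClinicalRecord, SampleProfile

log = logging.getLogger(__name__)

CONTRASTS = ("recurrence", "fast_recurrence", "lethal")

#: PSADT (months) at or below which recurrence counts as "fast"
FAST_PSADT_MONTHS = 4.0
#: PSADT (months) at or above which recurrence counts as "slow" (a
#: negative in the fast-recurrence contrast); 4 < PSADT < 15 is excluded
SLOW_PSADT_MONTHS = 15.0
#: recurrence within this many months (with fast PSADT) defines "lethal"
LETHAL_RELAPSE_MONTHS = 12.0

METRIC_NAMES = (
    "accuracy",
    "balanced_accuracy",
    "sensitivity",
    "specificity",
    "youden",
    "auc",
    "roc_p",
)


@dataclass
class SplitMetrics:
    """Classification metrics for one role (train or test) of one split.

    ``accuracy`` is the raw overall accuracy; ``balanced_accuracy`` the
    mean of sensitivity and specificity.  Both are carried because the
    study's single "accuracy" column is not pinned to either definition.
    """

    role: str
    accuracy: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    youden: float
    auc: float
    roc_p: float

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, m) for m in METRIC_NAMES])


@dataclass
class CVSummary:
    """Trimmed-averaged metrics over retained splits of a repeated CV."""

    train: SplitMetrics
    test: SplitMetrics
    retained_split_ids: list[int]
    representative_split_id: int
    per_split: list[tuple[SplitMetrics, SplitMetrics]]


# ---------------------------------------------------------------------------
# ROC primitives


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, float]:
    """ROC points and AUC; AUC equals the Mann-Whitney pair probability
    P(score+ > score-) + 0.5 P(tie)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    auc = roc_auc_score(y, s)
    return np.column_stack([fpr, tpr]), float(auc)


def roc_pvalue(
    scores: Sequence[float], labels: Sequence[int], method: str = "normal"
) -> float:
    """One-sided p-value for AUC > 0.5 (model vs the ROC diagonal).

    "normal": tie-corrected normal approximation to the Mann-Whitney
    statistic.  "exact": full enumeration of label assignments (only
    feasible for small classes, ~<= 12 per class).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("ROC p-value needs both classes present")
    if method == "normal":
        return float(
            stats.mannwhitneyu(pos, neg, alternative="greater", method="asymptotic").pvalue
        )
    if method == "exact":
        return _roc_pvalue_exact(s, y)
    raise ValueError(f"unknown method {method!r}")


def _roc_pvalue_exact(s: np.ndarray, y: np.ndarray) -> float:
    """Permutation p: fraction of label assignments with AUC >= observed."""
    n = s.size
    n_pos = int((y == 1).sum())
    ranks = stats.rankdata(s)
    r_obs = ranks[y == 1].sum()  # AUC is monotone in the positive rank sum
    count = total = 0
    for combo in itertools.combinations(range(n), n_pos):
        total += 1
        if ranks[list(combo)].sum() >= r_obs - 1e-9:
            count += 1
    return count / total


def geometric_mean_p(p_values: Sequence[float]) -> float:
    """exp(mean(log p)) — the aggregation used for cross-validated p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return float(np.exp(np.mean(np.log(p))))


# ---------------------------------------------------------------------------
# LDA


@dataclass
class LinearScorer:
    """Fisher discriminant scorer: score(x) = w.(x - m), higher = positive."""

    weights: np.ndarray
    offset: float
    feature_names: tuple[str, ...]

    def score(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_names)].to_numpy(dtype=float)
        return X @ self.weights + self.offset


def fit_lda(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence[int],
    ridge: bool = True,
) -> LinearScorer:
    """Two-class LDA via the closed form w = S_pooled^-1 (mu+ - mu-).

    The pooled within-class covariance gets a ridge of 1e-6 * trace/d on
    its diagonal when singular (binary covariates on small splits make
    exact singularity common); with ``ridge=False`` a singular covariance
    raises instead.
    """
    if isinstance(features, pd.DataFrame):
        names = tuple(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    y = np.asarray(labels, dtype=int)
    Xp, Xn = X[y == 1], X[y == 0]
    if Xp.shape[0] < 2 or Xn.shape[0] < 2:
        raise ValueError("LDA needs >= 2 samples in each class")
    mu_p, mu_n = Xp.mean(axis=0), Xn.mean(axis=0)
    Sp = np.cov(Xp, rowvar=False, ddof=1)
    Sn = np.cov(Xn, rowvar=False, ddof=1)
    n_p, n_n = Xp.shape[0], Xn.shape[0]
    S = ((n_p - 1) * np.atleast_2d(Sp) + (n_n - 1) * np.atleast_2d(Sn)) / (
        n_p + n_n - 2
    )
    d = S.shape[0]
    try:
        w = np.linalg.solve(S, mu_p - mu_n)
    except np.linalg.LinAlgError:
        if not ridge:
            raise
        eps = 1e-6 * max(np.trace(S), 1.0) / d
        w = np.linalg.solve(S + eps * np.eye(d), mu_p - mu_n)
    else:
        # solve() can succeed on numerically singular matrices; re-check
        if not np.all(np.isfinite(w)) or np.linalg.cond(S) > 1e12:
            if not ridge:
                raise np.linalg.LinAlgError("singular pooled covariance")
            eps = 1e-6 * max(np.trace(S), 1.0) / d
            w = np.linalg.solve(S + eps * np.eye(d), mu_p - mu_n)
    offset = -float(w @ (mu_p + mu_n) / 2.0)
    return LinearScorer(weights=w, offset=offset, feature_names=names)


# ---------------------------------------------------------------------------
# Contrast datasets


@dataclass
class ContrastData:
    """Samples of one outcome contrast: binary labels plus the inputs the
    models need (size profiles and clinical records), keyed by sample."""

    contrast: str
    labels: pd.Series  # index sample_id, values {0, 1}
    records: dict[str, ClinicalRecord]
    profiles: dict[str, SampleProfile]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)


def contrast_label(record: ClinicalRecord, contrast: str) -> int | None:
    """Label of a sample under a contrast, or None if the sample is excluded.

    recurrence:      recurrent vs non-recurrent (>= 90 months follow-up)
    fast_recurrence: PSADT <= 4 vs (eligible non-recurrent or PSADT >= 15)
    lethal:          recurrence <= 12 months with PSADT <= 4 vs eligible
                     non-recurrent
    """
    if contrast == "recurrence":
        if record.recurrent:
            return 1
        return 0 if record.eligible_nonrecurrent else None
    if contrast == "fast_recurrence":
        if record.recurrent:
            if record.psadt_months is None:
                return None
            if record.psadt_months <= FAST_PSADT_MONTHS:
                return 1
            if record.psadt_months >= SLOW_PSADT_MONTHS:
                return 0
            return None  # intermediate PSADT excluded
        return 0 if record.eligible_nonrecurrent else None
    if contrast == "lethal":
        if record.recurrent:
            lethal = (
                record.psadt_months is not None
                and record.psadt_months <= FAST_PSADT_MONTHS
                and record.followup_months <= LETHAL_RELAPSE_MONTHS
            )
            return 1 if lethal else None
        return 0 if record.eligible_nonrecurrent else None
    raise ValueError(f"unknown contrast {contrast!r}")


def build_contrast(
    records: Sequence[ClinicalRecord],
    profiles: Sequence[SampleProfile],
    contrast: str,
) -> ContrastData:
    prof = {p.sample_id: p for p in profiles}
    labels, recs = {}, {}
    for r in records:
        lab = contrast_label(r, contrast)
        if lab is None or r.sample_id not in prof:
            continue
        labels[r.sample_id] = lab
        recs[r.sample_id] = r
    if not labels:
        raise ValueError(f"no samples eligible for contrast {contrast!r}")
    series = pd.Series(labels, name="label", dtype=int)
    series.index.name = "sample"
    return ContrastData(
        contrast=contrast,
        labels=series,
        records=recs,
        profiles={sid: prof[sid] for sid in labels},
    )


# ---------------------------------------------------------------------------
# Split fitting and evaluation


@dataclass
class FittedModel:
    """Everything trained on one half: delta (if L used), scorer, cutoff."""

    modalities: tuple[str, ...]
    delta: float | None
    scorer: LinearScorer | None  # None for single-modality models
    cutoff: float

    def scores_for(self, data: ContrastData, sample_ids: Sequence[str]) -> np.ndarray:
        feats = _features_at_delta(data, sample_ids, self.modalities, self.delta)
        if self.scorer is None:
            return feats.iloc[:, 0].to_numpy(dtype=float)
        return self.scorer.score(feats)

    def predict(self, data: ContrastData, sample_ids: Sequence[str]) -> np.ndarray:
        return (self.scores_for(data, sample_ids) >= self.cutoff).astype(int)


def _features_at_delta(
    data: ContrastData,
    sample_ids: Sequence[str],
    modalities: tuple[str, ...],
    delta: float | None,
) -> pd.DataFrame:
    lsr_scores = None
    if "L" in modalities:
        if delta is None:
            raise ValueError("modality L requested but no delta fitted")
        lsr_scores = {
            s: compute_lsr(data.profiles[s], delta) for s in sample_ids
        }
    recs = [data.records[s] for s in sample_ids]
    feats = assemble_features(recs, lsr_scores, modalities)
    return feats.loc[list(sample_ids)]


def fit_half(
    data: ContrastData,
    train_ids: Sequence[str],
    modalities: tuple[str, ...],
    delta_grid: Sequence[float] = DEFAULT_DELTA_GRID,
) -> FittedModel:
    """Train delta (if L), LDA weights (if >= 2 modalities) and the Youden
    cutoff on one half of the data."""
    y_train = data.labels.loc[list(train_ids)].to_numpy()
    delta = None
    if "L" in modalities:
        profs = [data.profiles[s] for s in train_ids]
        delta, _, _ = optimize_delta(profs, y_train, delta_grid)
    feats = _features_at_delta(data, train_ids, modalities, delta)
    scorer = None
    if feats.shape[1] >= 2:
        scorer = fit_lda(feats, y_train)
        scores = scorer.score(feats)
    else:
        scores = feats.iloc[:, 0].to_numpy(dtype=float)
    cutoff, _ = fit_lsr_cutoff(scores, y_train)
    return FittedModel(
        modalities=modalities, delta=delta, scorer=scorer, cutoff=cutoff
    )


def evaluate_model(
    model: FittedModel, data: ContrastData, sample_ids: Sequence[str], role: str
) -> SplitMetrics:
    y = data.labels.loc[list(sample_ids)].to_numpy()
    scores = model.scores_for(data, sample_ids)
    pred = (scores >= model.cutoff).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    sens = float(((pred == 1) & (y == 1)).sum() / n_pos)
    spec = float(((pred == 0) & (y == 0)).sum() / n_neg)
    _, auc = roc_auc(scores, y)
    return SplitMetrics(
        role=role,
        accuracy=float((pred == y).mean()),
        balanced_accuracy=(sens + spec) / 2.0,
        sensitivity=sens,
        specificity=spec,
        youden=sens + spec - 1.0,
        auc=auc,
        roc_p=roc_pvalue(scores, y),
    )


def _equal_split(
    sample_ids: Sequence[str], labels: pd.Series, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """One random equal split with both classes in both halves (resampled,
    max 100 attempts, resamples logged)."""
    ids = np.asarray(sample_ids)
    for attempt in range(100):
        perm = rng.permutation(ids)
        half_a = list(perm[: ids.size // 2])
        half_b = list(perm[ids.size // 2 :])
        ok = all(
            labels.loc[h].nunique() == 2 for h in (half_a, half_b)
        )
        if ok:
            if attempt:
                log.info("resampled split %d time(s) to get both classes per half", attempt)
            return half_a, half_b
    raise RuntimeError("could not produce a two-class split in 100 attempts")


def run_split(
    data: ContrastData,
    modalities: Iterable[str],
    seed: int | np.random.SeedSequence,
    delta_grid: Sequence[float] = DEFAULT_DELTA_GRID,
) -> tuple[SplitMetrics, SplitMetrics]:
    """One two-fold cross-validation: split, train on each half in turn,
    evaluate both halves, and average the two train / two test evaluations.

    p-values are combined geometrically within the split; every other
    metric arithmetically.
    """
    mods = tuple(m for m in "LNFG" if m in set(modalities))
    if not mods:
        raise ValueError("at least one modality required")
    rng = np.random.default_rng(seed)
    half_a, half_b = _equal_split(data.sample_ids, data.labels, rng)
    trains, tests = [], []
    for train_ids, test_ids in ((half_a, half_b), (half_b, half_a)):
        model = fit_half(data, train_ids, mods, delta_grid)
        trains.append(evaluate_model(model, data, train_ids, "train"))
        tests.append(evaluate_model(model, data, test_ids, "test"))
    return _average_metrics(trains, "train"), _average_metrics(tests, "test")


def _average_metrics(metrics: Sequence[SplitMetrics], role: str) -> SplitMetrics:
    vals = {}
    for m in METRIC_NAMES:
        xs = [getattr(sm, m) for sm in metrics]
        vals[m] = geometric_mean_p(xs) if m == "roc_p" else float(np.mean(xs))
    return SplitMetrics(role=role, **vals)


def trimmed_cv(
    data: ContrastData,
    modalities: Iterable[str],
    n_repeats: int = 14,
    trim: int = 2,
    seed: int | np.random.SeedSequence = 0,
    delta_grid: Sequence[float] = DEFAULT_DELTA_GRID,
) -> CVSummary:
    """Repeat the two-fold CV, drop the ``trim`` best and worst repeats by
    train+test AUC, and average the rest.

    The representative split is the retained repeat whose concatenated
    train+test metric vector is closest (Euclidean) to the average.
    """
    if n_repeats <= 2 * trim:
        raise ValueError("n_repeats must exceed 2 * trim")
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    children = ss.spawn(n_repeats)
    per_split = [
        run_split(data, modalities, child, delta_grid) for child in children
    ]
    retained = retained_split_indices(
        [tr.auc + te.auc for tr, te in per_split], trim
    )
    train_avg = _average_metrics([per_split[i][0] for i in retained], "train")
    test_avg = _average_metrics([per_split[i][1] for i in retained], "test")
    target = np.concatenate([train_avg.vector(), test_avg.vector()])
    dists = [
        np.linalg.norm(
            np.concatenate([per_split[i][0].vector(), per_split[i][1].vector()])
            - target
        )
        for i in retained
    ]
    rep = retained[int(np.argmin(dists))]
    return CVSummary(
        train=train_avg,
        test=test_avg,
        retained_split_ids=retained,
        representative_split_id=rep,
        per_split=per_split,
    )


def retained_split_indices(auc_sums: Sequence[float], trim: int) -> list[int]:
    """Indices kept after dropping the ``trim`` highest and lowest AUC sums.

    Ties are resolved by original position (stable sort), so the retained
    set is deterministic.
    """
    order = np.argsort(np.asarray(auc_sums), kind="stable")
    n = len(auc_sums)
    keep = order[trim : n - trim] if trim else order
    return sorted(int(i) for i in keep)


def summary_table(results: Mapping[str, CVSummary]) -> pd.DataFrame:
    """Flatten {model name -> CVSummary} into a tidy train/test metric table."""
    rows = []
    for name, cv in results.items():
        for sm in (cv.train, cv.test):
            row = {"model": name, "role": sm.role}
            row.update({m: getattr(sm, m) for m in METRIC_NAMES})
            rows.append(row)
    return pd.DataFrame(rows)
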