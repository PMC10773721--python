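"""Model evaluation: confusion metrics, ROC-AUC, the repeated hold-out
protocol, and Welch ANOVA / Games-Howell comparisons across repeated runs.

Metrics follow the standard definitions

    sensitivity = TP / (TP + FN),   specificity = TN / (TN + FP),
    Gmean = sqrt(sensitivity * specificity)

with AUC the probability that a random positive outranks a random negative.
The hold-out protocol fits on a low-discrepancy subset of the training
windows, validates on the whole training set, tests on held-out athletes,
and repeats with consistent parameters (5 repeats by default).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from . import encoders, models, resampling, windowing

logger = logging.getLogger(__name__)

_PHI_INV = (np.sqrt(5.0) - 1.0) / 2.0  # 1/golden ratio


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    auc: float
    sensitivity: float
    specificity: float
    gmean: float


@dataclass
class RunReport:
    """Per-repeat metrics on each evaluation surface plus mean +/- sd."""

    validation: list[MetricSet]
    test: list[MetricSet]
    summary: dict = field(default_factory=dict)
    seeds: list[int] = field(default_factory=list)

    def summarize(self) -> dict:
        out = {}
        for surface, sets in (("validation", self.validation), ("test", self.test)):
            for name in ("auc", "sensitivity", "specificity", "gmean"):
                vals = np.array([getattr(m, name) for m in sets])
                out[f"{surface}_{name}_mean"] = round(float(vals.mean()), 3)
                out[f"{surface}_{name}_sd"] = round(float(vals.std(ddof=1)), 3) if len(vals) > 1 else 0.0
        self.summary = out
        return out


def confusion(labels: np.ndarray, probabilities: np.ndarray,
              threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts at a decision threshold (predict 1 iff p >= threshold)."""
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=float)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    pred = (p >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )


def metrics(counts: ConfusionCounts, labels: np.ndarray | None = None,
            probabilities: np.ndarray | None = None) -> MetricSet:
    """Sensitivity, specificity, Gmean from counts; AUC from the scores.

    AUC requires both classes; pass labels and probabilities for it
    (``nan`` otherwise).
    """
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else float("nan")
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else float("nan")
    gmean = float(np.sqrt(sens * spec))
    if labels is not None and probabilities is not None:
        y = np.asarray(labels)
        if len(np.unique(y)) < 2:
            raise ValueError("AUC undefined: only one class present")
        auc = float(roc_auc_score(y, probabilities))
    else:
        auc = float("nan")
    return MetricSet(auc=auc, sensitivity=float(sens), specificity=float(spec), gmean=gmean)


def relative_difference(a: float, b: float) -> float:
    """Percent difference of a metric vs a reference: 100 * (a - b) / b."""
    if b == 0:
        raise ValueError("reference metric must be nonzero")
    return 100.0 * (a - b) / b


def mean_difference(a: float, b: float) -> float:
    """Companion signed mean difference MD = b - a (reference minus value)."""
    return b - a


# ---------------------------------------------------------------------------
# Low-discrepancy subset selection
# ---------------------------------------------------------------------------

def low_discrepancy_subset(n: int, m: int, offset: float,
                           sequence: str = "golden") -> np.ndarray:
    """Indices of an m-of-n subset chosen by a deterministic low-discrepancy
    sequence, spreading selections evenly across the index range.

    ``sequence="golden"`` uses the additive golden-ratio sequence
    u_i = frac(offset + (i+1)/phi); ``"sobol"`` uses a scrambled-free Sobol
    stream.  The m indices with the smallest u are selected.
    """
    if not 0 <= m <= n:
        raise ValueError("need 0 <= m <= n")
    if sequence == "golden":
        u = np.mod(offset + (np.arange(1, n + 1)) * _PHI_INV, 1.0)
    elif sequence == "sobol":
        sob = stats.qmc.Sobol(d=1, scramble=False)
        sob.fast_forward(max(int(offset * 4096), 1))
        u = sob.random(n)[:, 0]
    else:
        raise ValueError(f"unknown sequence {sequence!r}")
    return np.sort(np.argsort(u)[:m])


# ---------------------------------------------------------------------------
# Repeated hold-out protocol
# ---------------------------------------------------------------------------

@dataclass
class HoldoutConfig:
    """Everything one repeat of the protocol needs, pinned and auditable."""

    method: str = "gasf"
    plan: resampling.ResamplingPlan = field(default_factory=resampling.ResamplingPlan)
    autoencoder: models.AutoencoderSpec = field(default_factory=models.AutoencoderSpec)
    classifier: models.ClassifierSpec = field(default_factory=models.ClassifierSpec)
    subset_fraction: float = 0.9
    repeats: int = 5
    sequence: str = "golden"
    threshold: float = 0.5
    seed: int = 0
    mtf_bins: int = encoders.DEFAULT_MTF_BINS


def _encode_scaled(matrices: np.ndarray, config: HoldoutConfig) -> np.ndarray:
    kwargs = {"q": config.mtf_bins} if config.method == "mtf" else {}
    stacks = encoders.encode_dataset(matrices, config.method, **kwargs)
    return models.scale_stack(stacks, config.method)


def fit_single(X_train, y_train, aid_train, config: HoldoutConfig,
               repeat: int = 0) -> tuple[models.DCAE, models.DNNClassifier, dict]:
    """One repeat of the protocol's fitting arm: select a low-discrepancy
    subset of the training windows, resample it, train the DCAE and the
    focal-loss classifier.  Returns both trained models plus resampling
    provenance."""
    seed = config.seed + 17 * repeat
    n = len(X_train)
    m = int(round(config.subset_fraction * n))
    offset = np.mod(config.seed * _PHI_INV + repeat * _PHI_INV**2, 1.0)
    subset = low_discrepancy_subset(n, m, offset, config.sequence)
    plan = resampling.ResamplingPlan(
        per_athlete_k=config.plan.per_athlete_k,
        n_injured_target=config.plan.n_injured_target,
        ratio=config.plan.ratio, smote_k=config.plan.smote_k,
        smote_target_ratio=config.plan.smote_target_ratio,
        smote_mode=config.plan.smote_mode, seed=seed,
    )
    flat = X_train[subset].reshape(len(subset), -1)
    res = resampling.multiple_resample(flat, y_train[subset], aid_train[subset], plan)
    mats = np.clip(res.X.reshape(-1, *X_train.shape[1:]), 0.0, 1.0)
    stacks = _encode_scaled(mats, config)
    dcae = models.dcae_fit(stacks, config.autoencoder, seed=seed)
    latents = dcae.encode(stacks)
    clf = models.dnn_fit(latents, res.y, config.classifier, seed=seed)
    return dcae, clf, res.provenance


def holdout_protocol(train_windows: Sequence[windowing.WindowSample],
                     test_windows: Sequence[windowing.WindowSample],
                     config: HoldoutConfig | None = None) -> RunReport:
    """Repeated hold-out evaluation of the full pipeline.

    ``train_windows`` / ``test_windows`` are normalized, padded (8 x 10)
    windows from disjoint athlete sets (overlap raises).  Each repeat fits
    on a low-discrepancy subset of the training windows (resampled by the
    three-step procedure), validates on the *entire* training set, and tests
    on the held-out athletes.
    """
    config = config or HoldoutConfig()
    train_aids = {w.athlete_id for w in train_windows}
    test_aids = {w.athlete_id for w in test_windows}
    overlap = train_aids & test_aids
    if overlap:
        raise ValueError(f"athletes present in both splits: {sorted(overlap)[:5]}")
    X_train, y_train, aid_train, _ = windowing.windows_to_arrays(train_windows)
    X_test, y_test, _, _ = windowing.windows_to_arrays(test_windows)
    stacks_val = _encode_scaled(X_train, config)
    stacks_test = _encode_scaled(X_test, config)

    report = RunReport(validation=[], test=[])
    for repeat in range(config.repeats):
        dcae, clf, _ = fit_single(X_train, y_train, aid_train, config, repeat)
        for stacks, labels, bucket in ((stacks_val, y_train, report.validation),
                                       (stacks_test, y_test, report.test)):
            probs = clf.predict_proba(dcae.encode(stacks))
            cc = confusion(labels, probs, config.threshold)
            bucket.append(metrics(cc, labels, probs))
        report.seeds.append(config.seed + 17 * repeat)
        logger.info("repeat %d: test AUC %.3f", repeat, report.test[-1].auc)
    report.summarize()
    return report


# ---------------------------------------------------------------------------
# Welch ANOVA and Games-Howell post-hoc comparisons
# ---------------------------------------------------------------------------

@dataclass
class WelchAnovaResult:
    f: float
    df1: float
    df2: float
    p: float


@dataclass
class GamesHowellComparison:
    group_a: int
    group_b: int
    md: float  # mean(a) - mean(b)
    t: float
    df: float
    p: float


def _group_stats(groups: Sequence[np.ndarray]):
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ns, means, variances = [], [], []
    for i, g in enumerate(groups):
        g = np.asarray(g, dtype=float)
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
        v = g.var(ddof=1)
        if v <= 0:
            raise ValueError(f"group {i} has zero variance")
        ns.append(g.size)
        means.append(g.mean())
        variances.append(v)
    return np.array(ns), np.array(means), np.array(variances)


def welch_anova(groups: Sequence[np.ndarray]) -> WelchAnovaResult:
    """Welch's heteroscedasticity-robust one-way ANOVA."""
    ns, means, variances = _group_stats(groups)
    k = len(ns)
    w = ns / variances
    w_total = w.sum()
    grand = (w * means).sum() / w_total
    a = (w * (means - grand) ** 2).sum() / (k - 1)
    lam = ((1 - w / w_total) ** 2 / (ns - 1)).sum()
    b = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * lam
    f = a / b
    df1 = k - 1
    df2 = (k**2 - 1) / (3.0 * lam)
    p = float(stats.f.sf(f, df1, df2))
    return WelchAnovaResult(f=float(f), df1=float(df1), df2=float(df2), p=p)


def games_howell(groups: Sequence[np.ndarray]) -> list[GamesHowellComparison]:
    """Games-Howell pairwise comparisons (studentized-range p-values)."""
    ns, means, variances = _group_stats(groups)
    k = len(ns)
    out = []
    for i, j in itertools.combinations(range(k), 2):
        se2 = variances[i] / ns[i] + variances[j] / ns[j]
        md = means[i] - means[j]
        t = md / np.sqrt(se2)
        df = se2**2 / ((variances[i] / ns[i]) ** 2 / (ns[i] - 1)
                       + (variances[j] / ns[j]) ** 2 / (ns[j] - 1))
        p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
        out.append(GamesHowellComparison(group_a=i, group_b=j, md=float(md),
                                         t=float(t), df=float(df), p=p))
    return out
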