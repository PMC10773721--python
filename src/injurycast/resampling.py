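"""Three-step multiple resampling for severely imbalanced injury data.

The raw windows are ~1.3% injured, and injury counts differ strongly between
athletes.  Training sets are therefore rebuilt in three steps:

1. *Balanced per-athlete sampling* — every athlete with at least one injured
   window contributes exactly k injured and k uninjured windows (drawn with
   replacement when fewer are available), removing athlete bias.
2. *Controlled unbalanced subsampling* — a fixed number of injured samples
   (default 650) and ``round(n_injured / ratio)`` uninjured samples (default
   ratio 0.136 -> 4,779) are drawn, restoring a realistic but workable
   imbalance.
3. *SMOTETomek* — Tomek links (mutual opposite-class nearest neighbours) have
   their majority-class member removed, then SMOTE interpolation grows the
   minority class to the configured balance.

Resampling operates on flattened 8 x 10 window features (80 values) *before*
image encoding, so every synthetic sample is a valid time series and the
encodings' structural invariants survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

#: Step-2 defaults printed with the method: 650 injured samples at ratio 0.136.
DEFAULT_N_INJURED_TARGET = 650
DEFAULT_RATIO = 0.136


@dataclass
class ResamplingPlan:
    """Parameters of the three-step procedure.

    ``per_athlete_k=None`` derives k as ceil(mean injured windows per athlete)
    from the data.  ``smote_target_ratio`` is the minority:majority ratio
    SMOTE grows towards (1.0 fully balances).  ``smote_mode`` selects the
    interpolation direction: ``"standard"`` uses d + u*(d_n - d); ``"literal"``
    uses d + u*(d - d_n), extrapolating away from the neighbour.
    """

    per_athlete_k: int | None = None
    n_injured_target: int = DEFAULT_N_INJURED_TARGET
    ratio: float = DEFAULT_RATIO
    smote_k: int = 5
    smote_target_ratio: float = 1.0
    smote_mode: str = "standard"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio <= 1.0:
            raise ValueError("ratio must lie in (0, 1]")
        if self.n_injured_target < 1:
            raise ValueError("n_injured_target must be >= 1")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")
        if self.smote_mode not in ("standard", "literal"):
            raise ValueError("smote_mode must be 'standard' or 'literal'")


@dataclass
class SyntheticSample:
    """Provenance of one SMOTE-generated point: d_new on the segment d -> d_n."""

    parent: int
    neighbor: int
    u: float


@dataclass
class ResampledSet:
    X: np.ndarray
    y: np.ndarray
    provenance: dict = field(default_factory=dict)
    synthetic: list[SyntheticSample] = field(default_factory=list)


def _class_counts(y: np.ndarray) -> tuple[int, int]:
    y = np.asarray(y)
    return int((y == 1).sum()), int((y == 0).sum())


def balanced_per_athlete_sample(X: np.ndarray, y: np.ndarray,
                                athlete_ids: Sequence, k: int,
                                seed: int = 0) -> ResampledSet:
    """Step 1: k injured + k uninjured samples per athlete (1:1 classes).

    Athletes without any injured (or any uninjured) window are excluded and
    recorded; draws are with replacement whenever an athlete holds fewer than
    k samples of a class.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    X = np.asarray(X)
    y = np.asarray(y)
    athlete_ids = np.asarray(athlete_ids)
    rng = np.random.default_rng(seed)
    keep_idx: list[np.ndarray] = []
    excluded: list[str] = []
    for aid in np.unique(athlete_ids):
        mask = athlete_ids == aid
        inj = np.flatnonzero(mask & (y == 1))
        uninj = np.flatnonzero(mask & (y == 0))
        if inj.size == 0 or uninj.size == 0:
            excluded.append(str(aid))
            continue
        keep_idx.append(rng.choice(inj, size=k, replace=inj.size < k))
        keep_idx.append(rng.choice(uninj, size=k, replace=uninj.size < k))
    if not keep_idx:
        raise ValueError("no athlete has both injured and uninjured samples")
    idx = np.concatenate(keep_idx)
    n_inj, n_uninj = _class_counts(y[idx])
    return ResampledSet(
        X=X[idx].copy(), y=y[idx].copy(),
        provenance={"step": "balanced_per_athlete", "k": k,
                    "n_injured": n_inj, "n_uninjured": n_uninj,
                    "excluded_athletes": excluded},
    )


def unbalanced_subsample(X: np.ndarray, y: np.ndarray, n_injured_target: int,
                         ratio: float, seed: int = 0) -> ResampledSet:
    """Step 2: exactly ``n_injured_target`` injured and round(n/ratio) uninjured.

    Draws are without replacement when enough samples exist, with replacement
    otherwise.  Duplicates introduced by Step 1 may persist.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    X = np.asarray(X)
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty input set")
    rng = np.random.default_rng(seed)
    inj = np.flatnonzero(y == 1)
    uninj = np.flatnonzero(y == 0)
    n_uninjured_target = int(round(n_injured_target / ratio))
    pick_inj = rng.choice(inj, size=n_injured_target, replace=inj.size < n_injured_target)
    pick_uninj = rng.choice(uninj, size=n_uninjured_target,
                            replace=uninj.size < n_uninjured_target)
    idx = np.concatenate([pick_inj, pick_uninj])
    return ResampledSet(
        X=X[idx].copy(), y=y[idx].copy(),
        provenance={"step": "unbalanced_subsample",
                    "n_injured": n_injured_target,
                    "n_uninjured": n_uninjured_target, "ratio": ratio},
    )


def tomek_majority_removal(X: np.ndarray, y: np.ndarray) -> ResampledSet:
    """Step 3a: remove the majority-class member of every Tomek link.

    A Tomek link is a pair of opposite-class points that are each other's
    nearest neighbour (Euclidean distance).  Minority points are never
    removed, so the minority count is preserved and no count increases.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_inj, n_uninj = _class_counts(y)
    if n_inj == 0 or n_uninj == 0:
        raise ValueError("both classes must be present")
    minority_label = 1 if n_inj <= n_uninj else 0
    nn = NearestNeighbors(n_neighbors=2).fit(X)
    _, indices = nn.kneighbors(X)
    # first neighbour that is not the point itself
    nearest = np.where(indices[:, 0] == np.arange(len(X)), indices[:, 1], indices[:, 0])
    removed = []
    for i in range(len(X)):
        j = nearest[i]
        if y[i] != y[j] and nearest[j] == i:
            majority = i if y[i] != minority_label else j
            removed.append(majority)
    removed = sorted(set(removed))
    keep = np.setdiff1d(np.arange(len(X)), removed)
    n_inj2, n_uninj2 = _class_counts(y[keep])
    return ResampledSet(
        X=X[keep], y=y[keep],
        provenance={"step": "tomek_majority_removal", "n_removed": len(removed),
                    "removed_indices": removed,
                    "n_injured": n_inj2, "n_uninjured": n_uninj2},
    )


def smote_oversample(X: np.ndarray, y: np.ndarray, target_minority_count: int,
                     smote_k: int = 5, seed: int = 0,
                     mode: str = "standard") -> ResampledSet:
    """Step 3b: grow the minority class to ``target_minority_count`` by SMOTE.

    Each synthetic point interpolates between a minority sample d and one of
    its ``smote_k`` minority nearest neighbours d_n: d_new = d + u*(d_n - d)
    with u ~ Uniform[0, 1) (``mode="standard"``), or d + u*(d - d_n)
    (``mode="literal"``).  Provenance (parent, neighbour, u) is recorded for
    every synthetic sample.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_inj, n_uninj = _class_counts(y)
    minority_label = 1 if n_inj <= n_uninj else 0
    minority_idx = np.flatnonzero(y == minority_label)
    n_minority = minority_idx.size
    if n_minority <= smote_k:
        raise ValueError(
            f"minority count {n_minority} must exceed smote_k={smote_k}; use a smaller k"
        )
    n_new = max(0, target_minority_count - n_minority)
    rng = np.random.default_rng(seed)
    synthetic: list[SyntheticSample] = []
    if n_new > 0:
        minority_X = X[minority_idx]
        nn = NearestNeighbors(n_neighbors=smote_k + 1).fit(minority_X)
        _, neigh = nn.kneighbors(minority_X)  # column 0 is the point itself
        parents = rng.integers(0, n_minority, size=n_new)
        which = rng.integers(1, smote_k + 1, size=n_new)
        us = rng.uniform(0.0, 1.0, size=n_new)
        rows = []
        for p, w, u in zip(parents, which, us):
            d = minority_X[p]
            d_n = minority_X[neigh[p, w]]
            step = (d_n - d) if mode == "standard" else (d - d_n)
            rows.append(d + u * step)
            synthetic.append(SyntheticSample(parent=int(minority_idx[p]),
                                             neighbor=int(minority_idx[neigh[p, w]]),
                                             u=float(u)))
        X = np.concatenate([X, np.stack(rows)])
        y = np.concatenate([y, np.full(n_new, minority_label, dtype=y.dtype)])
    n_inj2, n_uninj2 = _class_counts(y)
    return ResampledSet(
        X=X, y=y, synthetic=synthetic,
        provenance={"step": "smote_oversample", "n_synthetic": n_new,
                    "n_injured": n_inj2, "n_uninjured": n_uninj2, "mode": mode},
    )


def multiple_resample(X: np.ndarray, y: np.ndarray, athlete_ids: Sequence,
                      plan: ResamplingPlan) -> ResampledSet:
    """Compose steps 1-3 under one plan; provenance holds counts per step.

    ``plan.per_athlete_k=None`` uses ceil(mean injured windows per athlete
    among athletes with at least one injury).
    """
    y = np.asarray(y)
    athlete_ids = np.asarray(athlete_ids)
    if (y == 1).sum() == 0:
        raise ValueError("cohort contains no injured samples")
    k = plan.per_athlete_k
    if k is None:
        per_athlete = [int((y[athlete_ids == a] == 1).sum()) for a in np.unique(athlete_ids)]
        with_injury = [c for c in per_athlete if c > 0]
        k = int(np.ceil(np.mean(with_injury)))
    step1 = balanced_per_athlete_sample(X, y, athlete_ids, k=k, seed=plan.seed)
    step2 = unbalanced_subsample(step1.X, step1.y, plan.n_injured_target,
                                 plan.ratio, seed=plan.seed + 1)
    step3a = tomek_majority_removal(step2.X, step2.y)
    n_majority = int((step3a.y == 0).sum())
    target = int(round(plan.smote_target_ratio * n_majority))
    step3b = smote_oversample(step3a.X, step3a.y, target_minority_count=target,
                              smote_k=plan.smote_k, seed=plan.seed + 2,
                              mode=plan.smote_mode)
    provenance = {
        "plan": {"per_athlete_k": k, "n_injured_target": plan.n_injured_target,
                 "ratio": plan.ratio, "smote_k": plan.smote_k,
                 "smote_target_ratio": plan.smote_target_ratio,
                 "smote_mode": plan.smote_mode, "seed": plan.seed},
        "steps": [step1.provenance, step2.provenance,
                  {k_: v for k_, v in step3a.provenance.items() if k_ != "removed_indices"},
                  step3b.provenance],
    }
    return ResampledSet(X=step3b.X, y=step3b.y, provenance=provenance,
                        synthetic=step3b.synthetic)
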