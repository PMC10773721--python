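"""Shapley-value feature attribution for the representation and classifier.

Contributions are estimated against a background (reference) set: a feature's
value is "present" (taken from the explained sample) or "absent" (taken from
a background sample), and its Shapley value averages its marginal effect on
the model output over feature coalitions.  With 10 or fewer features the
exact enumeration over all 2^F coalitions is used; otherwise a
permutation-sampling estimate.

Two surfaces are explained:

* variable -> latent: the importance of each of the 10 input variables
  (whole image channels, so pixel contributions are summed per channel by
  construction) for each of the 5 latent outputs of the encoder;
* latent -> risk: the importance of the 5 latent variables for the
  classifier's injury probability, normalized to relative importance.

Per-feature importance is the mean of absolute per-sample contributions
(mean of *signed* contributions available as a literal mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np

_CHUNK = 4096


@dataclass
class AttributionReport:
    """Shapley contributions plus their aggregated importances.

    ``shap_values`` has one row per explained sample and one column per
    feature; ``base_values`` is the model output with every feature absent.
    ``relative_importance`` sums to 1.
    """

    shap_values: np.ndarray
    base_values: np.ndarray
    importance: np.ndarray
    relative_importance: np.ndarray
    feature_names: list[str] = field(default_factory=list)


def _coalition_masks(n_features: int) -> tuple[np.ndarray, np.ndarray]:
    """All 2^F coalitions as boolean masks, plus per-coalition sizes."""
    idx = np.arange(2**n_features)
    masks = (idx[:, None] >> np.arange(n_features)) & 1
    return masks.astype(bool), masks.sum(axis=1)


def _shapley_weights(n_features: int) -> np.ndarray:
    """w[s] = s! (F-1-s)! / F! for coalition size s (excluding the feature)."""
    f = n_features
    return np.array([factorial(s) * factorial(f - 1 - s) / factorial(f)
                     for s in range(f)])


def _batched(f, X: np.ndarray) -> np.ndarray:
    outs = [np.asarray(f(X[i : i + _CHUNK]), dtype=float)
            for i in range(0, len(X), _CHUNK)]
    out = np.concatenate(outs) if outs else np.empty((0,))
    if not np.isfinite(out).all():
        raise ValueError("model returned non-finite outputs")
    return out


def _exact_single(v: np.ndarray, masks: np.ndarray, weights: np.ndarray,
                  sizes: np.ndarray, n_features: int) -> np.ndarray:
    """Shapley values from coalition values v (2^F,) by direct summation."""
    phi = np.zeros(n_features)
    idx = np.arange(len(v))
    for j in range(n_features):
        without = ~masks[:, j]
        s_idx = idx[without]
        phi[j] = np.sum(weights[sizes[without]] * (v[s_idx | (1 << j)] - v[s_idx]))
    return phi


def shapley_attribution(model, X: np.ndarray, background: np.ndarray,
                        n_permutations: int | None = None,
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Shapley contributions of each feature of each row of X.

    ``model`` maps an (M, F) array to M scalars.  Returns ``(shap_values,
    base_values)``; additivity holds: ``shap_values.sum(1) + base_values ==
    model(X)`` (exactly for the enumeration estimator, within Monte-Carlo
    error for permutation sampling).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.size == 0:
        raise ValueError("background set must be nonempty")
    n, f = X.shape
    if n_permutations is None and f <= 10:
        return _exact_vector(model, X, background)
    n_permutations = n_permutations or 128
    return _sampled_vector(model, X, background, n_permutations, seed)


def _exact_vector(model, X, background):
    n, f = X.shape
    nb = len(background)
    masks, sizes = _coalition_masks(f)
    weights = _shapley_weights(f)
    shap_values = np.zeros((n, f))
    base_values = np.zeros(n)
    for i in range(n):
        # (2^F * nB, F): sample values where the coalition includes the feature
        z = np.where(masks[:, None, :], X[i][None, None, :], background[None, :, :])
        out = _batched(model, z.reshape(-1, f)).reshape(len(masks), nb)
        v = out.mean(axis=1)
        shap_values[i] = _exact_single(v, masks, weights, sizes, f)
        base_values[i] = v[0]
    return shap_values, base_values


def _sampled_vector(model, X, background, n_permutations, seed):
    n, f = X.shape
    rng = np.random.default_rng(seed)
    shap_values = np.zeros((n, f))
    base_values = _batched(model, background).mean() * np.ones(n)
    for i in range(n):
        acc = np.zeros(f)
        for _ in range(n_permutations):
            order = rng.permutation(f)
            b = background[rng.integers(len(background))]
            z = b.copy()
            prev = float(_batched(model, z[None, :])[0])
            for j in order:
                z[j] = X[i, j]
                cur = float(_batched(model, z[None, :])[0])
                acc[j] += cur - prev
                prev = cur
        shap_values[i] = acc / n_permutations
    return shap_values, base_values


def importance(shap_values: np.ndarray, absolute: bool = True) -> np.ndarray:
    """Per-feature importance: mean over samples of (absolute) contributions."""
    sv = np.atleast_2d(np.asarray(shap_values, dtype=float))
    if sv.size == 0:
        raise ValueError("no contributions to aggregate")
    return np.abs(sv).mean(axis=0) if absolute else sv.mean(axis=0)


def relative_importance(imp: np.ndarray) -> np.ndarray:
    """Importance normalized to sum to 1 (all-zero input stays zero)."""
    imp = np.asarray(imp, dtype=float)
    total = imp.sum()
    return imp / total if total > 0 else imp


def _make_report(shap_values, base_values, absolute, names) -> AttributionReport:
    imp = importance(shap_values, absolute=absolute)
    return AttributionReport(
        shap_values=shap_values, base_values=base_values, importance=imp,
        relative_importance=relative_importance(np.abs(imp)),
        feature_names=list(names),
    )


def latent_variable_importance(dcae, classifier, stacks: np.ndarray,
                               background_stacks: np.ndarray,
                               variable_names=None, absolute: bool = True,
                               ) -> tuple[list[AttributionReport], AttributionReport]:
    """Attribution of both pipeline surfaces by exact channel-level Shapley.

    Surface A: for each latent output, the contribution of each of the 10
    input variables (a variable is present/absent as a whole image channel).
    Returns one report per latent, each with a 10-vector importance.

    Surface B: the contribution of the 5 latent variables to the classifier's
    predicted risk, with relative importances summing to 1.
    """
    if not getattr(dcae, "trained", False) or not getattr(classifier, "trained", False):
        raise RuntimeError("both the encoder and the classifier must be trained")
    stacks = np.asarray(stacks, dtype=float)
    background_stacks = np.asarray(background_stacks, dtype=float)
    if background_stacks.ndim != 4 or len(background_stacks) == 0:
        raise ValueError("background_stacks must be a nonempty (B, 8, 8, 10) array")
    n, h, w, n_channels = stacks.shape
    names = list(variable_names) if variable_names is not None else [
        f"var{v}" for v in range(n_channels)]

    masks, sizes = _coalition_masks(n_channels)
    weights = _shapley_weights(n_channels)
    nb = len(background_stacks)
    latent_dim = dcae.spec.latent_dim
    per_latent_sv = np.zeros((latent_dim, n, n_channels))
    per_latent_base = np.zeros((latent_dim, n))
    for i in range(n):
        # substitute whole channels from the background per coalition
        z = np.where(masks[:, None, None, None, :],
                     stacks[i][None, None, :, :, :],
                     background_stacks[None, :, :, :, :])
        out = _batched(dcae.encode, z.reshape(-1, h, w, n_channels))
        v = out.reshape(len(masks), nb, latent_dim).mean(axis=1)
        for latent in range(latent_dim):
            per_latent_sv[latent, i] = _exact_single(v[:, latent], masks, weights,
                                                     sizes, n_channels)
            per_latent_base[latent, i] = v[0, latent]
    surface_a = [_make_report(per_latent_sv[latent], per_latent_base[latent],
                              absolute, names)
                 for latent in range(latent_dim)]

    latents = dcae.encode(stacks)
    background_latents = dcae.encode(background_stacks)
    sv, base = shapley_attribution(lambda z: classifier.predict_proba(z),
                                   latents, background_latents)
    surface_b = _make_report(sv, base, absolute,
                             [f"latent_{k + 1}" for k in range(latent_dim)])
    return surface_a, surface_b


def heatmap_matrix(surface_a: list[AttributionReport]) -> np.ndarray:
    """Stack surface-A importances into a (latent x variable) matrix, each
    row normalized to relative importance for display."""
    return np.stack([r.relative_importance for r in surface_a])
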