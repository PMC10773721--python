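"""Time-series image encodings: Gramian angular fields, Markov transition
field, and recurrence plot.

Each univariate, [0, 1]-normalized series of length n is transformed into an
n x n matrix; applied per variable to an 8 x 10 window this yields an
8 x 8 x 10 image stack.

GASF/GADF first map the series into polar coordinates, theta_i =
arccos(x_i), r_i = t_i / N, then form cos(theta_i + theta_j) (summation
field) or sin(theta_i - theta_j) (difference field).  The original series
sits on the GASF main diagonal as cos(2 theta_i).  The MTF tabulates
first-order transition probabilities between Q value bins and spreads them
over all time-point pairs.  The recurrence plot thresholds pairwise
phase-space distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default number of Markov transition field bins.
DEFAULT_MTF_BINS = 5
#: Default recurrence threshold as a fraction of the maximum pairwise distance.
DEFAULT_RP_FRACTION = 0.2

ENCODING_METHODS = ("gasf", "gadf", "mtf", "rp")


@dataclass
class PolarSeries:
    """Polar-coordinate representation of a normalized series."""

    theta: np.ndarray  # angles in [0, pi]
    r: np.ndarray  # radii t_i / N, strictly increasing
    n: int


@dataclass
class AngularFieldMatrix:
    kind: str  # "gasf" | "gadf"
    values: np.ndarray


@dataclass
class MarkovModel:
    """Binned first-order Markov model of a series plus its field matrix.

    ``W[i, j]`` is the estimated probability that a point in bin i is followed
    by a point in bin j; populated rows sum to 1, unvisited bins leave
    all-zero rows.  ``M[k, l] = W[bin(x_k), bin(x_l)]``.
    """

    q: int
    bin_edges: np.ndarray
    W: np.ndarray
    M: np.ndarray
    bin_assignments: np.ndarray


@dataclass
class RecurrenceMatrix:
    epsilon: float
    values: np.ndarray  # binary n x n
    states: np.ndarray  # K x embedding_dim phase-space vectors


def to_polar(series: np.ndarray, tol: float = 1e-9) -> PolarSeries:
    """Map a [0, 1] series to polar coordinates (angle arccos, radius t/N).

    Values outside [0, 1] by more than ``tol`` raise (the series was not
    normalized); smaller excursions are clamped before arccos.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("series must be a non-empty 1-D array")
    if (x < -tol).any() or (x > 1.0 + tol).any():
        raise ValueError(
            f"series values outside [0, 1] (min {x.min():.3g}, max {x.max():.3g}); "
            "normalize before encoding"
        )
    x = np.clip(x, 0.0, 1.0)
    n = x.size
    theta = np.arccos(x)
    r = np.arange(1, n + 1, dtype=float) / n
    return PolarSeries(theta=theta, r=r, n=n)


def gasf(polar: PolarSeries) -> AngularFieldMatrix:
    """Gramian angular summation field: cos(theta_i + theta_j)."""
    values = np.cos(polar.theta[:, None] + polar.theta[None, :])
    return AngularFieldMatrix(kind="gasf", values=values)


def gadf(polar: PolarSeries) -> AngularFieldMatrix:
    """Gramian angular difference field: sin(theta_i - theta_j)."""
    values = np.sin(polar.theta[:, None] - polar.theta[None, :])
    return AngularFieldMatrix(kind="gadf", values=values)


def _bin_assign(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # right-closed at the top edge so x == 1 lands in the last bin
    idx = np.searchsorted(edges, x, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def mtf(series: np.ndarray, q: int = DEFAULT_MTF_BINS,
        binning: str = "uniform", transpose: bool = False) -> MarkovModel:
    """Markov transition field of a normalized series.

    ``binning="uniform"`` uses Q equal-width bins over [0, 1];
    ``binning="quantile"`` uses empirical quantile edges.  Bins never visited
    leave all-zero rows in W.  ``transpose`` flips the conditioning direction
    of the field matrix.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("series must be 1-D with length >= 2")
    if q < 2:
        raise ValueError("Q must be >= 2")
    if binning == "uniform":
        edges = np.linspace(0.0, 1.0, q + 1)
    elif binning == "quantile":
        edges = np.quantile(x, np.linspace(0.0, 1.0, q + 1))
        edges[0], edges[-1] = min(edges[0], x.min()), max(edges[-1], x.max())
    else:
        raise ValueError(f"unknown binning {binning!r}")
    bins = _bin_assign(x, edges)
    counts = np.zeros((q, q))
    np.add.at(counts, (bins[:-1], bins[1:]), 1.0)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(row_sums > 0, counts / row_sums, 0.0)
    M = W[np.ix_(bins, bins)]
    if transpose:
        M = M.T
    return MarkovModel(q=q, bin_edges=edges, W=W, M=M, bin_assignments=bins)


def recurrence_plot(series: np.ndarray, epsilon: float | None = None,
                    embedding_dim: int = 1, delay: int = 1,
                    epsilon_fraction: float = DEFAULT_RP_FRACTION) -> RecurrenceMatrix:
    """Binary recurrence plot: R_lm = 1 iff ||S_l - S_m|| < epsilon.

    Phase-space states are delay vectors (x_l, x_{l+delay}, ...,
    x_{l+(m-1)delay}); with the default dim 1, delay 1 the states are the
    scalar values themselves.  When ``epsilon`` is not given it defaults to
    ``epsilon_fraction`` times the maximum pairwise state distance (with a
    tiny positive floor so a constant series recurs everywhere).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if embedding_dim < 1 or delay < 1:
        raise ValueError("embedding_dim and delay must be >= 1")
    k = x.size - (embedding_dim - 1) * delay
    if k < 1:
        raise ValueError(
            f"embedding (dim {embedding_dim}, delay {delay}) longer than series of length {x.size}"
        )
    states = np.stack([x[i * delay : i * delay + k] for i in range(embedding_dim)], axis=1)
    dists = np.linalg.norm(states[:, None, :] - states[None, :, :], axis=2)
    if epsilon is None:
        epsilon = epsilon_fraction * float(dists.max())
        if epsilon <= 0.0:
            epsilon = np.finfo(float).tiny  # constant series: everything recurs
    elif epsilon <= 0.0:
        raise ValueError("epsilon must be > 0")
    values = (dists < epsilon).astype(float)
    return RecurrenceMatrix(epsilon=float(epsilon), values=values, states=states)


def encode_series(series: np.ndarray, method: str, **kwargs) -> np.ndarray:
    """Encode one normalized series with the named method, returning n x n."""
    if method == "gasf":
        return gasf(to_polar(series)).values
    if method == "gadf":
        return gadf(to_polar(series)).values
    if method == "mtf":
        return mtf(series, **kwargs).M
    if method == "rp":
        return recurrence_plot(series, **kwargs).values
    raise ValueError(f"unknown encoding method {method!r}; valid: {ENCODING_METHODS}")


def encode_window(matrix: np.ndarray, method: str, **kwargs) -> np.ndarray:
    """Encode an 8 x 10 normalized window into an 8 x 8 x 10 image stack.

    Channel v is the encoding of variable v's 8-step series; channel order
    matches variable order.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError(f"window must be 2-D, got shape {matrix.shape}")
    n, m = matrix.shape
    stack = np.empty((n, n, m))
    for v in range(m):
        stack[:, :, v] = encode_series(matrix[:, v], method, **kwargs)
    return stack


def encode_dataset(matrices: np.ndarray, method: str, **kwargs) -> np.ndarray:
    """Encode a batch of windows (N, 8, 10) into image stacks (N, 8, 8, 10)."""
    matrices = np.asarray(matrices, dtype=float)
    return np.stack([encode_window(w, method, **kwargs) for w in matrices])


def export_channels_png(stack: np.ndarray, path_prefix: str,
                        variable_names=None, cmap: str = "viridis") -> list[str]:
    """Write each channel of an image stack to a PNG for visual inspection."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    n_channels = stack.shape[2]
    names = variable_names or [f"var{v}" for v in range(n_channels)]
    for v in range(n_channels):
        fig, ax = plt.subplots(figsize=(2.5, 2.5))
        ax.imshow(stack[:, :, v], cmap=cmap)
        ax.set_title(names[v], fontsize=8)
        ax.axis("off")
        out = f"{path_prefix}_{names[v]}.png"
        fig.savefig(out, dpi=100, bbox_inches="tight")
        plt.close(fig)
        paths.append(out)
    return paths
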