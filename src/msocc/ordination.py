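"""Correspondence analysis and resistant-fit Procrustes comparison.

Community structure in a sites x species presence-absence matrix is
summarized by correspondence analysis (CA): the singular value
decomposition of the matrix of standardized chi-square residuals, with
sites and species both expressed in principal coordinates. Two
ordinations of the same community (e.g. observed vs. threshold-informed)
are then superimposed by a resistant-fit Procrustes procedure — the
translation, rotation and dilation are estimated by repeated medians
over landmark pairs, so a minority of strongly displaced landmarks
cannot drag the fit — and the per-landmark residual lengths show which
sites and which species moved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd


# --------------------------------------------------------------------------
# correspondence analysis
# --------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    """Principal-coordinate scores from a correspondence analysis."""

    row_scores: pd.DataFrame  # sites x axes
    col_scores: pd.DataFrame  # species x axes
    singular_values: np.ndarray
    inertia: float
    dropped_rows: list = field(default_factory=list)
    dropped_cols: list = field(default_factory=list)


def correspondence_analysis(M: pd.DataFrame, n_axes: int = 2) -> OrdinationResult:
    """Correspondence analysis of a non-negative matrix.

    With ``P = M / grand total``, row masses ``r`` and column masses
    ``c``, the standardized residual matrix

        S = diag(r)^(-1/2) (P - r c^T) diag(c)^(-1/2)

    is decomposed as ``S = U Sigma V^T``; principal row coordinates are
    ``diag(r)^(-1/2) U Sigma`` and column coordinates
    ``diag(c)^(-1/2) V Sigma``. Total inertia (the chi-square statistic
    over the grand total) equals the sum of squared singular values.
    All-zero rows and columns are dropped with a warning; ``n_axes``
    beyond the rank is truncated with a warning.
    """
    M = pd.DataFrame(M)
    X = M.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("matrix must be non-negative")
    if X.sum() == 0:
        raise ValueError("matrix has no positive entries")

    row_keep = X.sum(axis=1) > 0
    col_keep = X.sum(axis=0) > 0
    dropped_rows = list(M.index[~row_keep])
    dropped_cols = list(M.columns[~col_keep])
    if dropped_rows or dropped_cols:
        warnings.warn(
            f"dropping all-zero rows {dropped_rows} and columns {dropped_cols}"
        )
        X = X[np.ix_(row_keep, col_keep)]
    index = M.index[row_keep]
    columns = M.columns[col_keep]

    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)

    rank = int(np.sum(sv > 1e-12))
    if n_axes > rank:
        warnings.warn(f"requested {n_axes} axes but rank is {rank}; truncating")
    d = min(n_axes, max(rank, 1))
    F = (U[:, :d] * sv[:d]) / np.sqrt(r)[:, None]
    G = (Vt.T[:, :d] * sv[:d]) / np.sqrt(c)[:, None]
    axes = [f"axis{k + 1}" for k in range(d)]
    return OrdinationResult(
        row_scores=pd.DataFrame(F, index=index, columns=axes),
        col_scores=pd.DataFrame(G, index=columns, columns=axes),
        singular_values=sv[:rank] if rank else sv[:1] * 0.0,
        inertia=float(np.sum(sv**2)),
        dropped_rows=dropped_rows,
        dropped_cols=dropped_cols,
    )


# --------------------------------------------------------------------------
# configuration alignment and resistant fit
# --------------------------------------------------------------------------


def _common_landmarks(X: pd.DataFrame, Y: pd.DataFrame):
    common = X.index.intersection(Y.index)
    if len(common) == 0:
        raise ValueError("configurations share no landmarks")
    if len(common) < len(X.index) or len(common) < len(Y.index):
        warnings.warn(
            f"dropping landmarks absent from one configuration; keeping {len(common)}"
        )
    return X.loc[common], Y.loc[common]


def align_configurations(X: pd.DataFrame, Y: pd.DataFrame) -> pd.DataFrame:
    """Resolve the arbitrary axis signs of an ordination.

    CA axes are determined only up to sign. Among all 2^d sign patterns
    applied to the axes of ``Y``, returns the one minimizing the total
    squared distance to ``X`` (landmarks matched by id).
    """
    if X.shape[1] != Y.shape[1]:
        raise ValueError("configurations must share dimensionality")
    if X.shape[1] > 3:
        raise ValueError("sign search supported for d <= 3")
    Xc, Yc = _common_landmarks(X, Y)
    best, best_ss = None, np.inf
    for signs in product((1.0, -1.0), repeat=X.shape[1]):
        ss = float(((Xc.to_numpy() - Yc.to_numpy() * np.array(signs)) ** 2).sum())
        if ss < best_ss:
            best, best_ss = np.array(signs), ss
    flipped = Y * best
    flipped.attrs["axis_signs"] = best.tolist()
    return flipped


@dataclass
class ProcrustesFit:
    """A similarity transform ``Y ~ scale * R(angle) X + translation``.

    ``residuals`` holds, per landmark, the Euclidean distance between
    the comparison configuration and the transformed reference.
    """

    scale: float
    angle: float  # radians, counter-clockwise
    rotation: np.ndarray
    translation: np.ndarray
    residuals: pd.Series
    n_pairs_used: int

    @property
    def angle_degrees(self) -> float:
        return float(np.degrees(self.angle))

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = self.scale * (X.to_numpy() @ self.rotation.T) + self.translation
        return pd.DataFrame(out, index=X.index, columns=X.columns)


def _repeated_median(E: np.ndarray) -> float:
    """Median over rows of the median over valid (non-NaN) columns."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        row_med = np.nanmedian(E, axis=1)
        return float(np.nanmedian(row_med))


def resistant_fit_procrustes(X: pd.DataFrame, Y: pd.DataFrame) -> ProcrustesFit:
    """Repeated-median Procrustes superimposition in the plane.

    For every ordered landmark pair the complex ratio of the difference
    vectors ``(Y_m - Y_l) / (X_m - X_l)`` votes for the dilation (its
    modulus) and the rotation (its argument); both are aggregated by the
    repeated median (median over the partner landmark, then over the
    anchor landmark), which tolerates arbitrary displacement of just
    under half the landmarks. The translation is the coordinatewise
    median of ``Y - scale * R X``. Angle votes are unwrapped around a
    provisional least-squares rotation so near-±pi estimates do not
    split into two clusters.

    Pairs coincident in the reference (zero length in ``X``) are
    excluded from both medians; pairs coincident in ``Y`` only are
    excluded from the angle median.
    """
    Xc, Yc = _common_landmarks(X, Y)
    if Xc.shape[1] != 2 or Yc.shape[1] != 2:
        raise ValueError("resistant fit is implemented for planar configurations")
    n = len(Xc)
    if n < 3:
        raise ValueError("need at least three landmarks")

    x = Xc.iloc[:, 0].to_numpy() + 1j * Xc.iloc[:, 1].to_numpy()
    y = Yc.iloc[:, 0].to_numpy() + 1j * Yc.iloc[:, 1].to_numpy()
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    valid_x = np.abs(dx) > 0
    np.fill_diagonal(valid_x, False)
    if not valid_x.any():
        raise ValueError("all landmark pairs coincide in the reference")

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid_x, dy / np.where(valid_x, dx, 1.0), np.nan)
    scale = _repeated_median(np.abs(ratio))

    # provisional least-squares rotation of the centered configurations
    xc = x - x.mean()
    yc = y - y.mean()
    theta0 = float(np.angle(np.sum(np.conj(xc) * yc)))
    angles = np.where(
        valid_x & (np.abs(dy) > 0), np.angle(ratio), np.nan
    )
    unwrapped = theta0 + np.angle(np.exp(1j * (angles - theta0)))
    angle = _repeated_median(unwrapped)
    if np.isnan(angle):  # every pair coincident in Y: pure collapse, no rotation
        angle = 0.0

    rot = scale * np.exp(1j * angle)
    shift = y - rot * x
    translation = np.array(
        [float(np.median(shift.real)), float(np.median(shift.imag))]
    )
    fitted = rot * x + (translation[0] + 1j * translation[1])
    residuals = pd.Series(np.abs(y - fitted), index=Xc.index, name="residual")

    R = np.array(
        [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
    )
    return ProcrustesFit(
        scale=float(scale),
        angle=float(angle),
        rotation=R,
        translation=translation,
        residuals=residuals,
        n_pairs_used=int(valid_x.sum()),
    )
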