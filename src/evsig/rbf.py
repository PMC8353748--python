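"""Radial-basis-function (RBF) compression of size-distribution curves.

A normalized curve is treated as noisy samples of an unknown function and
approximated by a fixed number of Gaussian radial basis functions,

    f(x) ~ bias + sum_j  c_j * exp(-(x - t_j)^2 / (2 w_j^2)),

with centers ``t_j``, widths ``w_j`` and coefficients ``c_j``.  The fitted
coefficients are an implicit, fixed-length description of the curve and are
used downstream as machine-learning features (30 RBFs by default, far fewer
than the curve's bins).

Two center-selection modes are provided:

``"ols"``
    Greedy forward (orthogonal-least-squares style) selection of centers from
    the curve's own grid points, one curve at a time.
``"grid"``
    Centers on a fixed uniform grid over the support.  Because the grid
    depends only on the support and the number of centers, every sample in a
    cohort shares the same basis, making coefficient positions comparable
    across samples.  This is the default for cohort feature extraction.

Widths follow a scale-adaptive rule (per-center width proportional to the
distance to the nearest other center) and coefficients are solved by
ridge-regularized least squares with a tiny penalty for numerical stability.
Everything is deterministic given the inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .nta import SizeDistributionCurve, normalize_curve

__all__ = [
    "RBFModel",
    "fit_rbf",
    "reconstruct",
    "features",
    "shared_centers",
    "compress_cohort",
    "relative_l2_error",
    "DEFAULT_N_RBF",
]

DEFAULT_N_RBF = 30
_DEFAULT_RIDGE = 1e-8


@dataclass(frozen=True)
class RBFModel:
    """A fitted Gaussian RBF approximation of one curve."""

    centers: np.ndarray
    widths: np.ndarray
    coefficients: np.ndarray
    bias: float
    training_rmse: float
    sample_id: str = ""
    ill_conditioned: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        w = np.asarray(self.widths, dtype=float)
        a = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "widths", w)
        object.__setattr__(self, "coefficients", a)
        if not (c.shape == w.shape == a.shape) or c.ndim != 1:
            raise ValidationError("centers, widths, coefficients must share one shape")
        if np.any(w <= 0):
            raise ValidationError("widths must be positive")
        if self.training_rmse < 0:
            raise ValidationError("training_rmse must be nonnegative")

    @property
    def n_rbf(self) -> int:
        return int(self.centers.size)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        for k in ("centers", "widths", "coefficients"):
            d[k] = list(map(float, d[k]))
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RBFModel":
        d = json.loads(Path(path).read_text())
        return cls(
            centers=np.asarray(d["centers"]),
            widths=np.asarray(d["widths"]),
            coefficients=np.asarray(d["coefficients"]),
            bias=float(d["bias"]),
            training_rmse=float(d["training_rmse"]),
            sample_id=d.get("sample_id", ""),
            ill_conditioned=bool(d.get("ill_conditioned", False)),
        )


def _design(x: np.ndarray, centers: np.ndarray, widths: np.ndarray) -> np.ndarray:
    z = (x[:, None] - centers[None, :]) / widths[None, :]
    return np.exp(-0.5 * z * z)


def _nearest_neighbor_widths(centers: np.ndarray, span: float, scale: float) -> np.ndarray:
    if centers.size == 1:
        return np.asarray([scale * span / 2.0])
    d = np.abs(centers[:, None] - centers[None, :])
    np.fill_diagonal(d, np.inf)
    return scale * d.min(axis=1)


def _greedy_centers(
    x: np.ndarray, y: np.ndarray, n_rbf: int, width: float
) -> np.ndarray:
    """Greedy forward selection of centers from the grid points of the curve.

    At each step the candidate whose kernel column most reduces the residual
    sum of squares (after orthogonalization against the selected columns) is
    added; ties go to the lowest grid index.
    """
    candidates = _design(x, x, np.full_like(x, width))  # column j: kernel at x_j
    # orthogonalize against the constant (bias) direction first
    q = [np.full_like(y, 1.0 / np.sqrt(y.size))]
    resid = y - q[0] * (q[0] @ y)
    cand = candidates - q[0][:, None] * (q[0] @ candidates)[None, :]
    chosen: list[int] = []
    for _ in range(n_rbf):
        norms = np.einsum("ij,ij->j", cand, cand)
        gains = np.zeros(x.size)
        ok = norms > 1e-12
        gains[ok] = (resid @ cand[:, ok]) ** 2 / norms[ok]
        gains[chosen] = -np.inf
        j = int(np.argmax(gains))  # argmax returns the first (lowest) index on ties
        chosen.append(j)
        qj = cand[:, j] / np.sqrt(norms[j])
        resid = resid - qj * (qj @ resid)
        cand = cand - qj[:, None] * (qj @ cand)[None, :]
    return np.sort(x[chosen])


def fit_rbf(
    curve: SizeDistributionCurve,
    n_rbf: int = DEFAULT_N_RBF,
    seed: int = 0,
    centers: Sequence[float] | None = None,
    widths: Sequence[float] | None = None,
    width_scale: float = 1.0,
    ridge: float = _DEFAULT_RIDGE,
    center_rule: str = "ols",
) -> RBFModel:
    """Fit an RBF model to one curve by regularized least squares.

    When ``centers`` (and optionally ``widths``) are given they are used as
    is; otherwise centers come from ``center_rule`` ("ols" greedy selection
    or a uniform "grid") and widths from the nearest-neighbor rule scaled by
    ``width_scale``.  The fit is deterministic given the inputs (``seed`` is
    accepted for interface symmetry; no randomness is involved).
    """
    del seed  # deterministic fit
    if n_rbf < 1:
        raise ValidationError("n_rbf must be >= 1")
    x = curve.sizes
    y = curve.values
    if centers is None and x.size < n_rbf + 1:
        raise ValidationError(
            f"curve has {x.size} bins; need at least n_rbf+1 = {n_rbf + 1}"
        )
    span = float(x[-1] - x[0])
    if centers is not None:
        centers = np.sort(np.asarray(centers, dtype=float))
        n_rbf = centers.size
    elif center_rule == "grid":
        centers = np.linspace(x[0], x[-1], n_rbf)
    elif center_rule == "ols":
        centers = _greedy_centers(x, y, n_rbf, width=width_scale * span / max(n_rbf, 2))
    else:
        raise ValidationError(f"unknown center_rule {center_rule!r}")
    if widths is not None:
        widths = np.asarray(widths, dtype=float)
        if widths.size == 1:
            widths = np.full(n_rbf, widths.item())
        if widths.shape != centers.shape:
            raise ValidationError("widths must match centers in length")
    else:
        widths = _nearest_neighbor_widths(centers, span, width_scale)

    phi = _design(x, centers, widths)
    design = np.column_stack([phi, np.ones_like(y)])
    # ridge on the kernel coefficients only, not the bias
    penalty = np.sqrt(ridge) * np.eye(n_rbf + 1)
    penalty[-1, -1] = 0.0
    aug_a = np.vstack([design, penalty])
    aug_b = np.r_[y, np.zeros(n_rbf + 1)]
    sol, _, rank, sv = np.linalg.lstsq(aug_a, aug_b, rcond=None)
    ill = bool(rank < n_rbf + 1 or (sv.size and sv[0] / max(sv[-1], 1e-300) > 1e12))
    fitted = design @ sol
    rmse = float(np.sqrt(np.mean((y - fitted) ** 2)))
    return RBFModel(
        centers=centers,
        widths=widths,
        coefficients=sol[:-1],
        bias=float(sol[-1]),
        training_rmse=rmse,
        sample_id=curve.sample_id,
        ill_conditioned=ill,
    )


def reconstruct(model: RBFModel, sizes: Sequence[float]) -> np.ndarray:
    """Evaluate the fitted RBF expansion at the given diameters."""
    x = np.asarray(sizes, dtype=float)
    return _design(x, model.centers, model.widths) @ model.coefficients + model.bias


def features(model: RBFModel) -> np.ndarray:
    """Coefficient vector in ascending-center order (the ML feature vector)."""
    order = np.argsort(model.centers, kind="stable")
    return model.coefficients[order]


def relative_l2_error(model: RBFModel, curve: SizeDistributionCurve) -> float:
    """Relative L2 reconstruction error of the model on a curve's grid."""
    yhat = reconstruct(model, curve.sizes)
    denom = float(np.linalg.norm(curve.values))
    if denom == 0:
        raise ValidationError("cannot measure relative error on an all-zero curve")
    return float(np.linalg.norm(curve.values - yhat) / denom)


def shared_centers(
    curves: Iterable[SizeDistributionCurve], n_rbf: int = DEFAULT_N_RBF
) -> np.ndarray:
    """Uniform center grid over the pooled support of a set of curves."""
    curves = list(curves)
    if not curves:
        raise ValidationError("need at least one curve")
    lo = min(float(c.sizes[0]) for c in curves)
    hi = max(float(c.sizes[-1]) for c in curves)
    return np.linspace(lo, hi, n_rbf)


def compress_cohort(
    curves: Iterable[SizeDistributionCurve],
    n_rbf: int = DEFAULT_N_RBF,
    width_scale: float = 1.0,
    normalize: bool = True,
    ridge: float = _DEFAULT_RIDGE,
) -> pd.DataFrame:
    """Compress a cohort of curves into an (n_samples x n_rbf) feature table.

    Uses a shared uniform center grid over the pooled support so that the
    j-th coefficient refers to the same diameter for every sample.  Curves
    are area-normalized first by default, so features describe the shape of
    the distribution and not its overall concentration.
    """
    curves = list(curves)
    centers = shared_centers(curves, n_rbf)
    span = float(centers[-1] - centers[0]) if n_rbf > 1 else 1.0
    widths = _nearest_neighbor_widths(centers, span, width_scale)
    rows = {}
    for c in curves:
        cc = normalize_curve(c) if normalize else c
        m = fit_rbf(cc, centers=centers, widths=widths, ridge=ridge)
        rows[cc.sample_id] = features(m)
    cols = [f"rbf_{i:02d}" for i in range(n_rbf)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
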