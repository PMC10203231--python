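"""Mass-univariate ordinary-least-squares engine.

Fits one OLS model per voxel with a shared design matrix (task/respiratory
regressors plus nuisance: constant, drift, motion), and derives one-sided
t/p maps, percent-signal-change (PSC) maps and thresholded maps from the fit.

PSC convention: for contrast weights ``w``,

    psc = 100 * (w . beta) * peak_height(w-weighted regressor) / beta_constant

where the peak height is taken from the pre-sampling (fine-grid) regressor so
that the value is the peak percent excursion of the fitted response relative
to the voxel baseline. An alternative raw-beta-ratio convention
(``scale_by_peak=False``) is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import ndimage
from scipy import stats as st

from .kernels import Regressor
from .runs import BoldRun

__all__ = [
    "DesignMatrix",
    "GlmResult",
    "StatMap",
    "PscMap",
    "make_design",
    "fit_glm",
    "contrast_t",
    "percent_signal_change",
    "threshold_map",
    "smooth_run",
]

log = logging.getLogger(__name__)


@dataclass
class DesignMatrix:
    """Column-labelled regressor matrix aligned to a run's volume times.

    Exactly one column must be named ``"constant"``; column names are unique;
    the matrix must be full column rank (checked at fit time). ``regressors``
    retains the :class:`~cvrkit.kernels.Regressor` objects for columns of
    interest so PSC scaling can recover peak heights.
    """

    values: np.ndarray
    names: list[str]
    tr: float
    regressors: dict[str, Regressor] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) != self.values.shape[1]:
            raise ValueError("one name per design column required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("design column names must be unique")
        if self.names.count("constant") != 1:
            raise ValueError("design must contain exactly one 'constant' column")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def column_index(self, name: str) -> int:
        return self.names.index(name)

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        """Build a contrast vector from a {column name: weight} mapping."""
        w = np.zeros(len(self.names))
        for name, wt in weights.items():
            w[self.column_index(name)] = wt
        return w

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)


@dataclass
class GlmResult:
    """Per-voxel OLS estimates over the analysis mask.

    ``betas`` has shape (n_mask_voxels, n_columns); ``sigma2`` is the
    residual variance with ``dof = n_volumes - rank(design)``.
    """

    betas: np.ndarray
    sigma2: np.ndarray
    dof: int
    design: DesignMatrix
    mask: np.ndarray
    xtx_inv: np.ndarray = field(repr=False, default=None)

    def unmask(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter per-voxel values back onto the 3D grid."""
        out = np.full(self.mask.shape, fill, dtype=float)
        out[self.mask] = values
        return out


@dataclass
class StatMap:
    """Per-voxel t statistic with one-sided upper-tail p, over ``mask``."""

    t: np.ndarray
    p: np.ndarray
    contrast: np.ndarray
    dof: int
    mask: np.ndarray

    def volume(self, which: str = "t", fill: float = np.nan) -> np.ndarray:
        out = np.full(self.mask.shape, fill)
        out[self.mask] = getattr(self, which)
        return out


@dataclass
class PscMap:
    """Per-voxel percent signal change (%) over ``mask``."""

    psc: np.ndarray
    contrast: np.ndarray
    baseline: np.ndarray
    mask: np.ndarray

    def volume(self, fill: float = np.nan) -> np.ndarray:
        out = np.full(self.mask.shape, fill)
        out[self.mask] = self.psc
        return out


def make_design(
    regressors: list[Regressor],
    n_volumes: int,
    tr: float,
    motion: np.ndarray | None = None,
    drift: str = "linear",
    highpass_cutoff: float = 128.0,
) -> DesignMatrix:
    """Assemble a design matrix from regressors of interest plus nuisance.

    Nuisance set: a constant column, a drift set (``"linear"`` adds a single
    linear trend; ``"cosine"`` adds a discrete-cosine high-pass basis with the
    given cutoff in seconds; ``"none"`` adds nothing), and optional motion
    columns (n_volumes x 6).
    """
    cols = [r.samples for r in regressors]
    names = [r.name for r in regressors]
    cols.append(np.ones(n_volumes))
    names.append("constant")
    t = np.arange(n_volumes, dtype=float)
    if drift == "linear":
        cols.append(t - t.mean())
        names.append("drift_linear")
    elif drift == "cosine":
        duration = n_volumes * tr
        order = int(np.floor(2 * duration / highpass_cutoff))
        for k in range(1, max(order, 0) + 1):
            cols.append(np.cos(np.pi * k * (t + 0.5) / n_volumes))
            names.append(f"drift_cos{k}")
    elif drift != "none":
        raise ValueError(f"unknown drift spec {drift!r}")
    if motion is not None:
        motion = np.asarray(motion, float)
        if motion.shape != (n_volumes, 6):
            raise ValueError("motion must be an (n_volumes, 6) array")
        for j in range(6):
            m = motion[:, j]
            cols.append(m - m.mean())
            names.append(f"motion{j + 1}")
    values = np.column_stack(cols)
    return DesignMatrix(values=values, names=names, tr=tr, regressors={r.name: r for r in regressors})


def fit_glm(run: BoldRun, design: DesignMatrix) -> GlmResult:
    """Fit the per-voxel OLS model Y = X b + e over the run's mask.

    Uses a QR factorization of the (shared) design, so betas are the exact
    normal-equation solution computed stably. Raises on rank deficiency,
    naming the dependent columns.
    """
    X = design.values
    if X.shape[0] != run.n_volumes:
        raise ValueError(
            f"design has {X.shape[0]} rows but run has {run.n_volumes} volumes"
        )
    if not run.mask.any():
        raise ValueError("empty analysis mask")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        dep = _dependent_columns(X, design.names)
        raise ValueError(f"design matrix is rank deficient; dependent columns: {dep}")
    Y = run.data[run.mask].T.astype(float)  # (T, V)
    Q, R = np.linalg.qr(X)
    betas = sla.solve_triangular(R, Q.T @ Y)  # (k, V)
    resid = Y - X @ betas
    dof = run.n_volumes - rank
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = sla.solve_triangular(R, sla.solve_triangular(R.T, np.eye(R.shape[0]), lower=True))
    return GlmResult(
        betas=betas.T,
        sigma2=sigma2,
        dof=dof,
        design=design,
        mask=run.mask,
        xtx_inv=xtx_inv,
    )


def _dependent_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[piv[i]] for i in range(len(names)) if i >= np.sum(diag > tol)]


def contrast_t(result: GlmResult, weights) -> StatMap:
    """One-sided t map for the contrast ``w``.

    t = (w.beta) / sqrt(sigma2 * w' (X'X)^-1 w); p is the upper-tail
    probability from Student's t with ``result.dof`` degrees of freedom.
    Voxels with zero residual variance *and* zero effect are reported as
    t = 0; zero-variance voxels with nonzero effect get +/- inf t and p of
    0 or 1 (these arise only in noiseless synthetic data).
    """
    w = np.asarray(weights, float)
    if w.size != result.betas.shape[1]:
        raise ValueError("contrast length must equal the number of design columns")
    effect = result.betas @ w
    var_scale = float(w @ result.xtx_inv @ w)
    se = np.sqrt(result.sigma2 * var_scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / np.where(se > 0, se, 1.0), np.where(effect == 0, 0.0, np.sign(effect) * np.inf))
    p = st.t.sf(t, result.dof)
    return StatMap(t=t, p=p, contrast=w, dof=result.dof, mask=result.mask)


def percent_signal_change(result: GlmResult, weights, scale_by_peak: bool = True) -> PscMap:
    """Percent-signal-change map for the contrast ``w``.

    With ``scale_by_peak`` the contrast estimate is multiplied by the peak
    height of the w-weighted fine-grid regressor, so the map reads as peak %
    excursion relative to the voxel baseline (constant-term beta). Voxels
    with non-positive baseline are removed from the map's mask.
    """
    w = np.asarray(weights, float)
    design = result.design
    const_idx = design.column_index("constant")
    baseline = result.betas[:, const_idx]
    effect = result.betas @ w
    if scale_by_peak:
        effect = effect * _weighted_peak_height(design, w)
    good = baseline > 0
    if not good.all():
        log.info("percent_signal_change: masking %d voxels with baseline <= 0", int((~good).sum()))
    mask = result.mask.copy()
    mask[result.mask] = good
    with np.errstate(divide="ignore", invalid="ignore"):
        psc = 100.0 * effect[good] / baseline[good]
    return PscMap(psc=psc, contrast=w, baseline=baseline[good], mask=mask)


def _weighted_peak_height(design: DesignMatrix, w: np.ndarray) -> float:
    """Peak |amplitude| of the weighted combination of interest regressors."""
    combo = None
    for j, name in enumerate(design.names):
        if w[j] == 0:
            continue
        reg = design.regressors.get(name)
        if reg is None or reg.highres is None:
            raise ValueError(
                f"contrast weights a column ({name!r}) with no stored regressor; "
                "peak-height PSC scaling needs the fine-grid regressor"
            )
        combo = w[j] * reg.highres if combo is None else combo + w[j] * reg.highres
    if combo is None:
        raise ValueError("contrast selects no columns")
    return float(np.max(np.abs(combo)))


def threshold_map(stat: StatMap, psc: PscMap, alpha: float = 0.001):
    """Keep PSC only at voxels significant at the one-sided level ``alpha``.

    Returns ``(masked PscMap, n_retained)``.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    sig3d = np.zeros(stat.mask.shape, bool)
    sig3d[stat.mask] = stat.p < alpha
    joint = sig3d & psc.mask
    keep_in_psc = joint[psc.mask]
    out = PscMap(
        psc=psc.psc[keep_in_psc],
        contrast=psc.contrast,
        baseline=psc.baseline[keep_in_psc],
        mask=joint,
    )
    return out, int(joint.sum())


def smooth_run(run: BoldRun, fwhm_mm: float) -> BoldRun:
    """Gaussian spatial smoothing (FWHM in mm), applied volume-wise.

    Voxel sizes are taken from the affine. Used in gas-challenge mode;
    breath-hold mode runs unsmoothed.
    """
    voxdims = np.sqrt((run.affine[:3, :3] ** 2).sum(axis=0))
    sigma_vox = (fwhm_mm / np.sqrt(8 * np.log(2))) / voxdims
    out = np.empty_like(run.data, dtype=float)
    for t in range(run.n_volumes):
        out[..., t] = ndimage.gaussian_filter(run.data[..., t].astype(float), sigma=sigma_vox)
    return BoldRun(data=out, tr=run.tr, mask=run.mask, affine=run.affine, meta=dict(run.meta))
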