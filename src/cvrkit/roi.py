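"""Atlas-ROI coupling between task response magnitude and CVR.

Per subject, thresholded task percent-signal-change maps and CVR maps are
averaged over each atlas parcel using only voxels significant in *both*
maps. Pooling subjects, each ROI gets an ordinary least-squares regression
of task PSC on the CVR measure, preceded by two outlier passes (a mean-
absolute-deviation filter on the CVR values, then a per-coordinate
standard-deviation filter on the pairs) and a minimum-subjects rule.
Benjamini-Hochberg FDR control is applied across the ROI family of each
task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st
from statsmodels.stats.multitest import multipletests

from .glm import PscMap
from .phantom import AtlasPhantom

__all__ = [
    "RoiSample",
    "RoiRegressionResult",
    "extract_roi_samples",
    "mad_filter",
    "sd_filter",
    "roi_regressions",
    "summarize",
]


@dataclass
class RoiSample:
    """One subject's averaged PSC/CVR in one ROI."""

    subject: int | str
    roi: int
    task_psc: float
    cvr_value: float
    n_voxels: int


@dataclass
class RoiRegressionResult:
    """Per-ROI OLS of task PSC on CVR across subjects."""

    roi: int
    slope: float
    intercept: float
    r2: float
    p: float
    n: int
    excluded_outliers: int
    fdr_significant: bool = False
    slope_stderr: float = float("nan")

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for the slope."""
        tcrit = st.t.ppf(0.5 + level / 2, self.n - 2)
        h = tcrit * self.slope_stderr
        return (self.slope - h, self.slope + h)


def extract_roi_samples(
    task_psc: PscMap,
    cvr_map,
    atlas: AtlasPhantom,
    subject,
) -> list[RoiSample]:
    """Average task PSC and CVR over each ROI's jointly significant voxels.

    ``task_psc`` and ``cvr_map`` must already be thresholded (their masks
    encode the significant voxels). Only voxels significant in both maps
    contribute; ROIs whose intersection is empty are omitted.
    """
    if cvr_map.mask.shape != atlas.label_volume.shape or task_psc.mask.shape != atlas.label_volume.shape:
        raise ValueError("atlas and maps must share a grid")
    joint = task_psc.mask & cvr_map.mask
    task_vol = task_psc.volume()
    cvr_vol = cvr_map.volume()
    out = []
    for roi in atlas.label_table:
        sel = joint & (atlas.label_volume == roi)
        n = int(sel.sum())
        if n == 0:
            continue
        out.append(
            RoiSample(
                subject=subject,
                roi=roi,
                task_psc=float(task_vol[sel].mean()),
                cvr_value=float(cvr_vol[sel].mean()),
                n_voxels=n,
            )
        )
    return out


def samples_to_frame(samples: list[RoiSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": [s.subject for s in samples],
            "roi": [s.roi for s in samples],
            "task_psc": [s.task_psc for s in samples],
            "cvr_value": [s.cvr_value for s in samples],
            "n_voxels": [s.n_voxels for s in samples],
        }
    )


def mad_filter(values, k: float = 3.0, center: str = "mean"):
    """Single-pass mean-absolute-deviation outlier filter.

    Removes values whose absolute deviation from the center (sample mean by
    default; ``center="median"`` for the median-centred convention) exceeds
    ``k`` times the mean absolute deviation about that center. If all values
    are identical nothing is removed.

    Returns ``(retained values, excluded indices)``.
    """
    v = np.asarray(values, float)
    if v.size < 3:
        raise ValueError("mad_filter needs at least 3 values")
    c = np.mean(v) if center == "mean" else np.median(v)
    dev = np.abs(v - c)
    mad = dev.mean()
    if mad == 0:
        return v, np.array([], int)
    bad = dev > k * mad
    return v[~bad], np.nonzero(bad)[0]


def sd_filter(x, y, k: float = 3.0):
    """Single-pass per-coordinate z-score filter on paired samples.

    A pair is removed when either coordinate deviates more than ``k``
    standard deviations from that coordinate's mean. A zero-variance
    coordinate contributes no removals.

    Returns ``(x kept, y kept, excluded indices)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("sd_filter needs at least 3 pairs")
    bad = np.zeros(x.size, bool)
    for v in (x, y):
        sd = v.std(ddof=0)
        if sd > 0:
            bad |= np.abs(v - v.mean()) > k * sd
    return x[~bad], y[~bad], np.nonzero(bad)[0]


def roi_regressions(
    samples: pd.DataFrame | list[RoiSample],
    min_n: int = 10,
    q: float = 0.05,
    mad_k: float = 3.0,
    sd_k: float = 3.0,
    mad_center: str = "mean",
) -> tuple[list[RoiRegressionResult], dict]:
    """Per-ROI OLS of task PSC on the CVR measure, with FDR control.

    For each ROI: the MAD filter removes subjects whose CVR value is an
    outlier (large-vessel contamination guard), the SD filter removes pairs
    with either coordinate beyond ``sd_k`` standard deviations, and ROIs
    retaining fewer than ``min_n`` subjects are dropped from the family.
    Two-sided slope p-values are corrected with the Benjamini-Hochberg
    step-up across the surviving ROIs. Returns the per-ROI results and a
    summary dict (see :func:`summarize`).
    """
    if min_n < 3:
        raise ValueError("min_n must be >= 3")
    df = samples if isinstance(samples, pd.DataFrame) else samples_to_frame(samples)
    results: list[RoiRegressionResult] = []
    pooled_x, pooled_y = [], []
    for roi, g in df.groupby("roi"):
        x = g["cvr_value"].to_numpy()
        y = g["task_psc"].to_numpy()
        excluded = 0
        if x.size >= 3:
            _, bad = mad_filter(x, k=mad_k, center=mad_center)
            keep = np.ones(x.size, bool)
            keep[bad] = False
            x, y = x[keep], y[keep]
            excluded += bad.size
            if x.size >= 3:
                x, y, bad2 = sd_filter(x, y, k=sd_k)
                excluded += bad2.size
        if x.size < min_n:
            continue
        if np.std(x) == 0:
            continue
        pooled_x.append(x)
        pooled_y.append(y)
        fit = st.linregress(x, y)
        r2 = float(fit.rvalue**2)
        results.append(
            RoiRegressionResult(
                roi=int(roi),
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                r2=r2,
                p=float(fit.pvalue),
                n=int(x.size),
                excluded_outliers=excluded,
                slope_stderr=float(fit.stderr),
            )
        )
    if results:
        rej, _, _, _ = multipletests([r.p for r in results], alpha=q, method="fdr_bh")
        for r, flag in zip(results, rej):
            r.fdr_significant = bool(flag)
    summary = summarize(results)
    summary["mad_center"] = mad_center
    summary["min_n"] = min_n
    summary["q"] = q
    if pooled_x:
        pooled = st.linregress(np.concatenate(pooled_x), np.concatenate(pooled_y))
        summary["pooled_slope"] = float(pooled.slope)
        summary["pooled_intercept"] = float(pooled.intercept)
    return results, summary


def summarize(results: list[RoiRegressionResult], top_k: int = 10) -> dict:
    """Counts and percentage of FDR-significant ROIs, plus a top-k table.

    The percentage is reported to one decimal place (e.g. 25 of 34
    significant -> 73.5). ``r2_table`` is the polar-plot-ready export of all
    per-ROI coefficients of determination.
    """
    n_eval = len(results)
    n_sig = sum(r.fdr_significant for r in results)
    pct = round(100.0 * n_sig / n_eval, 1) if n_eval else 0.0
    ranked = sorted(results, key=lambda r: r.p)
    top = [
        {"roi": r.roi, "p": r.p, "r2": r.r2, "n": r.n, "slope": r.slope}
        for r in ranked[:top_k]
    ]
    r2_table = [
        {"roi": r.roi, "r2": r.r2, "significant": r.fdr_significant} for r in results
    ]
    return {
        "n_evaluated": n_eval,
        "n_significant": n_sig,
        "percent_significant": pct,
        "top": top,
        "r2_table": r2_table,
    }
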