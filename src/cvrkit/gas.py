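"""Gas-challenge CVR in %BOLD/mmHg from a BOLD run and its capnograph trace.

Pipeline: per-breath end-tidal CO2 maxima are extracted from the breathing
trace and linearly interpolated onto the volume times; the end-tidal series
is then shifted forward in TR steps until its Pearson correlation with the
mean grey-matter BOLD time-course peaks (CO2 precedes the BOLD response by
the vascular transit delay); the optimally shifted series enters the GLM as
the regressor of interest; and the CVR map is the CO2 percent-signal-change
map divided by the maximum end-tidal change in mmHg.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import pearsonr

from .glm import StatMap, contrast_t, fit_glm, make_design, percent_signal_change, smooth_run
from .kernels import Regressor
from .phantom import RespiratoryTrace
from .runs import BoldRun

__all__ = ["EndTidalSeries", "ShiftReport", "CvrMap", "extract_end_tidal", "optimal_shift", "fit_gas_cvr"]

log = logging.getLogger(__name__)


@dataclass
class EndTidalSeries:
    """Per-breath end-tidal CO2 values and their volume-time interpolation.

    ``baseline`` is the mean end-tidal value over pre-challenge breaths;
    ``max_change`` the excursion of the interpolated series above baseline.
    """

    breath_times: np.ndarray
    petco2: np.ndarray
    resampled: np.ndarray
    volume_times: np.ndarray
    baseline: float
    max_change: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"breath_time": self.breath_times, "petco2_mmHg": self.petco2})


@dataclass
class ShiftReport:
    """Cross-correlation over forward shifts of the end-tidal regressor."""

    shifts_tested: np.ndarray
    correlations: np.ndarray
    chosen_shift: float

    def to_dict(self) -> dict:
        return {
            "shifts_tested": [float(s) for s in self.shifts_tested],
            "correlations": [None if np.isnan(r) else float(r) for r in self.correlations],
            "chosen_shift": float(self.chosen_shift),
        }


@dataclass
class CvrMap:
    """Per-voxel cerebrovascular reactivity over ``mask``."""

    values: np.ndarray
    mask: np.ndarray
    max_change: float
    units: str = "%BOLD/mmHg"

    def volume(self, fill: float = np.nan) -> np.ndarray:
        out = np.full(self.mask.shape, fill)
        out[self.mask] = self.values
        return out


def extract_end_tidal(
    trace: RespiratoryTrace,
    volume_times: np.ndarray,
    baseline_window: float = 120.0,
    min_separation: float = 2.0,
    prominence: float = 2.0,
) -> EndTidalSeries:
    """Extract per-breath end-tidal CO2 and interpolate to volume times.

    Breath maxima are local peaks of the CO2 trace at least
    ``min_separation`` seconds apart with prominence >= ``prominence`` mmHg.
    The end-tidal values are linearly interpolated onto ``volume_times``;
    the baseline is the mean end-tidal value of breaths within the
    pre-challenge ``baseline_window``; ``max_change`` is the maximum of the
    interpolated series minus baseline. A non-positive ``max_change`` (failed
    challenge) emits a warning.
    """
    time = np.asarray(trace.time, float)
    co2 = np.asarray(trace.co2, float)
    dt = float(np.median(np.diff(time)))
    peaks, _ = find_peaks(co2, distance=max(int(round(min_separation / dt)), 1), prominence=prominence)
    if peaks.size == 0:
        raise ValueError("no detectable breaths in the CO2 trace")
    breath_times = time[peaks]
    petco2 = co2[peaks]
    resampled = np.interp(volume_times, breath_times, petco2)
    pre = breath_times <= baseline_window
    if not pre.any():
        raise ValueError("no breaths inside the baseline window")
    baseline = float(petco2[pre].mean())
    max_change = float(resampled.max() - baseline)
    if max_change <= 0:
        warnings.warn("non-positive end-tidal change: the CO2 challenge failed", stacklevel=2)
    return EndTidalSeries(
        breath_times=breath_times,
        petco2=petco2,
        resampled=resampled,
        volume_times=np.asarray(volume_times, float),
        baseline=baseline,
        max_change=max_change,
    )


def optimal_shift(
    gm_mean_bold: np.ndarray,
    endtidal: EndTidalSeries,
    step: float,
    max_shift: float = 18.0,
    min_overlap: int = 10,
) -> ShiftReport:
    """Find the forward shift maximizing BOLD/end-tidal correlation.

    For each shift k*step the end-tidal series is delayed by k volumes and
    the Pearson r computed on the overlapping samples only. The shift with
    maximal r wins (r itself, not |r|); ties go to the smallest shift;
    shifts with fewer than ``min_overlap`` overlapping samples are skipped.
    """
    y = np.asarray(gm_mean_bold, float)
    x = endtidal.resampled
    if y.size != x.size:
        raise ValueError("BOLD series and resampled end-tidal series must have equal length")
    n_shift = int(np.floor(max_shift / step + 1e-9))
    shifts = np.arange(n_shift + 1) * step
    rs = np.full(shifts.size, np.nan)
    for k in range(shifts.size):
        overlap = y.size - k
        if overlap < min_overlap:
            log.info("shift %.1f s skipped: only %d overlapping samples", shifts[k], overlap)
            continue
        yy = y[k:]
        xx = x[: y.size - k]
        if np.std(yy) == 0 or np.std(xx) == 0:
            continue
        rs[k] = pearsonr(xx, yy).statistic
    if np.all(np.isnan(rs)):
        raise ValueError("no shift had enough overlapping samples")
    best = int(np.nanargmax(rs))
    return ShiftReport(shifts_tested=shifts, correlations=rs, chosen_shift=float(shifts[best]))


def shifted_regressor(endtidal: EndTidalSeries, shift: float, tr: float) -> Regressor:
    """End-tidal excursion (mmHg above baseline) delayed by ``shift`` seconds.

    Samples before the shifted start are held at 0 (pre-challenge level).
    The regressor is left in mmHg so the contrast estimate is directly
    interpretable per mmHg; its peak height equals the end-tidal excursion.
    """
    k = int(round(shift / tr))
    x = endtidal.resampled - endtidal.baseline
    s = np.zeros_like(x)
    s[k:] = x[: x.size - k] if k else x
    return Regressor(name="petco2", samples=s, peak_height=float(np.max(np.abs(s))), highres=s, highres_dt=tr)


def fit_gas_cvr(
    run: BoldRun,
    endtidal: EndTidalSeries,
    shift: ShiftReport | float,
    alpha: float = 0.001,
    motion: np.ndarray | None = None,
    drift: str = "linear",
    smooth_fwhm: float | None = None,
) -> tuple[CvrMap, StatMap]:
    """CVR map in %BOLD/mmHg from a gas run and its end-tidal series.

    The GLM regressor of interest is the optimally shifted end-tidal
    excursion (plus motion and drift nuisance); the CO2 percent-signal-change
    map is divided by the maximum end-tidal change to give reactivity per
    mmHg. The one-sided t map at the same contrast is returned alongside for
    thresholding.
    """
    if endtidal.max_change <= 0:
        raise ValueError("max_change must be positive to compute CVR")
    shift_s = shift.chosen_shift if isinstance(shift, ShiftReport) else float(shift)
    if smooth_fwhm:
        run = smooth_run(run, smooth_fwhm)
    reg = shifted_regressor(endtidal, shift_s, run.tr)
    design = make_design([reg], run.n_volumes, run.tr, motion=motion, drift=drift)
    res = fit_glm(run, design)
    w = design.contrast_vector({"petco2": 1.0})
    stat = contrast_t(res, w)
    psc = percent_signal_change(res, w)
    cvr = CvrMap(values=psc.psc / endtidal.max_change, mask=psc.mask, max_change=endtidal.max_change)
    return cvr, stat
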