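"""Hemodynamic and respiratory impulse-response kernels and regressor construction.

Every general linear model in the package builds its task and respiratory
regressors here: delta/stick or ramp inputs are formed on a fine time grid,
convolved with a response kernel, and sampled at the volume acquisition times.

Two kernels are provided:

* the canonical double-gamma hemodynamic response function (HRF), peaking
  near 5 s with a shallow undershoot, used for event-related task regressors;
* the respiratory response function (RRF), a slower difference of gammas with
  a much deeper and longer post-stimulus undershoot, appropriate for
  hypercapnic challenges such as breath-holding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "ResponseKernel",
    "Regressor",
    "canonical_hrf",
    "respiratory_response_function",
    "ramp_regressor",
    "build_regressor",
    "DEFAULT_OVERSAMPLING",
]

#: internal oversampling factor: regressors are built at dt = tr / 16
DEFAULT_OVERSAMPLING = 16


@dataclass(frozen=True)
class ResponseKernel:
    """A sampled impulse-response kernel, peak-normalized to 1.

    Attributes
    ----------
    dt : float
        Sampling interval of ``values`` in seconds.
    values : np.ndarray
        Kernel samples starting at t = 0.
    kind : str
        ``"hrf"`` or ``"rrf"``.
    support : float
        Temporal support in seconds (``values`` spans [0, support]).
    """

    dt: float
    values: np.ndarray
    kind: str
    support: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    @property
    def peak_time(self) -> float:
        return float(self.times[np.argmax(self.values)])

    @property
    def trough_time(self) -> float:
        return float(self.times[np.argmin(self.values)])

    @property
    def undershoot_ratio(self) -> float:
        """|minimum| / |maximum|; large for the RRF, ~1/11 for the HRF."""
        return float(abs(self.values.min()) / abs(self.values.max()))

    def undershoot_recovery_time(self, frac: float = 0.05) -> float:
        """Last time at which the kernel is below ``-frac`` of its peak."""
        below = np.nonzero(self.values < -frac * self.values.max())[0]
        return float(self.times[below[-1]]) if below.size else 0.0

    def to_tsv(self, path) -> None:
        """Dump as two-column TSV (time, amplitude) for inspection."""
        np.savetxt(
            path,
            np.column_stack([self.times, self.values]),
            delimiter="\t",
            header="time_s\tamplitude",
            comments="",
        )


@dataclass
class Regressor:
    """A design-matrix column sampled at volume times.

    ``highres``/``highres_dt`` keep the pre-sampling series so that the peak
    height of weighted regressor combinations can be computed exactly for
    percent-signal-change scaling.
    """

    name: str
    samples: np.ndarray
    peak_height: float
    highres: np.ndarray | None = field(default=None, repr=False)
    highres_dt: float | None = None


def _check_dt(dt: float) -> None:
    if not (0 < dt <= 1.0):
        raise ValueError(f"kernel dt must lie in (0, 1] s, got {dt}")


def canonical_hrf(dt: float, support: float = 32.0) -> ResponseKernel:
    """Canonical double-gamma hemodynamic response function.

    Difference of two gamma densities with peak delay 6 s, undershoot delay
    16 s, unit dispersions and undershoot ratio 1/6 — the conventional
    parameterization of the canonical HRF. Peak normalized to 1; the value at
    t = 0 is exactly 0.

    Parameters
    ----------
    dt : float
        Sample spacing in seconds, 0 < dt <= 1.
    support : float
        Kernel length in seconds (default 32 s).
    """
    _check_dt(dt)
    t = np.arange(0.0, support + dt / 2, dt)
    v = _gamma_dist.pdf(t, 6.0, scale=1.0) - _gamma_dist.pdf(t, 16.0, scale=1.0) / 6.0
    v = v / v.max()
    return ResponseKernel(dt=dt, values=v, kind="hrf", support=support)


# Respiratory response function coefficients, transcribed from the published
# formulation: rrf(t) = 0.6 t^2.1 exp(-t/1.6) - 0.0023 t^3.54 exp(-t/4.25).
RRF_COEFFICIENTS = {
    "a1": 0.6,
    "p1": 2.1,
    "tau1": 1.6,
    "a2": 0.0023,
    "p2": 3.54,
    "tau2": 4.25,
}


def respiratory_response_function(
    dt: float, support: float = 60.0, coefficients: dict | None = None
) -> ResponseKernel:
    """Respiratory response function: slow difference of gammas.

    Models the BOLD response to a respiratory/hypercapnic challenge: an early
    positive peak near 3 s followed by a deep undershoot around 15 s that
    recovers only after ~50 s, i.e. a longer and larger undershoot than the
    canonical HRF's. Default support is 60 s to capture the slow tail — at
    30 s the kernel still sits near -39% of its peak, so a 32-s support would
    clip substantial mass.

    ``coefficients`` may override the published parameterization
    (:data:`RRF_COEFFICIENTS`).
    """
    _check_dt(dt)
    c = dict(RRF_COEFFICIENTS)
    if coefficients:
        c.update(coefficients)
    t = np.arange(0.0, support + dt / 2, dt)
    v = c["a1"] * t ** c["p1"] * np.exp(-t / c["tau1"]) - c["a2"] * t ** c["p2"] * np.exp(
        -t / c["tau2"]
    )
    v = v / v.max()
    return ResponseKernel(dt=dt, values=v, kind="rrf", support=support)


def ramp_regressor(paradigm, dt: float, extend_into_rest: bool = False) -> np.ndarray:
    """Linear-accumulation input for breath-hold epochs on a fine time grid.

    Within each hold epoch the series rises linearly 0 -> 1 over the epoch
    duration, modelling the build-up of arterial CO2 while breathing is
    suspended; it is 0 during rest. With ``extend_into_rest`` the terminal
    value 1 is held until the next epoch (the washout then being absorbed by
    the convolution kernel's undershoot anyway).

    Parameters
    ----------
    paradigm : ParadigmSpec
        Must have ``kind == "breath_hold"``.
    dt : float
        Time grid spacing in seconds.

    Returns
    -------
    np.ndarray of length ceil(total_duration / dt).
    """
    if paradigm.kind != "breath_hold":
        raise ValueError(f"ramp_regressor requires a breath_hold paradigm, got {paradigm.kind!r}")
    onsets = np.asarray(paradigm.onsets, float)
    durations = np.asarray(paradigm.durations, float)
    ends = onsets + durations
    if np.any(onsets[1:] < ends[:-1]):
        raise ValueError("breath-hold epochs overlap")
    n = int(np.ceil(paradigm.total_duration / dt))
    t = np.arange(n) * dt
    out = np.zeros(n)
    for i, (on, dur) in enumerate(zip(onsets, durations)):
        inside = (t >= on) & (t < on + dur)
        out[inside] = (t[inside] - on) / dur
        if extend_into_rest:
            nxt = onsets[i + 1] if i + 1 < onsets.size else paradigm.total_duration
            out[(t >= on + dur) & (t < nxt)] = 1.0
    return out


def build_regressor(
    events_or_series,
    kernel: ResponseKernel,
    n_volumes: int,
    tr: float,
    onset_shift: float = 0.0,
    name: str = "task",
    amplitudes=None,
    oversampling: int = DEFAULT_OVERSAMPLING,
) -> Regressor:
    """Convolve an input with a response kernel and sample at volume times.

    The input is either an array of event onset times in seconds (rendered as
    unit-height sticks on the fine grid; ``amplitudes`` optionally scales each
    stick) or an already fine-gridded series (e.g. from
    :func:`ramp_regressor`) whose grid spacing must equal ``tr /
    oversampling``. Dispatch is by length: an input of exactly
    ``n_volumes * oversampling`` samples is taken to be a fine-grid series,
    anything else an onset list. ``onset_shift`` delays the input by that many
    seconds before convolution, implementing staggered-onset models. Events
    whose shifted onset falls beyond the run end are dropped with a warning.

    Discrete convolution is used (a unit impulse reproduces the sampled
    kernel exactly); sampling is at volume onsets t = 0, tr, 2*tr, ...
    """
    if onset_shift < 0:
        raise ValueError("onset_shift must be >= 0")
    dt = tr / oversampling
    n_hi = n_volumes * oversampling
    x = np.zeros(n_hi)
    arr = np.asarray(events_or_series, float)
    if arr.ndim != 1:
        raise ValueError("events_or_series must be one-dimensional")
    shift_samples = int(round(onset_shift / dt))
    if arr.size == n_hi and amplitudes is None:
        x[shift_samples:] = arr[: n_hi - shift_samples]
    else:
        amps = np.ones(arr.size) if amplitudes is None else np.asarray(amplitudes, float)
        if amps.size != arr.size:
            raise ValueError("amplitudes must match the number of events")
        idx = np.round((arr + onset_shift) / dt).astype(int)
        keep = idx < n_hi
        if not np.all(keep):
            warnings.warn(
                f"{int((~keep).sum())} event(s) fall beyond the run end after "
                f"shifting by {onset_shift} s and were dropped",
                stacklevel=2,
            )
        np.add.at(x, idx[keep], amps[keep])
    ker = kernel.values
    if abs(kernel.dt - dt) > 1e-9:
        # resample the kernel onto the regressor grid
        t_new = np.arange(0.0, kernel.support + dt / 2, dt)
        ker = np.interp(t_new, kernel.times, kernel.values)
    hi = np.convolve(x, ker)[:n_hi]
    samples = hi[::oversampling].copy()
    peak = float(np.max(np.abs(hi)))
    return Regressor(name=name, samples=samples, peak_height=peak, highres=hi, highres_dt=dt)
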