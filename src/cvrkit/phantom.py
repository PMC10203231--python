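"""Synthetic BOLD phantoms with known regional CVR and CVR-task coupling.

The study conditions this package analyses are emulated end to end: an
atlas-labelled grid of rectangular parcels (default 68, mirroring a
whole-cortex gyral parcellation), a per-parcel cerebrovascular reactivity
(CVR) field, a linear CVR -> task-amplitude coupling with subject noise, and
the three paradigm families:

* block breath-holding (5 holds of 13.5 s separated by 16.5 s of rest,
  2.5 min total), whose BOLD response follows a linear CO2-accumulation ramp
  convolved with the respiratory response function;
* a gas challenge (2 min air / 2 min 5% CO2 / 2 min air) with a synthetic
  capnograph trace whose end-tidal plateau rises ~9.81 mmHg;
* event-related cognitive designs (stick functions convolved with the
  canonical HRF), with a configurable fraction of trials flagged incorrect
  and carrying an independent response amplitude.

Every generator output is a pure function of its arguments including the
seed, so downstream estimators can be validated against exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import kernels
from .runs import BoldRun

__all__ = [
    "AtlasPhantom",
    "GroundTruth",
    "ParadigmSpec",
    "RespiratoryTrace",
    "generate_phantom",
    "draw_ground_truth",
    "simulate_run",
    "simulate_respiratory_trace",
    "simulate_motion",
    "breath_hold_paradigm",
    "gas_block_paradigm",
    "event_task_paradigm",
    "scap_paradigm",
    "stop_signal_paradigm",
    "task_switch_paradigm",
    "antr_paradigm",
    "condition_fraction",
]

MIN_PARCEL_VOXELS = 20
#: baseline end-tidal CO2 and hypercapnic plateau of the synthetic capnograph
#: (mmHg); the defaults reproduce a mean end-tidal rise of 9.81 mmHg.
PETCO2_BASELINE = 35.38
PETCO2_PLATEAU = 45.19
#: nominal end-tidal rise used to scale breath-hold plateau PSC (mmHg)
NOMINAL_DELTA_PETCO2 = PETCO2_PLATEAU - PETCO2_BASELINE


@dataclass
class ParadigmSpec:
    """Timing of one run: breath-hold blocks, gas blocks, or task events.

    Times are seconds from run start; ``correctness`` marks which events the
    (simulated) subject answered correctly and exists for event tasks only.
    """

    kind: str
    onsets: np.ndarray
    durations: np.ndarray
    conditions: list[str]
    total_duration: float
    tr: float
    correctness: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("breath_hold", "gas_block", "event_task"):
            raise ValueError(f"unknown paradigm kind {self.kind!r}")
        self.onsets = np.asarray(self.onsets, float)
        self.durations = np.asarray(self.durations, float)
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(self.onsets + self.durations > self.total_duration + 1e-9):
            raise ValueError("events extend past total_duration")
        if len(self.conditions) != self.onsets.size:
            raise ValueError("one condition label per event required")
        if self.correctness is not None:
            self.correctness = np.asarray(self.correctness, bool)
            if self.correctness.size != self.onsets.size:
                raise ValueError("one correctness flag per event required")

    @property
    def n_volumes(self) -> int:
        return int(round(self.total_duration / self.tr))

    def to_events_frame(self):
        import pandas as pd

        d = {
            "onset": self.onsets,
            "duration": self.durations,
            "trial_type": self.conditions,
        }
        if self.correctness is not None:
            d["correct"] = self.correctness.astype(int)
        return pd.DataFrame(d)


def condition_fraction(paradigm: ParadigmSpec, label=None, exclude=None) -> float:
    """Fraction of events whose condition equals ``label`` (or != ``exclude``)."""
    conds = np.asarray(paradigm.conditions)
    if label is not None:
        return float(np.mean(conds == label))
    if exclude is not None:
        return float(np.mean(conds != exclude))
    raise ValueError("give either label or exclude")


def breath_hold_paradigm(
    tr: float = 2.0, n_epochs: int = 5, hold: float = 13.5, rest: float = 16.5
) -> ParadigmSpec:
    """Block breath-hold design: rest, then alternating hold/rest epochs.

    Defaults give 5 holds of 13.5 s separated by 16.5 s of regular breathing,
    150 s (2.5 min) in total.
    """
    onsets = rest + np.arange(n_epochs) * (hold + rest)
    return ParadigmSpec(
        kind="breath_hold",
        onsets=onsets,
        durations=np.full(n_epochs, hold),
        conditions=["hold"] * n_epochs,
        total_duration=n_epochs * (hold + rest),
        tr=tr,
    )


def gas_block_paradigm(
    tr: float = 1.8, air: float = 120.0, co2: float = 120.0
) -> ParadigmSpec:
    """Gas challenge: air, a CO2-enriched block, then air again (2/2/2 min)."""
    return ParadigmSpec(
        kind="gas_block",
        onsets=np.array([air]),
        durations=np.array([co2]),
        conditions=["co2"],
        total_duration=2 * air + co2,
        tr=tr,
    )


def event_task_paradigm(
    n_trials: int,
    total_duration: float,
    tr: float,
    condition_labels: list[str],
    trial_duration: float = 1.0,
    incorrect_fraction: float = 0.1,
    seed: int = 0,
    min_isi: float = 2.0,
    tail: float = 20.0,
) -> ParadigmSpec:
    """Jittered event-related design.

    Inter-stimulus intervals are drawn uniformly and rescaled so the last
    trial ends ``tail`` seconds before the run end; ``condition_labels`` is
    cycled over trials unless it already has one label per trial; a seeded
    ``incorrect_fraction`` of trials is flagged incorrect.
    """
    rng = np.random.default_rng(seed)
    gaps = rng.uniform(min_isi, 3.0 * min_isi, size=n_trials)
    span = total_duration - tail - n_trials * trial_duration
    if span <= 0:
        raise ValueError("total_duration too short for the requested trials")
    gaps *= span / gaps.sum()
    onsets = np.cumsum(gaps) + np.arange(n_trials) * trial_duration
    if len(condition_labels) == n_trials:
        conds = list(condition_labels)
    else:
        conds = [condition_labels[i % len(condition_labels)] for i in range(n_trials)]
    n_incorrect = int(round(incorrect_fraction * n_trials))
    correct = np.ones(n_trials, bool)
    if n_incorrect:
        correct[rng.choice(n_trials, size=n_incorrect, replace=False)] = False
    return ParadigmSpec(
        kind="event_task",
        onsets=onsets,
        durations=np.full(n_trials, trial_duration),
        conditions=conds,
        total_duration=total_duration,
        tr=tr,
        correctness=correct,
    )


def scap_paradigm(tr: float = 2.0, seed: int = 0, incorrect_fraction: float = 0.1) -> ParadigmSpec:
    """Spatial working-memory design: 48 trials, 4 loads x 3 delays."""
    labels = [f"load{l}_delay{d}" for l in (1, 3, 5, 7) for d in ("1.5", "3", "4.5")]
    return event_task_paradigm(
        48, 440.0, tr, labels, trial_duration=2.0, incorrect_fraction=incorrect_fraction, seed=seed
    )


def stop_signal_paradigm(tr: float = 2.0, seed: int = 0, incorrect_fraction: float = 0.1) -> ParadigmSpec:
    """Response-inhibition design: 128 trials of which 32 (25%) are stop trials."""
    rng = np.random.default_rng(seed + 1)
    conds = np.array(["go"] * 128, dtype=object)
    conds[rng.choice(128, size=32, replace=False)] = "stop"
    return event_task_paradigm(
        128, 710.0, tr, list(conds), trial_duration=1.0, incorrect_fraction=incorrect_fraction, seed=seed
    )


def task_switch_paradigm(tr: float = 2.0, seed: int = 0, incorrect_fraction: float = 0.1) -> ParadigmSpec:
    """Task-switching design: 96 trials, one third switch trials."""
    rng = np.random.default_rng(seed + 1)
    conds = np.array(["no_switch"] * 96, dtype=object)
    conds[rng.choice(96, size=32, replace=False)] = "switch"
    return event_task_paradigm(
        96, 520.0, tr, list(conds), trial_duration=1.0, incorrect_fraction=incorrect_fraction, seed=seed
    )


def antr_paradigm(tr: float = 1.8, seed: int = 0, incorrect_fraction: float = 0.1) -> ParadigmSpec:
    """Cued-flanker attention design: 72 trials per run, 260 volumes (468 s).

    60 of 72 trials (83.3%) carry a visual cue (double, valid or invalid);
    the remaining 12 are uncued.
    """
    rng = np.random.default_rng(seed + 1)
    conds = np.array(
        ["no_cue"] * 12 + ["double_cue"] * 20 + ["valid_cue"] * 20 + ["invalid_cue"] * 20
    )
    rng.shuffle(conds)
    return event_task_paradigm(
        72, 468.0, tr, list(conds), trial_duration=0.5, incorrect_fraction=incorrect_fraction, seed=seed
    )


# ---------------------------------------------------------------------------
# atlas phantom


@dataclass
class AtlasPhantom:
    """Integer-labelled parcellation on a regular grid.

    Labels are contiguous 1..n_parcels; 0 is background; each parcel is a
    connected rectangular block of at least 20 voxels.
    """

    label_volume: np.ndarray
    grid_shape: tuple
    voxel_size: tuple
    label_table: dict

    @property
    def n_parcels(self) -> int:
        return len(self.label_table)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.label_volume > 0

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0], a[1, 1], a[2, 2] = self.voxel_size
        return a

    def parcel_indices(self, label: int) -> np.ndarray:
        return np.nonzero(self.label_volume == label)


def _axis_splits(grid_shape, n_parcels):
    """Smallest block partition hosting >= n_parcels blocks of >= 20 voxels."""
    best = None
    for sx in range(1, grid_shape[0] + 1):
        for sy in range(1, grid_shape[1] + 1):
            if sx * sy > 4 * n_parcels:
                break
            for sz in range(1, grid_shape[2] + 1):
                prod = sx * sy * sz
                if prod < n_parcels:
                    continue
                if prod > 4 * n_parcels:
                    break
                minblock = (
                    (grid_shape[0] // sx) * (grid_shape[1] // sy) * (grid_shape[2] // sz)
                )
                if minblock < MIN_PARCEL_VOXELS:
                    continue
                # prefer an even x-split so parcels fall into both hemispheres
                key = (prod, -minblock, sx % 2, max(sx, sy, sz))
                if best is None or key < best[0]:
                    best = (key, (sx, sy, sz))
    return None if best is None else best[1]


def generate_phantom(
    n_parcels: int = 68,
    grid_shape=(24, 24, 18),
    seed: int = 0,
    voxel_size=(3.0, 3.0, 3.0),
) -> AtlasPhantom:
    """Partition a grid into connected rectangular parcels.

    The grid is cut into near-equal blocks along each axis; ``n_parcels`` of
    the blocks receive labels 1..n_parcels in a seeded random arrangement,
    and any surplus blocks become background. Each parcel has at least 20
    voxels or a sizing error is raised naming the required minimum. Parcels
    in the low-x half are tagged left-hemisphere, the rest right.
    """
    if n_parcels < 2:
        raise ValueError("n_parcels must be >= 2")
    grid_shape = tuple(int(g) for g in grid_shape)
    total = int(np.prod(grid_shape))
    if total < n_parcels * MIN_PARCEL_VOXELS:
        raise ValueError(
            f"grid of {total} voxels cannot host {n_parcels} parcels of >= "
            f"{MIN_PARCEL_VOXELS} voxels; at least {n_parcels * MIN_PARCEL_VOXELS} "
            "voxels are required"
        )
    splits = _axis_splits(grid_shape, n_parcels)
    if splits is None:
        raise ValueError(
            f"no block partition of grid {grid_shape} supports {n_parcels} parcels "
            f"of >= {MIN_PARCEL_VOXELS} voxels; enlarge the grid"
        )
    edges = [np.linspace(0, g, s + 1).round().astype(int) for g, s in zip(grid_shape, splits)]
    blocks = []
    for i in range(splits[0]):
        for j in range(splits[1]):
            for k in range(splits[2]):
                blocks.append(
                    (
                        slice(edges[0][i], edges[0][i + 1]),
                        slice(edges[1][j], edges[1][j + 1]),
                        slice(edges[2][k], edges[2][k + 1]),
                    )
                )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(blocks))
    labels = np.zeros(grid_shape, dtype=np.int32)
    table = {}
    mid_x = grid_shape[0] / 2
    for lab, bidx in enumerate(order[:n_parcels], start=1):
        sl = blocks[bidx]
        labels[sl] = lab
        center_x = 0.5 * (sl[0].start + sl[0].stop)
        hemi = "L" if center_x < mid_x else "R"
        table[lab] = {"name": f"{hemi}_region{lab:02d}", "hemisphere": hemi}
    return AtlasPhantom(
        label_volume=labels, grid_shape=grid_shape, voxel_size=tuple(voxel_size), label_table=table
    )


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Known regional CVR and task amplitudes underlying a simulated cohort.

    ``cvr_true`` is the per-parcel reactivity in %BOLD/mmHg;
    ``subject_scale`` is a per-subject multiplicative vascular factor
    (inter-subject CVR spread, without which across-subject regressions would
    have a constant predictor); their outer product ``cvr_subject`` is the
    effective reactivity of parcel p in subject s. Task amplitudes follow

        task_amp_true[p, s] = intercept + slope * cvr_subject[p, s] * dPetCO2
                              + N(0, subject_sd)

    in % BOLD. All draws are reproducible from ``seed``.
    """

    cvr_true: np.ndarray
    subject_scale: np.ndarray
    task_amp_true: np.ndarray
    incorrect_amp_true: np.ndarray
    coupling_slope: float
    coupling_intercept: float
    subject_lag: np.ndarray
    noise_sd: float
    delta_petco2: float
    seed: int

    @property
    def n_subjects(self) -> int:
        return self.subject_scale.size

    @property
    def cvr_subject(self) -> np.ndarray:
        """Effective per-parcel, per-subject reactivity (%BOLD/mmHg)."""
        return np.outer(self.cvr_true, self.subject_scale)

    @property
    def bh_psc_true(self) -> np.ndarray:
        """Breath-hold plateau PSC implied by the reactivity (%BOLD)."""
        return self.cvr_subject * self.delta_petco2


def draw_ground_truth(
    phantom: AtlasPhantom,
    n_subjects: int,
    coupling_slope: float = 0.5,
    coupling_intercept: float = 0.2,
    cvr_log_mean: float = math.log(0.2),
    cvr_log_sd: float = 0.4,
    subject_sd: float = 0.3,
    subject_cvr_sd: float = 0.25,
    delta_petco2: float = NOMINAL_DELTA_PETCO2,
    noise_sd: float = 1.0,
    lag_choices=(0.0, 2.0, 4.0, 6.0),
    seed: int = 0,
) -> GroundTruth:
    """Draw the regional CVR field and the coupled task amplitudes.

    CVR is lognormal per parcel (median 0.2 %BOLD/mmHg by default, right
    skewed and positive as in real reactivity maps); subjects carry a
    lognormal multiplicative scale of log-sd ``subject_cvr_sd``. Task
    amplitudes follow the linear coupling model with Gaussian noise of sd
    ``subject_sd`` (%BOLD); incorrect-trial amplitudes are an independent
    draw around the intercept. Subject hemodynamic lags are drawn from
    ``lag_choices`` (seconds).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if cvr_log_sd <= 0:
        raise ValueError("cvr_log_sd must be positive (degenerate CVR distribution)")
    if subject_cvr_sd < 0 or subject_sd < 0:
        raise ValueError("noise standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    R = phantom.n_parcels
    cvr = np.exp(rng.normal(cvr_log_mean, cvr_log_sd, size=R))
    scale = (
        np.exp(rng.normal(0.0, subject_cvr_sd, size=n_subjects))
        if subject_cvr_sd > 0
        else np.ones(n_subjects)
    )
    noise = rng.normal(0.0, subject_sd, size=(R, n_subjects)) if subject_sd > 0 else np.zeros((R, n_subjects))
    task_amp = coupling_intercept + coupling_slope * np.outer(cvr, scale) * delta_petco2 + noise
    incorrect_amp = coupling_intercept + rng.normal(0.0, max(subject_sd, 0.1), size=(R, n_subjects))
    lags = rng.choice(np.asarray(lag_choices, float), size=n_subjects)
    return GroundTruth(
        cvr_true=cvr,
        subject_scale=scale,
        task_amp_true=task_amp,
        incorrect_amp_true=incorrect_amp,
        coupling_slope=coupling_slope,
        coupling_intercept=coupling_intercept,
        subject_lag=lags,
        noise_sd=noise_sd,
        delta_petco2=delta_petco2,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# respiratory trace


@dataclass
class RespiratoryTrace:
    """Synthetic capnograph recording: CO2 partial pressure vs time.

    The trace oscillates at the breathing period between the inspired level
    and an end-tidal envelope; per-breath maxima track the envelope, which
    rises from the normocapnic baseline to the hypercapnic plateau over a
    raised-cosine transition at each block edge.
    """

    time: np.ndarray
    co2: np.ndarray
    breath_period: float
    envelope: np.ndarray = field(default=None, repr=False)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.time, "co2_mmHg": self.co2})


def petco2_envelope(
    paradigm: ParadigmSpec,
    t: np.ndarray,
    baseline: float = PETCO2_BASELINE,
    plateau: float = PETCO2_PLATEAU,
    transition: float = 15.0,
) -> np.ndarray:
    """Ideal end-tidal CO2 time-course for a gas-block paradigm.

    Raised-cosine transitions of ``transition`` seconds at each block edge;
    exactly at ``plateau`` inside the block once the transition completes.
    """
    if paradigm.kind != "gas_block":
        raise ValueError("petco2_envelope requires a gas_block paradigm")
    env = np.full_like(t, baseline, dtype=float)
    for on, dur in zip(paradigm.onsets, paradigm.durations):
        off = on + dur
        rise = (t >= on) & (t < on + transition)
        env[rise] = baseline + (plateau - baseline) * 0.5 * (
            1 - np.cos(np.pi * (t[rise] - on) / transition)
        )
        env[(t >= on + transition) & (t < off)] = plateau
        fall = (t >= off) & (t < off + transition)
        env[fall] = baseline + (plateau - baseline) * 0.5 * (
            1 + np.cos(np.pi * (t[fall] - off) / transition)
        )
    return env


def simulate_respiratory_trace(
    paradigm: ParadigmSpec,
    baseline: float = PETCO2_BASELINE,
    plateau: float = PETCO2_PLATEAU,
    breath_period: float = 4.0,
    dt: float = 0.05,
    inspired: float = 1.0,
    transition: float = 15.0,
) -> RespiratoryTrace:
    """Synthesize the capnograph trace for a gas-block run.

    CO2 oscillates sinusoidally at ``breath_period`` between the inspired
    floor and the end-tidal envelope, so per-breath maxima equal the envelope
    at the breath peaks.
    """
    t = np.arange(0.0, paradigm.total_duration, dt)
    env = petco2_envelope(paradigm, t, baseline, plateau, transition)
    phase = 0.5 - 0.5 * np.cos(2 * np.pi * t / breath_period)
    co2 = inspired + (env - inspired) * phase
    return RespiratoryTrace(time=t, co2=co2, breath_period=breath_period, envelope=env)


def simulate_motion(n_volumes: int, seed: int, scale: float = 0.05) -> np.ndarray:
    """Slow random-walk motion parameters (3 translations mm, 3 rotations rad)."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, scale, size=(n_volumes, 6))
    return np.cumsum(steps, axis=0)


# ---------------------------------------------------------------------------
# forward simulation


def _gas_smoothing_kernel(dt: float, support: float = 32.0) -> np.ndarray:
    """Unit-gain hemodynamic smoothing kernel for the gas forward model.

    A single positive gamma (the main lobe of the canonical HRF: shape 6,
    unit dispersion) normalized to unit discrete sum. Its step response is
    monotone, so a sustained hypercapnic plateau passes through with gain
    exactly 1 and the plateau PSC equals cvr * dPetCO2 by construction; a
    biphasic kernel would overshoot the plateau through its undershoot lobe.
    """
    from scipy.stats import gamma as _gd

    t = np.arange(0.0, support + dt / 2, dt)
    v = _gd.pdf(t, 6.0, scale=1.0)
    return v / v.sum()


def simulate_run(
    phantom: AtlasPhantom,
    truth: GroundTruth,
    paradigm: ParadigmSpec,
    subject: int,
    noise_sd: float | None = None,
    seed: int = 0,
    baseline: float = 100.0,
    response_kernel: str = "rrf",
    ar_rho: float = 0.0,
    oversampling: int = kernels.DEFAULT_OVERSAMPLING,
):
    """Simulate one BOLD run for one subject.

    Voxel series are ``baseline * (1 + response_fraction) + noise`` with
    white Gaussian noise of sd ``noise_sd`` percent of baseline (optionally
    AR(1) with coefficient ``ar_rho``). The response per parcel is:

    * ``breath_hold`` — CO2-accumulation ramp convolved with the respiratory
      response function (or the canonical HRF when ``response_kernel="hrf"``,
      emulating subjects whose breath-hold response the RRF fits poorly),
      peak-normalized and scaled so the plateau PSC equals
      ``cvr_subject * delta_petco2``;
    * ``gas_block`` — the end-tidal excursion (mmHg) convolved with a
      unit-gain HRF, times ``cvr_subject / 100``; the matching capnograph
      trace is returned alongside the run;
    * ``event_task`` — correct-trial sticks convolved with the HRF and
      peak-normalized, scaled to ``task_amp_true``; incorrect trials carry
      the independent ``incorrect_amp_true`` amplitude.

    The subject's hemodynamic lag is applied as a pure delay of the response.
    Motion parameters (pure nuisance; they do not alter the signal) are
    attached as ``run.meta["motion"]``.

    Returns ``BoldRun`` (and additionally the ``RespiratoryTrace`` for gas
    runs).
    """
    if subject >= truth.n_subjects:
        raise IndexError(f"subject {subject} out of range (n={truth.n_subjects})")
    if noise_sd is None:
        noise_sd = truth.noise_sd
    tr = paradigm.tr
    n_vol = paradigm.n_volumes
    lag = float(truth.subject_lag[subject])
    dt = tr / oversampling
    n_hi = n_vol * oversampling
    amps = None  # (R,) percent amplitudes per normalized response component
    components = []  # list of (normalized response sampled at volumes, per-parcel amp %)

    if paradigm.kind == "breath_hold":
        ker = (
            kernels.respiratory_response_function(dt)
            if response_kernel == "rrf"
            else kernels.canonical_hrf(dt)
        )
        ramp = kernels.ramp_regressor(paradigm, dt)
        reg = kernels.build_regressor(
            ramp, ker, n_vol, tr, onset_shift=lag, oversampling=oversampling, name="bh"
        )
        shape = reg.samples / reg.peak_height
        amps = truth.bh_psc_true[:, subject]
        components.append((shape, amps))
        trace = None
    elif paradigm.kind == "gas_block":
        trace = simulate_respiratory_trace(paradigm)
        t_hi = np.arange(n_hi) * dt
        env = petco2_envelope(paradigm, t_hi)
        excursion = env - PETCO2_BASELINE
        ker = _gas_smoothing_kernel(dt)
        smoothed = np.convolve(excursion, ker)[:n_hi]
        lag_samples = int(round(lag / dt))
        delayed = np.zeros(n_hi)
        delayed[lag_samples:] = smoothed[: n_hi - lag_samples]
        shape = delayed[::oversampling]
        amps = truth.cvr_subject[:, subject]  # %BOLD per mmHg; shape is in mmHg
        components.append((shape, amps))
    elif paradigm.kind == "event_task":
        hrf = kernels.canonical_hrf(dt)
        correct = paradigm.correctness
        if correct is None:
            correct = np.ones(paradigm.onsets.size, bool)
        # the subject's vascular lag applies to hypercapnic responses; task
        # responses follow canonical HRF timing (as the task GLMs assume)
        reg_c = kernels.build_regressor(
            paradigm.onsets[correct], hrf, n_vol, tr,
            oversampling=oversampling, name="task_correct",
        )
        components.append((reg_c.samples / reg_c.peak_height, truth.task_amp_true[:, subject]))
        if (~correct).any():
            reg_i = kernels.build_regressor(
                paradigm.onsets[~correct], hrf, n_vol, tr,
                oversampling=oversampling, name="task_incorrect",
            )
            components.append(
                (reg_i.samples / reg_i.peak_height, truth.incorrect_amp_true[:, subject])
            )
        trace = None
    else:  # pragma: no cover - ParadigmSpec already validates
        raise ValueError(f"unknown paradigm kind {paradigm.kind!r}")

    labels = phantom.label_volume
    data = np.full(phantom.grid_shape + (n_vol,), baseline, dtype=float)
    # per-parcel response fractions, broadcast to voxels
    frac = np.zeros((phantom.n_parcels + 1, n_vol))
    for shape, amp in components:
        frac[1:] += np.outer(amp, shape) / 100.0
    data *= 1.0 + frac[labels]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sigma = noise_sd / 100.0 * baseline
        eps = rng.normal(0.0, sigma, size=data.shape)
        if ar_rho:
            for ti in range(1, n_vol):
                eps[..., ti] = ar_rho * eps[..., ti - 1] + np.sqrt(1 - ar_rho**2) * eps[..., ti]
        data += eps
    motion = simulate_motion(n_vol, seed=seed + 1)
    run = BoldRun(
        data=data,
        tr=tr,
        mask=phantom.brain_mask,
        affine=phantom.affine,
        meta={
            "subject": subject,
            "paradigm": paradigm.kind,
            "motion": motion,
            "seed": seed,
            "response_kernel": response_kernel if paradigm.kind == "breath_hold" else "hrf",
        },
    )
    if paradigm.kind == "gas_block":
        return run, trace
    return run
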