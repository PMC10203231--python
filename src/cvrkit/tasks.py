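"""First-level models for event-related cognitive tasks.

Correct trials are modelled as onset sticks convolved with the canonical
HRF; incorrect trials enter as a separate regressor of no interest; six
motion parameters and a drift term complete the nuisance set. The contrast
of interest is the correct-trial response versus baseline.
"""

from __future__ import annotations

import numpy as np

from .glm import PscMap, StatMap, contrast_t, fit_glm, make_design, percent_signal_change
from .kernels import build_regressor, canonical_hrf
from .phantom import ParadigmSpec
from .runs import BoldRun

__all__ = ["fit_task_psc"]


def fit_task_psc(
    run: BoldRun,
    paradigm: ParadigmSpec,
    motion: np.ndarray | None = None,
    drift: str = "linear",
    conditions: str = "pooled",
    smooth_fwhm: float | None = None,
) -> tuple[PscMap, StatMap]:
    """Task percent-signal-change and t maps for one run.

    With ``conditions="pooled"`` all correct trials share one regressor and
    the contrast selects it (the configuration used for amplitude-recovery
    validation). With ``conditions="separate"`` each condition label gets
    its own correct-trial regressor, mirroring multi-condition first-level
    models, and the contrast averages the condition columns.
    """
    if paradigm.kind != "event_task":
        raise ValueError("fit_task_psc requires an event_task paradigm")
    if smooth_fwhm:
        from .glm import smooth_run

        run = smooth_run(run, smooth_fwhm)
    hrf = canonical_hrf(run.tr / 16)
    correct = (
        paradigm.correctness
        if paradigm.correctness is not None
        else np.ones(paradigm.onsets.size, bool)
    )
    regs = []
    weights = {}
    if conditions == "pooled":
        regs.append(
            build_regressor(paradigm.onsets[correct], hrf, run.n_volumes, run.tr, name="task_correct")
        )
        weights["task_correct"] = 1.0
    elif conditions == "separate":
        labels = np.asarray(paradigm.conditions)
        uniq = [c for c in dict.fromkeys(labels[correct])]
        for c in uniq:
            sel = correct & (labels == c)
            regs.append(
                build_regressor(paradigm.onsets[sel], hrf, run.n_volumes, run.tr, name=f"cond_{c}")
            )
            weights[f"cond_{c}"] = 1.0 / len(uniq)
    else:
        raise ValueError("conditions must be 'pooled' or 'separate'")
    if (~correct).any():
        regs.append(
            build_regressor(
                paradigm.onsets[~correct], hrf, run.n_volumes, run.tr, name="task_incorrect"
            )
        )
    design = make_design(regs, run.n_volumes, run.tr, motion=motion, drift=drift)
    res = fit_glm(run, design)
    w = design.contrast_vector(weights)
    return percent_signal_change(res, w), contrast_t(res, w)
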