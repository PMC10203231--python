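"""Group-level activation maps with and without vascular covariate correction.

Three modes share one machinery: a plain one-sample t-test on per-subject
contrast images; voxel-wise correction, where each voxel gets its own model
of the subject contrast values on a mean-centred covariate image value at
that voxel (the adjusted group effect being the intercept t with n-2
degrees of freedom); and ROI-level correction, where one scalar covariate
per subject per ROI plays the same role inside ROI masks. A sign-flip
permutation cluster-extent null replaces external cluster-simulation
tooling, and a sensitivity report compares suprathreshold counts and peak t
across modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as st

__all__ = [
    "GroupStatMap",
    "SensitivityReport",
    "group_ttest",
    "voxelwise_covariate_correction",
    "roi_covariate_correction",
    "compare_sensitivity",
    "cluster_extent_threshold",
]

log = logging.getLogger(__name__)


@dataclass
class GroupStatMap:
    """Group-level t map over ``mask`` with one-sided upper-tail p."""

    t: np.ndarray
    p: np.ndarray
    dof: int
    mask: np.ndarray
    mode: str
    fallback_voxels: int = 0

    def volume(self, which: str = "t", fill: float = np.nan) -> np.ndarray:
        out = np.full(self.mask.shape, fill)
        out[self.mask] = getattr(self, which)
        return out


@dataclass
class SensitivityReport:
    """Suprathreshold counts and peak t per mode, and corrected-uncorrected deltas."""

    n_suprathreshold: dict
    peak_t: dict
    delta_voxels: dict = field(default_factory=dict)
    delta_peak_t: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_suprathreshold": self.n_suprathreshold,
            "peak_t": self.peak_t,
            "delta_voxels": self.delta_voxels,
            "delta_peak_t": self.delta_peak_t,
        }


def _stack_masked(images, mask):
    imgs = np.asarray(images, float)
    if imgs.ndim != 4:
        raise ValueError("images must be a (n_subjects, x, y, z) stack")
    return imgs[:, mask]  # (n, V)


def group_ttest(contrast_images, mask=None) -> GroupStatMap:
    """Standard one-sample t-test across subjects, per voxel.

    Voxels with zero between-subject variance are removed from the output
    mask (with a log entry); dof = n - 1.
    """
    imgs = np.asarray(contrast_images, float)
    n = imgs.shape[0]
    if n < 3:
        raise ValueError("group_ttest needs at least 3 subjects")
    if mask is None:
        mask = np.ones(imgs.shape[1:], bool)
    Y = _stack_masked(imgs, mask)
    sd = Y.std(axis=0, ddof=1)
    good = sd > 0
    if not good.all():
        log.info("group_ttest: masking %d zero-variance voxels", int((~good).sum()))
    outmask = mask.copy()
    outmask[mask] = good
    ybar = Y.mean(axis=0)[good]
    t = ybar / (sd[good] / np.sqrt(n))
    return GroupStatMap(t=t, p=st.t.sf(t, n - 1), dof=n - 1, mask=outmask, mode="uncorrected")


def voxelwise_covariate_correction(contrast_images, covariate_images, mask=None) -> GroupStatMap:
    """Group effect adjusted for a per-subject covariate image, voxel by voxel.

    At each voxel the subject contrast values are modelled on an intercept
    and the mean-centred covariate values at that voxel; the reported
    statistic is the intercept t (the covariate-adjusted group mean) with
    dof = n - 2. Voxels where the covariate has zero between-subject
    variance fall back to the uncorrected one-sample model and are counted
    in ``fallback_voxels``.
    """
    imgs = np.asarray(contrast_images, float)
    covs = np.asarray(covariate_images, float)
    if imgs.shape != covs.shape:
        raise ValueError("contrast and covariate stacks must have identical shapes")
    n = imgs.shape[0]
    if n < 4:
        raise ValueError("voxelwise correction needs at least 4 subjects")
    if mask is None:
        mask = np.ones(imgs.shape[1:], bool)
    Y = _stack_masked(imgs, mask)
    C = _stack_masked(covs, mask)
    Cc = C - C.mean(axis=0)
    scc = (Cc**2).sum(axis=0)
    cov_ok = scc > 0
    ybar = Y.mean(axis=0)
    Yc = Y - ybar
    with np.errstate(divide="ignore", invalid="ignore"):
        b1 = np.where(cov_ok, (Cc * Yc).sum(axis=0) / np.where(cov_ok, scc, 1.0), 0.0)
    rss = (Yc**2).sum(axis=0) - b1**2 * np.where(cov_ok, scc, 0.0)
    rss = np.clip(rss, 0.0, None)
    dof_vec = np.where(cov_ok, n - 2, n - 1)
    sigma2 = rss / dof_vec
    se = np.sqrt(sigma2 / n)  # centred covariate is orthogonal to the intercept
    good = se > 0
    outmask = mask.copy()
    outmask[mask] = good
    t = ybar[good] / se[good]
    p = st.t.sf(t, dof_vec[good])
    n_fallback = int((~cov_ok).sum())
    if n_fallback:
        log.info("voxelwise correction: %d voxels fell back to the uncorrected model", n_fallback)
    return GroupStatMap(
        t=t, p=p, dof=n - 2, mask=outmask, mode="voxel_covariate", fallback_voxels=n_fallback
    )


def roi_covariate_correction(contrast_images, roi_values: dict, roi_masks: dict) -> GroupStatMap:
    """Group effect adjusted for a scalar per-subject covariate, inside ROI masks.

    ``roi_values[roi]`` is the per-subject covariate vector (e.g. the ROI's
    averaged breath-hold PSC); ``roi_masks[roi]`` the binary search mask.
    Within each mask every voxel uses the same mean-centred scalar covariate;
    the intercept t (dof n - 2) is reported. ROIs absent from ``roi_masks``
    are absent from the output.
    """
    imgs = np.asarray(contrast_images, float)
    n = imgs.shape[0]
    if n < 4:
        raise ValueError("roi covariate correction needs at least 4 subjects")
    if not roi_masks:
        raise ValueError("no ROI masks given")
    union = np.zeros(imgs.shape[1:], bool)
    tvol = np.full(imgs.shape[1:], np.nan)
    dofmap = {}
    for roi, m in roi_masks.items():
        if not m.any():
            raise ValueError(f"ROI {roi} mask is empty")
        c = np.asarray(roi_values[roi], float)
        if c.size != n:
            raise ValueError("one covariate value per subject per ROI required")
        covs = np.broadcast_to(c[:, None, None, None], imgs.shape)
        sub = voxelwise_covariate_correction(imgs, covs, mask=m)
        tvol[sub.mask] = sub.t
        union |= sub.mask
        dofmap[roi] = sub.dof
    t = tvol[union]
    return GroupStatMap(t=t, p=st.t.sf(t, n - 2), dof=n - 2, mask=union, mode="roi_covariate")


def cluster_extent_threshold(
    contrast_images,
    mask=None,
    voxel_p: float = 0.005,
    n_permutations: int = 1000,
    fwe: float = 0.05,
    seed: int = 0,
) -> int:
    """Sign-flip permutation null for cluster extent.

    Under exchangeable symmetric noise, random sign flips of the subject
    images generate the null distribution of the largest suprathreshold
    cluster (one-sample t at ``voxel_p``, one-sided). Returns the cluster
    extent (voxel count) at the ``1 - fwe`` quantile: clusters at least this
    large are familywise-significant.
    """
    imgs = np.asarray(contrast_images, float)
    n = imgs.shape[0]
    if mask is None:
        mask = np.ones(imgs.shape[1:], bool)
    Y = _stack_masked(imgs, mask)
    tcrit = st.t.isf(voxel_p, n - 1)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_permutations, int)
    sqrt_n = np.sqrt(n)
    for i in range(n_permutations):
        signs = rng.choice([-1.0, 1.0], size=n)
        Yp = Y * signs[:, None]
        sd = Yp.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd > 0, Yp.mean(axis=0) / (sd / sqrt_n), 0.0)
        sig = np.zeros(mask.shape, bool)
        sig[mask] = t > tcrit
        _, sizes = _clusters(sig)
        maxima[i] = sizes.max() if sizes.size else 0
    return int(np.quantile(maxima, 1 - fwe, method="higher"))


def _clusters(binary: np.ndarray):
    lab, nlab = ndimage.label(binary)
    if nlab == 0:
        return lab, np.array([], int)
    sizes = ndimage.sum_labels(binary, lab, index=np.arange(1, nlab + 1)).astype(int)
    return lab, sizes


def compare_sensitivity(
    maps: dict[str, GroupStatMap],
    voxel_p: float = 0.001,
    cluster_extent: int = 0,
    reference: str = "uncorrected",
) -> SensitivityReport:
    """Suprathreshold voxel counts and peak t per mode, with deltas vs reference.

    Each map is thresholded at its own one-sided ``voxel_p``; clusters
    smaller than ``cluster_extent`` voxels are then discarded. Deltas are
    corrected minus the ``reference`` mode.
    """
    if not (0 < voxel_p < 1):
        raise ValueError("voxel_p must lie in (0, 1)")
    counts, peaks = {}, {}
    for mode, m in maps.items():
        sig = np.zeros(m.mask.shape, bool)
        sig[m.mask] = m.p < voxel_p
        if cluster_extent > 1:
            lab, sizes = _clusters(sig)
            for i, s in enumerate(sizes, start=1):
                if s < cluster_extent:
                    sig[lab == i] = False
        counts[mode] = int(sig.sum())
        peaks[mode] = float(np.max(m.t)) if m.t.size else float("nan")
    report = SensitivityReport(n_suprathreshold=counts, peak_t=peaks)
    if reference in maps:
        for mode in maps:
            if mode == reference:
                continue
            report.delta_voxels[mode] = counts[mode] - counts[reference]
            report.delta_peak_t[mode] = peaks[mode] - peaks[reference]
    return report
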