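"""Artifact scoring, dose-matching arithmetic and paired statistics.

The artifact score for one reconstruction is the absolute difference
between the mean HU of artifact-affected regions of interest and the mean
HU of a uniformity region on an insert-free reconstruction of the same
arm.  The absolute value matters: metal streaks show up as both intensity
loss and gain depending on direction.  Lower is better.

Method arms are compared with classical paired t-tests on scores paired
by (phantom, replicate); the pairwise matrix carries a directionality
sign, ``+`` in cell (X, Y) meaning the column method Y scores lower
(better) than the row method X.  No multiple-testing correction is
applied — raw pairwise p-values are reported at alpha = 0.01.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import PhantomSpec
from .recon import ReconImage

__all__ = [
    "ROISpec",
    "ComparisonMatrix",
    "auto_rois",
    "artifact_score",
    "cupping_metric",
    "dap_match_check",
    "paired_t_test",
    "comparison_table",
    "ARMS",
]

ARMS = ("routine_100kV", "MAR", "VMI", "VMI_MAR")


class DegenerateScoresError(ValueError):
    """Paired differences have zero variance but a nonzero mean."""


@dataclass(frozen=True)
class ROISpec:
    """Circular ROIs in pixel coordinates.

    ``artifact_rois`` is a tuple of ``(row, col, radius)`` discs on the
    artifact-affected image; ``uniformity_roi`` one disc on the insert-free
    image.
    """

    artifact_rois: tuple[tuple[float, float, float], ...]
    uniformity_roi: tuple[float, float, float]

    def __post_init__(self):
        if len(self.artifact_rois) == 0:
            raise ValueError("need at least one artifact ROI")
        for r, c, rad in (*self.artifact_rois, self.uniformity_roi):
            if rad <= 0:
                raise ValueError("ROI radius must be positive")


def _disc_mask(shape, row, col, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    mask = (rr - row) ** 2 + (cc - col) ** 2 <= radius**2
    if not mask.any():
        raise ValueError("ROI lies outside the image")
    return mask


def auto_rois(spec: PhantomSpec, roi_radius_px: float = 5.0,
              gap_px: float = 3.0,
              uniformity_radius_px: float = 8.0) -> ROISpec:
    """Place four artifact ROIs diagonally around a phantom's insert(s).

    ROI centers sit at 45/135/225/315 degrees around the centroid of the
    insert group, at a clearance of ``ROI radius + gap`` beyond the
    outermost insert edge, so the discs sample the most artifact-affected
    neighborhood without touching any insert footprint.  The uniformity
    ROI is a disc at the center of the (insert-free) uniformity image.
    """
    if not spec.inserts:
        raise ValueError("automatic ROI placement needs at least one insert")
    n = spec.grid_size
    c0 = (n - 1) / 2.0
    px = spec.pixel_spacing_mm
    centers = np.array([i.center_mm for i in spec.inserts], dtype=float)
    centroid = centers.mean(axis=0)
    # image convention: row ~ y, col ~ x
    ic_row = c0 + centroid[1] / px
    ic_col = c0 + centroid[0] / px
    reach_mm = max(np.hypot(*(c - centroid)) + max(i.radii_mm)
                   for c, i in zip(centers, spec.inserts))
    dist = reach_mm / px + roi_radius_px + gap_px
    rois = []
    for ang in (45, 135, 225, 315):
        a = np.deg2rad(ang)
        rois.append((ic_row + dist * np.sin(a), ic_col + dist * np.cos(a),
                     roi_radius_px))
    return ROISpec(artifact_rois=tuple(rois),
                   uniformity_roi=(c0, c0, uniformity_radius_px))


def artifact_score(img: ReconImage, uniformity_img: ReconImage,
                   rois: ROISpec) -> float:
    """Mean over per-ROI |mean(ROI_artifact) - mean(ROI_uniformity)| (HU)."""
    for im in (img, uniformity_img):
        if im.semantics != "HU":
            raise ValueError("artifact scoring expects HU images")
    u_mask = _disc_mask(uniformity_img.values.shape, *rois.uniformity_roi)
    u_mean = uniformity_img.values[u_mask].mean()
    scores = []
    for row, col, rad in rois.artifact_rois:
        mask = _disc_mask(img.values.shape, row, col, rad)
        scores.append(abs(img.values[mask].mean() - u_mean))
    return float(np.mean(scores))


def cupping_metric(img: ReconImage, disc_radius_px: float) -> float:
    """Center-to-edge mean difference inside a uniform disc (image units).

    Beam hardening depresses the center of a uniform object relative to
    its periphery; the metric is |mean(r < 0.25 R) - mean(0.55 R < r <
    0.8 R)| and should shrink under monochromatic synthesis.
    """
    n = img.values.shape[0]
    c0 = (n - 1) / 2.0
    rr, cc = np.ogrid[:n, :n]
    dist = np.sqrt((rr - c0) ** 2 + (cc - c0) ** 2)
    center = img.values[dist < 0.25 * disc_radius_px].mean()
    edge = img.values[(dist > 0.55 * disc_radius_px)
                      & (dist < 0.8 * disc_radius_px)].mean()
    return float(abs(center - edge))


def dap_match_check(dap_low: float, dap_routine: float,
                    dap_high: float) -> float:
    """Percent dose difference of the dual-energy pair vs the routine scan.

    ``100 * ((DAP_low + DAP_high) / DAP_routine - 1)``, rounded to one
    decimal for reporting.  Positive means the dual-energy protocol
    deposits more dose than the routine acquisition it replaces.
    """
    if min(dap_low, dap_routine, dap_high) <= 0:
        raise ValueError("DAP values must be positive")
    return round(100.0 * ((dap_low + dap_high) / dap_routine - 1.0), 1)


def paired_t_test(scores_a, scores_b) -> tuple[float, float, str]:
    """Classical paired t-test with a directionality sign.

    Returns ``(t, p, direction)`` where the two-sided p comes from the t
    distribution with n-1 degrees of freedom and direction is ``"+"``
    when ``scores_b`` has the lower mean (method b better at artifact
    reduction), ``"-"`` otherwise.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score sequences must have equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0, "="
        raise DegenerateScoresError(
            "constant nonzero paired differences: t is undefined")
    t = d.mean() / (sd / np.sqrt(d.size))
    p = 2.0 * stats.t.sf(abs(t), df=d.size - 1)
    direction = "+" if b.mean() < a.mean() else "-"
    return float(t), float(p), direction


@dataclass
class ComparisonMatrix:
    """Pairwise p-values and directionality between method arms."""

    p_values: pd.DataFrame
    direction: pd.DataFrame

    def formatted(self, alpha: float = 0.01) -> pd.DataFrame:
        """Human-readable cells like '<0.01 (+)' mirroring the score table."""
        out = self.p_values.copy().astype(object)
        for r in out.index:
            for c in out.columns:
                if r == c:
                    out.loc[r, c] = "1"
                    continue
                p = self.p_values.loc[r, c]
                ptxt = f"<{alpha:g}" if p < alpha else f"{p:.3g}"
                out.loc[r, c] = f"{ptxt} ({self.direction.loc[r, c]})"
        return out


def comparison_table(scores: pd.DataFrame, alpha: float = 0.01,
                     arms=ARMS) -> ComparisonMatrix:
    """All pairwise paired t-tests between method arms.

    ``scores`` needs columns ``phantom``, ``replicate``, ``arm``,
    ``score``; slice-wise scores are aggregated across phantoms, pairing
    on (phantom, replicate).  Cell (X, Y) holds the p-value of X vs Y and
    the sign is ``+`` when Y scores lower; the matrix is antisymmetric in
    sign with a p = 1 diagonal.
    """
    wide = scores.pivot_table(index=["phantom", "replicate"],
                              columns="arm", values="score")
    missing = [a for a in arms if a not in wide.columns]
    if missing or wide.isna().any().any():
        raise ValueError(f"every (phantom, replicate) needs all arms; "
                         f"missing {missing or 'some cells'}")
    p = pd.DataFrame(np.ones((len(arms), len(arms))), index=arms,
                     columns=arms)
    sign = pd.DataFrame("", index=arms, columns=arms)
    for x in arms:
        for y in arms:
            if x == y:
                continue
            _, pv, d = paired_t_test(wide[x].to_numpy(), wide[y].to_numpy())
            p.loc[x, y] = pv
            sign.loc[x, y] = d
    return ComparisonMatrix(p_values=p, direction=sign)
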