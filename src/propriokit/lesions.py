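"""Lesion-derived features: volume and the VLSM mean-Z score.

Voxel-based lesion-symptom mapping (VLSM) relates lesion location to
behaviour one voxel at a time: at each voxel, participants are split into
those with and without a lesion there and their behavioural scores are
compared; the test statistic becomes a z-score for that voxel.  Only
voxels lesioned in at least a minimum fraction of the cohort (5% by
convention) are tested, for statistical power.  A participant's **VLSM
mean Z** is the mean of the resulting z-map over their own lesioned,
tested voxels — a scalar summary of how behaviourally "eloquent" their
lesion location is.

The default voxel-wise test is a pooled-variance two-sample t converted to
a z-score through the normal quantile of the t cumulative probability;
positive z means the lesioned group scores higher (worse).  A rank-sum
(Mann-Whitney, normal approximation) alternative is available via
``test="ranksum"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import scipy.special as sc
import scipy.stats as st

__all__ = [
    "LesionMask",
    "VLSMMap",
    "MeanZResult",
    "lesion_volume",
    "min_overlap_count",
    "vlsm_zmap",
    "vlsm_mean_z",
    "vlsm_mean_z_loo",
]

_Z_CAP = 8.2  # |z| cap: beyond this the normal quantile saturates numerically


@dataclass
class LesionMask:
    """Binary 3D lesion mask with voxel geometry."""

    data: np.ndarray  # bool, 3D
    voxel_size: tuple[float, float, float]  # mm per axis
    space: str = "unspecified"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("lesion mask must be 3D")
        if self.data.dtype != bool:
            uniq = np.unique(self.data)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("lesion mask must be binary")
            self.data = self.data.astype(bool)
        if not self.data.any():
            raise ValueError("lesion mask must contain at least one lesioned voxel")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be three positive extents (mm)")

    # -- NIfTI I/O --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        affine = np.diag(list(self.voxel_size) + [1.0])
        img = nib.Nifti1Image(self.data.astype(np.uint8), affine)
        img.header.set_zooms(self.voxel_size)
        img.header["descrip"] = self.space.encode()[:79]
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "LesionMask":
        img = nib.load(str(path))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        space = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="replace") or "unspecified"
        return cls(data=np.asarray(img.dataobj) > 0.5, voxel_size=zooms, space=space)


@dataclass
class VLSMMap:
    """Voxel-wise z-statistic map from a lesion-behaviour comparison."""

    z: np.ndarray  # float 3D; NaN where untested
    tested: np.ndarray  # bool 3D
    overlap: np.ndarray  # int 3D: number of participants lesioned per voxel
    min_overlap: int
    voxel_size: tuple[float, float, float]

    def save(self, path: str | Path) -> None:
        affine = np.diag(list(self.voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(self.z.astype(np.float32), affine), str(path))


@dataclass(frozen=True)
class MeanZResult:
    """VLSM mean Z for one participant's lesion."""

    value: float
    n_voxels: int  # lesioned voxels that were tested
    no_tested_voxels: bool  # True when the lesion touched no tested voxel


def lesion_volume(mask: LesionMask) -> float:
    """Lesion volume in cubic centimetres (voxel count x voxel volume)."""
    voxel_cc = math.prod(mask.voxel_size) / 1000.0  # mm^3 -> cc
    return float(mask.data.sum() * voxel_cc)


def min_overlap_count(n_participants: int, fraction: float = 0.05) -> int:
    """Smallest integer >= fraction x n participants (minimum-overlap rule)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    return int(math.ceil(fraction * n_participants))


def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Map t statistics to z through the normal quantile of the t CDF, sign-safely."""
    # work on |t| in the survival tail for numerical stability, then restore sign
    sf = st.t.sf(np.abs(t), df)
    z = -sc.ndtri(np.clip(sf, 1e-300, 1.0))
    z = np.clip(z, 0.0, _Z_CAP)
    return np.sign(t) * z


def vlsm_zmap(
    masks: list[LesionMask],
    scores: np.ndarray,
    fraction: float = 0.05,
    test: str = "t",
) -> VLSMMap:
    """Voxel-wise lesion-symptom map.

    At each voxel lesioned in at least ``min_overlap_count(n, fraction)``
    participants (and with at least two participants in both the lesioned
    and non-lesioned groups), the behavioural ``scores`` of the two groups
    are compared and the statistic converted to a z-score; z > 0 means the
    lesioned group scores higher (worse).  ``test`` is ``"t"`` (pooled
    variance) or ``"ranksum"`` (Mann-Whitney normal approximation with tie
    correction).
    """
    n = len(masks)
    scores = np.asarray(scores, dtype=float)
    if len(scores) != n:
        raise ValueError("masks and scores must have equal length")
    shape = masks[0].data.shape
    vox = masks[0].voxel_size
    for m in masks:
        if m.data.shape != shape:
            raise ValueError("all masks must share one grid")
    M = np.stack([m.data.reshape(-1) for m in masks])  # (n, V) bool

    n1 = M.sum(axis=0)
    n0 = n - n1
    min_overlap = min_overlap_count(n, fraction)
    tested = (n1 >= max(min_overlap, 2)) & (n0 >= 2)

    z_flat = np.full(M.shape[1], np.nan)
    if tested.any():
        Mt = M[:, tested].astype(float)
        n1t, n0t = n1[tested], n0[tested]
        if test == "t":
            s1 = scores @ Mt
            s1_sq = (scores**2) @ Mt
            s_all, s_all_sq = scores.sum(), (scores**2).sum()
            mean1 = s1 / n1t
            mean0 = (s_all - s1) / n0t
            ss1 = s1_sq - n1t * mean1**2
            ss0 = (s_all_sq - s1_sq) - n0t * mean0**2
            df = n - 2
            sp2 = (ss1 + ss0) / df
            denom = np.sqrt(sp2 * (1.0 / n1t + 1.0 / n0t))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(denom > 0, (mean1 - mean0) / denom, 0.0)
            z_flat[tested] = _t_to_z(t, df)
        elif test == "ranksum":
            ranks = st.rankdata(scores)
            r1 = ranks @ Mt
            u1 = r1 - n1t * (n1t + 1) / 2.0
            mu = n1t * n0t / 2.0
            _, counts = np.unique(scores, return_counts=True)
            tie_term = (counts**3 - counts).sum() / (n * (n - 1))
            sigma = np.sqrt(n1t * n0t / 12.0 * ((n + 1) - tie_term))
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(sigma > 0, (u1 - mu) / sigma, 0.0)
            z_flat[tested] = np.clip(z, -_Z_CAP, _Z_CAP)
        else:
            raise ValueError(f"unknown test {test!r}")

    return VLSMMap(
        z=z_flat.reshape(shape),
        tested=tested.reshape(shape),
        overlap=n1.reshape(shape).astype(int),
        min_overlap=min_overlap,
        voxel_size=vox,
    )


def vlsm_mean_z(mask: LesionMask, zmap: VLSMMap) -> MeanZResult:
    """Mean z over a participant's lesioned voxels that were tested.

    Lesions touching no tested voxel yield 0 with ``no_tested_voxels=True``.
    """
    if mask.data.shape != zmap.z.shape:
        raise ValueError("lesion mask and z-map grids do not match")
    sel = mask.data & zmap.tested
    k = int(sel.sum())
    if k == 0:
        return MeanZResult(value=0.0, n_voxels=0, no_tested_voxels=True)
    return MeanZResult(value=float(zmap.z[sel].mean()), n_voxels=k, no_tested_voxels=False)


def vlsm_mean_z_loo(
    masks: list[LesionMask],
    scores: np.ndarray,
    fraction: float = 0.05,
    test: str = "t",
) -> list[MeanZResult]:
    """Leave-one-out variant: each participant's mean Z comes from a map fitted
    without that participant.  Avoids the (deliberate, convention-following)
    circularity of scoring a lesion against a map it helped build; off by
    default in the pipeline.
    """
    results = []
    idx = np.arange(len(masks))
    for i in idx:
        keep = idx != i
        zmap = vlsm_zmap([masks[j] for j in idx[keep]], np.asarray(scores)[keep], fraction, test)
        results.append(vlsm_mean_z(masks[i], zmap))
    return results
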