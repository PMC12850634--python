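"""Voxelwise R1/A map computation from weighted NIfTI volumes.

Applies any estimator from :mod:`vfamap.estimators` to a stack of
weighted volumes plus a transmit-field (ft) map, handling masking,
coarse-ft resampling, validity bookkeeping and NIfTI/JSON output.  The
pipeline adds I/O and masking only — per-voxel arithmetic is exactly
the estimators module's (a property the test suite spot-checks to bit
equality).

Inputs are assumed spatially aligned (registration is upstream) and
TE-matched or TE=0-extrapolated (R2* correction is upstream); the
pipeline refuses volumes whose grids or affines disagree.  No receive
bias correction is applied: the A map retains receive-field modulation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .estimators import (
    CAUSE_LABELS,
    UnsupportedProtocolError,
    get_estimator,
)
from .phantom import resample_ft_to_map_space
from .signal_model import AcquisitionProtocol, PreparedAngles

logger = logging.getLogger(__name__)

__all__ = [
    "MapJob",
    "ParameterMap",
    "compute_maps",
    "compute_maps_from_arrays",
    "relative_difference_map",
    "write_parameter_map",
]


@dataclass(frozen=True)
class MapJob:
    """File-level description of one map computation."""

    volume_paths: tuple
    ft_path: str
    protocol: AcquisitionProtocol
    method: str = "pade"
    mask_path: Optional[str] = None
    out_dir: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "volume_paths", tuple(str(p) for p in self.volume_paths))
        if len(self.volume_paths) != self.protocol.n_volumes:
            raise ValueError(
                f"{len(self.volume_paths)} volumes given but protocol has "
                f"{self.protocol.n_volumes}"
            )


@dataclass
class ParameterMap:
    """Voxel maps of R1 (s^-1) and A (a.u.) with validity mask and provenance.

    Voxels outside ``valid_mask`` are NaN in both maps.
    """

    r1_map: np.ndarray
    a_map: np.ndarray
    valid_mask: np.ndarray
    affine: np.ndarray
    provenance: dict = field(default_factory=dict)


def _check_method_protocol(method: str, protocol: AcquisitionProtocol) -> None:
    if method in ("exact", "exact_equal_tr") and not protocol.equal_tr:
        raise UnsupportedProtocolError(
            "exact equal-TR estimator requires equal repetition times; "
            "use pade or despot1"
        )


def compute_maps_from_arrays(
    volumes: np.ndarray,
    ft: np.ndarray,
    protocol: AcquisitionProtocol,
    method: str = "pade",
    mask: Optional[np.ndarray] = None,
    affine: Optional[np.ndarray] = None,
) -> tuple:
    """Array-level map computation.

    Parameters
    ----------
    volumes:
        Stack of weighted volumes, shape ``(n_volumes,) + grid``.
    ft:
        Transmit-field map on the same grid (dimensionless fraction).
    mask:
        Optional boolean mask restricting computation.

    Returns
    -------
    (ParameterMap, summary) where summary counts valid voxels and invalid
    voxels by cause; ``n_total = n_valid + sum(invalid by cause)``.
    """
    _check_method_protocol(method, protocol)
    volumes = np.asarray(volumes, dtype=float)
    grid = volumes.shape[1:]
    ft = np.asarray(ft, dtype=float)
    if ft.shape != grid:
        raise ValueError(f"ft shape {ft.shape} does not match volumes grid {grid}")
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != grid:
        raise ValueError("mask shape does not match volumes grid")

    # ft <= 0 cannot be prepared; treat such voxels as invalid input
    usable = mask & (ft > 0) & (ft * max(protocol.flip_nominal_deg) < 180.0)
    flat_ft = ft[usable]
    sig = volumes[:, usable]
    r1 = np.full(grid, np.nan)
    a = np.full(grid, np.nan)
    valid = np.zeros(grid, dtype=bool)
    cause_counts = {label: 0 for label in CAUSE_LABELS.values() if label != "valid"}
    cause_counts["unusable_ft"] = int(mask.sum() - usable.sum())

    if flat_ft.size:
        prepared = PreparedAngles.from_protocol(protocol, flat_ft)
        estimator = get_estimator(method)
        if method == "nonlinear":
            # per-voxel optimizer loop; intended for small regions
            n = flat_ft.size
            r1_flat = np.full(n, np.nan)
            a_flat = np.full(n, np.nan)
            v_flat = np.zeros(n, dtype=bool)
            causes = np.zeros(n, dtype=np.int8)
            for i in range(n):
                prep_i = PreparedAngles(
                    alpha_rad=prepared.alpha_rad[:, i], tau=prepared.tau[:, i]
                )
                est = estimator(sig[:, i], prep_i, protocol.tr_s_array)
                r1_flat[i] = est.r1_per_s
                a_flat[i] = est.a_au
                v_flat[i] = bool(np.asarray(est.valid))
                causes[i] = 0 if v_flat[i] else 3
        else:
            est = estimator(sig, prepared, protocol.tr_s_array)
            r1_flat, a_flat, v_flat = est.r1_per_s, est.a_au, est.valid
            causes = est.cause if est.cause is not None else np.where(v_flat, 0, 3)
        r1[usable] = r1_flat
        a[usable] = a_flat
        valid[usable] = v_flat
        for code, label in CAUSE_LABELS.items():
            if code == 0:
                continue
            cause_counts[label] += int(np.sum(causes == code))

    summary = {
        "n_total": int(mask.sum()),
        "n_valid": int(valid.sum()),
        "invalid_by_cause": cause_counts,
    }
    if summary["n_valid"] == 0:
        logger.warning("no valid voxels produced (method=%s)", method)
    logger.info(
        "maps computed: %d/%d valid voxels (%s)",
        summary["n_valid"],
        summary["n_total"],
        method,
    )
    pm = ParameterMap(
        r1_map=r1,
        a_map=a,
        valid_mask=valid,
        affine=np.eye(4) if affine is None else np.asarray(affine, dtype=float),
        provenance={
            "method": method,
            "software": f"vfamap {__version__}",
            "protocol": {
                "flip_nominal_deg": list(protocol.flip_nominal_deg),
                "tr_s": list(protocol.tr_s),
            },
            "summary": summary,
        },
    )
    return pm, summary


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def compute_maps(job: MapJob) -> ParameterMap:
    """File-level map computation: read NIfTI inputs, fit, optionally write.

    The ft map may share the weighted volumes' grid or be coarser; a
    coarser map is trilinearly resampled in world coordinates first.
    """
    import nibabel as nib

    _check_method_protocol(job.method, job.protocol)
    imgs = [nib.load(p) for p in job.volume_paths]
    grid = imgs[0].shape
    affine = imgs[0].affine
    for p, img in zip(job.volume_paths, imgs):
        if img.shape != grid or not np.allclose(img.affine, affine, atol=1e-6):
            raise ValueError(f"volume {p} is misaligned with the first volume")
    volumes = np.stack([np.asarray(img.dataobj, dtype=float) for img in imgs])

    ft_img = nib.load(job.ft_path)
    ft_data = np.asarray(ft_img.dataobj, dtype=float)
    if ft_img.shape == grid and np.allclose(ft_img.affine, affine, atol=1e-6):
        ft = ft_data
    else:
        ft = resample_ft_to_map_space(ft_data, ft_img.affine, grid, affine)

    mask = None
    if job.mask_path is not None:
        mask_img = nib.load(job.mask_path)
        if mask_img.shape != grid or not np.allclose(mask_img.affine, affine, atol=1e-6):
            raise ValueError("mask is misaligned with the weighted volumes")
        mask = np.asarray(mask_img.dataobj) > 0.5

    pm, summary = compute_maps_from_arrays(
        volumes, ft, job.protocol, job.method, mask=mask, affine=affine
    )
    pm.provenance["inputs"] = {
        str(p): _sha256(p) for p in list(job.volume_paths) + [job.ft_path]
        + ([job.mask_path] if job.mask_path else [])
    }
    if job.out_dir is not None:
        write_parameter_map(pm, job.out_dir, prefix=job.method)
    return pm


def write_parameter_map(pm: ParameterMap, out_dir, prefix: str = "") -> dict:
    """Write R1/A/validity volumes (float32 NIfTI) and a provenance sidecar."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = f"{prefix}_" if prefix else ""
    paths = {}
    for name, data in (
        ("r1", pm.r1_map),
        ("a", pm.a_map),
        ("valid", pm.valid_mask.astype(np.float32)),
    ):
        p = out_dir / f"{tag}{name}.nii"
        nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), pm.affine), p)
        paths[name] = p
    sidecar = out_dir / f"{tag}provenance.json"
    sidecar.write_text(json.dumps(pm.provenance, indent=2, default=str))
    paths["provenance"] = sidecar
    return paths


def relative_difference_map(map_a: ParameterMap, map_b: ParameterMap, which: str = "r1") -> np.ndarray:
    """Voxelwise percent difference ``100 (a - b) / b`` on the mask overlap.

    ``which`` selects the parameter ("r1" or "a").  NaN outside the mask
    intersection and where the reference is zero (counted in a warning).
    """
    if map_a.r1_map.shape != map_b.r1_map.shape:
        raise ValueError("maps are on different grids")
    both = map_a.valid_mask & map_b.valid_mask
    if not both.any():
        raise ValueError("valid masks are disjoint; no voxels to compare")
    va = map_a.r1_map if which == "r1" else map_a.a_map
    vb = map_b.r1_map if which == "r1" else map_b.a_map
    out = np.full(va.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = 100.0 * (va[both] - vb[both]) / vb[both]
    n_zero = int(np.sum(vb[both] == 0))
    if n_zero:
        logger.warning("%d reference voxels are zero; set to NaN", n_zero)
        rel[vb[both] == 0] = np.nan
    out[both] = rel
    return out
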