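"""Seeded synthetic phantom generator for dual flip angle mapping.

Produces the full set of volumes a desk-scale mapping experiment needs:
PD- and T1-weighted FLASH volumes generated voxelwise by the exact Ernst
equation, a smooth transmit-field (ft) map at full resolution plus a
deliberately coarse copy (emulating the low-resolution acquisition of
real B1+ mapping), ground-truth R1 and A maps, and per-compartment
masks.  Geometry is a stack of ellipsoidal tissue compartments on a
zero-signal background; the default phantom nests a "GM" shell around a
"WM" core with a single-lobe Gaussian ft field spanning the in vivo
transmit range, mimicking the center-bright transmit pattern of a head
coil at 7T.

Conventions: identity-like affine (voxel scaling only), 0-based voxel
indices, world coordinate = voxel index * voxel size (so the coarse ft
grid's affine carries the half-block offset that keeps coarse and fine
voxel centers aligned in world space).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.ndimage

from .signal_model import AcquisitionProtocol, PreparedAngles, TissueParams, ernst_signal

__all__ = [
    "Ellipsoid",
    "Compartment",
    "GaussianFtField",
    "PhantomSpec",
    "PhantomBundle",
    "default_spec",
    "generate_phantom",
    "resample_ft_to_map_space",
    "write_phantom",
]


class GeometryError(ValueError):
    """Raised when phantom geometry does not fit the voxel grid."""


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in voxel coordinates."""

    center_vox: tuple
    semiaxes_vox: tuple

    def mask(self, shape: tuple) -> np.ndarray:
        c = np.asarray(self.center_vox, dtype=float)
        s = np.asarray(self.semiaxes_vox, dtype=float)
        if np.any(c - s < -0.5) or np.any(c + s > np.asarray(shape) - 0.5):
            raise GeometryError(
                f"ellipsoid (center {self.center_vox}, semiaxes {self.semiaxes_vox}) "
                f"extends outside grid of shape {shape}"
            )
        grids = np.ogrid[tuple(slice(0, n) for n in shape)]
        d2 = sum(((g - ci) / si) ** 2 for g, ci, si in zip(grids, c, s))
        return d2 <= 1.0


@dataclass(frozen=True)
class Compartment:
    label: str
    geometry: Ellipsoid
    tissue: TissueParams


@dataclass(frozen=True)
class GaussianFtField:
    """Single-lobe Gaussian transmit field, min-max rescaled to a target span.

    The raw lobe ``exp(-0.5 |r - c|^2 / w^2)`` (c, w in fractions of the
    grid) is affinely rescaled so that its minimum and maximum over the
    grid hit ``ft_min`` and ``ft_max`` exactly.
    """

    ft_min: float = 0.45
    ft_max: float = 1.35
    center_frac: tuple = (0.45, 0.55, 0.4)
    width_frac: float = 0.35

    def __post_init__(self):
        if not (0.0 < self.ft_min <= self.ft_max < 1.8):
            raise ValueError("ft span must satisfy 0 < ft_min <= ft_max < 1.8")

    def evaluate(self, shape: tuple) -> np.ndarray:
        grids = np.ogrid[tuple(slice(0, n) for n in shape)]
        c = [f * (n - 1) for f, n in zip(self.center_frac, shape)]
        w = self.width_frac * max(shape)
        d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        raw = np.exp(-0.5 * d2 / w**2)
        lo, hi = raw.min(), raw.max()
        if hi == lo:
            return np.full(shape, 0.5 * (self.ft_min + self.ft_max))
        return self.ft_min + (raw - lo) * (self.ft_max - self.ft_min) / (hi - lo)


def default_compartments(shape: tuple) -> tuple:
    """Two nested ellipsoids: a "GM" shell (R1=0.55 s^-1, an arbitrary but
    plausible cortical value) overwritten by a "WM" core (R1=0.82 s^-1,
    typical of human white matter at 7T); A=1 in both."""
    c = tuple((n - 1) / 2.0 for n in shape)
    outer = tuple(0.42 * n for n in shape)
    inner = tuple(0.26 * n for n in shape)
    return (
        Compartment("GM", Ellipsoid(c, outer), TissueParams(0.55, 1.0)),
        Compartment("WM", Ellipsoid(c, inner), TissueParams(0.82, 1.0)),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic phantom; deterministic given seed."""

    shape: tuple = (64, 64, 64)
    voxel_size_mm: float = 1.0
    compartments: tuple = ()
    ft_field: GaussianFtField = field(default_factory=GaussianFtField)
    ft_map_downsample: int = 4
    noise_sd: Optional[float] = 0.0  # a.u.; None = auto (SNR 100 in WM PDw)
    seed: int = 0
    protocol: AcquisitionProtocol = field(
        default_factory=AcquisitionProtocol.in_vivo_7t
    )

    def __post_init__(self):
        if len(self.shape) != 3 or any(n < 2 for n in self.shape):
            raise ValueError("shape must be a 3-D grid with at least 2 voxels per axis")
        k = self.ft_map_downsample
        if k < 1 or any(n % k for n in self.shape):
            raise ValueError(
                "ft_map_downsample must be >= 1 and divide every grid dimension"
            )
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.compartments:
            object.__setattr__(self, "compartments", default_compartments(self.shape))

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "voxel_size_mm": self.voxel_size_mm,
            "compartments": [
                {
                    "label": comp.label,
                    "center_vox": list(comp.geometry.center_vox),
                    "semiaxes_vox": list(comp.geometry.semiaxes_vox),
                    "r1_per_s": float(np.asarray(comp.tissue.r1_per_s)),
                    "a_au": float(np.asarray(comp.tissue.a_au)),
                }
                for comp in self.compartments
            ],
            "ft_field": dataclasses.asdict(self.ft_field),
            "ft_map_downsample": self.ft_map_downsample,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "protocol": {
                "flip_nominal_deg": list(self.protocol.flip_nominal_deg),
                "tr_ms": [1e3 * t for t in self.protocol.tr_s],
            },
        }


@dataclass
class PhantomBundle:
    """All volumes of one synthetic acquisition, on a shared grid."""

    weighted: np.ndarray  # (n_volumes,) + shape
    ft_true: np.ndarray
    ft_map_coarse: np.ndarray
    truth_r1: np.ndarray
    truth_a: np.ndarray
    masks: dict
    affine: np.ndarray
    affine_coarse: np.ndarray
    spec: PhantomSpec

    @property
    def tissue_mask(self) -> np.ndarray:
        out = np.zeros(self.truth_r1.shape, dtype=bool)
        for m in self.masks.values():
            out |= m
        return out


def _fine_affine(voxel_size: float) -> np.ndarray:
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return aff


def _coarse_affine(voxel_size: float, k: int) -> np.ndarray:
    aff = np.diag([k * voxel_size] * 3 + [1.0])
    aff[:3, 3] = (k - 1) / 2.0 * voxel_size  # coarse centers sit mid-block
    return aff


def _block_mean(vol: np.ndarray, k: int) -> np.ndarray:
    if k == 1:
        return vol.copy()
    nx, ny, nz = vol.shape
    return vol.reshape(nx // k, k, ny // k, k, nz // k, k).mean(axis=(1, 3, 5))


def default_spec(
    preset: str = "invivo",
    shape: tuple = (64, 64, 64),
    noise_sd: Optional[float] = 0.0,
    seed: int = 0,
    ft_map_downsample: int = 4,
) -> PhantomSpec:
    """Convenience spec builder for the two protocol presets."""
    if preset == "invivo":
        protocol = AcquisitionProtocol.in_vivo_7t()
        ft_field = GaussianFtField(ft_min=0.45, ft_max=1.35)
    elif preset == "postmortem":
        protocol = AcquisitionProtocol.postmortem_7t()
        ft_field = GaussianFtField(ft_min=0.60, ft_max=1.10)
    else:
        raise ValueError("preset must be 'invivo' or 'postmortem'")
    return PhantomSpec(
        shape=tuple(shape),
        ft_field=ft_field,
        ft_map_downsample=ft_map_downsample,
        noise_sd=noise_sd,
        seed=seed,
        protocol=protocol,
    )


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Generate all volumes of the phantom described by ``spec``.

    Noiseless weighted volumes satisfy, voxel for voxel,
    ``S_n = ernst_signal(truth, ft_true * alpha_nominal_n, TR_n)`` inside
    compartments and 0 on the background.  With ``noise_sd > 0`` (or
    ``None`` for the automatic SNR-100 default) i.i.d. Gaussian noise is
    added per voxel per volume.  Bit-reproducible given the seed.
    """
    shape = spec.shape
    truth_r1 = np.zeros(shape)
    truth_a = np.zeros(shape)
    masks = {}
    for comp in spec.compartments:  # later compartments overwrite earlier
        m = comp.geometry.mask(shape)
        truth_r1[m] = float(np.asarray(comp.tissue.r1_per_s))
        truth_a[m] = float(np.asarray(comp.tissue.a_au))
        for prev in masks.values():
            prev &= ~m
        masks[comp.label] = m

    ft_true = spec.ft_field.evaluate(shape)
    tissue_mask = truth_r1 > 0

    n_vol = spec.protocol.n_volumes
    weighted = np.zeros((n_vol,) + shape)
    prepared = PreparedAngles.from_protocol(spec.protocol, ft_true[tissue_mask])
    tissue = TissueParams(
        r1_per_s=truth_r1[tissue_mask], a_au=truth_a[tissue_mask]
    )
    for n in range(n_vol):
        vol = np.zeros(shape)
        vol[tissue_mask] = ernst_signal(
            tissue, prepared.alpha_rad[n], spec.protocol.tr_s[n]
        )
        weighted[n] = vol

    noise_sd = spec.noise_sd
    if noise_sd is None:
        # auto: SNR 100 in the PD-weighted signal of the last (innermost)
        # compartment at nominal transmit field
        core = spec.compartments[-1].tissue
        prep1 = PreparedAngles.from_protocol(spec.protocol, 1.0)
        s_ref = ernst_signal(core, prep1.alpha_rad[0], spec.protocol.tr_s[0])
        noise_sd = float(s_ref) / 100.0
    if noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        weighted = weighted + rng.normal(0.0, noise_sd, size=weighted.shape)

    return PhantomBundle(
        weighted=weighted,
        ft_true=ft_true,
        ft_map_coarse=_block_mean(ft_true, spec.ft_map_downsample),
        truth_r1=truth_r1,
        truth_a=truth_a,
        masks=masks,
        affine=_fine_affine(spec.voxel_size_mm),
        affine_coarse=_coarse_affine(spec.voxel_size_mm, spec.ft_map_downsample),
        spec=spec,
    )


def resample_ft_to_map_space(
    ft_coarse: np.ndarray,
    coarse_affine: np.ndarray,
    target_shape: tuple,
    target_affine: np.ndarray,
) -> np.ndarray:
    """Trilinearly interpolate a coarse ft map onto a target voxel grid.

    Interpolation is performed in physical (world) coordinates; target
    voxel centers outside the coarse grid's support are edge-clamped.
    Raises :class:`GeometryError` when the physical extents do not
    overlap at all.
    """
    coarse_affine = np.asarray(coarse_affine, dtype=float)
    target_affine = np.asarray(target_affine, dtype=float)
    idx = np.indices(target_shape, dtype=float).reshape(3, -1)
    world = target_affine[:3, :3] @ idx + target_affine[:3, 3:4]
    inv = np.linalg.inv(coarse_affine)
    coarse_idx = inv[:3, :3] @ world + inv[:3, 3:4]
    upper = np.asarray(ft_coarse.shape, dtype=float).reshape(3, 1) - 1.0
    if np.any(coarse_idx.max(axis=1) < 0) or np.any(
        coarse_idx.min(axis=1) > upper.ravel()
    ):
        raise GeometryError("coarse ft map and target grid do not overlap")
    out = scipy.ndimage.map_coordinates(
        np.asarray(ft_coarse, dtype=float), coarse_idx, order=1, mode="nearest"
    )
    return out.reshape(target_shape)


def write_phantom(bundle: PhantomBundle, out_dir) -> dict:
    """Write the bundle as float32 NIfTI-1 volumes plus a JSON sidecar.

    Returns a mapping of logical names to written paths.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def save(name, data, affine):
        p = out_dir / f"{name}.nii"
        nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), p)
        paths[name] = p

    names = ["pdw"] + [f"t1w{i if i > 1 else ''}" for i in range(1, bundle.weighted.shape[0])]
    for name, vol in zip(names, bundle.weighted):
        save(name, vol, bundle.affine)
    save("ft_true", bundle.ft_true, bundle.affine)
    save("ft_map", bundle.ft_map_coarse, bundle.affine_coarse)
    save("truth_r1", bundle.truth_r1, bundle.affine)
    save("truth_a", bundle.truth_a, bundle.affine)
    for label, mask in bundle.masks.items():
        save(f"mask_{label}", mask.astype(np.float32), bundle.affine)
    sidecar = out_dir / "phantom.json"
    sidecar.write_text(json.dumps(bundle.spec.to_dict(), indent=2))
    paths["sidecar"] = sidecar
    return paths
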