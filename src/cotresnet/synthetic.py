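"""Synthetic 3-D brain phantoms with class-graded atrophy morphology.

Real dementia-stage MRI shows progressive atrophy: ventricular enlargement
and hippocampal thinning that worsen from healthy controls (HC) through mild
cognitive impairment (MCI) to Alzheimer's disease (AD).  The phantoms are a
deliberate caricature of exactly those two signatures:

* an ellipsoidal "head" of bright tissue;
* a central dark "ventricle" ellipsoid whose radius grows HC < MCI < AD;
* a bright curved "hippocampal band" (a half shell) whose thickness shrinks
  HC > MCI > AD;
* additive Gaussian noise.

Per-volume morphology is jittered (radius, thickness, sub-voxel centre
offset) so cohort statistics behave like a sample rather than a constant.
Intensities are in arbitrary units; downstream normalisation maps them to
[0, 255].  Defaults make the AD-vs-HC contrast strong and MCI intermediate,
mirroring the relative difficulty of the clinical tasks.

All randomness flows through one explicit numpy Generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import LABELS, Volume

__all__ = [
    "PhantomParams",
    "generate_phantom_volume",
    "generate_cohort",
    "save_cohort",
    "dark_region_voxels",
    "estimate_ventricle_radius",
    "estimate_band_thickness",
]

# generator intensity constants (arbitrary units, pre-normalisation)
TISSUE = 1000.0
VENTRICLE = 100.0
BAND = 1400.0
DARK_THRESHOLD = (TISSUE + VENTRICLE) / 2.0
BRIGHT_THRESHOLD = (TISSUE + BAND) / 2.0

# ventricle ellipsoid semi-axis factors relative to its nominal radius
_VENT_AXES = (1.0, 1.6, 0.8)
_BAND_RADIUS_FRAC = 0.28  # of grid size


@dataclass(frozen=True)
class PhantomParams:
    """Morphology parameters; linear measures are in voxels at grid=128.

    Class means are strictly ordered: ventricle radius AD > MCI > HC, band
    thickness HC > MCI > AD.  Measures scale proportionally with ``grid``.
    """

    grid: int = 128
    ventricle_radius_mean: dict = field(
        default_factory=lambda: {"HC": 6.0, "MCI": 9.0, "AD": 12.0}
    )
    band_thickness_mean: dict = field(
        default_factory=lambda: {"HC": 6.0, "MCI": 4.5, "AD": 3.0}
    )
    radius_jitter_sd: float = 0.5
    thickness_jitter_sd: float = 0.3
    center_jitter: float = 0.5  # uniform ±jitter sub-voxel ventricle offset
    noise_sd: float = 30.0

    def __post_init__(self):
        if self.grid < 8:
            raise ValueError("grid must be >= 8")
        r, t = self.ventricle_radius_mean, self.band_thickness_mean
        if not (0 < r["HC"] < r["MCI"] < r["AD"]):
            raise ValueError("ventricle radii must be positive with HC < MCI < AD")
        if not (t["AD"] < t["MCI"] < t["HC"]) or t["AD"] <= 0:
            raise ValueError("band thickness must be positive with AD < MCI < HC")
        if min(self.noise_sd, self.radius_jitter_sd,
               self.thickness_jitter_sd, self.center_jitter) < 0:
            raise ValueError("noise and jitter magnitudes must be >= 0")

    @property
    def scale(self) -> float:
        return self.grid / 128.0

    def radius(self, label: str) -> float:
        return self.ventricle_radius_mean[label] * self.scale

    def thickness(self, label: str) -> float:
        return self.band_thickness_mean[label] * self.scale

    @property
    def band_radius(self) -> float:
        return _BAND_RADIUS_FRAC * self.grid


def _coordinate_grid(n: int):
    c = (n - 1) / 2.0
    return np.meshgrid(*(np.arange(n, dtype=np.float32) - c,) * 3, indexing="ij")


def generate_phantom_volume(
    label: str, params: PhantomParams | None = None, rng: np.random.Generator | None = None,
    subject_id: str = "",
) -> Volume:
    """One phantom volume for the given diagnostic class.

    With ``noise_sd=0`` and zero jitter the volume is a deterministic
    function of the label.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    params = params or PhantomParams()
    rng = rng if rng is not None else np.random.default_rng()
    n = params.grid
    xx, yy, zz = _coordinate_grid(n)

    vox = np.zeros((n, n, n), dtype=np.float32)
    # head: bright tissue ellipsoid slightly elongated along the coronal axis
    head = (xx / (0.42 * n)) ** 2 + (yy / (0.46 * n)) ** 2 + (zz / (0.42 * n)) ** 2 <= 1.0
    vox[head] = TISSUE

    # hippocampal band: inferior half shell, class-dependent thickness
    thickness = params.thickness(label) + rng.normal(0.0, params.thickness_jitter_sd)
    thickness = max(thickness, 0.5)
    dist = np.sqrt(xx**2 + yy**2 + zz**2)
    band = (np.abs(dist - params.band_radius) <= thickness / 2.0) & (zz < 0) & head
    vox[band] = BAND

    # ventricle: central dark ellipsoid, class-dependent radius, jittered
    # sub-voxel centre so voxelisation error varies between volumes
    radius = params.radius(label) + rng.normal(0.0, params.radius_jitter_sd)
    radius = max(radius, 1.0)
    off = rng.uniform(-params.center_jitter, params.center_jitter, size=3)
    ax, ay, az = (radius * f for f in _VENT_AXES)
    vent = ((xx - off[0]) / ax) ** 2 + ((yy - off[1]) / ay) ** 2 + ((zz - off[2]) / az) ** 2 <= 1.0
    vox[vent] = VENTRICLE

    if params.noise_sd > 0:
        vox += rng.normal(0.0, params.noise_sd, size=vox.shape).astype(np.float32)

    return Volume(voxels=vox, subject_id=subject_id, label=label, coronal_axis=1)


def generate_cohort(
    n_per_class: tuple[int, int, int] = (200, 187, 116),
    params: PhantomParams | None = None,
    seed: int = 0,
) -> list[Volume]:
    """A labelled cohort: ``n_per_class`` counts in (AD, MCI, HC) order."""
    if any(n < 0 for n in n_per_class):
        raise ValueError("class counts must be >= 0")
    params = params or PhantomParams()
    rng = np.random.default_rng(seed)
    volumes = []
    for label, count in zip(LABELS, n_per_class):
        for i in range(count):
            volumes.append(
                generate_phantom_volume(
                    label, params, rng, subject_id=f"{label}-{i + 1:04d}"
                )
            )
    return volumes


def save_cohort(volumes: list[Volume], outdir) -> Path:
    """Write volumes as NIfTI plus a manifest CSV; returns the manifest path."""
    outdir = Path(outdir)
    (outdir / "volumes").mkdir(parents=True, exist_ok=True)
    rows = []
    for vol in volumes:
        rel = f"volumes/{vol.subject_id}.nii.gz"
        vol.to_nifti(outdir / rel)
        rows.append({"subject_id": vol.subject_id, "path": rel, "label": vol.label})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# morphology estimators (used to verify that phantoms carry their parameters)
# ---------------------------------------------------------------------------

def dark_region_voxels(vol: Volume) -> int:
    """Count of ventricle-dark voxels (inside the head, below threshold)."""
    n = vol.shape[0]
    xx, yy, zz = _coordinate_grid(n)
    head = (xx / (0.42 * n)) ** 2 + (yy / (0.46 * n)) ** 2 + (zz / (0.42 * n)) ** 2 <= 1.0
    return int(((vol.voxels < DARK_THRESHOLD) & head).sum())


def estimate_ventricle_radius(vol: Volume) -> float:
    """Nominal ventricle radius from the dark-region volume.

    Inverts V = (4/3)π · (a·b·c) r³ where (a, b, c) are the fixed semi-axis
    factors of the generator's ventricle ellipsoid.
    """
    v = dark_region_voxels(vol)
    factor = 4.0 / 3.0 * np.pi * np.prod(_VENT_AXES)
    return float((v / factor) ** (1.0 / 3.0))


def estimate_band_thickness(vol: Volume, params: PhantomParams) -> float:
    """Band thickness from the bright voxel count (half-shell geometry).

    A thin half shell of mid radius R and thickness t holds ≈ 2πR²t voxels.
    """
    bright = int((vol.voxels > BRIGHT_THRESHOLD).sum())
    return float(bright / (2.0 * np.pi * params.band_radius**2))
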