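"""Core in-memory containers shared by all pipeline stages.

Every image-bearing type carries its physical pixel size so downstream
stages (area in µm², displacements in µm, tractions in Pa) never have to
guess units. Containers are thin dataclasses around numpy arrays; they
validate their invariants at construction and are otherwise inert.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

__all__ = [
    "ChannelImage",
    "LabelMask",
    "CellRecord",
    "FretTriplet",
    "FretCalibration",
    "FretResult",
    "Substrate",
    "DisplacementField",
    "TractionField",
    "GroundTruth",
]


@dataclass
class ChannelImage:
    """Single-channel 2-D intensity image.

    Parameters
    ----------
    pixels : 2-D float array of finite, non-negative intensities.
    pixel_size : physical sampling, µm per pixel (> 0).
    channel_name : free-text channel label ("dapi", "donor", ...).
    """

    pixels: np.ndarray
    pixel_size: float = 0.1
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite intensities")
        if np.any(self.pixels < 0):
            raise ValueError("image contains negative intensities")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "ChannelImage":
        """Copy of this image with new pixel data, same metadata."""
        return ChannelImage(pixels, self.pixel_size, self.channel_name)


@dataclass
class LabelMask:
    """Labeled object mask: 0 = background, k > 0 = object k.

    Labels are kept contiguous 1..K so per-object tables index cleanly.
    """

    labels: np.ndarray
    pixel_size: float = 0.1

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        present = np.unique(self.labels)
        present = present[present > 0]
        if present.size and not np.array_equal(present, np.arange(1, present.size + 1)):
            raise ValueError("label set must be contiguous 1..K")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def areas_um2(self) -> np.ndarray:
        """Pixel-count area of each label, in µm², ordered by label id."""
        counts = np.bincount(self.labels.ravel(), minlength=self.n_labels + 1)[1:]
        return counts * self.pixel_size**2

    def border_labels(self) -> set[int]:
        """Labels with at least one pixel on the image border."""
        lab = self.labels
        edge = np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])
        return set(int(v) for v in np.unique(edge) if v > 0)


@dataclass
class CellRecord:
    """Per-cell quantification row (one nucleus = one record)."""

    cell_id: int
    nuclear_area: float = float("nan")  # µm²
    cell_area: float = float("nan")  # µm² (independent F-actin measurement)
    nc_ratio: float = float("nan")
    mean_nuclear_intensity: float = float("nan")
    mean_ring_intensity: float = float("nan")
    excluded: bool = False
    reason: str = ""

    def as_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class FretTriplet:
    """Donor / FRET / acceptor channel set for three-cube FRET imaging."""

    donor: ChannelImage
    fret: ChannelImage
    acceptor: ChannelImage
    registration_shift: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.donor.shape == self.fret.shape == self.acceptor.shape):
            raise ValueError("donor/fret/acceptor channels must share dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return self.donor.shape


@dataclass
class FretCalibration:
    """Spectral bleed-through fractions for the three-cube correction.

    dL: donor emission leaking into the FRET channel, slope of I_f vs I_d
    on donor-only controls. aL: direct acceptor cross-excitation, slope of
    I_f vs I_a on acceptor-only controls.
    """

    dL: float = 0.0
    aL: float = 0.0
    dL_se: float = float("nan")
    aL_se: float = float("nan")
    dL_r2: float = float("nan")
    aL_r2: float = float("nan")
    n_pixels_dL: int = 0
    n_pixels_aL: int = 0

    def __post_init__(self) -> None:
        for name, v in (("dL", self.dL), ("aL", self.aL)):
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name}={v} outside [0, 1)")

    @staticmethod
    def merge(donor_cal: "FretCalibration", acceptor_cal: "FretCalibration") -> "FretCalibration":
        """Combine single-control calibrations into one dL+aL record."""
        return FretCalibration(
            dL=donor_cal.dL,
            aL=acceptor_cal.aL,
            dL_se=donor_cal.dL_se,
            aL_se=acceptor_cal.aL_se,
            dL_r2=donor_cal.dL_r2,
            aL_r2=acceptor_cal.aL_r2,
            n_pixels_dL=donor_cal.n_pixels_dL,
            n_pixels_aL=acceptor_cal.n_pixels_aL,
        )

    def as_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class FretResult:
    """Pixelwise FRET index map plus the adhesion-restricted summary."""

    index_map: np.ndarray  # NaN where the acceptor is below the validity floor
    valid: np.ndarray  # bool, pixels where the index is defined
    adhesion_mask: LabelMask | None = None
    per_cell_mean_fret: float = float("nan")
    per_adhesion_mean_fret: np.ndarray | None = None
    normalized_fret: float = float("nan")
    status: str = "ok"


@dataclass
class Substrate:
    """Linear-elastic half-space substrate for traction microscopy.

    youngs_modulus in Pa; poisson_ratio dimensionless (0.5 = incompressible
    gel); regularization is the Tikhonov weight λ for the traction inverse.
    """

    youngs_modulus: float
    poisson_ratio: float = 0.5
    regularization: float = 1e-4
    regularization_mode: str = "relative"  # "relative" | "absolute"

    def __post_init__(self) -> None:
        if not self.youngs_modulus > 0:
            raise ValueError("Young's modulus must be > 0")
        if not (0.0 <= self.poisson_ratio <= 0.5):
            raise ValueError("Poisson ratio must be in [0, 0.5]")
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")
        if self.regularization_mode not in ("relative", "absolute"):
            raise ValueError("regularization_mode must be 'relative' or 'absolute'")


@dataclass
class DisplacementField:
    """Regular grid of in-plane substrate displacements.

    vectors[..., 0] is the row (y) component, vectors[..., 1] the column (x)
    component, both in µm. ``origin_px``/``spacing_px`` locate the nodes on
    the source image pixel grid so masks can be resampled onto the nodes.
    """

    vectors: np.ndarray  # (H, W, 2) µm
    grid_spacing: float  # µm between nodes
    quality: np.ndarray | None = None  # per-node peak correlation
    interpolated: np.ndarray | None = None  # bool, nodes filled from neighbors
    origin_px: tuple[float, float] = (0.0, 0.0)
    spacing_px: float = 1.0
    pixel_size: float = 0.1

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 3 or self.vectors.shape[-1] != 2:
            raise ValueError("displacement vectors must have shape (H, W, 2)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite vectors")
        if not self.grid_spacing > 0:
            raise ValueError("grid_spacing must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.vectors.shape[:2]  # type: ignore[return-value]

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.vectors[..., 0], self.vectors[..., 1])


@dataclass
class TractionField:
    """Regular grid of in-plane traction stress vectors (Pa)."""

    vectors: np.ndarray  # (H, W, 2) Pa, (y, x) components
    grid_spacing: float  # µm
    origin_px: tuple[float, float] = (0.0, 0.0)
    spacing_px: float = 1.0
    pixel_size: float = 0.1

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 3 or self.vectors.shape[-1] != 2:
            raise ValueError("traction vectors must have shape (H, W, 2)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("traction field contains non-finite vectors")
        if not self.grid_spacing > 0:
            raise ValueError("grid_spacing must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.vectors.shape[:2]  # type: ignore[return-value]

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.vectors[..., 0], self.vectors[..., 1])

    def net_force(self) -> tuple[float, float]:
        """Integrated (y, x) force over the frame, in Pa·µm²."""
        da = self.grid_spacing**2
        return (
            float(self.vectors[..., 0].sum() * da),
            float(self.vectors[..., 1].sum() * da),
        )


@dataclass
class GroundTruth:
    """Record of every true parameter behind a synthetic scene.

    Only the fields relevant to the scene kind are populated; consumed by
    tests and validation scripts, never by the measurement pipeline.
    """

    scene_id: str
    seed: int
    kind: str  # "nc" | "fret" | "tfm"
    # nc scenes: one row per nucleus
    nuclei: list[dict[str, float]] = field(default_factory=list)
    true_nc_ratio: list[float] = field(default_factory=list)
    background: float = 0.0
    # fret scenes
    fret_true: np.ndarray | None = None
    dL_true: float = float("nan")
    aL_true: float = float("nan")
    illum_field: np.ndarray | None = None
    shift_true: tuple[float, float] = (0.0, 0.0)
    background_true: float = 0.0
    cell_mask: np.ndarray | None = None
    adhesion_mask: np.ndarray | None = None
    # tfm scenes
    traction_true: TractionField | None = None
    displacement_true: DisplacementField | None = None
    substrate: Substrate | None = None
    bead_positions: np.ndarray | None = None
    noise_sd: float = 0.0
    pixel_size: float = 0.1
    frame_shape: tuple[int, int] = (512, 512)

    def nuclei_mask(self) -> LabelMask:
        """Ground-truth nucleus label mask rebuilt from the disk parameters."""
        lab = np.zeros(self.frame_shape, dtype=np.int32)
        yy, xx = np.mgrid[0 : self.frame_shape[0], 0 : self.frame_shape[1]]
        for k, nuc in enumerate(self.nuclei, start=1):
            r2 = (yy - nuc["cy"]) ** 2 + (xx - nuc["cx"]) ** 2
            lab[r2 <= nuc["radius"] ** 2] = k
        return LabelMask(lab, self.pixel_size)
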