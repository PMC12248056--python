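"""Seeded synthetic microscopy scenes with complete ground truth.

Three scene families mirror the three experimental assays:

* ``make_nc_scene`` — DAPI / antibody-stain / F-actin triplets of
  piecewise-constant disk nuclei with perinuclear rings, for
  nuclear-to-cytoplasmic ratio quantification.
* ``make_fret_triplet`` — donor / FRET / acceptor channel sets synthesized
  from a known true FRET index map and known bleed-through fractions, then
  corrupted by exactly the effects the correction cascade removes
  (multiplicative illumination gain, inter-channel pixel shift, additive
  background, Gaussian noise).
* ``make_tfm_pair`` — relaxed/deformed bead speckle pairs whose deformation
  is the displacement field of a known traction field under the Boussinesq
  forward operator.

All generators are pure functions of their parameters and ``seed``: the same
call reproduces the same images bit for bit. Every true parameter is
recorded in a :class:`~mechanoquant.containers.GroundTruth` sidecar that the
measurement pipeline never reads.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .containers import (
    ChannelImage,
    FretTriplet,
    GroundTruth,
    LabelMask,
    Substrate,
    TractionField,
)
from .tfm import forward_boussinesq

__all__ = [
    "make_nc_scene",
    "make_fret_triplet",
    "make_donor_only_control",
    "make_acceptor_only_control",
    "default_illum_field",
    "gaussian_traction_patch",
    "traction_dipole",
    "make_tfm_pair",
    "write_scene",
]


class GeometryError(ValueError):
    """Requested scene geometry cannot fit in the frame."""


def _finish(img: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


# ---------------------------------------------------------------------------
# nuclear / cytoplasmic ratio scenes
# ---------------------------------------------------------------------------

def make_nc_scene(
    n_cells: int,
    shape: tuple[int, int] = (512, 512),
    radius_range: tuple[float, float] = (15.0, 25.0),
    nuclear_intensity: float = 200.0,
    ring_intensity: float = 100.0,
    perinuclear_width: int = 12,
    cell_radius_factor: float = 2.0,
    dapi_intensity: float = 250.0,
    actin_intensity: float = 150.0,
    background: float = 10.0,
    stain_background: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    pixel_size: float = 0.1,
    scene_id: str = "nc",
    max_tries: int = 5000,
) -> tuple[ChannelImage, ChannelImage, ChannelImage, GroundTruth]:
    """Piecewise-constant nucleus/ring scene for N/C ratio validation.

    Each cell is a disk nucleus (intensity ``nuclear_intensity`` in the stain
    channel) surrounded by a perinuclear annulus of width
    ``perinuclear_width`` px at ``ring_intensity``, inside a larger "cell"
    footprint visible in the actin channel. Nuclei are placed by rejection
    sampling so that their ring neighborhoods do not overlap; the true N/C
    ratio of every cell is ``nuclear_intensity / ring_intensity`` by
    construction.

    Returns (dapi, stain, actin, ground_truth).

    Raises
    ------
    GeometryError
        If the requested number of nuclei cannot be placed without overlap.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if radius_range[0] < 5:
        raise ValueError("nuclear radii must be >= 5 px")
    rng = np.random.default_rng(seed)
    h, w = shape

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    tries = 0
    while len(centers) < n_cells:
        if tries >= max_tries:
            raise GeometryError(
                f"could not place {n_cells} nuclei of radius "
                f"{radius_range} in a {shape} frame after {max_tries} tries"
            )
        tries += 1
        r = rng.uniform(*radius_range)
        margin = r + perinuclear_width + 2
        if 2 * margin >= min(h, w):
            raise GeometryError("nucleus plus ring margin larger than the frame")
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        ok = all(
            np.hypot(cy - cy0, cx - cx0) > r + r0 + 2 * perinuclear_width + 2
            for (cy0, cx0), r0 in zip(centers, radii)
        )
        if ok:
            centers.append((cy, cx))
            radii.append(r)

    dapi = np.full(shape, background, dtype=float)
    stain = np.full(shape, stain_background, dtype=float)
    actin = np.full(shape, background, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    nuclei = []
    for (cy, cx), r in zip(centers, radii):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        nucleus = d2 <= r**2
        annulus = (d2 > r**2) & (d2 <= (r + perinuclear_width) ** 2)
        cell = d2 <= (cell_radius_factor * r) ** 2
        dapi[nucleus] = dapi_intensity
        stain[nucleus] = nuclear_intensity
        stain[annulus] = ring_intensity
        actin[cell] = actin_intensity
        nuclei.append(
            {
                "cy": float(cy),
                "cx": float(cx),
                "radius": float(r),
                "nuclear_intensity": float(nuclear_intensity),
                "ring_intensity": float(ring_intensity),
            }
        )

    gt = GroundTruth(
        scene_id=scene_id,
        seed=seed,
        kind="nc",
        nuclei=nuclei,
        true_nc_ratio=[nuclear_intensity / ring_intensity] * n_cells,
        background=background,
        noise_sd=noise_sd,
        pixel_size=pixel_size,
        frame_shape=shape,
    )
    return (
        ChannelImage(_finish(dapi, noise_sd, rng), pixel_size, "dapi"),
        ChannelImage(_finish(stain, noise_sd, rng), pixel_size, "stain"),
        ChannelImage(_finish(actin, noise_sd, rng), pixel_size, "actin"),
        gt,
    )


# ---------------------------------------------------------------------------
# FRET triplets
# ---------------------------------------------------------------------------

def default_illum_field(shape: tuple[int, int], strength: float = 0.15, seed: int = 0) -> np.ndarray:
    """Smooth multiplicative illumination gain, normalized to mean 1.

    A tilted plane plus a centered radial falloff of relative amplitude
    ``strength`` — the slowly varying shading a flat-field image corrects.
    """
    h, w = shape
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    tilt_y, tilt_x = rng.uniform(-1.0, 1.0, size=2)
    r2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
    field = 1.0 + strength * (0.5 * tilt_y * (yy / h - 0.5) + 0.5 * tilt_x * (xx / w - 0.5) - r2 / 2)
    return field / field.mean()


def _cell_and_adhesions(
    shape: tuple[int, int], rng: np.random.Generator, n_adhesions: int, texture_sd: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Elliptical cell footprint, adhesion amplitude map, smooth texture."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    # footprint leaves a clear frame margin so border-band background
    # estimation sees no cell signal
    ay, ax = 0.30 * h, 0.25 * w
    ell = ((yy - h / 2) / ay) ** 2 + ((xx - w / 2) / ax) ** 2
    cell = ell <= 1.0

    adh = np.zeros(shape)
    for _ in range(n_adhesions):
        # adhesions concentrate toward the cell margin, elongated radially
        frac = rng.uniform(0.55, 0.92)
        theta = rng.uniform(0, 2 * np.pi)
        cy = h / 2 + frac * ay * np.sin(theta)
        cx = w / 2 + frac * ax * np.cos(theta)
        amp = rng.uniform(2.0, 3.5)
        s_long = rng.uniform(3.0, 6.0)
        s_short = rng.uniform(1.2, 2.0)
        ang = theta + rng.normal(0, 0.3)
        c, s = np.cos(ang), np.sin(ang)
        u = (yy - cy) * s + (xx - cx) * c
        v = -(yy - cy) * c + (xx - cx) * s
        adh += amp * np.exp(-0.5 * ((u / s_long) ** 2 + (v / s_short) ** 2))
    adh *= cell

    smooth = ndimage.gaussian_filter(rng.normal(0.0, 1.0, shape), 6.0)
    texture = np.clip(1.0 + texture_sd * smooth / max(smooth.std(), 1e-9), 0.2, None)
    return cell, adh, texture


def make_fret_triplet(
    fret_true: float | np.ndarray,
    dL_true: float,
    aL_true: float,
    donor_total: float = 600.0,
    acceptor_total: float = 600.0,
    illum_field: np.ndarray | None = None,
    shift_true: tuple[float, float] = (0.0, 0.0),
    background_true: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.1,
    n_adhesions: int = 30,
    texture_sd: float = 0.35,
    scene_id: str = "fret",
) -> tuple[FretTriplet, GroundTruth]:
    """Three-cube FRET channel set from known truth, forward model of the
    correction cascade.

    Clean channels are built from a shared cell/adhesion structure
    (acceptor-tagged sensor marks adhesions brightly), then

        I_f = fret_true * I_a  +  dL_true * I_d  +  aL_true * I_a

    pixelwise. Corruption is applied in the order the correction inverts:
    the acceptor channel is shifted by ``shift_true`` (inter-channel optical
    offset), background is added, every channel is multiplied by the
    (mean-normalized) illumination field, and Gaussian noise of ``noise_sd``
    is added. In the noiseless, corruption-free limit the correction cascade
    followed by the index equation returns ``fret_true`` exactly.
    """
    if not (0.0 <= dL_true < 1.0 and 0.0 <= aL_true < 1.0):
        raise ValueError("bleed-through fractions must be in [0, 1)")
    h, w = shape
    if abs(shift_true[0]) >= h or abs(shift_true[1]) >= w:
        raise ValueError("inter-channel shift larger than the frame")
    fret_map = np.broadcast_to(np.asarray(fret_true, dtype=float), shape).copy()
    if fret_map.min() < 0 or fret_map.max() > 1:
        raise ValueError("fret_true must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    cell, adh, texture = _cell_and_adhesions(shape, rng, n_adhesions, texture_sd)
    structure = texture * (0.25 * cell + adh)

    Ia = acceptor_total * structure
    Id = donor_total * structure
    If = fret_map * Ia + dL_true * Id + aL_true * Ia

    if illum_field is None:
        illum = np.ones(shape)
    else:
        illum = np.asarray(illum_field, dtype=float)
        if illum.shape != shape:
            raise ValueError("illumination field shape mismatch")
        if illum.min() <= 0:
            raise ValueError("illumination field must be strictly positive")
        illum = illum / illum.mean()

    def corrupt(channel: np.ndarray, shifted: bool) -> np.ndarray:
        out = channel
        if shifted and shift_true != (0.0, 0.0):
            out = ndimage.shift(out, shift_true, order=1, mode="constant", cval=0.0)
        out = (out + background_true) * illum
        return _finish(out, noise_sd, rng)

    donor = corrupt(Id, shifted=False)
    fret = corrupt(If, shifted=False)
    acceptor = corrupt(Ia, shifted=True)

    gt = GroundTruth(
        scene_id=scene_id,
        seed=seed,
        kind="fret",
        fret_true=fret_map,
        dL_true=dL_true,
        aL_true=aL_true,
        illum_field=illum,
        shift_true=shift_true,
        background_true=background_true,
        cell_mask=cell,
        adhesion_mask=adh > 0.5,
        noise_sd=noise_sd,
        pixel_size=pixel_size,
        frame_shape=shape,
    )
    triplet = FretTriplet(
        ChannelImage(donor, pixel_size, "donor"),
        ChannelImage(fret, pixel_size, "fret"),
        ChannelImage(acceptor, pixel_size, "acceptor"),
    )
    return triplet, gt


def make_donor_only_control(dL_true: float, **kwargs) -> tuple[FretTriplet, GroundTruth]:
    """eGFP-only control scene: I_a = 0, no FRET, so I_f = dL * I_d exactly."""
    kwargs.setdefault("scene_id", "donor-only")
    return make_fret_triplet(0.0, dL_true, 0.0, acceptor_total=0.0, **kwargs)


def make_acceptor_only_control(aL_true: float, **kwargs) -> tuple[FretTriplet, GroundTruth]:
    """tagRFP-only control scene: I_d = 0, no FRET, so I_f = aL * I_a exactly."""
    kwargs.setdefault("scene_id", "acceptor-only")
    return make_fret_triplet(0.0, 0.0, aL_true, donor_total=0.0, **kwargs)


# ---------------------------------------------------------------------------
# traction force microscopy bead pairs
# ---------------------------------------------------------------------------

def gaussian_traction_patch(
    shape: tuple[int, int],
    center_px: tuple[float, float],
    peak_pa: float,
    sigma_um: float,
    direction: tuple[float, float] = (0.0, 1.0),
    pixel_size: float = 0.1,
) -> TractionField:
    """Band-limited Gaussian traction patch on the pixel grid.

    ``direction`` is the (y, x) traction orientation (normalized internally);
    the magnitude profile is ``peak_pa * exp(-r^2 / 2 sigma^2)``.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    sigma_px = sigma_um / pixel_size
    prof = peak_pa * np.exp(
        -0.5 * (((yy - center_px[0]) / sigma_px) ** 2 + ((xx - center_px[1]) / sigma_px) ** 2)
    )
    dy, dx = direction
    norm = np.hypot(dy, dx)
    if norm == 0:
        raise ValueError("traction direction must be nonzero")
    vectors = np.stack([prof * dy / norm, prof * dx / norm], axis=-1)
    return TractionField(vectors, grid_spacing=pixel_size, pixel_size=pixel_size)


def traction_dipole(
    shape: tuple[int, int],
    peak_pa: float = 300.0,
    sigma_um: float = 3.0,
    separation_um: float = 15.0,
    pixel_size: float = 0.1,
) -> TractionField:
    """Contractile patch pair: equal and opposite tractions pulling inward.

    Mimics a cell pulling its two ends toward its center; the net force is
    zero by construction, as required by mechanical equilibrium.
    """
    h, w = shape
    half = separation_um / (2 * pixel_size)
    left = gaussian_traction_patch(
        shape, (h / 2, w / 2 - half), peak_pa, sigma_um, direction=(0.0, 1.0), pixel_size=pixel_size
    )
    right = gaussian_traction_patch(
        shape, (h / 2, w / 2 + half), peak_pa, sigma_um, direction=(0.0, -1.0), pixel_size=pixel_size
    )
    return TractionField(
        left.vectors + right.vectors, grid_spacing=pixel_size, pixel_size=pixel_size
    )


def _render_beads(
    shape: tuple[int, int],
    positions: np.ndarray,
    amplitudes: np.ndarray,
    sigma: float,
    background: float,
) -> np.ndarray:
    img = np.full(shape, background, dtype=float)
    if len(positions) == 0:
        return img
    half = int(np.ceil(4 * sigma))
    h, w = shape
    offs = np.arange(-half, half + 1)
    py = positions[:, 0][:, None]
    px = positions[:, 1][:, None]
    ys = np.floor(py).astype(int) + offs  # (n, 2*half+1)
    xs = np.floor(px).astype(int) + offs
    gy = np.exp(-0.5 * ((ys - py) / sigma) ** 2)
    gx = np.exp(-0.5 * ((xs - px) / sigma) ** 2)
    vals = amplitudes[:, None, None] * gy[:, :, None] * gx[:, None, :]
    Y = np.broadcast_to(ys[:, :, None], vals.shape)
    X = np.broadcast_to(xs[:, None, :], vals.shape)
    ok = (Y >= 0) & (Y < h) & (X >= 0) & (X < w)
    np.add.at(img, (Y[ok], X[ok]), vals[ok])
    return img


def make_tfm_pair(
    traction_true: TractionField,
    substrate: Substrate,
    bead_density: float = 4.0,
    bead_amplitude: float = 100.0,
    bead_sigma: float = 1.0,
    background: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    piv_window: int = 32,
    scene_id: str = "tfm",
) -> tuple[ChannelImage, ChannelImage, LabelMask, GroundTruth]:
    """Relaxed/deformed bead image pair for a known traction field.

    The relaxed (post-lysis) image is a random speckle of sub-resolution
    beads rendered as 2-D Gaussians (sigma ~ 1 px, 0.1 µm FluoSpheres near
    the diffraction limit). The deformed image is the relaxed image warped
    by the displacement field of ``traction_true`` under the Boussinesq
    forward operator (inverse mapping, bilinear interpolation).
    ``bead_density`` is in beads/µm². The returned cell mask covers the
    traction support, standing in for the phase-contrast outline.

    Raises
    ------
    ValueError
        If the displacement anywhere exceeds half the PIV window —
        unrecoverable by window correlation.
    """
    if traction_true.grid_spacing != traction_true.pixel_size:
        raise ValueError("traction_true must be sampled on the image pixel grid")
    rng = np.random.default_rng(seed)
    h, w = traction_true.shape
    px = traction_true.pixel_size

    disp = forward_boussinesq(traction_true, substrate, pad_factor=2)
    u_px = disp.vectors / px
    max_disp = float(np.abs(u_px).max())
    if max_disp > piv_window / 2 - 2:
        raise ValueError(
            f"max displacement {max_disp:.1f} px exceeds half the {piv_window}-px "
            "PIV window; reduce traction or stiffen the substrate"
        )

    area_um2 = h * w * px**2
    n_beads = rng.poisson(bead_density * area_um2)
    positions = np.column_stack(
        [rng.uniform(0, h, size=n_beads), rng.uniform(0, w, size=n_beads)]
    )
    amplitudes = bead_amplitude * rng.uniform(0.6, 1.0, size=n_beads)

    relaxed_clean = _render_beads((h, w), positions, amplitudes, bead_sigma, background)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    deformed_clean = ndimage.map_coordinates(
        relaxed_clean,
        [yy - u_px[..., 0], xx - u_px[..., 1]],
        order=1,
        mode="nearest",
    )
    relaxed = _finish(relaxed_clean, noise_sd, rng)
    deformed = _finish(deformed_clean, noise_sd, rng)

    mag = traction_true.magnitude()
    if mag.max() > 0:
        support = mag > 0.05 * mag.max()
        support = ndimage.binary_dilation(support, iterations=int(2.0 / px))
    else:
        support = np.zeros((h, w), bool)
        yy2, xx2 = np.mgrid[0:h, 0:w]
        support[(yy2 - h / 2) ** 2 + (xx2 - w / 2) ** 2 <= (min(h, w) / 4) ** 2] = True
    cell_mask = LabelMask(support.astype(np.int32), px)

    gt = GroundTruth(
        scene_id=scene_id,
        seed=seed,
        kind="tfm",
        traction_true=traction_true,
        displacement_true=disp,
        substrate=substrate,
        bead_positions=positions,
        noise_sd=noise_sd,
        pixel_size=px,
        frame_shape=(h, w),
    )
    return (
        ChannelImage(deformed, px, "beads_deformed"),
        ChannelImage(relaxed, px, "beads_relaxed"),
        cell_mask,
        gt,
    )


# ---------------------------------------------------------------------------
# scene serialization
# ---------------------------------------------------------------------------

def write_scene(out_dir: str | Path, channels: dict[str, ChannelImage], gt: GroundTruth) -> Path:
    """Write per-channel TIFFs plus a JSON ground-truth sidecar.

    Large ground-truth arrays (FRET map, illumination field, traction field)
    are written as float32 TIFFs next to the sidecar; scalars and per-nucleus
    parameters go in the JSON.
    """
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, img in channels.items():
        tifffile.imwrite(out / f"{name}.tif", img.pixels.astype(np.float32))

    side: dict = {
        "scene_id": gt.scene_id,
        "seed": gt.seed,
        "kind": gt.kind,
        "nuclei": gt.nuclei,
        "true_nc_ratio": gt.true_nc_ratio,
        "background": gt.background,
        "dL_true": gt.dL_true,
        "aL_true": gt.aL_true,
        "shift_true": list(gt.shift_true),
        "background_true": gt.background_true,
        "noise_sd": gt.noise_sd,
        "pixel_size": gt.pixel_size,
        "frame_shape": list(gt.frame_shape),
    }
    for name, arr in (
        ("fret_true", gt.fret_true),
        ("illum_field", gt.illum_field),
    ):
        if arr is not None:
            tifffile.imwrite(out / f"gt_{name}.tif", np.asarray(arr, dtype=np.float32))
            side[name] = f"gt_{name}.tif"
    if gt.traction_true is not None:
        tifffile.imwrite(
            out / "gt_traction.tif", gt.traction_true.vectors.astype(np.float32)
        )
        side["traction_true"] = "gt_traction.tif"
        side["grid_spacing_um"] = gt.traction_true.grid_spacing
    if gt.substrate is not None:
        side["substrate"] = {
            "youngs_modulus": gt.substrate.youngs_modulus,
            "poisson_ratio": gt.substrate.poisson_ratio,
            "regularization": gt.substrate.regularization,
        }
    path = out / "ground_truth.json"
    path.write_text(json.dumps(side, indent=2, sort_keys=True))
    return out
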