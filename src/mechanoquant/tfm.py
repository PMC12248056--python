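"""Traction force microscopy by regularized Fourier Transform Traction Cytometry.

The substrate is modeled as a linear-elastic half-space (Boussinesq). In
Fourier space the tangential surface displacement u(k) produced by a
tangential traction t(k) is diagonal per wavevector,

    u(k) = G(k) t(k),

with the 2x2 Green tensor

    G(k) = 2 (1 + nu) / (E |k|^3) * [[(1-nu)|k|^2 + nu ky^2,  -nu kx ky],
                                      [-nu kx ky,  (1-nu)|k|^2 + nu kx^2]].

``forward_boussinesq`` applies G (used by the synthetic generator and for
validation); ``invert_fttc`` applies the Tikhonov-regularized inverse

    t(k) = (G^H G + lambda_eff^2 I)^-1 G^H u(k),

with the zero-frequency (rigid-motion) component set to zero in both
directions since G diverges at k = 0. ``estimate_displacement`` recovers the
displacement field from bead image pairs by windowed cross-correlation (PIV)
with Gaussian subpixel peak interpolation.

Conventions: vector component 0 is the image row (y) direction, component 1
the column (x) direction; wavevectors are angular (rad/µm).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import (
    ChannelImage,
    DisplacementField,
    LabelMask,
    Substrate,
    TractionField,
)

__all__ = [
    "greens_tensor",
    "forward_boussinesq",
    "invert_fttc",
    "estimate_displacement",
    "avg_traction_stress",
]


def greens_tensor(
    ky: np.ndarray, kx: np.ndarray, substrate: Substrate
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boussinesq half-space Green tensor components on a wavevector grid.

    Parameters
    ----------
    ky, kx : angular wavevector components (rad/µm), broadcastable grids.
    substrate : elastic parameters; only E and nu are used.

    Returns
    -------
    (Gyy, Gyx, Gxx) arrays in µm/Pa. Entries at k = 0 are set to zero
    (the tensor diverges there; the DC mode is handled by convention).
    """
    E = substrate.youngs_modulus
    nu = substrate.poisson_ratio
    k2 = ky**2 + kx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.sqrt(k2)
        pref = 2.0 * (1.0 + nu) / (E * k2 * k)
        Gyy = pref * ((1.0 - nu) * k2 + nu * kx**2)
        Gxx = pref * ((1.0 - nu) * k2 + nu * ky**2)
        Gyx = -pref * nu * kx * ky
    zero = k2 == 0
    for g in (Gyy, Gxx, Gyx):
        g[zero] = 0.0
    return Gyy, Gyx, Gxx


def _k_grids(shape: tuple[int, int], spacing: float) -> tuple[np.ndarray, np.ndarray]:
    ky = 2.0 * np.pi * np.fft.fftfreq(shape[0], d=spacing)
    kx = 2.0 * np.pi * np.fft.fftfreq(shape[1], d=spacing)
    return np.meshgrid(ky, kx, indexing="ij")


def forward_boussinesq(
    traction: TractionField, substrate: Substrate, pad_factor: int = 2
) -> DisplacementField:
    """Displacement field produced by a traction field on an elastic half-space.

    The traction grid is zero-padded by ``pad_factor`` before the FFT so that
    a localized traction patch sees (approximately) free-space rather than
    periodic boundary conditions; ``pad_factor=1`` gives the plain periodic
    spectral operator, which is the exact algebraic inverse of
    :func:`invert_fttc` at lambda = 0. The zero-frequency component is set to
    zero, i.e. the returned displacement has zero mean over the padded frame.
    """
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    h, w = traction.shape
    hp, wp = h * pad_factor, w * pad_factor
    ty = np.zeros((hp, wp))
    tx = np.zeros((hp, wp))
    ty[:h, :w] = traction.vectors[..., 0]
    tx[:h, :w] = traction.vectors[..., 1]

    ky, kx = _k_grids((hp, wp), traction.grid_spacing)
    Gyy, Gyx, Gxx = greens_tensor(ky, kx, substrate)

    Ty = np.fft.fft2(ty)
    Tx = np.fft.fft2(tx)
    Uy = Gyy * Ty + Gyx * Tx
    Ux = Gyx * Ty + Gxx * Tx
    uy = np.fft.ifft2(Uy).real[:h, :w]
    ux = np.fft.ifft2(Ux).real[:h, :w]

    return DisplacementField(
        np.stack([uy, ux], axis=-1),
        grid_spacing=traction.grid_spacing,
        origin_px=traction.origin_px,
        spacing_px=traction.spacing_px,
        pixel_size=traction.pixel_size,
    )


def _cosine_taper_pad(field: np.ndarray, pad_h: int, pad_w: int) -> np.ndarray:
    """Edge-replicate padding rolled smoothly to zero with a raised cosine."""
    padded = np.pad(field, ((pad_h, pad_h), (pad_w, pad_w)), mode="edge")
    h, w = padded.shape
    wy = np.ones(h)
    wx = np.ones(w)
    ramp_y = 0.5 * (1.0 - np.cos(np.pi * np.arange(pad_h) / max(pad_h, 1)))
    ramp_x = 0.5 * (1.0 - np.cos(np.pi * np.arange(pad_w) / max(pad_w, 1)))
    wy[:pad_h] = ramp_y
    wy[h - pad_h :] = ramp_y[::-1]
    wx[:pad_w] = ramp_x
    wx[w - pad_w :] = ramp_x[::-1]
    return padded * np.outer(wy, wx)


def invert_fttc(
    displacement: DisplacementField,
    substrate: Substrate,
    pad: bool = True,
) -> TractionField:
    """Recover tractions from a displacement field (regularized FTTC).

    Solves, independently per wavevector, the Tikhonov problem
    ``t(k) = (G^T G + lambda_eff^2 I)^-1 G^T u(k)``. In the default
    ``relative`` mode lambda_eff = lambda * sigma_max(G) where sigma_max is
    the largest singular value of G over the grid, making lambda a
    dimensionless fraction that transfers across grid sizes and stiffnesses;
    ``absolute`` mode uses lambda as-is (the literal convention of legacy
    scripts). The mean of u is removed first and the DC traction is zero, so
    the recovered field balances to ~zero net force.

    ``pad=True`` expands the field to 2x size with cosine-tapered margins
    before the transform to suppress wrap-around artifacts on non-periodic
    data; disable for exact round-trips with the periodic forward operator.
    """
    lam = substrate.regularization
    u = displacement.vectors - displacement.vectors.mean(axis=(0, 1))
    uy = u[..., 0]
    ux = u[..., 1]
    h, w = uy.shape
    if pad:
        pad_h, pad_w = h // 2, w // 2
        uy = _cosine_taper_pad(uy, pad_h, pad_w)
        ux = _cosine_taper_pad(ux, pad_h, pad_w)
    else:
        pad_h = pad_w = 0

    ky, kx = _k_grids(uy.shape, displacement.grid_spacing)
    Gyy, Gyx, Gxx = greens_tensor(ky, kx, substrate)

    # G is real symmetric per k: eigenvalues give the singular values.
    half_tr = 0.5 * (Gyy + Gxx)
    disc = np.sqrt((0.5 * (Gyy - Gxx)) ** 2 + Gyx**2)
    sigma_max = float((half_tr + disc).max())
    if substrate.regularization_mode == "relative":
        lam_eff = lam * sigma_max
    else:
        lam_eff = lam

    Uy = np.fft.fft2(uy)
    Ux = np.fft.fft2(ux)

    # Normal equations of the 2x2 system, vectorized over the grid.
    a = Gyy**2 + Gyx**2 + lam_eff**2
    b = Gyx * (Gyy + Gxx)
    c = Gyx**2 + Gxx**2 + lam_eff**2
    r1 = Gyy * Uy + Gyx * Ux
    r2 = Gyx * Uy + Gxx * Ux
    det = a * c - b**2
    with np.errstate(divide="ignore", invalid="ignore"):
        Ty = (c * r1 - b * r2) / det
        Tx = (a * r2 - b * r1) / det
    zero = (ky == 0) & (kx == 0)
    Ty[zero] = 0.0
    Tx[zero] = 0.0
    # Guard the lambda = 0, det -> 0 corner (fully damped modes).
    Ty[~np.isfinite(Ty)] = 0.0
    Tx[~np.isfinite(Tx)] = 0.0

    ty = np.fft.ifft2(Ty).real
    tx = np.fft.ifft2(Tx).real
    if pad:
        ty = ty[pad_h : pad_h + h, pad_w : pad_w + w]
        tx = tx[pad_h : pad_h + h, pad_w : pad_w + w]

    return TractionField(
        np.stack([ty, tx], axis=-1),
        grid_spacing=displacement.grid_spacing,
        origin_px=displacement.origin_px,
        spacing_px=displacement.spacing_px,
        pixel_size=displacement.pixel_size,
    )


def _subpixel_offset(c: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Three-point Gaussian (fallback parabolic) peak interpolation."""
    out = []
    for axis in range(2):
        idx = [peak[0], peak[1]]
        vals = []
        for d in (-1, 0, 1):
            idx[axis] = peak[axis] + d
            if 0 <= idx[axis] < c.shape[axis]:
                vals.append(c[idx[0], idx[1]])
            else:
                vals.append(np.nan)
            idx[axis] = peak[axis]
        cm, c0, cp = vals
        if not np.all(np.isfinite([cm, c0, cp])):
            out.append(0.0)
            continue
        if cm > 0 and c0 > 0 and cp > 0:
            lm, l0, lp = np.log([cm, c0, cp])
            denom = lm - 2 * l0 + lp
            out.append(0.5 * (lm - lp) / denom if denom < 0 else 0.0)
        else:
            denom = cm - 2 * c0 + cp
            out.append(0.5 * (cm - cp) / denom if denom < 0 else 0.0)
    return out[0], out[1]


def _window_correlate(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Full linear cross-correlation c(s) = sum_x a(x) b(x+s) via FFTs.

    Returned with lag s = 0 at index (a.shape - 1), matching
    ``scipy.signal.correlate(b, a, mode="full")`` ordering.
    """
    n0 = a.shape[0] + b.shape[0] - 1
    n1 = a.shape[1] + b.shape[1] - 1
    fa = np.fft.rfft2(a, s=(n0, n1))
    fb = np.fft.rfft2(b, s=(n0, n1))
    c = np.fft.irfft2(fb * np.conj(fa), s=(n0, n1))
    return np.roll(c, (a.shape[0] - 1, a.shape[1] - 1), axis=(0, 1))


def estimate_displacement(
    deformed: ChannelImage,
    relaxed: ChannelImage,
    window_px: int = 32,
    overlap: float = 0.5,
    subtract_drift: bool = True,
    quality_floor: float = 0.3,
    smooth_sigma: float = 0.7,
) -> DisplacementField:
    """PIV displacement of the deformed bead image relative to the relaxed one.

    The images are tiled into ``window_px`` windows with the given fractional
    overlap; each window pair is mean-subtracted and cross-correlated (FFT),
    the correlation peak is refined to subpixel precision with a three-point
    Gaussian fit, and the peak's normalized correlation coefficient is kept
    as a per-node quality score. Nodes below ``quality_floor`` (or with a
    peak at the search-range edge) are replaced by the median of their valid
    neighbors and flagged in ``interpolated``.

    Stage drift is removed by subtracting the median displacement of the
    border band of nodes (assumed far-field, cell-free); disable with
    ``subtract_drift=False`` to recover rigid shifts. The vector field is
    finally conditioned with a gentle Gaussian smoother of ``smooth_sigma``
    grid nodes (0 disables) — the standard step that averages out
    discontinuity errors in PIV fields before inversion and leaves uniform
    fields untouched.
    """
    if window_px < 16:
        raise ValueError("PIV window must be >= 16 px")
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    if deformed.shape != relaxed.shape:
        raise ValueError("deformed and relaxed images must share dimensions")
    img_d = deformed.pixels
    img_r = relaxed.pixels
    step = max(1, int(round(window_px * (1.0 - overlap))))
    h, w = img_d.shape
    ys = np.arange(0, h - window_px + 1, step)
    xs = np.arange(0, w - window_px + 1, step)
    if len(ys) == 0 or len(xs) == 0:
        raise ValueError("image smaller than one PIV window")

    max_disp = window_px // 2 - 1
    uy = np.zeros((len(ys), len(xs)))
    ux = np.zeros((len(ys), len(xs)))
    quality = np.zeros((len(ys), len(xs)))

    for i, y0 in enumerate(ys):
        for j, x0 in enumerate(xs):
            a = img_r[y0 : y0 + window_px, x0 : x0 + window_px]
            b = img_d[y0 : y0 + window_px, x0 : x0 + window_px]
            a = a - a.mean()
            b = b - b.mean()
            denom = np.sqrt((a**2).sum() * (b**2).sum())
            if denom <= 0:
                quality[i, j] = 0.0
                continue
            c = _window_correlate(a, b)
            # displacement (dy, dx) maps correlation index (window-1+dy, ...)
            center = window_px - 1
            lo, hi = center - max_disp, center + max_disp + 1
            c_search = c[lo:hi, lo:hi]
            pk = np.unravel_index(np.argmax(c_search), c_search.shape)
            quality[i, j] = float(c_search[pk] / denom)
            at_edge = (
                pk[0] in (0, c_search.shape[0] - 1)
                or pk[1] in (0, c_search.shape[1] - 1)
            )
            if at_edge:
                quality[i, j] = 0.0
                continue
            sy, sx = _subpixel_offset(c_search, pk)  # type: ignore[arg-type]
            uy[i, j] = (pk[0] - max_disp) + sy
            ux[i, j] = (pk[1] - max_disp) + sx

    valid = quality >= quality_floor
    if not valid.any():
        raise ValueError(
            "insufficient bead texture: no PIV node reached the correlation floor"
        )
    interpolated = ~valid
    if interpolated.any():
        for comp in (uy, ux):
            med = ndimage.generic_filter(
                np.where(valid, comp, np.nan), np.nanmedian, size=3, mode="nearest"
            )
            comp[interpolated] = np.where(
                np.isfinite(med[interpolated]), med[interpolated], 0.0
            )

    if subtract_drift:
        band = np.zeros_like(valid)
        nb = max(1, len(ys) // 8)
        band[:nb, :] = band[-nb:, :] = band[:, :nb] = band[:, -nb:] = True
        uy -= np.median(uy[band])
        ux -= np.median(ux[band])

    if smooth_sigma > 0:
        uy = ndimage.gaussian_filter(uy, smooth_sigma, mode="nearest")
        ux = ndimage.gaussian_filter(ux, smooth_sigma, mode="nearest")

    px = deformed.pixel_size
    vectors = np.stack([uy, ux], axis=-1) * px
    return DisplacementField(
        vectors,
        grid_spacing=step * px,
        quality=quality,
        interpolated=interpolated,
        origin_px=(ys[0] + window_px / 2.0 - 0.5, xs[0] + window_px / 2.0 - 0.5),
        spacing_px=float(step),
        pixel_size=px,
    )


def sample_mask_on_grid(mask: LabelMask, field: TractionField | DisplacementField) -> np.ndarray:
    """Label of the mask pixel nearest each grid node (0 = background)."""
    h, w = field.shape
    oy, ox = field.origin_px
    iy = np.clip(np.round(oy + np.arange(h) * field.spacing_px).astype(int), 0, mask.shape[0] - 1)
    ix = np.clip(np.round(ox + np.arange(w) * field.spacing_px).astype(int), 0, mask.shape[1] - 1)
    return mask.labels[np.ix_(iy, ix)]


def avg_traction_stress(traction: TractionField, cell_mask: LabelMask) -> pd.DataFrame:
    """Mean traction magnitude (Pa) over the mask of each cell.

    The pixel-resolution mask is sampled at the traction grid nodes; cells
    whose mask covers no node are returned excluded rather than dropped.
    """
    node_labels = sample_mask_on_grid(cell_mask, traction)
    mag = traction.magnitude()
    rows = []
    for lab in range(1, cell_mask.n_labels + 1):
        sel = node_labels == lab
        if not sel.any():
            rows.append(
                {"cell_id": lab, "avg_stress_Pa": np.nan, "n_nodes": 0,
                 "excluded": True, "reason": "mask covers no traction node"}
            )
        else:
            rows.append(
                {"cell_id": lab, "avg_stress_Pa": float(mag[sel].mean()),
                 "n_nodes": int(sel.sum()), "excluded": False, "reason": ""}
            )
    return pd.DataFrame(rows)
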