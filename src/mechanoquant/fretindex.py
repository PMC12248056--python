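"""Three-cube FRET index with spectral bleed-through calibration.

The sensitized-emission FRET channel of a donor/FRET/acceptor triplet is
contaminated by donor emission leaking through the FRET filter (fraction
``dL``) and by directly excited acceptor emission (fraction ``aL``). Both
fractions are measured as ordinary least-squares slopes on single-fluorophore
control cells (I_f vs I_d on donor-only, I_f vs I_a on acceptor-only). The
corrected FRET intensity and pixelwise index are then

    F_c = I_f - dL * I_d - aL * I_a,        index = F_c / I_a,

computed on channels that have first been corrected for illumination
gradient, inter-channel pixel shift, and background, followed by three-point
smoothing. For a talin tension sensor the index is averaged over focal
adhesions (segmented from the acceptor channel, which marks the sensor
itself) — higher force across the sensor means lower FRET.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats
from skimage import filters
from skimage.registration import phase_cross_correlation

from .containers import ChannelImage, FretCalibration, FretResult, FretTriplet, LabelMask
from .imgquant import remove_small

__all__ = [
    "RegistrationError",
    "correct_channels",
    "calibrate_bleedthrough",
    "compute_fret_index",
    "adhesion_mean_fret",
]


class RegistrationError(RuntimeError):
    """Inter-channel registration could not be resolved."""


def _border_band(shape: tuple[int, int], width: int = 20) -> np.ndarray:
    band = np.zeros(shape, bool)
    band[:width, :] = band[-width:, :] = True
    band[:, :width] = band[:, -width:] = True
    return band


def _smooth(img: np.ndarray, mode: str | None) -> np.ndarray:
    if mode is None:
        return img
    if mode == "box3":
        return ndimage.uniform_filter(img, size=3, mode="nearest")
    if mode == "separable3":
        k = np.array([0.25, 0.5, 0.25])
        out = ndimage.convolve1d(img, k, axis=0, mode="nearest")
        return ndimage.convolve1d(out, k, axis=1, mode="nearest")
    raise ValueError(f"unknown smoothing mode {mode!r}")


def correct_channels(
    raw: FretTriplet,
    illum_ref: np.ndarray | dict[str, np.ndarray] | None = None,
    background_region: np.ndarray | None = None,
    smooth: str | None = "box3",
    register: bool = True,
    registration_floor: float = 0.05,
    upsample_factor: int = 20,
) -> FretTriplet:
    """Shade, shift, and background correction of a raw triplet.

    Each channel is divided by its mean-normalized illumination reference
    (``illum_ref``: one field for all channels, a per-channel dict, or None
    to skip). The donor and acceptor channels are then co-registered to the
    FRET channel by phase cross-correlation with subpixel upsampling;
    channels without intensity dynamic range (blank in single-fluorophore
    controls) are passed through unregistered. The scalar background — the
    mean over ``background_region`` (default: a 20-px frame border band) —
    is subtracted, negatives are clipped to zero, and a three-point
    smoothing filter (``box3``: 3x3 mean; ``separable3``: [1,2,1]/4 taps;
    None to disable) is applied.

    Raises
    ------
    RegistrationError
        If a textured channel's correlation peak falls below
        ``registration_floor``.
    """
    shape = raw.shape
    region = background_region if background_region is not None else _border_band(shape)
    if not region.any():
        raise ValueError("background region is empty")

    def get_ref(name: str) -> np.ndarray | None:
        if illum_ref is None:
            return None
        ref = illum_ref[name] if isinstance(illum_ref, dict) else illum_ref
        ref = np.asarray(ref, dtype=float)
        if ref.min() <= 0:
            raise ValueError("illumination reference must be strictly positive")
        return ref / ref.mean()

    channels: dict[str, np.ndarray] = {}
    for name, ch in (("donor", raw.donor), ("fret", raw.fret), ("acceptor", raw.acceptor)):
        img = ch.pixels.astype(float)
        ref = get_ref(name)
        if ref is not None:
            img = img / ref
        channels[name] = img

    est_shift = (0.0, 0.0)
    if register:
        reference = channels["fret"]

        def has_signal(img: np.ndarray) -> bool:
            # structured content well above the background noise floor
            band = _border_band(img.shape)
            floor = img[band].mean() + 10.0 * img[band].std()
            return int((img > floor).sum()) >= 100

        for name in ("donor", "acceptor"):
            moving = channels[name]
            if not (has_signal(reference) and has_signal(moving)):
                continue  # blank channel (single-fluorophore control): nothing to register
            shift, error, _ = phase_cross_correlation(
                reference, moving, upsample_factor=upsample_factor, normalization=None
            )
            peak = 1.0 - float(error)
            if peak < registration_floor:
                raise RegistrationError(
                    f"registration of {name!r} against 'fret' failed "
                    f"(correlation {peak:.3f} < floor {registration_floor})"
                )
            if np.any(np.abs(shift) > 0):
                channels[name] = ndimage.shift(moving, shift, order=1, mode="nearest")
            if name == "acceptor":
                # report the offset of the raw channel relative to the
                # reference (the negative of the applied correction)
                est_shift = (-float(shift[0]), -float(shift[1]))

    out: dict[str, np.ndarray] = {}
    for name, img in channels.items():
        bg = float(img[region].mean())
        # smooth before clipping: truncating noisy dim pixels at zero first
        # would bias every downstream intensity statistic upward
        out[name] = np.clip(_smooth(img - bg, smooth), 0.0, None)

    px = raw.donor.pixel_size
    return FretTriplet(
        ChannelImage(out["donor"], px, "donor"),
        ChannelImage(out["fret"], px, "fret"),
        ChannelImage(out["acceptor"], px, "acceptor"),
        registration_shift=est_shift,
    )


def _block_mean(img: np.ndarray, b: int) -> np.ndarray:
    h, w = img.shape
    hb, wb = h // b, w // b
    return img[: hb * b, : wb * b].reshape(hb, b, wb, b).mean(axis=(1, 3))


def _se_inflation(bin_size: int, smoothing_width: int) -> float:
    """Slope-SE inflation for filter-correlated noise between blocks.

    A prior smoothing filter of width ``smoothing_width`` correlates the
    noise of neighboring ``bin_size`` blocks. For the separable composed
    kernel (box_b * box_s per axis) the lag-one block correlation is
    rho = sum_i w_i w_{i-b} / sum_i w_i^2, and the conservative variance
    inflation (smoothly varying predictor) is (1 + 2 rho)^2, i.e. a factor
    (1 + 2 rho) on the standard error. Equals 1 when no smoothing was
    applied or the blocks are wider than the composed kernel support.
    """
    if smoothing_width <= 1:
        return 1.0
    w = np.convolve(np.ones(bin_size), np.ones(smoothing_width))
    if bin_size >= len(w):
        return 1.0
    rho = float((w[bin_size:] * w[: len(w) - bin_size]).sum() / (w**2).sum())
    return 1.0 + 2.0 * rho


def calibrate_bleedthrough(
    control_triplets: list[FretTriplet] | FretTriplet,
    control_kind: str,
    foreground_floor: float | None = None,
    bin_size: int = 6,
    smoothing_width: int = 3,
) -> FretCalibration:
    """Bleed-through fraction from single-fluorophore control triplets.

    Pools foreground pixels (predictor channel above ``foreground_floor``;
    default: border-band mean + 3 SD) across the corrected control triplets
    and fits the ordinary least-squares slope of the FRET channel against
    the donor (``control_kind='donor-only'`` -> dL) or acceptor
    (``'acceptor-only'`` -> aL) channel. The regression runs on
    ``bin_size`` x ``bin_size`` block means of fully foreground blocks:
    block averaging suppresses the attenuation of the slope caused by noise
    on the predictor channel; the reported standard error includes a
    closed-form inflation for the residual correlation the three-point
    smoothing of :func:`correct_channels` leaves between neighboring blocks
    (``smoothing_width`` is that filter's width; pass 1 for unsmoothed
    inputs). ``bin_size=1`` gives the raw-pixel fit.

    Returns a :class:`FretCalibration` with the measured fraction, its
    standard error, r², and the raw foreground pixel count.
    """
    if control_kind not in ("donor-only", "acceptor-only"):
        raise ValueError("control_kind must be 'donor-only' or 'acceptor-only'")
    triplets = [control_triplets] if isinstance(control_triplets, FretTriplet) else list(control_triplets)
    if not triplets:
        raise ValueError("no control triplets given")

    xs, ys = [], []
    n_raw = 0
    for t in triplets:
        pred = (t.donor if control_kind == "donor-only" else t.acceptor).pixels
        resp = t.fret.pixels
        if foreground_floor is None:
            band = _border_band(pred.shape)
            floor = float(pred[band].mean() + 3.0 * pred[band].std())
        else:
            floor = foreground_floor
        fg = pred > floor
        n_raw += int(fg.sum())
        if bin_size > 1:
            pred_b = _block_mean(pred, bin_size)
            resp_b = _block_mean(resp, bin_size)
            fg_b = _block_mean(fg.astype(float), bin_size) == 1.0
            xs.append(pred_b[fg_b])
            ys.append(resp_b[fg_b])
        else:
            xs.append(pred[fg])
            ys.append(resp[fg])
    if n_raw < 100:
        raise ValueError(f"only {n_raw} foreground pixels; need >= 100 for calibration")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < 3 or x.std() == 0:
        raise ValueError("no intensity dynamic range in the predictor channel")

    fit = stats.linregress(x, y)
    slope = max(float(fit.slope), 0.0)
    se = float(fit.stderr) * _se_inflation(bin_size, smoothing_width)
    if control_kind == "donor-only":
        return FretCalibration(
            dL=slope, dL_se=se, dL_r2=float(fit.rvalue**2), n_pixels_dL=n_raw
        )
    return FretCalibration(
        aL=slope, aL_se=se, aL_r2=float(fit.rvalue**2), n_pixels_aL=n_raw
    )


def compute_fret_index(
    triplet: FretTriplet,
    calibration: FretCalibration,
    acceptor_floor: float | None = None,
) -> FretResult:
    """Pixelwise corrected FRET index F_c / I_a.

    F_c = I_f - dL*I_d - aL*I_a. Pixels whose acceptor intensity falls below
    ``acceptor_floor`` (default: border-band background mean + 3 SD) have an
    undefined index and are NaN in the map; the raw (unclipped) index is
    retained. If no pixel clears the floor an empty result with
    ``status='no acceptor signal above floor'`` is returned.
    """
    Id = triplet.donor.pixels
    If = triplet.fret.pixels
    Ia = triplet.acceptor.pixels
    if acceptor_floor is None:
        band = _border_band(Ia.shape)
        acceptor_floor = float(Ia[band].mean() + 3.0 * Ia[band].std())
    floor = max(acceptor_floor, 1e-12)

    Fc = If - calibration.dL * Id - calibration.aL * Ia
    valid = Ia > floor
    index = np.full(Ia.shape, np.nan)
    index[valid] = Fc[valid] / Ia[valid]
    if not valid.any():
        return FretResult(index_map=index, valid=valid, status="no acceptor signal above floor")
    return FretResult(index_map=index, valid=valid)


def adhesion_mean_fret(
    result: FretResult,
    acceptor: ChannelImage,
    min_adhesion_px: int = 10,
    cell_mask: np.ndarray | None = None,
    control_mean: float | None = None,
) -> tuple[float, LabelMask]:
    """Adhesion-restricted mean FRET index of a cell.

    Focal adhesions are segmented from the acceptor (sensor) channel by Otsu
    thresholding — restricted to ``cell_mask`` when given — with components
    below ``min_adhesion_px`` removed. The per-cell value is the pixel mean
    of the index over all adhesion pixels, i.e. the adhesion-area-weighted
    average (sum(index)/adhesion area); per-adhesion means are also stored
    on ``result`` for transparency. ``control_mean`` (e.g. the mean of a
    C-terminal control-sensor population) divides the result into
    ``result.normalized_fret``.

    Returns (per_cell_mean_fret, adhesion_mask); NaN mean and
    ``status='no adhesions detected'`` when segmentation finds nothing.
    """
    img = acceptor.pixels
    domain = cell_mask if cell_mask is not None else result.valid
    vals = img[domain & result.valid]
    if vals.size == 0 or vals.max() == vals.min():
        result.status = "no adhesions detected"
        result.per_cell_mean_fret = float("nan")
        empty = LabelMask(np.zeros(img.shape, dtype=np.int32), acceptor.pixel_size)
        result.adhesion_mask = empty
        return float("nan"), empty

    thr = filters.threshold_otsu(vals)
    adh = (img > thr) & result.valid
    if cell_mask is not None:
        adh &= cell_mask
    adh = remove_small(adh, min_adhesion_px)
    labels, n = ndimage.label(adh, structure=np.ones((3, 3), bool))
    mask = LabelMask(labels.astype(np.int32), acceptor.pixel_size)
    if n == 0:
        result.status = "no adhesions detected"
        result.per_cell_mean_fret = float("nan")
        result.adhesion_mask = mask
        return float("nan"), mask

    mean_fret = float(result.index_map[adh].mean())
    per_adh = np.array(
        [result.index_map[labels == k].mean() for k in range(1, n + 1)]
    )
    result.adhesion_mask = mask
    result.per_cell_mean_fret = mean_fret
    result.per_adhesion_mean_fret = per_adh
    if control_mean is not None and control_mean != 0:
        result.normalized_fret = mean_fret / control_mean
    return mean_fret, mask
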