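"""Per-pixel contraction-frequency mapping from mesh-motion intensity.

As the surface under the mesh contracts rhythmically, the fluorescent
lattice moves in and out of each pixel, modulating its intensity at the
contraction frequency.  The map is built by spatially downsampling and
blurring the movie (noise suppression), Savitzky-Golay smoothing each
pixel's intensity trace, taking the FFT power spectral density, and
assigning each pixel the off-DC frequency of maximum power.  The
pseudo-image is upsampled back to the original resolution and restricted
to the mesh footprint at the reference frame.

The FFT is taken at the native series length by default, so a recording of
``N`` frames at interval ``dt`` resolves frequencies on an exact
``1/(N*dt)`` Hz grid; zero-padding to the next power of two is available
(``pad="pow2"``) but shifts the bin grid off that natural resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import savgol_filter
from skimage.measure import block_reduce

from .simulate import ImageSeries

__all__ = ["FrequencyMap", "preprocess", "pixel_psd", "dominant_frequency_map"]


@dataclass
class FrequencyMap:
    """Per-pixel dominant frequency (Hz) restricted to the mesh footprint.

    ``frequencies`` is NaN outside the mesh mask and 0 where a pixel inside
    the mask carried no detectable oscillation (``valid`` False there).
    ``delta_f = 1/(N_padded * dt)`` is the frequency resolution.
    """

    frequencies: np.ndarray
    valid: np.ndarray
    mesh_mask: np.ndarray
    delta_f: float
    provenance: dict = _field(default_factory=dict)

    def modal_frequency(self, region: np.ndarray | None = None) -> float:
        """Most common dominant frequency over valid pixels (optionally
        within ``region``); ties break toward the lower frequency."""
        sel = self.valid.copy()
        if region is not None:
            sel &= np.asarray(region, bool)
        vals = self.frequencies[sel]
        if vals.size == 0:
            return float("nan")
        uniq, counts = np.unique(vals, return_counts=True)
        return float(uniq[np.argmax(counts)])

    def histogram(self):
        """(frequency, pixel count) table over valid pixels."""
        import pandas as pd
        vals = self.frequencies[self.valid]
        uniq, counts = np.unique(vals, return_counts=True)
        return pd.DataFrame({"frequency_hz": uniq, "n_pixels": counts})


def preprocess(series: ImageSeries, *, downsample: int = 4,
               blur_sigma: float = 1.0) -> ImageSeries:
    """Block-mean spatial downsampling then per-frame Gaussian blur.

    The frame interval is unchanged; the pixel size scales by the factor.
    Frames are cropped to a multiple of the factor before reduction.
    """
    if downsample < 1:
        raise ValueError("downsample factor must be >= 1")
    frames = series.frames
    if frames.ndim == 4:
        frames = frames.max(axis=1)       # stacks are analysed on the projection
    ny, nx = frames.shape[-2:]
    if downsample >= ny or downsample >= nx:
        raise ValueError("downsample factor exceeds the image size")
    f = downsample
    frames = frames[:, : (ny // f) * f, : (nx // f) * f]
    if f > 1:
        frames = block_reduce(frames, (1, f, f), np.mean)
    if blur_sigma > 0:
        frames = gaussian_filter(frames.astype(float), (0, blur_sigma, blur_sigma))
    return ImageSeries(np.asarray(frames, np.float32), series.pixel_size * f,
                       dt=series.dt, channel=series.channel)


def _nfft(n: int, pad) -> int:
    if pad in (None, "none", False):
        return n
    if pad == "pow2":
        return 1 << max(0, int(np.ceil(np.log2(n))))
    raise ValueError("pad must be None or 'pow2'")


def pixel_psd(ts: np.ndarray, dt: float, *, sg_window: int = 9,
              sg_order: int = 3, pad=None):
    """Power spectral density of one pixel's intensity trace.

    The trace is Savitzky-Golay smoothed (``sg_window`` frames, polynomial
    order ``sg_order``), mean-removed and Fourier transformed; power is the
    squared modulus.  Returns ``(frequencies, power)``; the DC bin is
    present but is excluded from any dominant-frequency search.
    """
    ts = np.asarray(ts, float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (len(ts) >= sg_window > sg_order):
        raise ValueError("require series length >= sg_window > sg_order")
    sm = savgol_filter(ts, sg_window, sg_order)
    x = sm - sm.mean()
    nfft = _nfft(len(x), pad)
    spec = np.fft.rfft(x, nfft)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(nfft, dt)
    return freqs, power


def dominant_frequency(ts: np.ndarray, dt: float, **kw):
    """(dominant frequency Hz, valid flag) for one trace; a trace with no
    detectable oscillation reports 0 Hz and valid=False."""
    freqs, power = pixel_psd(ts, dt, **kw)
    scale = max(float(np.max(np.abs(ts))), 1e-30)
    if float(np.sum(power[1:])) <= (1e-9 * scale) ** 2 * len(ts):
        return 0.0, False
    k = 1 + int(np.argmax(power[1:]))      # argmax takes the first (lowest) bin
    return float(freqs[k]), True


def dominant_frequency_map(series: ImageSeries, mesh_mask: np.ndarray, *,
                           downsample: int = 4, blur_sigma: float = 1.0,
                           sg_window: int = 9, sg_order: int = 3,
                           pad=None) -> FrequencyMap:
    """Per-pixel dominant-frequency pseudo-image over the mesh footprint.

    The mesh mask (binarised reference frame) is downsampled identically to
    the movie, the per-pixel PSD argmax (DC excluded) taken, and the result
    upsampled back to the original resolution by nearest neighbour and
    masked outside the mesh.
    """
    mesh_mask = np.asarray(mesh_mask, bool)
    if not mesh_mask.any():
        raise ValueError("empty mesh mask")
    if series.dt <= 0:
        raise ValueError("series needs a positive frame interval dt")
    ny, nx = mesh_mask.shape
    pre = preprocess(series, downsample=downsample, blur_sigma=blur_sigma)
    data = pre.frames.astype(float)
    T = data.shape[0]
    if not (T >= sg_window > sg_order):
        raise ValueError("require series length >= sg_window > sg_order")

    sm = savgol_filter(data, sg_window, sg_order, axis=0)
    x = sm - sm.mean(axis=0)
    nfft = _nfft(T, pad)
    power = np.abs(np.fft.rfft(x, nfft, axis=0)) ** 2
    freqs = np.fft.rfftfreq(nfft, series.dt)
    k = 1 + np.argmax(power[1:], axis=0)
    fmap_small = freqs[k]
    scale = np.maximum(np.abs(data).max(axis=0), 1e-30)
    valid_small = power[1:].sum(axis=0) > (1e-9 * scale) ** 2 * T
    fmap_small = np.where(valid_small, fmap_small, 0.0)

    f = downsample
    fmap = np.repeat(np.repeat(fmap_small, f, axis=0), f, axis=1)
    valid = np.repeat(np.repeat(valid_small, f, axis=0), f, axis=1)
    fmap = _pad_to(fmap, (ny, nx))
    valid = _pad_to(valid, (ny, nx))

    frequencies = np.where(mesh_mask, fmap, np.nan)
    valid = valid & mesh_mask
    prov = {"downsample": downsample, "blur_sigma": blur_sigma,
            "sg_window": sg_window, "sg_order": sg_order,
            "pad": pad, "nfft": int(nfft), "dt": float(series.dt)}
    return FrequencyMap(frequencies, valid, mesh_mask,
                        delta_f=1.0 / (nfft * series.dt), provenance=prov)


def _pad_to(arr: np.ndarray, shape: tuple) -> np.ndarray:
    """Edge-pad / crop a 2D array to ``shape`` (upsampling remainder)."""
    ny, nx = shape
    arr = arr[:ny, :nx]
    py, px = ny - arr.shape[0], nx - arr.shape[1]
    if py or px:
        arr = np.pad(arr, ((0, py), (0, px)), mode="edge")
    return arr
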