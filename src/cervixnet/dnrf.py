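"""Directional Noise Reduction Filter (DNRF).

A detect-then-filter impulse denoiser.  For every pixel, an 11x11 window is
placed around it and the four direction-placed pixel lines through the
center (horizontal, vertical, main diagonal, anti diagonal) are extracted.
Each line is sorted ascending after removing the center pixel *by position*,
and the smallest and largest values are dropped, leaving 8 trimmed values.
The direction with the lowest (population) standard deviation of its trimmed
values — the locally most homogeneous direction — is selected, and a
heuristic metric (HM) compares the center pixel against that direction's
trimmed values.  The pixel is declared noisy iff HM exceeds a threshold T,
and only then is it replaced by the mean of its 3x3 neighbourhood (center
excluded).  Clean pixels are copied through untouched, which is the filter's
advantage over blanket median/averaging filters.

Borders are handled by mirror (reflect-101) padding.  The detection pass
reads the original image; replacements are written to a copy, so earlier
replacements never feed later decisions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import as_gray

DIRECTIONS = ("horizontal", "vertical", "diag_main", "diag_anti")

#: Supported heuristic-metric forms.  "mad" is the default: the mean
#: absolute deviation of the center from the trimmed direction values.
#: "mean_diff" compares the center against the trimmed mean instead.
HM_MODES = ("mad", "mean_diff")


@dataclass
class DirectionalSample:
    """One direction-placed pixel line of a window.

    ``raw`` holds the window pixels on that line in spatial order (center
    included at position ``len(raw)//2``); ``trimmed`` and ``sigma`` are
    filled by :func:`trim_sort`.
    """

    direction: str
    raw: np.ndarray
    trimmed: np.ndarray | None = None
    sigma: float | None = None


@dataclass
class NoiseDecision:
    hm: float
    is_noisy: bool
    chosen_direction: str


def extract_directions(window: np.ndarray) -> tuple[DirectionalSample, ...]:
    """Extract the four direction lines from a square odd-sized window."""
    window = np.asarray(window)
    if window.ndim != 2 or window.shape[0] != window.shape[1] or window.shape[0] % 2 == 0:
        raise ValueError(f"window must be square with odd side, got {window.shape}")
    w = window.shape[0]
    idx = np.arange(w)
    c = w // 2
    lines = (
        window[c, :],
        window[:, c],
        window[idx, idx],
        window[idx, w - 1 - idx],
    )
    return tuple(
        DirectionalSample(direction=d, raw=np.asarray(line).copy())
        for d, line in zip(DIRECTIONS, lines)
    )


def trim_sort(sample: DirectionalSample) -> DirectionalSample:
    """Sort ascending, drop the center occurrence (by position) and both
    extremes, and record the population standard deviation."""
    raw = np.asarray(sample.raw)
    c = raw.size // 2
    rest = np.delete(raw, c)
    srt = np.sort(rest)
    trimmed = srt[1:-1]
    return DirectionalSample(
        direction=sample.direction,
        raw=raw,
        trimmed=trimmed,
        sigma=float(np.std(trimmed.astype(np.float64))),
    )


def heuristic_metric(center: float, trimmed: np.ndarray, mode: str = "mad") -> float:
    """Noisiness score of a center pixel against its most homogeneous
    direction's trimmed values."""
    trimmed = np.asarray(trimmed, dtype=np.float64)
    if trimmed.size == 0:
        raise ValueError("trimmed sequence is empty")
    if mode == "mad":
        return float(np.mean(np.abs(float(center) - trimmed)))
    if mode == "mean_diff":
        return float(abs(float(center) - trimmed.mean()))
    raise ValueError(f"unknown hm mode {mode!r}; expected one of {HM_MODES}")


def classify_pixel(hm: float, threshold: float) -> bool:
    """A pixel is noisy iff HM strictly exceeds the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return hm > threshold


def decide(window: np.ndarray, threshold: float, mode: str = "mad") -> NoiseDecision:
    """Full per-window decision: direction selection + HM + thresholding."""
    samples = [trim_sort(s) for s in extract_directions(window)]
    best = min(samples, key=lambda s: s.sigma)  # ties -> direction priority order
    c = window.shape[0] // 2
    hm = heuristic_metric(window[c, c], best.trimmed, mode=mode)
    return NoiseDecision(hm=hm, is_noisy=classify_pixel(hm, threshold), chosen_direction=best.direction)


def _direction_stacks(img: np.ndarray, window: int) -> np.ndarray:
    """(4, H, W, window) array of the four direction lines per pixel."""
    pad = window // 2
    padded = np.pad(img, pad, mode="reflect")
    win = sliding_window_view(padded, (window, window))
    c = window // 2
    idx = np.arange(window)
    return np.stack(
        [
            win[:, :, c, :],
            win[:, :, :, c],
            win[:, :, idx, idx],
            win[:, :, idx, window - 1 - idx],
        ]
    )


def detect(
    img: np.ndarray,
    threshold: float = 20.0,
    window: int = 11,
    hm_mode: str = "mad",
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-pixel noise detection.

    Returns ``(hm, mask)`` where ``hm`` is the per-pixel heuristic metric
    from the minimum-sigma direction and ``mask`` the boolean noise map.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if window % 2 == 0 or window < 5:
        raise ValueError("window must be odd and >= 5")
    img = as_gray(img, min_size=window)
    lines = _direction_stacks(img, window)  # (4, H, W, window)
    c = window // 2
    rest = np.delete(lines, c, axis=-1)
    srt = np.sort(rest, axis=-1)
    trimmed = srt[..., 1:-1].astype(np.float64)  # (4, H, W, window-3)
    sigma = trimmed.std(axis=-1)  # population std
    # argmin keeps the first minimum: ties resolve in DIRECTIONS order.
    choice = sigma.argmin(axis=0)
    sel = np.take_along_axis(trimmed, choice[None, :, :, None], axis=0)[0]
    center = img
    if hm_mode == "mad":
        hm = np.abs(center[..., None] - sel).mean(axis=-1)
    elif hm_mode == "mean_diff":
        hm = np.abs(center - sel.mean(axis=-1))
    else:
        raise ValueError(f"unknown hm mode {hm_mode!r}; expected one of {HM_MODES}")
    return hm, hm > threshold


def denoise(
    img: np.ndarray,
    threshold: float = 20.0,
    window: int = 11,
    avg_window: int = 3,
    hm_mode: str = "mad",
) -> tuple[np.ndarray, np.ndarray]:
    """Detect impulse pixels and replace only those by the local mean.

    Returns ``(filtered, mask)``; ``filtered`` is uint8 and equals the input
    everywhere the {0,1} uint8 ``mask`` is zero.  The replacement is the
    arithmetic mean of the ``avg_window`` x ``avg_window`` neighbourhood with
    the center pixel itself excluded, rounded to the nearest integer.
    """
    if avg_window % 2 == 0 or avg_window < 3:
        raise ValueError("avg_window must be odd and >= 3")
    arr = as_gray(img, min_size=window)
    _, mask = detect(arr, threshold=threshold, window=window, hm_mode=hm_mode)

    p = avg_window // 2
    padded = np.pad(arr, p, mode="reflect")
    win = sliding_window_view(padded, (avg_window, avg_window))
    total = win.sum(axis=(-1, -2))
    repl = (total - arr) / (avg_window * avg_window - 1)

    src = np.asarray(img)
    filtered = src.copy() if src.dtype == np.uint8 else np.rint(np.clip(arr, 0, 255)).astype(np.uint8)
    filtered[mask] = np.rint(repl[mask]).astype(np.uint8)
    return filtered, mask.astype(np.uint8)
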