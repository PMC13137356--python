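"""Independent brute-force reference implementations used only by tests."""

import numpy as np


def dnrf_reference(img, threshold=20.0, window=11, avg_window=3):
    """Literal per-pixel walk of the directional denoising procedure.

    For every pixel: place the window, pull the four direction lines, sort
    each after removing the center occurrence, drop both extremes, pick the
    direction with the lowest population standard deviation (priority order
    horizontal, vertical, main diagonal, anti diagonal on ties), score
    HM = mean |center - trimmed|, and if HM > threshold replace the pixel
    with the rounded mean of its neighbourhood excluding the center.
    Mirror padding everywhere; replacements are read from the original image.
    """
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    pad = window // 2
    p = np.pad(img, pad, mode="reflect")
    ap = avg_window // 2
    pa = np.pad(img, ap, mode="reflect")
    out = img.copy()
    mask = np.zeros((h, w), dtype=bool)
    c = window // 2
    for r in range(h):
        for q in range(w):
            win = p[r : r + window, q : q + window]
            lines = [
                win[c, :].tolist(),
                win[:, c].tolist(),
                [win[i, i] for i in range(window)],
                [win[i, window - 1 - i] for i in range(window)],
            ]
            best_sigma, best_trim = None, None
            for line in lines:
                rest = line[:c] + line[c + 1 :]
                rest.sort()
                trimmed = rest[1:-1]
                sigma = float(np.std(trimmed))
                if best_sigma is None or sigma < best_sigma:
                    best_sigma, best_trim = sigma, trimmed
            center = win[c, c]
            hm = float(np.mean([abs(center - t) for t in best_trim]))
            if hm > threshold:
                mask[r, q] = True
                nb = pa[r : r + avg_window, q : q + avg_window]
                out[r, q] = np.rint((nb.sum() - nb[ap, ap]) / (avg_window**2 - 1))
    return out.astype(np.uint8), mask


def glcm_pair_counts(quantized, levels, offset):
    """Brute-force symmetric co-occurrence counting."""
    q = np.asarray(quantized)
    h, w = q.shape
    dr, dc = offset
    counts = np.zeros((levels, levels), dtype=np.float64)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[q[r, c], q[r2, c2]] += 1
                counts[q[r2, c2], q[r, c]] += 1
    return counts / counts.sum()


def minkowski_dilate(mask, footprint):
    """Set-definition binary dilation (union of translated footprints)."""
    mask = np.asarray(mask).astype(bool)
    fh, fw = footprint.shape
    cr, cc = fh // 2, fw // 2
    out = np.zeros_like(mask)
    for r, c in zip(*np.nonzero(footprint)):
        dr, dc = r - cr, c - cc
        src = mask[
            max(0, -dr) : mask.shape[0] - max(0, dr),
            max(0, -dc) : mask.shape[1] - max(0, dc),
        ]
        out[
            max(0, dr) : mask.shape[0] - max(0, -dr),
            max(0, dc) : mask.shape[1] - max(0, -dc),
        ] |= src
    return out


def minkowski_erode(mask, footprint):
    """Erosion as complement-dilation with border treated as foreground."""
    inv = ~np.asarray(mask).astype(bool)
    fp = footprint[::-1, ::-1]
    return ~minkowski_dilate(inv, fp)
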