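"""Multi-level texture features and the 2-D feature matrix.

Four feature families are extracted from the Gabor cervigram image (GCI)
and assembled into one fixed-size 2-D matrix, the classifier input:

* **LBP** — 3x3 pattern-window codes.  The comparison rule used here is the
  *inverted* one this pipeline is built around: a neighbour strictly greater
  than the center produces bit 0, otherwise (<=) bit 1, so a constant patch
  codes to 255.  Bits are read clockwise from the top-left neighbour, first
  bit most significant.  The textbook rule (neighbour >= center -> 1) is
  available via ``rule="standard"``.
* **LTP** — ternary codes with tolerance ``t``: +1 above ``center+t``, -1
  below ``center-t``, else 0; split into an upper (+1 pattern) and lower
  (-1 pattern) 8-bit map, same bit order as LBP.
* **GLCM** — a symmetric, normalized co-occurrence matrix at the 45-degree
  offset ``(-1, +1)`` (up-right) on ``levels`` quantization bins, summarized
  by energy, correlation, entropy (base 2) and homogeneity.
* **NSCT** — a two-stage non-subsampled (shift-invariant) contourlet
  decomposition: an a-trous lowpass/highpass split per stage with the
  stage-2 kernel upsampled (holes), and each highpass partitioned into
  directional bands by a triangular angular partition of unity in the
  frequency plane.  All bands are image-sized; lowpass + all directional
  bands sum back to the input exactly (perfect reconstruction), and the
  transform commutes with circular shifts.

Assembly block-averages every 2-D map (LBP, LTP upper/lower, each
contourlet band) onto a fixed G x N grid, stacks the grids as row blocks,
scales everything to [0, 1], and appends one broadcast row carrying the
four GLCM scalars.  The resulting (M, N) shape depends only on the
configuration, never on the input image size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft
from skimage.feature import graycomatrix

from .core import as_gray

# Clockwise neighbour offsets starting at the top-left corner.
_NEIGHBOR_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))


@dataclass
class LTPMaps:
    upper: np.ndarray
    lower: np.ndarray
    t: float


@dataclass
class GLCMStats:
    energy: float
    correlation: float
    entropy: float
    homogeneity: float
    levels: int
    offset: tuple[int, int]


@dataclass
class ContourletVector:
    """Named, image-sized NSCT bands in a fixed documented order:
    stage-1 directional bands, stage-2 directional bands, final lowpass."""

    bands: dict[str, np.ndarray]

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(self.bands)

    def flatten(self) -> np.ndarray:
        return np.concatenate([b.ravel() for b in self.bands.values()])

    def reconstruct(self) -> np.ndarray:
        return sum(self.bands.values())


@dataclass
class FeatureMatrix:
    values: np.ndarray                       # (M, N) float32 in [0, 1]
    layout: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def channel(self, name: str) -> np.ndarray:
        lo, hi = self.layout[name]
        return self.values[lo:hi]


def _neighbor_views(img: np.ndarray):
    padded = np.pad(img, 1, mode="reflect")
    h, w = img.shape
    for dr, dc in _NEIGHBOR_OFFSETS:
        yield padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]


def lbp(img: np.ndarray, rule: str = "inverted") -> np.ndarray:
    """3x3 local binary pattern codes (uint8), mirror-padded borders."""
    img = as_gray(img, min_size=3)
    code = np.zeros(img.shape, dtype=np.uint8)
    for i, nb in enumerate(_neighbor_views(img)):
        if rule == "inverted":
            bit = nb <= img
        elif rule == "standard":
            bit = nb >= img
        else:
            raise ValueError(f"unknown LBP rule {rule!r}")
        code |= bit.astype(np.uint8) << (7 - i)
    return code


def ltp(img: np.ndarray, t: float = 5.0) -> LTPMaps:
    """Local ternary pattern, split into upper/lower 8-bit maps."""
    if t < 0:
        raise ValueError("tolerance t must be >= 0")
    img = as_gray(img, min_size=3)
    upper = np.zeros(img.shape, dtype=np.uint8)
    lower = np.zeros(img.shape, dtype=np.uint8)
    for i, nb in enumerate(_neighbor_views(img)):
        upper |= (nb > img + t).astype(np.uint8) << (7 - i)
        lower |= (nb < img - t).astype(np.uint8) << (7 - i)
    return LTPMaps(upper=upper, lower=lower, t=t)


def quantize(img: np.ndarray, levels: int) -> np.ndarray:
    """Uniform quantization of an intensity image onto [0, levels)."""
    img = as_gray(img)
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint8)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def glcm_features(img: np.ndarray, levels: int = 32, offset: tuple[int, int] = (-1, 1)) -> GLCMStats:
    """Co-occurrence statistics at a fixed offset (default 45 degrees)."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    img = np.asarray(img)
    if img.shape[0] <= abs(offset[0]) or img.shape[1] <= abs(offset[1]):
        raise ValueError("image smaller than the co-occurrence offset")
    q = quantize(img, levels)
    # skimage pairs (r, c) with (r + d sin(angle), c + d cos(angle))
    angle = float(np.arctan2(offset[0], offset[1]))
    dist = int(max(abs(offset[0]), abs(offset[1])))
    p = graycomatrix(q, [dist], [angle], levels=levels, symmetric=True, normed=True)[:, :, 0, 0]

    energy = float((p**2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    i, j = np.indices(p.shape)
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    mi = float((i * p).sum())
    mj = float((j * p).sum())
    vi = float(((i - mi) ** 2 * p).sum())
    vj = float(((j - mj) ** 2 * p).sum())
    if vi <= 0 or vj <= 0:
        correlation = 0.0  # degenerate (single-valued) image
    else:
        correlation = float((((i - mi) * (j - mj) * p).sum()) / np.sqrt(vi * vj))
    return GLCMStats(
        energy=energy,
        correlation=correlation,
        entropy=entropy,
        homogeneity=homogeneity,
        levels=levels,
        offset=tuple(offset),
    )


# ---------------------------------------------------------------------------
# NSCT realization: a-trous lowpass pyramid + angular partition of unity.
# ---------------------------------------------------------------------------

# 1-D B3-spline a-trous kernel taps (n = -2..2).
_SPLINE = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _lowpass_response(n: int, level: int) -> np.ndarray:
    """1-D circular frequency response of the spline kernel upsampled 2**level."""
    f = np.fft.fftfreq(n)
    s = 2**level
    return (
        _SPLINE[2]
        + 2.0 * _SPLINE[1] * np.cos(2.0 * np.pi * f * s)
        + 2.0 * _SPLINE[0] * np.cos(4.0 * np.pi * f * s)
    )


def _angular_windows(shape: tuple[int, int], n_dirs: int) -> np.ndarray:
    """Triangular partition of unity over frequency-plane angle mod pi."""
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    phi = np.mod(np.arctan2(fy, fx), np.pi)  # orientation, [0, pi)
    delta = np.pi / n_dirs
    centers = (np.arange(n_dirs) + 0.5) * delta
    wins = np.empty((n_dirs,) + phi.shape)
    for k, c in enumerate(centers):
        d = np.mod(phi - c + np.pi / 2.0, np.pi) - np.pi / 2.0
        wins[k] = np.maximum(0.0, 1.0 - np.abs(d) / delta)
    return wins


def nsct_decompose(img: np.ndarray, stages: int = 2, dirs: tuple[int, int] = (4, 2)) -> ContourletVector:
    """Two-stage non-subsampled contourlet decomposition (circular filtering).

    Stage 1 splits the image into lowpass L1 and highpass H1 = img - L1 and
    fans H1 into ``dirs[0]`` directional bands; stage 2 repeats on L1 with
    the holes-upsampled kernel and ``dirs[1]`` bands.  Bands and the final
    lowpass are image-sized and sum exactly to the input.
    """
    if stages != 2:
        raise ValueError("the decomposition is fixed at two stages")
    if len(dirs) != 2 or any(d < 1 for d in dirs):
        raise ValueError("dirs must give a positive band count per stage")
    img = as_gray(img, min_size=16)
    shape = img.shape
    spectrum = sfft.fft2(img)

    bands: dict[str, np.ndarray] = {}
    low = spectrum
    for stage, ndir in enumerate(dirs):
        h = _lowpass_response(shape[0], stage)[:, None] * _lowpass_response(shape[1], stage)[None, :]
        low_next = low * h
        high = low - low_next
        wins = _angular_windows(shape, ndir)
        for k in range(ndir):
            bands[f"s{stage + 1}_d{k}"] = sfft.ifft2(high * wins[k]).real
        low = low_next
    bands["lowpass"] = sfft.ifft2(low).real
    return ContourletVector(bands=bands)


# ---------------------------------------------------------------------------
# Feature-matrix assembly.
# ---------------------------------------------------------------------------


def block_mean(img: np.ndarray, grid: tuple[int, int]) -> np.ndarray:
    """Mean over an exact gh x gw rectangular partition of the image."""
    img = np.asarray(img, dtype=np.float64)
    gh, gw = grid
    h, w = img.shape
    if h < gh or w < gw:
        raise ValueError(f"image {img.shape} smaller than grid {grid}")
    er = (np.arange(gh) * h) // gh
    ec = (np.arange(gw) * w) // gw
    sums = np.add.reduceat(np.add.reduceat(img, er, axis=0), ec, axis=1)
    nr = np.diff(np.append(er, h))
    nc = np.diff(np.append(ec, w))
    return sums / np.outer(nr, nc)


def assemble(
    lbp_img: np.ndarray,
    ltp_maps: LTPMaps,
    glcm: GLCMStats,
    cv: ContourletVector,
    grid: tuple[int, int] = (16, 16),
) -> FeatureMatrix:
    """Stack all feature maps into one (M, N) matrix in [0, 1].

    M = (3 + number of contourlet bands) * grid rows + 1; the final row
    broadcasts the four GLCM scalars (energy, correlation mapped from
    [-1, 1] to [0, 1], entropy normalized by its 2*log2(levels) maximum,
    homogeneity) in four equal column segments.
    """
    gh, gw = grid
    blocks: list[np.ndarray] = []
    layout: dict[str, tuple[int, int]] = {}

    def push(name: str, arr: np.ndarray) -> None:
        layout[name] = (len(blocks) * gh, (len(blocks) + 1) * gh)
        blocks.append(arr)

    push("lbp", block_mean(lbp_img, grid) / 255.0)
    push("ltp_upper", block_mean(ltp_maps.upper, grid) / 255.0)
    push("ltp_lower", block_mean(ltp_maps.lower, grid) / 255.0)
    for name, band in cv.bands.items():
        if name == "lowpass":
            push(name, np.clip(block_mean(band, grid) / 255.0, 0.0, 1.0))
        else:
            # signed highpass on the 0-255 intensity scale -> centered at 0.5
            push(name, np.clip(0.5 + block_mean(band, grid) / 510.0, 0.0, 1.0))

    m = len(blocks) * gh + 1
    scalars = np.array(
        [
            glcm.energy,
            (glcm.correlation + 1.0) / 2.0,
            glcm.entropy / (2.0 * np.log2(glcm.levels)),
            glcm.homogeneity,
        ]
    )
    glcm_row = np.repeat(scalars, [len(seg) for seg in np.array_split(np.arange(gw), 4)])
    layout["glcm"] = (m - 1, m)

    values = np.vstack(blocks + [np.clip(glcm_row, 0.0, 1.0)[None, :]]).astype(np.float32)
    if not np.all(np.isfinite(values)):
        raise ValueError("feature matrix contains non-finite values")
    return FeatureMatrix(values=values, layout=layout)


def feature_matrix_shape(grid: tuple[int, int], dirs: tuple[int, int]) -> tuple[int, int]:
    """(M, N) implied by the configuration (3 pattern maps + NSCT bands + GLCM row)."""
    channels = 3 + dirs[0] + dirs[1] + 1
    return channels * grid[0] + 1, grid[1]


def compute_features(
    img: np.ndarray,
    grid: tuple[int, int] = (16, 16),
    ltp_t: float = 5.0,
    glcm_levels: int = 32,
    glcm_offset: tuple[int, int] = (-1, 1),
    lbp_rule: str = "inverted",
    nsct_dirs: tuple[int, int] = (4, 2),
) -> FeatureMatrix:
    """All four feature families on one image, assembled."""
    return assemble(
        lbp(img, rule=lbp_rule),
        ltp(img, t=ltp_t),
        glcm_features(img, levels=glcm_levels, offset=glcm_offset),
        nsct_decompose(img, dirs=nsct_dirs),
        grid=grid,
    )
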