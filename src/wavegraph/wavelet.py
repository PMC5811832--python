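"""Maximal-overlap discrete wavelet transform (MODWT) and wavelet correlation.

The MODWT is the non-decimated dyadic wavelet transform: level-j detail
coefficients carry the nominal frequency band [fs/2^(j+1), fs/2^j] and are
the same length as the input, so a Pearson correlation between two regions'
detail coefficients at one level is a band-restricted functional-connectivity
estimate.  With periodic boundary handling the transform partitions the
sample variance of the input exactly across levels, which is the identity
used to validate the implementation.

The pyramid algorithm follows the standard circular-filter formulation:

    W_{j,t} = sum_l h_l V_{j-1, (t - 2^(j-1) l) mod N}
    V_{j,t} = sum_l g_l V_{j-1, (t - 2^(j-1) l) mod N}

with (g, h) the DWT scaling/wavelet filter pair rescaled by 1/sqrt(2).
Filter coefficients come from PyWavelets; the pyramid itself is implemented
here because PyWavelets exposes only the decimated DWT and the
length-constrained SWT.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .types import ConnectivityMatrix, RoiTimeSeries

#: pywt name of the 4-tap Daubechies filter D(4) of the wavelet
#: time-series literature (pywt counts vanishing moments, not taps).
DEFAULT_FAMILY = "db2"


@dataclass(frozen=True)
class WaveletSpec:
    """Parameters of the multi-scale decomposition.

    family   : any orthogonal PyWavelets name ("db2" is the 4-tap D(4)).
    n_levels : decomposition depth (default 4).
    scale    : the level whose detail coefficients are correlated (default 2;
               band 0.0625-0.125 Hz at TR = 2 s).
    boundary : "periodic" (exact variance partition) or "reflection".
    """

    family: str = DEFAULT_FAMILY
    n_levels: int = 4
    scale: int = 2
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        if not 1 <= self.scale <= self.n_levels:
            raise ValueError("scale must satisfy 1 <= scale <= n_levels")
        if self.boundary not in ("periodic", "reflection"):
            raise ValueError("boundary must be 'periodic' or 'reflection'")
        wav = pywt.Wavelet(self.family)
        if not wav.orthogonal:
            raise ValueError(f"wavelet {self.family!r} is not orthogonal")

    @property
    def filter_length(self) -> int:
        return pywt.Wavelet(self.family).dec_len

    def equivalent_filter_width(self, level: int) -> int:
        """Width L_j = (2^j - 1)(L - 1) + 1 of the level-j equivalent filter."""
        return (2**level - 1) * (self.filter_length - 1) + 1


def scale_band(spec: WaveletSpec, tr: float, scale: int | None = None) -> tuple[float, float]:
    """Nominal dyadic frequency band (f_lo, f_hi) in Hz of a detail level.

    Level j of a series sampled at fs = 1/tr carries [fs/2^(j+1), fs/2^j];
    at TR = 2 s the level-2 band is 0.0625-0.125 Hz.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    j = spec.scale if scale is None else scale
    fs = 1.0 / tr
    return fs / 2 ** (j + 1), fs / 2**j


def modwt(x: np.ndarray, spec: WaveletSpec) -> tuple[list[np.ndarray], np.ndarray]:
    """MODWT of a series (or each column of a 2-D array).

    Returns ``(details, smooth)`` where ``details[j-1]`` is the level-j
    detail-coefficient array and ``smooth`` the level-``n_levels`` smooth,
    all the same shape as the input.  With periodic boundary the population
    variances of the details plus the smooth sum to the input's variance
    (ddof=0) to machine precision.
    """
    x = np.asarray(x, dtype=float)
    one_d = x.ndim == 1
    v = x[:, None] if one_d else x
    n = v.shape[0]
    min_len = spec.equivalent_filter_width(spec.n_levels)
    if n < min_len:
        raise ValueError(
            f"series of length {n} too short for {spec.n_levels} levels of "
            f"{spec.family}: need at least {min_len} timepoints"
        )

    if spec.boundary == "reflection":
        v = np.concatenate([v, v[::-1]], axis=0)

    wav = pywt.Wavelet(spec.family)
    g = np.asarray(wav.dec_lo, dtype=float) / math.sqrt(2.0)
    h = np.asarray(wav.dec_hi, dtype=float) / math.sqrt(2.0)

    details: list[np.ndarray] = []
    for j in range(1, spec.n_levels + 1):
        stride = 2 ** (j - 1)
        w = np.zeros_like(v)
        v_next = np.zeros_like(v)
        for l in range(len(g)):
            rolled = np.roll(v, stride * l, axis=0)
            w += h[l] * rolled
            v_next += g[l] * rolled
        details.append(w)
        v = v_next

    if spec.boundary == "reflection":
        details = [d[:n] for d in details]
        v = v[:n]
    if one_d:
        details = [d[:, 0] for d in details]
        v = v[:, 0]
    return details, v


def wavelet_correlation_matrix(series: RoiTimeSeries, spec: WaveletSpec) -> ConnectivityMatrix:
    """Pearson correlation of level-``spec.scale`` detail coefficients.

    Boundary-affected coefficients — the first L_j - 1, where L_j is the
    level-j equivalent filter width — are discarded before correlating,
    since the circular (or reflected) wrap-around would otherwise induce
    spurious covariance between regions.  A zero-variance coefficient
    vector yields correlation 0 with that region (with a warning); the
    diagonal is always 1.
    """
    details, _ = modwt(series.values, spec)
    coeffs = details[spec.scale - 1]
    n_boundary = spec.equivalent_filter_width(spec.scale) - 1
    coeffs = coeffs[n_boundary:]
    if coeffs.shape[0] < 2:
        raise ValueError(
            f"only {coeffs.shape[0]} non-boundary coefficients at level "
            f"{spec.scale}; need at least 2 (series too short)"
        )

    sd = coeffs.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        bad = [series.roi_labels[i] for i in np.nonzero(degenerate)[0]]
        warnings.warn(
            f"zero-variance wavelet coefficients for {bad}; correlations set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        coeffs = coeffs.copy()
        coeffs[:, degenerate] = np.nan  # excluded below

    with np.errstate(invalid="ignore"):
        r = np.corrcoef(coeffs, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(
        values=r,
        scale=spec.scale,
        roi_labels=series.roi_labels,
        subject=series.subject,
        session=series.session,
    )
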