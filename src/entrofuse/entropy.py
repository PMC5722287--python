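"""Entropy measures and autoregressive coefficients for single-channel epochs.

Four regularity/complexity statistics are computed per channel per epoch:

* spectral entropy (PE) — Shannon entropy of the normalized power
  spectrum, a measure of spectral flatness;
* approximate entropy (AE) — Pincus's template self-similarity
  statistic, self-matches included;
* sample entropy (SE) — Richman & Moorman's variant, self-matches
  excluded, less dependent on series length;
* fuzzy entropy (FE) — Chen's variant with mean-centered templates and
  a graded exponential membership in place of the hard match threshold.

All three embedding entropies use Chebyshev (max-norm) template distance
with embedding dimension ``m`` and tolerance ``r = r_factor * SD``,
where SD is the standard deviation of the series at hand. Lower values
mean a more regular (more predictable) signal; drowsiness-related
build-up of rhythmic low-frequency activity therefore lowers all four.

Autoregressive (AR) coefficients estimated from the Yule-Walker
equations serve as the comparison feature set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from statsmodels.regression.linear_model import yule_walker

MEASURES = ("PE", "AE", "SE", "FE")


@dataclass(frozen=True)
class EntropyParams:
    """Parameters shared by the embedding entropies.

    Attributes
    ----------
    m : int
        Embedding (template) dimension. Default 2, the common choice for
        series longer than ~200 samples.
    r_factor : float
        Similarity tolerance as a multiple of the series' standard
        deviation; the effective tolerance ``r = r_factor * SD`` is
        recomputed per channel per epoch. Default 0.2.
    n_grad : int
        Gradient of the fuzzy membership function
        ``exp(-(d/r)**n_grad)``. Default 2.
    """

    m: int = 2
    r_factor: float = 0.2
    n_grad: int = 2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if not self.r_factor > 0:
            raise ValueError("r_factor must be positive")
        if self.n_grad < 1:
            raise ValueError("n_grad must be >= 1")


@dataclass(frozen=True)
class ARSpec:
    """Autoregressive model specification (order p; p coefficients kept)."""

    order: int = 10

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("AR order must be >= 1")


def _as_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


def spectral_entropy(
    x, fs: float, band: tuple[float, float] = (0.15, 45.0)
) -> float:
    """Normalized Shannon entropy of the periodogram power spectrum.

    The periodogram of the full epoch is restricted to the analysis band
    (the DC bin falls outside it), normalized to a probability
    distribution, and its Shannon entropy is divided by ``log(n_bins)``
    so the result lies in [0, 1]: 0 for power concentrated in a single
    bin, 1 for a perfectly flat spectrum.

    Parameters
    ----------
    x : array-like
        Single-channel epoch.
    fs : float
        Sampling rate in Hz.
    band : (low, high)
        Analysis band in Hz; bins with ``low <= f <= high`` are kept.

    Returns
    -------
    float
        Spectral entropy in [0, 1]; 0 for a constant (zero-power) epoch.
    """
    x = _as_series(x)
    if x.size < 2:
        raise ValueError("need at least two samples")
    freqs, psd = sps.periodogram(x, fs=fs, detrend=False)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(mask):
        raise ValueError(f"no spectral bins inside band {band} at fs={fs}")
    p = psd[mask]
    total = p.sum()
    if total <= 0:  # constant / zero signal: degenerate spectrum
        return 0.0
    p = p / total
    nz = p[p > 0]
    h = -np.sum(nz * np.log(nz))
    return float(h / math.log(p.size))


def _templates(x: np.ndarray, m: int) -> np.ndarray:
    return sliding_window_view(x, m)


def _cheb(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs Chebyshev distances between template rows."""
    return np.max(np.abs(a[:, None, :] - b[None, :, :]), axis=-1)


def approximate_entropy(x, params: EntropyParams = EntropyParams()) -> float:
    """Approximate entropy AE = Phi^m(r) - Phi^(m+1)(r).

    ``Phi^m`` is the mean log fraction of templates within Chebyshev
    distance ``r`` of each length-``m`` template, self-matches included,
    so AE is defined (and 0) for perfectly regular series.

    Returns 0 for a constant series (zero tolerance base).
    """
    x = _as_series(x)
    m = params.m
    if x.size <= m + 1:
        raise ValueError(f"series length {x.size} too short for m={m}")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = params.r_factor * sd

    def phi(mm: int) -> float:
        t = _templates(x, mm)
        c = (_cheb(t, t) <= r).mean(axis=1)
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def sample_entropy(x, params: EntropyParams = EntropyParams()) -> float:
    """Sample entropy SE = -ln(A / B), self-matches excluded.

    ``B`` counts ordered template pairs (i != j) of length ``m`` within
    tolerance, ``A`` the same at length ``m + 1``; both use the first
    ``N - m`` templates so the counts are comparable.

    Degenerate cases: a constant series gives 0 (A = B); if no
    length-``m + 1`` pair matches (A = 0), the finite upper-bound
    sentinel ``ln(B)`` (= -ln(1/B)) is returned with a warning rather
    than infinity; if no pair matches at all (B = 0) the series carries
    no template structure at this tolerance and 0 is returned with a
    warning.
    """
    x = _as_series(x)
    m = params.m
    if x.size <= m + 1:
        raise ValueError(f"series length {x.size} too short for m={m}")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = params.r_factor * sd
    nt = x.size - m  # templates used at both lengths
    tm = _templates(x, m)[:nt]
    tm1 = _templates(x, m + 1)
    b = int((_cheb(tm, tm) <= r).sum()) - nt  # drop self-matches
    a = int((_cheb(tm1, tm1) <= r).sum()) - nt
    if b == 0:
        warnings.warn("sample entropy: no template matches at length m; returning 0")
        return 0.0
    if a == 0:
        warnings.warn(
            "sample entropy: no matches at length m+1; returning ln(B) sentinel"
        )
        return float(math.log(b))
    return float(-math.log(a / b))


def fuzzy_entropy(x, params: EntropyParams = EntropyParams()) -> float:
    """Fuzzy entropy FE = ln(phi^m) - ln(phi^(m+1)).

    Templates are mean-centered; similarity between two templates at
    Chebyshev distance ``d`` is the graded membership
    ``exp(-(d/r)**n_grad)`` instead of a hard threshold. ``phi^m`` is
    the mean pairwise similarity over distinct template pairs.
    Returns 0 for constant series (all similarities equal 1).
    """
    x = _as_series(x)
    m = params.m
    if x.size <= m + 1:
        raise ValueError(f"series length {x.size} too short for m={m}")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = params.r_factor * sd

    def phi(mm: int) -> float:
        t = _templates(x, mm)[: x.size - m]
        t = t - t.mean(axis=1, keepdims=True)
        d = _cheb(t, t)
        sim = np.exp(-((d / r) ** params.n_grad))
        n = t.shape[0]
        return float((sim.sum() - n) / (n * (n - 1)))  # exclude self-pairs

    return math.log(phi(m)) - math.log(phi(m + 1))


def ar_coefficients(x, spec: ARSpec = ARSpec()) -> np.ndarray:
    """Yule-Walker AR(p) coefficients with biased autocovariance estimates.

    The series is demeaned and the coefficients ``a_1..a_p`` of
    ``x_t = a_1 x_{t-1} + ... + a_p x_{t-p} + e_t`` are solved from the
    Yule-Walker equations; the innovation variance is not part of the
    feature vector. A constant (zero-variance) series has a singular
    autocovariance system and yields the zero vector with a warning.
    """
    x = _as_series(x)
    if x.size <= spec.order:
        raise ValueError(f"series length {x.size} must exceed AR order {spec.order}")
    if x.std() == 0:
        warnings.warn("AR fit on constant series: returning zero coefficients")
        return np.zeros(spec.order)
    rho, _sigma = yule_walker(x, order=spec.order, method="mle")
    return np.asarray(rho, dtype=float)
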