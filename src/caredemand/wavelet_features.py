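"""Multi-domain feature extraction from wavelet-decomposed health signals.

A multilevel discrete wavelet transform splits each signal into one
approximation band (low frequency, the overall trend) and J detail
bands (high frequency, volatility and noise).  From every band we take
time-domain statistics (mean, variance, standard deviation, skewness,
kurtosis), a nonlinear complexity measure (sample entropy), and the
band's spectral energy; two global descriptors — the Shannon entropy of
the band-energy distribution and the full-signal sample entropy —
complete the feature vector.

Conventions
-----------
* Orthonormal wavelet families with periodic (``periodization``) signal
  extension, so band energies sum exactly to the signal's squared norm
  (Parseval) and the cascade inverts perfectly.
* Population (1/N) moments; a zero-variance band has skewness and
  kurtosis defined as 0.
* All entropies are in nats (natural logarithm).
* Sample entropy uses the matched-template-pair counting convention
  with N−a templates at both embedding dimensions a and a+1 (so the
  a+1 match count never exceeds the a count), Chebyshev distance,
  self-matches excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "WaveletSpec",
    "WaveletDecomposition",
    "BandFeatures",
    "SampleEntropyResult",
    "dwt_decompose",
    "reconstruct",
    "band_features",
    "energy_entropy",
    "sample_entropy",
    "feature_names",
    "extract_features",
    "feature_matrix",
]


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet family and decomposition depth.

    ``family`` must name an orthogonal PyWavelets wavelet (default
    ``"haar"``; ``"db4"`` is the other tested choice).  ``levels`` is
    the number of cascade stages J ≥ 1.
    """

    family: str = "haar"
    levels: int = 3

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        wavelet = pywt.Wavelet(self.family)
        if not wavelet.orthogonal:
            raise ValueError(f"wavelet family {self.family!r} is not orthogonal")

    @property
    def wavelet(self) -> pywt.Wavelet:
        return pywt.Wavelet(self.family)

    @property
    def lowpass(self) -> np.ndarray:
        """Decomposition low-pass taps (the discrete scaling filter)."""
        return np.asarray(self.wavelet.dec_lo)

    @property
    def highpass(self) -> np.ndarray:
        """Decomposition high-pass taps (the discrete wavelet filter)."""
        return np.asarray(self.wavelet.dec_hi)


@dataclass(frozen=True)
class WaveletDecomposition:
    """Approximation band at level J plus detail bands at levels 1..J."""

    cA: np.ndarray
    cD: tuple[np.ndarray, ...]  # index 0 = level 1 (finest)
    spec: WaveletSpec

    @property
    def levels(self) -> int:
        return len(self.cD)

    @property
    def band_names(self) -> tuple[str, ...]:
        J = self.levels
        return (f"cA{J}",) + tuple(f"cD{j}" for j in range(1, J + 1))

    @property
    def bands(self) -> tuple[np.ndarray, ...]:
        return (self.cA,) + self.cD

    @property
    def band_energies(self) -> np.ndarray:
        """Sum of squared coefficients per band, ordered as ``band_names``."""
        return np.array([float(np.sum(b * b)) for b in self.bands])

    @property
    def total_energy(self) -> float:
        return float(self.band_energies.sum())


@dataclass(frozen=True)
class BandFeatures:
    """Time-domain and complexity statistics of one coefficient band."""

    mean: float
    variance: float
    std: float
    skewness: float
    kurtosis: float
    n_points: int
    complexity: float


@dataclass(frozen=True)
class SampleEntropyResult:
    """Sample entropy with its template-pair counts.

    ``count_a`` (matches at dimension ``a``) and ``count_a1`` (matches
    at ``a + 1``) satisfy ``0 <= count_a1 <= count_a``; the value is
    ``-ln(count_a1 / count_a)`` when both are positive.
    """

    value: float
    a: int
    b: float
    n: int
    count_a: int
    count_a1: int


def _signal_values(signal) -> np.ndarray:
    values = getattr(signal, "values", signal)
    return np.asarray(values, dtype=float).ravel()


def dwt_decompose(signal, spec: WaveletSpec = WaveletSpec()) -> WaveletDecomposition:
    """Cascade of filter-and-downsample stages on one signal.

    Each stage convolves with the spec's low/high-pass pair and
    downsamples by two; the approximation output feeds the next stage
    while each detail band is kept.
    """
    x = _signal_values(signal)
    if x.size < 2 ** spec.levels:
        raise ValueError(
            f"signal of length {x.size} is too short for {spec.levels} levels"
        )
    coeffs = pywt.wavedec(x, spec.wavelet, mode="periodization", level=spec.levels)
    cA, details = coeffs[0], coeffs[1:]  # details ordered level J .. 1
    return WaveletDecomposition(cA=cA, cD=tuple(details[::-1]), spec=spec)


def reconstruct(decomp: WaveletDecomposition) -> np.ndarray:
    """Invert the cascade; exact (to rounding) for orthonormal families."""
    coeffs = [decomp.cA] + list(decomp.cD[::-1])
    return pywt.waverec(coeffs, decomp.spec.wavelet, mode="periodization")


def _moments(values: np.ndarray):
    mean = float(values.mean())
    centred = values - mean
    variance = float(np.mean(centred ** 2))
    std = float(np.sqrt(variance))
    if std == 0.0:
        return mean, variance, std, 0.0, 0.0
    skewness = float(np.mean(centred ** 3) / std ** 3)
    kurtosis = float(np.mean(centred ** 4) / std ** 4)
    return mean, variance, std, skewness, kurtosis


def band_features(coefficients, sampen_a: int = 2, sampen_r: float = 0.2) -> BandFeatures:
    """Population moments plus sample-entropy complexity of one band."""
    values = np.asarray(coefficients, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty coefficient vector")
    mean, variance, std, skewness, kurtosis = _moments(values)
    complexity = sample_entropy(values, a=sampen_a, b=sampen_r * std).value
    return BandFeatures(
        mean=mean,
        variance=variance,
        std=std,
        skewness=skewness,
        kurtosis=kurtosis,
        n_points=values.size,
        complexity=complexity,
    )


def energy_entropy(decomp: WaveletDecomposition) -> float:
    """Shannon entropy (nats) of the band-energy distribution.

    Bands with zero energy contribute nothing; an all-zero signal has
    entropy 0 by convention.  The value lies in [0, ln(J + 1)].
    """
    energies = decomp.band_energies
    total = energies.sum()
    if total == 0.0:
        return 0.0
    p = energies / total
    p = p[p > 0.0]
    return float(-(p * np.log(p)).sum())


def sample_entropy(series, a: int = 2, b: float | None = None,
                   cap: float | None = None) -> SampleEntropyResult:
    """Sample entropy of a series under Chebyshev tolerance ``b``.

    ``b`` defaults to 0.2 times the series' population standard
    deviation (the literature standard).  When either template-match
    count is zero the value is undefined (+inf); it is reported as the
    configurable ``cap``, default ``ln(N − a) + ln(2)``.  A constant
    series with a relative tolerance yields 0 (every pair matches).
    """
    x = np.asarray(series, dtype=float).ravel()
    N = x.size
    if a < 1:
        raise ValueError("embedding dimension a must be >= 1")
    if N <= a + 1:
        raise ValueError(f"series of length {N} too short for a={a}")
    if b is None:
        b = 0.2 * float(x.std())
    if b < 0:
        raise ValueError("similarity threshold b must be >= 0")
    T = N - a  # templates used at both dimensions
    emb_a = sliding_window_view(x, a)[:T]
    emb_a1 = sliding_window_view(x, a + 1)
    d_a = np.abs(emb_a[:, None, :] - emb_a[None, :, :]).max(axis=-1)
    d_a1 = np.abs(emb_a1[:, None, :] - emb_a1[None, :, :]).max(axis=-1)
    iu = np.triu_indices(T, k=1)
    count_a = int((d_a[iu] <= b).sum())
    count_a1 = int((d_a1[iu] <= b).sum())
    if count_a == 0 or count_a1 == 0:
        value = float(np.log(N - a) + np.log(2)) if cap is None else float(cap)
    else:
        value = float(-np.log(count_a1 / count_a))
    return SampleEntropyResult(value=value, a=a, b=float(b), n=N,
                               count_a=count_a, count_a1=count_a1)


_BAND_STATS = ("mean", "variance", "std", "skewness", "kurtosis", "complexity", "energy")
_GLOBAL = ("global_energy_entropy", "global_sampen")


def feature_names(spec: WaveletSpec = WaveletSpec()) -> tuple[str, ...]:
    """The fixed, versioned feature layout for a given depth J.

    Per band (cA_J first, then cD_1..cD_J): the six time-domain /
    complexity statistics plus the band energy; then the two global
    features.  J = 3 gives 4 x 7 + 2 = 30 names.
    """
    J = spec.levels
    bands = [f"cA{J}"] + [f"cD{j}" for j in range(1, J + 1)]
    names = [f"{band}_{stat}" for band in bands for stat in _BAND_STATS]
    return tuple(names + list(_GLOBAL))


def extract_features(signal, spec: WaveletSpec = WaveletSpec(),
                     sampen_a: int = 2, sampen_r: float = 0.2) -> np.ndarray:
    """Full multi-domain feature vector for one signal.

    Deterministic; ordered exactly as :func:`feature_names`.
    """
    decomp = dwt_decompose(signal, spec)
    out: list[float] = []
    for band in decomp.bands:
        bf = band_features(band, sampen_a=sampen_a, sampen_r=sampen_r)
        out.extend([bf.mean, bf.variance, bf.std, bf.skewness, bf.kurtosis,
                    bf.complexity, float(np.sum(band * band))])
    out.append(energy_entropy(decomp))
    x = _signal_values(signal)
    out.append(sample_entropy(x, a=sampen_a, b=sampen_r * float(x.std())).value)
    return np.array(out)


def feature_matrix(signals: np.ndarray, spec: WaveletSpec = WaveletSpec(),
                   sampen_a: int = 2, sampen_r: float = 0.2) -> np.ndarray:
    """Vectorized :func:`extract_features` over rows of ``signals``.

    The wavelet cascade and the moment statistics are computed for all
    rows at once; sample entropies fall back to a per-row loop.
    """
    S = np.asarray(signals, dtype=float)
    if S.ndim != 2:
        raise ValueError("signals must be a 2D array (n_signals, length)")
    n, L = S.shape
    if L < 2 ** spec.levels:
        raise ValueError("signals too short for the requested depth")
    coeffs = pywt.wavedec(S, spec.wavelet, mode="periodization",
                          level=spec.levels, axis=1)
    bands = [coeffs[0]] + list(coeffs[1:][::-1])  # cA_J, cD1..cDJ as (n, k_j)
    blocks: list[np.ndarray] = []
    energies = np.column_stack([np.sum(B * B, axis=1) for B in bands])
    for B in bands:
        mean = B.mean(axis=1)
        centred = B - mean[:, None]
        var = np.mean(centred ** 2, axis=1)
        std = np.sqrt(var)
        safe = np.where(std == 0.0, 1.0, std)
        skew = np.where(std == 0.0, 0.0, np.mean(centred ** 3, axis=1) / safe ** 3)
        kurt = np.where(std == 0.0, 0.0, np.mean(centred ** 4, axis=1) / safe ** 4)
        complexity = np.array([
            sample_entropy(B[i], a=sampen_a, b=sampen_r * std[i]).value
            for i in range(n)
        ])
        energy = np.sum(B * B, axis=1)
        blocks.append(np.column_stack([mean, var, std, skew, kurt, complexity, energy]))
    total = energies.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total[:, None] > 0, energies / np.where(total[:, None] == 0, 1, total[:, None]), 0.0)
        ent_terms = np.where(p > 0, -p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    global_ent = ent_terms.sum(axis=1)
    global_sampen = np.array([
        sample_entropy(S[i], a=sampen_a, b=sampen_r * float(S[i].std())).value
        for i in range(n)
    ])
    return np.column_stack(blocks + [global_ent, global_sampen])
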