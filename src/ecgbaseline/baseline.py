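"""Stochastic sinusoidal baseline-wander model.

The artifact is a linear combination of K+1 cosines spanning 0 to f_c Hz on an
exact FFT grid:

    b(t) = C * sum_{k=0}^{K} a_k * cos(2*pi*k*delta_f*t + phi_k)

with delta_f = fs/N the spectral resolution of the record, a_k ~ U[0, 1],
phi_k ~ U[0, 2*pi), and C a scaling constant used to set the signal-to-noise
ratio.  At the defaults (fs = 512 Hz, N = 51200) delta_f = 0.01 Hz and
K = f_c/delta_f = 50, so the artifact band is 0-0.5 Hz with 51 components
including the DC (k = 0) term, which collapses to the constant a_0*cos(phi_0)
and models an electrode offset.

SNR is defined on mean-squared power of the full record, per lead:
10*log10(P_x / P_b) with the DC term counted as artifact power.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ContractError, DegenerateArtifactError, InvalidParameterError

__all__ = [
    "BaselineSpec",
    "BaselineRealization",
    "draw_realization",
    "render",
    "scale_to_snr",
    "corrupt",
]


@dataclass(frozen=True)
class BaselineSpec:
    """Spectral layout of the artifact: harmonics of delta_f = fs/N up to f_c."""

    fs: float = 512.0
    n_samples: int = 51200
    f_c: float = 0.5

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.fs <= 0 or self.f_c <= 0:
            raise InvalidParameterError("fs, n_samples and f_c must be positive")
        if self.f_c > self.fs / 2:
            raise InvalidParameterError("f_c must not exceed the Nyquist frequency")

    @property
    def delta_f(self) -> float:
        """Spectral resolution fs/N; every component falls on an FFT bin."""
        return self.fs / self.n_samples

    @property
    def n_harmonics(self) -> int:
        """K: index of the highest harmonic, K*delta_f = f_c (defaults: 50)."""
        return round(self.f_c / self.delta_f)


@dataclass(frozen=True)
class BaselineRealization:
    """Random amplitudes/phases of one artifact draw plus its scaling constant."""

    a: np.ndarray       # (K+1,) uniform [0, 1]
    phi: np.ndarray     # (K+1,) uniform [0, 2*pi)
    C: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.a.shape != self.phi.shape or self.a.ndim != 1:
            raise ContractError("a and phi must be 1-D arrays of equal length")
        if np.any(self.a < 0) or np.any(self.a > 1):
            raise ContractError("amplitudes must lie in [0, 1]")
        if np.any(self.phi < 0) or np.any(self.phi >= 2 * np.pi):
            raise ContractError("phases must lie in [0, 2*pi)")
        if not np.isfinite(self.C) or self.C <= 0:
            raise ContractError("C must be positive and finite")


def draw_realization(spec: BaselineSpec, seed: int) -> BaselineRealization:
    """Draw independent uniform amplitudes and phases; C is initialised to 1."""
    rng = np.random.default_rng(seed)
    k = spec.n_harmonics + 1
    a = rng.uniform(0.0, 1.0, size=k)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=k)
    return BaselineRealization(a=a, phi=phi, C=1.0, seed=int(seed))


def render(realization: BaselineRealization, spec: BaselineSpec) -> np.ndarray:
    """Evaluate b[n] = C * sum_k a_k cos(2*pi*k*n/N + phi_k) for n = 0..N-1.

    Because every component sits exactly on an FFT bin, the sum is evaluated
    through a single inverse real FFT (bit-equivalent to the direct cosine sum
    up to floating rounding, at O(N log N) cost).
    """
    K = spec.n_harmonics
    if len(realization.a) != K + 1:
        raise ContractError(
            f"realization holds {len(realization.a)} components, spec expects {K + 1}"
        )
    n = spec.n_samples
    spectrum = np.zeros(n // 2 + 1, dtype=complex)
    spectrum[0] = n * realization.a[0] * np.cos(realization.phi[0])
    spectrum[1 : K + 1] = (n / 2.0) * realization.a[1:] * np.exp(1j * realization.phi[1:])
    return realization.C * np.fft.irfft(spectrum, n)


def scale_to_snr(b: np.ndarray, x: np.ndarray, snr_db: float) -> tuple[np.ndarray, float]:
    """Rescale artifact ``b`` so that 10*log10(P_x / P_b') = ``snr_db``.

    Powers are mean-squared values over the full record.  Returns the scaled
    artifact and the multiplicative constant applied.
    """
    if len(b) != len(x):
        raise ContractError("signal and artifact lengths differ")
    p_x = float(np.mean(np.square(x)))
    p_b = float(np.mean(np.square(b)))
    if p_b == 0.0:
        raise DegenerateArtifactError("artifact is identically zero; cannot scale")
    if p_x == 0.0:
        raise InvalidParameterError("clean signal is identically zero; SNR undefined")
    c = float(np.sqrt(p_x / (p_b * 10.0 ** (snr_db / 10.0))))
    return b * c, c


def rescale(realization: BaselineRealization, c: float) -> BaselineRealization:
    """Return a copy of the realization with C multiplied by ``c``."""
    return replace(realization, C=realization.C * c)


def corrupt(x: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Additive corruption y = x + b."""
    if len(x) != len(b):
        raise ContractError("signal and artifact lengths differ")
    return x + b
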