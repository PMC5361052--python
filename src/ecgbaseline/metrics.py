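"""Reconstruction-quality statistics.

Before scoring, one second is trimmed from each end of both the reference and
the reconstructed signal, because every filter exhibits a boundary transient.
Three statistics are then computed:

* Pearson correlation coefficient (CC) — morphology match, invariant to
  scaling and offset.
* l_operator — Euclidean similarity, 1 - E{(x - x_hat)^2} / (E{x^2} +
  E{x_hat^2}); lies in [-1, 1] and equals 1 only for identical signals, so it
  is sensitive to scaling and offset where CC is not.
* K-point deviation (dKP) — amplitude change at the K point, the instant in
  each ST window where the across-lead envelope max_i |x_i(t)| is minimal.
  The K point is a detection-free surrogate of the clinical J point; it is
  located once on the clean 12-lead record and never re-estimated on
  filtered signals.  Per-beat deviations are aggregated by their median into
  one dKP per signal (configurable to pooling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, UndefinedStatisticError
from .synthetic import EcgRecord

__all__ = [
    "trim_boundaries",
    "correlation_coefficient",
    "l_operator",
    "KpAnnotation",
    "locate_kp",
    "kp_deviation",
]


def trim_boundaries(signal: np.ndarray, fs: float, margin: float = 1.0) -> np.ndarray:
    """Drop ``margin`` seconds (rounded to samples) from each end."""
    m = round(margin * fs)
    if m == 0:
        return np.asarray(signal)
    if len(signal) <= 2 * m:
        raise ContractError("signal is shorter than twice the trim margin")
    return np.asarray(signal)[m:-m]


def correlation_coefficient(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Pearson correlation between reference and reconstruction."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape or x.ndim != 1 or len(x) < 2:
        raise ContractError("inputs must be equal-length 1-D arrays of length >= 2")
    dx = x - x.mean()
    dy = x_hat - x_hat.mean()
    denom = np.sqrt(np.dot(dx, dx) * np.dot(dy, dy))
    if denom == 0.0:
        raise UndefinedStatisticError("correlation undefined for a constant signal")
    return float(np.clip(np.dot(dx, dy) / denom, -1.0, 1.0))


def l_operator(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Euclidean similarity 1 - E{(x - x_hat)^2} / (E{x^2} + E{x_hat^2})."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape or x.ndim != 1 or len(x) == 0:
        raise ContractError("inputs must be equal-length 1-D arrays")
    denom = np.mean(np.square(x)) + np.mean(np.square(x_hat))
    if denom == 0.0:
        raise UndefinedStatisticError("l_operator undefined when both signals are zero")
    return float(1.0 - np.mean(np.square(x - x_hat)) / denom)


@dataclass(frozen=True)
class KpAnnotation:
    """Absolute K-point sample index for each beat (untrimmed coordinates)."""

    kp_indices: np.ndarray

    def surviving(self, n_samples: int, margin_samples: int) -> np.ndarray:
        """K points that remain inside the record after boundary trimming."""
        idx = self.kp_indices
        return idx[(idx >= margin_samples) & (idx < n_samples - margin_samples)]


def locate_kp(record: EcgRecord) -> KpAnnotation:
    """Find the K point of every beat on the clean multi-lead record.

    For each ST window the envelope max over leads of |x_i(t)| is minimised
    over t; ties break to the earliest sample.
    """
    if len(record.st_windows) == 0:
        raise ContractError("record carries no ST-window annotations")
    envelope_src = np.abs(record.leads)
    kp = np.empty(len(record.st_windows), dtype=int)
    for i, (start, end) in enumerate(record.st_windows):
        env = envelope_src[:, start:end].max(axis=0)
        kp[i] = start + int(np.argmin(env))  # argmin returns the first minimum
    return KpAnnotation(kp_indices=kp)


def kp_deviation(
    x_lead: np.ndarray,
    x_hat_lead: np.ndarray,
    kp: KpAnnotation,
    margin_samples: int = 0,
    aggregate: str = "median",
):
    """Amplitude deviation x_hat - x at the clean-record K points (mV).

    ``margin_samples`` excludes beats whose K point falls inside the trimmed
    boundary region.  With ``aggregate='median'`` (default) one value per
    signal is returned; ``aggregate='pool'`` returns the per-beat deviations.
    """
    x_lead = np.asarray(x_lead, dtype=float)
    x_hat_lead = np.asarray(x_hat_lead, dtype=float)
    if x_lead.shape != x_hat_lead.shape:
        raise ContractError("signal lengths differ")
    idx = kp.surviving(len(x_lead), margin_samples)
    if idx.size == 0:
        raise ContractError("no K point survives boundary trimming")
    devs = x_hat_lead[idx] - x_lead[idx]
    if aggregate == "pool":
        return devs
    if aggregate == "median":
        return float(np.median(devs))
    raise ContractError(f"unknown aggregate {aggregate!r}")
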