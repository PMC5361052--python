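"""Synthetic 12-lead ischemic ECG generator.

Produces clean reference records that emulate the signal-level properties of a
multiscale electrophysiological simulation of ischemia: each beat consists of a
QRS complex, an ST segment with a controllable elevation/depression, and a
T wave (no P wave); the QT interval is fixed at 400 ms; RR intervals follow a
truncated Gaussian (mean 1 s, SD 50 ms); records are synthesized at the native
500 Hz rate and rationally resampled to 512 Hz so that a 100 s record holds
exactly 51200 samples.

Beat morphology is a sum of Gaussian lobes (Q, R, S, T) plus a raised-cosine
ST plateau whose amplitude is solved per lead so that the mean over the ST
window equals the requested ST level exactly.  Fiducial sample indices (QRS
onset/offset, ST window, T peak/end) are carried through resampling, so the
ground truth needed by the spline filter and the K-point statistic is always
available without any delineation algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import resample_poly

from .errors import ContractError, InvalidParameterError

__all__ = [
    "LEAD_NAMES",
    "FS_NATIVE",
    "FS_OUT",
    "QT_DURATION",
    "BeatTemplate",
    "RRModel",
    "EcgRecord",
    "make_beat_template",
    "draw_rr_series",
    "synthesize_record",
    "generate_setup_grid",
]

LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6")
N_LEADS = 12

FS_NATIVE = 500.0   # Hz, native rate of the beat synthesizer
FS_OUT = 512.0      # Hz, record rate after rational resampling (128/125)
QT_DURATION = 0.400  # s, fixed QT interval

# Gaussian lobes of the default beat: (name, center s, sigma s, amplitude mV).
# Amplitudes are per-unit; they are scaled by the per-lead gain.
_DEFAULT_LOBES = (
    ("Q", 0.030, 0.008, -0.10),
    ("R", 0.048, 0.010, 1.00),
    ("S", 0.066, 0.008, -0.20),
    ("T", 0.280, 0.038, 0.35),
)

# Relative lead gains roughly matching standard 12-lead R-wave projections
# (limb leads smaller, aVR inverted, precordial leads largest).
_DEFAULT_LEAD_GAINS = np.array(
    [0.70, 1.00, 0.45, -0.80, 0.40, 0.75, 0.55, 0.85, 1.15, 1.40, 1.20, 0.90]
)

# Fiducials on the native 500 Hz grid (samples).  t_end is exclusive.
_FIDUCIALS_NATIVE = {
    "qrs_onset": 0,
    "qrs_offset": 45,   # 90 ms: J-point analogue
    "st_onset": 55,     # 110 ms
    "st_offset": 105,   # 210 ms
    "t_peak": 140,      # 280 ms
    "t_end": 200,       # 400 ms = QT at 500 Hz
}


@dataclass(frozen=True)
class BeatTemplate:
    """One ischemic beat at the native rate, all 12 leads.

    ``samples`` has shape ``(12, n)`` in mV; ``fiducials`` are sample indices
    on the native grid with ``t_end`` exclusive; ``st_level`` is the signed ST
    offset per lead (elevation > 0, depression < 0) realised exactly as the
    mean over the ST window.
    """

    samples: np.ndarray
    fs: float
    qt_duration: float
    fiducials: dict[str, int]
    st_level: np.ndarray

    def __post_init__(self) -> None:
        f = self.fiducials
        order = ["qrs_onset", "qrs_offset", "st_onset", "st_offset", "t_peak", "t_end"]
        vals = [f[k] for k in order]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ContractError(f"fiducials must be strictly increasing, got {f}")
        n_qt = round(self.qt_duration * self.fs)
        if f["t_end"] - f["qrs_onset"] != n_qt:
            raise ContractError(
                f"t_end - qrs_onset = {f['t_end'] - f['qrs_onset']} samples "
                f"does not match QT = {self.qt_duration} s at {self.fs} Hz"
            )
        if not (f["qrs_offset"] < f["st_onset"] and f["st_offset"] < f["t_peak"]):
            raise ContractError("ST window must lie strictly between QRS offset and T peak")
        if self.samples.shape != (N_LEADS, f["t_end"]):
            raise ContractError(f"samples shape {self.samples.shape} != (12, {f['t_end']})")
        if np.any(self.samples[:, 0] != 0.0) or np.any(self.samples[:, -1] != 0.0):
            raise ContractError("beat must start and end at 0 mV (isoelectric join)")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class RRModel:
    """Gaussian RR-interval model, truncated to keep intervals positive."""

    mean_rr: float = 1.0
    sd_rr: float = 0.050
    lower: float | None = None   # default mean - 4 SD
    upper: float | None = None   # default mean + 4 SD

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean_rr) or self.mean_rr <= QT_DURATION:
            raise InvalidParameterError(
                f"mean_rr must be finite and exceed the {QT_DURATION} s QT interval"
            )
        if not np.isfinite(self.sd_rr) or self.sd_rr < 0:
            raise InvalidParameterError("sd_rr must be finite and >= 0")
        lo, hi = self.bounds
        if not (lo <= self.mean_rr <= hi):
            raise InvalidParameterError("truncation bounds must bracket mean_rr")

    @property
    def bounds(self) -> tuple[float, float]:
        lo = self.mean_rr - 4.0 * self.sd_rr if self.lower is None else self.lower
        hi = self.mean_rr + 4.0 * self.sd_rr if self.upper is None else self.upper
        return lo, hi


@dataclass
class EcgRecord:
    """A clean 12-lead record with ground-truth annotations.

    ``leads`` has shape ``(12, n_samples)`` in mV at ``fs`` Hz.  ``beat_onsets``
    are QRS-onset sample indices; ``st_windows`` are per-beat half-open
    ``[start, end)`` index pairs, shared by all leads.  ``meta`` carries the
    generator parameters and seed needed for bit-exact regeneration.
    """

    leads: np.ndarray
    fs: float
    beat_onsets: np.ndarray
    st_windows: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.leads = np.asarray(self.leads, dtype=float)
        self.beat_onsets = np.asarray(self.beat_onsets, dtype=int)
        self.st_windows = np.asarray(self.st_windows, dtype=int).reshape(-1, 2)
        if self.leads.ndim != 2:
            raise ContractError("leads must be a 2-D (n_leads, n_samples) array")
        n = self.n_samples
        w = self.st_windows
        if w.size:
            if w.min() < 0 or w.max() > n:
                raise ContractError("st_windows must lie within [0, n_samples)")
            if np.any(w[:, 0] >= w[:, 1]):
                raise ContractError("st_windows must be non-empty [start, end) pairs")
            if np.any(w[1:, 0] < w[:-1, 1]):
                raise ContractError("st_windows must not overlap")
        if len(self.beat_onsets) != len(w):
            raise ContractError("beat_onsets and st_windows must align one-to-one")

    @property
    def n_leads(self) -> int:
        return self.leads.shape[0]

    @property
    def n_samples(self) -> int:
        return self.leads.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def spline_anchors(self, pre_onset: float = 0.040) -> np.ndarray:
        """Isoelectric anchor indices ``pre_onset`` seconds before each QRS onset."""
        offset = round(pre_onset * self.fs)
        anchors = self.beat_onsets - offset
        return anchors[anchors >= 0]


def _raised_cosine_ramp(n: int) -> np.ndarray:
    """Smooth monotone 0 -> 1 ramp of length n (half-cosine)."""
    return 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, n)))


def make_beat_template(
    st_level,
    morphology: dict | None = None,
    seed: int = 0,
) -> BeatTemplate:
    """Build one 12-lead beat with an exactly controlled ST level.

    Parameters
    ----------
    st_level : array-like of 12 floats
        Signed ST offset per lead in mV (|level| <= 1 mV).  The mean of the
        returned beat over the ST window equals this value exactly per lead.
    morphology : dict, optional
        Overrides: ``lobes`` (list of (name, center s, sigma s, amp mV)),
        ``lead_gains`` (12 floats), ``gain_jitter`` (fractional SD of the
        per-lead multiplicative jitter, default 0.15).
    seed : int
        Seeds the per-lead gain jitter; identical (st_level, morphology, seed)
        yield bit-identical templates.
    """
    st_level = np.asarray(st_level, dtype=float)
    if st_level.shape != (N_LEADS,):
        raise InvalidParameterError(f"st_level must have shape (12,), got {st_level.shape}")
    if not np.all(np.isfinite(st_level)):
        raise InvalidParameterError("st_level entries must be finite")
    if np.any(np.abs(st_level) > 1.0):
        raise InvalidParameterError("|st_level| must not exceed 1 mV")

    morphology = dict(morphology or {})
    lobes = morphology.get("lobes", _DEFAULT_LOBES)
    gains = np.asarray(morphology.get("lead_gains", _DEFAULT_LEAD_GAINS), dtype=float)
    jitter_sd = float(morphology.get("gain_jitter", 0.15))
    if gains.shape != (N_LEADS,) or not np.all(np.isfinite(gains)):
        raise InvalidParameterError("lead_gains must be 12 finite floats")
    for lobe in lobes:
        if not all(np.isfinite(v) for v in lobe[1:]):
            raise InvalidParameterError(f"non-finite morphology parameter in lobe {lobe!r}")
    if not np.isfinite(jitter_sd) or jitter_sd < 0:
        raise InvalidParameterError("gain_jitter must be finite and >= 0")

    fid = dict(_FIDUCIALS_NATIVE)
    n = fid["t_end"]
    t = np.arange(n) / FS_NATIVE

    base = np.zeros(n)
    for _name, center, sigma, amp in lobes:
        base += amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)

    # Taper the first/last few samples so the beat joins the isoline exactly.
    n_head, n_tail = 5, 12
    base[:n_head] *= _raised_cosine_ramp(n_head)
    base[-n_tail:] *= _raised_cosine_ramp(n_tail)[::-1]
    base[0] = base[-1] = 0.0

    rng = np.random.default_rng(seed)
    lead_gain = gains * (1.0 + jitter_sd * rng.standard_normal(N_LEADS)) if jitter_sd else gains

    # ST plateau: exactly 1 over [st_onset, st_offset), raised-cosine shoulders.
    plateau = np.zeros(n)
    s0, s1 = fid["st_onset"], fid["st_offset"]
    plateau[s0:s1] = 1.0
    up = fid["qrs_offset"]
    plateau[up:s0] = _raised_cosine_ramp(s0 - up)
    down_end = min(fid["t_peak"], s1 + (s0 - up))
    plateau[s1:down_end] = _raised_cosine_ramp(down_end - s1)[::-1]

    samples = lead_gain[:, None] * base[None, :]
    window = slice(s0, s1)
    # Solve the plateau amplitude so the ST-window mean is exact per lead.
    c = st_level - samples[:, window].mean(axis=1)
    samples = samples + c[:, None] * plateau[None, :]
    samples[:, 0] = 0.0
    samples[:, -1] = 0.0

    return BeatTemplate(
        samples=samples,
        fs=FS_NATIVE,
        qt_duration=QT_DURATION,
        fiducials=fid,
        st_level=st_level,
    )


def draw_rr_series(model: RRModel, duration: float, seed: int) -> np.ndarray:
    """Draw truncated-Gaussian RR intervals whose cumulative sum covers ``duration``."""
    if not np.isfinite(duration) or duration <= 0:
        raise InvalidParameterError("duration must be positive")
    lo, hi = model.bounds
    rng = np.random.default_rng(seed)
    intervals: list[np.ndarray] = []
    total = 0.0
    # Chunked draws; each chunk conservatively sized from the lower bound.
    while total < duration:
        need = max(8, int(np.ceil((duration - total) / max(lo, 1e-6))) + 4)
        chunk = rng.normal(model.mean_rr, model.sd_rr, size=need) if model.sd_rr else np.full(need, model.mean_rr)
        chunk = np.clip(chunk, lo, hi)
        intervals.append(chunk)
        total += chunk.sum()
    rr = np.concatenate(intervals)
    keep = np.searchsorted(np.cumsum(rr), duration) + 1
    return rr[: min(keep, len(rr))]


def _map_index(idx, up: int = 128, down: int = 125) -> np.ndarray:
    """Map native-rate sample indices onto the resampled grid (nearest sample)."""
    return np.rint(np.asarray(idx) * (up / down)).astype(int)


def synthesize_record(
    template: BeatTemplate,
    rr: RRModel,
    duration: float = 100.0,
    fs_out: float = FS_OUT,
    seed: int = 0,
    record_id: str | None = None,
) -> EcgRecord:
    """Quasiperiodic extension of a beat template into a full record.

    Beats are placed at cumulative RR onsets on the native 500 Hz grid with
    exact isoelectric zeros in between, then the whole record is rationally
    resampled to ``fs_out`` (512 Hz, factor 128/125) with a linear-phase
    polyphase low-pass.  Beats whose QT interval would cross the record end
    are omitted.  Annotations are mapped onto the output grid.
    """
    if duration < QT_DURATION:
        raise InvalidParameterError("duration must accommodate at least one beat")
    if fs_out != FS_OUT:
        raise InvalidParameterError("only the 512 Hz output rate is supported")

    n_native = round(duration * FS_NATIVE)
    rr_series = draw_rr_series(rr, duration, seed)
    onsets_t = np.concatenate([[0.0], np.cumsum(rr_series)])
    onsets_native = np.rint(onsets_t * FS_NATIVE).astype(int)
    n_beat = template.n_samples
    onsets_native = onsets_native[onsets_native + n_beat <= n_native]

    x = np.zeros((N_LEADS, n_native))
    for o in onsets_native:
        x[:, o : o + n_beat] += template.samples

    leads = resample_poly(x, 128, 125, axis=1)
    n_out = round(duration * fs_out)
    if leads.shape[1] != n_out:  # resample_poly guarantees ceil(n*128/125); assert contract
        raise ContractError(f"resampling produced {leads.shape[1]} samples, expected {n_out}")

    fid = template.fiducials
    beat_onsets = _map_index(onsets_native + fid["qrs_onset"])
    # Round ST windows inward so they stay inside the true plateau.
    st_start = np.ceil((onsets_native + fid["st_onset"]) * 128 / 125).astype(int)
    st_end = np.floor((onsets_native + fid["st_offset"]) * 128 / 125).astype(int)
    st_windows = np.stack([st_start, st_end], axis=1)

    meta = {
        "record_id": record_id or f"rec-{seed}",
        "seed": int(seed),
        "duration": float(duration),
        "fs": float(fs_out),
        "rr_model": {"mean_rr": rr.mean_rr, "sd_rr": rr.sd_rr,
                     "lower": rr.bounds[0], "upper": rr.bounds[1]},
        "st_level": template.st_level.tolist(),
    }
    return EcgRecord(leads=leads, fs=fs_out, beat_onsets=beat_onsets,
                     st_windows=st_windows, meta=meta)


def generate_setup_grid(
    n_setups: int,
    master_seed: int,
    duration: float = 100.0,
    st_magnitude_range: tuple[float, float] = (0.05, 0.5),
    rr: RRModel | None = None,
):
    """Yield clean records emulating a database of ischemia configurations.

    Each setup draws per-lead ST levels with magnitudes uniform on
    ``st_magnitude_range`` (mV) and random signs, per-lead morphology jitter,
    and a random polarity per lead, standing in for distinct torso geometries
    and ischemia placements: across many electrode projections and ischemia
    sites the deflection polarity of a given lead is not fixed, so the
    per-lead net offset of the database is symmetric about zero.  Seeds derive
    from ``(master_seed, setup_index)`` via ``SeedSequence`` spawn keys, so
    any setup is reproducible in isolation.
    """
    if n_setups <= 0:
        raise InvalidParameterError("n_setups must be positive")
    rr = rr or RRModel()
    lo, hi = st_magnitude_range
    for i in range(n_setups):
        ss = np.random.SeedSequence(master_seed, spawn_key=(0, i))
        seed_st, seed_morph, seed_rr = ss.generate_state(3, dtype=np.uint32).tolist()
        rng = np.random.default_rng(seed_st)
        magnitude = rng.uniform(lo, hi, size=N_LEADS)
        sign = rng.choice([-1.0, 1.0], size=N_LEADS)
        polarity = rng.choice([-1.0, 1.0], size=N_LEADS)
        # Per-setup beat morphology: lobe amplitudes/widths vary across the
        # emulated database the way distinct hearts and torsos vary.
        rng_m = np.random.default_rng(seed_morph)
        lobes = (
            ("Q", 0.030, 0.008, -0.10 * rng_m.uniform(0.5, 1.5)),
            ("R", 0.048, rng_m.uniform(0.008, 0.012), 1.00),
            ("S", 0.066, 0.008, -0.20 * rng_m.uniform(0.5, 1.5)),
            ("T", 0.280, rng_m.uniform(0.032, 0.044), rng_m.uniform(0.25, 0.45)),
        )
        morphology = {"lead_gains": polarity * np.abs(_DEFAULT_LEAD_GAINS),
                      "lobes": lobes}
        template = make_beat_template(sign * magnitude, morphology=morphology,
                                      seed=seed_morph)
        record = synthesize_record(template, rr, duration=duration, seed=seed_rr,
                                   record_id=f"setup-{i:04d}")
        record.meta["generator"] = {
            "master_seed": int(master_seed),
            "setup_index": i,
            "duration": float(duration),
            "st_magnitude_range": [lo, hi],
            "rr_model": {"mean_rr": rr.mean_rr, "sd_rr": rr.sd_rr},
        }
        yield record


def regenerate_record(generator_meta: dict) -> EcgRecord:
    """Rebuild a grid record bit-exactly from its sidecar ``generator`` block."""
    g = generator_meta
    rr_cfg = g.get("rr_model", {})
    rr = RRModel(mean_rr=rr_cfg.get("mean_rr", 1.0), sd_rr=rr_cfg.get("sd_rr", 0.050))
    gen = generate_setup_grid(
        g["setup_index"] + 1,
        g["master_seed"],
        duration=g.get("duration", 100.0),
        st_magnitude_range=tuple(g.get("st_magnitude_range", (0.05, 0.5))),
        rr=rr,
    )
    record = None
    for record in gen:
        pass
    return record
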