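"""Synthetic annotated single-lead ECG records.

Real ambulatory ECG corpora cannot ship with the package, so this module
synthesises 360 Hz single-lead records with known R-peak locations and one of
four beat morphologies per beat, mirroring the clinical distinctions between
the AAMI classes:

* **N** — full P-QRS-T complex, narrow QRS;
* **VEB** — wide QRS (>= 1.5x the normal QRS width), no P wave, discordant T;
* **SVEB** — normal-shaped QRS but premature (short preceding RR) with an
  inverted P wave;
* **F** — fusion beat, a convex combination of the N and VEB templates.

Each beat template is a sum of Gaussian bumps (an ECGSYN-flavoured
parameterisation); the templates only need to be class-separable, not
physiologically exact.  Artifact noise follows the standard contamination
model: sinusoidal baseline wander (sub-Hz), sinusoidal power-line
interference at 50/60 Hz, and additive white Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .classes import AAMI_CLASSES
from .record_io import BeatAnnotation, ECGRecord

#: surrogate annotation symbols emitted for the four classes (MIT-BIH codes)
CLASS_SYMBOL = {"N": "N", "VEB": "V", "SVEB": "A", "F": "F"}


@dataclass(frozen=True)
class MorphologySpec:
    """Beat template for one AAMI class.

    ``wave_params`` is a list of Gaussian bumps ``(amplitude mV, center
    offset s, width s)``; the bump with offset 0 is the R apex.
    ``rr_scale`` multiplies the nominal RR interval preceding the beat
    (premature supraventricular beats use ``rr_scale < 1``).
    """

    class_label: str
    wave_params: tuple[tuple[float, float, float], ...]
    rr_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.class_label not in AAMI_CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if not any(c == 0.0 for _, c, _ in self.wave_params):
            raise ValueError("one bump must sit at offset 0 (the R apex)")
        if self.rr_scale <= 0:
            raise ValueError("rr_scale must be positive")

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the template on time offsets ``t`` (seconds from R)."""
        y = np.zeros_like(t, dtype=float)
        for amp, center, width in self.wave_params:
            y += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
        return y


def _n_template() -> MorphologySpec:
    return MorphologySpec(
        "N",
        (
            (0.15, -0.20, 0.025),   # P
            (-0.10, -0.040, 0.010), # Q
            (1.20, 0.0, 0.020),     # R
            (-0.25, 0.040, 0.012),  # S
            (0.35, 0.25, 0.060),    # T
        ),
    )


def _veb_template() -> MorphologySpec:
    # wide QRS (R width 0.05 s >= 1.5 x the N template's 0.02 s), no P,
    # discordant (negative) T
    return MorphologySpec(
        "VEB",
        (
            (-0.30, -0.090, 0.040),
            (1.00, 0.0, 0.050),
            (-0.45, 0.100, 0.045),
            (-0.40, 0.32, 0.080),
        ),
    )


def _sveb_template() -> MorphologySpec:
    n = _n_template()
    bumps = list(n.wave_params)
    p_amp, p_c, p_w = bumps[0]
    bumps[0] = (-p_amp, p_c, p_w)  # inverted P
    return MorphologySpec("SVEB", tuple(bumps), rr_scale=0.7)


def _fusion_template() -> MorphologySpec:
    n, v = _n_template(), _veb_template()
    half = lambda spec: tuple((0.5 * a, c, w) for a, c, w in spec.wave_params)
    return MorphologySpec("F", half(n) + half(v))


def default_morphologies() -> dict[str, MorphologySpec]:
    """The four default class templates."""
    return {
        "N": _n_template(),
        "VEB": _veb_template(),
        "SVEB": _sveb_template(),
        "F": _fusion_template(),
    }


@dataclass(frozen=True)
class NoiseSpec:
    """Additive artifact model: baseline wander + PLI + white noise.

    ``baseline_freq`` defaults to 0.2 Hz, inside the 0-0.35 Hz band that the
    level-9 approximation of a 9-level dyadic decomposition at 360 Hz spans.
    """

    baseline_amp: float = 0.0
    baseline_freq: float = 0.2
    pli_amp: float = 0.0
    pli_freq: float = 60.0
    white_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.baseline_amp, self.pli_amp, self.white_sigma) < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.pli_freq not in (50.0, 60.0, 50, 60):
            raise ValueError("pli_freq must be 50 or 60 Hz")


NO_NOISE = NoiseSpec()


def add_noise(signal: np.ndarray, fs: float, noise: NoiseSpec) -> np.ndarray:
    """Add baseline wander, power-line interference and white noise.

    Returns ``signal + b*sin(2*pi*f_b*t) + p*sin(2*pi*f_p*t) + N(0, sigma)``;
    the input is never modified.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("signal must be non-empty")
    t = np.arange(signal.size) / fs
    out = signal.copy()
    if noise.baseline_amp:
        out += noise.baseline_amp * np.sin(2 * np.pi * noise.baseline_freq * t)
    if noise.pli_amp:
        out += noise.pli_amp * np.sin(2 * np.pi * noise.pli_freq * t)
    if noise.white_sigma:
        rng = np.random.default_rng(noise.seed)
        out += rng.normal(0.0, noise.white_sigma, size=signal.size)
    return out


def generate_record(
    duration_s: float,
    fs: float = 360.0,
    class_probs: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0),
    mean_rr: float = 0.8,
    rr_jitter: float = 0.0,
    morphologies: dict[str, MorphologySpec] | None = None,
    noise: NoiseSpec = NO_NOISE,
    seed: int = 0,
    record_id: str = "syn",
) -> ECGRecord:
    """Generate one annotated synthetic record.

    Beat classes are drawn i.i.d. from ``class_probs`` (ordered N, VEB,
    SVEB, F); the RR interval preceding a beat is
    ``mean_rr * rr_scale(class) + U(-rr_jitter, +rr_jitter)``.  Annotations
    carry the true R-apex sample index and the surrogate MIT-BIH symbol of
    the class.  The same seed yields bit-identical output.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    probs = np.asarray(class_probs, dtype=float)
    if probs.shape != (4,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ValueError("class_probs must be a length-4 simplex vector")
    if duration_s < 3 * mean_rr:
        raise ValueError("duration must cover at least 3 beats")
    morphologies = morphologies or default_morphologies()

    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs))
    margin = 0.4  # template support half-width, seconds
    clean = np.zeros(n_samples)

    r_times: list[float] = []
    labels: list[str] = []
    t = margin
    while True:
        cls = AAMI_CLASSES[rng.choice(4, p=probs)]
        spec = morphologies[cls]
        if r_times:
            rr = mean_rr * spec.rr_scale
            if rr_jitter:
                rr += rng.uniform(-rr_jitter, rr_jitter)
            t = r_times[-1] + max(rr, 2.0 / fs)
        if t > duration_s - margin:
            break
        r_times.append(t)
        labels.append(cls)

    annotations = []
    for t_r, cls in zip(r_times, labels):
        idx = int(round(t_r * fs))
        lo = max(0, idx - int(margin * fs))
        hi = min(n_samples, idx + int(margin * fs) + 1)
        tt = (np.arange(lo, hi) - idx) / fs
        clean[lo:hi] += morphologies[cls].waveform(tt)
        annotations.append(BeatAnnotation(sample_index=idx, symbol=CLASS_SYMBOL[cls]))

    samples = add_noise(clean, fs, noise) if noise != NO_NOISE else clean
    return ECGRecord(
        record_id=record_id, fs=fs, lead="MLII", samples=samples,
        annotations=annotations,
    )


def generate_corpus(
    n_records: int,
    duration_s: float,
    class_probs: tuple[float, float, float, float],
    noise: NoiseSpec,
    seed: int,
    fs: float = 360.0,
    mean_rr: float = 0.8,
    rr_jitter: float = 0.05,
) -> list[ECGRecord]:
    """Generate a multi-patient corpus with per-record derived seeds.

    Per-record mean RR is itself jittered (+-10%) so synthetic "patients"
    differ in heart rate as well as in noise realisation.
    """
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_records):
        rec_seed = int(rng.integers(0, 2**31 - 1))
        rec_rr = mean_rr * float(rng.uniform(0.9, 1.1))
        rec_noise = replace(noise, seed=rec_seed + 1)
        records.append(
            generate_record(
                duration_s, fs=fs, class_probs=class_probs, mean_rr=rec_rr,
                rr_jitter=rr_jitter, noise=rec_noise, seed=rec_seed,
                record_id=f"syn{i:03d}",
            )
        )
    return records
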