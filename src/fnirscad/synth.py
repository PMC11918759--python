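"""Synthetic fNIRS cohort generator.

Emulates the statistical structure a prefrontal depression classifier
exploits, so the full pipeline is testable without clinical recordings:

* a block-design cognitive paradigm (default three 30-s task blocks
  separated by 30-s rests) with task-locked activation, built as a boxcar
  convolved with a canonical double-gamma hemodynamic response function;
* class-dependent hypoactivation — the depressed (MDD) class draws smaller
  activation amplitudes than healthy controls (HC);
* class-dependent inter-hemispheric asymmetry — per mirror pair the
  right-hemisphere amplitude is scaled by ``1 − asymmetry_index · u`` with
  ``u ~ Uniform(0.5, 1)`` drawn once per subject (left fixed; the direction
  is configurable because its sign varies across depression studies);
* ΔHbR modelled as a scaled, sign-inverted, lagged copy of the ΔHbO
  activation (default ratio 1/3, lag 1 s) with its own noise;
* physiological nuisance: Mayer-wave (~0.1 Hz) and respiratory (~0.25 Hz)
  sinusoids with random per-channel phases, linear drift, Gaussian white
  noise;
* optionally, forward projection of the concentrations to dual-wavelength
  optical density via the Beer–Lambert relation, so the preprocessing
  module's MBLL inversion can be exercised end to end.

Cohorts are a pure function of (config, seed): subject s of a cohort uses
``numpy.random.SeedSequence((cohort_seed, s))``, so identical configs give
bit-identical cohorts.

Not modelled: photon transport, motion artifacts, short-separation
channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import gamma as gamma_dist

from .preprocess import HbRecording, OpticalDensityRecording, forward_mbll

__all__ = [
    "TaskParadigm",
    "NoiseModel",
    "SyntheticCohortConfig",
    "SyntheticSubject",
    "canonical_hrf",
    "generate_subject",
    "generate_cohort",
    "high_contrast_config",
    "null_config",
    "asymmetry_only_config",
]

HC, MDD = 0, 1


@dataclass(frozen=True)
class TaskParadigm:
    """Block schedule: initial rest, then alternating task/rest blocks."""

    n_blocks: int = 3
    block_s: float = 30.0
    rest_s: float = 30.0
    initial_rest_s: float = 30.0

    @property
    def duration_s(self) -> float:
        return self.initial_rest_s + self.n_blocks * (self.block_s + self.rest_s)

    def onsets(self) -> list[float]:
        return [
            self.initial_rest_s + k * (self.block_s + self.rest_s)
            for k in range(self.n_blocks)
        ]

    def events(self) -> tuple[tuple[float, float, str], ...]:
        return tuple((onset, self.block_s, "task") for onset in self.onsets())


@dataclass(frozen=True)
class NoiseModel:
    """Additive nuisance components, amplitudes in µM.

    Mayer and respiratory amplitudes default to 10–30% of a 1-µM control
    activation; drift_amp is the maximal linear excursion over the
    recording; white_sd the per-sample Gaussian s.d.
    """

    mayer_hz: float = 0.1
    mayer_amp: float = 0.2
    resp_hz: float = 0.25
    resp_amp: float = 0.15
    drift_amp: float = 0.3
    white_sd: float = 0.1

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(mayer_amp=0.0, resp_amp=0.0, drift_amp=0.0, white_sd=0.0)

    def scaled(self, factor: float) -> "NoiseModel":
        return replace(
            self,
            mayer_amp=self.mayer_amp * factor,
            resp_amp=self.resp_amp * factor,
            drift_amp=self.drift_amp * factor,
            white_sd=self.white_sd * factor,
        )


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    Amplitudes are µM of ΔHbO at the activation peak; asymmetry indices are
    fractions in [0, 1] (0 = symmetric hemispheres).
    """

    n_mdd: int = 48
    n_hc: int = 68
    sampling_rate: float = 8.138
    n_channels: int = 68
    paradigm: TaskParadigm = field(default_factory=TaskParadigm)
    activation_amp_hc: float = 1.0
    activation_amp_mdd: float = 0.5
    asymmetry_index_mdd: float = 0.5
    asymmetry_index_hc: float = 0.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    amp_subject_sd: float = 0.1  # relative between-subject amplitude spread
    pair_gain_sd: float = 0.05  # relative spatial gain spread, shared in a pair
    #: which hemisphere carries the amplitude reduction: "right", "left", or
    #: "random" (drawn per subject — lateralization direction is heterogeneous
    #: across depression studies and plausibly across patients)
    asymmetry_direction: str = "right"
    hbr_ratio: float = 1.0 / 3.0
    hbr_lag_s: float = 1.0
    emit_od: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels <= 0 or self.n_channels % 2 != 0:
            raise ValueError("n_channels must be positive and even")
        for name in ("activation_amp_hc", "activation_amp_mdd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("asymmetry_index_mdd", "asymmetry_index_hc"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_mdd < 0 or self.n_hc < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.asymmetry_direction not in ("right", "left", "random"):
            raise ValueError("asymmetry_direction must be right, left or random")

    @property
    def n_samples(self) -> int:
        return int(round(self.paradigm.duration_s * self.sampling_rate))


@dataclass(frozen=True)
class SyntheticSubject:
    """One generated participant: concentrations, optional OD, ground truth."""

    subject_id: str
    label: int  # 0 = HC, 1 = MDD
    hb: HbRecording
    od: OpticalDensityRecording | None
    ground_truth: dict

    @property
    def events(self) -> tuple[tuple[float, float, str], ...]:
        return self.hb.events


def canonical_hrf(fs: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``fs``, peak normalized to 1.

    Response peak at 6 s, undershoot peak at 16 s, undershoot ratio 1/6 —
    the standard two-gamma impulse response used throughout task fMRI/fNIRS
    modelling.
    """
    t = np.arange(0.0, duration_s, 1.0 / fs)
    # gamma pdf mode is (a - 1) * scale: shapes 7 and 17 put the response
    # peak at 6 s and the undershoot at 16 s
    h = gamma_dist.pdf(t, a=7.0, scale=1.0) - gamma_dist.pdf(t, a=17.0, scale=1.0) / 6.0
    return h / h.max()


def _boxcar(cfg: SyntheticCohortConfig) -> np.ndarray:
    fs = cfg.sampling_rate
    box = np.zeros(cfg.n_samples)
    for onset in cfg.paradigm.onsets():
        a = int(round(onset * fs))
        b = int(round((onset + cfg.paradigm.block_s) * fs))
        box[a:b] = 1.0
    return box


def _activation_timecourse(cfg: SyntheticCohortConfig) -> np.ndarray:
    """Boxcar convolved with the canonical HRF, peak normalized to 1."""
    conv = np.convolve(_boxcar(cfg), canonical_hrf(cfg.sampling_rate))[: cfg.n_samples]
    peak = conv.max()
    return conv / peak if peak > 0 else conv


def _nuisance(
    rng: np.random.Generator, cfg: SyntheticCohortConfig
) -> np.ndarray:
    """One draw of the additive noise field, shape (time, channel).

    Systemic components (Mayer wave, respiration, drift) are spatially
    coherent and bilaterally symmetric: mirror-pair channels share the same
    phase/slope, as systemic physiology does on a symmetric montage.  White
    sensor noise is independent per channel.
    """
    nz = cfg.noise
    t = np.arange(cfg.n_samples) / cfg.sampling_rate
    c = cfg.n_channels
    n_left = c // 2
    out = np.zeros((cfg.n_samples, c))
    phases = np.tile(rng.uniform(0, 2 * np.pi, size=(2, n_left)), (1, 2))
    out += nz.mayer_amp * np.sin(2 * np.pi * nz.mayer_hz * t[:, None] + phases[0])
    out += nz.resp_amp * np.sin(2 * np.pi * nz.resp_hz * t[:, None] + phases[1])
    slopes = np.tile(rng.uniform(-nz.drift_amp, nz.drift_amp, size=n_left), 2)
    out += slopes[None, :] * (t[:, None] / t[-1])
    if nz.white_sd > 0:
        out += rng.normal(0.0, nz.white_sd, size=(cfg.n_samples, c))
    else:
        rng.normal(0.0, 1.0, size=(cfg.n_samples, c))  # keep stream position fixed
    return out


def subject_seed(cohort_seed: int, subject_index: int) -> np.random.SeedSequence:
    """Documented, fixed seed scheme: one SeedSequence per (cohort, subject)."""
    return np.random.SeedSequence((cohort_seed, subject_index))


def generate_subject(
    config: SyntheticCohortConfig,
    label: int,
    subject_index: int = 0,
    subject_id: str | None = None,
) -> SyntheticSubject:
    """Generate one synthetic participant.

    The per-channel ground-truth ΔHbO peak amplitude is
    ``amp_class · s · g_pair`` on the left hemisphere and the same value
    multiplied by ``1 − asymmetry_index · u`` on the right, where ``s`` is
    a per-subject relative amplitude factor, ``g_pair`` a per-pair gain
    shared between the two mirror channels, and ``u ~ Uniform(0.5, 1)``
    one per subject.  Returned ``ground_truth`` records all of these.
    """
    if label not in (HC, MDD):
        raise ValueError("label must be 0 (HC) or 1 (MDD)")
    rng = np.random.default_rng(subject_seed(config.seed, subject_index))
    fs = config.sampling_rate
    n_left = config.n_channels // 2

    amp_class = config.activation_amp_mdd if label == MDD else config.activation_amp_hc
    asym = config.asymmetry_index_mdd if label == MDD else config.asymmetry_index_hc
    subj_factor = max(0.1, 1.0 + config.amp_subject_sd * rng.standard_normal())
    pair_gain = np.maximum(
        0.1, 1.0 + config.pair_gain_sd * rng.standard_normal(n_left)
    )
    u = rng.uniform(0.5, 1.0)
    direction = config.asymmetry_direction
    if direction == "random":
        direction = "right" if rng.random() < 0.5 else "left"
    base_amp = amp_class * subj_factor * pair_gain
    if direction == "right":
        left_amp = base_amp
        right_amp = base_amp * (1.0 - asym * u)
    else:
        left_amp = base_amp * (1.0 - asym * u)
        right_amp = base_amp
    # channel order: left hemisphere block first, then mirrored right block,
    # matching montage.build_default_montage acquisition order
    amps = np.concatenate([left_amp, right_amp])

    act = _activation_timecourse(config)  # (T,)
    lag = int(round(config.hbr_lag_s * fs))
    act_lagged = np.concatenate([np.zeros(lag), act[: config.n_samples - lag]])

    dhbo = amps[None, :] * act[:, None] + _nuisance(rng, config)
    dhbr = (
        -config.hbr_ratio * amps[None, :] * act_lagged[:, None]
        + config.hbr_ratio * _nuisance(rng, config)
    )

    events = config.paradigm.events()
    hb = HbRecording(dhbo=dhbo, dhbr=dhbr, sampling_rate=fs, events=events)
    od = forward_mbll(hb) if config.emit_od else None
    sid = subject_id or f"s{subject_index:03d}"
    return SyntheticSubject(
        subject_id=sid,
        label=label,
        hb=hb,
        od=od,
        ground_truth={
            "amplitudes": amps,
            "asymmetry_u": u,
            "asymmetry_direction": direction,
            "asymmetry_index": asym,
            "subject_factor": subj_factor,
            "pair_gain": pair_gain,
            "class_amplitude": amp_class,
        },
    )


def generate_cohort(config: SyntheticCohortConfig) -> list[SyntheticSubject]:
    """Generate the full cohort: ``n_mdd`` MDD subjects then ``n_hc`` HCs.

    Deterministic given the config (subject k uses the documented
    per-subject seed scheme regardless of class layout).
    """
    subjects = []
    for k in range(config.n_mdd + config.n_hc):
        label = MDD if k < config.n_mdd else HC
        subjects.append(generate_subject(config, label, subject_index=k))
    return subjects


# ---------------------------------------------------------------------------
# Named study conditions for the synthetic recovery experiments.  Effect
# sizes are calibrated once so that each condition plays its intended role
# (see docs/methods.md); they are properties of the synthetic benchmark, not
# claims about clinical effect sizes.

def high_contrast_config(
    n_per_class: int = 20, seed: int = 0
) -> SyntheticCohortConfig:
    """Strong hypoactivation + asymmetry in MDD, low noise."""
    return SyntheticCohortConfig(
        n_mdd=n_per_class,
        n_hc=n_per_class,
        activation_amp_hc=1.0,
        activation_amp_mdd=0.3,
        asymmetry_index_mdd=0.6,
        asymmetry_index_hc=0.0,
        noise=NoiseModel().scaled(0.5),
        seed=seed,
    )


def null_config(n_per_class: int = 8, seed: int = 0) -> SyntheticCohortConfig:
    """Both classes drawn from identical generating parameters (no signal)."""
    return SyntheticCohortConfig(
        n_mdd=n_per_class,
        n_hc=n_per_class,
        activation_amp_hc=1.0,
        activation_amp_mdd=1.0,
        asymmetry_index_mdd=0.0,
        asymmetry_index_hc=0.0,
        noise=NoiseModel(),
        seed=seed,
    )


def asymmetry_only_config(
    n_per_class: int = 12, seed: int = 0
) -> SyntheticCohortConfig:
    """Classes differ only in hemispheric asymmetry, not class amplitude.

    Between-subject amplitude spread is raised (0.3) so absolute amplitude
    is an unreliable cue, and systemic noise is strong, leaving the
    left/right structure within mirror pairs as the dominant reliable
    class signal.
    """
    return SyntheticCohortConfig(
        n_mdd=n_per_class,
        n_hc=n_per_class,
        activation_amp_hc=1.0,
        activation_amp_mdd=1.0,
        asymmetry_index_mdd=0.6,
        asymmetry_index_hc=0.0,
        amp_subject_sd=0.3,
        pair_gain_sd=0.2,
        noise=NoiseModel(mayer_amp=0.5, resp_amp=0.4, drift_amp=0.3, white_sd=0.05),
        seed=seed,
    )
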