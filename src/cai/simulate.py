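"""Synthetic anesthesia EEG with known depth ground truth.

The generative model operationalizes the textbook mechanism of the
anesthetized cortex.  Scalp EEG is the summated postsynaptic activity
of many cortical pyramidal-cell sources.  Awake, sources fire
tonically; under anesthesia the population alternates between an
active *up-state* (a burst of firing) and a silent *down-state*, and
deepening anesthesia shortens the bursts while the silent periods grow
— culminating in burst suppression.  Depth of anesthesia is therefore
parameterized here by a single scalar ``d`` in [0, 1] defined as one
minus the expected fraction of time the source population spends in
the up-state.

Concretely, one population up/down state sequence is sampled as an
alternating renewal process with exponentially distributed dwell
times,

    mean_up(d)   = tau_up0 * (1 - d) + floor_up
    mean_down(d) = tau_down0 * d     + floor_down

(small dwell floors keep the renewal process non-degenerate at the
extremes of d), and every source fires Poisson spikes (rate
``firing_rate_up``, modulated by a depth-scaled delta-band rhythm —
the slow oscillation of deep anesthesia) during up-states only.  Spikes are convolved with an alpha-function
postsynaptic-potential kernel ``(t/tau) * exp(1 - t/tau) * amp``; the
sources are summed, demeaned, embedded in 1/f (pink) plus white
instrument noise, and AC-coupled with a monitor-style high-pass so the
standing depolarization pedestal of the up-state does not masquerade
as signal during down-states.  The up/down alternation is shared across
sources because the slow oscillation of anesthesia is cortex-wide
synchronized — independent per-source switching would average out and
could never produce the near-isoelectric suppression gaps of deep
anesthesia; spike trains remain independent across sources.

A surgery-shaped depth profile (awake -> induction -> maintenance
plateau -> emergence -> awake) and a cohort generator with sex/age/BMI
covariates emulate a laparoscopic-surgery recording session.  All
randomness flows from explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import EEGRecord, IndexSeries, ValidationError

__all__ = [
    "DepthProfile",
    "SimConfig",
    "SubjectMeta",
    "sample_state_sequence",
    "source_signal",
    "alpha_kernel",
    "simulate_eeg",
    "surgery_profile",
    "simulate_cohort",
    "synthetic_bis",
]

@dataclass(frozen=True)
class DepthProfile:
    """Piecewise-linear anesthetic-depth trajectory d(t) in [0, 1]."""

    times: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "d", d)
        if times.size != d.size or times.size < 2:
            raise ValidationError("DepthProfile needs >= 2 matching knots")
        if not np.all(np.diff(times) > 0):
            raise ValidationError("DepthProfile times must be increasing")
        if d.min() < 0 or d.max() > 1:
            raise ValidationError("depth values must lie in [0, 1]")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def at(self, t: float | np.ndarray) -> np.ndarray:
        """Depth at time(s) ``t`` by linear interpolation (clamped ends)."""
        return np.interp(t, self.times, self.d)


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for the synthetic EEG.

    Units: seconds for time constants, Hz for rates, microvolts for
    amplitudes.  ``seed`` fixes the full sample path.
    """

    n_sources: int = 50
    fs: float = 128.0
    tau_up0: float = 6.0  # mean up-state dwell at d=0
    tau_down0: float = 2.0  # mean down-state dwell at d=1
    firing_rate_up: float = 20.0  # Poisson spike rate per source in up-state
    delta_hz: float = 2.0  # frequency of rhythmic (delta) burst firing
    delta_mod: float = 1.0  # depth-scaled modulation depth of that rhythm
    psp_tau: float = 0.005  # alpha-kernel time constant
    psp_amp: float = 3.0  # alpha-kernel peak amplitude
    noise_pink: float = 1.0  # RMS of 1/f background
    noise_white: float = 1.0  # RMS of white instrument noise
    hp_hz: float = 0.3  # front-end AC-coupling high-pass (0 disables)
    floor_up: float = 0.05  # dwell-mean floor for up-states, seconds
    floor_down: float = 0.01  # dwell-mean floor for down-states, seconds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sources < 0:
            raise ValidationError("n_sources must be >= 0")
        for name in ("fs", "tau_up0", "tau_down0", "firing_rate_up", "psp_tau",
                     "psp_amp"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if self.noise_pink < 0 or self.noise_white < 0 or self.hp_hz < 0:
            raise ValidationError("noise levels and hp_hz must be non-negative")


@dataclass(frozen=True)
class SubjectMeta:
    """Cohort covariates: the regression adjusts for sex, age and BMI."""

    subject_id: str
    sex: str  # "F" or "M"
    age: float  # years, >= 18 (adult study population)
    bmi: float  # kg/m^2

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValidationError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.age < 18:
            raise ValidationError(f"age must be >= 18, got {self.age}")
        if not self.bmi > 0:
            raise ValidationError(f"bmi must be positive, got {self.bmi}")


def _dwell_means(d: float, cfg: SimConfig) -> tuple[float, float]:
    return (cfg.tau_up0 * (1.0 - d) + cfg.floor_up,
            cfg.tau_down0 * d + cfg.floor_down)


def _states(
    depth_at, cfg: SimConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Alternating-renewal up/down sequence sampled at cfg.fs.

    ``depth_at`` maps a time in seconds to d; dwell means are refreshed
    from the local depth at the start of each dwell.
    """
    out = np.zeros(n, dtype=bool)
    fs = cfg.fs
    t = 0.0
    mu_up, mu_down = _dwell_means(float(depth_at(0.0)), cfg)
    up_frac = mu_up / (mu_up + mu_down)
    state = bool(rng.random() < up_frac)  # start from the stationary mix
    end = n / fs
    while t < end:
        d = float(depth_at(t))
        mu_up, mu_down = _dwell_means(d, cfg)
        dwell = rng.exponential(mu_up if state else mu_down)
        if state:
            i0 = int(np.ceil(t * fs))
            i1 = min(n, int(np.ceil((t + dwell) * fs)))
            out[i0:i1] = True
        t += dwell
        state = not state
    return out


def sample_state_sequence(
    d: float, cfg: SimConfig, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Binary up(1)/down(0) sequence at ``cfg.fs`` for constant depth ``d``.

    At d=0 the sequence is almost always up (tonic firing); the expected
    up-fraction ``mean_up / (mean_up + mean_down)`` decreases
    monotonically in d.
    """
    if not 0 <= d <= 1:
        raise ValidationError(f"depth must lie in [0, 1], got {d}")
    n = int(round(duration * cfg.fs))
    return _states(lambda t: d, cfg, n, rng).astype(np.int8)


def alpha_kernel(cfg: SimConfig) -> np.ndarray:
    """Sampled postsynaptic-potential kernel ``(t/tau) exp(1 - t/tau) * amp``.

    Supported on [0, 8*tau]; peak value ``psp_amp`` at ``t = psp_tau``
    (attained exactly when psp_tau lies on the sample grid).
    """
    t = np.arange(0.0, 8.0 * cfg.psp_tau, 1.0 / cfg.fs)
    return (t / cfg.psp_tau) * np.exp(1.0 - t / cfg.psp_tau) * cfg.psp_amp


def source_signal(
    states: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    rate_profile: np.ndarray | None = None,
) -> np.ndarray:
    """One source: Poisson spikes during up-states, PSP-kernel convolved.

    ``rate_profile`` optionally scales the instantaneous firing rate
    per sample (used for the rhythmic delta firing of deep anesthesia);
    default is a constant ``firing_rate_up``.  Output is zero through
    any down-state that outlasts the kernel decay, and linear in
    ``psp_amp``.
    """
    states = np.asarray(states).astype(bool)
    lam = np.full(states.size, cfg.firing_rate_up / cfg.fs)
    if rate_profile is not None:
        lam = lam * np.clip(rate_profile, 0.0, None)
    counts = np.where(states, rng.poisson(lam), 0)
    return np.convolve(counts.astype(float), alpha_kernel(cfg))[: states.size]


def _pink_noise(n: int, rms: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-power noise via spectral shaping of seeded white noise."""
    if rms == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid the DC singularity
    spec /= np.sqrt(f)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x * (rms / np.std(x))


def simulate_eeg(
    profile: DepthProfile,
    cfg: SimConfig,
    index_dt: float = 2.0,
) -> tuple[EEGRecord, IndexSeries]:
    """Simulate one recording following a depth profile.

    Returns the microvolt trace and the ground-truth depth resampled on
    the index cadence (``index_dt`` seconds, timestamped at interval
    centers like the index streams).  Deep segments show
    burst-suppression morphology; the <4 Hz power fraction grows with
    depth.
    """
    if profile.duration < 10:
        raise ValidationError("profile must span at least 10 s")
    n = int(round(profile.duration * cfg.fs))
    rng = np.random.default_rng(cfg.seed)
    t_rel = lambda t: profile.at(profile.times[0] + t)

    total = np.zeros(n)
    if cfg.n_sources > 0:
        states = _states(t_rel, cfg, n, rng)  # shared population state
        # rhythmic (delta-band) burst firing, deepening with d: the slow
        # oscillation that dominates deep-anesthesia EEG
        tt = np.arange(n) / cfg.fs
        mod = np.clip(cfg.delta_mod * t_rel(tt), 0.0, 1.0)
        rate_profile = 1.0 + mod * np.sin(2.0 * np.pi * cfg.delta_hz * tt)
        for _ in range(cfg.n_sources):
            total += source_signal(states, cfg, rng, rate_profile)
        total -= total.mean()
    total += _pink_noise(n, cfg.noise_pink, rng)
    if cfg.noise_white > 0:
        total += cfg.noise_white * rng.standard_normal(n)
    if cfg.hp_hz > 0 and np.any(total):
        # monitor-style AC coupling: removes the standing depolarization
        # pedestal so down-states decay to isoelectric baseline
        from scipy.signal import butter, filtfilt

        b, a = butter(2, cfg.hp_hz / (cfg.fs / 2), btype="highpass")
        total = filtfilt(b, a, total)

    record = EEGRecord(total, fs=cfg.fs, channel_label="SIM", t0=float(profile.times[0]))
    t_grid = profile.times[0] + index_dt / 2 + index_dt * np.arange(
        int(profile.duration / index_dt)
    )
    truth = IndexSeries("depth", t_grid, profile.at(t_grid))
    return record, truth


def surgery_profile(
    rng: np.random.Generator,
    awake_s: float = 120.0,
    induction_s: float = 60.0,
    maintenance_s: float = 300.0,
    emergence_s: float = 60.0,
    recovery_s: float = 60.0,
    d_awake: float = 0.05,
    d_plateau: float = 0.7,
    plateau_sd: float = 0.1,
    wander_sd: float = 0.05,
    wander_knots: int = 5,
) -> DepthProfile:
    """Surgery-shaped depth template with per-draw jitter.

    Awake baseline -> induction ramp -> maintenance plateau (level
    ``d_plateau`` +/- ``plateau_sd`` with slow within-case wander) ->
    emergence ramp -> awake recovery.  Endpoints stay near awake
    (d < 0.2).
    """
    level = float(np.clip(rng.normal(d_plateau, plateau_sd), 0.3, 0.95))
    t_plateau = awake_s + induction_s
    knots_t = np.linspace(t_plateau, t_plateau + maintenance_s, wander_knots)
    knots_d = np.clip(level + rng.normal(0.0, wander_sd, wander_knots), 0.2, 0.98)
    times = np.concatenate(
        [
            [0.0, awake_s],
            knots_t,
            [t_plateau + maintenance_s + emergence_s,
             t_plateau + maintenance_s + emergence_s + recovery_s],
        ]
    )
    d = np.concatenate([[d_awake, d_awake], knots_d, [d_awake, d_awake]])
    return DepthProfile(times, d)


def simulate_cohort(
    n_subjects: int,
    cfg: SimConfig | None = None,
    seed: int | None = None,
    **template_kwargs,
) -> list[tuple[SubjectMeta, EEGRecord, DepthProfile]]:
    """Simulate a surgical cohort with covariates and per-subject seeds.

    Covariates: sex ~ Bernoulli(1/2), age ~ Normal(45, 12) truncated at
    18 years, BMI ~ Normal(24, 3) truncated above 15 kg/m^2.  Each
    subject's recording seed derives from the master seed, so the same
    master seed reproduces the cohort exactly.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    cfg = cfg or SimConfig()
    master = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    children = ss.spawn(n_subjects)

    out = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sex = "M" if rng.random() < 0.5 else "F"
        age = float(rng.normal(45.0, 12.0))
        while age < 18.0:
            age = float(rng.normal(45.0, 12.0))
        bmi = float(rng.normal(24.0, 3.0))
        while bmi <= 15.0:
            bmi = float(rng.normal(24.0, 3.0))
        meta = SubjectMeta(f"sub-{i + 1:03d}", sex, round(age, 1), round(bmi, 1))

        profile = surgery_profile(rng, **template_kwargs)
        subject_seed = int(rng.integers(0, 2**31 - 1))
        record, _ = simulate_eeg(profile, replace(cfg, seed=subject_seed))
        out.append((meta, record, profile))
    return out


def synthetic_bis(
    profile: DepthProfile,
    rng: np.random.Generator,
    dt: float = 5.0,
    noise_sd: float = 3.0,
) -> IndexSeries:
    """BIS-like stream: affine-plus-noise transform of ``1 - d`` truth.

    A stand-in for a monitor export when no real BIS CSV exists:
    ``5 + 90*(1 - d) + Normal(0, noise_sd)``, clipped to [0, 100],
    sampled every ``dt`` seconds.  Synthetic by construction — it
    carries none of the real BIS algorithm's internals.
    """
    t = profile.times[0] + dt * np.arange(int(profile.duration / dt) + 1)
    vals = 5.0 + 90.0 * (1.0 - profile.at(t)) + rng.normal(0.0, noise_sd, t.size)
    return IndexSeries("BIS", t, np.clip(vals, 0.0, 100.0))
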