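"""Synthetic neonatal EEG and cohort generation.

The EEG generator emulates the visual hallmarks that distinguish a
dysmature from a mature neonatal background at term age:

* **discontinuity** — the trace alternates bursts of higher-amplitude
  activity with lower-amplitude interburst intervals (trace alternant);
  dysmaturity lengthens the interburst intervals and deepens the
  amplitude contrast;
* **persistent slow delta** — a configurable fraction of spectral power
  is placed below 2 Hz;
* **interhemispheric asynchrony** — a configurable fraction of bursts in
  one hemisphere is not mirrored (is lagged) in the other.

Burst/interburst alternation is a two-state renewal process with
gamma-distributed state durations, chosen for positivity and a tunable
coefficient of variation. Sleep staging is not simulated.

The cohort generator draws per-subject visual-EEG flags and 24-month
outcomes (ASD risk, three developmental quotients) from a configurable
joint design, so that exposure-outcome statistics downstream can be
validated against their designed values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .recording import EEGRecording, FULL_19, REDUCED_9, channel_hemisphere

__all__ = [
    "MaturityProfile", "MATURE_PROFILE", "DYSMATURE_PROFILE",
    "SubjectRecord", "CohortDesign", "PAPER_DESIGN",
    "generate_eeg", "generate_cohort", "fractional_gaussian_noise",
]


# --------------------------------------------------------------------------
# maturity profiles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MaturityProfile:
    """Generative parameters for one EEG background maturity state.

    Parameters
    ----------
    ga_weeks : float
        Gestational age the profile represents, weeks.
    ibi_mean_s : float
        Mean interburst-interval duration, seconds.
    ibi_cv : float
        Coefficient of variation of state durations (dimensionless).
    burst_mean_s : float
        Mean burst duration, seconds.
    burst_amp_uv : float
        Burst RMS amplitude, µV. Must exceed ``interburst_amp_uv``.
    interburst_amp_uv : float
        Interburst RMS amplitude, µV.
    slow_delta_frac : float
        Fraction of burst spectral power below 2 Hz, in [0, 1].
    asynchrony_prob : float
        Probability that a burst onset in one hemisphere is not mirrored
        within the synchrony window in the other, in [0, 1].
    asynchrony_lag_ms : float
        Lag applied to non-mirrored bursts in the contralateral
        hemisphere, milliseconds.
    dysmature : bool
        Label; a dysmature profile must be at least as discontinuous,
        slow and asynchronous as the mature default.
    """

    ga_weeks: float = 42.0
    ibi_mean_s: float = 3.0
    ibi_cv: float = 0.3
    burst_mean_s: float = 6.0
    burst_amp_uv: float = 50.0
    interburst_amp_uv: float = 25.0
    slow_delta_frac: float = 0.4
    asynchrony_prob: float = 0.05
    asynchrony_lag_ms: float = 500.0
    dysmature: bool = False

    def __post_init__(self):
        for name in ("ibi_mean_s", "ibi_cv", "burst_mean_s",
                     "burst_amp_uv", "interburst_amp_uv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.burst_amp_uv <= self.interburst_amp_uv:
            raise ValueError("burst_amp_uv must exceed interburst_amp_uv")
        for name in ("slow_delta_frac", "asynchrony_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.asynchrony_lag_ms < 0:
            raise ValueError("asynchrony_lag_ms must be non-negative")
        if self.dysmature:
            ref = _MATURE_DEFAULTS
            ok = (self.ibi_mean_s >= ref["ibi_mean_s"]
                  and self.slow_delta_frac >= ref["slow_delta_frac"]
                  and self.asynchrony_prob >= ref["asynchrony_prob"])
            if not ok:
                raise ValueError(
                    "a dysmature profile requires ibi_mean_s, slow_delta_frac "
                    "and asynchrony_prob each >= the mature defaults "
                    f"({_MATURE_DEFAULTS})"
                )


_MATURE_DEFAULTS = {"ibi_mean_s": 3.0, "slow_delta_frac": 0.4,
                    "asynchrony_prob": 0.05}

#: Documented default profile of a mature term background.
MATURE_PROFILE = MaturityProfile()

#: Documented default profile of a dysmature background: long interburst
#: intervals, deep amplitude suppression, persistent slow delta, frequent
#: interhemispheric asynchrony.
DYSMATURE_PROFILE = MaturityProfile(
    ibi_mean_s=8.0, ibi_cv=0.5, burst_mean_s=4.0,
    burst_amp_uv=60.0, interburst_amp_uv=10.0,
    slow_delta_frac=0.7, asynchrony_prob=0.4, asynchrony_lag_ms=1500.0,
    dysmature=True,
)


# --------------------------------------------------------------------------
# EEG generation
# --------------------------------------------------------------------------

def _burst_intervals(rng: np.random.Generator, profile: MaturityProfile,
                     duration_s: float) -> list[tuple[float, float]]:
    """Master burst (onset, offset) times from the two-state renewal process."""
    intervals = []
    t = float(rng.gamma(1.0 / profile.ibi_cv**2,
                        profile.ibi_mean_s * profile.ibi_cv**2))
    while t < duration_s:
        b = max(float(rng.gamma(1.0 / profile.ibi_cv**2,
                                profile.burst_mean_s * profile.ibi_cv**2)), 1e-3)
        intervals.append((t, min(t + b, duration_s)))
        t += b
        t += max(float(rng.gamma(1.0 / profile.ibi_cv**2,
                                 profile.ibi_mean_s * profile.ibi_cv**2)), 1e-3)
    return intervals


def _state_track(intervals, n: int, fs: float) -> np.ndarray:
    track = np.zeros(n, dtype=bool)
    for on, off in intervals:
        i = int(round(on * fs))
        j = int(round(off * fs))
        track[max(i, 0): min(j, n)] = True
    return track


def _smooth_envelope(track: np.ndarray, fs: float, ramp_s: float = 0.25) -> np.ndarray:
    """Binary state track -> [0, 1] envelope with raised-cosine ramps."""
    w = int(round(ramp_s * fs))
    if w < 2:
        return track.astype(float)
    win = np.hanning(2 * w + 1)
    win /= win.sum()
    return np.convolve(track.astype(float), win, mode="same")


def _coloured_noise(rng: np.random.Generator, n: int, fs: float,
                    slow_delta_frac: float, f_lo: float = 0.1,
                    f_split: float = 2.0, f_hi: float = 30.0) -> np.ndarray:
    """Unit-RMS Gaussian noise whose spectrum puts ``slow_delta_frac`` of
    power below ``f_split`` Hz.

    The target PSD falls as 1/f^2 below the split (persistent slow delta)
    and as 1/f above it, with the two pieces weighted so the band-power
    fraction below 2 Hz equals ``slow_delta_frac`` exactly in expectation.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    psd = np.zeros_like(freqs)
    lo = (freqs >= f_lo) & (freqs < f_split)
    hi = (freqs >= f_split) & (freqs <= f_hi)
    # analytic band integrals of the two spectral shapes
    i_low = 1.0 / f_lo - 1.0 / f_split           # ∫ f^-2 df on [f_lo, f_split)
    i_high = math.log(f_hi / f_split)            # ∫ f^-1 df on [f_split, f_hi]
    a = slow_delta_frac / i_low if i_low > 0 else 0.0
    b = (1.0 - slow_delta_frac) / i_high
    psd[lo] = a / freqs[lo] ** 2
    psd[hi] = b / freqs[hi]
    amp = np.sqrt(psd)
    phases = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    phases[0] = 0.0
    x = np.fft.irfft(amp * phases, n=n)
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def generate_eeg(profile: MaturityProfile, duration_s: float, fs: float,
                 channels=REDUCED_9, seed: int = 0) -> EEGRecording:
    """Generate a multichannel neonatal EEG with the given maturity profile.

    The recording alternates burst and interburst states via a two-state
    renewal process (gamma durations with the profile's means and CV).
    Burst segments are coloured noise allocating ``slow_delta_frac`` of
    power below 2 Hz; homologous left/right channels share burst timing
    except for asynchronous events, which are lagged by
    ``asynchrony_lag_ms`` in the right hemisphere. Generation is
    reproducible given ``(profile, seed)``.

    Burst-state tracks per hemisphere are stored in
    ``recording.extras["state_left"/"state_right"/"state_midline"]``.

    Parameters
    ----------
    duration_s : float
        Recording length, seconds (>= 60).
    fs : float
        Sampling rate, Hz (>= 64).
    channels : sequence of str
        Subset of the 9-electrode reduced array or the full 19-lead
        10-20 montage.
    seed : int
        Seed for all randomness in this call.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    if duration_s < 60:
        raise ValueError("duration_s must be at least 60 s")
    if fs < 64:
        raise ValueError("fs must be at least 64 Hz")
    channels = tuple(channels)
    allowed = set(FULL_19) | set(REDUCED_9)
    for ch in channels:
        if ch not in allowed:
            raise ValueError(f"unknown channel label: {ch!r}")
    if len(set(channels)) != len(channels):
        raise ValueError("channel labels must be unique")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))

    master = _burst_intervals(rng, profile, duration_s)
    lag_s = profile.asynchrony_lag_ms / 1000.0
    mirrored = []
    for on, off in master:
        if rng.random() < profile.asynchrony_prob:
            mirrored.append((on + lag_s, off + lag_s))
        else:
            mirrored.append((on, off))

    tracks = {
        "left": _state_track(master, n, fs),
        "right": _state_track(mirrored, n, fs),
        "midline": _state_track(master, n, fs),
    }
    envelopes = {h: _smooth_envelope(t, fs) for h, t in tracks.items()}

    lo_amp, hi_amp = profile.interburst_amp_uv, profile.burst_amp_uv
    data = np.empty((len(channels), n))
    for i, ch in enumerate(channels):
        hemi = channel_hemisphere(ch)
        noise = _coloured_noise(rng, n, fs, profile.slow_delta_frac)
        amp = lo_amp + (hi_amp - lo_amp) * envelopes[hemi]
        data[i] = amp * noise

    rec = EEGRecording(
        data, fs, channels, ga_weeks=profile.ga_weeks,
        extras={
            "state_left": tracks["left"],
            "state_right": tracks["right"],
            "state_midline": tracks["midline"],
            "burst_intervals_left": list(master),
            "burst_intervals_right": list(mirrored),
            "profile": profile,
            "seed": seed,
        },
    )
    return rec


def fractional_gaussian_noise(n: int, hurst: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise by Davies-Harte circulant embedding.

    Returns ``n`` samples of zero-mean, unit-variance fGn with Hurst
    exponent ``hurst`` in (0, 1).
    """
    if not 0 < hurst < 1:
        raise ValueError("hurst must lie in (0, 1)")
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    lam = np.clip(lam, 0.0, None)  # clip tiny negative eigenvalues
    m = len(row)
    w = np.empty(m, dtype=complex)
    v = rng.standard_normal(n + 1)
    u1 = rng.standard_normal(n - 1)
    u2 = rng.standard_normal(n - 1)
    w[0] = math.sqrt(lam[0] / m) * v[0]
    w[n] = math.sqrt(lam[n] / m) * v[n]
    half = np.sqrt(lam[1:n] / (2 * m))
    w[1:n] = half * (u1 + 1j * u2)
    w[n + 1:] = np.conj(w[1:n][::-1])
    x = np.fft.fft(w).real[:n]
    return x


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    """One subject of a simulated infant cohort.

    ``abnormal_eeg`` is defined as the disjunction of interictal
    epileptiform discharges, background abnormality (dysmature background
    or focal slowing) and electrographic seizures, and is recomputed from
    those flags rather than stored independently. Missing outcomes are
    ``None``.
    """

    subject_id: str
    mutation: str                 # TSC1 | TSC2 | none_identified
    treatment: str                # preventive | conventional
    dysmature_eeg: bool
    ied_present: bool
    focal_slowing: bool
    electrographic_seizure: bool
    asd_24m: bool | None
    ados_score: int | None
    verbal: bool
    dq_cognitive: float | None
    dq_language: float | None
    dq_motor: float | None
    ga_first_eeg_weeks: float
    chron_age_first_eeg_days: float

    def __post_init__(self):
        if self.mutation not in ("TSC1", "TSC2", "none_identified"):
            raise ValueError(f"unknown mutation {self.mutation!r}")
        if self.treatment not in ("preventive", "conventional"):
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.ados_score is not None and self.ados_score < 0:
            raise ValueError("ados_score must be non-negative")
        for name in ("dq_cognitive", "dq_language", "dq_motor"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 160:
                raise ValueError(f"{name}={v} outside [0, 160]")

    @property
    def abnormal_eeg(self) -> bool:
        return (self.ied_present or self.dysmature_eeg or self.focal_slowing
                or self.electrographic_seizure)


@dataclass(frozen=True)
class CohortDesign:
    """Joint design of EEG flags, covariates and 24-month outcomes.

    The defaults are calibrated to the observed marginal and conditional
    frequencies of the study cohort this package models (n = 63 subjects
    with outcome data): dysmature background in 14/63, ASD risk 8/14
    given dysmature vs 11/49 given mature, IED 44%, focal slowing 23%,
    electrographic seizures 9%, TSC2 variant 72%, preventive treatment
    30%. DQ distributions differ in mean by dysmaturity status.
    """

    p_dysmature: float = 14 / 63
    p_asd_given_dysmature: float = 8 / 14
    p_asd_given_mature: float = 11 / 49
    p_ied: float = 28 / 64
    p_focal_slowing: float = 15 / 64
    p_seizure: float = 6 / 64
    p_tsc1: float = 17 / 64
    p_tsc2: float = 46 / 64
    p_preventive: float = 19 / 64
    p_verbal: float = 0.5
    dq_means_mature: tuple = (75.0, 68.0, 76.0)      # cognitive, language, motor
    dq_means_dysmature: tuple = (62.5, 59.0, 67.0)
    dq_sds: tuple = (15.0, 12.0, 14.0)
    n_missing_outcome: int = 1

    def __post_init__(self):
        for name in ("p_dysmature", "p_asd_given_dysmature", "p_asd_given_mature",
                     "p_ied", "p_focal_slowing", "p_seizure",
                     "p_tsc1", "p_tsc2", "p_preventive", "p_verbal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_tsc1 + self.p_tsc2 > 1.0 + 1e-12:
            raise ValueError("p_tsc1 + p_tsc2 must not exceed 1")
        if self.n_missing_outcome < 0:
            raise ValueError("n_missing_outcome must be >= 0")

    @property
    def designed_odds_ratio(self) -> float:
        """Closed-form dysmaturity-ASD odds ratio implied by the design."""
        p1, p0 = self.p_asd_given_dysmature, self.p_asd_given_mature
        return (p1 / (1 - p1)) / (p0 / (1 - p0))


#: Design calibrated to the study cohort's printed counts.
PAPER_DESIGN = CohortDesign()


def _draw_ados(rng, asd: bool, verbal: bool) -> int:
    """ADOS-2 total consistent with the (risk, verbal) cut-off bands."""
    if verbal:
        return int(rng.integers(8, 21)) if asd else int(rng.integers(0, 8))
    return int(rng.integers(10, 23)) if asd else int(rng.integers(0, 10))


def generate_cohort(n: int, design: CohortDesign = PAPER_DESIGN,
                    seed: int = 0) -> list[SubjectRecord]:
    """Simulate ``n`` subjects from the given cohort design.

    Dysmature background is Bernoulli(``p_dysmature``); the 24-month ASD
    outcome is Bernoulli on the dysmaturity-conditional probabilities;
    DQs are Gaussian (clipped to [0, 160]) with means shifted by
    dysmaturity status. Exactly ``design.n_missing_outcome`` subjects
    have the ASD/language/motor outcomes missing (cognitive retained),
    emulating incomplete follow-up. Reproducible given (design, seed).
    """
    if n < 10:
        raise ValueError("cohort size must be at least 10")
    rng = np.random.default_rng(seed)
    missing_idx = set(
        rng.choice(n, size=min(design.n_missing_outcome, n), replace=False).tolist()
    )
    records = []
    for i in range(n):
        dys = rng.random() < design.p_dysmature
        p_asd = design.p_asd_given_dysmature if dys else design.p_asd_given_mature
        asd = bool(rng.random() < p_asd)
        verbal = bool(rng.random() < design.p_verbal)
        ados = _draw_ados(rng, asd, verbal)
        u = rng.random()
        if u < design.p_tsc1:
            mutation = "TSC1"
        elif u < design.p_tsc1 + design.p_tsc2:
            mutation = "TSC2"
        else:
            mutation = "none_identified"
        means = design.dq_means_dysmature if dys else design.dq_means_mature
        dqs = [float(np.clip(rng.normal(mu, sd), 0.0, 160.0))
               for mu, sd in zip(means, design.dq_sds)]
        missing = i in missing_idx
        rec = SubjectRecord(
            subject_id=f"S{i + 1:04d}",
            mutation=mutation,
            treatment="preventive" if rng.random() < design.p_preventive
                      else "conventional",
            dysmature_eeg=bool(dys),
            ied_present=bool(rng.random() < design.p_ied),
            focal_slowing=bool(rng.random() < design.p_focal_slowing),
            electrographic_seizure=bool(rng.random() < design.p_seizure),
            asd_24m=None if missing else asd,
            ados_score=None if missing else ados,
            verbal=verbal,
            dq_cognitive=dqs[0],
            dq_language=None if missing else dqs[1],
            dq_motor=None if missing else dqs[2],
            ga_first_eeg_weeks=float(np.clip(rng.normal(42.6, 2.5), 36.0, 52.0)),
            chron_age_first_eeg_days=float(rng.lognormal(math.log(25.0), 0.9)),
        )
        records.append(rec)
    return records


def profile_for_subject(record: SubjectRecord) -> MaturityProfile:
    """Map a subject's visual dysmaturity flag to a generator profile."""
    base = DYSMATURE_PROFILE if record.dysmature_eeg else MATURE_PROFILE
    return replace(base, ga_weeks=record.ga_first_eeg_weeks)
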