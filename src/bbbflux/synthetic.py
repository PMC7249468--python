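"""Seeded synthetic cohorts with two-compartment biomarker kinetics.

The generator emulates the statistical structure of a one-week neurocritical
observation study: each subject releases a brain-enriched protein into CSF
(mono-exponential decay from an injury-scaled amplitude, plus optional
secondary-release events), has an albumin quotient trajectory ``Q(t)``
describing blood-brain-barrier integrity (roughly half of subjects
disrupted), and accumulates the protein in blood through two routes:

* a **barrier route** proportional to ``Q(t - delay_bbb) * C(t - delay_bbb)``
  -- transfer scales with how leaky the barrier is;
* an **alternative route** proportional to ``C(t - delay_alt)`` -- clearance
  that bypasses the barrier (e.g. glymphatic/lymphatic drainage) with its own
  transport delay.

Blood concentration follows ``dB/dt = k_bbb Q(t-d1) C(t-d1) + k_alt C(t-d2)
- lambda_e B`` integrated by forward Euler; delayed terms are zero before the
delay has elapsed.  Observations are taken on realistic schedules (biomarkers
every 6 h early then 12 h; albumin every 12 h then 24 h), CSF values are
window means over the preceding 6 h of pooled drainage, and all observations
carry multiplicative lognormal assay noise.

Secondary-release events and the shape of the disrupted ``Q(t)`` excess are
the two places where the generator goes beyond pure mono-exponentials; they
provide the within-subject structure that makes transport delays recoverable
by cross-correlation.  See ``docs/methods.md`` for the calibration rationale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import Analyte, write_long_table

__all__ = [
    "SamplingSchedule",
    "CohortConfig",
    "SubjectParams",
    "LatentTrajectory",
    "simulate_latent",
    "observe",
    "simulate_cohort",
    "make_study_like_cohort",
    "write_cohort",
    "S100B_LIKE",
    "NSE_LIKE",
]

LOG2 = float(np.log(2.0))


def _phase_times(phases, duration_h: float) -> np.ndarray:
    """Sampling times for a piecewise-constant schedule.

    ``phases`` is a sequence of ``(start, end, step)`` in hours; the final
    duration point is included when it closes the last phase, so a uniform
    12-h schedule over 168 h yields t = 0, 12, ..., 168 (15 points).
    """
    pts: list[float] = []
    for start, end, step in phases:
        t = float(start)
        stop = min(float(end), duration_h)
        while t < stop - 1e-9:
            pts.append(t)
            t += float(step)
    last_end = min(float(phases[-1][1]), duration_h)
    pts.append(last_end)
    return np.unique(np.asarray(pts, dtype=float))


@dataclass(frozen=True)
class SamplingSchedule:
    """Observation times for biomarkers (dense) and albumin (sparse)."""

    biomarker_phases: tuple = ((0.0, 48.0, 6.0), (48.0, 168.0, 12.0))
    albumin_phases: tuple = ((0.0, 48.0, 12.0), (48.0, 168.0, 24.0))

    def biomarker_times(self, duration_h: float) -> np.ndarray:
        return _phase_times(self.biomarker_phases, duration_h)

    def albumin_times(self, duration_h: float) -> np.ndarray:
        return _phase_times(self.albumin_phases, duration_h)


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of the synthetic cohort generator.

    Rates are per hour; concentrations in the analyte's canonical unit
    (biomarkers ug/L, CSF albumin mg/L, blood albumin g/L).
    """

    n_subjects: int = 16
    duration_h: float = 168.0
    seed: int = 0

    # analyte labels for the emitted long table
    csf_analyte: Analyte = Analyte.S100B_CSF
    blood_analyte: Analyte = Analyte.S100B_BLOOD

    # CSF release: C(t) = A exp(-lambda_c t) + secondary-release bumps
    csf_amp_med: float = 60.0  # lognormal median of A (ug/L)
    csf_amp_cv: float = 0.8
    csf_decay_halflife_h: float = 48.0
    csf_rise_tau_h: float = 0.0  # 0: release maximal at trauma; >0: accumulates over ~tau

    # albumin quotient: Q(t) = qa_base + D * shape(t) for disrupted subjects
    qa_disrupted_prob: float = 0.5
    qa_base: float = 0.004
    qa_excess_mu: float = 0.012  # lognormal median of D
    qa_excess_cv: float = 0.4
    qa_decay_halflife_h: float = 120.0
    qa_rise_tau_h: float = 0.0  # 0: disruption maximal at trauma; >0: rises over ~tau
    qa_onset_h: float = 0.0  # delayed component begins this long after trauma
    qa_early_frac: float = 0.0  # weight of an immediate (mechanical) disruption component

    # blood appearance routes
    k_bbb: float = 0.03  # per hour per unit Q_A
    k_alt: float = 0.0  # per hour
    delay_bbb_h: float = 12.0
    delay_alt_h: float = 24.0
    blood_halflife_h: float = 24.0
    blood_baseline: float = 0.05
    blood_floor: float = 0.03  # constant physiologic background seen in serum

    # secondary-release events (shared injury events bump C and, for
    # disrupted subjects, Q when qa_event_coupling > 0); the release
    # transient is narrow while the barrier stays open longer
    event_rate: float = 3.0  # expected events per subject over the window
    event_window_h: tuple = (12.0, 144.0)
    event_amp_frac: float = 0.6  # lognormal median, relative to subject amplitude
    event_amp_cv: float = 0.5
    event_width_h: float = 3.0
    qa_event_width_h: float = 12.0
    qa_event_coupling: float = 0.5  # Q bump amplitude relative to D per unit event size

    # extracranial contamination of blood values for multitrauma subjects
    extracranial_spike: bool = False
    spike_amp: float = 1.5
    spike_halflife_h: float = 2.5
    multitrauma_prob: float = 0.375

    # albumin and assay noise (albumin assays are far more precise than
    # the biomarker immunoassays)
    alb_blood_mean: float = 40.0  # g/L
    alb_blood_cv: float = 0.07
    noise_cv: float = 0.18
    alb_noise_cv: float = 0.05

    csf_pool_h: float = 6.0  # CSF observations average the preceding window
    schedule: SamplingSchedule = field(default_factory=SamplingSchedule)
    euler_step_h: float = 0.5

    def __post_init__(self) -> None:
        for name in ("csf_decay_halflife_h", "qa_decay_halflife_h", "blood_halflife_h"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("qa_disrupted_prob", "multitrauma_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.euler_step_h <= 1.0:
            raise ValueError("euler_step_h must be in (0, 1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")


@dataclass(frozen=True)
class SubjectParams:
    """Latent per-subject parameters drawn by the generator."""

    subject_id: str
    amp: float
    disrupted: bool
    qa_excess: float
    alb_blood: float
    multitrauma: bool
    event_times: tuple = ()
    event_sizes: tuple = ()  # relative amplitudes (fraction of subject amp)


@dataclass
class LatentTrajectory:
    """Noise-free state on the integration grid for one subject."""

    subject_id: str
    t: np.ndarray
    C: np.ndarray  # CSF concentration
    Q: np.ndarray  # albumin quotient
    B: np.ndarray  # blood concentration


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv**2)))


def _draw_subject(config: CohortConfig, idx: int, rng: np.random.Generator) -> SubjectParams:
    amp = config.csf_amp_med * np.exp(_lognormal_sigma(config.csf_amp_cv) * rng.standard_normal())
    disrupted = bool(rng.random() < config.qa_disrupted_prob)
    qa_excess = (
        config.qa_excess_mu
        * np.exp(_lognormal_sigma(config.qa_excess_cv) * rng.standard_normal())
        if disrupted
        else 0.0
    )
    alb = config.alb_blood_mean * np.exp(
        _lognormal_sigma(config.alb_blood_cv) * rng.standard_normal()
    )
    multi = bool(rng.random() < config.multitrauma_prob)
    n_ev = int(rng.poisson(config.event_rate))
    lo, hi = config.event_window_h
    ev_t = tuple(np.sort(rng.uniform(lo, min(hi, config.duration_h), size=n_ev)))
    ev_s = tuple(
        config.event_amp_frac
        * np.exp(_lognormal_sigma(config.event_amp_cv) * rng.standard_normal(n_ev))
    )
    return SubjectParams(
        subject_id=f"S{idx + 1:02d}",
        amp=float(amp),
        disrupted=disrupted,
        qa_excess=float(qa_excess),
        alb_blood=float(alb),
        multitrauma=multi,
        event_times=ev_t,
        event_sizes=ev_s,
    )


def _bumps(t: np.ndarray, times, sizes, width: float) -> np.ndarray:
    out = np.zeros_like(t)
    for s, a in zip(times, sizes):
        out += a * np.exp(-0.5 * ((t - s) / width) ** 2)
    return out


def _csf_curve(t: np.ndarray, config: CohortConfig, subject: SubjectParams) -> np.ndarray:
    lam = LOG2 / config.csf_decay_halflife_h
    base = np.exp(-lam * t)
    if config.csf_rise_tau_h > 0:
        tau = config.csf_rise_tau_h
        base = base * (1.0 - np.exp(-t / tau))
        t_peak = tau * np.log1p(1.0 / (lam * tau))
        base = base / ((1.0 - np.exp(-t_peak / tau)) * np.exp(-lam * t_peak))
    return subject.amp * (base + _bumps(t, subject.event_times, subject.event_sizes, config.event_width_h))


def _qa_curve(t: np.ndarray, config: CohortConfig, subject: SubjectParams) -> np.ndarray:
    q = np.full_like(t, config.qa_base)
    if subject.qa_excess <= 0:
        return q
    lam_q = LOG2 / config.qa_decay_halflife_h
    ts = np.clip(t - config.qa_onset_h, 0.0, None)
    if config.qa_rise_tau_h > 0:
        # delayed (vasogenic) disruption: rises over ~tau after onset, then decays
        tau = config.qa_rise_tau_h
        shape = (1.0 - np.exp(-ts / tau)) * np.exp(-lam_q * ts)
        t_peak = tau * np.log1p(1.0 / (lam_q * tau))
        shape = shape / ((1.0 - np.exp(-t_peak / tau)) * np.exp(-lam_q * t_peak))
    else:
        shape = np.exp(-lam_q * ts)
    if config.qa_early_frac > 0:
        # immediate mechanical disruption superimposed on the delayed component
        f = config.qa_early_frac
        shape = f * np.exp(-lam_q * t) + (1.0 - f) * shape
    q = q + subject.qa_excess * shape
    if config.qa_event_coupling > 0:
        q = q + subject.qa_excess * config.qa_event_coupling * _bumps(
            t, subject.event_times, subject.event_sizes, config.qa_event_width_h
        )
    return q


def simulate_latent(config: CohortConfig, subject: SubjectParams) -> LatentTrajectory:
    """Integrate one subject's latent (noise-free) trajectories.

    ``C`` and ``Q`` are evaluated in closed form; ``B`` solves the clearance
    ODE by forward Euler on a grid of ``euler_step_h`` hours.  Raises if the
    state becomes non-finite (diverging parameter set).
    """
    dt = config.euler_step_h
    n = int(round(config.duration_h / dt)) + 1
    t = np.arange(n) * dt
    C = _csf_curve(t, config, subject)
    Q = _qa_curve(t, config, subject)
    lam_e = LOG2 / config.blood_halflife_h

    def delayed(arr: np.ndarray, i: int, delay: float) -> float:
        j = i - int(round(delay / dt))
        return arr[j] if j >= 0 else 0.0

    B = np.empty(n)
    B[0] = config.blood_baseline
    for i in range(n - 1):
        inflow = 0.0
        if config.k_bbb != 0.0:
            inflow += config.k_bbb * delayed(Q, i, config.delay_bbb_h) * delayed(
                C, i, config.delay_bbb_h
            )
        if config.k_alt != 0.0:
            inflow += config.k_alt * delayed(C, i, config.delay_alt_h)
        B[i + 1] = B[i] + dt * (inflow - lam_e * B[i])
        if not np.isfinite(B[i + 1]):
            raise FloatingPointError(
                f"blood concentration diverged at t={t[i + 1]:.1f} h "
                f"(k_bbb={config.k_bbb}, k_alt={config.k_alt}, "
                f"blood_halflife_h={config.blood_halflife_h}, euler_step_h={dt})"
            )
    return LatentTrajectory(subject_id=subject.subject_id, t=t, C=C, Q=Q, B=np.maximum(B, 0.0))


def _window_mean(t: np.ndarray, values: np.ndarray, t_end: float, width: float) -> float:
    lo = max(0.0, t_end - width)
    mask = (t >= lo - 1e-9) & (t <= t_end + 1e-9)
    return float(values[mask].mean())


def observe(
    latent: LatentTrajectory,
    config: CohortConfig,
    rng: np.random.Generator,
    subject: SubjectParams,
) -> pd.DataFrame:
    """Sample noisy observations from a latent trajectory.

    CSF biomarker observations are means of ``C`` over the preceding pooling
    window (the drainage pool); blood observations are point values of ``B``;
    albumin observations follow the sparser albumin schedule with CSF albumin
    reconstructed as ``Q(t) * albumin_blood`` (mg/L).  All values receive
    multiplicative lognormal noise with coefficient of variation ``noise_cv``
    (mean-preserving).  With ``extracranial_spike`` on, multitrauma subjects
    get an additive blood bump decaying to ~0 within 12 h of trauma.

    Blood observations sit on a constant physiologic background
    (``blood_floor``): healthy subjects have non-zero serum levels from
    extracerebral production, so the measured value never falls below that
    scale even when intracranial transfer has not begun.
    """
    bt = config.schedule.biomarker_times(config.duration_h)
    at = config.schedule.albumin_times(config.duration_h)
    if len(bt) == 0 or len(at) == 0:
        raise ValueError("sampling schedule is empty")
    if latent.t[-1] < config.duration_h - 1e-9:
        raise ValueError("latent trajectory does not cover the full duration")

    def noisy(x: np.ndarray, cv: float = config.noise_cv) -> np.ndarray:
        if cv <= 0:
            return x
        sig = _lognormal_sigma(cv)
        return x * np.exp(sig * rng.standard_normal(np.shape(x)) - 0.5 * sig**2)

    rows = []
    csf_vals = np.array([_window_mean(latent.t, latent.C, te, config.csf_pool_h) for te in bt])
    blood_vals = np.interp(bt, latent.t, latent.B) + config.blood_floor
    if config.extracranial_spike and subject.multitrauma:
        blood_vals = blood_vals + config.spike_amp * np.power(2.0, -bt / config.spike_halflife_h)
    for te, v in zip(bt, noisy(csf_vals)):
        rows.append((subject.subject_id, config.csf_analyte.value, te, v))
    for te, v in zip(bt, noisy(blood_vals)):
        rows.append((subject.subject_id, config.blood_analyte.value, te, v))

    alb_blood = np.full(len(at), subject.alb_blood)
    alb_csf = np.interp(at, latent.t, latent.Q) * subject.alb_blood * 1000.0
    for te, v in zip(at, noisy(alb_csf, config.alb_noise_cv)):
        rows.append((subject.subject_id, Analyte.ALB_CSF.value, te, v))
    for te, v in zip(at, noisy(alb_blood, config.alb_noise_cv)):
        rows.append((subject.subject_id, Analyte.ALB_BLOOD.value, te, v))

    df = pd.DataFrame(rows, columns=["subject_id", "analyte", "time_h", "value"])
    df["unit"] = df["analyte"].map(
        {
            config.csf_analyte.value: "ug/L",
            config.blood_analyte.value: "ug/L",
            Analyte.ALB_CSF.value: "mg/L",
            Analyte.ALB_BLOOD.value: "g/L",
        }
    )
    return df


def _draw_demographics(
    subject: SubjectParams, rng: np.random.Generator
) -> dict:
    age = int(rng.integers(18, 76))
    sex = "M" if rng.random() < 0.8 else "F"
    gcs = int(rng.integers(3, 9))
    pupils = int(rng.choice([0, 1, 2], p=[0.5, 0.3, 0.2]))
    ais_head = int(rng.choice([3, 4, 5], p=[0.1, 0.3, 0.6]))
    ais_nonhead = int(rng.integers(2, 5)) if subject.multitrauma else int(rng.integers(0, 2))
    iss = int(min(75, ais_head**2 + ais_nonhead**2 + int(rng.integers(0, 5))))
    marshall = str(rng.choice(["II", "III", "IV", "VI"], p=[0.35, 0.2, 0.1, 0.35]))
    rotterdam = int(rng.integers(3, 7))
    stockholm = float(np.round(rng.uniform(1.2, 5.0), 1))
    progression = int(rng.random() < 0.31)
    gos = int(rng.choice([1, 2, 3, 4, 5], p=[0.15, 0.05, 0.3, 0.25, 0.25]))
    return {
        "subject_id": subject.subject_id,
        "age": age,
        "sex": sex,
        "gcs": gcs,
        "pupils": pupils,
        "multitrauma": int(subject.multitrauma),
        "ais_head": ais_head,
        "ais_nonhead": ais_nonhead,
        "iss": max(iss, 1),
        "marshall": marshall,
        "rotterdam": rotterdam,
        "stockholm": stockholm,
        "progression": progression,
        "gos": gos,
    }


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a full cohort: measurements, demographics, latent truth.

    Deterministic for a fixed config (the seed lives in the config): the same
    config yields byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    frames, demo_rows, truth = [], [], {}
    for i in range(config.n_subjects):
        subject = _draw_subject(config, i, rng)
        latent = simulate_latent(config, subject)
        frames.append(observe(latent, config, rng, subject))
        demo_rows.append(_draw_demographics(subject, rng))
        truth[subject.subject_id] = {
            "amp": subject.amp,
            "disrupted": subject.disrupted,
            "qa_excess": subject.qa_excess,
            "alb_blood": subject.alb_blood,
            "multitrauma": subject.multitrauma,
            "event_times": list(subject.event_times),
            "event_sizes": list(subject.event_sizes),
        }
    measurements = pd.concat(frames, ignore_index=True)
    demographics = pd.DataFrame(demo_rows)
    truth["config"] = dataclasses.asdict(config)
    truth["config"]["csf_analyte"] = config.csf_analyte.value
    truth["config"]["blood_analyte"] = config.blood_analyte.value
    return measurements, demographics, truth


# ---------------------------------------------------------------------------
# study-like profiles

#: barrier-dominated clearance (S100B-like): transfer through the disrupted
#: barrier with a ~12 h transport delay; injury events open the barrier and
#: release protein simultaneously.
S100B_LIKE = dict(
    csf_analyte=Analyte.S100B_CSF,
    blood_analyte=Analyte.S100B_BLOOD,
    csf_amp_med=60.0,
    csf_amp_cv=0.8,
    csf_decay_halflife_h=48.0,
    csf_rise_tau_h=0.0,
    k_bbb=0.2,
    k_alt=0.0,
    delay_bbb_h=12.0,
    delay_alt_h=24.0,
    blood_halflife_h=2.0,
    blood_baseline=0.05,
    blood_floor=0.03,
    qa_decay_halflife_h=60.0,
    qa_rise_tau_h=0.0,
    qa_event_coupling=2.0,
    qa_event_width_h=6.0,
    event_width_h=3.0,
    extracranial_spike=False,
    spike_amp=1.5,
    schedule=SamplingSchedule(albumin_phases=((24.0, 168.0, 12.0),)),
)

#: barrier-independent clearance (NSE-like): all transfer through the
#: alternative route with a ~24 h delay; barrier disruption follows its own
#: delayed (vasogenic) time course, uncoupled from release events.
NSE_LIKE = dict(
    csf_analyte=Analyte.NSE_CSF,
    blood_analyte=Analyte.NSE_BLOOD,
    csf_amp_med=120.0,
    csf_amp_cv=0.6,
    csf_decay_halflife_h=60.0,
    csf_rise_tau_h=4.0,
    k_bbb=0.0,
    k_alt=0.01,
    delay_bbb_h=12.0,
    delay_alt_h=24.0,
    blood_halflife_h=2.0,
    blood_baseline=3.0,
    blood_floor=2.0,
    qa_rise_tau_h=0.0,
    qa_decay_halflife_h=60.0,
    qa_event_coupling=0.0,
    event_width_h=2.5,
    extracranial_spike=False,
    schedule=SamplingSchedule(albumin_phases=((36.0, 168.0, 12.0),)),
)

_PROFILES = {"s100b_like": S100B_LIKE, "nse_like": NSE_LIKE, "s100b": S100B_LIKE, "nse": NSE_LIKE}


def make_study_like_cohort(
    profile: str, n: int = 16, seed: int = 0, **overrides
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Cohort with analyte-appropriate defaults for a named clearance profile.

    ``profile`` is ``"s100b_like"`` (barrier-mediated) or ``"nse_like"``
    (barrier-independent).  Roughly half the subjects are disrupted.
    """
    if n < 2:
        raise ValueError("a study-like cohort needs at least 2 subjects")
    key = profile.lower()
    if key not in _PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose s100b_like or nse_like")
    params = {**_PROFILES[key], **overrides}
    config = CohortConfig(n_subjects=n, seed=seed, **params)
    return simulate_cohort(config)


def write_cohort(
    outdir: str | Path,
    measurements: pd.DataFrame,
    demographics: pd.DataFrame,
    truth: dict,
) -> dict[str, Path]:
    """Write a simulated cohort to disk (long CSV, demographics CSV, truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": outdir / "measurements.csv",
        "demographics": outdir / "demographics.csv",
        "truth": outdir / "latent_truth.json",
    }
    write_long_table(measurements, paths["measurements"])
    demographics.to_csv(paths["demographics"], index=False)
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths
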