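"""Ground-truth synthetic sessions for the locomotion-modulation pipeline.

The generator emulates the statistical structure the analysis assumes:

* bout-structured walking speed (rest, ramp, plateau, ramp, rest) and a
  saturating optical treadmill-sensor trace that responds steeply at
  movement onset;
* spike trains as inhomogeneous Poisson processes whose rate steps from
  a baseline to baseline x gain inside modulation epochs that begin at
  bout onset + lead (negative leads model predictive modulation that
  precedes movement);
* EMG with amplitude-ramped broadband bursts beginning at bout onset +
  delay, with delays drawn per bout (negative delays model muscle
  activation preceding treadmill motion);
* a skull-vibration envelope linearly coupled to speed with noise that
  can be calibrated in closed form to hit a target 100-ms-bin Pearson
  correlation;
* audio containing a 4-kHz calibration tone of known SPL and shaped
  noise footstep transients whose per-event RMS realizes a target SPL.

Every draw descends from a single seed via numpy SeedSequence spawning,
so a (preset, seed) pair reproduces a byte-identical serialized bundle.
Presets encode the published population statistics this package is
benchmarked against (direction composition 44/22/34 %, lead medians
-216 / -88 ms, EMG delay median -125 ms, footstep SPL 40 dB against a
60 dB tone, vibration-speed r = 0.42).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig
from .modulation import DECREASED, INCREASED, NS
from .signals import ContinuousSignal, SpikeTrain

LOCO_RATE = 1000.0      # Hz, treadmill sensor / speed sampling
EMG_RATE = 2000.0       # Hz, synthetic raw EMG sampling
SENSOR_SCALE = 0.5      # cm/s; sensor = 1 - exp(-speed/SENSOR_SCALE)


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class UnitTruth:
    unit_id: str
    direction: str        # increased | decreased | ns
    gain: float           # rate multiplier during modulation epochs (1 for ns)
    lead: float           # s; epoch start relative to bout onset (negative = precedes)
    base_rate: float      # Hz


@dataclass
class GroundTruth:
    seed: int
    bouts: list = field(default_factory=list)            # (onset_s, end_s)
    units: list = field(default_factory=list)            # list[UnitTruth]
    emg_delays: list | None = None                       # s per bout
    vib_coupling: float | None = None                    # envelope units per cm/s
    vib_noise_sd: float | None = None
    footstep_times: list | None = None
    footstep_spl_db: float | None = None
    ref_tone_spl_db: float | None = None
    tone_interval: tuple | None = None
    quiet_interval: tuple | None = None


@dataclass
class SessionBundle:
    signals: dict                 # name -> ContinuousSignal
    units: list                   # list[SpikeTrain]
    meta: dict
    truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        durations = [sig.duration for sig in self.signals.values()]
        if durations:
            rates = [sig.rate for sig in self.signals.values()]
            tol = 1.0 / min(rates)
            if max(durations) - min(durations) > tol:
                raise ValueError("all signals must share the session duration")
        if self.truth is not None and "seed" not in self.meta:
            raise ValueError("bundles carrying ground truth must record their seed")

    @property
    def duration(self) -> float:
        if self.signals:
            return max(sig.duration for sig in self.signals.values())
        return max((u.duration for u in self.units), default=0.0)


# ---------------------------------------------------------------------------
# locomotion
# ---------------------------------------------------------------------------

def simulate_locomotion(
    duration: float,
    n_bouts: int,
    rng: np.random.Generator,
    rate: float = LOCO_RATE,
    bout_dur: tuple[float, float] = (3.0, 6.0),
    plateau: tuple[float, float] = (3.0, 15.0),
    ramp: tuple[float, float] = (0.1, 0.3),
    min_rest: float = 2.5,
    lead_in: float = 3.0,
    speed_noise_sd: float = 0.05,
    sensor_noise_sd: float = 0.003,
):
    """Bout-structured treadmill traces with known onsets.

    Returns (sensor, speed, bouts): the optical sensor trace (a.u.), the
    calibrated raw speed trace (cm/s), and the true bout intervals
    (onset, end).  Each bout ramps up over 100-300 ms to a 3-15 cm/s
    plateau and ramps down before the bout end; every onset is preceded
    by at least ``min_rest`` seconds of rest.  Raises when the requested
    bouts cannot be packed into the session.
    """
    if duration <= 0 or n_bouts < 0:
        raise ValueError("duration must be positive and n_bouts nonnegative")
    n = int(round(duration * rate))
    speed_true = np.zeros(n)
    bouts: list[tuple[float, float]] = []
    if n_bouts > 0:
        durs = rng.uniform(*bout_dur, n_bouts)
        required = lead_in + durs.sum() + n_bouts * min_rest
        slack = duration - required
        if slack < 0:
            raise ValueError(
                f"cannot pack {n_bouts} bouts (+rests) into {duration:.1f} s; "
                f"need at least {required:.1f} s"
            )
        extra = rng.dirichlet(np.ones(n_bouts + 1)) * slack
        plateaus = rng.uniform(*plateau, n_bouts)
        ramps = rng.uniform(*ramp, (n_bouts, 2))
        t_cursor = lead_in + extra[0]
        t = np.arange(n) / rate
        for k in range(n_bouts):
            onset = t_cursor
            end = onset + durs[k]
            up, down = ramps[k]
            v = plateaus[k]
            seg = slice(int(round(onset * rate)), int(round(end * rate)))
            tt = t[seg] - onset
            prof = np.full(tt.size, v)
            rising = tt < up
            prof[rising] = v * tt[rising] / up
            falling = tt > durs[k] - down
            prof[falling] = v * (durs[k] - tt[falling]) / down
            speed_true[seg] = np.maximum(prof, 0.0)
            bouts.append((float(onset), float(end)))
            t_cursor = end + min_rest + extra[k + 1]
    sensor_clean = 1.0 - np.exp(-speed_true / SENSOR_SCALE)
    sensor = ContinuousSignal(
        sensor_clean + rng.normal(0.0, sensor_noise_sd, n), rate, units="a.u."
    )
    speed = ContinuousSignal(
        speed_true + rng.normal(0.0, speed_noise_sd, n), rate, units="cm/s"
    )
    return sensor, speed, bouts


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

def _enforce_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    """Greedy dead-time thinning: drop spikes within ``refractory`` of the
    previously kept spike (chains handled by iterating to convergence)."""
    while times.size >= 2:
        bad = np.flatnonzero(np.diff(times) < refractory)
        if bad.size == 0:
            break
        first_of_run = bad[np.concatenate([[True], np.diff(bad) > 1])]
        times = np.delete(times, first_of_run + 1)
    return times


def simulate_unit(
    bouts: list[tuple[float, float]],
    direction: str,
    gain: float,
    lead: float,
    base_rate: float,
    duration: float,
    rng: np.random.Generator,
    unit_id: str = "u0",
    refractory: float = 0.001,
) -> SpikeTrain:
    """Inhomogeneous Poisson spike train with step modulation (thinning).

    The rate is ``base_rate`` outside modulation epochs and
    ``base_rate * gain`` inside; each epoch runs from bout onset + lead
    to the bout end.  Epochs that would start before t = 0 are clipped
    with a warning.  A 1-ms absolute refractory period is imposed by
    default (real units have one, and the inter-spike-interval QC of
    the analysis assumes it); pass ``refractory=0`` for a pure Poisson
    process.
    """
    if base_rate < 0 or gain <= 0:
        raise ValueError("base_rate must be >= 0 and gain > 0")
    if base_rate == 0:
        return SpikeTrain(np.array([]), duration, unit_id)
    epochs = []
    for onset, end in bouts:
        start = onset + lead
        if start < 0:
            warnings.warn(f"modulation epoch clipped at session start (unit {unit_id})")
            start = 0.0
        if end > start:
            epochs.append((start, min(end, duration)))
    lam_max = base_rate * max(gain, 1.0)
    n_cand = rng.poisson(lam_max * duration)
    t = np.sort(rng.uniform(0.0, duration, n_cand))
    lam = np.full(t.size, base_rate)
    if epochs and direction != NS:
        edges = np.array(epochs).ravel()
        inside = (np.searchsorted(edges, t, side="right") % 2) == 1
        lam[inside] = base_rate * gain
    keep = rng.uniform(0.0, 1.0, t.size) < lam / lam_max
    kept = t[keep]
    if refractory > 0:
        kept = _enforce_refractory(kept, refractory)
    return SpikeTrain(kept, duration, unit_id)


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------

def simulate_emg(
    bouts: list[tuple[float, float]],
    delays: np.ndarray,
    duration: float,
    rng: np.random.Generator,
    noise_sd: float = 0.1,
    burst_amp: float = 1.0,
    rate: float = EMG_RATE,
    rise: float = 0.15,
    decay: float = 0.1,
) -> ContinuousSignal:
    """Raw EMG: Gaussian baseline plus amplitude-ramped broadband bursts.

    For bout k the burst begins at onset + delays[k], ramps its
    amplitude linearly over ``rise`` seconds (locomotor EMG activation
    builds over ~100-150 ms rather than stepping), holds until the bout
    end, and decays over ``decay`` seconds.  The instantaneous standard
    deviation of the trace is noise_sd + burst_amp * env: EMG amplitude
    grows linearly with motor drive, so the rectified envelope ramps
    linearly from the burst start.
    """
    if burst_amp < 0:
        raise ValueError("burst_amp must be >= 0")
    if len(delays) != len(bouts):
        raise ValueError("need one delay per bout")
    n = int(round(duration * rate))
    env = np.zeros(n)
    t = np.arange(n) / rate
    for (onset, end), d in zip(bouts, delays):
        start = onset + d
        seg = slice(max(int(round(start * rate)), 0), min(int(round((end + decay) * rate)), n))
        tt = t[seg]
        prof = np.ones(tt.size)
        prof[tt < start + rise] = (tt[tt < start + rise] - start) / rise
        tail = tt > end
        prof[tail] = np.maximum(1.0 - (tt[tail] - end) / decay, 0.0)
        env[seg] = np.maximum(env[seg], np.clip(prof, 0.0, 1.0))
    sd = noise_sd + burst_amp * env
    return ContinuousSignal(rng.standard_normal(n) * sd, rate, units="V")


# ---------------------------------------------------------------------------
# skull vibration
# ---------------------------------------------------------------------------

def calibrate_vibration_noise(
    coupling: float, speed: ContinuousSignal, target_r: float, bin_s: float = 0.1
) -> float:
    """Noise SD (per 100-ms block) that yields ``target_r`` at the bin level.

    From r = a*sd(s) / sqrt(a^2 sd(s)^2 + sd_n^2):
    sd_n = a * sd(speed_binned) * sqrt(1/r^2 - 1), with sd(speed) taken
    over the same 100-ms bins the correlation is later computed on.
    """
    if not 0.0 < target_r <= 1.0:
        raise ValueError("target correlation must lie in (0, 1]")
    per = int(round(bin_s * speed.rate))
    n = (speed.n // per) * per
    binned = speed.samples[:n].reshape(-1, per).mean(axis=1)
    return float(coupling * binned.std() * np.sqrt(1.0 / target_r ** 2 - 1.0))


def simulate_vibration(
    speed: ContinuousSignal,
    coupling: float,
    rng: np.random.Generator,
    noise_sd: float | None = None,
    target_r: float | None = None,
    noise_block: float = 0.1,
) -> tuple[ContinuousSignal, float]:
    """Vibration envelope = coupling * speed + blockwise Gaussian noise.

    Noise is piecewise constant over ``noise_block`` (100 ms) blocks --
    the timescale the coupling correlation is measured at -- so the
    closed-form calibration of :func:`calibrate_vibration_noise` holds
    exactly at the analysis scale.  Provide either ``noise_sd`` or
    ``target_r``.  Returns (envelope, noise_sd_used).
    """
    if noise_sd is None:
        if target_r is None:
            raise ValueError("provide noise_sd or target_r")
        noise_sd = calibrate_vibration_noise(coupling, speed, target_r, noise_block)
    per = int(round(noise_block * speed.rate))
    n_blocks = int(np.ceil(speed.n / per))
    noise = np.repeat(rng.normal(0.0, noise_sd, n_blocks) if noise_sd > 0 else np.zeros(n_blocks), per)[: speed.n]
    env = coupling * speed.samples + noise
    return ContinuousSignal(env, speed.rate, units="a.u."), float(noise_sd)


# ---------------------------------------------------------------------------
# audio
# ---------------------------------------------------------------------------

def _footstep_template(rate: float, rise: float = 0.005, flat: float = 0.045, fall: float = 0.03) -> np.ndarray:
    """Amplitude envelope of one footstep transient (bounded support)."""
    n_r, n_f, n_d = (int(round(x * rate)) for x in (rise, flat, fall))
    up = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_r) / max(n_r, 1)))
    down = 0.5 * (1.0 + np.cos(np.pi * np.arange(n_d) / max(n_d, 1)))
    return np.concatenate([up, np.ones(n_f), down])


def simulate_audio(
    footstep_times: np.ndarray,
    footstep_spl_db: float,
    ref_tone_spl_db: float,
    rng: np.random.Generator,
    rate: float = 50000.0,
    snr: float = 10.0,
    tone_rms: float = 0.05,
    tone_freq: float = 4000.0,
    tone_interval: tuple[float, float] = (0.5, 1.5),
    quiet_interval: tuple[float, float] = (2.0, 4.0),
    duration: float | None = None,
):
    """Audio with a calibration tone and footstep transients of known SPL.

    Footstep transients are noise bursts band-limited to 2-10 kHz (the
    band locomotion sounds concentrate in) under a 5/45/30 ms
    rise/flat/decay envelope.  The per-event RMS over each transient's
    80-ms support is normalized exactly to
    tone_rms * 10**((footstep_spl - ref_spl)/20), so the SPL round trip
    through the detector is exact up to event-boundary effects.
    Background Gaussian noise is scaled to an amplitude SNR of ``snr``
    against the transient plateau.  Returns (audio, truth) where truth
    records the tone/quiet intervals and true event times.
    """
    if rate < 2 * tone_freq:
        raise ValueError("sample rate below twice the calibration tone frequency")
    times = np.sort(np.asarray(footstep_times, dtype=float))
    if times.size and times[0] < quiet_interval[1] + 0.1:
        raise ValueError("footsteps must start after the quiet reference interval")
    if duration is None:
        duration = (times[-1] + 1.0) if times.size else quiet_interval[1] + 1.0
    n = int(round(duration * rate))
    target_rms = tone_rms * 10.0 ** ((footstep_spl_db - ref_tone_spl_db) / 20.0)
    template = _footstep_template(rate)
    shape_rms = np.sqrt(np.mean(template ** 2))
    plateau_amp = target_rms / shape_rms
    noise_sd = plateau_amp / snr
    x = rng.normal(0.0, noise_sd, n)
    # calibration tone with 5-ms cosine tapers against spectral splatter
    i0, i1 = int(round(tone_interval[0] * rate)), int(round(tone_interval[1] * rate))
    tt = np.arange(i1 - i0) / rate
    tone = tone_rms * np.sqrt(2.0) * np.sin(2 * np.pi * tone_freq * tt)
    taper_n = int(round(0.005 * rate))
    window = np.ones(tone.size)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(taper_n) / taper_n))
    window[:taper_n] = ramp
    window[-taper_n:] = ramp[::-1]
    x[i0:i1] += tone * window
    from scipy import signal as sps

    hi = min(10000.0, 0.45 * rate)
    sos = sps.butter(4, [2000.0, hi], btype="bandpass", fs=rate, output="sos")
    for t_ev in times:
        j0 = int(round(t_ev * rate))
        j1 = min(j0 + template.size, n)
        carrier = sps.sosfiltfilt(sos, rng.standard_normal(template.size))[: j1 - j0]
        burst = template[: j1 - j0] * carrier
        rms = np.sqrt(np.mean(burst ** 2))
        if rms > 0:
            burst *= target_rms / rms
        x[j0:j1] += burst
    audio = ContinuousSignal(x, rate, units="a.u.")
    truth = GroundTruth(
        seed=-1,
        footstep_times=times.tolist(),
        footstep_spl_db=footstep_spl_db,
        ref_tone_spl_db=ref_tone_spl_db,
        tone_interval=tone_interval,
        quiet_interval=quiet_interval,
    )
    return audio, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

@dataclass
class Preset:
    """Study conditions for a paper-matched synthetic session."""

    name: str
    n_units: int = 0
    fractions: tuple[float, float, float] = (0.0, 0.0, 1.0)  # increased, decreased, ns
    duration: float = 400.0
    n_bouts: int = 30
    min_rest: float = 2.5
    # per-direction (median, sd) of the modulation lead in seconds
    lead_increased: tuple[float, float] = (-0.216, 0.06)
    lead_decreased: tuple[float, float] = (-0.088, 0.05)
    gain_increased: tuple[float, float] = (1.5, 4.0)
    gain_decreased: tuple[float, float] = (0.3, 0.8)
    # base firing rates: lognormal(log median, sigma) clipped to bounds
    base_rate_lognorm: tuple[float, float] = (6.0, 0.8)
    base_rate_bounds: tuple[float, float] = (0.5, 30.0)
    base_rate_uniform: tuple[float, float] | None = None  # overrides lognormal
    with_emg: bool = False
    emg_delay: tuple[float, float] = (-0.125, 0.04)       # (median, sd), seconds
    emg_snr: float = 10.0
    with_vibration: bool = False
    vib_coupling: float = 0.02
    vib_target_r: float = 0.42
    with_audio: bool = False
    n_footsteps: int = 100
    footstep_spl_db: float = 40.0
    ref_tone_spl_db: float = 60.0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("direction fractions must sum to 1")


PRESETS: dict[str, Preset] = {
    # full population composition of the deafened-cohort benchmark
    "deaf_population": Preset(
        name="deaf_population",
        n_units=146,
        fractions=(0.44, 0.22, 0.34),
        duration=400.0,
        n_bouts=30,
        with_emg=True,
        with_vibration=True,
    ),
    # high-SNR step-modulated units for latency recovery
    "latency_deaf_increased": Preset(
        name="latency_deaf_increased",
        n_units=17,
        fractions=(1.0, 0.0, 0.0),
        duration=180.0,
        n_bouts=20,
        min_rest=3.0,
        gain_increased=(5.0, 8.0),
        base_rate_uniform=(2.0, 8.0),
    ),
    "latency_deaf_decreased": Preset(
        name="latency_deaf_decreased",
        n_units=7,
        fractions=(0.0, 1.0, 0.0),
        duration=180.0,
        n_bouts=20,
        min_rest=3.0,
        gain_decreased=(0.02, 0.1),
        base_rate_uniform=(25.0, 35.0),
    ),
    # many onsets for the EMG-treadmill delay distribution
    "emg_delay": Preset(
        name="emg_delay",
        n_units=0,
        duration=980.0,
        n_bouts=121,
        with_emg=True,
    ),
    # footstep acoustics with SPL calibration
    "footstep_audio": Preset(
        name="footstep_audio",
        n_units=0,
        n_bouts=0,
        duration=45.0,
        with_audio=True,
    ),
    # speed-coupled skull vibration envelope
    "vibration_coupling": Preset(
        name="vibration_coupling",
        n_units=0,
        duration=600.0,
        n_bouts=40,
        with_vibration=True,
    ),
    # small all-signal session for demos and smoke tests
    "demo": Preset(
        name="demo",
        n_units=12,
        fractions=(0.5, 0.25, 0.25),
        duration=160.0,
        n_bouts=10,
        gain_increased=(3.0, 6.0),
        with_emg=True,
        with_vibration=True,
    ),
}


def largest_remainder_counts(n: int, fractions) -> np.ndarray:
    """Integer composition of n realizing ``fractions`` by largest remainder."""
    raw = np.asarray(fractions, dtype=float) * n
    base = np.floor(raw).astype(int)
    remainder = raw - base
    short = n - base.sum()
    order = np.argsort(-remainder, kind="stable")
    base[order[:short]] += 1
    return base


def build_paper_matched_session(
    preset_name: str,
    seed: int,
    cfg: AnalysisConfig | None = None,
    **overrides,
) -> SessionBundle:
    """Generate a SessionBundle (with GroundTruth) for a named preset.

    ``overrides`` replace preset fields (e.g. ``n_units=100``).  The same
    (preset, seed) pair always yields an identical bundle.
    """
    if preset_name not in PRESETS:
        raise ValueError(
            f"unknown preset {preset_name!r}; available: {sorted(PRESETS)}"
        )
    from dataclasses import replace

    preset = replace(PRESETS[preset_name], **overrides)
    cfg = cfg or AnalysisConfig()
    ss = np.random.SeedSequence(seed)
    keys = ss.spawn(5 + preset.n_units)
    rng_loco, rng_pop, rng_emg, rng_vib, rng_audio = (
        np.random.default_rng(k) for k in keys[:5]
    )
    signals: dict[str, ContinuousSignal] = {}
    truth = GroundTruth(seed=seed)

    if preset.with_audio:
        step_gap = 0.35
        times = 5.0 + np.arange(preset.n_footsteps) * step_gap + rng_audio.uniform(
            -0.05, 0.05, preset.n_footsteps
        )
        audio, a_truth = simulate_audio(
            times, preset.footstep_spl_db, preset.ref_tone_spl_db, rng_audio,
            duration=preset.duration,
        )
        signals["audio"] = audio
        truth.footstep_times = a_truth.footstep_times
        truth.footstep_spl_db = preset.footstep_spl_db
        truth.ref_tone_spl_db = preset.ref_tone_spl_db
        truth.tone_interval = a_truth.tone_interval
        truth.quiet_interval = a_truth.quiet_interval
        meta = {
            "deaf": True, "mouse_id": "synthetic", "seed": seed, "preset": preset.name,
            "audio": {
                "tone_interval": list(a_truth.tone_interval),
                "quiet_interval": list(a_truth.quiet_interval),
                "tone_spl_db": preset.ref_tone_spl_db,
                "tone_freq": 4000.0,
            },
        }
        return SessionBundle(signals=signals, units=[], meta=meta, truth=truth)

    sensor, speed, bouts = simulate_locomotion(
        preset.duration, preset.n_bouts, rng_loco, min_rest=preset.min_rest
    )
    signals["treadmill_sensor"] = sensor
    signals["speed"] = speed
    truth.bouts = bouts

    # population composition by largest remainder so printed percentages
    # are realized exactly at the preset n
    counts = largest_remainder_counts(preset.n_units, preset.fractions)
    directions = (
        [INCREASED] * counts[0] + [DECREASED] * counts[1] + [NS] * counts[2]
    )
    rng_pop.shuffle(directions)
    units: list[SpikeTrain] = []
    for i, direction in enumerate(directions):
        rng_u = np.random.default_rng(keys[5 + i])
        if preset.base_rate_uniform is not None:
            base = rng_u.uniform(*preset.base_rate_uniform)
        else:
            med, sigma = preset.base_rate_lognorm
            base = float(np.clip(
                np.exp(rng_u.normal(np.log(med), sigma)), *preset.base_rate_bounds
            ))
        if direction == INCREASED:
            gain = rng_u.uniform(*preset.gain_increased)
            lead = rng_u.normal(*preset.lead_increased)
        elif direction == DECREASED:
            gain = rng_u.uniform(*preset.gain_decreased)
            lead = rng_u.normal(*preset.lead_decreased)
        else:
            gain, lead = 1.0, 0.0
        uid = f"u{i:03d}"
        units.append(
            simulate_unit(bouts, direction, gain, lead, base, preset.duration, rng_u, uid)
        )
        truth.units.append(UnitTruth(uid, direction, gain, lead, base))

    if preset.with_emg:
        med, sd = preset.emg_delay
        delays = rng_emg.normal(med, sd, len(bouts))
        noise_sd = 0.1
        signals["emg"] = simulate_emg(
            bouts, delays, preset.duration, rng_emg,
            noise_sd=noise_sd, burst_amp=noise_sd * preset.emg_snr,
        )
        truth.emg_delays = delays.tolist()

    if preset.with_vibration:
        smooth_speed = ContinuousSignal(
            np.clip(speed.samples, 0.0, None), speed.rate, units="cm/s"
        )
        vib, used_sd = simulate_vibration(
            smooth_speed, preset.vib_coupling, rng_vib, target_r=preset.vib_target_r
        )
        signals["vibration"] = vib
        truth.vib_coupling = preset.vib_coupling
        truth.vib_noise_sd = used_sd

    meta = {"deaf": True, "mouse_id": "synthetic", "seed": seed, "preset": preset.name}
    return SessionBundle(signals=signals, units=units, meta=meta, truth=truth)
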