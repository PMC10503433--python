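"""Synthetic basket-electrogram generator with known ground truth.

Emulates the rhythm classes an electrographic-flow mapper must distinguish:

* ``planar_sr``      — sinus-rhythm-like centrifugal waves from a fixed focal
                       origin (the sinoatrial-node analog), slow rate.
* ``focal_paced``    — a repetitive focal driver (pacing with local capture) at
                       short cycle length, on top of an overdriven fibrillatory
                       background.
* ``fibrillatory``   — background AF: several short-lived, meandering focal
                       wavelet emitters with finite propagation radius; an
                       optional designated source gated by a per-segment
                       activity schedule.
* ``subthreshold_artifact`` — a narrow stimulus spike on the single channel
                       nearest the pacing site, with NO propagated deflections,
                       over a fibrillatory (or planar/quiescent) background.
* ``quiescent``      — far-field QRST and noise only.

Every unipolar trace is a superposition of biphasic atrial deflection
templates placed at activation times ``t0 + dist(electrode, origin)/cv``,
a far-field ventricular QRST template at its own rate (the ventricularly
paced rhythm), and white noise.  Low-contact electrodes have their
near-field (atrial) component attenuated; the far field is untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import BasketGeometry, GridLocation, label_to_grid, wave_distance
from .recording import EGMRecording, PacingEvent

__all__ = [
    "WaveScenario",
    "GroundTruth",
    "FWaveParams",
    "simulate",
    "preset",
    "simulate_bipolar_fwave",
]

SCENARIO_KINDS = (
    "planar_sr",
    "focal_paced",
    "fibrillatory",
    "subthreshold_artifact",
    "quiescent",
)

# Condition defaults (see docs/methods.md for rationale).
DEFAULT_FS_HZ = 1000.0
DEFAULT_CV = 30.0              # grid units / s
DEFLECTION_WIDTH_MS = 20.0
ATRIAL_P2P_MV = 1.0
QRST_P2P_MV = 0.4
QRST_RATE_BPM = 90.0           # VVI-paced ventricle analog
STIM_ARTIFACT_MV = 2.0
STIM_ARTIFACT_MS = 3.0
EMITTER_SPAWN_RATE_HZ = 1.5    # fibrillatory wavelet emitters per second
EMITTER_LIFETIME_S = 2.0       # mean exponential lifetime
EMITTER_CL_MS = (180.0, 20.0)  # mean, sd of per-emitter cycle length
EMITTER_RADIUS_RANGE = (2.0, 5.0)  # finite propagation radius, grid units
OVERDRIVE_SUPPRESSION = 0.5    # emitter-rate factor while capture pacing


@dataclass(frozen=True)
class WaveScenario:
    """Full description of one simulated rhythm condition."""

    kind: str
    origin: GridLocation | None = None
    conduction_velocity: float = DEFAULT_CV
    cycle_length_ms: float | None = None
    activity_schedule: tuple[float, ...] | None = None  # per-2-s segment, in [0,1]
    noise_sd: float = 0.05
    qrst_rate_bpm: float = QRST_RATE_BPM
    qrst_amplitude_mv: float = QRST_P2P_MV
    atrial_amplitude_mv: float = ATRIAL_P2P_MV
    low_contact_channels: tuple[tuple[str, float], ...] = ()  # (label, attenuation)
    background: str = "fibrillatory"  # for subthreshold_artifact scenarios
    background_origin: GridLocation | None = None  # planar background wave origin
    # optional second persistent driver (e.g. a spontaneous AF source mapped
    # while pacing elsewhere); colliding wavefronts partition the grid
    secondary_origin: GridLocation | None = None
    secondary_cycle_length_ms: float = 110.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind in ("planar_sr", "focal_paced", "subthreshold_artifact"):
            if self.origin is None:
                raise ValueError(f"{self.kind} scenario requires an origin")
        cl = self.effective_cycle_length_ms
        if self.kind != "quiescent" and cl <= 0:
            raise ValueError("cycle_length must be positive")
        if self.kind in ("planar_sr", "focal_paced") and cl < DEFLECTION_WIDTH_MS:
            raise ValueError(
                f"cycle length {cl} ms shorter than the {DEFLECTION_WIDTH_MS} ms "
                "deflection template"
            )
        if self.conduction_velocity <= 0:
            raise ValueError("conduction velocity must be positive")
        if self.activity_schedule is not None:
            sched = np.asarray(self.activity_schedule, dtype=float)
            if np.any((sched < 0) | (sched > 1)):
                raise ValueError("activity_schedule fractions must lie in [0,1]")

    @property
    def effective_cycle_length_ms(self) -> float:
        if self.cycle_length_ms is not None:
            return self.cycle_length_ms
        return {"planar_sr": 1000.0}.get(self.kind, 100.0)  # SR 60 bpm; pacing 100 ms


@dataclass
class GroundTruth:
    """What the generator actually put into a recording."""

    true_source_location: GridLocation | None
    segment_activity: np.ndarray  # per-2-s-segment true activity fraction in [0,1]
    near_far_ratio: dict[str, float] = field(default_factory=dict)
    emitter_log: list[tuple[float, float, float]] = field(default_factory=list)
    # (spawn time, row, col) of each background emitter


# ---------------------------------------------------------------------------
# waveform templates


def _deflection_template(fs: float, width_ms: float, p2p_mv: float) -> np.ndarray:
    """Biphasic RS-like atrial deflection: small positive then dominant negative lobe."""
    n = max(int(round(width_ms * fs / 1000.0)), 4)
    x = np.linspace(0.0, 1.0, n, endpoint=False)
    shape = 0.55 * np.exp(-((x - 0.32) ** 2) / (2 * 0.11**2)) - 0.95 * np.exp(
        -((x - 0.62) ** 2) / (2 * 0.14**2)
    )
    shape -= shape.mean()  # no DC step
    return shape * (p2p_mv / np.ptp(shape))


def _qrst_template(fs: float, p2p_mv: float) -> np.ndarray:
    """Far-field ventricular complex: sharp biphasic QRS plus a slow T wave."""
    n = int(round(0.32 * fs))
    t = np.arange(n) / fs
    qrs = 0.9 * np.exp(-((t - 0.035) ** 2) / (2 * 0.010**2)) - 0.6 * np.exp(
        -((t - 0.055) ** 2) / (2 * 0.012**2)
    )
    twave = 0.35 * np.exp(-((t - 0.22) ** 2) / (2 * 0.040**2))
    shape = qrs + twave
    shape -= shape.mean()
    return shape * (p2p_mv / np.ptp(shape))


def _stim_template(fs: float) -> np.ndarray:
    """Narrow biphasic stimulus artifact (non-propagating)."""
    n = max(int(round(STIM_ARTIFACT_MS * fs / 1000.0)), 3)
    x = np.linspace(0, 1, n, endpoint=False)
    shape = np.sin(2 * np.pi * x)
    return shape * (STIM_ARTIFACT_MV / max(np.ptp(shape), 1e-12))


def _add_template(trace: np.ndarray, template: np.ndarray, start: int) -> None:
    """Add ``template`` into ``trace`` beginning at sample ``start`` (clipped)."""
    n = trace.shape[0]
    if start >= n or start + template.shape[0] <= 0:
        return
    a = max(start, 0)
    b = min(start + template.shape[0], n)
    trace[a:b] += template[a - start : b - start]


# ---------------------------------------------------------------------------
# activation scheduling


def _electrode_positions(geometry: BasketGeometry) -> np.ndarray:
    """(64, 2) array of (row, col) electrode positions in label order."""
    return np.array(
        [label_to_grid(lab).position for lab in geometry.channel_labels], dtype=float
    )


def _spread_wave(
    near: np.ndarray,
    template: np.ndarray,
    t0: float,
    origin_pos: tuple[float, float],
    cv: float,
    fs: float,
    positions: np.ndarray,
    geometry: BasketGeometry,
    radius: float = np.inf,
    gain: float = 1.0,
    rival_pos: tuple[float, float] | None = None,
) -> None:
    """Place one propagated activation on every electrode within ``radius``.

    With a ``rival_pos`` (a competing persistent driver), the wavefront only
    reaches electrodes closer to its own origin — colliding wavefronts
    annihilate roughly midway between the two drivers.
    """
    for ch, pos in enumerate(positions):
        d = wave_distance(tuple(pos), origin_pos, geometry)
        if d > radius:
            continue
        if rival_pos is not None and d > wave_distance(tuple(pos), rival_pos, geometry) + 0.5:
            continue
        t = t0 + d / cv
        _add_template(near[ch], template * gain, int(round(t * fs)))


def _segment_of(t: float) -> int:
    return int(t // 2.0)


def _schedule_gate(schedule: np.ndarray | None, t: float, n_segments: int) -> bool:
    """True when the designated source is 'on' at time t.

    A fractional schedule value f means the source is active for the first
    f x 2 s of that segment.
    """
    if schedule is None:
        return True
    seg = _segment_of(t)
    if seg >= len(schedule):
        return False
    return (t - 2.0 * seg) < 2.0 * float(schedule[seg])


# ---------------------------------------------------------------------------
# main entry point


def simulate(
    scenario: WaveScenario,
    duration: float = 60.0,
    geometry: BasketGeometry | None = None,
    fs: float = DEFAULT_FS_HZ,
) -> tuple[EGMRecording, GroundTruth]:
    """Generate a unipolar basket recording plus its ground truth.

    Deterministic given (scenario, duration, fs): all randomness flows from
    ``scenario.seed``.
    """
    if duration < 4.0:
        raise ValueError("duration must be at least 4 s")
    geometry = geometry or BasketGeometry()
    rng = np.random.default_rng(scenario.seed)
    n = int(round(duration * fs))
    positions = _electrode_positions(geometry)
    labels = geometry.channel_labels
    near = np.zeros((64, n))          # near-field (atrial) component
    far = np.zeros((64, n))           # far-field (ventricular) component
    n_segments = max(int(duration // 2.0), 1)
    cv = scenario.conduction_velocity
    cl_s = scenario.effective_cycle_length_ms / 1000.0
    deflect = _deflection_template(fs, DEFLECTION_WIDTH_MS, scenario.atrial_amplitude_mv)
    schedule = (
        np.asarray(scenario.activity_schedule, dtype=float)
        if scenario.activity_schedule is not None
        else None
    )
    truth = GroundTruth(
        true_source_location=scenario.origin
        if scenario.kind in ("planar_sr", "focal_paced", "fibrillatory")
        else None,
        segment_activity=np.zeros(n_segments),
    )
    pacing: list[PacingEvent] = []

    sec = scenario.secondary_origin
    sec_cl = scenario.secondary_cycle_length_ms / 1000.0

    def run_designated_source(origin: GridLocation, rival: GridLocation | None = None) -> None:
        t = 0.0
        while t < duration:
            if _schedule_gate(schedule, t, n_segments):
                _spread_wave(
                    near, deflect, t, origin.position, cv, fs, positions, geometry,
                    rival_pos=rival.position if rival is not None else None,
                )
                seg = _segment_of(t)
                if seg < n_segments:
                    truth.segment_activity[seg] += cl_s / 2.0
            t += cl_s

    def run_secondary_source(rival: GridLocation | None = None) -> None:
        t = 0.0
        while t < duration:
            _spread_wave(
                near, deflect, t, sec.position, cv, fs, positions, geometry,
                rival_pos=rival.position if rival is not None else None,
            )
            t += sec_cl

    def run_fibrillatory_background(rate_factor: float = 1.0) -> None:
        """Short-lived meandering wavelet emitters with finite reach."""
        rate = EMITTER_SPAWN_RATE_HZ * rate_factor
        t_spawn = rng.exponential(1.0 / rate)
        # seed a few emitters already alive at t=0
        spawn_times = [0.0] * 3
        while t_spawn < duration:
            spawn_times.append(t_spawn)
            t_spawn += rng.exponential(1.0 / rate)
        for ts in spawn_times:
            life = rng.exponential(EMITTER_LIFETIME_S)
            cl = max(rng.normal(*EMITTER_CL_MS) / 1000.0, 0.08)
            pos = np.array([rng.uniform(0, 8), rng.uniform(0, 7)])
            radius = rng.uniform(*EMITTER_RADIUS_RANGE)
            truth.emitter_log.append((ts, pos[0], pos[1]))
            t = ts
            while t < min(ts + life, duration):
                _spread_wave(
                    near, deflect, t, (pos[0] % 8.0, float(np.clip(pos[1], 0, 7))),
                    cv, fs, positions, geometry, radius=radius,
                )
                pos = pos + rng.normal(0.0, 0.2, size=2)  # meander
                t += cl

    kind = scenario.kind
    if kind == "planar_sr":
        run_designated_source(scenario.origin)
    elif kind == "focal_paced":
        run_designated_source(scenario.origin, rival=sec)
        if sec is not None:
            run_secondary_source(rival=scenario.origin)
        run_fibrillatory_background(rate_factor=OVERDRIVE_SUPPRESSION)
        pacing.append(
            PacingEvent(0.0, str(GridLocation(scenario.origin.row, scenario.origin.col)), "high")
        )
    elif kind == "fibrillatory":
        run_fibrillatory_background()
        if scenario.origin is not None:
            run_designated_source(scenario.origin, rival=sec)
        if sec is not None:
            run_secondary_source(rival=scenario.origin)
    elif kind == "subthreshold_artifact":
        if sec is not None:  # a spontaneous driver unaffected by the stimulus
            run_secondary_source()
        if scenario.background == "fibrillatory":
            run_fibrillatory_background()
        elif scenario.background == "planar_sr":
            bg_origin = scenario.background_origin or GridLocation(0, 0)
            t = 0.0
            while t < duration:
                _spread_wave(
                    near, deflect, t, bg_origin.position, cv, fs, positions, geometry
                )
                t += 1.0
        elif scenario.background != "quiescent":
            raise ValueError(f"unknown background {scenario.background!r}")
        # stimulus spike ONLY on the channel nearest the site — no propagation
        stim = _stim_template(fs)
        nearest = int(
            np.argmin(
                [wave_distance(tuple(p), scenario.origin.position, geometry) for p in positions]
            )
        )
        t = 0.0
        while t < duration:
            _add_template(near[nearest], stim, int(round(t * fs)))
            t += cl_s
        pacing.append(
            PacingEvent(0.0, str(GridLocation(scenario.origin.row, scenario.origin.col)), "subthreshold")
        )
    elif kind == "quiescent":
        pass

    # low-contact attenuation applies to the near field only
    atten = np.ones(64)
    for lab, a in scenario.low_contact_channels:
        atten[labels.index(str(lab).strip().upper())] = a
    near *= atten[:, None]

    # far-field QRST: common template, mild per-channel gain spread
    if scenario.qrst_amplitude_mv > 0 and scenario.qrst_rate_bpm > 0:
        qrst = _qrst_template(fs, scenario.qrst_amplitude_mv)
        gains = rng.uniform(0.9, 1.1, size=64)
        beat = 60.0 / scenario.qrst_rate_bpm
        v_times = np.arange(0.0, duration, beat)
        for tv in v_times:
            start = int(round(tv * fs))
            for ch in range(64):
                _add_template(far[ch], qrst * gains[ch], start)
    else:
        v_times = np.array([])

    signals = near + far
    if scenario.noise_sd > 0:
        signals = signals + rng.normal(0.0, scenario.noise_sd, size=signals.shape)

    for ch, lab in enumerate(labels):
        truth.near_far_ratio[lab] = (
            scenario.atrial_amplitude_mv * atten[ch] / scenario.qrst_amplitude_mv
            if scenario.qrst_amplitude_mv > 0
            else math.inf
        )
    if kind in ("planar_sr", "focal_paced") and schedule is None:
        truth.segment_activity[:] = np.minimum(truth.segment_activity, 1.0)
    truth.segment_activity = np.clip(truth.segment_activity, 0.0, 1.0)

    rec = EGMRecording(
        signals=signals,
        sampling_rate=fs,
        channel_labels=list(labels),
        pacing_annotations=pacing,
        ventricular_times=v_times,
        geometry=geometry,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# bipolar f-wave generator (high-resolution contact-catheter analog)


@dataclass(frozen=True)
class FWaveParams:
    """Bipolar fibrillatory-wave generator parameters.

    ``frequency`` and ``amplitude`` are the dominant frequency (Hz) and the
    f-wave amplitude (mV, as measured peak-to-peak) the generated signal is
    calibrated to; the SDs set the window-to-window spread of each.
    """

    frequency: float
    frequency_sd: float
    amplitude: float
    amplitude_sd: float
    fractionated_fraction: float = 0.25   # fraction of time in fractionated salvos
    fractionated_gain: float = 0.6
    fractionated_suppression: float = 0.5  # organized-component attenuation in salvos
    fractionated_band_hz: tuple[float, float] = (15.0, 40.0)  # CFAE-like intervals < 70 ms
    freq_control_s: float = 4.0           # correlation time of the DF wander
    noise_sd: float = 0.01


_PRESETS = {
    # per-animal AF substrates: dominant frequency and f-wave amplitude with
    # their observed window-to-window spreads
    "animal_A": FWaveParams(frequency=3.92, frequency_sd=0.21, amplitude=0.47, amplitude_sd=0.04),
    "animal_B": FWaveParams(frequency=8.4, frequency_sd=2.1, amplitude=0.27, amplitude_sd=0.03),
}


def preset(name: str) -> FWaveParams:
    """Named per-animal f-wave generator presets (``animal_A``, ``animal_B``)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


def simulate_bipolar_fwave(
    params: FWaveParams,
    duration: float = 60.0,
    seed: int = 0,
    fs: float = DEFAULT_FS_HZ,
) -> np.ndarray:
    """Quasi-periodic bipolar f-wave train, mV, at sampling rate ``fs``.

    Alternates organized epochs (near-sinusoidal activity at the preset
    frequency with phase jitter) and fractionated salvos (higher-frequency,
    lower-amplitude); the noiseless spectral peak sits at the preset frequency.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # frequency wander with ~freq_control_s correlation time, so each 4-s
    # analysis window sees roughly one frequency offset (window-to-window SD
    # tracks frequency_sd)
    n_ctrl = max(int(np.ceil(duration / params.freq_control_s)), 2)
    ctrl = rng.normal(0.0, params.frequency_sd, size=n_ctrl + 1)
    inst_f = params.frequency + np.interp(
        t, np.linspace(0, duration, n_ctrl + 1), ctrl
    )
    inst_f = np.clip(inst_f, 0.3 * params.frequency, 2.5 * params.frequency)
    phase = 2 * np.pi * np.cumsum(inst_f) / fs
    organized = np.sin(phase)

    # per-second amplitude envelope; overall scale set by calibration below
    n_env = max(int(duration), 2)
    env_ctrl = np.abs(
        rng.normal(1.0, params.amplitude_sd / max(params.amplitude, 1e-9), size=n_env + 1)
    )
    envelope = np.interp(t, np.linspace(0, duration, n_env + 1), env_ctrl)
    signal = envelope * organized

    # fractionated salvos: chaotic broadband activity (no clean spectral line)
    # superposed on an attenuated organized component — the atrium keeps
    # activating near its dominant rate during fractionation
    if params.fractionated_fraction > 0:
        lo, hi = params.fractionated_band_hz
        white = rng.normal(0.0, 1.0, size=n)
        from scipy import signal as sps

        sos = sps.butter(3, [lo, min(hi, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
        burst = sps.sosfiltfilt(sos, white)
        burst *= 0.5 / max(np.sqrt(np.mean(burst**2)), 1e-12)  # RMS of a unit sine
        frac = params.fractionated_gain * envelope * burst
        t_cursor = rng.uniform(0.0, 2.0)
        mean_on = 1.0  # s, mean fractionated salvo length
        mean_off = mean_on * (1.0 - params.fractionated_fraction) / max(
            params.fractionated_fraction, 1e-9
        )
        mask = np.zeros(n, dtype=bool)
        while t_cursor < duration:
            on = rng.exponential(mean_on)
            a, b = int(t_cursor * fs), int(min(t_cursor + on, duration) * fs)
            mask[a:b] = True
            t_cursor += on + rng.exponential(mean_off)
        signal = np.where(
            mask, (1.0 - params.fractionated_suppression) * signal + frac, signal
        )

    noise = (
        rng.normal(0.0, params.noise_sd, size=n) if params.noise_sd > 0 else 0.0
    )

    # calibrate the atrial component so the measured f-wave amplitude (median
    # 0.5-s-chunk peak-to-peak) of the composite equals params.amplitude
    scale = params.amplitude / 2.0  # starting point: sinusoid p2p = 2a
    chunk = max(int(0.5 * fs), 2)
    for _ in range(3):
        comp = scale * signal + noise
        m = (comp.size // chunk) * chunk
        if m == 0:
            break
        measured = float(np.median(np.ptp(comp[:m].reshape(-1, chunk), axis=1)))
        if measured <= 0:
            break
        scale *= params.amplitude / measured
    return scale * signal + noise
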