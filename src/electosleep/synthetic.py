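"""Ground-truth-labeled synthetic multi-region LFP + EMG recordings.

The generator emulates the statistical structure the classifier assumes, not
mouse biophysics: 2 s epochs of a 3-state (wake/NREM/REM) Markov chain, where
each state colours every region's trace with band-limited Gaussian noise
(NREM: large 1-4 Hz delta; REM: 6-12 Hz theta plus 18-26 and 42-50 Hz bands;
wake: low-amplitude mixed-frequency activity), a shared across-region
component that creates cross-region synchrony, state-dependent EMG tone
(high in wake, low in NREM, atonia in REM), multiplicative log-normal
mouse x region gains, and occasional isolated high-amplitude artifact samples.
State changes occur exactly at window boundaries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import Recording, DEFAULT_FS, WINDOW_S
from .states import DEFAULT_REGIONS, NREM, REM, STATES, UNKNOWN, WAKE, state_name


@dataclass
class StateSpectrumSpec:
    """Spectral recipe for one state.

    ``band_components`` maps region name -> list of (center_hz, bandwidth_hz,
    amplitude) band-limited noise components; use :meth:`broadcast` to apply
    one component list to every region.  ``emg_tone`` is the RMS of the
    band-limited (30-250 Hz) EMG noise while the state is active.
    """

    state: int
    band_components: dict[str, list[tuple[float, float, float]]]
    broadband_noise_sd: float = 0.3
    emg_tone: float = 1.0

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state code {self.state}")
        if self.broadband_noise_sd < 0 or self.emg_tone < 0:
            raise ValueError("noise SD and EMG tone must be >= 0")
        if not self.band_components or not any(self.band_components.values()):
            raise ValueError("each state needs at least one band component")
        for comps in self.band_components.values():
            for c, bw, a in comps:
                if a < 0 or bw <= 0:
                    raise ValueError("component amplitude >= 0 and bandwidth > 0 required")
                if c >= DEFAULT_FS / 2:
                    raise ValueError(f"band center {c} Hz is above Nyquist")

    @classmethod
    def broadcast(
        cls,
        state: int,
        components: list[tuple[float, float, float]],
        regions=DEFAULT_REGIONS,
        broadband_noise_sd: float = 0.3,
        emg_tone: float = 1.0,
    ) -> "StateSpectrumSpec":
        return cls(state, {r: list(components) for r in regions},
                   broadband_noise_sd, emg_tone)


#: default transition matrix: strong self-transitions, REM entered only from NREM
DEFAULT_TRANSITIONS = np.array(
    [
        [0.980, 0.020, 0.000],   # wake -> (wake, NREM, REM)
        [0.015, 0.975, 0.010],   # NREM
        [0.050, 0.000, 0.950],   # REM
    ]
)


@dataclass
class SyntheticCohortSpec:
    """Cohort-level generator configuration (the study conditions)."""

    n_mice: int = 9
    recording_length_s: float = 1200.0
    fs: float = DEFAULT_FS
    transition_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITIONS.copy())
    region_names: tuple[str, ...] = DEFAULT_REGIONS
    shared_component_gain: float = 0.6
    mouse_gain_sd: float = 0.2
    artifact_rate: float = 0.5          # isolated artifact samples per minute
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        tm = self.transition_matrix
        if tm.shape != (3, 3) or (tm < 0).any() or np.abs(tm.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("transition_matrix must be 3x3 row-stochastic")
        if not (0.0 <= self.shared_component_gain <= 1.0):
            raise ValueError("shared_component_gain must be in [0, 1]")

    def n_windows(self) -> int:
        return int(self.recording_length_s // WINDOW_S)

    def spec_hash(self) -> str:
        payload = json.dumps(
            {
                "n_mice": self.n_mice,
                "recording_length_s": self.recording_length_s,
                "fs": self.fs,
                "transition_matrix": self.transition_matrix.tolist(),
                "region_names": list(self.region_names),
                "shared_component_gain": self.shared_component_gain,
                "mouse_gain_sd": self.mouse_gain_sd,
                "artifact_rate": self.artifact_rate,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_state_specs(regions=DEFAULT_REGIONS) -> dict[int, StateSpectrumSpec]:
    """The default state spectra: qualitative signatures turned into numbers.

    Amplitudes are fixture parameters, not biological claims.  NREM is
    delta-dominated with low EMG tone; REM carries theta plus two higher
    bands with near-zero EMG (atonia); wake is low-amplitude mixed-frequency
    with high EMG tone.
    """
    return {
        WAKE: StateSpectrumSpec.broadcast(
            WAKE,
            [(6.0, 8.0, 0.6), (20.0, 20.0, 0.5)],
            regions, broadband_noise_sd=0.8, emg_tone=2.0,
        ),
        NREM: StateSpectrumSpec.broadcast(
            NREM,
            [(2.5, 3.0, 3.0)],
            regions, broadband_noise_sd=0.4, emg_tone=0.4,
        ),
        REM: StateSpectrumSpec.broadcast(
            REM,
            [(9.0, 6.0, 1.6), (22.0, 8.0, 0.8), (46.0, 8.0, 0.7)],
            regions, broadband_noise_sd=0.4, emg_tone=0.05,
        ),
    }


@dataclass
class GroundTruth:
    """True per-window state sequence; windows tile the recording."""

    state_sequence: np.ndarray
    window_samples: int

    def __post_init__(self) -> None:
        self.state_sequence = np.asarray(self.state_sequence, dtype=np.int64)
        if not np.isin(self.state_sequence, STATES).all():
            raise ValueError("ground-truth states must be wake/NREM/REM codes")

    def onsets(self) -> np.ndarray:
        return np.arange(len(self.state_sequence)) * self.window_samples

    def __len__(self) -> int:
        return len(self.state_sequence)


def _stationary(tm: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(tm.T)
    pi = np.abs(np.real(v[:, int(np.argmin(np.abs(w - 1)))]))
    return pi / pi.sum()


def sample_state_sequence(
    spec: SyntheticCohortSpec, n_windows: int, seed: int
) -> GroundTruth:
    """Draw a Markov state sequence; initial state from the stationary law."""
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    rng = np.random.default_rng(seed)
    tm = spec.transition_matrix
    cum = np.cumsum(tm, axis=1)
    seq = np.empty(n_windows, dtype=np.int64)
    seq[0] = rng.choice(3, p=_stationary(tm))
    u = rng.random(n_windows - 1)
    for t in range(1, n_windows):
        seq[t] = np.searchsorted(cum[seq[t - 1]], u[t - 1], side="right")
    return GroundTruth(seq, int(round(WINDOW_S * spec.fs)))


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                center: float, bandwidth: float) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise via frequency-domain shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    sigma = max(bandwidth / 2.0, 1e-6)
    shape = np.exp(-0.5 * ((f - center) / sigma) ** 2)
    x = np.fft.irfft(spec * shape, n=n)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _emg_noise(rng: np.random.Generator, n: int, fs: float,
               lo: float = 30.0, hi: float = 250.0) -> np.ndarray:
    """Unit-RMS flat band-limited (30-250 Hz) noise for the EMG channel."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def synthesize_recording(
    spec: SyntheticCohortSpec,
    state_specs: dict[int, StateSpectrumSpec],
    truth: GroundTruth,
    mouse_index: int = 0,
) -> Recording:
    """Render one mouse's multi-region + EMG recording from a state sequence.

    Within each window every region trace is the sum of (i) the active
    state's band-limited components, each a mix ``sqrt(1-g^2)*independent +
    g*shared`` of region-private and cohort-shared noise (g =
    ``shared_component_gain``, so g=0 gives independent regions and synchrony
    grows monotonically with g), (ii) broadband white noise, all scaled by a
    log-normal mouse x region gain; isolated artifact samples are injected at
    ``artifact_rate`` per minute.
    """
    for s in np.unique(truth.state_sequence):
        if int(s) not in state_specs:
            raise ValueError(f"state {state_name(int(s))} missing from state_specs")
    fs = spec.fs
    wlen = truth.window_samples
    n_windows = len(truth)
    n = n_windows * wlen
    regions = list(spec.region_names)
    R = len(regions)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1000 + mouse_index]))

    gains = np.exp(rng.normal(0.0, spec.mouse_gain_sd, size=R))
    g = spec.shared_component_gain
    g_ind = np.sqrt(max(0.0, 1.0 - g * g))

    # per-window amplitude masks per state
    state_of_sample = np.repeat(truth.state_sequence, wlen)
    signals = np.zeros((R + 1, n))
    for s, sspec in state_specs.items():
        active = state_of_sample == s
        if not active.any():
            continue
        # collect the distinct bands used by this state across regions
        bands: dict[tuple[float, float], np.ndarray] = {}
        for comps in sspec.band_components.values():
            for c, bw, _a in comps:
                bands.setdefault((c, bw), None)
        for key in bands:
            bands[key] = _band_noise(rng, n, fs, *key)       # shared trace
        for ri, reg in enumerate(regions):
            tr = np.zeros(n)
            for c, bw, a in sspec.band_components.get(reg, []):
                shared = bands[(c, bw)]
                indep = _band_noise(rng, n, fs, c, bw)
                tr += a * (g_ind * indep + g * shared)
            tr += sspec.broadband_noise_sd * rng.standard_normal(n)
            signals[ri, active] += gains[ri] * tr[active]
        # EMG: band-limited 30-250 Hz noise at the state's tone
        emg = _emg_noise(rng, n, fs)
        signals[R, active] += sspec.emg_tone * emg[active]

    # isolated artifact samples: rare, huge relative to the channel's scale
    n_art = rng.poisson(spec.artifact_rate * n / fs / 60.0, size=R)
    for ri in range(R):
        if n_art[ri] == 0:
            continue
        idx = rng.choice(n, size=n_art[ri], replace=False)
        mad = np.median(np.abs(signals[ri] - np.median(signals[ri])))
        scale = mad if mad > 0 else 1.0
        signals[ri, idx] = np.sign(rng.standard_normal(n_art[ri])) * 60.0 * scale

    channel_map = {i: reg for i, reg in enumerate(regions)}
    return Recording(
        signals=signals, fs=fs, channel_region_map=channel_map,
        emg_channel=R, subject_id=f"mouse{mouse_index:02d}",
        session_id=f"seed{spec.seed}",
    )


def generate_cohort(
    spec: SyntheticCohortSpec,
    state_specs: dict[int, StateSpectrumSpec] | None = None,
) -> list[tuple[Recording, GroundTruth]]:
    """Generate all mice of a cohort (deterministic in the spec's seed)."""
    if state_specs is None:
        state_specs = default_state_specs(spec.region_names)
    n_windows = spec.n_windows()
    out = []
    for m in range(spec.n_mice):
        truth = sample_state_sequence(
            spec, n_windows,
            seed=np.random.SeedSequence([spec.seed, m]).generate_state(1)[0] % (2**31),
        )
        rec = synthesize_recording(spec, state_specs, truth, mouse_index=m)
        out.append((rec, truth))
    return out


def write_fixture_cohort(
    spec: SyntheticCohortSpec,
    out_dir,
    state_specs: dict[int, StateSpectrumSpec] | None = None,
) -> dict:
    """Write a cohort to disk: HDF5 recordings, hypnogram CSVs, JSON manifest."""
    from . import io as esio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(spec, state_specs)
    manifest = {
        "spec_hash": spec.spec_hash(),
        "seed": spec.seed,
        "n_mice": spec.n_mice,
        "regions": list(spec.region_names),
        "files": [],
    }
    for m, (rec, truth) in enumerate(cohort):
        rec_path = out_dir / f"mouse{m:02d}.h5"
        hyp_path = out_dir / f"mouse{m:02d}_truth.csv"
        esio.write_recording(rec_path, rec)
        esio.write_truth_csv(hyp_path, truth, window_s=WINDOW_S)
        manifest["files"].append(
            {"mouse": m, "recording": rec_path.name, "hypnogram": hyp_path.name}
        )
    man_path = out_dir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
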