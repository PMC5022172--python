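"""Trial-structured surrogate EEG with known coupling ground truth.

The generative model mirrors a two-subsystem working-memory circuit: a frontal
(F) region whose source mixes a 6 Hz theta rhythm with amplitude-co-modulated
broadband background activity, and a parieto-occipital (PO) region dominated
by an upper-alpha (alpha2) rhythm.  Three coupling pathways link the driver
theta phase/activity to the PO channels, each independently switchable:

``nm_phase_locking``
    A driven alpha2 component whose phase follows twice the delayed driver
    theta phase (2:1 phase-phase coupling).  Its own phase noise is tied to
    the locking level so that the parameter moves the measured 2:1 phase
    locking monotonically.
``pac_depth``
    The whole alpha2 envelope is modulated by the cosine of the delayed
    driver theta phase (phase-to-amplitude coupling).
``coupling_strength``
    Each PO channel receives a fixed-power broadband "afferent" background
    composed of a delayed copy of the transmitted frontal signal (weight c,
    attenuated theta carrier plus the full co-modulated broadband
    background) and an independent theta-carrier process (weight
    sqrt(1-c^2), scaled to the carrier's power share).  The coupling
    strength therefore sets only the correlated fraction of the afferent
    input -- total power, theta-band power and alpha2-band content of every
    PO channel are identical across conditions by construction, so only the
    causal, lag-carrying pathway differs between presets.  The transmitted
    background is notched in the alpha2 band to keep the phase-coupling
    axes (driven alpha2 component) separable from the causal axis.

The wrong-response preset multiplies the causal coupling strength by
``wrong_strength_factor`` on all F->PO pairs and sets the coupling lag of
bilateral-F -> right-PO pairs (P6, P8, PO8, PO4, O2) to 0 ms, reproducing in
kind the zero-lag anomaly reported for failed calculations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import SensorMontage, TrialSegment

__all__ = [
    "SynthConfig",
    "SynthGroundTruth",
    "SynthDataset",
    "generate_trial",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]

#: Wrong-trial counts per workload level used as default class sizes.
DEFAULT_WRONG_COUNTS = (42, 53, 59, 62, 61)
DEFAULT_CORRECT_COUNTS = (100, 100, 100, 100, 100)


@dataclass(frozen=True)
class SynthConfig:
    """Generative parameters; defaults define the study conditions."""

    fs: float = 256.0
    montage: SensorMontage = field(default_factory=SensorMontage.default)
    theta_freq: float = 6.0
    alpha_band: tuple[float, float] = (10.0, 13.0)
    coupling_strength: float = 0.6
    coupling_lag_ms: float = 120.0
    pac_depth: float = 0.4
    nm_phase_locking: float = 0.5
    noise_exponent: float = 1.0
    snr: float = 5.0
    #: per-CWL trial duration: base + step*(cwl-1) +- jitter, in ms
    duration_base_ms: float = 2000.0
    duration_step_ms: float = 1000.0
    duration_jitter_ms: float = 500.0
    n_trials_correct: tuple[int, ...] = DEFAULT_CORRECT_COUNTS
    n_trials_wrong: tuple[int, ...] = DEFAULT_WRONG_COUNTS
    n_subjects: int = 16
    #: wrong-trial contrast: strength multiplier and right-PO zero lag
    wrong_strength_factor: float = 0.4
    wrong_zero_lag: bool = True
    #: per-level multiplicative amplitude gain of the oscillatory sources
    cwl_amplitude_gain: float = 0.1
    #: theta frequency jitter SD (Hz, white per sample)
    theta_freq_jitter: float = 1.0
    #: bandwidth of envelope fluctuations (Hz) and their relative depth
    envelope_bandwidth: float = 2.5
    envelope_depth: float = 0.5
    #: relative amplitude of the co-modulated broadband background in F
    broadband_mix: float = 0.6
    #: amplitude of the PO afferent background relative to the alpha2 rhythm
    afferent_strength: float = 1.0
    #: relative weight of the theta carrier inside the transmitted signal
    #: (transmission is predominantly broadband; keeps PO alpha2-dominant)
    carrier_transmission: float = 0.4
    #: band removed from the transmitted background (keeps alpha2 clean)
    alpha_notch: tuple[float, float] = (9.5, 13.5)
    seed: int = 0

    def __post_init__(self):
        for name in ("coupling_strength", "pac_depth", "nm_phase_locking"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.coupling_lag_ms < 0:
            raise ValueError("coupling_lag_ms must be >= 0")
        if self.duration_base_ms <= 0 or self.duration_step_ms < 0:
            raise ValueError("trial durations must be positive")
        if self.duration_jitter_ms >= self.duration_base_ms:
            raise ValueError("duration jitter exceeds base duration")
        if len(self.n_trials_correct) != 5 or len(self.n_trials_wrong) != 5:
            raise ValueError("need trial counts for the 5 workload levels")
        if self.snr <= 0:
            raise ValueError("snr must be positive")

    def duration_range_ms(self, cwl: int) -> tuple[float, float]:
        center = self.duration_base_ms + self.duration_step_ms * (cwl - 1)
        return center - self.duration_jitter_ms, center + self.duration_jitter_ms


@dataclass
class SynthGroundTruth:
    """Generative parameters of one trial, expanded per ordered F->PO pair."""

    po_labels: tuple[str, ...]
    strength: dict[str, float]
    lag_samples: dict[str, int]
    pac_depth: float
    nm_phase_locking: float
    cwl: int
    response: str
    subject: int
    duration_ms: float

    def pair_strength(self, po_label: str) -> float:
        return self.strength[po_label]

    def pair_lag_samples(self, po_label: str) -> int:
        return self.lag_samples[po_label]

    def pair_lag_ms(self, po_label: str, fs: float = 256.0) -> float:
        return 1000.0 * self.lag_samples[po_label] / fs


@dataclass
class SynthDataset:
    trials: list[TrialSegment]
    ground_truths: list[SynthGroundTruth]
    config: SynthConfig

    def __len__(self) -> int:
        return len(self.trials)

    def subset(self, cwl: int | None = None, response: str | None = None):
        pairs = [
            (t, g)
            for t, g in zip(self.trials, self.ground_truths)
            if (cwl is None or t.cwl == cwl)
            and (response is None or t.response == response)
        ]
        trials = [p[0] for p in pairs]
        gts = [p[1] for p in pairs]
        return SynthDataset(trials, gts, self.config)


def _one_over_f_noise(rng, n: int, fs: float, exponent: float) -> np.ndarray:
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _lowpass_noise(rng, n: int, fs: float, cutoff: float) -> np.ndarray:
    b = signal.firwin(min(257, (n // 3) | 1), cutoff, fs=fs)
    x = signal.filtfilt(b, [1.0], rng.standard_normal(n),
                        padlen=min(3 * len(b), n - 1))
    sd = x.std()
    return x / sd if sd > 0 else x


def _ou_noise(rng, n: int, fs: float, sd: float, tau_s: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    a = np.exp(-1.0 / (tau_s * fs))
    e = rng.standard_normal(n) * sd * np.sqrt(1.0 - a * a)
    return signal.lfilter([1.0], [1.0, -a], e)


def generate_trial(
    config: SynthConfig,
    cwl: int,
    response: str,
    rng: np.random.Generator,
    subject: int = 0,
) -> tuple[TrialSegment, SynthGroundTruth]:
    """Generate one multichannel trial plus its ground truth.

    The same :class:`numpy.random.Generator` state yields byte-identical
    samples on repeated calls.
    """
    if not 1 <= cwl <= 5:
        raise ValueError("cwl must be in 1..5")
    if response not in ("correct", "wrong"):
        raise ValueError("response must be 'correct' or 'wrong'")
    fs = config.fs
    lo, hi = config.duration_range_ms(cwl)
    duration_ms = float(rng.uniform(lo, hi))
    if duration_ms <= 0:
        raise ValueError("non-positive trial duration")
    n = int(round(duration_ms / 1000.0 * fs))
    lag = int(round(config.coupling_lag_ms / 1000.0 * fs))
    if lag >= n:
        raise ValueError(
            f"coupling lag of {lag} samples exceeds the trial length {n}"
        )
    pad = int(2 * fs) + lag
    N = n + pad
    mont = config.montage

    f_alpha = 0.5 * (config.alpha_band[0] + config.alpha_band[1])
    gain_cwl = 1.0 + config.cwl_amplitude_gain * (cwl - 1)

    # driver theta phase (white frequency jitter) and envelopes
    phi_t = np.cumsum(
        2 * np.pi * (config.theta_freq
                     + config.theta_freq_jitter * rng.standard_normal(N)) / fs
    )
    psi = np.cumsum(
        2 * np.pi * (f_alpha
                     + config.theta_freq_jitter * rng.standard_normal(N)) / fs
    )
    A_t = np.clip(
        1.0 + config.envelope_depth * _lowpass_noise(rng, N, fs, config.envelope_bandwidth),
        0.05, None,
    )
    A_a0 = np.clip(
        1.0 + config.envelope_depth * _lowpass_noise(rng, N, fs, config.envelope_bandwidth),
        0.05, None,
    )
    def notched_background(w: np.ndarray) -> np.ndarray:
        b_bp = signal.firwin(257, [2.0, min(45.0, fs / 2 - 5)],
                             pass_zero=False, fs=fs)
        b_notch = signal.firwin(257, list(config.alpha_notch),
                                pass_zero="bandstop", fs=fs)
        out = signal.filtfilt(b_bp, [1.0], w, padlen=min(771, N - 1))
        out = signal.filtfilt(b_notch, [1.0], out, padlen=min(771, N - 1))
        return out / out.std()

    xi = notched_background(rng.standard_normal(N))
    S_F = A_t * (np.cos(phi_t) + config.broadband_mix * xi)
    S_F_std = S_F.std()
    # transmitted version of the frontal source: same broadband content and
    # envelope, attenuated theta carrier
    S_T = A_t * (config.carrier_transmission * np.cos(phi_t)
                 + config.broadband_mix * xi)
    S_T_std = S_T.std()

    # independent theta-carrier process complementing the transmitted copy:
    # scaled so the PO theta-band power is invariant to the coupling strength
    # (the copy's broadband remainder lies outside every measured band)
    phi_ind = np.cumsum(
        2 * np.pi * (config.theta_freq
                     + config.theta_freq_jitter * rng.standard_normal(N)) / fs
    )
    A_ind = np.clip(
        1.0 + config.envelope_depth * _lowpass_noise(rng, N, fs, config.envelope_bandwidth),
        0.05, None,
    )
    S_ind = A_ind * np.cos(phi_ind)
    carrier_share = (config.carrier_transmission * A_t * np.cos(phi_t)).var() / S_T.var()
    S_ind = S_ind / S_ind.std() * np.sqrt(carrier_share)

    lam = config.nm_phase_locking
    # locking-level-dependent phase noise of the driven alpha2 component:
    # E[exp(i eta)] = lam (capped), so the measured 2:1 locking tracks the
    # parameter; the noise also keeps the driven rhythm from being long-range
    # predictable from the driver, which would flatten the TE delay curve
    sig_eta = min(np.sqrt(-2.0 * np.log(lam)), 1.2) if 0 < lam < 1 else 0.0
    eta = _ou_noise(rng, N, fs, sig_eta, 0.15)
    gamma = rng.uniform(0, 2 * np.pi)

    c = config.coupling_strength
    if response == "wrong":
        c = c * config.wrong_strength_factor

    idx = np.arange(pad, N)
    intrinsic = A_a0[idx] * np.cos(psi[idx])

    # per-PO-channel lag: zero for right-PO channels in wrong trials
    po_lags: dict[str, int] = {}
    for i in mont.po_indices:
        label = mont.labels[i]
        zero = (
            response == "wrong"
            and config.wrong_zero_lag
            and mont.hemispheres[i] == "right"
        )
        po_lags[label] = 0 if zero else lag

    cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    # phase-phase and phase-amplitude pathways always use the nominal lag;
    # the zero-lag anomaly is a property of the causal transmission pathway
    # only, so the alpha2-band generative law is identical across presets
    d_nom = idx - lag
    pac_mod = 1.0 + config.pac_depth * np.cos(phi_t[d_nom])
    locked = A_a0[idx] * np.cos(2 * phi_t[d_nom] + gamma + eta[idx])

    inj_cache: dict[int, np.ndarray] = {}

    def injected_copy(L: int) -> np.ndarray:
        if L not in inj_cache:
            inj_cache[L] = S_T[idx - L] / S_T_std
        return inj_cache[L]

    norm_lam = np.sqrt((1 - lam) ** 2 + lam ** 2)
    channels = np.empty((len(mont), n))
    for ch, label in enumerate(mont.labels):
        gain = rng.uniform(0.8, 1.2) * gain_cwl
        if mont.regions[ch] == "F":
            sig = gain * S_F[idx]
        else:
            # the whole alpha2 envelope is modulated by the delayed theta phase
            alpha_osc = pac_mod * ((1 - lam) * intrinsic + lam * locked) / norm_lam
            a_std = alpha_osc.std()
            afferent = (
                c * injected_copy(po_lags[label])
                + np.sqrt(1.0 - c * c) * S_ind[idx]
            )
            sig = gain * a_std * (
                alpha_osc / a_std + config.afferent_strength * afferent
            )
        noise = _one_over_f_noise(rng, n, fs, config.noise_exponent)
        channels[ch] = sig + noise * (sig.std() / np.sqrt(config.snr))

    trial = TrialSegment(
        samples=channels,
        fs=fs,
        subject=subject,
        cwl=cwl,
        response=response,
        labels=mont.labels,
    )
    po_labels = tuple(mont.labels[i] for i in mont.po_indices)
    truth = SynthGroundTruth(
        po_labels=po_labels,
        strength={l: c for l in po_labels},
        lag_samples={l: po_lags[l] for l in po_labels},
        pac_depth=config.pac_depth,
        nm_phase_locking=lam,
        cwl=cwl,
        response=response,
        subject=subject,
        duration_ms=1000.0 * n / fs,
    )
    return trial, truth


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Generate the full 5 CWL x {correct, wrong} dataset.

    Default class sizes reproduce the study's wrong-trial counts per level
    (42/53/59/62/61, 277 in total) alongside a larger correct-trial count;
    subjects are assigned cyclically.
    """
    rng = np.random.default_rng(config.seed)
    trials: list[TrialSegment] = []
    truths: list[SynthGroundTruth] = []
    subject = 0
    for cwl in range(1, 6):
        for response, counts in (
            ("correct", config.n_trials_correct),
            ("wrong", config.n_trials_wrong),
        ):
            for _ in range(counts[cwl - 1]):
                t, g = generate_trial(config, cwl, response, rng,
                                      subject=subject % config.n_subjects)
                trials.append(t)
                truths.append(g)
                subject += 1
    return SynthDataset(trials, truths, config)


def _config_to_dict(config: SynthConfig) -> dict:
    d = dataclasses.asdict(config)
    d["montage"] = {
        "labels": list(config.montage.labels),
        "regions": list(config.montage.regions),
        "hemispheres": list(config.montage.hemispheres),
    }
    return d


def _config_from_dict(d: dict) -> SynthConfig:
    d = dict(d)
    m = d.pop("montage")
    montage = SensorMontage(
        labels=tuple(m["labels"]),
        regions=tuple(m["regions"]),
        hemispheres=tuple(m["hemispheres"]),
    )
    for key in ("alpha_band", "n_trials_correct", "n_trials_wrong"):
        d[key] = tuple(d[key])
    return SynthConfig(montage=montage, **d)


def save_dataset(dataset: SynthDataset, path: str | Path) -> None:
    """Write trials (array container), manifest (TSV) and ground truth (JSON)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {f"trial_{i:04d}": t.samples for i, t in enumerate(dataset.trials)}
    np.savez_compressed(path / "trials.npz", **arrays)
    manifest = pd.DataFrame(
        {
            "trial": np.arange(len(dataset.trials)),
            "subject": [t.subject for t in dataset.trials],
            "cwl": [t.cwl for t in dataset.trials],
            "response": [t.response for t in dataset.trials],
            "duration_ms": [t.duration_ms for t in dataset.trials],
        }
    )
    manifest.to_csv(path / "manifest.tsv", sep="\t", index=False)
    gt = [dataclasses.asdict(g) for g in dataset.ground_truths]
    with open(path / "ground_truth.json", "w") as fh:
        json.dump(gt, fh)
    with open(path / "config.json", "w") as fh:
        json.dump(_config_to_dict(dataset.config), fh, indent=2)


def load_dataset(path: str | Path) -> SynthDataset:
    path = Path(path)
    with open(path / "config.json") as fh:
        config = _config_from_dict(json.load(fh))
    with open(path / "ground_truth.json") as fh:
        gt_dicts = json.load(fh)
    manifest = pd.read_csv(path / "manifest.tsv", sep="\t")
    npz = np.load(path / "trials.npz")
    trials, truths = [], []
    for i, row in manifest.iterrows():
        trials.append(
            TrialSegment(
                samples=npz[f"trial_{i:04d}"],
                fs=config.fs,
                subject=int(row.subject),
                cwl=int(row.cwl),
                response=str(row.response),
                labels=config.montage.labels,
            )
        )
        g = gt_dicts[i]
        truths.append(
            SynthGroundTruth(
                po_labels=tuple(g["po_labels"]),
                strength={k: float(v) for k, v in g["strength"].items()},
                lag_samples={k: int(v) for k, v in g["lag_samples"].items()},
                pac_depth=g["pac_depth"],
                nm_phase_locking=g["nm_phase_locking"],
                cwl=int(g["cwl"]),
                response=g["response"],
                subject=int(g["subject"]),
                duration_ms=float(g["duration_ms"]),
            )
        )
    return SynthDataset(trials, truths, config)
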