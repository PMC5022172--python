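"""Within- and cross-frequency phase synchronization with Rayleigh filtering.

The phase locking value (PLV) between two sensors is the modulus of the
complex mean of their instantaneous phase difference, averaged jointly over
time samples and wavelet scales::

    PLV = | (1 / (W * Ds)) sum_t sum_s exp(i (phi_k(s, t) - phi_l(s, t))) |

The 2:1 cross-frequency variant replaces the difference with
``2 * phi_theta - phi_alpha2``, locking two theta cycles to one alpha2 cycle.
Edge significance is assessed with the Rayleigh test for circular uniformity,
using an effective sample count corrected for phase oversampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import (
    ALPHA2_BAND,
    THETA_BAND,
    AnalyticRepresentation,
    BandDefinition,
    SensorMontage,
    TrialSegment,
    morlet_phase,
)

__all__ = [
    "ConnectivityGraph",
    "SubgraphStrength",
    "plv",
    "nm_plv",
    "rayleigh_significance",
    "effective_sample_count",
    "build_fcg",
    "subgraph_strength",
]


@dataclass
class ConnectivityGraph:
    """Sensor x sensor weights from one estimator, with a significance mask."""

    weights: np.ndarray
    mask: np.ndarray
    estimator: str
    directed: bool
    labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.weights.shape != self.mask.shape:
            raise ValueError("mask shape must equal weight shape")
        if self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights must be square")

    @property
    def masked_weights(self) -> np.ndarray:
        return np.where(self.mask, self.weights, 0.0)


@dataclass
class SubgraphStrength:
    region: str
    strength: float
    estimator: str


def _stack_phases(phase: np.ndarray) -> np.ndarray:
    phase = np.asarray(phase)
    if phase.ndim == 1:
        phase = phase[np.newaxis, :]
    elif phase.ndim != 2:
        raise ValueError("phase must be 1-D (samples) or 2-D (scales x samples)")
    return phase


def plv(phase_k: np.ndarray, phase_l: np.ndarray) -> float:
    """Phase locking value in [0, 1].

    Inputs are instantaneous phases, either 1-D (samples) or 2-D
    (scales x samples).  The scale average happens inside the complex mean,
    not as an average of per-scale PLVs.
    """
    a = _stack_phases(phase_k)
    b = _stack_phases(phase_l)
    if a.shape != b.shape:
        raise ValueError(f"phase shape mismatch: {a.shape} vs {b.shape}")
    return float(np.abs(np.mean(np.exp(1j * (a - b)))))


def nm_plv(
    theta_phase: np.ndarray,
    alpha_phase: np.ndarray,
    n: int = 2,
    m: int = 1,
) -> float:
    """n:m cross-frequency phase locking (default 2:1 theta:alpha2).

    The argument roles are ordered: the first series is the slow (theta)
    phase multiplied by ``n``, the second the fast (alpha2) phase multiplied
    by ``m``.  Scale grids of the two bands may differ; the complex mean then
    runs over the Cartesian product of scale pairs.
    """
    a = _stack_phases(theta_phase)
    b = _stack_phases(alpha_phase)
    if a.shape[-1] != b.shape[-1]:
        raise ValueError(
            f"length mismatch: {a.shape[-1]} vs {b.shape[-1]} samples"
        )
    diff = n * a[:, np.newaxis, :] - m * b[np.newaxis, :, :]
    return float(np.abs(np.mean(np.exp(1j * diff))))


def rayleigh_significance(plv_value: float, n_effective: float) -> float:
    """Rayleigh-test p-value for a PLV at ``n_effective`` independent samples.

    Uses Z = n * PLV**2 with the standard finite-n correction; smaller PLV
    gives a larger p at fixed n.  For ``n_effective`` < 8 the approximation is
    unreliable: a warning is issued and p = 1 returned.
    """
    if not 0.0 <= plv_value <= 1.0 + 1e-12:
        raise ValueError("plv_value outside [0, 1]")
    if n_effective < 8:
        warnings.warn("n_effective < 8: Rayleigh approximation unreliable; p=1")
        return 1.0
    n = float(n_effective)
    r_abs = n * plv_value
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - r_abs * r_abs)) - (1.0 + 2.0 * n))
    return float(min(max(p, 0.0), 1.0))


def effective_sample_count(
    n_samples: int, band: BandDefinition, fs: float
) -> float:
    """Independent phase samples in a trial of ``n_samples``.

    Phases sampled at ``fs`` are oversampled relative to the band dynamics;
    the decimation factor fs / (2 * band.high) (two samples per fastest cycle)
    avoids inflating Rayleigh significance.
    """
    return n_samples / (fs / (2.0 * band.high))


def build_fcg(
    trial: TrialSegment,
    montage: SensorMontage,
    theta_band: BandDefinition = THETA_BAND,
    alpha_band: BandDefinition = ALPHA2_BAND,
    alpha: float = 0.05,
    theta_rep: AnalyticRepresentation | None = None,
    alpha_rep: AnalyticRepresentation | None = None,
    mask_correction: str = "per_edge",
) -> ConnectivityGraph:
    """Block-structured functional connectivity graph of one trial.

    F x F edges carry theta-band PLV, PO x PO edges alpha2-band PLV, and the
    F x PO cross block the 2:1 cross-frequency PLV (theta role from the F
    sensor, alpha2 role from the PO sensor).  The mask keeps edges whose
    Rayleigh p-value passes at level ``alpha``, either uncorrected per edge
    (``mask_correction='per_edge'``) or after a Benjamini-Hochberg step-up
    across the graph's edges (``'fdr_per_graph'``).  Precomputed analytic
    representations may be passed to avoid repeated wavelet transforms.
    """
    if mask_correction not in ("per_edge", "fdr_per_graph"):
        raise ValueError("mask_correction must be 'per_edge' or 'fdr_per_graph'")
    if len(montage) != trial.n_channels:
        raise ValueError("montage size must equal trial channel count")
    if theta_rep is None:
        theta_rep = morlet_phase(trial, theta_band)
    if alpha_rep is None:
        alpha_rep = morlet_phase(trial, alpha_band)
    valid = theta_rep.valid & alpha_rep.valid
    if not valid.any():
        valid = np.ones(trial.width, dtype=bool)
    th = theta_rep.phase[..., valid]
    al = alpha_rep.phase[..., valid]
    n_valid = int(valid.sum())

    n_ch = trial.n_channels
    W = np.zeros((n_ch, n_ch))
    P = np.ones((n_ch, n_ch))
    f_idx = montage.f_indices
    po_idx = montage.po_indices

    n_eff_th = effective_sample_count(n_valid, theta_band, trial.fs)
    n_eff_al = effective_sample_count(n_valid, alpha_band, trial.fs)
    n_eff_cross = min(n_eff_th, n_eff_al)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ii, i in enumerate(f_idx):
            for j in f_idx[ii + 1:]:
                v = plv(th[i], th[j])
                W[i, j] = W[j, i] = v
                P[i, j] = P[j, i] = rayleigh_significance(v, n_eff_th)
        for ii, i in enumerate(po_idx):
            for j in po_idx[ii + 1:]:
                v = plv(al[i], al[j])
                W[i, j] = W[j, i] = v
                P[i, j] = P[j, i] = rayleigh_significance(v, n_eff_al)
        for i in f_idx:
            for j in po_idx:
                v = nm_plv(th[i], al[j])
                W[i, j] = W[j, i] = v
                P[i, j] = P[j, i] = rayleigh_significance(v, n_eff_cross)

    if mask_correction == "fdr_per_graph":
        from .stats import fdr_bh

        # every off-diagonal pair carries exactly one estimator (the regions
        # partition the montage), so the correction runs over all edges once
        iu = np.triu_indices(n_ch, k=1)
        reject, _ = fdr_bh(P[iu], q=alpha)
        mask = np.zeros_like(P, dtype=bool)
        mask[iu] = reject
        mask |= mask.T
    else:
        mask = P < alpha
    return ConnectivityGraph(
        weights=W,
        mask=mask,
        estimator="plv_fcg",
        directed=False,
        labels=montage.labels,
        meta={"alpha": alpha, "mask_correction": mask_correction,
              "cwl": trial.cwl, "response": trial.response,
              "subject": trial.subject},
    )


def subgraph_strength(
    graph: ConnectivityGraph,
    montage: SensorMontage,
    region: str,
) -> SubgraphStrength:
    """Total significant edge weight over a region's edge set.

    ``region`` is ``'F'`` or ``'PO'`` (within-region, each undirected edge
    counted once) or ``'FxPO'`` (the cross block).
    """
    mw = graph.masked_weights
    if region == "F":
        idx = montage.f_indices
        total = sum(
            mw[i, j] for a, i in enumerate(idx) for j in idx[a + 1:]
        )
    elif region == "PO":
        idx = montage.po_indices
        total = sum(
            mw[i, j] for a, i in enumerate(idx) for j in idx[a + 1:]
        )
    elif region == "FxPO":
        total = float(mw[np.ix_(montage.f_indices, montage.po_indices)].sum())
    else:
        raise ValueError(f"unknown region {region!r}; use 'F', 'PO' or 'FxPO'")
    return SubgraphStrength(region=region, strength=float(total),
                            estimator=graph.estimator)
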