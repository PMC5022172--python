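"""Directed and effective connectivity: dPLI, PAC, delayed symbolic transfer
entropy (dSTE) and amplitude-envelope cross-correlation lag.

dSTE estimates the strength, net direction and delay of coupling between two
band-limited neural time series.  Both series are reduced to symbol sequences
(ordinal patterns or neural-gas vector quantization of embedded increment
vectors) and the transfer entropy

    STE_{X->Y}(d) = I( Y_{t+d} ; X_t | Y_past )

is scanned over a grid of candidate delays d.  The scan conditions on the
target symbol one embedding span behind the predicted symbol
(``Y_past = Y_{t+d-m*tau}``), which treats every delay on the grid --
including d = 0 -- identically and conditions away the slow, narrowband
self-predictability of oscillatory signals; the raw single-delay
:func:`ste` keeps the textbook conditioning on ``Y_t``.  The argmax of the
forward curve gives the coupling delay (ties resolved toward the smallest
delay), and the sign of ``delta dSTE = STE_fwd(d*) - STE_rev(d*)`` gives the
net direction.  Significance comes from circular time-shift surrogates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .preprocess import bandpass_filter

__all__ = [
    "CausalEstimate",
    "SymbolSequence",
    "PacEstimate",
    "dpli",
    "pac",
    "symbolize",
    "symbolize_channels",
    "ste",
    "dste_scan",
    "dste_scan_symbols",
    "envelope_xcorr_lag",
    "envelope_series",
    "wrap_phase",
]

#: conditioning gap of the delay scan, in multiples of the embedding span
_SCAN_GAP_EXTRA = 2


def _filter_halfwidth_for(fs: float, n: int, transition: float = 1.0) -> int:
    numtaps = int(np.ceil(3.3 * fs / transition)) | 1
    numtaps = min(numtaps, max(((n - 1) // 3) | 1, 5))
    return numtaps // 2


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phases to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(phi)))


def dpli(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Directed phase lag index: mean Heaviside of the wrapped phase difference.

    H(0) = 0.5, which keeps the antisymmetry dPLI(A,B) + dPLI(B,A) = 1 exact.
    Values above 0.5 mean the first signal consistently leads in phase.
    """
    a = np.asarray(phase_a, dtype=float).ravel()
    b = np.asarray(phase_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    d = wrap_phase(a - b)
    h = np.where(d > 0, 1.0, np.where(d < 0, 0.0, 0.5))
    return float(h.mean())


@dataclass
class PacEstimate:
    """Phase-to-amplitude coupling strength with optional surrogate p-value."""

    value: float
    p_value: float | None = None


def pac(
    lf_phase: np.ndarray,
    hf_amplitude: np.ndarray,
    fs: float,
    lf_band: tuple[float, float] = (5.0, 6.0),
    n_surrogates: int = 0,
    rng: np.random.Generator | None = None,
    min_shift_s: float = 1.0,
) -> PacEstimate:
    """Phase-to-amplitude coupling of a slow phase onto a fast envelope.

    The fast oscillation's envelope ``hf_amplitude`` is band-pass filtered
    within the slow band, its Hilbert phase extracted, and the PLV between
    that phase and ``lf_phase`` taken as the coupling index.  Surrogates
    circularly shift the raw envelope (by at least ``min_shift_s`` seconds)
    *before* the slow-band filtering, so observed and surrogate values share
    identical filter-edge processing; the p-value is one-sided empirical.
    """
    from .coupling import plv

    lf_phase = np.asarray(lf_phase, dtype=float).ravel()
    amp = np.asarray(hf_amplitude, dtype=float).ravel()
    if lf_phase.shape != amp.shape:
        raise ValueError("lf phase and hf amplitude must have equal length")

    def modulation_phase(a: np.ndarray) -> np.ndarray:
        filtered = bandpass_filter(a - a.mean(), lf_band[0], lf_band[1], fs)
        return np.angle(sp_signal.hilbert(filtered))

    value = plv(lf_phase, modulation_phase(amp))
    p = None
    if n_surrogates > 0:
        rng = rng or np.random.default_rng(0)
        n = len(amp)
        min_shift = min(int(min_shift_s * fs), max(n // 4, 1))
        # the circular shift leaves a filter transient at the wrap point;
        # masking its neighbourhood keeps the surrogate PLVs comparable to
        # the (transient-free) observed value
        half_filter = _filter_halfwidth_for(fs, n)
        count = 0
        for _ in range(n_surrogates):
            shift = int(rng.integers(min_shift, n - min_shift)) if n > 2 * min_shift else int(rng.integers(1, n))
            phi_s = modulation_phase(np.roll(amp, shift))
            wrap = n - shift
            keep = np.abs(np.arange(n) - wrap) > half_filter
            if not keep.any():
                keep = np.ones(n, dtype=bool)
            if plv(lf_phase[keep], phi_s[keep]) >= value:
                count += 1
        p = (1.0 + count) / (n_surrogates + 1.0)
    return PacEstimate(value=value, p_value=p)


@dataclass
class SymbolSequence:
    """Integer symbol sequence produced by one symbolization scheme."""

    symbols: np.ndarray
    n_symbols: int
    scheme: str
    m: int
    tau: int
    codebook: np.ndarray | None = None

    def __post_init__(self):
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.size and self.symbols.max() >= self.n_symbols:
            raise ValueError("symbol value exceeds alphabet size")

    def __len__(self) -> int:
        return len(self.symbols)


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = len(x) - (m - 1) * tau
    if n < 1:
        raise ValueError(
            f"series of length {len(x)} too short for m={m}, tau={tau}"
        )
    return np.stack([x[i * tau: i * tau + n] for i in range(m)], axis=1)


def _ordinal_codes(emb: np.ndarray) -> np.ndarray:
    """Lehmer code of each row's permutation -> symbol in [0, m!)."""
    m = emb.shape[1]
    ranks = np.zeros(len(emb), dtype=np.int64)
    for i in range(m - 1):
        smaller = np.zeros(len(emb), dtype=np.int64)
        for j in range(i + 1, m):
            smaller += (emb[:, j] < emb[:, i]).astype(np.int64)
        ranks = ranks * (m - i) + smaller
    return ranks


def _batch_neural_gas(
    V: np.ndarray,
    K: int,
    rng: np.random.Generator,
    n_iter: int = 15,
    max_train: int = 3000,
) -> np.ndarray:
    """Batch neural-gas codebook (K prototypes) for embedded vectors."""
    n = len(V)
    train = V if n <= max_train else V[rng.choice(n, max_train, replace=False)]
    W = train[rng.choice(len(train), K, replace=False)].astype(float).copy()
    lam0, lam_f = K / 2.0, 0.01
    for it in range(n_iter):
        lam = lam0 * (lam_f / lam0) ** (it / max(n_iter - 1, 1))
        D = ((train[:, None, :] - W[None]) ** 2).sum(-1)
        ranks = np.argsort(np.argsort(D, axis=1), axis=1)
        H = np.exp(-ranks / lam)
        denom = H.sum(0)
        good = denom > 0
        W[good] = (H[:, good, None] * train[:, None, :]).sum(0)[good] / denom[good, None]
    return W


def _assign(V: np.ndarray, W: np.ndarray) -> np.ndarray:
    D = ((V[:, None, :] - W[None]) ** 2).sum(-1)
    return np.argmin(D, axis=1)


def symbolize(
    series: np.ndarray,
    scheme: str = "neural_gas",
    m: int = 3,
    tau: int = 1,
    n_symbols: int = 8,
    rng: np.random.Generator | None = None,
    pool: np.ndarray | None = None,
    unit_norm: bool = False,
) -> SymbolSequence:
    """Reduce a real-valued series to a symbol sequence.

    ``ordinal`` maps each embedded vector to its permutation rank (alphabet
    m!); ``neural_gas`` learns ``n_symbols`` prototype vectors by neural-gas
    vector quantization (training pooled with the optional second series
    ``pool`` so both members of a pair share one codebook) and assigns
    nearest-prototype indices.  ``unit_norm`` normalizes embedded vectors to
    unit length, making the quantizer amplitude-invariant (shape-only).
    """
    x = np.asarray(series, dtype=float).ravel()
    if len(x) <= (m - 1) * tau + 1:
        raise ValueError("series too short for the requested embedding")
    emb = _embed(x, m, tau)
    if scheme == "ordinal":
        return SymbolSequence(
            symbols=_ordinal_codes(emb),
            n_symbols=math.factorial(m),
            scheme="ordinal",
            m=m,
            tau=tau,
        )
    if scheme != "neural_gas":
        raise ValueError(f"unknown scheme {scheme!r}")
    if n_symbols < 2:
        raise ValueError("need at least 2 symbols")
    rng = rng or np.random.default_rng(0)
    V = emb
    pool_emb = None
    if pool is not None:
        pool_emb = _embed(np.asarray(pool, dtype=float).ravel(), m, tau)
    if unit_norm:
        V = V / (np.linalg.norm(V, axis=1, keepdims=True) + 1e-12)
        if pool_emb is not None:
            pool_emb = pool_emb / (np.linalg.norm(pool_emb, axis=1, keepdims=True) + 1e-12)
    train = V if pool_emb is None else np.vstack([V, pool_emb])
    W = _batch_neural_gas(train, n_symbols, rng)
    return SymbolSequence(
        symbols=_assign(V, W),
        n_symbols=n_symbols,
        scheme="neural_gas",
        m=m,
        tau=tau,
        codebook=W,
    )


def symbolize_channels(
    series: np.ndarray,
    scheme: str = "neural_gas",
    m: int = 3,
    tau: int = 1,
    n_symbols: int = 8,
    rng: np.random.Generator | None = None,
    unit_norm: bool = True,
    differenced: bool = True,
) -> list[SymbolSequence]:
    """Symbolize every row of a channels x samples array with one shared
    codebook (neural gas trained on the pooled embedded vectors).

    Used by graph-level dSTE computations where training a codebook per pair
    would be redundant: all pairs of one trial share the codebook.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    rows = [np.diff(r) if differenced else r for r in series]
    if scheme == "ordinal":
        return [
            symbolize(r, "ordinal", m=m, tau=tau) for r in rows
        ]
    rng = rng or np.random.default_rng(0)
    embs = [_embed(r, m, tau) for r in rows]
    if unit_norm:
        embs = [e / (np.linalg.norm(e, axis=1, keepdims=True) + 1e-12) for e in embs]
    W = _batch_neural_gas(np.vstack(embs), n_symbols, rng)
    return [
        SymbolSequence(
            symbols=_assign(e, W),
            n_symbols=n_symbols,
            scheme="neural_gas",
            m=m,
            tau=tau,
            codebook=W,
        )
        for e in embs
    ]


def _te_from_counts(yf, yp, xp, Ky, Kx) -> float:
    nv = len(yf)
    cj = np.bincount((yf * Ky + yp) * Kx + xp, minlength=Ky * Ky * Kx).astype(float)
    cyy = np.bincount(yf * Ky + yp, minlength=Ky * Ky).astype(float)
    cyx = np.bincount(yp * Kx + xp, minlength=Ky * Kx).astype(float)
    cy = np.bincount(yp, minlength=Ky).astype(float)
    idx = np.nonzero(cj)[0]
    yf_i = idx // (Ky * Kx)
    yp_i = (idx // Kx) % Ky
    xp_i = idx % Kx
    return float(
        np.sum(
            cj[idx] / nv
            * np.log2(cj[idx] * cy[yp_i] / (cyx[yp_i * Kx + xp_i] * cyy[yf_i * Ky + yp_i]))
        )
    )


def ste(sym_x: SymbolSequence, sym_y: SymbolSequence, delta: int) -> float:
    """Symbolic transfer entropy X -> Y at a single delay, in bits (>= 0).

    Plug-in estimate of
    ``sum p(y_{t+d}, y_t, x_t) log2[ p(y_{t+d} | y_t, x_t) / p(y_{t+d} | y_t) ]``.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1 for the single-delay estimator")
    sx = sym_x.symbols
    sy = sym_y.symbols
    n = min(len(sx), len(sy))
    if delta >= n:
        raise ValueError(f"delta={delta} >= sequence length {n}")
    yf = sy[delta:n]
    yp = sy[: n - delta]
    xp = sx[: n - delta]
    return max(_te_from_counts(yf, yp, xp, sym_y.n_symbols, sym_x.n_symbols), 0.0)


def _te_scan_gap(
    sx: np.ndarray,
    sy: np.ndarray,
    Kx: int,
    Ky: int,
    deltas: np.ndarray,
    gap: int,
) -> np.ndarray:
    """TE_{X->Y}(d) = I(Y_{t+d}; X_t | Y_{t+d-gap}) on a common sample count."""
    n = min(len(sx), len(sy))
    dmax = int(deltas.max())
    nv = n - dmax - gap
    if nv < 10:
        raise ValueError("series too short for the requested delay grid")
    out = np.empty(len(deltas))
    for k, d in enumerate(deltas):
        t0 = max(gap - d, 0)
        yf = sy[t0 + d: t0 + d + nv]
        yp = sy[t0 + d - gap: t0 + d - gap + nv]
        xp = sx[t0: t0 + nv]
        out[k] = _te_from_counts(yf, yp, xp, Ky, Kx)
    return out


@dataclass
class CausalEstimate:
    """Strength, net direction and delay of one ordered sensor pair."""

    source: str
    target: str
    strength: float
    delta_dste: float
    net_direction: int
    delay_samples: int
    delay_ms: float
    p_value: float | None = None
    zero_lag: bool | None = None
    delays: np.ndarray | None = field(default=None, repr=False)
    te_forward: np.ndarray | None = field(default=None, repr=False)
    te_reverse: np.ndarray | None = field(default=None, repr=False)


def dste_scan_symbols(
    sym_x: SymbolSequence,
    sym_y: SymbolSequence,
    fs: float,
    deltas: np.ndarray,
    n_surrogates: int = 0,
    rng: np.random.Generator | None = None,
    min_shift_s: float = 1.0,
    zero_lag_tol: int = 1,
    alpha: float = 0.05,
    source: str = "x",
    target: str = "y",
) -> CausalEstimate:
    """Delay scan on pre-computed symbol sequences (see :func:`dste_scan`)."""
    deltas = np.asarray(deltas, dtype=int)
    if deltas.size == 0:
        raise ValueError("empty delay grid")
    if deltas.min() < 0:
        raise ValueError("delays must be >= 0")
    deltas = np.unique(deltas)
    gap = sym_x.m * sym_x.tau + _SCAN_GAP_EXTRA
    sx, sy = sym_x.symbols, sym_y.symbols
    Kx, Ky = sym_x.n_symbols, sym_y.n_symbols
    fwd = _te_scan_gap(sx, sy, Kx, Ky, deltas, gap)
    rev = _te_scan_gap(sy, sx, Ky, Kx, deltas, gap)
    best = int(np.argmax(fwd))  # argmax returns the first (smallest) delay
    delay = int(deltas[best])
    strength = float(fwd[best])
    delta_dste = float(fwd[best] - rev[best])
    direction = int(np.sign(delta_dste))
    p = None
    zero = None
    if n_surrogates > 0:
        rng = rng or np.random.default_rng(0)
        n = min(len(sx), len(sy))
        min_shift = min(int(min_shift_s * fs), max(n // 4, 1))
        hi = n - min_shift
        count = 0
        for _ in range(n_surrogates):
            shift = int(rng.integers(min_shift, hi)) if hi > min_shift else int(rng.integers(1, n))
            surro = np.roll(sx, shift)
            if _te_scan_gap(surro, sy, Kx, Ky, deltas, gap).max() >= strength:
                count += 1
        p = (1.0 + count) / (n_surrogates + 1.0)
        zero = bool(delay <= zero_lag_tol and p <= alpha)
    return CausalEstimate(
        source=source,
        target=target,
        strength=strength,
        delta_dste=delta_dste,
        net_direction=direction,
        delay_samples=delay,
        delay_ms=1000.0 * delay / fs,
        p_value=p,
        zero_lag=zero,
        delays=deltas,
        te_forward=fwd,
        te_reverse=rev,
    )


def dste_scan(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    max_delay_ms: float = 250.0,
    delay_step: int = 1,
    scheme: str = "neural_gas",
    m: int = 3,
    tau: int = 1,
    n_symbols: int = 8,
    rng: np.random.Generator | None = None,
    n_surrogates: int = 0,
    min_shift_s: float = 1.0,
    zero_lag_tol: int = 1,
    alpha: float = 0.05,
    source: str = "x",
    target: str = "y",
) -> CausalEstimate:
    """Delayed symbolic transfer entropy scan between two real-valued series.

    Both series are first differenced (the symbol alphabet then encodes local
    increment shape rather than absolute level), symbolized with a codebook
    shared across the pair, and scanned over delays 0..``max_delay_ms`` in
    steps of ``delay_step`` samples.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    rng = rng or np.random.default_rng(0)
    dx, dy = np.diff(x), np.diff(y)
    if scheme == "ordinal":
        sym_x = symbolize(dx, "ordinal", m=m, tau=tau)
        sym_y = symbolize(dy, "ordinal", m=m, tau=tau)
    else:
        sym_x = symbolize(dx, "neural_gas", m=m, tau=tau, n_symbols=n_symbols,
                          rng=rng, pool=dy, unit_norm=True)
        sym_y = SymbolSequence(
            symbols=_assign(
                _embed(dy, m, tau)
                / (np.linalg.norm(_embed(dy, m, tau), axis=1, keepdims=True) + 1e-12),
                sym_x.codebook,
            ),
            n_symbols=n_symbols,
            scheme="neural_gas",
            m=m,
            tau=tau,
            codebook=sym_x.codebook,
        )
    dmax = int(round(max_delay_ms / 1000.0 * fs))
    deltas = np.arange(0, dmax + 1, delay_step)
    return dste_scan_symbols(
        sym_x, sym_y, fs, deltas,
        n_surrogates=n_surrogates, rng=rng, min_shift_s=min_shift_s,
        zero_lag_tol=zero_lag_tol, alpha=alpha, source=source, target=target,
    )


def causal_series(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = (2.0, 45.0),
    notch: tuple[float, float] | None = None,
    transition: float = 2.0,
) -> np.ndarray:
    """Wideband series feeding the delay estimators.

    A generous band-pass keeps the broadband dynamics that carry transmission
    timing (band-limiting to a narrow rhythm destroys sample-level timing
    information).  The optional notch removes the narrowband alpha2 rhythm,
    whose quasi-periodicity can produce period-spaced sidelobes in the
    transfer-entropy delay curve; the rhythm's phase coupling is analysed by
    the PLV family instead.
    """
    x = np.asarray(x, dtype=float)
    out = bandpass_filter(x, band[0], band[1], fs, transition=transition)
    if notch is not None:
        n = out.shape[-1]
        numtaps = min(int(np.ceil(3.3 * fs / transition)) | 1,
                      max(((n - 1) // 3) | 1, 5))
        b = sp_signal.firwin(numtaps, list(notch), pass_zero="bandstop", fs=fs)
        out = sp_signal.filtfilt(b, [1.0], out, axis=-1,
                                 padlen=min(3 * numtaps, n - 1))
    return out


def envelope_series(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = (2.0, 45.0),
    detrend_hz: float | None = 8.0,
    transition: float = 2.0,
) -> np.ndarray:
    """Instantaneous amplitude of the band-limited analytic signal.

    With ``detrend_hz`` set, slow envelope components below that frequency
    are removed (zero-phase high-pass), which suppresses the slow co-modulation
    shared by all channels and sharpens envelope cross-correlation peaks.
    """
    x = np.asarray(x, dtype=float)
    filt = bandpass_filter(x, band[0], band[1], fs, transition=transition)
    nfft = int(2 ** np.ceil(np.log2(max(filt.shape[-1], 2))))
    amp = np.abs(sp_signal.hilbert(filt, N=nfft, axis=-1)[..., : filt.shape[-1]])
    if detrend_hz is not None:
        numtaps = min(257, (filt.shape[-1] // 3) | 1)
        b = sp_signal.firwin(numtaps, detrend_hz, pass_zero=False, fs=fs)
        amp = sp_signal.filtfilt(b, [1.0], amp, axis=-1,
                                 padlen=min(3 * numtaps, filt.shape[-1] - 1))
    return amp


def envelope_xcorr_lag(
    amp_x: np.ndarray,
    amp_y: np.ndarray,
    fs: float,
    max_lag_ms: float = 250.0,
) -> float:
    """Signed lag (ms) at the peak of the normalized envelope cross-correlation.

    Positive when ``amp_x`` precedes ``amp_y``.  Raises ``ValueError`` for a
    zero-variance envelope (the lag is undefined).
    """
    ax = np.asarray(amp_x, dtype=float).ravel()
    ay = np.asarray(amp_y, dtype=float).ravel()
    if ax.size != ay.size:
        raise ValueError("envelopes must have equal length")
    ax = ax - ax.mean()
    ay = ay - ay.mean()
    if ax.std() == 0 or ay.std() == 0:
        raise ValueError("zero-variance envelope: lag undefined")
    max_lag = int(round(max_lag_ms / 1000.0 * fs))
    if max_lag >= len(ax):
        raise ValueError("max_lag exceeds the trial length")
    cc = sp_signal.correlate(ay, ax, mode="full")
    lags = sp_signal.correlation_lags(len(ay), len(ax), mode="full")
    sel = (lags >= -max_lag) & (lags <= max_lag)
    lag = int(lags[sel][np.argmax(cc[sel])])
    return 1000.0 * lag / fs
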