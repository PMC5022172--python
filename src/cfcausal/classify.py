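"""Correct-vs-wrong trial classification per cognitive workload level.

Two routes, both ending in a k-NN classifier under stratified 10-fold
cross-validation:

* signal power / reaction-time feature vectors, screened with the Laplacian
  score (graph-locality feature selection);
* connectivity graphs (one sensor x sensor matrix per trial) stacked into a
  tensor and reduced by tensor subspace analysis (TSA), a bilinear
  locality-preserving projection U' W V of matrix-valued samples.

Estimator classes follow scikit-learn conventions (``fit``/``transform``,
``get_params``, fitted attributes with trailing underscores) and compose with
sklearn model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sp_linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .causal import causal_series, dpli, dste_scan_symbols, envelope_series, symbolize_channels
from .coupling import nm_plv, plv
from .preprocess import (
    ALPHA2_BAND,
    THETA_BAND,
    BandDefinition,
    SensorMontage,
    TrialSegment,
    bandpass_filter,
    hilbert_analytic,
    morlet_phase,
)

__all__ = [
    "LaplacianScore",
    "TensorSubspaceAnalysis",
    "CvResult",
    "knn_crossval",
    "run_classification_suite",
    "SUITE_ESTIMATORS",
]

SUITE_ESTIMATORS = (
    "ps", "plv_theta", "plv_alpha", "nm_plv", "pac", "dpli", "dste",
)


class LaplacianScore(BaseEstimator, TransformerMixin):
    """Rank features by graph-Laplacian smoothness (lower score = better).

    A k-nearest-neighbour similarity graph with a heat kernel is built over
    samples; each feature is scored by its Laplacian quadratic form
    normalized by its weighted variance.  Features preserving the local
    sample geometry score low and rank first.

    Attributes
    ----------
    scores_ : ndarray of shape (n_features,)
    ranking_ : ndarray of feature indices, ascending score
    """

    def __init__(self, n_neighbors: int = 5, n_features_to_select: int | None = None):
        self.n_neighbors = n_neighbors
        self.n_features_to_select = n_features_to_select

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        if d < 2:
            raise ValueError("need at least 2 features")
        if n < self.n_neighbors + 1:
            raise ValueError("need at least n_neighbors + 1 samples")
        D2 = pairwise_distances(X, metric="sqeuclidean")
        # kNN adjacency, symmetrized
        order = np.argsort(D2, axis=1)[:, 1: self.n_neighbors + 1]
        A = np.zeros((n, n), dtype=bool)
        rows = np.repeat(np.arange(n), self.n_neighbors)
        A[rows, order.ravel()] = True
        A |= A.T
        t = np.median(D2[A]) if A.any() else 1.0
        t = t if t > 0 else 1.0
        S = np.where(A, np.exp(-D2 / t), 0.0)
        Dg = S.sum(axis=1)
        scores = np.empty(d)
        for r in range(d):
            f = X[:, r]
            denom_w = Dg.sum()
            f_t = f - (f @ Dg) / denom_w
            var = f_t @ (Dg * f_t)
            if var <= 1e-12:
                warnings.warn(f"feature {r} has (weighted) zero variance; worst rank")
                scores[r] = np.inf
                continue
            lap = f_t @ (Dg * f_t) - f_t @ (S @ f_t)  # f' L f with L = D - S
            scores[r] = lap / var
        self.scores_ = scores
        self.ranking_ = np.argsort(scores, kind="stable")
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        k = self.n_features_to_select or X.shape[1]
        return X[:, self.ranking_[:k]]


def _fix_sign(U: np.ndarray) -> np.ndarray:
    for j in range(U.shape[1]):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    return U


class TensorSubspaceAnalysis(BaseEstimator, TransformerMixin):
    """Bilinear locality-preserving projection of matrix-valued samples.

    Each trial is a d1 x d2 connectivity matrix W_i, represented in the
    subspace as U' W_i V.  Row and column projections are optimized
    alternately to concentrate neighbouring trials (heat-kernel affinity on
    Frobenius distances; neighbour candidates restricted to the same class
    when labels are supplied), iterating until the objective changes by less
    than ``tol`` or ``max_iter`` rounds.  Initialization is the identity;
    given the same inputs the fit is deterministic (eigvector signs fixed).
    """

    def __init__(
        self,
        n_components: tuple[int, int] = (2, 2),
        n_neighbors: int = 5,
        max_iter: int = 10,
        tol: float = 1e-6,
        ridge: float = 1e-3,
    ):
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.max_iter = max_iter
        self.tol = tol
        self.ridge = ridge

    def _affinity(self, X: np.ndarray, y) -> np.ndarray:
        n = len(X)
        flat = X.reshape(n, -1)
        D2 = pairwise_distances(flat, metric="sqeuclidean")
        if y is not None:
            y = np.asarray(y)
            different = y[:, None] != y[None, :]
            D2 = D2 + np.where(different, np.inf, 0.0)
        k = min(self.n_neighbors, n - 1)
        order = np.argsort(D2, axis=1)[:, 1: k + 1]
        A = np.zeros((n, n), dtype=bool)
        rows = np.repeat(np.arange(n), k)
        A[rows, order.ravel()] = True
        A |= A.T
        finite = D2[A & np.isfinite(D2)]
        t = np.median(finite) if finite.size else 1.0
        t = t if t > 0 else 1.0
        with np.errstate(over="ignore"):
            S = np.where(A & np.isfinite(D2), np.exp(-D2 / t), 0.0)
        return S

    def _solve(self, M_S: np.ndarray, M_D: np.ndarray, p: int) -> np.ndarray:
        d = M_D.shape[0]
        reg = self.ridge * (np.trace(M_D) / d + 1.0)
        M_D = M_D + reg * np.eye(d)
        M_S = 0.5 * (M_S + M_S.T)
        try:
            w, v = sp_linalg.eigh(M_S, M_D)
        except np.linalg.LinAlgError:
            warnings.warn("singular affinity matrix; increasing ridge")
            M_D = M_D + 1e-3 * np.trace(M_D) / d * np.eye(d)
            w, v = sp_linalg.eigh(M_S, M_D)
        U = v[:, np.argsort(w)[::-1][:p]]
        return _fix_sign(U)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be 3-D: trials x d1 x d2")
        n, d1, d2 = X.shape
        p1, p2 = self.n_components
        if p1 > d1 or p2 > d2:
            raise ValueError("n_components exceed matrix dimensions")
        if y is not None:
            _, counts = np.unique(y, return_counts=True)
            if counts.min() < 2:
                raise ValueError("need at least 2 trials per class")
        # centre and scale each matrix entry across trials: the bilinear
        # objective is otherwise dominated by entry means and unit scales
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.scale_ = sd
        X = (X - self.mean_) / self.scale_
        S = self._affinity(X, y)
        Dg = S.sum(axis=1)
        U = np.eye(d1)[:, :p1]
        V = np.eye(d2)[:, :p2]
        prev_obj = None
        for _ in range(self.max_iter):
            XV = X @ V  # (n, d1, p2)
            M_D = np.einsum("i,iab,icb->ac", Dg, XV, XV)
            M_S = np.einsum("ij,iab,jcb->ac", S, XV, XV)
            U = self._solve(M_S, M_D, p1)
            UXt = np.einsum("da,idb->iba", U, X)  # (n, d2, p1)
            M_Dv = np.einsum("i,iab,icb->ac", Dg, UXt, UXt)
            M_Sv = np.einsum("ij,iab,jcb->ac", S, UXt, UXt)
            V = self._solve(M_Sv, M_Dv, p2)
            proj = np.einsum("da,idf,fb->iab", U, X, V).reshape(n, -1)
            diff = proj[:, None, :] - proj[None, :, :]
            obj = float(np.einsum("ij,ijk,ijk->", S, diff, diff))
            if prev_obj is not None and abs(prev_obj - obj) <= self.tol * max(abs(prev_obj), 1.0):
                break
            prev_obj = obj
        self.row_projection_ = U
        self.col_projection_ = V
        self.objective_ = prev_obj
        return self

    def transform(self, X):
        X = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        proj = np.einsum("da,idf,fb->iab", self.row_projection_, X, self.col_projection_)
        return proj.reshape(len(X), -1)


@dataclass
class CvResult:
    """Cross-validated accuracy of one estimator at one workload level."""

    accuracies: np.ndarray
    mean_accuracy: float
    sd_accuracy: float
    estimator: str = ""
    cwl: int | None = None

    @property
    def n_folds(self) -> int:
        return len(self.accuracies)


def knn_crossval(
    X,
    y,
    n_neighbors: int = 5,
    n_folds: int = 10,
    seed: int = 0,
    estimator: str = "",
    cwl: int | None = None,
    tensor_components: tuple[int, int] | None = None,
) -> CvResult:
    """Stratified k-fold cross-validated k-NN accuracy (percent).

    Features are min-max normalized inside each fold (fit on the training
    split only).  3-D inputs are reduced per fold by
    :class:`TensorSubspaceAnalysis` fit on the training split.  An odd
    ``n_neighbors`` avoids voting ties in the binary problem; residual ties
    fall back to the nearest neighbour's label (sklearn's ordering).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both classes for classification")
    folds = n_folds
    if counts.min() < n_folds:
        folds = max(int(counts.min()), 2)
        warnings.warn(f"reducing folds from {n_folds} to {folds} (small class)")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(np.zeros(len(y)), y):
        Xtr, Xte = X[train], X[test]
        if X.ndim == 3:
            tsa = TensorSubspaceAnalysis(
                n_components=tensor_components or (2, 2)
            )
            tsa.fit(Xtr, y[train])
            Xtr = tsa.transform(Xtr)
            Xte = tsa.transform(Xte)
        lo = Xtr.min(axis=0)
        span = Xtr.max(axis=0) - lo
        span[span == 0] = 1.0
        Xtr = (Xtr - lo) / span
        Xte = (Xte - lo) / span
        k = min(n_neighbors, len(Xtr))
        clf = KNeighborsClassifier(n_neighbors=k)
        clf.fit(Xtr, y[train])
        accs.append(100.0 * np.mean(clf.predict(Xte) == y[test]))
    accs = np.asarray(accs)
    return CvResult(
        accuracies=accs,
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        estimator=estimator,
        cwl=cwl,
    )


# ---------------------------------------------------------------------------
# trial representations for the estimator comparison suite


def _trial_representations(
    trial: TrialSegment,
    montage: SensorMontage,
    estimators: tuple[str, ...],
    rng: np.random.Generator,
    theta_band: BandDefinition,
    alpha_band: BandDefinition,
    pac_hf_band: tuple[float, float],
    causal_band: tuple[float, float],
    causal_notch: tuple[float, float] | None,
    max_delay_ms: float,
    delay_step: int,
    scheme: str,
    n_symbols: int,
) -> dict[str, np.ndarray]:
    """All requested per-trial feature representations, sharing transforms."""
    f_idx = montage.f_indices
    po_idx = montage.po_indices
    out: dict[str, np.ndarray] = {}

    need_wavelet = {"plv_theta", "plv_alpha", "nm_plv", "dpli"} & set(estimators)
    if need_wavelet:
        th = morlet_phase(trial, theta_band)
        al = morlet_phase(trial, alpha_band)
        valid = th.valid & al.valid
        if not valid.any():
            valid = np.ones(trial.width, dtype=bool)
        thp = th.phase[..., valid]
        alp = al.phase[..., valid]
        if "plv_theta" in estimators:
            M = np.zeros((len(f_idx), len(f_idx)))
            for a, i in enumerate(f_idx):
                for b_, j in enumerate(f_idx[a + 1:], start=a + 1):
                    M[a, b_] = M[b_, a] = plv(thp[i], thp[j])
            out["plv_theta"] = M
        if "plv_alpha" in estimators:
            M = np.zeros((len(po_idx), len(po_idx)))
            for a, i in enumerate(po_idx):
                for b_, j in enumerate(po_idx[a + 1:], start=a + 1):
                    M[a, b_] = M[b_, a] = plv(alp[i], alp[j])
            out["plv_alpha"] = M
        if "nm_plv" in estimators:
            M = np.zeros((len(f_idx), len(po_idx)))
            for a, i in enumerate(f_idx):
                for b_, j in enumerate(po_idx):
                    M[a, b_] = nm_plv(thp[i], alp[j])
            out["nm_plv"] = M
        if "dpli" in estimators:
            ic = int(np.argmin(np.abs(theta_band.freqs - theta_band.center)))
            jc = int(np.argmin(np.abs(alpha_band.freqs - alpha_band.center)))
            M = np.zeros((len(f_idx), len(po_idx)))
            for a, i in enumerate(f_idx):
                for b_, j in enumerate(po_idx):
                    M[a, b_] = dpli(2.0 * thp[i, ic], alp[j, jc])
            out["dpli"] = M

    if "ps" in estimators or "pac" in estimators:
        th_h = hilbert_analytic(trial, theta_band)
        al_h = hilbert_analytic(trial, alpha_band)
        v = th_h.valid & al_h.valid
        if not v.any():
            v = np.ones(trial.width, dtype=bool)
        if "ps" in estimators:
            p_th = 0.5 * (th_h.amplitude[:, 0, v] ** 2).mean(axis=1)
            p_al = 0.5 * (al_h.amplitude[:, 0, v] ** 2).mean(axis=1)
            ratio = p_th / np.where(p_al > 0, p_al, 1e-12)
            out["ps"] = np.concatenate([p_th, p_al, ratio, [trial.duration_ms]])
        if "pac" in estimators:
            from scipy.signal import hilbert as _hilbert

            # modulation phase of each PO envelope computed once, PLV against
            # every F theta phase (same estimate as pac(), cached per target)
            phi_mod = []
            for j in po_idx:
                amp = envelope_series(trial.samples[j], trial.fs,
                                      band=pac_hf_band, detrend_hz=None)
                filt = bandpass_filter(amp - amp.mean(), theta_band.low,
                                       theta_band.high, trial.fs)
                phi_mod.append(np.angle(_hilbert(filt)))
            M = np.zeros((len(f_idx), len(po_idx)))
            for a, i in enumerate(f_idx):
                lfp = th_h.phase[i, 0]
                for b_, j in enumerate(po_idx):
                    M[a, b_] = plv(lfp, phi_mod[b_])
            out["pac"] = M

    if "dste" in estimators:
        wide = causal_series(trial.samples, trial.fs, band=causal_band,
                             notch=causal_notch)
        syms = symbolize_channels(wide, scheme=scheme, n_symbols=n_symbols, rng=rng)
        dmax = int(round(max_delay_ms / 1000.0 * trial.fs))
        deltas = np.arange(0, dmax + 1, delay_step)
        S = np.zeros((len(f_idx), len(po_idx)))
        Dl = np.zeros_like(S)
        Dd = np.zeros_like(S)
        for a, i in enumerate(f_idx):
            for b_, j in enumerate(po_idx):
                est = dste_scan_symbols(syms[i], syms[j], trial.fs, deltas)
                S[a, b_] = est.strength
                Dl[a, b_] = est.delta_dste
                Dd[a, b_] = est.delay_ms
        out["dste"] = np.concatenate([S, Dl, Dd], axis=1)
    return out


def run_classification_suite(
    dataset,
    estimators: tuple[str, ...] = SUITE_ESTIMATORS,
    cwls: tuple[int, ...] = (1, 2, 3, 4, 5),
    n_folds: int = 10,
    n_neighbors: int = 5,
    seed: int = 0,
    tensor_components: tuple[int, int] = (2, 2),
    laplacian_select: int = 10,
    theta_band: BandDefinition = THETA_BAND,
    alpha_band: BandDefinition = ALPHA2_BAND,
    pac_hf_band: tuple[float, float] = (8.0, 18.0),
    causal_band: tuple[float, float] = (2.0, 45.0),
    causal_notch: tuple[float, float] | None = None,
    max_delay_ms: float = 250.0,
    delay_step: int = 1,
    scheme: str = "neural_gas",
    n_symbols: int = 8,
) -> pd.DataFrame:
    """Correct-vs-wrong cross-validated accuracy per estimator and CWL.

    Trials are pooled over subjects per workload level (a group-unified
    binary classifier).  Graph representations go through per-fold TSA + kNN;
    the power/reaction-time table goes through Laplacian-score screening +
    kNN.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    unknown = set(estimators) - set(SUITE_ESTIMATORS)
    if unknown:
        raise ValueError(f"unknown estimators: {sorted(unknown)}")
    montage = dataset.config.montage
    reps: list[dict[str, np.ndarray]] = []
    for trial in dataset.trials:
        reps.append(
            _trial_representations(
                trial, montage, tuple(estimators), rng,
                theta_band, alpha_band, pac_hf_band, causal_band,
                causal_notch, max_delay_ms, delay_step, scheme, n_symbols,
            )
        )
    rows = []
    for est in estimators:
        for cwl in cwls:
            sel = [k for k, t in enumerate(dataset.trials) if t.cwl == cwl]
            if not sel:
                continue
            y = np.array([dataset.trials[k].response for k in sel])
            if len(np.unique(y)) < 2:
                raise ValueError(f"need both classes at CWL {cwl}")
            X = np.stack([reps[k][est] for k in sel])
            if est == "ps":
                ls = LaplacianScore(
                    n_neighbors=n_neighbors,
                    n_features_to_select=min(laplacian_select, X.shape[1]),
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    X = ls.fit(X).transform(X)
            res = knn_crossval(
                X, y, n_neighbors=n_neighbors, n_folds=n_folds, seed=seed,
                estimator=est, cwl=cwl, tensor_components=tensor_components,
            )
            rows.append(
                {
                    "estimator": est,
                    "cwl": cwl,
                    "mean_accuracy": res.mean_accuracy,
                    "sd_accuracy": res.sd_accuracy,
                    "n_trials": len(sel),
                    "n_folds": res.n_folds,
                }
            )
    return pd.DataFrame(rows)
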