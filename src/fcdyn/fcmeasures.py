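"""The four windowed connectivity measures: BCorrU, BCorrD, COH1, PDC.

Two are correlation-based — BCorrU (undirected absolute Pearson
correlation) and BCorrD (directional lagged correlation, assigning the
direction i -> j when the past of i predicts the present of j better than
the reverse).  Two are MVAR-model-based: COH1 (ordinary coherence from the
model's cross-spectral density S(f) = H(f) Σ_w H(f)*) and PDC (partial
directed coherence, the column-normalized Fourier-domain coefficient
matrix Ā(f) of Baccalá & Sameshima).

Orientation convention used throughout the package: ``values[i, j]`` is the
strength of the influence of channel i (source row) on channel j (target
column).  The PDC literature indexes π_{i<-j}; that is transposed into the
source-row convention at this module's boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .recording import Recording

__all__ = [
    "MeasureMatrix",
    "SpectralModel",
    "preprocess",
    "bcorr_u",
    "bcorr_d",
    "fit_mvar",
    "coh1",
    "pdc",
    "compute_measures",
    "MEASURE_NAMES",
]

logger = logging.getLogger(__name__)

MEASURE_NAMES = ("BCorrU", "BCorrD", "COH1", "PDC")

DEFAULT_BAND = (1.0, 45.0)
DEFAULT_N_FREQS = 64
DEFAULT_MAX_ORDER = 10


@dataclass
class MeasureMatrix:
    """One connectivity measure on one window, entries in [0, 1], zero diag."""

    values: np.ndarray
    measure_name: str
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be square")
        self.values = v


@dataclass
class SpectralModel:
    """Fitted MVAR(p) model with its frequency-domain transforms.

    ``coeffs[k]`` is A_{k+1} with ``A_k[target, source]`` in
    ``x(t) = sum_k A_k x(t-k) + w(t)``.
    """

    order: int
    coeffs: np.ndarray
    residual_cov: np.ndarray
    fs: float
    bic: float | None = None
    ridge_used: float = 0.0

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def A_of_f(self, freqs: np.ndarray) -> np.ndarray:
        """Ā(f) = I − Σ_k A_k e^(−i 2π f k / fs), shape (n_freqs, n, n)."""
        freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
        n = self.n_channels
        k = np.arange(1, self.order + 1)
        phases = np.exp(-2j * np.pi * np.outer(freqs, k) / self.fs)
        out = np.tile(np.eye(n, dtype=complex), (freqs.size, 1, 1))
        out -= np.einsum("fk,kij->fij", phases, self.coeffs)
        return out

    def H_of_f(self, freqs: np.ndarray) -> np.ndarray:
        """Transfer function H(f) = Ā(f)^−1."""
        return np.linalg.inv(self.A_of_f(freqs))


def preprocess(window: Recording) -> np.ndarray:
    """Linear detrend + per-channel z-score; zero-variance rows left at 0."""
    x = scipy.signal.detrend(window.data, axis=1, type="linear")
    sd = x.std(axis=1, keepdims=True)
    flat = sd[:, 0] < 1e-15
    if flat.any():
        logger.warning("zero-variance channel(s) %s left at zero",
                       list(np.nonzero(flat)[0]))
        sd[flat] = 1.0
    return x / sd


def _check_window(window: Recording, min_samples: int = 100) -> None:
    if window.n_channels < 2:
        raise ValueError("need at least 2 channels")
    if window.n_samples < min_samples:
        raise ValueError(f"need at least {min_samples} samples")


def bcorr_u(window: Recording) -> MeasureMatrix:
    """Absolute pairwise Pearson correlation (undirected, symmetric)."""
    _check_window(window)
    x = preprocess(window)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[~np.isfinite(r)] = 0.0
    r[sd < 1e-15, :] = 0.0
    r[:, sd < 1e-15] = 0.0
    values = np.abs(r)
    np.fill_diagonal(values, 0.0)
    return MeasureMatrix(np.clip(values, 0.0, 1.0), "BCorrU")


def _lagged_corr_max(x: np.ndarray, max_lag: int) -> np.ndarray:
    """c+[i, j] = max over lag 1..max_lag of |r(x_i(t−lag), x_j(t))|."""
    n, T = x.shape
    c_plus = np.zeros((n, n))
    for lag in range(1, max_lag + 1):
        past = x[:, :T - lag]
        present = x[:, lag:]
        pz = past - past.mean(axis=1, keepdims=True)
        qz = present - present.mean(axis=1, keepdims=True)
        pn = np.linalg.norm(pz, axis=1)
        qn = np.linalg.norm(qz, axis=1)
        pn[pn < 1e-15] = np.inf
        qn[qn < 1e-15] = np.inf
        r = (pz / pn[:, None]) @ (qz / qn[:, None]).T
        np.maximum(c_plus, np.abs(r), out=c_plus)
    return c_plus


def bcorr_d(window: Recording, max_lag: int | None = None) -> MeasureMatrix:
    """Directional lagged correlation with winner-take-all direction.

    The best absolute lagged correlation of i's past with j's present,
    c+(i, j), is kept only when it beats the reverse direction c+(j, i);
    the losing direction is zeroed.  ``max_lag`` defaults to 100 ms.
    """
    _check_window(window)
    if max_lag is None:
        max_lag = max(1, int(round(0.1 * window.fs)))
    if not 1 <= max_lag < window.n_samples / 10:
        raise ValueError(f"max_lag {max_lag} out of range [1, n_samples/10)")
    x = preprocess(window)
    c_plus = _lagged_corr_max(x, max_lag)
    values = np.where(c_plus > c_plus.T, c_plus, 0.0)
    np.fill_diagonal(values, 0.0)
    return MeasureMatrix(np.clip(values, 0.0, 1.0), "BCorrD")


def _fit_mvar_order(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Least-squares VAR(p) fit on preprocessed data; returns (coeffs, cov, bic, ridge)."""
    n, T = x.shape
    neff = T - p
    Y = x[:, p:].T                                   # (neff, n)
    Z = np.empty((neff, n * p))
    for k in range(1, p + 1):
        Z[:, (k - 1) * n:k * n] = x[:, p - k:T - k].T
    ridge = 0.0
    gram = Z.T @ Z
    rhs = Z.T @ Y
    try:
        cond = np.linalg.cond(gram)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        ridge = 1e-6 * np.trace(gram) / gram.shape[0]
        logger.warning("near-singular regressor matrix; ridge %.3g applied", ridge)
    B = np.linalg.solve(gram + ridge * np.eye(gram.shape[0]), rhs)  # (n*p, n)
    resid = Y - Z @ B
    cov = resid.T @ resid / max(neff - n * p, 1)
    coeffs = np.empty((p, n, n))
    for k in range(p):
        # B[(k)*n + source, target] -> A_{k+1}[target, source]
        coeffs[k] = B[k * n:(k + 1) * n, :].T
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        logdet = -np.inf
    bic = logdet + (np.log(neff) / neff) * p * n * n
    return coeffs, cov, float(bic), ridge


def fit_mvar(window: Recording, order: int | str = "auto",
             max_order: int = DEFAULT_MAX_ORDER) -> SpectralModel:
    """Fit an MVAR model by multichannel least squares.

    ``order="auto"`` selects p in [1, max_order] by BIC.  A ridge fallback
    with logged strength handles near-singular regressors.
    """
    if isinstance(order, str):
        if order != "auto":
            raise ValueError(f"unknown order spec {order!r}")
        orders = range(1, max_order + 1)
    else:
        if order < 1:
            raise ValueError("order must be >= 1")
        orders = [int(order)]
    p_cap = max(orders)
    if window.n_samples <= 10 * p_cap * window.n_channels:
        raise ValueError(
            f"{window.n_samples} samples too few for order {p_cap} on "
            f"{window.n_channels} channels (need > {10 * p_cap * window.n_channels})"
        )
    x = preprocess(window)
    best = None
    for p in orders:
        coeffs, cov, bic, ridge = _fit_mvar_order(x, p)
        if best is None or bic < best[2]:
            best = (coeffs, cov, bic, ridge, p)
    coeffs, cov, bic, ridge, p = best
    return SpectralModel(p, coeffs, cov, window.fs, bic=bic, ridge_used=ridge)


def _band_freqs(band: tuple[float, float], n_freqs: int, fs: float) -> np.ndarray:
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} must lie within (0, {fs / 2})")
    return np.linspace(lo, hi, n_freqs)


def coh1(model: SpectralModel, band: tuple[float, float] = DEFAULT_BAND,
         n_freqs: int = DEFAULT_N_FREQS) -> MeasureMatrix:
    """Model-based coherence from the MVAR cross-spectral density.

    S(f) = H(f) Σ_w H(f)*; C_ij(f) = |S_ij| / sqrt(S_ii S_jj), averaged over
    ``n_freqs`` equispaced frequencies in ``band``.  Symmetric, zero diag.
    """
    freqs = _band_freqs(band, n_freqs, model.fs)
    H = model.H_of_f(freqs)
    S = H @ model.residual_cov @ H.conj().transpose(0, 2, 1)
    diag = np.real(np.diagonal(S, axis1=1, axis2=2))
    if (diag <= 0).any():
        raise ValueError("non-positive auto-spectrum: model invalid")
    denom = np.sqrt(diag[:, :, None] * diag[:, None, :])
    C = np.abs(S) / denom
    values = C.mean(axis=0)
    values = 0.5 * (values + values.T)   # symmetrize against rounding
    np.fill_diagonal(values, 0.0)
    return MeasureMatrix(np.clip(values, 0.0, 1.0), "COH1", band)


def pdc(model: SpectralModel, band: tuple[float, float] = DEFAULT_BAND,
        n_freqs: int = DEFAULT_N_FREQS) -> MeasureMatrix:
    """Partial directed coherence averaged over a frequency band.

    π_{i<-j}(f) = |Ā_ij(f)| / sqrt(Σ_k |Ā_kj(f)|²) quantifies the direct
    influence of source j on target i, normalized over all targets of j.
    The output uses the package's (source row, target column) convention:
    ``values[j, i]`` is the band-mean of π_{i<-j}.
    """
    freqs = _band_freqs(band, n_freqs, model.fs)
    A = model.A_of_f(freqs)
    col_norm = np.sqrt((np.abs(A) ** 2).sum(axis=1))      # (f, n) per source col
    if (col_norm < 1e-300).any():
        raise ValueError("zero source-column norm in A(f)")
    pi = np.abs(A) / col_norm[:, None, :]                 # pi[f, i, j] = i<-j
    values = pi.mean(axis=0).T                            # -> [source, target]
    np.fill_diagonal(values, 0.0)
    return MeasureMatrix(np.clip(values, 0.0, 1.0), "PDC", band)


def compute_measures(window: Recording, order: int | str = "auto",
                     max_order: int = DEFAULT_MAX_ORDER,
                     band: tuple[float, float] = DEFAULT_BAND,
                     n_freqs: int = DEFAULT_N_FREQS,
                     max_lag: int | None = None) -> dict[str, MeasureMatrix]:
    """All four measures on one window, keyed by measure name."""
    model = fit_mvar(window, order=order, max_order=max_order)
    return {
        "BCorrU": bcorr_u(window),
        "BCorrD": bcorr_d(window, max_lag=max_lag),
        "COH1": coh1(model, band, n_freqs),
        "PDC": pdc(model, band, n_freqs),
    }
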