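"""Vector autoregressive (VAR) models: construction, simulation, estimation,
and frequency-domain matrices.

A VAR(p) process on M channels is

    x(t) = A_1 x(t-1) + ... + A_p x(t-p) + e(t),   cov(e) = Sigma,

with e(t) Gaussian white noise. Everything downstream — spectral Granger
causality, directed coherence, the state-space reduction — is a functional of
(A_1..A_p, Sigma, fs). This module owns the VAR container, the companion-form
stability check, exact autocovariances via the discrete Lyapunov equation,
least-squares estimation, order selection, and the per-frequency coefficient
transform A(f), transfer H(f) = A(f)^-1 and cross-spectral density
S(f) = H(f) Sigma H(f)^H.

Spectra are reported in per-sample units (no division by the sampling rate):
every measure built on them in this package is a scale-invariant ratio, so the
convention only affects raw PSD values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg as sla

__all__ = [
    "VARModel",
    "MultichannelSeries",
    "FrequencyGrid",
    "SpectralMatrixSet",
    "make_var",
    "simulate_var",
    "fit_var_ols",
    "select_order",
    "var_spectral_matrices",
    "companion_matrix",
    "autocovariance_sequence",
    "lag_zero_covariance",
    "save_model_json",
    "load_model_json",
    "save_series_csv",
    "load_series_csv",
]

_SYM_TOL = 1e-12


class ValidationError(ValueError):
    """Raised when model or series inputs violate their invariants."""


def _default_labels(m: int) -> tuple[str, ...]:
    return tuple(f"ch{i + 1}" for i in range(m))


@dataclass(frozen=True)
class VARModel:
    """A VAR(p) process: lag coefficients, innovation covariance, sampling rate.

    Attributes
    ----------
    coeffs : ndarray, shape (p, M, M)
        Lag coefficient matrices ``A_1 .. A_p`` (lag-major).
    noise_cov : ndarray, shape (M, M)
        Innovation covariance ``Sigma`` (symmetric positive definite).
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
    is_stable : bool
        True iff the companion-matrix spectral radius is < 1. Ground-truth
        models are required to be stable before simulation; fitted models
        merely carry the flag.
    """

    coeffs: np.ndarray
    noise_cov: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    is_stable: bool = field(default=True)
    spectral_radius: float = field(default=0.0)

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def label_index(self, channel: int | str) -> int:
        """Resolve a channel given as 0-based index or label."""
        if isinstance(channel, (int, np.integer)):
            if not 0 <= channel < self.n_channels:
                raise ValidationError(
                    f"channel index {channel} out of range 0..{self.n_channels - 1}"
                )
            return int(channel)
        try:
            return self.channel_labels.index(channel)
        except ValueError:
            raise ValidationError(
                f"unknown channel {channel!r}; labels are {list(self.channel_labels)}"
            ) from None


def companion_matrix(coeffs: np.ndarray) -> np.ndarray:
    """Stack VAR lag matrices into the (M*p) x (M*p) companion form."""
    p, m, _ = coeffs.shape
    top = np.concatenate(list(coeffs), axis=1)
    if p == 1:
        return top
    lower = np.eye(m * (p - 1), m * p)
    return np.vstack([top, lower])


def make_var(
    coeffs,
    noise_cov,
    fs: float = 1.0,
    labels=None,
) -> VARModel:
    """Validate and construct a :class:`VARModel`.

    Raises :class:`ValidationError` for shape mismatches or a non-PD noise
    covariance. An unstable coefficient set is *not* an error (fitted models
    may be near-unstable): the model is returned with ``is_stable=False`` and
    a warning is emitted.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    noise_cov = np.asarray(noise_cov, dtype=float)
    if coeffs.ndim != 3 or coeffs.shape[1] != coeffs.shape[2]:
        raise ValidationError(
            f"coeffs must have shape (p, M, M); got {coeffs.shape}"
        )
    p, m, _ = coeffs.shape
    if p < 1 or m < 1:
        raise ValidationError("require order p >= 1 and M >= 1 channels")
    if not fs > 0:
        raise ValidationError(f"sampling rate must be positive, got {fs}")
    if noise_cov.shape != (m, m):
        raise ValidationError(
            f"noise_cov shape {noise_cov.shape} does not match M={m}"
        )
    if np.max(np.abs(noise_cov - noise_cov.T)) > _SYM_TOL * max(
        1.0, float(np.max(np.abs(noise_cov)))
    ):
        raise ValidationError("noise covariance is not symmetric")
    eigvals = np.linalg.eigvalsh(noise_cov)
    if eigvals.min() <= 0:
        raise ValidationError(
            f"noise covariance is not positive definite (min eigenvalue {eigvals.min():.3g})"
        )
    if labels is None:
        labels = _default_labels(m)
    labels = tuple(str(c) for c in labels)
    if len(labels) != m or len(set(labels)) != m:
        raise ValidationError("channel labels must be unique and match M")

    rho = float(np.max(np.abs(np.linalg.eigvals(companion_matrix(coeffs)))))
    stable = rho < 1.0
    if not stable:
        warnings.warn(
            f"VAR coefficients are unstable (companion spectral radius {rho:.4f})",
            RuntimeWarning,
            stacklevel=2,
        )
    return VARModel(
        coeffs=coeffs,
        noise_cov=noise_cov,
        fs=float(fs),
        channel_labels=labels,
        is_stable=stable,
        spectral_radius=rho,
    )


@dataclass(frozen=True)
class MultichannelSeries:
    """A T x M multichannel time series sampled at ``fs`` Hz."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValidationError("series data must be 2-D (samples x channels)")
        if not np.isfinite(data).all():
            raise ValidationError("series contains non-finite values")
        object.__setattr__(self, "data", data)
        if len(self.channel_labels) != data.shape[1]:
            raise ValidationError("label count does not match channel count")
        if not self.fs > 0:
            raise ValidationError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def label_index(self, channel: int | str) -> int:
        if isinstance(channel, (int, np.integer)):
            if not 0 <= channel < self.n_channels:
                raise ValidationError(f"channel index {channel} out of range")
            return int(channel)
        try:
            return list(self.channel_labels).index(channel)
        except ValueError:
            raise ValidationError(
                f"unknown channel {channel!r}; labels are {list(self.channel_labels)}"
            ) from None

    def demean(self) -> "MultichannelSeries":
        return MultichannelSeries(
            self.data - self.data.mean(axis=0), self.fs, self.channel_labels
        )


@dataclass(frozen=True)
class FrequencyGrid:
    """Monotonically increasing frequencies in Hz within [0, fs/2]."""

    freqs: np.ndarray
    fs: float

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        if freqs.ndim != 1 or freqs.size == 0:
            raise ValidationError("frequency grid must be a non-empty 1-D array")
        if np.any(np.diff(freqs) <= 0):
            raise ValidationError("frequencies must be strictly increasing")
        if freqs[0] < 0 or freqs[-1] > self.fs / 2 + 1e-12:
            raise ValidationError("frequencies must lie within [0, fs/2]")

    @classmethod
    def default(cls, fs: float, n_freq: int = 513, fmax: float | None = None):
        """Equally spaced grid of ``n_freq`` points on [0, fmax] (fmax defaults
        to the Nyquist frequency fs/2)."""
        if fmax is None:
            fmax = fs / 2
        return cls(np.linspace(0.0, fmax, n_freq), fs)

    @property
    def n_freq(self) -> int:
        return self.freqs.size

    @property
    def normalized(self) -> np.ndarray:
        """Angular frequencies 2*pi*f/fs in radians per sample."""
        return 2.0 * np.pi * self.freqs / self.fs


@dataclass(frozen=True)
class SpectralMatrixSet:
    """Per-frequency coefficient transform, transfer and cross-spectral density.

    ``A[k]`` is A(f_k) = I - sum_j A_j exp(-i 2 pi f_k j / fs), ``H[k]`` its
    inverse (the transfer function), and ``S[k] = H Sigma H^H`` the CPSD.
    """

    grid: FrequencyGrid
    A: np.ndarray  # (F, M, M) complex
    H: np.ndarray  # (F, M, M) complex
    S: np.ndarray  # (F, M, M) complex Hermitian


def coefficient_transform(coeffs: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """A(omega) = I - sum_k A_k e^{-i k omega} for angular frequencies omega."""
    p, m, _ = coeffs.shape
    lags = np.arange(1, p + 1)
    phase = np.exp(-1j * np.outer(omega, lags))  # (F, p)
    a = np.eye(m, dtype=complex) - np.einsum("fk,kij->fij", phase, coeffs)
    return a


def var_spectral_matrices(model: VARModel, grid: FrequencyGrid) -> SpectralMatrixSet:
    """Evaluate A(f), H(f)=A(f)^-1 and S(f)=H Sigma H^H on a frequency grid.

    H is obtained by a linear solve per frequency. A numerically singular
    A(f) raises with the offending frequency.
    """
    omega = grid.normalized
    a = coefficient_transform(model.coeffs, omega)
    m = model.n_channels
    eye = np.broadcast_to(np.eye(m, dtype=complex), a.shape)
    with np.errstate(all="ignore"):
        try:
            h = np.linalg.solve(a, eye)
        except np.linalg.LinAlgError as exc:
            # identify which frequency is singular for the error message
            for k, fk in enumerate(grid.freqs):
                if abs(np.linalg.det(a[k])) < 1e-300:
                    raise np.linalg.LinAlgError(
                        f"coefficient transform singular at f={fk:.6g} Hz"
                    ) from exc
            raise
    if not np.isfinite(h).all():
        bad = np.where(~np.isfinite(h).all(axis=(1, 2)))[0][0]
        raise np.linalg.LinAlgError(
            f"coefficient transform singular at f={grid.freqs[bad]:.6g} Hz"
        )
    s = h @ model.noise_cov @ np.conj(np.swapaxes(h, 1, 2))
    # enforce exact Hermitian symmetry against roundoff
    s = 0.5 * (s + np.conj(np.swapaxes(s, 1, 2)))
    return SpectralMatrixSet(grid=grid, A=a, H=h, S=s)


def lag_zero_covariance(model: VARModel) -> np.ndarray:
    """Exact process covariance Gamma(0) via the companion discrete Lyapunov
    equation P = F P F' + Q with Q the companion-embedded innovation cov."""
    p, m, _ = model.coeffs.shape
    comp = companion_matrix(model.coeffs)
    q = np.zeros((m * p, m * p))
    q[:m, :m] = model.noise_cov
    pmat = sla.solve_discrete_lyapunov(comp, q)
    return pmat[:m, :m]


def autocovariance_sequence(model: VARModel, max_lag: int) -> np.ndarray:
    """Exact autocovariances Gamma(k) = E[x(t) x(t-k)'] for k = 0..max_lag.

    Gamma(0..p-1) come from the companion Lyapunov solution; higher lags from
    the Yule-Walker recursion Gamma(k) = sum_j A_j Gamma(k-j).
    """
    p, m, _ = model.coeffs.shape
    comp = companion_matrix(model.coeffs)
    q = np.zeros((m * p, m * p))
    q[:m, :m] = model.noise_cov
    pmat = sla.solve_discrete_lyapunov(comp, q)
    gammas = [pmat[:m, j * m : (j + 1) * m] for j in range(min(p, max_lag + 1))]
    while len(gammas) <= max_lag:
        k = len(gammas)
        g = np.zeros((m, m))
        for j in range(1, p + 1):
            lag = k - j
            gj = gammas[lag] if lag >= 0 else gammas[-lag].T
            g = g + model.coeffs[j - 1] @ gj
        gammas.append(g)
    return np.stack(gammas[: max_lag + 1])


def simulate_var(
    model: VARModel,
    n_samples: int,
    seed: int | np.random.Generator | None = None,
    burn_in: int = 1000,
) -> MultichannelSeries:
    """Simulate ``n_samples`` observations of a stable VAR process.

    Gaussian innovations with covariance Sigma are drawn from
    ``numpy.random.default_rng(seed)`` (PCG64); identical (model, n, seed,
    burn_in) therefore yields bit-identical output. The recursion starts from
    zeros and ``burn_in`` initial samples are discarded.
    """
    if not model.is_stable:
        raise ValidationError(
            f"cannot simulate an unstable model (spectral radius {model.spectral_radius:.4f})"
        )
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    if burn_in < 0:
        raise ValidationError("burn_in must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p, m, _ = model.coeffs.shape
    total = n_samples + burn_in
    chol = np.linalg.cholesky(model.noise_cov)
    innov = rng.standard_normal((total, m)) @ chol.T
    x = np.zeros((total + p, m))
    coeffs = model.coeffs
    for t in range(total):
        acc = innov[t]
        for j in range(p):
            acc = acc + coeffs[j] @ x[t + p - 1 - j]
        x[t + p] = acc
    return MultichannelSeries(
        data=x[p + burn_in :], fs=model.fs, channel_labels=model.channel_labels
    )


def _lag_matrix(data: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Response Y (T-p, M) and lag-major regressors X (T-p, M*p)."""
    t, m = data.shape
    y = data[order:]
    x = np.concatenate(
        [data[order - k : t - k] for k in range(1, order + 1)], axis=1
    )
    return y, x


def fit_var_ols(series: MultichannelSeries, order: int) -> VARModel:
    """Ordinary-least-squares VAR fit (no intercept).

    Regresses x(t) on the ``order`` stacked lags; the innovation covariance is
    the residual covariance with divisor (T_eff - M*p), T_eff = T - p, an
    unbiased-flavour choice. Benchmark processes are zero mean, so no
    intercept is included; demean the series beforehand if needed.
    """
    if order < 1:
        raise ValidationError("order must be >= 1")
    t, m = series.data.shape
    if t <= m * order + 1:
        raise ValidationError(
            f"series too short: T={t} samples cannot identify a VAR({order}) "
            f"on {m} channels (need T > M*p + 1 = {m * order + 1})"
        )
    y, x = _lag_matrix(series.data, order)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValidationError(
            f"rank-deficient regressor matrix: rank {rank} < {x.shape[1]} columns "
            "(collinear or constant channels?)"
        )
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    t_eff = t - order
    dof = t_eff - m * order
    if dof <= 0:
        raise ValidationError("not enough samples for the residual covariance divisor")
    sigma = resid.T @ resid / dof
    sigma = 0.5 * (sigma + sigma.T)
    coeffs = np.stack(
        [beta[k * m : (k + 1) * m].T for k in range(order)]
    )  # beta rows are lag-major blocks; A_k = block_k^T
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # fitted models may be unstable
        return make_var(coeffs, sigma, fs=series.fs, labels=series.channel_labels)


def _information_criterion(series: MultichannelSeries, order: int, criterion: str) -> float:
    t, m = series.data.shape
    y, x = _lag_matrix(series.data, order)
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    t_eff = t - order
    sigma_ml = resid.T @ resid / t_eff
    sign, logdet = np.linalg.slogdet(sigma_ml)
    if sign <= 0:
        return np.inf
    k_params = m * m * order
    if criterion == "aic":
        penalty = 2.0 * k_params / t_eff
    elif criterion == "bic":
        penalty = np.log(t_eff) * k_params / t_eff
    else:
        raise ValidationError(f"unknown criterion {criterion!r} (use 'aic' or 'bic')")
    return float(logdet + penalty)


def select_order(
    series: MultichannelSeries, max_order: int, criterion: str = "bic"
) -> int:
    """Order minimizing AIC or BIC over 1..max_order; ties break to the
    smaller order."""
    if max_order < 1:
        raise ValidationError("max_order must be >= 1")
    scores = [
        _information_criterion(series, p, criterion) for p in range(1, max_order + 1)
    ]
    return int(np.argmin(scores)) + 1  # argmin takes the first (smallest) minimizer


# ---------------------------------------------------------------------------
# I/O: model JSON and series CSV
# ---------------------------------------------------------------------------


def save_model_json(model: VARModel, path) -> None:
    payload = {
        "order": model.order,
        "coeffs": model.coeffs.tolist(),
        "noise_cov": model.noise_cov.tolist(),
        "fs": model.fs,
        "labels": list(model.channel_labels),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model_json(path) -> VARModel:
    payload = json.loads(Path(path).read_text())
    return make_var(
        payload["coeffs"],
        payload["noise_cov"],
        fs=payload.get("fs", 1.0),
        labels=payload.get("labels"),
    )


def save_series_csv(series: MultichannelSeries, path, sidecar: bool = True) -> None:
    """Write the series as CSV (header = labels, one row per sample) with an
    optional sidecar JSON carrying the sampling rate."""
    df = pd.DataFrame(series.data, columns=list(series.channel_labels))
    df.to_csv(path, index=False, float_format="%.12g")
    if sidecar:
        Path(str(path) + ".json").write_text(json.dumps({"fs": series.fs}))


def load_series_csv(path, fs: float | None = None) -> MultichannelSeries:
    """Read a series CSV; the sampling rate comes from ``fs`` or the sidecar
    ``<path>.json``."""
    df = pd.read_csv(path)
    if fs is None:
        sidecar = Path(str(path) + ".json")
        if sidecar.exists():
            fs = json.loads(sidecar.read_text())["fs"]
        else:
            raise ValidationError(
                f"no sampling rate given and no sidecar found at {sidecar}"
            )
    return MultichannelSeries(
        data=df.to_numpy(dtype=float), fs=float(fs), channel_labels=tuple(df.columns)
    )
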