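"""Classical Geweke frequency-domain Granger causality.

Bivariate spectral GC decomposes the target's power spectrum into an
intrinsic part and a part driven by the (partialized) source innovations,

    f_{s->t}(f) = ln [ S_tt(f) / (S_tt(f) - sigma~^2_ss |H_ts(f)|^2) ],

where sigma~^2_ss = Sigma_ss - Sigma_ts^2 / Sigma_tt removes any
instantaneous correlation (Geweke's normalization; a no-op for diagonal
Sigma).

Conditional spectral GC follows Geweke's construction: a *reduced* model is
fitted on {target} u cond (source excluded), the full system is filtered
through the inverse reduced transfer, and the bivariate-style ratio is
applied with the flat reduced innovation variance in the numerator. The
"standard method" here fits both models to data by OLS at user-given orders
— the estimator whose bias/variance pathology the state-space route
(:mod:`specgc.state_space_gc`) avoids. The *theoretical* variant computes
the same quantity from exact model parameters, with the reduced model
obtained either by a high-order Yule-Walker projection or (preferred) by the
state-space closed form; the two routes agree to numerical precision and
cross-validate each other.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg as sla

from ._spectrum import CausalitySpectrum
from .state_space_gc import (
    _clamped_log_ratio,
    _conditional_gc_curve,
    ss_conditional_spectral_gc,
    subprocess_innovations,
    var_to_ss,
)
from .var_models import (
    FrequencyGrid,
    MultichannelSeries,
    VARModel,
    ValidationError,
    autocovariance_sequence,
    coefficient_transform,
    fit_var_ols,
    var_spectral_matrices,
)

__all__ = [
    "bivariate_spectral_gc",
    "conditional_spectral_gc_var",
    "theoretical_conditional_gc",
    "time_domain_gc",
    "time_domain_gc_null",
    "yule_walker_projection",
]

DEFAULT_PROJECTION_ORDER = 128


def _roles(labels, source, target, cond_set):
    def idx(ch):
        if isinstance(ch, str):
            try:
                return list(labels).index(ch)
            except ValueError:
                raise ValidationError(
                    f"unknown channel {ch!r}; labels are {list(labels)}"
                ) from None
        return int(ch)

    s, t = idx(source), idx(target)
    cond = [idx(c) for c in (cond_set or [])]
    if s == t:
        raise ValidationError("source and target must differ")
    if s in cond or t in cond:
        raise ValidationError("conditioning set must exclude source and target")
    return s, t, cond


def bivariate_spectral_gc(
    model2: VARModel, grid: FrequencyGrid, source=0, target=1
) -> CausalitySpectrum:
    """Geweke bivariate spectral GC for a two-channel VAR model."""
    if model2.n_channels != 2:
        raise ValidationError("bivariate GC requires a 2-channel model")
    s = model2.label_index(source)
    t = model2.label_index(target)
    if s == t:
        raise ValidationError("source and target must differ")
    spect = var_spectral_matrices(model2, grid)
    sigma = model2.noise_cov
    s_tt = np.real(spect.S[:, t, t])
    sig_part = sigma[s, s] - sigma[t, s] ** 2 / sigma[t, t]
    causal = (np.abs(spect.H[:, t, s]) ** 2) * sig_part
    vals, n_clamped = _clamped_log_ratio(s_tt, s_tt - causal)
    return CausalitySpectrum(
        kind="GGC",
        source=model2.channel_labels[s],
        target=model2.channel_labels[t],
        cond=(),
        grid=grid,
        values=vals,
        provenance={"route": "bivariate", "mode": "theoretical", "n_clamped": n_clamped},
    )


def yule_walker_projection(
    gammas: np.ndarray, order: int
) -> tuple[np.ndarray, np.ndarray]:
    """Best finite-order VAR approximation of a stationary process from its
    exact autocovariances Gamma(0..order) (block Yule-Walker / Whittle
    normal equations).

    Returns (coeffs (order, M, M), residual covariance). Used to project a
    VARMA subprocess onto a high-order VAR; the truncation error decays with
    the process' spectral radius to the power of ``order``.
    """
    m = gammas.shape[1]
    p = order
    if gammas.shape[0] < p + 1:
        raise ValidationError("need autocovariances up to the requested order")
    # R[i, j] = Gamma(j - i); B[:, i] = Gamma(1 + i)
    r = np.empty((m * p, m * p))
    for i in range(p):
        for j in range(p):
            lag = j - i
            g = gammas[lag] if lag >= 0 else gammas[-lag].T
            r[i * m : (i + 1) * m, j * m : (j + 1) * m] = g
    b = np.concatenate([gammas[1 + i] for i in range(p)], axis=1)  # (M, M*p)
    a_stack = sla.solve(r.T, b.T, assume_a="pos").T  # A_stack R = B
    coeffs = np.stack([a_stack[:, k * m : (k + 1) * m] for k in range(p)])
    sigma = gammas[0].copy()
    for j in range(1, p + 1):
        sigma -= coeffs[j - 1] @ gammas[j].T
    sigma = 0.5 * (sigma + sigma.T)
    return coeffs, sigma


def _var_conditional_curve(
    coeffs_full,
    sigma_full,
    coeffs_red,
    sigma_red,
    grid,
    n_red,
):
    """Conditional Geweke ratio from explicit full/reduced VAR parameter sets,
    both expressed in the channel ordering [target, cond..., source] (full)
    and [target, cond...] (reduced)."""
    omega = grid.normalized
    a_full = coefficient_transform(coeffs_full, omega)
    mw = coeffs_full.shape[1]
    h_w = np.linalg.solve(a_full, np.broadcast_to(np.eye(mw, dtype=complex), a_full.shape))
    a_red = coefficient_transform(coeffs_red, omega)  # direct transform; no inversion
    # row 0 of Q = diag(A_red, I) @ H_W  ->  A_red[0, :] @ H_W[:n_red, :]
    q_row_t = np.einsum("fk,fkj->fj", a_red[:, 0, :], h_w[:, :n_red, :])
    return _conditional_gc_curve(float(sigma_red[0, 0]), q_row_t, sigma_full, n_red)


def conditional_spectral_gc_var(
    series: MultichannelSeries,
    source,
    target,
    cond_set=(),
    order_full: int = 3,
    order_reduced: int | None = None,
    grid: FrequencyGrid | None = None,
) -> CausalitySpectrum:
    """The standard full/reduced VAR estimator of conditional spectral GC.

    Fits a full VAR on {target} u cond u {source} at ``order_full`` and a
    separate reduced VAR on {target} u cond at ``order_reduced`` (defaults to
    the same order — the usual practice), then applies Geweke's spectral
    ratio. The reduced model is structurally misspecified at any finite
    order, which is exactly the source of this estimator's bias (low order)
    or variance (high order).
    """
    if order_reduced is None:
        order_reduced = order_full
    if grid is None:
        grid = FrequencyGrid.default(series.fs)
    labels = list(series.channel_labels)
    s, t, cond = _roles(labels, source, target, cond_set)
    w_order = [t] + cond + [s]
    r_order = [t] + cond

    sub_full = MultichannelSeries(
        series.data[:, w_order], series.fs, tuple(labels[i] for i in w_order)
    )
    sub_red = MultichannelSeries(
        series.data[:, r_order], series.fs, tuple(labels[i] for i in r_order)
    )
    fit_full = fit_var_ols(sub_full, order_full)
    fit_red = fit_var_ols(sub_red, order_reduced)
    vals, n_clamped = _var_conditional_curve(
        fit_full.coeffs,
        fit_full.noise_cov,
        fit_red.coeffs,
        fit_red.noise_cov,
        grid,
        len(r_order),
    )
    return CausalitySpectrum(
        kind="GGC",
        source=labels[s],
        target=labels[t],
        cond=tuple(labels[c] for c in cond),
        grid=grid,
        values=vals,
        provenance={
            "route": "var-full-reduced",
            "mode": "estimated",
            "estimator": "var",
            "order_full": order_full,
            "order_reduced": order_reduced,
            "n_clamped": n_clamped,
        },
    )


def theoretical_conditional_gc(
    model: VARModel,
    source,
    target,
    cond_set=(),
    grid: FrequencyGrid | None = None,
    reduced_order: int = DEFAULT_PROJECTION_ORDER,
    method: str = "ss",
) -> CausalitySpectrum:
    """True conditional spectral GC from exact model parameters.

    ``method="ss"`` (default) delegates to the state-space closed form.
    ``method="projection"`` instead projects the reduced (and, if channels
    are marginalized, the joint) subprocess onto a VAR(``reduced_order``) via
    exact-autocovariance Yule-Walker; the two routes agree to ~1e-6 for the
    benchmark systems at the default order and serve as mutual oracles.
    """
    if grid is None:
        grid = FrequencyGrid.default(model.fs)
    if method == "ss":
        spec = ss_conditional_spectral_gc(var_to_ss(model), source, target, cond_set, grid)
        spec.provenance["mode"] = "theoretical"
        return spec
    if method != "projection":
        raise ValidationError(f"unknown method {method!r} (use 'ss' or 'projection')")

    labels = list(model.channel_labels)
    s, t, cond = _roles(labels, source, target, cond_set)
    w_order = [t] + cond + [s]
    r_order = [t] + cond
    gammas = autocovariance_sequence(model, reduced_order)

    if sorted(w_order) == list(range(model.n_channels)):
        perm = np.array(w_order)
        coeffs_full = model.coeffs[:, perm][:, :, perm]
        sigma_full = model.noise_cov[np.ix_(perm, perm)]
    else:
        gw = gammas[:, w_order][:, :, w_order]
        coeffs_full, sigma_full = yule_walker_projection(gw, reduced_order)
    gr = gammas[:, r_order][:, :, r_order]
    coeffs_red, sigma_red = yule_walker_projection(gr, reduced_order)

    vals, n_clamped = _var_conditional_curve(
        coeffs_full, sigma_full, coeffs_red, sigma_red, grid, len(r_order)
    )
    return CausalitySpectrum(
        kind="GGC",
        source=labels[s],
        target=labels[t],
        cond=tuple(labels[c] for c in cond),
        grid=grid,
        values=vals,
        provenance={
            "route": "projection",
            "mode": "theoretical",
            "reduced_order": reduced_order,
            "n_clamped": n_clamped,
        },
    )


def time_domain_gc(
    model_or_series,
    source,
    target,
    cond_set=(),
    order: int | None = None,
    order_reduced: int | None = None,
) -> float:
    """Time-domain Geweke GC F_{source->target|cond} = ln(var_R / var_F).

    For a :class:`VARModel` input the variances are the exact innovation
    variances of the reduced ({target} u cond) and joint subprocesses from
    the state-space reduction. For a series input they are OLS residual
    variances of full and reduced fits (``order`` required). Geweke's
    spectral-integral identity makes this the spectral-curve average for
    these processes.
    """
    if isinstance(model_or_series, VARModel):
        model = model_or_series
        labels = list(model.channel_labels)
        s, t, cond = _roles(labels, source, target, cond_set)
        ss = var_to_ss(model)
        w_order = [t] + cond + [s]
        if sorted(w_order) == list(range(model.n_channels)):
            var_full = model.noise_cov[t, t]
        else:
            _, v_w = subprocess_innovations(ss, w_order)
            var_full = v_w[0, 0]
        _, v_r = subprocess_innovations(ss, [t] + cond)
        val = float(np.log(v_r[0, 0] / var_full))
        return max(val, 0.0)

    series = model_or_series
    if order is None:
        raise ValidationError("estimating time-domain GC from data requires an order")
    if order_reduced is None:
        order_reduced = order
    labels = list(series.channel_labels)
    s, t, cond = _roles(labels, source, target, cond_set)
    w_order = [t] + cond + [s]
    r_order = [t] + cond
    sub_full = MultichannelSeries(
        series.data[:, w_order], series.fs, tuple(labels[i] for i in w_order)
    )
    sub_red = MultichannelSeries(
        series.data[:, r_order], series.fs, tuple(labels[i] for i in r_order)
    )
    fit_full = fit_var_ols(sub_full, order)
    fit_red = fit_var_ols(sub_red, order_reduced)
    v_full = fit_full.noise_cov[0, 0]
    v_red = fit_red.noise_cov[0, 0]
    if v_full <= 0 or v_red <= 0:
        raise ValidationError("non-positive residual variance in time-domain GC")
    return float(np.log(v_red / v_full))


def time_domain_gc_null(
    series: MultichannelSeries,
    source,
    target,
    cond_set=(),
    order: int = 3,
    n_perm: int = 100,
    seed: int | None = None,
    method: str = "circular_shift",
) -> np.ndarray:
    """Null distribution of the estimated time-domain GC obtained by
    destroying the temporal alignment of the source channel (circular shifts
    at random offsets, or time reversal) while leaving its marginal dynamics
    intact."""
    rng = np.random.default_rng(seed)
    labels = list(series.channel_labels)
    s_idx, _, _ = _roles(labels, source, target, cond_set)
    t_len = series.n_samples
    out = np.empty(n_perm)
    for i in range(n_perm):
        data = series.data.copy()
        if method == "circular_shift":
            shift = int(rng.integers(order + 1, t_len - order - 1))
            data[:, s_idx] = np.roll(data[:, s_idx], shift)
        elif method == "time_reversal":
            data[:, s_idx] = data[::-1, s_idx]
            if i > 0:
                shift = int(rng.integers(order + 1, t_len - order - 1))
                data[:, s_idx] = np.roll(data[:, s_idx], shift)
        else:
            raise ValidationError(f"unknown null method {method!r}")
        surrogate = MultichannelSeries(data, series.fs, series.channel_labels)
        out[i] = time_domain_gc(surrogate, source, target, cond_set, order=order)
    return out
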