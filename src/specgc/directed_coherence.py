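"""Directed coherence, partial directed coherence, and causal spectral
decomposition.

Directed coherence (DC) measures, per frequency, the fraction of the target
channel's spectral power that arrives from each source's innovations: with
diagonal innovation covariance,

    |gamma_{i<-j}(f)|^2 = sigma^2_j |H_ij(f)|^2 / sum_m sigma^2_m |H_im(f)|^2 ,

so the squared magnitudes sum to 1 over sources j for each target i (row
normalization). Partial directed coherence (PDC) is the dual, built on the
coefficient transform A(f) rather than the transfer H(f): it sees only
*direct* links, and its squared magnitudes sum to 1 over targets i for each
source j (column normalization).

Because DC is a power fraction, it decomposes the receiver's spectrum:
S_{t|j}(f) = S_tt(f) |gamma_{t<-j}(f)|^2 is the portion of the target PSD
causally explained by source j, the j = t term is the autonomous part, and
the portions sum exactly to S_tt(f). For bivariate processes DC is
analytically tied to Geweke's spectral GC: GG_{1->2} = -ln(1 - |DC_1->2|^2)
when the innovations are uncorrelated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _counters as counters
from ._spectrum import CausalitySpectrum
from .var_models import (
    FrequencyGrid,
    VARModel,
    ValidationError,
    var_spectral_matrices,
)

__all__ = [
    "CoherenceSet",
    "SpectralDecomposition",
    "directed_coherence",
    "partial_directed_coherence",
    "spectral_decomposition",
]

_CORR_WARN_THRESHOLD = 0.01


@dataclass(frozen=True)
class CoherenceSet:
    """Squared-magnitude DC or PDC for all ordered pairs on a grid.

    ``values[k, i, j]`` is the squared measure from source channel j to
    target channel i at grid frequency k (diagonal = autonomous term).
    """

    kind: str  # "DC" | "PDC"
    grid: FrequencyGrid
    values: np.ndarray  # (F, M, M) real in [0, 1]
    channel_labels: tuple[str, ...]

    def get(self, source, target) -> np.ndarray:
        i = self._idx(target)
        j = self._idx(source)
        return self.values[:, i, j]

    def _idx(self, ch) -> int:
        if isinstance(ch, str):
            return list(self.channel_labels).index(ch)
        return int(ch)

    def spectra(self):
        """Yield one :class:`CausalitySpectrum` per ordered pair (incl. the
        autonomous diagonal terms)."""
        m = len(self.channel_labels)
        for i in range(m):
            for j in range(m):
                yield CausalitySpectrum(
                    kind=self.kind,
                    source=self.channel_labels[j],
                    target=self.channel_labels[i],
                    cond=(),
                    grid=self.grid,
                    values=self.values[:, i, j],
                    provenance={"mode": "theoretical"},
                )


def _check_innovation_correlation(model: VARModel) -> float:
    sigma = model.noise_cov
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    off = np.abs(corr - np.diag(np.diag(corr)))
    return float(off.max()) if off.size else 0.0


def directed_coherence(
    model: VARModel,
    grid: FrequencyGrid | None = None,
    orthogonalize: str | None = None,
) -> CoherenceSet:
    """Squared-magnitude directed coherence for every ordered channel pair.

    Default uses the diagonal-Sigma formula and warns when innovation
    cross-correlations exceed 1%. ``orthogonalize="cholesky"`` applies the
    (channel-ordering-dependent) lower-Cholesky orthogonalization of the
    innovations instead.
    """
    if grid is None:
        grid = FrequencyGrid.default(model.fs)
    if not model.is_stable:
        raise ValidationError("directed coherence requires a stable model")
    spect = var_spectral_matrices(model, grid)
    sigma = model.noise_cov
    if orthogonalize is None:
        max_corr = _check_innovation_correlation(model)
        if max_corr > _CORR_WARN_THRESHOLD:
            counters.count("correlated_innovation_dc_warnings")
            warnings.warn(
                f"innovation cross-correlation up to {max_corr:.3f}; the "
                "diagonal-covariance DC formula ignores it (consider "
                "orthogonalize='cholesky')",
                RuntimeWarning,
                stacklevel=2,
            )
        weighted = (np.abs(spect.H) ** 2) * np.diag(sigma)[None, None, :]
    elif orthogonalize == "cholesky":
        chol = np.linalg.cholesky(sigma)
        weighted = np.abs(spect.H @ chol) ** 2
    else:
        raise ValidationError(f"unknown orthogonalize option {orthogonalize!r}")
    totals = weighted.sum(axis=2, keepdims=True)  # = diag S(f), > 0 for PD Sigma
    if np.any(totals <= 0):
        raise RuntimeError("zero total spectral power encountered (non-PD input?)")
    return CoherenceSet(
        kind="DC",
        grid=grid,
        values=weighted / totals,
        channel_labels=model.channel_labels,
    )


def partial_directed_coherence(
    model: VARModel, grid: FrequencyGrid | None = None
) -> CoherenceSet:
    """Squared-magnitude (original, coefficient-based) PDC for every ordered
    pair; columns sum to 1 per source."""
    if grid is None:
        grid = FrequencyGrid.default(model.fs)
    if not model.is_stable:
        raise ValidationError("partial directed coherence requires a stable model")
    spect = var_spectral_matrices(model, grid)
    mags = np.abs(spect.A) ** 2
    totals = mags.sum(axis=1, keepdims=True)  # per source column j
    if np.any(totals <= 0):
        raise RuntimeError("zero column norm in the coefficient transform")
    return CoherenceSet(
        kind="PDC",
        grid=grid,
        values=mags / totals,
        channel_labels=model.channel_labels,
    )


@dataclass(frozen=True)
class SpectralDecomposition:
    """Causal decomposition of one channel's PSD: S_tt(f) split into the
    portions explained by each source's innovations (autonomous part at
    ``source == target``). Portions sum to the total by construction."""

    target: str
    grid: FrequencyGrid
    total_psd: np.ndarray  # (F,) real
    partial_psd: dict[str, np.ndarray]  # source label -> (F,)
    channel_labels: tuple[str, ...]

    def autonomous(self) -> np.ndarray:
        return self.partial_psd[self.target]

    def additivity_error(self) -> float:
        total = np.sum(list(self.partial_psd.values()), axis=0)
        return float(np.max(np.abs(total - self.total_psd)))


def spectral_decomposition(
    model: VARModel,
    grid: FrequencyGrid | None = None,
    target=0,
    orthogonalize: str | None = None,
) -> SpectralDecomposition:
    """Decompose the target's PSD as S_{t|j}(f) = S_tt(f) |gamma_{t<-j}(f)|^2."""
    if grid is None:
        grid = FrequencyGrid.default(model.fs)
    t = model.label_index(target)
    dc = directed_coherence(model, grid, orthogonalize=orthogonalize)
    spect = var_spectral_matrices(model, grid)
    s_tt = np.real(spect.S[:, t, t])
    partial = {
        model.channel_labels[j]: s_tt * dc.values[:, t, j]
        for j in range(model.n_channels)
    }
    return SpectralDecomposition(
        target=model.channel_labels[t],
        grid=grid,
        total_psd=s_tt,
        partial_psd=partial,
        channel_labels=model.channel_labels,
    )
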