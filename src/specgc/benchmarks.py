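"""Benchmark systems and the Monte Carlo estimator-comparison study.

Two simulated systems exercise the estimators:

* **three_node** — a 3-channel VAR(3) of damped stochastic oscillators
  resonating at 40, 10 and 50 Hz (fs = 120 Hz) with a unidirectional
  coupling chain 1 -> 2 -> 3. The direction 3 -> 1 carries no coupling, so
  its true conditional GC is identically zero — the canonical probe for
  estimator bias.
* **two_node** — a transmitter oscillating at 50 Hz driving a receiver whose
  own resonance is varied (10/30/50 Hz) with the coupling untouched. The
  transmitter PSD, the DC and the spectral GC from 1 to 2 are invariant to
  the receiver's dynamics; the causal part of the receiver spectrum
  S_{2|1}(f) = S_22(f) |DC_{1->2}(f)|^2 is not.

Each diagonal block is an AR(2) with complex-conjugate poles at radius rho
and angle 2 pi f0 / fs (a1 = 2 rho cos(2 pi f0/fs), a2 = -rho^2), placing a
spectral peak near f0. Coupling is strictly lower-triangular in channel
order, so the companion eigenvalues are those of the uncoupled oscillators
and stability is inherited from rho < 1.

The study runner draws ``n_realizations`` independent series (seed_i =
master_seed + i), applies each requested estimator to each displayed
direction, and summarizes per-frequency medians and 5th-95th percentile
bands against the true (state-space closed-form) reference curve.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .geweke_gc import conditional_spectral_gc_var, theoretical_conditional_gc
from .state_space_gc import ss_gc_from_data
from .var_models import (
    FrequencyGrid,
    VARModel,
    ValidationError,
    make_var,
    simulate_var,
)

__all__ = [
    "BenchmarkConfig",
    "StudyResult",
    "load_default_config",
    "build_oscillator_var",
    "make_three_node_benchmark",
    "make_two_node_benchmark",
    "run_monte_carlo_study",
]


def load_default_config() -> dict:
    """The shipped, version-pinned benchmark defaults."""
    text = (
        importlib.resources.files("specgc")
        .joinpath("benchmark_defaults.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


@dataclass(frozen=True)
class BenchmarkConfig:
    """Resolved configuration for one benchmark system plus study settings."""

    example: str  # "three_node" | "two_node"
    fs: float
    resonances_hz: tuple[float, ...]
    pole_radius: float
    couplings: tuple[dict, ...]  # {source, target, lag, value}, 1-based channels
    innovation_variances: tuple[float, ...]
    order: int
    n_samples: int = 500
    n_realizations: int = 100
    master_seed: int = 0
    burn_in: int = 1000
    n_freq: int = 513

    @classmethod
    def default(cls, example: str, **overrides) -> "BenchmarkConfig":
        raw = load_default_config()
        if example not in ("three_node", "two_node"):
            raise ValidationError(f"unknown benchmark example {example!r}")
        sec = raw[example]
        study = raw["study"]
        if example == "three_node":
            resonances = tuple(sec["resonances_hz"])
        else:
            resonances = (sec["transmitter_hz"], sec["receiver_hz"])
        cfg = cls(
            example=example,
            fs=float(raw["fs"]),
            resonances_hz=resonances,
            pole_radius=float(sec["pole_radius"]),
            couplings=tuple(sec["couplings"]),
            innovation_variances=tuple(sec["innovation_variances"]),
            order=int(sec["order"]),
            n_samples=int(study["n_samples"]),
            n_realizations=int(study["n_realizations"]),
            master_seed=int(study["master_seed"]),
            burn_in=int(study["burn_in"]),
            n_freq=int(study["n_freq"]),
        )
        return replace(cfg, **overrides) if overrides else cfg

    def grid(self) -> FrequencyGrid:
        return FrequencyGrid.default(self.fs, self.n_freq)


def build_oscillator_var(freq_hz: float, radius: float, fs: float) -> tuple[float, float]:
    """AR(2) coefficients (a1, a2) with conjugate poles at radius ``radius``
    and angle 2 pi freq_hz / fs — a stochastic oscillator resonating near
    ``freq_hz``."""
    if not 0 < freq_hz < fs / 2:
        raise ValidationError(
            f"resonance {freq_hz} Hz must lie strictly inside (0, fs/2 = {fs / 2})"
        )
    if not 0 < radius < 1:
        raise ValidationError(f"pole radius must be in (0, 1), got {radius}")
    theta = 2.0 * np.pi * freq_hz / fs
    return 2.0 * radius * np.cos(theta), -(radius**2)


def _assemble(config: BenchmarkConfig, labels) -> VARModel:
    m = len(config.resonances_hz)
    p = config.order
    coeffs = np.zeros((p, m, m))
    for i, f0 in enumerate(config.resonances_hz):
        a1, a2 = build_oscillator_var(f0, config.pole_radius, config.fs)
        coeffs[0, i, i] = a1
        coeffs[1, i, i] = a2
    for c in config.couplings:
        src, tgt, lag = int(c["source"]) - 1, int(c["target"]) - 1, int(c["lag"])
        if not 1 <= lag <= p:
            raise ValidationError(f"coupling lag {lag} exceeds model order {p}")
        coeffs[lag - 1, tgt, src] = float(c["value"])
    sigma = np.diag(config.innovation_variances).astype(float)
    model = make_var(coeffs, sigma, fs=config.fs, labels=labels)
    if not model.is_stable:
        raise ValidationError(
            "benchmark model is unstable after coupling insertion; reduce the "
            "pole radius or coupling magnitudes"
        )
    return model


def make_three_node_benchmark(config: BenchmarkConfig | None = None) -> VARModel:
    """The 3-node chain system (40/10/50 Hz oscillators, 1->2->3 coupling)."""
    if config is None:
        config = BenchmarkConfig.default("three_node")
    if len(config.resonances_hz) != 3:
        raise ValidationError("three_node benchmark needs 3 resonance frequencies")
    for c in config.couplings:
        if (int(c["source"]), int(c["target"])) not in {(1, 2), (2, 3)}:
            raise ValidationError(
                "three_node couplings are restricted to the chain 1->2 and 2->3"
            )
    return _assemble(config, labels=("node1", "node2", "node3"))


def make_two_node_benchmark(
    receiver_freq_hz: float = 10.0, config: BenchmarkConfig | None = None
) -> VARModel:
    """The transmitter(50 Hz)->receiver system; only the receiver's own
    resonance varies across configurations, coupling identical."""
    if config is None:
        config = BenchmarkConfig.default("two_node")
    config = replace(
        config, resonances_hz=(config.resonances_hz[0], float(receiver_freq_hz))
    )
    for c in config.couplings:
        if (int(c["source"]), int(c["target"])) != (1, 2):
            raise ValidationError("two_node coupling must be 1->2 only")
    return _assemble(config, labels=("node1", "node2"))


# ---------------------------------------------------------------------------
# Monte Carlo study
# ---------------------------------------------------------------------------


def _parse_estimator(spec: str):
    """'var(3)', 'ss(20)' or 'oracle' -> (name, order|None)."""
    spec = spec.strip()
    if spec == "oracle":
        return "oracle", None
    for name in ("var", "ss"):
        if spec.startswith(name + "(") and spec.endswith(")"):
            return name, int(spec[len(name) + 1 : -1])
    raise ValidationError(
        f"unknown estimator spec {spec!r}; use 'var(p)', 'ss(p)' or 'oracle'"
    )


@dataclass(frozen=True)
class StudyResult:
    """Monte Carlo summary: per (estimator, direction, frequency) median and
    5th/95th percentiles over realizations, plus the true reference curve."""

    grid: FrequencyGrid
    directions: tuple[tuple[str, str, tuple[str, ...]], ...]  # (source, target, cond)
    estimators: tuple[str, ...]
    median: dict  # (estimator, direction_key) -> (F,)
    p5: dict
    p95: dict
    reference: dict  # direction_key -> (F,)
    n_realizations: int
    n_samples: int
    master_seed: int
    n_failed: int = 0
    raw: dict | None = field(default=None, repr=False)

    @staticmethod
    def direction_key(source, target, cond) -> str:
        cond_part = ",".join(cond)
        return f"{source}->{target}|{cond_part}" if cond_part else f"{source}->{target}"

    def integrated_abs_error(self, estimator: str, direction_key: str) -> float:
        """Trapezoidal integral (in Hz) of |median - reference|."""
        diff = np.abs(self.median[(estimator, direction_key)] - self.reference[direction_key])
        return float(np.trapezoid(diff, self.grid.freqs))

    def mean_band_width(self, estimator: str, direction_key: str) -> float:
        """Mean 5th-95th percentile band width over frequencies."""
        width = self.p95[(estimator, direction_key)] - self.p5[(estimator, direction_key)]
        return float(np.mean(width))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for src, tgt, cond in self.directions:
            key = self.direction_key(src, tgt, cond)
            for est in self.estimators:
                for k, f in enumerate(self.grid.freqs):
                    rows.append(
                        {
                            "estimator": est,
                            "source": src,
                            "target": tgt,
                            "cond_set": ",".join(cond),
                            "frequency_hz": f,
                            "median": self.median[(est, key)][k],
                            "p5": self.p5[(est, key)][k],
                            "p95": self.p95[(est, key)][k],
                            "reference": self.reference[key][k],
                        }
                    )
        return pd.DataFrame(rows)


def default_directions(model: VARModel):
    """All ordered pairs, each conditioned on the remaining channels."""
    labels = model.channel_labels
    out = []
    for s in labels:
        for t in labels:
            if s == t:
                continue
            cond = tuple(c for c in labels if c not in (s, t))
            out.append((s, t, cond))
    return tuple(out)


def displayed_directions(model: VARModel):
    """The three panels of the estimator-comparison figure for the 3-node
    system: 1->2|3, 2->3|1 and the uncoupled 3->1|2."""
    l = model.channel_labels
    return (
        (l[0], l[1], (l[2],)),
        (l[1], l[2], (l[0],)),
        (l[2], l[0], (l[1],)),
    )


def run_monte_carlo_study(
    model: VARModel,
    estimators=("var(3)", "var(20)", "ss(3)"),
    n_realizations: int = 100,
    n_samples: int = 500,
    grid: FrequencyGrid | None = None,
    master_seed: int = 0,
    directions=None,
    burn_in: int = 1000,
    keep_raw: bool = False,
) -> StudyResult:
    """Run the estimator-comparison study on a ground-truth model.

    Realization i uses seed ``master_seed + i``. A realization whose fit
    fails (e.g. an unstable high-order fit) is excluded with a logged count;
    more than 10% failures aborts the study.
    """
    if n_realizations < 2:
        raise ValidationError("need at least 2 realizations for percentile bands")
    if grid is None:
        grid = FrequencyGrid.default(model.fs)
    if directions is None:
        directions = (
            displayed_directions(model)
            if model.n_channels == 3
            else default_directions(model)
        )
    parsed = [(spec, *_parse_estimator(spec)) for spec in estimators]

    reference = {}
    for src, tgt, cond in directions:
        key = StudyResult.direction_key(src, tgt, cond)
        reference[key] = theoretical_conditional_gc(model, src, tgt, cond, grid).values

    samples: dict = {
        (spec, StudyResult.direction_key(*d)): [] for spec, _, _ in parsed for d in directions
    }
    n_failed = 0
    for i in range(n_realizations):
        seed = master_seed + i
        series = simulate_var(model, n_samples, seed=seed, burn_in=burn_in)
        try:
            for spec, name, order in parsed:
                for src, tgt, cond in directions:
                    key = StudyResult.direction_key(src, tgt, cond)
                    if name == "oracle":
                        vals = reference[key]
                    elif name == "var":
                        vals = conditional_spectral_gc_var(
                            series, src, tgt, cond, order_full=order, grid=grid
                        ).values
                    else:
                        vals = ss_gc_from_data(series, order, src, tgt, cond, grid).values
                    samples[(spec, key)].append(vals)
        except (ValidationError, RuntimeError, np.linalg.LinAlgError):
            n_failed += 1
            # drop any partial results from this realization
            for k, v in samples.items():
                depth = min(len(lst) for lst in samples.values())
                del v[depth:]
            if n_failed > 0.1 * n_realizations:
                raise RuntimeError(
                    f"{n_failed} of {n_realizations} realizations failed to fit; aborting"
                )

    median, p5, p95 = {}, {}, {}
    for key, vals in samples.items():
        arr = np.asarray(vals)
        median[key] = np.median(arr, axis=0)
        p5[key] = np.percentile(arr, 5, axis=0)
        p95[key] = np.percentile(arr, 95, axis=0)
    return StudyResult(
        grid=grid,
        directions=tuple(directions),
        estimators=tuple(estimators),
        median=median,
        p5=p5,
        p95=p95,
        reference=reference,
        n_realizations=n_realizations,
        n_samples=n_samples,
        master_seed=master_seed,
        n_failed=n_failed,
        raw={k: np.asarray(v) for k, v in samples.items()} if keep_raw else None,
    )
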