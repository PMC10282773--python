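"""Synthetic luminescence traces and expression time courses.

The trace generator emulates a luciferase reporter recording from an
excised leaf: a decaying baseline, a damped ~24-h circadian oscillation,
and a latent ~3-h ultradian component that switches on ~19 h after
excision and dampens out by ~60 h, plus additive measurement noise.  The
expression generator emulates a dense short time course (16 timepoints,
19-27 h after treatment, 30-min steps) in which a chosen fraction of genes
oscillates at ultradian periods.

Both generators are deterministic given their seed and return ground truth
suitable for parameter-recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .rhythms import ExpressionMatrix
from .wavelet import TimeSeriesTrace

__all__ = [
    "TraceModel",
    "ExpressionModel",
    "generate_trace",
    "generate_trace_set",
    "generate_expression_matrix",
]


@dataclass
class TraceModel:
    """Parameters of one synthetic excised-leaf reporter trace.

    Levels are arbitrary luminescence units; rates are per hour.  The
    ultradian component is windowed by a raised-cosine envelope that ramps
    up over ``ur_envelope_rise_h`` starting at ``ur_onset_h`` and ramps
    down to zero at ``ur_offset_h``.

    The default amplitudes, decay rates and noise level are calibrated so
    that a wild-type-like trace set scores an average ultradian wavelet
    power well above the 1.0 detection threshold while noise-only traces
    (both oscillation amplitudes zero) score well below it.
    """

    duration_h: float = 72.0
    dt_h: float = 0.5
    baseline: float = 100.0
    baseline_decay_rate: float = 0.02
    cr_period_h: float = 24.0
    cr_amplitude: float = 15.0
    cr_damping_rate: float = 0.02
    ur_period_h: float = 3.0
    ur_amplitude: float = 12.0
    ur_onset_h: float = 19.0
    ur_offset_h: float = 60.0
    ur_envelope_rise_h: float = 2.0
    noise_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.dt_h <= 0:
            raise ValueError("dt_h must be > 0")
        if self.duration_h < 2 * self.cr_period_h:
            raise ValueError("duration_h must be >= 2 * cr_period_h")
        if not (0 < self.ur_period_h < self.cr_period_h):
            raise ValueError("require 0 < ur_period_h < cr_period_h")
        if not (self.ur_onset_h < self.ur_offset_h <= self.duration_h + self.ur_envelope_rise_h):
            raise ValueError(
                "require ur_onset_h < ur_offset_h <= duration_h + ur_envelope_rise_h"
            )
        for name in ("baseline", "cr_amplitude", "ur_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def times_h(self) -> np.ndarray:
        n = int(round(self.duration_h / self.dt_h)) + 1
        return self.dt_h * np.arange(n)


def _raised_cosine_envelope(
    t: np.ndarray, onset: float, offset: float, rise: float
) -> np.ndarray:
    """Smooth 0->1->0 window: raised-cosine ramps inside [onset, offset]."""
    rise = min(rise, (offset - onset) / 2.0)
    env = np.zeros_like(t)
    if rise <= 0:
        env[(t >= onset) & (t <= offset)] = 1.0
        return env
    up = (t >= onset) & (t < onset + rise)
    env[up] = 0.5 * (1.0 - np.cos(np.pi * (t[up] - onset) / rise))
    env[(t >= onset + rise) & (t <= offset - rise)] = 1.0
    down = (t > offset - rise) & (t <= offset)
    env[down] = 0.5 * (1.0 - np.cos(np.pi * (offset - t[down]) / rise))
    return env


def _trace_values(
    model: TraceModel, rng: np.random.Generator, phi_cr: float, phi_ur: float
) -> np.ndarray:
    t = model.times_h()
    base = model.baseline * np.exp(-model.baseline_decay_rate * t)
    cr = (
        model.cr_amplitude
        * np.exp(-model.cr_damping_rate * t)
        * np.cos(2.0 * np.pi * t / model.cr_period_h + phi_cr)
    )
    env = _raised_cosine_envelope(
        t, model.ur_onset_h, model.ur_offset_h, model.ur_envelope_rise_h
    )
    ur = env * model.ur_amplitude * np.cos(2.0 * np.pi * t / model.ur_period_h + phi_ur)
    noise = rng.normal(0.0, model.noise_sd, t.size) if model.noise_sd > 0 else 0.0
    return base + cr + ur + noise


def generate_trace(model: TraceModel, sample_id: str = "sample_0") -> TimeSeriesTrace:
    """One synthetic reporter trace; phases drawn uniformly from the seed."""
    model.validate()
    rng = np.random.default_rng(model.seed)
    phi_cr, phi_ur = rng.uniform(0.0, 2.0 * np.pi, size=2)
    values = _trace_values(model, rng, phi_cr, phi_ur)
    return TimeSeriesTrace(sample_id=sample_id, times_h=model.times_h(), values=values)


def generate_trace_set(
    model: TraceModel,
    n_samples: int = 24,
    phase_jitter_h: float | None = None,
) -> list[TimeSeriesTrace]:
    """A set of traces with per-sample phases and independent noise.

    With ``phase_jitter_h=None`` (default) each sample draws its circadian
    and ultradian phases uniformly — leaves are excised asynchronously.
    Otherwise all samples share base phases drawn from ``model.seed`` and
    each is jittered uniformly within +/- ``phase_jitter_h`` hours (so
    ``phase_jitter_h=0`` with ``noise_sd=0`` gives identical traces).
    Per-sample seeds derive reproducibly from ``model.seed``.
    """
    model.validate()
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    base_rng = np.random.default_rng(model.seed)
    phi_cr0, phi_ur0 = base_rng.uniform(0.0, 2.0 * np.pi, size=2)
    children = np.random.SeedSequence(model.seed).spawn(n_samples)
    traces = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        if phase_jitter_h is None:
            phi_cr, phi_ur = rng.uniform(0.0, 2.0 * np.pi, size=2)
        else:
            jit = rng.uniform(-phase_jitter_h, phase_jitter_h, size=2)
            phi_cr = phi_cr0 + 2.0 * np.pi * jit[0] / model.cr_period_h
            phi_ur = phi_ur0 + 2.0 * np.pi * jit[1] / model.ur_period_h
        values = _trace_values(model, rng, phi_cr, phi_ur)
        traces.append(
            TimeSeriesTrace(sample_id=f"sample_{i}", times_h=model.times_h(), values=values)
        )
    return traces


@dataclass
class ExpressionModel:
    """Parameters of a synthetic expression time course.

    Rhythmic genes carry a cosine on the log2 scale with amplitude
    ``amplitude_log2`` and a period drawn uniformly from
    ``period_range_h``; phases are uniform over one period.  Noise is
    multiplicative lognormal (sd ``noise_log2_sd`` on the log2 scale) or
    negative binomial on the count scale with dispersion ``nb_dispersion``.
    The default amplitude-to-noise ratio of 3 reflects a robust oscillation
    over a dense, short sampling window.
    """

    n_genes: int = 1000
    frac_rhythmic: float = 0.3
    timepoints_h: np.ndarray = field(
        default_factory=lambda: 19.0 + 0.5 * np.arange(16)
    )
    period_range_h: tuple[float, float] = (2.9, 4.3)
    amplitude_log2: float = 1.0
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    noise_model: str = "lognormal"
    noise_log2_sd: float = 1.0 / 3.0
    nb_dispersion: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        tp = np.asarray(self.timepoints_h, dtype=float)
        if np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints_h must be strictly increasing")
        if not (0.0 <= self.frac_rhythmic <= 1.0):
            raise ValueError("frac_rhythmic must be in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.period_range_h
        step = float(np.median(np.diff(tp)))
        span = float(tp[-1] - tp[0])
        if not (2 * step < lo < hi <= span):
            raise ValueError(
                f"period_range_h {self.period_range_h} must lie within "
                f"(2*median step = {2*step:g}, span = {span:g}) h"
            )
        if self.noise_model not in ("lognormal", "negative-binomial"):
            raise ValueError("noise_model must be 'lognormal' or 'negative-binomial'")


def generate_expression_matrix(
    model: ExpressionModel,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Synthetic expression matrix plus its ground-truth table.

    Exactly ``round(frac_rhythmic * n_genes)`` genes (the first rows) carry
    a cosine signal; the rest are flat baselines plus noise.  Returns the
    matrix (linear scale) and a truth table with columns
    gene_id, is_rhythmic, true_period_h, true_phase_h.
    """
    model.validate()
    tp = np.asarray(model.timepoints_h, dtype=float)
    if tp.size < 8:
        warnings.warn(
            f"only {tp.size} timepoints; periodicity tests will be underpowered"
        )
    rng = np.random.default_rng(model.seed)
    n = model.n_genes
    n_rhythmic = int(round(model.frac_rhythmic * n))
    base = rng.normal(model.baseline_log_mean, model.baseline_log_sd, size=n)
    periods = np.full(n, np.nan)
    phases = np.full(n, np.nan)
    periods[:n_rhythmic] = rng.uniform(*model.period_range_h, size=n_rhythmic)
    phases[:n_rhythmic] = rng.uniform(0.0, 1.0, size=n_rhythmic) * periods[:n_rhythmic]

    log2_signal = np.tile(base[:, None], (1, tp.size)).astype(float)
    rhythm = model.amplitude_log2 * np.cos(
        2.0 * np.pi * (tp[None, :] - phases[:n_rhythmic, None]) / periods[:n_rhythmic, None]
    )
    log2_signal[:n_rhythmic] += rhythm

    if model.noise_model == "lognormal":
        values = 2.0 ** (log2_signal + rng.normal(0.0, model.noise_log2_sd, log2_signal.shape))
    else:
        mu = 2.0**log2_signal
        # NB with Var = mu + disp * mu^2, via gamma-Poisson mixture
        disp = model.nb_dispersion
        lam = rng.gamma(shape=1.0 / disp, scale=mu * disp) if disp > 0 else mu
        values = rng.poisson(lam).astype(float)

    gene_ids = [f"gene_{i:05d}" for i in range(n)]
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_rhythmic": np.arange(n) < n_rhythmic,
            "true_period_h": periods,
            "true_phase_h": phases,
        }
    )
    return ExpressionMatrix(gene_ids, tp, values), truth
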