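"""Ultradian power statistics on wavelet spectra.

The detection statistic is the average ultradian wavelet power: the mean
of variance-normalized power over the 2-6 h period band and over time
(cone-of-influence cells excluded), per sample, then averaged over
samples.  Because power is normalized so that white noise scores ~= 1, a
fixed threshold of 1.0 separates genuine ultradian oscillations from
noise; a sample whose average power exceeds the threshold is a detection.
The instantaneous power series (band-mean power per timepoint) localizes
the oscillation in time and yields onset/offset estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .wavelet import (
    CR_BAND_DEFAULT,
    UR_BAND_DEFAULT,
    PeriodBand,
    TimeSeriesTrace,
    WaveletSpectrum,
    cwt,
    decompose,
    preprocess,
)

__all__ = [
    "URResult",
    "GroupSummary",
    "ur_spectrum",
    "instantaneous_ur_power",
    "average_ur_power",
    "classify_ur",
    "estimate_period",
    "detect_window",
    "analyze_trace",
    "screen_mutants",
    "compare_groups",
]

THRESHOLD_DEFAULT = 1.0
MIN_RUN_DEFAULT_H = 2.0


@dataclass
class URResult:
    """Per-sample ultradian summary."""

    sample_id: str
    inst_power: np.ndarray
    times_h: np.ndarray
    avg_power: float
    dominant_period_h: float | None
    detected: bool
    onset_h: float | None = None
    offset_h: float | None = None

    def to_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "avg_power": self.avg_power,
            "period_h": self.dominant_period_h,
            "detected": self.detected,
            "onset_h": self.onset_h,
            "offset_h": self.offset_h,
        }


@dataclass
class GroupSummary:
    """One-way ANOVA with Tukey HSD letters across groups."""

    groups: list[str]
    means: dict[str, float]
    sems: dict[str, float]
    anova_f: float
    anova_p: float
    letters: dict[str, str]
    alpha: float
    tukey: pd.DataFrame = field(repr=False, default=None)


def ur_spectrum(
    trace: TimeSeriesTrace,
    cr_band: PeriodBand = CR_BAND_DEFAULT,
    periods_h: np.ndarray | None = None,
    detrend: str = "linear",
) -> WaveletSpectrum:
    """Wavelet spectrum of the circadian-subtracted residual of a trace.

    The trace is preprocessed, the circadian band reconstructed and
    subtracted, and the residual re-transformed — normalized by the
    variance of the *preprocessed trace* (not the residual), so ultradian
    power stays on the scale of the original recording and the 1.0
    white-noise threshold keeps its meaning.
    """
    pre = preprocess(trace, detrend=detrend)
    dec = decompose(pre, cr_band=cr_band, periods_h=periods_h, preprocessed=True)
    return cwt(dec.residual_trace(), periods_h=periods_h)


def _masked_band_power(spectrum: WaveletSpectrum, band: PeriodBand) -> np.ndarray:
    """Power restricted to the band, COI-masked cells set to NaN."""
    sel = band.mask(spectrum.periods_h)
    if not sel.any():
        raise ValueError(
            f"band [{band.lower_h}, {band.upper_h}] h does not intersect the period grid"
        )
    power = spectrum.power[sel].astype(float)
    ok = spectrum.coi_mask()[sel]
    return np.where(ok, power, np.nan)


def _window_mask(times_h: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.ones(times_h.size, dtype=bool)
    lo, hi = window
    mask = (times_h >= lo) & (times_h <= hi)
    if not mask.any():
        raise ValueError(f"window [{lo}, {hi}] h contains no timepoints")
    return mask


def instantaneous_ur_power(
    spectra: list[WaveletSpectrum],
    ur_band: PeriodBand = UR_BAND_DEFAULT,
):
    """Band-mean power per timepoint, averaged across samples.

    Per sample, the mean power over grid periods inside ``ur_band``
    (COI-masked cells excluded) at each timepoint; then across samples the
    mean and standard error per timepoint.  Timepoints whose band is fully
    inside the COI (the first/last ~2-3 h at ultradian scales) are NaN.

    Returns ``(times_h, mean, sem, per_sample)`` where per_sample is a
    (sample x time) array.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    times = spectra[0].times_h
    for sp in spectra[1:]:
        if sp.times_h.shape != times.shape or not np.allclose(sp.times_h, times):
            raise ValueError("all spectra must share one time grid")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns near edges
        per_sample = np.array(
            [np.nanmean(_masked_band_power(sp, ur_band), axis=0) for sp in spectra]
        )
        mean = np.nanmean(per_sample, axis=0)
        n_ok = np.sum(~np.isnan(per_sample), axis=0)
        sem = np.nanstd(per_sample, axis=0, ddof=1) / np.sqrt(np.maximum(n_ok, 1))
    return times, mean, sem, per_sample


def average_ur_power(
    spectra: list[WaveletSpectrum],
    ur_band: PeriodBand = UR_BAND_DEFAULT,
    window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, float]:
    """Time-and-band mean ultradian power per sample, and the group mean.

    The per-sample statistic is the mean of variance-normalized power over
    the period band and the time window (full record by default),
    excluding COI-masked cells.  Returns ``(per_sample, group_mean)``.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    out = []
    for sp in spectra:
        banded = _masked_band_power(sp, ur_band)[:, _window_mask(sp.times_h, window)]
        if np.isnan(banded).all():
            out.append(0.0)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out.append(float(np.nanmean(banded)))
    per_sample = np.array(out)
    return per_sample, float(per_sample.mean())


def classify_ur(avg_power: float, threshold: float = THRESHOLD_DEFAULT) -> bool:
    """Detection rule: average power strictly above the noise threshold.

    Boundary convention: a value exactly at the threshold is a
    non-detection.
    """
    if avg_power < 0:
        raise ValueError("avg_power must be >= 0")
    return bool(avg_power > threshold)


def estimate_period(
    spectrum: WaveletSpectrum,
    band: PeriodBand = UR_BAND_DEFAULT,
    window: tuple[float, float] | None = None,
) -> float | None:
    """Period (hours) maximizing time-averaged power within a band.

    A ridge summary: the grid period whose COI-excluded, time-averaged
    power is largest inside the band/window.  Ties break toward the
    shorter period; an all-zero band returns None.
    """
    banded = _masked_band_power(spectrum, band)[:, _window_mask(spectrum.times_h, window)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg = np.nanmean(banded, axis=1)
    avg = np.nan_to_num(avg, nan=0.0)
    if np.all(avg == 0):
        return None
    periods = spectrum.periods_h[band.mask(spectrum.periods_h)]
    return float(periods[np.argmax(avg)])  # argmax takes the first (shortest) on ties


def detect_window(
    times_h: np.ndarray,
    series: np.ndarray,
    threshold: float = THRESHOLD_DEFAULT,
    min_run_h: float = MIN_RUN_DEFAULT_H,
) -> tuple[float | None, float | None]:
    """Onset/offset of sustained supra-threshold power.

    Onset is the start time of the first run of consecutive timepoints
    above ``threshold`` lasting at least ``min_run_h`` (end minus start
    time); offset is the end of the last such run.  NaN values count as
    below threshold.  Returns ``(None, None)`` if no qualifying run.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(series, dtype=float)
    dt = float(np.median(np.diff(t)))
    if min_run_h < dt:
        raise ValueError(f"min_run_h ({min_run_h}) must be >= sampling step ({dt})")
    above = np.nan_to_num(y, nan=-np.inf) > threshold
    runs = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, above.size - 1))
    good = [(a, b) for a, b in runs if t[b] - t[a] >= min_run_h]
    if not good:
        return None, None
    return float(t[good[0][0]]), float(t[good[-1][1]])


def analyze_trace(
    trace: TimeSeriesTrace,
    cr_band: PeriodBand = CR_BAND_DEFAULT,
    ur_band: PeriodBand = UR_BAND_DEFAULT,
    threshold: float = THRESHOLD_DEFAULT,
    min_run_h: float = MIN_RUN_DEFAULT_H,
    window: tuple[float, float] | None = None,
    periods_h: np.ndarray | None = None,
) -> URResult:
    """Full per-sample ultradian analysis of one raw trace."""
    sp = ur_spectrum(trace, cr_band=cr_band, periods_h=periods_h)
    _, inst, _, _ = instantaneous_ur_power([sp], ur_band)
    per_sample, _ = average_ur_power([sp], ur_band, window)
    avg = float(per_sample[0])
    onset, offset = detect_window(sp.times_h, inst, threshold, min_run_h)
    return URResult(
        sample_id=trace.sample_id,
        inst_power=inst,
        times_h=sp.times_h,
        avg_power=avg,
        dominant_period_h=estimate_period(sp, ur_band, window),
        detected=classify_ur(avg, threshold),
        onset_h=onset,
        offset_h=offset,
    )


def screen_mutants(
    trace_sets: dict[str, list[TimeSeriesTrace]],
    cr_band: PeriodBand = CR_BAND_DEFAULT,
    ur_band: PeriodBand = UR_BAND_DEFAULT,
    threshold: float = THRESHOLD_DEFAULT,
    window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Score lines by group ultradian power and flag those lacking the rhythm.

    For each line: circadian subtraction, per-sample average ultradian
    power, group mean, detection against the threshold; ``ur_absent`` marks
    candidate lines whose group power does not exceed it.  Lines with no
    traces are skipped with a warning.
    """
    if not trace_sets:
        raise ValueError("need at least one line")
    rows = []
    for line, traces in trace_sets.items():
        if not traces:
            warnings.warn(f"line {line!r} has no traces; skipped")
            continue
        spectra = [ur_spectrum(tr, cr_band=cr_band) for tr in traces]
        _, group_power = average_ur_power(spectra, ur_band, window)
        detected = classify_ur(group_power, threshold)
        rows.append(
            {"line": line, "n": len(traces), "avg_power": group_power,
             "ur_absent": not detected}
        )
    return pd.DataFrame(rows)


def _maximal_cliques(adj: np.ndarray) -> list[frozenset]:
    """Maximal cliques of a small undirected graph (Bron-Kerbosch)."""
    n = adj.shape[0]
    neighbors = [set(np.flatnonzero(adj[i])) - {i} for i in range(n)]
    cliques: list[frozenset] = []

    def expand(r: set, p: set, x: set) -> None:
        if not p and not x:
            cliques.append(frozenset(r))
            return
        pivot = max(p | x, key=lambda v: len(neighbors[v] & p))
        for v in list(p - neighbors[pivot]):
            expand(r | {v}, p & neighbors[v], x & neighbors[v])
            p.remove(v)
            x.add(v)

    expand(set(), set(range(n)), set())
    return cliques


def compare_groups(
    powers_by_group: dict[str, np.ndarray],
    alpha: float = 0.01,
) -> GroupSummary:
    """One-way ANOVA with Tukey HSD and a compact letter display.

    Groups that share a letter are not significantly different at
    ``alpha`` (letters are the maximal cliques of the non-significance
    graph, ordered by group mean).  Raises if every group has zero
    within-group variance (the ANOVA denominator vanishes).
    """
    names = list(powers_by_group.keys())
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(powers_by_group[g], dtype=float) for g in names]
    for g, a in zip(names, arrays):
        if a.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    if all(np.var(a) == 0 for a in arrays):
        raise ValueError("all groups have zero within-group variance; ANOVA undefined")
    f_stat, p_val = stats.f_oneway(*arrays)

    res = stats.tukey_hsd(*arrays)
    k = len(names)
    ns = np.zeros((k, k), dtype=bool)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            p_ij = float(res.pvalue[i, j])
            ns[i, j] = ns[j, i] = p_ij >= alpha
            pairs.append({"group1": names[i], "group2": names[j], "p_adj": p_ij,
                          "significant": p_ij < alpha})
    np.fill_diagonal(ns, True)

    group_means = np.array([a.mean() for a in arrays])
    cliques = _maximal_cliques(ns)
    cliques.sort(key=lambda c: min(group_means[v] for v in c))
    letters = {name: "" for name in names}
    for idx, clique in enumerate(cliques):
        letter = chr(ord("a") + idx)
        for v in clique:
            letters[names[v]] += letter
    letters = {g: "".join(sorted(s)) for g, s in letters.items()}

    return GroupSummary(
        groups=names,
        means={g: float(a.mean()) for g, a in zip(names, arrays)},
        sems={g: float(a.std(ddof=1) / np.sqrt(a.size)) for g, a in zip(names, arrays)},
        anova_f=float(f_stat),
        anova_p=float(p_val),
        letters=letters,
        alpha=alpha,
        tukey=pd.DataFrame(pairs),
    )
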