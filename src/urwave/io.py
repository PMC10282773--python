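"""File formats, run configuration, and the two analysis pipelines.

Time is always in hours; tabular headers carry an ``_h`` suffix on time
columns.  Traces travel as tidy CSV (sample_id, time_h, value) or wide TSV
(one row per sample, columns named by time); expression matrices as TSV
with a gene_id column followed by one column per timepoint.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics, rhythms
from .rhythms import ExpressionMatrix, call_rhythmic_genes
from .wavelet import PeriodBand, TimeSeriesTrace, default_period_grid

__all__ = [
    "RunConfig",
    "read_traces",
    "write_traces",
    "read_expression",
    "write_expression",
    "run_trace_pipeline",
    "run_expression_pipeline",
]

logger = logging.getLogger("urwave")


@dataclass
class RunConfig:
    """Analysis parameters for both pipelines.

    Defaults are the study parameters: circadian band 16-32 h, ultradian
    band 2-6 h, detection threshold 1.0, gene-calling period window
    2-5 h at alpha 0.05.
    """

    cr_band: tuple[float, float] = (16.0, 32.0)
    ur_band: tuple[float, float] = (2.0, 6.0)
    threshold: float = 1.0
    min_run_h: float = 2.0
    detrend: str = "linear"
    omega0: float = 6.0
    period_grid_lower_h: float = 1.0
    period_grid_upper_h: float = 48.0
    period_grid_dj: float = 0.05
    minper: float = 2.0
    maxper: float = 5.0
    alpha: float = 0.05
    log_transform: bool = True
    window: tuple[float, float] | None = None
    seed: int = 0

    def cr(self) -> PeriodBand:
        return PeriodBand(*self.cr_band)

    def ur(self) -> PeriodBand:
        return PeriodBand(*self.ur_band)

    def periods_h(self) -> np.ndarray:
        return default_period_grid(
            self.period_grid_lower_h, self.period_grid_upper_h, self.period_grid_dj
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cr_band"] = list(d["cr_band"])
        d["ur_band"] = list(d["ur_band"])
        if d["window"] is not None:
            d["window"] = list(d["window"])
        return d

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
            else:
                json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        for key in ("cr_band", "ur_band", "window"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(float(v) for v in kwargs[key])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Trace IO


def _trace_from_sample(sample_id: str, times: np.ndarray, values: np.ndarray) -> TimeSeriesTrace:
    order = np.argsort(times)
    times, values = times[order], values[order]
    steps = np.diff(times)
    if steps.size:
        step = np.median(steps)
        bad = np.flatnonzero(~np.isclose(steps, step, rtol=1e-6, atol=1e-9))
        if bad.size:
            where = ", ".join(f"{times[b]:g}->{times[b+1]:g} h" for b in bad[:5])
            raise ValueError(
                f"sample {sample_id!r} is not uniformly sampled (gaps at {where}); "
                "fill or resample missing timepoints before analysis"
            )
    if np.isnan(values).any():
        t_bad = times[np.isnan(values)]
        raise ValueError(
            f"sample {sample_id!r} has missing values at t = "
            + ", ".join(f"{v:g}" for v in t_bad[:5])
        )
    return TimeSeriesTrace(sample_id=str(sample_id), times_h=times, values=values)


def read_traces(path: str | Path, dialect: str = "auto") -> list[TimeSeriesTrace]:
    """Read traces from tidy CSV (sample_id, time_h, value) or wide TSV.

    ``dialect="auto"`` decides by header: a ``time_h`` column means tidy.
    Duplicate (sample, time) rows and non-uniform grids are rejected with
    the offending entries named.
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if dialect == "auto":
        dialect = "tidy" if "time_h" in df.columns else "wide"
    traces = []
    if dialect == "tidy":
        required = {"sample_id", "time_h", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"tidy trace file must have columns {sorted(required)}")
        dup = df.duplicated(subset=["sample_id", "time_h"], keep=False)
        if dup.any():
            offenders = df.loc[dup, ["sample_id", "time_h"]].drop_duplicates()
            raise ValueError(
                "duplicate (sample, time) rows: "
                + "; ".join(f"{r.sample_id}@{r.time_h:g}h" for r in offenders.itertuples())
            )
        for sid, sub in df.groupby("sample_id", sort=False):
            traces.append(
                _trace_from_sample(sid, sub["time_h"].to_numpy(float), sub["value"].to_numpy(float))
            )
    elif dialect == "wide":
        first = df.columns[0]
        times = np.array([float(c) for c in df.columns[1:]])
        if df[first].duplicated().any():
            dups = df.loc[df[first].duplicated(), first].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        for row in df.itertuples(index=False):
            traces.append(_trace_from_sample(row[0], times.copy(), np.array(row[1:], float)))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return traces


def write_traces(
    traces: list[TimeSeriesTrace], path: str | Path, dialect: str = "tidy"
) -> None:
    """Write traces as tidy CSV or wide TSV (dialect ``tidy``/``wide``)."""
    path = Path(path)
    if dialect == "tidy":
        df = pd.concat(
            [
                pd.DataFrame(
                    {"sample_id": tr.sample_id, "time_h": tr.times_h, "value": tr.values}
                )
                for tr in traces
            ],
            ignore_index=True,
        )
        df.to_csv(path, index=False)
    elif dialect == "wide":
        times = traces[0].times_h
        df = pd.DataFrame(
            [tr.values for tr in traces], columns=[f"{t:g}" for t in times]
        )
        df.insert(0, "sample_id", [tr.sample_id for tr in traces])
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Expression IO


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x timepoints TSV (gene_id column + time-named columns)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise ValueError("first column of an expression TSV must be 'gene_id'")
    times = np.array([float(c) for c in df.columns[1:]])
    return ExpressionMatrix(
        gene_ids=df["gene_id"].astype(str).tolist(),
        timepoints_h=times,
        values=df.iloc[:, 1:].to_numpy(float),
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pipelines


def run_trace_pipeline(
    config: RunConfig,
    traces: list[TimeSeriesTrace],
    groups: dict[str, str] | None = None,
    out_dir: str | Path | None = None,
):
    """Trace pipeline: preprocess, decompose, ultradian statistics.

    Per trace: circadian subtraction, residual spectrum, instantaneous and
    average ultradian power, dominant period, threshold detection and
    onset/offset.  With ``groups`` (sample_id -> group label) a one-way
    ANOVA + Tukey comparison of average powers is added.  Writes
    ``ur_results.tsv`` (+ ``group_summary.json``/``.tsv``) under
    ``out_dir`` when given.

    Returns ``(results_df, group_summary_or_None)``.
    """
    logger.info(
        "trace pipeline: %d traces, CR band %s h, UR band %s h, threshold %g, seed %d",
        len(traces), config.cr_band, config.ur_band, config.threshold, config.seed,
    )
    results = []
    for tr in traces:
        try:
            results.append(
                metrics.analyze_trace(
                    tr,
                    cr_band=config.cr(),
                    ur_band=config.ur(),
                    threshold=config.threshold,
                    min_run_h=config.min_run_h,
                    window=config.window,
                    periods_h=config.periods_h(),
                )
            )
        except Exception as exc:
            raise RuntimeError(f"trace analysis failed for {tr.sample_id!r}: {exc}") from exc
    df = pd.DataFrame([r.to_row() for r in results])

    summary = None
    if groups:
        by_group: dict[str, list[float]] = {}
        for r in results:
            g = groups.get(r.sample_id)
            if g is not None:
                by_group.setdefault(g, []).append(r.avg_power)
        summary = metrics.compare_groups(
            {g: np.array(v) for g, v in by_group.items()}, alpha=0.01
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "ur_results.tsv", sep="\t", index=False)
        payload = {
            "config": config.to_dict(),
            "n_traces": len(traces),
            "group_mean_avg_power": float(df["avg_power"].mean()),
            "n_detected": int(df["detected"].sum()),
        }
        if summary is not None:
            payload["groups"] = {
                "means": summary.means,
                "sems": summary.sems,
                "anova_f": summary.anova_f,
                "anova_p": summary.anova_p,
                "letters": summary.letters,
                "alpha": summary.alpha,
            }
            summary.tukey.to_csv(out_dir / "group_summary.tsv", sep="\t", index=False)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(payload, fh, indent=2)
    return df, summary


def run_expression_pipeline(
    config: RunConfig,
    matrix: ExpressionMatrix,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Expression pipeline: rhythmic-gene calling with config parameters."""
    if matrix.n_genes == 0:
        logger.info("expression pipeline: empty gene set")
        calls = pd.DataFrame(
            columns=["gene_id", "p_ls", "p_jtk", "p_hr", "p_meta",
                     "period_h", "phase_h", "amplitude", "rhythmic"]
        )
    else:
        logger.info(
            "expression pipeline: %d genes x %d timepoints, period window %g-%g h, alpha %g",
            matrix.n_genes, matrix.timepoints_h.size, config.minper, config.maxper,
            config.alpha,
        )
        calls = call_rhythmic_genes(
            matrix,
            minper=config.minper,
            maxper=config.maxper,
            alpha=config.alpha,
            log_transform=config.log_transform,
        )
        logger.info(
            "expression pipeline: %d/%d genes called rhythmic",
            int(calls["rhythmic"].sum()), matrix.n_genes,
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        calls.to_csv(out_dir / "rhythm_calls.tsv", sep="\t", index=False)
    return calls
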