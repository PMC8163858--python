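"""Batch-culture kinetics: lag, zero-order rate, molar yields, cell yields.

Anaerobic batch cultures of the kind modelled here show a lag phase at the
initial substrate concentration, then zero-order (constant-rate) consumption
until the substrate is exhausted, with products accumulating at fixed molar
yields and cells at a fixed cells-per-mole yield.  Sampling is sparse
(days), so the lag/rate model is a two-segment piecewise-linear fit whose
breakpoint is searched only over observed timepoints.

Replicates are fitted independently and aggregated as unweighted
mean ± sample s.d. (the usual "± s.d., n = 3" convention); standard errors
of the mean combine per-replicate regression variances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesExperiment",
    "ReplicateKinetics",
    "KineticsFit",
    "YieldEstimate",
    "CsvFormatError",
    "fit_lag_rate",
    "molar_yield",
    "cells_from_copies",
    "cell_yield",
    "QPCR_ANALYTE",
    "QPCR_UNIT",
    "CONC_UNIT",
]

#: Tidy-CSV analyte name and unit used for qPCR counts.
QPCR_ANALYTE = "16S_copies"
QPCR_UNIT = "copies_per_ml"
CONC_UNIT = "uM"

_TS_COLUMNS = ["time_d", "replicate", "analyte", "value", "unit"]

# Detection threshold for the decline F-test: the two-segment model must
# reduce the flat-model SSE by this factor per extra parameter.
_F_THRESHOLD = 10.0


class CsvFormatError(ValueError):
    """A data file does not follow the documented CSV schema."""


@dataclass(frozen=True)
class TimeSeriesExperiment:
    """Replicate concentration / qPCR trajectories in tidy form.

    ``data`` columns: time_d, replicate, analyte, value, unit.  Concentration
    analytes are µM; qPCR counts (analyte ``16S_copies``) are copies/ml.
    ``amendments`` lists (time_d, added_um) substrate re-additions; when
    present, substrate kinetics are computed on cumulative consumption.
    """

    data: pd.DataFrame
    substrate: str
    amendments: tuple[tuple[float, float], ...] = ()
    liquid_volume_ml: float | None = None

    def __post_init__(self) -> None:
        missing = set(_TS_COLUMNS) - set(self.data.columns)
        if missing:
            raise CsvFormatError(f"time series missing columns {sorted(missing)}")
        if (self.data["value"] < 0).any():
            raise ValueError("negative values in time series")
        units = self.data.groupby("analyte")["unit"].nunique()
        if (units > 1).any():
            bad = units[units > 1].index.tolist()
            raise CsvFormatError(f"inconsistent units for analytes {bad}")
        for rep in self.replicates:
            for analyte in self.analytes:
                t = self._subset(rep, analyte)["time_d"].to_numpy()
                if t.size and not np.all(np.diff(t) > 0):
                    raise ValueError(f"times not strictly increasing ({rep}, {analyte})")

    # -- access ------------------------------------------------------------

    @property
    def replicates(self) -> list[str]:
        return sorted(self.data["replicate"].unique())

    @property
    def analytes(self) -> list[str]:
        return sorted(self.data["analyte"].unique())

    def _subset(self, replicate: str, analyte: str) -> pd.DataFrame:
        mask = (self.data["replicate"] == replicate) & (self.data["analyte"] == analyte)
        return self.data.loc[mask].sort_values("time_d")

    def series(self, replicate: str, analyte: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self._subset(replicate, analyte)
        if sub.empty:
            raise KeyError(f"no data for replicate {replicate!r}, analyte {analyte!r}")
        return sub["time_d"].to_numpy(float), sub["value"].to_numpy(float)

    def consumption(self, replicate: str) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative substrate consumed (µM) at each timepoint.

        Amendments at time ta (t0 < ta <= t) count toward the substrate
        supplied by time t; the first observation defines the baseline.
        """
        t, conc = self.series(replicate, self.substrate)
        added = np.array(
            [sum(a for ta, a in self.amendments if t[0] < ta <= ti) for ti in t]
        )
        # initial level: the two-segment fit's plateau estimate rather than a
        # single noisy baseline observation, whose error would shift every
        # consumption value in common.  With amendments the concentration
        # sawtooths, so the first observation is used directly.
        if self.amendments or len(t) < 4:
            level = conc[0]
        else:
            tt, yy = _trim_floor(t, conc)
            _, level, _, _, _, _ = _fit_breakpoint(tt, yy)
        return t, level + added - conc

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, path, amendments_path=None) -> None:
        out = self.data[_TS_COLUMNS].copy()
        out.to_csv(path, index=False, float_format="%.10g")
        if amendments_path is not None:
            pd.DataFrame(self.amendments, columns=["time_d", "added_um"]).to_csv(
                amendments_path, index=False, float_format="%.10g"
            )

    @classmethod
    def from_csv(cls, path, substrate: str, amendments_path=None, **kwargs) -> "TimeSeriesExperiment":
        path = Path(path)
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            raise CsvFormatError(f"{path}: file is empty") from None
        missing = set(_TS_COLUMNS) - set(df.columns)
        if missing:
            raise CsvFormatError(f"{path}: missing columns {sorted(missing)}")
        bad = pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header + 1-based
            raise CsvFormatError(f"{path}: non-numeric 'value' at line {line}")
        df["value"] = pd.to_numeric(df["value"])
        conc = df[df["analyte"] != QPCR_ANALYTE]
        if not conc.empty and not (conc["unit"] == CONC_UNIT).all():
            raise CsvFormatError(f"{path}: concentration analytes must use unit '{CONC_UNIT}'")
        amendments: tuple[tuple[float, float], ...] = ()
        if amendments_path is not None:
            am = pd.read_csv(amendments_path)
            need = {"time_d", "added_um"} - set(am.columns)
            if need:
                raise CsvFormatError(f"{amendments_path}: missing columns {sorted(need)}")
            amendments = tuple(zip(am["time_d"].astype(float), am["added_um"].astype(float)))
        return cls(data=df, substrate=substrate, amendments=amendments, **kwargs)


# ---------------------------------------------------------------------------
# Lag + zero-order rate


@dataclass(frozen=True)
class ReplicateKinetics:
    replicate: str
    lag_days: float
    rate: float  # µM/day, magnitude of the decline slope
    rate_se: float
    level: float  # fitted pre-breakpoint level
    sse: float
    decline_detected: bool


@dataclass(frozen=True)
class KineticsFit:
    """Aggregated lag/rate fit across replicates (mean ± s.d.)."""

    analyte: str
    lag_days: float
    lag_sd: float
    rate: float
    rate_sd: float
    rate_se: float
    breakpoint_sse: float
    no_decline: bool
    replicates: tuple[ReplicateKinetics, ...] = field(repr=False, default=())


def _trim_floor(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop trailing points sitting on the exhaustion floor, keeping the first.

    The two-segment model has no terminal plateau, so post-depletion samples
    (kept in the data for cell-count plateaus) would bias the slope.
    """
    span = y.max() - y.min()
    if span == 0:
        return t, y
    low = y.min() + 0.1 * span
    i = len(y)
    while i > 1 and y[i - 1] <= low:
        i -= 1
    keep = min(len(y), i + 1)
    if keep >= 4:
        return t[:keep], y[:keep]
    return t, y


def _fit_breakpoint(
    t: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, float, float, float]:
    """Two-segment LSQ: flat level a until tb, then decline at slope k.

    Breakpoint candidates are the observed timepoints with >=2 later points.
    Returns (tb, a, k, sse, se_k, se_a).  Ties in SSE resolve to the earliest
    tb.
    """
    n = len(t)
    best = None
    for i in range(0, n - 2):
        z = np.clip(t - t[i], 0.0, None)
        x = np.column_stack([np.ones(n), -z])
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        sse = float(((y - x @ coef) ** 2).sum())
        if best is None or sse < best[3] - 1e-12 * (1 + best[3]):
            dof = max(n - 3, 1)
            s2 = sse / dof
            cov = s2 * np.linalg.inv(x.T @ x)
            best = (
                float(t[i]),
                float(coef[0]),
                float(coef[1]),
                sse,
                math.sqrt(max(cov[1, 1], 0.0)),
                math.sqrt(max(cov[0, 0], 0.0)),
            )
    assert best is not None
    return best


def _fit_replicate(replicate: str, t: np.ndarray, y: np.ndarray) -> ReplicateKinetics:
    if len(t) < 4:
        raise ValueError(f"replicate {replicate!r}: need >=4 timepoints, got {len(t)}")
    t, y = _trim_floor(t, y)
    n = len(t)
    sse_flat = float(((y - y.mean()) ** 2).sum())
    tb, level, k, sse, se_k, _ = _fit_breakpoint(t, y)
    if k > 0 and sse_flat > sse:
        if sse == 0:
            detected = sse_flat > 0
        else:
            f_stat = ((sse_flat - sse) / 2.0) / (sse / max(n - 3, 1))
            detected = f_stat > _F_THRESHOLD
    else:
        detected = False
    if not detected:
        return ReplicateKinetics(replicate, 0.0, 0.0, float("nan"), float(y.mean()), sse_flat, False)
    return ReplicateKinetics(replicate, tb, k, se_k, level, sse, True)


def fit_lag_rate(ts: TimeSeriesExperiment, analyte: str | None = None) -> KineticsFit:
    """Lag phase and zero-order rate for an analyte (default: the substrate).

    Fits the two-segment flat-then-decline model per replicate.  For the
    substrate of an experiment with recorded amendments, the fit runs on the
    negated cumulative consumption, which declines monotonically through
    re-additions.  The fit is invariant to adding a constant to all
    concentrations (the level is a free parameter).  If no replicate shows a
    decline, the aggregate rate is zero and ``no_decline`` is set.
    """
    analyte = analyte or ts.substrate
    fits = []
    for rep in ts.replicates:
        if analyte == ts.substrate and ts.amendments:
            t, cons = ts.consumption(rep)
            y = -cons
        else:
            t, y = ts.series(rep, analyte)
        fits.append(_fit_replicate(rep, t, y))
    detected = [f for f in fits if f.decline_detected]
    pool = detected if detected else fits
    lags = np.array([f.lag_days for f in pool])
    rates = np.array([f.rate for f in pool])
    ses = np.array([f.rate_se for f in pool])
    n = len(pool)
    # s.e. of the mean rate: replicate scatter plus within-replicate OLS
    # variance (the latter alone understates error because the breakpoint is
    # model-selected)
    rate_var = np.nansum(ses**2) / n**2
    if n > 1:
        rate_var += rates.var(ddof=1) / n
    return KineticsFit(
        analyte=analyte,
        lag_days=float(lags.mean()),
        lag_sd=float(lags.std(ddof=1)) if n > 1 else 0.0,
        rate=float(rates.mean()),
        rate_sd=float(rates.std(ddof=1)) if n > 1 else 0.0,
        rate_se=float(np.sqrt(rate_var)) if detected else float("nan"),
        breakpoint_sse=float(np.mean([f.sse for f in pool])),
        no_decline=not detected,
        replicates=tuple(fits),
    )


# ---------------------------------------------------------------------------
# Molar and cell yields


@dataclass(frozen=True)
class YieldEstimate:
    """Aggregated yield (mean ± s.d. over replicates, se of the mean)."""

    numerator: str
    denominator: str
    value: float
    sd: float
    se: float
    mode: str = "regression"
    per_replicate: tuple[float, ...] = ()


def molar_yield(
    ts: TimeSeriesExperiment,
    product: str,
    substrate: str | None = None,
    mode: str = "regression",
) -> YieldEstimate:
    """Molar yield of ``product`` per mole of substrate consumed.

    ``mode="regression"`` (default) regresses product formed on cumulative
    substrate consumed through the origin, using all timepoints;
    ``mode="endpoint"`` is the final-product / final-consumption ratio.
    """
    substrate = substrate or ts.substrate
    if mode not in ("regression", "endpoint"):
        raise ValueError(f"unknown yield mode {mode!r}")
    slopes, variances = [], []
    for rep in ts.replicates:
        t, cons = ts.consumption(rep) if substrate == ts.substrate else _consumed(ts, rep, substrate)
        tp, prod = ts.series(rep, product)
        if not np.array_equal(t, tp):
            raise ValueError(f"timepoint mismatch between {substrate} and {product} in {rep}")
        if cons[-1] <= 1e-9 * max(1.0, float(np.abs(cons).max())):
            raise ValueError(f"no substrate consumption in replicate {rep!r}")
        tb = se_level = None
        if substrate == ts.substrate and not ts.amendments and len(t) >= 4:
            tt, yy = _trim_floor(*ts.series(rep, substrate))
            tb, *_, se_level = _fit_breakpoint(tt, yy)
        # product baseline: median over the pre-onset window (before the
        # fitted breakpoint when available) -- robust to the zero-truncation
        # of concentration noise, which biases the mean of near-zero
        # observations upward
        window = (t <= tb) if tb is not None else (cons <= 0.01 * cons[-1])
        baseline = float(np.median(prod[window])) if window.any() else prod[0]
        dy = prod - baseline
        if mode == "endpoint":
            slopes.append(dy[-1] / cons[-1])
            variances.append(np.nan)
            continue
        sxx = float((cons**2).sum())
        b = float((cons * dy).sum() / sxx)
        resid = dy - b * cons
        dof = max(len(cons) - 1, 1)
        var_b = float((resid**2).sum() / dof / sxx)
        # error of the estimated substrate level shifts every consumption
        # value in common and tilts the slope by -b * err * sum(x)/sum(x^2);
        # the through-origin residuals cannot see it, so add it explicitly
        if se_level is not None:
            var_b += (b * se_level * float(cons.sum()) / sxx) ** 2
        variances.append(var_b)
        slopes.append(b)
    slopes_arr = np.array(slopes)
    n = len(slopes_arr)
    if mode == "regression":
        var = np.nansum(variances) / n**2  # within-replicate regression variance
        if n > 1:
            var += slopes_arr.var(ddof=1) / n  # replicate scatter
        se = float(np.sqrt(var))
    else:
        se = float("nan")
    return YieldEstimate(
        numerator=product,
        denominator=substrate,
        value=float(slopes_arr.mean()),
        sd=float(slopes_arr.std(ddof=1)) if n > 1 else 0.0,
        se=se,
        mode=mode,
        per_replicate=tuple(slopes_arr),
    )


def _consumed(ts: TimeSeriesExperiment, rep: str, analyte: str) -> tuple[np.ndarray, np.ndarray]:
    t, conc = ts.series(rep, analyte)
    return t, conc[0] - conc


def cells_from_copies(copies_per_ml, operon_count: int = 4):
    """Convert 16S rRNA gene copies/ml to cells/ml.

    The genome carries ``operon_count`` 16S rRNA gene copies (4 for the
    organism modelled here), so cell numbers are copies divided by that
    count.  Accepts scalars or arrays.
    """
    if operon_count < 1:
        raise ValueError("operon_count must be >= 1")
    arr = np.asarray(copies_per_ml, dtype=float)
    if (arr < 0).any():
        raise ValueError("copy numbers must be non-negative")
    result = arr / operon_count
    return float(result) if np.isscalar(copies_per_ml) or result.ndim == 0 else result


def cell_yield(
    ts: TimeSeriesExperiment,
    substrate: str | None = None,
    operon_count: int = 4,
    copies_analyte: str = QPCR_ANALYTE,
) -> YieldEstimate:
    """Net cells produced per mole of substrate consumed.

    Per replicate, the net increase in cells per litre is divided by the
    moles of substrate consumed per litre.  To damp qPCR noise, the
    "initial" and "final" cell counts are averaged over the timepoints where
    cumulative consumption is still <=1% / already >=99% of its final value
    (a single endpoint when the plateau was not sampled); on noise-free data
    this reduces to the endpoint difference exactly.
    """
    substrate = substrate or ts.substrate
    yields = []
    for rep in ts.replicates:
        t, cons = ts.consumption(rep) if substrate == ts.substrate else _consumed(ts, rep, substrate)
        tq, copies = ts.series(rep, copies_analyte)
        if not np.array_equal(t, tq):
            raise ValueError(f"timepoint mismatch between {substrate} and qPCR in {rep}")
        if cons[-1] <= 1e-9 * max(1.0, float(np.abs(cons).max())):
            raise ValueError(f"no substrate consumption in replicate {rep!r}")
        cells_per_l = cells_from_copies(copies, operon_count) * 1000.0
        init_mask = cons <= 0.01 * cons[-1]
        final_mask = cons >= 0.99 * cons[-1]
        if substrate == ts.substrate and not ts.amendments and len(t) >= 4:
            tt, yy = _trim_floor(*ts.series(rep, substrate))
            tb, *_ = _fit_breakpoint(tt, yy)
            init_mask = t <= tb
        initial = cells_per_l[init_mask].mean() if init_mask.any() else cells_per_l[0]
        final = cells_per_l[final_mask].mean() if final_mask.any() else cells_per_l[-1]
        # robust total consumption: zero-truncated noise on exhausted-substrate
        # observations biases the single endpoint low
        total = float(np.median(cons[final_mask])) if final_mask.any() else cons[-1]
        yields.append((final - initial) / (total * 1e-6))
    arr = np.array(yields)
    n = len(arr)
    return YieldEstimate(
        numerator="cells",
        denominator=substrate,
        value=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if n > 1 else 0.0,
        se=float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan"),
        mode="plateau_endpoint",
        per_replicate=tuple(arr),
    )
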