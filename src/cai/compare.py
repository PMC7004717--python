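"""Comparison machinery for depth-of-anesthesia index streams.

The three streams (CAI, SpEn, imported BIS) live on different native
scales and update cadences, so comparison proceeds in three steps:

1. **standardize** each (subject, method) stream to zero mean and unit
   sample standard deviation, ``z = (x - mean(x)) / sd(x)``;
2. **align** pairs of streams by linear interpolation onto a common
   time grid over their overlap (no extrapolation);
3. **compare**: Pearson correlations on pooled aligned pairs,
   order-statistic descriptives (min / median / max / |max-min|), and
   the semiparametric regression of z on method, sex, age, BMI and a
   linear-plus-smooth time trend (see :mod:`cai.semiparametric`).

Standardization is per subject, per method, with the n-1 denominator:
each recording is scaled by its own variability, which makes traces
from different monitors and subjects commensurate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import IndexSeries, ValidationError
from .semiparametric import SemiparametricIndexModel, SemiparametricResults
from .simulate import SubjectMeta

__all__ = [
    "standardize",
    "align_series",
    "pearson",
    "descriptive_stats",
    "build_long_table",
    "fit_semiparametric",
    "run_comparison",
    "CohortReport",
]

METHODS = ("CAI", "SpEn", "BIS")


def standardize(series: IndexSeries) -> IndexSeries:
    """Center and scale a stream to mean 0, sample sd 1 (n-1 denominator).

    The output is named ``Z<name>`` and lives on the standardized
    scale (no [0, 100] constraint).  Constant streams have no scale and
    raise :class:`ValidationError`.
    """
    if len(series) < 2:
        raise ValidationError(f"{series.name}: need >= 2 points to standardize")
    sd = float(np.std(series.values, ddof=1))
    if sd == 0:
        raise ValidationError(f"{series.name}: constant series cannot be standardized")
    z = (series.values - series.values.mean()) / sd
    name = series.name if series.name.startswith("Z") else f"Z{series.name}"
    return IndexSeries(name, series.times, z)


def align_series(
    a: IndexSeries, b: IndexSeries, grid_step: float = 1.0
) -> pd.DataFrame:
    """Interpolate two streams onto a shared grid over their time overlap.

    Returns a DataFrame with columns ``time, a, b``; grid points are
    multiples of ``grid_step`` inside the overlap.  Disjoint supports
    or an overlap shorter than two grid points raise
    :class:`ValidationError`.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("both series need >= 2 points to align")
    lo = max(a.times[0], b.times[0])
    hi = min(a.times[-1], b.times[-1])
    if hi <= lo:
        raise ValidationError(
            f"series do not overlap: [{a.times[0]}, {a.times[-1]}] vs "
            f"[{b.times[0]}, {b.times[-1]}]"
        )
    start = np.ceil(lo / grid_step - 1e-9) * grid_step
    grid = np.arange(start, hi + 1e-9 * grid_step, grid_step)
    grid = grid[(grid >= lo - 1e-9) & (grid <= hi + 1e-9)]
    if grid.size < 2:
        raise ValidationError("overlap contains fewer than 2 grid points")
    return pd.DataFrame(
        {
            "time": grid,
            "a": np.interp(grid, a.times, a.values),
            "b": np.interp(grid, b.times, b.values),
        }
    )


def pearson(pairs: pd.DataFrame) -> float:
    """Product-moment correlation of the ``a``/``b`` columns."""
    x = pairs["a"].to_numpy(float)
    y = pairs["b"].to_numpy(float)
    if x.size < 3:
        raise ValidationError(f"need >= 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant margin")
    return float(np.corrcoef(x, y)[0, 1])


def descriptive_stats(z: np.ndarray) -> dict[str, float]:
    """Order statistics: min, median (midpoint convention), max, |max-min|."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValidationError("descriptive_stats needs a non-empty input")
    return {
        "min": float(z.min()),
        "median": float(np.median(z)),
        "max": float(z.max()),
        "range": float(abs(z.max() - z.min())),
    }


CohortInput = Iterable[tuple[SubjectMeta, Mapping[str, IndexSeries]]]


def build_long_table(cohort: CohortInput) -> pd.DataFrame:
    """Stack standardized per-subject streams into a long-format table.

    Each (subject, method) stream is standardized with its own mean and
    sd; covariates are replicated per row.  Subjects missing a method
    (a BIS monitor that was never connected, say) simply contribute no
    rows for it; a subject with zero usable streams is an error.
    """
    rows = []
    n_subjects = 0
    for meta, streams in cohort:
        n_subjects += 1
        usable = 0
        for method, series in streams.items():
            if method not in METHODS:
                raise ValidationError(f"unknown method {method!r}; expected {METHODS}")
            if series is None or len(series) < 2:
                continue
            z = standardize(series)
            usable += 1
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": meta.subject_id,
                        "method": method,
                        "time": z.times,
                        "z": z.values,
                        "sex": meta.sex,
                        "age": meta.age,
                        "bmi": meta.bmi,
                    }
                )
            )
        if usable == 0:
            raise ValidationError(f"subject {meta.subject_id} has no usable series")
    if n_subjects == 0:
        raise ValidationError("empty cohort")
    return pd.concat(rows, ignore_index=True)


def fit_semiparametric(
    table: pd.DataFrame,
    truncate_s: float | None = None,
    **model_kwargs,
) -> SemiparametricResults:
    """Fit the pooled semiparametric comparison model to a long table.

    ``truncate_s`` optionally drops rows with ``time > truncate_s``
    before fitting (late emergence-period data can be cut off when
    recordings have ragged ends).
    """
    if truncate_s is not None:
        table = table[table["time"] <= truncate_s]
    return SemiparametricIndexModel(table, **model_kwargs).fit()


@dataclass
class CohortReport:
    """Bundle of the comparison outputs (Tables 2-5 / Fig. 3 analogues)."""

    correlations: pd.DataFrame  # method x method Pearson matrix
    descriptives: pd.DataFrame  # per-method order statistics of pooled z
    regression: pd.DataFrame  # coefficient table + smooth row
    fitted_curves: pd.DataFrame  # per-method fitted z over time
    result: SemiparametricResults | None

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in [
            ("correlations", self.correlations),
            ("descriptives", self.descriptives),
            ("regression", self.regression),
            ("fitted_curves", self.fitted_curves),
        ]:
            path = outdir / f"{name}.csv"
            df.to_csv(path, float_format="%.10g")
            written.append(path)
        return written


def run_comparison(
    cohort: CohortInput,
    grid_step: float = 1.0,
    truncate_s: float | None = None,
    outdir: str | Path | None = None,
) -> CohortReport:
    """Full comparison pipeline on a cohort of index streams.

    Correlations are computed on standardized streams aligned to a
    ``grid_step`` grid per subject and pooled across subjects; the
    regression runs on the pooled long table.  Deterministic: the same
    cohort yields byte-identical CSV output.
    """
    cohort = [(meta, dict(streams)) for meta, streams in cohort]
    table = build_long_table(cohort)
    present = [m for m in METHODS if (table["method"] == m).any()]

    # pairwise pooled correlations on standardized, aligned streams
    corr = pd.DataFrame(np.eye(len(present)), index=present, columns=present)
    for i, m1 in enumerate(present):
        for m2 in present[i + 1 :]:
            pooled = []
            for meta, streams in cohort:
                s1, s2 = streams.get(m1), streams.get(m2)
                if s1 is None or s2 is None or len(s1) < 2 or len(s2) < 2:
                    continue
                try:
                    pooled.append(
                        align_series(standardize(s1), standardize(s2), grid_step)
                    )
                except ValidationError:
                    continue
            if pooled:
                r = pearson(pd.concat(pooled, ignore_index=True))
                corr.loc[m1, m2] = corr.loc[m2, m1] = r
            else:
                corr.loc[m1, m2] = corr.loc[m2, m1] = np.nan

    desc = pd.DataFrame(
        {
            m: descriptive_stats(table.loc[table["method"] == m, "z"].to_numpy())
            for m in present
        }
    ).T

    result: SemiparametricResults | None = None
    try:
        result = fit_semiparametric(table, truncate_s=truncate_s)
    except ValidationError:
        pass  # e.g. single-method cohorts: report correlations only

    if result is not None:
        reg = result.coefficient_table()
        smooth_row = pd.DataFrame(
            {
                "estimate": [result.edf_smooth],
                "se": [np.nan],
                "t": [result.f_smooth],
                "p": [result.p_smooth],
            },
            index=["s(time) edf"],
        )
        reg = pd.concat([reg, smooth_row])
        fitted = _fitted_curves(result)
    else:
        reg = pd.DataFrame(columns=["estimate", "se", "t", "p"])
        fitted = pd.DataFrame(columns=["time", "method", "fitted"])

    report = CohortReport(corr, desc, reg, fitted, result)
    if outdir is not None:
        report.write(outdir)
    return report


def _fitted_curves(result: SemiparametricResults, n_grid: int = 200) -> pd.DataFrame:
    """Fitted z(t) per method at reference covariates (Fig.-3-style)."""
    model = result.model
    df = model.table
    t = np.linspace(df["time"].min(), df["time"].max(), n_grid)
    smooth = result.smooth_curve(t)["smooth"].to_numpy()
    beta = result.params
    base = (
        beta["Intercept"]
        + beta["age"] * df["age"].mean()
        + beta["bmi"] * df["bmi"].mean()
        + beta["time"] * t
        + smooth
    )
    frames = []
    for m in sorted(df["method"].unique()):
        term = f"method[T.{m}]"
        offset = beta[term] if term in beta.index else 0.0
        frames.append(pd.DataFrame({"time": t, "method": m, "fitted": base + offset}))
    return pd.concat(frames, ignore_index=True)
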