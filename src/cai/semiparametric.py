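"""Semiparametric comparison regression for standardized index streams.

The model, fitted to a long-format table of standardized index values
pooled over subjects, is

    z = b0 + b_method + b_sex + b_age*age + b_bmi*bmi + b_t*time
        + s(time) + noise

where ``method`` is indicator-coded against the BIS reference,
``sex`` against Female, and ``s(time)`` is a penalized cubic-B-spline
smooth of time.  The smoothing parameter is chosen by generalized
cross-validation (GCV).  The method contrasts are the quantities of
interest: after removing scale (standardization) and the shared
time course (linear + smooth), does one index sit systematically
above or below another?

Construction details
--------------------
The spline basis uses ~20 interior knots on quantiles of time with a
second-difference penalty.  The penalty's null space (constant and
linear coefficient patterns) duplicates the explicit intercept and
linear time term, so the basis is reparameterized onto the penalized
eigenspace of the penalty and its columns are orthogonalized against
``[1, time]``; every remaining smooth direction is then strictly
penalized and the fit collapses onto the parametric model as
``lambda -> inf``.  The reported smooth effective degrees of freedom
count the whole time trend (the explicit linear term plus the spline
block), so they tend to 1 in that limit.

Standard errors are frequentist, ``sigma^2 A^-1 C'C A^-1`` with
``A = C'C + lambda*P``; p-values use a t reference with
``n - edf_total`` degrees of freedom.  The smooth's significance is an
approximate F-test against the parametric-only fit.  Both
approximations ignore smoothing-parameter selection uncertainty and
within-subject autocorrelation (the model pools rows without subject
random effects), so p-values are descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.interpolate import BSpline

from .io import ValidationError

__all__ = ["SemiparametricIndexModel", "SemiparametricResults"]

DEFAULT_LAMBDA_GRID = np.logspace(-4.0, 10.0, 57)


def _bspline_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    return BSpline.design_matrix(x, knots, 3, extrapolate=True).toarray()


class SemiparametricIndexModel:
    """Penalized-spline semiparametric model for long-format index data.

    Parameters
    ----------
    table
        DataFrame with columns ``subject_id, method, time, z, sex, age,
        bmi``.
    n_knots
        Interior spline knots placed on quantiles of time (default 20).
    method_reference, sex_reference
        Baseline factor levels (BIS and Female, falling back to the
        first level present).
    """

    PARAM_MIN_ROWS = 30

    def __init__(
        self,
        table: pd.DataFrame,
        n_knots: int = 20,
        method_reference: str = "BIS",
        sex_reference: str = "F",
    ):
        required = {"subject_id", "method", "time", "z", "sex", "age", "bmi"}
        missing = required - set(table.columns)
        if missing:
            raise ValidationError(f"long table is missing columns {sorted(missing)}")
        table = table.reset_index(drop=True)
        if not np.all(np.isfinite(table["z"])):
            raise ValidationError("z values must be finite")
        methods = sorted(table["method"].unique())
        if len(methods) < 2:
            raise ValidationError(
                f"need >= 2 methods to contrast, got {methods}"
            )
        if len(table) < self.PARAM_MIN_ROWS:
            raise ValidationError(
                f"need >= {self.PARAM_MIN_ROWS} rows, got {len(table)}"
            )
        if len(np.unique(table["time"])) < 10:
            raise ValidationError("time must span at least 10 distinct values")

        self.table = table
        self.method_reference = (
            method_reference if method_reference in methods else methods[0]
        )
        sexes = sorted(table["sex"].unique())
        self.sex_reference = sex_reference if sex_reference in sexes else sexes[0]
        self.n_knots = n_knots

        self._build_design()

    # -- design ---------------------------------------------------------

    def _build_design(self) -> None:
        df = self.table
        t = df["time"].to_numpy(float)
        n = len(df)

        cols: list[np.ndarray] = [np.ones(n)]
        names: list[str] = ["Intercept"]
        for m in sorted(df["method"].unique()):
            if m == self.method_reference:
                continue
            cols.append((df["method"] == m).to_numpy(float))
            names.append(f"method[T.{m}]")
        for s in sorted(df["sex"].unique()):
            if s == self.sex_reference:
                continue
            cols.append((df["sex"] == s).to_numpy(float))
            names.append(f"sex[T.{s}]")
        cols.append(df["age"].to_numpy(float))
        names.append("age")
        cols.append(df["bmi"].to_numpy(float))
        names.append("bmi")
        cols.append(t)
        names.append("time")
        X = np.column_stack(cols)
        self._check_rank(X, names)

        # interior knots on time quantiles, clamped cubic ends
        qs = np.linspace(0, 1, self.n_knots + 2)[1:-1]
        interior = np.quantile(t, qs)
        lo, hi = t.min(), t.max()
        span = max(hi - lo, 1.0)
        lo -= 1e-6 * span
        hi += 1e-6 * span
        knots = np.concatenate([[lo] * 4, interior, [hi] * 4])
        B = _bspline_design(t, knots)

        nb = B.shape[1]
        D = np.diff(np.eye(nb), 2, axis=0)  # second differences
        P = D.T @ D
        evals, evecs = np.linalg.eigh(P)
        keep = evals > evals.max() * 1e-10
        Z = evecs[:, keep]
        S = evals[keep]

        T = np.column_stack([np.ones(n), t])
        Bz = B @ Z
        Q, *_ = np.linalg.lstsq(T, Bz, rcond=None)
        Bzc = Bz - T @ Q

        self.param_names = names
        self.n_param = X.shape[1]
        self.X = X
        self.y = df["z"].to_numpy(float)
        self.C = np.column_stack([X, Bzc])
        self.penalty_diag = S  # penalty is diag(S) on the smooth block
        self._knots = knots
        self._Z = Z
        self._Q = Q

    @staticmethod
    def _check_rank(X: np.ndarray, names: list[str]) -> None:
        _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps * 10
        rank = int(np.sum(diag > tol))
        if rank < X.shape[1]:
            bad = sorted(names[j] for j in piv[rank:])
            raise ValidationError(
                "parametric design is rank deficient; collinear terms: "
                + ", ".join(bad)
            )

    def smooth_basis(self, times: np.ndarray) -> np.ndarray:
        """Constrained smooth basis evaluated at new time points."""
        times = np.asarray(times, dtype=float)
        B = _bspline_design(times, self._knots)
        T = np.column_stack([np.ones(times.size), times])
        return B @ self._Z - T @ self._Q

    # -- fitting --------------------------------------------------------

    def fit(
        self,
        lam: float | None = None,
        lam_grid: np.ndarray | None = None,
    ) -> "SemiparametricResults":
        """Fit by penalized least squares.

        ``lam=None`` selects the smoothing parameter by GCV over
        ``lam_grid`` (log-spaced 1e-4..1e10 by default);
        an explicit ``lam`` skips the search.
        """
        C, y = self.C, self.y
        n, p = C.shape
        CtC = C.T @ C
        Cty = C.T @ y
        yty = float(y @ y)
        pen = np.zeros(p)
        pen[self.n_param :] = self.penalty_diag

        def solve(lam_value: float):
            A = CtC + lam_value * np.diag(pen)
            cho = linalg.cho_factor(A)
            beta = linalg.cho_solve(cho, Cty)
            edf = float(np.trace(linalg.cho_solve(cho, CtC)))
            rss = max(yty - 2 * beta @ Cty + beta @ CtC @ beta, 0.0)
            return beta, edf, rss, cho

        if lam is None:
            grid = np.asarray(
                DEFAULT_LAMBDA_GRID if lam_grid is None else lam_grid, float
            )
            gcv = np.empty(grid.size)
            for i, g in enumerate(grid):
                _, edf, rss, _ = solve(g)
                gcv[i] = n * rss / (n - edf) ** 2
            best = int(np.argmin(gcv))
            lam = float(grid[best])
            gcv_path = pd.DataFrame({"lambda": grid, "gcv": gcv})
        else:
            gcv_path = None

        beta, edf, rss, cho = solve(lam)
        gcv_score = n * rss / (n - edf) ** 2
        sigma2 = rss / max(n - edf, 1.0)
        # frequentist covariance sigma^2 A^-1 C'C A^-1
        AinvCtC = linalg.cho_solve(cho, CtC)
        cov = sigma2 * linalg.cho_solve(cho, AinvCtC.T)

        # smooth block edf + the explicit linear time term
        edf_smooth_block = float(np.trace(AinvCtC[self.n_param :, self.n_param :]))

        # approximate F test of the smooth vs the parametric-only fit
        beta_par, rss0_resid, *_ = np.linalg.lstsq(self.X, y, rcond=None)
        rss0 = float(np.sum((y - self.X @ beta_par) ** 2))
        df_resid = n - edf
        if edf_smooth_block > 1e-8 and rss0 > rss:
            F = ((rss0 - rss) / edf_smooth_block) / (rss / df_resid)
            p_smooth = float(stats.f.sf(F, edf_smooth_block, df_resid))
        else:
            F, p_smooth = 0.0, 1.0

        return SemiparametricResults(
            model=self,
            params=pd.Series(beta[: self.n_param], index=self.param_names),
            _beta_full=beta,
            cov_params=pd.DataFrame(
                cov[: self.n_param, : self.n_param],
                index=self.param_names,
                columns=self.param_names,
            ),
            lam=float(lam),
            gcv=float(gcv_score),
            gcv_path=gcv_path,
            edf_total=edf,
            edf_smooth=1.0 + edf_smooth_block,
            f_smooth=float(F),
            p_smooth=p_smooth,
            sigma2=float(sigma2),
            rss=float(rss),
            nobs=n,
        )


@dataclass
class SemiparametricResults:
    """Fit results: estimates, uncertainties, smooth diagnostics."""

    model: SemiparametricIndexModel
    params: pd.Series
    _beta_full: np.ndarray
    cov_params: pd.DataFrame
    lam: float
    gcv: float
    gcv_path: pd.DataFrame | None
    edf_total: float
    edf_smooth: float
    f_smooth: float
    p_smooth: float
    sigma2: float
    rss: float
    nobs: int

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index
        )

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        df = max(self.nobs - self.edf_total, 1.0)
        return pd.Series(
            2.0 * stats.t.sf(np.abs(self.tvalues.to_numpy()), df),
            index=self.params.index,
        )

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.C @ self._beta_full

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues

    def smooth_curve(self, times: np.ndarray | None = None) -> pd.DataFrame:
        """The fitted smooth s(time) on a grid (excludes the linear term)."""
        if times is None:
            t = self.model.table["time"].to_numpy(float)
            times = np.linspace(t.min(), t.max(), 200)
        times = np.asarray(times, dtype=float)
        Bc = self.model.smooth_basis(times)
        return pd.DataFrame(
            {"time": times, "smooth": Bc @ self._beta_full[self.model.n_param :]}
        )

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = [
            "Semiparametric index comparison",
            "=" * 66,
            f"n_obs: {self.nobs}    total edf: {self.edf_total:.2f}    "
            f"sigma: {np.sqrt(self.sigma2):.4f}",
            f"GCV-selected lambda: {self.lam:.4g}    GCV score: {self.gcv:.6g}",
            "-" * 66,
            f"{'term':<16}{'estimate':>12}{'std err':>12}{'t':>9}{'P>|t|':>10}",
        ]
        tab = self.coefficient_table()
        for term, row in tab.iterrows():
            lines.append(
                f"{term:<16}{row.estimate:>12.5g}{row.se:>12.4g}"
                f"{row.t:>9.2f}{row.p:>10.3g}"
            )
        lines += [
            "-" * 66,
            f"s(time): edf={self.edf_smooth:.2f} (incl. linear), "
            f"F={self.f_smooth:.2f}, p={self.p_smooth:.3g}",
            f"reference levels: method={self.model.method_reference}, "
            f"sex={self.model.sex_reference}",
            "=" * 66,
        ]
        return "\n".join(lines)

    def plot_smooth(self, ax=None):
        """Plot the fitted nonlinear time component (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.smooth_curve()
        ax.plot(curve["time"], curve["smooth"], lw=2)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("s(time)")
        ax.set_title("Nonlinear time effect")
        return ax
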