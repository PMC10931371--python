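"""Group comparisons and dose-response regression for uptake records.

Two-sided unpaired t-tests (Welch by default, pooled available) between
concentration groups, ordinary least-squares dose-response fits with 95%
confidence intervals and mean-response bands, and a per-group summary table
with pairwise tests and significance marks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TestResult",
    "RegressionFit",
    "DoseResponseLinear",
    "ttest_unpaired",
    "fit_dose_response",
    "summarize_uptake",
    "UptakeSummary",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float
    variant: str
    labels: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def ttest_unpaired(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variant: str = "welch",
    labels: tuple[str, str] = ("A", "B"),
) -> TestResult:
    """Two-sided unpaired t-test between two groups of per-FOV values.

    ``variant="welch"`` (default) does not assume equal variances and uses
    Welch-Satterthwaite degrees of freedom; ``variant="pooled"`` is the
    classic equal-variance Student test with n_a + n_b - 2 df.  Both agree
    exactly when group sizes and variances are equal.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0 and a.mean() == b.mean():
        # identical degenerate groups: no evidence against the null
        df = a.size + b.size - 2 if variant == "pooled" else float(a.size - 1)
        return TestResult(0.0, df, 1.0, variant, labels)
    if va == 0 and vb == 0:
        raise ValueError("both groups have zero variance")
    if variant == "pooled":
        res = sps.ttest_ind(a, b, equal_var=True)
        df = float(a.size + b.size - 2)
    elif variant == "welch":
        res = sps.ttest_ind(a, b, equal_var=False)
        na, nb = a.size, b.size
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    return TestResult(
        float(res.statistic), float(df), float(res.pvalue), variant, labels
    )


@dataclass
class RegressionFit:
    """OLS dose-response fit with 95% intervals.

    slope is in bead-pixels-per-cell per (ug/cm^2).  ``confidence_band``
    evaluates the 95% mean-response interval at arbitrary concentrations;
    it is narrowest at the mean concentration of the data.
    """

    slope: float
    intercept: float
    slope_se: float
    ci95_slope: tuple[float, float]
    r_squared: float
    df_resid: float
    _result: object = field(repr=False, default=None)

    def predict(self, conc: Iterable[float]) -> np.ndarray:
        x = np.asarray(list(conc), dtype=float)
        return self.intercept + self.slope * x

    def confidence_band(
        self, conc: Iterable[float]
    ) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(list(conc), dtype=float)
        pred = self._result.get_prediction(sm.add_constant(x, has_constant="add"))
        ci = pred.conf_int(alpha=0.05)
        return ci[:, 0], ci[:, 1]


class DoseResponseLinear(RegressorMixin, BaseEstimator):
    """Ordinary least-squares dose-response line, scikit-learn style.

    ``fit(X, y)`` takes concentrations (1-D or a single-column 2-D array)
    and bead-px-per-cell values; fitted attributes expose the slope with
    its standard error, the 95% CI from the t distribution with n-2 df,
    and R^2.  ``confidence_band(X)`` returns the 95% mean-response band.
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("X must be a single concentration column")
            x = x[:, 0]
        y = np.asarray(y, dtype=float)
        if x.size != y.size:
            raise ValueError("X and y lengths differ")
        if x.size < 3:
            raise ValueError("need at least three points")
        if np.unique(x).size < 2:
            raise ValueError("need at least two distinct concentrations")
        res = sm.OLS(y, sm.add_constant(x, has_constant="add")).fit()
        ci = res.conf_int(alpha=0.05)
        self.result_ = res
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.slope_se_ = float(res.bse[1])
        self.ci95_slope_ = (float(ci[1, 0]), float(ci[1, 1]))
        self.r_squared_ = float(res.rsquared)
        self.df_resid_ = float(res.df_resid)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return self.intercept_ + self.slope_ * x

    def confidence_band(self, X):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        pred = self.result_.get_prediction(
            sm.add_constant(x, has_constant="add")
        )
        ci = pred.conf_int(alpha=0.05)
        return ci[:, 0], ci[:, 1]

    def to_fit(self) -> RegressionFit:
        return RegressionFit(
            slope=self.slope_,
            intercept=self.intercept_,
            slope_se=self.slope_se_,
            ci95_slope=self.ci95_slope_,
            r_squared=self.r_squared_,
            df_resid=self.df_resid_,
            _result=self.result_,
        )


def fit_dose_response(
    records: Iterable[tuple[float, float]]
) -> RegressionFit:
    """OLS fit of bead-px-per-cell against concentration.

    ``records`` is an iterable of (concentration, value) pairs; at least
    three points over at least two distinct concentrations are required.
    """
    arr = np.asarray(list(records), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("records must be (concentration, value) pairs")
    est = DoseResponseLinear().fit(arr[:, 0], arr[:, 1])
    return est.to_fit()


@dataclass
class UptakeSummary:
    """Summary of uptake records: group stats, pairwise tests, fits."""

    groups: pd.DataFrame
    tests: pd.DataFrame
    fits: dict[tuple[str, float], RegressionFit]

    def to_json_dict(self) -> dict:
        fits = {
            f"{cl}@{t}h": {
                "slope": f.slope,
                "intercept": f.intercept,
                "slope_se": f.slope_se,
                "ci95_slope": list(f.ci95_slope),
                "r_squared": f.r_squared,
            }
            for (cl, t), f in self.fits.items()
        }
        return {
            "groups": self.groups.to_dict(orient="records"),
            "tests": self.tests.to_dict(orient="records"),
            "fits": fits,
        }


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    rows = []
    for r in records:
        rows.append(
            {
                "cell_line": r.cell_line,
                "concentration": r.concentration,
                "time_h": r.time_h,
                "replicate": getattr(r, "replicate", 0),
                "bead_px_per_cell": getattr(
                    r, "bead_px_per_cell", getattr(r, "value", np.nan)
                ),
                "valid": getattr(r, "valid", True),
            }
        )
    return pd.DataFrame(rows)


def summarize_uptake(
    records,
    variant: str = "welch",
    alpha: float = 0.05,
    holm: bool = False,
) -> UptakeSummary:
    """Per-group statistics, pairwise concentration tests and regressions.

    Groups are cell_line x concentration x time; within each cell_line x
    time, every concentration pair is compared with a two-sided unpaired
    t-test and a dose-response line is fitted when at least two distinct
    concentrations are present.  Raw p-values are reported (``holm=True``
    applies a Holm step-down correction) and marked ``*`` at p <= alpha.
    """
    df = _records_frame(records)
    if df.empty:
        raise ValueError("no records to summarize")
    if "valid" in df:
        df = df[df["valid"]]
    if df.empty:
        raise ValueError("no valid records to summarize")

    groups = (
        df.groupby(["cell_line", "concentration", "time_h"])["bead_px_per_cell"]
        .agg(n="count", mean="mean", sd="std")
        .reset_index()
    )

    test_rows = []
    fits: dict[tuple[str, float], RegressionFit] = {}
    for (cl, t), sub in df.groupby(["cell_line", "time_h"]):
        concs = sorted(sub["concentration"].unique())
        for c1, c2 in combinations(concs, 2):
            a = sub.loc[sub["concentration"] == c1, "bead_px_per_cell"]
            b = sub.loc[sub["concentration"] == c2, "bead_px_per_cell"]
            if len(a) < 2 or len(b) < 2:
                continue
            res = ttest_unpaired(a, b, variant=variant, labels=(str(c1), str(c2)))
            test_rows.append(
                {
                    "cell_line": cl,
                    "time_h": t,
                    "conc_a": c1,
                    "conc_b": c2,
                    "statistic": res.statistic,
                    "df": res.degrees_of_freedom,
                    "p_value": res.p_value,
                    "variant": variant,
                }
            )
        if len(concs) >= 2 and len(sub) >= 3:
            fits[(cl, t)] = fit_dose_response(
                list(zip(sub["concentration"], sub["bead_px_per_cell"]))
            )

    tests = pd.DataFrame(
        test_rows,
        columns=[
            "cell_line", "time_h", "conc_a", "conc_b",
            "statistic", "df", "p_value", "variant",
        ],
    )
    if not tests.empty:
        if holm:
            order = np.argsort(tests["p_value"].values)
            m = len(tests)
            adj = np.empty(m)
            running = 0.0
            for rank, i in enumerate(order):
                running = max(running, (m - rank) * tests["p_value"].values[i])
                adj[i] = min(running, 1.0)
            tests["p_adjusted"] = adj
            pcol = "p_adjusted"
        else:
            pcol = "p_value"
        tests["significant"] = np.where(tests[pcol] <= alpha, "*", "")
    return UptakeSummary(groups=groups, tests=tests, fits=fits)
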