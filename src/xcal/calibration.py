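"""Bootstrap linear-regression cross-calibration between scanner generations.

The procedure is a hybrid of cross-validation and bootstrapping: the
cohort is randomly split into a training set (default 24 subjects) and a
held-out test set (default 12); from the training pairs, 1000 bootstrap
draws of 12 points (with replacement) are each fitted by ordinary least
squares of the second-generation value on the first-generation value, and
the averaged slope and intercept over the 1000 fits form the calibration
equation.  The reported R^2 is likewise the mean of the per-draw R^2
values.  Applying the equation to held-out first-generation values yields
the estimated second-generation outcomes (XCTII*), which the agreement
module compares with the measured values.

API shape follows the statsmodels convention: :class:`CrossCalibration` is
the model (data + procedure parameters), ``fit()`` returns a
:class:`CalibrationEquation` results object carrying point estimates,
bootstrap distributions and a ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import OutcomeTable

__all__ = [
    "SplitPlan",
    "split_cohort",
    "CrossCalibration",
    "CalibrationEquation",
    "EstimateSet",
    "bootstrap_calibrate",
    "apply_calibration",
    "CalibrationStudy",
]

logger = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    """Disjoint training/test partition of a cohort."""

    training_ids: list[str]
    test_ids: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        if set(self.training_ids) & set(self.test_ids):
            raise ValueError("training and test sets must be disjoint")
        if not self.training_ids or not self.test_ids:
            raise ValueError("training and test sets must be nonempty")


def split_cohort(table: OutcomeTable, n_test: int = 12,
                 seed: int | None = None) -> SplitPlan:
    """Uniformly random partition of the cohort's subjects (no replacement)."""
    subjects = table.subjects
    if n_test < 2:
        raise ValueError("n_test must be at least 2")
    if n_test >= len(subjects):
        raise ValueError(
            f"n_test={n_test} leaves no training subjects (cohort size "
            f"{len(subjects)})"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(subjects))
    test = sorted(subjects[i] for i in perm[:n_test])
    train = sorted(subjects[i] for i in perm[n_test:])
    return SplitPlan(training_ids=train, test_ids=test, seed=seed)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form simple OLS of y on x; returns (slope, intercept, r2).

    A draw with zero y-variance fitted exactly by a constant gets r2 = 1.
    """
    xm = x.mean()
    ym = y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_tot = float(((y - ym) ** 2).sum())
    ss_res = float(((y - slope * x - intercept) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 1.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return slope, intercept, r2


@dataclass
class CalibrationEquation:
    """Results of a bootstrap cross-calibration fit for one parameter."""

    parameter: str
    slope: float
    intercept: float
    r_squared: float
    n_boot: int
    boot_slopes: np.ndarray
    boot_intercepts: np.ndarray
    boot_r2: np.ndarray
    seed: int | None = None
    n_train: int = 0
    draw_size: int = 0
    redraw_count: int = 0

    def __post_init__(self) -> None:
        for name in ("boot_slopes", "boot_intercepts", "boot_r2"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != (self.n_boot,):
                raise ValueError(f"{name} must have length n_boot={self.n_boot}")
            setattr(self, name, arr)

    def predict(self, x) -> np.ndarray | float:
        """Estimated second-generation value(s): slope * x + intercept.

        Missing inputs (NaN) propagate as missing.
        """
        return self.slope * np.asarray(x, dtype=np.float64) + self.intercept

    def summary(self) -> str:
        lines = [
            f"Cross-calibration equation: {self.parameter}",
            f"  XCTII* = {self.slope:.4g} * XCTI {self.intercept:+.4g}",
            f"  mean R^2 over {self.n_boot} bootstrap fits: {self.r_squared:.4f}",
            f"  bootstrap slope SD {self.boot_slopes.std(ddof=1):.4g}, "
            f"intercept SD {self.boot_intercepts.std(ddof=1):.4g}",
            f"  training pairs {self.n_train}, draw size {self.draw_size}, "
            f"degenerate draws redrawn {self.redraw_count}",
        ]
        return "\n".join(lines)


@dataclass
class EstimateSet:
    """Estimated second-generation values (XCTII*) for test subjects."""

    parameter: str
    estimates: pd.Series  # indexed by subject_id
    equation: CalibrationEquation


class CrossCalibration:
    """Model object for one outcome parameter's inter-scanner relationship.

    Parameters
    ----------
    x, y : array-like
        Paired first-generation (x) and second-generation (y) training
        values; pairs with a missing member are dropped (counted in
        ``n_dropped``).
    parameter : str
        Outcome name carried through to the results object.
    """

    def __init__(self, x, y, parameter: str = "") -> None:
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1D arrays of equal length")
        ok = np.isfinite(x) & np.isfinite(y)
        self.n_dropped = int((~ok).sum())
        if self.n_dropped:
            logger.info("%s: dropped %d incomplete pair(s)", parameter or "fit",
                        self.n_dropped)
        self.x = x[ok]
        self.y = y[ok]
        self.parameter = parameter
        if self.x.size < 2 or np.unique(self.x).size < 2:
            raise ValueError("no variance for regression: need >= 2 distinct x values")

    @classmethod
    def from_tables(cls, xcti: OutcomeTable, xctii: OutcomeTable, parameter: str,
                    method: str | None = None) -> "CrossCalibration":
        """Build the model from a pair of outcome tables, joined on subject."""
        xs = xcti.values_for(parameter, scanner="XCTI")
        ys = xctii.values_for(parameter, scanner="XCTII", method=method)
        joined = pd.concat([xs.rename("x"), ys.rename("y")], axis=1, join="inner")
        return cls(joined["x"].to_numpy(), joined["y"].to_numpy(), parameter)

    def fit(self, n_boot: int = 1000, draw_size: int = 12,
            seed: int | None = None, max_redraws: int = 100_000) -> CalibrationEquation:
        """Bootstrap-averaged OLS fit.

        Each draw samples ``draw_size`` pairs with replacement from the
        training pairs; draws in which all x values coincide cannot be
        fitted and are redrawn (counted).  Fixing the seed fixes all draws.
        """
        if draw_size < 2:
            raise ValueError("draw_size must be at least 2")
        if n_boot < 1:
            raise ValueError("n_boot must be at least 1")
        rng = np.random.default_rng(seed)
        n = self.x.size
        slopes = np.empty(n_boot)
        intercepts = np.empty(n_boot)
        r2s = np.empty(n_boot)
        redraws = 0
        for b in range(n_boot):
            while True:
                idx = rng.integers(0, n, size=draw_size)
                xd = self.x[idx]
                if np.ptp(xd) > 0:
                    break
                redraws += 1
                if redraws > max_redraws:
                    raise RuntimeError("too many degenerate bootstrap draws")
            slopes[b], intercepts[b], r2s[b] = _ols(xd, self.y[idx])
        if redraws:
            logger.info("%s: redrew %d degenerate bootstrap draw(s)",
                        self.parameter or "fit", redraws)
        return CalibrationEquation(
            parameter=self.parameter,
            slope=float(slopes.mean()),
            intercept=float(intercepts.mean()),
            r_squared=float(r2s.mean()),
            n_boot=n_boot,
            boot_slopes=slopes,
            boot_intercepts=intercepts,
            boot_r2=r2s,
            seed=seed,
            n_train=n,
            draw_size=draw_size,
            redraw_count=redraws,
        )


def bootstrap_calibrate(
    train_xcti: OutcomeTable,
    train_xctii: OutcomeTable,
    parameter: str,
    n_boot: int = 1000,
    draw_size: int = 12,
    seed: int | None = None,
    method: str | None = None,
) -> CalibrationEquation:
    """Functional wrapper: build the model from tables and fit it."""
    model = CrossCalibration.from_tables(train_xcti, train_xctii, parameter,
                                         method=method)
    return model.fit(n_boot=n_boot, draw_size=draw_size, seed=seed)


def apply_calibration(eq: CalibrationEquation, xcti_values: pd.Series) -> EstimateSet:
    """Apply an equation to held-out first-generation values.

    Missing inputs propagate as missing estimates.
    """
    if not (np.isfinite(eq.slope) and np.isfinite(eq.intercept)):
        raise ValueError("calibration equation is not finite")
    xcti_values = pd.Series(xcti_values, dtype=np.float64)
    estimates = eq.slope * xcti_values + eq.intercept
    return EstimateSet(parameter=eq.parameter, estimates=estimates, equation=eq)


class CalibrationStudy:
    """Whole-cohort orchestration: split once, calibrate and validate every
    parameter present in both tables.

    ``run()`` returns (equations DataFrame shaped like a published
    calibration table, per-parameter EstimateSets keyed by parameter).
    """

    def __init__(self, xcti: OutcomeTable, xctii: OutcomeTable,
                 method: str | None = None) -> None:
        self.xcti = xcti
        self.xctii = xctii
        self.method = method
        self.parameters = sorted(set(xcti.parameters) & set(xctii.parameters))
        if not self.parameters:
            raise ValueError("no common parameters between the two tables")

    def run(self, n_test: int = 12, n_boot: int = 1000, draw_size: int = 12,
            seed: int | None = None):
        master = np.random.default_rng(seed)
        split_seed = int(master.integers(0, 2**31 - 1))
        plan = split_cohort(self.xcti, n_test=n_test, seed=split_seed)
        train_i = self.xcti.subset(plan.training_ids)
        train_ii = self.xctii.subset(plan.training_ids)
        test_i = self.xcti.subset(plan.test_ids)

        rows = []
        estimate_sets: dict[str, EstimateSet] = {}
        equations: dict[str, CalibrationEquation] = {}
        for param in self.parameters:
            fit_seed = int(master.integers(0, 2**31 - 1))
            eq = bootstrap_calibrate(train_i, train_ii, param, n_boot=n_boot,
                                     draw_size=draw_size, seed=fit_seed,
                                     method=self.method)
            equations[param] = eq
            x_test = test_i.values_for(param, scanner="XCTI")
            estimate_sets[param] = apply_calibration(eq, x_test)
            rows.append(
                dict(parameter=param, slope=eq.slope, intercept=eq.intercept,
                     r_squared=eq.r_squared, n_boot=eq.n_boot,
                     n_train=eq.n_train, redraws=eq.redraw_count)
            )
        table = pd.DataFrame(rows).set_index("parameter")
        self.plan = plan
        self.equations = equations
        return table, estimate_sets
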