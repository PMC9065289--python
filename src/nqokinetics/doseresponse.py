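"""SRB-viability normalization, logistic dose-response fitting and IC50 comparison.

Raw sulforhodamine-B absorbances (560 nm, total-protein stain) are normalized
per condition against the mean of that condition's untreated wells, then a
variable-slope four-parameter logistic is fitted on log10 drug concentration.
IC50s are compared on the log10 scale with a Welch two-tailed t-test, since
IC50 sampling distributions are approximately log-symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ratelaws import DoseResponseParams, logistic_response

__all__ = [
    "DosePlate",
    "DoseResponseModel",
    "DoseResponseResults",
    "Ic50Comparison",
    "normalize_viability",
    "fit_dose_response",
    "compare_ic50",
]

PLATE_COLUMNS = ("condition", "drug_uM", "modifier_uM", "replicate", "absorbance")


@dataclass(frozen=True)
class DosePlate:
    """Tidy cytotoxicity plate: one row per well.

    Columns: condition (cell line / modifier label), drug_uM, modifier_uM,
    replicate, absorbance (raw SRB reading at 560 nm).  Untreated wells are
    those with drug_uM == 0 and anchor the normalization of their condition.
    """

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(PLATE_COLUMNS) - set(self.wells.columns)
        if missing:
            raise ValueError(f"plate table is missing columns: {sorted(missing)}")

    @property
    def conditions(self) -> Tuple[str, ...]:
        return tuple(pd.unique(self.wells["condition"]))

    def validate(self) -> None:
        """Enforce the plate design invariants (≥3 replicates per dose,
        ≥4 distinct positive doses, untreated wells per condition)."""
        for cond, sub in self.wells.groupby("condition", sort=False):
            treated = sub[sub["drug_uM"] > 0]
            if (sub["drug_uM"] == 0).sum() == 0:
                raise ValueError(f"condition {cond!r} has no untreated wells")
            if treated["drug_uM"].nunique() < 4:
                raise ValueError(
                    f"condition {cond!r} has fewer than 4 distinct drug doses"
                )
            counts = treated.groupby("drug_uM").size()
            if (counts < 3).any():
                raise ValueError(
                    f"condition {cond!r} has doses with fewer than 3 replicates"
                )


def normalize_viability(plate: DosePlate) -> pd.DataFrame:
    """Divide each well by its condition's mean untreated absorbance.

    Returns the well table with a ``viability`` column added; untreated wells
    map to mean 1 by construction.  A condition without untreated wells is an
    error naming that condition.
    """
    frames = []
    for cond, sub in plate.wells.groupby("condition", sort=False):
        untreated = sub.loc[sub["drug_uM"] == 0, "absorbance"]
        if untreated.empty:
            raise ValueError(f"no untreated wells for condition {cond!r}")
        ref = float(untreated.mean())
        if not (ref > 0):
            raise ValueError(
                f"mean untreated absorbance for condition {cond!r} is not positive"
            )
        out = sub.copy()
        out["viability"] = out["absorbance"] / ref
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


class DoseResponseResults:
    """Fitted logistic dose-response curve with IC50 inference."""

    def __init__(
        self,
        model: "DoseResponseModel",
        params: DoseResponseParams,
        log10_ic50: float,
        log10_ic50_se: float,
        cov: np.ndarray,
        rss: float,
        nobs: int,
        converged: bool = True,
        flags: Tuple[str, ...] = (),
        message: str = "",
        df_resid: Optional[int] = None,
    ) -> None:
        self.model = model
        self.params = params
        self.log10_ic50 = log10_ic50
        self.log10_ic50_se = log10_ic50_se
        self.cov = cov
        self.rss = rss
        self.nobs = nobs
        self.converged = converged
        self.flags = flags
        self.message = message
        self._df_resid = df_resid

    @property
    def df_resid(self) -> int:
        return self.nobs - 4 if self._df_resid is None else self._df_resid

    @property
    def ic50(self) -> float:
        return self.params.ic50

    @property
    def ic50_unbounded(self) -> bool:
        return "ic50_unbounded" in self.flags

    @property
    def ic50_ci95(self) -> Tuple[float, float]:
        """t-based 95% CI, computed on the log10 scale and exponentiated."""
        if self.df_resid <= 0 or not np.isfinite(self.log10_ic50_se):
            return (0.0, math.inf)
        tq = float(stats.t.ppf(0.975, self.df_resid))
        lo = 10 ** (self.log10_ic50 - tq * self.log10_ic50_se)
        hi = 10 ** (self.log10_ic50 + tq * self.log10_ic50_se)
        return (lo, hi)

    def predict(self, conc) -> np.ndarray:
        return logistic_response(self.params, conc)

    def to_dict(self) -> dict:
        return {
            "condition": self.model.label,
            "top": self.params.top,
            "bottom": self.params.bottom,
            "hill": self.params.hill,
            "ic50_uM": self.params.ic50,
            "ic50_ci95_uM": list(self.ic50_ci95),
            "log10_ic50_se": self.log10_ic50_se,
            "rss": self.rss,
            "n_obs": self.nobs,
            "flags": list(self.flags),
        }

    def summary(self) -> str:
        lo, hi = self.ic50_ci95
        lines = [
            f"Dose-response fit: {self.model.label or '(unnamed)'}",
            f"n_obs = {self.nobs}   rss = {self.rss:.5g}",
            f"IC50 = {self.ic50:.4g} µM   95% CI [{lo:.4g}, {hi:.4g}]",
            f"top = {self.params.top:.3g}   bottom = {self.params.bottom:.3g}   "
            f"hill = {self.params.hill:.3g}",
        ]
        if self.flags:
            lines.append(f"flags: {', '.join(self.flags)}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c, v = self.model.conc, self.model.viability
        ax.semilogx(c, v, "o", ms=4)
        line = np.geomspace(c.min(), c.max(), 200)
        ax.semilogx(line, self.predict(line), "-")
        ax.set_xlabel("drug (µM)")
        ax.set_ylabel("normalized viability")
        ax.set_title(self.model.label)
        return ax


class DoseResponseModel:
    """Variable-slope logistic model of normalized viability vs drug dose.

    Zero-concentration wells anchor normalization only and must be excluded
    before construction (the fit runs on log10 concentration).
    """

    def __init__(self, conc, viability, label: str = "") -> None:
        conc = np.asarray(conc, dtype=float)
        viability = np.asarray(viability, dtype=float)
        if conc.shape != viability.shape or conc.ndim != 1:
            raise ValueError("conc and viability must be matching 1-D arrays")
        if np.any(conc <= 0):
            raise ValueError(
                "fit concentrations must be positive; zero-dose wells enter "
                "via normalization, not the log axis"
            )
        if np.unique(conc).size < 4:
            raise ValueError("need ≥ 4 distinct drug concentrations")
        self.conc = conc
        self.viability = viability
        self.label = label

    @classmethod
    def from_table(
        cls, table: pd.DataFrame, condition: Optional[str] = None
    ) -> "DoseResponseModel":
        """Build from a normalized-viability table (see normalize_viability)."""
        sub = table if condition is None else table[table["condition"] == condition]
        sub = sub[sub["drug_uM"] > 0]
        label = condition if condition is not None else ""
        return cls(sub["drug_uM"].to_numpy(float), sub["viability"].to_numpy(float), label)

    # ------------------------------------------------------------------
    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        top, bottom, l10ic50, hill = theta
        pred = bottom + (top - bottom) / (
            1.0 + 10 ** (hill * (np.log10(self.conc) - l10ic50))
        )
        return pred - self.viability

    def fit(
        self,
        n_starts: int = 6,
        top_band: Tuple[float, float] = (0.95, 1.05),
    ) -> DoseResponseResults:
        """Multi-start bounded least squares on (top, bottom, log10 IC50, hill).

        Because viability is normalized against the untreated wells, the
        upper asymptote is pinned at 1 by construction; ``top`` is therefore
        fitted only within ``top_band`` (normalization-level slack).  This
        keeps IC50 identifiable even when the whole tested range lies above
        the IC50, as for a strongly potentiated prodrug.  Bottom is
        constrained to [0, top).
        """
        l10c = np.log10(self.conc)
        lo = np.array([top_band[0], 0.0, l10c.min() - 3.0, 0.05])
        hi = np.array([top_band[1], 1.0, l10c.max() + 3.0, 10.0])
        top0 = 1.0
        bot0 = min(max(float(np.min(self.viability)), 0.0), 0.9)
        mids = np.linspace(l10c.min(), l10c.max(), max(n_starts - 2, 2))
        starts = [np.array([top0, bot0, m, 1.0]) for m in mids]
        starts += [
            np.array([top0, bot0, l10c.mean(), 0.5]),
            np.array([top0, bot0, l10c.mean(), 2.0]),
        ]
        best = None
        for x0 in starts:
            x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
            try:
                sol = optimize.least_squares(
                    self._residuals, x0, bounds=(lo, hi), max_nfev=5000,
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError(f"dose-response fit failed for {self.label!r}")

        top, bottom, l10ic50, hill = best.x
        bottom = min(bottom, top - 1e-9)
        params = DoseResponseParams(top=top, bottom=bottom, ic50=10**l10ic50, hill=hill)
        rss = float(2 * best.cost)
        nobs = self.conc.size
        # parameters pinned at a bound are constrained, not estimated: the
        # covariance runs over the free directions only (otherwise the IC50
        # uncertainty is grossly inflated whenever top sits on its anchor
        # band or bottom on zero)
        free = best.active_mask == 0
        n_free = int(free.sum())
        df = nobs - n_free
        cov = np.full((4, 4), np.nan)
        se_l10 = math.inf
        if df > 0 and free[2]:
            s2 = rss / df
            Jf = best.jac[:, free]
            try:
                cov_f = np.linalg.inv(Jf.T @ Jf) * s2
            except np.linalg.LinAlgError:
                cov_f = np.linalg.pinv(Jf.T @ Jf) * s2
            idx = np.flatnonzero(free)
            cov[np.ix_(idx, idx)] = cov_f
            pos = int(np.searchsorted(idx, 2))
            se_l10 = float(np.sqrt(max(cov_f[pos, pos], 0.0)))

        flags: Tuple[str, ...] = ()
        fitted = params.bottom + (params.top - params.bottom) / (
            1.0 + (self.conc / params.ic50) ** params.hill
        )
        if np.all(fitted > 0.8) or np.all(fitted < 0.2):
            flags = ("ic50_unbounded",)
        return DoseResponseResults(
            self, params, float(l10ic50), se_l10, cov, rss, nobs, True, flags,
            df_resid=df,
        )


def fit_dose_response(
    table: pd.DataFrame, condition: Optional[str] = None
) -> DoseResponseResults:
    """Fit the logistic curve to a normalized-viability table (one condition)."""
    return DoseResponseModel.from_table(table, condition).fit()


@dataclass(frozen=True)
class Ic50Comparison:
    """Fold change and two-tailed Welch t-test between two fitted IC50s."""

    fold_change: float
    t_stat: float
    df: float
    pvalue: float
    qualitative_only: bool = False

    def to_dict(self) -> dict:
        return {
            "fold_change": self.fold_change,
            "t": self.t_stat,
            "df": self.df,
            "pvalue": self.pvalue,
            "qualitative_only": self.qualitative_only,
        }


def compare_ic50(fit_a: DoseResponseResults, fit_b: DoseResponseResults) -> Ic50Comparison:
    """Fold change ic50_a/ic50_b and a two-tailed t-test on log10 IC50.

    Uses the fits' log10-IC50 standard errors with Welch-Satterthwaite
    degrees of freedom.  If either IC50 is flagged unbounded the comparison
    is marked qualitative-only (fold change still reported, p = NaN).
    """
    fold = fit_a.ic50 / fit_b.ic50
    if fit_a.ic50_unbounded or fit_b.ic50_unbounded:
        return Ic50Comparison(fold, math.nan, math.nan, math.nan, True)
    d = fit_a.log10_ic50 - fit_b.log10_ic50
    v1, v2 = fit_a.log10_ic50_se**2, fit_b.log10_ic50_se**2
    if v1 + v2 == 0:
        # identical, noise-free fits: no evidence of a difference
        return Ic50Comparison(fold, 0.0, math.inf, 1.0)
    t_stat = d / math.sqrt(v1 + v2)
    df1, df2 = max(fit_a.df_resid, 1), max(fit_b.df_resid, 1)
    df = (v1 + v2) ** 2 / (v1**2 / df1 + v2**2 / df2)
    pvalue = 2 * float(stats.t.sf(abs(t_stat), df))
    return Ic50Comparison(fold, t_stat, df, pvalue)
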