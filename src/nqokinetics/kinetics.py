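"""Global nonlinear least-squares estimation of ping-pong bi-substrate kinetics.

The workhorse is :class:`PingPongModel`, a statsmodels-flavoured model object
built from a :class:`RateGrid` of replicate initial-rate observations over a
two-substrate concentration grid.  ``fit()`` minimises the unweighted residual
sum of squares of observed vs predicted velocities jointly over the whole
grid, from multiple log-spaced starting points, and returns a
:class:`KineticResults` carrying estimates, the Jacobian-based covariance,
t-based approximate 95% confidence limits, and the derived catalytic
efficiency kcat/K_A with a first-order propagated CI.

Model variants
--------------
- global fit of (kcat, K_A, K_B) with or without the acceptor
  substrate-inhibition constant K_I;
- extra-sum-of-squares F-test selection between the two (K_I is retained only
  when the F-test favours it at the chosen alpha AND the estimate is
  identifiable, i.e. below 10x the largest tested acceptor concentration);
- constrained cosubstrate fits of (kcat, K_A) with the acceptor constants
  frozen at values determined with a good cosubstrate;
- an efficiency-only fallback for cosubstrates that cannot saturate the
  enzyme, where only the linear-regime slope — hence kcat/K_A — is estimable.

Parameters are optimised in log10 space (which enforces positivity without
active bounds); the covariance is mapped back to natural units at the
optimum by the chain rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ratelaws import RateLawParams, pingpong_rate

__all__ = [
    "RateGrid",
    "PingPongModel",
    "KineticResults",
    "EfficiencyEstimate",
    "fit_global_pingpong",
    "select_inhibition_model",
    "fit_cosubstrate_constrained",
    "fit_efficiency_only",
    "catalytic_efficiency",
    "efficiency_from_constants",
    "SaturationError",
]

ND = "ND"
_LN10 = math.log(10.0)


class SaturationError(ValueError):
    """Raised when the efficiency-only fallback is applied to saturating data."""


@dataclass(frozen=True)
class RateGrid:
    """Replicate initial-rate observations over a two-substrate grid.

    a: cosubstrate concentrations (µM), b: acceptor concentrations (µM),
    rate: observed velocities (µM·s⁻¹), one entry per well/replicate.
    """

    a: np.ndarray
    b: np.ndarray
    rate: np.ndarray
    replicate: np.ndarray
    enzyme_nM: float
    cosubstrate: str = "BNAH"
    acceptor: str = "menadione"

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        r = np.asarray(self.rate, dtype=float)
        rep = np.asarray(self.replicate)
        for name, arr in (("a", a), ("b", b), ("rate", r), ("replicate", rep)):
            if arr.ndim != 1 or arr.size != a.size:
                raise ValueError(f"{name} must be 1-D and congruent with a")
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("all substrate concentrations must be positive")
        if not (self.enzyme_nM > 0):
            raise ValueError("enzyme concentration must be positive")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "rate", r)
        object.__setattr__(self, "replicate", rep)

    @property
    def n_obs(self) -> int:
        return self.a.size

    @property
    def enzyme_uM(self) -> float:
        return self.enzyme_nM * 1e-3

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        enzyme_nM: float,
        cosubstrate: str = "BNAH",
        acceptor: str = "menadione",
    ) -> "RateGrid":
        """Build from a tidy table with columns
        cosubstrate_uM, acceptor_uM, rate_uM_s, replicate."""
        required = {"cosubstrate_uM", "acceptor_uM", "rate_uM_s", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"rate table is missing columns: {sorted(missing)}")
        return cls(
            a=df["cosubstrate_uM"].to_numpy(float),
            b=df["acceptor_uM"].to_numpy(float),
            rate=df["rate_uM_s"].to_numpy(float),
            replicate=df["replicate"].to_numpy(),
            enzyme_nM=enzyme_nM,
            cosubstrate=cosubstrate,
            acceptor=acceptor,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cosubstrate_uM": self.a,
                "acceptor_uM": self.b,
                "rate_uM_s": self.rate,
                "replicate": self.replicate,
            }
        )

    def require_bisubstrate(self) -> None:
        if np.unique(self.a).size < 2 or np.unique(self.b).size < 2:
            raise ValueError(
                "global bisubstrate fits need ≥ 2 distinct concentrations of "
                "each substrate"
            )


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Catalytic efficiency kcat/K_M in M⁻¹·s⁻¹ with a propagated 95% CI."""

    value: float
    se: float
    ci95: Tuple[float, float]

    @property
    def relative_ci_width(self) -> float:
        if self.value == 0:
            return math.inf
        return (self.ci95[1] - self.ci95[0]) / abs(self.value)


def efficiency_from_constants(kcat: float, K_M_uM: float) -> float:
    """kcat (s⁻¹) over K_M (µM) expressed in M⁻¹·s⁻¹."""
    return kcat / (K_M_uM * 1e-6)


class KineticResults:
    """Estimates, uncertainties and diagnostics from a kinetic fit.

    Attributes mirror statsmodels results: ``params`` (a
    :class:`RateLawParams` with frozen constants filled in), ``bse``,
    ``conf_int()``, ``cov``, ``rss``, ``nobs``, ``summary()``.
    """

    def __init__(
        self,
        model: "PingPongModel",
        params: Optional[RateLawParams],
        free_names: Tuple[str, ...],
        cov: np.ndarray,
        rss: float,
        nobs: int,
        method: str,
        converged: bool = True,
        inhibition_detected: str = ND,
        f_pvalue: Optional[float] = None,
        message: str = "",
        flags: Tuple[str, ...] = (),
        efficiency_override: Optional[EfficiencyEstimate] = None,
    ) -> None:
        self.model = model
        self.params = params
        self.free_names = free_names
        self.cov = np.asarray(cov, dtype=float)
        self.rss = float(rss)
        self.nobs = int(nobs)
        self.method = method
        self.converged = converged
        self.inhibition_detected = inhibition_detected
        self.f_pvalue = f_pvalue
        self.message = message
        self.flags = flags
        self._efficiency_override = efficiency_override

    # ------------------------------------------------------------------
    @property
    def df_resid(self) -> int:
        return self.nobs - len(self.free_names)

    @property
    def bse(self) -> Dict[str, float]:
        se = np.sqrt(np.clip(np.diag(self.cov), 0, np.inf))
        return dict(zip(self.free_names, se))

    def conf_int(self, alpha: float = 0.05) -> Dict[str, Tuple[float, float]]:
        """Per-parameter t-based approximate (1 - alpha) confidence limits."""
        if self.df_resid <= 0:
            tq = math.inf
        else:
            tq = float(stats.t.ppf(1 - alpha / 2, self.df_resid))
        out = {}
        for name, se in self.bse.items():
            est = getattr(self.params, name) if self.params is not None else math.nan
            out[name] = (est - tq * se, est + tq * se)
        return out

    @property
    def ci95(self) -> Dict[str, Tuple[float, float]]:
        return self.conf_int(0.05)

    @property
    def saturated(self) -> bool:
        """Whether the cosubstrate range saturates the enzyme (plateau seen)."""
        if self.params is None or "K_A" not in self.free_names:
            return False
        a_max = float(np.max(self.model.grid.a))
        hi = self.conf_int()["K_A"][1]
        return bool(self.params.K_A <= a_max and np.isfinite(hi))

    @property
    def efficiency(self) -> EfficiencyEstimate:
        """kcat/K_A in M⁻¹·s⁻¹, CI by first-order error propagation."""
        if self._efficiency_override is not None:
            return self._efficiency_override
        if self.params is None:
            return EfficiencyEstimate(math.nan, math.nan, (math.nan, math.nan))
        k, K = self.params.kcat, self.params.K_A
        eff = efficiency_from_constants(k, K)
        idx = {n: i for i, n in enumerate(self.free_names)}
        var_k = self.cov[idx["kcat"], idx["kcat"]] if "kcat" in idx else 0.0
        var_K = self.cov[idx["K_A"], idx["K_A"]] if "K_A" in idx else 0.0
        cov_kK = (
            self.cov[idx["kcat"], idx["K_A"]]
            if "kcat" in idx and "K_A" in idx
            else 0.0
        )
        rel_var = var_k / k**2 + var_K / K**2 - 2 * cov_kK / (k * K)
        se = abs(eff) * math.sqrt(max(rel_var, 0.0))
        tq = (
            float(stats.t.ppf(0.975, self.df_resid))
            if self.df_resid > 0
            else math.inf
        )
        return EfficiencyEstimate(eff, se, (eff - tq * se, eff + tq * se))

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        """JSON-ready record of the fit."""
        ci = self.conf_int() if self.params is not None else {}

        def cell(name: str):
            if self.params is None or not hasattr(self.params, name):
                return ND
            if self.method == "efficiency_only" and name in ("kcat", "K_A"):
                return ND
            if name == "K_I" and self.params.K_I is None:
                return ND
            return getattr(self.params, name)

        eff = self.efficiency
        return {
            "method": self.method,
            "converged": self.converged,
            "cosubstrate": self.model.grid.cosubstrate,
            "acceptor": self.model.grid.acceptor,
            "enzyme_nM": self.model.grid.enzyme_nM,
            "params": {n: cell(n) for n in ("kcat", "K_A", "K_B", "K_I")},
            "ci95": {n: list(v) for n, v in ci.items()},
            "efficiency_M_per_s": eff.value,
            "efficiency_ci95": list(eff.ci95),
            "inhibition_detected": self.inhibition_detected,
            "f_pvalue": self.f_pvalue,
            "saturated": "yes" if self.saturated else "no",
            "rss": self.rss,
            "n_obs": self.nobs,
            "flags": list(self.flags),
            "message": self.message,
        }

    def summary(self) -> str:
        """Plain-text summary table in the style of the published kinetics tables."""
        lines = [
            f"Ping-pong kinetic fit ({self.method})",
            f"cosubstrate: {self.model.grid.cosubstrate}   "
            f"acceptor: {self.model.grid.acceptor}   "
            f"E0 = {self.model.grid.enzyme_nM:g} nM",
            f"n_obs = {self.nobs}   rss = {self.rss:.6g}   "
            f"converged = {self.converged}",
            "-" * 62,
            f"{'parameter':<12}{'estimate':>14}{'95% CI':>30}",
        ]
        ci = self.conf_int() if self.params is not None else {}
        for name in ("kcat", "K_A", "K_B", "K_I"):
            val = None if self.params is None else getattr(self.params, name, None)
            if self.method == "efficiency_only" and name in ("kcat", "K_A"):
                val = None
            if val is None:
                lines.append(f"{name:<12}{ND:>14}")
                continue
            if name in ci:
                lo, hi = ci[name]
                lines.append(f"{name:<12}{val:>14.5g}{f'[{lo:.4g}, {hi:.4g}]':>30}")
            else:
                lines.append(f"{name:<12}{val:>14.5g}{'(fixed)':>30}")
        eff = self.efficiency
        lines.append("-" * 62)
        lines.append(
            f"kcat/K_A = {eff.value:.3g} M^-1 s^-1   "
            f"95% CI [{eff.ci95[0]:.3g}, {eff.ci95[1]:.3g}]"
        )
        lines.append(
            f"substrate inhibition: {self.inhibition_detected}   "
            f"saturated: {'yes' if self.saturated else 'no'}"
        )
        if self.flags:
            lines.append(f"flags: {', '.join(self.flags)}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Diagnostic plot: observed vs fitted velocities per acceptor level."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = self.model.grid
        for b in np.unique(g.b):
            m = g.b == b
            order = np.argsort(g.a[m])
            ax.plot(g.a[m][order], g.rate[m][order], "o", ms=4, label=f"b={b:g} µM")
            if self.params is not None:
                a_line = np.geomspace(g.a.min(), g.a.max(), 100)
                ax.plot(a_line, pingpong_rate(self.params, a_line, b), "-", lw=1)
        ax.set_xscale("log")
        ax.set_xlabel(f"[{g.cosubstrate}] (µM)")
        ax.set_ylabel("rate (µM/s)")
        ax.legend(fontsize=7)
        return ax


# ----------------------------------------------------------------------
# model

_FrozenLike = Union[RateLawParams, Mapping[str, float], None]


def _frozen_dict(frozen: _FrozenLike) -> Dict[str, float]:
    if frozen is None:
        return {}
    if isinstance(frozen, RateLawParams):
        out = {"K_B": frozen.K_B}
        if frozen.K_I is not None:
            out["K_I"] = frozen.K_I
        return out
    return {k: float(v) for k, v in frozen.items() if v is not None}


class PingPongModel:
    """Ping-pong bi-substrate rate-law model for a :class:`RateGrid`.

    Parameters
    ----------
    grid : RateGrid
        Replicate initial-rate observations; replicates enter as independent
        observations (no pre-averaging).
    with_inhibition : bool
        Include the acceptor substrate-inhibition constant K_I.
    frozen : mapping or RateLawParams, optional
        Constants to hold fixed (K_B and optionally K_I); when given, only
        kcat and K_A are free, matching the constrained fits used for poor
        cosubstrates.
    """

    def __init__(
        self,
        grid: RateGrid,
        with_inhibition: bool = False,
        frozen: _FrozenLike = None,
    ) -> None:
        self.grid = grid
        self.with_inhibition = with_inhibition
        self.frozen = _frozen_dict(frozen)
        if self.frozen:
            if "K_B" not in self.frozen:
                raise ValueError(
                    "constrained fits require the frozen acceptor constant K_B"
                )
            self.free_names: Tuple[str, ...] = ("kcat", "K_A")
        elif with_inhibition:
            self.free_names = ("kcat", "K_A", "K_B", "K_I")
        else:
            self.free_names = ("kcat", "K_A", "K_B")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        enzyme_nM: float,
        cosubstrate: str = "BNAH",
        acceptor: str = "menadione",
        **kwargs,
    ) -> "PingPongModel":
        return cls(
            RateGrid.from_dataframe(df, enzyme_nM, cosubstrate, acceptor), **kwargs
        )

    # ------------------------------------------------------------------
    def _params_from_vector(self, x_nat: np.ndarray) -> RateLawParams:
        vals = dict(zip(self.free_names, x_nat))
        vals.update(self.frozen)
        return RateLawParams(
            kcat=vals["kcat"],
            K_A=vals["K_A"],
            K_B=vals["K_B"],
            K_I=vals.get("K_I"),
            E0=self.grid.enzyme_nM,
        )

    def predict(self, params: RateLawParams) -> np.ndarray:
        return pingpong_rate(params, self.grid.a, self.grid.b)

    def _residuals_log(self, theta: np.ndarray) -> np.ndarray:
        p = self._params_from_vector(10.0**theta)
        return self.predict(p) - self.grid.rate

    def _starts(self, n_starts: int) -> np.ndarray:
        g = self.grid
        rmax = max(float(np.max(g.rate)), 1e-12)
        kcat0 = rmax / g.enzyme_uM
        a_lo, a_hi = float(np.min(g.a)), float(np.max(g.a))
        b_lo, b_hi = float(np.min(g.b)), float(np.max(g.b))
        starts = []
        if self.frozen:
            for ka in np.geomspace(a_lo, 10 * a_hi, max(n_starts // 2, 4)):
                for kscale in (1.0, 3.0):
                    starts.append({"kcat": kscale * kcat0, "K_A": ka})
        elif self.with_inhibition:
            for ka in np.geomspace(a_lo, a_hi, 2):
                for kb in np.geomspace(b_lo, b_hi, 2):
                    for ki in np.geomspace(b_hi / 3.0, 10 * b_hi, 2):
                        starts.append(
                            {"kcat": 2 * kcat0, "K_A": ka, "K_B": kb, "K_I": ki}
                        )
        else:
            for ka in np.geomspace(a_lo, a_hi, 2):
                for kb in np.geomspace(b_lo, b_hi, 2):
                    for kscale in (1.0, 3.0):
                        starts.append(
                            {"kcat": kscale * kcat0, "K_A": ka, "K_B": kb}
                        )
        arr = np.array(
            [[math.log10(s[n]) for n in self.free_names] for s in starts]
        )
        return arr[: max(n_starts, 8)]

    def fit(self, n_starts: int = 8, cov_type: str = "hc3") -> KineticResults:
        """Multi-start least-squares fit; the lowest-RSS solution is returned.

        ``cov_type`` selects the parameter covariance estimator: ``"hc3"``
        (default) is the heteroscedasticity-consistent sandwich with HC3
        leverage correction, appropriate because assay noise is roughly
        proportional to the rate while the loss is unweighted;
        ``"homoscedastic"`` is the classical s²(JᵀJ)⁻¹.

        Non-convergence from every start yields a results object with
        ``converged=False`` and diagnostics, never an exception.
        """
        if not self.frozen:
            self.grid.require_bisubstrate()
        best = None
        for x0 in self._starts(n_starts):
            try:
                sol = optimize.least_squares(
                    self._residuals_log, x0, method="lm", max_nfev=2000
                )
            except Exception:
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            return KineticResults(
                self,
                None,
                self.free_names,
                np.full((len(self.free_names),) * 2, np.nan),
                math.inf,
                self.grid.n_obs,
                method=self._method_name(),
                converged=False,
                message="no optimizer start converged",
            )
        params = self._params_from_vector(10.0**best.x)
        rss = float(2 * best.cost)
        cov = self._covariance(best, rss, cov_type)
        flags = self._flags(params)
        return KineticResults(
            self,
            params,
            self.free_names,
            cov,
            rss,
            self.grid.n_obs,
            method=self._method_name(),
            converged=True,
            inhibition_detected="yes" if params.K_I is not None else ND,
            flags=flags,
        )

    def _method_name(self) -> str:
        if self.frozen:
            return "constrained"
        return "global_with_KI" if self.with_inhibition else "global"

    def _covariance(self, sol, rss: float, cov_type: str = "hc3") -> np.ndarray:
        p_nat = 10.0**sol.x
        # residual Jacobian wrt natural params, by chain rule from log10 space
        J = sol.jac / (p_nat * _LN10)[None, :]
        n = self.grid.n_obs
        k = len(self.free_names)
        df = n - k
        if df <= 0:
            return np.full((k, k), np.nan)
        jtj = J.T @ J
        try:
            bread = np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            bread = np.linalg.pinv(jtj)
        if cov_type == "homoscedastic":
            return bread * (rss / df)
        if cov_type != "hc3":
            raise ValueError(f"unknown cov_type {cov_type!r}")
        r = sol.fun
        h = np.clip(np.einsum("ij,jk,ik->i", J, bread, J), 0.0, 1.0 - 1e-8)
        meat = J.T @ (J * (r**2 / (1.0 - h) ** 2)[:, None])
        return bread @ meat @ bread

    def _flags(self, params: RateLawParams) -> Tuple[str, ...]:
        flags = []
        if params.K_A > float(np.max(self.grid.a)):
            flags.append("K_A_above_tested_range")
        if params.K_I is not None and params.K_I > 10 * float(np.max(self.grid.b)):
            flags.append("K_I_above_identifiable_range")
        return tuple(flags)


# ----------------------------------------------------------------------
# spec-level operation surface

def fit_global_pingpong(
    grid: RateGrid, with_inhibition: bool = False, n_starts: int = 8
) -> KineticResults:
    """Global unweighted least-squares fit of the ping-pong rate law."""
    return PingPongModel(grid, with_inhibition=with_inhibition).fit(n_starts)


def select_inhibition_model(
    grid: RateGrid, alpha: float = 0.05, n_starts: int = 8
) -> KineticResults:
    """Fit with and without K_I; keep K_I only when defensible.

    The inhibition term is retained when the extra-sum-of-squares F-test
    favours it at ``alpha`` AND the K_I estimate is identifiable (below 10x
    the largest tested acceptor concentration); otherwise the no-inhibition
    fit is returned with ``inhibition_detected = "ND"``.
    """
    r0 = fit_global_pingpong(grid, with_inhibition=False, n_starts=n_starts)
    r1 = fit_global_pingpong(grid, with_inhibition=True, n_starts=n_starts)
    if not r0.converged:
        return r0
    if not r1.converged:
        r0.inhibition_detected = ND
        return r0
    df1 = grid.n_obs - 4
    if df1 <= 0 or r1.rss <= 0:
        r0.inhibition_detected = ND
        return r0
    fstat = max((r0.rss - r1.rss), 0.0) / (r1.rss / df1)
    pval = float(stats.f.sf(fstat, 1, df1))
    b_max = float(np.max(grid.b))
    retain = pval < alpha and r1.params.K_I is not None and r1.params.K_I < 10 * b_max
    if retain:
        r1.inhibition_detected = "yes"
        r1.f_pvalue = pval
        return r1
    r0.inhibition_detected = ND
    r0.f_pvalue = pval
    return r0


def fit_cosubstrate_constrained(
    grid: RateGrid, frozen: _FrozenLike, n_starts: int = 8
) -> KineticResults:
    """Fit kcat and K_A with the acceptor constants frozen.

    ``frozen`` must supply K_B (and K_I if inhibition applies), typically the
    values determined with a good cosubstrate on the same enzyme.
    """
    fr = _frozen_dict(frozen)
    if "K_B" not in fr:
        raise ValueError("frozen constants must include K_B")
    return PingPongModel(grid, frozen=fr).fit(n_starts)


def fit_efficiency_only(grid: RateGrid, frozen: _FrozenLike) -> KineticResults:
    """Linear-regime slope fit for cosubstrates that cannot saturate the enzyme.

    In the sub-saturating regime the ping-pong law reduces to
    rate ≈ E0·(kcat/K_A)·a / (1 + b/K_I), so a single through-origin slope on
    x = a/(1 + b/K_I) yields kcat/K_A directly; kcat and K_A individually are
    reported as ND.  Refuses (raises :class:`SaturationError`) when the data
    clearly plateau, in which case the constrained fit applies.
    """
    fr = _frozen_dict(frozen)
    K_I = fr.get("K_I")

    # saturation guard: a constrained Michaelis fit that confidently places
    # K_A inside the tested range means the data are not in the linear regime
    if "K_B" in fr and np.any(grid.rate > 0):
        probe = fit_cosubstrate_constrained(grid, fr)
        if probe.converged and probe.params is not None:
            a_max = float(np.max(grid.a))
            hi = probe.conf_int()["K_A"][1]
            if probe.params.K_A < a_max and np.isfinite(hi) and hi < a_max:
                raise SaturationError(
                    "rate grid shows saturation in the cosubstrate; "
                    "use fit_cosubstrate_constrained instead"
                )

    x = grid.a / (1.0 + grid.b / K_I) if K_I is not None else grid.a.copy()
    y = grid.rate
    sxx = float(np.sum(x * x))
    slope = float(np.sum(x * y)) / sxx  # s^-1, through-origin OLS
    resid = y - slope * x
    rss = float(np.sum(resid**2))
    df = grid.n_obs - 1
    se_slope = math.sqrt(rss / df / sxx) if df > 0 else math.inf

    eff = slope / grid.enzyme_uM * 1e6  # M^-1 s^-1
    se_eff = se_slope / grid.enzyme_uM * 1e6
    tq = float(stats.t.ppf(0.975, df)) if df > 0 else math.inf
    est = EfficiencyEstimate(eff, se_eff, (eff - tq * se_eff, eff + tq * se_eff))
    flags: Tuple[str, ...] = ("unsaturated",)
    if np.all(y == 0):
        flags = ("unsaturated", "degenerate")
    # lightweight model shell: efficiency-only fits have no free rate-law params
    model = PingPongModel.__new__(PingPongModel)
    model.grid = grid
    model.with_inhibition = K_I is not None
    model.frozen = fr
    model.free_names = ()
    return KineticResults(
        model,
        None,
        (),
        np.zeros((0, 0)),
        rss,
        grid.n_obs,
        method="efficiency_only",
        converged=True,
        inhibition_detected="yes" if K_I is not None else ND,
        flags=flags,
        efficiency_override=est,
    )


def catalytic_efficiency(
    result: Union[KineticResults, RateLawParams]
) -> EfficiencyEstimate:
    """Catalytic efficiency kcat/K_A in M⁻¹·s⁻¹ with propagated 95% CI.

    Accepts a :class:`KineticResults` (CI from the fit covariance) or a bare
    :class:`RateLawParams` (point value only).
    """
    if isinstance(result, RateLawParams):
        v = efficiency_from_constants(result.kcat, result.K_A)
        return EfficiencyEstimate(v, math.nan, (math.nan, math.nan))
    return result.efficiency
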