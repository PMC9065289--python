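"""Ground-truth synthetic data for the two experimental designs.

Two assay families are emulated, with presets matching the published study
conditions so every pipeline stage is testable without raw instrument data:

1. Steady-state kinetics: triplicate initial-rate grids over BNAH 5-340 µM x
   menadione 2-100 µM (cuvette assays at sub-nM enzyme), or NAD(P)H
   40 µM-12 mM at menadione 20/40 µM with µM-level enzyme in a plate reader
   (91 reads, one per minute, 1 h 30 min).  Rates come from the ping-pong
   rate law plus proportional-and-additive Gaussian noise; progress curves
   integrate cosubstrate depletion at the model rate (the acceptor is
   treated as non-depleting over the initial-rate window) and convert to
   absorbance via Beer-Lambert.

2. SRB cytotoxicity plates: 96-well dose-response series for CB1954
   (two-fold, 7.8-1,000 µM) ± NRH, from a logistic inhibition curve with
   Gaussian absorbance noise (untreated wells at 1.0 AU scale, sd 0.04).

All generators are pure functions of (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ratelaws import DoseResponseParams, RateLawParams, logistic_response, pingpong_rate
from .kinetics import RateGrid
from .doseresponse import DosePlate
from .progress import ProgressCurve

__all__ = [
    "KineticScenario",
    "CytotoxScenario",
    "simulate_rate_grid",
    "simulate_progress_curves",
    "simulate_cytotox_plate",
    "PRESET_TRUTHS",
    "BNAH_LEVELS",
    "MENADIONE_LEVELS",
    "MENADIONE_DENSE",
    "NADH_LEVELS",
    "NADH_MENADIONE_LEVELS",
    "CB1954_LEVELS",
    "FIGURE_CONDITIONS",
    "human_bnah_scenario",
    "alligator_bnah_scenario",
    "duck_bnah_scenario",
    "nadh_scenario",
    "cytotox_scenario",
]

# ---------------------------------------------------------------------------
# published study conditions (machine-readable truth presets)

#: Steady-state kinetic constants per enzyme/cosubstrate pair.  BNAH assays
#: ran at 0.46/2.06/4.89 nM enzyme; NAD(P)H assays needed µM enzyme
#: (human 6-24, reptile 5-10, bird 10-20 µM; midpoints used here, in nM).
PRESET_TRUTHS: Dict[str, RateLawParams] = {
    "human_bnah": RateLawParams(kcat=1190.0, K_A=96.0, K_B=65.0, K_I=None, E0=0.46),
    "alligator_bnah": RateLawParams(kcat=173.0, K_A=35.0, K_B=36.0, K_I=24.0, E0=2.06),
    "duck_bnah": RateLawParams(kcat=128.0, K_A=6.8, K_B=3.5, K_I=11.0, E0=4.89),
    "human_nadh": RateLawParams(kcat=0.0792, K_A=26800.0, K_B=65.0, K_I=None, E0=15000.0),
    "alligator_nadh": RateLawParams(kcat=0.116, K_A=8000.0, K_B=36.0, K_I=24.0, E0=7500.0),
    "duck_nadh": RateLawParams(kcat=0.0206, K_A=1600.0, K_B=3.5, K_I=11.0, E0=15000.0),
}

#: Concentration designs (µM).  Log-spaced levels spanning the tested ranges.
BNAH_LEVELS: np.ndarray = np.geomspace(5.0, 340.0, 8)
MENADIONE_LEVELS: np.ndarray = np.geomspace(2.0, 100.0, 6)
MENADIONE_DENSE: np.ndarray = np.geomspace(2.0, 100.0, 10)
NADH_LEVELS: np.ndarray = np.geomspace(40.0, 12000.0, 8)
NADH_MENADIONE_LEVELS: Tuple[float, float] = (20.0, 40.0)

#: CB1954 two-fold dilution series, 7.8-1,000 µM.
CB1954_LEVELS: np.ndarray = 1000.0 / 2.0 ** np.arange(7, -1, -1)

#: Dose-response truths for the knockout experiment: parental cells have
#: IC50 ≈ 200 µM for CB1954, dropping 45-fold with exogenous NRH; the
#: knockout's IC50 is unchanged by NRH.
FIGURE_CONDITIONS: Dict[str, DoseResponseParams] = {
    "parental": DoseResponseParams(top=1.0, bottom=0.0, ic50=200.0, hill=1.0),
    "parental+NRH": DoseResponseParams(top=1.0, bottom=0.0, ic50=200.0 / 45.0, hill=1.0),
    "knockout": DoseResponseParams(top=1.0, bottom=0.0, ic50=200.0, hill=1.0),
    "knockout+NRH": DoseResponseParams(top=1.0, bottom=0.0, ic50=200.0, hill=1.0),
}


# ---------------------------------------------------------------------------
# scenarios

@dataclass(frozen=True)
class KineticScenario:
    """One simulated kinetic experiment (rates or progress curves)."""

    truth: RateLawParams
    a_levels: Sequence[float]
    b_levels: Sequence[float]
    replicates: int = 3
    prop_sd: float = 0.05        # proportional noise, fraction of the true rate
    add_sd: float = 0.0          # additive noise, µM/s
    seed: int = 0
    cosubstrate: str = "BNAH"
    acceptor: str = "menadione"
    # progress-curve emission (plate-reader defaults: 91 reads over 1 h 30 min)
    duration_s: float = 5400.0
    read_interval_s: float = 60.0
    epsilon: float = 6220.0      # M^-1 cm^-1
    pathlength: float = 1.0      # cm
    read_noise_sd: float = 0.0   # AU

    def __post_init__(self) -> None:
        if self.prop_sd < 0 or self.add_sd < 0 or self.read_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be ≥ 1")
        if np.any(np.asarray(self.a_levels) <= 0) or np.any(np.asarray(self.b_levels) <= 0):
            raise ValueError("substrate levels must be positive")


@dataclass(frozen=True)
class CytotoxScenario:
    """One simulated SRB cytotoxicity experiment over several conditions."""

    truth: Dict[str, DoseResponseParams]
    drug_levels: Sequence[float] = tuple(CB1954_LEVELS)
    replicates: int = 3
    untreated_wells: int = 6
    scale: float = 1.0           # mean untreated absorbance, AU
    noise_sd: float = 0.04       # absorbance noise, AU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be ≥ 1")
        if np.any(np.asarray(self.drug_levels) <= 0):
            raise ValueError("drug levels must be positive")


# convenience constructors for the study presets -----------------------------

def human_bnah_scenario(seed: int = 0, **kw) -> KineticScenario:
    return KineticScenario(
        PRESET_TRUTHS["human_bnah"], BNAH_LEVELS, MENADIONE_LEVELS, seed=seed, **kw
    )


def alligator_bnah_scenario(seed: int = 0, **kw) -> KineticScenario:
    return KineticScenario(
        PRESET_TRUTHS["alligator_bnah"], BNAH_LEVELS, MENADIONE_DENSE, seed=seed, **kw
    )


def duck_bnah_scenario(seed: int = 0, dense_b: bool = True, **kw) -> KineticScenario:
    b = MENADIONE_DENSE if dense_b else MENADIONE_LEVELS
    return KineticScenario(
        PRESET_TRUTHS["duck_bnah"], BNAH_LEVELS, b, seed=seed, **kw
    )


def nadh_scenario(species: str = "human", seed: int = 0, **kw) -> KineticScenario:
    truth = PRESET_TRUTHS[f"{species}_nadh"]
    return KineticScenario(
        truth, NADH_LEVELS, NADH_MENADIONE_LEVELS, seed=seed,
        cosubstrate="NADH", **kw
    )


def cytotox_scenario(seed: int = 0, **kw) -> CytotoxScenario:
    return CytotoxScenario(dict(FIGURE_CONDITIONS), seed=seed, **kw)


# ---------------------------------------------------------------------------
# generators

def _rng(scenario_seed: int, seed: Optional[int]) -> np.random.Generator:
    return np.random.default_rng(scenario_seed if seed is None else seed)


def simulate_rate_grid(scenario: KineticScenario, seed: Optional[int] = None) -> RateGrid:
    """Draw a replicate initial-rate grid from the scenario's truth.

    Each observed rate is truth × (1 + N(0, prop_sd)) + N(0, add_sd),
    truncated at zero.  Deterministic given the seed.
    """
    rng = _rng(scenario.seed, seed)
    a_levels = np.asarray(scenario.a_levels, dtype=float)
    b_levels = np.asarray(scenario.b_levels, dtype=float)
    aa, bb = np.meshgrid(a_levels, b_levels, indexing="ij")
    a = np.repeat(aa.ravel(), scenario.replicates)
    b = np.repeat(bb.ravel(), scenario.replicates)
    rep = np.tile(np.arange(scenario.replicates), aa.size)
    true_rate = pingpong_rate(scenario.truth, a, b)
    noisy = np.array(true_rate, dtype=float)
    if scenario.prop_sd > 0:
        noisy = noisy * (1.0 + rng.normal(0.0, scenario.prop_sd, a.size))
    if scenario.add_sd > 0:
        noisy = noisy + rng.normal(0.0, scenario.add_sd, a.size)
    noisy = np.maximum(noisy, 0.0)
    return RateGrid(
        a=a, b=b, rate=noisy, replicate=rep,
        enzyme_nM=scenario.truth.E0,
        cosubstrate=scenario.cosubstrate, acceptor=scenario.acceptor,
    )


def _integrate_depletion(
    truth: RateLawParams, a0: float, b: float, times: np.ndarray, n_sub: int
) -> np.ndarray:
    """RK4 integration of da/dt = -v(a, b) with b held constant."""
    a = np.empty_like(times)
    a[0] = a0
    cur = a0

    def f(x: float) -> float:
        return -pingpong_rate(truth, max(x, 0.0), b)

    for i in range(1, times.size):
        dt = (times[i] - times[i - 1]) / n_sub
        for _ in range(n_sub):
            k1 = f(cur)
            k2 = f(cur + 0.5 * dt * k1)
            k3 = f(cur + 0.5 * dt * k2)
            k4 = f(cur + dt * k3)
            cur = max(cur + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
        a[i] = cur
    return a


def simulate_progress_curves(
    scenario: KineticScenario, seed: Optional[int] = None, n_sub: int = 8
) -> Tuple[List[ProgressCurve], pd.DataFrame]:
    """Integrate cosubstrate depletion and emit absorbance traces.

    The acceptor is held constant (regeneration assumed over the short
    initial-rate window).  The integration step is refined automatically
    until a half-step control changes the final concentration by < 1%.
    Returns the curves plus a table recording each well's true initial rate.
    """
    rng = _rng(scenario.seed, seed)
    times = np.arange(0.0, scenario.duration_s + 0.5 * scenario.read_interval_s,
                      scenario.read_interval_s)
    curves: List[ProgressCurve] = []
    records = []
    for a0 in np.asarray(scenario.a_levels, dtype=float):
        for b in np.asarray(scenario.b_levels, dtype=float):
            steps = n_sub
            conc = _integrate_depletion(scenario.truth, a0, b, times, steps)
            while True:
                control = _integrate_depletion(scenario.truth, a0, b, times, steps * 2)
                denom = control[-1] if control[-1] > 0 else 1.0
                if abs(conc[-1] - control[-1]) / denom <= 0.01:
                    conc = control
                    break
                conc, steps = control, steps * 2
            absorbance = conc * 1e-6 * scenario.epsilon * scenario.pathlength
            v0 = pingpong_rate(scenario.truth, a0, b)
            for rep in range(scenario.replicates):
                noisy = absorbance.copy()
                if scenario.read_noise_sd > 0:
                    noisy = noisy + rng.normal(0.0, scenario.read_noise_sd, times.size)
                well = f"a{a0:g}_b{b:g}_r{rep}"
                curves.append(
                    ProgressCurve(
                        times=times.copy(), absorbance=noisy,
                        epsilon=scenario.epsilon, pathlength=scenario.pathlength,
                        wavelength=340.0, well_id=well,
                    )
                )
                records.append(
                    {"well": well, "cosubstrate_uM": a0, "acceptor_uM": b,
                     "replicate": rep, "true_initial_rate_uM_s": v0}
                )
    return curves, pd.DataFrame.from_records(records)


def simulate_cytotox_plate(
    scenario: CytotoxScenario, seed: Optional[int] = None
) -> DosePlate:
    """Draw a tidy SRB plate from the scenario's per-condition logistic truths.

    absorbance = scale × viability + N(0, sd), floored at 0; untreated wells
    sit at drug concentration 0.  Deterministic given the seed.
    """
    rng = _rng(scenario.seed, seed)
    rows = []
    for cond, truth in scenario.truth.items():
        concs = np.concatenate(
            [np.zeros(scenario.untreated_wells),
             np.repeat(np.asarray(scenario.drug_levels, float), scenario.replicates)]
        )
        reps = np.concatenate(
            [np.arange(scenario.untreated_wells),
             np.tile(np.arange(scenario.replicates), len(scenario.drug_levels))]
        )
        viability = logistic_response(truth, concs)
        absorbance = scenario.scale * viability
        if scenario.noise_sd > 0:
            absorbance = absorbance + rng.normal(0.0, scenario.noise_sd, concs.size)
        absorbance = np.maximum(absorbance, 0.0)
        for c, r, ab in zip(concs, reps, absorbance):
            rows.append(
                {"condition": cond, "drug_uM": float(c), "modifier_uM": 0.0,
                 "replicate": int(r), "absorbance": float(ab)}
            )
    return DosePlate(pd.DataFrame.from_records(rows))
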