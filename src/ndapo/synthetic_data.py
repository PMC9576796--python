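"""Synthetic two-stage batch experiment generator.

Simulates a sealed triplicate batch test in which propane oxidation is
electron-coupled to stepwise nitrate reduction:

* **Stage 1** (nitrate present): NO3- -> NO2- at a zero-order rate, with part
  of the accumulating nitrite reduced on to N2 and (optionally) a negligible
  DNRA flux to NH4+.
* **Stage 2** (after nitrate depletion): the accumulated nitrite is consumed
  to N2 and NH4+; the flux split is chosen at the stage switch so that the
  end-of-run product partition equals the configured phi_N2 exactly.

Every step closes the electron ledger: electrons demanded by the N fluxes
(2 e- per N for NO3->NO2, 3 for NO2->N2, 6 for NO2->NH4) are supplied by
propane oxidation at 20 e- per propane.  CO2 production is 3 C per propane
oxidised, minus an optional assimilation fraction f_assim diverted to a
biomass-carbon ledger (so the simulated 13CO2:13C3H8 label ratio is
3(1 - f_assim)).

Isotope tracers follow the pools with no fractionation: 13C at a constant
propane atom fraction p13; 15N flows carry the instantaneous atom fraction of
their source pool, and N2 isotopologues are formed by binomial pairing from
the instantaneous nitrite fraction (single-atom bookkeeping available as a
switch).

The noiseless ("truth") trajectory is exactly mass- and electron-closed;
observations add independent Gaussian noise per analyte per timepoint
(sd = noise_sigma x initial nitrate-N), clipped at zero.  Everything is
deterministic given (params, seed).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
import numpy as np
import pandas as pd

from .balances import (
    ISOTOPE_COLUMNS,
    MAIN_COLUMNS,
    TIME_COLUMN,
    BatchTimeSeries,
)

__all__ = [
    "SimulationError",
    "SimulationParams",
    "SimulatedBatch",
    "simulate_batch",
    "generate_replicates",
]

#: Electron equivalents per mole for the simulated transformations.
_E_NO3_TO_NO2 = 2.0
_E_NO2_TO_N2 = 3.0
_E_NO2_TO_NH4 = 6.0
_E_PER_PROPANE = 20.0
_C_PER_PROPANE = 3.0


class SimulationError(ValueError):
    """Invalid simulation parameters or diverging integration."""


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the two-stage batch simulation.

    Defaults emulate the study conditions: a 650 mL vessel with 500 mL of
    culture holding ~730 umol nitrate-N (20 mg N/L), excess propane, nitrate
    depleted over ~2 days followed by ~2.5 days of nitrite consumption, a
    57.3% / 42.7% N2/NH4 end-product split, ~8 atom% 13C propane and
    ~1 atom% 15N nitrate, and triplicate vessels.
    """

    no3_umolN: float = 730.0          # initial nitrate, umol N
    propane_umol: float = 2000.0      # initial propane, umol (excess)
    r_no3: float = 15.0               # Stage-1 NO3->NO2 rate, umol N/h
    r_n2_s1: float = 6.0              # Stage-1 NO2->N2 rate, umol N/h
    r_n2_s2: float = 4.0              # Stage-2 NO2->N2 rate, umol N/h
    r_dnra: float = 4.0               # Stage-2 NO2->NH4 rate, umol N/h
    r_dnra_s1: float = 0.0            # Stage-1 DNRA rate (kept negligible)
    phi_n2: float = 0.573             # target end-run N2 share of products
    p13: float = 0.08                 # propane 13C atom fraction
    p15: float = 0.01                 # nitrate 15N atom fraction
    f_assim: float = 0.0              # oxidised C diverted to biomass
    noise_sigma: float = 0.0          # noise sd as fraction of initial NO3-N
    dt: float = 0.25                  # timestep, h
    horizon: float = 120.0            # run length, h
    n_replicates: int = 3
    seed: int = 0
    negligible_nh4_fraction: float = 0.02  # Stage-1 NH4 bound, fraction of NO3_0
    pairing: str = "binomial"         # N2 isotopologues: "binomial" | "single-atom"

    def __post_init__(self) -> None:
        rates = (self.r_no3, self.r_n2_s1, self.r_n2_s2, self.r_dnra, self.r_dnra_s1)
        if any(r < 0 for r in rates):
            raise SimulationError("rates must be non-negative")
        if self.r_no3 <= 0:
            raise SimulationError("r_no3 must be positive for a consuming experiment")
        if not 0.0 < self.phi_n2 < 1.0:
            raise SimulationError("phi_n2 must lie in (0, 1)")
        for name in ("p13", "p15"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.f_assim < 1.0:
            raise SimulationError("f_assim must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise SimulationError("noise_sigma must be non-negative")
        if self.dt <= 0 or self.horizon <= self.dt:
            raise SimulationError("need 0 < dt < horizon")
        if self.no3_umolN <= 0 or self.propane_umol <= 0:
            raise SimulationError("initial pools must be positive")
        if self.n_replicates < 1:
            raise SimulationError("need at least one replicate")
        if self.pairing not in ("binomial", "single-atom"):
            raise SimulationError(f"unknown pairing mode {self.pairing!r}")


@dataclass
class SimulatedBatch:
    """One simulated vessel: noisy observations plus the exact truth.

    ``truth`` satisfies all conservation laws to floating-point accuracy;
    ``observed`` is truth plus clipped Gaussian noise.  ``assimilated_c_umol``
    is the biomass-carbon ledger needed to close the carbon balance when
    f_assim > 0.
    """

    observed: BatchTimeSeries
    truth: BatchTimeSeries
    params: SimulationParams
    seed: int
    phi_true: float
    depletion_time: float | None
    assimilated_c_umol: float
    completed: bool  # all nitrite consumed before the horizon


def _simulate_truth(params: SimulationParams) -> tuple[pd.DataFrame, dict]:
    p = params
    n_steps = int(round(p.horizon / p.dt))
    times = np.arange(n_steps + 1) * p.dt

    no3, no2, nh4, n2n = p.no3_umolN, 0.0, 0.0, 0.0
    propane, co2, assim = p.propane_umol, 0.0, 0.0
    l_no3 = p.p15 * no3
    l_no2 = l_nh4 = l_n2 = 0.0
    n2_mol = n29 = n30 = 0.0  # N2 in molecule units
    l_prop = p.p13 * propane
    l_co2 = 0.0

    f2: float | None = None  # Stage-2 flux split to N2, fixed at the switch
    depletion_time: float | None = None

    rows = []

    def record(t: float) -> None:
        f29 = n29 / n2_mol if n2_mol > 0 else 0.0
        f30 = n30 / n2_mol if n2_mol > 0 else 0.0
        rows.append(
            (t, no3, no2, nh4, n2n, propane, co2,
             l_prop, l_co2, l_no3, l_no2, l_nh4, f29, f30)
        )

    record(0.0)
    for k in range(1, n_steps + 1):
        stage1 = no3 > 1e-12
        if stage1:
            f_no3 = min(p.r_no3 * p.dt, no3)
            r_out = p.r_n2_s1 + p.r_dnra_s1
            out = min(r_out * p.dt, no2)
            w_n2 = p.r_n2_s1 / r_out if r_out > 0 else 0.0
            n2_flux, dnra_flux = out * w_n2, out * (1.0 - w_n2)
        else:
            if depletion_time is None:
                depletion_time = float(times[k - 1])
            if f2 is None:
                total_products = n2n + nh4 + no2
                target_n2 = p.phi_n2 * total_products
                if no2 <= 0:
                    f2 = 0.0
                else:
                    f2 = (target_n2 - n2n) / no2
                if not -1e-9 <= f2 <= 1.0 + 1e-9:
                    raise SimulationError(
                        f"phi_n2={p.phi_n2} unreachable: Stage-1 already fixed "
                        f"an N2 share outside the target (split {f2:.3f})"
                    )
                f2 = min(max(f2, 0.0), 1.0)
            f_no3 = 0.0
            out = min((p.r_n2_s2 + p.r_dnra) * p.dt, no2)
            n2_flux, dnra_flux = out * f2, out * (1.0 - f2)

        e_step = (
            _E_NO3_TO_NO2 * f_no3
            + _E_NO2_TO_N2 * n2_flux
            + _E_NO2_TO_NH4 * dnra_flux
        )
        d_prop = e_step / _E_PER_PROPANE
        if d_prop > propane:
            raise SimulationError(
                "propane exhausted; raise propane_umol or lower N rates"
            )
        d_co2 = _C_PER_PROPANE * d_prop * (1.0 - p.f_assim)

        # isotope flows at the pre-step pool fractions (no fractionation)
        p_no3 = l_no3 / no3 if no3 > 0 else 0.0
        p_no2 = l_no2 / no2 if no2 > 0 else 0.0
        l_no3 -= f_no3 * p_no3
        l_no2 += f_no3 * p_no3 - (n2_flux + dnra_flux) * p_no2
        l_nh4 += dnra_flux * p_no2
        l_n2 += n2_flux * p_no2
        d_mol = n2_flux / 2.0
        if p.pairing == "binomial":
            n29 += d_mol * 2.0 * p_no2 * (1.0 - p_no2)
            n30 += d_mol * p_no2 * p_no2
        else:  # single-atom bookkeeping: every heavy atom makes a 29N2
            n29 += d_mol * 2.0 * p_no2
        n2_mol += d_mol
        l_prop -= d_prop * p.p13
        l_co2 += p.p13 * d_co2

        no3 -= f_no3
        no2 += f_no3 - n2_flux - dnra_flux
        nh4 += dnra_flux
        n2n += n2_flux
        propane -= d_prop
        co2 += d_co2
        assim += _C_PER_PROPANE * d_prop * p.f_assim

        if not all(map(math.isfinite, (no3, no2, nh4, n2n, propane, co2))):
            raise SimulationError(
                "non-finite pool encountered; use a smaller timestep"
            )
        record(float(times[k]))

    columns = [TIME_COLUMN, *MAIN_COLUMNS, *ISOTOPE_COLUMNS]
    frame = pd.DataFrame(rows, columns=columns)
    info = {
        "depletion_time": depletion_time,
        "assimilated_c_umol": assim,
        "completed": no2 < 1e-9,
        "label_n2_umolN": l_n2,
    }
    return frame, info


#: Columns receiving observation noise (measured analytes).
_NOISY_COLUMNS = MAIN_COLUMNS


def simulate_batch(params: SimulationParams, seed: int | None = None) -> SimulatedBatch:
    """Simulate one vessel; deterministic given (params, seed).

    The truth trajectory depends on ``params`` only; ``seed`` controls the
    observation noise.
    """
    if seed is None:
        seed = params.seed
    truth_frame, info = _simulate_truth(params)
    observed_frame = truth_frame.copy()
    if params.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        sd = params.noise_sigma * params.no3_umolN
        for col in _NOISY_COLUMNS:
            noise = rng.normal(0.0, sd, size=len(observed_frame))
            observed_frame[col] = np.clip(observed_frame[col] + noise, 0.0, None)
    return SimulatedBatch(
        observed=BatchTimeSeries(observed_frame, replicate=seed),
        truth=BatchTimeSeries(truth_frame.copy(), replicate=seed),
        params=params,
        seed=seed,
        phi_true=params.phi_n2,
        depletion_time=info["depletion_time"],
        assimilated_c_umol=info["assimilated_c_umol"],
        completed=info["completed"],
    )


def generate_replicates(
    params: SimulationParams,
) -> tuple[list[SimulatedBatch], dict]:
    """Simulate ``params.n_replicates`` vessels with derived per-replicate seeds.

    Replicate i uses seed ``params.seed + i``; the returned manifest records
    the parameters and seeds needed for exact reproduction.  Replicates share
    the same truth (noise differs).
    """
    seeds = [params.seed + i for i in range(params.n_replicates)]
    batches = [simulate_batch(params, seed) for seed in seeds]
    manifest = {
        "params": asdict(params),
        "master_seed": params.seed,
        "replicate_seeds": seeds,
        "phi_true": params.phi_n2,
        "depletion_time_h": batches[0].depletion_time,
        "completed": batches[0].completed,
    }
    return batches, manifest
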