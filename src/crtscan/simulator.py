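"""Stochastic behavioral model of fish association with an array of receivers.

A population of ``n_fish`` independent individuals moves between an
"unassociated" state and ``p`` receivers (e.g. instrumented fish
aggregating devices) in discrete time.  At each step a fish present at
a receiver leaves with probability ``theta``; an unassociated fish
joins some receiver with total probability ``p * mu_step``, the
destination drawn uniformly among the ``p`` receivers (so each
receiver gains unassociated fish at per-receiver rate ``mu_step``, the
discrete-time counterpart of the mean-field flux ``mu * X_u`` into each
receiver).  While present at a receiver, a fish is within detection
range and is logged at each step with probability ``eta`` (``eta = 1``
means noise-free detection; smaller values model sonic collisions and
ambient noise, i.i.d. per step).

Three scenarios of the joining probability are implemented:

1. *Memoryless with noise* — ``mu_step = mu`` constant.  Residence
   bouts are geometric with mean ``1/theta``; absence spells geometric
   with mean ``1/(p*mu)``.
2. *Time-dependent sigmoidal* — ``mu_step = mu(tau)`` rises
   sigmoidally with the time ``tau`` spent unassociated in the current
   spell: ``mu(tau) = mu_inf / (1 + K * exp(-gamma * tau))``, switching
   from small to large values around ``tau* = ln(K)/gamma``.  No
   detection noise.
3. *Sigmoidal with noise* — scenario 2 dynamics plus Bernoulli
   detection noise ``eta``.

The simulator doubles as the synthetic-data generator for validating
the MBP-scanning method: its output is an ordinary detection table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io_detections import COLUMNS, DetectionTable

__all__ = [
    "SimulationConfig",
    "joining_probability",
    "simulate",
    "scenario_presets",
    "scenario_config",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation run.

    Probabilities are per time step.  ``mu`` is required for scenario
    1; ``mu_inf``, ``big_k`` and ``gamma`` for scenarios 2 and 3.
    ``burn_in`` steps are simulated but not recorded (the recorded
    clock starts at 0 afterwards); the default is no burn-in, with all
    fish starting unassociated at ``tau = 0``.
    """

    scenario: int
    theta: float
    mu: float | None = None
    mu_inf: float | None = None
    big_k: float | None = None
    gamma: float | None = None
    eta: float = 1.0
    n_receivers: int = 2
    n_fish: int = 1000
    n_steps: int = 100_000
    seed: int | None = None
    burn_in: int = 0

    def __post_init__(self):
        if self.scenario not in (1, 2, 3):
            raise ValueError("scenario must be 1, 2 or 3")
        if self.n_receivers < 1 or self.n_fish < 1 or self.n_steps < 1:
            raise ValueError("n_receivers, n_fish and n_steps must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        for name in ("theta", "eta"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.scenario == 1:
            if self.mu is None or not 0 < self.mu <= 1:
                raise ValueError("scenario 1 requires mu in (0, 1]")
        else:
            if self.mu_inf is None or not 0 < self.mu_inf <= 1:
                raise ValueError("scenarios 2-3 require mu_inf in (0, 1]")
            if self.big_k is None or self.big_k <= 0:
                raise ValueError("scenarios 2-3 require big_k > 0")
            if self.gamma is None or self.gamma <= 0:
                raise ValueError("scenarios 2-3 require gamma > 0")


def joining_probability(tau, mu_inf: float, big_k: float, gamma: float):
    """Sigmoidal per-step joining probability ``mu(tau)``.

    ``mu(tau) = mu_inf / (1 + K * exp(-gamma * tau))`` where ``tau`` is
    the time spent unassociated in the current spell.  Rises from
    ``mu_inf / (1 + K)`` at ``tau = 0`` to ``mu_inf`` asymptotically,
    crossing ``mu_inf / 2`` at ``tau* = ln(K) / gamma``.
    """
    tau = np.asarray(tau, dtype=float)
    return mu_inf / (1.0 + big_k * np.exp(-gamma * tau))


def simulate(
    config: SimulationConfig, return_occupancy: bool = False
) -> DetectionTable | tuple[DetectionTable, np.ndarray]:
    """Run the Monte Carlo model and return the simulated detection log.

    Fish and receiver identifiers are 1-based integers; detection times
    are step indices (``time_unit="step"``).  The run is reproducible:
    the same configuration (including seed) yields a bit-identical
    table.  With ``return_occupancy`` the per-step count of associated
    fish is returned alongside (useful for checking conservation and
    stationarity).
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_receivers
    n_fish = config.n_fish
    total = config.burn_in + config.n_steps

    location = np.full(n_fish, -1, dtype=np.int64)  # -1 = unassociated
    tau = np.zeros(n_fish, dtype=np.int64)

    det_fish: list[np.ndarray] = []
    det_recv: list[np.ndarray] = []
    counts = np.zeros(config.n_steps, dtype=np.int64)
    occupancy = np.zeros(config.n_steps, dtype=np.int64) if return_occupancy else None

    eta = config.eta
    for step in range(total):
        u = rng.random(n_fish)
        present = location >= 0
        leave = present & (u < config.theta)
        if config.scenario == 1:
            p_join = p * config.mu
        else:
            p_join = np.minimum(
                1.0, p * joining_probability(tau, config.mu_inf, config.big_k, config.gamma)
            )
        join = ~present & (u < p_join)
        n_join = int(join.sum())
        location[leave] = -1
        if n_join:
            location[join] = rng.integers(0, p, n_join)
        tau[join] = 0
        away = location < 0
        tau[away] += 1
        tau[leave] = 1  # the leaving step is the first step spent outside

        present = ~away
        if eta < 1.0:
            detected = present & (rng.random(n_fish) < eta)
        else:
            detected = present
        if step >= config.burn_in:
            rec = step - config.burn_in
            idx = np.flatnonzero(detected)
            counts[rec] = idx.size
            if idx.size:
                det_fish.append(idx.astype(np.int32))
                det_recv.append(location[idx].astype(np.int32))
            if return_occupancy:
                occupancy[rec] = int(present.sum())

    if det_fish:
        fish = np.concatenate(det_fish) + 1
        recv = np.concatenate(det_recv) + 1
        times = np.repeat(np.arange(config.n_steps, dtype=np.int64), counts)
    else:
        fish = np.array([], dtype=np.int64)
        recv = np.array([], dtype=np.int64)
        times = np.array([], dtype=np.int64)

    order = np.lexsort((times, fish))  # canonical (animal, time) order up front
    frame = pd.DataFrame(
        {
            "receiver_id": recv[order],
            "animal_id": fish[order],
            "time": times[order],
        },
        columns=list(COLUMNS),
    )
    table = DetectionTable(frame.reset_index(drop=True), time_unit="step")
    if return_occupancy:
        return table, occupancy
    return table


# Table of standard parameterizations: two well-separated behavioral
# timescales (scenario 1), a sigmoidal rejoining sweep (scenario 2) and
# the mixed case (scenario 3), each at 100,000 steps, 2 receivers and
# 1000 fish.
_SCENARIO1_ETAS = (1.0, 0.1, 0.01, 0.005)
_SCENARIO2_GAMMAS = (0.01, 0.02, 0.04, 0.08)


def scenario_presets() -> Mapping[int, tuple[SimulationConfig, ...]]:
    """The standard validation parameterizations for the three scenarios.

    Scenario 1: ``theta=0.0002, mu=0.0001`` with noise levels
    ``eta = 1, 0.1, 0.01, 0.005``.  Scenario 2: ``theta=0.02,
    mu_inf=0.01, K=1000`` with ``gamma = 0.01, 0.02, 0.04, 0.08``.
    Scenario 3: ``theta=0.0002, mu_inf=0.01, K=1000, gamma=0.01,
    eta=0.1``.  All with 100,000 steps, 2 receivers, 1000 fish.
    """
    s1 = tuple(
        SimulationConfig(scenario=1, theta=0.0002, mu=0.0001, eta=eta)
        for eta in _SCENARIO1_ETAS
    )
    s2 = tuple(
        SimulationConfig(
            scenario=2, theta=0.02, mu_inf=0.01, big_k=1000, gamma=gamma, eta=1.0
        )
        for gamma in _SCENARIO2_GAMMAS
    )
    s3 = (
        SimulationConfig(
            scenario=3, theta=0.0002, mu_inf=0.01, big_k=1000, gamma=0.01, eta=0.1
        ),
    )
    return {1: s1, 2: s2, 3: s3}


def scenario_config(
    scenario: int,
    *,
    eta: float | None = None,
    gamma: float | None = None,
    seed: int | None = None,
    **overrides,
) -> SimulationConfig:
    """One preset configuration, selected by noise level / sigmoid rate.

    Convenience front end to :func:`scenario_presets`: starts from the
    preset of ``scenario`` matching ``eta`` (scenario 1) or ``gamma``
    (scenario 2) — or the scenario's first preset when no preset
    matches — then applies ``seed``, ``eta``/``gamma`` and any field
    overrides.
    """
    presets = scenario_presets().get(scenario)
    if presets is None:
        raise ValueError(f"unknown scenario {scenario!r}")
    matches = list(presets)
    if scenario == 1 and eta is not None:
        matches = [c for c in presets if c.eta == eta] or matches
    elif scenario == 2 and gamma is not None:
        matches = [c for c in presets if c.gamma == gamma] or matches
    config = matches[0]
    if eta is not None:
        overrides["eta"] = eta
    if gamma is not None:
        overrides["gamma"] = gamma
    return replace(config, seed=seed, **overrides)
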