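"""Shared fixtures: the two canonical forcing presets, simulated once per
session, plus live runs of the independent fixed-step oracle."""

from __future__ import annotations

import math
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from oracle import rk4_impact_oracle  # noqa: E402

from woodknock import extract_impact_train, preset_config, simulate  # noqa: E402

# Impact tables computed by tests/oracle.py (fixed-step RK4, h = 1e-3,
# bisection to 1e-10) on the two presets; frozen as regression anchors so a
# drift in either the solver or the oracle itself is caught.
FROZEN_PERIODIC_IMPACTS = [
    (7.39535314, 0.49994010),
    (8.23898449, 0.38184174),
    (9.05853040, 0.21227402),
    (15.40186496, 2.14283256),
    (21.56061073, 2.95849533),
    (27.76516274, 3.25054437),
    (34.00566632, 3.33001406),
    (40.26905673, 3.33740173),
    (46.54461560, 3.32818636),
    (52.82555475, 3.31965840),
    (59.10841510, 3.31478461),
    (66.14031583, 1.96792557),
    (72.34189281, 0.81107169),
    (79.12005372, 0.28550625),
]
FROZEN_IMPULSIVE_IMPACTS = [
    (62.42925206, 0.44202786),
    (63.19346120, 0.33918484),
    (64.08096932, 0.15500393),
]


@pytest.fixture(scope="session")
def periodic_sim():
    traj = simulate(*preset_config("fig2-periodic"))
    return traj, extract_impact_train(traj)


@pytest.fixture(scope="session")
def impulsive_sim():
    traj = simulate(*preset_config("fig2-impulsive"))
    return traj, extract_impact_train(traj)


def _periodic_forcing(t: float) -> float:
    return math.sin(t) if 2 * math.pi < t < 20 * math.pi else 0.0


def _impulsive_forcing(t: float) -> float:
    return math.exp(-((t - 20 * math.pi) ** 2))


@pytest.fixture(scope="session")
def periodic_oracle():
    return rk4_impact_oracle(_periodic_forcing, 30 * math.pi)


@pytest.fixture(scope="session")
def impulsive_oracle():
    return rk4_impact_oracle(_impulsive_forcing, 30 * math.pi)
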