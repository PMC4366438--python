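"""Writers and readers: trajectory CSV, analysis JSON, flat-text configs.

Trajectories are written as plain CSV (``time_weeks,S,T,R,event_flag``) so
runs are diff-able in review; pulse instants appear twice, the pre-pulse row
with ``event_flag`` 0 and the post-pulse row with ``event_flag`` 1.  All
floats are printed with 17 significant digits so a round-trip read
reproduces the binary values exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .models import CompartmentState, RepentanceForcing, STRSParams
from .scenarios import Scenario
from .simulate import PulseSchedule, Trajectory

__all__ = [
    "trajectory_to_frame",
    "write_trajectory",
    "read_trajectory",
    "pulse_events_to_records",
    "write_pulse_events",
    "equilibrium_report_to_dict",
    "write_json",
    "write_bifurcation_curve",
    "scenario_to_config",
    "scenario_from_config",
    "write_config",
    "read_config",
]

_FMT = "%.17g"


def _f(value: float) -> str:
    return _FMT % value


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """Trajectory as a DataFrame, with pulse instants duplicated.

    The grid point at a pulse instant carries the pre-pulse state; a second
    row holding the post-pulse state with ``event_flag`` 1 is inserted
    directly after it.
    """
    events_by_time = {ev.time: ev for ev in traj.pulse_events}
    rows: list[tuple[float, float, float, float, int]] = []
    for i, t in enumerate(traj.times):
        rows.append((t, traj.S[i], traj.T[i], traj.R[i], 0))
        ev = events_by_time.get(t)
        if ev is not None:
            rows.append((t, ev.after.S, ev.after.T, ev.after.R, 1))
    return pd.DataFrame(rows, columns=["time_weeks", "S", "T", "R", "event_flag"])


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write the trajectory CSV; floats at 17 significant digits."""
    frame = trajectory_to_frame(traj)
    path = Path(path)
    frame.to_csv(path, index=False, float_format=_FMT)
    return path


def read_trajectory(path: str | Path) -> pd.DataFrame:
    """Read a trajectory CSV back into a DataFrame (bit-exact floats)."""
    return pd.read_csv(path, float_precision="round_trip")


def pulse_events_to_records(traj: Trajectory) -> list[dict[str, Any]]:
    return [
        {
            "time_weeks": ev.time,
            "before": asdict(ev.before),
            "after": asdict(ev.after),
        }
        for ev in traj.pulse_events
    ]


def write_pulse_events(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(pulse_events_to_records(traj), indent=2) + "\n")
    return path


def equilibrium_report_to_dict(report) -> dict[str, Any]:
    """JSON-safe dict of an :class:`~strs.analysis.EquilibriumReport`."""
    idx = report.indices
    return {
        "label": report.label,
        "state": asdict(report.state),
        "eigenvalues": [[ev.real, ev.imag] for ev in report.eigenvalues],
        "stable": report.stable,
        "classification": report.classification,
        "basic_sabbath_number": idx.basic_sabbath_number,
        "cohesion_factor": (
            None if np.isinf(idx.cohesion_factor) else idx.cohesion_factor
        ),
    }


def write_json(payload: dict[str, Any], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def write_bifurcation_curve(
    sabbath_grid: np.ndarray, t_star: np.ndarray, path: str | Path
) -> Path:
    """CSV of the endemic branch: columns sabbath_number, T_star."""
    path = Path(path)
    frame = pd.DataFrame({"sabbath_number": sabbath_grid, "T_star": t_star})
    frame.to_csv(path, index=False, float_format=_FMT)
    return path


# -- flat key = value configuration ------------------------------------------

def scenario_to_config(scenario: Scenario) -> str:
    """Serialise a scenario to flat ``key = value`` text.

    Floats are written with :func:`repr`, the shortest decimal string that
    round-trips exactly, so reading the config back reproduces the scenario
    bit for bit.
    """
    params, forcing, init = scenario.params, scenario.params.forcing, scenario.init
    lines = [
        f"name = {scenario.name}",
        f"provenance = {scenario.provenance}",
        f"alpha = {params.alpha!r}",
        f"beta = {params.beta!r}",
        f"N = {params.N!r}",
        f"forcing_kind = {forcing.kind}",
        f"gamma_mean = {forcing.mean!r}",
        f"amplitude = {forcing.amplitude!r}",
        f"omega = {forcing.angular_frequency!r}",
        f"S0 = {init.S!r}",
        f"T0 = {init.T!r}",
        f"R0 = {init.R!r}",
        f"horizon = {scenario.horizon!r}",
    ]
    if scenario.pulses is not None:
        lines += [
            f"pulse_p = {scenario.pulses.p!r}",
            f"pulse_tau = {scenario.pulses.tau!r}",
            f"first_pulse_time = {scenario.pulses.first_pulse_time!r}",
        ]
    return "\n".join(lines) + "\n"


def _parse_flat(text: str) -> dict[str, str]:
    values: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise InvalidParameterError(f"config line {lineno} is not 'key = value'")
        key, _, value = line.partition("=")
        values[key.strip()] = value.strip()
    return values


def scenario_from_config(text: str) -> Scenario:
    """Rebuild a scenario from flat ``key = value`` text."""
    v = _parse_flat(text)
    forcing = RepentanceForcing(
        kind=v.get("forcing_kind", "constant"),
        mean=float(v["gamma_mean"]),
        amplitude=float(v.get("amplitude", "0.0")),
        angular_frequency=float(v.get("omega", repr(2 * np.pi))),
    )
    params = STRSParams(
        alpha=float(v["alpha"]),
        beta=float(v["beta"]),
        forcing=forcing,
        N=float(v["N"]),
    )
    init = CompartmentState(S=float(v["S0"]), T=float(v["T0"]), R=float(v["R0"]))
    pulses = None
    if "pulse_p" in v:
        pulses = PulseSchedule(
            p=float(v["pulse_p"]),
            tau=float(v["pulse_tau"]),
            first_pulse_time=(
                float(v["first_pulse_time"]) if "first_pulse_time" in v else None
            ),
        )
    return Scenario(
        name=v.get("name", "config"),
        params=params,
        init=init,
        horizon=float(v.get("horizon", "300.0")),
        provenance=v.get("provenance", "loaded from config"),
        pulses=pulses,
    )


def write_config(scenario: Scenario, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(scenario_to_config(scenario))
    return path


def read_config(path: str | Path) -> Scenario:
    return scenario_from_config(Path(path).read_text())
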