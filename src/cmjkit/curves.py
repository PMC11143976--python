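"""Time-normalized force and power curves.

Each jump is mapped onto a 0-100% normalized-time axis with the eccentric
phase occupying 0-50% and the concentric phase 50-100%: node 0 is movement
onset, node Q/2 the end of braking and node Q the take-off.  Within each
phase, values are linearly interpolated at equally spaced time fractions.
Averaging is hierarchical: per-participant trial mean first, then
across-participant mean +/- SD node-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import KinematicSeries, PhaseSegmentation

__all__ = ["NormalizedCurve", "normalize_curve", "average_curves"]


@dataclass
class NormalizedCurve:
    """A quantity sampled at Q+1 evenly spaced nodes on [0, 100]% of
    normalized jump time (eccentric 0-50%, concentric 50-100%)."""

    values: np.ndarray  # length Q + 1
    quantity: str  # "force" (N/kg) or "power" (W/kg)
    participant: str = ""
    condition: str = ""

    @property
    def n_nodes(self) -> int:
        return int(self.values.size)

    @property
    def q(self) -> int:
        return self.n_nodes - 1

    @property
    def percent(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, self.n_nodes)


def normalize_curve(
    kin: KinematicSeries,
    seg: PhaseSegmentation,
    quantity: str = "force",
    q: int = 100,
    *,
    participant: str = "",
    condition: str = "",
    g: float | None = None,
) -> NormalizedCurve:
    """Resample a per-sample quantity onto the 50/50 normalized-time grid.

    Parameters
    ----------
    quantity : ``"force"`` (mass-normalized GRF, N/kg) or ``"power"`` (W/kg).
    q : even number of intervals >= 10; the curve has q+1 nodes.
    """
    if q < 10 or q % 2:
        raise ValueError("q must be even and >= 10")
    if quantity == "force":
        from .constants import GRAVITY

        y = kin.net_acceleration + (GRAVITY if g is None else g)
    elif quantity == "power":
        y = kin.power
    else:
        raise ValueError("quantity must be 'force' or 'power'")

    t = kin.time
    t_on = t[seg.onset_index]
    t_eob = t[seg.end_of_braking_index]
    t_to = t[seg.takeoff_index]
    half = q // 2
    t_ecc = np.linspace(t_on, t_eob, half + 1)
    t_con = np.linspace(t_eob, t_to, half + 1)
    nodes_t = np.concatenate([t_ecc, t_con[1:]])
    vals = np.interp(nodes_t, t, y)
    return NormalizedCurve(
        values=vals, quantity=quantity, participant=participant, condition=condition
    )


def average_curves(
    curves: list[NormalizedCurve],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-condition mean and SD curves.

    Trials of the same participant are averaged first; the returned mean and
    SD are taken across participants, node-wise.  Returns
    ``{condition: (mean, sd)}``.
    """
    if not curves:
        raise ValueError("no curves to average")
    n_nodes = curves[0].n_nodes
    frame = pd.DataFrame(
        {
            "participant": [c.participant for c in curves],
            "condition": [c.condition for c in curves],
        }
    )
    mat = np.vstack([c.values for c in curves])
    if mat.shape[1] != n_nodes or len({c.quantity for c in curves}) != 1:
        raise ValueError("curves must share node count and quantity")

    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cond, idx in frame.groupby("condition", sort=False).groups.items():
        sub = frame.loc[idx]
        per_participant = np.vstack(
            [
                mat[list(pidx)].mean(axis=0)
                for _, pidx in sub.groupby("participant", sort=False).groups.items()
            ]
        )
        mean = per_participant.mean(axis=0)
        sd = (
            per_participant.std(axis=0, ddof=1)
            if per_participant.shape[0] > 1
            else np.zeros(n_nodes)
        )
        out[str(cond)] = (mean, sd)
    return out


def participant_mean_curves(
    curves: list[NormalizedCurve],
) -> dict[str, dict[str, np.ndarray]]:
    """Trial-mean curve per participant, grouped by condition:
    ``{condition: {participant: mean_curve}}`` (input to the paired SPM)."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for c in curves:
        out.setdefault(c.condition, {}).setdefault(c.participant, []).append(c.values)  # type: ignore[arg-type]
    return {
        cond: {p: np.mean(np.vstack(v), axis=0) for p, v in parts.items()}
        for cond, parts in out.items()
    }
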