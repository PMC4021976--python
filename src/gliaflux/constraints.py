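"""Von Neumann constraint assembly and feasibility checks.

The feasible set at a given capillary glucose uptake g is

    (S nu)_m >= 0   for every intracellular/extracellular species m,
    (S nu)_m  = 0   for the capillary nutrients (glucose, oxygen),
    lb_j <= nu_j <= ub_j   ([0, nu_max] irreversible, [-nu_max, nu_max]
                            reversible),
    nu_{glucose intake} = g  (the only pinned flux; oxygen intake is free).

Net production of internal species is allowed (soft steady state); net
consumption is not.  Equalities are handled as pairs of inequalities in the
sampler; pins are encoded as degenerate bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .network import MetabolicNetwork, MissingRoleError

__all__ = [
    "ConstraintSet",
    "make_constraints",
    "constraints_for",
    "production_vector",
    "check_feasibility",
]


@dataclass
class ConstraintSet:
    """Row partition, pins and bounds for one sampling problem."""

    inequality_rows: np.ndarray  # species indices with (S nu)_m >= 0
    equality_rows: np.ndarray    # species indices with (S nu)_m  = 0
    pins: Dict[str, float]       # reaction id -> fixed value
    lb: np.ndarray               # length N
    ub: np.ndarray               # length N
    nu_max: float = 1.0

    def pin_array(self, net: MetabolicNetwork) -> Tuple[np.ndarray, np.ndarray]:
        idx = np.array([net.reaction_index(r) for r in self.pins], dtype=np.int64)
        val = np.array(list(self.pins.values()), dtype=float)
        return idx, val


def production_vector(net: MetabolicNetwork, nu: np.ndarray) -> np.ndarray:
    """Per-species net production S @ nu."""
    nu = np.asarray(nu, dtype=float)
    if nu.shape[-1] != net.n_reactions:
        raise ValueError(
            f"flux vector has {nu.shape[-1]} components, network has "
            f"{net.n_reactions} reactions"
        )
    return nu @ net.S.T


def constraints_for(
    net: MetabolicNetwork,
    pins: Dict[str, float],
    nu_max: float = 1.0,
    extra_equality_species: Tuple[str, ...] = (),
) -> ConstraintSet:
    """Generic constraint assembly: equality rows for ``is_intake`` species
    (plus any listed extras), inequality rows for everything else."""
    eq_ids = {s.id for s in net.species if s.is_intake}
    eq_ids.update(extra_equality_species)
    eq = np.array(sorted(net.species_index(s) for s in eq_ids), dtype=np.int64)
    ineq = np.array(
        [i for i in range(net.n_species) if i not in set(eq.tolist())],
        dtype=np.int64,
    )
    rev = net.reversible_mask()
    lb = np.where(rev, -nu_max, 0.0)
    ub = np.full(net.n_reactions, nu_max)
    for rid, val in pins.items():
        j = net.reaction_index(rid)
        lb[j] = ub[j] = val
    return ConstraintSet(ineq, eq, dict(pins), lb, ub, nu_max)


def make_constraints(
    net: MetabolicNetwork,
    glucose_level: float,
    nu_max: float = 1.0,
    eq7_strict: bool = False,
    ros_fraction: float = 0.10,
    pin_vcyc_zero: bool = False,
) -> ConstraintSet:
    """Constraints with the capillary glucose uptake pinned to ``glucose_level``.

    With ``eq7_strict`` the extracellular glucose balance is also promoted to
    an equality (no net interstitial glucose production); by default it is
    left as the ordinary >= 0 row.

    ``ros_fraction`` sizes the mitochondrial ROS side reaction: each cell's
    H2O2 production is capped at ``ros_fraction x glucose_level`` so that
    detoxifying it demands NADPH on the order of the pentose-phosphate
    throughput (5-15% of glucose; default 10%).

    ``pin_vcyc_zero`` additionally pins the astrocytic glutamine synthetase
    flux to zero -- the suppressed-neurotransmission ensemble used for the
    correlation analysis.
    """
    if glucose_level <= 0:
        raise ValueError("glucose_level must be positive")
    glc_in = net.role_index.get("GLC_to_c")
    if glc_in is None or not net.has_reaction(glc_in):
        raise MissingRoleError("GLC_to_c role required to pin glucose uptake")
    extra = ("GLC[e]",) if eq7_strict else ()
    pins = {glc_in: glucose_level}
    if pin_vcyc_zero:
        gs = net.role_index.get("GS_a")
        if gs is None or not net.has_reaction(gs):
            raise MissingRoleError("GS_a role required to pin V_cyc to zero")
        pins[gs] = 0.0
    cs = constraints_for(net, pins, nu_max, extra)
    for rid in ("ROS_n", "ROS_a"):
        if net.has_reaction(rid):
            j = net.reaction_index(rid)
            cs.ub[j] = min(cs.ub[j], ros_fraction * glucose_level)
    return cs


def check_feasibility(
    net: MetabolicNetwork,
    nu: np.ndarray,
    cs: ConstraintSet,
    epsilon: float = 1e-9,
) -> Tuple[bool, float]:
    """Return (feasible, max violation magnitude) at tolerance epsilon."""
    nu = np.asarray(nu, dtype=float)
    r = production_vector(net, nu)
    worst = 0.0
    if cs.inequality_rows.size:
        worst = max(worst, float(np.max(-r[..., cs.inequality_rows], initial=0.0)))
    if cs.equality_rows.size:
        worst = max(worst, float(np.max(np.abs(r[..., cs.equality_rows]), initial=0.0)))
    worst = max(worst, float(np.max(cs.lb - nu, initial=0.0)))
    worst = max(worst, float(np.max(nu - cs.ub, initial=0.0)))
    return worst <= epsilon, worst
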