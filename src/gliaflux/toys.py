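"""Small stoichiometric networks with enumerable feasible sets.

These toys mirror the structure the analysis assumes -- a pinned intake
feeding a capillary-like species held at equality, ordinary species under
the soft ``S nu >= 0`` rule, reversible exchanges -- at a scale where the
feasible polytope can be characterized analytically or enumerated on a
grid, so the sampler and the observables can be validated without the
full brain reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Optional, Tuple

import numpy as np

from .constraints import ConstraintSet, check_feasibility, constraints_for
from .network import MetabolicNetwork, Reaction, Species

__all__ = [
    "ToyNetworkSpec",
    "make_chain",
    "make_diamond",
    "make_minibrain",
    "make_random_network",
    "build_toy",
    "brute_force_polytope",
]


@dataclass(frozen=True)
class ToyNetworkSpec:
    kind: str  # chain | diamond | minibrain | random
    length: int = 3
    M: int = 6
    N: int = 9
    density: float = 0.4
    seed: int = 0


def build_toy(spec: ToyNetworkSpec) -> MetabolicNetwork:
    if spec.kind == "chain":
        return make_chain(spec.length)
    if spec.kind == "diamond":
        return make_diamond()
    if spec.kind == "minibrain":
        return make_minibrain()
    if spec.kind == "random":
        return make_random_network(spec.M, spec.N, spec.density, spec.seed)[0]
    raise ValueError(f"unknown toy kind {spec.kind!r}")


def _rxn(rid: str, stoich: Dict[str, int | Fraction], rev: bool = False,
         tag: str = "other", scope: str = "shared") -> Reaction:
    return Reaction(rid, rid, {k: Fraction(v) for k, v in stoich.items()},
                    rev, tag, scope)


def make_chain(length: int) -> MetabolicNetwork:
    """Linear pathway: intake -> A0 (equality) -> A1 -> ... -> A_L -> efflux.

    With the intake pinned to 1 the transport out of A0 is forced to 1 and
    the downstream fluxes form a monotone non-increasing chain:
    ``1 = nu_1 >= nu_2 >= ... >= nu_{L+1} >= 0``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    species = [Species("A0[c]", "A0", "c", carbon_count=1, is_intake=True)]
    species += [Species(f"A{i}[e]", f"A{i}", "e", carbon_count=1)
                for i in range(1, length + 1)]
    reactions = [_rxn("IN", {"A0[c]": 1}, tag="intake")]
    prev = "A0[c]"
    for i in range(1, length + 1):
        cur = f"A{i}[e]"
        reactions.append(_rxn(f"T{i}", {prev: -1, cur: 1}, tag="transport"))
        prev = cur
    reactions.append(_rxn("OUT", {prev: -1}, tag="efflux"))
    net = MetabolicNetwork(species, reactions, {"GLC_to_c": "IN"}, name="chain")
    net.validate()
    return net


def make_diamond() -> MetabolicNetwork:
    """Two parallel routes: intake -> A -> {B1, B2} -> C -> efflux."""
    species = [
        Species("A0[c]", "A0", "c", carbon_count=1, is_intake=True),
        Species("A[e]", "A", "e", carbon_count=1),
        Species("B1[e]", "B1", "e", carbon_count=1),
        Species("B2[e]", "B2", "e", carbon_count=1),
        Species("C[e]", "C", "e", carbon_count=1),
    ]
    reactions = [
        _rxn("IN", {"A0[c]": 1}, tag="intake"),
        _rxn("T", {"A0[c]": -1, "A[e]": 1}, tag="transport"),
        _rxn("R1", {"A[e]": -1, "B1[e]": 1}),
        _rxn("R2", {"A[e]": -1, "B2[e]": 1}),
        _rxn("J1", {"B1[e]": -1, "C[e]": 1}),
        _rxn("J2", {"B2[e]": -1, "C[e]": 1}),
        _rxn("OUT", {"C[e]": -1}, tag="efflux"),
    ]
    net = MetabolicNetwork(species, reactions, {"GLC_to_c": "IN"}, name="diamond")
    net.validate()
    return net


def make_minibrain() -> MetabolicNetwork:
    """Eight-reaction caricature of the brain model.

    A pinned glucose intake splits between two cells, each with a lumped
    glycolysis (1 glucose -> 2 lactate) and a lumped oxidation (1 lactate +
    3 O2 -> 3 CO2; i.e. 6 O2 per glucose, so the fully oxidative corner has
    OGI exactly 6), plus a reversible lactate exchange with a shared
    extracellular pool.  The oxygen intake is free at equality.  The sign of
    the lactate exchange is forced by the imbalance between a cell's glucose
    share and its oxidation.
    """
    species = [
        Species("GLC[c]", "glucose", "c", carbon_count=6, is_intake=True),
        Species("O2[c]", "oxygen", "c", carbon_count=0, is_intake=True),
        Species("LAC[nc]", "lactate", "nc", carbon_count=3),
        Species("LAC[ac]", "lactate", "ac", carbon_count=3),
        Species("LAC[e]", "lactate", "e", carbon_count=3),
        Species("CO2[nc]", "CO2", "nc", carbon_count=1),
        Species("CO2[ac]", "CO2", "ac", carbon_count=1),
    ]
    reactions = [
        _rxn("GLC_in", {"GLC[c]": 1}, tag="intake", scope="capillary"),
        _rxn("O2_in", {"O2[c]": 1}, tag="intake", scope="capillary"),
        _rxn("GLY_n", {"GLC[c]": -1, "LAC[nc]": 2}, tag="glycolysis", scope="neuron"),
        _rxn("GLY_a", {"GLC[c]": -1, "LAC[ac]": 2}, tag="glycolysis",
             scope="astrocyte"),
        _rxn("OX_n", {"LAC[nc]": -1, "O2[c]": -3, "CO2[nc]": 3}, tag="oxphos",
             scope="neuron"),
        _rxn("OX_a", {"LAC[ac]": -1, "O2[c]": -3, "CO2[ac]": 3}, tag="oxphos",
             scope="astrocyte"),
        _rxn("LACT_n", {"LAC[nc]": -1, "LAC[e]": 1}, rev=True, tag="transport",
             scope="neuron"),
        _rxn("LACT_a", {"LAC[ac]": -1, "LAC[e]": 1}, rev=True, tag="transport",
             scope="astrocyte"),
    ]
    roles = {
        "GLC_to_c": "GLC_in",
        "O2_to_c": "O2_in",
        "GLC_c_to_a": "GLY_a",
        "LAC_a_to_n": "LACT_a",
        "LAC_n_to_e": "LACT_n",
    }
    net = MetabolicNetwork(species, reactions, roles, name="minibrain")
    net.validate()
    return net


def make_random_network(
    M: int, N: int, density: float = 0.4, seed: int = 0
) -> Tuple[MetabolicNetwork, np.ndarray]:
    """Random sparse integer stoichiometry with an embedded feasible point.

    The first N-1 columns are random; the last column is a supply/intake
    column built so that the known flux vector ``nu_dagger`` (returned
    alongside) satisfies ``S nu_dagger >= 0`` -- the network is non-empty by
    construction.
    """
    if N <= M:
        raise ValueError("need N > M (underdetermined)")
    rng = np.random.default_rng(seed)
    species = [Species(f"S{i}[e]", f"S{i}", "e") for i in range(M)]
    sids = [s.id for s in species]
    reactions: List[Reaction] = []
    nu_dagger = np.zeros(N)
    S = np.zeros((M, N))
    for j in range(N - 1):
        while True:
            mask = rng.random(M) < density
            if mask.sum() >= 2:
                break
        coeffs = rng.choice([-2, -1, 1, 2], size=int(mask.sum()))
        if (coeffs > 0).all():
            coeffs[0] = -coeffs[0]
        if (coeffs < 0).all():
            coeffs[0] = -coeffs[0]
        stoich = {sids[i]: int(c) for i, c in zip(np.nonzero(mask)[0], coeffs)}
        rev = bool(rng.random() < 0.3)
        reactions.append(_rxn(f"R{j}", stoich, rev=rev))
        for sid, c in stoich.items():
            S[sids.index(sid), j] = c
        nu_dagger[j] = rng.uniform(0.1, 0.5)
    r = S[:, : N - 1] @ nu_dagger[: N - 1]
    supply = {sids[i]: Fraction(-r[i]).limit_denominator(10**6)
              for i in range(M) if r[i] < 0}
    if not supply:  # ensure the balancer column is non-trivial
        supply = {sids[0]: Fraction(1)}
    reactions.append(Reaction("SUPPLY", "SUPPLY", supply, False, "intake", "shared"))
    nu_dagger[N - 1] = 1.0
    net = MetabolicNetwork(species, reactions, {}, name=f"random-{seed}")
    return net, nu_dagger


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_polytope(
    net: MetabolicNetwork,
    cs: ConstraintSet,
    resolution: int = 21,
    max_free_dim: int = 6,
    epsilon: float = 1e-9,
) -> np.ndarray:
    """Exhaustive grid scan of the feasible set (oracle for small toys).

    Pinned variables are fixed, equality rows are eliminated by Gaussian
    pivoting (dependent variables computed from the independent ones), and
    the remaining free dimensions are scanned on a regular grid within the
    bounds.  Every returned point passes :func:`check_feasibility`.  Raises
    if the free dimension exceeds ``max_free_dim``.
    """
    S = net.S
    N = net.n_reactions
    pinned = cs.lb == cs.ub
    freecols = np.nonzero(~pinned)[0]
    E = S[cs.equality_rows][:, freecols] if cs.equality_rows.size else np.zeros((0, len(freecols)))
    rhs = (
        -S[cs.equality_rows][:, pinned] @ cs.lb[pinned]
        if cs.equality_rows.size
        else np.zeros(0)
    )
    # row-reduce [E | rhs]
    A = np.hstack([E, rhs[:, None]]) if E.size else np.zeros((0, len(freecols) + 1))
    pivots: List[int] = []
    row = 0
    for col in range(len(freecols)):
        if row >= A.shape[0]:
            break
        p = row + int(np.argmax(np.abs(A[row:, col])))
        if abs(A[p, col]) < 1e-12:
            continue
        A[[row, p]] = A[[p, row]]
        A[row] /= A[row, col]
        for rr in range(A.shape[0]):
            if rr != row and A[rr, col] != 0:
                A[rr] -= A[rr, col] * A[row]
        pivots.append(col)
        row += 1
    if row < A.shape[0] and np.any(np.abs(A[row:, -1]) > 1e-9):
        return np.zeros((0, N))  # inconsistent equalities: empty polytope
    indep = [c for c in range(len(freecols)) if c not in pivots]
    if len(indep) > max_free_dim:
        raise ValueError(
            f"free dimension {len(indep)} exceeds max_free_dim={max_free_dim}"
        )
    axes = [
        np.linspace(cs.lb[freecols[c]], cs.ub[freecols[c]], resolution)
        for c in indep
    ]
    if axes:
        grids = np.meshgrid(*axes, indexing="ij")
        pts_indep = np.stack([g.ravel() for g in grids], axis=1)
    else:
        pts_indep = np.zeros((1, 0))
    n_pts = pts_indep.shape[0]
    X = np.tile(cs.lb, (n_pts, 1))
    X[:, freecols[indep] if indep else []] = pts_indep
    # dependent variables from the reduced equalities
    for r_i, col in enumerate(pivots):
        val = A[r_i, -1] - pts_indep @ A[r_i, indep] if indep else np.full(n_pts, A[r_i, -1])
        X[:, freecols[col]] = val
    # vectorized feasibility screen, then exact per-point audit
    R = X @ S.T
    ok = np.ones(n_pts, dtype=bool)
    if cs.inequality_rows.size:
        ok &= (R[:, cs.inequality_rows] >= -epsilon).all(axis=1)
    if cs.equality_rows.size:
        ok &= (np.abs(R[:, cs.equality_rows]) <= epsilon).all(axis=1)
    ok &= (X >= cs.lb - epsilon).all(axis=1) & (X <= cs.ub + epsilon).all(axis=1)
    pts = X[ok]
    return pts
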