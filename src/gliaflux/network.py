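"""Stoichiometric network objects for compartmentalized brain energy metabolism.

The model distinguishes four anatomical elements -- neuron (n), astrocyte (a),
extracellular (interstitial) space (e) and blood capillary (c) -- with the two
cells further split into cytosol (nc, ac), mitochondria (nm, am) and, for the
neuron only, synaptic vesicles (nv).  A network is a list of species, a list of
reactions with signed rational stoichiometric coefficients, the resulting
M x N matrix S, and a role index that locates the handful of fluxes the
downstream observables need by name (glucose/oxygen intakes and routes,
astrocytic glutamine synthetase, neuronal pyruvate dehydrogenase, lactate
transport).

Coefficients are stored as :class:`fractions.Fraction` so that elemental
audits are exact; the dense float matrix is materialized on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "COMPARTMENTS",
    "Compartment",
    "Species",
    "Reaction",
    "MetabolicNetwork",
    "NetworkConstructionError",
    "MissingRoleError",
    "parse_equation",
    "format_equation",
    "stoichiometric_matrix",
    "carbon_balance_check",
    "nitrogen_balance_check",
]

#: the seven legal compartment codes; nv exists in neurons only
COMPARTMENTS: Dict[str, str] = {
    "c": "blood capillary",
    "e": "extracellular space",
    "nc": "neuronal cytosol",
    "nm": "neuronal mitochondria",
    "nv": "neuronal synaptic vesicles",
    "ac": "astrocytic cytosol",
    "am": "astrocytic mitochondria",
}

#: roles every full brain network must resolve
REQUIRED_ROLES = (
    "GS_a",
    "PDH_n",
    "GLC_to_c",
    "O2_to_c",
    "GLC_c_to_a",
    "GLC_c_to_e",
    "GLC_e_to_a",
    "GLC_e_to_n",
    "O2_c_to_a",
    "O2_c_to_n",
    "LAC_a_to_n",
)

#: reaction classes exempt from elemental balance checks
EXCHANGE_TAGS = frozenset({"intake", "efflux"})


class NetworkConstructionError(ValueError):
    """Raised when a network violates a structural invariant at build time."""


class MissingRoleError(KeyError):
    """Raised when an observable needs a named role the network cannot resolve."""


@dataclass(frozen=True)
class Compartment:
    code: str
    label: str

    def __post_init__(self) -> None:
        if self.code not in COMPARTMENTS:
            raise NetworkConstructionError(f"unknown compartment code {self.code!r}")


@dataclass(frozen=True)
class Species:
    """One chemical species in one compartment.

    ``carbon_count``/``nitrogen_count`` are fixed per chemical identity
    (glucose 6, lactate 3, glutamate 5C/1N, ...) regardless of compartment.
    ``is_intake`` is True only for the capillary nutrients (glucose, oxygen)
    whose mass balance is kept as a strict equality.
    """

    id: str
    name: str
    compartment: str
    carbon_count: int = 0
    nitrogen_count: int = 0
    is_intake: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise NetworkConstructionError(
                f"species {self.id!r}: unknown compartment {self.compartment!r}"
            )
        if self.carbon_count < 0 or self.nitrogen_count < 0:
            raise NetworkConstructionError(f"species {self.id!r}: negative element count")


@dataclass(frozen=True)
class Reaction:
    """A reaction or transport step; coefficients negative = consumed."""

    id: str
    name: str
    stoichiometry: Mapping[str, Fraction]  # species id -> signed coefficient
    reversible: bool = False
    pathway_tag: str = "other"
    cell_scope: str = "shared"  # neuron | astrocyte | shared | capillary

    @property
    def is_exchange(self) -> bool:
        return self.pathway_tag in EXCHANGE_TAGS


def parse_equation(text: str) -> Tuple[Dict[str, Fraction], Dict[str, Fraction]]:
    """Parse an equation string like ``"2 A[nc] + B[e] -> C[ac]"``.

    Returns (reactants, products) as species-id -> positive coefficient maps.
    An empty side denotes an intake (``"-> GLC[c]"``) or efflux (``"CO2[c] ->"``).
    """
    for arrow in ("<->", "->"):
        if arrow in text:
            lhs, rhs = text.split(arrow)
            break
    else:
        raise ValueError(f"no arrow in equation {text!r}")

    def side(chunk: str) -> Dict[str, Fraction]:
        out: Dict[str, Fraction] = {}
        chunk = chunk.strip()
        if not chunk:
            return out
        for term in chunk.split("+"):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 2:
                coeff = Fraction(parts[0])
                sid = parts[1]
            elif len(parts) == 1:
                coeff = Fraction(1)
                sid = parts[0]
            else:
                raise ValueError(f"cannot parse term {term!r}")
            if "[" not in sid or not sid.endswith("]"):
                raise ValueError(f"species token {sid!r} lacks [compartment]")
            out[sid] = out.get(sid, Fraction(0)) + coeff
        return out

    return side(lhs), side(rhs)


def format_equation(rxn: Reaction) -> str:
    """Render a reaction back into the ``A[x] + 2 B[y] -> C[z]`` dialect."""

    def fmt(side: List[Tuple[str, Fraction]]) -> str:
        bits = []
        for sid, coeff in side:
            bits.append(sid if coeff == 1 else f"{coeff} {sid}")
        return " + ".join(bits)

    lhs = [(s, -c) for s, c in rxn.stoichiometry.items() if c < 0]
    rhs = [(s, c) for s, c in rxn.stoichiometry.items() if c > 0]
    arrow = "<->" if rxn.reversible else "->"
    return f"{fmt(lhs)} {arrow} {fmt(rhs)}".strip()


RoleTarget = str  # reaction id


@dataclass
class MetabolicNetwork:
    """Species, reactions and the M x N stoichiometric matrix S.

    ``role_index`` maps the named roles used by the observables to reaction
    ids.  The sign convention for ``LAC_a_to_n`` is that a positive flux of
    the referenced (reversible, astrocyte-side) transporter exports lactate
    from the astrocyte toward the extracellular pool, i.e. toward the neuron.
    """

    species: List[Species]
    reactions: List[Reaction]
    role_index: Dict[str, RoleTarget] = field(default_factory=dict)
    name: str = "network"

    def __post_init__(self) -> None:
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise NetworkConstructionError("duplicate species ids")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise NetworkConstructionError("duplicate reaction ids")
        self._species_idx = {s.id: i for i, s in enumerate(self.species)}
        self._reaction_idx = {r.id: j for j, r in enumerate(self.reactions)}
        known = set(self._species_idx)
        for r in self.reactions:
            unknown = set(r.stoichiometry) - known
            if unknown:
                raise NetworkConstructionError(
                    f"reaction {r.id!r} references unknown species {sorted(unknown)}"
                )
        self._S: Optional[np.ndarray] = None

    # -- basic geometry -------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, sid: str) -> int:
        return self._species_idx[sid]

    def reaction_index(self, rid: str) -> int:
        return self._reaction_idx[rid]

    def has_reaction(self, rid: str) -> bool:
        return rid in self._reaction_idx

    @property
    def S(self) -> np.ndarray:
        if self._S is None:
            self._S = stoichiometric_matrix(self)
        return self._S

    @property
    def intake_reactions(self) -> List[str]:
        return [r.id for r in self.reactions if r.pathway_tag == "intake"]

    def role_column(self, role: str) -> int:
        """Column index for a named role; raises MissingRoleError if unset."""
        rid = self.role_index.get(role)
        if rid is None or rid not in self._reaction_idx:
            raise MissingRoleError(
                f"role {role!r} is not resolved on network {self.name!r}"
            )
        return self._reaction_idx[rid]

    def reversible_mask(self) -> np.ndarray:
        return np.array([r.reversible for r in self.reactions], dtype=bool)

    def validate(self) -> None:
        """Check construction invariants; raise NetworkConstructionError."""
        bad = carbon_balance_check(self)[0]
        if bad:
            raise NetworkConstructionError(f"carbon imbalance in {bad}")
        badn = nitrogen_balance_check(self)[0]
        if badn:
            raise NetworkConstructionError(f"nitrogen imbalance in {badn}")
        for r in self.reactions:
            if r.is_exchange:
                continue
            has_neg = any(c < 0 for c in r.stoichiometry.values())
            has_pos = any(c > 0 for c in r.stoichiometry.values())
            if not (has_neg and has_pos):
                raise NetworkConstructionError(
                    f"reaction {r.id!r} is one-sided but not tagged intake/efflux"
                )


def stoichiometric_matrix(net: MetabolicNetwork) -> np.ndarray:
    """Materialize S: entry (i, j) = coefficient of species i in reaction j."""
    S = np.zeros((net.n_species, net.n_reactions), dtype=float)
    for j, r in enumerate(net.reactions):
        for sid, coeff in r.stoichiometry.items():
            S[net.species_index(sid), j] = float(coeff)
    return S


def _element_balance(
    net: MetabolicNetwork, attr: str
) -> Tuple[List[Tuple[str, Fraction]], List[str]]:
    violations: List[Tuple[str, Fraction]] = []
    exempt: List[str] = []
    counts = {s.id: getattr(s, attr) for s in net.species}
    for r in net.reactions:
        if r.is_exchange:
            exempt.append(r.id)
            continue
        total = sum(
            (coeff * counts[sid] for sid, coeff in r.stoichiometry.items()),
            Fraction(0),
        )
        if total != 0:
            violations.append((r.id, total))
    return violations, exempt


def carbon_balance_check(
    net: MetabolicNetwork,
) -> Tuple[List[Tuple[str, Fraction]], List[str]]:
    """Audit carbon conservation reaction by reaction.

    Returns ``(violations, exempt)`` where ``violations`` lists
    ``(reaction id, net carbon)`` for every non-exchange reaction with
    unbalanced carbon and ``exempt`` the intake/efflux reactions that are
    excluded from the audit.
    """
    return _element_balance(net, "carbon_count")


def nitrogen_balance_check(
    net: MetabolicNetwork,
) -> Tuple[List[Tuple[str, Fraction]], List[str]]:
    """Same as :func:`carbon_balance_check` for nitrogen."""
    return _element_balance(net, "nitrogen_count")
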