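"""Network and ensemble I/O.

Two interchange formats are supported for networks:

* a TSV reaction table (UTF-8, tab-separated, header row) with equation
  strings in the ``"2 A[nc] + B[e] -> C[ac]"`` dialect (compartment in
  square brackets, ``<->`` marks reversibility alongside the boolean
  column).  Species metadata and role annotations travel in ``#species``
  and ``#role`` comment lines so a round trip reproduces S exactly.
* SBML Level 3 Version 1 (core), species/reaction/compartment structure
  plus reversibility; roles, pathway tags, cell scopes and element counts
  are carried in annotation elements under a package namespace.

Ensembles persist as a TSV flux table (header = reaction ids, one row per
solution) with a JSON provenance sidecar.
"""

from __future__ import annotations

import json
import warnings
from fractions import Fraction
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from .network import (
    MetabolicNetwork,
    NetworkConstructionError,
    Reaction,
    Species,
    carbon_balance_check,
    format_equation,
    parse_equation,
)
from .sampling import SamplerConfig, SolutionEnsemble

__all__ = [
    "export_network",
    "import_network",
    "write_ensemble",
    "read_ensemble",
]

_NS = "https://gliaflux.invalid/annotations"


def export_network(net: MetabolicNetwork, path: str | Path, format: str = "tsv") -> Path:
    """Write a network as 'tsv' or 'sbml'; returns the path written."""
    path = Path(path)
    if format == "tsv":
        _export_tsv(net, path)
    elif format == "sbml":
        _export_sbml(net, path)
    else:
        raise ValueError(f"unsupported format {format!r}")
    return path


def import_network(path: str | Path, format: Optional[str] = None) -> MetabolicNetwork:
    """Read a network written by :func:`export_network` (or conforming files).

    Unknown carbon balances in third-party files produce a warning, not an
    error; missing role annotations leave the role index empty, and
    observables that need those roles fail fast.
    """
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "tsv"
    if format == "tsv":
        net = _import_tsv(path)
    elif format == "sbml":
        net = _import_sbml(path)
    else:
        raise ValueError(f"unsupported format {format!r}")
    bad = carbon_balance_check(net)[0]
    if bad:
        warnings.warn(f"imported network has carbon imbalances: {bad}")
    return net


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------


def _export_tsv(net: MetabolicNetwork, path: Path) -> None:
    lines = [f"#network\t{net.name}"]
    for s in net.species:
        lines.append(
            "#species\t{id}\t{name}\t{comp}\t{c}\t{n}\t{intake}".format(
                id=s.id, name=s.name, comp=s.compartment,
                c=s.carbon_count, n=s.nitrogen_count, intake=int(s.is_intake),
            )
        )
    for role, rid in net.role_index.items():
        lines.append(f"#role\t{role}\t{rid}")
    lines.append("id\tname\tequation\treversible\tpathway_tag\tcell_scope")
    for r in net.reactions:
        lines.append(
            f"{r.id}\t{r.name}\t{format_equation(r)}\t{int(r.reversible)}"
            f"\t{r.pathway_tag}\t{r.cell_scope}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _import_tsv(path: Path) -> MetabolicNetwork:
    species: List[Species] = []
    roles: Dict[str, str] = {}
    name = path.stem
    reactions: List[Reaction] = []
    header_seen = False
    seen_species: Dict[str, Species] = {}
    for raw in path.read_text(encoding="utf-8").splitlines():
        if not raw.strip():
            continue
        if raw.startswith("#network\t"):
            name = raw.split("\t", 1)[1]
            continue
        if raw.startswith("#species\t"):
            _, sid, sname, comp, c, n, intake = raw.split("\t")
            sp = Species(sid, sname, comp, int(c), int(n), bool(int(intake)))
            species.append(sp)
            seen_species[sid] = sp
            continue
        if raw.startswith("#role\t"):
            _, role, rid = raw.split("\t")
            roles[role] = rid
            continue
        if raw.startswith("#"):
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        parts = raw.split("\t")
        if len(parts) != 6:
            raise ValueError(f"malformed TSV row: {raw!r}")
        rid, rname, eq, rev, tag, scope = parts
        reactants, products = parse_equation(eq)
        stoich = {sid: -c for sid, c in reactants.items()}
        for sid, c in products.items():
            stoich[sid] = stoich.get(sid, Fraction(0)) + c
        for sid in stoich:
            if sid not in seen_species:
                base, comp = sid[:-1].split("[")
                sp = Species(sid, base, comp)
                species.append(sp)
                seen_species[sid] = sp
        reactions.append(Reaction(rid, rname, stoich, bool(int(rev)), tag, scope))
    net = MetabolicNetwork(species, reactions, roles, name=name)
    return net


# ---------------------------------------------------------------------------
# SBML Level 3
# ---------------------------------------------------------------------------


def _sbml_id(sid: str) -> str:
    return sid.replace("[", "__").replace("]", "")


def _export_sbml(net: MetabolicNetwork, path: Path) -> None:
    import libsbml

    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId(_sbml_id(net.name) or "network")
    used_comps = sorted({s.compartment for s in net.species})
    for code in used_comps:
        comp = model.createCompartment()
        comp.setId(code)
        comp.setConstant(True)
        comp.setSize(1.0)
    for s in net.species:
        sp = model.createSpecies()
        sp.setId(_sbml_id(s.id))
        sp.setName(s.name)
        sp.setCompartment(s.compartment)
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(True)
        sp.setBoundaryCondition(False)
        sp.setInitialAmount(0.0)
        sp.appendAnnotation(
            f'<gf:meta xmlns:gf="{_NS}" carbon="{s.carbon_count}" '
            f'nitrogen="{s.nitrogen_count}" intake="{int(s.is_intake)}" '
            f'original_id="{s.id}"/>'
        )
    for r in net.reactions:
        rx = model.createReaction()
        rx.setId(_sbml_id(r.id))
        rx.setName(r.name)
        rx.setReversible(r.reversible)
        rx.setFast(False)
        for sid, coeff in r.stoichiometry.items():
            if coeff < 0:
                ref = rx.createReactant()
                ref.setStoichiometry(float(-coeff))
            else:
                ref = rx.createProduct()
                ref.setStoichiometry(float(coeff))
            ref.setSpecies(_sbml_id(sid))
            ref.setConstant(True)
        rx.appendAnnotation(
            f'<gf:meta xmlns:gf="{_NS}" pathway_tag="{r.pathway_tag}" '
            f'cell_scope="{r.cell_scope}" original_id="{r.id}"/>'
        )
    roles = "".join(
        f'<gf:role name="{k}" reaction="{v}"/>' for k, v in net.role_index.items()
    )
    if roles:
        model.appendAnnotation(f'<gf:roles xmlns:gf="{_NS}">{roles}</gf:roles>')
    libsbml.writeSBMLToFile(doc, str(path))


def _annot_attrs(node) -> Dict[str, str]:
    out: Dict[str, str] = {}
    if node is None:
        return out
    stack = [node]
    while stack:
        cur = stack.pop()
        attrs = cur.getAttributes()
        for i in range(attrs.getLength()):
            out[attrs.getName(i)] = attrs.getValue(i)
        for i in range(cur.getNumChildren()):
            stack.append(cur.getChild(i))
    return out


def _import_sbml(path: Path) -> MetabolicNetwork:
    import libsbml

    doc = libsbml.readSBMLFromString(Path(path).read_text(encoding="utf-8"))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ValueError(
            f"SBML parse failure: {doc.getErrorLog().toString()}"
        )
    model = doc.getModel()
    species: List[Species] = []
    id_map: Dict[str, str] = {}
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        meta = _annot_attrs(sp.getAnnotation())
        orig = meta.get("original_id", f"{sp.getId()}")
        id_map[sp.getId()] = orig
        species.append(
            Species(
                orig,
                sp.getName() or orig,
                sp.getCompartment(),
                int(meta.get("carbon", 0)),
                int(meta.get("nitrogen", 0)),
                bool(int(meta.get("intake", 0))),
            )
        )
    reactions: List[Reaction] = []
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        meta = _annot_attrs(rx.getAnnotation())
        stoich: Dict[str, Fraction] = {}
        for k in range(rx.getNumReactants()):
            ref = rx.getReactant(k)
            sid = id_map[ref.getSpecies()]
            stoich[sid] = stoich.get(sid, Fraction(0)) - Fraction(
                ref.getStoichiometry()
            ).limit_denominator(10**6)
        for k in range(rx.getNumProducts()):
            ref = rx.getProduct(k)
            sid = id_map[ref.getSpecies()]
            stoich[sid] = stoich.get(sid, Fraction(0)) + Fraction(
                ref.getStoichiometry()
            ).limit_denominator(10**6)
        reactions.append(
            Reaction(
                meta.get("original_id", rx.getId()),
                rx.getName() or rx.getId(),
                stoich,
                rx.getReversible(),
                meta.get("pathway_tag", "other"),
                meta.get("cell_scope", "shared"),
            )
        )
    roles: Dict[str, str] = {}
    ann = model.getAnnotation()
    if ann is not None:
        stack = [ann]
        while stack:
            cur = stack.pop()
            if cur.getName() == "role":
                attrs = {}
                a = cur.getAttributes()
                for i in range(a.getLength()):
                    attrs[a.getName(i)] = a.getValue(i)
                if "name" in attrs and "reaction" in attrs:
                    roles[attrs["name"]] = attrs["reaction"]
            for i in range(cur.getNumChildren()):
                stack.append(cur.getChild(i))
    return MetabolicNetwork(species, reactions, roles, name=model.getId())


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------


def write_ensemble(ens: SolutionEnsemble, path: str | Path) -> Path:
    """Persist an ensemble as TSV (reaction-id header, one row per solution)
    plus a ``<path>.json`` provenance sidecar."""
    path = Path(path)
    header = "\t".join(ens.reaction_ids)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, ens.solutions, delimiter="\t", fmt="%.17g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(ens.provenance(), indent=1), encoding="utf-8")
    return path


def read_ensemble(path: str | Path) -> SolutionEnsemble:
    """Load an ensemble written by :func:`write_ensemble`."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header or any(not tok for tok in header.split("\t")):
            raise ValueError(f"corrupted flux table header in {path}")
        try:
            data = np.loadtxt(fh, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise ValueError(f"corrupted flux table {path}: {exc}") from exc
    rids = header.split("\t")
    if data.size and data.shape[1] != len(rids):
        raise ValueError(
            f"corrupted flux table {path}: {data.shape[1]} columns for "
            f"{len(rids)} reaction ids"
        )
    sidecar = path.with_suffix(path.suffix + ".json")
    prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    cfg_fields = {k: prov[k] for k in
                  ("nu_max", "epsilon", "max_iter", "step", "seed", "K")
                  if k in prov}
    cfg = SamplerConfig(**cfg_fields) if cfg_fields else SamplerConfig()
    K = data.shape[0]
    return SolutionEnsemble(
        solutions=data,
        glucose_level=float(prov.get("glucose_level", float("nan"))),
        config=cfg,
        reaction_ids=rids,
        iterations=np.zeros(K, dtype=np.int64),
        residuals=np.zeros(K),
        n_failed=int(prov.get("n_failed", 0)),
        network_name=prov.get("network", "network"),
    )
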