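"""Rule-based model text export/import (BNGL dialect).

The network can be serialized as a BioNetGen-style model file: molecule
types with site states, seed species, and one bind/unbind plus one
catalysis rule per enzyme-substrate dimer.  Rules are written fully
grounded (every site state explicit), so re-parsing reconstructs exactly
the species list that generated them -- the round trip is lossless.

Dimer bonds connect the enzyme's catalytic site ``cat`` to the substrate's
tyrosine: ``LCK(cat!1,...).LCK(y394~U!1,...)``.  The dead-LCK variant adds
a competence site ``act~on~off``; dead-enzyme dimers catalyze with the
reserved zero-valued rate ``k_zero``.
"""

from __future__ import annotations

import re

from .network import Molecule, ReactionNetwork, Species, enumerate_reactions
from .params import RateParameterSet

ZERO_RATE = "k_zero"


def _mol_str(
    m: Molecule, with_act: bool, bond_site: str | None = None, enzyme_bond: bool = False
) -> str:
    fields = []
    fields.append("cat!1" if enzyme_bond else "cat")
    for site, state in (("y394", m.form[0]), ("y505", m.form[1])):
        tag = f"{site}~{state}"
        if bond_site is not None and site == bond_site.lower():
            tag += "!1"
        fields.append(tag)
    if with_act:
        fields.append("act~off" if m.dead else "act~on")
    return f"LCK({','.join(fields)})"


def _species_str(s: Species, with_act: bool) -> str:
    if s.kind == "free_lck":
        return _mol_str(s.substrate, with_act)
    if s.kind == "free_csk":
        return "CSK(cat)"
    if s.kind == "lck_dimer":
        return (
            _mol_str(s.enzyme, with_act, enzyme_bond=True)
            + "."
            + _mol_str(s.substrate, with_act, bond_site=s.site)
        )
    return "CSK(cat!1)." + _mol_str(s.substrate, with_act, bond_site=s.site)


def export_rules(
    network: ReactionNetwork, params: RateParameterSet | None = None
) -> str:
    """Serialize the network as rule-based model text.

    Parameter values default to 1.0 when no rate set is supplied (the text
    still carries the parameter names, which is all the structure needs).
    """
    with_act = network.include_dead
    lines = ["begin model", "begin parameters"]
    pnames = sorted(
        {r.param for r in network.reactions if r.param is not None},
        key=lambda n: n,
    )
    for name in pnames:
        value = params.value_of(name) if params is not None else 1.0
        lines.append(f"  {name} {value:.6e}")
    if any(r.param is None for r in network.reactions):
        lines.append(f"  {ZERO_RATE} 0.0")
    lines.append("end parameters")
    lines.append("begin molecule types")
    lck_sites = "cat,y394~U~P,y505~U~P"
    if with_act:
        lck_sites += ",act~on~off"
    lines.append(f"  LCK({lck_sites})")
    if any(s.kind == "free_csk" for s in network.species):
        lines.append("  CSK(cat)")
    lines.append("end molecule types")
    lines.append("begin seed species")
    for s in network.species:
        if s.kind in ("free_lck", "free_csk"):
            lines.append(f"  {_species_str(s, with_act)} 0.0")
    lines.append("end seed species")
    lines.append("begin reaction rules")
    for s in network.species:
        if s.kind == "lck_dimer":
            enz = _mol_str(s.enzyme, with_act)
            sub = _mol_str(s.substrate, with_act)
            dimer = _species_str(s, with_act)
            pair_off = _find_rate(network, s, "dissociation")
            pair_cat = _find_rate(network, s, "catalysis")
            lines.append(f"  {enz} + {sub} <-> {dimer} k_on, {pair_off}")
            prod = _mol_str(
                Molecule(_phospho_form(s), s.substrate.dead), with_act
            )
            lines.append(f"  {dimer} -> {enz} + {prod} {pair_cat or ZERO_RATE}")
        elif s.kind == "csk_dimer":
            sub = _mol_str(s.substrate, with_act)
            dimer = _species_str(s, with_act)
            pair_off = _find_rate(network, s, "dissociation")
            pair_cat = _find_rate(network, s, "catalysis")
            prod = _mol_str(
                Molecule(_phospho_form(s), s.substrate.dead), with_act
            )
            lines.append(f"  CSK(cat) + {sub} <-> {dimer} k_on_csk, {pair_off}")
            lines.append(f"  {dimer} -> CSK(cat) + {prod} {pair_cat or ZERO_RATE}")
    lines.append("end reaction rules")
    lines.append("end model")
    return "\n".join(lines) + "\n"


def _phospho_form(s: Species) -> str:
    from .params import phosphorylate

    return phosphorylate(s.substrate.form, s.site)


def _find_rate(network: ReactionNetwork, dimer: Species, kind: str) -> str | None:
    i = network.index[dimer.label]
    for r in network.reactions:
        if r.kind == kind and r.reactants == (i,):
            return r.param
    raise ValueError(f"no {kind} reaction found for {dimer.label}")


_MOL_RE = re.compile(r"(LCK|CSK)\(([^)]*)\)")


def _parse_molecule(text: str) -> tuple[str, Molecule | None, str | None, bool]:
    """Return (mol kind, Molecule or None for CSK, bonded site or None, enzyme bond)."""
    m = _MOL_RE.fullmatch(text.strip())
    if not m:
        raise ValueError(f"cannot parse molecule {text!r}")
    kind, body = m.group(1), m.group(2)
    if kind == "CSK":
        return "CSK", None, None, "cat!1" in body
    states = {"y394": "U", "y505": "U"}
    bond_site = None
    dead = False
    enzyme_bond = False
    for fld in body.split(","):
        fld = fld.strip()
        if fld.startswith("cat"):
            enzyme_bond = "!" in fld
        elif fld.startswith("act"):
            dead = fld.endswith("off")
        else:
            name, _, rest = fld.partition("~")
            states[name] = rest[0]
            if "!" in rest:
                bond_site = {"y394": "Y394", "y505": "Y505"}[name]
    form = states["y394"] + states["y505"]
    return "LCK", Molecule(form, dead), bond_site, enzyme_bond


def _parse_species(text: str) -> Species:
    parts = text.strip().split(".")
    if len(parts) == 1:
        kind, mol, _, _ = _parse_molecule(parts[0])
        if kind == "CSK":
            return Species("free_csk")
        return Species("free_lck", substrate=mol)
    if len(parts) != 2:
        raise ValueError(f"cannot parse species {text!r}")
    first, second = (_parse_molecule(p) for p in parts)
    # identify enzyme (bond on cat) and substrate (bond on a tyrosine)
    if first[0] == "CSK":
        _, sub, site, _ = second
        return Species("csk_dimer", substrate=sub, site=site)
    enz_entry = first if first[3] else second
    sub_entry = second if first[3] else first
    return Species(
        "lck_dimer",
        enzyme=enz_entry[1],
        substrate=sub_entry[1],
        site=sub_entry[2],
    )


def parse_rules(text: str) -> tuple[ReactionNetwork, dict[str, float]]:
    """Re-parse exported model text into a network and its parameter values.

    Species appear in the order seeds are declared followed by first
    appearance of each dimer in the rules, which matches the exporter's
    enumeration order.
    """
    params: dict[str, float] = {}
    species: list[Species] = []
    seen: set[str] = set()

    def add(sp: Species) -> None:
        if sp.label not in seen:
            seen.add(sp.label)
            species.append(sp)

    section = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("begin "):
            section = line[6:]
            continue
        if line.startswith("end "):
            section = None
            continue
        if section == "parameters":
            name, value = line.split()
            params[name] = float(value)
        elif section == "seed species":
            spec_text = line.rsplit(None, 1)[0]
            add(_parse_species(spec_text))
        elif section == "reaction rules":
            if "<->" in line:
                lhs, rhs = line.split("<->")
                dimer_text = rhs.rsplit(None, 2)[0]
                add(_parse_species(dimer_text))
    network = enumerate_reactions(species)
    return network, params
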