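"""Rule-based construction of the LCK/CSK reaction network.

Species are free LCK monomers (one of four phospho-forms, optionally a
catalytically dead variant), free CSK, and enzyme-substrate dimers.  A dimer
records which tyrosine of the substrate is occupied, so two dimers of the
same pair of molecules bound at different sites are distinct species.  Every
dimer supports three unidirectional mass-action reactions:

    association   E + S        -> E.S      rate k_on (k_on_csk for CSK)
    dissociation  E.S          -> E + S    rate k_off of the pair
    catalysis     E.S          -> E + P    rate k_cat of the pair

where P is the substrate with the bound site phosphorylated.  Catalytically
dead LCK shares all binding rates with active LCK but its dimers carry
k_cat = 0 (it binds and sequesters substrate without turning it over).

The fully active network has 23 species (4 free LCK + 1 free CSK + 16
LCK-LCK dimers + 2 CSK-LCK dimers) and 54 reactions.  The dead-LCK variant
used for the mixed active/dead membrane experiment has, under the default
policy (dead LCK participates both as substrate and as binding-competent
enzyme, no CSK binding because that experiment contains no CSK):
8 free LCK + 1 free CSK + 64 dimers = 73 species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import (
    CSK_PAIRS,
    FORMS,
    LCK_PAIRS,
    PAIR_INDEX,
    SUBSTRATE_SITES,
    RateParameterSet,
    phosphorylate,
)

DEAD_POLICIES = ("binder", "substrate_only")


@dataclass(frozen=True)
class Molecule:
    """An LCK molecule: phospho-form plus catalytic competence."""

    form: str
    dead: bool = False

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}")

    @property
    def label(self) -> str:
        return self.form + ("*" if self.dead else "")


@dataclass(frozen=True)
class Species:
    """A network species.

    kind is one of ``free_lck``, ``free_csk``, ``lck_dimer``, ``csk_dimer``.
    For dimers, ``substrate`` is the molecule whose ``site`` is occupied and
    ``enzyme`` the molecule (or CSK, enzyme=None) occupying it.
    """

    kind: str
    enzyme: Molecule | None = None
    substrate: Molecule | None = None
    site: str | None = None

    @property
    def label(self) -> str:
        if self.kind == "free_lck":
            return self.substrate.label
        if self.kind == "free_csk":
            return "CSK"
        if self.kind == "lck_dimer":
            return f"{self.enzyme.label}:{self.substrate.label}@{self.site}"
        return f"CSK:{self.substrate.label}@{self.site}"

    def lck_count(self) -> int:
        return {"free_lck": 1, "free_csk": 0, "lck_dimer": 2, "csk_dimer": 1}[
            self.kind
        ]

    def csk_count(self) -> int:
        return {"free_lck": 0, "free_csk": 1, "lck_dimer": 0, "csk_dimer": 1}[
            self.kind
        ]

    def molecules(self) -> tuple[Molecule, ...]:
        """The LCK molecules contained in this species."""
        if self.kind == "free_lck":
            return (self.substrate,)
        if self.kind == "free_csk":
            return ()
        if self.kind == "lck_dimer":
            return (self.enzyme, self.substrate)
        return (self.substrate,)


@dataclass(frozen=True)
class Reaction:
    """A unidirectional mass-action reaction referencing a named rate."""

    kind: str  # 'association' | 'dissociation' | 'catalysis'
    reactants: tuple[int, ...]
    products: tuple[int, ...]
    param: str | None  # flat parameter name; None means rate fixed to 0


def _substrate_molecules(dead: bool) -> list[tuple[Molecule, str]]:
    """(host molecule, site) pairs that can act as substrates."""
    return [(Molecule(host, dead), site) for site, host in SUBSTRATE_SITES]


def enumerate_species(
    include_dead: bool = False,
    dead_policy: str = "binder",
    csk_binding: bool = True,
) -> list[Species]:
    """Enumerate all species in a deterministic, stable order.

    Order: free active LCK (UU, PU, UP, PP), free dead LCK (same order, dead
    variant only), free CSK, LCK-LCK dimers (active-active in canonical pair
    order, then active enzyme/dead substrate, then -- under the ``binder``
    policy -- dead enzyme on active and dead substrates), CSK-LCK dimers
    (active hosts UU, PU, then dead hosts).

    With ``include_dead=False`` this yields exactly the 23 species of the
    fully active model.
    """
    if dead_policy not in DEAD_POLICIES:
        raise ValueError(f"dead_policy must be one of {DEAD_POLICIES}")
    species: list[Species] = []
    for form in FORMS:
        species.append(Species("free_lck", substrate=Molecule(form)))
    if include_dead:
        for form in FORMS:
            species.append(Species("free_lck", substrate=Molecule(form, dead=True)))
    species.append(Species("free_csk"))

    # enzyme-role molecules: active always; dead only under the binder policy
    enzyme_deads = [False] + (
        [True] if include_dead and dead_policy == "binder" else []
    )
    substrate_deads = [False] + ([True] if include_dead else [])
    for enz_dead in enzyme_deads:
        for sub_dead in substrate_deads:
            if not enz_dead and not sub_dead:
                # active-active block in canonical pair order
                for enz_form, site, host in LCK_PAIRS:
                    species.append(
                        Species(
                            "lck_dimer",
                            enzyme=Molecule(enz_form),
                            substrate=Molecule(host),
                            site=site,
                        )
                    )
            else:
                for enz_form, site, host in LCK_PAIRS:
                    species.append(
                        Species(
                            "lck_dimer",
                            enzyme=Molecule(enz_form, dead=enz_dead),
                            substrate=Molecule(host, dead=sub_dead),
                            site=site,
                        )
                    )
    if csk_binding:
        for sub_dead in substrate_deads:
            for site, host in CSK_PAIRS:
                species.append(
                    Species(
                        "csk_dimer",
                        substrate=Molecule(host, dead=sub_dead),
                        site=site,
                    )
                )
    return species


def count_pair_dimers(form_a: str, form_b: str) -> int:
    """Number of heterodimer species between one molecule of each given form.

    Mirrors the published schematic for a representative pair of LCK forms:
    one molecule of ``form_a`` and one of ``form_b`` (distinct forms), with
    either acting as enzyme on any free substrate site of the other.
    """
    if form_a == form_b:
        raise ValueError("pair must be two distinct forms")
    n = 0
    for site, host in SUBSTRATE_SITES:
        if host == form_a:
            n += 1  # form_b enzyme on form_a's site
        if host == form_b:
            n += 1
    return n


@dataclass
class ReactionNetwork:
    """Enumerated species + reactions, with stoichiometry and observables.

    ``conservation_groups`` maps a name to a per-species weight vector whose
    dot product with the state is conserved by every reaction.
    """

    species: list[Species]
    reactions: list[Reaction]
    include_dead: bool = False
    dead_policy: str = "binder"
    csk_binding: bool = True

    index: dict[str, int] = field(init=False, repr=False)
    stoichiometry: np.ndarray = field(init=False, repr=False)
    conservation_groups: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {s.label: i for i, s in enumerate(self.species)}
        if len(self.index) != len(self.species):
            raise ValueError("duplicate species labels")
        n, m = len(self.species), len(self.reactions)
        S = np.zeros((n, m))
        for j, rxn in enumerate(self.reactions):
            for i in rxn.reactants:
                S[i, j] -= 1.0
            for i in rxn.products:
                S[i, j] += 1.0
        self.stoichiometry = S
        groups = {
            "lck_total": np.array([s.lck_count() for s in self.species], float),
            "csk_total": np.array([s.csk_count() for s in self.species], float),
        }
        if self.include_dead:
            for name, dead in (("lck_active", False), ("lck_dead", True)):
                groups[name] = np.array(
                    [
                        sum(1 for m_ in s.molecules() if m_.dead == dead)
                        for s in self.species
                    ],
                    float,
                )
        self.conservation_groups = groups

    # -- observable count vectors ----------------------------------------------------

    def count_vector(self, predicate) -> np.ndarray:
        """Per-species count of contained LCK molecules satisfying a predicate."""
        return np.array(
            [sum(1 for m in s.molecules() if predicate(m)) for s in self.species],
            float,
        )

    def phospho_y394_counts(self) -> np.ndarray:
        return self.count_vector(lambda m: m.form[0] == "P")

    def phospho_y505_counts(self) -> np.ndarray:
        return self.count_vector(lambda m: m.form[1] == "P")

    def doubly_phospho_counts(self) -> np.ndarray:
        return self.count_vector(lambda m: m.form == "PP")

    def lck_counts(self) -> np.ndarray:
        return self.conservation_groups["lck_total"]

    def n_lck_dimers(self) -> int:
        return sum(1 for s in self.species if s.kind == "lck_dimer")

    def n_csk_dimers(self) -> int:
        return sum(1 for s in self.species if s.kind == "csk_dimer")


def enumerate_reactions(
    species: list[Species], params: RateParameterSet | None = None
) -> ReactionNetwork:
    """Derive the reaction list from an enumerated species list.

    ``params`` is accepted for interface symmetry but reactions only hold
    named parameter references; rates are resolved when building the RHS.
    """
    index = {s.label: i for i, s in enumerate(species)}
    include_dead = any(
        m.dead for s in species for m in s.molecules()
    )
    reactions: list[Reaction] = []
    for s in species:
        if s.kind == "lck_dimer":
            enz, sub, site = s.enzyme, s.substrate, s.site
            pair = PAIR_INDEX[(enz.form, site, sub.form)]
            i_dimer = index[s.label]
            i_enz = index[Species("free_lck", substrate=enz).label]
            i_sub = index[Species("free_lck", substrate=sub).label]
            product = Molecule(phosphorylate(sub.form, site), sub.dead)
            i_prod = index[Species("free_lck", substrate=product).label]
            reactions.append(
                Reaction("association", (i_enz, i_sub), (i_dimer,), "k_on")
            )
            reactions.append(
                Reaction("dissociation", (i_dimer,), (i_enz, i_sub), f"k_off_{pair}")
            )
            # dead enzymes bind with identical kinetics but never catalyze
            cat_param = None if enz.dead else f"k_cat_{pair}"
            reactions.append(
                Reaction("catalysis", (i_dimer,), (i_enz, i_prod), cat_param)
            )
        elif s.kind == "csk_dimer":
            sub, site = s.substrate, s.site
            tag = "uu" if sub.form == "UU" else "pu"
            i_dimer = index[s.label]
            i_csk = index["CSK"]
            i_sub = index[Species("free_lck", substrate=sub).label]
            product = Molecule(phosphorylate(sub.form, site), sub.dead)
            i_prod = index[Species("free_lck", substrate=product).label]
            reactions.append(
                Reaction("association", (i_csk, i_sub), (i_dimer,), "k_on_csk")
            )
            reactions.append(
                Reaction("dissociation", (i_dimer,), (i_csk, i_sub), f"k_off_csk_{tag}")
            )
            reactions.append(
                Reaction("catalysis", (i_dimer,), (i_csk, i_prod), f"k_cat_csk_{tag}")
            )
        elif s.kind not in ("free_lck", "free_csk"):
            raise ValueError(f"unknown species kind {s.kind!r}")
    dead_policy = "binder" if any(
        s.kind == "lck_dimer" and s.enzyme.dead for s in species
    ) or not include_dead else "substrate_only"
    csk_binding = any(s.kind == "csk_dimer" for s in species)
    return ReactionNetwork(
        list(species),
        reactions,
        include_dead=include_dead,
        dead_policy=dead_policy,
        csk_binding=csk_binding,
    )


def build_network(
    include_dead: bool = False,
    dead_policy: str = "binder",
    csk_binding: bool = True,
) -> ReactionNetwork:
    """Enumerate species and reactions in one step."""
    return enumerate_reactions(
        enumerate_species(include_dead, dead_policy, csk_binding)
    )


def build_validation_network() -> ReactionNetwork:
    """The 73-species mixed active/dead model for the no-CSK validation setup."""
    return build_network(include_dead=True, dead_policy="binder", csk_binding=False)


class MassActionRHS:
    """Time-derivative evaluator ``(t, y) -> dy/dt`` with analytic Jacobian.

    Densities may go slightly negative inside the integrator; the rate law is
    evaluated as-is (bilinear), so derivatives stay finite for any state.
    """

    def __init__(self, network: ReactionNetwork, params: RateParameterSet):
        self.network = network
        self.params = params
        m = len(network.reactions)
        k = np.zeros(m)
        ra = np.zeros(m, dtype=int)
        rb = np.full(m, -1, dtype=int)
        for j, rxn in enumerate(network.reactions):
            k[j] = 0.0 if rxn.param is None else params.value_of(rxn.param)
            ra[j] = rxn.reactants[0]
            if len(rxn.reactants) == 2:
                rb[j] = rxn.reactants[1]
            elif len(rxn.reactants) != 1:
                raise ValueError("only uni/bimolecular reactions supported")
        self.k, self.ra, self.rb = k, ra, rb
        self.bimol = rb >= 0
        self.S = network.stoichiometry

    def rates(self, y: np.ndarray) -> np.ndarray:
        f = y[self.ra].astype(float).copy()
        f[self.bimol] *= y[self.rb[self.bimol]]
        return self.k * f

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.S @ self.rates(np.asarray(y))

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        m, n = len(self.k), self.S.shape[0]
        D = np.zeros((m, n))
        rows = np.arange(m)
        # d(rate)/d(first reactant)
        partial_a = self.k.copy()
        partial_a[self.bimol] *= y[self.rb[self.bimol]]
        D[rows, self.ra] += partial_a
        bi = np.where(self.bimol)[0]
        D[bi, self.rb[bi]] += self.k[bi] * y[self.ra[bi]]
        return self.S @ D


def build_rhs(network: ReactionNetwork, params: RateParameterSet) -> MassActionRHS:
    """Bind a parameter set to a network, yielding the ODE right-hand side."""
    return MassActionRHS(network, params)
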