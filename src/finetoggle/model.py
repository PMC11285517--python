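"""Reaction-network definition of the fine-grained two-gene toggle switch.

Two genes mutually repress each other: the protein product of each gene
oligomerizes, and the oligomer of order ``n`` (monomer to tetramer) binds
and inactivates the opposing promoter.  The model explicitly tracks
promoters (free and bound), mRNA, monomer protein and every oligomer up to
order ``n``, with elementary mass-action kinetics throughout.  Cellular
energy status enters as a dimensionless ATP multiplier that linearly
scales the gene-expression rates.

The module compiles a chosen variant into a :class:`ModelSpec` holding the
explicit reaction list plus flat arrays consumed by the deterministic and
stochastic engines.  The same compiled network drives both the mass-action
ODE right-hand side and the stochastic propensity functions, so the two
pictures are guaranteed to describe the same chemistry.

Conventions
-----------
* Unit volume: deterministic concentrations and stochastic copy numbers
  share units (molecules).
* The constitutive transcription factor z_i is a fixed constant 1, folded
  into the transcription rate; it is not a dynamic species.
* Deterministic mass-action flux of a homodimerization step ``2P -> PP``
  is ``ca1 * p**2`` (contributing ``-2*ca1*p**2`` to the monomer and
  ``+ca1*p**2`` to the dimer); the matching stochastic propensity is
  ``ca1 * x * (x - 1)`` so that the large-count drift of the jump process
  reproduces the ODE coefficients at unit volume.
* Higher oligomerization steps (``P + PP -> PPP`` etc.) are ordinary
  hetero-bimolecular reactions with flux ``k * x * y``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from typing import Dict, List, Mapping, Tuple

import numpy as np

__all__ = [
    "RATE_NAMES",
    "ATP_MODES",
    "RateSet",
    "Reaction",
    "ModelSpec",
    "apply_atp_scaling",
    "build_model",
]

#: The nine kinetic constants of the network, in canonical order.
RATE_NAMES: Tuple[str, ...] = (
    "lambda2",  # transcription (s^-1)
    "lambda3",  # translation (s^-1)
    "ca1",      # oligomer association (s^-1 per molecule)
    "cd1",      # oligomer dissociation (s^-1)
    "ca2",      # regulator-promoter association (s^-1 per molecule)
    "cd2",      # regulator-promoter dissociation (s^-1)
    "gamma2",   # mRNA degradation (s^-1)
    "gamma3",   # monomer protein degradation (s^-1)
    "gamma4",   # oligomer degradation (s^-1)
)

#: Supported modes of ATP coupling to gene expression.
ATP_MODES: Tuple[str, ...] = (
    "transcription",
    "translation",
    "both",
    "both_plus_degradation",
)


@dataclass(frozen=True)
class RateSet:
    """Kinetic constants of the toggle switch plus the ATP coupling.

    Defaults are the literature-derived parameterization of the two-gene
    switch (all in s^-1; association rates per molecule at unit volume).
    ``atp`` is a dimensionless multiplier applied linearly to the rates
    selected by ``atp_mode`` — a linear approximation to the centre of the
    sigmoidal dependence of expression rates on ATP concentration.
    """

    lambda2: float = 0.0067
    lambda3: float = 0.0474
    ca1: float = 0.0023
    cd1: float = 0.00023
    ca2: float = 0.1038
    cd2: float = 1.04
    gamma2: float = 0.00023
    gamma3: float = 0.00077
    gamma4: float = 0.00058
    atp: float = 1.0
    atp_mode: str = "both"

    def __post_init__(self) -> None:
        for name in RATE_NAMES + ("atp",):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"rate constant {name!r} must be >= 0, got {value!r}")
        if self.atp_mode not in ATP_MODES:
            raise ValueError(
                f"unknown atp_mode {self.atp_mode!r}; expected one of {ATP_MODES}"
            )

    def replace(self, **changes: object) -> "RateSet":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def scaled_by(self, factors: Mapping[str, float]) -> "RateSet":
        """Return a copy with named rates multiplied by scale factors.

        Factors are relative to the current values, which makes
        order-of-magnitude sweeps around the default parameterization a
        one-liner: ``RateSet().scaled_by({"gamma3": 10})``.
        """
        changes = {}
        for name, factor in factors.items():
            if name not in RATE_NAMES:
                raise KeyError(f"unknown rate name {name!r}")
            if factor <= 0:
                raise ValueError(f"scale factor for {name!r} must be > 0")
            changes[name] = getattr(self, name) * factor
        return self.replace(**changes)

    def as_dict(self) -> Dict[str, object]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def apply_atp_scaling(rates: RateSet) -> RateSet:
    """Return the effective rates after applying the ATP multiplier.

    ``both`` scales transcription and translation (lambda2, lambda3);
    ``transcription`` / ``translation`` scale only the named process;
    ``both_plus_degradation`` additionally scales monomer protein
    degradation gamma3, modelling ATP-dependent proteolysis.  The returned
    RateSet carries ``atp=1`` so that scaling is idempotent.
    """
    a = rates.atp
    changes: Dict[str, object] = {"atp": 1.0}
    if rates.atp_mode in ("transcription", "both", "both_plus_degradation"):
        changes["lambda2"] = rates.lambda2 * a
    if rates.atp_mode in ("translation", "both", "both_plus_degradation"):
        changes["lambda3"] = rates.lambda3 * a
    if rates.atp_mode == "both_plus_degradation":
        changes["gamma3"] = rates.gamma3 * a
    return rates.replace(**changes)


@dataclass(frozen=True)
class Reaction:
    """One directed reaction: reactants -> products at a named rate."""

    reactants: Tuple[Tuple[str, int], ...]
    products: Tuple[Tuple[str, int], ...]
    rate_name: str
    rate: float

    def __post_init__(self) -> None:
        for side in (self.reactants, self.products):
            for species, count in side:
                if count < 0 or count != int(count):
                    raise ValueError(
                        f"stoichiometry of {species!r} must be a non-negative integer"
                    )

    def __str__(self) -> str:
        def side(pairs: Tuple[Tuple[str, int], ...]) -> str:
            if not pairs:
                return "0"
            return " + ".join(f"{c if c > 1 else ''}{s}" for s, c in pairs)

        return f"{side(self.reactants)} -> {side(self.products)}  [{self.rate_name}]"


def _oligomer_name(order: int, gene: int) -> str:
    return "p" * order + str(gene)


def _bound_promoter_name(order: int, regulator_gene: int) -> str:
    # propp1 = promoter of gene 2 with the dimer of gene 1 bound, etc.
    return "pro" + "p" * order + str(regulator_gene)


@dataclass(frozen=True)
class ModelSpec:
    """A compiled toggle-switch variant.

    Holds the species list, the directed reaction list and flat arrays
    (stoichiometry matrix, reactant index pairs, rate vector) used by the
    numerical engines.  ``rates`` are the raw inputs, ``effective_rates``
    the post-ATP-scaling values actually compiled into the reactions.
    """

    oligomer_order: int
    rates: RateSet
    effective_rates: RateSet
    species: Tuple[str, ...]
    reactions: Tuple[Reaction, ...]
    z: Tuple[float, float] = (1.0, 1.0)
    # compiled arrays (reactant species index pairs with -1 = empty slot,
    # net stoichiometry changes, effective rate constants)
    reactant_pairs: np.ndarray = field(repr=False, default=None)
    stoich: np.ndarray = field(repr=False, default=None)
    rate_vector: np.ndarray = field(repr=False, default=None)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    # ------------------------------------------------------------------
    # state helpers
    # ------------------------------------------------------------------
    def initial_state(
        self,
        p1: float = 0.0,
        p2: float = 0.0,
        rna1: float = 0.0,
        rna2: float = 0.0,
    ) -> np.ndarray:
        """Standard initial condition: one free promoter per gene, all
        other species zero except the optional protein/mRNA overrides."""
        y = np.zeros(self.n_species)
        y[self.species_index("pro1")] = 1.0
        y[self.species_index("pro2")] = 1.0
        y[self.species_index("p1")] = p1
        y[self.species_index("p2")] = p2
        y[self.species_index("rna1")] = rna1
        y[self.species_index("rna2")] = rna2
        return y

    def promoter_totals(self, state: np.ndarray) -> Tuple[float, float]:
        """(free + bound) promoter totals for gene 1 and gene 2.

        Promoter 1 is either free (pro1) or bound by the regulator of
        gene 2, so its conserved total pairs pro1 with the bound complex
        carrying index 2 — and vice versa.
        """
        n = self.oligomer_order
        b1 = self.species_index(_bound_promoter_name(n, 2))
        b2 = self.species_index(_bound_promoter_name(n, 1))
        i1 = self.species_index("pro1")
        i2 = self.species_index("pro2")
        state = np.asarray(state)
        return state[..., i1] + state[..., b1], state[..., i2] + state[..., b2]

    def swap_permutation(self) -> np.ndarray:
        """Index permutation exchanging gene labels 1 <-> 2."""
        perm = np.empty(self.n_species, dtype=np.int64)
        for i, name in enumerate(self.species):
            other = name[:-1] + ("2" if name.endswith("1") else "1")
            perm[i] = self.species_index(other)
        return perm

    # ------------------------------------------------------------------
    # dynamics
    # ------------------------------------------------------------------
    def ode_rhs(self, state: np.ndarray) -> np.ndarray:
        """Mass-action time derivative of ``state`` (molecules / s)."""
        state = np.asarray(state, dtype=float)
        if state.shape != (self.n_species,):
            raise ValueError(
                f"state has shape {state.shape}, expected ({self.n_species},)"
            )
        from ._kernels import mass_action_rhs

        return mass_action_rhs(state, self.reactant_pairs, self.stoich, self.rate_vector)

    def propensities(self, counts: np.ndarray) -> np.ndarray:
        """Stochastic propensity of every reaction channel at ``counts``."""
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (self.n_species,):
            raise ValueError(
                f"counts has shape {counts.shape}, expected ({self.n_species},)"
            )
        if (counts < 0).any():
            raise ValueError("copy numbers must be non-negative")
        from ._kernels import propensity_vector

        return propensity_vector(counts, self.reactant_pairs, self.stoich, self.rate_vector)

    # ------------------------------------------------------------------
    # export
    # ------------------------------------------------------------------
    def to_json(self) -> str:
        """Machine-readable dump of the compiled reaction network."""
        payload = {
            "oligomer_order": self.oligomer_order,
            "species": list(self.species),
            "rates": self.rates.as_dict(),
            "effective_rates": self.effective_rates.as_dict(),
            "reactions": [
                {
                    "reactants": {s: c for s, c in r.reactants},
                    "products": {s: c for s, c in r.products},
                    "rate_name": r.rate_name,
                    "rate": r.rate,
                }
                for r in self.reactions
            ],
        }
        return json.dumps(payload, indent=2)


def _species_list(order: int) -> List[str]:
    species = ["pro1", "pro2"]
    species += [_bound_promoter_name(order, 1), _bound_promoter_name(order, 2)]
    species += ["rna1", "rna2", "p1", "p2"]
    for m in range(2, order + 1):
        species += [_oligomer_name(m, 1), _oligomer_name(m, 2)]
    return species


def build_model(oligomer_order: int = 2, rates: RateSet | None = None) -> ModelSpec:
    """Compile the toggle-switch variant with a given regulator order.

    ``oligomer_order`` selects the oligomer that represses the opposing
    promoter: 1 monomer, 2 dimer (default), 3 trimer, 4 tetramer.  The
    assembly chain runs stepwise (P+P <-> PP, P+PP <-> PPP, ...) and only
    the top oligomer binds the promoter.  ATP scaling per ``rates.atp`` /
    ``rates.atp_mode`` is applied before compilation.
    """
    if oligomer_order not in (1, 2, 3, 4):
        raise ValueError(f"oligomer_order must be in 1..4, got {oligomer_order!r}")
    rates = rates if rates is not None else RateSet()
    eff = apply_atp_scaling(rates)

    species = _species_list(oligomer_order)
    z = (1.0, 1.0)
    reactions: List[Reaction] = []

    def add(reactants, products, rate_name, rate):
        reactions.append(
            Reaction(tuple(reactants), tuple(products), rate_name, float(rate))
        )

    for i, j in ((1, 2), (2, 1)):
        pro_i, rna_i, p_i = f"pro{i}", f"rna{i}", f"p{i}"
        top_i = _oligomer_name(oligomer_order, i)
        bound_i = _bound_promoter_name(oligomer_order, i)
        pro_j = f"pro{j}"

        # transcription from the active promoter (z_i constitutive, = 1)
        add([(pro_i, 1)], [(pro_i, 1), (rna_i, 1)], "lambda2", eff.lambda2 * z[i - 1])
        # translation
        add([(rna_i, 1)], [(rna_i, 1), (p_i, 1)], "lambda3", eff.lambda3)
        # stepwise oligomer assembly / disassembly
        for m in range(2, oligomer_order + 1):
            lower = p_i if m == 2 else _oligomer_name(m - 1, i)
            upper = _oligomer_name(m, i)
            if m == 2:
                add([(p_i, 2)], [(upper, 1)], "ca1", eff.ca1)
            else:
                add([(p_i, 1), (lower, 1)], [(upper, 1)], "ca1", eff.ca1)
            if m == 2:
                add([(upper, 1)], [(p_i, 2)], "cd1", eff.cd1)
            else:
                add([(upper, 1)], [(p_i, 1), (lower, 1)], "cd1", eff.cd1)
        # regulator binding / unbinding to the opposing promoter
        add([(pro_j, 1), (top_i, 1)], [(bound_i, 1)], "ca2", eff.ca2)
        add([(bound_i, 1)], [(pro_j, 1), (top_i, 1)], "cd2", eff.cd2)
        # degradation of free species
        add([(rna_i, 1)], [], "gamma2", eff.gamma2)
        add([(p_i, 1)], [], "gamma3", eff.gamma3)
        for m in range(2, oligomer_order + 1):
            add([(_oligomer_name(m, i), 1)], [], "gamma4", eff.gamma4)

    index = {s: k for k, s in enumerate(species)}
    n_r, n_s = len(reactions), len(species)
    pairs = np.full((n_r, 2), -1, dtype=np.int64)
    stoich = np.zeros((n_r, n_s), dtype=np.float64)
    k_vec = np.empty(n_r, dtype=np.float64)
    for r_idx, r in enumerate(reactions):
        slot = 0
        for s, c in r.reactants:
            if s not in index:
                raise ValueError(f"reaction references unknown species {s!r}")
            for _ in range(c):
                pairs[r_idx, slot] = index[s]
                slot += 1
            stoich[r_idx, index[s]] -= c
        for s, c in r.products:
            stoich[r_idx, index[s]] += c
        k_vec[r_idx] = r.rate

    return ModelSpec(
        oligomer_order=oligomer_order,
        rates=rates,
        effective_rates=eff,
        species=tuple(species),
        reactions=tuple(reactions),
        z=z,
        reactant_pairs=pairs,
        stoich=stoich,
        rate_vector=k_vec,
    )
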