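"""Explicit species/reaction representations of the protofibril kinetic models.

Four mass-action reaction networks describe Aβ42 aggregation at the
molecular level:

* the **simple model** — monomer addition to seeded protofibrils
  (``A₁ + F_{i−1} ⇌ F_i``), valid in the first minutes of elongation;
* the **complete model** — the simple model plus lateral association of
  standard protofibrils with elongated ones (``F + F_{m−1} ⇌ F_{m+1599}``);
* the **lateral model** — a stand-alone, monomer-free network of
  protofibril–protofibril association bounded at a 10-fold size increase,
  matched against dynamic-light-scattering data;
* the **full pathway model** — the generic nucleation-dependent
  polymerization chain ``A_i + A₁ ⇌ A_{i+1}`` with a slow pre-nucleation and
  a fast post-nucleation regime, used for lag-time comparisons.

A standard protofibril ``F`` is idealized as a 1600-mer of ~64 nm; elongation
saturates at an average length of 170 nm, which caps the number of monomer
additions at ``round(1600·170/64 − 1600) = 2650``.

All concentrations are mM and all times hours, matching the units of the
printed rate constants (h⁻¹·mM⁻¹, h⁻¹); micromolar inputs are converted at
the package boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ModelConfig",
    "KineticParams",
    "Reaction",
    "ModelSpec",
    "derive_elongation_capacity",
    "build_simple_model",
    "build_complete_model",
    "build_lateral_model",
    "build_full_pathway_model",
    "write_reaction_table",
    "read_reaction_table",
    "SIZE_SCALINGS",
]

UM_PER_MM = 1000.0


def uM_to_mM(value_uM: float) -> float:
    """Convert a micromolar concentration to millimolar."""
    return value_uM / UM_PER_MM


def _inv_cbrt(i: float) -> float:
    return float(i) ** (-1.0 / 3.0)


def _smoluchowski(i: float) -> float:
    # Encounter-rate kernel for a monomer meeting an i-mer, normalized to 1
    # at i = 1: (D_1 + D_i)(r_1 + r_i) with D ∝ i^(-1/3), r ∝ i^(1/3).
    x = float(i) ** (1.0 / 3.0)
    return (1.0 + 1.0 / x) * (1.0 + x) / 4.0


#: Size-dependence g(i) of the forward rate constant for monomer addition to
#: an i-mer in the full pathway model; g(1) = 1 for every choice.
SIZE_SCALINGS: dict[str, Callable[[float], float]] = {
    "inv_cbrt": _inv_cbrt,
    "smoluchowski": _smoluchowski,
}


def derive_elongation_capacity(
    base_mers: float, base_len_nm: float, saturation_len_nm: float
) -> int:
    """Number of monomers a protofibril can add before elongation saturates.

    A ``base_mers``-mer protofibril of length ``base_len_nm`` grows until its
    average length reaches ``saturation_len_nm``; at a constant mass per unit
    length it then holds ``base_mers · saturation_len/base_len`` monomers, so
    the addable count is the excess over ``base_mers``.

    >>> derive_elongation_capacity(1600, 64, 170)
    2650
    """
    if base_mers <= 0 or base_len_nm <= 0 or saturation_len_nm <= 0:
        raise ValueError("all elongation-capacity arguments must be positive")
    return int(round(base_mers * saturation_len_nm / base_len_nm - base_mers))


@dataclass(frozen=True)
class ModelConfig:
    """Structural constants shared by the model builders.

    Parameters
    ----------
    base_protofibril_mers
        Monomer count of a standard protofibril F (default 1600).
    base_protofibril_len_nm, saturation_len_nm
        Average protofibril length before elongation and at saturation;
        together with ``base_protofibril_mers`` they fix ``max_elongation``.
    max_elongation
        Number of monomer-addition steps. Derived from the lengths when not
        given explicitly; small explicit values are useful for testing.
    lateral_coupling_count
        Number of lateral reactions F + F_{m−1} ⇌ F_{m+1599} in the complete
        model (default 1051, so the last one produces F_2650).
    lateral_fold_cap
        Maximum fold increase in protofibril size in the stand-alone lateral
        model (default 10, i.e. species up to F_14400).
    self_reaction_factor
        Stoichiometric consumption of the shared reactant in self-reactions
        (F + F, G_i + G_i). 2 conserves monomer-equivalent mass exactly
        (default); 1 reproduces a plain single-count of the flux.
    size_scaling
        Key into :data:`SIZE_SCALINGS` for the full pathway model.
    """

    base_protofibril_mers: int = 1600
    base_protofibril_len_nm: float = 64.0
    saturation_len_nm: float = 170.0
    max_elongation: int | None = None
    lateral_coupling_count: int | None = None
    lateral_fold_cap: int = 10
    self_reaction_factor: int = 2
    size_scaling: str = "inv_cbrt"

    def __post_init__(self) -> None:
        if self.base_protofibril_mers <= 0:
            raise ValueError("base_protofibril_mers must be positive")
        if self.max_elongation is None:
            object.__setattr__(
                self,
                "max_elongation",
                derive_elongation_capacity(
                    self.base_protofibril_mers,
                    self.base_protofibril_len_nm,
                    self.saturation_len_nm,
                ),
            )
        if self.max_elongation < 1:
            raise ValueError("max_elongation must be at least 1")
        if self.lateral_coupling_count is None:
            object.__setattr__(
                self,
                "lateral_coupling_count",
                max(self.max_elongation - (self.base_protofibril_mers - 1), 0),
            )
        offset = self.base_protofibril_mers - 1
        if self.lateral_coupling_count > max(self.max_elongation - offset, 0):
            raise ValueError(
                "lateral_coupling_count inconsistent with max_elongation: "
                f"largest lateral product F_{self.lateral_coupling_count + offset} "
                f"exceeds F_{self.max_elongation}"
            )
        if self.lateral_fold_cap < 2:
            raise ValueError("lateral_fold_cap must be >= 2")
        if self.self_reaction_factor not in (1, 2):
            raise ValueError("self_reaction_factor must be 1 or 2")
        if self.size_scaling not in SIZE_SCALINGS:
            raise ValueError(
                f"unknown size_scaling {self.size_scaling!r}; "
                f"choose from {sorted(SIZE_SCALINGS)}"
            )


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and observable mapping constants.

    Second-order constants are h⁻¹·mM⁻¹, first-order constants h⁻¹. The
    defaults are the best-fit elongation/lateral values (k_fb,1 = 9.0×10³,
    k_fb− = 4.5×10², k_la = 9.0×10⁻¹, k_la− = 6.0×10⁻³) together with the
    literature nucleation constants for the insulin-derived pathway model
    (k_nu,1 = 1.38, k_nu− = 1.01×10⁻³, post-nucleation k_fb,1 = 1.37×10⁴,
    k_fb− = 3.02×10² — set those explicitly when reproducing that model).
    ``b_tht`` and ``b_dls`` map weighted concentration sums (mM) to
    instrument signal units, one constant per modality.
    """

    k_fb1: float = 9.0e3
    k_fb_rev: float = 4.5e2
    k_la: float = 9.0e-1
    k_la_rev: float = 6.0e-3
    k_nu1: float = 1.38
    k_nu_rev: float = 1.01e-3
    b_tht: float = 2000.0
    b_dls: float = 6500.0

    def __post_init__(self) -> None:
        for name in ("k_fb1", "k_fb_rev", "k_la", "k_la_rev", "k_nu1", "k_nu_rev"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.b_tht <= 0 or self.b_dls <= 0:
            raise ValueError("mapping constants must be positive")

    def rate(self, name: str) -> float:
        return float(getattr(self, name))

    def b_map(self, modality: str) -> float:
        if modality == "ThT":
            return self.b_tht
        if modality == "DLS":
            return self.b_dls
        raise ValueError(f"unknown modality {modality!r}")


@dataclass(frozen=True)
class Reaction:
    """One reversible mass-action reaction X + Y ⇌ Z.

    ``reactants`` holds one index (self-reaction, forward flux k·[X]²) or
    two; ``multiplicity`` is the consumption count per reactant per event.
    ``forward``/``reverse`` name the rate constants in
    :class:`KineticParams`; the forward constant is multiplied by
    ``forward_scale`` (the size scaling g(i) in the pathway model, else 1).
    """

    reactants: tuple[int, ...]
    product: int
    forward: str
    reverse: str
    multiplicity: tuple[int, ...]
    forward_scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.reactants) not in (1, 2):
            raise ValueError("a reaction has one or two reactant indices")
        if len(self.multiplicity) != len(self.reactants):
            raise ValueError("multiplicity must match reactants")


@dataclass(frozen=True)
class ModelSpec:
    """A fully enumerated reaction network.

    ``masses`` are monomer-equivalent masses per species (A₁ = 1, F = 1600,
    F_i = 1600 + i, G_i = (i+1)·1600, A_i = i); every reaction's reactant
    masses sum exactly to its product mass.
    """

    kind: str  # "simple" | "complete" | "lateral" | "pathway"
    species: tuple[str, ...]
    masses: np.ndarray
    reactions: tuple[Reaction, ...]
    config: ModelConfig

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("species labels must be unique")
        if len(self.masses) != len(self.species):
            raise ValueError("masses must match species")
        n = len(self.species)
        for rx in self.reactions:
            if not all(0 <= i < n for i in rx.reactants) or not 0 <= rx.product < n:
                raise ValueError("reaction index out of range")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def index(self, label: str) -> int:
        return self.species.index(label)

    def reaction_mass_balance(self, rx: Reaction) -> float:
        """Reactant mass sum minus product mass (0 for a balanced reaction)."""
        m = self.masses
        total = sum(m[i] * k for i, k in zip(rx.reactants, rx.multiplicity))
        # a self-reaction with multiplicity 1 is intentionally unbalanced
        if len(rx.reactants) == 1 and rx.multiplicity[0] == 1:
            total = 2 * m[rx.reactants[0]]
        return float(total - m[rx.product])

    def initial_state(
        self, monomer_mM: float = 0.0, protofibril_mM: float = 0.0
    ) -> np.ndarray:
        """State vector with all mass in monomer and/or the seed species.

        Monomer goes to A₁; protofibril to F (elongation models), G_0
        (lateral model). The pathway model accepts monomer only.
        """
        c = np.zeros(self.n_species)
        if monomer_mM:
            if self.kind == "lateral":
                raise ValueError("the lateral model contains no monomers")
            c[self.index("A1")] = monomer_mM
        if protofibril_mM:
            if self.kind == "pathway":
                raise ValueError("the pathway model starts from monomer only")
            seed = "G0" if self.kind == "lateral" else "F"
            c[self.index(seed)] = protofibril_mM
        return c


def build_simple_model(config: ModelConfig | None = None) -> ModelSpec:
    """Monomer-addition network A₁ + F_{i−1} ⇌ F_i, i = 1 … max_elongation.

    Species are ordered [A₁, F, F₁, …, F_max]; with the default config this
    gives 2652 species and 2650 reactions.
    """
    config = config or ModelConfig()
    n = config.max_elongation
    base = config.base_protofibril_mers
    species = ["A1", "F"] + [f"F{i}" for i in range(1, n + 1)]
    masses = np.array([1, base] + [base + i for i in range(1, n + 1)], dtype=float)
    reactions = tuple(
        Reaction(
            reactants=(0, 1 + (i - 1)),  # A1 and F_{i-1} (F ≡ F_0 at index 1)
            product=1 + i,
            forward="k_fb1",
            reverse="k_fb_rev",
            multiplicity=(1, 1),
        )
        for i in range(1, n + 1)
    )
    return ModelSpec("simple", tuple(species), masses, reactions, config)


def build_complete_model(config: ModelConfig | None = None) -> ModelSpec:
    """Simple model plus lateral association F + F_{m−1} ⇌ F_{m+1599}.

    The species list is identical to the simple model's. Lateral reactions
    run m = 1 … lateral_coupling_count (default 1051), so the largest
    protofibril F_2650 is produced both by the last monomer addition and by
    the last lateral reaction. The m = 1 reaction is the self-association
    F + F ⇌ F_1600.
    """
    config = config or ModelConfig()
    simple = build_simple_model(config)
    offset = config.base_protofibril_mers - 1  # product index shift: m -> m+1599
    lateral = []
    for m in range(1, config.lateral_coupling_count + 1):
        product = 1 + (m + offset)
        if m == 1:
            rx = Reaction(
                reactants=(1,),
                product=product,
                forward="k_la",
                reverse="k_la_rev",
                multiplicity=(config.self_reaction_factor,),
            )
        else:
            rx = Reaction(
                reactants=(1, 1 + (m - 1)),
                product=product,
                forward="k_la",
                reverse="k_la_rev",
                multiplicity=(1, 1),
            )
        lateral.append(rx)
    return ModelSpec(
        "complete",
        simple.species,
        simple.masses,
        simple.reactions + tuple(lateral),
        config,
    )


def build_lateral_model(config: ModelConfig | None = None) -> ModelSpec:
    """Stand-alone lateral-association network bounded at a 10-fold size cap.

    Species G_k represent protofibrils of (k+1)·1600 monomers (G_0 ≡ F,
    G_9 ≡ F_14400); reactions G_i + G_j ⇌ G_{i+j+1} for i = 0…4,
    j = i…8−i (25 reactions at the default cap). No monomers take part.
    """
    config = config or ModelConfig()
    cap = config.lateral_fold_cap
    base = config.base_protofibril_mers
    species = tuple(f"G{k}" for k in range(cap))
    masses = np.array([(k + 1) * base for k in range(cap)], dtype=float)
    top = cap - 1
    reactions = []
    for i in range(0, (top - 1) // 2 + 1):
        for j in range(i, top - 1 - i + 1):
            if i == j:
                rx = Reaction(
                    reactants=(i,),
                    product=i + j + 1,
                    forward="k_la",
                    reverse="k_la_rev",
                    multiplicity=(config.self_reaction_factor,),
                )
            else:
                rx = Reaction(
                    reactants=(i, j),
                    product=i + j + 1,
                    forward="k_la",
                    reverse="k_la_rev",
                    multiplicity=(1, 1),
                )
            reactions.append(rx)
    return ModelSpec("lateral", species, masses, tuple(reactions), config)


def build_full_pathway_model(
    n: int, max_size: int = 100, config: ModelConfig | None = None
) -> ModelSpec:
    """Nucleation-dependent polymerization chain A_i + A₁ ⇌ A_{i+1}.

    Monomer addition below the nucleation mass ``n`` uses the slow
    pre-nucleation constants (k_nu,1·g(i), k_nu−); from ``i ≥ n`` the fast
    post-nucleation constants (k_fb,1·g(i), k_fb−) apply. g is the
    configured size scaling with g(1) = 1; A_max_size is the absorbing top
    size.
    """
    config = config or ModelConfig()
    if not 2 <= n < max_size:
        raise ValueError("need 2 <= n < max_size")
    g = SIZE_SCALINGS[config.size_scaling]
    species = tuple("A1" if i == 1 else f"A{i}" for i in range(1, max_size + 1))
    masses = np.arange(1, max_size + 1, dtype=float)
    reactions = []
    for i in range(1, max_size):
        pre = i < n
        if i == 1:
            rx = Reaction(
                reactants=(0,),
                product=1,
                forward="k_nu1" if pre else "k_fb1",
                reverse="k_nu_rev" if pre else "k_fb_rev",
                multiplicity=(config.self_reaction_factor,),
                forward_scale=g(1),
            )
        else:
            rx = Reaction(
                reactants=(i - 1, 0),
                product=i,
                forward="k_nu1" if pre else "k_fb1",
                reverse="k_nu_rev" if pre else "k_fb_rev",
                multiplicity=(1, 1),
                forward_scale=g(i),
            )
        reactions.append(rx)
    return ModelSpec("pathway", species, masses, tuple(reactions), config)


def write_reaction_table(model: ModelSpec, path: str | Path) -> None:
    """Serialize the reaction list as a TSV table for inspection."""
    lines = ["reactants\tproduct\tforward\treverse\tmultiplicity\tforward_scale"]
    for rx in model.reactions:
        lines.append(
            "{}\t{}\t{}\t{}\t{}\t{:.12g}".format(
                ",".join(model.species[i] for i in rx.reactants),
                model.species[rx.product],
                rx.forward,
                rx.reverse,
                ",".join(str(m) for m in rx.multiplicity),
                rx.forward_scale,
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_reaction_table(path: str | Path, model: ModelSpec) -> tuple[Reaction, ...]:
    """Read back a TSV reaction table against a model's species labels."""
    rows = Path(path).read_text().strip().splitlines()
    out = []
    for line in rows[1:]:
        reactants, product, fwd, rev, mult, scale = line.split("\t")
        out.append(
            Reaction(
                reactants=tuple(model.index(s) for s in reactants.split(",")),
                product=model.index(product),
                forward=fwd,
                reverse=rev,
                multiplicity=tuple(int(m) for m in mult.split(",")),
                forward_scale=float(scale),
            )
        )
    return tuple(out)
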