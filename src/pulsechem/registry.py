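"""Chemical registry: species, reactions, and effective reaction radii.

Species and reactions are loaded from delimited text tables.  Bimolecular
rate constants are converted to effective (fully diffusion-controlled)
reaction radii by inverting the Smoluchowski rate expression

    k = 4 pi N_A D' R  (with k in dm3 mol-1 s-1, hence the 1e-3 factor),

where D' is the mutual diffusion coefficient of the pair.  Partially
diffusion-controlled channels are absorbed into R so that the long-time
observed rate is reproduced.  For identical-reactant channels (A + A) the
tabulated constant is read in the observed-loss convention
(-d[A]/dt = k [A]^2) and the pair-encounter rate is k/2; the factor is
applied exactly once, here, at radius derivation.

An optional Debye correction for charged pairs rescales the radius via the
Onsager length; it is off by default.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError, ValidationError

__all__ = [
    "AVOGADRO",
    "Species",
    "Reaction",
    "Registry",
    "effective_radius",
    "effective_radius_debye",
    "onsager_length",
    "load_registry",
    "default_registry",
]

AVOGADRO = 6.02214076e23          # mol^-1
ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23          # J/K
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
WATER_RELATIVE_PERMITTIVITY = 78.3


def effective_radius(rate_constant: float, mutual_diffusion: float) -> float:
    """Smoluchowski inversion: reaction radius (m) reproducing ``rate_constant``.

    Parameters
    ----------
    rate_constant : bimolecular rate constant, dm3 mol-1 s-1 (>= 0).
    mutual_diffusion : D1 + D2 of the pair, m2 s-1 (> 0).
    """
    if mutual_diffusion <= 0:
        raise InvalidParameterError(
            f"mutual_diffusion must be > 0, got {mutual_diffusion}"
        )
    if rate_constant < 0:
        raise InvalidParameterError(f"rate_constant must be >= 0, got {rate_constant}")
    return (rate_constant * 1e-3) / (4.0 * math.pi * mutual_diffusion * AVOGADRO)


def onsager_length(z1: int, z2: int, temperature: float = 298.15) -> float:
    """Onsager (Debye) length r_c for a charge pair in water, metres; signed."""
    return (
        z1
        * z2
        * ELEMENTARY_CHARGE**2
        / (
            4.0
            * math.pi
            * VACUUM_PERMITTIVITY
            * WATER_RELATIVE_PERMITTIVITY
            * BOLTZMANN
            * temperature
        )
    )


def effective_radius_debye(
    rate_constant: float,
    mutual_diffusion: float,
    z1: int,
    z2: int,
    temperature: float = 298.15,
) -> float:
    """Effective radius with Coulomb interaction between charged reactants.

    Inverts k = 4 pi N_A D' r_c / (exp(r_c / R) - 1) for R.  Reduces to the
    plain Smoluchowski inversion for a neutral pair.
    """
    r_smol = effective_radius(rate_constant, mutual_diffusion)
    if z1 * z2 == 0 or rate_constant == 0:
        return r_smol
    r_c = onsager_length(z1, z2, temperature)
    # exp(r_c/R) = 1 + r_c / r_smol  =>  R = r_c / log1p(r_c / r_smol)
    x = r_c / r_smol
    if x <= -1.0:
        # attractive pair observed below the Onsager capture rate: no contact
        # radius reproduces it in the capture model; keep the neutral radius
        warnings.warn(
            "observed rate below the Onsager capture limit for this attractive "
            "pair; using the neutral Smoluchowski radius"
        )
        return r_smol
    return r_c / math.log1p(x)


@dataclass(frozen=True)
class Species:
    """A diffusing chemical species."""

    name: str
    charge: int
    diffusion_coefficient: float  # m2/s

    def __post_init__(self):
        if self.diffusion_coefficient <= 0:
            raise ValidationError(
                f"species {self.name!r}: diffusion_coefficient must be > 0"
            )


@dataclass(frozen=True)
class Reaction:
    """A reaction channel between registry species (indices)."""

    reactants: tuple[int, ...]          # 1 (first-order) or 2 species indices
    products: tuple[int, ...]           # 0+ species indices; implicit H2O allowed
    rate_constant: float                # dm3 mol-1 s-1 or s-1
    unit: str                           # "M-1s-1" | "s-1"
    effective_radius: float = 0.0       # m; bimolecular only
    label: str = ""

    @property
    def bimolecular(self) -> bool:
        return len(self.reactants) == 2


_FORMULA_RE = re.compile(r"([HO])(\d*)")


def _composition(name: str) -> tuple[int, int]:
    """(n_H, n_O) for a species name; the solvated electron has none."""
    if name.lower() in ("e_aq", "e-", "eaq", "e_aq-"):
        return (0, 0)
    core = name.rstrip("+-")  # strip charge sign, keep formula digits (H2O2)
    counts = {"H": 0, "O": 0}
    pos = 0
    for m in _FORMULA_RE.finditer(core):
        if m.start() != pos:
            raise ValidationError(f"cannot parse element composition of {name!r}")
        counts[m.group(1)] += int(m.group(2) or 1)
        pos = m.end()
    if pos != len(core):
        raise ValidationError(f"cannot parse element composition of {name!r}")
    return counts["H"], counts["O"]


def _check_balance(
    row_label: str,
    reactant_names: list[str],
    product_names: list[str],
    charges: dict[str, int],
) -> None:
    """Charge must balance exactly; H/O must balance up to implicit H2O."""
    qr = sum(charges[n] for n in reactant_names)
    qp = sum(charges[n] for n in product_names)
    if qr != qp:
        raise ValidationError(
            f"{row_label}: charge imbalance (reactants {qr:+d}, products {qp:+d})"
        )
    hr = sum(_composition(n)[0] for n in reactant_names)
    orr = sum(_composition(n)[1] for n in reactant_names)
    hp = sum(_composition(n)[0] for n in product_names)
    op = sum(_composition(n)[1] for n in product_names)
    dh, do = hp - hr, op - orr
    # implicit water on either side: the element deficit must be w*(2, 1)
    if dh != 2 * do:
        raise ValidationError(
            f"{row_label}: element imbalance even with implicit H2O "
            f"(delta H={dh}, delta O={do})"
        )


class Registry:
    """Validated species + reaction set with engine lookup tables.

    Attributes
    ----------
    pair_reaction : (n, n) int array, reaction index per species pair or -1.
    pair_radius   : (n, n) float array of effective radii (m).
    pair_dprime   : (n, n) float array of mutual diffusion coefficients.
    first_order   : list of (species_index, reaction_index, rate s-1).
    """

    def __init__(self, species: list[Species], reactions: list[Reaction]):
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ValidationError("species names must be unique")
        self.species = list(species)
        self.names = names
        self.index = {n: i for i, n in enumerate(names)}
        self.reactions = list(reactions)
        self.diffusion = np.array([s.diffusion_coefficient for s in species])
        self.charges = np.array([s.charge for s in species], dtype=int)

        n = len(species)
        self.pair_reaction = np.full((n, n), -1, dtype=np.int64)
        self.pair_radius = np.zeros((n, n))
        self.pair_dprime = self.diffusion[:, None] + self.diffusion[None, :]
        self.first_order: list[tuple[int, int, float]] = []
        for r_idx, rx in enumerate(reactions):
            if rx.bimolecular:
                i, j = rx.reactants
                if self.pair_reaction[i, j] != -1:
                    raise ValidationError(
                        f"duplicate channel for pair "
                        f"({names[i]}, {names[j]})"
                    )
                self.pair_reaction[i, j] = self.pair_reaction[j, i] = r_idx
                self.pair_radius[i, j] = self.pair_radius[j, i] = rx.effective_radius
            else:
                (i,) = rx.reactants
                self.first_order.append((i, r_idx, rx.rate_constant))

    def __len__(self) -> int:
        return len(self.species)

    def species_index(self, name: str) -> int:
        try:
            return self.index[name]
        except KeyError:
            raise ValidationError(f"unknown species {name!r}") from None

    def max_radius(self) -> float:
        return float(self.pair_radius.max(initial=0.0))

    def with_scavenger(self, name: str, concentration: float) -> "Registry":
        """Convert bimolecular channels on a background species into
        pseudo-first-order channels at a fixed concentration (mol/dm3)."""
        if concentration < 0:
            raise InvalidParameterError("concentration must be >= 0")
        bg = self.species_index(name)
        reactions = []
        for rx in self.reactions:
            if rx.bimolecular and bg in rx.reactants:
                if concentration == 0.0:
                    continue
                other = rx.reactants[0] if rx.reactants[1] == bg else rx.reactants[1]
                reactions.append(
                    Reaction(
                        reactants=(other,),
                        products=rx.products,
                        rate_constant=rx.rate_constant * concentration,
                        unit="s-1",
                        label=rx.label + f" (scavenger {name})",
                    )
                )
            else:
                reactions.append(rx)
        return Registry(self.species, reactions)


def _read_rows(text: str) -> list[tuple[int, list[str]]]:
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append((lineno, [f.strip() for f in line.split("\t")]))
    return rows


def parse_species_table(text: str) -> list[Species]:
    rows = _read_rows(text)
    if not rows:
        raise ValidationError("empty species table")
    header = rows[0][1]
    if header[:3] != ["name", "charge", "diffusion_coefficient_m2_s"]:
        raise ValidationError(f"unexpected species table header: {header}")
    out = []
    for lineno, fields in rows[1:]:
        if len(fields) < 3:
            raise ValidationError(f"species table line {lineno}: need 3 columns")
        try:
            out.append(Species(fields[0], int(fields[1]), float(fields[2])))
        except ValueError as exc:
            raise ValidationError(f"species table line {lineno}: {exc}") from None
    return out


def parse_reaction_table(
    text: str, species: list[Species], debye: bool = False
) -> list[Reaction]:
    names = {s.name: i for i, s in enumerate(species)}
    charges = {s.name: s.charge for s in species}
    diff = {s.name: s.diffusion_coefficient for s in species}
    rows = _read_rows(text)
    if not rows:
        return []
    header = rows[0][1]
    if header[:5] != ["reactant1", "reactant2", "products", "rate_constant", "unit"]:
        raise ValidationError(f"unexpected reaction table header: {header}")
    out = []
    for lineno, fields in rows[1:]:
        fields = (fields + [""] * 5)[:5]
        r1, r2, prod_s, k_s, unit = fields
        label = f"reaction table line {lineno} ({r1} + {r2})"
        products = [p for p in prod_s.split(";") if p]
        for nm in [r1] + ([r2] if r2 else []) + products:
            if nm not in names:
                raise ValidationError(f"{label}: unknown species {nm!r}")
        try:
            k = float(k_s)
        except ValueError:
            raise ValidationError(f"{label}: bad rate constant {k_s!r}") from None
        if k < 0:
            raise ValidationError(f"{label}: negative rate constant")
        reactant_names = [r1] + ([r2] if r2 else [])
        _check_balance(label, reactant_names, products, charges)
        if r2:
            if unit not in ("M-1s-1", "dm3/mol/s"):
                raise ValidationError(f"{label}: bimolecular unit must be M-1s-1")
            k_pair = k / 2.0 if r1 == r2 else k  # observed-loss convention
            dprime = diff[r1] + diff[r2]
            if debye:
                radius = effective_radius_debye(
                    k_pair, dprime, charges[r1], charges[r2]
                )
            else:
                radius = effective_radius(k_pair, dprime)
            out.append(
                Reaction(
                    reactants=(names[r1], names[r2]),
                    products=tuple(names[p] for p in products),
                    rate_constant=k,
                    unit="M-1s-1",
                    effective_radius=radius,
                    label=f"{r1} + {r2} -> {prod_s or 'H2O'}",
                )
            )
        else:
            if unit != "s-1":
                raise ValidationError(f"{label}: first-order unit must be s-1")
            out.append(
                Reaction(
                    reactants=(names[r1],),
                    products=tuple(names[p] for p in products),
                    rate_constant=k,
                    unit="s-1",
                    label=f"{r1} -> {prod_s or 'H2O'}",
                )
            )
    return out


def load_registry(
    species_table: str | Path,
    reaction_table: str | Path,
    debye: bool = False,
) -> Registry:
    """Load and validate a registry from two delimited text files."""
    species = parse_species_table(Path(species_table).read_text())
    reactions = parse_reaction_table(
        Path(reaction_table).read_text(), species, debye=debye
    )
    return Registry(species, reactions)


def default_registry(debye: bool = False, o2_concentration: float = 0.0) -> Registry:
    """The bundled pure-water radiolysis registry.

    ``o2_concentration`` (mol/dm3) converts the dissolved-O2 rows into
    pseudo-first-order scavenging channels; at the default 0 they are removed.
    """
    data = resources.files("pulsechem.data")
    species = parse_species_table((data / "species.tsv").read_text())
    reactions = parse_reaction_table(
        (data / "reactions.tsv").read_text(), species, debye=debye
    )
    reg = Registry(species, reactions)
    return reg.with_scavenger("O2", o2_concentration)
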