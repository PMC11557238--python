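"""Synthetic physical/physicochemical stage: spur-based electron tracks.

Full condensed-history transport is deliberately replaced by a parameterised
spur model: an electron deposits its kinetic energy as a sequence of
localised spurs along a straight line, spaced by eps / S(E) where eps is the
sampled spur energy and S the collision stopping power at the current
residual energy.  Each spur is then populated with chemistry-ready radicals
at the physicochemical-stage yields, Gaussian-spread around the spur centre,
born one physicochemical offset (default 1 ps) after the track's arrival.

The question this package studies — the effect of the *pulse time
structure* on radiolytic yields — depends on when tracks are born and how
their radical clouds evolve, not on fine track topology, which is why a
spur caricature of the physical stage is adequate here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import json
import numpy as np

from .errors import EnergyRangeError, GeometryError, InvalidParameterError, ValidationError
from .geometry import Phantom
from .registry import Registry
from .state import Ensemble, ParticleState

__all__ = [
    "StoppingPower",
    "TrackParams",
    "SpurEvent",
    "stopping_power",
    "generate_track",
    "populate_spur",
    "track_to_ensemble",
    "dump_spurs",
]

#: initial (~1 ps) yields per 100 eV for low-LET water radiolysis;
#: literature-standard physicochemical-stage values, editable via config.
DEFAULT_INITIAL_YIELDS = {
    "e_aq": 4.8,
    "OH": 5.5,
    "H": 0.62,
    "H2": 0.15,
    "H3O+": 4.8,  # count is pair-matched to e_aq for charge neutrality
}


class StoppingPower:
    """Log-log interpolated collision stopping power for liquid water."""

    def __init__(self, energies_eV: np.ndarray, values_eV_per_m: np.ndarray):
        e = np.asarray(energies_eV, dtype=float)
        v = np.asarray(values_eV_per_m, dtype=float)
        if e.ndim != 1 or e.shape != v.shape or len(e) < 2:
            raise ValidationError("stopping-power table needs >= 2 (E, S) rows")
        if np.any(np.diff(e) <= 0):
            raise ValidationError("stopping-power energies must be increasing")
        if np.any(v <= 0) or np.any(e <= 0):
            raise ValidationError("stopping-power table must be positive")
        self.energies = e
        self.values = v
        self._log_e = np.log(e)
        self._log_v = np.log(v)

    @classmethod
    def from_table(cls, path: str | Path) -> "StoppingPower":
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("energy_eV"):
                continue
            a, b = line.split("\t")
            rows.append((float(a), float(b)))
        arr = np.array(rows)
        return cls(arr[:, 0], arr[:, 1])

    @classmethod
    def bundled(cls) -> "StoppingPower":
        data = resources.files("pulsechem.data") / "stopping_power_water.tsv"
        with resources.as_file(data) as p:
            return cls.from_table(p)

    def __call__(self, energy_eV: float | np.ndarray) -> float | np.ndarray:
        e = np.asarray(energy_eV, dtype=float)
        if np.any(e < self.energies[0]) or np.any(e > self.energies[-1]):
            raise EnergyRangeError(
                f"energy {energy_eV} outside table range "
                f"[{self.energies[0]:g}, {self.energies[-1]:g}] eV"
            )
        out = np.exp(np.interp(np.log(e), self._log_e, self._log_v))
        return float(out) if np.isscalar(energy_eV) else out


_BUNDLED: StoppingPower | None = None


def stopping_power(energy_eV: float) -> float:
    """Collision stopping power (eV/m) from the bundled water table."""
    global _BUNDLED
    if _BUNDLED is None:
        _BUNDLED = StoppingPower.bundled()
    return _BUNDLED(energy_eV)


@dataclass
class TrackParams:
    """Parameters of the synthetic electron track model."""

    kinetic_energy: float = 1e4            # eV, paper range 1e4-1e6
    entry_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    spur_energy_range: tuple[float, float] = (17.0, 100.0)  # eV, sampled uniform
    cutoff_energy: float = 500.0           # eV, transport stops below this
    initial_yields: dict = field(default_factory=lambda: dict(DEFAULT_INITIAL_YIELDS))
    sigma_heavy: float = 2.0e-9            # m, spur spread of heavy species
    sigma_electron: float = 5.0e-9         # m, e_aq thermalisation spread
    pc_offset: float = 1e-12               # s, physicochemical-stage duration
    max_spurs: int | None = None           # track-segment mode cap

    def __post_init__(self):
        if not (self.kinetic_energy >= self.cutoff_energy > 0):
            raise InvalidParameterError(
                "need kinetic_energy >= cutoff_energy > 0, got "
                f"{self.kinetic_energy} / {self.cutoff_energy}"
            )
        lo, hi = self.spur_energy_range
        if not (0 < lo <= hi):
            raise InvalidParameterError("bad spur_energy_range")
        if any(y < 0 for y in self.initial_yields.values()):
            raise InvalidParameterError("initial yields must be >= 0")
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise InvalidParameterError("direction must be a non-zero vector")
        self.direction = tuple(d / n)

    @property
    def mean_spur_energy(self) -> float:
        return 0.5 * (self.spur_energy_range[0] + self.spur_energy_range[1])


@dataclass
class SpurEvent:
    """One localised energy deposition and the radicals it seeds."""

    center: np.ndarray
    energy: float
    birth_time: float                  # track arrival time
    particles: list[ParticleState] = field(default_factory=list)


def populate_spur(
    energy: float,
    center: np.ndarray,
    birth_time: float,
    params: TrackParams,
    registry: Registry,
    rng: np.random.Generator,
    phantom: Phantom | None = None,
    track_id: int = -1,
) -> list[ParticleState]:
    """Draw the chemistry-ready radical content of one spur.

    Species counts are Poisson with mean ``energy * yield / 100`` except that
    the hydronium count is set equal to the solvated-electron count so every
    spur is born charge-neutral.  Particle birth times are the spur birth
    time plus the physicochemical offset.
    """
    if energy < 0:
        raise InvalidParameterError("spur energy must be >= 0")
    center = np.asarray(center, dtype=float)
    yields = params.initial_yields
    counts: dict[str, int] = {}
    n_eaq = None
    for name in sorted(yields):
        mean = energy * yields[name] / 100.0
        if name == "H3O+":
            continue  # paired below
        counts[name] = int(rng.poisson(mean))
        if name == "e_aq":
            n_eaq = counts[name]
    if "H3O+" in yields:
        counts["H3O+"] = n_eaq if n_eaq is not None else int(
            rng.poisson(energy * yields["H3O+"] / 100.0)
        )
    for name in counts:
        if counts[name] > 0 and name not in ("e_aq", "H3O+"):
            if registry.charges[registry.species_index(name)] != 0:
                raise ValidationError(
                    f"charged species {name!r} in initial yields breaks the "
                    "e_aq/H3O+ pairing rule"
                )

    particles: list[ParticleState] = []
    birth = birth_time + params.pc_offset
    for name in sorted(counts):
        k = counts[name]
        if k == 0:
            continue
        s_idx = registry.species_index(name)
        sigma = params.sigma_electron if name == "e_aq" else params.sigma_heavy
        pos = center + rng.normal(0.0, sigma, size=(k, 3))
        if phantom is not None:
            bad = ~phantom.contains(pos)
            while np.any(bad):  # redraw the rare escapers back inside
                pos[bad] = center + rng.normal(0.0, sigma, size=(int(bad.sum()), 3))
                bad = ~phantom.contains(pos)
        for row in pos:
            particles.append(
                ParticleState(
                    species=s_idx,
                    position=row,
                    birth_time=birth,
                    track_id=track_id,
                )
            )
    return particles


def generate_track(
    params: TrackParams,
    arrival_time: float,
    rng: np.random.Generator,
    registry: Registry,
    phantom: Phantom | None = None,
    entry_point: np.ndarray | None = None,
    direction: np.ndarray | None = None,
    stopping: StoppingPower | None = None,
    track_id: int = 0,
) -> tuple[list[SpurEvent], float]:
    """Generate one straight spur track; returns (spurs, deposited energy eV).

    Spur k is placed a distance eps_k / S(E_k) beyond the previous one, where
    E_k is the residual energy; generation stops at the cutoff energy, the
    phantom boundary, or the optional spur cap.  Deposited energy is exactly
    the sum of the emitted spur energies.
    """
    if phantom is None:
        phantom = Phantom()
    entry = np.asarray(
        entry_point if entry_point is not None else params.entry_point, dtype=float
    )
    if not phantom.on_entry_face(entry):
        raise GeometryError(f"entry point {entry} is not on the phantom entry face")
    d = np.asarray(direction if direction is not None else params.direction, float)
    d = d / np.linalg.norm(d)
    if stopping is None:
        global _BUNDLED
        if _BUNDLED is None:
            _BUNDLED = StoppingPower.bundled()
        stopping = _BUNDLED

    lo, hi = params.spur_energy_range
    spurs: list[SpurEvent] = []
    deposited = 0.0
    energy = float(params.kinetic_energy)
    pos = entry.copy()
    while energy > params.cutoff_energy:
        eps = float(rng.uniform(lo, hi)) if hi > lo else lo
        if energy - eps < params.cutoff_energy:
            break
        step = eps / stopping(energy)
        pos = pos + step * d
        if not phantom.contains(pos):
            break  # electron leaves the phantom
        spur = SpurEvent(center=pos.copy(), energy=eps, birth_time=arrival_time)
        spur.particles = populate_spur(
            eps, pos, arrival_time, params, registry, rng, phantom, track_id
        )
        spurs.append(spur)
        deposited += eps
        energy -= eps
        if params.max_spurs is not None and len(spurs) >= params.max_spurs:
            break
    return spurs, deposited


def track_to_ensemble(spurs: list[SpurEvent], ensemble: Ensemble | None = None) -> Ensemble:
    """Pool the particles of one or more tracks into an Ensemble."""
    particles = [p for s in spurs for p in s.particles]
    if ensemble is None:
        ensemble = Ensemble(max(len(particles), 1))
    if particles:
        ensemble.add(
            [p.species for p in particles],
            np.array([p.position for p in particles]),
            np.array([p.birth_time for p in particles]),
            np.array([p.track_id for p in particles]),
        )
    return ensemble


def dump_spurs(spurs: list[SpurEvent], registry: Registry, path: str | Path) -> None:
    """Write one JSON line per spur (center, energy, birth time, counts)."""
    with open(path, "w") as fh:
        for s in spurs:
            counts: dict[str, int] = {}
            for p in s.particles:
                counts[registry.names[p.species]] = counts.get(
                    registry.names[p.species], 0
                ) + 1
            fh.write(
                json.dumps(
                    {
                        "center_m": list(map(float, s.center)),
                        "energy_eV": s.energy,
                        "birth_time_s": s.birth_time,
                        "species_counts": counts,
                    }
                )
                + "\n"
            )
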