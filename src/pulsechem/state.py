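"""In-memory containers for chemical particles and reaction events.

The chemistry engine operates on a structure-of-arrays :class:`Ensemble`;
:class:`ParticleState` is the one-particle record view used at API
boundaries and in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ParticleState", "ReactionEvent", "EventLog", "Ensemble"]


@dataclass
class ParticleState:
    """One chemical species instance."""

    species: int            # species index in the registry
    position: np.ndarray    # (3,) metres
    birth_time: float       # seconds, >= 0
    alive: bool = True
    track_id: int = -1


@dataclass
class ReactionEvent:
    """One executed reaction: reactants die, products are born at ``time``."""

    time: float
    reaction: int
    reactant_ids: tuple[int, ...]
    product_ids: tuple[int, ...]
    position: np.ndarray


@dataclass
class EventLog:
    """Time-ordered record of executed reaction events."""

    events: list[ReactionEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events], dtype=float)


class Ensemble:
    """Growable structure-of-arrays particle pool.

    Positions are stored at each particle's *birth time*; the IRT engine
    blurs them forward analytically when it needs a later-time position.
    """

    def __init__(self, capacity: int = 0):
        capacity = max(int(capacity), 1)
        self.species = np.full(capacity, -1, dtype=np.int64)
        self.positions = np.zeros((capacity, 3), dtype=float)
        self.birth_times = np.zeros(capacity, dtype=float)
        self.alive = np.zeros(capacity, dtype=bool)
        self.track_ids = np.full(capacity, -1, dtype=np.int64)
        self.n = 0

    # -- construction -------------------------------------------------
    def _ensure(self, extra: int) -> None:
        need = self.n + extra
        if need <= len(self.species):
            return
        new_cap = max(need, 2 * len(self.species))
        self.species = np.resize(self.species, new_cap)
        self.birth_times = np.resize(self.birth_times, new_cap)
        self.track_ids = np.resize(self.track_ids, new_cap)
        pos = np.zeros((new_cap, 3), dtype=float)
        pos[: self.n] = self.positions[: self.n]
        self.positions = pos
        alive = np.zeros(new_cap, dtype=bool)
        alive[: self.n] = self.alive[: self.n]
        self.alive = alive

    def add(self, species, positions, birth_times, track_ids=-1) -> np.ndarray:
        """Append a batch of particles; returns their integer ids."""
        species = np.atleast_1d(np.asarray(species, dtype=np.int64))
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        k = len(species)
        birth_times = np.broadcast_to(
            np.asarray(birth_times, dtype=float), (k,)
        )
        track_ids = np.broadcast_to(np.asarray(track_ids, dtype=np.int64), (k,))
        self._ensure(k)
        sl = slice(self.n, self.n + k)
        self.species[sl] = species
        self.positions[sl] = positions
        self.birth_times[sl] = birth_times
        self.track_ids[sl] = track_ids
        self.alive[sl] = True
        ids = np.arange(self.n, self.n + k)
        self.n += k
        return ids

    @classmethod
    def from_particles(cls, particles: list[ParticleState]) -> "Ensemble":
        ens = cls(len(particles))
        for p in particles:
            (i,) = ens.add(p.species, p.position, p.birth_time, p.track_id)
            ens.alive[i] = p.alive
        return ens

    # -- views --------------------------------------------------------
    def particle(self, i: int) -> ParticleState:
        return ParticleState(
            species=int(self.species[i]),
            position=self.positions[i].copy(),
            birth_time=float(self.birth_times[i]),
            alive=bool(self.alive[i]),
            track_id=int(self.track_ids[i]),
        )

    def species_counts(self, n_species: int, alive_only: bool = True) -> np.ndarray:
        mask = self.alive[: self.n] if alive_only else np.ones(self.n, bool)
        return np.bincount(self.species[: self.n][mask], minlength=n_species)

    def __len__(self) -> int:
        return self.n
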