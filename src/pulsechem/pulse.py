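"""Beam geometry and pulse time structure.

A pulse is n electrons entering the water phantom through the inert air
gap, each with an arrival time drawn from the pulse envelope on [0, tau]
and a transverse entry position drawn from the Gaussian beam profile.
Each electron seeds a spur track (``tracks.generate_track``); all radicals
are pooled into one ensemble so the chemistry stage can resolve both
intra-track and inter-track encounters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .geometry import Phantom
from .registry import Registry
from .state import Ensemble
from .tracks import StoppingPower, TrackParams, generate_track, track_to_ensemble

__all__ = [
    "PulseSpec",
    "Phantom",
    "sample_arrival_times",
    "sample_entry_position",
    "assemble_pulse",
    "GAUSS_FWHM_TO_SIGMA",
]

#: FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian profile
GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PulseSpec:
    """One electron pulse: count, duration, energy, beam width, envelope."""

    n_electrons: int = 10
    pulse_duration: float = 1e-12       # s (tau); studied range 1e-13..1e-6
    kinetic_energy: float = 1e4         # eV; studied range 1e4..1e6
    beam_fwhm: float = 5e-6             # m
    envelope: str = "tophat"            # "tophat" | "gaussian"
    seed: int | None = None

    def __post_init__(self):
        if self.n_electrons < 1:
            raise InvalidParameterError("n_electrons must be >= 1")
        if self.pulse_duration < 0:
            raise InvalidParameterError("pulse_duration must be >= 0")
        if self.beam_fwhm < 0:
            raise InvalidParameterError("beam_fwhm must be >= 0")
        if self.envelope not in ("tophat", "gaussian"):
            raise InvalidParameterError(f"unknown envelope {self.envelope!r}")


def sample_arrival_times(
    n: int, tau: float, envelope: str, rng: np.random.Generator
) -> np.ndarray:
    """n arrival times in [0, tau] from the pulse envelope.

    The top-hat envelope is i.i.d. uniform on [0, tau]; the Gaussian
    envelope is centred at tau/2 with sigma = tau * FWHM->sigma factor,
    truncated to [0, tau] by redraw.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if tau < 0:
        raise InvalidParameterError("tau must be >= 0")
    if tau == 0.0:
        return np.zeros(n)
    if envelope == "tophat":
        return rng.uniform(0.0, tau, size=n)
    if envelope == "gaussian":
        sigma = tau * GAUSS_FWHM_TO_SIGMA
        t = rng.normal(tau / 2.0, sigma, size=n)
        bad = (t < 0) | (t > tau)
        while np.any(bad):
            t[bad] = rng.normal(tau / 2.0, sigma, size=int(bad.sum()))
            bad = (t < 0) | (t > tau)
        return t
    raise InvalidParameterError(f"unknown envelope {envelope!r}")


def sample_entry_position(
    beam_fwhm: float,
    rng: np.random.Generator,
    phantom: Phantom | None = None,
) -> np.ndarray:
    """Entry position on the z = 0 face; transverse coordinates are i.i.d.
    Gaussian with sigma = FWHM / (2 sqrt(2 ln 2)); points off the face are
    redrawn."""
    if beam_fwhm < 0:
        raise InvalidParameterError("beam_fwhm must be >= 0")
    if phantom is None:
        phantom = Phantom()
    if beam_fwhm == 0.0:
        return np.zeros(3)
    sigma = beam_fwhm * GAUSS_FWHM_TO_SIGMA
    hx, hy = phantom.extents[0] / 2.0, phantom.extents[1] / 2.0
    while True:
        x, y = rng.normal(0.0, sigma, size=2)
        if abs(x) <= hx and abs(y) <= hy:
            return np.array([x, y, 0.0])


def assemble_pulse(
    spec: PulseSpec,
    track_params: TrackParams,
    registry: Registry,
    rng: np.random.Generator,
    phantom: Phantom | None = None,
    stopping: StoppingPower | None = None,
) -> tuple[Ensemble, float, np.ndarray]:
    """Build the pooled multi-track ensemble for one pulse.

    For each electron, in order: arrival time, entry position, spur track.
    Returns (ensemble, total deposited energy eV, arrival times).  The air
    gap upstream of the water is an inert lossless drift: it shifts nothing
    and absorbs nothing, so it does not appear in the bookkeeping.
    """
    if phantom is None:
        phantom = Phantom()
    arrivals = sample_arrival_times(
        spec.n_electrons, spec.pulse_duration, spec.envelope, rng
    )
    params = track_params
    if params.kinetic_energy != spec.kinetic_energy:
        import dataclasses

        params = dataclasses.replace(track_params, kinetic_energy=spec.kinetic_energy)
    ensemble = Ensemble()
    total = 0.0
    for i in range(spec.n_electrons):
        entry = sample_entry_position(spec.beam_fwhm, rng, phantom)
        spurs, dep = generate_track(
            params,
            float(arrivals[i]),
            rng,
            registry,
            phantom=phantom,
            entry_point=entry,
            direction=(0.0, 0.0, 1.0),
            stopping=stopping,
            track_id=i,
        )
        track_to_ensemble(spurs, ensemble)
        total += dep
    return ensemble, total, arrivals
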