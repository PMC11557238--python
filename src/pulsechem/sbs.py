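"""Step-by-step Brownian dynamics: the brute-force chemistry oracle.

Every alive particle is propagated with explicit Gaussian steps; after each
step any pair closer than its channel's effective radius reacts (closest
pair first).  Pairs that end the step outside contact may still have
crossed the reaction surface *during* it; that is scored with the
Brownian-bridge crossing probability exp(-d0 d1 / (D' dt)) on the
distances-to-contact before and after the step, which removes the leading
discretisation bias of a naively absorbing boundary.  This is slow and
only admitted for small ensembles, but it makes no independent-pair
approximation, so it serves as the validation oracle for the IRT engine
on 2-10 particle fixtures.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError
from .registry import Registry
from .state import Ensemble, EventLog, ReactionEvent

__all__ = ["run_sbs", "pair_reaction_frequency_sbs"]


def _min_channel_radius(registry: Registry, species_present: np.ndarray) -> float:
    sub = registry.pair_radius[np.ix_(species_present, species_present)]
    rx = registry.pair_reaction[np.ix_(species_present, species_present)]
    radii = sub[rx >= 0]
    return float(radii.min()) if len(radii) else np.inf


def run_sbs(
    ensemble: Ensemble,
    registry: Registry,
    t_end: float,
    dt: float,
    rng: np.random.Generator,
    max_particles: int = 50,
) -> tuple[Ensemble, EventLog]:
    """Brute-force Brownian chemistry with fixed time step ``dt``.

    Guards: the ensemble must be small (<= ``max_particles``) and the step
    displacement sqrt(2 D_max dt) must stay below one third of the smallest
    reaction radius present, otherwise contact events are skipped over.
    """
    if t_end <= 0 or dt <= 0:
        raise InvalidParameterError("t_end and dt must be > 0")
    if ensemble.n > max_particles:
        raise InvalidParameterError(
            f"SBS oracle is guarded to <= {max_particles} particles; "
            "use run_irt for large ensembles"
        )
    species_present = np.unique(ensemble.species[: ensemble.n])
    r_min = _min_channel_radius(registry, species_present)
    d_max = float(registry.diffusion[species_present].max())
    if np.isfinite(r_min) and np.sqrt(2.0 * d_max * dt) >= r_min / 3.0:
        raise InvalidParameterError(
            "dt too coarse: sqrt(2 D_max dt) must be < R_min/3; "
            f"need dt < {(r_min / 3.0) ** 2 / (2.0 * d_max):.3e} s"
        )

    log = EventLog()
    t = float(ensemble.birth_times[: ensemble.n].min()) if ensemble.n else 0.0
    while t < t_end:
        step_end = min(t + dt, t_end)
        n = ensemble.n
        ids = np.nonzero(ensemble.alive[:n] & (ensemble.birth_times[:n] < step_end))[0]
        if len(ids) == 0:
            t = step_end
            continue
        # partial step for particles born inside this interval
        dt_eff = step_end - np.maximum(t, ensemble.birth_times[ids])
        D = registry.diffusion[ensemble.species[ids]]
        sigma = np.sqrt(2.0 * D * dt_eff)
        pos_before = ensemble.positions[ids].copy()
        ensemble.positions[ids] += rng.normal(size=(len(ids), 3)) * sigma[:, None]

        # bridge-corrected contact detection on the moved pairs
        sp = ensemble.species[ids]
        pos = ensemble.positions[ids]
        dist0 = np.linalg.norm(pos_before[:, None, :] - pos_before[None, :, :], axis=-1)
        dist1 = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        rx_m = registry.pair_reaction[sp[:, None], sp[None, :]]
        radius_m = registry.pair_radius[sp[:, None], sp[None, :]]
        dp_m = registry.pair_dprime[sp[:, None], sp[None, :]]
        upper = np.triu(np.ones_like(dist1, bool), 1)
        channel = (rx_m >= 0) & upper
        contact = channel & (dist1 < radius_m)
        d0 = np.maximum(dist0 - radius_m, 0.0)
        d1 = np.maximum(dist1 - radius_m, 0.0)
        with np.errstate(over="ignore"):
            p_cross = np.where(
                channel & ~contact, np.exp(-d0 * d1 / (dp_m * dt)), 0.0
            )
        u = rng.random(p_cross.shape)
        hit_m = contact | (channel & ~contact & (u < p_cross))
        # execute this step's hits closest-first, then let same-step products
        # react by plain contact
        for ai, aj in sorted(
            zip(*np.nonzero(hit_m)), key=lambda p: dist1[p[0], p[1]]
        ):
            id_a, id_b = int(ids[ai]), int(ids[aj])
            if not (ensemble.alive[id_a] and ensemble.alive[id_b]):
                continue
            _execute(ensemble, registry, log, id_a, id_b, int(rx_m[ai, aj]), step_end)

        while True:
            ids = np.nonzero(
                ensemble.alive[: ensemble.n]
                & (ensemble.birth_times[: ensemble.n] <= step_end)
            )[0]
            if len(ids) < 2:
                break
            pos = ensemble.positions[ids]
            sp = ensemble.species[ids]
            diff = pos[:, None, :] - pos[None, :, :]
            dist = np.linalg.norm(diff, axis=-1)
            rx = registry.pair_reaction[sp[:, None], sp[None, :]]
            radius = registry.pair_radius[sp[:, None], sp[None, :]]
            hit = (rx >= 0) & (dist < radius) & np.triu(np.ones_like(dist, bool), 1)
            if not np.any(hit):
                break
            ai, aj = np.nonzero(hit)
            k = np.argmin(dist[ai, aj])
            _execute(
                ensemble, registry, log,
                int(ids[ai[k]]), int(ids[aj[k]]), int(rx[ai[k], aj[k]]), step_end,
            )
        t = step_end
    return ensemble, log


def _execute(ensemble, registry, log, id_a, id_b, rx_idx, when) -> None:
    reaction = registry.reactions[rx_idx]
    da = registry.diffusion[ensemble.species[id_a]]
    db = registry.diffusion[ensemble.species[id_b]]
    w_a = db / (da + db)
    x_p = w_a * ensemble.positions[id_a] + (1.0 - w_a) * ensemble.positions[id_b]
    ensemble.alive[id_a] = False
    ensemble.alive[id_b] = False
    prods = list(reaction.products)
    new_ids = (
        ensemble.add(prods, np.tile(x_p, (len(prods), 1)), when, ensemble.track_ids[id_a])
        if prods
        else np.array([], dtype=int)
    )
    log.events.append(
        ReactionEvent(
            time=when,
            reaction=rx_idx,
            reactant_ids=(id_a, id_b),
            product_ids=tuple(int(x) for x in new_ids),
            position=x_p,
        )
    )


def pair_reaction_frequency_sbs(
    r0: float,
    R_eff: float,
    mutual_diffusion: float,
    t_end: float,
    dt: float,
    n_rep: int,
    rng: np.random.Generator,
) -> float:
    """Fraction of isolated pairs reacting by ``t_end`` (brute force).

    Works in the relative coordinate, which diffuses with D' = D1 + D2 and
    is absorbed at the contact radius; vectorised over replicates.
    """
    if r0 <= 0 or R_eff < 0 or mutual_diffusion <= 0:
        raise InvalidParameterError("bad pair geometry")
    n_steps = int(np.ceil(t_end / dt))
    x = np.zeros((n_rep, 3))
    x[:, 2] = r0
    alive = np.ones(n_rep, dtype=bool)
    sigma = np.sqrt(2.0 * mutual_diffusion * dt)
    d_prev = np.full(n_rep, max(r0 - R_eff, 0.0))
    for _ in range(n_steps):
        idx = np.nonzero(alive)[0]
        if len(idx) == 0:
            break
        x[idx] += rng.normal(size=(len(idx), 3)) * sigma
        d_new = np.maximum(np.linalg.norm(x[idx], axis=1) - R_eff, 0.0)
        # bridge correction: crossing within the step even if outside at both ends
        p_cross = np.exp(-d_prev[idx] * d_new / (mutual_diffusion * dt))
        hit = (d_new <= 0.0) | (rng.random(len(idx)) < p_cross)
        alive[idx[hit]] = False
        d_prev[idx] = d_new
    return 1.0 - alive.mean()
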