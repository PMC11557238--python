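"""Independent-reaction-times (IRT) Monte Carlo chemistry.

Each candidate reactant pair is assigned a reaction time drawn once from
the diffusion-controlled pair survival function

    W(t) = (R/r0) * erfc((r0 - R) / sqrt(4 D' t)),

where r0 is the initial separation, R the channel's effective radius and
D' the mutual diffusion coefficient.  Events are executed in global time
order; an event fires only if both reactants are still alive.  Products
sample fresh times against alive neighbours; existing pair times are not
revised when third parties react (classic, non-revisable IRT — the
step-by-step Brownian oracle in :mod:`pulsechem.sbs` quantifies the error
of that approximation on small systems).

Staggered birth times — the mechanism by which a long pulse decouples its
tracks — are handled explicitly: for a pair born at different times, the
earlier particle's position is blurred by its free-diffusion propagator to
the later birth, and the pair clock starts there.
"""

from __future__ import annotations

import heapq
import warnings

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import erfcinv

from .errors import InvalidParameterError
from .registry import Registry
from .state import Ensemble, EventLog, ReactionEvent

__all__ = [
    "pair_reaction_time",
    "ultimate_reaction_probability",
    "propagate_position",
    "run_irt",
]

_PAIR_CHUNK = 1_000_000  # candidate pairs processed per vectorised block


def ultimate_reaction_probability(r0: float, R_eff: float) -> float:
    """Probability that an isolated pair at separation r0 ever reacts: R/r0."""
    if R_eff <= 0:
        raise InvalidParameterError("R_eff must be > 0")
    if r0 < R_eff:
        warnings.warn("r0 < R_eff: pair already in contact, probability clamped to 1")
        return 1.0
    return R_eff / r0


def pair_reaction_time(
    r0,
    R_eff,
    mutual_diffusion,
    rng: np.random.Generator | None = None,
    u=None,
):
    """Sample the pair reaction time (s); ``inf`` means the pair never reacts.

    Inverse-transform sampling of W(t): draw u ~ U(0,1); if u >= R/r0 the
    pair escapes; otherwise t = (r0-R)^2 / (4 D' erfcinv(u r0/R)^2).
    Pairs already in contact (r0 <= R) react at time 0.  Vectorised.
    """
    scalar = np.isscalar(r0)
    r0 = np.atleast_1d(np.asarray(r0, dtype=float))
    R = np.broadcast_to(np.asarray(R_eff, dtype=float), r0.shape)
    D = np.broadcast_to(np.asarray(mutual_diffusion, dtype=float), r0.shape)
    if np.any(r0 <= 0):
        raise InvalidParameterError("r0 must be > 0")
    if np.any(R < 0):
        raise InvalidParameterError("R_eff must be >= 0")
    if np.any(D <= 0):
        raise InvalidParameterError("mutual_diffusion must be > 0")
    if u is None:
        if rng is None:
            raise InvalidParameterError("provide either rng or u")
        u = rng.random(r0.shape)
    else:
        u = np.broadcast_to(np.asarray(u, dtype=float), r0.shape)

    t = np.full(r0.shape, np.inf)
    contact = r0 <= R
    t[contact] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(r0 > 0, R / r0, 0.0)
    finite = (~contact) & (u < p)
    if np.any(finite):
        arg = u[finite] * r0[finite] / R[finite]
        inv = erfcinv(arg)
        t[finite] = (r0[finite] - R[finite]) ** 2 / (4.0 * D[finite] * inv**2)
    return float(t[0]) if scalar else t


def propagate_position(
    position: np.ndarray, D: float, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Free Brownian displacement: each coordinate gets N(0, 2 D dt)."""
    if dt < 0:
        raise InvalidParameterError("dt must be >= 0")
    position = np.asarray(position, dtype=float)
    if dt == 0.0:
        return position.copy()
    return position + rng.normal(0.0, np.sqrt(2.0 * D * dt), size=position.shape)


def _sample_pairs(
    i: np.ndarray,
    j: np.ndarray,
    X: np.ndarray,
    b: np.ndarray,
    s: np.ndarray,
    registry: Registry,
    t_end: float,
    cutoff_factor: float,
    r_cut_max: float,
    rng: np.random.Generator,
):
    """Vectorised candidate processing for pair index arrays (i, j).

    Returns (t_abs, i, j, rx, xi, xj) for pairs with a finite sampled
    reaction time <= t_end; xi/xj are the birth-adjusted positions used to
    measure r0 (kept for product placement).
    """
    rx = registry.pair_reaction[s[i], s[j]]
    keep = rx >= 0
    if not np.any(keep):
        return None
    i, j, rx = i[keep], j[keep], rx[keep]

    bi, bj = b[i], b[j]
    start = np.maximum(bi, bj)
    keep = start < t_end
    if not np.any(keep):
        return None
    i, j, rx, start = i[keep], j[keep], rx[keep], start[keep]

    R = registry.pair_radius[s[i], s[j]]
    Dp = registry.pair_dprime[s[i], s[j]]
    horizon = t_end - start
    r_cut = np.minimum(r_cut_max, R + cutoff_factor * np.sqrt(2.0 * Dp * horizon))

    # blur the earlier-born partner to the pair's common start time
    delta = np.abs(b[i] - b[j])
    d_early = np.where(b[i] <= b[j], registry.diffusion[s[i]], registry.diffusion[s[j]])
    sigma = np.sqrt(2.0 * d_early * delta)

    d_birth = np.linalg.norm(X[i] - X[j], axis=1)
    keep = d_birth <= r_cut + 4.0 * sigma
    if not np.any(keep):
        return None
    i, j, rx, start = i[keep], j[keep], rx[keep], start[keep]
    R, Dp, r_cut, sigma = R[keep], Dp[keep], r_cut[keep], sigma[keep]

    xi = X[i].copy()
    xj = X[j].copy()
    blur = sigma > 0
    if np.any(blur):
        noise = rng.normal(size=(int(blur.sum()), 3)) * sigma[blur, None]
        early_is_i = b[i[blur]] <= b[j[blur]]
        xi[blur] += np.where(early_is_i[:, None], noise, 0.0)
        xj[blur] += np.where(early_is_i[:, None], 0.0, noise)

    r0 = np.linalg.norm(xi - xj, axis=1)
    keep = r0 <= r_cut
    if not np.any(keep):
        return None
    i, j, rx, start = i[keep], j[keep], rx[keep], start[keep]
    R, Dp, r0 = R[keep], Dp[keep], r0[keep]
    xi, xj = xi[keep], xj[keep]

    u = rng.random(len(i))
    t_rel = np.full(len(i), np.inf)
    contact = r0 <= R
    t_rel[contact] = 0.0
    ok = (~contact) & (u * r0 < R)
    if np.any(ok):
        inv = erfcinv(u[ok] * r0[ok] / R[ok])
        t_rel[ok] = (r0[ok] - R[ok]) ** 2 / (4.0 * Dp[ok] * inv**2)
    t_abs = start + t_rel
    keep = t_abs <= t_end
    if not np.any(keep):
        return None
    return (t_abs[keep], i[keep], j[keep], rx[keep], xi[keep], xj[keep])


def run_irt(
    ensemble: Ensemble,
    registry: Registry,
    t_end: float,
    rng: np.random.Generator,
    cutoff_factor: float = 10.0,
    r_cut_max: float = 3e-7,
) -> tuple[Ensemble, EventLog]:
    """Run IRT chemistry on a pooled ensemble until ``t_end`` (s).

    The ensemble is mutated in place: reactants are marked dead, products
    appended.  Returns the same ensemble and the time-sorted event log.
    Particles born at or after ``t_end`` take no part in the chemistry.
    """
    if t_end <= 0:
        raise InvalidParameterError("t_end must be > 0")
    n0 = ensemble.n
    log = EventLog()
    if n0 == 0:
        return ensemble, log

    s = ensemble.species
    X = ensemble.positions
    b = ensemble.birth_times
    alive = ensemble.alive

    d_max = float(registry.diffusion.max())
    dp_max = float(registry.pair_dprime.max())
    r_chem = min(r_cut_max, registry.max_radius() + cutoff_factor * np.sqrt(2.0 * dp_max * t_end))
    born = b[:n0]
    b_span = float(born.max() - born.min()) if n0 > 1 else 0.0
    b_max_global = float(born.max())
    b_min_global = float(born.min())
    r_enum = r_chem + 3.0 * np.sqrt(2.0 * d_max * b_span)

    tree = cKDTree(X[:n0])
    heap: list[tuple] = []
    seq = 0
    payload: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    pairs = tree.query_pairs(r_enum, output_type="ndarray")
    if len(pairs):
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        pairs = pairs[order]
    for lo in range(0, len(pairs), _PAIR_CHUNK):
        block = pairs[lo : lo + _PAIR_CHUNK]
        out = _sample_pairs(
            block[:, 0], block[:, 1], X, b, s, registry, t_end,
            cutoff_factor, r_cut_max, rng,
        )
        if out is None:
            continue
        t_abs, ii, jj, rr, xi, xj = out
        for k in range(len(t_abs)):
            a_id, b_id = int(ii[k]), int(jj[k])
            lo_id, hi_id = (a_id, b_id) if a_id < b_id else (b_id, a_id)
            heapq.heappush(heap, (float(t_abs[k]), lo_id, hi_id, seq, int(rr[k])))
            payload[seq] = (xi[k], xj[k])
            seq += 1

    # first-order channels: competing exponential lifetimes from birth
    def _push_first_order(ids: np.ndarray) -> None:
        nonlocal seq
        for sp_idx, rx_idx, rate in registry.first_order:
            sel = ids[ensemble.species[ids] == sp_idx]
            if len(sel) == 0 or rate <= 0:
                continue
            life = rng.exponential(1.0 / rate, size=len(sel))
            t_abs = ensemble.birth_times[sel] + life
            for k in np.nonzero(t_abs <= t_end)[0]:
                pid = int(sel[k])
                heapq.heappush(heap, (float(t_abs[k]), pid, -1, seq, rx_idx))
                payload[seq] = (ensemble.positions[pid].copy(), None)
                seq += 1

    if registry.first_order:
        _push_first_order(np.arange(n0))

    # --- event loop --------------------------------------------------
    while heap:
        t_ev, id_a, id_b, key, rx_idx = heapq.heappop(heap)
        xi, xj = payload.pop(key)
        if not ensemble.alive[id_a]:
            continue
        if id_b >= 0 and not ensemble.alive[id_b]:
            continue
        reaction = registry.reactions[rx_idx]
        if id_b >= 0:
            da = registry.diffusion[ensemble.species[id_a]]
            db = registry.diffusion[ensemble.species[id_b]]
            # encounter point sits closer to the slower diffuser
            w_a = db / (da + db)
            x_p = w_a * xi + (1.0 - w_a) * xj
            ensemble.alive[id_a] = False
            ensemble.alive[id_b] = False
            reactant_ids = (id_a, id_b)
        else:
            d = registry.diffusion[ensemble.species[id_a]]
            x_p = propagate_position(xi, d, max(t_ev - ensemble.birth_times[id_a], 0.0), rng)
            ensemble.alive[id_a] = False
            reactant_ids = (id_a,)

        prod_species = list(reaction.products)
        if prod_species:
            new_ids = ensemble.add(
                prod_species,
                np.tile(x_p, (len(prod_species), 1)),
                t_ev,
                ensemble.track_ids[id_a],
            )
        else:
            new_ids = np.array([], dtype=int)
        log.events.append(
            ReactionEvent(
                time=t_ev,
                reaction=rx_idx,
                reactant_ids=reactant_ids,
                product_ids=tuple(int(x) for x in new_ids),
                position=x_p,
            )
        )
        if len(new_ids) == 0 or t_ev >= t_end:
            continue

        # fresh candidates: each product vs alive neighbours (and siblings)
        horizon = t_end - t_ev
        r_chem_p = min(
            r_cut_max,
            registry.max_radius() + cutoff_factor * np.sqrt(2.0 * dp_max * horizon),
        )
        # allowance for both future-birth blur and the back-blur of partners
        # that have been diffusing since their (much earlier) birth
        r_enum_p = (
            r_chem_p
            + 3.0 * np.sqrt(2.0 * d_max * max(b_max_global - t_ev, 0.0))
            + 3.0 * np.sqrt(2.0 * d_max * max(t_ev - b_min_global, 0.0))
        )
        for pid in new_ids:
            pid = int(pid)
            near = tree.query_ball_point(ensemble.positions[pid], r_enum_p)
            near = np.array(sorted(near), dtype=int)
            near = near[ensemble.alive[near]] if len(near) else near
            # alive later-made particles (products); only ids below pid so a
            # sibling pair created in one event is sampled exactly once
            extra = np.arange(n0, pid)
            extra = extra[ensemble.alive[extra]]
            if len(extra):
                d_extra = np.linalg.norm(
                    ensemble.positions[extra] - ensemble.positions[pid], axis=1
                )
                extra = extra[d_extra <= r_enum_p]
            partners = np.concatenate([near, extra]) if len(extra) else near
            if len(partners):
                out = _sample_pairs(
                    np.full(len(partners), pid),
                    partners,
                    ensemble.positions,
                    ensemble.birth_times,
                    ensemble.species,
                    registry,
                    t_end,
                    cutoff_factor,
                    r_cut_max,
                    rng,
                )
                if out is not None:
                    t_abs, ii, jj, rr, pxi, pxj = out
                    for k in range(len(t_abs)):
                        a2, b2 = int(ii[k]), int(jj[k])
                        lo2, hi2 = (a2, b2) if a2 < b2 else (b2, a2)
                        heapq.heappush(
                            heap, (float(t_abs[k]), lo2, hi2, seq, int(rr[k]))
                        )
                        payload[seq] = (pxi[k], pxj[k])
                        seq += 1
            if registry.first_order:
                _push_first_order(np.array([pid]))

    return ensemble, log
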