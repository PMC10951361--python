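"""The basic multicellular unit (BMU) lifecycle.

A remodeling event passes through initiation (bone-lining cells express
RANKL, recruiting preosteoclasts), resorption (fused osteoclasts excavate a
trench of bone, releasing BDF), reversal (the implicit interval between
osteoclast death and the first osteoblast), formation (osteoblasts refill the
trench; each osteoblast's lifespan and budget are set by the resorbed depth of
its site, coupling formation to resorption), and quiescence.

Operations here mutate the :class:`~marrowsim.grid.WorldState` in place and
are composed by the engine in a fixed order each step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .grid import (
    NEIGH8,
    CellKind,
    WorldState,
    bone_perimeter_mask,
    disk_offsets,
    sites_within_radius,
)

TURNOVER_DAYS = 4 * 365.0  # trabecular bone pool replacement time


class BmuPhase(Enum):
    INITIATION = "initiation"
    RESORPTION = "resorption"
    REVERSAL = "reversal"
    FORMATION = "formation"
    QUIESCENT = "quiescent"


_PHASE_ORDER = list(BmuPhase)


@dataclass
class BmuEvent:
    """One remodeling event and its phase timestamps."""

    origin: tuple[int, int]
    t_start: float
    lining_sites: list = field(default_factory=list)
    phase: BmuPhase = BmuPhase.INITIATION
    oc_site: tuple[int, int] | None = None
    t_phase: dict = field(default_factory=dict)
    resorbed_total: float = 0.0
    formed_total: float = 0.0
    oc_count: int = 0
    mm_triggered: bool = False

    def advance(self, phase: BmuPhase, t: float) -> None:
        if _PHASE_ORDER.index(phase) < _PHASE_ORDER.index(self.phase):
            raise ValueError(f"phase cannot move backwards: {self.phase} -> {phase}")
        if phase != self.phase:
            self.phase = phase
            self.t_phase[phase.value] = t


@dataclass
class RemodelingParams:
    """BMU rates and thresholds.

    ``event_rate`` (initiations/day) defaults to the closed-form turnover
    calibration: the expected cumulative resorption over four years equals the
    initial bone pool, with one osteoclast of lifespan ``oc_lifespan`` and
    resorption rate ``resorb_rate`` per event.  BDF thresholds are fractions
    of the calibrated homeostatic plume peak (~0.45 concentration units at the
    default field parameters).
    """

    event_rate: float | None = None      # BMU initiations/day (None -> calibrated)
    delivery_efficiency: float = 0.55    # fraction of scheduled resorption realized
    n_lining_activated: int = 5
    preoc_spawn_count: int = 10
    recruit_radius_um: float = 150.0     # preosteoclast recruitment ring
    preoc_speed: float = 24.0            # chemotaxis speed (sites/day)
    preoc_lifespan: float = 30.0         # days
    p_fuse: float = 0.5                  # per-step fusion probability
    fusion_min: int = 5
    fusion_radius_um: float = 40.0       # cluster neighborhood for fusion
    rankl_fusion_min: float = 1.0        # minimum local RANKL for fusion
    lining_activation_days: float = 30.0
    oc_lifespan: float = 14.0            # days
    resorb_rate: float = 1.0             # density/day per osteoclast at saturating BDF
    oc_bdf_floor: float = 0.15           # resorption activity floor without BDF
    K_oc_bdf: float = 0.35               # BDF half-saturation of osteoclast activity
    msc_radius_um: float = 40.0
    msc_lifespan: float = 30.0           # days
    msc_div_max: float = 1.8             # asymmetric divisions/day at saturation
    msc_max_divisions: int = 16          # progenitor pool per MSC
    K_msc: float = 0.01                  # BDF half-saturation for MSC division
    msc_floor: float = 0.06              # BDF below which MSC division stops
    preob_threshold: float = 0.15        # BDF proliferate/differentiate switch
    preob_div_rate: float = 0.02         # symmetric divisions/day above threshold
    preob_death_rate: float = 0.02       # 1/day
    ob_lifespan_per_depth: float = 90.0  # days of OB life per unit resorbed depth
    p_burial: float = 0.05
    ob_lining_fraction: float = 0.5      # fate split at natural OB death
    exclusion_radius_um: float = 80.0    # no re-initiation near an active event

    def __post_init__(self) -> None:
        if self.fusion_min < 2:
            raise ValueError("fusion_min must be >= 2")
        for p in (self.p_fuse, self.p_burial, self.ob_lining_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def calibrated_event_rate(self, bone_pool: float) -> float:
        """Initiations/day so that E[resorption] over four years equals
        ``bone_pool`` density units (one osteoclast per event)."""
        per_event = self.resorb_rate * self.oc_lifespan
        return bone_pool / (per_event * TURNOVER_DAYS)


def schedule_bmu_initiations(params: RemodelingParams, horizon: float,
                             bone_pool: float, seed) -> np.ndarray:
    """Event times uniformly distributed over ``horizon`` days at the
    turnover-calibrated rate (deterministic under ``seed``)."""
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")
    if horizon == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    rate = params.event_rate if params.event_rate is not None \
        else params.calibrated_event_rate(bone_pool)
    n = rng.poisson(rate * horizon)
    return np.sort(rng.uniform(0.0, horizon, size=n))


def initiate_bmu(state: WorldState, site: tuple[int, int],
                 params: RemodelingParams, mm_triggered: bool = False) -> BmuEvent:
    """Start a remodeling event at a bone-perimeter site: activate up to
    ``n_lining_activated`` contiguous LINING cells and introduce
    ``preoc_spawn_count`` preosteoclasts in the surrounding marrow."""
    i, j = state.grid.wrap(*site)
    if state.bone.density[i, j] <= 0:
        raise ValueError(f"site {(i, j)} is not bone")
    if not any(state.bone.density[state.grid.wrap(i + di, j + dj)] == 0
               for di, dj in NEIGH8):
        raise ValueError(f"site {(i, j)} has no marrow neighbor")

    # contiguous stretch of lining cells along the perimeter, BFS from origin
    activated: list[tuple[int, int]] = []
    seen = {(i, j)}
    queue = [(i, j)]
    while queue and len(activated) < params.n_lining_activated:
        ci, cj = queue.pop(0)
        if state.kind[ci, cj] == CellKind.LINING:
            state.rankl_active[ci, cj] = True
            activated.append((ci, cj))
        for di, dj in NEIGH8:
            ni, nj = state.grid.wrap(ci + di, cj + dj)
            if (ni, nj) not in seen and state.kind[ni, nj] == CellKind.LINING:
                seen.add((ni, nj))
                queue.append((ni, nj))

    event = BmuEvent(origin=(i, j), t_start=state.t, lining_sites=activated,
                     mm_triggered=mm_triggered)
    event.t_phase[BmuPhase.INITIATION.value] = state.t

    ring = [s for s in sites_within_radius((i, j), params.recruit_radius_um, state.grid)
            if state.free_marrow(*s)]
    if ring:
        k = min(params.preoc_spawn_count, len(ring))
        idx = state.rng.choice(len(ring), size=k, replace=False)
        for m in idx:
            state.add_agent(CellKind.PRE_OC, ring[m], lifespan=params.preoc_lifespan)
    return event


def _chemotax(state: WorldState, site: tuple[int, int], field: np.ndarray,
              n_moves: int) -> tuple[int, int]:
    """Steepest-ascent walk on ``field`` restricted to free marrow sites,
    uniform random tie-break; stops at a local maximum."""
    i, j = site
    nx, ny = state.grid.nx, state.grid.ny
    kind, dens = state.kind, state.bone.density
    for _ in range(n_moves):
        best, best_val = [], field[i, j]
        for di, dj in NEIGH8:
            ni, nj = (i + di) % nx, (j + dj) % ny
            if kind[ni, nj] != 0 or dens[ni, nj] >= 1.0:
                continue
            v = field[ni, nj]
            if v > best_val + 1e-15:
                best, best_val = [(ni, nj)], v
            elif best and abs(v - best_val) <= 1e-15:
                best.append((ni, nj))
        if not best:
            break
        ti, tj = best[state.rng.integers(len(best))] if len(best) > 1 else best[0]
        from .grid import move_agent
        if not move_agent(state, (i, j), (ti, tj)):
            break
        i, j = ti, tj
    return i, j


def update_preosteoclasts(state: WorldState, params: RemodelingParams,
                          events: list[BmuEvent], dt: float,
                          fusion_block_p: float = 0.0,
                          on_fusion=None) -> None:
    """Chemotaxis of preosteoclasts up the RANKL gradient and probabilistic
    fusion of >= ``fusion_min`` clustered precursors into one osteoclast under
    the highest local RANKL concentration.

    ``fusion_block_p`` is the per-attempt veto probability applied under
    bortezomib; ``on_fusion(state, oc_site)`` is invoked for each new
    osteoclast (MSC placement and myeloma seeding hook).
    """
    R = state.fields.R_L
    sites = [tuple(s) for s in state.sites_of(CellKind.PRE_OC)]
    state.rng.shuffle(sites)
    n_moves = max(1, int(round(params.preoc_speed * dt)))
    current: list[tuple[int, int]] = []
    for s in sites:
        i, j = s
        state.age[i, j] += dt
        if state.age[i, j] >= state.lifespan[i, j]:
            state.remove_agent((i, j))
            continue
        current.append(_chemotax(state, (i, j), R, n_moves))

    # fusion: anchor on the precursor at the highest RANKL in each cluster
    offs = disk_offsets(params.fusion_radius_um, state.grid.h)
    alive = set(current)
    tried: set = set()  # one fusion attempt per cluster per step
    for s in sorted(alive, key=lambda p: -R[p]):
        if s not in alive or s in tried:
            continue
        cluster = []
        for di, dj in offs:
            q = state.grid.wrap(s[0] + di, s[1] + dj)
            if q in alive:
                cluster.append(q)
        if len(cluster) < params.fusion_min or R[s] < params.rankl_fusion_min:
            continue
        tried.update(cluster)
        # fusion happens at an activated remodeling site: require an
        # initiation-phase event nearby (also caps one osteoclast per BMU)
        ev = _nearest_event(events, s, state, BmuPhase.INITIATION)
        if ev is None:
            continue
        r_ex = (params.exclusion_radius_um / state.grid.h) ** 2
        di = min(abs(ev.origin[0] - s[0]), state.grid.nx - abs(ev.origin[0] - s[0]))
        dj = min(abs(ev.origin[1] - s[1]), state.grid.ny - abs(ev.origin[1] - s[1]))
        if di * di + dj * dj > r_ex:
            continue
        if state.rng.random() >= params.p_fuse:
            continue
        if fusion_block_p > 0 and state.rng.random() < fusion_block_p:
            continue  # bortezomib vetoes this fusion attempt
        cluster.sort(key=lambda q: (q[0] - s[0]) ** 2 + (q[1] - s[1]) ** 2)
        fused = cluster[: params.fusion_min]

        def bone_adj(q):
            return any(state.bone.density[state.grid.wrap(q[0] + di, q[1] + dj)] > 0
                       for di, dj in NEIGH8)

        # the osteoclast forms on a bone-abutting member so it can resorb
        s = max(fused, key=lambda q: (bone_adj(q), R[q]))
        for q in fused:
            state.remove_agent(q)
            alive.discard(q)
        state.add_agent(CellKind.OC, s, lifespan=params.oc_lifespan,
                        budget=params.resorb_rate * params.oc_lifespan)
        state.cum_oc += 1
        ev.advance(BmuPhase.RESORPTION, state.t)
        ev.oc_site = s
        ev.oc_count += 1
        for ls in ev.lining_sites:
            if state.kind[ls] == CellKind.LINING:
                state.rankl_active[ls] = False
        if on_fusion is not None:
            on_fusion(state, s)


def _nearest_event(events: list[BmuEvent], site: tuple[int, int],
                   state: WorldState, phase: BmuPhase | None = None) -> BmuEvent | None:
    best, best_d = None, np.inf
    nx, ny = state.grid.nx, state.grid.ny
    for ev in events:
        if phase is not None and ev.phase != phase:
            continue
        di = min(abs(ev.origin[0] - site[0]) % nx, (-(ev.origin[0] - site[0])) % nx)
        dj = min(abs(ev.origin[1] - site[1]) % ny, (-(ev.origin[1] - site[1])) % ny)
        d = di * di + dj * dj
        if d < best_d:
            best, best_d = ev, d
    return best


def update_osteoclasts(state: WorldState, params: RemodelingParams,
                       events: list[BmuEvent], dt: float,
                       zol_effect: float = 0.0) -> None:
    """Resorption: each osteoclast removes up to ``resorb_rate * (1 -
    zol_effect) * dt`` density from the adjacent bone site of highest density,
    advancing into fully excavated sites, and dies at the end of its lifespan
    or when its resorption budget is spent."""
    sites = [tuple(s) for s in state.sites_of(CellKind.OC)]
    state.rng.shuffle(sites)
    for (i, j) in sites:
        state.age[i, j] += dt
        # BDF stimulates osteoclastic activity (the resorption arm of the
        # vicious cycle); activity saturates in local BDF with a floor
        T_loc = state.fields.T_beta[i, j]
        activity = (params.oc_bdf_floor + (1.0 - params.oc_bdf_floor)
                    * T_loc / (params.K_oc_bdf + T_loc))
        remaining = min(params.resorb_rate * activity * (1.0 - zol_effect) * dt,
                        state.budget[i, j])
        while remaining > 1e-12:
            # adjacent bone target: finish the site already being excavated,
            # else surface (perimeter) bone of highest density, so the cavity
            # stays a marrow-accessible full-depth trench
            best, best_key = None, (-1, -1, 0.0)
            for di, dj in NEIGH8:
                ni, nj = state.grid.wrap(i + di, j + dj)
                v = state.bone.density[ni, nj]
                if v <= 0:
                    continue
                started = int(state.bone.resorbed_depth[ni, nj] > 0)
                on_surface = int(any(
                    state.bone.density[state.grid.wrap(ni + ddi, nj + ddj)] == 0
                    for ddi, ddj in NEIGH8))
                key = (started, on_surface, v)
                if key > best_key:
                    best, best_key = (ni, nj), key
            if best is None:
                break  # no adjacent bone: idle
            db = min(remaining, best_key[2])
            remaining -= db
            state.bone.density[best] -= db
            state.bone.resorbed_depth[best] += db
            state.resorbed_this_step[best] += db
            state.remodeled[best] = True
            state.budget[i, j] -= db
            if state.kind[best] == CellKind.LINING:
                state.remove_agent(best)  # lining retracts once resorption starts
            elif state.kind[best] == CellKind.OB:
                # deepening under a working osteoblast extends its job
                state.budget[best] += db
                state.lifespan[best] += db * params.ob_lifespan_per_depth
            ev = _nearest_event(events, (i, j), state)
            if ev is not None:
                ev.resorbed_total += db
            if state.bone.density[best] <= 1e-12:
                state.bone.density[best] = 0.0
                if state.kind[best] == CellKind.EMPTY:
                    # advance along the resorption front
                    from .grid import move_agent
                    move_agent(state, (i, j), best)
                    i, j = best
        if state.age[i, j] >= state.lifespan[i, j] or state.budget[i, j] <= 1e-9:
            ev = _nearest_event(events, (i, j), state, BmuPhase.RESORPTION)
            state.remove_agent((i, j))
            if ev is not None and ev.oc_site is not None:
                ev.advance(BmuPhase.REVERSAL, state.t)


def place_msc_near_oc(state: WorldState, oc_site: tuple[int, int],
                      params: RemodelingParams) -> bool:
    """Place one MSC at a uniformly chosen free marrow site within
    ``msc_radius_um`` of a newly fused osteoclast, unless an MSC is already in
    that neighborhood.  Returns whether a placement happened."""
    hood = sites_within_radius(oc_site, params.msc_radius_um, state.grid)
    if any(state.kind[s] == CellKind.MSC for s in hood):
        return False
    free = [s for s in hood if state.free_marrow(*s)]
    if not free:
        return False
    s = free[state.rng.integers(len(free))]
    state.add_agent(CellKind.MSC, s, lifespan=params.msc_lifespan,
                    budget=float(params.msc_max_divisions))
    return True


def msc_division_rate(T_local: float, params: RemodelingParams) -> float:
    """Asymmetric-division rate of an MSC: monotone saturating in local BDF,
    zero below the survival/proliferation floor (the source of the biphasic
    bone response to BDF depletion)."""
    if T_local < params.msc_floor:
        return 0.0
    return params.msc_div_max * T_local / (params.K_msc + T_local)


def update_mscs(state: WorldState, params: RemodelingParams, dt: float) -> None:
    """Asymmetric MSC division into a free neighboring site (the MSC
    persists); deferred when crowded; MSC dies at the end of its lifespan."""
    sites = [tuple(s) for s in state.sites_of(CellKind.MSC)]
    state.rng.shuffle(sites)
    T = state.fields.T_beta
    for (i, j) in sites:
        state.age[i, j] += dt
        if state.age[i, j] >= state.lifespan[i, j]:
            state.remove_agent((i, j))
            continue
        # BDF recruits MSCs toward the remodeling site: one uphill move/step
        i, j = _chemotax(state, (i, j), T, 1)
        rate = msc_division_rate(T[i, j], params)
        if (rate > 0 and state.budget[i, j] > 0
                and state.rng.random() < rate * dt):
            free = state.free_neighbors((i, j))
            if free:
                s = free[state.rng.integers(len(free))]
                state.add_agent(CellKind.PRE_OB, s)
                state.budget[i, j] -= 1.0


def update_preosteoblasts(state: WorldState, params: RemodelingParams,
                          events: list[BmuEvent], dt: float,
                          blocked: np.ndarray | None = None) -> None:
    """Above the BDF threshold preosteoblasts proliferate symmetrically;
    below it they differentiate into an osteoblast on an adjacent resorbed
    site, with lifespan and formation budget proportional to that site's
    resorbed depth.  Differentiation is vetoed where ``blocked`` is set
    (myeloma within the blockade radius).  Idle cells wander one site."""
    sites = [tuple(s) for s in state.sites_of(CellKind.PRE_OB)]
    state.rng.shuffle(sites)
    T = state.fields.T_beta
    depth = state.bone.resorbed_depth
    # osteopontin-like homing cue: distance to the nearest resorbed site
    from scipy import ndimage as _ndi
    if (depth > 0).any():
        cavity_dist = _ndi.distance_transform_edt(depth <= 0)
    else:
        cavity_dist = None
    # differentiation waits for reversal: no conversion next to a working OC
    oc_mask = state.kind == CellKind.OC
    if oc_mask.any():
        from .myeloma import _dilate
        oc_near = _dilate(oc_mask, params.msc_radius_um, state.grid.h)
    else:
        oc_near = None
    from .grid import move_agent
    for (i, j) in sites:
        if state.kind[i, j] != CellKind.PRE_OB:
            continue  # consumed earlier this pass
        state.age[i, j] += dt
        if state.rng.random() < params.preob_death_rate * dt:
            state.remove_agent((i, j))
            continue
        if T[i, j] > params.preob_threshold:
            if state.rng.random() < params.preob_div_rate * dt:
                free = state.free_neighbors((i, j))
                if free:
                    s = free[state.rng.integers(len(free))]
                    state.add_agent(CellKind.PRE_OB, s)
            continue
        if blocked is not None and blocked[i, j]:
            continue  # may still proliferate next step, never differentiates now
        if oc_near is not None and oc_near[i, j]:
            continue  # reversal follows resorption: wait out the active osteoclast
        # differentiate on own site if resorbed, else an adjacent resorbed site
        target = None
        if depth[i, j] > 0:
            target = (i, j)
        else:
            cand = []
            for di, dj in NEIGH8:
                ni, nj = state.grid.wrap(i + di, j + dj)
                if depth[ni, nj] > 0 and state.free_marrow(ni, nj):
                    cand.append((ni, nj))
            if cand:
                target = cand[state.rng.integers(len(cand))]
        if target is None:
            free = state.free_neighbors((i, j))
            if free:  # home toward the nearest resorption cavity
                if cavity_dist is not None:
                    d = np.array([cavity_dist[s] for s in free])
                    best = np.flatnonzero(d == d.min())
                    pick = free[best[state.rng.integers(len(best))]]
                else:
                    pick = free[state.rng.integers(len(free))]
                move_agent(state, (i, j), pick)
            continue
        if target != (i, j):
            if not move_agent(state, (i, j), target):
                continue
        d = float(depth[target])
        extra = state.unassigned_budget
        state.unassigned_budget = 0.0
        lifespan = params.ob_lifespan_per_depth * (d + extra)
        state.remove_agent(target)
        state.add_agent(CellKind.OB, target, lifespan=lifespan, budget=d + extra,
                        ob_rate=1.0 / params.ob_lifespan_per_depth)
        ev = _nearest_event(events, target, state)
        if ev is not None:
            ev.advance(BmuPhase.FORMATION, state.t)
            state.ob_event[(int(target[0]), int(target[1]))] = ev


def _nearest_ob(state: WorldState, site: tuple[int, int]) -> tuple[int, int] | None:
    obs = state.sites_of(CellKind.OB)
    if len(obs) == 0:
        return None
    nx, ny = state.grid.nx, state.grid.ny
    di = np.minimum(np.abs(obs[:, 0] - site[0]), nx - np.abs(obs[:, 0] - site[0]))
    dj = np.minimum(np.abs(obs[:, 1] - site[1]), ny - np.abs(obs[:, 1] - site[1]))
    d2 = di * di + dj * dj
    best = np.flatnonzero(d2 == d2.min())
    pick = best[state.rng.integers(len(best))] if len(best) > 1 else best[0]
    return tuple(obs[pick])


def update_osteoblasts(state: WorldState, params: RemodelingParams,
                       events: list[BmuEvent], dt: float,
                       anabolic_boost: float = 0.0) -> None:
    """Bone formation: each osteoblast deposits ``budget / lifespan`` density
    per day into its own site (scaled by ``1 + anabolic_boost`` under
    bortezomib), clamped at full mineralization.  On completing its site an
    osteoblast may be buried (probability ``p_burial``), transferring any
    unbuilt budget to the nearest surviving osteoblast; at the end of its
    lifespan it becomes a quiescent lining cell or is removed."""
    sites = [tuple(s) for s in state.sites_of(CellKind.OB)]
    state.rng.shuffle(sites)
    dens = state.bone.density
    depth = state.bone.resorbed_depth
    for (i, j) in sites:
        if state.kind[i, j] != CellKind.OB:
            continue  # received a transfer/was buried earlier this pass
        state.age[i, j] += dt
        dep = min(state.ob_rate[i, j] * (1.0 + anabolic_boost) * dt,
                  state.budget[i, j], 1.0 - dens[i, j])
        ev = state.ob_event.get((i, j))
        if dep > 0:
            dens[i, j] += dep
            depth[i, j] = max(0.0, depth[i, j] - dep)
            state.budget[i, j] -= dep
            if ev is not None:
                ev.formed_total += dep
        done_site = dens[i, j] >= 1.0 - 1e-12
        if done_site:
            depth[i, j] = 0.0  # fully mineralized: no residual cavity
        expired = state.age[i, j] >= state.lifespan[i, j]
        if done_site and state.rng.random() < params.p_burial:
            _retire_ob(state, (i, j), params, become_lining=False)
        elif expired or (done_site and state.budget[i, j] <= 1e-12):
            become_lining = state.rng.random() < params.ob_lining_fraction
            _retire_ob(state, (i, j), params, become_lining=become_lining and done_site)
            if ev is not None and ev.phase == BmuPhase.FORMATION:
                # quiescence once no osteoblast of this event remains nearby
                hood = sites_within_radius(ev.origin, params.exclusion_radius_um,
                                           state.grid)
                if not any(state.kind[s] == CellKind.OB for s in hood):
                    ev.advance(BmuPhase.QUIESCENT, state.t)


def _retire_ob(state: WorldState, site: tuple[int, int], params: RemodelingParams,
               become_lining: bool) -> None:
    """Remove an osteoblast, transferring its unbuilt budget to the nearest
    surviving osteoblast (lifespan extended accordingly), or parking the
    remainder for the next differentiation if no osteoblast survives."""
    remainder = float(state.budget[site])
    state.remove_agent(site)
    state.ob_event.pop((int(site[0]), int(site[1])), None)
    if remainder > 1e-12:
        nb = _nearest_ob(state, site)
        if nb is not None:
            state.budget[nb] += remainder
            state.lifespan[nb] += remainder * params.ob_lifespan_per_depth
            # the receiving site can only absorb up to full mineralization;
            # route overflow through its own resorbed depth bookkeeping
        else:
            state.unassigned_budget += remainder
    if become_lining:
        state.add_agent(CellKind.LINING, site)


def event_log(events: list[BmuEvent]) -> "object":
    """Tidy per-BMU table: origin, phase timestamps, resorbed/reformed
    totals, and osteoclast count (raw material for phase-ordering checks)."""
    import pandas as pd
    rows = []
    for ev in events:
        rows.append({
            "origin_i": ev.origin[0], "origin_j": ev.origin[1],
            "t_start": ev.t_start, "phase": ev.phase.value,
            "mm_triggered": ev.mm_triggered, "oc_count": ev.oc_count,
            "resorbed_total": ev.resorbed_total, "formed_total": ev.formed_total,
            **{f"t_{p.value}": ev.t_phase.get(p.value, np.nan) for p in BmuPhase},
        })
    return pd.DataFrame(rows)
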