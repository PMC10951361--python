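"""Myeloma agents and the tumor-bone "vicious cycle" couplings.

Myeloma cells move and proliferate in response to BDF released by bone
resorption, gain a further proliferative advantage near MSCs/preosteoblasts
(stroma), and survive better where BDF is high.  In turn they recruit MSCs in
proportion to tumor burden, trigger new remodeling events when clustered
against bone, and block preosteoblast differentiation in an 80 um halo --
closing the feed-forward loop of osteolysis and growth.

The per-cell update is vectorized over the whole population (death draws,
biased movement, division proposals) with sequential conflict resolution in
random order, so multi-thousand-cell tumors remain tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import CellKind, NEIGH8, WorldState, disk_offsets


@dataclass
class MMParams:
    """Myeloma rates and interaction radii.

    The division rate is a saturating (Hill-type) function of local BDF with
    a multiplicative stroma bonus; death is a step function of BDF (lower
    death above the survival threshold).  Values are package calibrations
    reproducing sigmoidal marrow takeover on a ~1-year timescale.
    """

    r_base: float = 0.06         # intrinsic division rate (1/day)
    a_bdf: float = 2.0           # max fold-increase of division from BDF
    K_bdf: float = 0.20          # BDF half-saturation (conc)
    stroma_boost: float = 1.2    # division multiplier near MSC/PRE_OB
    stroma_radius_um: float = 20.0
    d_low: float = 0.004         # death/day below the BDF survival threshold
    d_high: float = 0.002        # death/day above it
    theta_surv: float = 0.15     # BDF survival threshold (conc)
    block_radius_um: float = 80.0
    msc_recruit_coeff: float = 5e-4  # MSCs recruited per MM cell per day
    msc_recruit_radius_um: float = 100.0  # recruited stroma homes to the tumor
    msc_recruit_lifespan: float = 120.0   # days; stroma tracks tumor size
    mm_remodel_min: int = 3      # MM adjacent to bone triggering a BMU
    msc_recruit_divisions: float = 16.0  # progenitor pool of recruited MSCs
    move_rate: float = 0.1       # site moves per day
    move_bias: float = 4.0       # softmax inverse temperature on T_beta / K_bdf
    seed_radius_um: float = 40.0

    def __post_init__(self) -> None:
        if self.d_low < self.d_high:
            raise ValueError("d_low must be >= d_high (survival advantage above threshold)")


def mm_division_rate(T_local: float, stroma_near: bool, resistant: bool,
                     params: MMParams, cost_factor: float = 1.0) -> float:
    """Division rate (1/day): r_base * (1 + a*T/(K+T)) * stroma * cost."""
    rate = params.r_base * (1.0 + params.a_bdf * T_local / (params.K_bdf + T_local))
    if stroma_near:
        rate *= params.stroma_boost
    if resistant:
        rate *= cost_factor
    return rate


def mm_death_prob(T_local: float, params: MMParams) -> float:
    """Baseline death probability per day (step in BDF); therapy composes its
    kill term on top of this."""
    return params.d_high if T_local > params.theta_surv else params.d_low


def stroma_mask(state: WorldState, radius_um: float) -> np.ndarray:
    """Sites within ``radius_um`` (inclusive) of any MSC or preosteoblast."""
    src = (state.kind == CellKind.MSC) | (state.kind == CellKind.PRE_OB)
    return _dilate(src, radius_um, state.grid.h)


_KERNEL_CACHE: dict = {}


def _dilate(mask: np.ndarray, radius_um: float, h: float) -> np.ndarray:
    """Periodic binary dilation by a Euclidean disk (inclusive radius),
    computed by FFT convolution with a cached kernel."""
    key = (mask.shape, radius_um, h)
    kf = _KERNEL_CACHE.get(key)
    if kf is None:
        kern = np.zeros(mask.shape)
        for di, dj in disk_offsets(radius_um, h):
            kern[di % mask.shape[0], dj % mask.shape[1]] = 1.0
        kf = np.fft.rfft2(kern)
        _KERNEL_CACHE[key] = kf
    conv = np.fft.irfft2(np.fft.rfft2(mask.astype(float)) * kf, s=mask.shape)
    return conv > 0.5


def mm_blocks_differentiation(state: WorldState, params: MMParams) -> np.ndarray:
    """Boolean map: preosteoblast differentiation is vetoed at sites within
    ``block_radius_um`` of any myeloma cell."""
    mm = state.kind == CellKind.MM
    if not mm.any():
        return np.zeros(state.grid.shape, dtype=bool)
    return _dilate(mm, params.block_radius_um, state.grid.h)


def seed_mm(state: WorldState, oc_site: tuple[int, int], params: MMParams) -> bool:
    """Recruit the single founding myeloma cell (clone 0, drug-sensitive) at a
    free marrow site within 40 um of the first fused osteoclast.  No-op once
    seeding has happened; returns whether a cell was placed."""
    if state.mm_seeded:
        return False
    from .grid import sites_within_radius
    free = [s for s in sites_within_radius(oc_site, params.seed_radius_um, state.grid)
            if state.free_marrow(*s)]
    if not free:
        return False  # retried at the next fusion
    s = free[state.rng.integers(len(free))]
    state.add_agent(CellKind.MM, s, clone_id=0, resistant=False)
    state.mm_seeded = True
    return True


def recruit_mscs_for_mm(state: WorldState, params: MMParams, dt: float) -> int:
    """Tumor-burden-proportional MSC recruitment: Poisson with mean
    ``msc_recruit_coeff * n_MM * dt``.  Recruited stroma homes to the tumor:
    each MSC lands at a free marrow site within ``msc_recruit_radius_um`` of
    a randomly chosen myeloma cell."""
    mm = state.sites_of(CellKind.MM)
    if len(mm) == 0:
        return 0
    n_new = state.rng.poisson(params.msc_recruit_coeff * len(mm) * dt)
    placed = 0
    from .grid import sites_within_radius
    mscs = state.sites_of(CellKind.MSC)
    for _ in range(n_new):
        # stromal niches aggregate: join an existing tumor-side niche when
        # one exists, otherwise found a new one near the tumor
        if len(mscs) and state.rng.random() < 0.7:
            anchor = tuple(mscs[state.rng.integers(len(mscs))])
            radius = 40.0
        else:
            anchor = tuple(mm[state.rng.integers(len(mm))])
            radius = params.msc_recruit_radius_um
        free = [s for s in sites_within_radius(anchor, radius, state.grid)
                if state.free_marrow(*s)]
        if not free:
            continue
        s = free[state.rng.integers(len(free))]
        state.add_agent(CellKind.MSC, s, lifespan=params.msc_recruit_lifespan,
                        budget=params.msc_recruit_divisions)
        placed += 1
    return placed


def mm_adjacent_bone_clusters(state: WorldState, params: MMParams) -> list[tuple[int, int]]:
    """Bone-perimeter initiation sites where >= ``mm_remodel_min`` myeloma
    cells sit within one lattice site of bone ("close to bone").

    Adjacent myeloma cells are grouped into connected clusters; each
    sufficiently large cluster nominates the bone site nearest its centroid.
    """
    bone = state.bone.density > 0
    if not bone.any():
        return []
    near_bone = np.zeros_like(bone)  # within one lattice site, 8-connected
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            near_bone |= np.roll(bone, (di, dj), axis=(0, 1))
    mm_near = (state.kind == CellKind.MM) & near_bone & ~bone
    if not mm_near.any():
        return []
    lab, nlab = ndimage.label(mm_near, structure=np.ones((3, 3)))
    out = []
    for k in range(1, nlab + 1):
        pts = np.argwhere(lab == k)
        if len(pts) < params.mm_remodel_min:
            continue
        ci, cj = pts.mean(axis=0)
        # bone site adjacent to the cluster, nearest its centroid
        best, best_d = None, np.inf
        for (i, j) in pts:
            for di, dj in NEIGH8:
                ni, nj = state.grid.wrap(i + di, j + dj)
                if bone[ni, nj]:
                    d = (ni - ci) ** 2 + (nj - cj) ** 2
                    if d < best_d:
                        best, best_d = (ni, nj), d
        if best is not None:
            out.append(best)
    return out


def update_mm(state: WorldState, params: MMParams, dt: float, *,
              kill_prob: np.ndarray | None = None,
              cost_factor: float = 1.0,
              on_division=None) -> None:
    """One step of myeloma death, biased movement, and division.

    ``kill_prob`` is an optional per-site additional death probability for
    *sensitive* cells (the bortezomib kill, already EMDR-adjusted).
    ``on_division(state, parent_site, daughter_site)`` runs after each
    successful division (resistance-acquisition hook).
    """
    mm_sites = state.sites_of(CellKind.MM)
    if len(mm_sites) == 0:
        return
    T = state.fields.T_beta
    ii, jj = mm_sites[:, 0], mm_sites[:, 1]

    # --- death (vectorized draw) ----------------------------------------
    t_loc = T[ii, jj]
    p_death = np.where(t_loc > params.theta_surv, params.d_high, params.d_low) * dt
    if kill_prob is not None:
        sens = ~state.resistant[ii, jj]
        p_death = p_death + np.where(sens, kill_prob[ii, jj], 0.0)
    die = state.rng.random(len(mm_sites)) < p_death
    for i, j in mm_sites[die]:
        state.remove_agent((i, j))
    mm_sites = mm_sites[~die]
    if len(mm_sites) == 0:
        return

    # --- biased movement (softmax over neighbor BDF) ---------------------
    kind, dens = state.kind, state.bone.density
    nx, ny = state.grid.nx, state.grid.ny
    rng = state.rng
    # softmax weights precomputed once per step
    w_field = np.exp(params.move_bias * np.clip(T / params.K_bdf, 0.0, 50.0))
    movers = rng.random(len(mm_sites)) < params.move_rate * dt
    order = rng.permutation(np.flatnonzero(movers))
    mm_code = int(CellKind.MM)
    for m in order:
        i, j = mm_sites[m]
        if kind[i, j] != mm_code:
            continue
        free = []
        for di, dj in NEIGH8:
            ni, nj = (i + di) % nx, (j + dj) % ny
            if kind[ni, nj] == 0 and dens[ni, nj] < 1.0:
                free.append((ni, nj))
        if not free:
            continue
        w = np.array([w_field[s] for s in free])
        s = free[rng.choice(len(free), p=w / w.sum())]
        from .grid import move_agent
        if move_agent(state, (i, j), s):
            mm_sites[m] = s

    # --- division --------------------------------------------------------
    ii, jj = mm_sites[:, 0], mm_sites[:, 1]
    stroma = stroma_mask(state, params.stroma_radius_um)
    t_loc = T[ii, jj]
    rate = params.r_base * (1.0 + params.a_bdf * t_loc / (params.K_bdf + t_loc))
    rate = rate * np.where(stroma[ii, jj], params.stroma_boost, 1.0)
    rate = rate * np.where(state.resistant[ii, jj], cost_factor, 1.0)
    dividing = rng.random(len(mm_sites)) < rate * dt
    order = rng.permutation(np.flatnonzero(dividing))
    for m in order:
        i, j = mm_sites[m]
        if kind[i, j] != mm_code:
            continue
        free = []
        for di, dj in NEIGH8:
            ni, nj = (i + di) % nx, (j + dj) % ny
            if kind[ni, nj] == 0 and dens[ni, nj] < 1.0:
                free.append((ni, nj))
        if not free:
            continue  # contact inhibition
        s = free[rng.integers(len(free))]
        state.add_agent(CellKind.MM, s, clone_id=int(state.clone[i, j]),
                        resistant=bool(state.resistant[i, j]))
        if on_division is not None:
            on_division(state, (int(i), int(j)), s)
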