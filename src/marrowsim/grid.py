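"""Lattice geometry, bone matrix, and agent bookkeeping.

The world is a 2D rectangular grid of square sites (default 160 x 150 sites of
10 um, i.e. a 1600 x 1500 um^2 cross-section of trabecular bone marrow) with
periodic boundaries.  Each site holds at most one cell agent; mineralized bone
is a continuous per-site density in [0, 1], with trabecular structures placed
in the center of the grid at a target area fraction (12.9% by default, the
BA/TA of healthy murine trabecular bone).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import IntEnum
from functools import lru_cache

import numpy as np
from scipy import ndimage


class CellKind(IntEnum):
    """Agent types on the lattice.  EMPTY marks an unoccupied site."""

    EMPTY = 0
    PRE_OC = 1   # preosteoclast (osteoclast precursor)
    OC = 2       # active multinucleated osteoclast
    MSC = 3      # mesenchymal stem cell
    PRE_OB = 4   # preosteoblast
    OB = 5       # matrix-forming osteoblast
    LINING = 6   # quiescent bone-lining cell (osteoblast lineage)
    MM = 7       # multiple myeloma cell


#: kinds whose agents age and die
MORTAL_KINDS = (CellKind.PRE_OC, CellKind.OC, CellKind.MSC, CellKind.PRE_OB, CellKind.OB)


@dataclass(frozen=True)
class GridSpec:
    """Lattice geometry.

    Parameters
    ----------
    nx, ny : int
        Lattice extent in sites.  Defaults give a 1600 x 1500 um^2 domain.
    h : float
        Site edge length in micrometers.
    periodic : bool
        Periodic wrap on all sides (applies to both agents and cytokine
        fields; the only supported convention).
    """

    nx: int = 160
    ny: int = 150
    h: float = 10.0
    periodic: bool = True

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError("grid must be at least 3 x 3 sites")
        if self.h <= 0:
            raise ValueError("site edge length must be positive")

    @property
    def n_sites(self) -> int:
        return self.nx * self.ny

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    def wrap(self, i: int, j: int) -> tuple[int, int]:
        return i % self.nx, j % self.ny


@lru_cache(maxsize=128)
def disk_offsets(r_um: float, h: float) -> tuple[tuple[int, int], ...]:
    """Integer offsets (di, dj) whose center-to-center Euclidean distance is
    <= ``r_um`` (inclusive) on a lattice with spacing ``h``."""
    if r_um < 0:
        raise ValueError("radius must be nonnegative")
    m = int(r_um // h) + 1
    out = []
    r2 = (r_um / h) ** 2 + 1e-12  # inclusive boundary
    for di in range(-m, m + 1):
        for dj in range(-m, m + 1):
            if di * di + dj * dj <= r2:
                out.append((di, dj))
    return tuple(out)


#: 8-neighborhood (Moore) offsets, excluding the center
NEIGH8 = tuple((di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0))
#: 4-neighborhood (von Neumann) offsets
NEIGH4 = ((1, 0), (-1, 0), (0, 1), (0, -1))


def sites_within_radius(center: tuple[int, int], r_um: float, spec: GridSpec) -> set[tuple[int, int]]:
    """All sites whose center lies within ``r_um`` micrometers of ``center``
    (Euclidean, inclusive, periodic wrap)."""
    ci, cj = center
    return {spec.wrap(ci + di, cj + dj) for di, dj in disk_offsets(r_um, spec.h)}


@dataclass
class BoneField:
    """Mineralized bone density (1 = fully mineralized, 0 = marrow) and the
    cumulative density resorbed since the last formation cycle."""

    density: np.ndarray
    resorbed_depth: np.ndarray

    @classmethod
    def zeros(cls, spec: GridSpec) -> "BoneField":
        return cls(np.zeros(spec.shape), np.zeros(spec.shape))


@dataclass
class CellAgent:
    """A typed agent snapshot/view at one lattice site.

    ``payload`` fields that do not apply to a kind are left at defaults
    (budget for OC resorption or OB formation, clone_id/resistant for MM,
    rankl_active for LINING).
    """

    kind: CellKind
    site: tuple[int, int]
    age: float = 0.0
    lifespan: float = np.inf
    budget: float = 0.0
    clone_id: int = -1
    resistant: bool = False
    rankl_active: bool = False


@dataclass
class WorldState:
    """Full simulator state: occupancy lattice, bone matrix, cytokine fields,
    clone registry, and clock.

    Agents are stored struct-of-arrays (one value per site) so that large
    myeloma populations can be updated with vectorized numpy operations; the
    :class:`CellAgent` view is materialized on demand.
    """

    grid: GridSpec
    bone: BoneField
    kind: np.ndarray          # int8 CellKind codes
    age: np.ndarray           # days, for the occupying agent
    lifespan: np.ndarray      # days
    budget: np.ndarray        # OC resorption / OB formation budget (density units)
    ob_rate: np.ndarray       # OB deposition rate (density/day)
    clone: np.ndarray         # MM clone id (-1 elsewhere)
    resistant: np.ndarray     # bool, MM resistance flag
    rankl_active: np.ndarray  # bool, LINING RANKL expression flag
    fields: "object" = None   # CytokineFields (set by init_world)
    t: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    # bookkeeping
    resorbed_this_step: np.ndarray = None
    remodeled: np.ndarray = None          # sites resorbed at least once
    initial_bone: np.ndarray = None       # bone mask at t = 0
    unassigned_budget: float = 0.0        # formation budget awaiting an osteoblast
    ob_event: dict = field(default_factory=dict)  # OB site -> its BmuEvent
    clones: dict = field(default_factory=dict)   # clone_id -> CloneRecord
    cum_oc: int = 0                       # cumulative osteoclasts fused
    mm_seeded: bool = False
    n_clip_events: int = 0

    # ---------------------------------------------------------------- agents
    def agent_at(self, site: tuple[int, int]) -> CellAgent | None:
        i, j = self.grid.wrap(*site)
        k = CellKind(self.kind[i, j])
        if k == CellKind.EMPTY:
            return None
        return CellAgent(
            kind=k, site=(i, j), age=float(self.age[i, j]),
            lifespan=float(self.lifespan[i, j]), budget=float(self.budget[i, j]),
            clone_id=int(self.clone[i, j]), resistant=bool(self.resistant[i, j]),
            rankl_active=bool(self.rankl_active[i, j]),
        )

    def add_agent(self, kind: CellKind, site: tuple[int, int], *, age: float = 0.0,
                  lifespan: float = np.inf, budget: float = 0.0, ob_rate: float = 0.0,
                  clone_id: int = -1, resistant: bool = False,
                  rankl_active: bool = False) -> None:
        i, j = self.grid.wrap(*site)
        if self.kind[i, j] != CellKind.EMPTY:
            raise ValueError(f"site {(i, j)} already occupied")
        self.kind[i, j] = kind
        self.age[i, j] = age
        self.lifespan[i, j] = lifespan
        self.budget[i, j] = budget
        self.ob_rate[i, j] = ob_rate
        self.clone[i, j] = clone_id
        self.resistant[i, j] = resistant
        self.rankl_active[i, j] = rankl_active

    def remove_agent(self, site: tuple[int, int]) -> None:
        i, j = self.grid.wrap(*site)
        self.kind[i, j] = CellKind.EMPTY
        self.age[i, j] = 0.0
        self.lifespan[i, j] = np.inf
        self.budget[i, j] = 0.0
        self.ob_rate[i, j] = 0.0
        self.clone[i, j] = -1
        self.resistant[i, j] = False
        self.rankl_active[i, j] = False

    def sites_of(self, kind: CellKind) -> np.ndarray:
        """(n, 2) array of sites occupied by ``kind``."""
        return np.argwhere(self.kind == kind)

    def count(self, kind: CellKind) -> int:
        return int(np.count_nonzero(self.kind == kind))

    def free_marrow(self, i: int, j: int) -> bool:
        return self.kind[i, j] == 0 and self.bone.density[i, j] < 1.0

    def free_neighbors(self, site: tuple[int, int]) -> list[tuple[int, int]]:
        i, j = site
        nx, ny = self.grid.nx, self.grid.ny
        kind, dens = self.kind, self.bone.density
        out = []
        for di, dj in NEIGH8:
            ii, jj = (i + di) % nx, (j + dj) % ny
            if kind[ii, jj] == 0 and dens[ii, jj] < 1.0:
                out.append((ii, jj))
        return out

    def copy(self) -> "WorldState":
        new = dataclasses.replace(
            self,
            bone=BoneField(self.bone.density.copy(), self.bone.resorbed_depth.copy()),
            kind=self.kind.copy(), age=self.age.copy(), lifespan=self.lifespan.copy(),
            budget=self.budget.copy(), ob_rate=self.ob_rate.copy(),
            clone=self.clone.copy(), resistant=self.resistant.copy(),
            rankl_active=self.rankl_active.copy(),
            resorbed_this_step=self.resorbed_this_step.copy(),
            remodeled=self.remodeled.copy(), initial_bone=self.initial_bone.copy(),
            ob_event=dict(self.ob_event), clones=dict(self.clones),
        )
        if self.fields is not None:
            new.fields = dataclasses.replace(
                self.fields, R_L=self.fields.R_L.copy(), T_beta=self.fields.T_beta.copy())
        return new


def bone_perimeter_mask(density: np.ndarray) -> np.ndarray:
    """Bone sites (density > 0) with at least one zero-density 4-neighbor."""
    bone = density > 0
    marrow = ~bone
    adj = np.zeros_like(bone)
    for di, dj in NEIGH4:
        adj |= np.roll(marrow, (di, dj), axis=(0, 1))
    return bone & adj


def _trabecular_mask(spec: GridSpec, target_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Procedural trabecular geometry: Gaussian-smoothed noise, weighted toward
    the grid center, thresholded to exactly ``round(target * n_sites)`` sites,
    with small disconnected fragments reassigned to the main structures."""
    n_target = int(round(target_fraction * spec.n_sites))
    noise = rng.standard_normal(spec.shape)
    sigma = max(3.0, min(spec.nx, spec.ny) / 20.0)  # strut scale tracks grid size
    smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="wrap")
    smooth /= max(smooth.std(), 1e-12)
    # ridges near the zero level-set of the smoothed field give strut-like
    # trabeculae a few sites (~tens of um) thick rather than solid blobs
    ridges = -np.abs(smooth)
    # soft-edged central region keeps trabeculae away from the wrap seam
    x = (np.arange(spec.nx) - (spec.nx - 1) / 2) / spec.nx
    y = (np.arange(spec.ny) - (spec.ny - 1) / 2) / spec.ny
    r = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)
    score = ridges - 20.0 * np.clip(r - 0.30, 0.0, None) ** 2
    flat = np.argsort(score, axis=None)[::-1]
    mask = np.zeros(spec.shape, dtype=bool)
    mask.flat[flat[:n_target]] = True
    # connected-component cleanup: drop specks, then refill to the exact count
    lab, nlab = ndimage.label(mask)
    if nlab > 1:
        sizes = ndimage.sum_labels(np.ones(spec.shape), lab, index=np.arange(1, nlab + 1))
        keep = np.isin(lab, 1 + np.flatnonzero(sizes >= 12))
        mask &= keep
    deficit = n_target - int(mask.sum())
    while deficit > 0:
        grown = ndimage.binary_dilation(mask) & ~mask
        cand = np.argwhere(grown)
        if len(cand) == 0:
            break
        order = np.argsort(score[grown])[::-1]
        take = cand[order[:deficit]]
        mask[take[:, 0], take[:, 1]] = True
        deficit = n_target - int(mask.sum())
    return mask


def init_world(spec: GridSpec | None = None, target_bone_fraction: float = 0.129,
               seed: int | None = 0, mask: np.ndarray | None = None) -> WorldState:
    """Create a world whose trabecular bone occupies ``target_bone_fraction``
    of the total area (+-1 site), with LINING agents on the bone perimeter and
    zeroed cytokine fields.

    Parameters
    ----------
    mask : array, optional
        Per-site bone density override (values in [0, 1]); its area fraction
        must lie within 5% relative of the target.
    """
    from .fields import CytokineFields  # local import avoids a cycle

    spec = spec or GridSpec()
    if not 0.0 < target_bone_fraction < 1.0:
        raise ValueError("target_bone_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if mask is not None:
        mask = np.asarray(mask, dtype=float)
        if mask.shape != spec.shape:
            raise ValueError(f"mask shape {mask.shape} does not match grid {spec.shape}")
        frac = mask.sum() / spec.n_sites
        if frac == 0 or abs(frac - target_bone_fraction) / target_bone_fraction > 0.05:
            raise ValueError(
                f"mask bone fraction {frac:.4f} deviates more than 5% from "
                f"target {target_bone_fraction:.4f}")
        density = mask.copy()
    else:
        density = _trabecular_mask(spec, target_bone_fraction, rng).astype(float)

    bone = BoneField(density=density, resorbed_depth=np.zeros(spec.shape))
    state = WorldState(
        grid=spec, bone=bone,
        kind=np.zeros(spec.shape, dtype=np.int8),
        age=np.zeros(spec.shape), lifespan=np.full(spec.shape, np.inf),
        budget=np.zeros(spec.shape), ob_rate=np.zeros(spec.shape),
        clone=np.full(spec.shape, -1, dtype=np.int32),
        resistant=np.zeros(spec.shape, dtype=bool),
        rankl_active=np.zeros(spec.shape, dtype=bool),
        fields=CytokineFields.zeros(spec),
        rng=rng,
        resorbed_this_step=np.zeros(spec.shape),
        remodeled=np.zeros(spec.shape, dtype=bool),
        initial_bone=density > 0,
    )
    perim = bone_perimeter_mask(density)
    if not perim.any():
        raise ValueError("bone has no marrow-facing perimeter to seed lining cells")
    for i, j in np.argwhere(perim):
        state.add_agent(CellKind.LINING, (int(i), int(j)))
    return state


def area_fractions(state: WorldState) -> dict:
    """BA/TA, myeloma fraction of the marrow (non-bone sites of the current
    frame), and exact per-kind agent counts."""
    n = state.grid.n_sites
    marrow_sites = int(np.count_nonzero(state.bone.density == 0))
    counts = {k.name: state.count(k) for k in CellKind if k != CellKind.EMPTY}
    mm = counts["MM"]
    return {
        "ba_ta": float(state.bone.density.sum()) / n,
        "mm_marrow_fraction": (mm / marrow_sites) if marrow_sites else 0.0,
        "cell_counts": counts,
    }


def move_agent(state: WorldState, site: tuple[int, int], target: tuple[int, int]) -> bool:
    """Relocate the agent at ``site`` to ``target`` (after periodic wrap).

    Returns False (agent stays put) if the target is occupied or fully
    mineralized bone -- contention, not failure.
    """
    si, sj = site[0] % state.grid.nx, site[1] % state.grid.ny
    ti, tj = target[0] % state.grid.nx, target[1] % state.grid.ny
    if state.kind[si, sj] == 0:
        raise ValueError(f"no agent at {site}")
    if not (state.kind[ti, tj] == 0 and state.bone.density[ti, tj] < 1.0):
        return False
    for arr in (state.kind, state.age, state.lifespan, state.budget, state.ob_rate,
                state.clone, state.resistant, state.rankl_active):
        arr[ti, tj] = arr[si, sj]
    state.remove_agent((si, sj))
    return True
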