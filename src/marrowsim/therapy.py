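"""Treatment scheduling, drug effects, and resistance evolution.

Bortezomib (BTZ) is cytotoxic to sensitive myeloma cells, vetoes
preosteoclast fusion, and boosts osteoblastic deposition; zoledronate (ZOL)
scales down per-osteoclast resorption (and hence resorption-driven BDF
release).  Treatment starts when tumor burden reaches 10% of the marrow area
and relapse is declared at 20%.  After treatment has started, each division
of a sensitive cell carries probability ``p_omega`` of founding a new,
heritably resistant clone (with a proliferation cost).  Environment-mediated
drug resistance (EMDR) multiplies the BTZ kill on *sensitive* cells that are
within 20 um of an MSC/preosteoblast or on high BDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .grid import CellKind, WorldState
from .myeloma import stroma_mask
from .observables import CloneRecord, OriginContext, classify_origin


class Drug(Enum):
    NONE = "none"
    BTZ = "btz"
    ZOL = "zol"


@dataclass
class TherapySchedule:
    """When a drug is on.

    Treatment begins the first time myeloma burden reaches ``start_trigger``
    of the marrow area; ``pulsed`` mode then cycles ``on_days`` on /
    ``off_days`` off (default 2 weeks on, 1 week off), ``continuous`` mode
    stays on.  ``stop_trigger`` is the relapse burden.
    """

    drug: Drug = Drug.NONE
    mode: str = "continuous"       # or "pulsed"
    on_days: int = 14
    off_days: int = 7
    start_trigger: float = 0.10
    stop_trigger: float = 0.20
    dose: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.start_trigger < self.stop_trigger <= 1.0:
            raise ValueError("need 0 < start_trigger < stop_trigger <= 1")
        if self.on_days < 0 or self.off_days < 0:
            raise ValueError("on/off days must be nonnegative")


@dataclass
class ResistanceParams:
    """Resistance-acquisition and drug-effect magnitudes.

    ``p_omega`` is the per-division probability that a sensitive daughter
    acquires heritable resistance (literature range 1e-6..1e-3); the other
    magnitudes are package calibrations.
    """

    p_omega: float = 0.0
    cost_factor: float = 0.90         # division-rate multiplier for resistant cells
    emdr_enabled: bool = True
    emdr_kill_multiplier: float = 0.01  # BTZ kill factor for protected sensitive cells
    theta_emdr: float = 0.50          # BDF threshold for protection
    btz_kill: float = 0.35            # kill probability/day of exposed sensitive MM at dose 1
    btz_fusion_block: float = 0.85    # probability a fusion attempt is vetoed
    btz_anabolic: float = 0.3         # OB deposition boost under BTZ
    zol_resorb_block: float = 0.7     # fractional reduction of per-OC resorption

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_omega <= 1.0:
            raise ValueError("p_omega must lie in [0, 1]")
        if not 0.0 < self.cost_factor <= 1.0:
            raise ValueError("cost_factor must lie in (0, 1]")


@dataclass
class TherapyState:
    """Runtime treatment bookkeeping carried by the engine."""

    started: bool = False
    t_start: float = np.inf
    next_clone_id: int = 1


def drug_active(schedule: TherapySchedule, therapy: TherapyState, t: float) -> bool:
    """Whether the scheduled drug is being applied at time ``t``."""
    if schedule.drug == Drug.NONE or not therapy.started or t < therapy.t_start:
        return False
    if schedule.mode == "continuous":
        return True
    period = schedule.on_days + schedule.off_days
    if period == 0:
        return True
    return (t - therapy.t_start) % period < schedule.on_days


def protection_mask(state: WorldState, params: ResistanceParams,
                    stroma_radius_um: float = 20.0) -> np.ndarray:
    """Per-site EMDR predicate: within 20 um of an MSC/preosteoblast
    (inclusive) or local BDF above ``theta_emdr``.  All-False when EMDR is
    disabled."""
    if not params.emdr_enabled:
        return np.zeros(state.grid.shape, dtype=bool)
    return stroma_mask(state, stroma_radius_um) | (state.fields.T_beta > params.theta_emdr)


def emdr_protected(state: WorldState, site: tuple[int, int],
                   params: ResistanceParams) -> bool:
    """EMDR predicate for a single (sensitive) myeloma cell."""
    return bool(protection_mask(state, params)[state.grid.wrap(*site)])


def btz_kill_map(state: WorldState, params: ResistanceParams,
                 schedule: TherapySchedule, dt: float) -> np.ndarray:
    """Per-site additional death probability for sensitive myeloma cells this
    step: ``btz_kill * dose * dt``, reduced by ``emdr_kill_multiplier`` where
    the EMDR predicate holds.  (Resistant cells never receive this term.)"""
    base = params.btz_kill * schedule.dose * dt
    prot = protection_mask(state, params)
    return np.where(prot, base * params.emdr_kill_multiplier, base)


def maybe_acquire_resistance(state: WorldState, daughter_site: tuple[int, int],
                             params: ResistanceParams, therapy: TherapyState) -> bool:
    """Per-division resistance acquisition for a sensitive daughter after
    treatment has started: with probability ``p_omega`` the daughter becomes
    resistant, receives a fresh clone id, and a :class:`CloneRecord` is opened
    with its spatial origin context.  Heritable and irreversible."""
    i, j = state.grid.wrap(*daughter_site)
    if not therapy.started or state.resistant[i, j]:
        return False
    if params.p_omega <= 0 or state.rng.random() >= params.p_omega:
        return False
    cid = therapy.next_clone_id
    therapy.next_clone_id += 1
    state.resistant[i, j] = True
    state.clone[i, j] = cid
    ctx = classify_origin((i, j), state, theta_emdr=params.theta_emdr)
    state.clones[cid] = CloneRecord(clone_id=cid, t_birth=state.t,
                                    origin_site=(i, j), origin_context=ctx)
    return True


def apply_btz(state: WorldState, params: ResistanceParams,
              schedule: TherapySchedule, dt: float) -> int:
    """Standalone BTZ cytotoxicity: kill sensitive myeloma cells with the
    EMDR-adjusted per-step probability.  Returns the number killed.

    (The engine normally folds :func:`btz_kill_map` into the myeloma death
    draw; this entry point supports isolated use and testing.)
    """
    if schedule.dose <= 0:
        return 0
    kill = btz_kill_map(state, params, schedule, dt)
    mm = state.sites_of(CellKind.MM)
    killed = 0
    for i, j in mm:
        if state.resistant[i, j]:
            continue
        if state.rng.random() < kill[i, j]:
            state.remove_agent((i, j))
            killed += 1
    return killed


def apply_zol(params: ResistanceParams, active: bool) -> float:
    """Fractional per-osteoclast resorption reduction this step (0 when ZOL
    is off); lowering resorption also lowers BDF release through the source
    coupling."""
    return params.zol_resorb_block if active else 0.0
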