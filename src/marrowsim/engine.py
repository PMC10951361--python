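"""Simulation loop, presets, and cohort experiments.

Operator order within one agent step (fixed convention):

1. scheduled and myeloma-triggered BMU initiations (subject to an 80 um
   exclusion zone around active events),
2. PDE sub-steps of the cytokine fields using the previous step's sources,
3. agent updates in fixed kind order (PRE_OC, OC, MSC, PRE_OB, OB, MM), each
   kind in randomized within-kind order,
4. treatment trigger/application bookkeeping,
5. recording.

A (seed, config) pair fully determines the trajectory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fields as flds
from . import myeloma as mye
from . import remodeling as rem
from . import therapy as thr
from .grid import CellKind, GridSpec, WorldState, area_fractions, bone_perimeter_mask, init_world
from .observables import FrameRecorder, census_from_state, origin_tally


@dataclass
class EngineConfig:
    """Stepping and recording configuration.

    The agent step is 0.5 day; movement speeds are expressed in sites/day and
    resolved as micro-moves within a step, so per-step event probabilities
    stay small (<~0.15) and the discretization error is covered by a
    self-convergence test.  ``pde_substeps`` subdivides the agent step so the
    FTCS stability bound holds at the default diffusion coefficients.
    """

    dt_agent: float = 0.5
    pde_substeps: int = 4
    horizon: float = 4 * 365.0
    treat_horizon: float = 3 * 365.0   # censoring horizon after treatment start
    record_every: float = 5.0
    seed: int = 0
    event_timeout: float = 200.0       # days after which a BMU stops excluding others

    def __post_init__(self) -> None:
        if self.dt_agent <= 0 or self.pde_substeps < 1:
            raise ValueError("dt_agent must be positive and pde_substeps >= 1")


class Simulation:
    """One replicate of the bone-marrow ecosystem."""

    def __init__(self, *,
                 grid: GridSpec | None = None,
                 engine: EngineConfig | None = None,
                 field_params: flds.FieldParams | None = None,
                 remodel: rem.RemodelingParams | None = None,
                 mm: mye.MMParams | None = None,
                 schedule: thr.TherapySchedule | None = None,
                 resistance: thr.ResistanceParams | None = None,
                 target_bone_fraction: float = 0.129,
                 mask: np.ndarray | None = None,
                 tumor: bool = False,
                 drugs_from_start: bool = False,
                 initial_event: bool | None = None):
        self.grid = grid or GridSpec()
        self.engine = engine or EngineConfig()
        self.field_params = field_params or flds.FieldParams()
        self.field_params.dt_pde = self.engine.dt_agent / self.engine.pde_substeps
        if not self.field_params.stable_for(self.grid.h):
            raise ValueError("FTCS stability bound violated for this configuration")
        self.remodel = remodel or rem.RemodelingParams()
        self.mm = mm or (mye.MMParams() if tumor else None)
        self.tumor = tumor or mm is not None
        self.schedule = schedule or thr.TherapySchedule()
        self.resistance = resistance or thr.ResistanceParams()
        self.drugs_from_start = drugs_from_start

        ss = np.random.SeedSequence(self.engine.seed)
        s_world, s_sched, s_run = ss.spawn(3)
        self.state = init_world(self.grid, target_bone_fraction,
                                seed=s_world, mask=mask)
        self.state.rng = np.random.default_rng(s_run)
        bone_pool = float(self.state.bone.density.sum())
        # turnover calibration is on *realized* resorption: scale the closed-form
        # rate by the fraction of initiations that complete (abortive events
        # never assemble enough precursors to fuse)
        sched_params = self.remodel
        if sched_params.event_rate is None:
            sched_params = dataclasses.replace(
                sched_params,
                event_rate=(sched_params.calibrated_event_rate(bone_pool)
                            / sched_params.delivery_efficiency))
        self.initiation_times = rem.schedule_bmu_initiations(
            sched_params, self.engine.horizon, bone_pool, s_sched)
        if initial_event is None:
            initial_event = self.tumor
        if initial_event:
            self.initiation_times = np.concatenate([[0.0], self.initiation_times])
        self._next_event_idx = 0
        self.events: list[rem.BmuEvent] = []
        self.therapy = thr.TherapyState()
        if drugs_from_start:
            self.therapy.started = True
            self.therapy.t_start = 0.0
        self.recorder = FrameRecorder()
        self._next_record = 0.0
        self.outcome: dict | None = None
        self.relapse_t: float | None = None
        self._extinct_t: float | None = None

    # ------------------------------------------------------------------ utils
    def active_events(self) -> list[rem.BmuEvent]:
        t = self.state.t
        return [e for e in self.events
                if e.phase != rem.BmuPhase.QUIESCENT
                and t - e.t_start < self.engine.event_timeout]

    def _excluded(self, site: tuple[int, int], phases=None) -> bool:
        r2 = (self.remodel.exclusion_radius_um / self.grid.h) ** 2
        nx, ny = self.grid.nx, self.grid.ny
        events = self.active_events()
        if phases is not None:
            events = [e for e in events if e.phase in phases]
        for ev in events:
            di = min(abs(ev.origin[0] - site[0]), nx - abs(ev.origin[0] - site[0]))
            dj = min(abs(ev.origin[1] - site[1]), ny - abs(ev.origin[1] - site[1]))
            if di * di + dj * dj <= r2:
                return True
        return False

    def _initiate_at_random_perimeter(self) -> None:
        perim = np.argwhere(bone_perimeter_mask(self.state.bone.density))
        if len(perim) == 0:
            return
        for _ in range(40):  # keep drawing until a non-excluded site turns up
            i, j = perim[self.state.rng.integers(len(perim))]
            if not self._excluded((i, j)):
                try:
                    ev = rem.initiate_bmu(self.state, (int(i), int(j)), self.remodel)
                except ValueError:
                    continue
                self.events.append(ev)
                return

    # ------------------------------------------------------------------- step
    def step(self) -> None:
        st = self.state
        dt = self.engine.dt_agent
        btz_on = (self.schedule.drug == thr.Drug.BTZ
                  and thr.drug_active(self.schedule, self.therapy, st.t))
        zol_on = (self.schedule.drug == thr.Drug.ZOL
                  and thr.drug_active(self.schedule, self.therapy, st.t))

        # abortive initiations: shut RANKL off after the activation window
        for ev in self.events:
            if (ev.phase == rem.BmuPhase.INITIATION
                    and st.t - ev.t_start > self.remodel.lining_activation_days):
                for ls in ev.lining_sites:
                    if st.kind[ls] == CellKind.LINING:
                        st.rankl_active[ls] = False
                ev.advance(rem.BmuPhase.QUIESCENT, st.t)

        # (1) remodeling initiations
        while (self._next_event_idx < len(self.initiation_times)
               and self.initiation_times[self._next_event_idx] <= st.t):
            self._next_event_idx += 1
            self._initiate_at_random_perimeter()
        if self.mm is not None:
            # tumor-driven re-initiation waits only for active resorption
            # nearby, not for the (often blocked) formation phase -- repeated
            # waves of osteolysis at the tumor-bone interface
            mm_phases = (rem.BmuPhase.INITIATION, rem.BmuPhase.RESORPTION)
            for site in mye.mm_adjacent_bone_clusters(st, self.mm):
                if not self._excluded(site, phases=mm_phases):
                    try:
                        ev = rem.initiate_bmu(st, site, self.remodel, mm_triggered=True)
                    except ValueError:
                        continue
                    self.events.append(ev)

        # (2) cytokine fields (sources from the previous step's resorption)
        rates = flds.production_rates(st, self.field_params, dt)
        st.resorbed_this_step[:] = 0.0
        for _ in range(self.engine.pde_substeps):
            flds.ftcs_step(st.fields, self.field_params, rates, self.grid.h, st)

        # (3) agents, fixed kind order
        active = self.active_events()

        def on_fusion(state: WorldState, oc_site) -> None:
            rem.place_msc_near_oc(state, oc_site, self.remodel)
            if self.tumor:
                mye.seed_mm(state, oc_site, self.mm)

        rem.update_preosteoclasts(
            st, self.remodel, active, dt,
            fusion_block_p=self.resistance.btz_fusion_block if btz_on else 0.0,
            on_fusion=on_fusion)
        rem.update_osteoclasts(st, self.remodel, active, dt,
                               zol_effect=thr.apply_zol(self.resistance, zol_on))
        rem.update_mscs(st, self.remodel, dt)
        blocked = mye.mm_blocks_differentiation(st, self.mm) if self.mm is not None else None
        rem.update_preosteoblasts(st, self.remodel, active, dt, blocked=blocked)
        rem.update_osteoblasts(st, self.remodel, active, dt,
                               anabolic_boost=self.resistance.btz_anabolic if btz_on else 0.0)
        if self.mm is not None:
            kill = thr.btz_kill_map(st, self.resistance, self.schedule, dt) if btz_on else None

            def on_division(state: WorldState, parent, daughter) -> None:
                thr.maybe_acquire_resistance(state, daughter, self.resistance, self.therapy)

            mye.update_mm(st, self.mm, dt, kill_prob=kill,
                          cost_factor=self.resistance.cost_factor,
                          on_division=on_division)
            mye.recruit_mscs_for_mm(st, self.mm, dt)

        # (4) treatment trigger / outcome bookkeeping
        if self.mm is not None:
            frac = area_fractions(st)["mm_marrow_fraction"]
            if (not self.therapy.started and self.schedule.drug != thr.Drug.NONE
                    and frac >= self.schedule.start_trigger):
                self.therapy.started = True
                self.therapy.t_start = st.t
            if (self.therapy.started and self.relapse_t is None
                    and st.t > self.therapy.t_start
                    and frac >= self.schedule.stop_trigger):
                self.relapse_t = st.t
            if (st.mm_seeded and self._extinct_t is None
                    and st.count(CellKind.MM) == 0):
                self._extinct_t = st.t

        # (5) clock and recording
        st.t += dt
        if st.t >= self._next_record - 1e-9:
            self.recorder.record_frame(st)
            self._next_record += self.engine.record_every

    def fork(self, *, emdr: bool | None = None, p_omega: float | None = None,
             seed_offset: int | None = None) -> "Simulation":
        """Deep-copied replicate sharing this simulation's history.

        Treatment arms that only differ in post-treatment parameters (EMDR
        on/off, resistance probability) can branch from one pre-treatment
        trajectory; ``seed_offset`` optionally re-seeds the forked stream so
        arms diverge stochastically after the branch point.
        """
        import copy
        new = copy.deepcopy(self)
        if emdr is not None:
            new.resistance.emdr_enabled = emdr
        if p_omega is not None:
            new.resistance.p_omega = p_omega
        if seed_offset is not None:
            mix = np.random.SeedSequence([self.engine.seed, seed_offset])
            new.state.rng = np.random.default_rng(mix)
        return new

    def run_until_treatment(self, horizon: float | None = None) -> bool:
        """Advance until the treatment trigger fires (or the tumor dies or
        the horizon passes); returns whether treatment started."""
        horizon = self.engine.horizon if horizon is None else horizon
        while (not self.therapy.started and self._extinct_t is None
               and self.state.t < horizon - 1e-9):
            self.step()
        return self.therapy.started

    # -------------------------------------------------------------------- run
    def run(self, horizon: float | None = None, stop_on_relapse: bool = True,
            stop_on_extinction: bool = True) -> pd.DataFrame:
        horizon = self.engine.horizon if horizon is None else horizon
        self.recorder.record_frame(self.state)
        while self.state.t < horizon - 1e-9:
            self.step()
            if stop_on_relapse and self.relapse_t is not None:
                break
            if stop_on_extinction and self._extinct_t is not None:
                break
            if (self.therapy.started
                    and self.state.t - self.therapy.t_start >= self.engine.treat_horizon):
                break
        self.recorder.record_frame(self.state)
        self.outcome = self._summarize()
        return self.recorder.to_frame()

    def _summarize(self) -> dict:
        st = self.state
        relapse = self.relapse_t is not None
        extinct = self._extinct_t is not None and not relapse
        if relapse:
            outcome = "relapse"
            t_event = self.relapse_t - self.therapy.t_start
        elif extinct:
            # extinction before the treatment trigger is a failed take,
            # not a treatment response
            outcome = "extinction" if self.therapy.started else "no_take"
            t_event = (min(st.t, self._extinct_t) - self.therapy.t_start
                       if self.therapy.started else np.nan)
        else:
            outcome = "persistent-censored"
            t_event = (st.t - self.therapy.t_start) if self.therapy.started else np.nan
        return {
            "seed": self.engine.seed,
            "emdr": self.resistance.emdr_enabled,
            "p_omega": self.resistance.p_omega,
            "schedule": self.schedule.mode if self.schedule.drug != thr.Drug.NONE else "none",
            "drug": self.schedule.drug.value,
            "outcome": outcome,
            "relapse": relapse,
            "extinct": extinct,
            "t_event": t_event,
            "t_end": st.t,
            "treatment_started": self.therapy.started,
            "t_treat_start": self.therapy.t_start if self.therapy.started else np.nan,
            "mm_final": st.count(CellKind.MM),
            "n_subclones_gt10": census_from_state(st),
            "n_resistance_events": len(st.clones),
            "ba_ta_final": area_fractions(st)["ba_ta"],
            **{f"origin_{k}": v for k, v in origin_tally(st).items()},
        }


# ---------------------------------------------------------------- presets

PRESETS = ("homeostasis", "tgfb_perturb", "rankl_perturb", "mm_progression",
           "treatment_cohort", "naive_bone_drugs", "competition")


def make_simulation(preset: str, seed: int = 0, **overrides) -> Simulation:
    """Build a Simulation for a named experiment preset.

    Overrides are keyword arguments understood by :class:`Simulation`; the
    convenience scalars ``tgfb_scale``, ``rankl_scale``, ``p_omega``, ``emdr``,
    ``drug``, ``mode``, ``dose``, ``horizon``, and ``grid_shape`` are expanded
    into the right parameter objects.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    eng = overrides.pop("engine", None) or EngineConfig(seed=seed)
    eng.seed = seed
    explicit_horizon = "horizon" in overrides
    if explicit_horizon:
        eng.horizon = float(overrides.pop("horizon"))
    if "grid_shape" in overrides:
        nx, ny = overrides.pop("grid_shape")
        overrides["grid"] = GridSpec(nx=nx, ny=ny)
    fp = overrides.pop("field_params", None) or flds.FieldParams()
    if "tgfb_scale" in overrides:
        fp.tgfb_scale = float(overrides.pop("tgfb_scale"))
    if "rankl_scale" in overrides:
        fp.rankl_scale = float(overrides.pop("rankl_scale"))
    res = overrides.pop("resistance", None) or thr.ResistanceParams()
    if "p_omega" in overrides:
        res.p_omega = float(overrides.pop("p_omega"))
    if "emdr" in overrides:
        res.emdr_enabled = bool(overrides.pop("emdr"))
    sched = overrides.pop("schedule", None)
    drug = overrides.pop("drug", None)
    mode = overrides.pop("mode", "continuous")
    dose = float(overrides.pop("dose", 1.0))

    kw: dict = dict(engine=eng, field_params=fp, resistance=res)
    if preset in ("homeostasis", "tgfb_perturb", "rankl_perturb"):
        kw.update(tumor=False)
    elif preset == "mm_progression":
        kw.update(tumor=True)
        if not explicit_horizon:
            eng.horizon = 400.0
    elif preset == "treatment_cohort":
        kw.update(tumor=True,
                  schedule=sched or thr.TherapySchedule(
                      drug=thr.Drug[(drug or "BTZ").upper()], mode=mode, dose=dose))
    elif preset == "naive_bone_drugs":
        kw.update(tumor=False, drugs_from_start=True,
                  schedule=sched or thr.TherapySchedule(
                      drug=thr.Drug[(drug or "ZOL").upper()], mode=mode, dose=dose))
    elif preset == "competition":
        kw.update(tumor=True)
    kw.update(overrides)
    return Simulation(**kw)


def run_cohort(preset: str, n_replicates: int, seeds=None,
               progress: bool = False, **overrides) -> pd.DataFrame:
    """Independent replicates with distinct seeds; returns the per-replicate
    outcome table (one row per run)."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if seeds is None:
        base = overrides.pop("base_seed", 0)
        seeds = [base + 1000 * k for k in range(n_replicates)]
    rows = []
    for s in seeds:
        sim = make_simulation(preset, seed=int(s), **_fresh(overrides))
        sim.run()
        rows.append(sim.outcome)
        if progress:
            print(f"  seed {s}: {sim.outcome['outcome']} "
                  f"(t_event={sim.outcome['t_event']})", flush=True)
    return pd.DataFrame(rows)


def _fresh(overrides: dict) -> dict:
    """Deep-ish copy of parameter objects so replicates do not share state."""
    out = {}
    for k, v in overrides.items():
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            out[k] = dataclasses.replace(v)
        else:
            out[k] = v
    return out


def perturb_tgfb(scales, n_replicates: int = 5, base_seed: int = 0,
                 horizon: float = 4 * 365.0, **overrides) -> pd.DataFrame:
    """Tumor-free runs at each BDF production scale; returns the final BA/TA
    ensemble mean +- SD per scale."""
    rows = []
    for scale in scales:
        finals = []
        for k in range(n_replicates):
            sim = make_simulation("tgfb_perturb", seed=base_seed + 1000 * k,
                                  tgfb_scale=scale, horizon=horizon,
                                  **_fresh(overrides))
            sim.run()
            finals.append(sim.outcome["ba_ta_final"])
        rows.append({"tgfb_scale": scale, "ba_ta_mean": float(np.mean(finals)),
                     "ba_ta_sd": float(np.std(finals, ddof=1)) if n_replicates > 1 else 0.0,
                     "n": n_replicates})
    return pd.DataFrame(rows)


def competition_assay(seed_mix: float, n_seed: int = 100, horizon: float = 120.0,
                      seed: int = 0, cost_factor: float = 0.7,
                      **overrides) -> pd.DataFrame:
    """Mixed sensitive/resistant seeding without treatment; returns the
    resistant-fraction time series (cost of resistance assay)."""
    res = thr.ResistanceParams(cost_factor=cost_factor, p_omega=0.0)
    sim = make_simulation("competition", seed=seed, resistance=res, **overrides)
    sim.engine.horizon = horizon
    st = sim.state
    free = np.argwhere((st.kind == CellKind.EMPTY) & (st.bone.density < 1.0))
    idx = st.rng.choice(len(free), size=min(n_seed, len(free)), replace=False)
    n_res = int(round(seed_mix * len(idx)))
    for m, f in enumerate(idx):
        resistant = m < n_res
        st.add_agent(CellKind.MM, tuple(free[f]), clone_id=1 if resistant else 0,
                     resistant=resistant)
    st.mm_seeded = True
    ts = sim.run(stop_on_extinction=False)
    ts["resistant_fraction"] = np.where(ts["mm_total"] > 0,
                                        ts["mm_resistant"] / ts["mm_total"].clip(lower=1),
                                        np.nan)
    return ts
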