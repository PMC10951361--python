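"""Reaction-diffusion dynamics of RANKL and BDF (TGF-beta).

Both cytokines obey

    du/dt = D * laplacian(u) + production - delta * u

solved with the explicit forward-time centered-space (FTCS) scheme on the
periodic lattice.  RANKL is produced by RANKL-expressing osteoblast-lineage
cells; BDF has a basal production term plus release proportional to the bone
density actively resorbed by osteoclasts.  Concentrations are in arbitrary
units; thresholds elsewhere in the package are calibrated against the
homeostatic resorption-plume peak of this module's defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import CellKind, GridSpec, WorldState


@dataclass
class CytokineFields:
    """Per-site RANKL (R_L) and BDF (T_beta) concentration lattices."""

    R_L: np.ndarray
    T_beta: np.ndarray

    @classmethod
    def zeros(cls, spec: GridSpec) -> "CytokineFields":
        return cls(np.zeros(spec.shape), np.zeros(spec.shape))


@dataclass
class FieldParams:
    """Reaction-diffusion parameters.

    Diffusion coefficients are um^2/day and are bounded above by the FTCS
    stability condition D * dt_pde / h^2 <= 1/4; they are therefore effective
    (grid-scale) coefficients, far below molecular diffusivities, as is usual
    for explicit on-lattice cytokine solvers.

    tgfb_scale / rankl_scale are global production multipliers used by the
    perturbation experiments (1 = baseline).
    """

    D_R: float = 180.0       # RANKL diffusion (um^2/day)
    D_T: float = 180.0       # BDF diffusion (um^2/day)
    alpha_R: float = 10.0    # RANKL production per expressing cell (conc/day)
    alpha_B: float = 0.0075  # basal BDF production (conc/day)
    alpha_T: float = 8.0     # BDF release per unit bone resorbed (conc/density)
    delta_R: float = 0.05    # RANKL decay (1/day)
    delta_T: float = 0.15    # BDF decay (1/day)
    dt_pde: float = 0.125    # PDE time step (days)
    tgfb_scale: float = 1.0
    rankl_scale: float = 1.0
    rankl_bdf_K: float = 0.0  # BDF half-saturation of RANKL expression (0 disables)
    rankl_from_ob: bool = False       # let OB/PRE_OB express RANKL too
    bdf_release_mode: str = "resorption"  # or "bone_content"

    def stable_for(self, h: float) -> bool:
        return max(self.D_R, self.D_T) * self.dt_pde / h**2 <= 0.25 + 1e-12


def source_maps(state: WorldState, params: FieldParams | None = None) -> dict:
    """Cytokine source maps for the current step.

    rankl_sources: 1 at sites of RANKL-expressing osteoblast-lineage agents
    (activated LINING; optionally OB/PRE_OB).  bdf_sources: bone density
    resorbed at each site during the current agent step (so BDF release is
    tied to active resorption), or, in ``bone_content`` mode, the standing
    bone density at osteoclast-adjacent sites.
    """
    params = params or FieldParams()
    rankl = (state.rankl_active & (state.kind == CellKind.LINING)).astype(float)
    if params.rankl_from_ob:
        rankl += (state.kind == CellKind.OB) + (state.kind == CellKind.PRE_OB)
    if params.rankl_bdf_K > 0:
        # BDF upregulates RANKL on osteoblast-lineage cells (TGF-beta/RANKL
        # axis); expression saturates in local BDF
        T = state.fields.T_beta
        rankl = rankl * (T / (params.rankl_bdf_K + T))
    if params.bdf_release_mode == "bone_content":
        oc_adj = np.zeros(state.grid.shape, dtype=bool)
        oc = state.kind == CellKind.OC
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                oc_adj |= np.roll(oc, (di, dj), axis=(0, 1))
        bdf = state.bone.density * oc_adj
    else:
        bdf = state.resorbed_this_step.copy()
    return {"rankl_sources": rankl, "bdf_sources": bdf}


def _laplacian(u: np.ndarray, h: float) -> np.ndarray:
    """5-point Laplacian with periodic wrap (slice-based, avoids np.roll
    temporaries)."""
    out = -4.0 * u
    out[1:, :] += u[:-1, :]
    out[0, :] += u[-1, :]
    out[:-1, :] += u[1:, :]
    out[-1, :] += u[0, :]
    out[:, 1:] += u[:, :-1]
    out[:, 0] += u[:, -1]
    out[:, :-1] += u[:, 1:]
    out[:, -1] += u[:, 0]
    out /= h**2
    return out


def ftcs_step(fields: CytokineFields, params: FieldParams, sources: dict,
              h: float, state: WorldState | None = None) -> CytokineFields:
    """One explicit FTCS update of both cytokine fields (in place).

    ``sources`` holds production *rates* (conc/day): ``rankl`` and ``bdf``
    (the latter excluding the basal term, which is added here).  Negative
    values produced by round-off are clipped at zero and counted on
    ``state.n_clip_events``.
    """
    if not params.stable_for(h):
        raise ValueError(
            f"FTCS stability violated: max D * dt / h^2 = "
            f"{max(params.D_R, params.D_T) * params.dt_pde / h**2:.3f} > 1/4")
    dt = params.dt_pde
    R, T = fields.R_L, fields.T_beta
    R += dt * (params.D_R * _laplacian(R, h) + sources["rankl"] - params.delta_R * R)
    T += dt * (params.D_T * _laplacian(T, h)
               + params.alpha_B * params.tgfb_scale + sources["bdf"]
               - params.delta_T * T)
    for u in (R, T):
        neg = u < 0
        if neg.any():
            if state is not None:
                state.n_clip_events += int(neg.sum())
            np.clip(u, 0.0, None, out=u)
    return fields


def production_rates(state: WorldState, params: FieldParams, dt_agent: float) -> dict:
    """Convert source maps into production rates for :func:`ftcs_step`.

    Resorption maps accumulate density removed over one agent step of
    ``dt_agent`` days, so the release rate is alpha_T * resorbed / dt_agent.
    """
    src = source_maps(state, params)
    rankl = params.alpha_R * params.rankl_scale * src["rankl_sources"]
    if params.bdf_release_mode == "bone_content":
        bdf = params.alpha_T * params.tgfb_scale * src["bdf_sources"]
    else:
        bdf = params.alpha_T * params.tgfb_scale * src["bdf_sources"] / dt_agent
    return {"rankl": rankl, "bdf": bdf}


def field_stats(fields: CytokineFields) -> dict:
    """Exact lattice reductions per cytokine."""
    out = {}
    for name, u in (("rankl", fields.R_L), ("bdf", fields.T_beta)):
        out[name] = {"mean": float(u.mean()), "max": float(u.max()),
                     "total": float(u.sum())}
    return out
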