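"""Time-series recording, relapse-free survival, and subclone accounting.

A :class:`FrameRecorder` appends one row per recording cadence with bone,
tumor, and stromal readouts (the columns mirror the population panels the
simulator is meant to regenerate).  Cohort outcomes feed a Kaplan-Meier
product-limit estimate of relapse-free survival (via lifelines) and a census
of resistant subclones with more than ``min_size`` cells, each tagged with
the microenvironmental context in which it originated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .grid import CellKind, WorldState, area_fractions


class OriginContext(Enum):
    NEAR_STROMA = "near_stroma"
    BDF_HIGH = "bdf_high"
    NEITHER = "neither"


@dataclass
class CloneRecord:
    """Lineage entry for one resistance-acquisition event."""

    clone_id: int
    t_birth: float
    origin_site: tuple[int, int]
    origin_context: OriginContext
    size_series: list = field(default_factory=list)  # (t, count) pairs


def classify_origin(site: tuple[int, int], state: WorldState,
                    theta_emdr: float, stroma_radius_um: float = 20.0) -> OriginContext:
    """Spatial context of a resistance event: proximity to MSC/preosteoblast
    takes precedence over high BDF."""
    from .myeloma import stroma_mask
    i, j = state.grid.wrap(*site)
    if stroma_mask(state, stroma_radius_um)[i, j]:
        return OriginContext.NEAR_STROMA
    if state.fields.T_beta[i, j] > theta_emdr:
        return OriginContext.BDF_HIGH
    return OriginContext.NEITHER


class FrameRecorder:
    """Accumulates per-frame observables into a tidy DataFrame."""

    def __init__(self) -> None:
        self.rows: list[dict] = []

    def record_frame(self, state: WorldState, extra: dict | None = None) -> dict:
        from .fields import field_stats
        fr = area_fractions(state)
        counts = fr["cell_counts"]
        n_mm = counts["MM"]
        mm_sites = state.sites_of(CellKind.MM)
        n_res = int(state.resistant[mm_sites[:, 0], mm_sites[:, 1]].sum()) if n_mm else 0
        marrow = int(np.count_nonzero(state.bone.density == 0))
        fs = field_stats(state.fields)
        row = {
            "t": state.t,
            "ba_ta": fr["ba_ta"],
            "mm_fraction": fr["mm_marrow_fraction"],
            "mm_total": n_mm,
            "mm_sensitive": n_mm - n_res,
            "mm_resistant": n_res,
            "msc_pct_ma": 100.0 * counts["MSC"] / marrow if marrow else 0.0,
            "pre_ob": counts["PRE_OB"],
            "ob": counts["OB"],
            "oc": counts["OC"],
            "pre_oc": counts["PRE_OC"],
            "lining": counts["LINING"],
            "cum_oc": state.cum_oc,
            "rankl_mean": fs["rankl"]["mean"],
            "bdf_mean": fs["bdf"]["mean"],
            "bdf_max": fs["bdf"]["max"],
        }
        # per-clone census for Muller export
        if state.clones:
            ids, cts = np.unique(state.clone[state.kind == CellKind.MM],
                                 return_counts=True)
            live = dict(zip(ids.tolist(), cts.tolist()))
            for cid, rec in state.clones.items():
                rec.size_series.append((state.t, live.get(cid, 0)))
            row["clone_sizes"] = {int(c): int(n) for c, n in live.items()}
        if extra:
            row.update(extra)
        self.rows.append(row)
        return row

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def km_estimate(cohort: pd.DataFrame, horizon: float | None = None) -> pd.DataFrame:
    """Product-limit relapse-free survival over a cohort table with columns
    ``t_event`` (days from treatment start) and ``relapse`` (event indicator;
    non-relapsed replicates are censored at their recorded time)."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    from lifelines import KaplanMeierFitter
    km = KaplanMeierFitter()
    km.fit(cohort["t_event"], event_observed=cohort["relapse"].astype(int))
    tbl = km.event_table
    out = pd.DataFrame({
        "t": tbl.index.to_numpy(dtype=float),
        "S": km.survival_function_["KM_estimate"].to_numpy(),
        "n_at_risk": tbl["at_risk"].to_numpy(dtype=int),
        "n_events": tbl["observed"].to_numpy(dtype=int),
    })
    return out.reset_index(drop=True)


def subclone_census(clone_sizes: dict[int, int], min_size: int = 10) -> int:
    """Number of *resistant* clones strictly larger than ``min_size`` cells
    (clone 0 is the sensitive founder and is excluded)."""
    return sum(1 for cid, n in clone_sizes.items() if cid != 0 and n > min_size)


def census_from_state(state: WorldState, min_size: int = 10) -> int:
    mm = state.kind == CellKind.MM
    ids, cts = np.unique(state.clone[mm], return_counts=True)
    return subclone_census({int(c): int(n) for c, n in zip(ids, cts)}, min_size)


def origin_tally(state: WorldState) -> dict[str, int]:
    """Counts of resistance-acquisition events by origin context."""
    tally = {c.value: 0 for c in OriginContext}
    for rec in state.clones.values():
        tally[rec.origin_context.value] += 1
    return tally


def muller_export(state: WorldState, timeseries: pd.DataFrame) -> pd.DataFrame:
    """Long-format clone-size table {t, clone_id, parent_id, count}; clone 0
    is the sensitive founder and the parent of every resistant clone."""
    rows = []
    for _, r in timeseries.iterrows():
        sizes = r.get("clone_sizes")
        if not isinstance(sizes, dict):
            sizes = {0: int(r["mm_total"])} if r["mm_total"] else {}
        for cid, n in sizes.items():
            rows.append({"t": r["t"], "clone_id": int(cid),
                         "parent_id": -1 if cid == 0 else 0, "count": int(n)})
    return pd.DataFrame(rows, columns=["t", "clone_id", "parent_id", "count"])
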