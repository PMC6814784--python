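"""Damage protocols: lamellar disruption and SMC-to-GAG replacement.

Lamellar disruption is purely topological — no damage constitutive law:
(i) the neo-Hookean constants of the selected segment are zeroed (its
strain energy vanishes), (ii) the ruptured particles are removed from
every neighbour list, and (iii) intact particles of the same lamella on
opposite sides of the gap are disconnected from each other, severing the
lamella completely.  A relaxation step then dissipates the released
elastic energy.

SMC loss proceeds through ordered pool steps:
I   loss of contractility (active stress of the pool zeroed),
II  stiffness reduction (constituents replaced by a soft isotropic GAG),
III Gibbs-Donnan osmotic swelling switched on,
IV  rupture of the lamellae bounding the pool (radial propagation).
Each step is followed by relaxation before observables are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import materials as mats
from .dynamics import StabilizationParams, WallModel
from .geometry import ParticleSystem, WallGeometry, build_wall
from .materials import donnan_pressure

POOL_STEP_NAMES = {1: "I_contractility", 2: "II_stiffness", 3: "III_swelling"}


class ScenarioError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# event primitives


def _segment_mask(system: ParticleSystem, members, center_deg: float, extent_deg: float):
    th = np.rad2deg(system.theta)
    half = extent_deg / 2.0
    return members & (np.abs(th - center_deg) <= half)


def disrupt_lamella(model: WallModel, lamella: int, extent_deg: float,
                    center_deg: float | None = None, relax: bool = True):
    """Rupture a lamellar segment (steps i-iii) and relax.

    Only pairs crossing the gap within the sector are severed; defects are
    kept away from the periodic edges (default centre = sector midline).
    """
    sys_, mat, t = model.system, model.mat, model.table
    if center_deg is None:
        center_deg = sys_.geometry.sector_deg / 2.0
    if extent_deg <= 0:
        raise ValueError("extent must be positive")
    members = sys_.lamella == lamella
    if not members.any():
        raise ValueError(f"no lamella with index {lamella}")
    seg = _segment_mask(sys_, members, center_deg, extent_deg) & ~mat.ruptured
    if not seg.any():
        raise ScenarioError(
            f"disruption extent {extent_deg} deg selects no particles "
            "(below lattice resolution)"
        )
    # (i) zero the strain energy of the segment
    mat.mu[seg] = 0.0
    mat.lam[seg] = 0.0
    mat.phib[seg] = 0.0
    mat.ruptured[seg] = True
    # (ii) remove ruptured particles from all neighbour lists
    t.detach_particles(np.flatnonzero(seg), recompute=False)
    # (iii) fully disconnect intact same-lamella particles across the gap
    th = np.rad2deg(sys_.theta)
    half = extent_deg / 2.0
    intact = members & ~mat.ruptured
    left = intact & (th < center_deg - half)
    right = intact & (th > center_deg + half)
    cross = (
        t.active
        & (t.rot == 0)
        & ((left[t.src] & right[t.dst]) | (right[t.src] & left[t.dst]))
    )
    t.active &= ~cross
    t.compute_corrections()
    # remember segment ends for the tip-exclusion rule
    R_lam = float(np.mean(sys_.R[members]))
    for ang in (center_deg - half, center_deg + half):
        a = np.deg2rad(ang)
        tips = getattr(model, "damage_tips", [])
        tips.append((R_lam * np.cos(a), R_lam * np.sin(a)))
        model.damage_tips = tips
    if relax:
        model.relax()


@dataclass
class Pool:
    """A contiguous pool of intra-lamellar particles earmarked for SMC loss."""

    band: int
    extent_deg: float
    center_deg: float
    ids: np.ndarray
    stage: int = 0  # last completed step

    @property
    def bounding_lamellae(self):
        return (self.band, self.band + 1)


def select_pool(system: ParticleSystem, band: int, extent_deg: float,
                center_deg: float | None = None) -> Pool:
    if center_deg is None:
        center_deg = system.geometry.sector_deg / 2.0
    members = system.band == band
    if not members.any():
        raise ValueError(f"no intra-lamellar band {band}")
    mask = _segment_mask(system, members, center_deg, extent_deg)
    if not mask.any():
        raise ScenarioError(f"pool extent {extent_deg} deg selects no particles")
    return Pool(band, extent_deg, center_deg, np.flatnonzero(mask))


def pool_step(model: WallModel, pool: Pool, step: int, relax: bool = True):
    """Apply pool step I, II or III (in order) and relax."""
    if step not in (1, 2, 3):
        raise ValueError("pool step must be 1 (I), 2 (II) or 3 (III)")
    if step != pool.stage + 1:
        raise ScenarioError(
            f"pool step {step} applied out of order (last completed: {pool.stage})"
        )
    mat = model.mat
    ids = pool.ids
    if step == 1:
        mat.contractile[ids] = False
    elif step == 2:
        mat.is_gag[ids] = True
        model.system.group[ids] = mats.GAG
    else:
        p = model.system.params or _default_params()
        mat.p_swell[ids] = donnan_pressure(p.c_fc, p.c_star)
    pool.stage = step
    if relax:
        model.relax()


def disrupt_nearest_lamellae(model: WallModel, pool: Pool, relax: bool = True):
    """Step IV: rupture both lamellae bounding the pool over its full extent."""
    if pool.stage < 3:
        raise ScenarioError("step IV requires completed steps I-III")
    for j in pool.bounding_lamellae:
        disrupt_lamella(model, j, pool.extent_deg, pool.center_deg, relax=False)
    pool.stage = 4
    if relax:
        model.relax()


def _default_params():
    from .materials import MaterialParams

    return MaterialParams()


# ---------------------------------------------------------------------------
# declarative scenarios


@dataclass(frozen=True)
class DisruptLamella:
    lamella: int
    extent_deg: float
    center_deg: float | None = None


@dataclass(frozen=True)
class PoolStep:
    pool: str
    step: int  # 1, 2, 3


@dataclass(frozen=True)
class DisruptNearestLamellae:
    pool: str


@dataclass(frozen=True)
class PoolSpec:
    band: int
    extent_deg: float
    center_deg: float | None = None


@dataclass(frozen=True)
class RegionSpec:
    """Named observation region: a lamella ring or intra-lamellar band,
    restricted to a narrow angular window (the radial line through the
    defect midpoint for damage read-outs)."""

    name: str
    kind: str       # "lamella" | "band"
    index: int
    center_deg: float
    half_deg: float


@dataclass
class Scenario:
    """Ordered damage/activation events with evaluation pressures."""

    events: list
    pools: dict = field(default_factory=dict)
    regions: list = field(default_factory=list)
    pressures: tuple = (102.0, 136.0, 184.0)
    tone_on: bool = False
    pre_events: list = field(default_factory=list)  # applied before the baseline record

    def validate(self, sector_deg: float):
        seen = {name: 0 for name in self.pools}
        for ev in self.events:
            if isinstance(ev, PoolStep):
                if ev.pool not in self.pools:
                    raise ScenarioError(f"unknown pool {ev.pool!r}")
                if ev.step != seen[ev.pool] + 1:
                    raise ScenarioError("pool steps must run I -> II -> III in order")
                seen[ev.pool] = ev.step
            elif isinstance(ev, DisruptNearestLamellae):
                if seen.get(ev.pool, 0) < 3:
                    raise ScenarioError("step IV requires completed steps I-III")
                seen[ev.pool] = 4
        for spec in self.pools.values():
            if not 0 < spec.extent_deg <= sector_deg:
                raise ScenarioError("pool extent must be positive and fit the sector")


def region_ids(system: ParticleSystem, spec: RegionSpec):
    if spec.kind == "lamella":
        members = system.lamella == spec.index
    elif spec.kind == "band":
        members = system.band == spec.index
    else:
        raise ValueError(f"unknown region kind {spec.kind!r}")
    return np.flatnonzero(_segment_mask(system, members, spec.center_deg, 2 * spec.half_deg))


def regional_max_stress(record, system: ParticleSystem, ids, tips=(), support: float = 0.0):
    """Maximum circumferential Cauchy stress over a region.

    Particles within one kernel support of a disrupted-segment end are
    excluded: the near-tip field of a severed lamella is not resolved by
    the smoothing length, only the radial load transfer across the defect
    midline is.
    """
    ids = np.asarray(ids)
    if ids.size == 0:
        raise ValueError("empty region")
    keep = np.ones(ids.size, dtype=bool)
    if len(tips) and support > 0:
        X = system.X[ids]
        for tx, ty in tips:
            d = np.hypot(X[:, 0] - tx, X[:, 1] - ty)
            keep &= d > support
    if not keep.any():
        raise ValueError("region empty after tip exclusion")
    return float(np.max(record.sigma_tt[ids[keep]]))


def run_scenario(model: WallModel, scenario: Scenario,
                 pressures=None) -> pd.DataFrame:
    """Execute a scenario at each pressure on fresh copies of the model state.

    For each pressure: equilibrate, apply the events in order (each
    followed by relaxation), and record the regional maximum
    circumferential stresses after the baseline and after every event.
    Deterministic given the configuration.

    The passed model must be at its (relaxed) homeostatic reference; it
    is deep-copied per pressure so damage never leaks across runs.
    """
    scenario.validate(model.system.geometry.sector_deg)
    pressures = scenario.pressures if pressures is None else pressures
    rows = []
    for p in pressures:
        m = _copy_model(model)
        m.tone_on = scenario.tone_on
        pools = {
            name: select_pool(m.system, s.band, s.extent_deg, s.center_deg)
            for name, s in scenario.pools.items()
        }
        for ev in scenario.pre_events:
            _apply_event(m, ev, pools)
        rec = m.equilibrate_pressure(p)
        rows += _record(m, rec, "baseline", p, scenario)
        for ev in scenario.events:
            label, diag = _apply_event(m, ev, pools)
            rec = m.measure(diag)
            rows += _record(m, rec, label, p, scenario)
    return pd.DataFrame(rows)


def _apply_event(model, ev, pools):
    """Apply one event, then relax; a relaxation that exhausts its budget
    is recorded (converged=False) rather than fatal — severed-tip regions
    can retain slow, localised residual motion that leaves the midline
    observables stationary."""
    if isinstance(ev, DisruptLamella):
        disrupt_lamella(model, ev.lamella, ev.extent_deg, ev.center_deg, relax=False)
        label = f"disrupt_lamella_{ev.lamella}"
    elif isinstance(ev, PoolStep):
        pool_step(model, pools[ev.pool], ev.step, relax=False)
        label = f"{ev.pool}:{POOL_STEP_NAMES[ev.step]}"
    elif isinstance(ev, DisruptNearestLamellae):
        disrupt_nearest_lamellae(model, pools[ev.pool], relax=False)
        label = f"{ev.pool}:IV_lamellar_disruption"
    else:
        raise ScenarioError(f"unknown event {ev!r}")
    warn = model.stab.warn_only
    model.stab.warn_only = True
    try:
        diag = model.relax()
    finally:
        model.stab.warn_only = warn
    return label, diag


def _record(model, rec, event, pressure, scenario):
    tips = getattr(model, "damage_tips", [])
    rows = []
    for spec in scenario.regions:
        ids = region_ids(model.system, spec)
        try:
            smax = regional_max_stress(rec, model.system, ids, tips, model.table.support)
        except ValueError:
            smax = np.nan
        rows.append(
            {
                "pressure_mmhg": pressure,
                "event": event,
                "region": spec.name,
                "max_sigma_tt_kpa": smax,
                "reported_pressure_mmhg": rec.pressure_mmhg,
                "outer_diameter_um": rec.outer_diameter,
                "converged": rec.converged,
            }
        )
    return rows


def _copy_model(model: WallModel) -> WallModel:
    """Fresh WallModel sharing nothing mutable with the original."""
    import copy

    sys0 = model.system
    sys_ = ParticleSystem(
        geometry=sys0.geometry,
        X=sys0.X.copy(), R=sys0.R.copy(), theta=sys0.theta.copy(), V=sys0.V.copy(),
        group=sys0.group.copy(), lamella=sys0.lamella.copy(), band=sys0.band.copy(),
        ring=sys0.ring.copy(), inner_rim=sys0.inner_rim.copy(),
        outer_rim=sys0.outer_rim.copy(), lamella_radii=sys0.lamella_radii.copy(),
        materials=sys0.materials.copy(), params=sys0.params,
    )
    from .neighbors import NeighborTable

    table = NeighborTable.__new__(NeighborTable)
    t0 = model.table
    for name in ("n", "support", "sector_angle"):
        setattr(table, name, getattr(t0, name))
    for name in ("X", "V", "src", "dst", "rot", "rot_cos", "rot_sin", "rvec",
                 "rlen", "weight", "grad_raw", "grad_corr", "active", "A", "live"):
        setattr(table, name, getattr(t0, name).copy())
    table.V = sys_.V
    m = WallModel.__new__(WallModel)
    m.system = sys_
    m.table = table
    m.mat = sys_.materials
    m.stab = copy.deepcopy(model.stab)
    m.x = model.x.copy()
    m.v = model.v.copy()
    m.tone_on = model.tone_on
    m.lambda_z = model.lambda_z
    m.rim_scale = model.rim_scale
    m._mass_boost = model._mass_boost
    m.damage_tips = list(getattr(model, "damage_tips", []))
    return m


# ---------------------------------------------------------------------------
# canonical damage-study constructors


def _window(center_deg, extent_deg, system: ParticleSystem, support: float):
    """Angular half-window of the read-out region.

    Stress concentrations are read along the radial line through the
    defect *midpoint* (transmurally across the defect, away from the
    severed tips where the smoothed fields are unreliable), so the window
    is one degree or one particle arc-spacing, whichever is wider — not
    the defect extent.
    """
    r_mid = system.geometry.r_in + system.geometry.h_media / 2.0
    return max(1.0, np.rad2deg(system.geometry.spacing / r_mid))


def scenario_lamellar_rupture(system: ParticleSystem, extent_deg: float,
                              support: float, center_deg: float | None = None,
                              sequence=(3, 4, 2), tone_on: bool = False) -> Scenario:
    """Sequential rupture of the middle, next-outer and next-inner lamellae.

    Observables: maximum circumferential stress in the intra-lamellar
    bands just outside (band 3) and inside (band 2) the middle lamella.
    """
    c = system.geometry.sector_deg / 2.0 if center_deg is None else center_deg
    half = _window(c, extent_deg, system, support)
    regions = [
        RegionSpec("outer_intra", "band", 3, c, half),
        RegionSpec("inner_intra", "band", 2, c, half),
    ]
    events = [DisruptLamella(j, extent_deg, c) for j in sequence]
    return Scenario(events=events, regions=regions, tone_on=tone_on)


def _pool_regions(system, band, c, half):
    lo, hi = band, band + 1
    regions = [
        RegionSpec("nearest_lamella", "lamella", hi, c, half),
        RegionSpec("nearest_lamella_inner", "lamella", lo, c, half),
        RegionSpec("nearest_intra", "band", band + 1, c, half),
        RegionSpec("nearest_intra_inner", "band", band - 1, c, half),
        RegionSpec("second_lamella", "lamella", hi + 1, c, half),
        RegionSpec("second_intra", "band", band - 2, c, half),
    ]
    return [r for r in regions if _region_exists(system, r)]


def _region_exists(system, r):
    if r.kind == "lamella":
        return 0 <= r.index < system.geometry.n_lamellae
    return 0 <= r.index < system.geometry.n_units


def scenario_single_pool(system: ParticleSystem, extent_deg: float, support: float,
                         band: int = 3, center_deg: float | None = None,
                         with_step4: bool = True, tone_on: bool = True) -> Scenario:
    """Steps I-III (optionally IV) for one pool between the middle and
    next-outer lamellae."""
    c = system.geometry.sector_deg / 2.0 if center_deg is None else center_deg
    half = _window(c, extent_deg, system, support)
    pools = {"pool": PoolSpec(band, extent_deg, c)}
    events = [PoolStep("pool", 1), PoolStep("pool", 2), PoolStep("pool", 3)]
    if with_step4:
        events.append(DisruptNearestLamellae("pool"))
    return Scenario(events=events, pools=pools,
                    regions=_pool_regions(system, band, c, half), tone_on=tone_on)


def scenario_two_pools(system: ParticleSystem, extent_deg: float, support: float,
                       bands=(2, 4), center_deg: float | None = None,
                       with_step4: bool = True, tone_on: bool = True) -> Scenario:
    """Two pools of equal extent separated radially by one intact
    intra-lamellar space.

    The default bands (2, 4) sandwich the single-pool band 3, so the
    'interior' lamellae between the pools are the same lamellae that
    bound the single pool — the two studies are then read off identical
    material regions.  'Exterior' regions sit on the far sides.
    Step IV ruptures the interior lamellae.
    """
    lo, hi = bands
    if hi - lo != 2:
        raise ScenarioError("pools must be separated by exactly one intact band")
    c = system.geometry.sector_deg / 2.0 if center_deg is None else center_deg
    half = _window(c, extent_deg, system, support)
    mid = lo + 1
    regions = [
        RegionSpec("interior_lamella", "lamella", mid, c, half),
        RegionSpec("interior_lamella_outer", "lamella", mid + 1, c, half),
        RegionSpec("exterior_lamella", "lamella", lo, c, half),
        RegionSpec("exterior_lamella_outer", "lamella", hi + 1, c, half),
        RegionSpec("interior_intra", "band", mid, c, half),
        RegionSpec("exterior_intra", "band", lo - 1, c, half),
    ]
    regions = [r for r in regions if _region_exists(system, r)]
    pools = {"A": PoolSpec(lo, extent_deg, c), "B": PoolSpec(hi, extent_deg, c)}
    events = []
    for step in (1, 2, 3):
        events += [PoolStep("A", step), PoolStep("B", step)]
    scen = Scenario(events=events, pools=pools, regions=regions, tone_on=tone_on)
    if with_step4:
        # rupture only the interior (shared-side) lamellae, over the pool extent
        scen.events.append(DisruptLamella(mid, extent_deg, c))
        scen.events.append(DisruptLamella(mid + 1, extent_deg, c))
    return scen


def scenario_merged_pools(system: ParticleSystem, extent_deg: float, support: float,
                          bands=(2, 3), center_deg: float | None = None,
                          with_step4: bool = True, tone_on: bool = True) -> Scenario:
    """Two pools in adjacent bands merged by removing the shared lamella
    before the baseline; extents are doubled relative to the single-pool
    study by the caller."""
    lo, hi = bands
    if hi - lo != 1:
        raise ScenarioError("merged pools must occupy adjacent bands")
    c = system.geometry.sector_deg / 2.0 if center_deg is None else center_deg
    half = _window(c, extent_deg, system, support)
    regions = [
        RegionSpec("nearest_lamella", "lamella", hi + 1, c, half),
        RegionSpec("nearest_lamella_inner", "lamella", lo, c, half),
        RegionSpec("nearest_intra", "band", hi + 1, c, half),
        RegionSpec("nearest_intra_inner", "band", lo - 1, c, half),
        RegionSpec("second_lamella", "lamella", hi + 2, c, half),
    ]
    regions = [r for r in regions if _region_exists(system, r)]
    pools = {"A": PoolSpec(lo, extent_deg, c), "B": PoolSpec(hi, extent_deg, c)}
    events = []
    for step in (1, 2, 3):
        events += [PoolStep("A", step), PoolStep("B", step)]
    scen = Scenario(
        events=events, pools=pools, regions=regions, tone_on=tone_on,
        pre_events=[DisruptLamella(hi, extent_deg, c)],
    )
    if with_step4:
        scen.events.append(DisruptLamella(lo, extent_deg, c))
        scen.events.append(DisruptLamella(hi + 1, extent_deg, c))
    return scen
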