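"""Synthetic heat-stress phenotyping experiment generator.

Emulates the full factorial screen the analysis assumes: 2 genotypes
(WT, hsp101) x 4 heat regimes (control, 3 h, 6 h, 9 h at 45 deg C) x 20
replicates, imaged daily from one day before stress (DAS -1) to seven days
after (DAS 7).  For every alive plant-day the generator produces

* a latent physiological state (true rosette area, fluorescence depression,
  quenching retention, leaf-temperature offset, leaf geometry),
* a binary top-view rosette mask (parametric leaf-lobe rosette),
* a raw chlorophyll-fluorescence light-curve record,
* a thermal raster.

The injected dynamics mirror the qualitative behaviour of the real screen:
logistic rosette growth with a stress-proportional penalty and an acute
turgor-loss shrinkage on the stress day, a dip of the maximum PSII quantum
yield at DAS 0 that wild type clears after 1 day and hsp101 only after 2,
stress-hour-proportional Fm depression (capped), a reduction of
photochemical quenching whose retention is coupled to a latent per-plant
tolerance variable that also modulates post-stress growth (so early
quenching predicts late rosette area in stressed plants), elevated leaf
temperature right after heat exposure, morphology shifts (less slender
leaves, more open rosettes), and sporadic death under the 9 h regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from phenoheat.fluortraits import LightStepSignal, RawFluorescence
from phenoheat.morphometry import RosetteMask, ThermalRaster

GENOTYPES = ("WT", "hsp101")
TREATMENTS = ("control", "HS3h", "HS6h", "HS9h")
STRESS_HOURS: Mapping[str, float] = {"control": 0.0, "HS3h": 3.0, "HS6h": 6.0, "HS9h": 9.0}
DAS_DAYS = tuple(range(-1, 8))
TRAY_CAPACITY = 20  # 5 x 4 pots per tray


class RenderOverflowError(ValueError):
    """Rosette does not fit on the requested raster at the given scale."""


@dataclass(frozen=True)
class LightProtocol:
    """Light-curve protocol: increasing actinic steps after dark adaptation."""

    actinic_intensities: tuple[float, ...] = (95.0, 210.0, 320.0, 440.0, 555.0, 670.0)
    step_duration_s: int = 60
    dark_adaptation_min: int = 15

    def __post_init__(self) -> None:
        ints = tuple(float(v) for v in self.actinic_intensities)
        if any(b <= a for a, b in zip(ints, ints[1:])):
            raise ValueError("actinic intensities must be strictly increasing")
        object.__setattr__(self, "actinic_intensities", ints)

    @property
    def n_steps(self) -> int:
        return len(self.actinic_intensities)


@dataclass
class PlantRecord:
    """One plant of the design registry."""

    plant_id: str
    genotype: str
    treatment: str
    tray: int
    position: int
    tolerance_latent: float
    failed_to_grow: bool = False
    death_das: int | None = None

    def alive(self, das: int) -> bool:
        """Alive at the given imaging day (monotone: death is permanent)."""
        return self.death_das is None or das < self.death_das

    @property
    def excluded(self) -> bool:
        """Flagged for removal: died during the experiment or never grew."""
        return self.failed_to_grow or self.death_das is not None


@dataclass
class ExperimentDesign:
    plants: list[PlantRecord]
    days: tuple[int, ...] = DAS_DAYS
    light_protocol: LightProtocol = field(default_factory=LightProtocol)

    @property
    def n_trays(self) -> int:
        return len({p.tray for p in self.plants})


def _default_treatment_map(value_by_treatment: dict[str, float]):
    return field(default_factory=lambda: dict(value_by_treatment))


@dataclass
class SimulationParams:
    """All tunable generator parameters (units noted per field)."""

    seed: int = 0

    # --- growth (mm^2, per day) ---
    initial_area_mm2: float = 300.0
    growth_rate_per_day: float = 0.25
    carrying_capacity_mm2: float = 3000.0
    #: multiplicative growth-rate penalty per treatment, applied from DAS 0
    growth_penalty: dict[str, float] = _default_treatment_map(
        {"control": 0.0, "HS3h": 0.17, "HS6h": 0.33, "HS9h": 0.50}
    )
    #: extra penalty suffered by hsp101 (vanishes at 9 h, where both
    #: genotypes are equally damaged)
    hsp101_growth_penalty_extra: dict[str, float] = _default_treatment_map(
        {"control": 0.0, "HS3h": 0.08, "HS6h": 0.12, "HS9h": 0.0}
    )
    #: acute area shrinkage (turgor loss) on the stress day, per stress hour
    stress_shrink_per_hour: float = 0.025
    growth_noise_sd: float = 0.03
    runt_probability: float = 0.05
    runt_growth_factor: float = 0.1

    # --- chlorophyll fluorescence (a.u., dimensionless) ---
    f0_baseline: float = 200.0
    qymax_baseline: float = 0.80
    qymax_noise_sd: float = 0.02
    #: multiplicative Fm depression per stress hour on the stress day
    fm_depression_per_hour: float = 0.05
    fm_depression_cap: float = 0.45
    hsp101_depression_multiplier: float = 1.8
    #: per-plant heterogeneity of the heat damage, growing with severity:
    #: the depression is scaled by exp(N(0, sd*sqrt(hours))) — severe stress
    #: produces erratic damage, blurring genotype contrasts at 9 h
    damage_heterogeneity_sd: float = 0.06
    #: days until the QY-max (Fm) deficit decays to zero
    qymax_recovery_delay_days: dict[str, int] = field(
        default_factory=lambda: {"WT": 1, "hsp101": 2}
    )
    npq_per_step: tuple[float, ...] = (0.10, 0.25, 0.45, 0.70, 0.95, 1.20)
    qp_per_step: tuple[float, ...] = (0.87, 0.79, 0.71, 0.63, 0.55, 0.47)
    #: fractional qP drop at DAS 0 per treatment (WT)
    qp_drop: dict[str, float] = _default_treatment_map(
        {"control": 0.0, "HS3h": 0.25, "HS6h": 0.40, "HS9h": 0.50}
    )
    hsp101_qp_extra_drop: dict[str, float] = _default_treatment_map(
        {"control": 0.0, "HS3h": 0.15, "HS6h": 0.20, "HS9h": 0.05}
    )
    #: days until qP recovers (WT); hsp101 adds one day
    qp_recovery_delay_days: dict[str, int] = _default_treatment_map(
        {"control": 0, "HS3h": 1, "HS6h": 2, "HS9h": 3}
    )
    hsp101_qp_recovery_extra_days: int = 1
    npq_drop_per_hour: float = 0.03
    fluor_noise_sd: float = 0.02
    vigor_sd: float = 0.05

    #: couples the latent per-plant tolerance to DAS 0 quenching retention
    #: and to post-stress growth (0 = decoupled)
    tolerance_coupling: float = 0.6
    qp_tolerance_span: float = 0.5
    growth_tolerance_span: float = 0.6

    # --- thermal (deg C) ---
    ambient_temp_c: float = 22.0
    transpiration_cooling_c: float = 1.2
    #: leaf-temperature offset per stress hour, on the stress day
    temp_offset_per_hour_c: float = 0.25
    thermal_pixel_noise_sd: float = 0.15
    plant_temp_noise_sd: float = 0.2

    # --- mortality ---
    death_probability_hs9h: float = 0.1

    # --- morphology ---
    leaf_aspect_baseline: float = 2.6
    #: fractional reduction of leaf aspect (slenderness) per stress hour,
    #: ramping in over two days after stress
    leaf_aspect_drop_per_hour: float = 0.02
    #: genotype amplification of the morphology response; near-equal at 9 h
    #: where the stress overwhelms both genotypes
    hsp101_aspect_extra_factor: dict[str, float] = _default_treatment_map(
        {"control": 1.0, "HS3h": 1.5, "HS6h": 1.6, "HS9h": 1.1}
    )
    openness_baseline: float = 0.45
    openness_stress_gain_per_hour: float = 0.015

    def validate(self) -> None:
        for name, d in (
            ("growth_penalty", self.growth_penalty),
            ("hsp101_growth_penalty_extra", self.hsp101_growth_penalty_extra),
            ("qp_drop", self.qp_drop),
            ("hsp101_qp_extra_drop", self.hsp101_qp_extra_drop),
        ):
            for k, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}[{k}]={v} outside [0, 1]")
        if not 0.0 <= self.death_probability_hs9h <= 1.0:
            raise ValueError("death probability must lie in [0, 1]")
        for name in (
            "growth_noise_sd",
            "qymax_noise_sd",
            "fluor_noise_sd",
            "thermal_pixel_noise_sd",
            "plant_temp_noise_sd",
            "vigor_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.qymax_baseline < 1.0:
            raise ValueError("qymax_baseline must lie in (0, 1)")


@dataclass
class PlantDayState:
    """Latent state of one alive plant on one imaging day."""

    plant_id: str
    genotype: str
    treatment: str
    das: int
    alive: bool
    true_area_mm2: float
    qymax_true: float
    fm_factor: float  # multiplicative Fm depression (1 = unstressed)
    qp_scale: float  # multiplier on the baseline per-step qP profile
    npq_scale: float  # multiplier on the baseline per-step NPQ profile
    leaf_temp_offset_c: float
    n_leaves: int
    leaf_aspect: float
    openness: float
    vigor: float
    tolerance: float


def build_design(
    n_reps: int, seed: int, light_protocol: LightProtocol | None = None
) -> ExperimentDesign:
    """Build the factorial design registry: 2 genotypes x 4 treatments x n_reps.

    Plants are laid out on trays of 20 positions, genotypes alternating
    within a treatment block (checkerboard-style), replicates evenly
    distributed.  Deterministic for a fixed seed (the seed feeds the latent
    per-plant tolerance draws).
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    plants: list[PlantRecord] = []
    idx = 0
    for treatment in TREATMENTS:
        for rep in range(n_reps):
            for genotype in GENOTYPES:  # alternate genotypes within a tray
                tol = float(rng.uniform(0.0, 1.0))
                plants.append(
                    PlantRecord(
                        plant_id=f"P{idx + 1:03d}",
                        genotype=genotype,
                        treatment=treatment,
                        tray=idx // TRAY_CAPACITY + 1,
                        position=idx % TRAY_CAPACITY + 1,
                        tolerance_latent=tol,
                    )
                )
                idx += 1
    return ExperimentDesign(
        plants=plants,
        days=DAS_DAYS,
        light_protocol=light_protocol or LightProtocol(),
    )


def _relief(das: int, delay: float) -> float:
    """Linear decay of a stress deficit: 1 at DAS 0, 0 from DAS >= delay."""
    if das < 0 or delay <= 0:
        return 0.0
    return max(0.0, 1.0 - das / delay)


def _plant_rng(seed: int, plant_index: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 777, plant_index, tag]))


def simulate_experiment(
    design: ExperimentDesign, params: SimulationParams
) -> list[PlantDayState]:
    """Simulate the latent per-plant-day states of the whole experiment.

    Side effects on the registry: sets ``failed_to_grow`` (runts) and
    ``death_das`` (sporadic death under the 9 h regime, decided on the
    stress day).  Dead plants emit no further states.  Deterministic for a
    fixed ``params.seed``.
    """
    params.validate()
    states: list[PlantDayState] = []
    for i, plant in enumerate(design.plants):
        rng = _plant_rng(params.seed, i, 0)
        hours = STRESS_HOURS[plant.treatment]
        is_hsp = plant.genotype == "hsp101"
        tol = plant.tolerance_latent
        vigor = float(np.exp(rng.normal(0.0, params.vigor_sd)))

        plant.failed_to_grow = bool(rng.uniform() < params.runt_probability)
        plant.death_das = None
        if plant.treatment == "HS9h" and rng.uniform() < params.death_probability_hs9h:
            plant.death_das = 0

        # growth-rate schedule
        r_base = params.growth_rate_per_day * (
            params.runt_growth_factor if plant.failed_to_grow else 1.0
        )
        penalty = params.growth_penalty[plant.treatment]
        if is_hsp:
            penalty = min(1.0, penalty + params.hsp101_growth_penalty_extra[plant.treatment])
        tol_growth = 1.0 + params.tolerance_coupling * params.growth_tolerance_span * (
            tol - 0.5
        ) * (1.0 if hours > 0 else 0.0)
        r_post = r_base * (1.0 - penalty) * tol_growth

        # fluorescence depression and quenching schedules
        depression = min(
            params.fm_depression_per_hour
            * hours
            * (params.hsp101_depression_multiplier if is_hsp else 1.0),
            params.fm_depression_cap,
        )
        if hours > 0 and params.damage_heterogeneity_sd > 0:
            jitter = float(
                np.exp(rng.normal(0.0, params.damage_heterogeneity_sd * math.sqrt(hours)))
            )
            depression = min(depression * jitter, 0.55)
        qy_delay = params.qymax_recovery_delay_days[plant.genotype]
        qp_drop = params.qp_drop[plant.treatment]
        if is_hsp:
            qp_drop = min(0.9, qp_drop + params.hsp101_qp_extra_drop[plant.treatment])
        if hours > 0:
            qp_drop = float(
                np.clip(
                    qp_drop
                    - params.tolerance_coupling * params.qp_tolerance_span * (tol - 0.5),
                    0.0,
                    0.95,
                )
            )
        qp_delay = params.qp_recovery_delay_days[plant.treatment] + (
            params.hsp101_qp_recovery_extra_days if (is_hsp and hours > 0) else 0
        )
        npq_drop = min(params.npq_drop_per_hour * hours, 0.5)

        area = params.initial_area_mm2 * vigor * float(
            np.exp(rng.normal(0.0, params.growth_noise_sd))
        )
        k_cap = params.carrying_capacity_mm2
        for das in design.days:
            if not plant.alive(das):
                continue
            if das == 0 and hours > 0:
                area *= 1.0 - params.stress_shrink_per_hour * hours
            qymax = 1.0 - (1.0 - params.qymax_baseline) / (
                1.0 - depression * _relief(das, qy_delay)
            )
            qymax = float(
                np.clip(qymax + rng.normal(0.0, params.qymax_noise_sd), 0.05, 0.92)
            )
            aspect_drop = (
                params.leaf_aspect_drop_per_hour
                * hours
                * (params.hsp101_aspect_extra_factor[plant.treatment] if is_hsp else 1.0)
                * min(1.0, max(0.0, das + 1) / 2.0)  # ramps in over 2 days
            )
            openness = params.openness_baseline + (
                params.openness_stress_gain_per_hour * hours if das >= 0 else 0.0
            )
            states.append(
                PlantDayState(
                    plant_id=plant.plant_id,
                    genotype=plant.genotype,
                    treatment=plant.treatment,
                    das=das,
                    alive=True,
                    true_area_mm2=area,
                    qymax_true=qymax,
                    fm_factor=1.0 - depression * _relief(das, qy_delay),
                    qp_scale=1.0 - qp_drop * _relief(das, qp_delay),
                    npq_scale=1.0 - npq_drop * _relief(das, qp_delay),
                    leaf_temp_offset_c=(
                        params.temp_offset_per_hour_c * hours if das == 0 else 0.0
                    ),
                    n_leaves=6 + int(area // 250.0),
                    leaf_aspect=max(1.0, params.leaf_aspect_baseline * (1.0 - aspect_drop)),
                    openness=float(np.clip(openness, 0.0, 0.8)),
                    vigor=vigor,
                    tolerance=tol,
                )
            )
            # grow to the next day (penalty applies once stress happened)
            r_day = (r_post if das >= 0 else r_base) * float(
                np.exp(rng.normal(0.0, params.growth_noise_sd))
            )
            area = k_cap / (1.0 + (k_cap / area - 1.0) * math.exp(-r_day))
    return states


# ---------------------------------------------------------------------------
# rosette mask rendering


def _render_rosette(
    shape: tuple[int, int],
    radius_px: float,
    n_leaves: int,
    aspect: float,
    openness: float,
    angles: np.ndarray,
    length_jitter: np.ndarray,
) -> np.ndarray:
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.indices((h, w), dtype=np.float64)
    dy, dx = yy - cy, xx - cx
    grid = np.zeros((h, w), dtype=bool)
    if n_leaves == 1:
        # single leaf degenerates to a centred ellipse
        la = radius_px
        lb = la / aspect
        cos_a, sin_a = math.cos(angles[0]), math.sin(angles[0])
        u = cos_a * dx + sin_a * dy
        v = -sin_a * dx + cos_a * dy
        grid |= (u / la) ** 2 + (v / lb) ** 2 <= 1.0
    else:
        ri = openness * radius_px * 0.5
        for i in range(n_leaves):
            tip = radius_px * length_jitter[i]
            la = max((tip - ri) / 2.0, 1.0)
            lb = max(la / aspect, 0.8)
            d0 = (ri + tip) / 2.0
            cos_a, sin_a = math.cos(angles[i]), math.sin(angles[i])
            ly = cy + d0 * sin_a
            lx = cx + d0 * cos_a
            u = cos_a * (xx - lx) + sin_a * (yy - ly)
            v = -sin_a * (xx - lx) + cos_a * (yy - ly)
            grid |= (u / la) ** 2 + (v / lb) ** 2 <= 1.0
        r0 = max(ri * 1.1, radius_px * 0.15)
        grid |= dy**2 + dx**2 <= r0**2
    return grid


def render_rosette_mask(
    state: PlantDayState,
    grid: tuple[int, int] = (180, 180),
    scale: float = 0.6,
    seed: int = 0,
) -> RosetteMask:
    """Render a parametric binary rosette whose pixel area matches the state.

    The rosette is a centre disk plus ``n_leaves`` elliptic lobes; the
    radial extent is solved iteratively so the foreground pixel count
    matches ``true_area_mm2 / scale**2`` within 2% (well inside the 5%
    contract).  Bit-identical for identical state and seed.
    """
    target_px = state.true_area_mm2 / scale**2
    if target_px < 1.0:
        raise RenderOverflowError("target area below one pixel at this scale")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3001]))
    n = max(1, int(state.n_leaves))
    angles = (
        2.0 * math.pi * np.arange(n) / n
        + rng.uniform(0.0, 2.0 * math.pi)
        + rng.normal(0.0, 0.12, size=n)
    )
    length_jitter = np.clip(1.0 + rng.normal(0.0, 0.08, size=n), 0.7, 1.3)
    fill_guess = 0.5 if n > 1 else 1.0 / state.leaf_aspect
    radius = math.sqrt(target_px / (math.pi * max(fill_guess, 0.05)))
    half = (min(grid) - 1) / 2.0
    mask = None
    for _ in range(8):
        if radius * max(length_jitter) >= half - 1.0:
            raise RenderOverflowError(
                f"rosette radius {radius:.1f}px exceeds grid half-extent {half:.1f}px"
            )
        mask = _render_rosette(
            grid, radius, n, state.leaf_aspect, state.openness, angles, length_jitter
        )
        got = int(mask.sum())
        if got == 0:
            radius *= 1.5
            continue
        ratio = target_px / got
        if abs(ratio - 1.0) <= 0.02:
            break
        radius *= math.sqrt(ratio)
    assert mask is not None
    return RosetteMask(grid=mask, scale=scale)


def simulate_fluorescence_day(
    state: PlantDayState,
    protocol: LightProtocol,
    params: SimulationParams,
    seed: int = 0,
) -> RawFluorescence:
    """Emit one raw light-curve record for an alive plant-day.

    The noiseless construction guarantees ``Fm > F0`` and, per step,
    ``Fm' > Ft' >= F0'`` with ``Fm'`` monotonically decreasing over the
    increasing actinic intensities (NPQ builds up with light).  Gaussian
    multiplicative noise is added afterwards; in the rare case noise breaks
    an ordering the signals are redrawn (up to 10 times) so downstream
    derivations stay in-domain.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4001]))
    n_steps = protocol.n_steps
    if len(params.npq_per_step) < n_steps or len(params.qp_per_step) < n_steps:
        raise ValueError("per-step baseline profiles shorter than the protocol")
    # amplitude is a plant-mean signal, independent of rosette size
    f0_true = params.f0_baseline
    qy = min(state.qymax_true, 0.92)
    fm_true = f0_true / (1.0 - qy)

    def noisy(value: float) -> float:
        return value * max(1e-3, 1.0 + float(rng.normal(0.0, params.fluor_noise_sd)))

    f0 = noisy(f0_true)
    fm = noisy(fm_true)
    while fm <= f0:  # essentially unreachable at realistic noise levels
        fm = noisy(fm_true)
    steps: list[LightStepSignal] = []
    for k in range(n_steps):
        npq_k = params.npq_per_step[k] * state.npq_scale
        qp_k = float(np.clip(params.qp_per_step[k] * state.qp_scale, 0.02, 0.98))
        fmp_true = fm_true / (1.0 + npq_k)
        # light-adapted minimal fluorescence (Oxborough-Baker form)
        f0p_true = f0_true / (qy + f0_true / fmp_true)
        ftp_true = fmp_true - qp_k * (fmp_true - f0p_true)
        for _ in range(10):
            f0p, ftp, fmp = noisy(f0p_true), noisy(ftp_true), noisy(fmp_true)
            if fmp > ftp and fmp > f0p and fm > f0p:
                break
        steps.append(LightStepSignal(f0p=f0p, ftp=ftp, fmp=fmp))
    return RawFluorescence(f0=f0, fm=fm, steps=tuple(steps))


def simulate_thermal_day(
    mask: RosetteMask,
    state: PlantDayState,
    params: SimulationParams,
    seed: int = 0,
) -> ThermalRaster:
    """Emit a thermal raster paired with a rendered mask.

    Background sits at ambient; rosette pixels at ambient minus
    transpiration cooling, plus the stress-day offset, a per-plant offset
    and per-pixel noise.
    """
    if not mask.grid.any():
        raise ValueError("mask has no foreground pixels")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5001]))
    h, w = mask.grid.shape
    grid = params.ambient_temp_c + rng.normal(
        0.0, params.thermal_pixel_noise_sd, size=(h, w)
    )
    leaf_temp = (
        params.ambient_temp_c
        - params.transpiration_cooling_c
        + state.leaf_temp_offset_c
        + float(rng.normal(0.0, params.plant_temp_noise_sd))
    )
    grid[mask.grid] = leaf_temp + rng.normal(
        0.0, params.thermal_pixel_noise_sd, size=int(mask.grid.sum())
    )
    return ThermalRaster(grid=grid)


def registry_frame(design: ExperimentDesign):
    """Design registry as a flat table (one row per plant)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "plant_id": [p.plant_id for p in design.plants],
            "genotype": [p.genotype for p in design.plants],
            "treatment": [p.treatment for p in design.plants],
            "tray": [p.tray for p in design.plants],
            "position": [p.position for p in design.plants],
            "tolerance_latent": [p.tolerance_latent for p in design.plants],
            "failed_to_grow": [p.failed_to_grow for p in design.plants],
            "death_das": [p.death_das for p in design.plants],
            "excluded": [p.excluded for p in design.plants],
        }
    )


def states_frame(states: Iterable[PlantDayState]):
    """Per-plant-day latent states as a flat table."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "plant_id": s.plant_id,
                "genotype": s.genotype,
                "treatment": s.treatment,
                "das": s.das,
                "alive": s.alive,
                "true_area_mm2": s.true_area_mm2,
                "qymax_true": s.qymax_true,
                "fm_factor": s.fm_factor,
                "qp_scale": s.qp_scale,
                "npq_scale": s.npq_scale,
                "leaf_temp_offset_c": s.leaf_temp_offset_c,
                "n_leaves": s.n_leaves,
                "leaf_aspect": s.leaf_aspect,
                "openness": s.openness,
                "vigor": s.vigor,
                "tolerance": s.tolerance,
            }
            for s in states
        ]
    )


def null_params(seed: int = 0) -> SimulationParams:
    """Parameters with every stress effect switched off (null generator)."""
    return SimulationParams(
        seed=seed,
        growth_penalty={t: 0.0 for t in TREATMENTS},
        hsp101_growth_penalty_extra={t: 0.0 for t in TREATMENTS},
        stress_shrink_per_hour=0.0,
        fm_depression_per_hour=0.0,
        hsp101_depression_multiplier=1.0,
        qp_drop={t: 0.0 for t in TREATMENTS},
        hsp101_qp_extra_drop={t: 0.0 for t in TREATMENTS},
        npq_drop_per_hour=0.0,
        temp_offset_per_hour_c=0.0,
        death_probability_hs9h=0.0,
        runt_probability=0.0,
        damage_heterogeneity_sd=0.0,
        leaf_aspect_drop_per_hour=0.0,
        hsp101_aspect_extra_factor={t: 1.0 for t in TREATMENTS},
        openness_stress_gain_per_hour=0.0,
        tolerance_coupling=0.0,
    )
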