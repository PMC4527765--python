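"""Synthetic data with known ground truth.

Two generators back the whole test pyramid:

* :func:`generate_mask_sequence` renders a deforming, translocating cell as
  a radial blob (a star-convex region ``r(θ)`` around a moving center) so
  that translation speed and protrusive/retractive boundary activity are
  directly controllable;
* :func:`generate_feature_table` draws an observation table in the layout
  of the experimental dataset — latent Cell Speed (heavy-tailed lognormal)
  and an independent latent membrane-activity residual — and plants feature
  columns with known relationship archetypes (linear, plateau,
  non-monotone, null) at stated effect sizes.

Everything is driven by a single :class:`numpy.random.Generator` seeded
from the spec, so a fixed seed reproduces outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masks import DEFAULT_FRAME_INTERVAL_MIN, DEFAULT_PIXEL_SIZE_UM, MaskSequence

__all__ = [
    "MaskSimSpec",
    "TableSimSpec",
    "FeaturePlan",
    "ARCHETYPES",
    "generate_mask_sequence",
    "generate_feature_table",
    "make_plan",
]

# fraction of the area excess relaxed back toward the base area each frame;
# keeps symmetric-rate simulations bounded without suppressing single-frame
# protrusion/retraction events
_AREA_RELAXATION = 0.05
_N_THETA = 720  # angular samples of the radial profile


@dataclass(frozen=True)
class MaskSimSpec:
    """Parameters of one simulated mask movie."""

    n_frames: int = 20
    grid_size: int = 128
    base_radius: float = 18.0
    speed_px_per_frame: float = 0.0
    protrusion_rate: float = 0.0  # expected new boundary pixels per frame
    retraction_rate: float = 0.0  # expected removed boundary pixels per frame
    shape_noise: float = 0.0  # boundary roughness scale, pixels
    gap_frames: frozenset[int] = frozenset()
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        if self.speed_px_per_frame < 0:
            raise ValueError("speed must be non-negative")
        if self.protrusion_rate < 0 or self.retraction_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.shape_noise < 0:
            raise ValueError("shape_noise must be non-negative")
        # worst-case footprint: start center + total travel + inflated radius
        travel = self.speed_px_per_frame * (self.n_frames - 1)
        reach = 1.8 * self.base_radius + 4 * self.shape_noise
        if 2 * reach + travel >= self.grid_size - 2:
            raise ValueError(
                "cell would exit the grid: increase grid_size or reduce "
                "speed/n_frames/base_radius"
            )


def _render_blob(
    grid_size: int, center: tuple[float, float], radii: np.ndarray
) -> np.ndarray:
    """Rasterize the star-convex region {p : |p-c| <= r(θ(p))}."""
    rr, cc = np.mgrid[0:grid_size, 0:grid_size]
    dy = rr - center[0]
    dx = cc - center[1]
    theta = np.arctan2(dy, dx)  # [-pi, pi]
    idx = ((theta + np.pi) / (2 * np.pi) * len(radii)).astype(int) % len(radii)
    return dy * dy + dx * dx <= radii[idx] ** 2


def _smooth_profile(rng: np.random.Generator, scale: float) -> np.ndarray:
    """Smooth zero-mean angular perturbation from low-order Fourier modes."""
    theta = np.linspace(0, 2 * np.pi, _N_THETA, endpoint=False)
    out = np.zeros(_N_THETA)
    for k in range(2, 7):
        amp = rng.normal(0.0, 1.0) / k
        phase = rng.uniform(0, 2 * np.pi)
        out += amp * np.cos(k * theta + phase)
    sd = out.std()
    return out * (scale / sd) if sd > 0 else out


def _add_bump(radii: np.ndarray, rng: np.random.Generator, target_px: float, sign: int) -> None:
    """Add (sign=+1) or carve (−1) a local boundary bump of ~target_px area."""
    if target_px <= 0:
        return
    width = rng.uniform(0.25, 0.7)  # radians
    center = rng.uniform(0, 2 * np.pi)
    theta = np.linspace(0, 2 * np.pi, _N_THETA, endpoint=False)
    d = np.angle(np.exp(1j * (theta - center)))
    profile = np.exp(-0.5 * (d / (width / 2)) ** 2)
    r_local = radii[np.abs(d) < width].mean()
    eff_width = profile.sum() * 2 * np.pi / _N_THETA
    # wedge area between r and r±h over width w is (r·h ± h²/2)·w; solve the
    # quadratic exactly so symmetric rates add and remove equal areas
    disc = r_local**2 + sign * 2 * target_px / max(eff_width, 1e-9)
    if disc <= 4.0:  # carving would collapse the boundary; cap the notch
        height = r_local - 2.0
    else:
        height = sign * (np.sqrt(disc) - r_local)
    radii += sign * height * profile
    np.clip(radii, 2.0, None, out=radii)


def generate_mask_sequence(spec: MaskSimSpec) -> MaskSequence:
    """Simulate a mask movie of one deforming, translocating cell.

    The center of area advances by ``speed_px_per_frame`` per frame along a
    fixed direction (displacements are rounded to whole pixels so that a
    pure-translation movie is an exact pixel shift). Boundary activity adds
    protrusive bumps and carves retractive notches whose expected pixel
    counts match the requested rates; a weak relaxation pulls the area back
    toward the base area so symmetric rates do not drift.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    radii = np.full(_N_THETA, float(spec.base_radius))
    if spec.shape_noise > 0:
        radii += _smooth_profile(rng, spec.shape_noise)
        np.clip(radii, 2.0, None, out=radii)
    base_area = np.pi * spec.base_radius**2

    start = (spec.grid_size / 2.0, 1.8 * spec.base_radius + 4 * spec.shape_noise + 1)
    frames = np.zeros((spec.n_frames, spec.grid_size, spec.grid_size), dtype=bool)
    gaps = np.zeros(spec.n_frames, dtype=bool)

    for t in range(spec.n_frames):
        if t > 0:
            if spec.protrusion_rate > 0:
                _add_bump(radii, rng, rng.poisson(spec.protrusion_rate), +1)
            if spec.retraction_rate > 0:
                _add_bump(radii, rng, rng.poisson(spec.retraction_rate), -1)
            if spec.shape_noise > 0:
                radii += _smooth_profile(rng, spec.shape_noise * 0.3)
                np.clip(radii, 2.0, None, out=radii)
            if spec.protrusion_rate > 0 or spec.retraction_rate > 0 or spec.shape_noise > 0:
                # relax area toward base to keep long runs bounded
                area = 0.5 * (radii**2).sum() * 2 * np.pi / _N_THETA
                radii *= np.sqrt(1 + _AREA_RELAXATION * (base_area / area - 1))
        center = (start[0], start[1] + round(t * spec.speed_px_per_frame))
        if t in spec.gap_frames:
            gaps[t] = True
            continue
        frames[t] = _render_blob(spec.grid_size, center, radii)

    return MaskSequence(
        frames=frames,
        pixel_size_um=spec.pixel_size_um,
        frame_interval_min=spec.frame_interval_min,
        gap_flags=gaps,
        cell_id=f"sim{spec.seed}",
        experiment_id="sim",
    )


# --------------------------------------------------------------------------
# feature-table generator
# --------------------------------------------------------------------------

#: supported planted relationship shapes
ARCHETYPES = (
    "linear-increase",
    "linear-decrease",
    "plateau-early",
    "plateau-late",
    "weak-nonmonotone",
    "null",
)


@dataclass(frozen=True)
class FeaturePlan:
    """Planted relationship of one synthetic feature to the latent processes.

    Effects are expressed in units of the noise standard deviation.
    """

    name: str
    speed_archetype: str = "null"
    speed_effect: float = 0.0
    cmd_archetype: str = "null"
    cmd_effect: float = 0.0

    def validate(self) -> None:
        for a in (self.speed_archetype, self.cmd_archetype):
            if a not in ARCHETYPES:
                raise ValueError(f"unknown archetype {a!r}")
        if self.speed_effect < 0 or self.cmd_effect < 0:
            raise ValueError("effect sizes must be non-negative")

    @property
    def expected_class(self) -> str:
        s = self.speed_archetype != "null" and self.speed_effect > 0
        c = self.cmd_archetype != "null" and self.cmd_effect > 0
        return {(True, True): "both", (True, False): "speed_only",
                (False, True): "cmd_only", (False, False): "neither"}[(s, c)]


@dataclass(frozen=True)
class TableSimSpec:
    """Parameters of one simulated observation table.

    Latent Cell Speed is lognormal (heavy-tailed, positive, most cells slow);
    the latent membrane-activity residual is Gaussian and independent of
    speed. Dynamic Cell Area is ``k*speed + m + residual``, mirroring the
    linear speed–dynamic-area coupling the analysis corrects for.
    """

    n_cells: int = 50
    frames_per_cell: int = 100
    n_features: int = 150
    archetype_plan: tuple[FeaturePlan, ...] = ()
    noise_sd: float = 1.0
    speed_dca_slope: float = 300.0  # k, μm² per (μm/min)
    speed_dca_intercept: float = 60.0  # m, μm²
    speed_log_mean: float = float(np.log(0.15))  # median ~0.15 μm/min
    speed_log_sd: float = 0.7
    cmd_sd: float = 40.0  # sd of the latent residual, μm²
    delta_coupling: float = 0.008  # protrusion-fraction decrease per speed sd
    cells_per_experiment: int = 8
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1 or self.frames_per_cell < 1:
            raise ValueError("n_cells and frames_per_cell must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        plan = self.resolved_plan()
        if len(plan) != self.n_features:
            raise ValueError("archetype_plan length must equal n_features")
        for p in plan:
            p.validate()

    def resolved_plan(self) -> tuple[FeaturePlan, ...]:
        if self.archetype_plan:
            return self.archetype_plan
        return tuple(FeaturePlan(f"feature_{i:03d}") for i in range(self.n_features))


def make_plan(
    n_features: int = 150,
    speed_only: int = 0,
    cmd_only: int = 0,
    both: int = 0,
    effect: float = 5.0,
    archetype: str = "linear-increase",
) -> tuple[FeaturePlan, ...]:
    """Convenience plan: planted features first, nulls padding to n_features."""
    plans: list[FeaturePlan] = []
    for i in range(speed_only):
        plans.append(FeaturePlan(f"speed_f{i:03d}", archetype, effect))
    for i in range(cmd_only):
        plans.append(FeaturePlan(f"cmd_f{i:03d}", "null", 0.0, archetype, effect))
    for i in range(both):
        plans.append(FeaturePlan(f"both_f{i:03d}", archetype, effect, archetype, effect))
    if len(plans) > n_features:
        raise ValueError("more planted features than n_features")
    for i in range(n_features - len(plans)):
        plans.append(FeaturePlan(f"null_f{i:03d}"))
    return tuple(plans)


def _archetype_transform(u: np.ndarray, kind: str) -> np.ndarray:
    """Response shape on percentile ranks u ∈ (0, 1), standardized to sd 1."""
    if kind == "null":
        return np.zeros_like(u)
    if kind == "linear-increase":
        g = u
    elif kind == "linear-decrease":
        g = -u
    elif kind == "plateau-early":
        g = np.minimum(u, 0.4) / 0.4  # saturates at the quintile-3 boundary
    elif kind == "plateau-late":
        g = np.maximum(u - 0.6, 0.0) / 0.4  # flat through quintile 3
    elif kind == "weak-nonmonotone":
        g = 1.0 - 2.0 * np.abs(u - 0.5)  # symmetric triangular bump
    else:  # pragma: no cover
        raise ValueError(f"unknown archetype {kind!r}")
    g = g - g.mean()
    sd = g.std()
    return g / sd if sd > 0 else g


def _ranks01(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    r = np.empty(len(x))
    r[order] = np.arange(1, len(x) + 1)
    return r / (len(x) + 1)


def generate_feature_table(spec: TableSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw an observation table plus its ground-truth feature labels.

    Returns ``(table, truth)``. The table carries the index columns
    (experiment_id, cell_trace_id, frame_number), the process columns
    (cell_speed, protrusion/retraction/short_lived pixels, dynamic_cell_area,
    cmd), a ``valid`` flag and one column per planned feature. ``cmd`` is the
    residual of dynamic_cell_area on cell_speed fitted on this very table,
    as the experimental dataset ships it. ``truth`` records each feature's
    planted archetypes, effect sizes and expected selection class.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    plan = spec.resolved_plan()
    n = spec.n_cells * spec.frames_per_cell

    cell_ids = np.repeat(np.arange(spec.n_cells), spec.frames_per_cell)
    frame_no = np.tile(np.arange(1, spec.frames_per_cell + 1), spec.n_cells)
    exp_ids = cell_ids // spec.cells_per_experiment

    speed = rng.lognormal(spec.speed_log_mean, spec.speed_log_sd, size=n)
    latent_cmd = rng.normal(0.0, spec.cmd_sd, size=n)
    dca = spec.speed_dca_slope * speed + spec.speed_dca_intercept + latent_cmd
    dca = np.maximum(dca, 0.0)

    # split dynamic area into pixels; protrusion fraction drifts down with
    # speed so fast cells shrink on net (negative Δarea–speed coupling)
    px2 = spec.pixel_size_um**2
    dyn_px = np.round(dca / px2).astype(int)
    dca = dyn_px * px2  # dynamic area is exactly the summed pixel area
    z_speed = (speed - speed.mean()) / speed.std()
    frac_short = np.clip(rng.normal(0.15, 0.03, size=n), 0.02, 0.4)
    frac_prot = np.clip(
        0.5 - spec.delta_coupling * z_speed + rng.normal(0.0, 0.05, size=n),
        0.05,
        0.95,
    ) * (1 - frac_short)
    short_px = np.round(dyn_px * frac_short).astype(int)
    prot_px = np.minimum(np.round(dyn_px * frac_prot).astype(int), dyn_px - short_px)
    retr_px = dyn_px - short_px - prot_px

    table = pd.DataFrame(
        {
            "experiment_id": [f"exp{e:02d}" for e in exp_ids],
            "cell_trace_id": [f"cell{c:03d}" for c in cell_ids],
            "frame_number": frame_no,
            "cell_speed": speed,
            "protrusion_pixels": prot_px,
            "retraction_pixels": retr_px,
            "short_lived_pixels": short_px,
            "dynamic_cell_area": dca,
            "valid": True,
        }
    )

    u_speed = _ranks01(speed)
    u_cmd = _ranks01(latent_cmd)
    truth_rows = []
    feature_cols = {}
    for p in plan:
        y = rng.normal(0.0, spec.noise_sd, size=n)
        if p.speed_archetype != "null" and p.speed_effect > 0:
            y = y + p.speed_effect * spec.noise_sd * _archetype_transform(
                u_speed, p.speed_archetype
            )
        if p.cmd_archetype != "null" and p.cmd_effect > 0:
            y = y + p.cmd_effect * spec.noise_sd * _archetype_transform(
                u_cmd, p.cmd_archetype
            )
        feature_cols[p.name] = y
        truth_rows.append(
            {
                "feature": p.name,
                "speed_archetype": p.speed_archetype,
                "speed_effect": p.speed_effect,
                "cmd_archetype": p.cmd_archetype,
                "cmd_effect": p.cmd_effect,
                "expected_class": p.expected_class,
            }
        )

    # ship cmd as the fitted residual, like the experimental dataset does
    k, m = np.polyfit(speed, dca, 1)
    table.insert(8, "cmd", dca - k * speed - m)
    table = pd.concat([table, pd.DataFrame(feature_cols, index=table.index)], axis=1)
    table.attrs["feature_columns"] = [p.name for p in plan]

    return table, pd.DataFrame(truth_rows)
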