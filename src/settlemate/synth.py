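"""Seeded synthetic landscapes, nests, playbacks, settlements and choices.

The generator produces data with the statistical structure the two
analyses assume, at study-like sizes, so every downstream stage can be
exercised end to end without field data:

* a positive latent attractiveness surface (Gaussian habitat hotspots
  on a constant floor — forest habitat structure is heterogeneous);
* nests accumulated over multiple years, placed proportionally to the
  latent surface (females nest where habitat suits them);
* paired-speaker playback stations with high/low song-rate labels;
* male settlement patterns drawn from the loglinear intensity
  lambda(u) = exp(beta0 + beta_hab*hab(u) + beta_prox*prox(u)) by
  thinning a dominating homogeneous process;
* sequential female choice events drawn from the conditional-logit
  model A_i = H_i**alpha1 * C_i**alpha2 at stated effect sizes.

One global seed is forked deterministically per generator, so any
subset of the outputs is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from . import mate_choice as mc
from .ppm import PointPattern
from .raster import (
    GridRaster,
    Window,
    build_attractiveness_raster,
    build_proximity_raster,
    sample_raster,
    station_midpoints,
)

#: habitat covariate is expressed as nests per hectare (1e4 m^2); on
#: that scale the settlement coefficient 0.109 spans a realistic
#: density range (exp(0.109 * range) ~ 10 across ~20 nests/ha).
HAB_SCALE = 1.0e4

# sub-seed keys, one per generator
_K_LANDSCAPE, _K_NESTS, _K_MALES, _K_CHOICES, _K_LAYOUT = range(5)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic site.

    Defaults emulate the field study: a ~100 ha forest site, nests
    accumulated over 11 seasons, about ten settled males per site-year,
    settlement coefficients (beta_hab, beta_prox) = (0.109, 1.773) and
    choice exponents (alpha1, alpha2) = (0.625, -0.06).  ``beta0=None``
    asks the male generator to solve the intercept so the expected
    count equals `expected_males`.
    """

    seed: int = 0
    site: str = "S1"
    window: tuple[float, float] = (1000.0, 1000.0)  # metres
    n_years: int = 11
    first_year: int = 2010
    hotspot_count: int = 6
    hotspot_scale: float = 40.0  # metres (sd of a habitat hotspot)
    hotspot_amplitude: float = 25.0  # peak height relative to floor 1
    nests_per_year: float = 18.0
    playback_layout: tuple[tuple[float, float, str], ...] | None = None
    true_beta: tuple[float | None, float, float] = (None, 0.109, 1.773)
    expected_males: float = 10.0  # used when beta0 is None
    true_alpha: tuple[float, float] = (0.625, -0.06)
    n_females: int = 59
    season: tuple[str, str] = ("2017-04-15", "2017-06-15")
    cell: float = 10.0
    bandwidth: float = 25.0  # KDE bandwidth for the habitat covariate
    presence_prob: float = 0.9  # per-event male presence (survey turnover)
    connectivity_decay: float = 200.0
    include_playbacks: bool = True
    speaker_spacing: float = 100.0

    def __post_init__(self) -> None:
        if self.window[0] <= 0 or self.window[1] <= 0:
            raise ValueError("window dimensions must be positive")
        if self.nests_per_year < 0 or self.n_females < 0:
            raise ValueError("expected counts must be non-negative")

    @property
    def win(self) -> Window:
        return Window(0.0, 0.0, *self.window)

    def rng(self, key: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(key)])


def gen_landscape(config: SimulationConfig) -> GridRaster:
    """Latent attractiveness surface: Gaussian hotspots on a unit floor.

    Strictly positive on the covariate grid; ``hotspot_count=0`` gives a
    constant surface, and as ``hotspot_scale`` grows the surface
    flattens (its coefficient of variation tends to zero).
    """
    rng = config.rng(_K_LANDSCAPE)
    win = config.win
    from .raster import grid_for_window

    nrow, ncol = grid_for_window(win, config.cell)
    cx = win.x0 + (np.arange(ncol) + 0.5) * config.cell
    cy = win.y0 + (np.arange(nrow) + 0.5) * config.cell
    values = np.ones((nrow, ncol))
    centres = rng.uniform(
        [win.x0, win.y0],
        [win.x0 + win.width, win.y0 + win.height],
        size=(config.hotspot_count, 2),
    )
    s2 = config.hotspot_scale**2
    for hx, hy in centres:
        values += config.hotspot_amplitude * np.exp(
            -((cx[None, :] - hx) ** 2 + (cy[:, None] - hy) ** 2) / (2 * s2)
        )
    return GridRaster(win.x0, win.y0, config.cell, values)


def sample_points_from_surface(
    surface: GridRaster, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n points with density proportional to the surface.

    Cells are picked by a weighted multinomial and each point is
    jittered uniformly within its cell, so all points stay inside the
    gridded window.
    """
    w = surface.values.ravel()
    idx = rng.choice(w.size, size=n, p=w / w.sum())
    row, col = np.divmod(idx, surface.ncol)
    x = surface.x0 + (col + rng.uniform(size=n)) * surface.cell
    y = surface.y0 + (row + rng.uniform(size=n)) * surface.cell
    return np.column_stack([x, y])


def gen_nests(config: SimulationConfig, surface: GridRaster | None = None) -> pd.DataFrame:
    """Multi-year nest table with clutch data.

    Per year the nest count is Poisson(`nests_per_year`) and locations
    follow the latent surface; each record carries site, year, female
    id, clutch size (5-7 eggs) and clutch completion date, from which
    the nesting timeline can be back-calculated.
    """
    if surface is None:
        surface = gen_landscape(config)
    if np.any(surface.values <= 0):
        raise ValueError("latent surface must be strictly positive")
    rng = config.rng(_K_NESTS)
    rows = []
    for yi in range(config.n_years):
        year = config.first_year + yi
        n = rng.poisson(config.nests_per_year)
        if n == 0:
            continue
        xy = sample_points_from_surface(surface, n, rng)
        sizes = rng.integers(5, 8, size=n)
        offsets = rng.integers(0, 30, size=n)  # completion mid-May .. mid-June
        for i in range(n):
            completion = date(year, 5, 15) + timedelta(days=int(offsets[i]))
            rows.append(
                {
                    "site": config.site,
                    "year": year,
                    "x": xy[i, 0],
                    "y": xy[i, 1],
                    "female_id": f"F{year}-{i + 1}",
                    "clutch_size": int(sizes[i]),
                    "clutch_completion": completion.isoformat(),
                }
            )
    cols = ["site", "year", "x", "y", "female_id", "clutch_size", "clutch_completion"]
    return pd.DataFrame(rows, columns=cols)


def default_playback_layout(
    config: SimulationConfig, n_high: int = 4, n_low: int = 4
) -> tuple[tuple[float, float, str], ...]:
    """Quasi-regular station midpoints with randomised high/low labels.

    Stations sit on a jittered grid well inside the window (so both
    speakers, 50 m either side of the midpoint, stay inside), with song
    rate classes assigned at random — the field layout interleaved
    high- and low-song-rate stations across the habitat gradient.
    """
    rng = config.rng(_K_LAYOUT)
    n = n_high + n_low
    win = config.win
    margin = config.speaker_spacing / 2 + 10.0
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    gx = np.linspace(win.x0 + margin, win.x0 + win.width - margin, ncol)
    gy = np.linspace(win.y0 + margin, win.y0 + win.height - margin, nrow)
    pts = np.array([(x, y) for y in gy for x in gx])[:n]
    pts = pts + rng.uniform(-30, 30, size=pts.shape)
    classes = np.array(["high"] * n_high + ["low"] * n_low)
    rng.shuffle(classes)
    return tuple((float(x), float(y), str(c)) for (x, y), c in zip(pts, classes))


def gen_playbacks(config: SimulationConfig, year: int | None = None) -> pd.DataFrame:
    """Playback station table (paired speakers flanking each midpoint)."""
    layout = config.playback_layout or default_playback_layout(config)
    half = config.speaker_spacing / 2
    year = year if year is not None else config.first_year + config.n_years - 1
    rows = [
        {
            "site": config.site,
            "year": int(year),
            "ax": x - half,
            "ay": y,
            "bx": x + half,
            "by": y,
            "song_rate_class": cls,
        }
        for x, y, cls in layout
    ]
    return pd.DataFrame(rows)


def resolve_beta0(
    config: SimulationConfig, hab: GridRaster, prox: GridRaster
) -> tuple[float, float, float]:
    """Fill in beta0 so that the expected male count matches the config."""
    beta0, bh, bp = config.true_beta
    if beta0 is None:
        cell_area = hab.cell**2
        total = cell_area * np.sum(np.exp(bh * hab.values + bp * prox.values))
        beta0 = float(np.log(config.expected_males / total))
    return float(beta0), float(bh), float(bp)


def gen_male_pattern(
    config: SimulationConfig,
    hab: GridRaster,
    prox: GridRaster,
    year: int | None = None,
    rng: np.random.Generator | None = None,
) -> PointPattern:
    """Inhomogeneous Poisson settlement pattern by thinning.

    A homogeneous process at the exact grid upper bound
    exp(beta0 + max(beta_hab*hab) + max(beta_prox*prox)) is simulated
    and each point retained with probability lambda(u)/bound, so the
    expected count equals the intensity integral over the window.
    """
    if not hab.aligned_with(prox):
        raise ValueError("hab and prox rasters must share one grid")
    rng = rng if rng is not None else config.rng(_K_MALES)
    beta0, bh, bp = resolve_beta0(config, hab, prox)
    log_bound = beta0 + np.max(bh * hab.values) + np.max(bp * prox.values)
    bound = np.exp(log_bound)
    if not np.isfinite(bound):
        raise ValueError("intensity bound is not finite")
    win = config.win
    n = rng.poisson(bound * win.area)
    x = rng.uniform(win.x0, win.x0 + win.width, size=n)
    y = rng.uniform(win.y0, win.y0 + win.height, size=n)
    if n:
        lam = np.exp(beta0 + bh * sample_raster(hab, x, y) + bp * sample_raster(prox, x, y))
        keep = rng.uniform(size=n) < lam / bound
        x, y = x[keep], y[keep]
    year = year if year is not None else config.first_year + config.n_years - 1
    ids = [f"M{year}-{i + 1}" for i in range(len(x))]
    return PointPattern(config.site, int(year), win, x, y, ids)


def gen_choice_events(
    config: SimulationConfig,
    males: PointPattern,
    hab: GridRaster,
    playbacks: pd.DataFrame | None = None,
    n_events: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[mc.ChoiceEvent]:
    """Sequential female choices from the conditional-logit model.

    For each arriving female a candidate snapshot is built (each male
    independently present with `presence_prob`, at least one present —
    males come and go between surveys), H and C are computed exactly as
    the fitting side computes them, and the chosen male is drawn with
    probability p_i proportional to H_i**alpha1 * C_i**alpha2 at the
    true exponents.  Arrival dates are uniform over the season.
    """
    if males.n == 0:
        raise ValueError("need at least one settled male")
    rng = rng if rng is not None else config.rng(_K_CHOICES)
    n_events = config.n_females if n_events is None else int(n_events)
    spec = mc.MateChoiceSpec(
        include_playbacks=config.include_playbacks,
        connectivity_decay=config.connectivity_decay,
    )
    xy_all = np.column_stack([males.x, males.y])
    pb = None
    if playbacks is not None and len(playbacks):
        pb = station_midpoints(playbacks)
    t0 = date.fromisoformat(config.season[0])
    t1 = date.fromisoformat(config.season[1])
    span = max((t1 - t0).days, 1)
    a1, a2 = config.true_alpha
    events = []
    for e in range(n_events):
        present = rng.uniform(size=males.n) < config.presence_prob
        if not present.any():
            present[rng.integers(males.n)] = True
        idx = np.flatnonzero(present)
        xy = xy_all[idx]
        H = np.atleast_1d(sample_raster(hab, xy[:, 0], xy[:, 1]))
        C = np.array(
            [
                mc.connectivity(tuple(xy[i]), np.delete(xy, i, axis=0), pb, spec)
                for i in range(len(idx))
            ]
        )
        ev = mc.ChoiceEvent(
            female_id=f"SF{e + 1}",
            site=config.site,
            decision_date=(t0 + timedelta(days=int(rng.integers(span + 1)))).isoformat(),
            male_ids=[males.male_ids[i] for i in idx],
            xy=xy,
            H=H,
            C=C,
            chosen=0,
        )
        p = mc.choice_probabilities(ev, a1, a2)
        ev.chosen = int(rng.choice(len(p), p=p))
        events.append(ev)
    return events


@dataclass
class Scene:
    """Everything one synthetic site-year contributes to the analyses."""

    config: SimulationConfig
    landscape: GridRaster
    nests: pd.DataFrame
    playbacks: pd.DataFrame
    hab: GridRaster  # KDE habitat covariate, nests/ha, leave-one-year-out
    prox_all: GridRaster
    prox_low: GridRaster | None
    males: PointPattern
    true_beta: tuple[float, float, float]
    events: list[mc.ChoiceEvent] = field(default_factory=list)


def make_scene(config: SimulationConfig, with_choices: bool = True) -> Scene:
    """Generate one full synthetic site-year.

    The habitat covariate is the kernel-density surface of the nests
    excluding the focal (experiment) year — the leave-one-site-year-out
    rule — expressed in nests per hectare.
    """
    landscape = gen_landscape(config)
    nests = gen_nests(config, landscape)
    focal_year = config.first_year + config.n_years - 1
    playbacks = gen_playbacks(config, year=focal_year)
    hab = build_attractiveness_raster(
        nests,
        config.win,
        exclude=(config.site, focal_year),
        bandwidth=config.bandwidth,
        cell=config.cell,
    )
    hab = GridRaster(hab.x0, hab.y0, hab.cell, hab.values * HAB_SCALE)
    prox_all = build_proximity_raster(playbacks, config.win, "all", cell=config.cell)
    has_low = (playbacks["song_rate_class"] == "low").any()
    prox_low = (
        build_proximity_raster(playbacks, config.win, "low_only", cell=config.cell)
        if has_low
        else None
    )
    true_beta = resolve_beta0(config, hab, prox_all)
    males = gen_male_pattern(config, hab, prox_all, year=focal_year)
    scene = Scene(
        config, landscape, nests, playbacks, hab, prox_all, prox_low, males, true_beta
    )
    if with_choices and males.n:
        scene.events = gen_choice_events(config, males, hab, playbacks)
    return scene


def make_study(
    seed: int,
    n_scenes: int = 5,
    n_events_total: int | None = None,
    **config_overrides,
) -> list[Scene]:
    """A study-like collection of site-year scenes.

    Five scenes mirror the five experimental site-years; choice events
    are split evenly across scenes (n_events_total defaults to each
    scene's own n_females).
    """
    scenes = []
    for s in range(n_scenes):
        cfg = SimulationConfig(
            seed=int(seed) * 1009 + s, site=f"S{s + 1}", **config_overrides
        )
        per = None if n_events_total is None else n_events_total // n_scenes + (
            1 if s < n_events_total % n_scenes else 0
        )
        scene = make_scene(cfg, with_choices=False)
        if scene.males.n and (per is None or per > 0):
            scene.events = gen_choice_events(
                cfg, scene.males, scene.hab, scene.playbacks, n_events=per
            )
        scenes.append(scene)
    return scenes
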