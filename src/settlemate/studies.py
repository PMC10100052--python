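"""Parameter-recovery and model-selection simulation studies.

Drivers that repeatedly simulate study-like data at known effect sizes
and re-estimate them, quantifying estimator error, confidence-interval
coverage and AICc model-ranking behaviour.  Shared by the analysis
scripts, the test suite and the acceptance script so every reported
number comes from the same code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import mate_choice as mc
from .model_selection import delta_and_weights
from .ppm import fit_ppm
from .synth import SimulationConfig, gen_choice_events, gen_male_pattern, make_scene, make_study

TRUE_ALPHA = (0.625, -0.06)
TRUE_BETA_HAB = 0.109
TRUE_BETA_PROX = 1.773


def simulate_choice_study(
    seed: int,
    n_events: int,
    n_scenes: int = 5,
    true_alpha: tuple[float, float] = TRUE_ALPHA,
) -> list[mc.ChoiceEvent]:
    """Choice events pooled over a fresh study-like set of site-years."""
    scenes = make_study(
        seed=seed, n_scenes=n_scenes, n_events_total=n_events, true_alpha=true_alpha
    )
    return [e for s in scenes for e in s.events]


def mate_choice_recovery(
    seed: int,
    n_reps: int,
    n_events: int,
    true_alpha: tuple[float, float] = TRUE_ALPHA,
    model: str = "hab+connectivity",
) -> pd.DataFrame:
    """Re-estimate the choice exponents on repeated simulated studies.

    Each replicate draws a fresh set of site-year scenes and `n_events`
    choices at the true exponents, then fits `model`; returns one row
    per replicate with the estimates and their errors.
    """
    rows = []
    for rep in range(n_reps):
        events = simulate_choice_study(seed * 100003 + rep, n_events, true_alpha=true_alpha)
        fit = mc.fit_mate_choice(events, model)
        rows.append(
            {
                "rep": rep,
                "alpha1_hat": fit.alpha1,
                "alpha2_hat": fit.alpha2,
                "err_alpha1": fit.alpha1 - true_alpha[0],
                "err_alpha2": fit.alpha2 - true_alpha[1],
                "log_likelihood": fit.log_likelihood,
                "n_events": fit.n_events,
            }
        )
    return pd.DataFrame(rows)


def model_selection_study(
    seed: int,
    n_reps: int,
    n_events: int,
    true_alpha: tuple[float, float],
) -> pd.DataFrame:
    """AICc ranking of the four choice models over repeated studies.

    Returns one row per replicate with each model's AICc and the name
    of the AICc-best model.
    """
    rows = []
    for rep in range(n_reps):
        events = simulate_choice_study(seed * 100019 + rep, n_events, true_alpha=true_alpha)
        fits = mc.fit_all_models(events)
        aiccs = {m: f.aicc for m, f in fits.items()}
        best = delta_and_weights(aiccs).iloc[0]["model"]
        rows.append({"rep": rep, "best": best, **{f"aicc_{m}": v for m, v in aiccs.items()}})
    return pd.DataFrame(rows)


def ppm_recovery(
    seed: int,
    n_reps: int,
    expected_males: float = 150.0,
    true_beta_hab: float = TRUE_BETA_HAB,
    true_beta_prox: float = TRUE_BETA_PROX,
    dummy_spacing: float = 10.0,
) -> pd.DataFrame:
    """Wald-interval coverage for the habitat settlement coefficient.

    Every replicate draws a fresh synthetic scene (landscape, nests,
    playbacks, hence fresh covariate rasters), simulates one settlement
    pattern at the true coefficients, and refits the habitat +
    proximity model.  `expected_males` is set so the point count puts
    the Wald interval in its asymptotic regime rather than confounding
    coverage error with small-sample effects.  Returns one row per
    replicate with the estimate, its standard error, and whether the
    95% interval covers the truth.
    """
    rows = []
    for rep in range(n_reps):
        cfg = SimulationConfig(
            seed=seed * 1013 + rep,
            expected_males=expected_males,
            true_beta=(None, true_beta_hab, true_beta_prox),
        )
        sc = make_scene(cfg, with_choices=False)
        pattern = sc.males
        if pattern.n < 5:
            continue
        fit = fit_ppm(
            [pattern], [[sc.hab, sc.prox_all]], names=["hab", "prox"],
            dummy_spacing=dummy_spacing,
        )
        bh = fit.coefficients[1]
        se = fit.se()[1]
        lo, hi = bh - 1.959963984540054 * se, bh + 1.959963984540054 * se
        rows.append(
            {
                "rep": rep,
                "beta_hab_hat": bh,
                "se": se,
                "ci_low": lo,
                "ci_high": hi,
                "covered": bool(lo <= true_beta_hab <= hi),
                "n_points": fit.n_points,
            }
        )
    return pd.DataFrame(rows)
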