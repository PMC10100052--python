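"""Small-sample information-theoretic model comparison.

AICc, delta-AICc / Akaike-weight tables, model averaging (conditional,
full, and top-set variants) and the percent-change translation of a
fitted choice exponent.  Shared by the settlement point-process models
and the mate-choice models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: models within this delta-AICc of the best are flagged as having
#: substantial support
SUPPORT_DELTA = 2.0


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """AICc = -2*logLik + 2k + 2k(k+1)/(n-k-1).

    `n` is the sample size the correction refers to (choice events, or
    total settlement points).  Requires n > k + 1; at k = 0 the
    correction vanishes and AICc = -2*logLik.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def delta_and_weights(aicc_values: dict[str, float]) -> pd.DataFrame:
    """Comparison table: AICc, delta-AICc, Akaike weights, support flag.

    Rows sorted by AICc; weights w_i = exp(-delta_i/2) normalised over
    the candidate set (invariant to adding a constant to every AICc);
    models with delta <= 2 are flagged as substantially supported.
    """
    if not aicc_values:
        raise ValueError("need at least one model")
    tab = pd.DataFrame(
        {"model": list(aicc_values), "AICc": [float(v) for v in aicc_values.values()]}
    )
    tab["dAICc"] = tab["AICc"] - tab["AICc"].min()
    rel = np.exp(-tab["dAICc"] / 2.0)
    tab["weight"] = rel / rel.sum()
    tab["substantial_support"] = tab["dAICc"] <= SUPPORT_DELTA
    return tab.sort_values("AICc", kind="stable", ignore_index=True)


def format_weight(w: float) -> str:
    """Render an Akaike weight to 2 decimals, with '<0.01' below 0.005."""
    return "<0.01" if w < 0.005 else f"{w:.2f}"


def model_average(
    estimates: dict[str, float],
    weights: dict[str, float],
    mode: str = "conditional",
    deltas: dict[str, float] | None = None,
) -> float:
    """Akaike-weight average of a coefficient across candidate models.

    conditional
        renormalise the weights over the models that contain the
        coefficient (`estimates` keys) and average over those;
    full
        absent coefficients enter as 0 with their original weights;
    top_set
        restrict to models with delta-AICc <= 2 (needs `deltas`),
        then behave like conditional.
    """
    if mode not in ("conditional", "full", "top_set"):
        raise ValueError(f"unknown averaging mode {mode!r}")
    if mode == "top_set":
        if deltas is None:
            raise ValueError("top_set averaging needs delta-AICc values")
        keep = {m for m, d in deltas.items() if d <= SUPPORT_DELTA}
        estimates = {m: v for m, v in estimates.items() if m in keep}
        weights = {m: w for m, w in weights.items() if m in keep}
        mode = "conditional"
    if mode == "conditional":
        present = [m for m in weights if m in estimates]
        if not present:
            raise ValueError("coefficient absent from every candidate model")
        wsum = sum(weights[m] for m in present)
        return sum(weights[m] * estimates[m] for m in present) / wsum
    # full: every model counts, absentees contribute zero
    return sum(w * estimates.get(m, 0.0) for m, w in weights.items())


def percent_change(alpha: float, step: float = 0.10) -> float:
    """Percent change in choice odds per fractional `step` in the covariate.

    A choice exponent alpha means a (1+step)**alpha-fold change in a
    male's attractiveness for each (100*step)% increase in the
    underlying variable; returned as a percentage, e.g. alpha = 0.625
    with step 0.10 gives +6.1 (1.1**0.625 = 1.061).
    """
    if step <= -1:
        raise ValueError("step must exceed -1")
    return 100.0 * ((1.0 + step) ** alpha - 1.0)
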