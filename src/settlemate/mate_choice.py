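"""Conditional-logit model of female mate choice.

Each settling female faces the set of males present in her site at the
time she begins nesting.  Male *i*'s attractiveness is modelled as a
power function of the habitat value at his territory centre and of his
connectivity with other males,

    A_i = H_i**alpha1 * C_i**alpha2,

and the probability that the female chooses him is the conditional-logit
share p_i = A_i / sum_j A_j over the real males in her choice set.
Connectivity is the metapopulation-style distance-weighted neighbour
count C_i = sum_{j != i} exp(-d_ij / decay); playback stations can count
as competitors (they raise real males' C) but are never choosable.

Four candidate models — null (alpha1 = alpha2 = 0), habitat only,
connectivity only, full — are fitted by maximising the summed log
probability of the observed choices and compared by AICc with n equal
to the number of choice events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .model_selection import aicc

#: default connectivity decay length (m); matches the proximity
#: covariate's exp(-d/200).  decay=1 reproduces exp(-d) with d in metres.
DEFAULT_DECAY = 200.0

MODELS = ("null", "hab", "connectivity", "hab+connectivity")

_FREE: dict[str, tuple[str, ...]] = {
    "null": (),
    "hab": ("alpha1",),
    "connectivity": ("alpha2",),
    "hab+connectivity": ("alpha1", "alpha2"),
}

_START_GRID = (-1.0, -0.5, 0.0, 0.5, 1.0)


@dataclass(frozen=True)
class MateChoiceSpec:
    """Which exponents are free, and how connectivity is computed."""

    free_parameters: tuple[str, ...] = ("alpha1", "alpha2")
    include_playbacks: bool = True
    connectivity_decay: float = DEFAULT_DECAY

    def __post_init__(self) -> None:
        if self.connectivity_decay <= 0:
            raise ValueError("connectivity decay must be positive")
        bad = set(self.free_parameters) - {"alpha1", "alpha2"}
        if bad:
            raise ValueError(f"unknown free parameters: {sorted(bad)}")

    @classmethod
    def from_model(cls, model: str, **kw) -> "MateChoiceSpec":
        return cls(free_parameters=_FREE[model], **kw)

    @property
    def model(self) -> str:
        for name, free in _FREE.items():
            if set(free) == set(self.free_parameters):
                return name
        raise AssertionError


@dataclass
class ChoiceEvent:
    """One female's decision among the males present when she settled."""

    female_id: str
    site: str
    decision_date: object  # datetime.date or ISO string; day resolution
    male_ids: list[str]
    xy: np.ndarray  # (n_candidates, 2)
    H: np.ndarray  # habitat attractiveness at each male's location, > 0
    C: np.ndarray  # connectivity of each male, >= 0
    chosen: int

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        self.H = np.asarray(self.H, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.male_ids)
        if n == 0:
            raise ValueError("choice event has an empty candidate set")
        if not (0 <= self.chosen < n):
            raise ValueError("chosen index out of range")
        if self.H.shape != (n,) or self.C.shape != (n,):
            raise ValueError("H and C must have one value per candidate")
        if not np.all(np.isfinite(self.H)) or np.any(self.H <= 0):
            raise ValueError("attractiveness H must be finite and positive")

    @property
    def n_candidates(self) -> int:
        return len(self.male_ids)


@dataclass
class MateChoiceFit:
    model: str
    alpha1: float
    alpha2: float
    log_likelihood: float
    n_events: int
    k: int
    aicc: float
    converged: bool
    spec: MateChoiceSpec = field(repr=False)


def connectivity(
    focal: tuple[float, float],
    others: np.ndarray,
    playbacks: np.ndarray | None = None,
    spec: MateChoiceSpec | None = None,
) -> float:
    """Distance-weighted neighbour count C = sum_j exp(-d_ij / decay).

    `others` are the competitor males' coordinates (the focal male
    excluded); playback midpoints are appended as competitors when the
    spec includes them.  Distant males contribute negligibly, so the
    varying extents of different sites do not bias the measure.
    """
    spec = spec or MateChoiceSpec()
    pts = np.asarray(others, dtype=float).reshape(-1, 2)
    if spec.include_playbacks and playbacks is not None:
        pb = np.asarray(playbacks, dtype=float).reshape(-1, 2)
        pts = np.vstack([pts, pb]) if len(pts) else pb
    if len(pts) == 0:
        return 0.0
    d = np.hypot(pts[:, 0] - focal[0], pts[:, 1] - focal[1])
    return float(np.sum(np.exp(-d / spec.connectivity_decay)))


def _log_weights(event: ChoiceEvent, alpha1: float, alpha2: float) -> np.ndarray:
    logw = alpha1 * np.log(event.H)
    if alpha2 != 0.0:
        if np.any(event.C <= 0) and event.n_candidates > 1:
            raise ValueError(
                "zero connectivity in a multi-candidate event; C must be "
                "positive when alpha2 is free"
            )
        with np.errstate(divide="ignore"):
            logw = logw + alpha2 * np.log(event.C)
    return logw


def choice_probabilities(event: ChoiceEvent, alpha1: float, alpha2: float) -> np.ndarray:
    """p_i = H_i^a1 C_i^a2 / sum_j H_j^a1 C_j^a2 over the candidates.

    Computed on the log scale; invariant to rescaling all H (or all C)
    by a common factor, which is what makes choice sets of different
    sizes comparable.
    """
    if event.n_candidates == 1:
        return np.array([1.0])
    logw = _log_weights(event, alpha1, alpha2)
    if not np.all(np.isfinite(logw)):
        raise ValueError("non-finite attractiveness")
    return np.exp(logw - logsumexp(logw))


def log_likelihood(events, alpha1: float, alpha2: float) -> float:
    """Summed log probability of the observed choices, sum ln p_chosen.

    Single-candidate events contribute exactly zero.
    """
    total = 0.0
    for ev in events:
        if ev.n_candidates == 1:
            continue
        logw = _log_weights(ev, alpha1, alpha2)
        total += float(logw[ev.chosen] - logsumexp(logw))
    return total


class _PackedEvents:
    """Events flattened to arrays for fast repeated likelihood evaluation."""

    def __init__(self, events):
        logH, logC, starts, chosen = [], [], [], []
        pos = 0
        for ev in events:
            if ev.n_candidates == 1:
                continue
            logH.append(np.log(ev.H))
            c = ev.C
            if np.any(c <= 0):
                raise ValueError("zero connectivity in a multi-candidate event")
            logC.append(np.log(c))
            starts.append(pos)
            chosen.append(pos + ev.chosen)
            pos += ev.n_candidates
        self.n_multi = len(starts)
        if self.n_multi:
            self.logH = np.concatenate(logH)
            self.logC = np.concatenate(logC)
            self.starts = np.array(starts)
            self.chosen = np.array(chosen)
            self.event_of = np.repeat(np.arange(self.n_multi), np.diff(np.append(self.starts, pos)))

    def loglik(self, alpha1: float, alpha2: float) -> float:
        logw = alpha1 * self.logH + alpha2 * self.logC
        # per-event log-sum-exp via a stable segmented reduction
        m = np.maximum.reduceat(logw, self.starts)
        sums = np.zeros(self.n_multi)
        np.add.at(sums, self.event_of, np.exp(logw - m[self.event_of]))
        lse = m + np.log(sums)
        return float(np.sum(logw[self.chosen] - lse))


def fit_mate_choice(events, spec: MateChoiceSpec | str = "hab+connectivity") -> MateChoiceFit:
    """Maximum-likelihood fit of one candidate mate-choice model.

    Free exponents are estimated by Nelder–Mead simplex search with five
    multi-starts per free parameter from {-1, -0.5, 0, 0.5, 1} (the
    exponents are unconstrained); fixed exponents stay at zero.  AICc
    uses n = number of choice events and k = number of free exponents.
    """
    if isinstance(spec, str):
        spec = MateChoiceSpec.from_model(spec)
    events = list(events)
    if not events:
        raise ValueError("no choice events")
    free = tuple(p for p in ("alpha1", "alpha2") if p in spec.free_parameters)
    k = len(free)
    n = len(events)

    packed = _PackedEvents(events)
    if k == 0:
        ll = packed.loglik(0.0, 0.0) if packed.n_multi else 0.0
        return MateChoiceFit("null", 0.0, 0.0, ll, n, 0, aicc(ll, 0, n), True, spec)
    if packed.n_multi == 0:
        raise ValueError("all events have a single candidate; likelihood is flat")

    def unpack(theta: np.ndarray) -> tuple[float, float]:
        a = dict(zip(free, theta))
        return a.get("alpha1", 0.0), a.get("alpha2", 0.0)

    def nll(theta: np.ndarray) -> float:
        return -packed.loglik(*unpack(theta))

    best = None
    for s in _START_GRID:
        res = minimize(
            nll,
            x0=np.full(k, s),
            method="Nelder-Mead",
            options={"fatol": 1e-8, "xatol": 1e-6, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    a1, a2 = unpack(best.x)
    ll = -float(best.fun)
    return MateChoiceFit(spec.model, a1, a2, ll, n, k, aicc(ll, k, n), bool(best.success), spec)


def fit_all_models(events, include_playbacks: bool = True, decay: float = DEFAULT_DECAY):
    """Fit the four candidate models; returns {model: MateChoiceFit}."""
    out = {}
    for model in MODELS:
        spec = MateChoiceSpec.from_model(
            model, include_playbacks=include_playbacks, connectivity_decay=decay
        )
        out[model] = fit_mate_choice(events, spec)
    return out
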