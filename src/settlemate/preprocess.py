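"""Raw observation tables -> analysis units.

Field observations arrive as repeated singing-location records per male
(territory mapping every 1-2 weeks), nest records with clutch data, and
playback station layouts.  This module applies the filtering and timing
rules that turn them into the two analysis units:

* settled-male point patterns — one territory centre per male per
  site-year, keeping only males present >= 5 days, collapsing
  polyterritorial males (singing locations >= 150 m apart are distinct
  territories) to their longest-tenure territory;
* female choice events — for each nest, the survey snapshot of male
  locations closest in time to the back-calculated nest-initiation
  date becomes the candidate set, with habitat value H and
  connectivity C attached per candidate male.

All dates are timezone-free at day resolution (ISO-8601 in files).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from . import mate_choice as mc
from .raster import GridRaster, sample_raster, station_midpoints

MIN_TENURE_DAYS = 5
TERRITORY_SPLIT_M = 150.0
NEST_BUILD_DAYS = 7
INCUBATION_DAYS = 14


@dataclass
class Territory:
    """A cluster of one male's singing locations with its tenure."""

    male_id: str
    site: str
    year: int
    centre: tuple[float, float]
    first_seen: date
    last_seen: date
    n_locations: int

    @property
    def tenure(self) -> int:
        """Inclusive day count from first to last observation."""
        return (self.last_seen - self.first_seen).days + 1


def _as_date(v) -> date:
    if isinstance(v, date):
        return v
    return date.fromisoformat(str(v)[:10])


def cluster_territories(
    observations: pd.DataFrame, threshold: float = TERRITORY_SPLIT_M
) -> list[Territory]:
    """Split one male's singing locations into territories.

    Single-linkage clustering: locations closer than `threshold` metres
    (the polyterritoriality definition: territories are singing
    locations >= 150 m apart) are chained into one territory; the
    territory centre is the centroid of its member locations and the
    tenure spans its member observations.  `observations` must all
    belong to one male in one site-year.
    """
    if observations.empty:
        return []
    if observations["male_id"].nunique() > 1:
        raise ValueError("cluster_territories expects observations of a single male")
    pts = observations[["x", "y"]].to_numpy(dtype=float)
    if len(pts) == 1:
        labels = np.array([1])
    else:
        Z = linkage(pdist(pts), method="single")
        # merge strictly-below-threshold pairs; exactly 150 m stays split
        labels = fcluster(Z, t=threshold * (1 - 1e-12), criterion="distance")
    first = observations["first_seen"].map(_as_date)
    last = observations["last_seen"].map(_as_date)
    out = []
    for lab in np.unique(labels):
        m = labels == lab
        out.append(
            Territory(
                male_id=str(observations["male_id"].iloc[0]),
                site=str(observations["site"].iloc[0]),
                year=int(observations["year"].iloc[0]),
                centre=(float(pts[m, 0].mean()), float(pts[m, 1].mean())),
                first_seen=min(first[m]),
                last_seen=max(last[m]),
                n_locations=int(m.sum()),
            )
        )
    out.sort(key=lambda t: (t.first_seen, t.centre))
    return out


def filter_settled_males(observations: pd.DataFrame) -> pd.DataFrame:
    """Settled males: one territory centre per male per site-year.

    A male counts as settled only if his site presence (first to last
    observation, inclusive) spans at least 5 days.  Polyterritorial
    males contribute the territory with the longest tenure; tenure ties
    go to the chronologically first territory.

    Returns columns male_id, site, year, x, y, tenure.
    """
    rows = []
    if observations.empty:
        return pd.DataFrame(columns=["male_id", "site", "year", "x", "y", "tenure"])
    for (site, year, male), grp in observations.groupby(["site", "year", "male_id"]):
        first = grp["first_seen"].map(_as_date).min()
        last = grp["last_seen"].map(_as_date).max()
        presence = (last - first).days + 1
        if presence < MIN_TENURE_DAYS:
            continue
        terrs = cluster_territories(grp)
        best = max(terrs, key=lambda t: t.tenure)  # ties -> earliest (stable sort above)
        rows.append(
            {
                "male_id": str(male),
                "site": str(site),
                "year": int(year),
                "x": best.centre[0],
                "y": best.centre[1],
                "tenure": best.tenure,
            }
        )
    return pd.DataFrame(rows)


def estimate_nest_initiation(record: pd.Series | dict) -> dict:
    """Back-calculate nesting dates from clutch completion and clutch size.

    One egg is laid per day, so clutch initiation = completion -
    (clutch_size - 1) days; nest (building) initiation is 7 days before
    clutch initiation; incubation runs 14 days from clutch completion.
    """
    rec = dict(record)
    size = int(rec["clutch_size"])
    if size < 1:
        raise ValueError("clutch_size must be >= 1")
    completion = _as_date(rec["clutch_completion"])
    clutch_init = completion - timedelta(days=size - 1)
    rec["clutch_initiation"] = clutch_init
    rec["nest_initiation"] = clutch_init - timedelta(days=NEST_BUILD_DAYS)
    rec["incubation_start"] = completion
    rec["incubation_end"] = completion + timedelta(days=INCUBATION_DAYS)
    return rec


def anonymous_male_ids(observations: pd.DataFrame) -> pd.DataFrame:
    """Give unringed males (blank male_id) site-year-scoped anonymous tags."""
    obs = observations.copy()
    blank = obs["male_id"].isna() | (obs["male_id"].astype(str).str.strip() == "")
    if blank.any():
        tags = (
            obs.loc[blank, "site"].astype(str)
            + "-"
            + obs.loc[blank, "year"].astype(str)
            + "-anon"
            + (np.arange(int(blank.sum())) + 1).astype(str)
        )
        obs.loc[blank, "male_id"] = tags
    return obs


def build_choice_events(
    females: pd.DataFrame,
    surveys: pd.DataFrame,
    hab: GridRaster | dict[str, GridRaster],
    playbacks: pd.DataFrame | None = None,
    spec: mc.MateChoiceSpec | None = None,
) -> list[mc.ChoiceEvent]:
    """Assemble one choice event per female nest record.

    For each female the survey snapshot (columns site, survey_date,
    male_id, x, y) closest in time to her nest-initiation date is the
    candidate map — already-paired males stay in it, since polygyny
    occurs.  Ties between equally distant snapshots go to the earlier
    survey (females typically start building the day they arrive, so
    earlier information is the safer proxy).  H is the habitat raster
    value at each male's location (`hab` may be a per-site dict) and C
    comes from :func:`mate_choice.connectivity`; playback midpoints
    count as competitors only when the spec includes them, and are
    never candidates themselves.

    The chosen male is the one named by a ``mate_id`` column when
    present, otherwise the candidate nearest to the nest.
    """
    spec = spec or mc.MateChoiceSpec()
    surveys = surveys.copy()
    surveys["survey_date"] = surveys["survey_date"].map(_as_date)
    events = []
    for _, f in females.iterrows():
        rec = estimate_nest_initiation(f)
        site = str(rec["site"])
        ss = surveys.loc[surveys["site"].astype(str) == site]
        if ss.empty:
            raise ValueError(f"no survey snapshots for site {site!r}")
        gaps = ss["survey_date"].map(lambda d: abs((d - rec["nest_initiation"]).days))
        # sort by (gap, date): equal gaps resolve to the earlier survey
        snap_date = ss.assign(gap=gaps).sort_values(["gap", "survey_date"])["survey_date"].iloc[0]
        snap = ss.loc[ss["survey_date"] == snap_date]
        xy = snap[["x", "y"]].to_numpy(dtype=float)
        raster = hab[site] if isinstance(hab, dict) else hab
        H = np.atleast_1d(sample_raster(raster, xy[:, 0], xy[:, 1]))
        pb = None
        if playbacks is not None and len(playbacks):
            pbs = playbacks.loc[playbacks["site"].astype(str) == site]
            if "year" in pbs.columns and "year" in rec:
                pbs = pbs.loc[pbs["year"].astype(int) == int(rec["year"])]
            if len(pbs):
                pb = station_midpoints(pbs)
        C = np.array(
            [
                mc.connectivity(tuple(xy[i]), np.delete(xy, i, axis=0), pb, spec)
                for i in range(len(xy))
            ]
        )
        male_ids = snap["male_id"].astype(str).tolist()
        if "mate_id" in rec and rec.get("mate_id") not in (None, "", float("nan")) and str(
            rec.get("mate_id")
        ) in male_ids:
            chosen = male_ids.index(str(rec["mate_id"]))
        else:
            d2 = (xy[:, 0] - float(rec["x"])) ** 2 + (xy[:, 1] - float(rec["y"])) ** 2
            chosen = int(np.argmin(d2))
        events.append(
            mc.ChoiceEvent(
                female_id=str(rec.get("female_id", "")),
                site=site,
                decision_date=rec["nest_initiation"],
                male_ids=male_ids,
                xy=xy,
                H=H,
                C=C,
                chosen=chosen,
            )
        )
    return events


def events_to_frame(events: list[mc.ChoiceEvent]) -> pd.DataFrame:
    """Long-format choices table (one row per candidate, chosen flagged 0/1)."""
    rows = []
    for ev in events:
        for i, mid in enumerate(ev.male_ids):
            rows.append(
                {
                    "female_id": ev.female_id,
                    "site": ev.site,
                    "decision_date": str(ev.decision_date),
                    "candidate_male_id": mid,
                    "x": ev.xy[i, 0],
                    "y": ev.xy[i, 1],
                    "H": ev.H[i],
                    "C": ev.C[i],
                    "chosen": int(i == ev.chosen),
                }
            )
    return pd.DataFrame(rows)


def events_from_frame(frame: pd.DataFrame) -> list[mc.ChoiceEvent]:
    """Inverse of :func:`events_to_frame`."""
    events = []
    for (fid, site, ddate), grp in frame.groupby(
        ["female_id", "site", "decision_date"], sort=False
    ):
        chosen = int(np.argmax(grp["chosen"].to_numpy()))
        events.append(
            mc.ChoiceEvent(
                female_id=str(fid),
                site=str(site),
                decision_date=ddate,
                male_ids=grp["candidate_male_id"].astype(str).tolist(),
                xy=grp[["x", "y"]].to_numpy(dtype=float),
                H=grp["H"].to_numpy(dtype=float),
                C=grp["C"].to_numpy(dtype=float),
                chosen=chosen,
            )
        )
    return events
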