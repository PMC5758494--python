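"""Synthetic landscape generator.

Emulates the data layers the invasion-risk analysis consumes: clustered
waterbody point locations, stream polylines carrying route identifiers
("Kittle numbers"), major-road polylines, two-census invasion histories for
zebra mussel (ZM) and Eurasian watermilfoil (EWM), and watercraft-inspection
survey records.  The observation model reports true infestations with a
probability that increases with road access and boater traffic, reproducing
the reporting bias of a passive, public-report-based surveillance system:
accessible, high-traffic waterbodies are detected preferentially, remote ones
are under-reported.  The reporting process never produces false positives.

All randomness flows from ``config.seed`` through named per-process streams
(:mod:`aisrisk._rng`), so outputs are byte-reproducible and adding one
generator never perturbs another.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import stream
from .errors import AlignmentError, InvalidConfigError

__all__ = [
    "SPECIES",
    "GeneratorConfig",
    "StreamSegment",
    "RoadSegment",
    "Landscape",
    "generate_waterbodies",
    "generate_streams_roads",
    "generate_surveys",
    "generate_true_invasions",
    "generate_reported_invasions",
    "generate_landscape",
]

#: The two aquatic invasive species modelled: zebra mussel and Eurasian
#: watermilfoil.
SPECIES = ("zm", "ewm")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic landscape.

    Counts and probabilities are validated on use.  Coordinates are in a
    projected plane with kilometre units.  Default magnitudes follow the
    observed system where it reports them (census growth 57->125 for ZM,
    251->304 for EWM; 21 % survey eligibility) and are desk-scale design
    choices otherwise.
    """

    n_waterbodies: int = 600
    extent: tuple[float, float, float, float] = (0.0, 30.0, 0.0, 30.0)
    #: Thomas-type cluster process: parents uniform in the extent, offspring
    #: displaced by an isotropic Gaussian of sd ``cluster_spread`` km.
    n_parents: int = 40
    cluster_spread: float = 1.2
    river_fraction: float = 0.05

    n_streams: int = 30
    stream_size: int = 8  # mean waterbodies threaded per stream
    n_roads: int = 12

    base_prevalence_t1: dict[str, float] = field(
        default_factory=lambda: {"zm": 0.05, "ewm": 0.08}
    )
    growth_factor: dict[str, float] = field(
        default_factory=lambda: {"zm": 2.2, "ewm": 1.2}
    )

    # latent risk-score coefficients (applied to standardized covariates)
    traffic_effect: float = 1.2
    road_effect: float = 0.8
    field_effect: float = 1.0
    field_range_km: float = 3.0
    proximity_effect: float = 5.0
    proximity_scale_km: float = 2.0
    connectivity_effect: float = 1.5

    # observation model: logistic in standardized road access and traffic
    reporting_intercept: float = 1.5
    reporting_bias: float = 1.0

    survey_count: int = 5000
    n_stations: int = 45
    ineligible_fraction: float = 0.79
    missing_link_fraction: float = 0.10

    seed: int = 0

    def validate(self) -> None:
        if self.n_waterbodies <= 0:
            raise InvalidConfigError("n_waterbodies must be positive")
        if self.n_parents <= 0:
            raise InvalidConfigError("n_parents must be positive")
        x0, x1, y0, y1 = self.extent
        if not (x1 > x0 and y1 > y0):
            raise InvalidConfigError("extent must be a non-degenerate box")
        for name, p in (
            ("river_fraction", self.river_fraction),
            ("ineligible_fraction", self.ineligible_fraction),
            ("missing_link_fraction", self.missing_link_fraction),
            *((f"base_prevalence_t1[{s}]", v) for s, v in self.base_prevalence_t1.items()),
        ):
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1], got {p}")
        if self.survey_count < 0:
            raise InvalidConfigError("survey_count must be non-negative")
        if self.cluster_spread < 0:
            raise InvalidConfigError("cluster_spread must be non-negative")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class StreamSegment:
    """A stream/river polyline carrying a route ("Kittle") identifier."""

    kittle_id: str
    vertices: np.ndarray  # (n, 2) km

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] != 2:
            raise InvalidConfigError("stream polyline needs >=2 (x, y) vertices")
        if not self.kittle_id:
            raise InvalidConfigError("kittle_id must be non-empty")
        object.__setattr__(self, "vertices", v)


@dataclass(frozen=True)
class RoadSegment:
    """A major-road polyline (interstate/freeway/arterial/major collector)."""

    vertices: np.ndarray  # (n, 2) km
    road_class: str = "arterial"

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] != 2:
            raise InvalidConfigError("road polyline needs >=2 (x, y) vertices")
        object.__setattr__(self, "vertices", v)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def _standardize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def generate_waterbodies(config: GeneratorConfig) -> pd.DataFrame:
    """Draw clustered waterbody point locations (Thomas cluster process).

    Returns a frame with columns ``id, x, y, kind`` where ``kind`` is
    ``"lake"`` or ``"river"`` (river points stand for river midpoints).
    Offspring displaced outside the extent are clipped to its boundary.
    """
    config.validate()
    rng = stream(config.seed, "waterbodies")
    x0, x1, y0, y1 = config.extent
    parents = np.column_stack(
        [rng.uniform(x0, x1, config.n_parents), rng.uniform(y0, y1, config.n_parents)]
    )
    assign = rng.integers(0, config.n_parents, config.n_waterbodies)
    pts = parents[assign] + rng.normal(0.0, config.cluster_spread, (config.n_waterbodies, 2))
    pts[:, 0] = np.clip(pts[:, 0], x0, x1)
    pts[:, 1] = np.clip(pts[:, 1], y0, y1)
    n_river = int(round(config.river_fraction * config.n_waterbodies))
    kind = np.array(["lake"] * config.n_waterbodies, dtype=object)
    if n_river:
        kind[rng.choice(config.n_waterbodies, n_river, replace=False)] = "river"
    width = len(str(config.n_waterbodies))
    ids = [f"W{i:0{width}d}" for i in range(config.n_waterbodies)]
    return pd.DataFrame({"id": ids, "x": pts[:, 0], "y": pts[:, 1], "kind": kind})


def generate_streams_roads(
    config: GeneratorConfig, waterbodies: pd.DataFrame
) -> tuple[list[StreamSegment], list[RoadSegment], dict[str, set[str]]]:
    """Generate stream and road polylines plus the waterbody->stream map.

    Each stream threads a random, spatially coherent subset of waterbody
    locations (its vertices pass exactly through them), so those waterbodies
    intersect the stream and share its Kittle number.  Roads are polylines
    spanning the extent.
    """
    config.validate()
    rng = stream(config.seed, "streams_roads")
    x0, x1, y0, y1 = config.extent
    xy = waterbodies[["x", "y"]].to_numpy(float)
    ids = waterbodies["id"].to_numpy(object)
    n = len(waterbodies)

    streams: list[StreamSegment] = []
    assignment: dict[str, set[str]] = {wid: set() for wid in ids}
    letters = string.ascii_uppercase
    for k in range(config.n_streams):
        size = max(2, int(rng.poisson(config.stream_size)))
        size = min(size, n)
        anchor = rng.integers(0, n)
        d = np.hypot(xy[:, 0] - xy[anchor, 0], xy[:, 1] - xy[anchor, 1])
        member_idx = np.argsort(d)[:size]
        members = xy[member_idx]
        # order along the principal axis so the polyline flows one way
        centred = members - members.mean(axis=0)
        u = np.linalg.svd(centred, full_matrices=False)[2][0]
        order = np.argsort(centred @ u)
        verts = members[order]
        if len(verts) < 2:  # degenerate tiny stream
            verts = np.vstack([verts, verts + 1e-3])
        kittle = f"{letters[k % 26]}{k:03d}"
        streams.append(StreamSegment(kittle_id=kittle, vertices=verts))
        for i in member_idx:
            assignment[ids[i]].add(kittle)

    roads: list[RoadSegment] = []
    classes = ("interstate", "freeway", "arterial", "major_collector")
    for k in range(config.n_roads):
        horizontal = rng.random() < 0.5
        n_v = 4
        if horizontal:
            xs = np.linspace(x0, x1, n_v)
            ys = rng.uniform(y0, y1) + rng.normal(0, (y1 - y0) * 0.03, n_v)
            verts = np.column_stack([xs, np.clip(ys, y0, y1)])
        else:
            ys = np.linspace(y0, y1, n_v)
            xs = rng.uniform(x0, x1) + rng.normal(0, (x1 - x0) * 0.03, n_v)
            verts = np.column_stack([np.clip(xs, x0, x1), ys])
        roads.append(RoadSegment(vertices=verts, road_class=classes[k % len(classes)]))

    return streams, roads, assignment


def generate_surveys(
    waterbodies: pd.DataFrame, propensity: np.ndarray, config: GeneratorConfig
) -> pd.DataFrame:
    """Draw watercraft-inspection survey records.

    Inspection stations are a subset of waterbodies sampled proportionally to
    ``propensity`` (a traffic-attractiveness weight, e.g. waterbody size).
    The previous / next waterbody of each interviewed boater is drawn with a
    gravity-style weight ``propensity / (distance + d0)`` from the station;
    links are occasionally absent and a fixed fraction of records is flagged
    ineligible (reporting errors), contributing no network edges downstream.

    Returns columns ``station_id, prev_id, next_id, eligible`` where absent
    links are empty strings.
    """
    config.validate()
    propensity = np.asarray(propensity, dtype=float)
    if len(propensity) != len(waterbodies):
        raise AlignmentError("propensity must align with waterbodies")
    if np.any(propensity < 0) or propensity.sum() <= 0:
        raise InvalidConfigError("propensity must be non-negative with positive sum")
    rng = stream(config.seed, "surveys")
    if config.survey_count == 0:
        return pd.DataFrame(columns=["station_id", "prev_id", "next_id", "eligible"])

    ids = waterbodies["id"].to_numpy(object)
    xy = waterbodies[["x", "y"]].to_numpy(float)
    n = len(ids)
    p = propensity / propensity.sum()

    n_st = min(config.n_stations, int((propensity > 0).sum()))
    stations = rng.choice(n, size=n_st, replace=False, p=p)
    st_w = propensity[stations]
    st_p = st_w / st_w.sum()
    st_idx = stations[rng.choice(n_st, size=config.survey_count, p=st_p)]

    d0 = 0.5  # km, gravity softening
    records = []
    # per-station gravity weights, cached
    grav_cache: dict[int, np.ndarray] = {}
    for s in st_idx:
        g = grav_cache.get(s)
        if g is None:
            d = np.hypot(xy[:, 0] - xy[s, 0], xy[:, 1] - xy[s, 1])
            g = propensity / (d + d0)
            g[s] = 0.0  # a trip is between two distinct waterbodies
            g = g / g.sum()
            grav_cache[s] = g
        prev_id = next_id = ""
        if rng.random() >= config.missing_link_fraction:
            prev_id = ids[rng.choice(n, p=g)]
        if rng.random() >= config.missing_link_fraction:
            next_id = ids[rng.choice(n, p=g)]
        records.append((ids[s], prev_id, next_id))
    eligible = rng.random(config.survey_count) >= config.ineligible_fraction
    out = pd.DataFrame(records, columns=["station_id", "prev_id", "next_id"])
    out["eligible"] = eligible
    return out


def _calibrate_intercept(scores: np.ndarray, target: float) -> float:
    """Find a0 with mean(sigmoid(a0 + scores)) == target, by bisection."""
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _sigmoid(mid + scores).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _gaussian_field(xy: np.ndarray, range_km: float, rng: np.random.Generator) -> np.ndarray:
    """Spatially autocorrelated standard-normal surface.

    Random Fourier-feature approximation of a Gaussian-covariance process
    (256 features), O(n) in the number of waterbodies so full-state scale
    runs stay cheap.
    """
    m = 256
    omega = rng.normal(0.0, 1.0 / max(range_km, 1e-9), (m, 2))
    phase = rng.uniform(0, 2 * np.pi, m)
    f = np.sqrt(2.0 / m) * np.cos(xy @ omega.T + phase).sum(axis=1) / np.sqrt(1.0)
    # the RFF sum has unit variance already; re-standardize to be exact
    return _standardize(f) if f.std() > 0 else f


def generate_true_invasions(
    waterbodies: pd.DataFrame,
    stream_assignment: dict[str, set[str]],
    traffic_scores: np.ndarray,
    road_scores: np.ndarray,
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Simulate the true two-census invasion history per species.

    Census-1 presence is Bernoulli with a logistic latent score combining
    boater-traffic centrality, road access and a spatially autocorrelated
    field; the intercept is calibrated so the expected census-1 prevalence
    equals ``base_prevalence_t1``.  Census-2 adds new infestations (never
    removes any: no effective eradication) with probability increasing with
    proximity to census-1 infestations and shared-stream connectivity, scaled
    so the expected census-2 count is ``growth_factor`` times the census-1
    count.

    Returns columns ``{species}_t1, {species}_t2`` aligned to ``waterbodies``.
    """
    config.validate()
    n = len(waterbodies)
    traffic_scores = np.asarray(traffic_scores, dtype=float)
    road_scores = np.asarray(road_scores, dtype=float)
    if len(traffic_scores) != n or len(road_scores) != n:
        raise AlignmentError("covariate score vectors must align with waterbodies")

    xy = waterbodies[["x", "y"]].to_numpy(float)
    ids = waterbodies["id"].to_numpy(object)
    z_traffic = _standardize(traffic_scores)
    z_road = _standardize(road_scores)

    out = {}
    for sp in SPECIES:
        rng = stream(config.seed, f"invasion_{sp}")
        base = config.base_prevalence_t1.get(sp, 0.0)
        lin = config.traffic_effect * z_traffic + config.road_effect * z_road
        if config.field_effect != 0.0:
            lin = lin + config.field_effect * _gaussian_field(
                xy, config.field_range_km, rng
            )
        a0 = _calibrate_intercept(lin, base)
        p1 = _sigmoid(a0 + lin) if np.isfinite(a0) else (np.ones(n) if a0 > 0 else np.zeros(n))
        t1 = (rng.random(n) < p1).astype(np.int8)

        t2 = t1.copy()
        n1 = int(t1.sum())
        growth = config.growth_factor.get(sp, 1.0)
        target_new = max(0, int(round((growth - 1.0) * n1)))
        if n1 > 0 and target_new > 0:
            infested_xy = xy[t1 == 1]
            sus = np.flatnonzero(t1 == 0)
            if len(sus):
                d = np.sqrt(
                    ((xy[sus, None, :] - infested_xy[None, :, :]) ** 2).sum(-1)
                ).min(axis=1)
                prox = np.exp(-d / config.proximity_scale_km)
                infested_streams: set[str] = set()
                for i in np.flatnonzero(t1 == 1):
                    infested_streams |= stream_assignment.get(ids[i], set())
                conn = np.array(
                    [
                        1.0
                        if stream_assignment.get(ids[i], set()) & infested_streams
                        else 0.0
                        for i in sus
                    ]
                )
                w = np.exp(
                    config.proximity_effect * prox + config.connectivity_effect * conn
                )
                p_add = np.minimum(1.0, target_new * w / w.sum())
                t2[sus[rng.random(len(sus)) < p_add]] = 1
        out[f"{sp}_t1"] = t1
        out[f"{sp}_t2"] = t2
    res = pd.DataFrame(out)
    res.insert(0, "id", ids)
    return res


def generate_reported_invasions(
    true_status: pd.DataFrame,
    road_scores: np.ndarray,
    traffic_scores: np.ndarray,
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Apply the biased observation process to the true invasion history.

    Each true infestation is reported with probability
    ``logistic(reporting_intercept + reporting_bias * (z_road + z_traffic))``:
    accessible, high-traffic waterbodies are detected preferentially.  There
    are no false positives (reports are confirmed before being recorded), so
    reported is a subset of true; an infestation missed at census 1 gets a
    fresh detection opportunity at census 2, and reported status never
    decreases between censuses.
    """
    config.validate()
    n = len(true_status)
    z = _standardize(np.asarray(road_scores, float)) + _standardize(
        np.asarray(traffic_scores, float)
    )
    if len(z) != n:
        raise AlignmentError("score vectors must align with true_status")
    out = {"id": true_status["id"].to_numpy(object)}
    for sp in SPECIES:
        rng = stream(config.seed, f"reporting_{sp}")
        arg = config.reporting_intercept + config.reporting_bias * z
        with np.errstate(over="ignore"):
            r = _sigmoid(arg)
        if np.isposinf(config.reporting_intercept):
            r = np.ones(n)
        elif np.isneginf(config.reporting_intercept):
            r = np.zeros(n)
        t1 = true_status[f"{sp}_t1"].to_numpy(np.int8)
        t2 = true_status[f"{sp}_t2"].to_numpy(np.int8)
        rep1 = (t1 == 1) & (rng.random(n) < r)
        rep2 = rep1 | ((t2 == 1) & (rng.random(n) < r))
        out[f"{sp}_t1"] = rep1.astype(np.int8)
        out[f"{sp}_t2"] = rep2.astype(np.int8)
    return pd.DataFrame(out)


@dataclass
class Landscape:
    """A fully generated synthetic study system."""

    config: GeneratorConfig
    waterbodies: pd.DataFrame
    streams: list[StreamSegment]
    roads: list[RoadSegment]
    stream_assignment: dict[str, set[str]]
    surveys: pd.DataFrame
    true_status: pd.DataFrame
    reported_status: pd.DataFrame
    road_scores: np.ndarray
    traffic_scores: np.ndarray


def generate_landscape(config: GeneratorConfig) -> Landscape:
    """Run every generator stage in dependency order.

    Traffic centrality (from the survey-derived network) and road access
    feed the invasion and reporting models, mirroring the real system where
    human-mediated dispersal drives both where invasions occur and where
    they get noticed.
    """
    from .covariates import inverse_road_distance
    from .networks import build_traffic_network, eigenvector_centrality

    config.validate()
    wb = generate_waterbodies(config)
    streams, roads, assignment = generate_streams_roads(config, wb)
    sizes = stream(config.seed, "sizes").lognormal(0.0, 1.0, len(wb))
    surveys = generate_surveys(wb, sizes, config)
    road_scores = inverse_road_distance(wb, roads)

    traffic = np.zeros(len(wb))
    if len(surveys):
        net = build_traffic_network(surveys, known_ids=set(wb["id"]))
        if net.number_of_edges() > 0:
            cv = eigenvector_centrality(net)
            idx = {wid: i for i, wid in enumerate(wb["id"])}
            for wid, s in cv.scores.items():
                traffic[idx[wid]] = s

    true = generate_true_invasions(wb, assignment, traffic, road_scores, config)
    reported = generate_reported_invasions(true, road_scores, traffic, config)
    return Landscape(
        config=config,
        waterbodies=wb,
        streams=streams,
        roads=roads,
        stream_assignment=assignment,
        surveys=surveys,
        true_status=true,
        reported_status=reported,
        road_scores=road_scores,
        traffic_scores=traffic,
    )
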