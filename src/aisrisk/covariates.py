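"""Waterbody-specific covariates and correlation screening.

Six predictors are attached to every waterbody, per census year:

1. ``v1_zm``      zebra mussel invasion status {0,1} (primary)
2. ``v2_ewm``     Eurasian watermilfoil invasion status {0,1} (primary)
3. ``v3_conn_zm`` stream connectivity to a ZM-invaded waterbody {0,1}
4. ``v4_conn_ewm`` stream connectivity to an EWM-invaded waterbody {0,1}
5. ``v5_eig``     eigenvector centrality in the boater-traffic network
6. ``v6_invroad`` inverse Euclidean distance to the nearest major road (1/km)

v5 and v6 are shared between census years (the traffic survey is a single
snapshot and the road network is assumed unchanged); statuses and
connectivity are year-specific.  Candidate secondary variables for the
co-kriging model of each species are screened by Pearson correlation with
that species' status at a configurable threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import AlignmentError, InsufficientDataError, MissingLayerError

__all__ = [
    "VARIABLES",
    "inverse_road_distance",
    "assemble",
    "pearson_screen",
]

VARIABLES = ("v1_zm", "v2_ewm", "v3_conn_zm", "v4_conn_ewm", "v5_eig", "v6_invroad")

#: Distance floor (km) so waterbodies sitting on a road keep a finite score.
D_MIN_KM = 0.01


def inverse_road_distance(
    waterbodies: pd.DataFrame, roads, d_min: float = D_MIN_KM
) -> np.ndarray:
    """Inverse distance (1/km) from each waterbody to the nearest major road.

    The minimum Euclidean point-to-polyline distance over all road segments,
    floored at ``d_min`` km before inversion.
    """
    from shapely.geometry import LineString, Point
    from shapely.strtree import STRtree

    roads = list(roads)
    if not roads:
        raise MissingLayerError("no major-road segments supplied")
    lines = [LineString(r.vertices) for r in roads]
    tree = STRtree(lines)
    out = np.empty(len(waterbodies))
    for i, row in enumerate(waterbodies.itertuples(index=False)):
        p = Point(row.x, row.y)
        nearest = tree.nearest(p)
        d = lines[nearest].distance(p)
        out[i] = 1.0 / max(d, d_min)
    return out


def assemble(
    waterbodies: pd.DataFrame,
    statuses: pd.DataFrame,
    connectivity: dict[str, dict[str, int]],
    centrality: np.ndarray | None,
    road_scores: np.ndarray,
    census_year: str,
) -> pd.DataFrame:
    """Assemble the six-variable covariate table for one census year.

    Parameters
    ----------
    statuses : frame with ``id`` plus ``zm_<year>``/``ewm_<year>`` columns
        of reported status.
    connectivity : per species, waterbody-id -> {0,1} flag for this year.
    centrality : traffic centrality aligned to ``waterbodies`` (0 for
        unsurveyed waterbodies); None means nobody was surveyed.
    census_year : "t1" or "t2" (2010 / 2015 in the source system).
    """
    ids = waterbodies["id"].to_numpy(object)
    n = len(ids)
    st = statuses.set_index("id")
    for sp in ("zm", "ewm"):
        col = f"{sp}_{census_year}"
        if col not in st.columns:
            raise AlignmentError(f"statuses lack column {col}")
    if not st.index.is_unique or set(ids) - set(st.index):
        raise AlignmentError("status ids do not cover the waterbody set")
    if centrality is None:
        centrality = np.zeros(n)
    centrality = np.asarray(centrality, float)
    road_scores = np.asarray(road_scores, float)
    if len(centrality) != n or len(road_scores) != n:
        raise AlignmentError("v5/v6 vectors must align with waterbodies")

    conn_zm = connectivity.get("zm", {})
    conn_ewm = connectivity.get("ewm", {})
    table = pd.DataFrame(
        {
            "id": ids,
            "x": waterbodies["x"].to_numpy(float),
            "y": waterbodies["y"].to_numpy(float),
            "v1_zm": st.loc[ids, f"zm_{census_year}"].to_numpy(np.int8),
            "v2_ewm": st.loc[ids, f"ewm_{census_year}"].to_numpy(np.int8),
            "v3_conn_zm": [int(conn_zm.get(i, 0)) for i in ids],
            "v4_conn_ewm": [int(conn_ewm.get(i, 0)) for i in ids],
            "v5_eig": centrality,
            "v6_invroad": road_scores,
            "year": census_year,
        }
    )
    return table


def pearson_screen(
    table: pd.DataFrame, threshold: float = 0.1
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Pearson correlation matrix of the six covariates + candidate screen.

    Binary columns enter as 0/1 numerics (point-biserial).  For each primary
    (v1_zm, v2_ewm) the candidate secondary set is every other variable with
    r >= ``threshold`` against it — the other species' status included.
    Zero-variance columns get undefined (NaN) correlations, are excluded
    from candidacy, and trigger a warning.

    Returns the 6x6 matrix (unit diagonal, symmetric) and the per-primary
    candidate lists in fixed variable order.
    """
    if len(table) < 3:
        raise InsufficientDataError("need at least 3 waterbodies to screen")
    x = table[list(VARIABLES)].to_numpy(float)
    sd = x.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        bad = [v for v, d in zip(VARIABLES, degenerate) if d]
        warnings.warn(
            f"zero-variance columns excluded from screening: {bad}", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, 1.0)
    mat = pd.DataFrame(corr, index=VARIABLES, columns=VARIABLES)

    candidates: dict[str, list[str]] = {}
    for primary in ("v1_zm", "v2_ewm"):
        cands = []
        for v in VARIABLES:
            if v == primary:
                continue
            r = mat.loc[primary, v]
            if np.isfinite(r) and r >= threshold:
                cands.append(v)
        candidates[primary] = cands
    return mat, candidates
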