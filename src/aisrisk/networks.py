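"""Boater-movement network and stream-connectivity indicators.

The watercraft-inspection survey asks each boater for the previous waterbody
visited and the next one planned, so a completed interview contributes two
undirected edges: previous--station and station--next.  Edge multiplicities
accumulate over records and act as weights.  Three node centralities
(eigenvector, betweenness, degree) summarize a waterbody's position in the
traffic network; the one correlating best with invasion status becomes the
boater-traffic covariate.

Stream connectivity uses shared route identifiers (Kittle numbers): any
waterbody sharing a stream with an invaded waterbody is flagged connected,
up- and downstream alike, since both drift and watercraft can carry
propagules either way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import EmptyInputError, ConvergenceError, ReferentialIntegrityError

__all__ = [
    "CentralityVector",
    "build_traffic_network",
    "eigenvector_centrality",
    "betweenness_centrality",
    "degree_centrality",
    "select_centrality",
    "assign_streams",
    "connectivity_to_invaded",
]

CENTRALITY_ORDER = ("eigenvector", "betweenness", "degree")


@dataclass(frozen=True)
class CentralityVector:
    """Per-node centrality scores for one measure."""

    measure: str
    scores: dict[str, float]

    def aligned(self, ids) -> np.ndarray:
        """Scores as an array aligned to ``ids``; absent nodes score 0."""
        return np.array([self.scores.get(i, 0.0) for i in ids], dtype=float)


def build_traffic_network(
    records: pd.DataFrame, known_ids: set[str] | None = None
) -> nx.Graph:
    """Build the undirected, multiplicity-weighted traffic network.

    Each eligible record adds edge (prev, station) when the previous
    waterbody is present and (station, next) when the next one is; repeated
    pairs accumulate an integer ``weight``.  Ineligible records contribute
    nothing.  Self-loops (prev == station) are dropped — they carry no
    between-waterbody transport.

    Parameters
    ----------
    records : frame with columns station_id, prev_id, next_id, eligible;
        absent links are empty strings or NaN.
    known_ids : optional universe of valid waterbody ids; any reference
        outside it raises ``ReferentialIntegrityError``.
    """
    g = nx.Graph()

    def _clean(v) -> str:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return ""
        return str(v)

    for row in records.itertuples(index=False):
        station = _clean(row.station_id)
        prev = _clean(row.prev_id)
        nxt = _clean(row.next_id)
        if known_ids is not None:
            for ref in (station, prev, nxt):
                if ref and ref not in known_ids:
                    raise ReferentialIntegrityError(
                        f"survey references unknown waterbody {ref!r}"
                    )
        if not row.eligible:
            continue
        for a, b in ((prev, station), (station, nxt)):
            if not a or not b or a == b:
                continue
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    return g


def eigenvector_centrality(
    network: nx.Graph, tol: float = 1e-10, max_iter: int = 10_000
) -> CentralityVector:
    """Dominant-eigenvector scores of the weighted adjacency matrix.

    Computed by power iteration on the largest connected component (the
    dominant eigenvector is ill-defined across components); nodes outside it
    score 0.  Scores are non-negative and normalized to unit Euclidean norm.
    """
    if network.number_of_nodes() == 0:
        raise EmptyInputError("cannot compute centrality of an empty network")
    comp = max(nx.connected_components(network), key=len)
    nodes = sorted(comp)
    a = nx.to_numpy_array(network, nodelist=nodes, weight="weight")
    # Perron shift: iterate on A + I so bipartite components (eigenvalues
    # +/- lambda) cannot make the iteration oscillate; the dominant
    # eigenvector of a nonnegative matrix is unchanged.
    a = a + np.eye(len(nodes))
    v = np.ones(len(nodes)) / np.sqrt(len(nodes))
    if len(nodes) > 1:
        for _ in range(max_iter):
            nv = a @ v
            norm = np.linalg.norm(nv)
            if norm == 0:  # isolated component of size>1 cannot occur, be safe
                break
            nv /= norm
            if np.abs(nv - v).max() < tol:
                v = nv
                break
            v = nv
        else:
            raise ConvergenceError(
                f"power iteration did not converge in {max_iter} iterations"
            )
    v = np.abs(v)
    n = np.linalg.norm(v)
    if n > 0:
        v = v / n
    scores = {node: 0.0 for node in network.nodes}
    scores.update({node: float(s) for node, s in zip(nodes, v)})
    return CentralityVector("eigenvector", scores)


def betweenness_centrality(network: nx.Graph) -> CentralityVector:
    """Unnormalized shortest-path betweenness (unweighted hop counts).

    Edge multiplicities encode trip frequency, not travel cost, so they are
    ignored for path finding.
    """
    if network.number_of_nodes() == 0:
        raise EmptyInputError("cannot compute centrality of an empty network")
    scores = nx.betweenness_centrality(network, normalized=False, weight=None)
    return CentralityVector("betweenness", {k: float(v) for k, v in scores.items()})


def degree_centrality(network: nx.Graph) -> CentralityVector:
    """Weighted degree: the number of recorded trips touching each node."""
    if network.number_of_nodes() == 0:
        raise EmptyInputError("cannot compute centrality of an empty network")
    return CentralityVector(
        "degree", {n: float(d) for n, d in network.degree(weight="weight")}
    )


def select_centrality(
    centralities: dict[str, CentralityVector],
    status_by_species: dict[str, pd.Series],
) -> str:
    """Pick the centrality that best correlates with invasion status.

    The chosen measure maximizes the mean (over species) Pearson correlation
    with the 0/1 invasion status over all waterbodies; ties break by the
    fixed order eigenvector > betweenness > degree.  Statuses are indexed by
    waterbody id; unsurveyed waterbodies enter with centrality 0.
    """
    if not centralities:
        raise EmptyInputError("no centrality vectors supplied")
    best_measure, best_r = None, -np.inf
    for measure in CENTRALITY_ORDER:
        if measure not in centralities:
            continue
        cv = centralities[measure]
        rs = []
        skip = False
        for sp, status in status_by_species.items():
            x = cv.aligned(status.index)
            y = status.to_numpy(float)
            if x.std() == 0 or y.std() == 0:
                warnings.warn(
                    f"zero variance when correlating {measure} with {sp} status; "
                    "measure skipped",
                    stacklevel=2,
                )
                skip = True
                break
            rs.append(float(np.corrcoef(x, y)[0, 1]))
        if skip or not rs:
            continue
        mean_r = float(np.mean(rs))
        if mean_r > best_r:  # strict: earlier measures win ties
            best_measure, best_r = measure, mean_r
    if best_measure is None:
        raise EmptyInputError("no centrality measure had usable correlations")
    return best_measure


def assign_streams(
    waterbodies: pd.DataFrame,
    streams,
    buffer_km: float = 0.1,
    invaded_ids: set[str] | None = None,
    intersect_tol: float = 1e-6,
) -> dict[str, set[str]]:
    """Map each waterbody to the Kittle ids of the streams it touches.

    A waterbody collects every stream polyline within ``intersect_tol``
    (point-on-line intersection).  An *invaded* waterbody intersecting no
    stream is additionally assigned its single nearest stream within
    ``buffer_km`` (the 100 m buffer convention); beyond the buffer nothing is
    assigned.
    """
    from shapely.geometry import LineString, Point

    lines = [(s.kittle_id, LineString(s.vertices)) for s in streams]
    invaded_ids = invaded_ids or set()
    out: dict[str, set[str]] = {}
    for row in waterbodies.itertuples(index=False):
        p = Point(row.x, row.y)
        hits = {kid for kid, line in lines if line.distance(p) <= intersect_tol}
        if not hits and row.id in invaded_ids and lines:
            dists = [(line.distance(p), kid) for kid, line in lines]
            dmin, kid = min(dists)
            if dmin <= buffer_km:
                hits = {kid}
        out[row.id] = hits
    return out


def connectivity_to_invaded(
    assignments: dict[str, set[str]], invaded_ids: set[str]
) -> dict[str, int]:
    """Flag waterbodies stream-connected to an invaded waterbody.

    A waterbody is flagged (1) when it shares at least one Kittle id with any
    invaded waterbody, regardless of flow direction.  Invaded waterbodies on
    a stream are therefore flagged themselves.  Recomputed per species and
    census with that census's invaded set.
    """
    invaded_streams: set[str] = set()
    for wid in invaded_ids:
        invaded_streams |= assignments.get(wid, set())
    return {
        wid: int(bool(kittles & invaded_streams))
        for wid, kittles in assignments.items()
    }
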