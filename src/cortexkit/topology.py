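"""Structure-function analysis: simplices, enrichment, meso-scale graphs.

Directed n-simplices are n+1 nodes all-to-all connected in a feed-forward
fashion: an ordered tuple with an edge from every earlier to every later
node, each ordering counting as a distinct simplex. A node's participation
in dimension n counts the directed n-simplices containing it, generalising
total degree (the n = 1 case). Meso-scale analysis bins neurons
into hexagonal prisms in a flattened view and relates the synapse-count
graph between subvolumes to the correlation structure of their spiking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .network import SpikeRecording


# ---------------------------------------------------------------------------
# Directed simplex counting
# ---------------------------------------------------------------------------

def node_participation(edges, n_nodes: int | None = None,
                       max_dim: int | None = None) -> np.ndarray:
    """Node-by-dimension matrix of directed-simplex participation counts.

    ``edges`` is an iterable of (u, v) pairs (duplicates ignored, self-loops
    rejected). Counting enumerates simplices as totally ordered chains
    v0 -> v1 -> ... -> vk with an edge from every earlier to every later
    node; each simplex has exactly one such order, so each is counted once.
    Column k holds Par_k; Par_1(v) is the total degree of v.
    """
    if max_dim is not None and max_dim < 1:
        raise ValueError("max_dim must be >= 1")
    edge_set = set()
    for u, v in edges:
        if u == v:
            raise ValueError("self-loops are not allowed")
        edge_set.add((int(u), int(v)))
    nodes = {u for u, _ in edge_set} | {v for _, v in edge_set}
    n = (max(nodes) + 1 if nodes else 0) if n_nodes is None else int(n_nodes)
    out_adj: dict[int, set[int]] = {v: set() for v in range(n)}
    for u, v in edge_set:
        out_adj[u].add(v)

    cap = max_dim if max_dim is not None else max(n - 1, 1)
    par = np.zeros((n, cap + 1), dtype=np.int64)
    par[:, 0] = 1  # every node is a 0-simplex

    chain: list[int] = []

    def extend(candidates: set[int]) -> None:
        dim = len(chain)  # dimension of the simplex formed by chain + [w]
        if dim > cap:
            return
        for w in candidates:
            chain.append(w)
            for v in chain:
                par[v, dim] += 1
            nxt = candidates & out_adj[w]
            if nxt and dim < cap:
                extend(nxt)
            chain.pop()

    for v0 in range(n):
        if out_adj[v0]:
            chain.append(v0)
            extend(out_adj[v0])
            chain.pop()
    return par


def simplex_counts(edges, n_nodes: int | None = None,
                   max_dim: int | None = None) -> np.ndarray:
    """Total number of directed k-simplices per dimension k."""
    par = node_participation(edges, n_nodes=n_nodes, max_dim=max_dim)
    dims = np.arange(par.shape[1])
    return (par.sum(axis=0) // (dims + 1)).astype(np.int64)


def weighted_mean_by_dimension(values: np.ndarray, participation: np.ndarray,
                               k: int, compat_normalization: bool = False
                               ) -> float:
    """Average of a node property weighted by dimension-k participation.

    mean_k = (values . Par_k) / sum(Par_k). ``compat_normalization`` divides
    additionally by the number of nodes (compatibility with an alternative
    printed convention)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(participation[:, k], dtype=float)
    total = w.sum()
    if total == 0:
        raise ZeroDivisionError(f"no simplices in dimension {k}")
    mean = float(np.dot(v, w) / total)
    if compat_normalization:
        mean /= len(v)
    return mean


def hypergeom_enrichment(N_total: int, N_m: int, C_top: int, C_m: int
                         ) -> tuple[float, float]:
    """Exact under-/over-expression tail probabilities.

    For a random sample of size ``C_top`` from ``N_total`` objects of which
    ``N_m`` belong to the class of interest:
    p_under = P(Counts <= C_m), p_over = P(Counts >= C_m).
    """
    dist = hypergeom(N_total, N_m, C_top)
    p_under = float(dist.cdf(C_m))
    p_over = float(dist.sf(C_m - 1))
    return p_under, p_over


def top_participation_set(participation: np.ndarray, k: int,
                          top_fraction: float = 0.05) -> np.ndarray:
    """Ids of nodes in the highest ``top_fraction`` of Par_k.

    Ties at the cutoff value are all included."""
    w = participation[:, k]
    n_top = max(int(math.ceil(top_fraction * len(w))), 1)
    cutoff = np.sort(w)[::-1][n_top - 1]
    return np.flatnonzero(w >= cutoff)


# ---------------------------------------------------------------------------
# Hexagonal binning in flat space
# ---------------------------------------------------------------------------

def hex_bin(xy_um: np.ndarray, diameter_um: float
            ) -> tuple[np.ndarray, np.ndarray]:
    """Assign flat locations to a regular hexagonal tiling.

    ``diameter_um`` is the flat-to-flat hexagon diameter, equal to the pitch
    (center distance) of adjacent hexagons. Points map to the hexagon whose
    center is nearest (cube rounding); occupied hexagons are indexed in
    sorted axial order. Returns (assignment per point, centers (n_hex, 2)).
    """
    xy = np.asarray(xy_um, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("xy must be (n, 2)")
    size = diameter_um / math.sqrt(3.0)  # center-to-vertex, pointy-top
    # pixel -> fractional axial coordinates
    q = (math.sqrt(3.0) / 3.0 * xy[:, 0] - xy[:, 1] / 3.0) / size
    r = (2.0 / 3.0 * xy[:, 1]) / size
    qi, ri = _cube_round(q, r)
    keys = np.stack([qi, ri], axis=1)
    uniq, assignment = np.unique(keys, axis=0, return_inverse=True)
    cx = size * math.sqrt(3.0) * (uniq[:, 0] + uniq[:, 1] / 2.0)
    cy = size * 1.5 * uniq[:, 1]
    centers = np.stack([cx, cy], axis=1)
    return assignment, centers


def _cube_round(q: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = -q - r
    qi = np.round(q)
    ri = np.round(r)
    si = np.round(s)
    dq = np.abs(qi - q)
    dr = np.abs(ri - r)
    ds = np.abs(si - s)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    qi = np.where(fix_q, -ri - si, qi)
    ri = np.where(fix_r, -qi - si, ri)
    return qi.astype(np.int64), ri.astype(np.int64)


# ---------------------------------------------------------------------------
# Meso-scale graphs
# ---------------------------------------------------------------------------

@dataclass
class MesoGraph:
    centers_um: np.ndarray     # (n_sub, 2) flat centers
    S: np.ndarray              # (n_sub, n_sub) synapse counts, directed
    F: np.ndarray              # (n_sub, n_sub) correlations; diagonal = E/I
    hex_diameter_um: float
    assignment: np.ndarray     # per-neuron subvolume index


def meso_graph(recording: SpikeRecording, xy_um: np.ndarray,
               edge_pre: np.ndarray, edge_post: np.ndarray,
               edge_nsyn: np.ndarray, hex_diameter_um: float,
               bin_ms: float = 5.0, t_start: float = 0.0) -> MesoGraph:
    """Meso-scale synapse-count and correlation matrices over hex subvolumes.

    S counts synapses between subvolume assignments of the edge endpoints.
    F holds Pearson correlations of pooled 5 ms spike-count series between
    subvolumes; the diagonal uses the separate E and I series within each
    subvolume.
    """
    assignment, centers = hex_bin(xy_um, hex_diameter_um)
    n_sub = len(centers)

    S = np.zeros((n_sub, n_sub), dtype=np.int64)
    np.add.at(S, (assignment[edge_pre], assignment[edge_post]),
              np.asarray(edge_nsyn, dtype=np.int64))

    edges = np.arange(t_start, recording.duration + bin_ms * 0.5, bin_ms)
    n_bins = len(edges) - 1
    series = np.zeros((n_sub, n_bins))
    sub_of_spike = assignment[recording.neuron_ids]
    bin_of_spike = np.clip(((recording.times_ms - t_start) / bin_ms).astype(int),
                           0, n_bins - 1)
    in_win = recording.times_ms >= t_start
    np.add.at(series, (sub_of_spike[in_win], bin_of_spike[in_win]), 1.0)

    is_e_pop = np.array([lab.endswith("_E") for lab in recording.pop_labels])
    is_e = is_e_pop[recording.pop_index[recording.neuron_ids]]
    series_e = np.zeros((n_sub, n_bins))
    series_i = np.zeros((n_sub, n_bins))
    np.add.at(series_e, (sub_of_spike[in_win & is_e], bin_of_spike[in_win & is_e]), 1.0)
    ii = in_win & ~is_e
    np.add.at(series_i, (sub_of_spike[ii], bin_of_spike[ii]), 1.0)

    F = np.eye(n_sub)
    with np.errstate(invalid="ignore", divide="ignore"):
        std = series.std(axis=1)
        centered = series - series.mean(axis=1, keepdims=True)
        cov = centered @ centered.T / n_bins
        denom = np.outer(std, std)
        off = np.where(denom > 0, cov / denom, np.nan)
    F[:] = off
    for s in range(n_sub):
        e, i = series_e[s], series_i[s]
        if e.std() > 0 and i.std() > 0:
            F[s, s] = float(np.corrcoef(e, i)[0, 1])
        else:
            F[s, s] = np.nan
    return MesoGraph(centers_um=centers, S=S, F=F,
                     hex_diameter_um=hex_diameter_um, assignment=assignment)


def input_correlation_estimate(meso: MesoGraph, target: int
                               ) -> tuple[np.ndarray, np.ndarray, float]:
    """Distribution of mid-range input correlations into one subvolume.

    The column S_i of input counts defines pair weights P = S_i S_i^T; the
    correlation of a source pair (j, k) is F[j, k] (F[j, j], the internal E/I
    correlation, for j = k). Returns (correlation values, weights, weighted
    mean)."""
    s_i = meso.S[:, target].astype(float)
    P = np.outer(s_i, s_i)
    vals = meso.F.flatten()
    w = P.flatten()
    ok = np.isfinite(vals) & (w > 0)
    vals, w = vals[ok], w[ok]
    if w.sum() == 0:
        raise ValueError("target subvolume has no inputs")
    return vals, w, float(np.average(vals, weights=w))


@dataclass
class RichClubResult:
    members: np.ndarray          # subvolume ids with >= 1 suprathreshold edge
    components: list[set]        # connected components (undirected) of members
    adjacent_to_member: np.ndarray  # hex-adjacency flags per subvolume


def rich_club(meso: MesoGraph, threshold_synapses: float,
              directed: bool = False) -> RichClubResult:
    """Threshold the meso synapse-count graph and report its components.

    Components are taken in the undirected sense by default. A subvolume is
    'adjacent to a member' if its hex center lies one tiling pitch away from
    a member's center."""
    import networkx as nx
    S = meso.S.copy().astype(float)
    np.fill_diagonal(S, 0.0)
    mask = S >= threshold_synapses
    g = nx.DiGraph() if directed else nx.Graph()
    g.add_nodes_from(range(len(S)))
    for a, b in zip(*np.nonzero(mask)):
        g.add_edge(int(a), int(b))
    members = np.array(sorted({n for n in g.nodes if g.degree(n) > 0}),
                       dtype=np.int64)
    sub = g.subgraph(members)
    comp_iter = nx.weakly_connected_components(sub) if directed \
        else nx.connected_components(sub)
    components = [set(c) for c in comp_iter]

    pitch = meso.hex_diameter_um
    adj = np.zeros(len(S), dtype=bool)
    if len(members):
        d = np.linalg.norm(meso.centers_um[:, None, :]
                           - meso.centers_um[None, members, :], axis=2)
        adj = np.any(np.abs(d - pitch) < 1e-6 * max(pitch, 1.0), axis=1)
    return RichClubResult(members=members, components=components,
                          adjacent_to_member=adj)


def correlation_vs_distance(meso: MesoGraph, n_bins: int | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Mean pairwise correlation per center-distance bin.

    With ``n_bins=None`` every distinct (rounded) pairwise distance forms its
    own bin, so the adjacent-hexagon distance appears exactly at the tiling
    pitch."""
    n = len(meso.centers_um)
    iu = np.triu_indices(n, k=1)
    d = np.linalg.norm(meso.centers_um[iu[0]] - meso.centers_um[iu[1]], axis=1)
    r = meso.F[iu]
    ok = np.isfinite(r)
    d, r = d[ok], r[ok]
    if n_bins is None:
        dr = np.round(d, 6)
        uniq = np.unique(dr)
        means = np.array([r[dr == u].mean() for u in uniq])
        return uniq, means
    edges = np.linspace(d.min(), d.max(), n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    means = np.array([r[idx == b].mean() if np.any(idx == b) else np.nan
                      for b in range(n_bins)])
    return centers, means


def missing_synapses(dendritic_length_um: float, existing_count: int,
                     density_per_um: float = 1.1) -> tuple[int, bool]:
    """Estimated missing excitatory synapses on a neuron.

    max(0, round(density * length) - existing); the flag marks the floored
    case where the model already holds more synapses than the estimate."""
    if dendritic_length_um < 0 or existing_count < 0 or density_per_um < 0:
        raise ValueError("inputs must be non-negative")
    total = int(round(density_per_um * dendritic_length_um))
    missing = total - existing_count
    return (missing, False) if missing >= 0 else (0, True)


def midrange_local_ratio(midrange_synapses: float, local_synapses: float
                         ) -> float:
    """Mid-range synapse count as a percentage of the local count (the mean
    relative increase in intrinsic synapses per neuron when mid-range
    connectivity is added)."""
    if local_synapses <= 0:
        raise ValueError("local synapse count must be > 0")
    return 100.0 * midrange_synapses / local_synapses
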