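"""Dyadic behavioral state discretization and transition-graph estimation.

Each fish occupies one of 8 states (2 flaring levels x 4 orientation
categories); a dyad occupies one of 64 combinatorial states.  Transition
probabilities are estimated over state-change events (the embedded jump
chain, self-transitions excluded); occupancy is the per-state fraction of
frames.  Graphs can be filtered by occupancy and edge probability and laid
out in 2-D using the leading nontrivial eigenvectors of the symmetrized
transition structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

ORIENTATION_CATEGORIES = ("facing", "turning", "lateral", "turning_away")
ORIENTATION_BOUNDS_DEG = (45.0, 90.0, 135.0)
N_PER_FISH_STATES = 8
N_DYAD_STATES = 64


def categorize_orientation(orientation_deg: np.ndarray,
                           angular_velocity: np.ndarray | None = None,
                           dynamic: bool = False,
                           turning_speed_thresh: float = 30.0) -> np.ndarray:
    """Map orientation angles (deg, [0, 180]) to the 4 categories.

    Static rule (default): facing < 45, turning 45-90, lateral 90-135,
    turning-away >= 135.  The dynamic rule reassigns the middle bands using
    angular speed: within 45-135, fast motion away from the stimulus
    (orientation increasing above ``turning_speed_thresh`` deg/s) is
    'turning_away', fast motion toward is 'turning'.
    """
    deg = np.asarray(orientation_deg, dtype=float)
    cat = np.digitize(deg, ORIENTATION_BOUNDS_DEG).astype(np.int8)
    if dynamic:
        if angular_velocity is None:
            raise ValueError("dynamic rule requires angular_velocity (deg/s)")
        vel = np.asarray(angular_velocity, dtype=float)
        mid = (deg >= 45.0) & (deg < 135.0)
        cat = cat.copy()
        cat[mid & (vel > turning_speed_thresh)] = 3    # carried past lateral, away
        cat[mid & (vel < -turning_speed_thresh)] = 1   # turning toward
    return cat


def discretize(flare: np.ndarray, orientation_deg: np.ndarray,
               angular_velocity: np.ndarray | None = None,
               dynamic: bool = False) -> np.ndarray:
    """Per-frame 8-state ids: 4 * flaring + orientation category."""
    flare = (np.asarray(flare) != 0).astype(np.int8)
    orientation_deg = np.asarray(orientation_deg, dtype=float)
    if flare.shape != orientation_deg.shape:
        raise ValueError("flare and orientation must have equal length")
    cat = categorize_orientation(orientation_deg, angular_velocity, dynamic)
    return (4 * flare + cat).astype(np.int8)


def dyad_states(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Combinatorial dyad state ids: 8 * focal + opponent, in 0..63."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("state sequences must have equal length")
    if a.size and ((a < 0).any() or (a >= 8).any() or (b < 0).any() or (b >= 8).any()):
        raise ValueError("per-fish state ids must lie in 0..7")
    return (8 * a + b).astype(np.int8)


@dataclass
class TransitionGraph:
    counts: np.ndarray            # (n, n) change-event counts
    probabilities: np.ndarray     # row-stochastic where a row has counts
    occupancy: np.ndarray         # per-state frame fraction, sums to 1
    dwell_frames: dict            # state -> array of complete dwell lengths
    n_states: int
    frame_rate: float | None = None
    retained_nodes: np.ndarray | None = None
    edges: list = field(default_factory=list)    # (src, dst, p) after filtering

    @property
    def nodes(self) -> np.ndarray:
        if self.retained_nodes is not None:
            return self.retained_nodes
        return np.flatnonzero(self.occupancy > 0)


def transition_matrix(sequences, n_states: int = N_DYAD_STATES,
                      frame_rate: float | None = None,
                      frame_level: bool = False) -> TransitionGraph:
    """Estimate occupancy and directional transition probabilities.

    Counts are pooled across sequences, never across a sequence boundary.
    By default transitions are counted at state-change events only (the
    embedded jump chain); ``frame_level=True`` counts every frame pair
    including self-transitions.  Dwell samples exclude runs truncated by
    a record boundary.
    """
    if isinstance(sequences, np.ndarray) and sequences.ndim == 1:
        sequences = [sequences]
    sequences = [np.asarray(s, dtype=int) for s in sequences]
    if not sequences:
        raise ValueError("need at least one sequence")

    counts = np.zeros((n_states, n_states), dtype=float)
    occ = np.zeros(n_states, dtype=float)
    dwell = {s: [] for s in range(n_states)}
    total_frames = 0
    for seq in sequences:
        if seq.size == 0:
            continue
        if (seq < 0).any() or (seq >= n_states).any():
            raise ValueError(f"state ids must lie in 0..{n_states - 1}")
        occ += np.bincount(seq, minlength=n_states)
        total_frames += seq.size
        if seq.size < 2:
            continue
        src, dst = seq[:-1], seq[1:]
        if frame_level:
            np.add.at(counts, (src, dst), 1.0)
        else:
            chg = src != dst
            np.add.at(counts, (src[chg], dst[chg]), 1.0)
        # complete (non-censored) dwells: runs not touching either boundary
        change_at = np.flatnonzero(np.diff(seq) != 0)
        if change_at.size >= 2:
            run_lens = np.diff(change_at)
            run_states = seq[change_at[:-1] + 1]
            for st, ln in zip(run_states, run_lens):
                dwell[int(st)].append(int(ln))

    if total_frames == 0:
        raise ValueError("all sequences are empty")
    occupancy = occ / total_frames
    rowsum = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(rowsum > 0, counts / np.maximum(rowsum, 1e-300), 0.0)
    dwell = {s: np.asarray(v, dtype=int) for s, v in dwell.items() if v}
    return TransitionGraph(counts=counts, probabilities=P, occupancy=occupancy,
                           dwell_frames=dwell, n_states=n_states,
                           frame_rate=frame_rate)


def filter_graph(g: TransitionGraph, occ_min: float = 0.02,
                 p_min: float = 0.0025,
                 companion: TransitionGraph | None = None) -> TransitionGraph:
    """Remove rare states and weak edges.

    Nodes with occupancy below ``occ_min`` are removed.  An edge between
    retained nodes is removed only when its probability is below ``p_min``
    in this graph AND in the companion graph (when provided); without a
    companion the single-graph rule applies.
    """
    keep = np.flatnonzero(g.occupancy >= occ_min)
    keepset = set(keep.tolist())
    edges = []
    for i in keep:
        for j in np.flatnonzero(g.probabilities[i] > 0):
            if j not in keepset or i == j:
                continue
            p = g.probabilities[i, j]
            weak_here = p < p_min
            weak_other = (companion is None
                          or companion.probabilities[i, j] < p_min)
            if weak_here and weak_other:
                continue
            edges.append((int(i), int(j), float(p)))
    return TransitionGraph(counts=g.counts, probabilities=g.probabilities,
                           occupancy=g.occupancy, dwell_frames=g.dwell_frames,
                           n_states=g.n_states, frame_rate=g.frame_rate,
                           retained_nodes=keep, edges=edges)


def _fix_sign(v: np.ndarray) -> np.ndarray:
    nz = np.flatnonzero(np.abs(v) > 1e-12)
    if nz.size and v[nz[0]] < 0:
        return -v
    return v


def spectral_layout(g: TransitionGraph) -> dict:
    """2-D coordinates from the two leading nontrivial eigenvectors.

    The (filtered, if available) transition structure is row-normalized,
    symmetrized as (P + P^T)/2 and eigendecomposed per connected component;
    coordinates are the eigenvectors of the 2nd and 3rd largest eigenvalues
    (sign fixed so the first nonzero entry is positive).  Disconnected
    components are laid out independently and offset along x.
    """
    nodes = g.nodes
    if nodes.size < 2:
        raise ValueError("need at least 2 retained nodes for a layout")
    index = {int(s): k for k, s in enumerate(nodes)}
    n = nodes.size
    W = np.zeros((n, n))
    if g.edges:
        for i, j, p in g.edges:
            W[index[i], index[j]] = p
    else:
        sub = g.probabilities[np.ix_(nodes, nodes)].copy()
        np.fill_diagonal(sub, 0.0)
        W = sub
    rowsum = W.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Wn = np.where(rowsum > 0, W / np.maximum(rowsum, 1e-300), 0.0)
    M = (Wn + Wn.T) / 2.0

    graph = nx.from_numpy_array((M > 0).astype(int))
    graph.add_nodes_from(range(n))
    coords = np.zeros((n, 2))
    x_offset = 0.0
    for comp in sorted(nx.connected_components(graph), key=min):
        ids = np.array(sorted(comp))
        sub = M[np.ix_(ids, ids)]
        if ids.size == 1:
            coords[ids[0]] = (x_offset, 0.0)
            x_offset += 1.0
            continue
        w, v = np.linalg.eigh(sub)
        order = np.argsort(w)[::-1]
        x = _fix_sign(v[:, order[1]])
        y = _fix_sign(v[:, order[2]]) if ids.size > 2 else np.zeros(ids.size)
        coords[ids, 0] = x + x_offset
        coords[ids, 1] = y
        x_offset += float(x.max() - x.min()) + 1.0
    return {int(s): (float(coords[k, 0]), float(coords[k, 1]))
            for s, k in index.items()}


@dataclass
class DwellCheck:
    state: int
    n: int
    mean_s: float
    ks_statistic: float
    p_value: float


def dwell_distribution_check(g: TransitionGraph, frame_rate: float | None = None,
                             min_samples: int = 20) -> dict:
    """Kolmogorov-Smirnov test of per-state dwell times against an
    exponential with the state's empirical mean.

    Returns {"checked": [DwellCheck, ...], "skipped": [(state, n), ...]}.
    """
    fps = frame_rate or g.frame_rate or 1.0
    checked, skipped = [], []
    for state, frames in sorted(g.dwell_frames.items()):
        if frames.size < min_samples:
            skipped.append((state, int(frames.size)))
            continue
        d = frames / fps
        mean = float(d.mean())
        res = stats.kstest(d, "expon", args=(0, mean))
        checked.append(DwellCheck(state=state, n=int(d.size), mean_s=mean,
                                  ks_statistic=float(res.statistic),
                                  p_value=float(res.pvalue)))
    return {"checked": checked, "skipped": skipped}
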