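"""Distance-dependent consensus-based weighted group-representative.

From a cohort of subject networks over one shared node set, a single
representative network is built in three stages:

1. every edge observed in any subject is assigned to one of 22 (by default)
   length bins using the cohort-average length of that connection;
2. within each bin — separately for intra- and inter-hemispheric edges, so
   long inter-hemispheric links are not crowded out — the retained edge
   count is the rounded average number of subject-level edges in that bin,
   and the retained edges are the most frequently occurring ones (ties go to
   the higher average weight, then the canonical edge index);
3. each retained edge gets a weight drawn at random from the subject-level
   weights observed for that connection — never an average, which would
   distort the weight distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Cohort, WeightedNetwork

__all__ = ["DistanceBins", "build_distance_bins", "consensus_select", "assign_group_weights",
           "group_representative"]


@dataclass
class DistanceBins:
    """Union-edge catalogue with per-edge length bin and consensus statistics.

    Arrays are aligned: row e describes undirected union edge (i[e], j[e]).
    """

    i: np.ndarray
    j: np.ndarray
    bin_id: np.ndarray
    length: np.ndarray          # cohort-average length proxy
    occurrence: np.ndarray      # number of subjects containing the edge
    mean_weight: np.ndarray     # mean weight over subjects containing it
    inter_hemi: np.ndarray      # bool: endpoints in different hemispheres
    edges_per_subject: list[np.ndarray]  # per subject, union-edge row indices
    bin_edges: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1


def _union_catalogue(cohort: Cohort):
    n = len(cohort.nodes)
    key_to_row: dict[int, int] = {}
    ii: list[int] = []
    jj: list[int] = []
    occurrence: list[int] = []
    wsum: list[float] = []
    weight_lists: list[list[float]] = []
    subject_rows: list[np.ndarray] = []
    for net in cohort.subjects:
        rows = np.empty(net.n_edges, dtype=np.int64)
        for e, ((a, b), w) in enumerate(zip(net.edges, net.weights)):
            key = int(a) * n + int(b)
            row = key_to_row.get(key)
            if row is None:
                row = len(ii)
                key_to_row[key] = row
                ii.append(int(a))
                jj.append(int(b))
                occurrence.append(0)
                wsum.append(0.0)
                weight_lists.append([])
            occurrence[row] += 1
            wsum[row] += float(w)
            weight_lists[row].append(float(w))
            rows[e] = row
        subject_rows.append(rows)
    i = np.array(ii, dtype=np.int64)
    j = np.array(jj, dtype=np.int64)
    occ = np.array(occurrence, dtype=np.int64)
    mean_w = np.array(wsum) / occ
    return i, j, occ, mean_w, weight_lists, subject_rows


def build_distance_bins(
    cohort: Cohort, n_bins: int = 22, mode: str = "equal_width"
) -> DistanceBins:
    """Catalogue the union of subject edges and bin them by cohort-average length.

    ``mode`` is "equal_width" (default) or "equal_occupancy" (quantile edges).
    With a single subject-observed length the catalogue degenerates to one
    occupied bin.  Lengths come from the shared node positions, so they are
    identical across subjects by construction.
    """
    i, j, occ, mean_w, _, subject_rows = _union_catalogue(cohort)
    if len(i) == 0:
        raise ValueError("cohort has no edges")
    length = cohort.edge_length(i, j)
    if np.any(~np.isfinite(length)) or np.any(length <= 0):
        bad = np.flatnonzero(~np.isfinite(length) | (length <= 0))
        raise ValueError(f"missing/invalid length proxies for union edges {bad[:10].tolist()}")
    lo, hi = float(length.min()), float(length.max())
    if mode == "equal_width":
        edges = np.linspace(lo, hi, n_bins + 1)
    elif mode == "equal_occupancy":
        edges = np.quantile(length, np.linspace(0.0, 1.0, n_bins + 1))
    else:
        raise ValueError(f"unknown binning mode {mode!r}")
    edges[-1] = np.nextafter(max(edges[-1], hi), np.inf)
    bin_id = np.clip(np.searchsorted(edges, length, side="right") - 1, 0, n_bins - 1)
    hemi = cohort.nodes.hemisphere
    if hemi is None:
        raise ValueError("consensus selection needs hemisphere labels")
    inter_hemi = hemi[i] != hemi[j]
    return DistanceBins(
        i=i, j=j, bin_id=bin_id, length=length, occurrence=occ, mean_weight=mean_w,
        inter_hemi=inter_hemi, edges_per_subject=subject_rows, bin_edges=edges,
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def consensus_select(cohort: Cohort, bins: DistanceBins) -> tuple[np.ndarray, dict]:
    """Distance-dependent consensus edge selection.

    For each (bin, hemisphere-class) cell, keep round(mean subject edge
    count) edges ranked by occurrence, then mean weight, then canonical
    index.  Returns the selected union-edge row indices and a provenance
    dict of per-cell retained counts.
    """
    n_subj = cohort.n_subjects
    # per-subject edge count per (bin, class)
    counts = np.zeros((bins.n_bins, 2, n_subj))
    for s, rows in enumerate(bins.edges_per_subject):
        b = bins.bin_id[rows]
        c = bins.inter_hemi[rows].astype(int)
        np.add.at(counts[:, :, s], (b, c), 1)
    mean_counts = counts.mean(axis=2)

    selected: list[np.ndarray] = []
    provenance: dict[str, dict] = {}
    for b in range(bins.n_bins):
        for cls, cls_name in ((0, "intra"), (1, "inter")):
            cand = np.flatnonzero((bins.bin_id == b) & (bins.inter_hemi == bool(cls)))
            target = _round_half_up(float(mean_counts[b, cls]))
            if len(cand) == 0:
                continue  # empty cell: nothing to keep
            target = min(target, len(cand))
            order = np.lexsort((cand, -bins.mean_weight[cand], -bins.occurrence[cand]))
            keep = cand[order[:target]]
            selected.append(keep)
            provenance[f"bin{b}_{cls_name}"] = {
                "mean_subject_count": float(mean_counts[b, cls]),
                "retained": int(target),
                "candidates": int(len(cand)),
            }
    rows = np.sort(np.concatenate(selected)) if selected else np.zeros(0, np.int64)
    return rows, provenance


def assign_group_weights(
    selected_rows: np.ndarray, cohort: Cohort, bins: DistanceBins, seed: int = 0
) -> WeightedNetwork:
    """Give each selected edge a weight sampled from its subject-level weight
    multiset (deterministic per seed)."""
    _, _, _, _, weight_lists, _ = _union_catalogue(cohort)
    rng = np.random.default_rng(seed)
    w = np.empty(len(selected_rows))
    for out_idx, row in enumerate(selected_rows):
        choices = weight_lists[row]
        w[out_idx] = choices[int(rng.integers(0, len(choices)))]
    edges = np.column_stack([bins.i[selected_rows], bins.j[selected_rows]])
    return WeightedNetwork(len(cohort.nodes), edges, w)


def group_representative(
    cohort: Cohort, n_bins: int = 22, seed: int = 0, mode: str = "equal_width"
) -> tuple[WeightedNetwork, dict]:
    """Full pipeline: bins → consensus selection → subject-sampled weights."""
    bins = build_distance_bins(cohort, n_bins=n_bins, mode=mode)
    rows, provenance = consensus_select(cohort, bins)
    net = assign_group_weights(rows, cohort, bins, seed=seed)
    return net, provenance
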