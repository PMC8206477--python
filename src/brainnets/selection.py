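"""Automatic triage of ICA components into networks vs noise.

Components are clustered hierarchically (average linkage on 1 - r over
their group time courses), the tree is cut into its two top-level branches,
and the branch whose members concentrate more spectral power in the
0.01-0.1 Hz resting-state band is labeled "good".  Good components are then
matched to named reference networks by spatial correlation (greedy, one
reference per component, rejecting weak matches), and the survivors are
reordered into the canonical network order used as the classifier's channel
order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import welch
from scipy.spatial.distance import squareform

from .group_ica import ComponentSet
from .io_core import DegenerateInputError, DimensionError, InputError
from .synthetic import NETWORK_NAMES

__all__ = [
    "SelectionReport", "cluster_components", "lowfreq_fraction",
    "template_match", "select_components", "linkage_to_newick",
]

BAND_HZ = (0.01, 0.1)
DEFAULT_R_MIN = 0.25


@dataclass
class SelectionReport:
    """Everything the triage decided, in one inspectable record."""

    linkage_matrix: np.ndarray
    cluster_labels: list[str]                 # per component: good | artifact
    lowfreq_fractions: np.ndarray             # per component, in [0, 1]
    match_table: pd.DataFrame                 # component, reference, spatial_r, assigned
    selected: list[int]                       # component indices, canonical order
    selected_names: list[str]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.match_table.to_csv(out / "match_table.csv", index=False)
        (out / "selection.yaml").write_text(yaml.safe_dump({
            "cluster_labels": self.cluster_labels,
            "lowfreq_fractions": [float(v) for v in self.lowfreq_fractions],
            "selected": [int(i) for i in self.selected],
            "selected_names": self.selected_names,
        }))
        (out / "dendrogram.nwk").write_text(
            linkage_to_newick(self.linkage_matrix,
                              [f"IC{i}" for i in range(len(self.cluster_labels))]))


# ---------------------------------------------------------------------------
# Spectral criterion
# ---------------------------------------------------------------------------

def lowfreq_fraction(tc: np.ndarray, tr_seconds: float,
                     band: tuple[float, float] = BAND_HZ) -> float:
    """Fraction of Welch-spectrum power inside the resting-state band.

    Power at exactly 0 Hz is excluded from the total; the denominator runs
    over (0, Nyquist].
    """
    tc = np.asarray(tc, dtype=float).ravel()
    if tc.size < 64:
        raise InputError("time course too short for a stable spectrum (need >= 64)")
    if np.std(tc) == 0:
        raise DegenerateInputError("constant time course has no spectrum")
    fs = 1.0 / tr_seconds
    nperseg = min(tc.size, 256)
    freqs, pxx = welch(tc, fs=fs, nperseg=nperseg)
    keep = freqs > 0
    total = pxx[keep].sum()
    in_band = pxx[keep & (freqs >= band[0]) & (freqs <= band[1])].sum()
    return float(in_band / total)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_components(cset: ComponentSet, tr_seconds: float,
                       distance: str = "timecourse",
                       band: tuple[float, float] = BAND_HZ,
                       good_fraction_cut: float = 0.6,
                       ) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Hierarchical clustering of components into a good and an artifact branch.

    Distance is 1 - r over component time courses (or spatial maps with
    ``distance='spatial'``), average linkage.  The tree is cut into its two
    top-level branches and each branch is labeled by its mean low-frequency
    fraction: a branch concentrating at least ``good_fraction_cut`` of its
    members' power in the resting-state band is "good" (band-limited network
    time courses sit near 1, broadband artifacts near the flat-spectrum
    value ~0.36 at TR = 2 s).  If neither branch clears the cut, the
    higher-fraction branch is kept as "good" so the triage never discards
    everything.

    Returns (linkage matrix, per-component labels, low-frequency fractions).
    """
    K = cset.K
    if K < 2:
        raise InputError("need at least 2 components to cluster")
    if distance == "timecourse":
        feats = cset.group_tcs.T
    elif distance == "spatial":
        feats = cset.maps
    else:
        raise InputError(f"unknown distance {distance!r}")
    r = np.corrcoef(feats)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    branch = fcluster(Z, t=2, criterion="maxclust")

    frac = np.array([lowfreq_fraction(cset.group_tcs[:, k], tr_seconds, band)
                     for k in range(K)])
    means = {b: frac[branch == b].mean() for b in np.unique(branch)}
    good_branches = {b for b, m in means.items() if m >= good_fraction_cut}
    if not good_branches:
        good_branches = {max(means, key=means.get)}
    labels = ["good" if b in good_branches else "artifact" for b in branch]
    return Z, labels, frac


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    n = len(leaf_names)

    def build(node: int) -> str:
        if node < n:
            return leaf_names[node]
        i, j, dist, _ = Z[node - n]
        return f"({build(int(i))},{build(int(j))}):{dist:.6g}"

    return build(2 * n - 2) + ";" if n > 1 else leaf_names[0] + ";"


# ---------------------------------------------------------------------------
# Template matching
# ---------------------------------------------------------------------------

def _pearson_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """(len(A), len(B)) Pearson correlations between rows of A and B."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    A = A / np.linalg.norm(A, axis=1, keepdims=True)
    B = B / np.linalg.norm(B, axis=1, keepdims=True)
    return A @ B.T


def template_match(cset: ComponentSet, references: dict[str, np.ndarray],
                   good: list[int] | None = None,
                   r_min: float = DEFAULT_R_MIN,
                   canonical_order: list[str] | None = None,
                   ) -> tuple[pd.DataFrame, list[int], list[str]]:
    """Match good components to named reference maps by spatial correlation.

    Greedy assignment in descending |r|; each reference claims at most one
    component and pairs below ``r_min`` are rejected.  The selected
    components are returned in canonical network order (the classifier's
    channel order).
    """
    ref_names = list(references)
    ref_mat = np.stack([np.asarray(references[n], dtype=float).ravel()
                        for n in ref_names])
    if ref_mat.shape[1] != cset.n_voxels:
        raise DimensionError(
            f"reference grid ({ref_mat.shape[1]} voxels) does not match "
            f"components ({cset.n_voxels} voxels)")
    comp_idx = list(range(cset.K)) if good is None else list(good)
    comp_maps = cset.maps[comp_idx]
    r = _pearson_rows(comp_maps, ref_mat)

    rows = [{"component": comp_idx[i], "reference": ref_names[j],
             "spatial_r": float(r[i, j]), "assigned": False}
            for i in range(len(comp_idx)) for j in range(len(ref_names))]
    table = pd.DataFrame(rows).sort_values("spatial_r", ascending=False,
                                           kind="mergesort").reset_index(drop=True)
    taken_comp: set[int] = set()
    taken_ref: set[str] = set()
    assignment: dict[str, int] = {}
    for idx, row in table.iterrows():
        if row.spatial_r < r_min:
            break
        if row.component in taken_comp or row.reference in taken_ref:
            continue
        table.at[idx, "assigned"] = True
        taken_comp.add(int(row.component))
        taken_ref.add(str(row.reference))
        assignment[str(row.reference)] = int(row.component)

    order = canonical_order or [n for n in NETWORK_NAMES if n in ref_names]
    order = order + [n for n in ref_names if n not in order]
    selected = [assignment[n] for n in order if n in assignment]
    names = [n for n in order if n in assignment]
    return table, selected, names


# ---------------------------------------------------------------------------
# One-call triage
# ---------------------------------------------------------------------------

def select_components(cset: ComponentSet, tr_seconds: float,
                      references: dict[str, np.ndarray],
                      r_min: float = DEFAULT_R_MIN,
                      distance: str = "timecourse") -> SelectionReport:
    """Cluster, label, and template-match in one pass."""
    Z, labels, frac = cluster_components(cset, tr_seconds, distance=distance)
    good = [k for k, lab in enumerate(labels) if lab == "good"]
    table, selected, names = template_match(cset, references, good=good,
                                            r_min=r_min)
    cset.labels = labels
    return SelectionReport(linkage_matrix=Z, cluster_labels=labels,
                           lowfreq_fractions=frac, match_table=table,
                           selected=selected, selected_names=names)
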