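"""Inter-network connectivity statistics.

Per subject, the K selected network time courses give a K x K ridge-
regularized partial-correlation matrix (negated, normalized inverse of the
shrunk correlation matrix — the direct-connection estimator).  Off-diagonal
entries are Fisher z-transformed and the two groups are compared edgewise
with an unpaired permutation test on the group mean difference; the same
label permutation is applied to every edge so cross-edge dependence is
preserved.  Edges at p <= alpha are reported with their difference sign
(hyper- vs hypo-connectivity) and per-group box-plot summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import InputError, NumericError, ParameterError

__all__ = [
    "NetMat", "EdgeComparison", "partial_corr_ridge", "fisher_z",
    "permutation_group_test", "select_edges", "edge_group_summaries",
]


@dataclass
class NetMat:
    """K x K partial-correlation matrix; zero diagonal by convention."""

    pc: np.ndarray
    rho: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not np.allclose(self.pc, self.pc.T, atol=1e-10):
            raise NumericError("partial-correlation matrix is not symmetric")

    @property
    def K(self) -> int:
        return self.pc.shape[0]


@dataclass
class EdgeComparison:
    """Edgewise group comparison over the upper triangle."""

    edges: list[tuple[int, int]]
    observed: np.ndarray        # mean(case z) - mean(control z) per edge
    p_values: np.ndarray
    n_perm: int
    alpha: float
    p_bonferroni: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.p_bonferroni = np.minimum(self.p_values * len(self.edges), 1.0)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "i": [e[0] for e in self.edges],
            "j": [e[1] for e in self.edges],
            "observed_diff": self.observed,
            "p_value": self.p_values,
            "p_bonferroni": self.p_bonferroni,
            "selected": self.p_values <= self.alpha,
            "direction": np.where(self.observed > 0, "case > control",
                                  "case < control"),
        })


# ---------------------------------------------------------------------------
# Partial correlation
# ---------------------------------------------------------------------------

def partial_corr_ridge(tcs: np.ndarray, rho: float = 0.1,
                       subject_id: str = "") -> NetMat:
    """Ridge partial correlation of K time courses.

    Columns are standardized; the precision matrix is the inverse of
    (correlation + rho * I); pc(i, j) = -prec(i, j) / sqrt(prec_ii prec_jj)
    off the diagonal, 0 on it.
    """
    tcs = np.asarray(tcs, dtype=float)
    T, K = tcs.shape
    if T <= K:
        raise InputError(f"need T > K, got T = {T}, K = {K}")
    if rho < 0:
        raise ParameterError("rho must be >= 0")
    sd = tcs.std(axis=0)
    if np.any(sd == 0):
        raise InputError("constant time-course column")
    X = (tcs - tcs.mean(axis=0)) / sd
    R = (X.T @ X) / T
    A = R + rho * np.eye(K)
    try:
        cond = np.linalg.cond(A)
        if cond > 1e12:
            raise np.linalg.LinAlgError(f"condition number {cond:.2e}")
        prec = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise NumericError(
            f"correlation matrix is singular at rho = {rho}; "
            "use rho > 0 to regularize") from exc
    d = np.sqrt(np.diag(prec))
    pc = -prec / np.outer(d, d)
    pc = (pc + pc.T) / 2.0
    np.fill_diagonal(pc, 0.0)
    return NetMat(pc=pc, rho=rho, subject_id=subject_id)


def fisher_z(netmat: NetMat) -> np.ndarray:
    """Elementwise atanh of the off-diagonal entries; diagonal stays 0."""
    pc = netmat.pc
    off = ~np.eye(netmat.K, dtype=bool)
    if np.any(np.abs(pc[off]) >= 1.0):
        raise NumericError("|partial correlation| = 1; Fisher transform overflows")
    z = np.zeros_like(pc)
    z[off] = np.arctanh(pc[off])
    return z


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def _upper_edges(K: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(K) for j in range(i + 1, K)]


def permutation_group_test(znetmats: list[np.ndarray], labels: np.ndarray,
                           n_perm: int = 5000, seed: int = 0,
                           alpha: float = 0.05) -> EdgeComparison:
    """Unpaired two-tailed permutation test on every edge.

    Statistic: mean(case z) - mean(control z).  The same random relabeling
    is applied to all edges at once; p = (1 + #{|T_perm| >= |T_obs|}) /
    (1 + n_perm), so p > 0 always and is exact under exchangeability.
    """
    labels = np.asarray(labels).astype(int)
    n_case = int((labels == 1).sum())
    n_ctrl = int((labels == 0).sum())
    if n_case < 2 or n_ctrl < 2:
        raise InputError("each group needs at least 2 subjects")
    K = znetmats[0].shape[0]
    edges = _upper_edges(K)
    iu = np.triu_indices(K, k=1)
    Z = np.stack([z[iu] for z in znetmats])          # (N, E)
    case_mask = labels == 1

    obs = Z[case_mask].mean(axis=0) - Z[~case_mask].mean(axis=0)
    rng = np.random.default_rng(seed)
    n = len(labels)
    abs_obs = np.abs(obs)
    # sample subsets of the smaller group's size: |T| does not depend on
    # which side is called "case", so p is invariant to relabeling; the
    # same relabeling applies to every edge, preserving cross-edge
    # dependence.  All permutations are evaluated as one matrix product.
    k = min(n_case, n_ctrl)
    total = Z.sum(axis=0)
    count = np.zeros(len(edges))
    chunk = 1000
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        order = rng.random((m, n)).argsort(axis=1)
        masks = np.zeros((m, n))
        np.put_along_axis(masks, order[:, :k], 1.0, axis=1)
        sums_a = masks @ Z                       # (m, E) group-A sums
        t_perm = sums_a / k - (total - sums_a) / (n - k)
        count += (np.abs(t_perm) >= abs_obs - 1e-15).sum(axis=0)
        done += m
    p = (1.0 + count) / (1.0 + n_perm)
    return EdgeComparison(edges=edges, observed=obs, p_values=p,
                          n_perm=n_perm, alpha=alpha)


def select_edges(comparison: EdgeComparison, alpha: float = 0.05,
                 ) -> pd.DataFrame:
    """Edges with p <= alpha, annotated with the group-difference sign."""
    frame = comparison.as_frame()
    frame["selected"] = frame["p_value"] <= alpha
    return frame[frame["selected"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Box-plot summaries
# ---------------------------------------------------------------------------

def _five_number(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return {
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "whisker_low": float(inside.min()), "whisker_high": float(inside.max()),
        "outliers": [float(v) for v in outliers],
    }


def edge_group_summaries(znetmats: list[np.ndarray], labels: np.ndarray,
                         edges: list[tuple[int, int]],
                         names: list[str] | None = None) -> pd.DataFrame:
    """Per-edge, per-group five-number summaries (1.5 IQR whisker rule)."""
    if not edges:
        raise InputError("no edges to summarize")
    labels = np.asarray(labels).astype(int)
    Z = np.stack(znetmats)
    rows = []
    for (i, j) in edges:
        for group, mask in (("case", labels == 1), ("control", labels == 0)):
            s = _five_number(Z[mask, i, j])
            label = (f"{names[i]}-{names[j]}" if names else f"{i}-{j}")
            rows.append({"edge": label, "i": i, "j": j, "group": group, **s})
    return pd.DataFrame(rows)


def save_boxplot(znetmats: list[np.ndarray], labels: np.ndarray,
                 edges: list[tuple[int, int]], path: str | Path,
                 names: list[str] | None = None) -> None:
    """Write the group box plots for the selected edges."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels).astype(int)
    Z = np.stack(znetmats)
    fig, axes = plt.subplots(1, max(len(edges), 1),
                             figsize=(3 * max(len(edges), 1), 4), squeeze=False)
    for ax, (i, j) in zip(axes[0], edges):
        data = [Z[labels == 1, i, j], Z[labels == 0, i, j]]
        ax.boxplot(data, tick_labels=["case", "control"])
        ax.set_title(f"{names[i]}-{names[j]}" if names else f"edge {i}-{j}")
        ax.set_ylabel("Fisher z partial correlation")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
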