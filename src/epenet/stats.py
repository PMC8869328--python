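"""Kruskal–Wallis group comparisons on connectivity and graph metrics.

The Kruskal–Wallis test — the nonparametric analogue of one-way ANOVA,
extending the Wilcoxon rank-sum test to more than two groups — is applied
per electrode and per frequency band.  The per-subject, per-electrode
summary for connectivity is the node's mean connectivity to the other
n-1 electrodes (node strength / (n-1)); this reduction is recorded in the
output metadata.  Significance thresholds (p < 0.05) are applied only at
reporting time, never inside the computation, and no multiple-testing
correction is applied by default (a Benjamini–Hochberg column is optional).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from epenet.connectivity import AdjacencyMatrix

__all__ = [
    "GroupTestResult",
    "kruskal_wallis",
    "per_electrode_tests",
    "clustering_group_test",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class GroupTestResult:
    """One Kruskal–Wallis comparison across groups."""

    electrode: str  # electrode label, or "global" for whole-network tests
    band: str
    measure: str
    h: float
    p: float
    n_per_group: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "electrode": self.electrode,
            "band": self.band,
            "measure": self.measure,
            "H": self.h,
            "p": self.p,
            **{f"n_{g}": n for g, n in self.n_per_group.items()},
        }


def kruskal_wallis(samples: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-squared p-value.

    Degenerate case: if every pooled value is identical the test carries no
    information and (H, p) = (0, 1) is returned.
    """
    if len(samples) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    arrays = [np.asarray(s, dtype=float).ravel() for s in samples]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must contain at least one value")
    total = sum(a.size for a in arrays)
    if total < 5:
        raise ValueError(f"total sample size {total} < 5; chi-squared approximation invalid")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def per_electrode_tests(
    matrices_by_group: dict[str, list[AdjacencyMatrix]],
    band: str,
    measure: str,
) -> list[GroupTestResult]:
    """Kruskal–Wallis per electrode on per-subject mean node connectivity.

    For each subject the per-electrode summary is the mean of that
    electrode's connectivity to the other n-1 electrodes.
    """
    groups = list(matrices_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    per_group = {}
    labels = None
    for g, mats in matrices_by_group.items():
        sel = [m for m in mats if m.band.name == band and m.measure == measure]
        if not sel:
            raise ValueError(f"group {g}: no {measure} matrices for band {band!r}")
        if labels is None:
            labels = sel[0].channel_labels
        n = len(labels)
        # subjects x electrodes: node strength / (n - 1)
        per_group[g] = np.array([m.values.sum(axis=1) / (n - 1) for m in sel])

    results = []
    n_per_group = {g: per_group[g].shape[0] for g in groups}
    for e, lab in enumerate(labels):
        h, p = kruskal_wallis([per_group[g][:, e] for g in groups])
        results.append(
            GroupTestResult(
                electrode=lab, band=band, measure=measure, h=h, p=p, n_per_group=n_per_group
            )
        )
    return results


def clustering_group_test(
    tables_by_group: dict[str, pd.DataFrame],
    band: str,
    measure: str = "clustering",
) -> GroupTestResult:
    """Kruskal–Wallis across groups on the n per-electrode metric values.

    Each group contributes its full vector of per-node values (30 clustering
    coefficients for the standard montage) from the group-average network.
    """
    sizes = {len(df) for df in tables_by_group.values()}
    if len(sizes) != 1:
        raise ValueError(f"mismatched node counts across groups: {sorted(sizes)}")
    samples = [df[measure].to_numpy() for df in tables_by_group.values()]
    h, p = kruskal_wallis(samples)
    return GroupTestResult(
        electrode="global",
        band=band,
        measure=measure,
        h=h,
        p=p,
        n_per_group={g: len(df) for g, df in tables_by_group.items()},
    )


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional reporting column, off by default)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        running = min(running, p[order[rank]] * m / (rank + 1))
        adj[order[rank]] = running
    return adj


def results_to_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
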