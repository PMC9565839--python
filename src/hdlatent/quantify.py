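"""Per-subject pattern-cluster frequency histograms and per-cluster
channel summaries from sliding-window assignments."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .caefc import PatchAssignment
from .containers import Patch

__all__ = ["SubjectHistogram", "PatternSummary", "subject_histogram",
           "pattern_summaries", "histogram_matrix"]


@dataclass
class SubjectHistogram:
    subject_id: str
    frequencies: np.ndarray     # length C, sums to 1

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be non-negative and sum to 1")
        self.frequencies = f


@dataclass
class PatternSummary:
    cluster_id: int
    mean_density: float        # nan when the cluster is empty
    mean_j: float
    n_patches: int


def subject_histogram(assignments: list[PatchAssignment], n_clusters: int,
                      subject_id: str = "") -> SubjectHistogram:
    """Whole-lung pattern-cluster frequencies: counts / total windows."""
    if not assignments:
        raise ValueError("subject has no lung-covering windows")
    counts = np.bincount([a.cluster_id for a in assignments], minlength=n_clusters)
    return SubjectHistogram(subject_id, counts / counts.sum())


def pattern_summaries(assignments: list[PatchAssignment],
                      patches: list[Patch], n_clusters: int) -> list[PatternSummary]:
    """Per-cluster mean of each member patch's in-lung channel means
    (average CT density and average Jacobian of the pattern)."""
    per_cluster: dict[int, list[tuple[float, float]]] = {c: [] for c in range(n_clusters)}
    for a in assignments:
        p = patches[a.patch_id]
        m = p.lung_mask
        if not m.any():
            continue
        per_cluster[a.cluster_id].append((p.data[0][m].mean(), p.data[1][m].mean()))
    out = []
    for c in range(n_clusters):
        vals = per_cluster[c]
        if vals:
            arr = np.asarray(vals)
            out.append(PatternSummary(c, float(arr[:, 0].mean()), float(arr[:, 1].mean()), len(vals)))
        else:
            out.append(PatternSummary(c, float("nan"), float("nan"), 0))
    return out


def histogram_matrix(histograms: list[SubjectHistogram]) -> pd.DataFrame:
    """Subjects x clusters frequency matrix (CSV-ready)."""
    return pd.DataFrame(
        [h.frequencies for h in histograms],
        index=[h.subject_id for h in histograms],
        columns=[f"pc{c}" for c in range(len(histograms[0].frequencies))],
    )
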