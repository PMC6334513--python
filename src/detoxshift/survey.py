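"""Host-range survey analysis: cluster species groups by their binary
presence/absence host profiles and list commonly shared host taxa."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hierclust import Dendrogram, cut_into_k, hierarchical_cluster
from .types import HostRangeMatrix, ValidationError

__all__ = [
    "binary_euclidean_distance",
    "survey_cluster",
    "shared_taxa",
    "cut_into_k",
]


def binary_euclidean_distance(matrix: HostRangeMatrix) -> pd.DataFrame:
    """Pairwise Euclidean distance between binary host-range rows.

    For 0/1 rows this is sqrt(Hamming count): d(i, j) = sqrt(#columns where
    the two species groups differ).
    """
    arr = matrix.values.to_numpy(dtype=float)
    if arr.shape[0] < 2:
        raise ValidationError("need at least 2 species groups")
    diff = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    d = np.sqrt(diff.astype(float))
    return pd.DataFrame(d, index=matrix.groups, columns=matrix.groups)


def survey_cluster(matrix: HostRangeMatrix, linkage: str = "complete") -> Dendrogram:
    """Cluster species groups on binary Euclidean distances.

    Default linkage is complete; UPGMA is available because published figure
    captions in this field sometimes use it for the same display.
    """
    return hierarchical_cluster(binary_euclidean_distance(matrix), linkage=linkage)


def shared_taxa(matrix: HostRangeMatrix, min_fraction: float = 0.5) -> list[str]:
    """Host taxa recorded in strictly more than ``min_fraction`` of groups.

    Operationalizes "commonly shared by most species" as column prevalence
    > min_fraction (default 0.5); returned in input column order.
    """
    if not 0 < min_fraction < 1:
        raise ValidationError(f"min_fraction must be in (0, 1), got {min_fraction}")
    prev = matrix.values.mean(axis=0)
    return [t for t in matrix.taxa if prev[t] > min_fraction]
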