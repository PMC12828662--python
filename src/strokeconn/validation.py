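"""Template-applicability check: data-driven modularity vs the scheme.

Derives a community partition of the modules from the patient group's mean
Fisher-z connectivity (positive weights only, Louvain-style greedy
modularity maximisation) and quantifies its agreement with the scheme's
network template by the Hubert-Arabie Adjusted Rand Index. A high ARI
indicates that the canonical network parcellation remains a valid
description of the patient connectome despite lesions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.metrics import adjusted_rand_score

from .parcellation import ModuleScheme

__all__ = [
    "Partition",
    "detect_communities",
    "adjusted_rand_index",
    "template_partition",
    "validate_template",
]


@dataclass(frozen=True)
class Partition:
    """Community labels for a fixed item set; label values are arbitrary."""

    labels: tuple[int, ...]

    @property
    def n_items(self) -> int:
        return len(self.labels)

    @property
    def n_communities(self) -> int:
        return len(set(self.labels))


def detect_communities(mean_z: np.ndarray, seed: int = 0) -> Partition:
    """Louvain community detection on the positive part of a symmetric
    connectivity matrix.

    Negative weights are zeroed (modularity is defined for non-negative
    weights); an all-zero matrix yields a single community with a warning.
    Deterministic given the seed.
    """
    w = np.asarray(mean_z, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(w, w.T, atol=1e-8):
        raise ValueError("expected a symmetric matrix")
    w = np.where(w > 0, w, 0.0)
    np.fill_diagonal(w, 0.0)
    m = w.shape[0]
    if w.sum() == 0:
        warnings.warn("no positive off-diagonal weight; single community")
        return Partition(labels=(0,) * m)
    g = nx.from_numpy_array(w)
    communities = nx.community.louvain_communities(
        g, weight="weight", seed=seed, resolution=1.0, threshold=1e-6
    )
    labels = [0] * m
    for cid, nodes in enumerate(communities):
        for node in nodes:
            labels[node] = cid
    return Partition(labels=tuple(labels))


def adjusted_rand_index(a: Partition, b: Partition) -> float:
    """Hubert-Arabie chance-corrected pair-counting agreement between two
    partitions of the same item set (1 = identical up to relabeling)."""
    if a.n_items != b.n_items:
        raise ValueError("partitions cover different item sets")
    return float(adjusted_rand_score(a.labels, b.labels))


def template_partition(scheme: ModuleScheme) -> Partition:
    """The scheme's network template as a partition: modules of the same
    network share a community regardless of hemisphere or structure."""
    networks = sorted({m.network for m in scheme.modules})
    lookup = {name: k for k, name in enumerate(networks)}
    return Partition(labels=tuple(lookup[m.network] for m in scheme.modules))


def validate_template(
    mean_z: np.ndarray, scheme: ModuleScheme, seed: int = 0
) -> dict:
    """Full template check: detected partition, template partition, ARI and
    modularity of the detected partition."""
    detected = detect_communities(mean_z, seed=seed)
    template = template_partition(scheme)
    w = np.where(mean_z > 0, mean_z, 0.0).copy()
    np.fill_diagonal(w, 0.0)
    g = nx.from_numpy_array(w)
    groups = [
        {i for i, lab in enumerate(detected.labels) if lab == c}
        for c in sorted(set(detected.labels))
    ]
    modularity = (
        nx.community.modularity(g, groups, weight="weight")
        if w.sum() > 0 else float("nan")
    )
    return {
        "detected_labels": list(detected.labels),
        "template_labels": list(template.labels),
        "n_communities": detected.n_communities,
        "modularity": float(modularity),
        "ari": adjusted_rand_index(detected, template),
    }
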