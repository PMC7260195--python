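"""Three-marker k-means caller for memory/effector T-cell subsets.

The naive, central-memory, effector-memory and effector (TEMRA) subsets
of CD4+ helper and CD8+ cytotoxic T cells are better separated by three
surface markers (CCR7, CD45RA, CD28) than by any two, which puts them
out of reach of conventional two-dimensional gating.  This module
clusters the pooled helper+cytotoxic events in the three-marker space
with k-means (fixed k=4), labels each cluster +/- per marker by ranking
cluster medians (the top two medians are "+"), maps the (CCR7, CD45RA)
sign pair onto the four subsets, uses CD28 as a consistency check, and
splits the labelled events back by parent into eight output populations.
Samples whose clusters cannot be mapped one-to-one onto the subsets are
flagged for manual gating rather than silently mislabelled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

MARKER_ORDER = ("CCR7", "CD45RA", "CD28")
SUBSET_NAMES = ("naive", "central_memory", "effector_memory", "effector")

#: (CCR7, CD45RA) sign pair -> subset.  CD28 carries the expected third
#: sign of each targeted triple: CCR7+ memory-naive subsets retain CD28,
#: CCR7- effector-type subsets have lost it (the effector triple is
#: CCR7-/CD45RA+/CD28-).
SIGN_TO_SUBSET = {
    ("+", "+"): "naive",
    ("+", "-"): "central_memory",
    ("-", "-"): "effector_memory",
    ("-", "+"): "effector",
}
CD28_EXPECTED = {"naive": "+", "central_memory": "+",
                 "effector_memory": "-", "effector": "-"}

MIN_EVENTS_K4 = 40


class SubsetError(ValueError):
    pass


@dataclass
class SubsetCallInput:
    """Pooled CD4+/CD8+ T-cell events restricted to the three markers.

    ``events`` is n x 3 in marker order (CCR7, CD45RA, CD28), unscaled;
    ``parent`` labels each event with its parent population.
    """

    events: np.ndarray
    parent: np.ndarray
    parent_names: tuple[str, str] = ("CD4", "CD8")

    def __post_init__(self):
        self.events = np.asarray(self.events, dtype=np.float64)
        self.parent = np.asarray(self.parent)
        if self.events.ndim != 2 or self.events.shape[1] != 3:
            raise SubsetError("events must be an n x 3 matrix (CCR7, CD45RA, CD28)")
        if self.parent.shape[0] != self.events.shape[0]:
            raise SubsetError("parent labels must match events")
        unknown = set(np.unique(self.parent)) - set(self.parent_names)
        if unknown:
            raise SubsetError(f"unknown parent labels {sorted(unknown)}")


@dataclass
class SubsetCall:
    """Result of the four-cluster subset call.

    ``counts[parent][subset]`` holds per-parent event counts for the
    eight output populations; ``fractions`` the same as fractions of the
    parent.  ``flagged`` marks samples routed to manual gating.
    """

    assignment: np.ndarray
    cluster_signs: list[tuple[str, str, str]]
    subset_label: list[str]
    flagged: bool
    counts: dict[str, dict[str, int]]
    fractions: dict[str, dict[str, float]]
    seed: int
    flag_reasons: list[str] = field(default_factory=list)


def scale_markers(x: np.ndarray) -> np.ndarray:
    """Standardize each marker column to mean 0, SD 1 (ddof=1)."""
    x = np.asarray(x, dtype=np.float64)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [MARKER_ORDER[i] for i in np.nonzero(sd == 0)[0]]
        raise SubsetError(f"zero-variance marker column(s): {bad}")
    return (x - x.mean(axis=0)) / sd


def cluster_k4(x_scaled: np.ndarray, seed: int = 0) -> np.ndarray:
    """Lloyd's k-means with k=4, k-means++ init, 10 restarts, fixed seed.

    Returns the per-event cluster assignment of the restart with minimal
    within-cluster sum of squares.  Deterministic for a fixed seed.
    """
    x_scaled = np.asarray(x_scaled, dtype=np.float64)
    if x_scaled.shape[0] < MIN_EVENTS_K4:
        raise SubsetError(
            f"need at least {MIN_EVENTS_K4} events for k=4 clustering, "
            f"got {x_scaled.shape[0]}"
        )
    km = KMeans(n_clusters=4, init="k-means++", n_init=10, max_iter=300,
                tol=1e-6, algorithm="lloyd", random_state=seed)
    assignment = km.fit_predict(x_scaled)
    if len(np.unique(assignment)) < 4:
        raise SubsetError("k-means collapsed to fewer than 4 clusters")
    return assignment


def label_clusters(x: np.ndarray, assignment: np.ndarray) -> list[tuple[str, str, str]]:
    """Assign +/- per marker to each cluster from cluster medians.

    For each marker independently, the two clusters with the highest
    median marker value are "+" and the other two "-".  Ties in median
    are broken by cluster size (larger ranks higher), then by cluster id
    (lower ranks higher), so the 2/2 split is always exact and
    deterministic.  Medians are taken on unscaled marker values.
    """
    x = np.asarray(x, dtype=np.float64)
    sizes = np.bincount(assignment, minlength=4)
    if np.any(sizes == 0):
        raise SubsetError("label_clusters requires 4 non-empty clusters")
    signs = [["-"] * 3 for _ in range(4)]
    for j in range(3):
        medians = [float(np.median(x[assignment == c, j])) for c in range(4)]
        ranked = sorted(range(4), key=lambda c: (-medians[c], -sizes[c], c))
        for c in ranked[:2]:
            signs[c][j] = "+"
    return [tuple(s) for s in signs]


def map_subsets(cluster_signs: list[tuple[str, str, str]],
                cd28_strict: bool = True) -> tuple[list[str], bool, list[str]]:
    """Map cluster sign triples to subset names via the (CCR7, CD45RA) key.

    (+,+) -> naive, (+,-) -> central_memory, (-,-) -> effector_memory,
    (-,+) -> effector.  The sample is flagged for manual gating when any
    cluster cannot be mapped onto a targeted subset: either the four
    (CCR7, CD45RA) pairs do not cover all four subsets exactly once, or
    (by default) a cluster's CD28 sign contradicts its target — naive
    expects CD28+, effector expects CD28-.  Set ``cd28_strict=False``
    to downgrade the CD28 check to a warning.

    Returns ``(subset_label_per_cluster, flagged, reasons)``.
    """
    labels = [SIGN_TO_SUBSET[(s[0], s[1])] for s in cluster_signs]
    reasons: list[str] = []
    flagged = False
    if sorted(labels) != sorted(SUBSET_NAMES):
        flagged = True
        reasons.append(
            "clusters do not map one-to-one onto the four subsets: "
            + ",".join(labels)
        )
    for c, (lab, s) in enumerate(zip(labels, cluster_signs)):
        expected = CD28_EXPECTED.get(lab)
        if expected is not None and s[2] != expected:
            msg = (f"cluster {c} labelled {lab} but CD28 is {s[2]} "
                   f"(expected {expected})")
            warnings.warn(msg, stacklevel=2)
            reasons.append(msg)
            if cd28_strict:
                flagged = True
    return labels, flagged, reasons


def call_subsets(inp: SubsetCallInput, seed: int = 0,
                 cd28_strict: bool = True) -> SubsetCall:
    """Run the full subset call: scale -> cluster -> label -> map -> split.

    Flagged samples still return counts (with the manual-gating flag
    set); only hard preconditions raise.  The eight per-parent subset
    counts always partition the input events exactly.
    """
    x_scaled = scale_markers(inp.events)
    assignment = cluster_k4(x_scaled, seed=seed)
    cluster_signs = label_clusters(inp.events, assignment)
    subset_label, flagged, reasons = map_subsets(cluster_signs, cd28_strict=cd28_strict)

    counts: dict[str, dict[str, int]] = {}
    fractions: dict[str, dict[str, float]] = {}
    for parent in inp.parent_names:
        pmask = inp.parent == parent
        n_parent = int(pmask.sum())
        counts[parent] = {}
        fractions[parent] = {}
        for subset in SUBSET_NAMES:
            clusters = [c for c, lab in enumerate(subset_label) if lab == subset]
            n = int((pmask & np.isin(assignment, clusters)).sum())
            counts[parent][subset] = n
            fractions[parent][subset] = n / n_parent if n_parent else 0.0

    if flagged:
        logger.info("sample flagged for manual gating: %s", "; ".join(reasons))
    return SubsetCall(
        assignment=assignment, cluster_signs=cluster_signs,
        subset_label=subset_label, flagged=flagged,
        counts=counts, fractions=fractions, seed=seed,
        flag_reasons=reasons,
    )
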