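"""Stage I: profile nearest-neighbor search and marker-based estimates.

Given a query domain profile, stage I finds the K most similar reference
profiles, extracts a query-specific set of *dynamic markers* (families
with the same nonzero count in all K neighbors — not restricted to
single-copy families), and derives completeness and contamination from
the query's counts over those markers:

    cont = (1/M) * sum_m [C_q(m)/C_r(m) - 1]_+
    comp = (1/M) * sum_m  C_q(m)/C_r(m)       - cont

with [z]_+ = max(z, 0) and C_q(m) = 0 for markers missing from the
query.  Estimates outside the trusted range (completeness < 60% or
contamination > 30%) are reported as final; otherwise the query is
routed to the stage-II regression refinement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .profiles import ConfigurationError, DomainProfile
from .reference_db import ReferenceDatabase, marker_presence_completeness

COMPLETENESS_ROUTE_THRESHOLD = 0.60
CONTAMINATION_ROUTE_THRESHOLD = 0.30
PREFILTER_THRESHOLD = 0.10
DEFAULT_K = 9

ROUTE_FINAL = "final"
ROUTE_REFINE = "refine"
ROUTE_REJECTED = "rejected"


class NoMarkersError(ValueError):
    """The K neighbors share no family with a common nonzero count."""


@dataclass(frozen=True)
class MarkerMap:
    """Query-specific markers with their agreed reference counts."""

    markers: Mapping[str, int]

    def __post_init__(self):
        for fam, c in self.markers.items():
            if c < 1:
                raise ValueError(f"marker {fam!r} has non-positive count {c}")
        object.__setattr__(self, "markers", dict(self.markers))

    def __len__(self) -> int:
        return len(self.markers)

    def __bool__(self) -> bool:
        return bool(self.markers)


@dataclass
class Stage1Result:
    """Marker-based estimates plus neighborhood provenance.

    ``completeness`` is the raw (unclamped) estimate; use
    ``completeness_clamped`` for reporting.  ``route`` is one of
    ``final`` / ``refine`` / ``rejected``.
    """

    completeness: float
    contamination: float
    neighbor_ids: List[Tuple[str, float]]  # (genome_id, similarity), desc
    marker_count: int
    route: str
    reject_reason: Optional[str] = None

    @property
    def completeness_clamped(self) -> float:
        return min(self.completeness, 1.0)

    @property
    def top_similarity(self) -> float:
        return self.neighbor_ids[0][1] if self.neighbor_ids else float("nan")


# ---------------------------------------------------------------------------
# Profile similarity and KNN search
# ---------------------------------------------------------------------------

def profile_similarity(q: DomainProfile, r: DomainProfile) -> float:
    """Count-coincidence similarity between two sparse profiles.

    The number of families with identical nonzero counts in both
    profiles, normalized by the geometric mean of the two support
    sizes.  Requiring exact equality means mostly small counts
    contribute, which damps the influence of high-copy families and of
    contaminants.
    """
    if len(q) == 0 or len(r) == 0:
        raise ValueError("profile_similarity requires nonempty profiles")
    small, large = (q.counts, r.counts) if len(q) <= len(r) else (r.counts, q.counts)
    coinciding = sum(1 for fam, c in small.items() if large.get(fam) == c)
    return coinciding / math.sqrt(len(q) * len(r))


def knn_search(
    q: DomainProfile, db: ReferenceDatabase, K: int = DEFAULT_K
) -> List[Tuple[str, float]]:
    """The K reference entries most similar to the query.

    Returns (genome_id, similarity) pairs sorted by similarity
    descending, ties broken by genome_id ascending.  If the database
    holds fewer than K entries, all are returned with a warning.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if len(db) == 0:
        raise ValueError("empty reference database")
    scored = [
        (e.genome_id, profile_similarity(q, e.profile)) for e in db.entries
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    if len(scored) < K:
        warnings.warn(
            f"database has only {len(scored)} entries; K={K} requested",
            stacklevel=2,
        )
        return scored
    return scored[:K]


# ---------------------------------------------------------------------------
# Dynamic marker extraction and the marker-based estimate
# ---------------------------------------------------------------------------

def extract_markers(neighbors: Sequence[DomainProfile]) -> MarkerMap:
    """Families with an identical nonzero count in every neighbor."""
    if not neighbors:
        raise ValueError("extract_markers requires at least one neighbor")
    agreed = dict(neighbors[0].counts)
    for nb in neighbors[1:]:
        agreed = {
            fam: c for fam, c in agreed.items() if nb.counts.get(fam) == c
        }
        if not agreed:
            break
    return MarkerMap(agreed)


def stage1_estimate(q: DomainProfile, markers: MarkerMap) -> Tuple[float, float]:
    """(completeness, contamination) from query counts over the markers.

    Completeness can exceed 1 when query counts exceed reference counts
    asymmetrically; callers clamp for reporting but keep the raw value
    for downstream features.
    """
    if not markers:
        raise NoMarkersError(
            "no shared nonzero-count families among the nearest neighbors"
        )
    M = len(markers)
    mean_ratio = 0.0
    cont = 0.0
    for fam, c_ref in markers.markers.items():
        ratio = q.get(fam) / c_ref
        mean_ratio += ratio
        cont += max(ratio - 1.0, 0.0)
    mean_ratio /= M
    cont /= M
    comp = mean_ratio - cont
    return comp, cont


# ---------------------------------------------------------------------------
# Prefiltering and routing
# ---------------------------------------------------------------------------

def prefilter(
    q: DomainProfile,
    db: ReferenceDatabase,
    threshold: float = PREFILTER_THRESHOLD,
) -> str:
    """'pass' unless the query misses both universal marker sets.

    The query is rejected only when its marker-presence completeness is
    below ``threshold`` for every superkingdom marker set in the
    database; reaching the threshold on a single set suffices to pass.
    """
    if not db.universal_markers:
        raise ConfigurationError("reference database has no universal marker sets")
    for sk, markers in db.universal_markers.items():
        if not markers:
            raise ConfigurationError(f"empty universal marker set for {sk!r}")
        if marker_presence_completeness(q, markers) >= threshold:
            return "pass"
    return "rejected"


def route(comp: float, cont: float) -> str:
    """'final' if stage I is outside the trusted range, else 'refine'.

    Strict inequalities: completeness *below* 60% or contamination
    *above* 30% bypasses stage II; the boundary values refine.
    """
    if not (math.isfinite(comp) and math.isfinite(cont)):
        raise ValueError("estimates must be finite")
    if comp < COMPLETENESS_ROUTE_THRESHOLD or cont > CONTAMINATION_ROUTE_THRESHOLD:
        return ROUTE_FINAL
    return ROUTE_REFINE


def run_stage1(
    q: DomainProfile, db: ReferenceDatabase, K: int = DEFAULT_K
) -> Stage1Result:
    """Prefilter, KNN search, marker extraction and estimate in one call."""
    if prefilter(q, db) == "rejected":
        return Stage1Result(
            completeness=float("nan"),
            contamination=float("nan"),
            neighbor_ids=[],
            marker_count=0,
            route=ROUTE_REJECTED,
            reject_reason="completeness below 10% for all universal marker sets",
        )
    neighbors = knn_search(q, db, K)
    profiles = [db.get(gid).profile for gid, _ in neighbors]
    markers = extract_markers(profiles)
    if not markers:
        return Stage1Result(
            completeness=float("nan"),
            contamination=float("nan"),
            neighbor_ids=neighbors,
            marker_count=0,
            route=ROUTE_REJECTED,
            reject_reason="no shared markers among nearest neighbors",
        )
    comp, cont = stage1_estimate(q, markers)
    return Stage1Result(
        completeness=comp,
        contamination=cont,
        neighbor_ids=neighbors,
        marker_count=len(markers),
        route=route(comp, cont),
    )


# ---------------------------------------------------------------------------
# LCA taxonomy of the neighborhood
# ---------------------------------------------------------------------------

def lca_taxonomy(
    neighbor_taxids: Sequence[int], taxonomy: Mapping[int, int]
) -> int:
    """Lowest common ancestor of the neighbor taxids in a rooted tree.

    ``taxonomy`` maps child -> parent; the root maps to itself.
    """
    if not neighbor_taxids:
        raise ValueError("no neighbor taxids")

    def path_to_root(t: int) -> List[int]:
        if t not in taxonomy:
            raise KeyError(f"unknown taxid {t}")
        path = [t]
        while taxonomy[path[-1]] != path[-1]:
            nxt = taxonomy[path[-1]]
            if nxt not in taxonomy:
                raise KeyError(f"unknown taxid {nxt} (parent of {path[-1]})")
            path.append(nxt)
        return path[::-1]  # root first

    paths = [path_to_root(t) for t in neighbor_taxids]
    lca = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        level = {p[depth] for p in paths}
        if len(level) == 1:
            lca = level.pop()
        else:
            break
    return lca
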