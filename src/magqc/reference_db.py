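"""Reference-database construction: dereplication and universal markers.

The reference database backing the nearest-neighbor search is built from
annotated genomes in four deterministic steps:

1. agglomerative clustering (average linkage, Bray-Curtis dissimilarity
   on relative-frequency profiles) dereplicates near-identical genomes,
   keeping one medoid representative per cluster;
2. superkingdom-specific *universal single-copy markers* are discovered
   on the representatives: a family qualifies iff it occurs exactly once
   in at least a coverage fraction (default 95%) of them;
3. genomes whose marker-presence completeness against their own
   superkingdom's marker set falls below a cutoff (default 95%) are
   discarded — a guard against mislabeled "complete" inputs;
4. survivors are re-clustered with the same method; the resulting
   medoids form the database entries.

The module is fully deterministic: no randomness, lexicographic
tie-breaks throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .profiles import (
    SUPERKINGDOMS,
    ConfigurationError,
    DomainProfile,
    ProfileError,
    ReferenceEntry,
    read_profile_table,
    write_profile_table,
)


class DatabaseBuildError(ValueError):
    """Raised when the multistage filter leaves nothing usable."""


@dataclass
class ClusterAssignment:
    """Cluster labels and the medoid representative of each cluster."""

    labels: Dict[str, int]
    representatives: Dict[int, str]


@dataclass
class BuildParams:
    clustering_threshold: float = 0.10
    marker_coverage: float = 0.95
    min_completeness: float = 0.95


@dataclass
class ReferenceDatabase:
    """Dereplicated reference entries plus universal marker sets."""

    entries: List[ReferenceEntry]
    universal_markers: Dict[str, Set[str]]
    build_params: BuildParams = field(default_factory=BuildParams)

    def __post_init__(self):
        self._by_id = {e.genome_id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, genome_id: str) -> ReferenceEntry:
        return self._by_id[genome_id]

    def profiles(self) -> List[DomainProfile]:
        return [e.profile for e in self.entries]


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _relative_frequency_matrix(profiles: Sequence[DomainProfile]):
    """Dense relative-frequency matrix over the union of families."""
    families = sorted(set().union(*(p.support for p in profiles)))
    index = {f: j for j, f in enumerate(families)}
    mat = np.zeros((len(profiles), len(families)))
    for i, p in enumerate(profiles):
        tot = p.total()
        for fam, c in p.counts.items():
            mat[i, index[fam]] = c / tot
    return mat


def _bray_curtis_condensed(mat: np.ndarray) -> np.ndarray:
    """Condensed Bray-Curtis dissimilarity for rows that each sum to 1."""
    n = mat.shape[0]
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n - 1):
        diffs = np.abs(mat[i + 1:] - mat[i]).sum(axis=1) / 2.0
        out[k:k + len(diffs)] = diffs
        k += len(diffs)
    return out


def cluster_profiles(
    profiles: Sequence[DomainProfile], dissimilarity_threshold: float
) -> ClusterAssignment:
    """Average-linkage agglomerative clustering on Bray-Curtis dissimilarity.

    Profiles are normalized to relative frequencies before computing
    distances; the dendrogram is cut at ``dissimilarity_threshold``.
    Each cluster's representative is its medoid (minimum summed
    dissimilarity to cluster members, ties broken by smallest
    genome_id).
    """
    if not profiles:
        raise ValueError("cluster_profiles requires at least one profile")
    if not (0.0 < dissimilarity_threshold < 1.0):
        raise ValueError("dissimilarity threshold must lie in (0, 1)")
    ids = [p.genome_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome_ids in clustering input")
    if len(profiles) == 1:
        return ClusterAssignment({ids[0]: 0}, {0: ids[0]})

    mat = _relative_frequency_matrix(profiles)
    condensed = _bray_curtis_condensed(mat)
    tree = linkage(condensed, method="average")
    raw_labels = fcluster(tree, t=dissimilarity_threshold, criterion="distance")

    square = squareform(condensed)
    labels: Dict[str, int] = {}
    members: Dict[int, List[int]] = {}
    # renumber clusters by order of first appearance for determinism
    remap: Dict[int, int] = {}
    for i, raw in enumerate(raw_labels):
        cl = remap.setdefault(int(raw), len(remap))
        labels[ids[i]] = cl
        members.setdefault(cl, []).append(i)

    representatives: Dict[int, str] = {}
    for cl, idxs in members.items():
        best = min(
            idxs, key=lambda i: (square[i, idxs].sum(), ids[i])
        )
        representatives[cl] = ids[best]
    return ClusterAssignment(labels, representatives)


# ---------------------------------------------------------------------------
# Universal markers and the marker-presence completeness
# ---------------------------------------------------------------------------

def find_universal_markers(
    representatives: Sequence[ReferenceEntry],
    superkingdom: str,
    coverage: float = 0.95,
) -> Set[str]:
    """Families occurring exactly once in >= ``coverage`` of the reps.

    Only representatives of the requested superkingdom are considered.
    """
    reps = [r for r in representatives if r.superkingdom == superkingdom]
    if not reps:
        raise ValueError(f"no representatives for superkingdom {superkingdom!r}")
    n = len(reps)
    single_copy_counts: Dict[str, int] = {}
    for r in reps:
        for fam, c in r.profile.counts.items():
            if c == 1:
                single_copy_counts[fam] = single_copy_counts.get(fam, 0) + 1
    return {f for f, k in single_copy_counts.items() if k / n >= coverage}


def marker_presence_completeness(q: DomainProfile, markers: Set[str]) -> float:
    """Fraction of marker families present (count >= 1) in the query."""
    if not markers:
        raise ValueError("empty marker set")
    present = sum(1 for m in markers if q.get(m) >= 1)
    return present / len(markers)


# ---------------------------------------------------------------------------
# Full build pipeline
# ---------------------------------------------------------------------------

def build_reference_db(
    entries: Sequence[ReferenceEntry],
    params: Optional[BuildParams] = None,
) -> ReferenceDatabase:
    """Run the four-step dereplicate/mark/filter/re-cluster pipeline."""
    params = params or BuildParams()
    if not entries:
        raise DatabaseBuildError("no input genomes")
    by_id = {e.genome_id: e for e in entries}

    # (1) first clustering round
    assign1 = cluster_profiles(
        [e.profile for e in entries], params.clustering_threshold
    )
    reps1 = [by_id[g] for g in sorted(assign1.representatives.values())]

    # (2) universal markers per superkingdom present among representatives
    kingdoms = sorted({e.superkingdom for e in entries})
    markers: Dict[str, Set[str]] = {}
    for sk in kingdoms:
        if any(r.superkingdom == sk for r in reps1):
            found = find_universal_markers(reps1, sk, params.marker_coverage)
        else:  # all genomes of sk were absorbed into clusters led by the other sk
            found = find_universal_markers(
                [e for e in entries if e.superkingdom == sk], sk,
                params.marker_coverage,
            )
        if not found:
            raise DatabaseBuildError(
                f"no universal markers found for superkingdom {sk!r} "
                f"({sum(1 for r in reps1 if r.superkingdom == sk)} representatives)"
            )
        markers[sk] = found

    # (3) completeness filter against the genome's own superkingdom markers
    survivors = [
        e
        for e in entries
        if marker_presence_completeness(e.profile, markers[e.superkingdom])
        >= params.min_completeness
    ]
    if not survivors:
        raise DatabaseBuildError(
            f"all {len(entries)} genomes fell below the "
            f"{params.min_completeness:.0%} marker-presence cutoff "
            f"(stage counts: input={len(entries)}, reps={len(reps1)}, survivors=0)"
        )

    # (4) final clustering round on the survivors
    assign2 = cluster_profiles(
        [e.profile for e in survivors], params.clustering_threshold
    )
    final = [by_id[g] for g in sorted(assign2.representatives.values())]
    return ReferenceDatabase(entries=final, universal_markers=markers,
                             build_params=params)


# ---------------------------------------------------------------------------
# On-disk format: a directory of TSVs plus a params JSON
# ---------------------------------------------------------------------------

def save_reference_db(db: ReferenceDatabase, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_profile_table([e.profile for e in db.entries], d / "profiles.tsv")
    with open(d / "metadata.tsv", "w", encoding="utf-8") as fh:
        fh.write("genome_id\tsuperkingdom\ttaxid\trelease_date\n")
        for e in db.entries:
            taxid = "" if e.taxid is None else str(e.taxid)
            rdate = "" if e.release_date is None else e.release_date.isoformat()
            fh.write(f"{e.genome_id}\t{e.superkingdom}\t{taxid}\t{rdate}\n")
    with open(d / "markers.tsv", "w", encoding="utf-8") as fh:
        fh.write("superkingdom\tfamily_id\n")
        for sk in sorted(db.universal_markers):
            for fam in sorted(db.universal_markers[sk]):
                fh.write(f"{sk}\t{fam}\n")
    with open(d / "params.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "clustering_threshold": db.build_params.clustering_threshold,
                "marker_coverage": db.build_params.marker_coverage,
                "min_completeness": db.build_params.min_completeness,
            },
            fh,
            indent=2,
        )


def load_reference_db(directory) -> ReferenceDatabase:
    d = Path(directory)
    profiles = {p.genome_id: p for p in read_profile_table(d / "profiles.tsv")}
    entries: List[ReferenceEntry] = []
    with open(d / "metadata.tsv", encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            gid, sk, taxid, rdate = line.rstrip("\n").split("\t")
            entries.append(
                ReferenceEntry(
                    profile=profiles[gid],
                    superkingdom=sk,
                    taxid=int(taxid) if taxid else None,
                    release_date=date.fromisoformat(rdate) if rdate else None,
                )
            )
    markers: Dict[str, Set[str]] = {}
    with open(d / "markers.tsv", encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            sk, fam = line.rstrip("\n").split("\t")
            markers.setdefault(sk, set()).add(fam)
    with open(d / "params.json", encoding="utf-8") as fh:
        raw = json.load(fh)
    return ReferenceDatabase(
        entries=entries,
        universal_markers=markers,
        build_params=BuildParams(**raw),
    )
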