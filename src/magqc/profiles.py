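"""Protein-domain count profiles: data model, I/O and shared similarities.

A genome's *domain profile* maps protein-family identifiers to copy
counts, as produced by a protein-domain annotation backend (e.g. a
translated-ORF domain search).  Profiles are stored sparsely: a family
with count zero is simply absent.  Everything downstream — the
nearest-neighbor search, the dynamic marker extraction and the count
ratio histograms — only touches nonzero entries, so the full dimension
of the underlying domain catalog is never materialized.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date
from typing import Dict, Iterable, List, Mapping, Optional, Protocol, Sequence

import numpy as np

SUPERKINGDOMS = ("bacteria", "archaea")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class ProfileError(ValueError):
    """Malformed or invalid profile data."""


class ConfigurationError(ValueError):
    """Invalid configuration (duplicate tokens, missing marker sets, ...)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DomainProfile:
    """Sparse map from protein-family id to a positive copy count."""

    genome_id: str
    counts: Mapping[str, int]

    def __post_init__(self):
        for fam, c in self.counts.items():
            if not isinstance(c, (int, np.integer)) or isinstance(c, bool) or c < 1:
                raise ProfileError(
                    f"profile {self.genome_id!r}: count for {fam!r} must be a "
                    f"positive integer, got {c!r}"
                )
        object.__setattr__(self, "counts", dict(self.counts))

    @property
    def support(self) -> frozenset:
        """Families with nonzero count."""
        return frozenset(self.counts)

    def get(self, family: str) -> int:
        return self.counts.get(family, 0)

    def __len__(self) -> int:
        return len(self.counts)

    def total(self) -> int:
        return sum(self.counts.values())

    def relative_frequencies(self) -> Dict[str, float]:
        tot = self.total()
        return {f: c / tot for f, c in self.counts.items()}


@dataclass(frozen=True)
class ReferenceEntry:
    """A reference genome's profile plus database metadata."""

    profile: DomainProfile
    superkingdom: str
    taxid: Optional[int] = None
    release_date: Optional[date] = None

    def __post_init__(self):
        if self.superkingdom not in SUPERKINGDOMS:
            raise ProfileError(
                f"superkingdom must be one of {SUPERKINGDOMS}, "
                f"got {self.superkingdom!r}"
            )

    @property
    def genome_id(self) -> str:
        return self.profile.genome_id


class AnnotationBackend(Protocol):
    """Contract for a protein-domain annotator.

    ``annotate`` consumes nucleotide sequences of one genome/bin and
    returns a :class:`DomainProfile` whose support is a subset of
    ``families``.  A production backend would run a translated domain
    search; tests use :class:`TokenAnnotator`.
    """

    name: str
    families: List[str]

    def annotate(self, sequences: Sequence[str], genome_id: str) -> DomainProfile:
        ...


# ---------------------------------------------------------------------------
# Profile table I/O
# ---------------------------------------------------------------------------

PROFILE_HEADER = ("genome_id", "family_id", "count")


def read_profile_table(path) -> List[DomainProfile]:
    """Read a profile TSV (``genome_id  family_id  count``).

    Returns one profile per distinct genome id, in order of first
    appearance.  Counts must parse as positive integers.
    """
    per_genome: Dict[str, Dict[str, int]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and tuple(row) == PROFILE_HEADER:
                continue
            if len(row) != 3:
                raise ProfileError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields, "
                    f"got {len(row)}"
                )
            gid, fam, count_s = row
            try:
                count = int(count_s)
            except ValueError:
                raise ProfileError(
                    f"{path}: line {lineno}: count {count_s!r} is not an integer"
                ) from None
            if count <= 0:
                raise ProfileError(
                    f"{path}: line {lineno}: count must be positive, got {count}"
                )
            counts = per_genome.setdefault(gid, {})
            counts[fam] = counts.get(fam, 0) + count
    return [DomainProfile(gid, counts) for gid, counts in per_genome.items()]


def write_profile_table(profiles: Iterable[DomainProfile], path) -> None:
    """Write profiles as a TSV, round-trippable with read_profile_table."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PROFILE_HEADER)
        for p in profiles:
            for fam in sorted(p.counts):
                writer.writerow((p.genome_id, fam, p.counts[fam]))


# ---------------------------------------------------------------------------
# Toy exact-match annotation backend
# ---------------------------------------------------------------------------

def _count_overlapping(haystack: str, needle: str) -> int:
    n, start = 0, 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return n
        n += 1
        start = idx + 1


_BASE5 = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode_base5(seq: str) -> np.ndarray:
    """Encode A,C,G,T as 0..3 and anything else as 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int64)
    for base, code in _BASE5.items():
        out[arr == ord(base)] = code
    return out


def _window_codes(encoded: np.ndarray, k: int) -> np.ndarray:
    """Base-5 integer code of every length-k window (exact, collision-free)."""
    if len(encoded) < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, k)
    weights = 5 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return windows @ weights


def _token_code(token: str) -> int:
    code = 0
    for ch in token.upper():
        code = code * 5 + _BASE5[ch]
    return code


def toy_annotate(
    sequences: Sequence[str],
    catalog: Mapping[str, str],
    genome_id: str = "query",
) -> DomainProfile:
    """Exact-match annotator over a token catalog (family id -> token).

    The count for family *f* is the number of (possibly overlapping)
    occurrences of its token on either strand, summed over all
    sequences.  Families with count zero are absent from the result.
    Tokens must be distinct strings over {A,C,G,T} of length >= 20.
    """
    seen_tokens: Dict[str, str] = {}
    for fam, token in catalog.items():
        t = token.upper()
        if any(ch not in _BASE5 for ch in t):
            raise ConfigurationError(f"token for {fam!r} contains non-ACGT characters")
        if len(t) < 20:
            raise ConfigurationError(f"token for {fam!r} is shorter than 20 nt")
        if t in seen_tokens:
            raise ConfigurationError(
                f"duplicate token shared by families {seen_tokens[t]!r} and {fam!r}"
            )
        seen_tokens[t] = fam

    counts: Dict[str, int] = {}
    # Group token lengths; windows <= 26 nt fit a base-5 int64 code exactly.
    by_length: Dict[int, List[str]] = {}
    for fam, token in catalog.items():
        by_length.setdefault(len(token), []).append(fam)

    encoded = [_encode_base5(s) for s in sequences]
    for k, fams in sorted(by_length.items()):
        if k > 26:
            for fam in fams:
                token = catalog[fam].upper()
                rc = reverse_complement(token)
                n = 0
                for seq in sequences:
                    s = seq.upper()
                    n += _count_overlapping(s, token)
                    if rc != token:
                        n += _count_overlapping(s, rc)
                if n:
                    counts[fam] = counts.get(fam, 0) + n
            continue
        code_to_fam: Dict[int, str] = {}
        fam_counts: Dict[str, int] = {fam: 0 for fam in fams}
        for fam in fams:
            token = catalog[fam].upper()
            code_to_fam[_token_code(token)] = fam
            rc = reverse_complement(token)
            if rc != token:
                code_to_fam[_token_code(rc)] = fam
        for enc in encoded:
            codes = _window_codes(enc, k)
            if codes.size == 0:
                continue
            uniq, cnt = np.unique(codes, return_counts=True)
            for code, n in zip(uniq.tolist(), cnt.tolist()):
                fam = code_to_fam.get(code)
                if fam is not None:
                    fam_counts[fam] += n
        for fam, n in fam_counts.items():
            if n:
                counts[fam] = counts.get(fam, 0) + n
    return DomainProfile(genome_id, counts)


@dataclass
class TokenAnnotator:
    """AnnotationBackend implementation backed by :func:`toy_annotate`."""

    catalog: Mapping[str, str]
    name: str = "token-exact-match"
    families: List[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.families:
            self.families = sorted(self.catalog)

    def annotate(self, sequences: Sequence[str], genome_id: str) -> DomainProfile:
        return toy_annotate(sequences, self.catalog, genome_id)


# ---------------------------------------------------------------------------
# Bray-Curtis similarity
# ---------------------------------------------------------------------------

def bray_curtis_similarity(x, y) -> float:
    """1 - sum|x_i - y_i| / sum(x_i + y_i) for nonnegative vectors.

    Symmetric, in [0, 1], and equal to 1 iff x == y elementwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    denom = float(np.sum(x + y))
    if denom == 0.0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return 1.0 - float(np.sum(np.abs(x - y))) / denom


def profile_bray_curtis_dissimilarity(a: DomainProfile, b: DomainProfile) -> float:
    """Bray-Curtis dissimilarity between two relative-frequency profiles."""
    fa = a.relative_frequencies()
    fb = b.relative_frequencies()
    num = 0.0
    for fam in set(fa) | set(fb):
        num += abs(fa.get(fam, 0.0) - fb.get(fam, 0.0))
    return num / 2.0  # both frequency vectors sum to 1
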