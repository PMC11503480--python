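"""Ground-truth bin simulation and the synthetic domain world.

Two jobs live here.  First, the bin simulator: it emulates a metagenome
binning result by fragmenting a query genome (20-kb fragments by
default), sampling fragments to hit a completeness drawn from
U(60%, 100%), and admixing fragments from compositionally similar
genomes (tetramer-signature Bray-Curtis similarity >= 80%) to hit a
contamination drawn from U(0%, 30%), where contamination is measured
relative to the complete query genome length.  Realized (quantized)
values are recorded as ground truth, so evaluation is exact.

Second, the synthetic world generator: a population of artificial
genomes carrying planted domain "tokens" (exact-match surrogates for
protein-domain hits) organized into clades, with core families that are
single-copy almost everywhere — mimicking universal single-copy genes —
and clade-correlated accessory families.  Clades differ in nucleotide
composition so that tetramer similarity is high within a clade, and
release dates span three eras to support date-based data splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .profiles import (
    DomainProfile,
    ReferenceEntry,
    TokenAnnotator,
    bray_curtis_similarity,
    reverse_complement,
    toy_annotate,
)

DEFAULT_FRAGMENT_LENGTH = 20_000
COMP_RANGE = (0.60, 1.00)
CONT_RANGE = (0.0, 0.30)
CONTAMINANT_MIN_SIMILARITY = 0.80
_TAIL_KEEP_FRACTION = 0.25

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    """Unrealizable simulation request (e.g. no eligible contaminant)."""


# ---------------------------------------------------------------------------
# Tetramer signatures
# ---------------------------------------------------------------------------

def _canonical_tetramer_index() -> Tuple[np.ndarray, int]:
    """Map each of the 256 tetramer codes to a canonical bin index."""
    rc = np.empty(256, dtype=np.int64)
    for code in range(256):
        digits = [(code >> (2 * (3 - i))) & 3 for i in range(4)]
        rc_digits = [3 - d for d in reversed(digits)]
        rc_code = 0
        for d in rc_digits:
            rc_code = (rc_code << 2) | d
        rc[code] = rc_code
    canonical = np.minimum(np.arange(256), rc)
    uniq = np.unique(canonical)
    index = np.empty(256, dtype=np.int64)
    for i, c in enumerate(uniq):
        index[canonical == c] = i
    return index, len(uniq)


_TETRA_INDEX, N_CANONICAL_TETRAMERS = _canonical_tetramer_index()  # 136 bins


def _encode_acgt(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else -> 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int64)
    for code, base in enumerate(b"ACGT"):
        out[arr == base] = code
    return out


def tetramer_profile(sequence: str) -> np.ndarray:
    """Canonical 4-mer frequency vector (136 dimensions).

    Each window is mapped to the lexicographically smaller of itself and
    its reverse complement; windows containing non-ACGT characters are
    skipped.
    """
    if len(sequence) < 4:
        raise ValueError("sequence shorter than 4 nt")
    enc = _encode_acgt(sequence)
    windows = np.lib.stride_tricks.sliding_window_view(enc, 4)
    valid = (windows < 4).all(axis=1)
    if not valid.any():
        raise ValueError("no valid ACGT tetramer window in sequence")
    codes = windows[valid] @ np.array([64, 16, 4, 1], dtype=np.int64)
    counts = np.bincount(_TETRA_INDEX[codes], minlength=N_CANONICAL_TETRAMERS)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------

def fragment_genome(sequence: str, fragment_length: int) -> List[str]:
    """Non-overlapping consecutive windows from position 0.

    A trailing remainder is kept as a shorter final fragment when it is
    at least 25% of the fragment length, otherwise dropped.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if fragment_length < 1:
        raise ValueError(f"fragment_length must be >= 1, got {fragment_length}")
    n_full = len(sequence) // fragment_length
    frags = [
        sequence[i * fragment_length:(i + 1) * fragment_length]
        for i in range(n_full)
    ]
    tail = sequence[n_full * fragment_length:]
    if tail and len(tail) >= _TAIL_KEEP_FRACTION * fragment_length:
        frags.append(tail)
    if not frags:
        raise ValueError(
            f"sequence of {len(sequence)} nt yields no fragment at "
            f"fragment_length {fragment_length}"
        )
    return frags


# ---------------------------------------------------------------------------
# Genomes and the simulated bin record
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """One synthetic genome with its true domain profile and metadata."""

    genome_id: str
    sequence: str
    profile: DomainProfile
    superkingdom: str
    taxid: int
    release_date: date
    clade: int = 0
    _tetramers: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def tetramers(self) -> np.ndarray:
        if self._tetramers is None:
            self._tetramers = tetramer_profile(self.sequence)
        return self._tetramers

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SimulatedBin:
    """Contigs mixed from a query genome and eligible contaminants."""

    bin_id: str
    contigs: List[str]
    provenance: List[Tuple[str, int]]  # (source genome_id, fragment index)
    truth_completeness: float
    truth_contamination: float
    source_genome: str
    contaminant_ids: List[str]
    fragment_length: int
    seed: Optional[int] = None

    def query_bases(self) -> int:
        return sum(
            len(c) for c, (src, _) in zip(self.contigs, self.provenance)
            if src == self.source_genome
        )

    def contaminant_bases(self) -> int:
        return sum(
            len(c) for c, (src, _) in zip(self.contigs, self.provenance)
            if src != self.source_genome
        )


def select_contaminants(
    query_genome: Genome,
    pool: Sequence[Genome],
    rng: np.random.Generator,
    min_similarity: float = CONTAMINANT_MIN_SIMILARITY,
) -> List[Genome]:
    """Eligible contaminants for a query, in uniform random order.

    A pool genome is eligible when the Bray-Curtis similarity between
    its tetramer signature and the query's is at least
    ``min_similarity``.  The caller consumes the returned list in order
    until the contamination target is met.
    """
    eligible = [
        g
        for g in pool
        if g.genome_id != query_genome.genome_id
        and bray_curtis_similarity(query_genome.tetramers, g.tetramers)
        >= min_similarity
    ]
    if not eligible:
        raise SimulationError(
            f"no genome in the pool reaches tetramer similarity "
            f">= {min_similarity:.2f} to {query_genome.genome_id!r}; "
            "query unusable for contaminated bins"
        )
    order = rng.permutation(len(eligible))
    return [eligible[i] for i in order]


def simulate_bin(
    query_genome: Genome,
    pool: Sequence[Genome],
    rng: Optional[np.random.Generator] = None,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    comp_range: Tuple[float, float] = COMP_RANGE,
    cont_range: Tuple[float, float] = CONT_RANGE,
    bin_id: Optional[str] = None,
    seed: Optional[int] = None,
) -> SimulatedBin:
    """Draw one simulated bin with recorded realized ground truth.

    Completeness and contamination targets are drawn uniformly from
    their ranges; fragment counts are rounded to the nearest integer and
    the *realized* base fractions are stored as truth.  With
    ``fragment_length = 0`` the genome is used as a single unfragmented
    contig (native-contig passthrough).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if fragment_length > 0:
        frags_q = fragment_genome(query_genome.sequence, fragment_length)
    else:
        frags_q = [query_genome.sequence]
    L_q = len(query_genome.sequence)

    comp_target = float(rng.uniform(*comp_range))
    cont_target = float(rng.uniform(*cont_range))

    n_q = int(round(comp_target * len(frags_q)))
    n_q = max(0, min(n_q, len(frags_q)))
    chosen = sorted(rng.choice(len(frags_q), size=n_q, replace=False).tolist())
    contigs = [frags_q[i] for i in chosen]
    provenance = [(query_genome.genome_id, i) for i in chosen]

    # Contamination is measured against the complete query genome length.
    contaminant_ids: List[str] = []
    if fragment_length > 0:
        n_c = int(round(cont_target * L_q / fragment_length))
    else:
        n_c = 0 if cont_target * L_q < 1 else None  # bases-driven, below
    target_cont_bases = cont_target * L_q

    if (n_c is None or n_c > 0) and cont_target > 0:
        contaminants = select_contaminants(query_genome, pool, rng)
        added_bases = 0
        added = 0
        done = False
        for cg in contaminants:
            if fragment_length > 0:
                c_frags = fragment_genome(cg.sequence, fragment_length)
            else:
                c_frags = [cg.sequence]
            order = rng.permutation(len(c_frags))
            used_any = False
            for idx in order:
                if n_c is not None and added >= n_c:
                    done = True
                    break
                if n_c is None and added_bases >= target_cont_bases:
                    done = True
                    break
                contigs.append(c_frags[idx])
                provenance.append((cg.genome_id, int(idx)))
                added_bases += len(c_frags[idx])
                added += 1
                used_any = True
            if used_any:
                contaminant_ids.append(cg.genome_id)
            if done:
                break
        else:
            if (n_c is not None and added < n_c) or (
                n_c is None and added_bases < target_cont_bases
            ):
                raise SimulationError(
                    f"contamination target {cont_target:.3f} unrealizable for "
                    f"{query_genome.genome_id!r}: eligible pool exhausted"
                )

    query_bases = sum(len(frags_q[i]) for i in chosen)
    cont_bases = sum(len(c) for c in contigs) - query_bases
    return SimulatedBin(
        bin_id=bin_id or f"{query_genome.genome_id}_bin",
        contigs=contigs,
        provenance=provenance,
        truth_completeness=query_bases / L_q,
        truth_contamination=cont_bases / L_q,
        source_genome=query_genome.genome_id,
        contaminant_ids=contaminant_ids,
        fragment_length=fragment_length,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Synthetic world
# ---------------------------------------------------------------------------

TOKEN_LENGTH = 24

# Three release-date eras; the oldest is meant to serve as the reference
# part of a date split, the two recent ones as training/validation parts.
_ERA_STARTS = (date(2019, 1, 1), date(2021, 6, 1), date(2023, 6, 1))
DEFAULT_SPLIT_DATES = (date(2021, 1, 1), date(2023, 1, 1))


@dataclass
class SyntheticWorld:
    """A seeded population of token-bearing genomes with known profiles."""

    catalog: Dict[str, str]  # family id -> token
    genomes: List[Genome]
    taxonomy: Dict[int, int]  # child taxid -> parent taxid (root -> itself)
    core_families: List[str]
    accessory_families: List[str]
    seed: int

    def annotator(self) -> TokenAnnotator:
        return TokenAnnotator(self.catalog)

    def reference_entries(
        self, genome_ids: Optional[Set[str]] = None
    ) -> List[ReferenceEntry]:
        return [
            ReferenceEntry(
                profile=g.profile,
                superkingdom=g.superkingdom,
                taxid=g.taxid,
                release_date=g.release_date,
            )
            for g in self.genomes
            if genome_ids is None or g.genome_id in genome_ids
        ]

    def get(self, genome_id: str) -> Genome:
        return next(g for g in self.genomes if g.genome_id == genome_id)


def _random_tokens(rng: np.random.Generator, n: int, length: int) -> List[str]:
    """Distinct random ACGT tokens whose reverse complements also collide-free."""
    tokens: List[str] = []
    seen: Set[str] = set()
    while len(tokens) < n:
        t = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        rc = reverse_complement(t)
        if t in seen or rc in seen or t == rc:
            continue
        seen.add(t)
        seen.add(rc)
        tokens.append(t)
    return tokens


def _random_background(
    rng: np.random.Generator, length: int, gc: float
) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def generate_synthetic_world(
    n_genomes: int = 60,
    n_core_families: int = 150,
    n_accessory_families: int = 300,
    genome_length: int = 300_000,
    n_clades: int = 6,
    seed: int = 0,
) -> SyntheticWorld:
    """Build a clade-structured world of token-bearing genomes.

    Core families are single-copy in at least 95% of genomes by
    construction (each family deviates in at most 5% of genomes);
    accessory families carry clade-correlated counts in 0..3.  Each
    clade has its own GC content, drawn evenly from 0.40..0.60, so
    genomes are compositionally similar within a clade.  Token planting
    is verified by re-annotation, making the round trip exact.
    """
    rng = np.random.default_rng(seed)
    core = [f"C{i:04d}" for i in range(n_core_families)]
    accessory = [f"A{i:04d}" for i in range(n_accessory_families)]
    tokens = _random_tokens(rng, len(core) + len(accessory), TOKEN_LENGTH)
    catalog = dict(zip(core + accessory, tokens))

    clade_of = [i % n_clades for i in range(n_genomes)]
    clade_gc = np.linspace(0.40, 0.60, n_clades)
    # clade base counts for accessory families (0..3)
    clade_accessory = rng.integers(0, 4, size=(n_clades, n_accessory_families))

    # core deviations: per family, at most floor(5% n) genomes deviate
    counts = np.ones((n_genomes, n_core_families), dtype=np.int64)
    max_dev = n_genomes // 20
    for j in range(n_core_families):
        k = min(int(rng.binomial(n_genomes, 0.02)), max_dev)
        if k:
            rows = rng.choice(n_genomes, size=k, replace=False)
            counts[rows, j] = rng.choice([0, 2], size=k)

    # Strain-level accessory variation: a third of the accessory families
    # deviate from the clade base per genome, so that genomes of one clade
    # are related but not redundant (dereplication should keep them apart).
    acc_counts = np.empty((n_genomes, n_accessory_families), dtype=np.int64)
    for i in range(n_genomes):
        base = clade_accessory[clade_of[i]].copy()
        jitter = rng.random(n_accessory_families) < 0.35
        base[jitter] += rng.choice([-1, 1], size=int(jitter.sum()))
        acc_counts[i] = np.clip(base, 0, 3)

    n_slots = genome_length // TOKEN_LENGTH
    families = core + accessory
    taxonomy: Dict[int, int] = {1: 1, 2: 1, 3: 1}
    for c in range(n_clades):
        taxonomy[10 + c] = 2 if c < (n_clades + 1) // 2 else 3

    genomes: List[Genome] = []
    era_cycle = (0, 1, 0, 2)  # oldest era gets ~half the genomes
    per_clade_seen: Dict[int, int] = {}
    for i in range(n_genomes):
        gid = f"G{i:03d}"
        clade = clade_of[i]
        fam_counts = {
            fam: int(c)
            for fam, c in zip(
                families, np.concatenate([counts[i], acc_counts[i]])
            )
            if c > 0
        }
        profile = DomainProfile(gid, fam_counts)
        total_tokens = sum(fam_counts.values())
        if total_tokens > n_slots:
            raise ValueError(
                f"genome length {genome_length} too short to host "
                f"{total_tokens} tokens of {TOKEN_LENGTH} nt"
            )
        for _attempt in range(5):
            background = _random_background(rng, genome_length, clade_gc[clade])
            slots = rng.choice(n_slots, size=total_tokens, replace=False)
            k = 0
            for fam in families:
                c = fam_counts.get(fam, 0)
                for _ in range(c):
                    token = catalog[fam]
                    if rng.random() < 0.5:
                        token = reverse_complement(token)
                    start = int(slots[k]) * TOKEN_LENGTH
                    background[start:start + TOKEN_LENGTH] = np.frombuffer(
                        token.encode("ascii"), dtype=np.uint8
                    )
                    k += 1
            sequence = background.tobytes().decode("ascii")
            observed = toy_annotate([sequence], catalog, gid)
            if observed.counts == fam_counts:
                break
        else:  # pragma: no cover - astronomically unlikely collision loop
            raise RuntimeError(f"could not plant tokens cleanly for {gid}")

        rank = per_clade_seen.get(clade, 0)
        per_clade_seen[clade] = rank + 1
        era = era_cycle[rank % len(era_cycle)]
        release = _ERA_STARTS[era] + timedelta(days=int(rng.integers(0, 360)))
        taxid = 100 + i
        taxonomy[taxid] = 10 + clade
        genomes.append(
            Genome(
                genome_id=gid,
                sequence=sequence,
                profile=profile,
                superkingdom="bacteria" if taxonomy[10 + clade] == 2 else "archaea",
                taxid=taxid,
                release_date=release,
                clade=clade,
            )
        )
    return SyntheticWorld(
        catalog=catalog,
        genomes=genomes,
        taxonomy=taxonomy,
        core_families=core,
        accessory_families=accessory,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Bin I/O: FASTA per bin plus a manifest TSV
# ---------------------------------------------------------------------------

MANIFEST_HEADER = (
    "bin_id\ttruth_completeness\ttruth_contamination\tsource\t"
    "contaminants\tfragment_length\tseed\n"
)


def write_bins(bins: Sequence[SimulatedBin], directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "manifest.tsv", "w", encoding="utf-8") as mf:
        mf.write(MANIFEST_HEADER)
        for b in bins:
            with open(d / f"{b.bin_id}.fasta", "w", encoding="utf-8") as fh:
                for contig, (src, idx) in zip(b.contigs, b.provenance):
                    fh.write(f">{b.bin_id}|src={src}|frag={idx}\n")
                    for j in range(0, len(contig), 80):
                        fh.write(contig[j:j + 80] + "\n")
            mf.write(
                f"{b.bin_id}\t{b.truth_completeness:.10g}\t"
                f"{b.truth_contamination:.10g}\t{b.source_genome}\t"
                f"{','.join(b.contaminant_ids)}\t{b.fragment_length}\t"
                f"{'' if b.seed is None else b.seed}\n"
            )


def read_manifest(path) -> List[Dict[str, object]]:
    rows: List[Dict[str, object]] = []
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            bin_id, comp, cont, src, contams, flen, seed = line.rstrip("\n").split("\t")
            rows.append(
                {
                    "bin_id": bin_id,
                    "truth_completeness": float(comp),
                    "truth_contamination": float(cont),
                    "source": src,
                    "contaminants": contams.split(",") if contams else [],
                    "fragment_length": int(flen),
                    "seed": int(seed) if seed else None,
                }
            )
    return rows
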