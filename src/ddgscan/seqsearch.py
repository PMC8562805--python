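"""Pairwise alignment, sequence identity, significance gating, discovery.

Candidate homolog chains are found by aligning every chain of every
candidate structure against every user-specified chain and keeping hits
whose expectation value falls below the cutoff (default 1e-11).  Hits are
grouped by structure ID; each group is a candidate homolog complex for the
downstream three-stage filter.

Identity statistic
------------------
identity = (identical aligned positions) / min(query length, subject length)

so a fragment that matches a full-length chain end to end scores 1.0.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from Bio import Align
from Bio.Align import substitution_matrices

from .structures import ComplexStructure, SubunitDefinition, read_structure

__all__ = [
    "AlignmentResult",
    "ChainHit",
    "align_pair",
    "sequence_identity",
    "estimate_evalue",
    "find_candidates",
    "SearchProvider",
    "LocalDirectoryProvider",
    "ProviderError",
]

# Karlin-Altschul parameters for gapped BLOSUM62 (gap 11/1), as tabulated
# for protein database search statistics.
KA_LAMBDA = 0.267
KA_K = 0.041

#: default significance gate on the expectation value
DEFAULT_EVALUE_CUTOFF = 1e-11


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise alignment reduced to its residue-index correspondence."""

    aligned_pairs: tuple[tuple[int, int], ...]  # (query idx, subject idx), 0-based
    n_identical: int
    score: float
    query_len: int
    subject_len: int

    def __post_init__(self) -> None:
        pairs = self.aligned_pairs
        for (q0, s0), (q1, s1) in zip(pairs, pairs[1:]):
            if q1 <= q0 or s1 <= s0:
                raise ValueError("aligned_pairs must be strictly increasing")
        if self.n_identical > len(pairs):
            raise ValueError("n_identical exceeds number of aligned pairs")

    def subject_index(self, query_index: int) -> int | None:
        """Subject residue index aligned to a query index, or None (gap)."""
        for q, s in self.aligned_pairs:
            if q == query_index:
                return s
        return None

    def query_index(self, subject_index: int) -> int | None:
        for q, s in self.aligned_pairs:
            if s == subject_index:
                return q
        return None


@dataclass(frozen=True)
class ChainHit:
    structure_id: str
    chain_id: str
    evalue: float
    matched_user_chain: str
    identity: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # affine cost 11 + k for a gap of length k (NCBI convention)
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    # end gaps free: a short chain may match a fragment of a longer one
    aligner.end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def align_pair(query: str, subject: str) -> AlignmentResult:
    """Globally align two sequences (BLOSUM62, gap 11/1, free end gaps).

    Deterministic: of co-optimal alignments the aligner's first is taken.
    """
    if not query or not subject:
        raise ValueError("cannot align an empty sequence")
    query = query.upper()
    subject = subject.upper()
    alignment = _ALIGNER.align(query, subject)[0]
    pairs: list[tuple[int, int]] = []
    n_identical = 0
    for (qs, qe), (ss, se) in zip(*alignment.aligned):
        for offset in range(qe - qs):
            qi, si = qs + offset, ss + offset
            pairs.append((qi, si))
            if query[qi] == subject[si]:
                n_identical += 1
    return AlignmentResult(
        aligned_pairs=tuple(pairs),
        n_identical=n_identical,
        score=float(alignment.score),
        query_len=len(query),
        subject_len=len(subject),
    )


def sequence_identity(alignment: AlignmentResult) -> float:
    """Identical aligned positions over the shorter chain's length."""
    return alignment.n_identical / min(alignment.query_len, alignment.subject_len)


def estimate_evalue(alignment: AlignmentResult, database_size: int) -> float:
    """Karlin-Altschul expectation value E = K * m * n * exp(-lambda * S).

    ``m`` is the query length, ``n`` the total residues searched, ``S`` the
    raw alignment score.  Monotone decreasing in the score.  These locally
    computed values gate significance; they are not comparable digit for
    digit with any particular search server's E-values.
    """
    if database_size <= 0:
        raise ValueError("database_size must be positive")
    return KA_K * alignment.query_len * database_size * math.exp(
        -KA_LAMBDA * alignment.score
    )


# ---------------------------------------------------------------------------
# Candidate discovery
# ---------------------------------------------------------------------------


class ProviderError(RuntimeError):
    """A homolog source failed (I/O, endpoint down); retriable, distinct
    from a successful search returning no hits."""


class SearchProvider(ABC):
    """Source of candidate structures; local directory or remote service."""

    @abstractmethod
    def structures(self) -> Iterator[ComplexStructure]:
        """Yield every candidate complex."""

    @abstractmethod
    def total_residues(self) -> int:
        """Total residue count of the collection (the database size for
        E-value estimation)."""

    def get(self, structure_id: str) -> ComplexStructure:
        for st in self.structures():
            if st.structure_id == structure_id:
                return st
        raise KeyError(structure_id)


class LocalDirectoryProvider(SearchProvider):
    """Desk-scale provider: every structure file found in a directory."""

    PATTERNS = ("*.pdb", "*.ent", "*.cif", "*.mmcif")

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        if not self.directory.is_dir():
            raise ProviderError(f"not a directory: {self.directory}")

    def _files(self) -> list[Path]:
        files: list[Path] = []
        for pat in self.PATTERNS:
            files.extend(self.directory.glob(pat))
        return sorted(set(files))

    def structures(self) -> Iterator[ComplexStructure]:
        files = self._files()
        if not files:
            return
        for path in files:
            try:
                yield read_structure(path)
            except ValueError:
                continue  # unparseable files are not candidates

    def total_residues(self) -> int:
        return sum(st.n_residues() for st in self.structures())


def find_candidates(
    query: ComplexStructure,
    subunits: SubunitDefinition,
    provider: SearchProvider,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> dict[str, list[ChainHit]]:
    """Discover candidate homolog structures, grouped by structure ID.

    Every chain of every provider structure is aligned against every
    user-specified query chain; chains with E-value below the cutoff are
    hits.  A structure with at least one hit becomes a candidate group.
    """
    subunits.validate_against(query)
    database_size = max(provider.total_residues(), 1)
    groups: dict[str, list[ChainHit]] = {}
    for subject in provider.structures():
        hits: list[ChainHit] = []
        for user_chain_id in subunits.all_chains:
            user_seq = query.chain(user_chain_id).sequence
            for subject_chain in subject.chains:
                if not subject_chain.residues:
                    continue
                aln = align_pair(user_seq, subject_chain.sequence)
                ev = estimate_evalue(aln, database_size)
                if ev < evalue_cutoff:
                    hits.append(
                        ChainHit(
                            structure_id=subject.structure_id,
                            chain_id=subject_chain.chain_id,
                            evalue=ev,
                            matched_user_chain=user_chain_id,
                            identity=sequence_identity(aln),
                        )
                    )
        if hits:
            groups[subject.structure_id] = hits
    return groups
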