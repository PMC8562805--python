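"""Three-stage homolog filter: chain completeness, identity, complex RMSD.

A candidate structure is accepted as a usable homolog when

1. it contains a distinct counterpart for every user-specified chain
   (*chain check*),
2. each counterpart has sequence identity >= the cutoff (default 0.90)
   against its user chain (*identity check*), and
3. after one global rigid superposition of the whole candidate onto the
   query — fitted on the pooled Calpha atoms of aligned residue pairs across
   all corresponding chains — the RMSD is <= the cutoff (default 6.0 A)
   (*RMSD check*).

The single global fit is deliberate: it preserves quaternary structure, so
a candidate with the right chains in a different mutual arrangement fails
stage 3 even though each chain individually superposes well.  Chains of the
candidate with no user counterpart ("extraneous" chains) are carried along
rigidly by the same transform.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

from .seqsearch import AlignmentResult, align_pair, sequence_identity
from .structures import ComplexStructure, SubunitDefinition, transform_structure

__all__ = [
    "ChainCorrespondence",
    "RigidTransform",
    "HomologDecision",
    "match_chains",
    "kabsch_superpose",
    "superpose_complex",
    "filter_homolog",
    "DEFAULT_IDENTITY_CUTOFF",
    "DEFAULT_RMSD_CUTOFF",
]

DEFAULT_IDENTITY_CUTOFF = 0.90
DEFAULT_RMSD_CUTOFF = 6.0  # Angstroms


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation matrix must be proper (det = +1)")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix must be orthogonal")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class ChainCorrespondence:
    """One-to-one mapping of user chains onto subject chains."""

    pairs: dict[str, tuple[str, AlignmentResult]]
    unmatched_subject_chains: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        subject_ids = [sid for sid, _ in self.pairs.values()]
        if len(subject_ids) != len(set(subject_ids)):
            raise ValueError("chain correspondence must be injective")

    @property
    def identities(self) -> dict[str, float]:
        return {
            user: sequence_identity(aln) for user, (_, aln) in self.pairs.items()
        }

    def subject_chain(self, user_chain: str) -> str:
        return self.pairs[user_chain][0]

    def alignment(self, user_chain: str) -> AlignmentResult:
        return self.pairs[user_chain][1]


@dataclass
class HomologDecision:
    """Audit record of one candidate's path through the filter cascade."""

    structure_id: str
    stage_reached: str  # chain_check | identity_check | rmsd_check | accepted
    per_chain_identity: dict[str, float] = field(default_factory=dict)
    rmsd: Optional[float] = None
    accepted: bool = False
    reason: str = ""

    def as_row(self) -> dict:
        return {
            "structure_id": self.structure_id,
            "stage_reached": self.stage_reached,
            "accepted": self.accepted,
            "rmsd": "" if self.rmsd is None else round(self.rmsd, 4),
            "per_chain_identity": ";".join(
                f"{k}:{v:.4f}" for k, v in sorted(self.per_chain_identity.items())
            ),
            "reason": self.reason,
        }


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rigid transform minimising the RMSD between the
    transformed mobile points and the reference points, and that minimum
    RMSD in the units of the input coordinates.  Reflections are excluded
    by sign-correcting the smallest singular direction, so the result is a
    physical rotation even for near-planar point sets.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points for superposition, got {n}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # degenerate (collinear) sets leave the rotation under-determined
    for label, X in (("mobile", P0), ("reference", Q0)):
        sv = np.linalg.svd(X, compute_uv=False)
        if sv[1] <= 1e-8 * max(sv[0], 1.0):
            raise ValueError(f"{label} points are collinear; superposition is degenerate")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    transform = RigidTransform(R, t)
    moved = transform.apply(P)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return transform, rmsd


# ---------------------------------------------------------------------------
# Chain correspondence
# ---------------------------------------------------------------------------


def _identity_matrix(
    query: ComplexStructure,
    user_chains: tuple[str, ...],
    subject: ComplexStructure,
) -> tuple[np.ndarray, dict[tuple[int, int], AlignmentResult]]:
    m, n = len(user_chains), len(subject.chains)
    ident = np.zeros((m, n))
    alns: dict[tuple[int, int], AlignmentResult] = {}
    for i, uc in enumerate(user_chains):
        useq = query.chain(uc).sequence
        for j, sc in enumerate(subject.chains):
            if not sc.residues:
                continue
            aln = align_pair(useq, sc.sequence)
            alns[(i, j)] = aln
            ident[i, j] = sequence_identity(aln)
    return ident, alns


def _pooled_rmsd_for(
    query: ComplexStructure,
    subject: ComplexStructure,
    user_chains: tuple[str, ...],
    assignment: tuple[int, ...],
    alns: dict[tuple[int, int], AlignmentResult],
) -> float:
    corr = ChainCorrespondence(
        pairs={
            uc: (subject.chains[j].chain_id, alns[(i, j)])
            for i, (uc, j) in enumerate(zip(user_chains, assignment))
        }
    )
    mob, ref = _pooled_ca_pairs(query, subject, corr)
    if len(mob) < 3:
        return float("inf")
    _, rmsd = kabsch_superpose(np.array(mob), np.array(ref))
    return rmsd


def match_chains(
    query: ComplexStructure,
    subunits: SubunitDefinition,
    subject: ComplexStructure,
    identity_cutoff: float = 0.0,
) -> Optional[ChainCorrespondence]:
    """Assign every user chain a distinct subject chain, or reject.

    The assignment maximises total sequence identity over the bipartite
    user-chain x subject-chain identity matrix.  For homo-oligomers, ties
    on total identity are broken by the smaller pooled superposition RMSD,
    then by lexicographic subject chain ID.  Returns ``None`` when no
    complete one-to-one assignment exists or when any assigned chain falls
    below ``identity_cutoff``.
    """
    user_chains = subunits.all_chains
    m, n = len(user_chains), len(subject.chains)
    if n < m:
        return None
    ident, alns = _identity_matrix(query, user_chains, subject)

    candidates: list[tuple[int, ...]]
    if n <= 8 and m <= 5:
        # enumerate all injective assignments so tie-breaks are exact
        best_total = -1.0
        ties: list[tuple[int, ...]] = []
        for perm in itertools.permutations(range(n), m):
            total = sum(ident[i, j] for i, j in enumerate(perm))
            if total > best_total + 1e-12:
                best_total, ties = total, [perm]
            elif abs(total - best_total) <= 1e-12:
                ties.append(perm)
        candidates = ties
    else:
        row, col = linear_sum_assignment(-ident)
        candidates = [tuple(col[np.argsort(row)])]

    if len(candidates) > 1:
        scored = []
        for perm in candidates:
            rmsd = _pooled_rmsd_for(query, subject, user_chains, perm, alns)
            ids = tuple(subject.chains[j].chain_id for j in perm)
            scored.append((round(rmsd, 9), ids, perm))
        scored.sort()
        best = scored[0][2]
    else:
        best = candidates[0]

    corr = ChainCorrespondence(
        pairs={
            uc: (subject.chains[j].chain_id, alns[(i, j)])
            for i, (uc, j) in enumerate(zip(user_chains, best))
        },
        unmatched_subject_chains=[
            subject.chains[j].chain_id for j in range(n) if j not in best
        ],
    )
    if identity_cutoff > 0 and any(
        v < identity_cutoff for v in corr.identities.values()
    ):
        return None
    return corr


# ---------------------------------------------------------------------------
# Complex superposition
# ---------------------------------------------------------------------------


def _pooled_ca_pairs(
    query: ComplexStructure,
    subject: ComplexStructure,
    correspondence: ChainCorrespondence,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Calpha coordinate pairs over aligned residues, pooled across chains.

    Gapped positions contribute nothing; residues lacking a Calpha atom are
    skipped (tolerates incompletely modelled residues).
    """
    mobile: list[np.ndarray] = []
    reference: list[np.ndarray] = []
    for user_chain, (subject_chain_id, aln) in correspondence.pairs.items():
        q_res = query.chain(user_chain).residues
        s_res = subject.chain(subject_chain_id).residues
        for qi, si in aln.aligned_pairs:
            q_ca = q_res[qi].ca
            s_ca = s_res[si].ca
            if q_ca is None or s_ca is None:
                continue
            reference.append(q_ca.position)
            mobile.append(s_ca.position)
    return mobile, reference


def superpose_complex(
    query: ComplexStructure,
    subunits: SubunitDefinition,
    subject: ComplexStructure,
    correspondence: ChainCorrespondence,
) -> tuple[ComplexStructure, float]:
    """One global rigid fit of the whole subject complex onto the query.

    Superposition points are the pooled Calpha pairs across ALL
    corresponding chains; the resulting single transform moves the entire
    subject, extraneous chains included.
    """
    mobile, reference = _pooled_ca_pairs(query, subject, correspondence)
    if len(mobile) < 3:
        raise ValueError(
            f"only {len(mobile)} pooled Calpha pairs; cannot superpose"
        )
    transform, rmsd = kabsch_superpose(np.array(mobile), np.array(reference))
    moved = transform_structure(subject, transform.rotation, transform.translation)
    return moved, rmsd


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------


def filter_homolog(
    query: ComplexStructure,
    subunits: SubunitDefinition,
    candidate: ComplexStructure,
    identity_cutoff: float = DEFAULT_IDENTITY_CUTOFF,
    rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF,
) -> HomologDecision:
    """Run the three checks on one candidate and record the outcome.

    The decision records the first failing stage, or acceptance with the
    per-chain identities and the complex RMSD.  Structural failures are
    captured as failed decisions, never raised.
    """
    sid = candidate.structure_id
    try:
        corr = match_chains(query, subunits, candidate, identity_cutoff=0.0)
        if corr is None:
            return HomologDecision(
                structure_id=sid,
                stage_reached="chain_check",
                reason="no complete one-to-one chain assignment",
            )
        identities = corr.identities
        low = {c: v for c, v in identities.items() if v < identity_cutoff}
        if low:
            return HomologDecision(
                structure_id=sid,
                stage_reached="identity_check",
                per_chain_identity=identities,
                reason=(
                    "identity below cutoff for "
                    + ",".join(f"{c} ({v:.2f})" for c, v in sorted(low.items()))
                ),
            )
        _, rmsd = superpose_complex(query, subunits, candidate, corr)
        if rmsd > rmsd_cutoff:
            return HomologDecision(
                structure_id=sid,
                stage_reached="rmsd_check",
                per_chain_identity=identities,
                rmsd=rmsd,
                reason=f"RMSD {rmsd:.2f} A exceeds {rmsd_cutoff:.1f} A",
            )
        return HomologDecision(
            structure_id=sid,
            stage_reached="accepted",
            per_chain_identity=identities,
            rmsd=rmsd,
            accepted=True,
        )
    except (ValueError, KeyError) as exc:
        return HomologDecision(
            structure_id=sid,
            stage_reached="chain_check",
            reason=f"structural failure: {exc}",
        )
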