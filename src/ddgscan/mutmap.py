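"""Mutation strings and their translation into homolog numbering.

Grammar: semicolon-separated tokens ``<wt><chain><number>[icode]<mut>``,
e.g. ``EA63Q`` (Glu 63 of chain A to Gln) or ``EA63Q;KB14A`` for two
simultaneous substitutions.  One to four substitutions per specification.

Different PDB entries of the same complex frequently number equivalent
residues differently (offsets, insertion codes, missing termini).  The
positions the user gives are in the query's numbering; for every accepted
homolog they are mapped through the chain-correspondence alignment onto
that homolog's own author numbering.  A homolog in which a mutated site is
unresolved (aligned to a gap), or in which the residue at the mapped site
is not the stated wild type, cannot host the requested mutation and is
skipped with a recorded status.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .matcher import ChainCorrespondence
from .structures import ComplexStructure

__all__ = [
    "Substitution",
    "MutationSpec",
    "parse_mutation",
    "translate_mutation",
    "UnmappableSubstitutionError",
    "WildTypeMismatchError",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")
_TOKEN = re.compile(
    r"^(?P<wt>[A-Za-z])(?P<chain>[A-Za-z0-9])(?P<number>\d+)"
    r"(?P<icode>[A-Za-z]?)(?P<mut>[A-Za-z])$"
)


class UnmappableSubstitutionError(ValueError):
    """The mutated site aligns to a gap (unresolved) in the subject."""


class WildTypeMismatchError(ValueError):
    """The subject's residue at the mapped site is not the stated wild type."""


@dataclass(frozen=True)
class Substitution:
    chain_id: str
    wt_aa: str
    number: int
    icode: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa not in _AA or self.mut_aa not in _AA:
            raise ValueError(
                f"{self.token()}: wild-type and mutant must be canonical amino acids"
            )
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"{self.token()}: silent substitution (wt == mutant)")

    def token(self) -> str:
        return f"{self.wt_aa}{self.chain_id}{self.number}{self.icode}{self.mut_aa}"

    def site(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)


@dataclass(frozen=True)
class MutationSpec:
    substitutions: tuple[Substitution, ...]
    context_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.substitutions)
        if not 1 <= n <= 4:
            raise ValueError(f"need 1-4 simultaneous substitutions, got {n}")
        sites = [s.site() for s in self.substitutions]
        if len(sites) != len(set(sites)):
            raise ValueError("duplicate substitution site")

    def text(self) -> str:
        return ";".join(s.token() for s in self.substitutions)

    def canonical(self) -> str:
        """Order-independent form, for cache keys."""
        return ";".join(sorted(s.token() for s in self.substitutions))

    @property
    def chain_ids(self) -> set[str]:
        return {s.chain_id for s in self.substitutions}


def parse_mutation(text: str, context_id: str = "") -> MutationSpec:
    """Parse a mutation string into a validated :class:`MutationSpec`."""
    tokens = [t.strip() for t in text.split(";") if t.strip()]
    if not tokens:
        raise ValueError("empty mutation string")
    if len(tokens) > 4:
        raise ValueError(
            f"{len(tokens)} substitutions given; at most 4 simultaneous "
            "substitutions are supported"
        )
    subs = []
    for tok in tokens:
        m = _TOKEN.match(tok)
        if m is None:
            raise ValueError(
                f"malformed mutation token {tok!r} "
                "(expected <wt><chain><number>[icode]<mut>, e.g. EA63Q)"
            )
        subs.append(
            Substitution(
                chain_id=m.group("chain"),
                wt_aa=m.group("wt").upper(),
                number=int(m.group("number")),
                icode=m.group("icode").upper(),
                mut_aa=m.group("mut").upper(),
            )
        )
    return MutationSpec(substitutions=tuple(subs), context_id=context_id)


def _residue_index(chain, number: int, icode: str) -> int:
    for i, r in enumerate(chain.residues):
        if r.number == number and r.icode == icode:
            return i
    raise UnmappableSubstitutionError(
        f"residue {number}{icode} not resolved in chain {chain.chain_id}"
    )


def translate_mutation(
    spec: MutationSpec,
    correspondence: ChainCorrespondence,
    query: ComplexStructure,
    subject: ComplexStructure,
) -> MutationSpec:
    """Re-express a mutation in the subject structure's numbering.

    Each substitution's (chain, number, icode) is located in the query,
    mapped through the aligned residue pairs, and re-labelled with the
    subject's chain ID and author numbering.  The amino-acid identities are
    never altered.  Raises :class:`UnmappableSubstitutionError` when a site
    is unresolved or gapped in the subject, and
    :class:`WildTypeMismatchError` when the subject carries a different
    residue at the mapped site.
    """
    out = []
    for sub in spec.substitutions:
        if sub.chain_id not in correspondence.pairs:
            raise UnmappableSubstitutionError(
                f"{sub.token()}: chain {sub.chain_id} has no counterpart in "
                f"{subject.structure_id}"
            )
        subject_chain_id, aln = correspondence.pairs[sub.chain_id]
        q_chain = query.chain(sub.chain_id)
        s_chain = subject.chain(subject_chain_id)
        qi = _residue_index(q_chain, sub.number, sub.icode)
        if q_chain.residues[qi].one_letter != sub.wt_aa:
            raise WildTypeMismatchError(
                f"{sub.token()}: query residue at {sub.number}{sub.icode} is "
                f"{q_chain.residues[qi].one_letter}, not {sub.wt_aa}"
            )
        si = aln.subject_index(qi)
        if si is None:
            raise UnmappableSubstitutionError(
                f"{sub.token()}: position aligns to a gap in "
                f"{subject.structure_id} chain {subject_chain_id}"
            )
        s_res = s_chain.residues[si]
        if s_res.one_letter != sub.wt_aa:
            raise WildTypeMismatchError(
                f"{sub.token()}: {subject.structure_id} chain "
                f"{subject_chain_id} has {s_res.one_letter} at {s_res.label}, "
                f"not {sub.wt_aa}"
            )
        out.append(
            Substitution(
                chain_id=subject_chain_id,
                wt_aa=sub.wt_aa,
                number=s_res.number,
                icode=s_res.icode,
                mut_aa=sub.mut_aa,
            )
        )
    return MutationSpec(substitutions=tuple(out), context_id=subject.structure_id)
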