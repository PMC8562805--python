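"""Pluggable per-structure ddG evaluation, caching, and Kd conversion.

The pipeline treats the energy function as a black box satisfying the
:class:`DdgBackend` contract: given a structure, a subunit partition, and a
mutation in that structure's numbering, return a binding ddG in kcal/mol,
deterministically.  Three backends ship:

``surrogate``
    A deterministic contact-hydropathy score used throughout the test
    fixtures.  It is NOT a physical potential — it exists so that every
    pipeline stage can be exercised end to end with reproducible numbers.
``table``
    Lookup of precomputed per-structure ddG values from a CSV, for users
    who run their own energy program offline.
``external``
    Adapter that shells out to a user-supplied binary (e.g. an empirical
    force-field program) and parses a tabular ddG from its output; never
    required by the tests.

Every successful evaluation is cached persistently under
(structure, subunits, canonicalised mutation, backend name), so repeated
pipeline runs never re-evaluate.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from math import exp
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .cache import JsonFileCache, NullCache
from .mutmap import MutationSpec
from .structures import ComplexStructure, SubunitDefinition

__all__ = [
    "DdgResult",
    "DdgBackend",
    "SurrogateBackend",
    "TableBackend",
    "ExternalBinaryBackend",
    "compute_ddg",
    "surrogate_ddg",
    "table_backend",
    "kd_from_dg",
    "KYTE_DOOLITTLE",
    "GAS_CONSTANT_KCAL",
]

#: gas constant in kcal / (mol K)
GAS_CONSTANT_KCAL = 1.987e-3

#: Kyte-Doolittle hydropathy index per amino acid
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: surrogate weight, kcal/mol per (contact x hydropathy unit)
SURROGATE_WEIGHT = 0.05
#: heavy-atom contact radius for the surrogate, Angstroms
SURROGATE_CONTACT_RADIUS = 6.0


@dataclass
class DdgResult:
    structure_id: str
    mutation: Optional[MutationSpec]  # in the structure's own numbering
    ddg: Optional[float]  # kcal/mol, present iff status == "ok"
    backend: str
    status: str  # ok | failed | skipped_unmappable | skipped_wt_mismatch
    detail: str = ""

    def __post_init__(self) -> None:
        if (self.status == "ok") != (self.ddg is not None):
            raise ValueError("ddg must be present exactly when status is ok")
        if self.ddg is not None and not np.isfinite(self.ddg):
            raise ValueError("ddg must be finite")


class DdgBackend:
    """Contract: a named, deterministic per-structure ddG evaluator."""

    name: str = "abstract"

    def evaluate(
        self,
        structure: ComplexStructure,
        subunits: SubunitDefinition,
        mutation: MutationSpec,
    ) -> float:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# Surrogate backend
# ---------------------------------------------------------------------------


def _count_cross_contacts(
    structure: ComplexStructure,
    subunits: SubunitDefinition,
    chain_id: str,
    number: int,
    icode: str,
) -> int:
    """Heavy atoms of the OTHER subunit within the contact radius of any
    atom of the named residue."""
    side = subunits.side_of(chain_id)
    other = subunits.subunit2 if side == 1 else subunits.subunit1
    chain = structure.chain(chain_id)
    res = next(
        (r for r in chain.residues if r.number == number and r.icode == icode),
        None,
    )
    if res is None:
        raise ValueError(
            f"residue {number}{icode} absent from chain {chain_id} of "
            f"{structure.structure_id}"
        )
    res_xyz = np.array([a.position for a in res.atoms if a.element != "H"])
    count = 0
    for other_chain_id in other:
        try:
            other_chain = structure.chain(other_chain_id)
        except KeyError:
            continue
        for r in other_chain.residues:
            for a in r.atoms:
                if a.element == "H":
                    continue
                d2 = np.sum((res_xyz - a.position) ** 2, axis=1)
                if np.any(d2 <= SURROGATE_CONTACT_RADIUS**2):
                    count += 1
    return count


def surrogate_ddg(
    structure: ComplexStructure,
    subunits: SubunitDefinition,
    mutation: MutationSpec,
) -> float:
    """Deterministic contact-hydropathy surrogate score (kcal/mol).

    Sum over substitutions of ``w * C * (h(wt) - h(mut))`` where ``C`` is
    the number of heavy atoms of the opposite subunit within 6 A of any
    atom of the mutated residue, ``h`` the Kyte-Doolittle hydropathy, and
    ``w`` = 0.05 kcal/mol per contact per hydropathy unit.  A mutation with
    no cross-interface contacts scores exactly 0.  Invariant under rigid
    motion of the whole complex.  Not a physical potential.
    """
    total = 0.0
    for sub in mutation.substitutions:
        c = _count_cross_contacts(
            structure, subunits, sub.chain_id, sub.number, sub.icode
        )
        total += SURROGATE_WEIGHT * c * (
            KYTE_DOOLITTLE[sub.wt_aa] - KYTE_DOOLITTLE[sub.mut_aa]
        )
    return total


class SurrogateBackend(DdgBackend):
    name = "surrogate"

    def evaluate(self, structure, subunits, mutation):
        return surrogate_ddg(structure, subunits, mutation)


# ---------------------------------------------------------------------------
# Table backend
# ---------------------------------------------------------------------------


class TableBackend(DdgBackend):
    """Lookup backend over a CSV of precomputed per-structure ddG values.

    Required columns: ``structure_id``, ``mutation``, ``ddg``.  Mutation
    strings are canonicalised (token order ignored).  Duplicate keys with
    conflicting values are an integrity error at load time.
    """

    def __init__(self, csv_path: str | Path):
        self.name = f"table:{csv_path}"
        try:
            # round_trip parsing: reloaded ddG values must equal the
            # exported ones bit for bit
            df = pd.read_csv(
                csv_path,
                dtype={"structure_id": str, "mutation": str},
                float_precision="round_trip",
            )
        except (pd.errors.ParserError, OSError, ValueError) as exc:
            raise ValueError(f"cannot read ddG table {csv_path}: {exc}") from exc
        missing = {"structure_id", "mutation", "ddg"} - set(df.columns)
        if missing:
            raise ValueError(f"{csv_path}: missing columns {sorted(missing)}")
        self._table: dict[tuple[str, str], float] = {}
        from .mutmap import parse_mutation

        for i, row in df.iterrows():
            try:
                canon = parse_mutation(str(row["mutation"])).canonical()
                ddg = float(row["ddg"])
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{csv_path} row {i + 2}: {exc}") from exc
            key = (str(row["structure_id"]), canon)
            if key in self._table and self._table[key] != ddg:
                raise ValueError(
                    f"{csv_path} row {i + 2}: duplicate key {key} with "
                    f"conflicting ddg values"
                )
            self._table[key] = ddg

    def evaluate(self, structure, subunits, mutation):
        key = (structure.structure_id, mutation.canonical())
        if key not in self._table:
            raise KeyError(f"no ddG entry for {key}")
        return self._table[key]


def table_backend(csv_path: str | Path) -> TableBackend:
    return TableBackend(csv_path)


# ---------------------------------------------------------------------------
# External binary adapter (optional; never required by tests)
# ---------------------------------------------------------------------------


class ExternalBinaryBackend(DdgBackend):
    """Shell out to a user-supplied ddG program.

    The binary is invoked as ``<binary> <structure.pdb> <mutation-string>
    [extra args...]`` and must print a ddG value (kcal/mol) as the last
    whitespace-separated token of its last non-empty stdout line.  Run
    parameters of the wrapped program (number of runs, pH, ionic strength,
    ...) are passed through verbatim via ``extra_args``.
    """

    def __init__(self, binary: str, extra_args: tuple[str, ...] = ()):
        if shutil.which(binary) is None and not Path(binary).exists():
            raise FileNotFoundError(f"ddG binary not found: {binary}")
        self.binary = binary
        self.extra_args = tuple(extra_args)
        self.name = f"external:{Path(binary).name}"

    def evaluate(self, structure, subunits, mutation):
        from .structures import write_structure
        import tempfile

        with tempfile.TemporaryDirectory() as tmp:
            pdb = Path(tmp) / f"{structure.structure_id}.pdb"
            write_structure(structure, pdb, format="pdb")
            proc = subprocess.run(
                [self.binary, str(pdb), mutation.text(), *self.extra_args],
                capture_output=True,
                text=True,
                check=True,
            )
        lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
        if not lines:
            raise RuntimeError(f"{self.binary}: no output")
        return float(lines[-1].split()[-1])


# ---------------------------------------------------------------------------
# Cached evaluation
# ---------------------------------------------------------------------------


def compute_ddg(
    structure: ComplexStructure,
    subunits: SubunitDefinition,
    mutation: MutationSpec,
    backend: DdgBackend,
    cache: JsonFileCache | None = None,
) -> DdgResult:
    """Evaluate one structure's ddG through the cache.

    The cache key is (structure, subunit partition, canonicalised mutation,
    backend name), so each evaluation happens once ever per cache file.
    Backend failures are captured as a ``failed`` result, never raised, so
    one bad homolog cannot abort the ensemble.
    """
    cache = cache if cache is not None else NullCache()
    key = "|".join(
        [structure.structure_id, subunits.key(), mutation.canonical(), backend.name]
    )
    cached = cache.get(key)
    if cached is not None:
        return DdgResult(
            structure_id=structure.structure_id,
            mutation=mutation,
            ddg=cached["ddg"],
            backend=backend.name,
            status="ok",
        )
    try:
        value = float(backend.evaluate(structure, subunits, mutation))
        if not np.isfinite(value):
            raise ValueError(f"backend returned non-finite ddG {value}")
    except Exception as exc:  # backend failures must not abort the ensemble
        return DdgResult(
            structure_id=structure.structure_id,
            mutation=mutation,
            ddg=None,
            backend=backend.name,
            status="failed",
            detail=str(exc),
        )
    cache.put(key, {"ddg": value})
    return DdgResult(
        structure_id=structure.structure_id,
        mutation=mutation,
        ddg=value,
        backend=backend.name,
        status="ok",
    )


def kd_from_dg(dg: float, temperature: float = 298.0) -> float:
    """Equilibrium dissociation constant Kd = exp(dG / RT).

    ``dg`` in kcal/mol, ``temperature`` in Kelvin (default 298 K),
    R = 1.987e-3 kcal/(mol K).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (Kelvin)")
    return exp(dg / (GAS_CONSTANT_KCAL * temperature))
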