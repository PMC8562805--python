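"""Synthetic complexes and ddG observation sets with known ground truth.

Real inputs to this pipeline are crystallographic entries that differ from
one another by rigid placement, sub-Angstrom coordinate shifts, point
mutations, renumbering conventions, insertion codes, extra or missing
chains, and occasionally a different quaternary arrangement.  This module
manufactures exactly those situations from scratch, with a seed, so the
whole filter-translate-evaluate-average pipeline can be exercised and the
expected outcome of every stage is known by construction.

Toy complexes are idealized poly-alanine-like backbones (N, CA, C, O, CB
per residue) laid out as extended strands with the two subunits in van der
Waals contact.  They are geometrically sane for alignment, contact and
superposition logic, but are not physically realistic proteins.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .evalstats import BenchmarkRecord
from .structures import (
    AtomRecord,
    Chain,
    ComplexStructure,
    Residue,
    SubunitDefinition,
    write_structure,
)

__all__ = [
    "FixtureRecipe",
    "Perturbation",
    "make_toy_complex",
    "derive_homolog",
    "simulate_ddg_observations",
    "write_fixture_battery",
    "STANDARD_BATTERY",
]

# 19-letter alphabet: every generated residue carries a CB atom, so glycine
# is excluded from random sequences
_ALPHABET = "ACDEFHIKLMNPQRSTVWY"

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: spacing of consecutive residues along the strand axis, Angstroms
_RESIDUE_SPACING = 3.8
#: gap between the two subunits' facing chains, Angstroms
_INTERFACE_GAP = 4.6
#: spacing of additional chains within one subunit, Angstroms
_INTRA_SUBUNIT_SPACING = 9.0

# atom offsets (x, y, z) from the CA base point of each residue
_ATOM_OFFSETS = {
    "N": (-1.2, 0.3, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "C": (1.2, 0.4, 0.0),
    "O": (1.3, 1.6, 0.0),
    "CB": (0.0, -0.8, 1.2),
}
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


@dataclass(frozen=True)
class FixtureRecipe:
    """Blueprint for a toy two-subunit complex."""

    n_chains_subunit1: int = 1
    n_chains_subunit2: int = 1
    residues_per_chain: int = 50
    seed: int = 0
    structure_id: str = "query"

    def __post_init__(self) -> None:
        if self.n_chains_subunit1 < 1 or self.n_chains_subunit2 < 1:
            raise ValueError("each subunit needs at least one chain")
        if self.residues_per_chain < 5:
            raise ValueError("chains shorter than 5 residues are not useful fixtures")

    def subunits(self) -> SubunitDefinition:
        n1 = self.n_chains_subunit1
        ids = [chr(ord("A") + i) for i in range(n1 + self.n_chains_subunit2)]
        return SubunitDefinition(ids[:n1], ids[n1:])


@dataclass(frozen=True)
class Perturbation:
    """What to do to a base complex to manufacture a near-redundant variant.

    All fields default to 'no change'; combine freely.  ``drop_chains``
    removes chains outright; ``displace_subunit2`` translates the second
    subunit rigidly (a wrong quaternary arrangement); ``delete_residues``
    removes individual residues (emulating unresolved sites);
    ``mutate_sites`` forces substitutions at specific sites.
    """

    rigid: bool = False
    rigid_translation_scale: float = 15.0  # Angstroms
    noise_sigma: float = 0.0  # Angstroms, per coordinate
    mutation_fraction: float = 0.0
    renumber_offset: int = 0
    icode_insertions: int = 0
    drop_chains: tuple[str, ...] = ()
    displace_subunit2: float = 0.0  # Angstroms
    delete_residues: tuple[tuple[str, int], ...] = ()  # (chain, author number)
    mutate_sites: tuple[tuple[str, int], ...] = ()  # forced point mutations

    def expected_stage(
        self, identity_cutoff: float = 0.90, rmsd_cutoff: float = 6.0
    ) -> str:
        """Filter stage this variant is expected to reach, by construction.

        Dropping any required chain fails the chain check.  A mutated
        fraction f leaves identity ~= 1 - f.  Displacing one of two
        subunits by d leaves a best-fit RMSD of roughly d/2 (each half
        ends up ~d/2 from its counterpart), so d substantially above
        2 * rmsd_cutoff must fail the RMSD check.
        """
        if self.drop_chains:
            return "chain_check"
        if 1.0 - self.mutation_fraction < identity_cutoff:
            return "identity_check"
        if self.displace_subunit2 / 2.0 > rmsd_cutoff + 2.0:
            return "rmsd_check"
        return "accepted"


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_ALPHABET), size=length))


def _build_residue(one_letter: str, number: int, icode: str, base: np.ndarray) -> Residue:
    atoms = [
        AtomRecord(
            name=name,
            element=_ELEMENTS[name],
            position=base + np.array(off),
        )
        for name, off in _ATOM_OFFSETS.items()
    ]
    return Residue(
        number=number, icode=icode, resname=_ONE_TO_THREE[one_letter], atoms=atoms
    )


def _build_chain(chain_id: str, sequence: str, y0: float, z0: float) -> Chain:
    residues = []
    for i, aa in enumerate(sequence):
        # small deterministic zigzag keeps CA traces non-collinear
        base = np.array(
            [i * _RESIDUE_SPACING, y0, z0 + 0.6 * np.sin(1.7 * i)]
        )
        residues.append(_build_residue(aa, i + 1, "", base))
    return Chain(chain_id=chain_id, residues=residues)


def make_toy_complex(recipe: FixtureRecipe) -> ComplexStructure:
    """Build a deterministic two-subunit complex from a recipe.

    Subunit 1 chains sit at y = 0, +9, +18, ...; subunit 2 chains at
    y = -4.6, -13.6, ... so the two facing chains share an interface with
    well over 20 inter-subunit atom pairs within 6 A.
    """
    rng = np.random.default_rng(recipe.seed)
    subunits = recipe.subunits()
    chains = []
    for k, cid in enumerate(subunits.subunit1):
        seq = _random_sequence(rng, recipe.residues_per_chain)
        chains.append(_build_chain(cid, seq, y0=k * _INTRA_SUBUNIT_SPACING, z0=0.0))
    for k, cid in enumerate(subunits.subunit2):
        seq = _random_sequence(rng, recipe.residues_per_chain)
        chains.append(
            _build_chain(
                cid, seq, y0=-_INTERFACE_GAP - k * _INTRA_SUBUNIT_SPACING, z0=0.0
            )
        )
    return ComplexStructure(
        structure_id=recipe.structure_id, chains=chains, source_path="<generated>"
    )


def derive_homolog(
    base: ComplexStructure,
    perturbation: Perturbation,
    seed: int,
    subunits: SubunitDefinition | None = None,
    structure_id: str | None = None,
) -> tuple[ComplexStructure, dict]:
    """Apply perturbations to a base complex; return variant + ground truth.

    The metadata dictionary records the perturbation parameters and the
    filter stage the variant is expected to reach at default cutoffs.
    """
    rng = np.random.default_rng(seed)
    pert = perturbation
    if pert.drop_chains and set(pert.drop_chains) >= {c.chain_id for c in base.chains}:
        raise ValueError("cannot drop every chain")

    new_chains: list[Chain] = []
    mutated_sites: list[str] = []
    for chain in base.chains:
        if chain.chain_id in pert.drop_chains:
            continue
        residues = [
            Residue(
                r.number,
                r.icode,
                r.resname,
                [AtomRecord(a.name, a.element, a.position.copy()) for a in r.atoms],
                r.is_canonical,
            )
            for r in chain.residues
            if (chain.chain_id, r.number) not in pert.delete_residues
        ]
        # sequence mutations: a spread-out fraction of positions
        if pert.mutation_fraction > 0:
            n_mut = int(round(pert.mutation_fraction * len(residues)))
            idx = rng.choice(len(residues), size=n_mut, replace=False)
            for i in sorted(idx):
                old = residues[i].one_letter
                choices = [a for a in _ALPHABET if a != old]
                new = rng.choice(choices)
                residues[i] = dataclasses.replace(
                    residues[i], resname=_ONE_TO_THREE[new]
                )
                mutated_sites.append(f"{chain.chain_id}{residues[i].label}")
        for cid, number in pert.mutate_sites:
            if cid != chain.chain_id:
                continue
            for i, r in enumerate(residues):
                if r.number == number and r.icode == "":
                    old = r.one_letter
                    new = next(a for a in _ALPHABET if a != old)
                    residues[i] = dataclasses.replace(r, resname=_ONE_TO_THREE[new])
                    mutated_sites.append(f"{chain.chain_id}{r.label}")
        # insertion-coded residues duplicated near the chain middle
        if pert.icode_insertions > 0:
            mid = len(residues) // 2
            inserted = []
            for k in range(pert.icode_insertions):
                template = residues[mid + k]
                extra = Residue(
                    number=template.number,
                    icode=chr(ord("A") + k),
                    resname=_ONE_TO_THREE[_random_sequence(rng, 1)],
                    atoms=[
                        AtomRecord(a.name, a.element, a.position + np.array([0.0, 0.0, 2.5]))
                        for a in template.atoms
                    ],
                )
                inserted.append(extra)
            residues = residues[: mid + 1] + inserted + residues[mid + 1 :]
        if pert.renumber_offset:
            residues = [
                dataclasses.replace(r, number=r.number + pert.renumber_offset)
                for r in residues
            ]
        new_chains.append(Chain(chain.chain_id, residues))

    variant = ComplexStructure(
        structure_id=structure_id or f"{base.structure_id}_variant",
        chains=new_chains,
        source_path="<derived>",
    )

    # geometric perturbations
    if pert.displace_subunit2 > 0:
        if subunits is None:
            raise ValueError("displace_subunit2 requires the subunit definition")
        shift = np.array([0.0, -pert.displace_subunit2, 0.0])
        for chain in variant.chains:
            if chain.chain_id in subunits.subunit2:
                for r in chain.residues:
                    for a in r.atoms:
                        a.position = a.position + shift
    if pert.noise_sigma > 0:
        for chain in variant.chains:
            for r in chain.residues:
                for a in r.atoms:
                    a.position = a.position + rng.normal(0, pert.noise_sigma, 3)
    if pert.rigid:
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(0, pert.rigid_translation_scale, 3)
        for chain in variant.chains:
            for r in chain.residues:
                for a in r.atoms:
                    a.position = R @ a.position + t

    metadata = {
        "structure_id": variant.structure_id,
        "base_id": base.structure_id,
        "seed": seed,
        "perturbation": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(pert).items()
        },
        "expected_stage": pert.expected_stage(),
        "expected_accepted": pert.expected_stage() == "accepted",
        "mutated_sites": mutated_sites,
    }
    return variant, metadata


# ---------------------------------------------------------------------------
# The standard battery
# ---------------------------------------------------------------------------

#: named perturbations covering every designed defect the filter must catch
STANDARD_BATTERY: dict[str, Perturbation] = {
    "copy": Perturbation(),
    "rigid": Perturbation(rigid=True),
    "noise05": Perturbation(noise_sigma=0.5),
    "rigid_noise02": Perturbation(rigid=True, noise_sigma=0.2),
    "mut05": Perturbation(mutation_fraction=0.05),
    "mut15": Perturbation(mutation_fraction=0.15),
    "mut30": Perturbation(mutation_fraction=0.30),
    "renum5": Perturbation(renumber_offset=5),
    "renum5_rigid": Perturbation(renumber_offset=5, rigid=True),
    "icode2": Perturbation(icode_insertions=2),
    "dropB": Perturbation(drop_chains=("B",)),
    "displaced20": Perturbation(displace_subunit2=20.0),
    "displaced30_rigid": Perturbation(displace_subunit2=30.0, rigid=True),
    "combo": Perturbation(
        mutation_fraction=0.05, renumber_offset=5, noise_sigma=0.2, rigid=True
    ),
}


def write_fixture_battery(
    directory: str | Path,
    recipe: FixtureRecipe | None = None,
    battery: dict[str, Perturbation] | None = None,
    seed: int = 0,
) -> list[dict]:
    """Write the query plus a battery of variants as PDB files + sidecars.

    Each variant gets a JSON sidecar recording its perturbation and the
    filter stage it must reach.  Returns the manifest (list of metadata
    dicts, query first).  Byte-identical for a fixed seed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    recipe = recipe or FixtureRecipe(seed=seed)
    battery = battery if battery is not None else STANDARD_BATTERY
    query = make_toy_complex(recipe)
    subunits = recipe.subunits()
    write_structure(query, directory / f"{query.structure_id}.pdb", format="pdb")
    manifest = [
        {
            "structure_id": query.structure_id,
            "base_id": query.structure_id,
            "expected_stage": "accepted",
            "expected_accepted": True,
            "is_query": True,
        }
    ]
    for i, (name, pert) in enumerate(sorted(battery.items())):
        variant, meta = derive_homolog(
            query,
            pert,
            seed=seed + 1000 + i,
            subunits=subunits,
            structure_id=name,
        )
        write_structure(variant, directory / f"{name}.pdb", format="pdb")
        with open(directory / f"{name}.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
        manifest.append(meta)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# ddG observation simulator
# ---------------------------------------------------------------------------


def simulate_ddg_observations(
    sigma_single: float,
    sigma_systematic: float,
    n_structures: int,
    n_mutants: int,
    seed: int,
    true_ddg: np.ndarray | None = None,
    true_sd: float = 1.5,
) -> list[BenchmarkRecord]:
    """Simulate per-structure ddG predictions under the two-component
    error model.

    Per mutant, a systematic offset ~ Normal(0, sigma_systematic) is shared
    by all its structures; each structure adds independent
    Normal(0, sigma_single) noise.  The experimental value equals the true
    value, so all prediction error comes from the two modelled components.
    When ``true_ddg`` is not supplied, true values are drawn
    Normal(0, true_sd) with true_sd = 1.5 kcal/mol, a typical spread of
    measured interface-mutation ddG values.
    """
    if sigma_single < 0 or sigma_systematic < 0:
        raise ValueError("noise scales must be non-negative")
    if n_structures < 1 or n_mutants < 1:
        raise ValueError("need at least one structure and one mutant")
    rng = np.random.default_rng(seed)
    if true_ddg is None:
        truth = rng.normal(0.0, true_sd, n_mutants)
    else:
        truth = np.asarray(true_ddg, dtype=float)
        if truth.shape != (n_mutants,):
            raise ValueError("true_ddg length must equal n_mutants")
    offsets = rng.normal(0.0, sigma_systematic, n_mutants)
    noise = rng.normal(0.0, sigma_single, (n_mutants, n_structures))
    preds = truth[:, None] + offsets[:, None] + noise
    return [
        BenchmarkRecord(
            mutant_id=f"m{i:05d}",
            ddg_experimental=float(truth[i]),
            per_structure_predictions=tuple(float(x) for x in preds[i]),
        )
        for i in range(n_mutants)
    ]
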