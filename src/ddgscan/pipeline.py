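"""End-to-end orchestration: search, filter, translate, evaluate, average.

The flow for one job:

1. discover candidate structures whose chains match the query's chains at
   high significance, grouped by structure ID (the query itself always
   participates);
2. run the three-stage filter on each candidate (chain completeness,
   per-chain identity, complex RMSD after one global superposition);
3. translate the user's mutation into each accepted homolog's numbering,
   skipping homologs where a site is unresolved or carries a different
   wild type;
4. evaluate the per-structure ddG through the configured backend, cached
   so every evaluation happens once ever;
5. average over the usable homologs and report mean, spread, and standard
   error, plus a full per-candidate decision table.

Filter decisions and ddG values are cached persistently, so a re-run of
the same job re-reads everything from cache and performs zero backend
evaluations.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .aggregate import EnsembleReport, average_ensemble
from .cache import JsonFileCache, NullCache
from .ddg import (
    DdgBackend,
    DdgResult,
    ExternalBinaryBackend,
    SurrogateBackend,
    TableBackend,
    compute_ddg,
)
from .matcher import (
    DEFAULT_IDENTITY_CUTOFF,
    DEFAULT_RMSD_CUTOFF,
    HomologDecision,
    filter_homolog,
    match_chains,
)
from .mutmap import (
    MutationSpec,
    UnmappableSubstitutionError,
    WildTypeMismatchError,
    parse_mutation,
    translate_mutation,
)
from .seqsearch import (
    DEFAULT_EVALUE_CUTOFF,
    LocalDirectoryProvider,
    SearchProvider,
    find_candidates,
)
from .structures import ComplexStructure, SubunitDefinition, read_structure

logger = logging.getLogger("ddgscan")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "make_backend"]


class ConfigError(ValueError):
    """Invalid run configuration."""


class NoUsableHomologError(RuntimeError):
    """The mutation could not be evaluated on any structure."""


@dataclass
class RunConfig:
    query_path: str
    subunit1: tuple[str, ...]
    subunit2: tuple[str, ...]
    mutation: str
    provider: str | SearchProvider = ""  # "dir:<path>" or a provider object
    backend: str | DdgBackend = "surrogate"
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
    identity_cutoff: float = DEFAULT_IDENTITY_CUTOFF
    rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF
    cache_dir: Optional[str] = None
    output_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.identity_cutoff <= 1:
            raise ConfigError("identity cutoff must be in (0, 1]")
        if self.rmsd_cutoff <= 0 or self.evalue_cutoff < 0:
            raise ConfigError("cutoffs must be positive")


@dataclass
class PipelineResult:
    report: Optional[EnsembleReport]
    decisions: list[HomologDecision]
    n_candidates: int
    n_accepted: int
    n_backend_evaluations: int
    warnings: list[str] = field(default_factory=list)
    output_files: dict[str, Path] = field(default_factory=dict)


class _CountingBackend(DdgBackend):
    """Wraps a backend to count actual (non-cached) evaluations."""

    def __init__(self, inner: DdgBackend):
        self.inner = inner
        self.name = inner.name
        self.n_evaluations = 0

    def evaluate(self, structure, subunits, mutation):
        self.n_evaluations += 1
        return self.inner.evaluate(structure, subunits, mutation)


def make_backend(spec: str | DdgBackend) -> DdgBackend:
    if isinstance(spec, DdgBackend):
        return spec
    if spec == "surrogate":
        return SurrogateBackend()
    if spec.startswith("table:"):
        return TableBackend(spec.split(":", 1)[1])
    if spec.startswith(("foldx:", "external:")):
        return ExternalBinaryBackend(spec.split(":", 1)[1])
    raise ConfigError(f"unknown backend spec {spec!r}")


def _make_provider(spec: str | SearchProvider) -> SearchProvider:
    if isinstance(spec, SearchProvider):
        return spec
    if spec.startswith("dir:"):
        return LocalDirectoryProvider(spec.split(":", 1)[1])
    raise ConfigError(
        f"unknown provider spec {spec!r} (expected 'dir:<path>' or a provider)"
    )


def _decision_cache_key(
    query_id: str, subunits: SubunitDefinition, candidate_id: str, config: RunConfig
) -> str:
    return "|".join(
        [
            "decision",
            query_id,
            subunits.key(),
            candidate_id,
            f"ev={config.evalue_cutoff:g}",
            f"id={config.identity_cutoff:g}",
            f"rmsd={config.rmsd_cutoff:g}",
        ]
    )


def _verify_mutation_in_query(
    spec: MutationSpec, query: ComplexStructure
) -> None:
    for sub in spec.substitutions:
        if sub.chain_id not in query.chain_ids:
            raise ConfigError(
                f"mutation chain {sub.chain_id!r} not in query "
                f"{query.structure_id}"
            )
        chain = query.chain(sub.chain_id)
        res = next(
            (
                r
                for r in chain.residues
                if r.number == sub.number and r.icode == sub.icode
            ),
            None,
        )
        if res is None:
            raise ConfigError(
                f"{sub.token()}: residue {sub.number}{sub.icode} not resolved "
                f"in query chain {sub.chain_id}"
            )
        if res.one_letter != sub.wt_aa:
            raise ConfigError(
                f"{sub.token()}: query has {res.one_letter} at "
                f"{sub.chain_id}{res.label}, not {sub.wt_aa}"
            )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute one full scan-filter-evaluate-average job."""
    query = read_structure(config.query_path)
    subunits = SubunitDefinition(config.subunit1, config.subunit2)
    try:
        subunits.validate_against(query)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    mutation = parse_mutation(config.mutation, context_id=query.structure_id)
    _verify_mutation_in_query(mutation, query)

    provider = _make_provider(config.provider)
    backend = _CountingBackend(make_backend(config.backend))

    if config.cache_dir:
        cache_dir = Path(config.cache_dir)
        decision_cache: JsonFileCache = JsonFileCache(cache_dir / "decisions.json")
        ddg_cache: JsonFileCache = JsonFileCache(cache_dir / "ddg.json")
    else:
        decision_cache = NullCache()
        ddg_cache = NullCache()

    groups = find_candidates(query, subunits, provider, config.evalue_cutoff)
    logger.info("discovered %d candidate structure(s)", len(groups))

    # the query itself is always a member of the ensemble; it trivially
    # passes every gate against itself
    candidates: dict[str, ComplexStructure] = {query.structure_id: query}
    for structure_id in sorted(groups):
        if structure_id == query.structure_id:
            continue
        try:
            candidates[structure_id] = provider.get(structure_id)
        except KeyError:
            logger.warning("candidate %s vanished from provider", structure_id)

    decisions: list[HomologDecision] = []
    results: list[DdgResult] = []
    warnings: list[str] = []

    for structure_id, candidate in candidates.items():
        dkey = _decision_cache_key(query.structure_id, subunits, structure_id, config)
        cached = decision_cache.get(dkey)
        if cached is not None:
            decision = HomologDecision(**cached)
        else:
            decision = filter_homolog(
                query,
                subunits,
                candidate,
                identity_cutoff=config.identity_cutoff,
                rmsd_cutoff=config.rmsd_cutoff,
            )
            decision_cache.put(dkey, dataclasses.asdict(decision))
        decisions.append(decision)
        logger.info(
            "candidate %-20s stage=%-14s accepted=%s",
            structure_id,
            decision.stage_reached,
            decision.accepted,
        )
        if not decision.accepted:
            continue

        corr = match_chains(query, subunits, candidate, identity_cutoff=0.0)
        try:
            local_mutation = translate_mutation(mutation, corr, query, candidate)
        except UnmappableSubstitutionError as exc:
            results.append(
                DdgResult(
                    structure_id=structure_id,
                    mutation=None,
                    ddg=None,
                    backend=backend.name,
                    status="skipped_unmappable",
                    detail=str(exc),
                )
            )
            logger.info("candidate %s: mutation unmappable (%s)", structure_id, exc)
            continue
        except WildTypeMismatchError as exc:
            results.append(
                DdgResult(
                    structure_id=structure_id,
                    mutation=None,
                    ddg=None,
                    backend=backend.name,
                    status="skipped_wt_mismatch",
                    detail=str(exc),
                )
            )
            logger.info("candidate %s: wild-type mismatch (%s)", structure_id, exc)
            continue
        results.append(
            compute_ddg(candidate, subunits, local_mutation, backend, ddg_cache)
        )

    n_accepted = sum(d.accepted for d in decisions)
    ok = [r for r in results if r.status == "ok"]
    if not ok:
        raise NoUsableHomologError(
            "mutation could not be evaluated on any accepted structure "
            f"({len(results)} accepted, all skipped or failed)"
        )
    if len(ok) == 1:
        warnings.append(
            "ensemble contains a single usable structure; no averaging benefit"
        )
    report = average_ensemble(results, mutation=mutation)

    output_files: dict[str, Path] = {}
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        decisions_df = pd.DataFrame([d.as_row() for d in decisions])
        per_structure_df = report.to_frame()
        summary_df = pd.DataFrame([report.summary_row()])
        for name, df in [
            ("decisions", decisions_df),
            ("ddg_per_structure", per_structure_df),
            ("summary", summary_df),
        ]:
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            output_files[name] = path

    return PipelineResult(
        report=report,
        decisions=decisions,
        n_candidates=len(candidates),
        n_accepted=n_accepted,
        n_backend_evaluations=backend.n_evaluations,
        warnings=warnings,
        output_files=output_files,
    )
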