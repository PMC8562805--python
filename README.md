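# ddgscan

Ensemble averaging of protein–protein interface-mutation ΔΔG over
near-redundant homolog structures.

## The problem

The change in binding free energy upon mutation,
ΔΔG = ΔG_mutant − ΔG_wild-type (kcal/mol, negative = affinity-improving),
is routinely predicted with limited-flexibility, implicit-solvent energy
functions that locally repair the mutated side chain and re-score the
interface.  Those predictors are fast and reasonably accurate, but their
output depends on the particular crystallographic coordinate set used:
two independently solved structures of the *same* complex can give ΔΔG
values differing by a kcal/mol or more.

Structure databases are full of near-redundant entries — the same complex
re-solved at better resolution, with a ligand, with an extra subunit, or
by another lab.  If the per-structure prediction behaves like a draw from
a distribution with mean μ and spread σ, the mean over *n* independent
coordinate sets still estimates μ but with spread σ/√n.  `ddgscan`
automates exactly this: find all usable near-redundant homologs of a
query complex, evaluate the mutation on each, and report the average.

## The protocol

For a query complex, a two-subunit chain partition, and a mutation of 1–4
simultaneous substitutions:

1. **Sequence search.** Every chain of every candidate structure is
   aligned against every user chain (global, end-gap-free, BLOSUM62,
   gap 11/1); chains with expectation value E < 10⁻¹¹ are hits, grouped
   by structure ID.
2. **Chain check.** Candidates lacking a distinct counterpart for any
   user chain are discarded.
3. **Identity check.** Each counterpart must satisfy
   identity = matches / min(query length, subject length) ≥ 0.90.
4. **RMSD check.** One global Kabsch superposition, fitted on pooled Cα
   pairs across *all* corresponding chains, must give RMSD ≤ 6 Å —
   candidates with the right chains in a different quaternary arrangement
   fail here.  Extraneous chains are carried along rigidly.
5. **Translate & evaluate.** The mutation is re-expressed in each
   accepted homolog's author numbering via the alignment (homologs where
   the site is unresolved, or carries a different wild-type residue, are
   skipped with a recorded status) and scored by a pluggable ΔΔG backend.
6. **Average.** The report gives the plain mean over the usable homologs
   plus sample SD and standard error σ/√n.

All filter decisions and ΔΔG evaluations are cached persistently; a
repeated run performs zero backend evaluations.

Backends: `surrogate` (deterministic contact-hydropathy score for testing
— not a physical potential), `table:<csv>` (precomputed values), and
`external:<binary>` (adapter for a user-supplied energy program, e.g. an
empirical force field).

An evaluation toolkit (`ddgscan.evalstats`) provides RMSE, Pearson
correlation, ROC as TPR-vs-TNR with AUC, PPV curves with their TP+FP
denominator, the Wilcoxon signed-rank test on paired squared errors
(exact for n ≤ 25), and a randomized single-structure baseline; the
`aggregate` module fits the error decomposition
RMSE(n)² = σ²_single/n + σ²_systematic.

## Worked example

`ddgscan` ships a synthetic-fixture generator so the whole pipeline can be
tried without downloading anything.  It writes a 2-chain query complex and
14 near-redundant variants with designed defects (rigid transforms, 0.5 Å
coordinate noise, 5–30 % mutated sequences, +5 renumbering, insertion
codes, a dropped chain, 20–30 Å displaced subunits):

```sh
ddgscan make-fixtures demo --seed 0
ddgscan scan --pdb demo/query.pdb --subunit1 A --subunit2 B \
    --mutation "TA10D" --provider dir:demo --backend surrogate \
    --cache-dir demo_cache --out demo_out
```

prints

```
candidates=15 accepted=10 used=9
mean ddG = 1.851 kcal/mol +/- 0.031 (SE)
```

15 candidates were discovered; 10 passed all three checks (the dropped-
chain variant failed the chain check, the 15 % and 30 % mutated variants
failed the identity check at 0.84 and 0.70, and the displaced-subunit
decoys failed the RMSD check at 10.0 and 15.0 Å); of the 10 accepted, one
was skipped because its residue at the mapped site is not the stated
wild type, and the remaining 9 were averaged.  `demo_out/decisions.csv`
holds the per-candidate filter trace, and `demo_out/ddg_per_structure.csv`
shows the mutation re-numbered per homolog (`TA10D` → `TA15D` in the
+5-renumbered variant):

```
structure_id,mutation,ddg_kcal_mol,backend,status,detail
query,TA10D,1.8199999999999998,surrogate,ok,
combo,,,surrogate,skipped_wt_mismatch,"TA10D: combo chain A has N at 15, not T"
copy,TA10D,1.8199999999999998,surrogate,ok,
...
renum5,TA15D,1.8199999999999998,surrogate,ok,
```

Re-running the same command evaluates nothing: every decision and ΔΔG
comes from `demo_cache`, and the output CSVs are byte-identical.

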