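# fluxtk

A constraint-based metabolic modeling toolkit implementing three
evidence-driven model-building algorithms on top of a small
stoichiometric core:

* **Slack-flux gapfilling** — a MILP that adds a minimum-cost set of
  candidate-database reactions (or direction reversals) so that as many
  gene-associated model reactions as possible can carry flux on a given
  growth media.  Per-reaction slack variables (forced to 0.01 exactly
  when a reaction is off) make the objective continuous; binaries appear
  only to forbid simultaneous forward+reverse flux.
* **Transcriptome-based model reduction** — GPR-aware expression scores
  (max over complexes of min over subunits of max over genes, on
  median-normalized expression) classify reactions as high/low at a
  strict 0.2 threshold; a second MILP activates high-expression
  reactions while zeroing low-expression flux, and pruning drops the
  zero-flux low reactions to produce a growth-capable submodel.
* **QP flux fitting** — fits model fluxes to measured fluxomics values
  by minimizing the squared distance over the FBA polytope (reversible
  reactions not decomposed, exchange cap 50), and reports the Spearman
  rank correlation, its p-value, and the blocked-reaction percentage.

A seeded fixture generator (`fluxtk.synthgen`) produces models with
known pathway structure, gapfill cases with exhaustively verified
minimal completions, expression matrices with planted high/low
pathways, and measured-flux sets sampled from feasible solutions, so
the entire pipeline runs and is tested without any external data.

## Conventions

* Exchange reactions touch exactly one metabolite; the **uptake
  direction is the one producing that metabolite** (so `-> A` has
  uptake as positive flux).  Media membership gates the uptake bound
  (`min(limit, cap)`, default cap 100 for gapfilling, 50 for flux
  fitting); secretion is always allowed up to the cap.
* Internal bounds derive from the `reversible` flag: `[0, cap]` or
  `[-cap, cap]` (cap 100 in the MILPs, 1000 in the QP).
* A reaction is *active* when its net flux reaches 0.01 (the slack
  threshold); GPR rules are stored in an OR(AND(OR)) normal form.

## Command line

```bash
# write a ready-to-run synthetic input set
fluxtk simulate --preset gapfill --seed 1 --out fixtures/

fluxtk gapfill --model fixtures/model.tsv --db fixtures/database.tsv \
    --media fixtures/media.tsv --a 0.1 --require-growth --seed 7 \
    --out solution.tsv

fluxtk score  --model model.tsv --expression expr.tsv --condition target \
    --threshold 0.2 --out scores.tsv

fluxtk reduce --model model.tsv --expression expr.tsv --condition target \
    --media media.tsv --out reduced.tsv

fluxtk fitflux --model model.tsv --fluxes measured.tsv --media media.tsv \
    --out fit.tsv
```

Models are read/written as SBML level 3 (FBC) or a TSV dialect
(`id  equation  gpr  role  subsystem` with equations like
`(1) A[c] + (2) B[c] <=> (1) C[c]`).  Every output carries a provenance
header; identical seed + config gives byte-identical files.  Exit codes:
0 success, 2 validation error, 3 solver failure.

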