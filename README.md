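# microred

Relative-entropy measures of single-function redundancy and interdependency
for functionally annotated microbial communities, plus the classical
community-level contrast and supporting tooling.

Given per-sample relative abundances and per-species quantitative outputs of a
function (e.g. maximal metabolite secretion fluxes from constraint-based
community models, in mmol·gDW⁻¹·h⁻¹ with positive = secretion), the package
computes, per (sample, function) pair, in nats (natural log):

* **sample taxon-based redundancy** — `H(shares) − log n`; 0 when every
  sampled species contributes equally, `−log n` when one species carries the
  whole function;
* **reference taxon-based redundancy** — `H(shares) − log m` against a fixed
  external reference of all `m` species able to perform the function, making
  values comparable across samples;
* **abundance-based redundancy** — `−KL(shares ‖ abundances)`; 0 when shares
  mirror abundances;
* **functional interdependency index** — `KL(producer shares ‖
  producer-renormalised abundances)`; 0 iff each producer's output is
  proportional to its abundance — plus its per-sample median (global
  interdependency).

Also included:

* alpha-diversity indices (richness, Shannon, Simpson, evenness);
* the community-level multi-trait redundancy `FR = D − Q` (Simpson minus
  Rao's quadratic entropy over a Gower dissimilarity) with a keystone-series
  generator showing how it diverges from the single-function measures;
* preprocessing with auditable filter rules (universe restriction and
  renormalisation, <25-species sample exclusion, uptake/no-producer
  missingness, >80 % non-missing function filter);
* a Dirichlet simulation quantifying the effect of unclassified species on
  the three measures;
* programmatic fixture scenarios (`toy`, `keystone`, `proportional`,
  `dirichlet`).

## CLI

```sh
# end-to-end computation from tables
microred compute --abundances abund.tsv --fluxes flux.tsv \
    --reference reference.tsv --min-species 25 --min-nonmissing 0.8 \
    --tolerance 1e-9 --out results/

# unclassified-species simulation
microred simulate --n-species 100 --iterations 1000 --seed 1 \
    --out sim.tsv --summary sim_summary.tsv

# write a named scenario's input tables
microred fixtures keystone --n-max 100 --m 100 --out fixtures/keystone

# community-level redundancy from a trait matrix
microred rao --abundances abund.tsv --traits traits.tsv --out rao.tsv
```

Formats (TSV/CSV, UTF-8, header row): abundances wide (species × samples) or
long (`sample_id`, `species_id`, `abundance`); fluxes long (`sample_id`,
`species_id`, `function_id`, `flux`) — pass `--invert-sign` if positive means
uptake in your raw output; reference two-column (`function_id`,
`species_id`); trait matrices species × trait with a `kind` row
(`binary`|`quantitative`) under the header. Missing output values are `NA`
with a reason column. A YAML config mirroring the flags can be passed via
`--config`; unknown keys are rejected.

## Layout

```
src/microred/
  core.py           entropy/KL primitives, domain types, the four measures
  diversity.py      richness, Shannon, Simpson, evenness
  rao.py            Gower dissimilarity, Rao's Q, community FR, keystone series
  preprocessing.py  restriction, renormalisation, filter rules, audit report
  simulation.py     Dirichlet communities, unknown-species experiment
  io.py             readers/writers, run configuration, compute pipeline
  fixtures.py       named scenario generators
  cli.py            click entry points
```
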