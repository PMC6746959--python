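# Methods

## Scope and data model

`cnvtrio` prioritizes rare recurrent CNVs from four mutually exclusive
cohorts: a discovery cohort of exome-sequenced family trios, an independent
exome trio cohort, an SNP-array cohort of unrelated cases and controls, and
a small WGS trio cohort. Calls enter in the native dialect of each caller
family (`xcnv` for exome read-depth calls, `rawcnv` for array-intensity
calls, a BED-like `svbed` for WGS structural variants) and are normalized
at the parser boundary to a single in-memory representation: 1-based,
fully inclusive coordinates with canonical `chr`-prefixed chromosome labels
(`23`→`chrX`, `24`→`chrY`). BED inputs (0-based half-open) are converted on
read; the conversion preserves interval length.

Upstream calling is out of scope: the package consumes caller output.
The only caller-level rule re-implemented is the WGS read-support filter
(calls with support fraction < 0.50 are rejected at parse time with a
recorded reason), because it is a published property of the call sets the
pipeline expects, not of the caller internals.

## Matching and the filter layers

All matching uses **reciprocal overlap**, the minimum of the two one-way
coverage fractions — the standard CNV equivalence criterion. Because no
single fraction is canonical, the thresholds are configuration with
deliberate defaults:

| parameter | default | role |
|---|---|---|
| ρ (`rho`) | 0.50 | inheritance and independent-control matching |
| ρ_rep (`rho_rep`) | 0.25 | replication support/veto matching |
| f_kb | 0.50 | one-way coverage of a candidate by a knowledge-base record |

ρ_rep is looser than ρ on purpose: different platforms recover different
spans of the same locus, and a partial-span or opposite-type call at a
locus is still evidence the locus is copy-number labile. For the same
reason inheritance/control/replication matching ignores DEL/DUP type — a
conservative convention under which any overlapping CNV in a relative or
control blocks de novo certification. Knowledge-base screening uses
one-way coverage *of the candidate* so a small candidate inside a megabase
syndromic record counts as covered while a megabase record clipping the
edge of a candidate does not.

Layer 1 classifies each discovery proband call as de novo (relatives
genotyped, none match), inherited (some relative matches), or unclassified
(no genotyped relatives; excluded from the de novo channel but kept in the
audit trace). Siblings are included among blocking relatives, not just
parents: the goal is certification, and the cheapest conservative choice
is to let any first-degree relative's call block. Layer 2 requires at
least one replication *proband* match and zero matches in *any*
replication control (family controls or unrelated array controls); veto
dominates support. Supported calls plus their supporting replication calls
are merged into regions by single-linkage clustering at ≥ 1 bp overlap per
chromosome (implemented as a sweep over start-sorted intervals; regions
are maximal and order-invariant, with IDs derived from the union-span
coordinates). Carriers are counted as distinct samples, never calls.

Layer 3's relevance criteria are OR-ed, following the published screen
they reproduce: (1) a mapped gene is on the developmentally-heart-expressed
list; (2) the region does **not** physically overlap previously reported
disease-associated CNV loci — novelty counts toward relevance, which is
counter-intuitive but is the screen as stated, so an
`--invert-criterion2` switch is provided; (3) the region is absent from
the common-CNV catalogue. The separate "novel de novo" list is the de novo
regions absent from the common-CNV catalogue, with a recurrent sub-list at
≥ 2 case carriers.

## Carrier permutation test

The null treats the k carriers of a region as exchangeable labels over the
n_case + n_control individuals. One permutation = one uniform reassignment
without replacement; its case-carrier count is exactly a hypergeometric
draw, so the Monte Carlo permutations are sampled as
`Hypergeom(n, n_case, k)` variates (mathematically identical to shuffling
labels, and far cheaper). The test is one-sided for case excess because
the screen selects case-only variants. `p_mc` uses the add-one estimator
so it can never be zero; `se_mc = sqrt(p_mc(1-p_mc)/n_perm)`; `p_exact` is
the closed-form upper tail computed by scipy in log space. Per-region RNG
seeds mix a master seed with a CRC-32 of the region ID, so results are
independent of processing order. Zero-carrier regions return p = 1 with a
warning; carrier counts exceeding cohort sizes are fatal.

Default denominators are the combined trio cohorts of the full design,
2,458 probands vs 4,455 family controls; the pipeline substitutes the
actual pedigree counts of the data in hand. Region p-values are reported
unadjusted (the design screens on replication, not on p); a
Benjamini–Hochberg helper is provided for reporting only.

The null-calibration check draws regions with k ~ Uniform{150..300}
carriers. The choice is dictated by discreteness: for small k the
achievable p-values of a hypergeometric tail jump over 0.05 and the test
is so conservative that the fraction of null regions below 0.05 is near
zero; for k in the hundreds the largest achievable p below 0.05 approaches
0.05 and the expected fraction (0.043 by closed-form calculation over this
k range) sits inside the [0.03, 0.07] calibration band.

## Expression validation

Cardiac biopsies exist only for affected probands, so contrasts compare
carrier probands against non-carrier probands of the same tissue — a
within-case design that can show a variant's dosage effect but not its
effect relative to healthy tissue.

Housekeeping normalization rescales each sample so the geometric mean of
its housekeeping FPKM (default G6PD and ACTB) equals a fixed anchor of
100 FPKM. Anchoring to a constant rather than to the cohort geometric mean
makes the normalized matrix — and therefore every downstream p-value and
fold change — invariant under global rescaling of the input (library
depth), exactly in real arithmetic and to float round-off in practice; it
also makes the operation idempotent. `target="cohort"` is available when
cohort-relative output is wanted. Samples with a zero housekeeping value
admit no geometric mean and are excluded with a warning.

The two-group test is a two-sided Welch t on log2(FPKM + 1) when both
groups have ≥ 3 samples. With 1–2 carriers (common: many regions have a
single biopsied carrier) no two-sample test is defensible, so the contrast
reports a z score of the carrier mean against the non-carrier log2
distribution, labelled `z_outlier` and never pooled with Welch results;
with < 3 non-carriers the p-value is absent. Fold change uses a
pseudocount of 1 in normalized-FPKM units for bounded behaviour near zero.

## Synthetic cohort generator

The generator defines the study conditions for every test; it emulates the
full design at a scale that keeps a complete pipeline run under a minute:

| condition | default | rationale |
|---|---|---|
| cohort shapes | 100 / 200 trios, 75+75 array singletons, 10 WGS trios | scaled-down analogue of 760 / 1,712 trios, 1,860 singletons, 33 trios |
| families with genotyped relatives | 0.86 | 652/760 in the full design |
| polymorphic loci | 10, carrier frequency U(0.05, 0.30), length 20–200 kb | the benign background the filters must remove |
| background de novo rate | 0.05 per proband | order of ~100 de novo CNVs per ~2,400 families |
| planted regions | 5 case-only DEL loci, 4–7 carriers across datasets | the recoverable signal |
| platform degradation | sensitivity 0.90–0.98, jitter sd 50–500 bp, false-call rate 0.02, type-miscall 0.02 | array noisiest, WGS cleanest |
| expression | baseline 30 FPKM, dosage 0.5× per carried deletion, σ_log2 = 0.5; housekeeping 40/250 FPKM at σ_log2/4 | heterozygous-deletion dosage with biological noise |

Polymorphic loci have fixed population breakpoints and are transmitted
Mendelianly (each parental allele passes with probability 0.5); a child
carrier always has a transmitting parent. Probands without genotyped
parents draw carrier status at the marginal frequency. Background de novo
events are rejection-sampled away from polymorphic loci and planted
regions so every emitted call has an unambiguous truth label. Breakpoint
jitter is applied independently per endpoint and redrawn until the
interval stays valid; false calls are placed uniformly over the genome
with log-uniform length 1 kb–1 Mb. All generation flows from one
`numpy` Generator seeded by the master seed in a fixed iteration order, so
identical configurations produce byte-identical files.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: locus-specific detection sensitivity
(e.g. probe density, segmental duplications), linkage disequilibrium
between CNV loci, parental mosaicism, batch effects in expression, and
genotyping error correlated within families. The pipeline's recovery rates
on synthetic cohorts are upper bounds for cohorts with these features.

## Numerical and engineering choices

- Exact tail probabilities via `scipy.stats.hypergeom.sf` (log-space);
  brute-force enumeration oracles live only in the tests.
- Overlap queries use per-chromosome interval trees; merging uses a sort
  + sweep, so pipeline stages are near-linear in call count.
- All output tables are TSV with a fixed, documented column order, floats
  serialized with `repr` so write→read→write is byte-stable; rows sort by
  genomic position. The run log contains stage names and counts only, so
  reruns under one configuration are byte-identical across every output.
- Stages compose on disk through canonical TSVs; running subcommands
  individually equals a single end-to-end run bit-exactly.
- Ties in matching evidence are broken by descending overlap then call ID.
- Degenerate inputs: empty call files parse to empty lists with a warning;
  cn=2 array records, unknown CNV states, and malformed lines are rejected
  per record with line numbers; `write_regions([])` yields a header-only
  file that reads back to an empty list.

## Known limitations

- The carrier test conditions on the observed carrier count k; it does not
  model locus-specific mutation or detection rates.
- Replication matching is evidence-agnostic about call quality; quality
  scores are carried through but not thresholded.
- The genome model is a flat chromosome-length table; no mappability or
  segmental-duplication structure.
- Expression p-values are per-contrast and unadjusted; with one or two
  carriers they are descriptive (`z_outlier`), not confirmatory.
- The novelty direction of relevance criterion 2 follows the published
  screen; users who want the intuitive direction must set
  `--invert-criterion2`.
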