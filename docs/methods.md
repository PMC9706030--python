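# Methods

## Quantities

All statistics are read-share based. With `N` the metagenome's total clean
read count, `N_g` the summed mapped-read counts of genus *g*'s genes, `N_f`
the summed reads of genes carrying at least one CAZy family mapped to
function *f*, and `N_g-f` the genus-restricted part of `N_f`:

    R_g   = N_g / N          genus relative abundance
    R_g-f = N_g-f / N_f      genus share of function f's enzyme reads
    CC    = R_g-f / R_g      contribution coefficient

Within a function, a gene is counted once even when several of its families
carry that function; across functions and across family-level summaries, a
multi-modular gene carries its full read count into every family/function it
is annotated with (no read apportionment between catalytic modules). Read
counts are used as reported by the aligner, with no gene-length
normalization — CC is a ratio of shares from the same sampling process, so
length effects largely cancel within a column.

Two denominator conventions exist for `R_g`: total clean reads `N` (the
default and the standard definition) or the summed per-gene mapped reads.
Because `CC = R_g-f / R_g`, the choice cancels only if applied consistently;
`genus_abundances(..., denominator=...)` enforces one choice per analysis.

Undefined CC cells (`R_g = 0` or `N_f = 0`) are NaN and rendered blank,
never zero — a zero would be a strong claim (no contribution at all), while
NaN means the ratio does not exist.

## Function ontology

The packaged map (`data/function_map.tsv`) is a frozen curation, not an
automatic derivation from a CAZy release. Fifteen categories are tracked:
twelve GH hydrolase functions (endoglucanase, exoglucanase, β-glucosidase;
endo-β-1,4-xylanase, β-xylosidase, β-mannanase; arabinofuranosidase,
α-mannosidase, galactosidase, α-rhamnosidase, α-fucosidase, glucuronidase),
esterases (CE families), lignin-active auxiliary activities (AA families),
and carbohydrate-binding modules (CBMs). Substrate roll-ups combine them
into cellulose / hemicellulose / lignin columns.

Conventions adopted where the source material was ambiguous:

* **Curated lists vs. description-level activities.** Each category has a
  curated family list whose size is the headline count (10 endoglucanase
  families, 9 β-xylosidase, 11 galactosidase, ...). A few families carry an
  activity in their catalogue description that is outside the curated list
  (e.g. the β-glucuronidase activity of GH1 and GH30_8); these memberships
  participate in read aggregation but not in list cardinalities
  (`families_for` vs. `categories_of(..)`/`listed_only=False`).
* **Subfamily roll-ups.** GH5 and GH43 are mapped at parent level ("GH5
  subfamilies") and count as one family each; subfamily labels (GH5_4,
  GH43_11) inherit the parent's categories. GH30_8 is mapped exactly and
  its parent GH30 is not mapped.
* **β-mannanase** is the main-chain mannan category with the 3-family list
  GH1/GH2/GH5 (the β-mannosidase/β-mannanase terminology is collapsed into
  one category); GH26 and GH113, described as β-mannanases at family level,
  are retained only under their other memberships.
* **α-rhamnosidase** is completed to its 3-family count with GH105
  (rhamnogalacturonyl hydrolase, cleaving at rhamnose residues) alongside
  GH78 and GH106; GH105 also remains in the 7-family glucuronidase list.
  The map's `source_note` column records this.
* **CH88 → GH88**: an obvious transcription slip normalized to the family's
  class-level spelling.
* **Binding modules** are profiled but excluded from CC function columns
  and from role classification: CBMs bind rather than cleave, so they say
  nothing about enzyme supply.

Users can supply their own map via `--function-map` / `load_map`.

## Role classification

The qualitative rule "CC > 1 over-contributes, CC < 1 under-contributes"
needs an operational cutoff to become a genus-level call. The rule used:
over the twelve hydrolase functions (lignin AAs and esterases excluded —
cheating is defined against the sugar-releasing machinery), a genus is a
*contributor* if at least a `cheater_quantile` fraction (default 0.75) of
its defined CC cells exceed `contributor_cutoff` (default 1.0), a *cheater*
if at least that fraction fall below `cheater_cutoff` (default 1.0), and
*intermediate* otherwise; genera with no defined cells are *undetermined*.
All three knobs are exposed in the config and CLI. There is no significance
test attached: no null model for CC is defined, so calls are descriptive.

## Synthetic catalog generator

Simulation starts at the annotation layer (no sequences or reads are
generated). One `numpy` Generator seeded from `SimConfig.seed` drives all
randomness; identical configs reproduce byte-identical catalogs.

1. **Gene assignment.** A fraction `1 − noncazyme_fraction` of the `n_genes`
   genes are CAZymes. Their joint (genus, function) assignment follows
   probabilities ∝ `abundance_g × base_weight_f × m_g,f`, where the
   allocation multiplier `m` plants contributor-like (>1) or cheater-like
   (<1) structure. Non-CAZyme genes are then allocated so every genus's
   overall expected read share equals its planted abundance. Families are
   drawn uniformly from the function's curated list, resolving GH5/GH43 to
   concrete subfamilies; 15 % of CAZyme genes carry an extra CBM module,
   exercising the multi-family code paths.
2. **Read counts.** Each gene receives a Gamma-distributed relative
   coverage weight (shape = `dispersion`, mean 1; default 2.0, i.e. a
   coefficient of variation ≈ 0.7) and reads are drawn multinomially over
   genes. Marginally the per-gene counts are negative-binomial-like
   (gamma-mixed), while *conditional on the catalog structure* read noise
   shrinks as `1/sqrt(depth)` — which is what deeper sequencing of a fixed
   community does. The structure-conditional expected genus shares are part
   of the returned ground truth, so depth-scaling behaviour is testable.
3. **Expected CC.** Because every function column renormalizes to 1
   (`Σ_g R_g·CC_g,f = 1` is an identity), the expected CC of a cell is
   `m'_g,f / Σ_g' R_g'·m'_g',f`, with `m'` folding in family cross-listing
   (a gene drawn for one function whose family carries a second activity
   counts in both columns). `expected_cc()` computes this matrix exactly
   from a config, and it is what estimates converge to.

### The consortium-emulation preset

`tmc7_preset` encodes the emulated study community: nine genera at the
profile 42.85 / 18.41 / 10.44 / 7.48 / 2.65 / 2.47 / 2.33 / 1.56 / 1.26 %,
the remaining 10.55 % in the unassigned bin. The two dominant genera are
planted contributors (multiplier 1.2 on all hydrolase functions; the most
abundant genus is additionally under-represented on lignin, multiplier
0.45), the two planted cheaters get multiplier 0.2 on all hydrolase
functions but 1.2 on lignin/esterase, and the five remaining genera get a
division-of-labor pattern (1.5 on one substrate cluster, 0.6 on the other)
that leaves them intermediate overall. The unassigned bin's multiplier is
solved per function so the abundance-weighted mean multiplier is ≈ 1,
making the planted multipliers directly recoverable as CCs (without this
balancing, the column renormalization shifts every CC by the community
mean).

Preset sizes: 50,000 genes (a realistic ORF count for a consortium
assembly) at depth 10^6 reads, with 30 % of genes CAZymes. The CAZyme
fraction is deliberately far above what real catalogs show (a few percent):
at realistic sparsity, a 1–3 %-abundance genus carries 0–2 genes per
function and its CC cell is dominated by gene-sampling noise, so planted
roles could not be recovered reliably at desk scale. The enrichment buys
stable per-function genus shares while keeping every distributional feature
the pipeline must be robust to (overdispersion, multi-family genes, an
unassigned tail). Consequences for interpretation: passing recovery tests
shows the estimator and classifier are correct under the planted model, not
that real CC heatmap cells for rare genera are precise — on real data those
cells inherit the same sparsity noise and should be read qualitatively.

What the generator does not emulate: assembly and binning artefacts,
chimeric or fragmented genes, taxonomy misassignment (the lineage is always
correct), between-sample variation (a single metagenome is drawn), and any
correlation between a gene's function and its expression or copy number.

## Numerical conventions

* Reported percentages are rounded half-up to 2 decimals; internal math is
  full precision.
* Result tables are UTF-8 TSVs, rows ordered lexicographically by the first
  column unless the table defines its own order; the Circos export keeps
  matrix order and bit-exact integer read counts, so column sums reproduce
  `N_f`.
* Genera below 1 % abundance are merged into "others" only at report time;
  underlying matrices always keep every genus.
* Test problem sizes: identity/oracle properties use catalogs of ≤ 1,000
  genes (where a pure-Python per-record re-aggregation is feasible as an
  independent oracle); recovery tests use the preset at depth 10^6 over 20
  seeds; depth-scaling uses 50 replicates at depths 5×10^4 vs 2×10^5, where
  the conditional standard error should shrink by ≈ 2 (noise scales as
  `1/sqrt(depth)`, so halving the error requires quadrupling the depth).

## Known limitations

* The function ontology is a frozen transcription of one curation; it does
  not track CAZy releases, and subfamily-level activity differences beyond
  the GH5/GH43/GH30_8 handling are not represented.
* Whether per-gene counts are reads or read pairs is not modelled; counts
  are opaque.
* Whether published per-function shares are read shares or gene-count
  shares is ambiguous in parts of the source material; read shares are the
  default and a gene-count mode (`by="genes"`) is provided rather than
  resolving the ambiguity.
* CC has no attached uncertainty; cells built from few genes are noisy, and
  the classifier's quantile rule is a pragmatic cutoff, not an inference.
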