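# Methods

## The problem

In a tumour microenvironment (TME) profiled by single-cell RNA-seq, many
ligand–receptor pairs are co-expressed across cell types, but co-expression
alone says nothing about whether a putative interaction actually changes the
transcriptional state of the receiving cell. `contacttracing` infers such
*ligand effects* from two layers of intrinsic variability: (1) within a target
cell type, some cells detect the receptor (target+) and some do not
(target−); (2) across experimental conditions (e.g. high vs low chromosomal
instability, or depletion of a signalling gene in tumour cells), the ligand's
availability in the TME varies. A gene that responds to receptor engagement
*only when the ligand is conditionally available* is evidence for a
condition-dependent interaction; a gene merely co-expressed with the receptor
responds in every condition and is a confounder.

## Hurdle model and likelihood-ratio tests

Single-gene expression is modelled in two parts, as is standard for sparse
single-cell data:

* a logistic regression of the detection indicator `1[y > 0]` on the design
  (discrete part), and
* a Gaussian linear regression of log-normalized expression `y` among detected
  cells (continuous part).

Nested models are compared with a likelihood-ratio statistic summed over the
two parts and referred to chi-square with degrees of freedom equal to the
number of parameters dropped across the non-degenerate parts. Every design
includes an intercept and the cellular detection rate (CDR, the fraction of
genes detected in the cell), which absorbs cell-level technical variation in
capture efficiency.

Three tests are built on this engine:

| test | full model | dropped term |
|---|---|---|
| target | `Y ~ CDR + condition + target` | `target` (receptor detected) |
| ligand condition | `Y ~ CDR + condition` (donor cells, two conditions) | `condition` |
| interaction | `Y ~ CDR + condition + target + target:condition_of_interest` | the interaction indicator |

The interaction test is run per contrast (pair of conditions), restricted to
cells of those conditions, with the indicator set for cells that are both
target+ and in the ligand-high condition. The target test keeps the full
categorical condition covariate over all levels present.

Numerical choices: aliased design columns are dropped greedily left-to-right
per part (the detected-cell subset can alias columns that are full-rank
overall); a part is degenerate when all/no cells are detected, fewer than
`k_min = 3` cells are detected, or the detected values have no residual
variance; degenerate parts contribute neither likelihood nor degrees of
freedom, and a test with zero remaining degrees of freedom reports p = 1 with
status `degenerate` and is excluded from the BH family. Perfect separation in
the logistic part falls back to an L2 penalty of 1e-6; the reported
log-likelihood is always the unpenalized likelihood at the returned
coefficients, keeping the LRT well defined. Plain maximum likelihood is used
rather than empirical-Bayes variance shrinkage: the model formula, not the
shrinkage, carries the method's logic, and the plain likelihood is directly
checkable against an independent numerical maximizer (the test suite does this
to 1e-6 relative tolerance).

The per-gene log2 fold change defaults to a combined estimate: the difference
in predicted expression `P(detected) x E[y | detected]` between contrast
levels with other covariates at their means, converted to log2. A
continuous-coefficient-only variant is selectable (`lfc_mode="continuous"`).

## Significance rule, response scores, embedding

An interaction (ligand, donor type, receptor, target type) is called
condition-dependent when, for every configured contrast, (a) at least 10 genes
pass the interaction test at FDR < 0.25, (b) the ligand is differentially
expressed in the donor type at FDR < 0.05 with |log2FC| > 0.12, and (c) the
ligand fold-change sign agrees across contrasts. All four thresholds are
configurable (`Thresholds`). Interactions are ranked by the number of
interaction effects, ties broken by the number of target-test DEGs, further
ties preserving input order.

Per (receptor, target type), a response vector scores each gene as
`-log10(p_Bonferroni) x log2FC` from the target test, with the Bonferroni
family being the genes tested in that slice. Rows of the resulting matrix are
embedded with PCA; the number of components is the kneepoint of the cumulative
variance curve (maximum perpendicular distance to the chord, ties to the
earliest point). The first diffusion component (DC1) orders rows along the
dominant axis of response variation: a kNN-restricted Gaussian kernel with
per-point adaptive bandwidth (distance to the ⌈k/2⌉-th neighbour,
k = min(15, rows−1)) is symmetrized, row-normalized into a Markov matrix, and
its second eigenvector is taken, with the sign fixed so the row of largest L2
norm is non-negative.

## Subcluster mapping

Subcluster markers are one-vs-rest hurdle LRTs (`Y ~ CDR + membership`) within
a cell type, BH-corrected per subcluster. A response row is mapped to
subclusters by the dot product between its scores and the marker log2FCs
(masked to 0 at FDR > 0.15), standardized to the per-row maximum; subclusters
with standardized score strictly greater than 0.5 are assigned (several may
be). Negative dot products are retained but can never be assigned since
standardization divides by the positive maximum; if no dot product is
positive, nothing is assigned. Ligands are assigned to subclusters where they
are positively enriched (log2FC > 0, FDR < 0.15).

## Spatial colocalization

For spot-based spatial data with per-spot cell-type probabilities, an
interaction is scored as `sum over spots of log1p(ligand) x Pr(target type) x
1[receptor expressed]`. The log1p form (natural log with a pseudocount of 1)
keeps zero expression at zero; it is configurable by passing transformed
values. The null permutes the ligand vector across spots, holding the receptor
indicator and the probabilities fixed; the one-sided p-value uses the add-one
convention `(1 + #{perm >= obs}) / (1 + n_perm)` so p is never 0. A
radius-pooled variant replaces each spot's ligand signal with the sum over
spots within a Euclidean radius (inclusive of the focal spot) before scoring;
the pooling construction is this package's own design choice for
neighbourhood-level colocalization.

## CNV diversity index

Per sample, copy-number variant (clone) profiles carry a cell fraction
`freq_i` and an alteration magnitude `delta_i = sum over bins |state −
neutral|` (state units; the neutral state defaults to 3, the centre of a
six-state model, and is configurable). The index is the Shannon entropy of
`s_i = freq_i x delta_i / sum freq x delta`, after dropping zero-weight
variants (0 ln 0 := 0). It is 0 for a single clone, ln(n) for n equally
frequent and equally altered clones, and invariant to rescaling all deltas.

## Benchmarking utilities

Top-N interaction lists are compared with the overlap coefficient
`|X∩Y| / min(|X|,|Y|)` (size-corrected; Jaccard also available). Predicted
up-regulated response genes (target-test log2FC > 0 and interaction FDR <
0.05) are compared against a reference ranking with a weighted KS running-sum
connectivity score: hits add `1/n_hits`, misses subtract `1/n_misses`, and the
score is the signed maximum deviation in [−1, 1]. This concrete running-sum
form is one of several connectivity-score variants in the literature and is
isolated behind a single function so an alternative is drop-in. Matched vs
unmatched score groups are compared with a one-sided Mann–Whitney test; the
default cell-type matching groups are epithelial/stromal, myeloid, and
lymphoid compartments, editable by callers.

## Synthetic data generator

`simulate_tme` emulates exactly the statistical structure the tests exploit:

* negative-binomial counts (gamma–Poisson, `var = mu + 0.5 mu^2`) with
  log-normal gene means and log-normal per-cell size factors (sd 0.35) that
  create CDR heterogeneity;
* a block of ~30 highly expressed housekeeping genes so that library sizes are
  dominated by a stable background, as in real cells — without it, a handful
  of planted genes can shift a cell's library size by tens of percent and
  normalization artifacts leak into every other gene;
* receptors detected in a configurable fraction (default 0.5) of target-type
  cells, independent of the size factor;
* ligands expressed in the donor type and multiplied by `2^1.5` in the
  ligand-high condition when the planted interaction is condition-dependent;
* effect genes multiplied by `2^1` in target+ cells of the ligand-available
  condition only (condition-dependent) or of every condition
  (condition-independent / confounders).

Defaults are three conditions (`CINhigh`, `CINlow`, `STINGkd`), two cell types
(donor `Tumor`, target `Macrophage`) and 500 cells per cell type per
condition, which yields ~250 target+ cells per condition arm. All generators
are pure functions of (config, seed).

What the generator does **not** emulate: ambient RNA, doublets, batch effects,
per-sample correlation structure, gene–gene co-expression modules, or
realistic gene-panel sizes. Passing calibration and discrimination checks on
these data therefore demonstrates the statistical machinery behaves as
designed under its own assumptions; it does not certify performance on real
tissue, where condition is confounded with sample and batch.

## Problem sizes used in the checks

Calibration uses 1,000 null genes at 500 cells per cell type per condition;
discrimination checks use 200 planted confounders and 200 planted effects
spread over 10 replicate datasets of 20 each (keeping planted genes a small
fraction of each library); the end-to-end check plants 3 condition-dependent
and 3 condition-independent interactions; spatial checks use 50 planted
replicates and 200 null interactions at 100 permutations. These sizes make the
whole suite reproducible on a laptop-class single core in minutes.

## Known limitations

* The LRT relies on asymptotic chi-square calibration; very small cell counts
  or near-degenerate detection patterns are flagged rather than exactly
  corrected.
* The ligand-condition test treats cells as independent; sample-level
  pseudoreplication is not modelled (no random effects).
* Ortholog mapping implements one-to-one renaming, uppercase fallback and
  average-or-drop for multi-mapped destinations; species pairs with heavier
  paralogy need a curated map.
* The connectivity score's normalization follows the running-sum form stated
  above; other published variants differ in weighting.
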