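# Methods

This note documents the models, the synthetic-data generator, the parameter
choices that matter, and the limits of what the shipped tests demonstrate.

## The experimental design being modeled

The pipeline assumes eight expression conditions of a mammary epithelial
line: wild type, TGF-β treatment, a CRISPR ZEB1 knockout (dZEB), TGF-β on
the knockout, a DMSO control, DOX-induced ZEB1 overexpression, TGF-β
receptor inhibition (SB), and ZEB1 overexpression under receptor inhibition.
Eight treatment-minus-control contrasts are derived from these (fixed order
throughout the package): TGF-β vs WT, DOX vs DMSO, SB vs DMSO, dZEB vs WT,
TGF-β+dZEB vs dZEB, TGF-β vs TGF-β+dZEB, DOX+SB vs SB, and DOX vs DOX+SB.
Every expression table is a genes × 8 matrix of logFC with per-contrast
q-values; differential-expression testing itself is upstream of this package
and out of scope.

## Synthetic-data generator

`generate_expression_profiles` draws each gene's logFC vector as its class
template plus i.i.d. Gaussian noise, with five classes: E, M1, M2, M3 and
genomic background. Defaults, chosen once as the package's study conditions:

- **100 genes per class.** Comparable to the curated EMT list split across
  its classes, and large enough for stable rank statistics.
- **Templates.** The M-class entries for the induction and dependence
  contrasts carry the characteristic cluster medians (M1: 0.83 under TGF-β,
  0.0 under ZEB1 alone, 0.14 without ZEB1; M2: 1.01 / 0.57 with responses
  independent of the other factor; M3: 0.35 under TGF-β falling to 0 without
  ZEB1, 0.7 under ZEB1). Entries for the remaining contrasts are defaults
  consistent with each class's regulatory logic, flagged as such in the
  config — published cluster summaries give medians, not full 8-profiles.
- **noise_sd = 0.3 logFC**, a typical replicate-level dispersion for
  moderately expressed genes in a deeply sequenced transcriptome assay.
  Note a consequence measured by the test suite: at this noise the three M
  templates overlap enough after row scaling that even an oracle
  nearest-template classifier labels only ≈94% of M genes correctly, so
  perfect sub-cluster recovery is not attainable and the recovery tests
  document the pipeline's distance from that ceiling rather than a clean
  pass (E/M separation, a larger-margin problem, stays ≥95% accurate).
- **Annotated fraction 0.57** of E/M genes carry their curated annotation
  (mirroring a curated set of 416 annotated plus 319 unannotated EMT genes);
  the rest are 'none' and only receive propagated labels. Background genes
  are marked `emt = False`: the map is trained on the EMT list only, while
  background participates in responder calling, divergence and enrichment.
- **q-model.** Simulated q-values are BH-adjusted two-sided normal tails of
  |logFC|/noise_sd, computed per contrast across genes — monotone in effect
  size, exactly 0/1 in the zero-noise limit. This emulates the *output* of a
  count-based test without modeling counts.

Trajectories are discrete-time persistent random walks: step length =
speed × 15 min; the heading accumulates wrapped-normal noise with standard
deviation √(−2 ln ρ) so that the per-step heading correlation equals the
configured persistence ρ ∈ [0, 1] (ρ = 1 gives straight tracks, ρ = 0
uncorrelated headings). Cells start uniformly in a 500 µm square; no
interaction, confinement, division or death is simulated, so neighbor-count
statistics reflect density only.

What the generator does **not** emulate: mapping/sequencing noise,
heavy-tailed logFC outliers, correlated noise across contrasts (shared
controls induce correlation in real contrast tables), annotation errors in
the curated gene lists, and cell–cell interactions in the motility data.
Passing tests therefore demonstrate correctness of the analysis logic under
clean planted structure, not robustness to every artifact of real data.

## Divergence analysis

Responders per contrast: q ≤ q_max (default 0.05) and |logFC| ≥ threshold
(default 0, the base case; both overridable). The Jaccard analysis uses
direction-agnostic responder sets (union of up and down) because overlap
counts in this design include both activation and repression; a
direction-specific variant is available through the responder sets
themselves. A Jaccard index over an empty union is returned as an explicit
undefined marker and excluded from the one-sample t-test over the 28
per-pair differences J_E − J_M; zero-variance difference vectors are
reported as degenerate rather than assigned p = 0.

## SOM classifier

The map is an online SOM on a 10 × 10 hexagonal lattice (odd rows offset by
half a cell, rows √3/2 apart). Training presents the full row-scaled data
set 1000 times in per-epoch reshuffled order (seeded); the learning rate
declines linearly from 0.05 to 0.01 across all presentations. The
neighborhood is a bubble (hard radius) on inter-node Euclidean distance,
shrinking linearly from 2/3 of the grid diameter to below one inter-node
spacing, so training ends with BMU-only fine-tuning; this schedule is the
convention of the classical SOM environments, as the published description
fixes only the grid, the presentation count and the learning-rate schedule.
Codebooks initialize from random training samples. Row scaling uses the
sample standard deviation; constant rows scale to zero with a warning.

Node labeling uses the ≥ 2:1 dominance rule (nodes at exactly 2:1 are
flagged, since the rule's boundary reading is ambiguous); nodes without
genes are 'empty', nodes whose annotated genes miss the ratio — including
nodes with only unannotated genes — are 'mixed'. Genes in labeled nodes
inherit the node label; genes in mixed/empty nodes stay unlabeled.

M-dominant node codebooks are clustered by complete-linkage agglomeration on
Euclidean distance (the default of the classical environment; configurable),
cut at the k maximizing the second difference of the WSS curve (ties to the
smallest k), with an explicit override (e.g. k = 4) available. Clusters are
renamed M1, M2, M3 by descending gene count; further clusters collapse to
'other'. An optional low-variance node filter can exclude codebooks of
never-expressed genes (off by default). The two-cluster hierarchical
baseline runs on the same row-scaled profiles and labels each cluster by
majority annotation.

## Gate inference

For a cluster with contrast medians m_t (TGF-β), m_z (ZEB1), m_t∖z (TGF-β
without ZEB1) and m_z∖t (ZEB1 without TGF-β), with effect_min = 0.3 logFC
(the package's formalization of "responds"; configurable) and α = 0.05:

- AND: m_t ≥ effect_min, m_t∖z < effect_min, m_z < effect_min;
- OR: m_t, m_z ≥ effect_min and neither dependence Mann–Whitney test is
  significant (response unchanged without the other factor);
- ZEB1-only: m_z, m_z∖t ≥ effect_min and m_t∖z < effect_min;
- repressed-E: m_t, m_z ≤ −effect_min;
- otherwise indeterminate.

The OR rule's reliance on a *non-significant* dependence test means its
behavior depends on sample size; this is inherited from the underlying
analysis design and noted rather than resolved.

## Statistical primitives

The Mann–Whitney U test (shared by gate inference and motility comparisons)
enumerates the full permutation distribution when both groups have ≤ 10
observations — exact under ties, two-sided by distance of U from its mean —
and otherwise uses the tie-corrected normal approximation with continuity
correction. Fisher enrichment is one-sided toward over-representation by
default (the general-statistics convention elsewhere in the analysis is
two-sided; both are offered and the discrepancy is deliberate), with the
universe defaulting to all genes in the annotation table and no ontology
propagation. BH adjustment is the standard step-up with monotonicity
enforcement. Spearman correlations use midranks; constant vectors yield an
explicit undefined flag.

## Motility

Tracks must be strictly longer than 24 frames (6 h at 15-min frames).
Units are µm/min, fixed by the 15-minute frame interval. The neighbor count
treats the 30 µm search radius as inclusive. Per-condition metric summaries
for expression–motility correlation use the median across tracks (mean via
flag); whether the original analysis used medians or means is not stated.

## Circuit model

Six nodes: T (TGF-β signaling), Z (ZEB1), E, M1, M2, M3, each obeying
dX_i/dt = γ_i (F(σ_i W_i) − X_i) with F the logistic function and W_i the
basal weight plus weighted inputs. All parameters dimensionless; one time
unit ≈ one day. Defaults: γ = 1 everywhere; σ = 10 for switch-like nodes
(Z, E, M2, M3), 20 for M1 (sharpens the AND gate) and 2 for T (graded
receptor-level response, which lets ZEB1 activate T only partially).

Structural constraints enforced by `validate_gates`: each M1 input weight is
smaller than −ω⁰_M1 (since states live in (0,1), no single input can drive
W_M1 positive) while the joint input activates; each M2 input alone
activates; M3 and E receive only ZEB1 input (activating / repressing);
T and Z mutually activate; Z and E mutually inhibit. The mutual-inhibition
partner of ZEB1 (a miR-200/OVOL2/GRHL2-like factor) is identified with the
E node itself rather than a seventh node; a seventh-node variant is a
natural extension. Exogenous ZEB1 (s_Z) adds to the total ZEB1 activity seen
by every target; ZEB1 knockout silences only endogenous production, and SB
inhibition clamps T to zero (receptor-level block, so the Z→T feedback is
blocked too).

The shipped default weights were hand-constructed inside this constraint
region and verified against six qualitative behaviors: TGF-β-driven
bistability with an M branch persisting at zero signal (irreversible
commitment); knockout of ZEB1 yielding a partial state where only M2 rises
and the epithelial branch is recovered at zero signal (reversible);
ZEB1-driven irreversible transition with M1 staying low; loss of that
irreversibility under TGF-β inhibition; and the two corresponding
time-course protocols. `calibrate_default_parameters` reproduces a member
of this family by seeded random search over the same region, as no
quantitative parameter table was available to transcribe. The exogenous
signal axes default to 0–4 (TGF-β) and 0–1 (ZEB1, comparable to the
endogenous activity range).

Numerics: LSODA integration with analytic Jacobian (rtol 1e-8, atol 1e-10);
steady states by multi-start settling (24 seeded starts in [0,1]⁶ plus the
epithelial and mesenchymal corners, 200 time units) followed by Newton
refinement to residual < 1e-9; duplicates merged below 1e-6; stability from
the Jacobian spectrum. Reversibility of a protocol ending at zero signal is
judged by whether the final EMT score (M1+M2+M3−E) falls below the midpoint
of the stable branch scores at zero signal; if no stable state with a
negative score exists the verdict is an explicit indeterminate.

## Problem sizes

The default test and report conditions are 500 genes (100 per class), a
10 × 10 map trained with 1000 presentations, 120 trajectories of 160 frames,
17- and 11-point bifurcation grids with 24 starts per point, and 150-unit
time courses. The full pipeline completes in well under a minute per stage
on a single CPU.

## Known limitations

- The SOM is single-seed by design (multi-seed stability is exercised only
  in tests); no batch or landmark variants.
- Gate inference is a median-threshold formalization; clusters with
  heterogeneous membership can be called indeterminate.
- The circuit model omits intermediate-state cascades and additional
  feedback loops known to shape EMT dynamics, and does no limit-cycle
  continuation; bifurcation diagrams are fixed-point only.
- Survival aggregation consumes externally computed per-gene survival
  differences; no survival-curve estimation is performed.
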