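# Methods

## Scope and model

The package compares genome evolution between two named clades of a
rooted, time-calibrated phylogeny (branch lengths in My).  Its unit of
observation is the *branch*: per-branch gene-family count changes, per-
branch dN/dS values, and per-species enzyme repertoires derived from a
shared ancestor.  Branches carry deterministic identifiers (a hash of the
sorted descendant leaf set, with a chain index for the degenerate unary
case), so tables produced from any serialization of the same tree join
correctly.

### Ancestral family sizes and turnover events

Ancestral counts are reconstructed by Sankoff dynamic programming over
integer states 0..max(count) with linear per-copy costs (`gain_cost`,
`loss_cost`, both 1 by default).  The minimization is exact; ties are
resolved deterministically — smallest state at the root, and below it the
state closest to the parent's assignment (then smallest).  The per-branch
change is Δ = child − parent; the gain-and-loss rate of a branch scope is
Σ|Δ| divided by the summed branch time.  Zero-length branches are excluded
from every per-My denominator, and their events receive p = 1 in the rapid
test (a time-based null is undefined there).  A root-age denominator is
available as an option; the branch-sum default keeps the global, clade,
and per-branch definitions mutually consistent.

This parsimony reconstruction is a deliberately simple stand-in for
birth–death likelihood methods (CAFE-style) at the reconstruction layer;
the statistic layer on top of it — rates, flags, contrasts — is where the
analysis lives, and it accepts externally produced event tables
(`TurnoverResults.from_events`) in place of the built-in reconstruction.

**Validity regime and undercounting.**  Parsimony reports the minimal
change consistent with the leaves, so it can only undercount the true
process.  The undercount is small only while the expected number of events
per branch is well below one.  Measured against the generator's true event
tables: at the default 0.005 gains and 0.005 losses per copy per My
(roughly the range birth–death estimates take in real gene-family studies)
the relative error of the global rate is 8–14 % depending on tree shape;
at 0.02/copy/My it reaches ~26 %, and at 0.1/copy/My the critical
birth–death process saturates (several events per branch, heavy extinction
of whole families) and parsimony recovers barely half the realized events
while clade-rate contrasts lose direction entirely.  The defaults were
fixed in the valid sparse regime for this reason.  Users feeding real
count matrices should treat the global rate as a lower bound whenever
turnover is dense relative to branch lengths.

### Rapid events

The null for event significance is uniform turnover: the genome-wide
per-family event rate r̂ = Σ|Δ| / (n_families · total tree length) gives
each branch an expected event count λ = r̂·t, and an observed |Δ| = d ≥ 1
is flagged rapid when P(Poisson(λ) ≥ d) < α (α = 0.05).  The per-pair
type-I rate is below α *unconditionally*; note that among event-bearing
pairs the flagged fraction is much higher in sparse regimes, because a
single event on a short branch is itself improbable under the uniform
null (p = 1 − e^(−λ) < 0.05 whenever λ < 0.051).  That is selection, not
miscalibration, and the calibration test asserts the unconditional rate.

### Clade contrast statistics

* **Rapid-event enrichment**: per family, a 2×2 table of clade × (rapid,
  non-rapid) branch counts, Pearson chi-square without Yates correction
  (configurable), odds ratio ad/bc with the Haldane–Anscombe +0.5 applied
  to all cells iff any cell is zero.  Families with no rapid event in
  either clade are excluded before the BH adjustment, so the FDR is over
  tested families only.
* **Rate / size / location contrasts**: Mann–Whitney U.  When the pooled
  sample is ≤ 12 the p-value is exact by full enumeration of the
  C(n_a+n_b, n_a) labelings with midrank ties (so a fully tied sample has
  one-sided p = 1, the exact value); larger samples use the tie- and
  continuity-corrected normal approximation.  One-sided decisions
  additionally require the observed direction.
* **Presence rules**: presence means count ≥ 1.  "Over 70 %" and "more
  than 20 %" are strict inequalities; "no more than 2 %" is inclusive —
  the literal reading of the rules.  Missing and novel-core families
  require complete absence on the other side by default; a fraction knob
  relaxes this.
* **CoV**: sample (n−1) standard deviation over the mean; undefined (NaN,
  logged) for n < 2 or zero mean.  Decile screens use empirical quantiles
  with inclusive boundaries.
* **BH FDR** is the standard step-up adjustment (via statsmodels).  Note
  it is not idempotent — re-adjusting adjusted p-values is a user error,
  not a supported operation.

### Pathway coverage

The ancestral pathway of each reference pathway is combine(outgroup EC
sets) ∩ pathway ECs, with combine = union by default (intersection and
majority > 50 % available; union maximizes retained ancestral content when
outgroup annotations are incomplete).  Pathways are kept with ≥ 5 retained
ECs and a reference-species flag.  PC(s, p) = |ECs(s) ∩ retained(p)| /
|retained(p)|.  EC matching is literal by default; a wildcard mode lets an
annotated `1.1.1.-` match any retained EC agreeing on the specified
components.  Contrasts: a global pooled one-tailed U test over all
(pathway, species) PC values, per-pathway tests in both directions with BH
per direction (joint-BH optional), and per-superpathway one-tailed tests
on the pathways' PC-CoV values (superpathways with < 2 kept pathways are
skipped).

## The synthetic generator

The generator emulates the statistical structure the analyses assume, not
any particular dataset:

* **Counts**: per family, a root copy number (geometric(0.5), support
  ≥ 1, mean 2) evolves along each branch by a linear birth–death process
  per copy, simulated event-by-event; zero is absorbing (a gained gene
  needs a template).  Clade multipliers scale both rates on the clade's
  branches.  Defaults: 2,000 families, 0.005 gains and 0.005 losses per
  copy per My — chosen once, in the regime where the parsimony stand-in is
  valid and per-family turnover over a 500-My tree is a handful of events,
  as in real orthogroup data.
* **Branch ω**: base 0.2 (typical purifying dN/dS) times a clade factor
  times mean-one lognormal noise with chosen CoV (default 0.3; the
  dispersion-shift study uses 0.6 vs 0.2).
* **EC repertoires**: outgroup species carry the full pathway EC sets;
  every other species drops each EC independently with its clade's loss
  probability (effect studies use 0.3 vs 0).

Randomness is split into counter-based substreams
(`SeedSequence(seed, spawn_key=(stream, unit))`) per family/species, so
outputs are byte-identical for a given seed regardless of iteration order.

**Trees.**  Two designs: a 32-leaf random coalescent-shaped demo tree
(8 outgroup + 12 + 12, total length rescaled to 500 My) mimicking the
shape of a real dated phylogeny, and a deterministic *balanced* study tree
(8 + 32 + 32 leaves, equal branch lengths, total 500 My) used for
calibration and power studies.  The balanced design removes branch-length
randomness so that study outcomes vary only with family-level noise; the
larger clades (62 branches each) give the per-family Mann–Whitney tests
the sample size they need — with 12-leaf clades (22 branches) the
per-family rate contrast cannot reach high recovery at any turnover rate,
a power constraint, not an implementation one.

**What passing tests do not show.**  The generator draws families i.i.d.,
uses a single global rate with clean multiplicative clade effects, and
attaches no annotation error, assembly artifacts, or gene-tree discordance.
Passing calibration and recovery on it demonstrates the statistics behave
as designed under their own assumptions; it says nothing about robustness
to correlated families, rate heterogeneity among families, or annotation
noise in real genomes.

## Study designs in the acceptance suite

* Null calibration: balanced study tree, 2,000 families, no clade
  effects; each scan's flagged fraction at FDR 0.05 is reported.  The
  branch-level scans (rapid enrichment, rate contrast, ω contrast)
  measure ≈ 0 %.  The species-level size contrast measures ≈ 18–26 % and
  is reported as such: under a tree-structured null, drift on stem and
  deep branches creates genuinely clade-coherent size differences, and a
  species-level test — which assumes exchangeable species — correctly
  rejects.  This is the familiar phylogenetic pseudo-replication problem;
  interpreting species-level family-size scans on real data requires the
  same caution.
* Effect recovery: the same tree with a 5× turnover multiplier on one
  clade (≈ 58–64 % of families flagged), and 30 % enzyme loss in one clade
  for the pathway contrast (global p ≪ 10⁻⁶, all reduced pathways
  flagged).
* Oracle equivalence: the exact Mann–Whitney path against an independent
  enumeration oracle (U by pairwise comparison), and the Sankoff DP
  against exhaustive ancestral-state enumeration on trees ≤ 6 leaves.
* Conservation: for every family and leaf, summed Δ along the root-to-
  leaf path telescopes exactly to leaf − root count.
* Determinism: two identically seeded demo-pipeline runs produce
  byte-identical files (SHA-256).

## Known limitations

* Parsimony undercounts dense turnover (quantified above) and cannot
  separate a gain on one sister branch from a loss on the other when the
  data are symmetric; tie-breaks make a deterministic, conservative
  choice (toward fewer/lower ancestral copies).
* The Poisson rapid-event null assumes one global rate; genuinely
  heterogeneous families make its p-values conservative for slow families
  and liberal for fast ones.
* The species-level size contrast is not calibrated against phylogenetic
  drift (see above); branch-level contrasts are the better-behaved tools.
* EC-based pathway coverage inherits all biases of the upstream
  annotation; coverage is membership-only and ignores pathway topology,
  so a "complete" pathway can still be non-functional and vice versa.
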