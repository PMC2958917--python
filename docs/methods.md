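# Methods

## The differential-survival test

A mutation that arose long ago and kept spreading subtends many of
today's haplotypes; a young or doomed mutation subtends few.  On a
haplotype network rooted with an outgroup, every oriented mutation
(an edge's single site change, read ancestral → derived away from the
root) defines a derived clade, and its descendant-haplotype count *f* —
the number of **observed** haplotypes on the derived side of the edge —
is the survival proxy.  Under neutrality the effect class of a mutation
(synonymous vs nonsynonymous) is independent of its genealogical
position, so the two classes' *f* values are exchangeable; positive
selection pushes nonsynonymous *f* upward, purifying selection downward.

Mutations with *f* < 3 are discarded before testing: singletons and
doubletons are dominated by drift and have not yet been through the
survival filter (the threshold is the `min_f` option).  The remaining
counts are compared by a Mann–Whitney rank test with midranks for ties,
reported with the convention that positive z means nonsynonymous
mutations rank higher.

Three p-value routes are provided:

* **normal approximation** — tie-corrected variance
  `Var(U) = n1*n2/(N(N-1)) * ((N^3-N)/12 - sum(t^3-t)/12)` and a 0.5
  continuity correction (switchable with `continuity=False`);
* **exact permutation** — the exact distribution of U over all label
  assignments, computed by dynamic programming over tie groups (feasible
  for any group sizes that arise here); the two-tailed p doubles the
  smaller tail;
* **auto** — exact when `n1*n2 <= 400`, else normal.

The two routes agree well in the moderate tail, but in the deep tail
(p ~ 1e-4 and beyond, as in the bundled worked example) the normal
approximation overstates the exact doubled-tail probability several-fold;
this is a generic property of normal-type approximations under heavy
ties, not a numerical defect, and an Edgeworth-corrected tail does not
close the gap either.  Inferences should quote the exact p when the
sample permits it; both are reported.

The bundled example table (44 internal *fruitless* C3 mutations, 9
nonsynonymous vs 35 synonymous) reproduces the published tied ranks
exactly from its *f* column; the recomputed statistics are U(nonsyn) =
288.5, z = 3.90, normal p = 9.5e-5, exact p = 2.1e-5.  These recomputed
values, not any printed summary statistics, are the package's regression
values; only the p ≤ 0.02 significance bound is treated as a
reproduction target.

Templeton's contrast — interior/tip × nonsynonymous/synonymous counts —
is evaluated with Fisher's exact test (expected counts are routinely
small); the sample odds ratio takes a 0.5 Haldane correction only when a
zero cell exists, and is flagged when it does.

## Statistical-parsimony networks

Distinct haplotypes (collapsed on the analyzed columns of the region,
see *Data conventions*) are connected agglomeratively: candidate pairs in
increasing Hamming distance, a pair at distance *d* joined through
*d* − 1 single-step intermediates unless a path of length ≤ *d* already
exists, and pairs beyond the connection limit left unconnected.  Pair
order within a distance class prefers higher sample counts, then higher
current degree, then lexicographic ids — a deterministic rendering of
the frequency/topology preference criteria of the TCS approach.

**Connection limit.**  With *j* observed differences over *m* analyzed
columns, per-site substitution counts are modeled as Poisson with mean
given by the Jukes–Cantor correction of p = j/m; the connection is
parsimonious when every observed difference is due to exactly one
substitution, so `P(j, m) = P(exactly one hit | visibly different)^j`,
and the limit is the largest *j* with P ≥ 0.95 (`--alpha`), overridable
with `--max-steps`.  This is the package's rendering of statistical
parsimony; it reproduces the magnitudes familiar from TCS (about 9–13
steps for 0.6–1.2 kb).  For 721 columns the 95% limit is 10 steps
(frozen as a regression value).

**Intermediate placement.**  Within a chain the differing sites are
flipped in ascending order of the carrier count of the current state.
On homoplasy-free data the haplotypes carrying one endpoint's state at a
path mutation are exactly the haplotypes on that endpoint's side of the
edge, and these grow monotonically along the path — so this order
reconstructs the true ancestral intermediates and lets different chains
reuse them.  Ties (path segments with no sampled lineage branching off)
are broken by undoing putatively derived states first (outgroup state
where informative, majority state otherwise) and by preferring a flip
that lands on an existing node, keeping re-walked segments
direction-independent.  On simulated infinite-sites data the result is
exactly the true tree restricted to the sample (verified as the
Steiner-minimal single-step network by exhaustive search on small
cases).  On data with homoplasy, residual alternative connections can
form loops; mutations on loop edges (non-bridges) are excluded from
orientation with a logged count.

## Orientation, effect classification, counting

The network is rooted, per connected component, at the node with the
fewest differences from the outgroup over the columns where the outgroup
is A/C/G/T (ties: higher sample count, then node id).  Edges are
oriented away from the root by breadth-first traversal.  A mutation is
dropped from the oriented set when the outgroup carries a gap/N or a
state matching neither allele at its site.  Without an outgroup,
`fallback=True` roots at the highest-count haplotype (frequency
criterion) and flags every mutation `confidence="frequency"`.

Effects are classified on the **parent node's codon** — the ancestral
background along the root-to-edge path — under the standard genetic
code.  Because edges carry exactly one site change by construction, two
mutations striking one codon are necessarily on different edges and each
is evaluated on the background present when it arose; joint same-codon
pathway averaging is therefore never needed in the network path (it is
used in the Nei–Gojobori diversity computations).  Codons broken by
excluded columns give `effect="indeterminate"` (excluded from tests,
logged).

*f* counts distinct observed haplotypes on the derived side (inferred
intermediates never count).  The published worked example requires this
reading — its largest count, 60, approaches the total haplotype count,
not the sample size — but `count="individuals"` switches to carrier
individuals for sensitivity analysis.  A mutation is a **tip** mutation
when its derived side contains exactly one observed haplotype and that
node is a tip (degree ≤ 1); otherwise **interior**.

## Diversity and SFS statistics

All site statistics use complete deletion: columns with a gap or N in
any ingroup sequence are excluded everywhere, and haplotype identity is
defined on the analyzed columns of the region under study (exon and
intron collapse independently).

* Hd = n(1 − Σp²)/(n − 1) with Nei's sampling variance.
* π = mean pairwise differences per analyzed site; its SD uses the
  standard no-recombination (stochastic + sampling) variance.
* πs/πa by uncorrected Nei–Gojobori pathway counting: per-codon
  synonymous site fractions (changes to stop codons count as
  nonsynonymous), pathway-averaged Sd/Nd per codon pair with
  stop-containing pathways discarded unless all are, per-pair
  normalization by the pair's mean site counts.  Ls + La equals the
  analyzed coding length by construction.
* θW = S/(a₁L) with the usual variance `theta/a1 + a2 theta²/a1²`.
* Polymorphic coding sites are Sy when every observed state pair is
  synonymous on every observed codon background, otherwise NSy; `sg`
  counts biallelic and `m3` multi-state segregating sites (sg + m3 = S).
* Tajima's D with the standard e₁/e₂ constants (NA when S = 0 or n < 4).
* Fu & Li's D and F, outgroup versions, with the Simonsen-corrected
  normalizing constants; η is the number of derived states over
  polarizable segregating sites and η_e the derived singletons.
* Fay & Wu's H = θπ − θH, the unnormalized per-locus form (matching the
  magnitudes reported for data like Table 5 of the motivating study).

Polarization uses the outgroup base at each analyzed column; sites where
the outgroup is not A/C/G/T or carries a state absent from the ingroup
are skipped and their number reported.  At multi-state sites each
non-ancestral state contributes one derived class (an infinite-sites
approximation).

Significance of the SFS statistics is assessed against a **fixed-S
neutral coalescent null**: genealogies sampled from the Kingman
coalescent, exactly S mutations dropped proportionally to branch
lengths, two-tailed empirical p with add-one smoothing, 10,000 replicates
by default, seeded.

The two-sample z contrast for diversity estimates is
z = (e₁ − e₂)/√(s₁² + s₂²).  Applied to the printed πa/πs values and SDs
of the motivating study's Table 4 this gives z ≈ −9, not the < −30 the
text reports; the operation implements the stated formula and no
reproduction claim attaches to that comparison.

## The simulator and calibration

`SimConfig` defaults are the study conditions used throughout:
n = 50 sequences, L = 720 coding columns, θ = 20 per locus (≈ 0.028 per
site — the per-species scale of the motivating data), outgroup
divergence 0.005 substitutions per site.  The outgroup is deliberately a
*close* relative: polarized statistics (Fay & Wu's H especially) are
biased by outgroup homoplasy at roughly −2(n−2i)/(n−1) per mispolarized
site, so calibration against a distant outgroup would measure that bias
rather than the statistics.  Truth-recovery oracles use divergence 0
(outgroup = ancestral sequence) to isolate the counting logic.

Neutral mode is the standard Kingman coalescent with infinite-sites
mutations (collisions re-drawn); the ancestral sequence is built from
sense codons and mutations avoid creating stops on their background, so
effect classification stays biologically sane.  Sweep mode truncates the
coalescent at `tau` (scaled time since a completed hard sweep): lineages
still distinct at `tau` coalesce there in a star join, except that each
escapes independently with probability `sweep_escape_prob` (default 0.1)
and coalesces neutrally above — the standard genealogical shorthand for
recombining off the swept background during the sweep.  Escape lineages
are essential, not decorative: a complete no-recombination hard sweep
produces only a singleton excess, whereas the post-sweep signature being
emulated is the *coexistence* of low- and high-frequency derived
variants, and the high-frequency class arises from mutations on the long
branches that separate escaped lineages from the swept majority.
tau = 0 with escape 0 degenerates to a zero-depth star (a monomorphic
locus); with growing tau the truncation stops binding and everything
converges to the neutral model.

`calibrate` runs the full pipeline (collapse → network → orient →
classify → filter → rank test) or an SFS test per replicate and returns
the rejection rate with a binomial CI, excluding (and counting)
replicates where a test cannot run.  SFS p-values reuse a fixed-S null
cache keyed by the observed S.  For the survival test the harness
calibrates the tie-corrected z **without** continuity correction: under
the heavy ties of f-counts the exact permutation test and its
continuity-corrected approximation are conservative by construction
(measured rejection ≈ 0.016 and 0.023 at nominal 0.05 under the default
conditions), so nominal-size calibration is only informative for the
plain z (≈ 0.04).  All three variants remain available through the
`method`/`continuity` arguments.

Problem sizes used by the shipped calibration studies: 1000 replicates
for the type-I and neutral-mean checks, 250 per mode for the sweep power
ordering with 200-replicate nulls, chosen as the smallest sizes at which
the binomial/Monte-Carlo error is well inside the tolerances being
checked.

**What the simulator does not emulate:** recombination within the locus
(a config hook is reserved; the motivating data showed no recombination
signal), demography (growth, structure, bottlenecks other than the
sweep), codon usage bias and unequal base composition, transition/
transversion bias, overlapping reading frames, sequencing error, and
alignment uncertainty.  Passing calibration therefore shows the
statistics and the pipeline are correct and calibrated under clean
neutral/post-sweep genealogies — not that the survival test is robust to
demographic confounding on real data, where (as with all SFS-based
tests) demographic alternatives must be weighed.

## Numerical conventions and degenerate inputs

* Coordinates are 0-based half-open internally; all user-facing exports
  and the CLI use 1-based positions.
* Haplotypes order by (descending count, lexicographic sequence);
  node ids, edge processing and chain construction are deterministic, so
  identical inputs give byte-identical outputs, independent of input
  sequence order.
* Mann–Whitney: all observations tied → z = 0, p = 1 (degenerate guard);
  empty group → error; the exact two-tailed p is min(1, 2·min(tails)).
* LRT statistics negative beyond 1e-6 are clamped to 0 with a warning
  (optimizer noise in upstream fits); the mixture p at 0 is 1.
* Tajima's D and Fu & Li's D/F report NaN when undefined (S = 0, or all
  sites unpolarizable).
* IUPAC ambiguity codes on input are demoted to N with a warning.

## Known limitations

* The connection-limit model is this package's own multiple-hit
  rendering of statistical parsimony; it matches the magnitude of
  published TCS limits but is not a line-by-line reimplementation of the
  original recursion.
* Loop resolution beyond the deterministic construction rules is not
  attempted; mutations on residual loops are excluded rather than
  averaged over resolutions.
* The exact Mann–Whitney route enumerates the permutation distribution
  of U; for very large groups (n1·n2 ≫ 400) only the normal route is
  practical (automatic).
* πs/πa standard deviations reuse the no-recombination π variance with
  the synonymous/nonsynonymous site counts; this is an approximation, as
  is any single-number SD for pathway-averaged quantities.
* Fu & Li's starred (no-outgroup) variants are not implemented; the
  frequency-based orientation fallback is provided for the network test
  but outgroup-requiring SFS statistics simply report NA.
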