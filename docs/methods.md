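# Methods

## Study design being modelled

The package analyses a two-library, pooled circulating small-RNA
experiment: many donors' serum pooled into one sequencing library and
plasma into another, so there is exactly one count per feature per fluid
and no replicate-level variance estimate. All statistics are therefore
count-based with a Poisson sampling model, not dispersion-based (no
negative-binomial GLM); this is the appropriate regime for comparing two
pooled tag libraries and the explicit scope of the package.

## Demultiplexing

Reads are base-space, laid out as a 6-nt barcode followed by the insert
and optionally a 3' adaptor. Decoding accepts the unique barcode within
Hamming distance 1; if two or more barcodes are within distance 1 the read
is ambiguous and discarded, if none is it is unmatched. An `N` mismatches
every base, including another `N` — conservative and deterministic.
Adaptor trimming is exact-substring at the leftmost occurrence; a read
with no adaptor occurrence keeps its full post-barcode tail. Insert length
bounds default to 15–35 nt, a small-RNA window around the 22-nt mode;
inserts outside the window are classed `no_insert`. Mean-quality filtering
exists but defaults off, since no quantitative quality rule is part of the
modelled protocol. Every read lands in exactly one of five filter classes
and the class tallies always sum to the input count.

## Annotation cascade

Classification is by containment: an insert matches a reference if either
is a substring of the other, exact by default (`mismatches=0`), with a
sliding-window Hamming tolerance up to 2 available. Categories are tested
in a fixed priority order — rRNA, tRNA, snRNA, snoRNA, then miRNA/miRNA\*
— so a read consistent with both a structural RNA and a miRNA is counted
as the structural RNA ("filter first, count second"). Within-category ties
go to the lexicographically smallest feature name and are tallied in an
ambiguity counter; each read contributes to at most one feature. Strand
is respected (no reverse-complement matching): small-RNA libraries are
stranded. Star strands (miRNA\*, the passenger strand of the pre-miRNA
duplex) are distinct features, counted and reported both separately and
combined. Percentages are computed over all demux-surviving inserts.
Features flagged `excluded_as_fragment` — miRNA-annotated sequences that
are actually cleavage fragments of another RNA class — are removed from
count tables after counting, so the exclusion is auditable.

## Quantification

The reliable profile keeps raw counts strictly greater than 10; the
abundance set uses strictly greater than 20 by default with a `strict`
flag exposing the ≥ variant, since both conventions circulate. CPM is
computed over the *post-filter* miRNA profile (each profile then sums to
10⁶ exactly), not over total sequenced reads — normalizing the expression
profile actually carried forward. The comparison universe is the union of
both libraries' post-filter features, absent features carrying count 0.

## Exact test for two Poisson rates

Under equal concentrations, x ~ Poisson(λN₁) and y ~ Poisson(λN₂);
conditioning on t = x + y eliminates λ: x | t ~ Binomial(t, N₁/(N₁+N₂)).
The two-sided P doubles the smaller of P[X ≤ x] and P[X ≥ x], capped at 1;
x = y = 0 is defined as P = 1 (no evidence). The test is symmetric under
library swap and monotone in |x − y| at fixed t. An Audic–Claverie-style
alternative (posterior-predictive negative binomial, r = x + 1,
p = N₁/(N₁+N₂)) is provided for cross-checking; the two agree in ordering
on small grids but are distinct statistics. Doubling the smaller discrete
tail makes the test conservative: at per-feature mean 10 (10,000 features
at depth 10⁵) its exact rejection rate at nominal 0.05 is 0.0293, rising
toward 0.05 as counts grow. No multiple-testing correction is applied to
DE calls by default (raw thresholds); Benjamini–Hochberg is available via
a flag.

Calls: up iff CPM fold change > f and P < α; down iff fold change < 1/f
and P < α; defaults f = 2, α = 0.001 (the stricter of the two thresholds
in circulation for this workflow; configurable to 0.01). Fold change is
computed on CPM, which corrects for depth; when exactly one side is zero a
half-CPM pseudocount is added to both sides, and both-zero is NaN. Features
detected on only one side are flagged `serum_only`/`plasma_only` and not
called — a fold change against an unobserved denominator is reported as
exclusivity, not magnitude.

## Clustering

Called features are clustered on log₂(CPM+1) with average linkage on
Euclidean distances (SciPy); ties break by input order, making the leaf
order deterministic. The merge tree exports as Newick with merge heights
as branch lengths.

## Enrichment

The query is the set of genes targeted by at least `min_mirnas` (default
2) differential miRNAs; the miRNA→gene map is consumed as a file (target
prediction itself is out of scope). Terms are tested with the
hypergeometric upper tail P[X ≥ k] via stable log-combinatorics; the
universe M is all genes annotated in the term's namespace (GO-process and
KEGG namespaces get separate universes), and query genes outside the
universe are dropped for that namespace. "Benjamini" correction is
implemented as Benjamini–Hochberg FDR (with Bonferroni and none as
options). Terms with zero hits are reported (P = 1) but excluded from the
correction denominator. Significance requires corrected P < 0.05 *and*
k ≥ 2 hit genes.

## RT-qPCR

Triplicate Ct values are averaged arithmetically; missing replicates are
tolerated down to one with an `incomplete` flag. ΔCt = Ct_miRNA − Ct_U6
within each fluid; ΔΔCt = ΔCt_serum − ΔCt_plasma; fold change =
E^(−ΔΔCt) with amplification efficiency E = 2 (100%) by default —
standard-curve efficiency estimation is out of scope, but E is a
parameter. Cross-platform agreement is the Pearson correlation of log₂
fold changes (sequencing log₂FC vs −ΔΔCt) over shared miRNA names; log
scale is the only scale on which the two platforms are commensurate. Fewer
than three shared miRNAs or zero variance yields a flagged undefined
result.

## Synthetic-data generator

The generator emulates the statistical structure of the modelled
experiment; all randomness flows from one integer seed through
per-operation streams, so identical configurations reproduce outputs bit
for bit.

* **References**: random-sequence stand-ins per category (miRNA 22–24 nt,
  tRNA 75, snoRNA 80, snRNA 95, rRNA 120 nt); `round(0.15 · n_mirnas)`
  star strands; one decoy miRNA flagged as a tRNA fragment so the
  exclusion path is exercised.
* **Reads**: barcode + insert (+ optional adaptor in "raw mode"), insert
  lengths drawn from a distribution peaked at 22 nt
  (20:0.05, 21:0.20, 22:0.50, 23:0.15, 24:0.10) and capped at the
  reference length; per-base substitution errors at a configurable rate
  (default 0: the error model is a knob for robustness probing, not part
  of the null). Default compositions make serum tRNA-dominated
  (74.6% tRNA, 21.0% miRNA) and plasma miRNA-dominated (52.0% miRNA),
  the hallmark fluid difference for circulating small RNA.
* **Counts**: plasma proportions from lognormal abundance weights
  (σ = 1.0 default — realistically skewed; an optional `min_cpm`
  water-filling floor guarantees every feature a minimum base abundance
  when a fixture requires all features detectable). Serum proportions are
  plasma proportions times the per-feature fold change, renormalized;
  serum-exclusive features have plasma proportion exactly 0. Counts are
  independent Poisson at depth × proportion; a gamma-mixed overdispersion
  knob exists and defaults off, matching the Poisson null of the test.
  Defaults: 10% of miRNAs truly differential at fold change 4, of which
  25% point down (mirroring the mostly-up, partly-down balance typical of
  serum-vs-plasma contrasts); 5% serum-exclusive; depth 10⁵ per library
  (2.9M/6.9M full-scale runs are reachable through `n_reads`).
  Because proportions renormalize, an unbalanced DE set shifts every null
  feature's effective CPM ratio away from 1 (compositionality); with the
  default direction mix the shift is small (~0.9) and null features stay
  well inside the fold-change gate.
* **qPCR**: Ct triplicates constructed so the noise-free ΔΔCt equals
  −log₂(true fold change) exactly (U6 at 20 cycles, miRNA baseline 28),
  with Gaussian replicate noise (default sd 0.1 cycles) on every row.
* **Target/term maps**: random miRNA→gene maps over a synthetic gene
  universe and random GMT-style term maps, with one term seeded from the
  query so an enrichment signal exists by construction.

What the generator does **not** model — and hence what passing tests do
not establish about real data: ligation and amplification sequence bias,
realistic quality-score degradation, cross-mapping between homologous
miRNA family members, hairpin/Dicer biogenesis, biological replicate
variance (pooling removes it by design), and overdispersion beyond the
optional gamma knob. Results on real libraries depend on annotation
database versions and mapping tolerance in ways the synthetic channel
cannot probe.

## Numerical and scale choices

Test and acceptance fixtures run at desk scale: 10⁴–10⁵ reads per library
for read-level stages, 10⁵–10⁶ expected counts for count-level stages,
200 miRNA features (10,000 for calibration checks). These sizes were
chosen so each check's sampling error is far below its assertion margin —
e.g. composition recovery at 10⁵ reads has binomial noise ≲ 0.3 points
against a 2-point tolerance. Oracle comparisons (conditional-binomial and
hypergeometric enumerations) are exact to 1e-12. The canonical
differential-expression fixture uses `min_cpm = 100` at depth 10⁶ so every
feature clears the count>10 filter and exclusive-detection recovery is
exact rather than truncation-limited; the read-level end-to-end fixture
scales the floor accordingly (`min_cpm = 5000` at 4×10⁴ reads).

## Known limitations

* Exact-substring annotation (default) under-counts reads carrying
  sequencing errors; the mismatch-tolerant mode is quadratic in reference
  count and meant for small reference sets.
* The conditional exact test is conservative at low counts (see above);
  at per-feature means below ~5 its power is limited and the count>10
  filter exists partly for this reason.
* Compositional renormalization means "fold change" is relative to the
  profile, not absolute concentration — as in any library-normalized
  sequencing comparison without spike-ins.
* The enrichment universe is the annotation file's gene set; results are
  only as meaningful as the supplied target and term maps.
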