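# Methods

## Model

`paccmit` scores a miRNA–3′UTR pair by over-representation of the seed-match
word. The word is the reverse complement (in DNA, U→T) of the miRNA
subsequence at 1-based positions `[seed_start, seed_start + seed_len − 1]`;
the default 2–8 gives the canonical 7-mer seed, and both parameters are
free, so 6-, 8-mer or shifted seeds are supported. Matching is exact — no
wobble pairs, no mismatches, no 3′-supplementary pairing or context
features.

The score is the upper binomial tail

    P_SH = P(X ≥ c_filter),   X ~ Binomial(t_filter, p_word),

with `t_filter` the number of eligible k-mer windows of the UTR,
`c_filter` the number of seed matches among them, and `p_word` the word's
probability under a zeroth-order background model. The binomial form treats
window occupancies as independent trials; that independence is an
approximation (overlapping windows are correlated), which is why a
Monte-Carlo calibration backs the unit tests. The tail itself is computed
exactly through the regularized incomplete beta function (scipy's
`binom.sf`), accurate down to ~1e-300; no series approximation is used.
`P_SH(t, 0, p) = 1` exactly, and pairs with `c_filter = 0` are flagged
non-predictions and excluded from ranked output rather than emitted as
`P_SH = 1` rows.

Ranking is by ascending `P_SH` with deterministic tie-breaking (descending
`c_filter`, then `gene_id`, then `mirna_id`), so rankings are bit-for-bit
reproducible.

### Background model

`p_word` is the product of the mononucleotide frequencies of the word's
letters, computed from the scored UTR itself (N bases excluded from the
counts). Per-UTR composition is the most local, assumption-light choice;
a global composition table can be supplied instead (`--background global`).
Composition is computed from the full sequence, not from filtered windows
only — the filter restricts which windows count, not what the background
is. If a needed letter has frequency zero while a match was observed, the
model is inconsistent with the data and scoring raises.

### Window universe and N handling

`t` and `c` are counted over the same universe: k-windows that contain no
N. A window containing an unknown base can neither be claimed as a match
nor counted as an eligible trial. This guarantees `c ≤ t` by construction
in every filter mode.

## Filters

Filtering never changes the score's form — only which windows enter `t`
and `c`. Four modes: `none`, `access`, `cons`, `cons+access` (the
intersection: windows both conserved and accessible, regardless of
complementarity to the seed, form `t`; seed matches among them form `c`).

### Accessibility

A k-window is accessible iff at least one of its `k − u + 1` contained
u-mers (u = 4) is unpaired with probability `P_free ≥ P_cutoff`. The
comparison is **inclusive** and `P_cutoff` defaults to 0.2. `P_free`
profiles are inputs, parsed from the `_lunp` dialect of windowed
partition-function folding (RNAplfold, `-u 4`, window W = 80, maximum
pairing span L = 40); the partition function is never recomputed here. The
`_lunp` row convention is fixed as: the row with first column i (1-based)
gives the probability that the u-mer **ending** at i is unpaired, so the
u-mer starting at 0-based s ends at 1-based s + u. "NA" cells (always
present for i < u) are undefined; a window whose contained u-mers are all
undefined is classified inaccessible — absence of evidence is not
accessibility, and the rule is deterministic and testable.

### Conservation

Conservation is **positional**: the multiple alignment defines orthology,
and a species carries a site only if its row at exactly the ref-bearing
columns of the window (the columns holding the reference's k letters) is
gap-free and spells the word. Columns where the reference is gapped
(insertions in other species) are skipped; a gap in the species at a
ref-bearing column — an indel inside the site — breaks it. A species absent
from the alignment is an all-gap row and never carries a site. Two rules:

* **Any-S** — at least S species carry the site, the reference included
  (Any-1 is therefore equivalent to no filter), regardless of identity.
* **Selected-S** — every species of a fixed list carries it. The default
  ladder orders species by increasing distance from human: chimp, rhesus,
  mouse, dog, cow, chicken; Selected-4 (human, chimp, rhesus, mouse) is the
  package default.

For the filtered total `t_cons`, the rule is applied to *every* window,
taking the reference k-mer at that window as the word. The implementation
vectorizes this with a per-species, per-position match array and a sliding
window; the per-window predicate (`is_conserved`) is retained and the test
suite checks the two agree exactly, including on gapped references.

MAF species names are keyed by the text before the first dot of the source
field ("assembly.chrom" convention). Alignments are normalized to the
reference + strand at read time; 3′UTRs are stored as sense-strand mRNA.
Coordinates are 0-based half-open everywhere internally.

## Evaluation harness

Negative sets are sampled uniformly without replacement from
miRNAs × unbound genes, sized equal to the positive set so precision is
well spread in (0, 1). miRNA sets are split into three near-equal
subgroups ("small" datasets; 74 → 25/25/24, 26 → 9/9/8) under a recorded
seed — the split is randomized since no stratification is prescribed.
"Predictions per miRNA" is realized as global ranking depth divided by the
number of miRNAs; a per-miRNA top-k variant exists behind a flag for
sensitivity analysis. Predictions outside the labeled universe are ignored
by the metrics; precision is reported as missing when no labeled prediction
falls above the cut. Rank-bin analysis supports doubling bins
(10, 20, 40, …) and fixed-size bins, reporting mean log₂FC, SEM, and n per
bin. Significance helpers delegate to scipy (one-sided paired t test across
small-dataset replicates; one-sided Wilcoxon rank-sum between log₂FC
samples). A labeling helper classifies expression rows functional at
log₂FC ≤ −0.2.

## Synthetic data

The generator emulates the *structure* of a target-prediction study, not
its physics:

* UTRs are i.i.d. draws from a base composition (default uniform,
  lengths 500–1000 nt).
* Accessibility is planted, not folded: profiles separate a high value
  (0.9) inside designated windows from a low band (≤ 0.05) elsewhere, so
  classification at the 0.2 cutoff is exact by construction. Geometry
  note: an interior k-window can be isolated only if one of its u-mers is
  contained in no unlisted window, which requires listed runs of length
  ≥ k − u + 1 (or a sequence end); infeasible requests raise.
* Conservation is planted likewise: species copy the reference inside
  designated windows and mutate i.i.d. (rate 0.3 per site per species)
  outside; no indels by default, no substitution model beyond that.
* Benchmarks pair each gene with one miRNA, half functional and half not.
  In the *highly conserved* scenario, functional sites are conserved and
  accessible while decoys are never conserved (accessible with
  probability 0.5); in the *weakly conserved* scenario, functional sites
  are accessible but not conserved while decoys are conserved but
  inaccessible — by design, the conservation filter is informative in the
  first scenario and misleading in the second.
* Functional site counts follow a decaying "cohorts" design (≈ n/20 genes
  with 5 sites, 2× that with 4, 4× with 3, 8× with 2, the rest with one):
  most targets have a single site, strong multi-site targets are rare.
  Expression is log₂FC = −effect · (number of planted sites) + Gaussian
  noise (defaults: effect 0.5 per site, sd 0.3), so the ranked list has a
  graded top and rank-bin means can resolve the ranking/downregulation
  correlation. A uniform site-count design is available as an alternative.

Passing tests on these fixtures demonstrates that the counting, filtering,
scoring and evaluation logic is correct and that the filters behave as
designed when their premises hold. It does **not** demonstrate predictive
performance on real data: real accessibility comes from folding
thermodynamics, real conservation from phylogeny, and real
miRNA regulation has effect-size structure far richer than a per-site
constant.

## Numerical and design choices

* Overlapping seed-match occurrences all count in `c`, consistent with `t`
  counting every window.
* Exact binomial tail; oracle tests pin it to direct pmf summation at
  1e-12 relative error.
* Sub-seeds for independent random streams are derived with
  `numpy.random.SeedSequence`; every stochastic operation is reproducible
  bit-for-bit from one integer seed.
* Degenerate inputs: empty ranked lists, all-undefined accessibility
  windows, species missing from alignments, and UTRs shorter than the word
  all have defined, tested behavior (empty output, inaccessible, all-gap,
  zero windows respectively).
* CLI outputs are written to a temp file and atomically renamed, so failed
  runs leave no partial files.
* Problem sizes in the test suite and acceptance script (50 miRNAs × 400
  genes per scenario, 10⁵ Monte-Carlo sequences of 500 nt, 200 genes for
  the filter-algebra check) were chosen as the smallest scales at which the
  trends and calibration are statistically unambiguous.

## Known limitations

* The zeroth-order background ignores dinucleotide structure of real
  3′UTRs; the word probability can be biased for CpG-depleted or repeat
  sequences.
* The binomial independence approximation overstates significance slightly
  for self-overlapping words (the Monte-Carlo test uses a border-free word
  to separate this effect from implementation error).
* Conservation treats the alignment as truth; misalignment and the
  positional-orthology reading (rather than "word present anywhere in the
  orthologous UTR") make the filter strict.
* Accessibility profiles are only as good as the folding parameters used to
  produce them; the package does not validate W/L provenance beyond
  recording it.
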