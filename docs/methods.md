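# Methods

`premir` predicts pre-miRNA hairpin precursors genome-wide by combining a
rule-based structural prefilter, a 46-feature RBF support-vector
classifier with calibrated probabilities, and a conservation-based
homology search. This note records the model, the conventions the
implementation fixes, and what the synthetic benchmarks do and do not
demonstrate.

## Windowing and screening

Genomes and coding sequence are cut into 90-nt windows advanced 9 nt at
a time; ~90 nt covers the bulk of the animal precursor length
distribution, and the 9-nt step guarantees several windows fully contain
any precursor-sized hairpin. Trailing partial windows are dropped, not
padded, because several features are normalised by a fixed window length.
Windows containing N (assembly gaps or ambiguity codes) are discarded,
as are simple repeats: a mononucleotide run of ≥ 8, a dinucleotide unit
tandem-repeated ≥ 7 times, or a trinucleotide unit repeated ≥ 4 times
(thresholds anchored to the canonical examples AAAAAAAA, (AG)₇, (ATG)₄).
Overlapping repeat rules are all reported. Both strands are scanned by
default; minus-strand windows keep forward coordinates (0-based,
half-open everywhere, so BED output is native).

## Folding and hairpin anatomy

Secondary structure comes from ViennaRNA (2.x programmatic interface) at
37 °C with default parameters, lonely pairs allowed; T is transliterated
to U first. Besides the MFE structure the wrapper reports three
Boltzmann-ensemble quantities: the probability of the MFE structure in
the ensemble, the ensemble diversity (expected base-pair distance
between two ensemble structures, nt), and the expected base-pair
distance between the ensemble and the MFE structure (ensemble defect ×
length, nt). The last two are deliberately distinct summaries of
ensemble spread; the second is RNAfold's "ensemble diversity".

The anatomy parser decomposes a balanced dot-bracket string by the
standard loop decomposition: every maximal unpaired run is attributed to
exactly one element — external tail, hairpin (terminal) loop, bulge
(unpaired on one strand), internal loop (both strands; symmetric when
the two sides are equal), or multiloop. Conventions fixed here:

* **NNB** counts base *pairs*, not paired nucleotides. Only this
  reading makes the filter band ANNB ∈ [0.30, 0.43] jointly satisfiable
  with the > 17-pair minimum at 90-nt windows.
* **NNS** (stem-region nucleotides) = every nucleotide in a helix,
  bulge or internal loop; for a single hairpin this is the span from
  the outermost to the innermost pair on both arms inclusive, excluding
  the terminal loop and external tails.
* **Symmetry region** = maximal perfect helix; **relaxed symmetry
  region** = consecutive helices bridged only by symmetric internal
  loops (bulges, asymmetric loops and multiloop junctions break it).
* **Inter-loop distance** = the helix run (nt along the 5′ arm)
  separating two consecutive loops/bulges on one stem; fewer than two
  loops ⇒ mean distance 0.
* Multi-branched structures are parsed, not rejected; rejecting them is
  the prefilter's job (rule a).

The parser is verified against an independent flat, scan-based
re-implementation on the exhaustive set of 1,344,379 balanced
dot-bracket strings of length ≤ 16, plus randomized property tests
(nucleotide conservation; invariance under strand reversal).

## The 46 features

Fourteen scalars, then 32 left-triplet frequencies, in a frozen order
recorded (with a fingerprint) in every model file:

| feature | definition |
|---|---|
| N(MFE) | −MFE/1000 (kcal/mol) |
| N(MFEI) | MFEI/10, MFEI = (−100·MFE/LS)/GC% |
| N(AMFE) | (−MFE/LS)·10 |
| N(NNB), N(ANNB), N(NNS) | pairs/1000, pairs/LS, pairs/NNS |
| N(GC) | (#G + #C)/1000 |
| N(Diversity), N(Freq/100), N(dD) | diversity/LS, P(MFE structure), ensemble–MFE distance/LS |
| N(D_interlp/1000) | mean inter-loop distance/1000 |
| N(\|A−U\|/LS), N(l_rsym_rgn/100), N(l_sym_rgn/100) | as printed |

Decisions worth noting: AMFE is read as (−MFE/LS)·10 so the feature
stays O(1)–O(10) like its siblings; GC in N(GC) is the nucleotide
*count* (parallel to NNB/1000) while MFEI uses the GC *percentage*; the
MFE-structure frequency is already a probability, so the "/100" of its
conventional name is a no-op here; the /LS normalisations of the two
ensemble-distance features are this package's convention.

The left-triplet code of a position is (its nucleotide, the pairing
pattern of three adjacent positions) with ")" collapsed onto "(" — the
coding is arm-agnostic — giving 4 × 8 = 32 codes. Windows slide within
each arm of the stem region only: external tails and the terminal loop
are excluded and never crossed, while interior loops and bulges within
an arm are included. Counts are normalised to sum to one; a stem too
short for any width-3 window yields the zero vector.

## Prefilters

The full cascade (a)–(n) evaluates, on the MFE structure only, with no
short-circuiting: (a) exactly one hairpin loop; (b) < 6 symmetric loops;
(c) < 4 asymmetric loops; (d) < 5 bulges; (e) sym+asym < 8; (f)
sym+asym+bulges < 10; (g) > 17 base pairs; (h) 0.30 ≤ ANNB ≤ 0.43; (i)
each symmetric-loop side < 5; (j) each asymmetric loop < 6 (longer
side — the stricter reading); (k) each bulge < 6; (l) MFE < −15
kcal/mol; (m) MFEI > 0.7; (n) 30 % ≤ GC ≤ 70 %. "Between" bounds are
inclusive; loop-size rules bound each element, not the category sum;
GC is computed over the whole window. The relaxed genome filter keeps
only (a), (g), (l) and MFEI > 0.6, leaving borderline windows for the
classifier. Because the genome rules are a subset with a weaker MFEI
cut, a full-cascade pass implies a genome pass — asserted on 10,000
mixed fixture windows.

Pseudo-hairpin mining (`extract_pseudo`) applies gap/complexity
screening and a cascade to CDS windows; the full cascade is the default
(matching how a negative class is mined from coding sequence at genome
scale). Rule evaluation needs only the MFE structure, so mining skips
partition-function folds.

## Classifier

Training pools are split reproducibly into a balanced training set and
two held-out test sets (real / pseudo). With reference-scale pools the
split is 184+184 training, 40 real and 1000 pseudo test examples; for
smaller pools the sizes scale proportionally (balanced training halves;
the pseudo test scaled by the pool ratio, rounded half-up).

Features are min/max-scaled to [0, 1] on training data only. A
stratified 5-fold cross-validated grid search over C ∈ {2⁻⁵ … 2¹⁵} and
g ∈ {2⁻¹⁵ … 2³} (powers of 4, the customary libsvm coarse grid) picks
the accuracy-maximising pair, ties broken toward the smallest C then the
smallest g. The final SVC is refit on the full training set, and a Platt
sigmoid P(+1|f) = 1/(1+exp(A·f+B)) is fitted to cross-validated decision
values by the regularised Newton method of Lin, Lin & Weng — the same
calibration libsvm applies internally. Implementing the sigmoid
explicitly makes the fitted model a plain parameter set: the results
object serialises to a self-describing JSON text file (support vectors,
dual coefficients, scaling, sigmoid, feature fingerprint, backend
version), and because prediction always runs through the package's own
kernel expansion, a save → load round trip reproduces probabilities
bit-for-bit.

Evaluation reports sensitivity on the real test set, specificity on the
pseudo test set, and overall accuracy **ACC = (SE+SP)/2** — the
unweighted mean, which is the definition consistent with quoting ACC
95.6 % for SE 100 % / SP 91.2 % on 40/1000 test sets (pooled accuracy
would be 91.5 %). ROC curves sweep the probability threshold over the
pooled test sets.

## Genome scan and post-processing

Per window: gap → complexity → MFE-only fold → genome prefilter →
partition-function fold + feature encoding → calibrated probability.
The expensive ensemble fold runs only for the ~1 % of windows that pass
the cheap stages. At genome scale the retention threshold is 0.99995;
at fixture scale (50-kb toy genomes) 0.5 is used — with ~10³–10⁴ windows
rather than 10⁸, the extreme-tail threshold is not meaningful.
Overlapping same-strand candidates are merged transitively and
represented by the highest-probability member (ties → leftmost); the
merge rule is this package's convention. Candidates matching a known
precursor exactly over > 90 % of their length (identity 100 %, found by
longest-common-substring) are flagged `novel=False` but kept, so counts
stay auditable; `--novel-only` drops them. Clusters chain candidates on
one chromosome+strand whose starts differ by ≤ 50 kb (single linkage,
start-to-start — the measuring points are this package's choice).

## Homology search

Cross-species precursor queries are first purged of anything highly
homologous (coverage > 85 %, identity > 85 % — the same thresholds used
for genomic mapping, chosen for symmetry) to an already-known native
precursor. Remaining queries are mapped to the genome on both strands
with edlib semi-global (infix) alignment — the whole query must align,
so coverage is 100 % and identity = 1 − edits/|query|; edlib reports
best-scoring loci, which for the near-exact matches of interest is the
full hit set. Retrieved fragments (no flank extension by default) are
validated against five criteria: single stem-loop, MFE < −15 kcal/mol,
≥ 18 base pairs, no multiloop, GC within 30–70 %. An external tabular
aligner (e.g. blastn) can substitute for the built-in backend at larger
scales.

## Synthetic fixtures

* **Hairpins**: 5′ flank + random stem + loop + reverse-complement stem
  + 3′ flank, with optional single-nucleotide bulges; stem sizes 28–36
  bp, loops 4–8 nt, GC 0.38–0.62 — placing recovered pair counts in the
  27–38 band that 90-nt precursors occupy. Stems are perfectly
  complementary, so the backend recovers ≥ 90 % of planted pairs.
* **CDS-like negatives**: ATG + random sense codons with a mild GC3
  bias, no internal stops, resampled until free of simple repeats.
* **Toy genomes**: hairpins planted at recorded non-overlapping loci on
  either strand in a dinucleotide-shuffled (Altschul–Erikson) random
  background, so local composition statistics of the background are
  preserved and the negative windows are not trivially distinguishable.

What the fixtures do *not* emulate: real miRNA families and their
conserved loop motifs, isochore-scale composition variation, repetitive
elements, and the genome-scale multiple-testing burden (10⁸ windows vs
10⁴). Passing the planted-genome benchmark therefore demonstrates the
pipeline's mechanics and separability at fixture scale, not field
performance on a real genome.

## Benchmark scale

The shipped benchmarks train on 200+200 examples (positive pool ~230
single-hairpin folds from 240 generated records, negative pool 240
mined pseudo hairpins), evaluate on 20 real + 40 pseudo held-out
examples over three split seeds, and scan 50-kb planted genomes. Negative mining at fixture scale uses the relaxed
genome cascade: the full cascade retains only ~0.2 % of codon-like
windows, so mining a full-cascade pool of useful size would spend
nearly all benchmark time folding; the relaxed pool (~1 % retention)
preserves the character of the negative class — hairpin-like coding
windows — at a practical size. `extract_pseudo(mode="full")` remains
the default for real mining runs.

## Known limitations

* Probabilities are Platt-calibrated on small CV samples; at fixture
  scale the extreme tail (0.99995) is unpopulated, which is why toy
  benchmarks threshold at 0.5.
* The built-in homology backend reports best-score loci per
  query/chromosome/strand; secondary, weaker loci require the external
  aligner backend.
* Dedup's merge rule and the cluster measuring points are conventions;
  counts downstream of them are convention-dependent.
* Rules are evaluated on the single MFE structure; no ensemble voting.
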