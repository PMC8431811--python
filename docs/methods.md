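# Methods

## Conservation profile

Each alignment column is scored two ways. Shannon entropy uses a
five-state model — A, T, C, G and the gap character all count as states —
so a fully gapped but uniform column still scores 0 and the upper bound
is `log(5)` in the configured base (natural log by default; base 2 and 10
are available because the choice only rescales the track). IUPAC
ambiguity codes carry no information under a five-state model and are
excluded from the counts; the `coverage` track records the fraction of
rows that did contribute, and a column consisting only of ambiguity codes
becomes NaN and is listed in `flagged_columns` rather than aborting the
profile. Similarity is the percentage of rows carrying the modal
*nucleotide*: gaps inflate the denominator but can never be the mode, so
a gap-rich column scores low even if its residues agree. Columns are
1-based everywhere the profile is reported.

## Primer design

Conserved windows are maximal runs of columns that simultaneously satisfy
an entropy ceiling and a similarity floor; each primer-length sub-window
yields a candidate oligo built from the column-majority consensus
(alphabetical tie-break; gap-majority columns are dropped). Reverse
candidates are the reverse complement of the consensus slice.

Universality of a candidate is the fraction of alignment sequences whose
ungapped slice at the site matches within a mismatch budget and with
zero mismatches in the 3′-terminal anchor (default 3 nt) — the end the
polymerase extends from, where a mismatch is most disruptive. Defaults
are strict (no mismatches) because a universal screening primer should
bind every known sequence of the target group.

Pairs are screened for: amplicon length inside an acceptance window
(default 150–260 nt, target 200 — short enough for single-strand
conformers to resolve on a native gel); at least one enclosed column
above the 90th entropy percentile when `require_variable_core` is set
(the assay only discriminates if the amplified core actually varies);
and thermodynamic gates. Ranking is universality (desc), enclosed
maximum entropy (desc), distance of the expected length from the target
(asc) and a thermodynamic penalty (asc), with ties broken by leftmost
forward coordinate. The weights live in one place (`enumerate_pairs`)
and are deliberately coarse — the screens are meant to cut, not to
fine-rank near-equivalent pairs.

## Thermodynamics

Melting temperature is the two-state nearest-neighbor model via
Biopython's `Tm_NN` (unified parameter set, Owczarzy monovalent salt
correction), with the oligo concentration entering as total single
strand in excess — the convention of the popular short-oligo web
calculators. Defaults are 50 mM monovalent, 0.25 µM oligo. Under these
conditions the engine reproduces the published Tm of the reference
primer pair to within 0.9 °C.

Dimer and hairpin screens use the classic Breslauer doublet ΔG°37 table.
The duplex score scans every anti-parallel offset of the two oligos and
returns the most negative single contiguous complementary stretch
(≥ 2 bp), summing stacking terms only. This convention — Breslauer
table, best single window, no initiation term — reproduces the reference
calculator's printed self-dimer and heterodimer values for the published
primer pair to ≤ 0.1 kcal/mol, which is why it was preferred over the
unified table with initiation terms (that variant underestimates the
printed magnitudes by several kcal/mol). The hairpin score enumerates
every contiguous stem/loop decomposition (loop ≥ 3 nt), scoring stems by
the same stacking table and loops by the standard length-dependent
closure penalty with logarithmic extrapolation beyond 30 nt. Bulges,
internal loops, dangling ends and terminal mismatches are not modeled;
hairpin agreement with full secondary-structure tools is therefore
qualitative (weakly stable primers score near zero, strong hairpins
score clearly negative), and the screens should be read as rankings, not
physical free energies.

## In-silico PCR

Binding sites are exhaustive sliding-window matches of the primer (plus
strand) and its reverse complement (minus strand) under the same
mismatch/3′-anchor rule; ambiguous template bases count as mismatches.
Template search defaults are looser than design-time universality
(2 mismatches, anchor 3) because real templates diverge from a consensus
primer. The amplicon spans first base of the forward site to last base
of the reverse site — primer regions included, matching how product
length reads on a gel. All candidate products are enumerated and then
size-filtered; a template with no in-window product raises
`NoAmplification` and one with several raises `AmbiguousProduct`, and the
batch runner converts both into per-template statuses so one bad template
never aborts a screen. Identity grouping is an exact string partition
(case- and U/T-normalized), sorted by size then sequence so the output is
order-invariant. Substitution mapping requires equal-length
representatives (the no-indel case); anything else must be aligned
externally first.

## Gel fingerprints

The standard curve models migration distance as a Gaussian in
`s = log10(size)`, `d(s) = A·exp(−(s−µ)²/2σ²) + c`, fitted by
least squares to the ladder lane (≥ 4 rungs required), with a log-linear
fallback. The fitted branch must be monotone across the ladder or
inversion is refused. R² is computed on the ladder points; curves below
0.95 are rejected at normalization time. Cross-gel normalization inverts
the local curve (position → size, Brent root-finding on the monotone
branch) and evaluates the reference curve (size → position); bands
outside the calibrated range are mapped by clamped extrapolation and
flagged, never silently dropped.

Band-pattern similarity matches bands one-to-one when their normalized
positions differ by at most the tolerance (default 4 reference-scale
units), maximizing the match count; because eligibility on sorted
positions forms an interval bigraph, a two-pointer greedy is provably
maximal (and is verified against an exhaustive assignment oracle in the
tests). Similarity is Dice, `100·2m/(nA+nB)`, with Jaccard available;
two empty patterns score 100 (identical absence) and empty-vs-non-empty
scores 0 — conventions needed for totality. Clustering is UPGMA on
`100 − similarity` (single and complete linkage available); leaves are
sorted lexicographically before linkage so tie-breaking is deterministic,
and Newick children are emitted in canonical order. Partition agreement
against an external grouping (e.g. amplicon identity) is the adjusted
Rand index plus a contingency table.

## Synthetic data

The simulators exist so every stage can be tested with planted truth and
no downloads; their defaults mirror the screening study design this
toolkit reimplements.

* `simulate_msa`: blocks of columns descend from one ancestral segment;
  conserved blocks substitute at 0.005–0.01 per site, variable blocks at
  0.30, 24 sequences by default — enough rows for column statistics to
  separate the two block classes cleanly.
* `simulate_templates`: each template is random flank + forward site +
  insert variant + reverse-complemented reverse site + random flank; the
  insert's identity is the group truth. The default group sizes are
  17/15/7/20/8/5/1 — seven groups over 73 samples.
* `simulate_gel`: fingerprints are three-band patterns whose band
  positions sit on a slot grid spaced 9 units apart, with the seven
  groups' slot triples forming a Fano-plane design: any two groups share
  exactly one slot, so between-group Dice similarity is structurally
  33.3 % while within-group similarity is ~100 %. Samples are dealt
  round-robin over 8 gels; each gel gets an affine warp (scale
  0.92–1.08, shift ±3) of a reference migration law (Gaussian,
  A=140, µ=1.5, σ=1.2, c=5 over a 100-bp ladder), ladder lanes first and
  last with 0.25-unit rung noise, and 0.8-unit band noise. An affine
  warp of a Gaussian in `s` is again Gaussian in `s`, so the fitted
  standard curves are well-specified and the end-to-end re-clustering
  test isolates the pipeline rather than the fit family. The documented
  similarity cut for flat clusters is 60 % (distance 40), midway between
  the within-group and between-group similarity levels.

What the simulations do *not* emulate: sequence-dependent conformer
mobility (the physical mechanism linking sequence to band position is
not modeled — band patterns are assigned per group by construction),
band intensity variation, partial digestion or heteroduplex artifacts,
smiling or other non-affine within-gel distortion, and real rDNA
covariation structure in the alignments. Passing tests therefore
demonstrate the correctness of the computations on well-behaved input,
not the wet-lab discriminatory power of SSCP itself.

## Numerical choices and limitations

* Gaussian curve fits start from a single heuristic initial guess; on
  noise-free or mildly noisy ladders (≈1 % of span) this recovers the
  generating parameters to high accuracy. Heavily corrupted ladders can
  converge to mirrored parameterizations that still interpolate the
  rungs correctly (the R² gate, not parameter identity, is the contract).
* Curve inversion clamps out-of-range positions to the calibrated
  boundary; downstream code must consult the extrapolation flags before
  trusting such bands.
* Test and acceptance problem sizes (1,000 random columns, 200 oligos of
  length ≤ 10 for the exhaustive dimer oracle, 500 amplification round
  trips, 500 band-pattern pairs, 200 five-leaf UPGMA instances, one
  73-sample/8-gel recovery run) were chosen so exhaustive oracles stay
  exact while the whole suite runs in seconds.
* The external-sequence parts of the original study (amplifying the real
  isolate set and reproducing its seven sample-sets and their
  substitution positions) require GenBank material that is not shipped;
  the identical machinery is exercised end to end on the synthetic
  counterparts with the same group-size structure.
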