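# Methods

`svjunction` analyzes structural-variant (SV) breakpoint junctions from
single-molecule capture sequencing of unstable loci such as common fragile
sites. This note documents the models and procedures the package implements,
the choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Junction model and coordinates

A junction is described simultaneously in reference coordinates and in the
coordinates of the sequenced source molecule that carries it. On each side
the breakpoint is the last aligned base nearest the junction. With `a` the
molecule index of the first segment's last aligned base and `b` that of the
second segment's first aligned base, the signed offset is `b - a - 1`:

* `offset < 0` — microhomology: `-offset` molecule bases aligned to both
  reference flanks;
* `offset = 0` — blunt joint;
* `offset > 0` — de novo insertion of `offset` bases aligning to neither
  flank.

Reference positions are 1-based inclusive everywhere in memory; BED I/O
converts at the boundary. Molecule order differs by SV type: deletions read
both segments forward in reference order; tandem duplications read the end
of the duplicated unit before its start; inversions read the second segment
on the reverse strand. All offset arithmetic goes through a single
molecule-order helper so the three types share one code path.

**Canonicalization.** Aligners place shiftable junctions arbitrarily, so
ambiguous junctions are canonicalized to *maximal* microhomology: homology is
extended base by base in both directions across the junction (treating N or
lowercase bases and contig edges as mismatches), and breakpoints are shifted
to the rightmost placement in first-segment orientation. The operation is
idempotent, never shortens microhomology, and leaves insertion junctions
untouched. Canonical breakpoints key the single-molecule uniqueness filter,
making duplicate detection placement-invariant.

**Transcription orientation** is a reporting-frame flip, not a coordinate
rewrite: for a '-' strand target, breakpoint roles (left/right) swap while
template strand labels are preserved — "top/bottom" means same/opposite
strand as the junction molecule, which is invariant under mirroring both the
query and the reference. Applying the flip twice restores the original call.

## Filtering and coverage

Filters aim to count only de novo junctions, in a fixed order so the first
failing rule per call is reproducible:

1. **uniqueness** — the junction key (type + canonical breakpoint pair) must
   occur in exactly one source molecule (keyed by sample and outer
   endpoints) in one sample; all occurrences of a duplicated key are
   rejected;
2. **support** — ≥ 3 redundant read pairs (late-PCR chimeras typically have
   one);
3. **mapping quality** — ≥ 30 on at least one flank and ≥ 20 on both;
4. **location** — ≥ 1 breakpoint inside an unpadded capture target, both
   within the 800 kb padded span;
5. **size** — deletions/duplications in [10 kb, 1.2 Mb]; inversions ≥ 50 kb
   (excluding a known artifact class of small inversions in transposase
   libraries). The 1.2 Mb ceiling is also applied to inversions — the upper
   bound reflects the locus geometry, not the artifact class — which is a
   package choice.

**Coverage** counts only bases that could have reported a junction: non-SV
molecules with ≥ 3 read pairs, each adjusted by subtracting 2 × 20 bp of
terminal dead zone (floored at zero), summed over on-target molecules and
divided by the unpadded target length. The binned track averages base-level
coverage of molecule interiors over 100 bp bins anchored at the capture
start, with partial terminal bins length-weighted. **SV frequency** is the
kept-junction count divided by fold-coverage, approximating the fraction of
sequenced target haplotypes carrying a de novo SV. **Breakpoint density**
bins each breakpoint once into 5 kb bins over the padded span;
coverage-normalized density is defined only on bins with ≥ 500× coverage on
the *adjusted* track (whether the mask should use raw or adjusted coverage is
not externally fixed; adjusted is used and bins below threshold carry NaN,
never zero).

## Insertion-template discovery

Inserted bases at end-joining junctions are frequently copied from sequence
near the breakpoints, bounded by priming and resolving microhomologies — the
signature of polymerase-theta-mediated end joining (TMEJ). The search:

1. **Query** — the inserted bases plus `max(1, ceil((7 - s) / 2))` bases of
   flanking microhomology per side, read from the molecule: a 1 bp insertion
   is queried with 3 bp flanks (7 bases), a 4 bp insertion with 2 bp flanks
   (8 bases), insertions ≥ 5 bp with single-base flanks. Odd shortfalls are
   split by ceiling on both sides, matching the printed 1/4/≥5 bp anchors.
2. **Scan** — exact matches of the query in 500 bp on each side of both
   breakpoints on both strands: 2 breakpoints × 2 strands × 2 sides ×
   500 bp = 4 kb of sequence.
3. **Extension** — each match's flanking microhomologies are extended base by
   base against the molecule context, stopping just before the first
   mismatch. Extensions are capped at the window width or the end of the
   available molecule context; capped flanks are flagged (self-similar
   sequence, e.g. the retained arm of an expansion repeat, would otherwise
   extend without bound). Maximal hits are deduplicated on (side, strand,
   extended span) so overlapping sub-hits of one locus are not double
   counted.
4. **Selection** — longest total span including flanks; ties broken by
   distance to the junction, then deterministically (breakpoint 1, top
   strand, leftmost).
5. **Classification** — by strand and retained/lost placement relative to
   the transcription-oriented breakpoints: bottom-strand fully-retained hits
   are *foldback* (subclassified *palindrome* when the extended template
   equals its own reverse complement — an explicit operational stand-in for
   a narrative criterion); top-strand fully-retained are *cross-junction*;
   bottom-strand hits touching lost sequence are *strand-switching*;
   top-strand hits crossing from retained into lost are *expansion*;
   top-strand fully-lost hits are unclassified and flagged. Retained/lost is
   defined for deletions (retained = outside the deleted interval); for
   duplications and inversions the same search runs but classes other than
   cross-junction carry a low-confidence flag.

Windows are measured from canonicalized breakpoints.

## Statistics

**Template enrichment.** Random matches of an `n`-base query in the 4 kb
search space arise at Poisson rate `mu = 4000 / 4^n`, giving per-junction
trial probability `p = 1 - exp(-mu)`. Each searched junction of a given
insertion size is a Bernoulli trial; the p-value is the upper binomial tail
`P(X >= nFound)` at `X ~ Binomial(nSearched, p)`. `n` is the *initial* query
length (the quantity in the printed rate formula), not the extended span.
Note the p-value decreases as `n` grows at fixed yield: longer queries make
the same yield more surprising.

**Junction profiles.** Two per-sample axes: mean microhomology length over
junctions without an insertion (`mean(-offset | offset <= 0)`), and the
fraction of all junctions with a 2–15 bp insertion (inclusive).

**SV-frequency comparison.** Per-sample counts are modeled as an
overdispersed Poisson: `log E[nSvs] = intercept + groupCoef·[group = alt]
+ batch effects + log(coverage)` with NB2 dispersion `alpha` estimated by
maximum likelihood (`statsmodels` discrete NB with coverage exposure;
`alpha = 1/theta` in `glm.nb` terms). Batch enters as indicator contrasts
against the alphabetically first level; a batch perfectly confounded with
group (rank-deficient design) is dropped with a warning. The intergroup
p-value is the two-sided Wald test on the group coefficient. The fit falls
back to a plain Poisson GLM when the NB fit does not converge, its standard
errors are not finite, or the fitted dispersion implies variance/mean below
1 + 1e-6. Zero-count groups propagate their instability with a flag; no
pseudocounts are added anywhere.

*Small-sample caution:* at 6 samples per group the Wald p-value is
anti-conservative under the null (empirical rejection ≈ 0.11–0.13 at
nominal 0.05; the same behavior is reproduced by `MASS::glm.nb` on identical
data). Uniformity of the null p-value holds at larger per-group sizes
(≈ 20+), which is where the calibration test operates. Conclusions at
`p <= 0.01` from half a dozen samples per group should be read with this in
mind.

## Synthetic cohorts

The generator emulates the *output schema* of a single-molecule capture
pipeline — no reads are simulated; source molecules and SV calls are drawn
directly. Its defaults encode the TMEJ regime: mechanism mix 62%
microhomology / 13% blunt / 25% insertion; microhomology lengths peaked at
2 bp; geometric-ish insertion sizes over 1–20 bp; 36% of insertions locally
templated; template classes dominated by foldback and cross-junction with a
small strand-switching weight (their relative rate is only known to be
"rarer", so the default is small and configurable); template distances
exponentially decaying with most mass within 20 bp; priming/resolving
microhomologies peaked at 2–3 bp; log-normal SV sizes with 200 kb median
truncated to [10 kb, 1.2 Mb]; NB per-sample counts with theta = 10 around
rate × coverage. The `POLQ_KO` preset shifts the microhomology mode to 1 bp
and nearly eliminates insertions ≥ 3 bp; `NHEJ_like` is blunt-heavy with
short microhomology.

Key constructive choices:

* **Edited references.** Planted homologies and templates are made real by
  editing the reference, then forcing a mismatch just beyond every planted
  flank so the declared overlap is provably maximal. This makes oracle
  round-trips exact: characterization recovers every planted offset,
  canonicalization is a no-op on emitted junctions, and planted templates
  are recovered at exact coordinates.
* **Plant geometry.** Each junction reserves a small neighborhood around
  both breakpoints so edits of different SVs cannot interact; retained-side
  templates keep a minimum distance of `max(priming, resolving) + 2` from
  the breakpoint so a template edit can never overwrite its own flank
  source. Planted flank homologies are clipped up to the initial query flank
  (shorter flanks would make the template undiscoverable by construction).
  Distances are therefore rejection-sampled above a small floor (~4–7 bp);
  real data can contain templates closer to the junction than the generator
  plants.
* **Expansions** are perfect two-unit direct repeats that gain a third unit
  at the junction. Their priming flank self-matches retained sequence, so
  the search reports a context-capped priming extension; truth records the
  priming length as undefined. Interrupted repeats, iterative multi-template
  synthesis, and untemplated polymerase activity are not modeled — which is
  one reason real cohorts find templates for only a minority of insertions.
* **Molecules.** Non-SV molecule lengths are uniform 300–600 bp; read-pair
  counts are 2 + Geometric(1/2) with a 4% low-support fraction (1–2 pairs)
  and a 3% low-mapping-quality fraction, so both filter branches are
  exercised while ≥ 95% of molecules pass support. One target region per
  genome; multi-target cohorts are built by concatenation.
* **Scale.** Default cohorts run 2 × 6 samples at 60× coverage over a
  150 kb target in a 4 Mb genome — deliberately smaller than a real capture
  experiment (~1000× over Mb-scale targets) so the full pipeline runs in
  seconds. At these coverages most 5 kb density bins sit below the 500×
  mask; density tests construct high-coverage tracks explicitly. Junction-
  level analyses use independent per-junction mini-references
  (`simulate_junction_set`), which keeps template windows statistically
  clean and embarrassingly parallel.

What passing tests show: the algorithms are internally consistent, agree
with independent brute-force oracles, and are calibrated against their own
null models. What they do not show: robustness to alignment artifacts,
non-uniform base composition, repeat-rich references, or capture-efficiency
structure — none of which the generator emulates.

## Numerical and degenerate-input conventions

* Homology extension treats N/lowercase bases and contig edges as universal
  mismatches (conservative).
* All probability vectors must sum to 1 within 1e-9; every byte of generator
  output is determined by one seed.
* Empty call sets yield an explicit empty-profile marker (NaN metrics, n = 0);
  zero coverage makes SV frequency an error, not a zero.
* Selection and rejection-reason orders are fully deterministic, so pipeline
  reruns are byte-identical and filter conservation (kept + rejected =
  input) is auditable from logs.

## Known limitations

* Template classes are defined on the deletion geometry; duplication and
  inversion hits outside cross-junction are flagged low-confidence rather
  than reinterpreted.
* The palindrome criterion (extended template equals its own reverse
  complement) is an operational stand-in for a narrative definition.
* No multiple-testing correction across contrasts (per-contrast p-values
  are compared to fixed thresholds, matching the analysis convention).
* The NB Wald test is anti-conservative at very small per-group sample
  sizes (see above).
* Translocations travel through the data model but are not planted by the
  generator and have no size rule.
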