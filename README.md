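# svjunction

Analysis of structural-variant (SV) breakpoint junctions from
single-molecule capture sequencing, aimed at studies of SV formation
mechanisms at unstable loci such as common fragile sites: which repair
pathway built a junction, where inserted bases were copied from, and how SV
rates differ between experimental conditions.

The package implements five connected analyses plus a synthetic-cohort
generator that plants junctions with known mechanisms so every stage is
verifiable without sequencing data:

1. **Junction characterization.** Each junction is described by a signed
   breakpoint offset in source-molecule coordinates: microhomology < 0
   (shared bases aligned to both reference flanks), blunt = 0, de novo
   insertion > 0. Ambiguous junctions are canonicalized to maximal
   microhomology.
2. **Single-molecule filtering and coverage.** De novo junctions must be
   unique to one molecule in one sample, supported by ≥ 3 read pairs, pass
   mapping-quality and on-target rules, and fall in a type-specific size
   window. Target fold-coverage sums adjusted molecule lengths
   (length − 2×20 bp of terminal dead zone) over the unpadded target;
   SV frequency = junction count / fold-coverage.
3. **Insertion-template discovery** — the theta-mediated end-joining (TMEJ)
   signature. Inserted bases plus flanking microhomology form an exact-match
   query (≥ 7 bases: 3 bp flanks for a 1 bp insert, 2 bp for 4 bp, 1 bp for
   ≥ 5 bp) searched over 2 breakpoints × 2 strands × 2 sides × 500 bp = 4 kb.
   Matches are maximally extended, the longest/closest hit selected, and
   classified as foldback/palindrome, cross-junction, strand-switching, or
   expansion by strand and retained/lost placement.
4. **Enrichment statistics.** Random matches arise at Poisson rate
   μ = 4000/4ⁿ for an n-base query; each searched junction is a Bernoulli
   trial with success probability 1 − e^(−μ), and the per-insertion-size
   p-value is the upper binomial tail at the observed template yield.
5. **SV-frequency comparison.** Per-sample counts follow a negative-binomial
   GLM, log E[nSvs] = β₀ + β₁·group + batch + log(coverage) (coverage as an
   exposure offset of slope 1), with a Wald test on the group coefficient
   and a Poisson fallback when the overdispersed fit fails — exposed
   statsmodels-style as `SvFrequencyModel.fit() → SvFrequencyResults` with
   `summary()`.

See `docs/methods.md` for the full model description, defaults, and
limitations.

## Worked example

Simulate a two-group cohort (group B planted at a 5-fold higher SV rate per
haplotype than group A), filter, profile the junctions, and fit the
frequency model:

```python
from svjunction import (SimConfig, simulate_cohort, FilterConfig, filter_svs,
                        compute_coverage)
from svjunction.stats import SvFrequencyModel, junction_profile

cohort = simulate_cohort(SimConfig(seed=42), "out/demo")
kept, rejected = filter_svs(cohort.calls, cohort.molecules, cohort.samples,
                            cohort.targets, FilterConfig(), cohort.reference)
prof = junction_profile([c.offset for c in kept])

rows = []
for s in cohort.samples:
    mols = [m for m in cohort.molecules if m.sample_id == s.sample_id]
    fold = compute_coverage(mols, cohort.targets).fold
    rows.append((s.group, s.batch,
                 sum(c.sample_id == s.sample_id for c in kept), fold))
res = SvFrequencyModel([r[2] for r in rows], [r[3] for r in rows],
                       [r[0] for r in rows], [r[1] for r in rows]).fit()
print(res.summary())
```

Output:

```
kept 202 of 213 calls (rejections: {'read_pairs': 7, 'mapq': 4})
mean MH (non-insertion) = 2.21 bp; 2-15 bp insertions = 16.3%
SV frequency comparison (counts ~ group + batch + offset(log coverage))
  model:         negative_binomial
  contrast:      B vs A
  n samples:     6 ref, 6 alt
  log rate ratio +1.5681  (SE 0.2387)
  rate ratio     4.7975
  Wald p-value   5.071e-11
  dispersion     alpha = 0.0656
```

The junction profile shows the TMEJ fingerprint the generator planted
(microhomology peaked near 2 bp, a substantial minority of insertions), the
11 rejected calls are the planted low-support/low-mapq molecules, and the
fitted rate ratio 4.80 (p ≈ 5e-11) recovers the planted 5-fold contrast.

Template search on one kept insertion junction:

```python
from svjunction.templates import build_query, scan_templates, classify_template

ins = next(c for c in kept if c.offset >= 2)
q = build_query(ins)
result = scan_templates(q, cohort.reference, ins)
hit = result.selected_hit
classify_template(hit, ins)
```

```
call sv00001: 5 bp insertion, query 'TTAACTT', 1 candidate(s),
selected expansion at +0 bp (span 201)
```

— a top-strand template crossing the breakpoint from retained into lost
sequence: an expansion-class insertion (the long span reflects maximal flank
extension through the self-similar repeat arm).

The same stages are scriptable from the shell:

```bash
svjunction simulate --mode TMEJ --seed 42 --out out/demo
svjunction report --reference out/demo/reference.fa --targets out/demo/targets.bed \
    --calls out/demo/svcalls.tsv --molecules out/demo/molecules.tsv \
    --manifest out/demo/manifest.tsv --out out/report
```

`report` writes kept/rejected calls, coverage and breakpoint-density tracks,
the per-SV template table and pileup, per-size enrichment, per-sample
junction profiles, frequency comparisons, and a machine-readable run
summary; reruns are byte-identical.

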