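# Methods

## The problem and the model

Deep amplicon sequencing of tumor tissue and plasma cell-free DNA (cfDNA)
is limited, at low variant allele fractions (VAF), by substitution errors
introduced during PCR and sequencing: at a per-base error rate of about
10⁻³ a genuine 0.1–0.5% variant is indistinguishable from noise in raw
read counts. Dual molecular barcoding suppresses this noise by tagging
each template molecule, before amplification, with a random unique
molecular tag (UMT) at both the 5′ and 3′ end. All reads carrying one
(sample, amplicon, UMT5, UMT3) key descend from one template and form a
**molecular family**; a family with at least 2 members is **functional**.
An allele is credited to a family only when **every** member read carries
it (unanimous consensus), so an error present in a subset of members is
eliminated, and evidence is counted in molecules rather than reads.

For a family of size *s* and per-read per-base error rate *e*, the
probability that the family unanimously supports one specific spurious
allele at a position is (e/3)^s — about 10⁻⁷ per position per family at
e = 10⁻³, s = 2 — which is what makes molecular counting usable three
orders of magnitude below the raw error floor. The residual dangerous
error class is *heritable* damage (first-cycle PCR errors, FFPE cytosine
deamination) that enters the template before tagging is resolved; the
simulator models it explicitly so the callers can be probed against it.

## The molecular-barcode (MB) caller

Per locus, functional families contribute: `FAO` (alternate-allele family
count), `FDP` (functional-family depth; families that are ambiguous at
the position stay in the denominator — a deliberately conservative
choice), molecular VAF = FAO/FDP, and a one-sided exact binomial tail
p-value P(X ≥ FAO | n = FDP, p = background error rate). The background
rate defaults to 10⁻⁴ per family per allele and can be overridden per
substitution class (e.g. elevated C>T for residual deamination). The
filter cascade, applied in order with every applicable verdict recorded:

| filter | rule | default |
|---|---|---|
| min_supporting_families | families ≥ class minimum (SNV 2, hotspot 2, INDEL 6) | 2/2/6 |
| min_alt_allele_count | FAO ≥ 2 | 2 |
| common_snp | locus not in the user-supplied common-SNP set | — |
| max_p_value | p < 0.02 | 0.02 |
| indel_evidence (indels) | VAF ≥ 0.002 and FAO > 3 | 0.002 / 4 |
| nonhotspot_alt_count (non-hotspot) | FAO > 3 | 4 |
| homopolymer_family_size (homopolymer indels) | every supporting family ≥ size floor | 2 |
| tumor_vaf (tumor context only) | VAF ≥ 0.005 | 0.005 |

All counts are molecular. "Alternate allele count" is interpreted as the
functional-family count (the workflow counts molecules after consensus);
hotspot membership and the common-SNP exclusion set are user-supplied
lists, not live database lookups. A homopolymer context is a reference
run of ≥ 4 identical bases immediately following the indel anchor. In
plasma the 0.005 VAF cutoff does not apply; sub-threshold evidence at
externally nominated loci (e.g. loci mutated in the paired tumor) can be
surfaced with `rescue_report` instead of being silently dropped.

## Indel-aware consensus without genome alignment

Reads arrive with a known amplicon assignment (primer matching within a
Hamming budget, default 2 mismatches, ambiguous ties rejected), so the
only alignment needed is read-versus-insert. Each read is reduced to
per-position tokens against the amplicon insert: a base for a
substitution, `B+SEQ` / `B-k` for VCF-anchored insertions and deletions,
`*` under a deletion, `N` for no-calls. Equal-length reads are compared
positionally; length-discordant reads are globally aligned with affine
gap penalties (match 2, mismatch −3, gap open −7, extend −0.25) so a
multi-base indel stays one contiguous event — plain edit-distance
alignment fragments long deletions into co-optimal scattered gaps and
destroys the allele. Unanimity is then evaluated on tokens, covering
SNVs and indels with a single rule. An `N` is treated as missing data:
ignored when ≥ 2 remaining members agree, otherwise the position is
ambiguous. A member whose length differs from the insert by more than
half the insert is irreconcilable and fails the family's consensus
(excluded from tallies, logged). Tokenization is memoized per distinct
(insert, read) pair, which makes deep amplicon data cheap to process.

## The read-level (non-MB) baseline

The conventional caller ignores UMTs entirely — every read counts once,
PCR duplicates included, as amplicon data cannot be deduplicated without
tags. A tumor call passes with ≥ 10 alternate reads, ≥ 20× depth, absence
from the common-SNP set, and (when a matched normal is supplied) at most
1 alternate read and ≤ 2% VAF in the normal; the confident-somatic
thresholds are configuration because vendor semantics are not public. An
optional VAF operating floor (`min_vaf`) models the practical reporting
threshold of read-level plasma analysis.

## The simulator

`simulate_scenario` draws, per amplicon, `round(input_mass_ng ×
copies_per_ng)` template molecules (default 303 genome equivalents per
ng, i.e. 3.3 pg per haploid genome, so 20 ng ≈ 6,060 molecules); mutant
molecules per truth variant are Binomial(total, VAF). Each molecule gets
a distinct UMT pair (6 bases per end): pairs are sampled *without
replacement*, because at 20,000 molecules over the 4¹² pair space about
a dozen birthday collisions would otherwise silently merge unrelated
molecules — the chemistry's working assumption is unique tagging, and
enforcing it keeps molecule-count conservation exact. Heritable noise is
drawn once per molecule and inherited by all its reads: FFPE deamination
(each template C → T with the configured rate; default 0, preset 3×10⁻⁴)
and lineage PCR errors (per-base probability, default 10⁻⁶; a per-cycle
amplification tree is deliberately not modeled — the lineage draw
reproduces the error class that survives consensus at a fraction of the
complexity). Each molecule then emits k reads, k ~ Poisson(mean 6)
truncated to ≥ 1 (so most families are functional, matching the deep
coverage regime of UMT assays), with i.i.d. per-base substitution errors
(default 10⁻³) uniform over the three non-template bases.

What the generator does **not** emulate: cfDNA fragment-length
distributions, GC/pool coverage bias, polymerase-specific error spectra,
UMT sequencing errors (off by default; distance-1 family merging exists
for studying them), strand-aware duplex information, and alignment
artifacts of a real mapper. Passing tests therefore demonstrate the
statistical behavior of the counting and filtering machinery under the
stated noise model, not performance on any particular instrument's data.

Scenario presets: `make_dilution_panel` builds eight single-variant
amplicons (six SNVs, one 15-bp deletion, one 9-bp insertion as the
long-insertion analogue) with random seeded 50-bp inserts, regenerated
until each mutant template tokenizes back to exactly its (pos, ref, alt)
so there is no alignment ambiguity by construction;
`serial_dilution_scenarios` spikes all eight at each ladder level
(0.1, 0.25, 0.5, 1, 2.5, 5%) at constant 20 ng input.
`plasma_scenario` spikes one SNV into an exact molecule count on a 30-bp
single-amplicon panel. Desk-scale insert lengths (30–50 bp) were chosen
because none of the measured quantities depend on insert length beyond
per-read error opportunity; real assays run ~110–120 bp amplicons.

## Evaluation definitions

* **Detection table**: one row per engineered variant, one column per
  expected-VAF level; a cell is the observed molecular VAF in percent
  (two decimals, falling back to two significant figures when two
  decimals would print 0.00 for a non-zero value — the same renderer
  reproduces published count→VAF conversions like 9/249,780 → 0.0036%)
  or ND when no PASS call matches the variant exactly.
* **Concordance**: R² is the squared Pearson correlation of paired VAFs;
  undefined (raises) for n < 2 or a constant vector. A
  regression-through-origin variant was considered and not adopted as
  default.
* **LoD**: the smallest ladder VAF with PASS detection in ≥ 50% of
  seeded replicates. This replicate-based definition is strictly
  stronger than single-run detection.

## Numerical and determinism choices

* Exact binomial tail via `scipy.stats.binom.sf(k−1, n, p)`;
  verified in tests against an exact big-integer summation oracle to
  1e-12 relative error up to n = 10⁵. Depth 0 or FAO 0 → p = 1.
* Coordinates are 1-based inclusive everywhere (VCF convention). Indels
  are VCF-anchored on the preceding base.
* The INDEL VAF threshold is inclusive (≥ 0.002), the mutated-allele
  exclusions are "≤ 3 excluded" (i.e. ≥ 4 required).
* All collection outputs are sorted (families by key, calls by
  chrom/pos/alt), and all randomness flows from one integer seed, so a
  seeded run is bit-reproducible end to end (FASTQ included).
* Family-key matching is exact string equality by default; the optional
  distance-1 UMT merge absorbs a family into a ≥ 2×-larger neighbor
  (greedy by descending size, lexicographic tie-break) and is OFF by
  default as the conservative, reproducible choice.
* Multi-allelic loci are filtered per alternate allele with no joint
  normalization; each family contributes exactly one molecular count.

## Known limitations

* The binomial null assumes independent families and a single background
  rate per class; clustered artifacts (e.g. strand-specific damage) are
  not modeled and would inflate significance.
* Unanimity discards all evidence from mixed families rather than
  down-weighting, which costs a little sensitivity at very large family
  sizes (a ~0.6% relative loss of alternate counts at e = 10⁻³ and mean
  family size 6 — well inside binomial sampling noise at the tested
  scales).
* Primer-based amplicon assignment tolerates substitutions but not
  indels in primers.
* Tumor–normal read-level calling trusts the supplied normal tallies;
  there is no contamination model.
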