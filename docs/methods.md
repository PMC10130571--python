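# Methods

This note documents the models, parameter choices and numerical conventions
behind `parasnv`, and what the synthetic-data tests do and do not establish
about behavior on real metagenomes.

## The convergence null model

At a single homologous site, a population's SNV is summarized as an ordered
(original base, variant base) pair. The null model treats the pairs of `k`
populations as independent and uniform over all 4 × 4 = 16 combinations
(identity "changes" included, exactly as the combinatorial argument counts
them). Of the 16^k joint assignments, 12 correspond to all `k` populations
undergoing the identical real substitution, so

    p(k) = 12 / 16^k,    E[convergent] = p(k) · n_same_site.

`convergence_probability` returns this as an exact `fractions.Fraction`;
floats appear only at rendering. `enumerate_matches` re-derives the count by
brute-force enumeration over all 16^k assignments (guarded to k ≤ 5), and
`monte_carlo_convergence` re-derives it by simulation; both are used as
cross-checks in the test suite and in the acceptance script.

The evidence rule is strict inequality on the *unrounded* expectation:
`observed_same_substitution > p(k)·n` ⇒ `gene_flow_or_ancestry`, else
`none`. The label is deliberately a disjunction — the statistic cannot
separate gene flow from shared ancestry; that separation comes from context
(cross-clade pairs, ANI corroboration, element incongruence). The model
assumes uniform substitution; real mutational spectra are transition-biased,
which the rendered tables do not correct for — with large shared-SNV counts
the conclusion is insensitive to this, which is why the uniform model is
kept as the default and only model.

Rendering follows the reporting convention for expected counts: exact zero
prints `0`, positive values below one print `<1` (the report also shows the
numeric value in parentheses), and larger values print with two decimals
for pairs and more for triplets.

## Synthetic scenario generator

The generator emulates a two-clade, three-depth community of six
populations with the following default conditions:

| parameter | default | meaning |
| --- | --- | --- |
| `contig_lengths` | 6 × 40 kb | per-population genome (240 kb, desk scale) |
| `orf_fraction` | 0.85 | coding density typical of thermophile genomes |
| `clade_divergence` | 0.16 | between-clade per-site substitution fraction ⇒ ~84% ANI |
| `within_clade_divergence` | 5 × 10⁻⁵ | per population from its clade reference ⇒ within-clade pairs at ~10⁻⁴ ⇒ ~99.99% ANI |
| `snv_rate` | 5 × 10⁻³ per ORF bp | per-population burden of order 10³ on the default genome, scaling to the observed 10³–10⁴ burdens at full genome size |
| `snv_freq_range` | U(0.05, 0.35) | minor-allele frequencies; no published spectrum exists for the system, so a flat range below the 0.40 consensus ceiling is used |
| `coverage`, `read_length`, `insert_median/sd` | 50×, 150 bp, 400 ± 50 bp | short-read pair geometry |
| `error_rate` | 10⁻³ | post-trimming substitution error |
| `mapq_default`, `zero_mapq_fraction` | 30, 0.02 | mapQ is simulated, not computed by a mapper; the zero fraction exercises the mapQ filter |

Construction order: founder genome (forward-strand ORFs: ATG start,
sense-codon body, stop codon; ORF lengths 100–400 codons laid out to hit the
coding-density target per contig) → ancestral mobile-element insertions →
clade divergence (the `S` reference is the founder; the `D` reference
carries substitutions at `clade_divergence`, uniform over the three
alternative bases, so between-clade identity ≈ 1 − 0.16 by direct positional
comparison) → per-population divergence → per-population polymorphism
(sites uniform over ORF positions; the contig sequence is the consensus and
reads carry the variant at the truth frequency) → recombination tracts →
element transfer. All randomness flows from per-stage child streams of the
configured seed, so identical configurations give byte-identical outputs.

Design choices worth knowing:

- **Recombination tracts never split an ORF.** Tract endpoints are snapped
  outward to ORF boundaries. This models homologous recombination at gene
  granularity and guarantees that a transferred polymorphism sits in an ORF
  whose entire sequence is donor-derived, so the protein-clustering route
  can recover it. Donor polymorphisms inside the tract are copied into the
  recipient truth (the ground-truth same-substitution signal); pre-existing
  recipient polymorphisms there are dropped, i.e. the tract is modeled as
  having replaced the recipient haplotypes at that locus.
- **Element insertions are intergenic** and shift downstream ORF, SNV and
  element coordinates consistently. Vertical inheritance is modeled by
  inserting into the founder before divergence; horizontal transfer by
  overwriting one population's copy with another's after divergence;
  truncated homologs by inserting a prefix of the element.
- **Uniform divergence and cross-clade orthology.** With substitutions
  uniform across sites, 16% nucleotide divergence puts *every* cross-clade
  protein pair near 60–70% identity — below the 0.90 clustering threshold.
  Real genomes concentrate divergence outside conserved genes, so real
  cross-clade orthologs often do cluster. In the simulator, cross-clade
  homologous sites are therefore identifiable only where a recombination
  tract has homogenized the sequence. Consequences: the no-recombination
  null (cross-clade evidence `none`) holds essentially deterministically in
  simulation, and the 1/3 same-substitution ratio property is exercised on
  within-clade pairs, where consensus bases agree and orthologs cluster.
  Passing these tests shows the machinery is correct under the model's
  assumptions; it does not calibrate cross-clade cluster recovery on real
  data.
- **No indels** (in evolution or sequencing) by default; ORFs are
  forward-strand by default. Reverse-strand handling exists in the types
  and coordinate logic but is not exercised by the generator.

## SNV calling

Read pairs are filtered sequentially: identity to the reference < 0.90
discarded (bound inclusive: exactly 0.90 is retained); both mates need
mapQ ≥ 1; insert sizes must lie in [50 bp, 3 × median insert], the median
taken over pairs that already passed the identity and mapQ filters
(two-pass), both bounds inclusive. The filter log records per-filter
removal counts and satisfies `input = retained + Σ removed`.

Pileups count both mates, including overlapping mate bases (a configurable
choice; the default keeps the contract simple). Per site: the consensus is
the most frequent base and must also carry the highest mean mapQ among
observed bases — count ties or a higher-mapQ minor base reject the site
(logged). The variant is the most frequent non-consensus base with
≥ 2 supporting reads and frequency ≥ 0.05; a variant reaching ≥ 0.40 of
reads is a "consensus SNV" — unresolvable allelic heterogeneity — and is
discarded (counted, not emitted). The support floor of 2 reads stops
singleton sequencing errors from becoming SNVs; the 0.05 floor is the
source caller's canonical default.

Operating characteristics at the defaults (50× coverage, 10⁻³ error, truth
frequencies U(0.05, 0.35)) are measured by the test suite on a 100 kb
simulation: precision ≈ 0.99, recall ≈ 0.90. The recall ceiling is
structural, not a tuning artifact: a site at the 0.05 frequency floor
yields an expected variant count of 2.5 at depth 50, indistinguishable from
the ~35–40 two-read error doublets that arise per 100 kb at this error
rate, and truth frequencies near 0.35 cross the hard 0.40 consensus ceiling
by sampling noise. Dropping the frequency floor trades to precision ≈ 0.92,
recall ≈ 0.95. No count/frequency rule attains 0.95/0.95 simultaneously
under these conditions; the defaults favor precision, which is the
conservative choice for a shared-SNV analysis (false SNVs could fabricate
shared sites).

Only SNVs inside ORFs proceed downstream (genome-wide and in-ORF totals are
both reported). The collated per-SNV table carries the site, frequencies,
ORF location and coding-strand offset, the ORF nucleotide sequence, the
inferred protein, the protein cluster, and an empty annotation column.

## Orthology and site mapping

Clustering is greedy and incremental in the canonical longest-first order
(ties broken lexicographically), so it is invariant to input order: a
sequence joins the first cluster whose representative it matches at ≥ 0.90
global identity, else founds a new cluster. Identity is matched columns /
alignment columns under an optimal unit-cost global alignment (edlib);
gaps count in the denominator, so identity can never exceed
min(len)/max(len) — that bound doubles as a cheap pre-alignment screen.

Site maps align each member ORF (nucleotide, coding strand) to the cluster
representative and record all aligned (non-gap/non-gap) columns, mismatches
included. Member-to-member correspondence is composed through the
representative, which makes the correspondence transitively consistent by
construction; with no indels it reduces to the identity mapping, which the
tests verify on every simulated homolog pair. Cross-population "same site"
is defined exclusively through these maps.

## Shared SNVs and group statistics

SNVs are bucketed by (cluster, representative coordinate). A bucket with
≥ 2 distinct populations is a shared site; it is `same_substitution` when
every participant carries the identical (consensus, variant) pair. Pair
counts are computed pairwise from the participants (a site shared by three
populations contributes to all three pairs); triplet counts require all
three members to carry an SNV at the site. Records present in all six
populations are flagged ancestral. Group comparisons (abundance class,
clade, depth-interval pairs × four SNV-profile metrics) use two-tailed
Student's t-tests (equal variance; Welch available), with undersized groups
reported as undefined rather than zero.

## Fragment ANI

The query contig is cut into non-overlapping 3 kb fragments (whole contig
if shorter; a sub-fragment tail is dropped). Fragments are placed by exact
16-mer seeding — seeds every 16 bp vote for diagonal offsets, the top five
offsets are scored — and each fragment takes the best positional identity
over candidate windows. Fragments under 0.80 identity are unmapped; ANI is
the mean identity of mapped fragments × 100, undefined when nothing maps
(sequences below the floor cannot be aligned reliably, so no number is
reported rather than a misleading one). Reported ANI averages both
directions. Seeding has no gapped extension, which is adequate for the
generator's indel-free genomes and for the comparative (not absolute) use
the pipeline makes of ANI. The shared/non-shared group comparison averages
ANI over contig pairs (unweighted) and t-tests per-pair mean length and
mean coverage as confound checks.

## Element identity and congruence

Per element, pairwise global-alignment identity over full sequences —
end-to-end, so a truncated homolog scores roughly its retained fraction
(a 600 bp prefix of a 1,000 bp element scores ≈ 0.60). The congruence rule
is declared rather than inferred: `congruent` iff the minimum within-clade
identity strictly exceeds the maximum between-clade identity,
`incongruent` iff some between-clade identity strictly exceeds some
within-clade identity, `undetermined` on exact ties or when either clade
has fewer than two carriers.

## Pipeline and reproducibility

`run_pipeline` executes simulate → call → cluster → share → converge → ANI
→ elements → report under one run directory and writes a manifest with a
SHA-256 hash of every emitted file; reruns with the same configuration are
byte-identical (verified in tests). Coordinates are 0-based half-open
internally, 1-based closed in GFF3. The command-line interface is a thin
layer over these functions.

## Problem sizes used in the tests

The test suite exercises the statistics at desk scale: 100 kb single-contig
genomes for caller precision/recall, 3 × 8 kb six-population scenarios for
the 50-replicate shared-SNV/evidence/ANI studies (the shared-SNV stages run
from ground-truth tables there, isolating them from caller noise, whose
recovery is measured separately), 10⁵–10⁶ sites for Monte-Carlo
validation, and 10-replicate element-congruence studies. These sizes keep
the full suite under a minute while leaving every statistical check
non-degenerate.

## Known limitations

- No indel evolution, no selection or demography, no real read mapping or
  FASTQ emission; mapQ is assigned, not computed.
- The convergence model's uniformity assumption is kept by design; no
  transition/transversion weighting is applied to reported tables.
- Element detection is consumed, not performed: the pipeline compares
  annotated elements, it does not find them.
- Relative abundance and completeness are inputs from upstream binning,
  never computed here.
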