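# Methods

This note documents the models, rules and numerical choices behind
`markerpanel`, and what the simulated-data tests do and do not demonstrate.

## Data model

Genotypes live in a samples × variants matrix of alt-allele dosages
{0, 1, 2, MISSING}, with an optional read-depth layer of identical shape.
Coordinates are 1-based as in VCF and windows are inclusive at both ends
unless stated otherwise. Half-calls (`0/.`) are treated as missing: none of
the filtering rules distinguish them from full no-calls, and low-coverage
data makes the distinction unreliable anyway. Sites are keyed by
`scaffold:pos:allele1:allele2` with alleles sorted lexicographically, so a
site called with opposite ref/alt polarisation in two cohorts maps to one
key; this is what makes cross-cohort unions and intersections well defined.

Per-site statistics are computed from integer genotype counts. MAF is the
minor-allele count over 2 × called samples rather than `min(p, 1−p)` in
floating point: at the boundary the two differ (1 − 0.8 < 0.2 in doubles),
and the boundary is exactly where the filters operate. The observed
heterozygosity denominator excludes missing genotypes — the standard
definition, and the only one stable under variable call rates.

## Filter profiles

A `FilterProfile` bundles the thresholds of one cohort's filtering column.
Rules run in a fixed order (depth mask → density screen → alt-read support →
missingness → Ho cap → MAF floor → rare-allele carriers → per-group call
rate) and each dropped variant is attributed to the first rule that rejects
it, so drop counts plus survivors always equal the input count.

Boundary semantics: every threshold keeps the boundary value
(missingness ≤ 0.30 keeps 0.30; Ho ≤ 0.49 keeps 0.49; MAF ≥ 0.2 keeps 0.2),
except the GBS profile's MAF floor, which is strict (> 0.2). The inclusive
whole-genome MAF floor is forced by the filter's own arithmetic at small
cohort sizes: with 10 diploids, 4 minor-allele copies among 20 is exactly
0.2, and 4 is the intended minimum passing count — a strict comparison would
silently raise it to 5.

The Ho ≤ 0.49 cap targets collapsed paralogs: two duplicated loci genotyped
as one site make essentially every sample appear heterozygous. The cap is
the only paralog diagnostic implemented; allele-ratio (read-level) paralog
statistics are out of scope because the data model carries genotypes, not
allele-specific reads. For the same reason the minimum-alt-read rule
approximates per-site alt support as Σ depth·dosage/2 over carriers — exact
in expectation for unbiased calls — and raises if no depth layer is present
rather than silently passing.

The density screen (> 3 variants in any 100 bp window) is applied post hoc
to the called variant table; variant callers often enforce the same
predicate at calling time, but applying it as a filter keeps it usable on
any upstream caller's output. The linked-loci screen drops the
downstream member of any pair closer than the window with identical dosage
vectors on ≥ 10 jointly called samples (configurable); the overlap minimum
protects against identical-by-chance matches on nearly-empty columns.

## Even-spacing selection

Per scaffold, greedily: select the first candidate; from the last selected
position L, take the candidate in [L+min_gap, L+max_gap] closest to
L+target_gap (ties to the smaller position); if the window is empty, take
the first candidate beyond L+max_gap and record an over-length gap.
Candidates closer than min_gap are skipped. Defaults: target 50 kb, bounds
30/60 kb. Anchoring each scaffold on its first candidate maximises the
number of scaffolds represented, which is what the represented-fraction
coverage statistic rewards on fragmented assemblies. The rule is checked
against a naive list-scan oracle on random scaffolds with ≤ 20 candidates.

## Probe-design screens

A candidate is rejected if any other detected variant — including ones that
failed quality filters — lies within ±20 bp, since nearby polymorphism
disrupts probe hybridisation regardless of its quality.

Flank uniqueness is decided by exact two-strand matching of the 101-mer
window centred on the site, with the variant base free to match either
allele; both allele versions hit the native locus, so a clean locus scores
exactly 2 and any duplicated flank elsewhere scores more (`multi`). Exact
matching is a deterministic, dependency-free proxy for alignment-based
screens; mismatch-tolerant mapping is deliberately out of scope, so the
screen is conservative in the direction of calling borderline repeats
unique. Windows overrunning a scaffold edge are flagged `edge` and cannot be
designed. The flank length defaults to 50 bp and is configurable.

Design output is the standard 101-mer with a `[A/B]` allele block (alleles
alphabetical) at position 51. Failed probes are replaced by the nearest
eligible candidate in an inclusive [P−20 kb, P+10 kb] window, ties broken
downstream (arbitrary but fixed); empty windows mark the probe unreplaced.

## DAPC assignment panels

Missing dosages are mean-imputed per variant before centering — the model is
kept fully linear so new samples project through the stored means, PC
loadings and discriminant coefficients with no refitting. PCA retains either
an explicit number of axes or the axes reaching 80% cumulative variance,
capped at n_samples/3; retaining too many axes overfits the discriminant
step, and the cap also keeps the within-class scatter well conditioned. The
discriminant step is an eigen-solver LDA on the PC scores. Variant
contributions per axis are the squared composites of PC loadings with
discriminant coefficients, normalised to sum to one per axis.

Ranking collapses per-axis contributions by their maximum over axes
(default), preserving variants that discriminate strongly on any single
axis; an eigenvalue-weighted sum is available via configuration.
Hierarchically structured populations are handled by an ordered list of
contrasts (subset + relabel); the panel is the deduplicated union of the
per-contrast top-N lists (default 2,000 per contrast). Assignment of new
samples is by nearest group centroid in discriminant space, with normalised
inverse-distance scores; all-missing samples collapse to the training mean
and are flagged low-confidence.

## Sexing

X-based calls use mean observed heterozygosity per sample over X-linked
SNPs, after refining the X set to SNPs never heterozygous in males
(pseudoautosomal proxy). With no male metadata a two-pass self-refinement is
used: provisional sexes from all X SNPs, then SNPs heterozygous in any
provisional male are dropped and heterozygosity recomputed. A sample is
called male when its X Ho is strictly below 0.03; the boundary lands on the
female side because female Ho can be genuinely low in inbred populations
while male Ho above the threshold indicates a real problem. Y-probe calls
classify a sample female when its missing fraction over functional probes is
at least 0.50 (inclusive); dead probes — called in no sample — are excluded
from the denominator. The two calls are combined into a consensus that flags
conflicts explicitly and reports concordance against known metadata.

## LD

Composite r² (squared Pearson correlation of dosages over jointly called
samples) requires ≥ 10 shared calls and is undefined for constant vectors —
undefined pairs are counted and excluded from means rather than zero-filled.
Group averages default to adjacent selected-marker pairs within 500 kb; an
all-pairs-within-window mode exists. How a published per-group "average LD"
was paired is generally underdetermined, so both modes are exposed and
reported with their pair counts.

## Simulator

The simulator generates what the pipeline consumes, with truth tables.
Population structure follows the Balding–Nichols model: per-population
allele frequencies are Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral
frequency p, so F is interpretable directly as FST and is checkable with the
Weir–Cockerham estimator (the test suite recovers a configured 0.1 within
±0.02 at 20 samples/population and ~5,000 sites). Ancestral frequencies are
uniform on [0.05, 0.95] by default; a U-shaped Beta(0.4, 0.4) spectrum with
rare alleles is available. Bottlenecked populations get a multiplied F
(default 5×, capped at 0.9).

Default study conditions: five 200 kb autosomal scaffolds plus one 200 kb X
scaffold, one SNP per ~2 kb, three populations of 20 diploids at FST 0.1,
2% missing genotypes, Poisson depth with mean 8 (low-coverage WGS
territory), 2% paralog-like sites, balanced sex ratio, six Y probes. These
are desk-scale stand-ins for a multi-cohort design study; tests state their
own sizes where they differ.

Male X genotypes are drawn haploid and reported as diploid homozygotes, the
way a genotyping chip reports hemizygous calls. Y probes are call/no-call
markers: present (reference call) in males, systematically missing in
females, with the global dropout rate applied on top. Paralog-like sites are
forced heterozygous in every sample. Sites are independent by construction,
so the default simulator induces no LD beyond the 1/n sampling floor; for LD
tests a founder-haplotype block mode draws each population's chromosomes
from a finite founder pool per block, so small pools (low effective size)
mechanistically elevate r².

All randomness flows from a single integer seed through one generator;
identical configurations produce byte-identical VCF/FASTA/TSV output.

What passing tests on simulated data do **not** show: behaviour under real
linkage structure, ascertainment bias of real SNP discovery, genotyping
batch effects, related individuals, or reference-assembly errors. The
simulator is a correctness harness, not a population-genetic forecast.

## Known limitations

* Uniqueness screening is exact-match only; diverged repeats that would
  cross-hybridise are not detected.
* Alt-read support is approximated from DP when AD is unavailable.
* The assignment model assumes the panel's variants are present (possibly
  missing) in new samples; no marker-subset projection is provided.
* No variant calling, imputation, phasing, haplotype statistics, or
  relatedness-based sample QC.
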