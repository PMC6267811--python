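# Methods

`varrep` quantifies how representative a benchmark dataset of single amino
acid substitutions (SAASs) is of the human protein universe.  A dataset is
projected into five category spaces — chromosomes, CATH structural
classes, Pfam families, Enzyme Commission (EC) numbers and Gene Ontology
(GO) terms — and each projection is compared against a proteome-wide
background distribution with a statistical battery.  This note records the
model, its assumptions, the tunable parameters, and the design choices made
where the procedure was genuinely open.

## Pipeline

1. **Identifier resolution.**  Variants carry a reference-sequence
   identifier in one of three namespaces.  UniProt accessions pass through
   when the accession exists in the reference.  RefSeq and Ensembl
   identifiers map through a cross-reference table *only when the foreign
   and canonical sequence lengths match exactly*; a length mismatch means
   the two records describe different isoforms and the variant coordinate
   cannot be trusted.  A resolved variant whose position exceeds the
   canonical protein length is demoted back to unmapped.

2. **Structure-residue mapping.**  Candidate structures are those whose
   chain interval (SIFTS-style residue mapping) contains the variant
   position.  They are tried best resolution first.  If the residue at the
   position is not observed in the crystal (`Not_Observed`), the *whole
   structure* is discarded and the next one tried — even if another chain
   of the same structure is observed there; this is the strictest reading
   of the selection rule and keeps the procedure a simple total order.
   Within the chosen structure, the first chain in input-file order
   containing the position wins.  Structures without a resolution value
   (NMR-like) sort after all resolved structures; remaining ties break on
   structure id lexicographically.  These two tie-breaks are our own: the
   procedure needs a total order to be deterministic, and the source data
   do not supply one.

3. **Category projection.**  CATH codes come from the domain whose segment
   (in structure residue numbering) contains the mapped residue; CATH
   assignment therefore requires a structure, with no sequence-based
   fallback.  Pfam families are all families whose interval contains the
   protein position.  EC and GO assignments are protein-level lookups,
   independent of position.  EC codes keep their native depth: a 3-level
   code contributes to levels 1–3 and silently drops out of level-4
   counts.  A variant contributing several categories at one level
   (overlapping Pfam domains, several GO terms) increments each category
   once; counting only the first is available behind the
   `multiplicity="first_only"` switch.

4. **Backgrounds.**  The CATH background takes the first chain of each
   95 %-identity cluster as its representative and counts each domain on
   that chain once.  Pfam, EC and GO backgrounds count annotation rows
   over all proteins.  The chromosome background stores both weighting
   bases — protein-coding gene counts and summed coding-sequence (CDS)
   lengths — because both are used.

## Statistical battery

* **Per-chromosome two-tailed binomial test.**  For chromosome *c* with
  weight *w_c*, the observed count *k_c* out of *n* assigned variants is
  tested against `p0 = w_c / Σw`.  The p-value follows the
  minimum-likelihood definition: the total probability of all outcomes
  whose Binomial(n, p0) mass does not exceed the mass at *k_c*, with a
  `1 + 1e-7` relative slack on the comparison so that floating-point
  near-ties are included.  Expected counts are `n · w_c / Σw` and sum to
  *n* exactly.
* **Pearson chi-square** over all chromosomes with `k − 1` degrees of
  freedom (the expectations come from fixed proportions, no estimated
  parameters).  Zero expected cells are an error, never smoothed.
* **Two-sample Kolmogorov-Smirnov** on the per-category *relative
  frequency vectors* (category counts normalised by the level's total
  assignments) of dataset versus background.  D is the exact maximum ECDF
  gap.  The p-value evaluates the Kolmogorov distribution at
  `(e_n + 0.12 + 0.11/e_n) · D` with `e_n = sqrt(nm/(n+m))` — the
  classical small-sample-corrected asymptotic approximation.  It is used
  even at tiny sample sizes (for GO aspects, n = m = 3) because the
  procedure is defined that way; an exact permutation-distribution p-value
  is available via `ks_mode="exact"` for honest small-sample work.
* **Coverage** `A(DS)/A`: the fraction of background classes with at least
  one representative in the dataset.  Labels found in the dataset but
  absent from the background are counted separately and never enter the
  numerator.
* **Benign-contamination screen.**  A variant matches the allele-frequency
  table when an entry with the identical (accession, position, reference,
  alternate) has a minor allele frequency *strictly* between 1 % and 25 %
  in at least one of the populations (default 7).  Bounds are strict: a
  MAF of exactly 0.25 does not match.

**Significance levels.**  Chromosome binomial tests use α = 0.05;
KS tests use α = 0.01.  Both are configurable (`AssessmentConfig`).

**Summary score.**  Eleven category tests (CATH class / architecture /
topology / homology, EC levels 1–4, Pfam, GO terms, GO aspects) each score
1 when unbiased (p > α) and 0 otherwise; the score is the sum.  The
per-chromosome unbiased count is reported beside the score, not inside it.
A category that cannot be computed — e.g. all four CATH levels when no
variant reached a structure — scores 0 and is listed in
`score.not_computable`; silent omission would make scores of different
datasets incomparable.  The unbiased-chromosome count uses the gene-count
basis by default (`chromosome_basis="gene"`), with the CDS basis reported
alongside.

**Rounding.**  Reported percentages use two decimals, round-half-even.

## Synthetic universe

The generator (`varrep.synth`) emits a miniature human-like proteome so
the whole pipeline is testable without downloads.

| parameter | default | rationale |
|---|---|---|
| `n_chromosomes` | 24 (1–22, X, Y) | human nuclear genome, no MT |
| `genes_per_chromosome` | census-proportional | apportioned from the packaged per-chromosome protein-coding gene counts (19,786 total) |
| `cds_lognormal_mean/sigma` | 7.2 / 0.6 (log nt) | log-normal CDS lengths, median ≈ 1.3 kb, matching the human median coding length |
| `protein_count` | 200 | one canonical protein per gene; small enough for fast tests |
| `structure_coverage_fraction` | 0.4 | fraction of proteins with ≥ 1 structure; order of magnitude of human structural coverage |
| `unobserved_residue_rate` | 0.05 | per-residue probability of a `Not_Observed` flag (flexible termini, loops) |
| CATH counts | 4/12/40/90 | the human hierarchy (4 classes, 30 architectures, 508 topologies, 907 superfamilies) scaled ~1:10 below class level |
| `n_pfam_families` | 60 | ~1:100 of the human 5,734 |
| `enzyme_fraction` | 0.21 | 21 % of human proteins carry an EC number |
| `ec_incomplete_rate` | 0.15 | fraction of codes lacking the 4th level, matching the observed drop between level-3 and level-4 annotation counts |
| `go_terms_total` | 150 | three aspects in a 25/55/20 molecular-function / biological-process / cellular-component split |
| `crossref_mismatch_rate` | 0.02 | fraction of cross-references with a length mismatch, exercising the isoform-mismatch rule |

Protein length is derived from CDS length as `floor(CDS/3) − 1` with a
30-residue floor — genes and lengths are thereby coupled but distinct, so
the gene-weighted and length-weighted chromosome tests remain separate
checks.  Each structure-covered protein's first structure spans the full
protein and later structures are fragments; with coverage fraction 1 and
unobserved rate 0 every residue is therefore mappable, while the defaults
leave realistic gaps.  Clusters group all chains of one protein,
emulating 95 %-identity redundancy grouping.

**Sampling modes.**  `uniform` draws residues uniformly over all residues
of all proteins (the unbiased null).  `hotspot` draws proteins with
probability ∝ rank^(−γ) — a Zipf rank law — and then a residue uniformly
within the protein, emulating the extreme per-protein concentration of
curated disease datasets (a handful of intensively studied proteins
carrying thousands of variants).  The true family-size and hotspot shapes
of the human data are heavy-tailed but not documented in any form usable
here; the power law / Zipf choices are explicit stand-ins.

Each generator operation draws from its own independently seeded stream
(`numpy` `SeedSequence.spawn`), so adding a registry never perturbs
another's output, and identical configurations yield byte-identical
emitted tables.

**What the generator does not emulate:** real human gene content, real
CATH/Pfam frequency spectra, linkage between variants, nucleotide-level
mutation processes, or shared structures between different proteins.
Passing tests on synthetic data therefore demonstrate the correctness and
calibration of the *procedure*, not conclusions about any real dataset.

## Calibration and known behaviour

Under uniform sampling the per-chromosome binomial test at α = 0.05 flags
each chromosome in ≈ 5 % of replicate datasets, and the CDS-weighted
chi-square accepts (p > 0.01) in ≥ 95 % of replicates — the battery's
false-positive rate is nominal.  The chromosome chi-square grows
monotonically with hotspot concentration.

One structural property deserves emphasis: dataset category frequencies
are *variant-weighted* (a protein with many variants contributes many
counts) while the backgrounds are annotation censuses.  Even uniform
sampling therefore converges to a length-weighted profile, not exactly to
the background, and deep levels with many small categories (CATH homology,
EC levels 3–4, Pfam, GO terms) tend to stay flagged as biased at large n.
Total-variation distance to the background decreases with dataset size but
plateaus at this weighting floor.  The same signature — shallow levels
unbiased, deep levels biased even for the largest, most neutral datasets —
is exactly what the method reports on real benchmarks, so it is treated as
a property of the statistic, not a defect.

## Degenerate inputs and numerical notes

* Empty datasets produce zero tallies, header-only report tables, and all
  category tests marked not-computable.
* Malformed variant rows (non-positive positions, identical or
  non-canonical residues — B/Z/X/U are rejected) are dropped and counted,
  never repaired.
* Reference bundles are validated on load; any dangling annotation or
  out-of-bounds segment raises an error listing the offenders.
* Overlapping CATH segments on one chain are treated as a corrupt
  reference (error), since domain boundaries partition a chain.
* All residue coordinates are 1-based inclusive; structure versus protein
  numbering is crossed only inside the chain-mapping record.

## Problem sizes

The test suite runs the worked chromosome example at its native size
(n = 445,989; large-n binomial p-values take ~1 s for all 24
chromosomes), and the synthetic properties at 200–500 proteins with
datasets of 10²–10⁴ variants, 50–200 replicate seeds for the calibration
and directional-power checks.  The acceptance script adds a 300-protein
end-to-end run with two 5,000-variant datasets.

## Limitations

* No GO-graph propagation to ancestor terms; frequencies are over
  directly annotated terms.
* No sequence alignment anywhere: cross-reference mapping is lookup plus
  length equality, which discards isoform-shifted variants rather than
  rescuing them.
* The KS asymptotic p-value is anticonservative at very small category
  counts; the exact mode exists but changes the defined procedure.
* No multiple-testing correction across the eleven category tests; the
  score is a descriptive summary, not a family-wise inference.
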