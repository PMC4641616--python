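# Methods

## Model and procedure

`varinfer` treats variant identification as a set-cover problem over
peptide evidence. The observed unit is the peptide-spectrum match (PSM): a
peptide sequence identified in a sample (a 2-D gel spot or an LC-MS run)
with a search-engine tier (pass-1 matches are independently reliable;
pass-2 matches only supplement existing identifications), a score, optional
modifications and an observed mass. The hypothesis space is a restricted
database of candidate variant sequences. A peptide supports a variant iff
it occurs in the variant's fully tryptic in-silico digest under the
configured missed-cleavage limit; modifications never affect this matching
(they change mass, not identity), so modified and unmodified observations
of one sequence collapse to a single evidence row.

The inference pipeline is:

1. discard pass-2 PSMs (`filter_pass_two`);
2. build the boolean peptide × variant incidence matrix; peptides matching
   no variant go to an orphan report and never fail the run;
3. greedy parsimony: repeatedly select the variant matching the most
   remaining peptides, prune every other candidate whose remaining peptide
   set is a subset of the selection (recorded `subsumed_by:<accession>`),
   remove the assigned peptides, and iterate until none remain. Assigned
   sets are therefore pairwise disjoint and exhaust the explainable
   peptides;
4. evidence pruning: a selected variant's *distinguishing evidence* is the
   set of PSMs supporting its assigned peptides that occur in **no other
   database entry** — its variant-specific peptides. If fewer than
   `min_unique_psms` of those PSMs are acceptable (tier-1 unless
   `accept_tier2_unique`, and at or above `score_floor`), the variant is
   removed, its peptides return to the pool, and greedy assignment is
   re-run over the surviving candidates. A variant with *no*
   variant-specific peptides is selected purely on shared evidence (it is
   the representative of an indistinguishable or shared-only group) and is
   never removed by this rule — removing it could only substitute an
   equally shared alternative or orphan its peptides. Retained variants
   whose distinguishing evidence is exactly one acceptable PSM are flagged
   `single-unique-peptide` so the underlying spectrum can be reviewed
   manually.

Tie-breaking in step 3 is deterministic: peptide count, then summed PSM
score over the matched peptides, then potential sequence coverage, then
lexicographically smaller accession. All reports are byte-reproducible
from the same inputs and configuration; the full configuration is echoed
into every report header and timestamps appear only in logs.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_missed_cleavages` | 1 | internal K/R sites allowed per peptide |
| `proline_rule` | on | no cleavage of K/R–P bonds (Keil rule) |
| `min_length` | 1 | minimum peptide length emitted by the digest |
| `min_unique_psms` | 2 | acceptable distinguishing PSMs required to keep a variant; 1 = manual mode (retain + flag) |
| `score_floor` | 0 | PSMs scoring below it count as doubtful |
| `accept_tier2_unique` | off | whether pass-2 PSMs may serve as unique evidence |
| `substring` | off | fall back to substring matching for non-tryptic exports |
| `il_equivalent` | off | merge Leu/Ile for peptide matching |
| `pooled` | off | merge spots instead of inferring per spot |

Identity between sequences is computed by global (end-to-end) alignment
with BLOSUM62, gap open 10, gap extend 1, as
100 × identical columns / alignment length (gap columns included). The
convention matters at the ±1-point level for truncated entries; the
relationship classes use strict thresholds (identical = 100; variant
> 90; isoallergen > 67; distinct ≤ 67, so exactly 90 is an isoallergen and
exactly 67 is distinct). Monoisotopic masses use the standard residue
table plus water (18.010565 Da); supported modifications are fixed
carbamidomethyl-C (+57.02146 Da) and variable deamidation-N/Q
(+0.98402 Da) and oxidation-M (+15.99491 Da). Mass accuracy is reported as
signed ppm error.

## Synthetic data

`make_family` draws a random base sequence (default 160 residues, combined
K+R frequency 0.11 — the size and cleavage-site density of a typical
PR-10 pollen allergen, giving realistic tryptic peptide lengths) and
derives each variant by a configured number of random point substitutions
(logged, so all pairwise identities are derivable). Substitutions may
create or destroy cleavage sites, as real variant families do.
`simulate_psms` detects each digest peptide of each true variant
independently (default probability 0.7; the validation studies use 0.9),
downgrades a detected peptide to pass-2 with probability `tier2_rate`,
samples log-normal scores (μ = ln 1000, σ = 1, loosely spanning the score
range of a typical search-engine export — scores only feed tie-breaking
and the pruning floor, so the exact law is non-critical), applies a normal
mass error (sd 3 ppm, the scale of routinely reported accuracies), samples
deamidation/oxidation states, and optionally adds Poisson-distributed
contaminant PSMs that match no database entry. Everything is driven by
explicit seeds and is byte-reproducible.

The generator emulates the *evidence structure* of real data — homology,
peptide sharing, missed detections, unreliable supplementary matches — but
not spectra, retention behaviour, intensities, truncated database entries,
or correlated detection failures (e.g. poorly ionising peptides missing in
every variant). Passing recovery tests therefore demonstrates the
correctness of the inference logic under the stated detection model, not
performance on any particular instrument or sample.

## Validation studies and problem sizes

The test suite and `scripts/acceptance.py` run five studies, sized to
complete in seconds: (1) the three-entry worked example in the README;
(2) 500 random incidence matrices (2–10 variants × 2–15 peptides,
membership density 0.3) compared against the exhaustive minimum-set-cover
oracle; (3) noise-free recovery on ten seeds of a 20-variant family
(160 aa, 3–15 substitutions per variant, 8 true variants, detection 0.9) —
precision = recall = 1 on every seed; (4) a planted decoy variant whose
sole distinguishing evidence is a single pass-2 PSM, removed by the
default pruning policy, restoring precision to 1; (5) the digestion
partition invariant on 1000 random sequences.

## Design choices and numerical notes

- **Fully tryptic matching** rather than substring matching: the upstream
  search space is tryptic, and substring matching would create spurious
  sharing between variants. The `substring` flag covers non-tryptic
  exports.
- **Greedy, not exact, cover** as the primary algorithm: it reproduces the
  iterative manual procedure exactly, is deterministic and fast, and the
  exhaustive oracle is available for instances up to 20 variants. Greedy
  can exceed the true minimum when a non-essential entry matching the most
  peptides is selected before entries forced by unique peptides (an
  explicit counterexample is kept in the test suite); on the random panels
  above this affects a few percent of instances and never produces an
  under-cover or a missed peptide.
- **Evidence pruning compares against all database candidates**, not only
  co-selected entries: a variant's claim to existence is exactly its
  variant-specific peptides, and a selected superset-entry whose extra
  peptide is one doubtful spectrum must be removable in favour of the
  entry it subsumed.
- **Degenerate inputs**: an empty PSM table or an incidence matrix with no
  rows yields an empty result, not an error; peptides explainable by no
  entry are reported as orphans; a database must be non-empty for
  inference.
- **Coordinates** are 1-based inclusive in every interface; every
  occurrence of a repeated peptide counts for coverage, overlapping
  residues count once.
- **N-terminal methionine** is not removed automatically; an optional
  digestion flag enables it.

## Limitations

Spectrum-level re-evaluation of single-peptide identifications cannot be
automated here; the `single-unique-peptide` flag marks where a human (or
an external rescoring tool) must look. The tool performs the restricted-
database step of a two-step search strategy; the initial broad-taxonomy
search that establishes basic protein identity lives upstream in the
search engine, and running both steps means running the tool with two
different FASTA inputs. Identity values depend on the alignment convention
at the ±1-point level for entries of very different lengths.
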