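# varinfer

Parsimony-based disambiguation of closely related protein sequence variants
from peptide-level mass-spectrometry identifications.

## The problem

Shotgun and MS<sup>E</sup> proteomics identify proteins from tryptic
peptides, and when a sample contains families of highly similar sequences —
isoallergens (>67% identity) and variants (>90% identity) of a pollen
allergen, isoforms, closely related homologues — most peptides match many
database entries at once. Search engines then either report large redundant
protein groups or promote entries supported by a single spectrum of
arguable quality. This is the classical *protein inference problem*, and it
is acute in the quality control of allergen products, where knowing *which*
isoallergens are present matters clinically.

`varinfer` implements a conservative, fully deterministic analysis strategy
for this situation as a reusable library and command-line tool:

1. **Restricted variant database** — read a FASTA of candidate variants,
   collapse 100%-identical entries (keeping a preferred accession if
   configured), and characterise the family: pairwise identity matrix
   (global alignment, BLOSUM62, gap open 10 / extend 1), relationship
   classes, and a census of shared vs. variant-specific tryptic peptides.
2. **PSM quality filtering** — read a tab-separated peptide-spectrum-match
   table (peptide, spot, pass-1/pass-2 tier, score, modifications, observed
   mass) and remove all pass-two matches, which are not reliable enough to
   identify a protein on their own.
3. **Greedy parsimony assignment** — build the boolean peptide × variant
   incidence matrix from in-silico tryptic digests and iteratively select
   the entry matching the largest number of remaining peptides, remove
   every entry identified by the same set or a subset of those peptides
   (subsumption), remove the assigned peptides, and repeat until every
   peptide is assigned. The result explains all the peptide evidence with
   the smallest achievable number of protein entries (Occam's razor).
4. **Evidence pruning** — remove selected entries whose variant-specific
   evidence rests on fewer acceptable spectra than the policy allows
   (e.g. a single pass-two match), re-assigning their shared peptides;
   single-spectrum identifications that survive are flagged for manual
   review of the fragmentation spectrum.
5. **Validation tooling** — an exhaustive minimum-set-cover oracle, a
   grouping-scenario classifier (distinct / differentiable /
   indistinguishable / subset / subsumable / shared-only /
   random-assignment), per-entry sequence coverage, and a synthetic-data
   generator producing seeded homologous families and ground-truth PSM
   tables for end-to-end benchmarking.

Formally: given peptides *P*, variants *V* and incidence
*M ∈ {0,1}^{|P|×|V|}*, the method approximates the minimum set cover
argmin<sub>S⊆V</sub> |S| s.t. ∪<sub>v∈S</sub> {p : M<sub>pv</sub>=1} ⊇ P
with the classical greedy algorithm, with deterministic tie-breaking
(summed PSM score, then potential coverage, then accession), and audits
every removal.

## Worked example

Three candidate entries — `A` (full length), `B` (N-terminally incomplete,
missing the first tryptic peptide) and `C` (a fragment containing only the
last) — and five identified peptides, all of which occur in `A`:

```bash
varinfer infer variants.fasta psms.tsv --min-unique-psms 1 --outdir out
```

`out/result.tsv` (configuration header omitted):

```
spot_id  accession  round  n_peptides  n_unique_peptides  evidence_class         coverage_pct  peptides
28       A          1      5           1                  single-unique-peptide  100.0         AAAK;CCDK;EEFK;GGHK;IIMK
```

`out/pruning.tsv`:

```
spot_id  accession  reason
28       B          subsumed_by:A
28       C          subsumed_by:A
```

All five peptides are assigned to the single entry `A`; `B` and `C` are
pruned because their peptides are a fraction of `A`'s — a search engine
distributing the same five peptides across all three entries would have
reported two spurious variants. The `random-assignment` label in
`out/scenarios.tsv` marks exactly this pattern (one entry's peptide set
contains the union of the others'). `A` is flagged `single-unique-peptide`
because only one peptide (the N-terminal one) separates it from `B`, so a
reviewer knows the call hinges on that one spectrum. With the default
policy (`--min-unique-psms 2`) such single-spectrum distinctions are
pruned automatically instead of flagged.

Other subcommands: `collapse`, `digest`, `identity`, `census`,
`simulate family`, `simulate psms`, `evaluate` (see `varinfer --help`).

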