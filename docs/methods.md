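# Methods

`dbdrescue` implements a domain-centric error-tracking protocol for fungal
zinc-cluster transcription factors (TFs). This note records the models,
parameters and numerical choices behind each stage, what the synthetic
benchmark does and does not emulate, and the known limitations.

## Background and model

The most abundant fungal TF family pairs an N-terminal Zn(II)2Cys6
("Zn2C6") binuclear-cluster DNA-binding domain (DBD) — six conserved
cysteines spaced `C-x(2)-C-x(6)-C-x(5,16)-C-x(2)-C-x(6,8)-C` — with a long
(~225–405 residue) all-alpha middle homology domain (MHD) downstream. A
smaller class pairs the MHD with one or two classical C2H2 zinc fingers.
Predicted proteins annotated with an MHD but *no* DBD ("MHD-only") are
treated here as candidate gene-model errors: in compact fungal genomes the
DBD-coding sequence usually survives in the genome even when the gene
caller truncated the protein, so it can be recovered by homology.

Two complementary protocols are implemented:

1. **Reference-guided diagnosis** (`tracking`). When an error-free
   full-architecture ortholog is available (the strain-panel setting), a
   six-frame translated local search of the reference against the assembly
   locates the homologous segments, and a fixed rule cascade names the
   cause: qualifying hits on ≥2 scaffolds → `assembly_split`; one scaffold
   but ≥2 reading frames → `frameshift`; a single hit covering 100% of the
   reference → `wrong_start`; otherwise `undetermined`. A hit qualifies at
   identity > 95% and aligned length > 20 residues. A corrected protein is
   rebuilt by translating the qualifying hits in their own frames and
   concatenating them in query order (overlaps resolved toward the
   higher-scoring hit), then re-screened for the motif.

2. **Nearest-neighbor rescue** (`recovery`). Without a same-species
   reference, the best full-architecture homolog (DBD + MHD, BLASTP-style
   E < 0.005) is taken from a reference panel. The gene body plus up to
   1000 nt of upstream sequence is searched two ways: a translated local
   search with the neighbor's DBD segment (E < 1e-4), and a spliced global
   alignment of the full neighbor protein, projecting the neighbor's DBD
   coordinates onto the genome. Candidates are validated against a domain
   profile (E < 0.1) *and* conserved-residue patterns (Zn2C6: two
   `C-x(2)-C`; C2H2: one `C-x(2,4)-C` and one `H-x(3,5)-H`), and must not
   overlap the annotated MHD. Failures are classified: `no_neighbor`,
   `no_genomic_sequence`, `n_region` (undefined sequence, N-run ≥ 10 nt),
   `partial_hit` (candidate passes only one of profile/patterns),
   `too_distant` (see below), `low_similarity`.

The protocol only diagnoses proteins that actually lack the full motif:
annotated proteins are screened with the motif scan first, and clean
proteins bypass diagnosis entirely. Applying the coverage rule to a clean
gene would otherwise mislabel it `wrong_start`.

## Alignment machinery

* **Protein local alignment**: optimal Smith–Waterman (no seeding
  heuristics; queries are desk-scale), BLOSUM62, affine gaps costing
  11 + k. E-values follow Karlin–Altschul, `E = K·m·n·exp(−λS)` with the
  gapped BLOSUM62 constants λ = 0.267, K = 0.041 and `n` the total target
  residues. Exact parity with NCBI BLAST is a non-goal; the constants
  reproduce the scale at which the protocol's E-value thresholds are
  meaningful.
* **Translated search**: the query is aligned against all six frame
  translations; stops score as mismatches (`*` column of BLOSUM62). Up to
  four non-overlapping hits per frame are extracted greedily (best hit,
  then recurse left and right of its span). Hit spans are reported in
  forward-strand nucleotide coordinates.
* **Hit refinement**: a maximal local alignment can gain score from a few
  chance-matching columns beyond a breakpoint, diluting identity below the
  95% rule. Qualification therefore considers the best sub-alignment above
  the threshold: columns are weighted +1 (match) / −19 (otherwise), so any
  positive-sum window has identity > 95%, and the maximum-sum window
  (linear scan) is used when the full hit fails the rule.
* **Spliced aligner**: a codon-level dynamic program, global in the query
  and local in the genome, with GT–AG introns of length ≥ 20 nt between
  codon-aligned blocks (intron opening penalty 15), linear costs of 4 per
  deleted query residue and 4 per inserted genomic codon, and no
  frameshift state (frame disruptions are the diagnosis stage's job).
  Intron transitions use a running-maximum over donor positions, keeping
  the DP at O(m·n); the kernel is JIT-compiled with numba. Ties prefer
  fewer introns, then the leftmost genomic start. Degenerate inputs (no
  positive-scoring chain) return an empty alignment with score 0.
  The linear (rather than affine) within-exon gap costs keep the traceback
  simple; under the study conditions gaps inside exons are short and the
  choice does not affect the recovered coordinates.

## Profile validation

Pfam-style HMM scoring is replaced by a self-contained stand-in: an
ungapped position log-odds profile built from the reference panel's own DBD
segments, anchored at each segment's first cysteine, with +1 pseudocounts
against a uniform background; profile length is the median anchored segment
length. A peptide's score is the best sliding-window column sum, and its
"E-value" is the empirical exceedance probability under a null of 10,000
random background peptides scored once per profile (fixed internal seed, so
the null is deterministic and independent of the data seed). The accept
threshold of 0.1 mirrors the role of the hmmsearch cut-off; combined with
the mandatory pattern rules it holds the measured false-acceptance rate on
DBD-free genomes below 1%.

## Global-candidate anchoring and the `too_distant` call

Because the spliced alignment is global in the query, the neighbor's DBD
residues are placed *somewhere* even when no DBD-coding sequence exists in
the window — scattered over intergenic DNA in spurious intron-patched
fragments. The projected-DBD region is therefore required to be positively
anchored: its substitution-score sum, minus intron/insertion/deletion
charges within its span, must exceed 1.5 points per DBD residue. Genuine
DBD-coding segments score ≈3–5 points per residue under the study
conditions; spurious placements ≈0–0.8. When the neighbor's body (MHD
region) aligns well (≥50% of non-DBD residues placed) but its DBD has no
anchored placement and no N-run explains it, the failure is reported as
`too_distant` — the DBD-coding region presumably lies beyond the searched
window. This is a heuristic: the method cannot observe the true distance.

Accepted candidates are trimmed to the motif span (first leftmost-shortest
match) when it is unambiguous, so the reported peptide corresponds to the
C...C core of the domain.

## Motif scanning conventions

All start positions are reported; at one start, alternative spacer
combinations collapse to the leftmost-shortest (smallest third spacer, then
smallest fifth — lazy regex quantifiers implement exactly this enumeration
order). `X` never satisfies a position requiring a specific residue.
Pattern counting for validation is non-overlapping, greedy left-to-right.

## Synthetic benchmark

The generator (`simulate`) emulates the statistical structure the protocols
assume, with full ground truth. Each locus is
`M + prefix (3–7 aa) + DBD + linker (28–45 aa) + MHD (250 aa) + tail`,
back-translated with uniformly sampled synonymous codons, embedded in
≥1600 nt of random intergenic DNA on either side, on a random strand.
The MHD is a cohort-wide consensus block mutated at 12% per gene so that
neighbor searches have signal; no attempt is made to model the real MHD's
eight internal motifs. Spacer/prefix/linker residues are drawn
cysteine-free so the planted motif is the unique match in its neighborhood
and recovered peptides can be compared to the truth exactly. Errors are
planted as described in the module docstring; the panel homolog of each
gene is a point-substituted copy at the configured identity (default 70%)
with the motif's anchoring residues frozen.

Two named default configurations pin the study conditions:

* `yeast_defaults` — intronless genes (budding-yeast-like), error spectrum
  75% frameshift / 4% scaffold split / 18% wrong start / 3% clean,
  matching the observed spectrum in closely related strain assemblies.
* `pan_fungal_defaults` — 0–3 short (30–80 nt) GT–AG introns, MHD-only
  annotations whose DBD lies 120–900 nt upstream of the annotated start,
  spectrum 40% wrong start / 30% missing upstream exon / 30% frameshift.
  The upstream-exon intron length is the knob that sets the DBD distance.
* `null_defaults` — no DBD anywhere in the genome; panel entries carry an
  unrelated DBD so the machinery runs end to end (false-positive control).

What passing tests show — and do not show. The generator's amino-acid
background is uniform and its intergenic DNA is i.i.d. random; real genomes
have biased composition, repeats, pseudogenes and paralogs, all of which
can only *raise* false-positive rates relative to the clean null measured
here. Conversely the planted errors are ideal-typical (exact codon-boundary
cuts, single insertions); real annotation errors are messier and the
measured recovery rates are an upper bound on field performance. The
reported problem sizes (cohorts of 200 genes) were chosen as the smallest
at which the binomial noise on the measured rates is comfortably below the
margins being tested.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `identity_min` | 95 | % | diagnostic hit qualification |
| `hit_len_min` | 20 | residues | diagnostic hit qualification |
| `neighbor_evalue` | 0.005 | E | nearest-neighbor acceptance |
| `local_evalue` | 1e-4 | E | translated DBD-segment hits |
| `profile_evalue` | 0.1 | p | profile validation threshold |
| `upstream_window` | 1000 | nt | searched upstream extent |
| `intron_open` | 15 | score | spliced-aligner intron charge |
| `min_intron` | 20 | nt | smallest recognizable intron |
| anchor margin | 1.5 | score/residue | global-candidate anchoring |
| N-run threshold | 10 | nt | `n_region` failure call |

## Known limitations

* The spliced aligner has no frameshift state; genes whose DBD region
  itself contains an indel are recoverable only via the local route.
* Introns are recognized at codon boundaries only (codon-complete blocks);
  phase-1/2 introns are not modelled, matching the generator.
* The `wrong_start` rule demands a single full-coverage hit, so a
  wrong-start gene that also carries introns in a real genome would fall
  through to `undetermined`.
* Multi-DBD architectures are reported through the first accepted
  candidate only.
* The C-terminal control and the rescue share one neighbor search; a
  pathological panel (no MHD signal) disables both identically.
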