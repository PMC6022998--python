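# Methods

This note records the model implemented by `ltrcraft`, the default
parameters and why they were chosen, and the limitations of the
implementation. No empirical claim here goes beyond what the test
suite (`tests/`) and `scripts/acceptance.py` compute.

## 1. Input model

The primary input is a *predictor report*: per element, the full
nucleotide sequence, the 5′- and 3′-LTR sequences (which must be exact
prefix and suffix of the full sequence), the element length, and the
predictor's LTR identity. Reports are validated strictly
(`seqio.PredictorRecord.validate`): length mismatches, non-terminal
LTRs and identities outside [0, 100] are rejected with named errors.

A FASTA-only mode is also supported; there the LTR pair is located
de novo (§5).

Nucleotide input is uppercased and any non-ACGTN symbol (including
IUPAC ambiguity codes) is mapped to N; a strict mode rejects such
symbols instead.

## 2. Pairwise alignment

Global (Needleman–Wunsch) and local (Smith–Waterman) alignments with
affine gaps are computed by `Bio.Align.PairwiseAligner` (an exact
Gotoh implementation in C), wrapped so the rest of the package sees
one result type.

* Nucleotide scoring: match +5, mismatch −4, gap open 10, gap extend
  0.5 (a gap of length L costs 10 + (L−1)·0.5). N scores as a
  mismatch against everything, including N.
* Protein scoring: BLOSUM62, same gap model; X is neutral.
* Significance of local hits: ungapped Karlin–Altschul statistics
  (λ = 0.3176, K = 0.134 for the +5/−4 scheme), E = K·m·n·e^(−λS),
  with a **raw-score floor** (default 100) applied as well. The floor
  exists because ungapped constants under-penalise gapped random
  alignments: random-sequence local scores under this scheme were
  observed around 40–75, while genuine domain hits score ≥ 700, so
  100 separates the two regimes by a wide margin on both sides.
* Multiple local hits are produced by query masking: after each hit
  the matched query span is masked (N/X) and the search repeated.

The alignment kernels are verified against a brute-force enumeration
oracle (no dynamic programming; every alignment path is enumerated)
on random nucleotide and protein pairs in `tests/test_acceptance.py`.

## 3. Domain scanning and classification

Each element is translated in all six frames and scanned against a
protein reference library whose headers encode
`DOMAIN_CODE_LINEAGE_FAMILY` (e.g. `RT_RLG_Del_Peabody`). A hit must
pass the E-value cutoff (default 1e-4) and the raw-score floor. Per
domain kind the best hit is kept (score, then E-value, then position,
then reference id — fully deterministic). Amino-acid hit coordinates
are mapped back to forward-strand nucleotide spans, including for
negative frames.

Classification rules, applied in order:

1. **Chimera first**: if the enzymatic domains (RT, INT, RNASEH) carry
   both RLC and RLG labels, the element is NO_CLASS regardless of
   anything else.
2. Enzymatic domains all RLG → **GYPSY**; all RLC → **COPIA**. The
   lineage is the RT hit's lineage; without an RT hit, the majority
   lineage of INT/RNASEH, ties broken by score.
3. No domains at all → **TRIM** if shorter than 2000 bp, else
   **LARD** (the 2000-bp cutoff is configurable;
   exactly 2000 bp is LARD).
4. GAG only, or GAG + AP → **TR_GAG**.
5. Anything else (e.g. AP or ENV without enzymatic domains) →
   **NO_CLASS**.

GAG/AP/ENV labels never influence the superfamily call; only
enzymatic domains vote.

**80/80/80 rescue.** Each remaining NO_CLASS element is locally
aligned against every classified element. The best donor (score, then
donor id) is accepted when identity ≥ 80 %, query coverage ≥ 80 % and
aligned bases ≥ 80; the element then inherits the donor's category
and lineage, with the donor recorded as evidence. All three
thresholds are inclusive at exactly 80 and the procedure is
idempotent and donor-order independent. The boundary behaviour
(79.9 vs 80.0 % identity, 79 vs 80 % coverage, 79 vs 80 bases) is
pinned by constructed cases in the acceptance tests.

The full decision table — every subset of the six domains × every
RLC/RLG labeling of the enzymatic domains × both sides of the
TRIM/LARD boundary — is checked exhaustively against an independently
written truth table.

## 4. Insertion dating

The 5′ and 3′ LTRs are aligned globally; over gap-free, N-free
columns the transition proportion P and transversion proportion Q
give the Kimura 2-parameter distance

    K = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)

and the insertion age **T = K / (2r)**. The factor 2 reflects that
both LTR copies accumulate substitutions independently after
insertion.

* r defaults to 1.3 × 10⁻⁸ substitutions per site per year, a widely
  used average plant rate; it is configurable
  (`substitution_rate`) because the appropriate rate is
  taxon-specific. At the default rate, K = 0.026 dates to exactly
  1.0 million years.
* When the logarithm arguments are non-positive the divergence is
  **saturated**: the element is flagged and excluded from the age
  histogram (a separate `bin_index = -1` row), never clamped into the
  oldest bin.
* Ages are binned per lineage (per category for non-autonomous
  elements) in 0.5-million-year bins.

Recovery was validated on simulated cohorts: 50 elements simulated at
1.25 and at 1.75 million years (1-kb LTRs, r = 1.3 × 10⁻⁸, κ = 2)
date back to within 10 % of truth in the mean, with the modal bins at
[1.0, 1.5) and [1.5, 2.0) respectively.

## 5. De-novo LTR location (FASTA mode)

When input lacks predictor coordinates, the terminal direct repeat is
located by an anchored seed-and-vote search: exact 12-mers shared
between the two terminal windows vote for dot-plot diagonals; because
a terminal repeat of length L places `prefix[i]` against
`suffix[w−L+i]`, each diagonal corresponds to one candidate L. The
top candidates are verified by global alignment of the terminal
slices (≥ 70 % identity, 100–5000 bp). Anchoring at the termini makes
this robust to repetitive internal sequence, which distracts an
unanchored local-alignment search.

## 6. RT phylogeny

RT hit spans are translated in their hit frame (reverse-complemented
for negative frames), trailing stop codons stripped and translations
truncated at the first internal stop. The length filter is **strict**:
more than 200 aa in element mode, more than 150 aa in genome mode;
exactly-threshold translations are rejected and reported with
reasons.

Accepted RTs are labeled `elementID#category#lineage`, aligned with
MAFFT (`--retree 2`, progressive), and pairwise p-distances over
mutually ungapped columns feed an in-package neighbor-joining
implementation (Saitou–Nei Q criterion, deterministic lowest-index
tie-breaking, trifurcating root, negative branch estimates clamped to
zero and counted). NJ is validated for exact topology and branch
lengths on random additive matrices (100 trials in the acceptance
tests) and cross-checked against scikit-bio's implementation.

## 7. Synthetic element generator

`ltrcraft.synth` is part of the package proper, not a test helper. It
simulates:

* an ancestral LTR with canonical TG…CA termini;
* an internal region containing back-translated reference domains (in
  the canonical domain order per superfamily) separated by random
  pads, or none for TRIM/LARD;
* divergence: each LTR copy independently accumulates substitutions
  with per-site probability r·T years, transitions favoured by
  κ/(κ+2) with κ = 2 — i.e. exactly the K2P generative model the
  dating step inverts.

It emulates sequence divergence of the LTR pair and domain content;
it does **not** emulate indels, nested insertions, target-site
duplications, solo-LTR formation or recombination. Back-translation
uses one fixed codon per amino acid, so simulated internal regions
are codon-biased; domain-scan validation relies on protein-level
alignment and is insensitive to this.

Reference domain lengths are drawn from 150–400 aa, so a simulated
library can legitimately contain RT references below the 200-aa
element-mode filter; the resulting rejections are correct behaviour
(see the README example).

## 8. Determinism and parallelism

The element scan parallelises over elements with a spawn-based
process pool; results are merged in input order, so outputs are
byte-identical for any worker count (verified for 1, 4 and 8
workers). Every run writes `run_manifest.json` with the configuration
snapshot, SHA-256 digests of the inputs, the outputs and a timestamp
(the only output that differs between otherwise identical runs).

## 9. Parameter defaults

| Parameter | Default | Rationale |
| --- | --- | --- |
| `evalue_cutoff` | 1e-4 | standard domain-search stringency |
| `min_raw_score` | 100 | above gapped-random noise (≈ 40–75), far below genuine hits (≥ 700) |
| `trim_lard_cutoff_bp` | 2000 | TRIM/LARD size boundary |
| `rt_min_aa_element` | 200 (strict >) | element-mode RT filter |
| `rt_min_aa_genome` | 150 (strict >) | genome-mode RT filter |
| `substitution_rate` | 1.3e-8 /site/year | average plant rate; taxon-specific, configurable |
| `bin_width_my` | 0.5 | age histogram resolution |
| 80/80/80 | 80 % / 80 % / 80 bp, inclusive | similarity-rescue rule |

## 10. Limitations

* Classification is reference-library driven; lineages absent from
  the library cannot be assigned.
* Karlin–Altschul constants are for ungapped statistics; gapped
  significance is handled by the raw-score floor rather than gapped
  λ/K estimation.
* Dating assumes a strict molecular clock and no gene conversion
  between LTRs (conversion makes elements look younger).
* The de-novo LTR locator requires exact 12-mer seeds, so extremely
  diverged LTR pairs (roughly > 25–30 % divergence) may be missed in
  FASTA mode; report mode is unaffected.
* NJ produces unrooted trees and inherits NJ's known distortions for
  strongly non-additive distances; branch lengths are clamped at
  zero when negative.
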