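# ltrcraft

Classification, insertion dating and phylogenetic placement of
full-length LTR retrotransposons.

## The problem

LTR retrotransposons (LTR-RTs) are the dominant repeat class in plant
genomes. A full-length element is a pair of long terminal repeats
(LTRs) flanking an internal region that may encode up to six protein
domains — GAG, aspartic protease (AP), reverse transcriptase (RT),
RNase H (RNASEH), integrase (INT) and, rarely, envelope (ENV). Given a
set of full-length elements (typically the output of a structural LTR
predictor), three questions follow:

1. **What is each element?** Elements with enzymatic domains (RT, INT,
   RNASEH) are *autonomous* and belong to the **Gypsy** (RLG) or
   **Copia** (RLC) superfamily, subdivided into lineages (Del, Reina,
   CRM, Galadriel, TAT, Athila for Gypsy; Tork, Retrofit, Oryco, SIRE,
   Bianca for Copia). Elements without enzymatic domains are
   *non-autonomous*: **TRIM** (terminal-repeat retrotransposon in
   miniature, < 2000 bp), **LARD** (large retrotransposon derivative,
   ≥ 2000 bp) or **TR_GAG** (GAG, optionally with AP, but no pol
   domains). Elements with mixed Gypsy/Copia domain evidence are
   chimeric and stay **NO_CLASS**; remaining NO_CLASS elements get a
   second chance via the **80/80/80 rule** — rescue by ≥ 80 % identity
   over ≥ 80 % of the element and ≥ 80 aligned bases against an
   already-classified element.
2. **When did each element insert?** At insertion the two LTRs are
   identical copies; their divergence clocks the insertion age. With
   the Kimura 2-parameter distance K between the aligned LTRs and a
   per-site, per-year substitution rate r (default 1.3 × 10⁻⁸),
   the age is **T = K / (2r)**. Ages are binned in 0.5-million-year
   intervals per lineage.
3. **How are the elements related?** RT domains longer than 200 aa
   (element mode; 150 aa in genome mode) are extracted, translated,
   aligned, and placed on a neighbor-joining tree with leaves labeled
   `elementID#category#lineage`.

`ltrcraft` implements this pipeline end to end, including a
first-class **synthetic element generator** that produces elements of
every category at known ages with ground truth, used throughout the
test suite.

## Worked example

Simulate a 12-element dataset with ground truth, then run the whole
pipeline on it:

```sh
ltrcraft simulate --n 12 --seed 7 --outdir data
printf 'input_mode=report
input_path=data/predictor_report.txt
library_path=data/reference_domains.faa
result_dir=out
' > demo.cfg
ltrcraft all --config demo.cfg
```

`out/classification.tsv` (first four columns):

```text
element_id	category	lineage	rules
synth_0000	COPIA	Tork	autonomous-single-superfamily
synth_0001	COPIA	SIRE	autonomous-single-superfamily
synth_0002	COPIA	Tork	autonomous-single-superfamily
synth_0003	GYPSY	CRM	autonomous-single-superfamily
synth_0004	GYPSY	Del	autonomous-single-superfamily
synth_0005	GYPSY	CRM	autonomous-single-superfamily
synth_0006	LARD	NONE	no-domains-long
synth_0007	LARD	NONE	no-domains-long
synth_0008	TRIM	NONE	no-domains-short
synth_0009	TRIM	NONE	no-domains-short
synth_0010	TR_GAG	NONE	gag-only
synth_0011	TR_GAG	NONE	gag-only
```

All 12 elements match their simulated ground truth
(`data/truth.tsv`). Ages land in half-million-year bins per lineage
(`out/age_histogram.tsv`):

```text
group	bin_index	bin_start_my	bin_end_my	count	percent
CRM	0	0.0000	0.5000	1	50.0000
CRM	1	0.5000	1.0000	1	50.0000
Del	6	3.0000	3.5000	1	100.0000
LARD	0	0.0000	0.5000	1	50.0000
...
```

The RT length filter is strict; in this particular simulated library
the Gypsy RT references are 188–191 aa, so those translations are
rejected and reported (`out/rt_rejected.tsv`):

```text
element_id	length_aa	reason
synth_0003	191	translated RT of 191 aa not larger than 200 aa (element mode)
```

The three surviving Copia RTs are aligned and placed on a
neighbor-joining tree (`out/rt_tree.nwk`):

```text
(synth_0000#COPIA#Tork:0.000000,synth_0001#COPIA#SIRE:0.691011,synth_0002#COPIA#Tork:0.000000);
```

Each step is also available individually (`preprocess`, `classify`,
`extract-rt`, `date`, `tree`); outputs compose identically to a single
`all` run, and multi-worker runs (`--workers N`) are byte-identical to
single-worker runs.

## Package layout

| Module | Contents |
| --- | --- |
| `ltrcraft.seqio` | FASTA and predictor-report I/O, configuration, tabular/newick writers |
| `ltrcraft.align` | Global/local pairwise alignment, six-frame translation, E-values |
| `ltrcraft.domains` | Reference protein library, six-frame domain scanning |
| `ltrcraft.classify` | Superfamily/lineage decision rules, 80/80/80 rescue |
| `ltrcraft.dating` | K2P distance, insertion dating, LTR location, age binning |
| `ltrcraft.phylo` | RT extraction, multiple alignment, neighbor joining |
| `ltrcraft.synth` | Synthetic element generator with ground truth |
| `ltrcraft.cli` | `ltrcraft` command-line pipeline |

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.
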