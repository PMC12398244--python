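# crt1kit

Analysis toolkit for the creatine transporter **CRT1** (gene *SLC6A8*): a
635-residue, 12-transmembrane (LeuT-fold) protein whose loss-of-function
variants cause X-linked creatine transporter deficiency. The package is for
researchers who want to reproduce — or rerun on new inputs — three linked
analyses:

1. **Cross-species conservation.** Optimal Needleman–Wunsch global alignment
   with affine gaps (BLOSUM62, open −10, extend −0.5) of each ortholog
   against a reference, reporting percent identity
   (`100 · n_identical / n_columns`), percent similarity (columns with a
   positive substitution score), a per-residue difference list with
   conservative/non-conservative calls, and a neighbor-joining tree on
   p-distances `d = 1 − identity/100` (Newick output).
2. **Topology-aware variant interpretation.** HGVS p.-notation parsing
   (missense, nonsense, deletion, duplication, frameshift), mapping onto a
   region tiling (N-terminus, TM1–TM12 with alternating extracellular and
   intracellular loops, C-terminus; truncating variants lose everything
   downstream), benign/pathogenic tallies per region class, sliding-window
   missense hotspot detection, and binning of per-residue missense-tolerance
   scores (<0.5 highly intolerant; 0.5–0.7 moderately intolerant; 0.7–1.0
   intermediate; >1.0 tolerant).
3. **Uptake statistics.** Per-genotype creatine-uptake replicates normalized
   to percent of wild type, Welch's heteroscedastic one-way ANOVA

   F = [Σᵢ wᵢ(x̄ᵢ − x̄w)² / (k−1)] / [1 + 2(k−2)/(k²−1) · Σᵢ (1−wᵢ/W)²/(nᵢ−1)],
   wᵢ = nᵢ/sᵢ², with Welch–Satterthwaite denominator degrees of freedom,

   per-variant Welch t tests against WT, and severity calls (severe at ≥88%
   reduction with significance, moderate if significant below that,
   unimpaired otherwise).

Seeded synthetic-data generators produce ortholog panels, variant catalogs
and uptake tables with the statistical structure these analyses assume, so
the whole pipeline runs and is validated without any downloads.

## Worked example

Generate a synthetic ortholog panel and score conservation:

```sh
crt1kit simulate panel --seed 42 --out sim
crt1kit conserve sim/panel.fasta --out conserve_out
head -8 conserve_out/identity_similarity.tsv
```

```
# crt1kit_version: 0.1.0
# input: sim/panel.fasta
# reference: reference
species	identity_pct	similarity_pct	n_columns	n_identical
species_01	99.37	99.69	635	631
species_02	99.37	99.53	635	631
species_03	99.84	100.0	635	634
```

Each row is one species aligned to the reference: `species_01` differs at 4
of 635 positions (99.37% identity), and its 99.69% similarity means most of
those changes are conservative. `conserve_out/` also contains the
per-residue `differences.tsv`, the p-distance matrix, and `tree.nwk`.

Annotate the packaged 43-variant missense catalog against the default
topology:

```sh
crt1kit variants catalog.tsv --out var_out
```

`var_out/region_tally.tsv`:

```
region_class	benign	pathogenic	unknown	pathogenic_pct	benign_pct
terminus	8	0	0	0	100
loop	9	16	0	64	36
tm	3	7	0	70	30
```

All 8 terminus variants are benign (100%), while 64% of loop and 70% of
transmembrane missense variants are pathogenic — the termini tolerate
substitution, the membrane-spanning core does not. `hotspots.tsv` flags one
enriched stretch (`280–418`, 19 of the 43 variants), the cluster spanning
TM6–TM8.

Analyze uptake replicates:

```sh
crt1kit simulate uptake --seed 42 --out usim
crt1kit uptake usim/uptake.csv --out up_out
```

`up_out/uptake_summary.tsv` (abridged):

```
genotype	n	pct_of_wt	pct_reduction	p_vs_wt	severity
SD1	6	7.78	92.22	9.75262e-06	severe
SD9	6	65.97	34.03	0.000499699	moderate
```

SD1 retains only 7.8% of wild-type uptake (92% reduction, p ≈ 1e−5:
severe), SD9 a 34% reduction (moderate). The omnibus Welch ANOVA
(F(9, 20.28) = 68.9, p ≈ 3e−13) appears in the file header.

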