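# tagkit

Design and in-silico simulation of homologous-recombination (HR)
protein-tagging constructs for the chicken DT40 B-cell line, together
with the downstream quantitative-proteomics calculations: AP-MS
(CoIP) interaction scoring, Quant-peptide absolute quantification, and
construction of a transcriptome-derived protein search database.

## Who this is for

DT40 cells recombine transfected DNA into homologous genomic loci at
exceptionally high rates, which makes them a practical vertebrate system
for tagging proteins at their endogenous loci. `tagkit` is for groups
running such multi-gene tagging projects: it turns a genomic locus (plus
the position of the ORF's stop codon) into a complete, simulated and
verified targeting design, and then handles the numbers that come back
from the mass spectrometer.

## What it computes

**Construct design** (`tagkit.construct_design`, `tagkit design`).
Given a locus and a circular tagging vector whose layout is
`HindIII site — tag CDS (Quant remnant + TEV site + reporter + stop) —
loxP — β-actin 3'UTR — SV40 promoter + selection marker — backbone —
loxP — XhoI site`, the designer:

1. extracts 2.2–2.5 kb homology arms, the left arm ending right before
   the stop codon and the right arm starting with it;
2. designs the outer PCR primers (NotI sites on 4-base-spacer overhangs),
   simulates the arm PCR, the NotI digest and the self-circularization;
3. designs the inner primers that re-amplify from the circle — inverting
   the arm order — and add 30 bp of terminal identity to the
   HindIII/XhoI-linearized vector;
4. SLIC-assembles insert and vector, confirms a unique NotI
   linearization site (~10 kb targeting DNA), and simulates the HR
   integration and the Cre/loxP excision of 3'UTR + selection cassette +
   backbone;
5. predicts the post-Cre tagged locus and the fusion protein, and
   designs PCR primer pairs (genomic primer outside each arm × primer
   inside the integrated vector) that amplify only the targeted allele —
   one pair spanning the entire selection-marker CDS.

The simulation layer (`tagkit.cloning_sim`) is a small deterministic
molecular-biology engine: restriction digestion with cohesive-end
bookkeeping, PCR with strict primer-uniqueness, ligation, SLIC assembly
with maximal-terminal-identity detection, Cre/loxP excision and
HR integration.

**Absolute quantification** (`tagkit.absolute_quant`, `tagkit absquant`).
After TEV elution and tryptic digestion, the bait releases one
10-residue Quant peptide (LAADITSLYK) per molecule. Against a
heavy-lysine internal standard (Lys ¹³C₆,¹⁵N₂; +8.0142 Da ≈ +8 Da,
default spike 0.5 pmol):

    fmol_eluate = (V_light / V_heavy) × spike_fmol
    copies/cell = fmol × 10⁻¹⁵ × N_A / (n_cells × yield)

with a default CoIP yield of 50% and copy numbers reported to one
significant figure (raw values retained). Calibration series are checked
for linearity by OLS.

**CoIP scoring** (`tagkit.coip_scoring`, `tagkit coip-score`). From a
proteinGroups-style intensity table: abundance = mean bait-replicate
intensity / molecular mass (kDa); specificity = mean bait intensity /
mean control intensity, with the background arbitrarily set to 1 for
proteins undetected in the control.

**Search-database construction** (`tagkit.protein_db_builder`,
`tagkit dbbuild`). Six-frame ORF finding on assembled transcripts
(ATG-initiated, ≥100 aa by default), best-hit annotation from 12-column
alignment tabular output (e-value cut-off 1e-10, lowest e-value
separately per species), longest representative per transcript group,
FASTA export with the Quant peptide appended.

**Synthetic fixtures** (`tagkit.fixtures`, `tagkit fixtures`). Seeded
generators for loci, vectors, intensity tables, heavy/light
measurements and transcript sets, each with a ground-truth manifest —
every module is testable without downloads.

## Worked example

```bash
tagkit fixtures --preset all --seed 1 --out fix
tagkit design --locus fix/locus.fasta --stop-pos 3000 \
    --vector fix/vector.fasta --features fix/vector_features.json --out design
tagkit absquant --measurements fix/quant_measurements.tsv --yield 0.5 --out quant.tsv
```

prints

```
wrote fixtures (locus, vector, coip, quant, transcripts) with seed 1 -> fix
INFO tagkit: designing construct for geneA_locus (arm=2500, overlap=30, enzyme=NotI)
construct: 10010 bp -> design
quantified 2 proteins -> quant.tsv
```

The design report shows a 10,010-bp circular construct (≈10 kb targeting
DNA: two 2.5-kb arms around a ~5-kb vector), SLIC overlaps of exactly
(30, 30) bp and a 558-aa fusion protein; `primers.tsv` lists every
primer with its nearest-neighbour Tm, e.g.

```
name            sequence                                   tm_c   purpose
geneA_locus_5F  CAGTGCGGCCGCCTGTGATAGTCATGACATGTAAAAGGGGT  60.49  outer_pcr
geneA_locus_3R  CAGTGCGGCCGCTTGTGGGGAACTGATCACCTATTTACG    60.72  outer_pcr
```

`quant.tsv` contains the recovered copy numbers for the two planted
baits (true values 2000 and 6000 copies/cell, 5% volume noise):

```
protein  n_replicates  fmol_mean  fmol_sd  copies_raw  copies_reported
baitA    3             66.34      3.40     1997.6      2000.0
baitB    3             190.77     15.64    5744.2      6000.0
```

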