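# Methods

This note records the models, conventions and design choices behind
`tagkit`, in the spirit of a package methods appendix: what is being
simulated, which knobs matter, and what the synthetic fixtures do and do
not show about real data.

## The tagging system being modelled

A C-terminal tag is knocked into the endogenous locus of a gene of
interest by homologous recombination in DT40 cells. The tag consists of
an 11-residue quantification remnant (KLAADITSLYK), a TEV protease
cleavage site (ENLYFQ↓G) and a reporter (protein A, FLAG or EGFP).
Everything the selection required — β-actin 3'UTR, SV40-driven
resistance cassette, plasmid backbone — sits between two
same-orientation loxP sites and is excised by Cre after verification,
leaving the gene in its natural genomic context with only the tag
inserted before its stop codon. TEV elution leaves
…KLAADITSLYK·ENLYFQ on the bait; trypsin then releases the 10-residue
Quant peptide LAADITSLYK exactly once per bait molecule, which carries
the absolute quantification.

## Cloning simulation

* **Coordinates** are 0-based half-open internally; reports are 1-based
  inclusive. Circular molecules have an origin but all searches are
  rotation-invariant (doubled-string scan truncated to avoid double
  counting).
* **Restriction digestion.** Enzymes carry top/bottom-strand cut offsets
  within their recognition site (NotI = GC^GGCCGC with a 4-nt 5'
  extension; HindIII A^AGCTT; XhoI C^TCGAG). Fragments are sliced at
  top-strand cut positions, so each overhang sequence appears exactly
  once in exactly one fragment; fragment ends carry a `(kind, scar)`
  descriptor and ligation compatibility is exact descriptor equality.
  Consequences: digestion exactly partitions the input (linear n sites →
  n+1 fragments, circular → n), ligation is plain concatenation, and
  self-circularization preserves fragment length. Enzymes that cut
  outside their recognition site (e.g. EarI) do not fit this model and
  are not in the bundled table.
* **PCR** is perfect-match only: each anneal region must occur exactly
  once on its strand of the template (checked template-wide), products
  are `fwd_overhang + core + revcomp(rev_overhang)`, amplicons are
  capped at 12 kb by default, and primers facing away from each other on
  a linear template yield no product. This is a design-time tool, not a
  mispriming predictor.
* **SLIC assembly** detects the maximal exact terminal identity between
  each vector end and the corresponding insert end (both insert
  orientations are tried; two valid orientations are reported as
  ambiguous). Both junctions must reach `min_overlap` (default 25 bp;
  designs use 30 bp). Product length is
  `len(vector) + len(insert) − overlap5 − overlap3`. Heteroduplex and
  gap-repair chemistry is not modelled beyond exact-overlap annealing.
* **Cre/loxP.** The wild-type 34-bp loxP site is used for both vector
  positions; the source vectors distinguish an "L" and an "R" site
  without giving sequences, so wild-type excision behaviour (documented
  via marker loss) is assumed. Exactly two same-orientation sites are
  required; the intervening segment leaves as a circle carrying one
  loxP, the remaining molecule keeps the other, and total base content
  is conserved. Opposite-orientation sites (inversion substrates) are
  rejected rather than inverted.
* **HR integration** anchors a `min_arm`-long seed from each construct
  terminus uniquely and colinearly in the genome and splices the
  construct between the genomic arm copies. Because NotI linearization
  leaves a few non-genomic scar bases at the termini, the seed may start
  up to `end_trim` (default 10) bases in from each end — a stand-in for
  the exonucleolytic end resection that precedes strand invasion.
  Random (non-homologous) integration is not modelled.

## Construct design

* **Arms**: default 2500 bp, bounds 2200–2500 bp (configurable); the
  left arm ends on the ORF's final sense codon, the right arm starts
  with the stop codon.
* **Junction frame.** The fixture vector is built so that the
  HindIII-side junction contributes exactly two codons (AGC TTG,
  Ser-Leu: the 5-nt HindIII cut remnant plus a 1-nt linker) between the
  gene's last sense codon and the tag CDS, which supplies its own stop.
  Where the fusion's stop codon lies is a genuine design freedom; the
  choice here keeps the post-Cre product a clean in-frame fusion and is
  validated by translation in the tests.
* **Primers** grow their anneal region from 18 to 30 nt until the
  nearest-neighbour Tm reaches 60 ± 3 °C; among in-window candidates the
  shortest wins, ties broken by fewer 3'-terminal A/T. Outer primers put
  4 fixed spacer bases (CAGT) before the NotI site so the enzyme can cut
  near the fragment end. Tm uses the unified NN parameter set (Allawi &
  SantaLucia) via Biopython's `Tm_NN`, at 50 mM monovalent salt and
  500 nM primer with the entropy salt correction — chosen for
  reproducibility rather than instrument-grade accuracy.
* **Verification primers** pair a genomic primer outside each homology
  arm with a primer inside the integrated vector (marker CDS and SV40
  promoter respectively), so the wild-type allele never amplifies. The
  promoter-side pair's product spans the entire marker CDS, matching the
  PCR strategy used to call targeted integrants. Minus-strand loci are
  reverse-complemented at ingest; all designs are reported on the coding
  strand. Intron/exon structure is ignored — the locus is treated as
  plain genomic sequence, as the wet-lab design does.

## Peptide chemistry

* TEV recognition is ENLYFQ with cleavage before G or S (the canonical
  site; the tag uses G at P1').
* Trypsin follows the classical Keil rule — cleave after K/R, never
  before P. Zero missed cleavages for quant-peptide extraction
  (configurable elsewhere). The Quant peptide contains neither motif
  internally, so TEV→trypsin and trypsin→TEV commute for it.
* Monoisotopic masses come from a residue table summed with one water
  plus modification shifts; an independent elemental-composition oracle
  (pyteomics) cross-checks them to 1e-3 Da in the tests. The
  heavy-lysine label Lys(¹³C₆,¹⁵N₂) shifts by 8.0142 Da from standard
  isotope masses.
* The spiked standard is modelled as the 10-mer LAADITSLY[K-heavy], i.e.
  the exact tryptic product carrying the label on its lysine.

## CoIP scoring

"Signal intensity" for a run group is the arithmetic mean with
missing-as-zero — the background-floor rule (denominator 1 for proteins
undetected in the control) only makes sense if zeros are meaningful, so
mean-over-detected-only was rejected. Molecular weight is taken from the
table column (kDa). For multi-control designs the control intensities
are averaged before ratioing. The scores are descriptive, exactly as
defined for the abundance-vs-specificity scatter; no FDR or
enrichment-model layer is added, and thresholding is left to the user.

## Absolute quantification

Copy numbers are reported to one significant figure because that is the
precision at which such measurements are meaningful (raw values are
always emitted alongside); rounding is half-up by default and
configurable. Replicates are summarised as mean ± sample SD of the
per-replicate fmol values. Peak "volume" is an abstract scalar per
peptide per run — XIC integration from raw spectra is out of scope, as
is any correction for C-terminal degradation of the bait (which
truncates the tag and silently deflates the Quant signal; manual
inspection of peptide maps remains the recommended quality control).

## Database construction

ORFs are ATG-initiated, stop-terminated stretches of ≥100 aa across six
frames (the ATG requirement and partial-ORF tolerance are configurable;
the exact scoring of the original assembler script is not public, so
this is a documented, deliberately simple definition). "Longest
representative" is measured in amino acids of the chosen ORF, not
transcript nucleotides, because the final artifact is a protein
database. Grouping keys come from a configurable transcript-id regex
(default strips an `_i<N>` isoform suffix); species assignment of hits
comes from a subject-id prefix map. Unannotated proteins are kept in the
final set and counted separately. Default extra entries include the
Quant peptide; the TEV protease entry shipped by the fixtures is a
clearly-labelled synthetic stand-in (pass the real sequence via
`extras` for production use).

## Synthetic fixtures

All generators are pure functions of `FixtureConfig` (seed included);
each generator kind draws from a domain-tagged RNG stream so that, e.g.,
a vector never replicates locus subsequences when built from the same
seed. Defaults mirror the study conditions the pipeline targets: 6-kb
loci with a 900-nt ORF stopping at the midpoint, 2.5-kb arms with an
enzyme/loxP-free arm window (rejection-sampled), ~5-kb vectors, two bait
replicates + one control with 10% CV log-normal intensity noise and
planted enrichments of 30–80×, 500-fmol spikes with 5% volume noise at
2000–6000 planted copies per 4×10⁷ cells with 50% yield, and 12
transcript groups of 1–3 isoforms.

What the fixtures do **not** emulate: real spectra or chromatograms,
peptide-level missingness structure, intron-containing loci, repetitive
genomes (primer uniqueness is nearly guaranteed in random sequence),
biological replicate variance (quantification noise is modelled as
technical), or genome-scale transcriptomes. Passing tests therefore
demonstrate the correctness of the arithmetic, the sequence logic and
the recovery of planted ground truth under idealised noise — not
performance on real LC-MS or sequencing data, whose database-scale
results (tens of thousands of ORFs from ~22 Gb of reads) are far beyond
desk scale.

## Problem sizes and numerical choices

The test suite designs constructs for 100 seeded loci (~30 ms each),
checks the ORF finder against a brute-force six-frame oracle on 200
random transcripts, and recovers quantification round trips over 20
replicates × 10 seeds. OLS linearity uses `scipy.stats.linregress` with
an r² ≥ 0.99 default threshold. Deterministic tie-breaks everywhere:
annotation by (e-value, −bit score, subject id); representatives by
(−length, id); primer picking as above. Degenerate inputs raise typed
errors (`tagkit.errors`) rather than returning partial results.

## Known limitations

Single-locus scope (no off-target scans beyond the supplied sequence);
no N-terminal tagging; no loxP inversion; no thermodynamic mispriming
model; no modelling of the multi-round transfections needed for
trisomic chromosomes. These were deliberately excluded to keep the
engine deterministic and auditable.
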