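"""End-to-end design of C-terminal tagging constructs.

Reproduces the two-PCR SLIC workflow for DT40 gene targeting:

1. extract 2.2-2.5 kb homology arms around the ORF stop codon (the left
   arm ends right before the termination codon, the right arm starts
   with it);
2. amplify both arms in one PCR whose primers add NotI sites on their
   overhangs; digest with NotI and self-circularize;
3. re-amplify from the circle with inner primers annealing at the
   insertion site — this inverts the arm order and adds 30-bp SLIC
   homology to the HindIII/XhoI-linearized tagging vector;
4. SLIC-assemble, confirm a unique linearization site, linearize, and
   simulate the homologous-recombination integration plus the subsequent
   Cre/loxP excision of the selection cassette;
5. predict the post-Cre tagged locus and the fusion protein, and design
   PCR primers that verify targeted integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as mt

from . import cloning_sim as cs
from .cloning_sim import (
    ENZYMES,
    NucleotideSequence,
    Primer,
    RestrictionEnzyme,
    STOP_CODONS,
    find_sites,
    reverse_complement,
)
from .errors import DesignError, NonSpecificPrimingError, NoProductError, SequenceError


@dataclass
class LocusModel:
    """A genomic locus with a known ORF termination codon.

    ``stop_start`` is the 0-based position of the first base of the stop
    codon on the coding strand. Minus-strand loci are normalised to the
    coding strand at construction time.
    """

    sequence: NucleotideSequence
    stop_start: int
    strand: str = "+"
    gene_id: str = "gene"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise SequenceError("strand must be '+' or '-'")
        if self.strand == "-":
            n = len(self.sequence)
            self.sequence = self.sequence.reverse_complement()
            self.stop_start = n - (self.stop_start + 3)
            self.strand = "+"
        codon = self.sequence.seq[self.stop_start : self.stop_start + 3]
        if codon not in STOP_CODONS:
            raise SequenceError(
                f"{self.gene_id}: no stop codon at position {self.stop_start} (found {codon!r})"
            )

    @property
    def seq(self) -> str:
        return self.sequence.seq


@dataclass
class VectorTemplate:
    """A circular pQuant-style tagging vector with an ordered feature map.

    Expected circular feature order: HindIII cloning site, tag CDS
    (Quant remnant + TEV site + reporter + stop), loxP L, beta-actin
    3'UTR, selection cassette (SV40 promoter + marker CDS), backbone,
    loxP R, XhoI cloning site.
    """

    sequence: NucleotideSequence
    features: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence.is_circular:
            raise SequenceError("vector template must be circular")
        prev_end = None
        for label, start, end in self.features:
            if not 0 <= start < end <= len(self.sequence):
                raise SequenceError(f"feature {label}: bad interval [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise SequenceError(f"feature {label} overlaps its predecessor")
            prev_end = end
        tag = self.feature_seq("tag_cds", required=False)
        if tag is not None:
            if len(tag) % 3 != 0 or tag[-3:] not in STOP_CODONS:
                raise SequenceError("tag CDS must be in frame and end with a stop codon")

    def feature_seq(self, label: str, required: bool = True) -> str | None:
        for lab, start, end in self.features:
            if lab == label:
                return self.sequence.seq[start:end]
        if required:
            raise DesignError(f"vector has no feature {label!r}")
        return None

    def linearize(self, enzymes: tuple[str, str] = ("HindIII", "XhoI")) -> NucleotideSequence:
        """Double digest at the cloning sites; the large fragment is the
        SLIC-ready linear vector (small stuffer discarded)."""
        frags = cs.digest(self.sequence, ENZYMES[enzymes[0]])
        if len(frags) != 1:
            raise DesignError(f"{enzymes[0]} must cut the vector exactly once")
        linear = NucleotideSequence(self.sequence.id + "_lin0", frags[0].seq, "linear")
        frags2 = cs.digest(linear, ENZYMES[enzymes[1]])
        if len(frags2) != 2:
            raise DesignError(f"{enzymes[1]} must cut the vector exactly once")
        big = max(frags2, key=len)
        return NucleotideSequence(self.sequence.id + "_linear", big.seq, "linear")


@dataclass
class DesignConfig:
    arm_len: int = 2500
    arm_bounds: tuple[int, int] = (2200, 2500)
    overlap: int = 30
    min_overlap: int = 25
    circ_enzyme: str = "NotI"
    spacer: str = "CAGT"  # fixed bases 5' of the restriction site
    target_tm: float = 60.0
    tm_tolerance: float = 3.0
    anneal_min: int = 18
    anneal_max: int = 30
    max_amplicon: int = 12_000
    end_trim: int = 10
    na_mm: float = 50.0
    primer_nm: float = 500.0
    enforce_arm_bounds: bool = True


@dataclass
class TargetingDesign:
    """Complete output of the design pipeline for one locus."""

    gene_id: str
    left_arm: str
    right_arm: str
    outer_primers: tuple[Primer, Primer]  # 5F, 3R
    inner_primers: tuple[Primer, Primer]  # 3F, 5R
    insert: NucleotideSequence
    construct: NucleotideSequence
    linearized: NucleotideSequence
    verification_primers: list[tuple[Primer, Primer]]
    tagged_locus_pre_cre: NucleotideSequence
    tagged_locus_post_cre: NucleotideSequence
    fusion_protein: str
    slic_overlaps: tuple[int, int]
    locus: "LocusModel | None" = None
    vector: "VectorTemplate | None" = None

    def report(self) -> dict:
        """Human-facing summary; coordinates 1-based inclusive."""
        return {
            "gene_id": self.gene_id,
            "arm_length_left": len(self.left_arm),
            "arm_length_right": len(self.right_arm),
            "construct_size_bp": len(self.construct),
            "targeting_dna_size_bp": len(self.linearized),
            "slic_overlaps_bp": list(self.slic_overlaps),
            "fusion_protein_length_aa": len(self.fusion_protein),
            "n_verification_pairs": len(self.verification_primers),
            "primers": [
                {"name": p.name, "sequence": p.full, "tm_c": round(compute_tm(p), 2)}
                for pair in (self.outer_primers, self.inner_primers, *self.verification_primers)
                for p in pair
            ],
        }


def compute_tm(
    primer: Primer | str, na_mm: float = 50.0, primer_nm: float = 500.0
) -> float:
    """Nearest-neighbour melting temperature (degrees C) of the anneal
    region, unified NN parameter set, entropy-based salt correction,
    excess-primer approximation."""
    anneal = primer.anneal if isinstance(primer, Primer) else primer
    if len(anneal) < 15:
        raise SequenceError("anneal region must be >= 15 nt for Tm computation")
    return float(
        mt.Tm_NN(
            Seq(anneal),
            nn_table=mt.DNA_NN3,
            Na=na_mm,
            dnac1=primer_nm,
            dnac2=0,
            saltcorr=5,
        )
    )


def extract_arms(locus: LocusModel, arm_len: int) -> tuple[str, str]:
    """Left arm ends immediately before the stop codon; right arm starts
    with it."""
    if arm_len <= 0:
        raise DesignError("arm length must be positive")
    s = locus.stop_start
    max_left = s
    max_right = len(locus.sequence) - s
    if arm_len > max_left or arm_len > max_right:
        raise DesignError(
            f"insufficient flanking sequence for {arm_len}-bp arms; "
            f"maximum feasible arm length is {min(max_left, max_right)} bp"
        )
    return locus.seq[s - arm_len : s], locus.seq[s : s + arm_len]


def _pick_anneal(
    template: str,
    anchor: int,
    direction: str,
    cfg: DesignConfig,
) -> str:
    """Grow a primer anneal region from a fixed anchor until the NN Tm
    reaches target +/- tolerance; among in-window candidates the shortest
    wins, otherwise closest Tm, then shorter, then fewer terminal A/T."""
    candidates = []
    for length in range(cfg.anneal_min, cfg.anneal_max + 1):
        if direction == "fwd":
            sub = template[anchor : anchor + length]
        else:
            sub = reverse_complement(template[anchor - length : anchor])
        if len(sub) < length:
            break
        tm = compute_tm(sub, cfg.na_mm, cfg.primer_nm)
        candidates.append((sub, length, tm))
    if not candidates:
        raise DesignError("template region too short for a primer")
    in_window = [c for c in candidates if abs(c[2] - cfg.target_tm) <= cfg.tm_tolerance]
    pool = in_window or candidates
    pool.sort(
        key=lambda c: (
            0 if in_window else round(abs(c[2] - cfg.target_tm), 6),
            c[1],
            1 if c[0][-1] in "AT" else 0,
        )
    )
    return pool[0][0]


def design_outer_primers(
    locus: LocusModel,
    arm_len: int,
    circ_enzyme: str = "NotI",
    cfg: DesignConfig | None = None,
) -> tuple[Primer, Primer]:
    """First-PCR primers: amplify left+right arm as one fragment, adding
    the circularization enzyme's site on 4-base-spacer overhangs."""
    cfg = cfg or DesignConfig()
    enzyme = ENZYMES[circ_enzyme]
    s = locus.stop_start
    region = NucleotideSequence("arms", locus.seq[s - arm_len : s + arm_len], "linear")
    if find_sites(region, enzyme):
        alternates = [
            name
            for name, enz in ENZYMES.items()
            if name != circ_enzyme and not find_sites(region, enz)
        ]
        raise DesignError(
            f"{circ_enzyme} cuts inside the amplified region; "
            f"site-free alternates from the enzyme table: {', '.join(alternates) or 'none'}"
        )
    overhang = cfg.spacer + enzyme.recognition
    fwd = Primer(
        f"{locus.gene_id}_5F",
        anneal=_pick_anneal(locus.seq, s - arm_len, "fwd", cfg),
        overhang=overhang,
    )
    rev = Primer(
        f"{locus.gene_id}_3R",
        anneal=_pick_anneal(locus.seq, s + arm_len, "rev", cfg),
        overhang=overhang,
    )
    return fwd, rev


def design_inner_primers(
    locus: LocusModel,
    vector: VectorTemplate,
    overlap: int = 30,
    cfg: DesignConfig | None = None,
) -> tuple[Primer, Primer]:
    """Second-PCR primers: anneal at the insertion site on the
    circularized arm template (inverting the arms) and add ``overlap``
    bases of terminal identity to the HindIII/XhoI-linearized vector."""
    cfg = cfg or DesignConfig()
    vlin = vector.linearize()
    enzyme = ENZYMES[cfg.circ_enzyme]
    for terminus in (vlin.seq[:overlap], vlin.seq[-overlap:]):
        if find_sites(NucleotideSequence("ovl", terminus, "linear"), enzyme):
            raise DesignError(
                f"SLIC overlap region contains a {cfg.circ_enzyme} site; "
                "choose another circularization enzyme"
            )
    s = locus.stop_start
    fwd = Primer(
        f"{locus.gene_id}_3F",
        anneal=_pick_anneal(locus.seq, s, "fwd", cfg),
        overhang=vlin.seq[-overlap:],
    )
    rev = Primer(
        f"{locus.gene_id}_5R",
        anneal=_pick_anneal(locus.seq, s, "rev", cfg),
        overhang=reverse_complement(vlin.seq[:overlap]),
    )
    return fwd, rev


def _find_cds_start(locus: LocusModel) -> int:
    """Position of the translation start for the ORF ending at the stop:
    the first in-frame ATG after the nearest upstream in-frame stop."""
    seq = locus.seq
    s = locus.stop_start
    p = s - 3
    boundary = s % 3  # frame-preserving leftmost position
    while p >= 0:
        if seq[p : p + 3] in STOP_CODONS:
            boundary = p + 3
            break
        p -= 3
    for q in range(boundary, s, 3):
        if seq[q : q + 3] == "ATG":
            return q
    raise DesignError("no in-frame ATG found upstream of the stop codon")


def design_construct(
    locus: LocusModel,
    vector: VectorTemplate,
    cfg: DesignConfig | None = None,
) -> TargetingDesign:
    """Run the full design chain and simulate every cloning stage."""
    cfg = cfg or DesignConfig()
    if cfg.enforce_arm_bounds and not (
        cfg.arm_bounds[0] <= cfg.arm_len <= cfg.arm_bounds[1]
    ):
        raise DesignError(
            f"arm length {cfg.arm_len} outside configured bounds {cfg.arm_bounds}"
        )
    enzyme = ENZYMES[cfg.circ_enzyme]

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            if isinstance(exc, DesignError) and str(exc).startswith("["):
                raise
            raise DesignError(f"[{name}] {exc}") from exc

    left_arm, right_arm = stage("extract_arms", extract_arms, locus, cfg.arm_len)
    outer = stage(
        "design_outer_primers", design_outer_primers, locus, cfg.arm_len, cfg.circ_enzyme, cfg
    )
    pcr1 = stage(
        "pcr_arms", cs.simulate_pcr, locus.sequence, outer[0], outer[1], cfg.max_amplicon
    )
    frags = stage("notI_digest", cs.digest, pcr1, enzyme)
    cohesive = [f for f in frags if f.end5.kind != "blunt" and f.end3.kind != "blunt"]
    if len(cohesive) != 1:
        raise DesignError("[notI_digest] expected exactly one doubly-cohesive arm fragment")
    circle = stage(
        "self_circularize", cs.self_circularize, cohesive[0], f"{locus.gene_id}_armcircle"
    )
    inner = stage("design_inner_primers", design_inner_primers, locus, vector, cfg.overlap, cfg)
    insert = stage(
        "pcr_inversion", cs.simulate_pcr, circle, inner[0], inner[1], cfg.max_amplicon
    )
    vlin = stage("vector_linearization", vector.linearize)
    assembly = stage("slic_assemble", cs.slic_assemble, vlin, insert, cfg.min_overlap)
    construct = NucleotideSequence(
        f"{locus.gene_id}_targeting_construct", assembly.product.seq, "circular"
    )
    sites = find_sites(construct, enzyme)
    if len(sites) != 1:
        raise DesignError(
            f"[linearization_check] construct has {len(sites)} {cfg.circ_enzyme} sites, need 1"
        )
    lin_frags = stage("linearize", cs.digest, construct, enzyme)
    linearized = NucleotideSequence(
        f"{locus.gene_id}_targeting_dna", lin_frags[0].seq, "linear"
    )
    pre_cre = stage(
        "hr_integration",
        cs.simulate_hr_integration,
        locus.sequence,
        linearized,
        cfg.arm_len,
        cfg.end_trim,
    )
    post_cre, _excised = stage("cre_excision", cs.cre_excise, pre_cre)

    cds_start = stage("fusion_prediction", _find_cds_start, locus)
    readable = post_cre.seq[cds_start:]
    readable = readable[: len(readable) - len(readable) % 3]
    fusion = str(Seq(readable).translate(to_stop=True))
    if "*" in fusion or not fusion:
        raise DesignError("[fusion_prediction] fusion protein translation failed")

    design = TargetingDesign(
        gene_id=locus.gene_id,
        left_arm=left_arm,
        right_arm=right_arm,
        outer_primers=outer,
        inner_primers=inner,
        insert=insert,
        construct=construct,
        linearized=linearized,
        verification_primers=[],
        tagged_locus_pre_cre=pre_cre,
        tagged_locus_post_cre=NucleotideSequence(
            f"{locus.gene_id}_tagged_postcre", post_cre.seq, "linear"
        ),
        fusion_protein=fusion,
        slic_overlaps=(assembly.overlap5, assembly.overlap3),
        locus=locus,
        vector=vector,
    )
    design.verification_primers = stage(
        "verification_primers", design_verification_primers, design, locus.sequence
    )
    return design


def design_verification_primers(
    design: TargetingDesign, genome: NucleotideSequence
) -> list[tuple[Primer, Primer]]:
    """PCR pairs that prove targeted integration: each pair combines a
    genomic primer outside a homology arm with a primer inside the
    integrated vector, so the wild-type locus yields no product. The
    second pair's forward primer sits at the start of the selection
    cassette (SV40 promoter), so its product spans the entire marker CDS.
    """
    if design.locus is None or design.vector is None:
        raise DesignError("design lacks locus/vector context")
    locus, vector, cfg = design.locus, design.vector, DesignConfig()
    s = locus.stop_start
    arm = len(design.left_arm)
    if s - arm < cfg.anneal_max + 60 or len(genome) - (s + arm) < cfg.anneal_max + 60:
        raise DesignError("no genomic sequence outside the homology arms for verification primers")

    marker = vector.feature_seq("marker_cds")
    sv40 = vector.feature_seq("sv40_promoter")
    gen_fwd = Primer(
        f"{design.gene_id}_vfy_genL_F",
        anneal=_pick_anneal(genome.seq, s - arm - 80, "fwd", cfg),
    )
    marker_rev = Primer(
        f"{design.gene_id}_vfy_marker_R",
        anneal=reverse_complement(marker[40 : 40 + 22]),
    )
    sv40_fwd = Primer(f"{design.gene_id}_vfy_sv40_F", anneal=sv40[5 : 5 + 22])
    gen_rev = Primer(
        f"{design.gene_id}_vfy_genR_R",
        anneal=_pick_anneal(genome.seq, s + arm + 80, "rev", cfg),
    )
    pairs = [(gen_fwd, marker_rev), (sv40_fwd, gen_rev)]

    for fwd, rev in pairs:
        product = cs.simulate_pcr(design.tagged_locus_pre_cre, fwd, rev, max_length=30_000)
        if len(product) == 0:
            raise DesignError("verification pair yields no product on the targeted allele")
        try:
            cs.simulate_pcr(genome, fwd, rev, max_length=30_000)
        except (NonSpecificPrimingError, NoProductError):
            continue
        raise DesignError("verification pair amplifies the wild-type locus")
    span_product = cs.simulate_pcr(
        design.tagged_locus_pre_cre, pairs[1][0], pairs[1][1], max_length=30_000
    )
    if marker not in span_product.seq:
        raise DesignError("cassette-spanning product does not contain the full marker CDS")
    return pairs
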