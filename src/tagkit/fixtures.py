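"""Deterministic, seeded generators for every input the pipeline
consumes: genomic loci, tagging vectors, proteinGroups-style intensity
tables, heavy/light quantification measurements, and assembled
transcripts with alignment hits.

Everything here is synthetic. Placeholder CDSs (reporter, selection
marker) are random codon sequences rather than real EGFP/marker genes:
the pipeline's contracts depend on the vector *layout*, not on the
identity of those sequences, and real sequences can be dropped in via
configuration. All generators are pure functions of a
:class:`FixtureConfig` (seed included), so regenerated fixtures are
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .cloning_sim import ENZYMES, WT_LOXP, NucleotideSequence, reverse_complement
from .construct_design import LocusModel, VectorTemplate
from .coip_scoring import ProteinGroupTable
from .errors import TagkitError
from .peptide_tools import RESIDUE_MONO, TagArchitecture
from .protein_db_builder import AlignmentHit, TranscriptRecord

_BASES = np.array(list("ACGT"))
_AA = sorted(set(RESIDUE_MONO) - {"M"})

_table = CodonTable.unambiguous_dna_by_id[1]
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in sorted(_table.forward_table.items()):
    _CODONS_BY_AA.setdefault(aa, []).append(codon)

#: Patterns that must stay out of homology arms and vector interiors.
FORBIDDEN_SITES = [
    ENZYMES["NotI"].recognition,
    ENZYMES["HindIII"].recognition,
    ENZYMES["XhoI"].recognition,
    WT_LOXP,
    reverse_complement(WT_LOXP),
]

DEFAULT_SPECIES_MAP = {"GG_": "chicken", "HS_": "human"}


@dataclass
class FixtureConfig:
    """All knobs for the synthetic inputs, with defaults matching the
    study conditions the pipeline was built for (2.5-kb arms, ~5-kb
    vector, 500-fmol spike, 4e7 cells, 50% CoIP yield)."""

    seed: int = 0
    # locus
    locus_len: int = 6000
    arm_len: int = 2500
    orf_len: int = 900  # nt, ATG..stop inclusive, multiple of 3
    stop_pos: int | None = None
    # vector part sizes
    reporter_aa: int = 239
    utr_len: int = 600
    sv40_len: int = 350
    marker_aa: int = 199
    backbone_len: int = 2600
    stuffer_len: int = 20
    # CoIP table
    n_background: int = 200
    planted_interactors: list[tuple[str, float, float]] = field(
        default_factory=lambda: [
            ("PLANTED_1", 50.0, 60.0),
            ("PLANTED_2", 30.0, 45.0),
            ("PLANTED_3", 80.0, 120.0),
        ]
    )
    n_bait_replicates: int = 2
    n_control_runs: int = 1
    noise_cv: float = 0.10
    # absolute quantification
    planted_copies: list[tuple[str, float, int, float]] = field(
        default_factory=lambda: [
            ("baitA", 2000.0, 40_000_000, 0.5),
            ("baitB", 6000.0, 40_000_000, 0.5),
        ]
    )
    spike_fmol: float = 500.0
    quant_noise: float = 0.05
    n_replicates: int = 3
    # transcripts
    n_groups: int = 12
    min_aa: int = 100
    # fusion fixture
    bait_aa: int = 300


def _rng(
    cfg: FixtureConfig, rng: np.random.Generator | None, domain: int = 0
) -> np.random.Generator:
    """Per-generator stream: the domain tag decorrelates the different
    fixture kinds so e.g. a vector never replicates locus subsequences
    when both are built from the same seed."""
    return rng if rng is not None else np.random.default_rng([domain, cfg.seed])


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _rand_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_AA, n))


def _encode(rng: np.random.Generator, protein: str) -> str:
    """Random codon-balanced back-translation."""
    return "".join(
        _CODONS_BY_AA[aa][rng.integers(0, len(_CODONS_BY_AA[aa]))] for aa in protein
    )


def _clean(seq: str, patterns=FORBIDDEN_SITES) -> bool:
    return not any(p in seq for p in patterns)


def _noise_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def make_locus(
    cfg: FixtureConfig, rng: np.random.Generator | None = None, gene_id: str = "geneA"
) -> LocusModel:
    """A random locus carrying one ORF whose stop codon sits at a known
    position, with the homology-arm window free of NotI/HindIII/XhoI and
    loxP sequence. An in-frame stop delimiter precedes the planted ATG so
    the ORF start is recoverable by upstream scanning."""
    rng = _rng(cfg, rng, domain=1)
    if cfg.orf_len % 3 or cfg.orf_len < 9:
        raise TagkitError("orf_len must be a multiple of 3, >= 9")
    stop_pos = cfg.stop_pos if cfg.stop_pos is not None else cfg.locus_len // 2
    cds_start = stop_pos + 3 - cfg.orf_len
    if cds_start < 3:
        raise TagkitError("locus too short for the requested ORF upstream of the stop")
    if stop_pos + 3 > cfg.locus_len:
        raise TagkitError("stop codon outside the locus")
    window_lo = max(0, stop_pos - cfg.arm_len - 60)
    window_hi = min(cfg.locus_len, stop_pos + cfg.arm_len + 60)
    for _ in range(500):
        protein = "M" + _rand_protein(rng, cfg.orf_len // 3 - 2)
        cds = _encode(rng, protein) + "TAA"
        seq = (
            _rand_dna(rng, cds_start - 3)
            + "TGA"
            + cds
            + _rand_dna(rng, cfg.locus_len - (stop_pos + 3))
        )
        if _clean(seq[window_lo:window_hi]):
            return LocusModel(
                NucleotideSequence(f"{gene_id}_locus", seq, "linear"),
                stop_start=stop_pos,
                gene_id=gene_id,
            )
    raise TagkitError("could not satisfy locus constraints in 500 attempts")


def make_vector(
    cfg: FixtureConfig,
    reporter: str = "EGFP",
    rng: np.random.Generator | None = None,
    arch: TagArchitecture | None = None,
) -> VectorTemplate:
    """A circular ~5-kb tagging vector realising the pQuant feature
    order: HindIII cloning site, tag CDS (Quant remnant + TEV site +
    reporter + stop), loxP L, beta-actin 3'UTR, SV40 promoter + marker
    CDS, backbone, loxP R, XhoI cloning site.

    The 6 nt preceding the tag CDS on the linearized vector ("AGCTT" cut
    remnant + 1-nt linker) keep the gene-to-tag junction in frame, and
    the tag CDS supplies the fusion's stop codon.
    """
    rng = _rng(cfg, rng, domain=2)
    arch = arch or TagArchitecture(reporter=reporter)
    for _ in range(500):
        reporter_seq = _rand_protein(rng, cfg.reporter_aa)
        tag_prot = arch.tag_protein(reporter_seq)
        if arch.tev_motif in reporter_seq or arch.quant_peptide in reporter_seq:
            continue
        tag_cds = _encode(rng, tag_prot) + "TAA"
        utr = _rand_dna(rng, cfg.utr_len)
        sv40 = _rand_dna(rng, cfg.sv40_len)
        marker = "ATG" + _encode(rng, _rand_protein(rng, cfg.marker_aa)) + "TAA"
        backbone = _rand_dna(rng, cfg.backbone_len)
        stuffer = _rand_dna(rng, cfg.stuffer_len)
        linker = "G"  # AGCTT + G = two in-frame junction codons (Ser-Leu)
        parts = [
            ("cloning_site_hindiii", "AAGCTT"),
            ("linker", linker),
            ("tag_cds", tag_cds),
            ("loxp_l", WT_LOXP),
            ("actin3utr", utr),
            ("sv40_promoter", sv40),
            ("marker_cds", marker),
            ("backbone", backbone),
            ("loxp_r", WT_LOXP),
            ("cloning_site_xhoi", "CTCGAG"),
            ("stuffer", stuffer),
        ]
        seq = "".join(p for _, p in parts)
        circ = NucleotideSequence(f"pquant_{arch.reporter}", seq, "circular")
        if len(find := _site_counts(circ)) and (
            find["HindIII"] == 1
            and find["XhoI"] == 1
            and find["NotI"] == 0
            and seq.count(WT_LOXP) == 2
            and reverse_complement(WT_LOXP) not in seq
        ):
            features = []
            pos = 0
            for label, part in parts:
                features.append((label, pos, pos + len(part)))
                pos += len(part)
            return VectorTemplate(circ, features)
    raise TagkitError("could not satisfy vector constraints in 500 attempts")


def _site_counts(seq: NucleotideSequence) -> dict[str, int]:
    from .cloning_sim import find_sites

    return {name: len(find_sites(seq, ENZYMES[name])) for name in ("HindIII", "XhoI", "NotI")}


def make_fusion(
    cfg: FixtureConfig,
    rng: np.random.Generator | None = None,
    arch: TagArchitecture | None = None,
) -> tuple[str, str, str]:
    """(bait, reporter, fusion) protein sequences for the tag-chemistry
    fixtures; the bait is guaranteed not to contain the Quant peptide or
    the TEV motif itself."""
    rng = _rng(cfg, rng, domain=3)
    arch = arch or TagArchitecture()
    for _ in range(100):
        bait = "M" + _rand_protein(rng, cfg.bait_aa - 1)
        reporter = _rand_protein(rng, cfg.reporter_aa)
        clean = all(
            motif not in s
            for s in (bait, reporter)
            for motif in (arch.quant_peptide, arch.tev_motif)
        )
        if clean:
            return bait, reporter, arch.build_fusion(bait, reporter)
    raise TagkitError("could not generate a clean bait/reporter pair")


def make_proteingroups(
    cfg: FixtureConfig, rng: np.random.Generator | None = None
) -> tuple[ProteinGroupTable, dict]:
    """Background proteins with log-normal intensities in bait and
    control runs; planted interactors get their bait intensities
    multiplied by the configured enrichment. Returns the table and a
    ground-truth manifest."""
    rng = _rng(cfg, rng, domain=4)
    bait_runs = [f"bait_{i + 1}" for i in range(cfg.n_bait_replicates)]
    control_runs = [f"control_{i + 1}" for i in range(cfg.n_control_runs)]
    rows = []
    for i in range(cfg.n_background):
        base = rng.lognormal(mean=np.log(1e7), sigma=1.0)
        mw = rng.uniform(10, 300)
        row = {"group_id": f"bg_{i:04d}", "protein_ids": f"BG{i:04d}", "mol_weight_kda": mw}
        noise = _noise_factors(rng, cfg.noise_cv, len(bait_runs) + len(control_runs))
        for j, run in enumerate(bait_runs + control_runs):
            row[run] = base * noise[j]
        rows.append(row)
    for name, enrichment, mw in cfg.planted_interactors:
        base = rng.lognormal(mean=np.log(1e7), sigma=0.5)
        row = {"group_id": name, "protein_ids": name, "mol_weight_kda": mw}
        noise = _noise_factors(rng, cfg.noise_cv, len(bait_runs) + len(control_runs))
        for j, run in enumerate(bait_runs):
            row[run] = base * enrichment * noise[j]
        for j, run in enumerate(control_runs, start=len(bait_runs)):
            row[run] = base * noise[j]
        rows.append(row)
    table = ProteinGroupTable(pd.DataFrame(rows), bait_runs, control_runs)
    manifest = {
        "planted": [
            {"group_id": name, "enrichment": e, "mol_weight_kda": mw}
            for name, e, mw in cfg.planted_interactors
        ],
        "n_background": cfg.n_background,
        "noise_cv": cfg.noise_cv,
    }
    return table, manifest


def make_quant_measurements(
    cfg: FixtureConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict]:
    """Invert the copies-per-cell formula to generate light/heavy peak
    volumes for the configured spike, with multiplicative noise."""
    from .absolute_quant import AVOGADRO

    rng = _rng(cfg, rng, domain=5)
    rows = []
    for protein, copies, n_cells, coip_yield in cfg.planted_copies:
        fmol_true = copies * n_cells * coip_yield / AVOGADRO * 1e15
        for rep in range(1, cfg.n_replicates + 1):
            heavy = 1e6 * float(_noise_factors(rng, cfg.quant_noise, 1)[0])
            ratio = fmol_true / cfg.spike_fmol * float(_noise_factors(rng, cfg.quant_noise, 1)[0])
            rows.append(
                {
                    "protein": protein,
                    "replicate": rep,
                    "light_volume": heavy * ratio,
                    "heavy_volume": heavy,
                    "spike_fmol": cfg.spike_fmol,
                    "n_cells": n_cells,
                }
            )
    manifest = {
        "planted": [
            {"protein": p, "copies": c, "n_cells": n, "coip_yield": y}
            for p, c, n, y in cfg.planted_copies
        ],
        "noise": cfg.quant_noise,
    }
    return pd.DataFrame(rows), manifest


def _six_frame_orf_proteins(seq: str, min_aa: int) -> set[str]:
    """Independent scanner: ATG-initiated, stop-terminated ORF proteins
    of length >= min_aa across six frames (used to validate planted
    transcripts without calling the ORF finder under test)."""
    stops = {"TAA", "TAG", "TGA"}
    aa = _table.forward_table
    found = set()
    for work in (seq, reverse_complement(seq)):
        for off in range(3):
            codons = [work[i : i + 3] for i in range(off, len(work) - 2, 3)]
            i = 0
            while i < len(codons):
                if codons[i] == "ATG":
                    prot = []
                    j = i
                    while j < len(codons) and codons[j] not in stops:
                        prot.append(aa.get(codons[j], "X"))
                        j += 1
                    if j < len(codons) and len(prot) >= min_aa:
                        found.add("".join(prot))
                    i = j
                i += 1
    return found


def make_transcripts(
    cfg: FixtureConfig, rng: np.random.Generator | None = None
) -> tuple[list[TranscriptRecord], list[AlignmentHit], dict]:
    """Transcript groups with 1-3 isoforms of differing ORF length, a
    synthetic alignment-hit table over two species (with sub-cutoff
    decoys), and a ground-truth manifest."""
    rng = _rng(cfg, rng, domain=6)
    transcripts: list[TranscriptRecord] = []
    hits: list[AlignmentHit] = []
    manifest: dict = {"groups": {}}
    for g in range(1, cfg.n_groups + 1):
        group_id = f"c{g}_g1"
        n_iso = int(rng.integers(1, 4))
        lengths = sorted(
            rng.choice(np.arange(cfg.min_aa, cfg.min_aa + 160), size=n_iso, replace=False)
        )
        chicken_annotated = g % 5 != 0
        group_entry = {"isoforms": {}, "chicken_annotated": chicken_annotated}
        for j, aa_len in enumerate(lengths, start=1):
            tid = f"{group_id}_i{j}"
            for _ in range(200):
                protein = "M" + _rand_protein(rng, int(aa_len) - 1)
                seq = (
                    _rand_dna(rng, 30) + _encode(rng, protein) + "TAA" + _rand_dna(rng, 30)
                )
                if _six_frame_orf_proteins(seq, cfg.min_aa) == {protein}:
                    break
            else:
                raise TagkitError("could not generate a single-ORF transcript")
            transcripts.append(TranscriptRecord(tid, group_id, seq))
            group_entry["isoforms"][tid] = int(aa_len)
            orf_id = f"{tid}.orf1"
            if chicken_annotated:
                e_gg = 10.0 ** -float(rng.uniform(20, 60))
                hits.append(
                    _hit(orf_id, f"GG_{group_id}", e_gg, 200.0 + float(rng.uniform(0, 50)),
                         int(aa_len))
                )
            else:
                # decoy above the cut-off: must never annotate
                hits.append(_hit(orf_id, f"GG_DECOY_{group_id}", 1e-5, 40.0, int(aa_len)))
            e_hs = 10.0 ** -float(rng.uniform(15, 50))
            hits.append(
                _hit(orf_id, f"HS_{group_id}", e_hs, 180.0 + float(rng.uniform(0, 40)),
                     int(aa_len))
            )
        longest_tid = max(group_entry["isoforms"], key=lambda t: group_entry["isoforms"][t])
        group_entry["representative"] = f"{longest_tid}.orf1"
        manifest["groups"][group_id] = group_entry
    manifest["n_groups"] = cfg.n_groups
    manifest["n_without_chicken"] = sum(
        1 for ge in manifest["groups"].values() if not ge["chicken_annotated"]
    )
    order = rng.permutation(len(hits))
    hits = [hits[i] for i in order]
    return transcripts, hits, manifest


def _hit(query: str, subject: str, e_value: float, bit: float, qlen: int) -> AlignmentHit:
    return AlignmentHit(
        query_id=query,
        subject_id=subject,
        pct_identity=95.0,
        align_len=qlen,
        mismatches=max(0, qlen // 20),
        gap_opens=0,
        q_start=1,
        q_end=qlen,
        s_start=1,
        s_end=qlen,
        e_value=e_value,
        bit_score=bit,
    )


def write_hits_tsv(hits: list[AlignmentHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("# query\tsubject\tpident\tlength\tmismatch\tgapopen\t"
                 "qstart\tqend\tsstart\tsend\tevalue\tbitscore\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity}\t{h.align_len}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.q_start}\t{h.q_end}\t{h.s_start}\t"
                f"{h.s_end}\t{h.e_value:.3g}\t{h.bit_score}\n"
            )


def synthetic_tev_protease(rng: np.random.Generator) -> tuple[str, str]:
    """A synthetic stand-in entry for the TEV protease database record
    (random 236-aa protein; replace with the real sequence via the
    ``extras`` argument of the database builder when available)."""
    return ("TEV_protease_synthetic", "M" + _rand_protein(rng, 235))
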