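"""Transcriptome-derived MS search-database construction.

From assembled transcripts: six-frame ORF finding and translation,
best-hit annotation from protein-alignment tabular output (12-column
format, e-value cut-off 1e-10, lowest e-value separately per species),
longest-representative selection per transcript group, and FASTA export
with configured extra entries (e.g. the Quant peptide).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .cloning_sim import reverse_complement
from .errors import SequenceError, TagkitError
from .io import write_fasta

logger = logging.getLogger(__name__)

#: Grouping key from a transcript id: assembler isoform suffix stripped.
DEFAULT_GROUP_PATTERN = r"^(?P<group>.+)_i\d+$"

DEFAULT_EXTRAS = [("Quant_peptide", "LAADITSLYK")]


@dataclass
class TranscriptRecord:
    transcript_id: str
    group_id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.group_id:
            raise SequenceError("group_id must be non-empty")


@dataclass
class OrfRecord:
    """An open reading frame located on a transcript.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    plus strand of the transcript, covering the coding codons only (the
    stop codon is excluded), so ``end - start`` is divisible by 3.
    """

    transcript_id: str
    frame: int  # one of +1, +2, +3, -1, -2, -3
    start: int
    end: int
    protein: str
    orf_id: str = ""

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise SequenceError("ORF span must be divisible by 3")
        if "*" in self.protein:
            raise SequenceError("ORF protein contains an internal stop")


@dataclass(frozen=True)
class AlignmentHit:
    """One row of 12-column tabular protein-alignment output
    (coordinates 1-based inclusive, as in the source format)."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    subject_species: str = ""


@dataclass
class AnnotatedProtein:
    id: str
    protein: str
    name_chicken: str | None = None
    name_human: str | None = None
    group_id: str = ""


def find_orfs(
    transcript: TranscriptRecord,
    min_aa: int = 100,
    require_atg: bool = True,
    allow_partial: bool = False,
) -> list[OrfRecord]:
    """All maximal ORFs across the six frames with protein length
    >= ``min_aa``, sorted by protein length descending.

    ORFs are stop-to-stop stretches; with ``require_atg`` (default) the
    reported ORF starts at the first in-frame ATG of the stretch. A
    stretch running off the 3' end of the frame (no stop codon) is only
    reported when ``allow_partial`` is set.
    """
    n = len(transcript.seq)
    records: list[OrfRecord] = []
    for strand, work in (("+", transcript.seq), ("-", reverse_complement(transcript.seq))):
        for offset in range(3):
            usable = (len(work) - offset) // 3 * 3
            if usable < 3:
                continue
            prot = str(Seq(work[offset : offset + usable]).translate())
            pos = 0
            for segment in prot.split("*"):
                has_stop = pos + len(segment) < len(prot)
                aa_start = pos
                piece = segment
                if require_atg:
                    m = piece.find("M")
                    if m == -1:
                        piece = ""
                    else:
                        aa_start += m
                        piece = piece[m:]
                if piece and len(piece) >= min_aa and (has_stop or allow_partial):
                    s_work = offset + 3 * aa_start
                    e_work = s_work + 3 * len(piece)
                    if strand == "+":
                        start, end = s_work, e_work
                        frame = offset + 1
                    else:
                        start, end = n - e_work, n - s_work
                        frame = -(offset + 1)
                    records.append(
                        OrfRecord(transcript.transcript_id, frame, start, end, piece)
                    )
                pos += len(segment) + 1
    records.sort(key=lambda r: (-len(r.protein), abs(r.frame), r.frame < 0, r.start))
    for k, rec in enumerate(records, start=1):
        rec.orf_id = f"{transcript.transcript_id}.orf{k}"
    return records


def read_hits_tsv(path, species_map: dict[str, str] | None = None) -> list[AlignmentHit]:
    """Parse 12-column tabular alignment output; comment lines are
    tolerated, malformed rows are skipped with a logged warning.
    ``species_map`` maps subject-id prefixes to species labels."""
    hits: list[AlignmentHit] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 12:
                    raise ValueError(f"{len(fields)} columns")
                hit = AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    align_len=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    e_value=float(fields[10]),
                    bit_score=float(fields[11]),
                    subject_species=_species_of(fields[1], species_map),
                )
                if hit.e_value < 0:
                    raise ValueError("negative e-value")
            except ValueError as exc:
                logger.warning("skipping malformed hit row %d: %s", lineno, exc)
                skipped += 1
                continue
            hits.append(hit)
    if skipped:
        logger.warning("skipped %d malformed hit rows", skipped)
    return hits


def _species_of(subject_id: str, species_map: dict[str, str] | None) -> str:
    if species_map:
        for prefix, species in species_map.items():
            if subject_id.startswith(prefix):
                return species
    return ""


def annotate(
    orfs: list[OrfRecord],
    hits: list[AlignmentHit],
    e_cutoff: float = 1e-10,
    species_map: dict[str, str] | None = None,
    group_pattern: str = DEFAULT_GROUP_PATTERN,
) -> list[AnnotatedProtein]:
    """Assign, separately for chicken and human, the name of the passing
    hit with the lowest e-value (ties: higher bit score, then
    lexicographic subject id). Hits above the cut-off never annotate."""
    pattern = re.compile(group_pattern)
    best: dict[tuple[str, str], AlignmentHit] = {}
    orf_ids = {o.orf_id for o in orfs}
    for hit in hits:
        species = hit.subject_species or _species_of(hit.subject_id, species_map)
        if hit.e_value > e_cutoff or not species:
            continue
        if hit.query_id not in orf_ids:
            continue
        key = (hit.query_id, species)
        cur = best.get(key)
        if cur is None or (hit.e_value, -hit.bit_score, hit.subject_id) < (
            cur.e_value,
            -cur.bit_score,
            cur.subject_id,
        ):
            best[key] = hit
    out = []
    for orf in orfs:
        m = pattern.match(orf.transcript_id)
        group = m.group("group") if m else orf.transcript_id
        chicken = best.get((orf.orf_id, "chicken"))
        human = best.get((orf.orf_id, "human"))
        out.append(
            AnnotatedProtein(
                id=orf.orf_id,
                protein=orf.protein,
                name_chicken=chicken.subject_id if chicken else None,
                name_human=human.subject_id if human else None,
                group_id=group,
            )
        )
    return out


def select_representatives(
    annotated: list[AnnotatedProtein], grouping=None
) -> list[AnnotatedProtein]:
    """Exactly one protein per transcript group: the longest (in amino
    acids), ties broken by lexicographic id. Input order is irrelevant."""
    key = grouping or (lambda rec: rec.group_id)
    groups: dict[str, list[AnnotatedProtein]] = {}
    for rec in annotated:
        groups.setdefault(key(rec), []).append(rec)
    return [
        sorted(members, key=lambda r: (-len(r.protein), r.id))[0]
        for _, members in sorted(groups.items())
    ]


def build_fasta_db(
    final: list[AnnotatedProtein],
    extras: list[tuple[str, str]] | None = None,
    out_path=None,
) -> tuple[list[tuple[str, str, str]], dict]:
    """Database records plus a summary report; optionally written as
    FASTA with stable ``id | chicken | human | group`` headers."""
    if extras is None:
        extras = list(DEFAULT_EXTRAS)
    records = []
    seen: set[str] = set()
    for rec in final:
        if rec.id in seen:
            raise TagkitError(f"duplicate database id {rec.id!r}")
        seen.add(rec.id)
        desc = (
            f"chicken={rec.name_chicken or 'NA'} human={rec.name_human or 'NA'} "
            f"group={rec.group_id or 'NA'}"
        )
        records.append((rec.id, rec.protein, desc))
    for rid, seq in extras:
        if rid in seen:
            raise TagkitError(f"duplicate database id {rid!r}")
        seen.add(rid)
        records.append((rid, seq, "extra"))
    report = {
        "total": len(records),
        "from_transcripts": len(final),
        "extras": len(extras),
        "no_chicken_annotation": sum(1 for r in final if r.name_chicken is None),
        "no_human_annotation": sum(1 for r in final if r.name_human is None),
    }
    if out_path is not None:
        write_fasta(records, out_path)
    return records, report
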