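"""Deterministic in-silico molecular biology engine.

Models the DNA manipulations used to build gene-targeting constructs for
DT40 cells: PCR, restriction digestion, self-ligation, SLIC assembly,
Cre/loxP cassette excision and homologous-recombination (HR) integration.

Conventions
-----------
* Coordinates are 0-based, half-open. Circular molecules have a defined
  origin but every search operation is rotation-invariant (pattern
  searches run on a doubled string truncated to avoid double counting).
* Restriction fragments are sliced at *top-strand* cut positions, so each
  cohesive overhang appears exactly once, in exactly one fragment.
  Fragment ends carry a descriptor ``(kind, scar)`` where ``scar`` is the
  inter-cut top-strand sequence; two ends are ligatable iff their
  descriptors are identical (exact-sequence cohesion). Under this
  convention digestion exactly partitions the input and ligation simply
  concatenates fragment sequences.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

from .errors import (
    AmbiguousAssemblyError,
    InsufficientHomologyError,
    LigationError,
    NonSpecificPrimingError,
    NoProductError,
    RecombinationError,
    SequenceError,
    TargetingError,
    UncutSequenceError,
)

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Wild-type 34-bp loxP site (13-bp inverted repeats flanking the 8-bp
#: directional spacer). Used for both the upstream and downstream site.
WT_LOXP = "ATAACTTCGTATAATGTATGCTATACGAAGTTAT"

STOP_CODONS = ("TAA", "TAG", "TGA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) match start positions of needle."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


@dataclass
class NucleotideSequence:
    """A DNA molecule with linear or circular topology."""

    id: str
    seq: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise SequenceError(f"{self.id}: empty sequence")
        if not _VALID_BASES.issuperset(self.seq):
            bad = sorted(set(self.seq) - _VALID_BASES)
            raise SequenceError(
                f"{self.id}: non-ACGT characters {bad} (ambiguity codes are rejected)"
            )
        if self.topology not in ("linear", "circular"):
            raise SequenceError(f"{self.id}: unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(self.id + "_rc", reverse_complement(self.seq), self.topology)

    def rotated(self, offset: int) -> "NucleotideSequence":
        """The same circle with its origin moved to ``offset``."""
        if not self.is_circular:
            raise SequenceError("only circular sequences can be rotated")
        n = len(self.seq)
        offset %= n
        return NucleotideSequence(self.id, self.seq[offset:] + self.seq[:offset], "circular")

    def search_space(self, pattern_len: int) -> str:
        """Plus-strand text to search: doubled (truncated) when circular."""
        if self.is_circular and pattern_len > 1:
            return self.seq + self.seq[: pattern_len - 1]
        return self.seq


@dataclass
class Primer:
    """An oligonucleotide: 3' annealing region plus optional 5' overhang.

    The overhang carries restriction sites or SLIC homology; the anneal
    region must match the template exactly (design-time tool, no mismatch
    model).
    """

    name: str
    anneal: str
    overhang: str = ""

    def __post_init__(self) -> None:
        self.anneal = self.anneal.upper()
        self.overhang = self.overhang.upper()
        if len(self.anneal) < 15:
            raise SequenceError(f"{self.name}: anneal region must be >= 15 nt")
        for part in (self.anneal, self.overhang):
            if part and not _VALID_BASES.issuperset(part):
                raise SequenceError(f"{self.name}: non-ACGT characters in primer")

    @property
    def full(self) -> str:
        return self.overhang + self.anneal


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        if len(self.recognition) < 6:
            raise SequenceError(f"{self.name}: recognition must be >= 6 nt")
        for off in (self.cut_top, self.cut_bottom):
            if not 0 <= off <= len(self.recognition):
                raise SequenceError(f"{self.name}: cut offset outside recognition site")

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == reverse_complement(self.recognition)

    @property
    def overhang_kind(self) -> str:
        if self.cut_top < self.cut_bottom:
            return "5ext"
        if self.cut_top > self.cut_bottom:
            return "3ext"
        return "blunt"


@dataclass(frozen=True)
class End:
    """Descriptor of a fragment terminus: blunt or a cohesive scar."""

    kind: str  # 'blunt' | '5ext' | '3ext'
    scar: str = ""

    def compatible(self, other: "End") -> bool:
        return self.kind == other.kind and self.scar == other.scar


BLUNT = End("blunt", "")


@dataclass
class Fragment:
    """A double-stranded digestion/ligation product (top strand stored)."""

    seq: str
    end5: End = BLUNT
    end3: End = BLUNT

    def __len__(self) -> int:
        return len(self.seq)


def load_enzymes(path=None) -> dict[str, RestrictionEnzyme]:
    """Bundled enzyme table (name, recognition, cut_top, cut_bottom)."""
    if path is None:
        ref = importlib.resources.files("tagkit") / "data" / "enzymes.tsv"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    enzymes = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for line in lines[1:]:
        name, recog, ct, cb = line.split("\t")
        enzymes[name] = RestrictionEnzyme(name, recog.upper(), int(ct), int(cb))
    return enzymes


ENZYMES = load_enzymes()


def find_sites(seq: NucleotideSequence, enzyme: RestrictionEnzyme) -> list[int]:
    """0-based start positions of the recognition site on the plus strand.

    Matches of the reverse-complement recognition are included for
    non-palindromic enzymes; on circular molecules matches spanning the
    origin are found and positions are reported modulo the length.
    """
    patterns = {enzyme.recognition, reverse_complement(enzyme.recognition)}
    n = len(seq)
    positions: set[int] = set()
    for pat in patterns:
        hay = seq.search_space(len(pat))
        for p in _find_all(hay, pat):
            positions.add(p % n if seq.is_circular else p)
    return sorted(positions)


def _cuts_for(seq: NucleotideSequence, enzyme: RestrictionEnzyme) -> list[tuple[int, End]]:
    """(top-strand cut position, end descriptor) for every site."""
    n = len(seq)
    rec = enzyme.recognition
    cuts = []
    for p in find_sites(seq, enzyme):
        window = seq.search_space(len(rec))[p : p + len(rec)] if not seq.is_circular else (
            (seq.seq + seq.seq)[p : p + len(rec)]
        )
        if window == rec:
            ct, cb = enzyme.cut_top, enzyme.cut_bottom
        else:  # reverse-complement match of a non-palindromic site
            ct = len(rec) - enzyme.cut_bottom
            cb = len(rec) - enzyme.cut_top
        lo, hi = min(ct, cb), max(ct, cb)
        scar = (seq.seq + seq.seq)[p + lo : p + hi] if seq.is_circular else seq.seq[p + lo : p + hi]
        kind = "5ext" if ct < cb else ("3ext" if ct > cb else "blunt")
        top = (p + ct) % n if seq.is_circular else p + ct
        cuts.append((top, End(kind, scar)))
    # distinct top-cut positions, in sequence order
    seen: dict[int, End] = {}
    for pos, end in sorted(cuts):
        seen.setdefault(pos, end)
    return sorted(seen.items())


def digest(seq: NucleotideSequence, enzyme: RestrictionEnzyme) -> list[Fragment]:
    """Cut at every site. Linear input with n sites yields n+1 fragments,
    circular yields n; the concatenation of fragment sequences (in order)
    reconstructs the input exactly."""
    cuts = _cuts_for(seq, enzyme)
    if not cuts:
        if seq.is_circular:
            raise UncutSequenceError(f"{enzyme.name} does not cut {seq.id}")
        return [Fragment(seq.seq, BLUNT, BLUNT)]
    s, n = seq.seq, len(seq)
    frags = []
    if seq.is_circular:
        doubled = s + s
        for (p1, e1), (p2, e2) in zip(cuts, cuts[1:] + [(cuts[0][0] + n, cuts[0][1])]):
            frags.append(Fragment(doubled[p1:p2], end5=e1, end3=e2))
    else:
        bounds = [(0, BLUNT)] + cuts + [(n, BLUNT)]
        for (p1, e1), (p2, e2) in zip(bounds, bounds[1:]):
            frags.append(Fragment(s[p1:p2], end5=e1, end3=e2))
    return frags


def ligate(a: Fragment, b: Fragment) -> Fragment:
    """Join a's 3' end to b's 5' end (cohesive ends must match exactly)."""
    if not a.end3.compatible(b.end5):
        raise LigationError(
            f"incompatible ends: {a.end3.kind}/{a.end3.scar!r} vs {b.end5.kind}/{b.end5.scar!r}"
        )
    return Fragment(a.seq + b.seq, end5=a.end5, end3=b.end3)


def self_circularize(frag: Fragment, seq_id: str = "circle") -> NucleotideSequence:
    """Intramolecular ligation of a fragment's two ends."""
    if not frag.end5.compatible(frag.end3):
        raise LigationError(
            "ligation failure: 5' and 3' ends are not complementary "
            f"({frag.end5.kind}/{frag.end5.scar!r} vs {frag.end3.kind}/{frag.end3.scar!r})"
        )
    return NucleotideSequence(seq_id, frag.seq, "circular")


def _unique_occurrence(seq: NucleotideSequence, pattern: str, what: str) -> int:
    hay = seq.search_space(len(pattern))
    hits = _find_all(hay, pattern)
    if seq.is_circular:
        hits = sorted({h % len(seq) for h in hits})
    if len(hits) != 1:
        raise NonSpecificPrimingError(
            f"{what} binds {len(hits)} times on {seq.id} (exactly one required)"
        )
    return hits[0]


def simulate_pcr(
    template: NucleotideSequence,
    fwd: Primer,
    rev: Primer,
    max_length: int = 12_000,
) -> NucleotideSequence:
    """Amplify the region from the forward anneal start through the
    reverse anneal site; primer overhangs are appended to the product.

    Each anneal region must occur exactly once on its strand. On a
    circular template the amplicon may span the origin (this is how the
    arm-inversion PCR works); on a linear template primers facing away
    from each other give no product.
    """
    f_start = _unique_occurrence(template, fwd.anneal, f"forward primer {fwd.name}")
    rev_site = reverse_complement(rev.anneal)
    r_start = _unique_occurrence(template, rev_site, f"reverse primer {rev.name}")
    n = len(template)
    r_end = r_start + len(rev_site)
    if template.is_circular:
        core_len = (r_end - f_start) % n
        if core_len == 0:
            core_len = n
        core = (template.seq + template.seq)[f_start : f_start + core_len]
    else:
        if r_start < f_start:
            raise NoProductError(
                f"primers {fwd.name}/{rev.name} face away from each other on linear {template.id}"
            )
        core = template.seq[f_start:r_end]
    product = fwd.overhang + core + reverse_complement(rev.overhang)
    if len(product) > max_length:
        raise NoProductError(
            f"amplicon of {len(product)} bp exceeds the configured maximum of {max_length} bp"
        )
    return NucleotideSequence(f"pcr_{template.id}", product, "linear")


def _z_array(s: str) -> list[int]:
    z = [0] * len(s)
    z[0] = len(s)
    l = r = 0
    for i in range(1, len(s)):
        if i < r:
            z[i] = min(r - i, z[i - l])
        while i + z[i] < len(s) and s[z[i]] == s[i + z[i]]:
            z[i] += 1
        if i + z[i] > r:
            l, r = i, i + z[i]
    return z


def terminal_overlap(a: str, b: str) -> int:
    """Length of the longest suffix of ``a`` equal to a prefix of ``b``."""
    t = b + "\x00" + a
    z = _z_array(t)
    best = 0
    for k in range(1, min(len(a), len(b)) + 1):
        if z[len(t) - k] >= k:
            best = k
    return best


@dataclass
class SlicAssembly:
    product: NucleotideSequence
    overlap5: int  # vector 3' end  -> insert 5' end junction
    overlap3: int  # insert 3' end -> vector 5' end junction
    insert_flipped: bool


def slic_assemble(
    vector: NucleotideSequence,
    insert: NucleotideSequence,
    min_overlap: int = 25,
) -> SlicAssembly:
    """Sequence- and ligation-independent cloning of one insert into a
    linearized vector.

    The terminal homology between each vector end and the corresponding
    insert end (maximal exact terminal identity, the in-vitro annealing
    region exposed by T4 polymerase) must reach ``min_overlap`` at both
    junctions; insert orientation is auto-detected by trying both strands.
    """
    if vector.is_circular or insert.is_circular:
        raise SequenceError("slic_assemble requires linear vector and insert")
    candidates = []
    for flipped, ins in ((False, insert.seq), (True, reverse_complement(insert.seq))):
        k1 = terminal_overlap(vector.seq, ins)
        k2 = terminal_overlap(ins, vector.seq)
        if k1 >= min_overlap and k2 >= min_overlap and k1 + k2 <= len(ins):
            candidates.append((flipped, ins, k1, k2))
    if not candidates:
        raise InsufficientHomologyError(
            f"insufficient homology: terminal identity below {min_overlap} bp at a junction"
        )
    if len(candidates) > 1:
        raise AmbiguousAssemblyError("ambiguous assembly: both insert orientations fit")
    flipped, ins, k1, k2 = candidates[0]
    circle = NucleotideSequence(
        f"{vector.id}__{insert.id}",
        vector.seq + ins[k1 : len(ins) - k2],
        "circular",
    )
    return SlicAssembly(circle, k1, k2, flipped)


def cre_excise(
    seq: NucleotideSequence, loxp: str = WT_LOXP
) -> tuple[NucleotideSequence, NucleotideSequence]:
    """Cre-mediated excision between two same-orientation loxP sites.

    Returns ``(remaining, excised)``: the intervening segment pops out as
    a circle carrying one loxP and the remaining molecule keeps the
    other, so total base content is conserved. Opposite-orientation sites
    (inversion substrates) are rejected.
    """
    loxp = loxp.upper()
    hay = seq.search_space(len(loxp))
    n = len(seq)
    fwd = sorted({p % n for p in _find_all(hay, loxp)}) if seq.is_circular else _find_all(hay, loxp)
    hay_rc = seq.search_space(len(loxp))
    rc = reverse_complement(loxp)
    rev = (
        sorted({p % n for p in _find_all(hay_rc, rc)}) if seq.is_circular else _find_all(hay_rc, rc)
    )
    if len(fwd) + len(rev) != 2:
        raise RecombinationError(
            f"need exactly 2 loxP copies, found {len(fwd) + len(rev)} on {seq.id}"
        )
    if fwd and rev:
        raise RecombinationError("loxP sites are in opposite orientation (inversion not modelled)")
    p1, p2 = sorted(fwd or rev)
    s = seq.seq
    remaining = NucleotideSequence(f"{seq.id}_postcre", s[:p1] + s[p2:], seq.topology)
    excised = NucleotideSequence(f"{seq.id}_excised", s[p1:p2], "circular")
    return remaining, excised


def simulate_hr_integration(
    genome: NucleotideSequence,
    construct: NucleotideSequence,
    min_arm: int,
    end_trim: int = 10,
) -> NucleotideSequence:
    """Targeted integration of a linear construct via its terminal
    homology arms.

    The first/last ``min_arm`` bases of the construct (allowing up to
    ``end_trim`` non-homologous terminal bases, e.g. restriction-site
    remnants removed by end resection) must each map uniquely and
    colinearly to the genome. The cassette between the arms is inserted
    between the genomic arm copies; genome outside the arms is unchanged.
    """
    if construct.is_circular:
        raise TargetingError("targeting DNA must be linearized before integration")
    g, c = genome.seq, construct.seq
    if len(c) < 2 * min_arm:
        raise TargetingError("construct shorter than two homology arms")

    def locate(offsets, seed_of):
        for t in offsets:
            seed = seed_of(t)
            if seed is None:
                continue
            hits = _find_all(g, seed)
            if len(hits) == 1:
                return t, hits[0]
            if len(hits) > 1:
                raise TargetingError("targeting failure: homology arm is not unique in the genome")
        raise TargetingError("targeting failure: homology arm not found in the genome")

    def left_seed(t):
        return c[t : t + min_arm] if t + min_arm <= len(c) else None

    def right_seed(t):
        return c[len(c) - t - min_arm : len(c) - t] if t + min_arm <= len(c) else None

    t5, i = locate(range(end_trim + 1), left_seed)
    t3, j = locate(range(end_trim + 1), right_seed)
    if j < i + min_arm:
        raise TargetingError("targeting failure: arms map in the wrong order/orientation")
    inserted = c[t5 : len(c) - t3]
    return NucleotideSequence(
        f"{genome.id}_targeted", g[:i] + inserted + g[j + min_arm :], genome.topology
    )
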