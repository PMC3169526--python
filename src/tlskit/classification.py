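"""Clone-read alignment and bypass-event classification.

Each sequenced clone is aligned to its construct reference and assigned to
exactly one event category:

``ACCURATE``
    the 4-nt window equals the accurate window and no indel touches it;
``TARGETED``
    mutation(s) only at the two lesion-opposite positions, including a
    single-nucleotide deletion there (written as a Greek Delta in spectra);
``SEMI_TARGETED``
    mutation(s) only at the two window flank positions;
``MIXED``
    mutations at both lesion-opposite and flank positions;
``NON_TLS``
    large deletions or any insertion — the signature of double-strand-break
    repair of the gapped plasmid rather than lesion bypass;
``UNSCORABLE``
    the read does not convincingly align to the construct (anchor identity
    below threshold) or the window cannot be called (ambiguous base or no
    coverage).

The first four categories are translesion-synthesis (TLS) events; mutation
percentages are always reported out of TLS events only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from Bio import Align

from .constructs import CloneRead, LesionConstruct

__all__ = [
    "Category",
    "Edit",
    "Alignment",
    "EventClassification",
    "SpectrumTable",
    "make_aligner",
    "align_read",
    "classify_event",
    "classify_read",
    "summarize_spectrum",
    "DELETION_MARK",
    "ANCHOR_IDENTITY_THRESHOLD",
]

DELETION_MARK = "Δ"  # Δ, single-nucleotide deletion in spectrum notation

#: minimum fraction of anchor positions matching the reference for a read
#: to be scorable; tolerant of Sanger end noise, rejects unrelated inserts
ANCHOR_IDENTITY_THRESHOLD = 0.8


class Category(str, Enum):
    ACCURATE = "ACCURATE"
    TARGETED = "TARGETED"
    SEMI_TARGETED = "SEMI_TARGETED"
    MIXED = "MIXED"
    NON_TLS = "NON_TLS"
    UNSCORABLE = "UNSCORABLE"

    @property
    def is_tls(self) -> bool:
        return self in _TLS_CATEGORIES


_TLS_CATEGORIES = frozenset(
    {Category.ACCURATE, Category.TARGETED, Category.SEMI_TARGETED, Category.MIXED}
)

SUB, DEL, INS = "SUB", "DEL", "INS"


@dataclass(frozen=True)
class Edit:
    """One difference against the reference.

    ``ref_pos`` is 0-based on the reference; for DEL, ``ref`` holds the
    deleted bases; for INS, ``alt`` holds the bases inserted before
    ``ref_pos``.  Indels are left-aligned: shifted to the smallest
    equivalent reference position.
    """

    ref_pos: int
    kind: str  # SUB | DEL | INS
    ref: str
    alt: str

    def __str__(self) -> str:
        if self.kind == SUB:
            return f"{self.ref}>{self.alt}@{self.ref_pos}"
        if self.kind == DEL:
            return f"del{len(self.ref)}@{self.ref_pos}"
        return f"ins{len(self.alt)}@{self.ref_pos}"


@dataclass
class Alignment:
    """Gapped alignment of a clone read against its construct reference."""

    aligned_ref: str
    aligned_read: str
    edits: list[Edit]
    anchor_identity: float
    read_at_ref: dict[int, str] = field(repr=False, default_factory=dict)
    score: float = 0.0


@dataclass(frozen=True)
class EventClassification:
    clone_id: str
    category: Category
    is_tls: bool
    observed_window: str
    edit_summary: str
    anchor_identity: float
    condition_id: str = ""
    replicate_id: str = ""


def make_aligner(
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    """Global affine-gap aligner with free end gaps.

    End gaps are free on both sequences so that vector sequence beyond the
    construct, or a truncated read, is not forced into spurious edits; the
    defaults favour substitution calls over spurious indels.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # set after open/extend: those setters overwrite the end-gap scores
    aligner.end_gap_score = 0.0
    return aligner


def _left_align(edits: list[Edit], reference: str) -> list[Edit]:
    """Shift each indel to its smallest equivalent reference position."""
    out = []
    for e in edits:
        if e.kind == DEL:
            p, seq = e.ref_pos, e.ref
            while p > 0 and reference[p - 1] == seq[-1]:
                seq = reference[p - 1] + seq[:-1]
                p -= 1
            out.append(Edit(p, DEL, seq, ""))
        elif e.kind == INS:
            p, seq = e.ref_pos, e.alt
            while p > 0 and reference[p - 1] == seq[-1]:
                seq = reference[p - 1] + seq[:-1]
                p -= 1
            out.append(Edit(p, INS, "", seq))
        else:
            out.append(e)
    return sorted(out, key=lambda e: (e.ref_pos, e.kind))


def align_read(
    read: CloneRead,
    construct: LesionConstruct,
    aligner: Align.PairwiseAligner | None = None,
) -> Alignment:
    """Align a clone read to its construct and extract the edit list.

    Terminal gap columns (free end gaps) are excluded from the edit list:
    read overhang is vector sequence, and uncovered reference ends show up
    as reduced anchor identity / window coverage instead of edits.
    """
    if aligner is None:
        aligner = make_aligner()
    ref = construct.reference
    aln = aligner.align(ref, read.sequence)[0]
    aligned_ref, aligned_read = str(aln[0]), str(aln[1])

    n = len(aligned_ref)
    i0 = 0
    while i0 < n and (aligned_ref[i0] == "-" or aligned_read[i0] == "-"):
        i0 += 1
    i1 = n
    while i1 > i0 and (aligned_ref[i1 - 1] == "-" or aligned_read[i1 - 1] == "-"):
        i1 -= 1

    rp = sum(1 for c in aligned_ref[:i0] if c != "-")
    edits: list[Edit] = []
    read_at_ref: dict[int, str] = {}
    i = i0
    while i < i1:
        a, b = aligned_ref[i], aligned_read[i]
        if a != "-" and b != "-":
            read_at_ref[rp] = b
            if a != b:
                edits.append(Edit(rp, SUB, a, b))
            rp += 1
            i += 1
        elif b == "-":  # deletion run
            start = rp
            seq = []
            while i < i1 and aligned_read[i] == "-":
                read_at_ref[rp] = "-"
                seq.append(aligned_ref[i])
                rp += 1
                i += 1
            edits.append(Edit(start, DEL, "".join(seq), ""))
        else:  # insertion run
            seq = []
            while i < i1 and aligned_ref[i] == "-":
                seq.append(aligned_read[i])
                i += 1
            edits.append(Edit(rp, INS, "", "".join(seq)))

    edits = _left_align(edits, ref)
    # identity over anchor positions aligned to a read base; positions inside
    # deletions are excluded so that a clean large deletion (a non-TLS event,
    # not an unalignable read) does not drag the identity down
    anchor_pos = construct.anchor_positions
    aligned_pos = [p for p in anchor_pos if read_at_ref.get(p) not in (None, "-")]
    if aligned_pos:
        identity = sum(1 for p in aligned_pos if read_at_ref[p] == ref[p]) / len(aligned_pos)
    else:
        identity = 0.0
    return Alignment(aligned_ref, aligned_read, edits, identity, read_at_ref, aln.score)


_WINDOW_LABELS = ("flank5", "opp1", "opp2", "flank3")


def _observed_window(aln: Alignment, construct: LesionConstruct) -> str:
    """Window string over {A,C,G,T,N,Δ}; Δ marks a deleted position."""
    chars = []
    for p in construct.window_positions:
        base = aln.read_at_ref.get(p)
        if base is None:
            chars.append("?")  # not covered by the read
        elif base == "-":
            chars.append(DELETION_MARK)
        else:
            chars.append(base)
    return "".join(chars)


def classify_event(
    aln: Alignment,
    construct: LesionConstruct,
    clone_id: str = "",
    condition_id: str = "",
    replicate_id: str = "",
    anchor_threshold: float = ANCHOR_IDENTITY_THRESHOLD,
) -> EventClassification:
    """Assign exactly one event category to an aligned clone.

    Rules, in order: unalignable reads (anchor identity below threshold,
    uncovered window, or N in the window) are UNSCORABLE; any insertion,
    any deletion of two or more nucleotides, or a single-nucleotide
    deletion outside the window is NON_TLS; an untouched window is
    ACCURATE; otherwise the window positions hit (lesion-opposite vs
    flank) decide TARGETED / SEMI_TARGETED / MIXED.
    """
    window = _observed_window(aln, construct)
    ws = construct.window_start
    window_range = range(ws, ws + 4)

    def make(category: Category, summary: str) -> EventClassification:
        return EventClassification(
            clone_id=clone_id,
            category=category,
            is_tls=category.is_tls,
            observed_window=window,
            edit_summary=summary,
            anchor_identity=aln.anchor_identity,
            condition_id=condition_id,
            replicate_id=replicate_id,
        )

    if aln.anchor_identity < anchor_threshold:
        return make(Category.UNSCORABLE, "low_anchor_identity")
    if "?" in window:
        return make(Category.UNSCORABLE, "window_not_covered")
    if "N" in window:
        return make(Category.UNSCORABLE, "ambiguous_base_in_window")

    for e in aln.edits:
        if e.kind == INS:
            return make(Category.NON_TLS, str(e))
        if e.kind == DEL:
            if len(e.ref) >= 2:
                return make(Category.NON_TLS, str(e))
            if e.ref_pos not in window_range:
                return make(Category.NON_TLS, str(e))

    window_edits = [
        e
        for e in aln.edits
        if (e.kind == SUB and e.ref_pos in window_range)
        or (e.kind == DEL and e.ref_pos in window_range)
    ]
    if not window_edits:
        return make(Category.ACCURATE, "")

    opp = set(construct.opposite_positions)
    summary_parts = []
    opp_hit = flank_hit = False
    for e in window_edits:
        label = _WINDOW_LABELS[e.ref_pos - ws]
        if e.ref_pos in opp:
            opp_hit = True
        else:
            flank_hit = True
        if e.kind == DEL:
            summary_parts.append(f"{DELETION_MARK}@{label}")
        else:
            summary_parts.append(f"{e.ref}→{e.alt}@{label}")
    summary = ",".join(summary_parts)

    if opp_hit and flank_hit:
        return make(Category.MIXED, summary)
    if opp_hit:
        return make(Category.TARGETED, summary)
    return make(Category.SEMI_TARGETED, summary)


def classify_read(
    read: CloneRead,
    construct: LesionConstruct,
    aligner: Align.PairwiseAligner | None = None,
    anchor_threshold: float = ANCHOR_IDENTITY_THRESHOLD,
) -> EventClassification:
    """Convenience wrapper: align then classify one clone read."""
    aln = align_read(read, construct, aligner)
    return classify_event(
        aln,
        construct,
        clone_id=read.clone_id,
        condition_id=read.condition_id,
        replicate_id=read.replicate_id,
        anchor_threshold=anchor_threshold,
    )


@dataclass
class SpectrumTable:
    """Per-condition mutation spectrum.

    Percentages of the TLS categories are calculated out of all TLS events;
    UNSCORABLE clones are excluded from every denominator, and NON_TLS
    events enter only ``fraction_tls``.
    """

    n_clones: int
    n_scored: int
    category_counts: dict[str, int]
    window_counts: dict[str, int]
    fraction_tls: float | None
    tls_category_pct: dict[str, float] | None
    mutagenic_pct: float | None

    @property
    def n_tls(self) -> int:
        return sum(self.category_counts[c.value] for c in _TLS_CATEGORIES)

    @property
    def undefined(self) -> bool:
        return self.mutagenic_pct is None


def summarize_spectrum(events: list[EventClassification]) -> SpectrumTable:
    """Tally categories and window sequences for one condition.

    With zero TLS events the percentages are undefined and reported as
    ``None`` (flagged via :attr:`SpectrumTable.undefined`).
    """
    if not events:
        raise ValueError("summarize_spectrum: empty event list")
    cat_counts = Counter(e.category.value for e in events)
    counts = {c.value: cat_counts.get(c.value, 0) for c in Category}
    windows = Counter(e.observed_window for e in events if e.is_tls)
    n = len(events)
    n_scored = n - counts[Category.UNSCORABLE.value]
    n_tls = sum(counts[c.value] for c in _TLS_CATEGORIES)
    fraction_tls = n_tls / n_scored if n_scored else None
    if n_tls:
        pct = {c.value: 100.0 * counts[c.value] / n_tls for c in _TLS_CATEGORIES}
        mutagenic = 100.0 * (n_tls - counts[Category.ACCURATE.value]) / n_tls
    else:
        pct = None
        mutagenic = None
    return SpectrumTable(
        n_clones=n,
        n_scored=n_scored,
        category_counts=counts,
        window_counts=dict(sorted(windows.items())),
        fraction_tls=fraction_tls,
        tls_category_pct=pct,
        mutagenic_pct=mutagenic,
    )
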