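"""Lesion-bearing construct definitions and coordinate conventions.

A gap-lesion plasmid carries a single-stranded gap with one site-specific
DNA lesion.  After the gap is filled inside the cell, the newly synthesized
strand is sequenced.  Everything downstream works on that strand, read
5'->3', with 0-based half-open coordinates; no strand flipping is ever
performed.

The classification window is the 4-nt stretch of the filled-in strand whose
middle two nucleotides lie opposite the lesion dinucleotide: flank, two
lesion-opposite positions, flank.  Accurate bypass leaves the window equal
to ``accurate_window`` (5'-CAAC-3' opposite the TT lesions, 5'-GCCT-3'
opposite the cisplatin GG adduct).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

__all__ = [
    "LesionConstruct",
    "CloneRead",
    "ConstructError",
    "load_constructs",
    "dump_constructs",
    "default_constructs",
    "LESION_DINUCLEOTIDE",
    "complement",
]

LESION_KINDS = ("TT_CPD", "TT_64PP", "CISPT_GG")

#: dinucleotide carried by the lesion strand, 5'->3'
LESION_DINUCLEOTIDE = {"TT_CPD": "TT", "TT_64PP": "TT", "CISPT_GG": "GG"}

MARKERS = ("KANR", "CMR")

_COMPL = str.maketrans("ACGTN", "TGCAN")

DNA = set("ACGT")
DNA_N = set("ACGTN")

#: default anchor length taken immediately 5' and 3' of the window
ANCHOR_LEN = 20


def complement(seq: str) -> str:
    """Watson-Crick complement, position by position (no reversal)."""
    return seq.translate(_COMPL)


class ConstructError(ValueError):
    """A construct definition violates an invariant; message names the field."""


@dataclass(frozen=True)
class LesionConstruct:
    """One gap-lesion construct: reference strand plus window geometry.

    Parameters
    ----------
    id : short label, e.g. ``"TT_CPD"``.
    lesion_kind : one of ``TT_CPD``, ``TT_64PP``, ``CISPT_GG``.
    reference : filled-in strand sequence, 5'->3', 60-300 nt.
    window_start : 0-based offset of the 4-nt classification window.
    accurate_window : the window sequence produced by error-free bypass.
    anchor5, anchor3 : alignment anchors flanking the window; derived as the
        20 nt on each side of the window when not given explicitly.
    marker : bacterial selection marker; ``KANR`` for lesion plasmids,
        ``CMR`` for the lesion-free control plasmid.
    """

    id: str
    lesion_kind: str
    reference: str
    window_start: int
    accurate_window: str
    anchor5: str = ""
    anchor3: str = ""
    marker: str = "KANR"

    def __post_init__(self) -> None:
        if self.lesion_kind not in LESION_KINDS:
            raise ConstructError(
                f"{self.id}: lesion_kind {self.lesion_kind!r} not one of {LESION_KINDS}"
            )
        if self.marker not in MARKERS:
            raise ConstructError(f"{self.id}: marker {self.marker!r} not one of {MARKERS}")
        if not set(self.reference) <= DNA:
            bad = sorted(set(self.reference) - DNA)
            raise ConstructError(f"{self.id}: reference contains non-DNA characters {bad}")
        if not 60 <= len(self.reference) <= 300:
            raise ConstructError(
                f"{self.id}: reference length {len(self.reference)} outside 60-300 nt"
            )
        if len(self.accurate_window) != 4 or not set(self.accurate_window) <= DNA:
            raise ConstructError(f"{self.id}: accurate_window must be 4 nt of ACGT")
        ws = self.window_start
        if not 0 <= ws <= len(self.reference) - 4:
            raise ConstructError(f"{self.id}: window_start {ws} out of range")
        if self.reference[ws : ws + 4] != self.accurate_window:
            raise ConstructError(
                f"{self.id}: reference[{ws}:{ws + 4}] = "
                f"{self.reference[ws:ws + 4]!r} != accurate_window {self.accurate_window!r}"
            )
        expected = complement(LESION_DINUCLEOTIDE[self.lesion_kind])
        if self.accurate_window[1:3] != expected:
            raise ConstructError(
                f"{self.id}: accurate_window middle {self.accurate_window[1:3]!r} is not "
                f"the complement {expected!r} of the {self.lesion_kind} dinucleotide"
            )
        if not self.anchor5:
            object.__setattr__(self, "anchor5", self.reference[max(0, ws - ANCHOR_LEN) : ws])
        if not self.anchor3:
            object.__setattr__(self, "anchor3", self.reference[ws + 4 : ws + 4 + ANCHOR_LEN])
        for name, anchor in (("anchor5", self.anchor5), ("anchor3", self.anchor3)):
            if len(anchor) < 15:
                raise ConstructError(f"{self.id}: {name} shorter than 15 nt")
            if self.reference.count(anchor) != 1:
                raise ConstructError(f"{self.id}: {name} does not occur exactly once in reference")
        a5_start = self.reference.index(self.anchor5)
        a3_start = self.reference.index(self.anchor3)
        if a5_start + len(self.anchor5) > ws or a3_start < ws + 4:
            raise ConstructError(f"{self.id}: anchors overlap the classification window")

    # -- window geometry -------------------------------------------------

    @property
    def window_slice(self) -> slice:
        return slice(self.window_start, self.window_start + 4)

    @property
    def window_positions(self) -> tuple[int, int, int, int]:
        ws = self.window_start
        return (ws, ws + 1, ws + 2, ws + 3)

    @property
    def opposite_positions(self) -> tuple[int, int]:
        """Reference positions opposite the lesion dinucleotide."""
        return (self.window_start + 1, self.window_start + 2)

    @property
    def flank_positions(self) -> tuple[int, int]:
        """The single nucleotide on each side of the lesion-opposite pair."""
        return (self.window_start, self.window_start + 3)

    @property
    def anchor_positions(self) -> tuple[int, ...]:
        a5 = self.reference.index(self.anchor5)
        a3 = self.reference.index(self.anchor3)
        return tuple(range(a5, a5 + len(self.anchor5))) + tuple(
            range(a3, a3 + len(self.anchor3))
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CloneRead:
    """One sequenced plasmid isolate, on the filled-in strand, 5'->3'."""

    clone_id: str
    condition_id: str
    replicate_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ConstructError(f"{self.clone_id}: empty sequence")
        seq = self.sequence.upper()
        if not set(seq) <= DNA_N:
            bad = sorted(set(seq) - DNA_N)
            raise ConstructError(f"{self.clone_id}: non-IUPAC(ACGTN) characters {bad}")
        object.__setattr__(self, "sequence", seq)


# -- config I/O ----------------------------------------------------------


def load_constructs(config_path: str | Path) -> list[LesionConstruct]:
    """Load constructs from a JSON config ``{"constructs": [...]}``.

    Anchors are derived automatically as the 20 nt flanking the window
    unless given in the config.  Any invariant violation raises
    :class:`ConstructError` naming the offending field.
    """
    path = Path(config_path)
    if not path.exists():
        raise FileNotFoundError(f"construct config not found: {path}")
    data = json.loads(path.read_text())
    if not isinstance(data, dict) or "constructs" not in data:
        raise ConstructError(f"{path}: expected a JSON object with a 'constructs' list")
    allowed = {
        "id", "lesion_kind", "reference", "window_start",
        "accurate_window", "anchor5", "anchor3", "marker",
    }
    out = []
    for entry in data["constructs"]:
        extra = set(entry) - allowed
        if extra:
            raise ConstructError(f"unknown construct fields: {sorted(extra)}")
        out.append(LesionConstruct(**entry))
    ids = [c.id for c in out]
    if len(set(ids)) != len(ids):
        raise ConstructError("duplicate construct ids in config")
    return out


def dump_constructs(constructs: list[LesionConstruct], config_path: str | Path) -> None:
    """Write constructs to JSON, round-trippable via :func:`load_constructs`."""
    payload = {"constructs": [c.to_dict() for c in constructs]}
    Path(config_path).write_text(json.dumps(payload, indent=2) + "\n")


# Default constructs.  The published assay does not print the plasmid
# sequence around the lesion, only the 4-nt windows, so these references are
# synthetic placeholders: 148 nt of fixed random-composition flank on each
# side of the window (a realistic Sanger-read span), designed so the anchors
# are unique, no homopolymer run reaches 4 nt, and the bases adjacent to the
# window differ from the window ends (keeps left-aligned single-nt deletions
# inside the window).
_DEFAULT_REFS = {
    "TT_CPD": (
        "TCTAACCGAATTGCTAGTGAAGAGGGTCGACCAGGCTTCGCGATGATATGTACCTTGGCTCAAAGGTGTTGTGGGCCTGG"
        "CCTCGACATAGGCTACCCGGGCAAGGAATTTAATATTCCGCTAGTGTTGGCCACTCGTGAGAAAGAGGCAACTTCGCAAC"
        "ACATGAATGAGTAGTATGGATCTATGGAAGTTTACAATAAGTACGCTATACGCGAAAGCCAGAGCCATGCTCTTAGGGAA"
        "GATCCTTGGCGAAATGCCTGCGCCTCCTAGCAAGATGTGTTTGCTTGATTAGCTAGCAGA"
    ),
    "TT_64PP": (
        "ATTTCCCTCGATACGTTAATAATCTGCTTCAGCTCATGCGGACTGTAACTCCATTATTGAGGATCTCGAGTCGACGTGAG"
        "TGTCGGCAAGAGCCGCATTTATTATCGAGGGCACCTTGTCGCATCAAACTGGATCTGTGCCAAAGCGACAACGAACCCTT"
        "GAAGCTTCCGGCCCGTAATTTAAATCCAAACCTCTGCACTCTAGTTCGTATGTCCATTTGAACCCATCGGCGCTCGATCG"
        "CGTCTTCGTCTTACCCGCCCTTCGCTCACGGTTTAGGCTGAGGACACTATTATATAAATC"
    ),
    "CISPT_GG": (
        "CTAACACGACCGATGGTGGAAACGGCCGGACGGGAGTTGCTTAACTCGCTAAGACTAATTCCACCCAGATTCCGAGGCCC"
        "TCCGACACCTGCCAGGTCTATGTAAGTGAACATGTTGCAGCGTCTTAGCCTTAGTGACTTGTACGTGAGCCTATGTATCT"
        "GCGATAGATTGCGGAGAGGAGCGAATCGATCTGGAGTCCCAGAGTCAATTGAATAAGGCTATAAAGTGGACTACACGCAT"
        "GGATACTTATTCCAATTGCACTACTCATCAACTAAACGCTATCCCACCTAGGCGCTCAGA"
    ),
}


def default_constructs() -> list[LesionConstruct]:
    """Built-in constructs for the three lesions (synthetic references)."""
    return [
        LesionConstruct(
            id=kind,
            lesion_kind=kind,
            reference=_DEFAULT_REFS[kind],
            window_start=148,
            accurate_window="CAAC" if kind.startswith("TT") else "GCCT",
        )
        for kind in LESION_KINDS
    ]
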