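"""Cut-locus geometry for a single chromosomal double-strand break.

A site-specific nuclease such as HO endonuclease cleaves a defined position in
the reference, leaving two broken ends.  Everything downstream (joint
enumeration, read classification) is driven by two numbers: the cut position
``t`` (the top-strand coordinate of the most distal base of the left end's
overhang) and the overhang length ``v``.  HO leaves 4-nucleotide 3' overhangs,
so the default geometry is ``v = 4`` with ``polarity = "3p"``.

Coordinates are 1-based and inclusive on the top strand throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Tuple

from Bio import SeqIO

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class LocusError(ValueError):
    """Invalid locus sequence or cut geometry."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DsbLocus:
    """A reference top strand plus the geometry of one staggered cut.

    Parameters
    ----------
    name:
        Free-text label for the locus.
    top_strand:
        Reference top-strand sequence over ``{A, C, G, T}`` (uppercase only;
        ambiguity codes are rejected because every downstream comparison is an
        exact base comparison).
    cut_pos:
        ``t`` — top-strand position (1-based) of the most distal base of the
        left end's overhang.
    overhang_len:
        ``v`` — number of single-stranded bases in each overhang; ``v = 0``
        describes a blunt cut.
    amplicon_window:
        ``(start, end)`` positions covered by the sequencing read on the top
        strand.  The window must span the cut.
    polarity:
        ``"3p"`` (default, HO-style 3' overhangs) or ``"5p"``.  With ``t``
        anchored on the most distal overhang base the product algebra is the
        same for both polarities, so this field is descriptive metadata plus a
        validation hook.
    """

    name: str
    top_strand: str
    cut_pos: int
    overhang_len: int
    amplicon_window: Tuple[int, int]
    polarity: str = "3p"

    def __post_init__(self) -> None:
        seq = self.top_strand
        if not seq:
            raise LocusError("empty reference sequence")
        bad = set(seq) - VALID_BASES
        if bad:
            raise LocusError(
                f"reference contains characters outside A/C/G/T: {sorted(bad)!r} "
                "(lowercase and ambiguity codes are rejected)"
            )
        if self.polarity not in ("3p", "5p"):
            raise LocusError(f"polarity must be '3p' or '5p', got {self.polarity!r}")
        t, v, n = self.cut_pos, self.overhang_len, len(seq)
        if v < 0:
            raise LocusError(f"overhang_len must be >= 0, got {v}")
        if not (1 <= t <= n - 1):
            raise LocusError(f"cut_pos={t} must leave both ends non-empty (1 <= t <= {n - 1})")
        if not (v <= t <= n - v):
            raise LocusError(
                f"cut_pos={t} with overhang_len={v} leaves an end without its "
                f"overhang inside the {n}-base sequence (need {v} <= t <= {n - v})"
            )
        start, end = self.amplicon_window
        if not (1 <= start <= end <= n):
            raise LocusError(f"amplicon_window {self.amplicon_window} outside sequence 1..{n}")
        if start > t - v or end < t + 1:
            raise LocusError(
                f"amplicon_window {self.amplicon_window} does not span the cut "
                f"(need start <= {t - v} and end >= {t + 1})"
            )

    @property
    def n(self) -> int:
        return len(self.top_strand)


def end_sequences(locus: DsbLocus) -> Tuple[str, str, Tuple[str, str]]:
    """Return (left_end, right_end, (left_overhang, right_overhang)).

    The left end is the top strand through ``t``; its single-stranded portion
    is the terminal ``v`` bases.  The right end templates the top strand from
    ``t - v + 1`` onward via its bottom-strand overhang, which covers the same
    ``v`` reference positions as the left overhang — the two overhangs are
    therefore reverse-complementary by construction, which is what makes
    precise religation possible.  Overhangs are reported 5'->3'.
    """
    seq, t, v = locus.top_strand, locus.cut_pos, locus.overhang_len
    left_end = seq[:t]
    right_end = seq[t - v:]
    left_oh = seq[t - v:t]
    right_oh = reverse_complement(left_oh)
    return left_end, right_end, (left_oh, right_oh)


@dataclass(frozen=True)
class ReadLayout:
    """Structure of a forward sequencing read.

    ``index_len`` inline sample-index bases, then ``primer_len`` locus-specific
    primer bases, then amplicon sequence, for ``read_len`` bases total.  The
    defaults model a 100 bp read carrying a 6-base inline index.
    """

    index_len: int = 6
    primer_len: int = 0
    read_len: int = 100

    def __post_init__(self) -> None:
        if self.index_len < 1 or self.primer_len < 0 or self.read_len < 1:
            raise LocusError("index_len >= 1, primer_len >= 0, read_len >= 1 required")
        if self.index_len + self.primer_len >= self.read_len:
            raise LocusError(
                f"index_len + primer_len ({self.index_len + self.primer_len}) "
                f"must be < read_len ({self.read_len})"
            )

    @property
    def genomic_len(self) -> int:
        """Number of locus-derived bases in the read (primer included)."""
        return self.read_len - self.index_len


def read_ref_start(locus: DsbLocus, layout: ReadLayout) -> int:
    """1-based top-strand position of the first locus base in the read.

    The primer anneals immediately upstream of the amplicon window, so the
    genomic portion of the read starts ``primer_len`` bases before the window.
    """
    rs = locus.amplicon_window[0] - layout.primer_len
    if rs < 1:
        raise LocusError(
            f"primer_len={layout.primer_len} extends before the start of the "
            f"reference (amplicon window starts at {locus.amplicon_window[0]})"
        )
    if rs > locus.cut_pos - locus.overhang_len:
        raise LocusError("read must begin on the left of the cut")
    return rs


def load_locus(fasta_path: str | Path, geometry: Mapping) -> DsbLocus:
    """Read a single-record FASTA and build a validated :class:`DsbLocus`.

    ``geometry`` supplies ``cut_pos``, ``overhang_len``, ``amplicon_window``
    and optionally ``name`` and ``polarity`` (e.g. parsed from a YAML/JSON
    config block).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise LocusError(f"expected exactly one FASTA record in {fasta_path}, found {len(records)}")
    rec = records[0]
    window = tuple(geometry["amplicon_window"])
    return DsbLocus(
        name=str(geometry.get("name", rec.id)),
        top_strand=str(rec.seq),
        cut_pos=int(geometry["cut_pos"]),
        overhang_len=int(geometry["overhang_len"]),
        amplicon_window=(int(window[0]), int(window[1])),
        polarity=str(geometry.get("polarity", "3p")),
    )
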