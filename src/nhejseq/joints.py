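"""Enumeration and naming of candidate end-joining repair products.

Every repair product of a staggered cut that a short amplicon read can
identify is described by five fields:

* ``D`` — net base pairs gained (positive) or lost (negative) overall,
* ``M`` — microhomologous base pairs at the junction,
* ``L`` — bases deleted from the left end, measured from the most distal
  overhang base,
* ``R`` — same for the right end,
* ``I`` — non-templated inserted bases (0-2 nt), read from the top strand.

These satisfy the descriptor algebra ``D = v - L - R - M + |I|`` where ``v``
is the overhang length.  The precise religation product is ``L = R = 0,
M = v, I = ""`` and hence ``D = 0``.  With the reference top strand ``s``
(1-based) and cut position ``t``, the repaired top strand is::

    product = s[1 .. t-L] + I + s[t-v+R+M+1 .. N]

Microhomology is only meaningful when the ``M`` junction bases carried by the
left end are identical to the ``M`` bases the right end would otherwise
template (``s[t-L-M+1 .. t-L] == s[t-v+R+1 .. t-v+R+M]``): those bases anneal
and appear once in the product.  The same rule covers partially annealed
overhangs that are filled in by polymerase — the classic "+CA"-type joints —
whose unannealed overhang bases are duplicated, and the fully blunt fill-in
joint (``M = 0``, ``D = +v``) that duplicates the whole overhang.

Because a deduplicated product string can often be written several ways (a
one-base microhomology deletion is also a plain deletion shifted by one), each
product is assigned a canonical descriptor: maximal ``M``, then minimal
``|I|``, then minimal ``L`` — templated explanations beat non-templated ones
and identifiers are deterministic.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .locus import DsbLocus, ReadLayout, read_ref_start

PRECISE_ID = "precise"

_ID_RE = re.compile(r"^D(0|[+-]\d+)_M(\d+)_L(\d+)_R(\d+)(?:_I([ACGT]{1,2}))?$")


class JointError(ValueError):
    """Descriptor inconsistent with the locus geometry."""


class MicrohomologyMismatch(JointError):
    """The M junction bases are not identical between the two ends."""


class WindowError(JointError):
    """Enumeration limits push the junction or product outside the read."""


class UnexplainableProduct(JointError):
    """Product sequence not derivable from the two ends within the limits."""


@dataclass(frozen=True)
class JointDescriptor:
    """The (D, M, L, R, I) record naming one repair product."""

    net_change: int
    microhomology: int
    left_deleted: int
    right_deleted: int
    insertion: str = ""
    is_precise: bool = False

    def __post_init__(self) -> None:
        if min(self.microhomology, self.left_deleted, self.right_deleted) < 0:
            raise JointError("M, L and R must all be >= 0")
        if len(self.insertion) > 2:
            raise JointError(f"at most 2 inserted bases allowed, got {self.insertion!r}")
        if self.insertion and set(self.insertion) - set("ACGT"):
            raise JointError(f"insertion must be uppercase A/C/G/T, got {self.insertion!r}")
        if self.insertion and self.microhomology > 0:
            raise JointError("insertions are only modelled at M=0 (blunt-type) junctions")

    @classmethod
    def build(
        cls,
        overhang_len: int,
        microhomology: int = 0,
        left_deleted: int = 0,
        right_deleted: int = 0,
        insertion: str = "",
    ) -> "JointDescriptor":
        """Construct a descriptor, deriving D and the precise flag from v."""
        d = overhang_len - left_deleted - right_deleted - microhomology + len(insertion)
        precise = (
            left_deleted == 0
            and right_deleted == 0
            and microhomology == overhang_len
            and not insertion
        )
        return cls(d, microhomology, left_deleted, right_deleted, insertion, precise)


def precise_descriptor(locus: DsbLocus) -> JointDescriptor:
    return JointDescriptor.build(locus.overhang_len, microhomology=locus.overhang_len)


def product_sequence(desc: JointDescriptor, locus: DsbLocus) -> str:
    """Reconstruct the full repaired top strand for a descriptor.

    Raises :class:`MicrohomologyMismatch` when the claimed microhomology bases
    are not identical between the ends, and :class:`JointError` when L/R/M run
    off the sequence or the descriptor algebra is violated.
    """
    s, t, v = locus.top_strand, locus.cut_pos, locus.overhang_len
    m, l, r, ins = (
        desc.microhomology,
        desc.left_deleted,
        desc.right_deleted,
        desc.insertion,
    )
    expected_d = v - l - r - m + len(ins)
    if desc.net_change != expected_d:
        raise JointError(
            f"descriptor algebra violated: D={desc.net_change} but "
            f"v-L-R-M+|I| = {expected_d}"
        )
    if t - l - m < 0:
        raise JointError(f"L={l} with M={m} deletes past the left end of the sequence")
    if t - v + r < 0 or t - v + r + m > locus.n:
        raise JointError(f"R={r} with M={m} runs off the right end of the sequence")
    if m and s[t - l - m : t - l] != s[t - v + r : t - v + r + m]:
        raise MicrohomologyMismatch(
            f"M={m} junction bases differ between ends: left "
            f"{s[t - l - m: t - l]!r} vs right {s[t - v + r: t - v + r + m]!r}"
        )
    return s[: t - l] + ins + s[t - v + r + m :]


def encode_joint_id(desc: JointDescriptor) -> str:
    """Render a descriptor as a canonical text identifier.

    The precise religation joint encodes as ``"precise"``; every other joint
    as ``D{+n|-n|0}_M{m}_L{l}_R{r}`` with ``_I{seq}`` appended when inserted
    bases are present.
    """
    if desc.is_precise:
        return PRECISE_ID
    d = desc.net_change
    d_str = f"{d:+d}" if d else "0"
    out = f"D{d_str}_M{desc.microhomology}_L{desc.left_deleted}_R{desc.right_deleted}"
    if desc.insertion:
        out += f"_I{desc.insertion}"
    return out


def decode_joint_id(text: str, overhang_len: int | None = None) -> JointDescriptor:
    """Parse a joint identifier back into a descriptor.

    ``"precise"`` carries no field values, so decoding it requires the
    overhang length of the locus it refers to.
    """
    if text == PRECISE_ID:
        if overhang_len is None:
            raise JointError("decoding 'precise' requires the locus overhang length")
        return precise_descriptor_from_v(overhang_len)
    match = _ID_RE.match(text)
    if not match:
        raise JointError(f"malformed joint identifier {text!r}")
    d, m, l, r, ins = match.groups()
    desc = JointDescriptor(int(d), int(m), int(l), int(r), ins or "", is_precise=False)
    if overhang_len is not None:
        expected = overhang_len - desc.left_deleted - desc.right_deleted - desc.microhomology
        expected += len(desc.insertion)
        if desc.net_change != expected:
            raise JointError(f"identifier {text!r} violates D = v - L - R - M + |I| for v={overhang_len}")
    return desc


def precise_descriptor_from_v(overhang_len: int) -> JointDescriptor:
    return JointDescriptor.build(overhang_len, microhomology=overhang_len)


@dataclass(frozen=True)
class JointLimits:
    """Bounds on the enumerated joint space.

    The read must still cover the junction, so the effective deletion range is
    additionally bounded by the amplicon window.  No deletion bound is implied
    by the chemistry itself; the defaults are simply generous enough that any
    junction a 100 bp read can identify is enumerated.
    """

    left_max: int = 25
    right_max: int = 25
    mh_max: int = 10
    insertion_max: int = 2
    insertion_alphabet: str = "ACGT"

    def insertions(self) -> Iterable[str]:
        for length in range(1, self.insertion_max + 1):
            for combo in itertools.product(sorted(self.insertion_alphabet), repeat=length):
                yield "".join(combo)


@dataclass(frozen=True)
class JointTemplate:
    """A descriptor paired with its reconstructed product and read sequence."""

    descriptor: JointDescriptor
    joint_id: str
    product: str
    read_template: str
    junction_offset: int  # 0-based read position of the first base after the left segment


def build_template(desc: JointDescriptor, locus: DsbLocus, layout: ReadLayout) -> JointTemplate:
    """Construct the expected read for a joint: index placeholder + primer +
    product restricted to the amplicon window, truncated to ``read_len``."""
    product = product_sequence(desc, locus)
    rs = read_ref_start(locus, layout)  # 1-based, identical in product coords (left of cut)
    genomic = product[rs - 1 : rs - 1 + layout.genomic_len]
    joint_id = encode_joint_id(desc)
    if len(genomic) < layout.genomic_len:
        raise WindowError(
            f"joint {joint_id}: product too short for the read window "
            f"(need {layout.genomic_len} bases from position {rs}, have {len(genomic)})"
        )
    junction_offset = layout.index_len + (locus.cut_pos - desc.left_deleted - rs + 1)
    if junction_offset <= layout.index_len:
        raise WindowError(f"joint {joint_id}: left deletion L={desc.left_deleted} pushes the junction before the read start")
    if junction_offset + 3 + len(desc.insertion) > layout.read_len:
        raise WindowError(
            f"joint {joint_id}: junction at read offset {junction_offset} is not "
            f"covered with 3 flanking bases inside a {layout.read_len}-base read"
        )
    return JointTemplate(
        descriptor=desc,
        joint_id=joint_id,
        product=product,
        read_template="N" * layout.index_len + genomic,
        junction_offset=junction_offset,
    )


def _canonical_rank(desc: JointDescriptor) -> tuple:
    # max M, then min |I|, then min L; trailing fields only break exact ties
    return (
        -desc.microhomology,
        len(desc.insertion),
        desc.left_deleted,
        desc.right_deleted,
        desc.insertion,
    )


def _descriptor_candidates(locus: DsbLocus, limits: JointLimits) -> Iterable[JointDescriptor]:
    v = locus.overhang_len
    for l in range(limits.left_max + 1):
        for r in range(limits.right_max + 1):
            for m in range(limits.mh_max + 1):
                yield JointDescriptor.build(v, m, l, r)
            for ins in limits.insertions():
                yield JointDescriptor.build(v, 0, l, r, ins)


def enumerate_joints(
    locus: DsbLocus,
    layout: ReadLayout,
    limits: JointLimits = JointLimits(),
) -> tuple[JointTemplate, ...]:
    """Enumerate every candidate repair product supported by the two ends.

    Returns a deduplicated (by product sequence) tuple of templates sorted by
    joint identifier.  Each product carries its canonical descriptor, and the
    precise religation joint is always present.  Limits that push any junction
    outside the read raise :class:`WindowError` naming the offending joint.
    """
    best: dict[str, JointDescriptor] = {}
    for desc in _descriptor_candidates(locus, limits):
        try:
            product = product_sequence(desc, locus)
        except MicrohomologyMismatch:
            continue
        except JointError:
            # deletion bounds beyond the sequence: genuinely impossible joints
            continue
        prev = best.get(product)
        if prev is None or _canonical_rank(desc) < _canonical_rank(prev):
            best[product] = desc
    templates = [build_template(desc, locus, layout) for desc in best.values()]
    templates.sort(key=lambda tm: tm.joint_id)
    return tuple(templates)


def canonical_descriptor(
    product: str,
    locus: DsbLocus,
    limits: JointLimits = JointLimits(),
) -> JointDescriptor:
    """Find the canonical descriptor explaining a product sequence.

    Searches all (L, R, M, I) within the limits whose reconstruction equals
    ``product`` and applies the canonical tie-break.  Raises
    :class:`UnexplainableProduct` if none match.
    """
    s, t, v, n = locus.top_strand, locus.cut_pos, locus.overhang_len, locus.n
    d = len(product) - n
    candidates = []
    for l in range(min(limits.left_max, t) + 1):
        if product[: t - l] != s[: t - l]:
            continue
        for r in range(limits.right_max + 1):
            for m in range(limits.mh_max + 1):
                ilen = d - v + l + r + m
                if ilen < 0 or ilen > limits.insertion_max:
                    continue
                if ilen and m:
                    continue
                desc = JointDescriptor.build(v, m, l, r, product[t - l : t - l + ilen])
                try:
                    if product_sequence(desc, locus) == product:
                        candidates.append(desc)
                except JointError:
                    continue
    if not candidates:
        raise UnexplainableProduct(
            f"product of length {len(product)} not derivable from the ends of "
            f"locus {locus.name!r} within {limits}"
        )
    return min(candidates, key=_canonical_rank)


def alias_moore_haber(desc: JointDescriptor, locus: DsbLocus) -> str | None:
    """Classical short alias for simple joints: ``+<dup>`` / ``-<deleted>``.

    Pure fill-in duplications (``L = R = 0``, ``I`` empty, ``0 < M < v``) are
    named by the duplicated overhang bases; pure deletions (``D < 0``, ``I``
    empty) by the deleted bases when that string is unambiguous.  Everything
    else (precise joints, insertions, composite events) has no alias.
    """
    s, t, v = locus.top_strand, locus.cut_pos, locus.overhang_len
    if desc.is_precise or desc.insertion:
        return None
    if desc.left_deleted == 0 and desc.right_deleted == 0 and 0 < desc.microhomology < v:
        dup = s[t - v + desc.microhomology : t]
        return "+" + dup
    if desc.net_change < 0:
        deleted = _deleted_strings(desc, locus)
        if len(deleted) == 1:
            return "-" + deleted.pop()
    return None


def _deleted_strings(desc: JointDescriptor, locus: DsbLocus) -> set[str]:
    """Deleted substrings over every deletion-only explanation of the product."""
    product = product_sequence(desc, locus)
    s, t, v = locus.top_strand, locus.cut_pos, locus.overhang_len
    span = -desc.net_change + v  # L + R + M for any empty-insertion explanation
    out: set[str] = set()
    for l in range(min(span, t) + 1):
        for r in range(span - l + 1):
            m = span - l - r
            d2 = JointDescriptor.build(v, m, l, r)
            try:
                if product_sequence(d2, locus) == product:
                    out.add(s[t - l : t - v + r + m])
            except JointError:
                continue
    return out


def joint_table(templates: Sequence[JointTemplate]) -> pd.DataFrame:
    """Tabulate an enumerated joint space (one row per joint)."""
    rows = []
    for tm in templates:
        d = tm.descriptor
        rows.append(
            {
                "joint_id": tm.joint_id,
                "D": d.net_change,
                "M": d.microhomology,
                "L": d.left_deleted,
                "R": d.right_deleted,
                "I": d.insertion,
                "product_length": len(tm.product),
                "read_template": tm.read_template,
            }
        )
    return pd.DataFrame(rows).set_index("joint_id")


def write_joint_table(templates: Sequence[JointTemplate], path) -> None:
    joint_table(templates).to_csv(path, sep="\t")


def write_templates_fasta(templates: Sequence[JointTemplate], path) -> None:
    with open(path, "w") as fh:
        for tm in templates:
            fh.write(f">{tm.joint_id}\n{tm.read_template}\n")
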