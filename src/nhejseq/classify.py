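"""Demultiplexing, contaminant filtering and joint assignment of reads.

Reads carry an inline sample index at their 5' end, then locus sequence
crossing the cut site.  Classification is purely substitution-based: because
every insertion/deletion joint is represented as its own full-length read
template, a read is compared to each template by Hamming distance over the
non-index bases and no gapped alignment is ever needed.  A read matching
exactly one template within the mismatch tolerance is assigned to that joint;
a read whose best match is tied between templates is ambiguous; a read
matching none is unmatched.  Control-library (PhiX-type) reads are removed up front by
a shared-k-mer filter.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .joints import JointTemplate
from .locus import DsbLocus, ReadLayout, reverse_complement

logger = logging.getLogger(__name__)

#: special CountTable rows that are not repair joints
SPECIAL_ROWS = ("ambiguous", "unmatched", "contaminant")

UNASSIGNED = "unassigned_index"

CATEGORY_JOINT = "joint"
CATEGORY_AMBIGUOUS = "ambiguous"
CATEGORY_UNMATCHED = "unmatched"
CATEGORY_CONTAMINANT = "contaminant"


class ClassifyError(ValueError):
    pass


@dataclass(frozen=True)
class SampleIndexTable:
    """Mapping from inline index sequence to sample label."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ClassifyError("empty sample index table")
        lengths = {len(ix) for ix in self.mapping}
        if len(lengths) != 1:
            raise ClassifyError(f"indexes must all have the same length, got lengths {sorted(lengths)}")
        for ix in self.mapping:
            if set(ix) - set("ACGT"):
                raise ClassifyError(f"index {ix!r} contains non-ACGT characters")
        labels = list(self.mapping.values())
        if len(set(labels)) != len(labels):
            raise ClassifyError("sample labels must be unique")
        indexes = list(self.mapping)
        for i, a in enumerate(indexes):
            for b in indexes[i + 1 :]:
                if sum(x != y for x, y in zip(a, b)) < 2:
                    warnings.warn(
                        f"indexes {a} and {b} differ by fewer than 2 bases; a single "
                        "sequencing error can swap samples",
                        stacklevel=2,
                    )

    @property
    def index_len(self) -> int:
        return len(next(iter(self.mapping)))

    @property
    def samples(self) -> list[str]:
        return sorted(self.mapping.values())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleIndexTable":
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                index, sample = line.split("\t")[:2]
                if index in mapping:
                    raise ClassifyError(f"duplicate index {index!r} in {path}")
                mapping[index] = sample
        return cls(mapping)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for index, sample in self.mapping.items():
                fh.write(f"{index}\t{sample}\n")


def demultiplex(seq: str, table: SampleIndexTable, layout: ReadLayout) -> str:
    """Exact-match the leading index bases; anything else is unassigned.

    Six-base indexes are short, so no mismatch tolerance is applied — a read
    with a sequencing error in its index is conservatively dropped rather than
    risking sample swaps.
    """
    if not seq:
        raise ClassifyError("empty read")
    return table.mapping.get(seq[: layout.index_len], UNASSIGNED)


class KmerContaminantFilter:
    """Flag reads sharing a large fraction of k-mers with a contaminant.

    The reference's k-mers (both strands) are hashed once; a read is called
    contaminant when at least ``threshold`` of its k-mers occur in that set.
    This replaces an external aligner for the simple task of removing a
    spiked-in control library whose sequence is unrelated to the locus.
    """

    def __init__(self, reference: str, k: int = 21, threshold: float = 0.5):
        if k < 11:
            raise ClassifyError(f"k must be >= 11 for specificity, got {k}")
        if not reference:
            raise ClassifyError("empty contaminant reference")
        if not 0 < threshold <= 1:
            raise ClassifyError(f"threshold must be in (0, 1], got {threshold}")
        self.k = k
        self.threshold = threshold
        self._kmers: set[str] = set()
        for strand in (reference, reverse_complement(reference)):
            for i in range(len(strand) - k + 1):
                self._kmers.add(strand[i : i + k])

    @classmethod
    def from_fasta(cls, path: str | Path, k: int = 21, threshold: float = 0.5) -> "KmerContaminantFilter":
        seq = "".join(str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta"))
        return cls(seq, k=k, threshold=threshold)

    def shared_fraction(self, seq: str) -> float:
        n = len(seq) - self.k + 1
        if n < 1:
            raise ClassifyError(f"read shorter than k={self.k}")
        hits = sum(seq[i : i + self.k] in self._kmers for i in range(n))
        return hits / n

    def __call__(self, seq: str) -> bool:
        return self.shared_fraction(seq) >= self.threshold


@dataclass(frozen=True)
class ReadAssignment:
    """Outcome of classifying a single read."""

    read_id: str
    sample: str
    category: str
    joint_id: str | None = None
    mismatches: int | None = None


def _template_hits(
    genomic: str,
    templates: Sequence[JointTemplate],
    layout: ReadLayout,
    max_mismatch: int,
) -> list[tuple[int, JointTemplate]]:
    hits = []
    for tm in templates:
        tg = tm.read_template[layout.index_len :]
        jg = tm.junction_offset - layout.index_len
        if len(genomic) < jg + 4:  # junction plus 3 flanking bases must be covered
            continue
        n = min(len(genomic), len(tg))
        dist = sum(a != b for a, b in zip(genomic[:n], tg[:n]))
        if dist <= max_mismatch:
            hits.append((dist, tm))
    return hits


def classify_read(
    seq: str,
    templates: Sequence[JointTemplate],
    layout: ReadLayout,
    max_mismatch: int = 1,
    read_id: str = "",
    sample: str = "",
) -> ReadAssignment:
    """Assign one read to a joint, or call it ambiguous/unmatched.

    The index bases are masked from mismatch counting.  Among templates within
    the mismatch tolerance the unique best (lowest-distance) hit wins; a tie
    for best is ambiguous.  Best-hit rather than any-hit resolution is needed
    because a rich joint space always contains deletion-plus-insertion joints
    one substitution away from the precise product — an exact read would
    otherwise never be assignable.  Reads shorter than ``read_len`` are
    compared over their length but must still cover the junction plus 3 bases
    on each side; template order never affects the call.
    """
    if not templates:
        raise ClassifyError("no joint templates supplied")
    genomic = seq[layout.index_len : layout.read_len]
    hits = _template_hits(genomic, templates, layout, max_mismatch)
    if not hits:
        return ReadAssignment(read_id, sample, CATEGORY_UNMATCHED)
    best = min(dist for dist, _ in hits)
    winners = [tm for dist, tm in hits if dist == best]
    if len(winners) > 1:
        return ReadAssignment(read_id, sample, CATEGORY_AMBIGUOUS)
    return ReadAssignment(read_id, sample, CATEGORY_JOINT, winners[0].joint_id, best)


def _open_maybe_gzip(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class _TemplateMatrix:
    """Vectorised Hamming comparison of full-length reads to all templates."""

    def __init__(self, templates: Sequence[JointTemplate], layout: ReadLayout):
        self.templates = list(templates)
        self.layout = layout
        self.matrix = np.vstack(
            [_encode(tm.read_template[layout.index_len :]) for tm in self.templates]
        )

    def classify(self, genomic_rows: np.ndarray, max_mismatch: int):
        """Return (category codes, joint indexes) for a block of reads.

        Codes: 0 joint, 1 ambiguous, 2 unmatched.
        """
        n_reads = genomic_rows.shape[0]
        dists = np.empty((n_reads, len(self.templates)), dtype=np.int32)
        for j in range(len(self.templates)):
            dists[:, j] = (genomic_rows != self.matrix[j]).sum(axis=1)
        best = dists.min(axis=1)
        n_best = (dists == best[:, None]).sum(axis=1)
        codes = np.full(n_reads, 2, dtype=np.int8)
        hit = best <= max_mismatch
        codes[hit & (n_best == 1)] = 0
        codes[hit & (n_best > 1)] = 1
        joint_idx = dists.argmin(axis=1)
        return codes, joint_idx


def classify_batch(
    fastq_path: str | Path,
    templates: Sequence[JointTemplate],
    index_table: SampleIndexTable,
    layout: ReadLayout,
    contaminant: KmerContaminantFilter | None = None,
    max_mismatch: int = 1,
    chunk_size: int = 4000,
) -> tuple[pd.DataFrame, dict]:
    """Classify every read of a FASTQ into a joints-by-samples count table.

    Processing order mirrors the experimental logic: contaminant reads are
    removed first (they carry no meaningful index), remaining reads are
    demultiplexed by exact index match, then assigned to joints.  The count
    table has one row per joint plus the special rows ``ambiguous``,
    ``unmatched`` and ``contaminant``; reads whose index matches no sample are
    tallied in ``run_stats`` only.  Read conservation holds exactly::

        table.sum() + unassigned_index + contaminant_unassigned + truncated
            == total_reads
    """
    if index_table.index_len != layout.index_len:
        raise ClassifyError(
            f"index table uses {index_table.index_len}-base indexes but layout "
            f"expects {layout.index_len}"
        )
    samples = index_table.samples
    rows = [tm.joint_id for tm in templates] + list(SPECIAL_ROWS)
    counts = pd.DataFrame(0, index=rows, columns=samples, dtype=np.int64)
    matrix = _TemplateMatrix(templates, layout)
    stats = {
        "total_reads": 0,
        "contaminant": 0,
        "contaminant_unassigned": 0,
        "unassigned_index": 0,
        "truncated": 0,
    }
    joint_ids = [tm.joint_id for tm in templates]

    chunk_rows: list[np.ndarray] = []
    chunk_samples: list[str] = []

    def flush() -> None:
        if not chunk_rows:
            return
        block = np.vstack(chunk_rows)
        codes, joint_idx = matrix.classify(block, max_mismatch)
        for code, jix, sample in zip(codes, joint_idx, chunk_samples):
            if code == 0:
                counts.loc[joint_ids[jix], sample] += 1
            elif code == 1:
                counts.loc["ambiguous", sample] += 1
            else:
                counts.loc["unmatched", sample] += 1
        chunk_rows.clear()
        chunk_samples.clear()

    with _open_maybe_gzip(fastq_path) as fh:
        for read_id, seq, _qual in FastqGeneralIterator(fh):
            stats["total_reads"] += 1
            if stats["total_reads"] % 1_000_000 == 0:
                logger.info("processed %d reads", stats["total_reads"])
            seq = seq.upper()
            if contaminant is not None and len(seq) >= contaminant.k and contaminant(seq):
                sample = demultiplex(seq, index_table, layout)
                stats["contaminant"] += 1
                if sample == UNASSIGNED:
                    stats["contaminant_unassigned"] += 1
                else:
                    counts.loc["contaminant", sample] += 1
                continue
            if len(seq) <= layout.index_len:
                stats["truncated"] += 1
                continue
            sample = demultiplex(seq, index_table, layout)
            if sample == UNASSIGNED:
                stats["unassigned_index"] += 1
                continue
            if len(seq) >= layout.read_len:
                chunk_rows.append(_encode(seq[layout.index_len : layout.read_len]))
                chunk_samples.append(sample)
                if len(chunk_rows) >= chunk_size:
                    flush()
            else:
                assignment = classify_read(seq, templates, layout, max_mismatch)
                row = assignment.joint_id if assignment.category == CATEGORY_JOINT else assignment.category
                counts.loc[row, sample] += 1
    flush()

    stats["per_sample_totals"] = counts.sum(axis=0).to_dict()
    accounted = (
        int(counts.to_numpy().sum())
        + stats["unassigned_index"]
        + stats["contaminant_unassigned"]
        + stats["truncated"]
    )
    stats["conservation_ok"] = accounted == stats["total_reads"]
    return counts, stats
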