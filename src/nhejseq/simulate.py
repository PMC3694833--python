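"""Synthetic amplicon datasets with known ground truth.

Generates FASTQ files with the statistical structure the analysis assumes —
a joint spectrum over an enumerated joint space, inline 6-base sample
indexes, i.i.d. per-base substitution error, and a contaminant (control
library) spike-in — together with the exact planted counts, so every
pipeline stage can be tested end to end without any external data.

The built-in spectra emulate the canonical single-cut recleavage experiment:
before nuclease induction essentially every read is the intact cut site
(precise fraction >= 0.98); after 24 hours of continuous recleavage a
repair-proficient strain accumulates ~40% imprecise joints with a long-tailed
profile dominated by a handful of major joints; a ligase-IV-deletion strain
stays ~97% precise.  A catalytic-point-mutant spectrum shares the wild-type
profile but with planted fold changes on individual joints in both
directions, giving the differential stage a known answer key.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .joints import PRECISE_ID, JointLimits, JointTemplate, enumerate_joints
from .locus import DsbLocus, ReadLayout

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

SPECTRUM_KINDS = ("pre_induction", "wt_24h", "k466a_24h", "dnl4del_24h")

#: imprecise mass per kind; the 24 h repair-proficient strains sit at 40%
IMPRECISE_MASS = {
    "pre_induction": 0.005,
    "wt_24h": 0.40,
    "k466a_24h": 0.40,
    "dnl4del_24h": 0.03,
}

#: concentration of the symmetric Dirichlet spreading the imprecise mass;
#: 0.3 yields the long-tailed, few-major-joints profile seen in real spectra
DIRICHLET_CONCENTRATION = 0.3

#: planted fold change applied to alternating major joints in the mutant kind
PLANTED_FOLD = 6.0
N_PLANTED_EACH_WAY = 6
#: first weight rank carrying a planted fold change; skipping the very largest
#: joints keeps the renormalisation mild so realised ratios stay near the fold
PLANT_RANK_START = 4
#: minimum base weight (share of the imprecise mass) of a planted joint, so
#: every planted change sits on a major joint as in the assay this emulates
PLANT_WEIGHT_FLOOR = 0.01


class SimulateError(ValueError):
    pass


def _encode_seq(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def synthetic_contaminant(length: int = 5000, seed: int = 7) -> str:
    """A seeded random DNA sequence standing in for a spiked control library.

    Synthetic: this is not the real PhiX genome, just an unrelated sequence
    with the same role in tests and simulations.
    """
    rng = np.random.default_rng(seed)
    return _decode(rng.integers(0, 4, size=length).astype(np.uint8))


def default_indexes(samples: Sequence[str], seed: int = 11, length: int = 6) -> dict[str, str]:
    """Assign each sample a random index, pairwise Hamming distance >= 2."""
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    out: dict[str, str] = {}
    for sample in samples:
        for _ in range(10000):
            ix = _decode(rng.integers(0, 4, size=length).astype(np.uint8))
            if all(sum(a != b for a, b in zip(ix, prev)) >= 2 for prev in chosen):
                chosen.append(ix)
                out[sample] = ix
                break
        else:  # pragma: no cover - would need absurdly many samples
            raise SimulateError("could not find enough well-separated indexes")
    return out


@dataclass(frozen=True)
class SpectrumConfig:
    """Complete description of one simulated sequencing run.

    ``sample_frequencies`` maps sample label -> {joint_id -> frequency}; each
    sample's frequencies must sum to 1.  ``reads_per_sample`` may be a single
    integer applied to every sample or a per-sample mapping.  The seed is
    mandatory: every simulated dataset is reproducible by construction.
    """

    locus: DsbLocus
    sample_frequencies: Mapping[str, Mapping[str, float]]
    reads_per_sample: int | Mapping[str, int]
    sample_indexes: Mapping[str, str]
    seed: int
    error_rate: float = 0.0
    contaminant_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate <= 0.1:
            raise SimulateError(f"error_rate must be in [0, 0.1], got {self.error_rate}")
        if not 0 <= self.contaminant_fraction < 1:
            raise SimulateError("contaminant_fraction must be in [0, 1)")
        for sample, freqs in self.sample_frequencies.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise SimulateError(f"frequencies for {sample} sum to {total}, not 1")
            if any(f < 0 for f in freqs.values()):
                raise SimulateError(f"negative frequency in {sample}")
            if sample not in self.sample_indexes:
                raise SimulateError(f"no index assigned to sample {sample}")

    def reads_for(self, sample: str) -> int:
        if isinstance(self.reads_per_sample, int):
            return self.reads_per_sample
        return int(self.reads_per_sample[sample])


def template_separations(templates: Sequence[JointTemplate], layout: ReadLayout) -> np.ndarray:
    """Minimum Hamming distance from each template to any other template."""
    mat = np.vstack([_encode_seq(tm.read_template[layout.index_len :]) for tm in templates])
    n = len(templates)
    out = np.full(n, np.iinfo(np.int32).max, dtype=np.int32)
    for i in range(n):
        d = (mat != mat[i]).sum(axis=1)
        d[i] = np.iinfo(np.int32).max
        out[i] = d.min()
    return out


def separable_joints(
    templates: Sequence[JointTemplate],
    layout: ReadLayout,
    min_separation: int = 3,
) -> list[str]:
    """Imprecise joints whose template is well separated from every other.

    Under best-hit classification error-free reads are always uniquely
    assigned, but sequencing errors can convert a read into an exact match of
    a template ``min_separation - 2`` away; joints listed here are immune to
    that cross-talk at one mismatch of tolerance.  Note that an exhaustively
    enumerated space with insertions leaves few joints fully separable —
    deletion joints always have deletion-plus-insertion variants one
    substitution away.
    """
    sep = template_separations(templates, layout)
    return [
        tm.joint_id
        for tm, s in zip(templates, sep)
        if s >= min_separation and tm.joint_id != PRECISE_ID
    ]


def make_spectrum(
    kind: str,
    locus: DsbLocus,
    seed: int,
    layout: ReadLayout = ReadLayout(),
    templates: Sequence[JointTemplate] | None = None,
    limits: JointLimits = JointLimits(left_max=6, right_max=6, mh_max=4),
    n_imprecise: int = 40,
    reads: int = 20000,
    error_rate: float = 0.0,
    contaminant_fraction: float = 0.0,
) -> SpectrumConfig:
    """Build a single-sample spectrum of the requested kind.

    The imprecise profile is a seeded symmetric Dirichlet draw over a seeded
    random subset of up to ``n_imprecise`` enumerated imprecise joints.  All kinds share the same base
    profile for a given seed, so ``wt_24h`` and ``k466a_24h`` spectra built
    with the same seed form a comparable pair: the mutant multiplies
    alternating major joints by ``PLANTED_FOLD`` up or down before
    renormalising its imprecise mass.
    """
    if kind not in SPECTRUM_KINDS:
        raise SimulateError(f"unknown spectrum kind {kind!r}; choose from {SPECTRUM_KINDS}")
    if templates is None:
        templates = enumerate_joints(locus, layout, limits)
    candidates = [tm.joint_id for tm in templates if tm.joint_id != PRECISE_ID]
    if not candidates:
        raise SimulateError("no imprecise joints available for a spectrum")
    rng = np.random.default_rng(seed)  # same base profile for every kind
    chosen = list(rng.choice(candidates, size=min(n_imprecise, len(candidates)), replace=False))
    weights = rng.dirichlet(np.full(len(chosen), DIRICHLET_CONCENTRATION))
    order = np.argsort(weights)[::-1]
    chosen = [chosen[i] for i in order]
    weights = weights[order]
    # identical in every kind for a given seed: lift the to-be-planted joints
    # to major-joint weight so differential changes are always well counted
    plant = slice(PLANT_RANK_START, PLANT_RANK_START + 2 * N_PLANTED_EACH_WAY)
    weights[plant] = np.maximum(weights[plant], PLANT_WEIGHT_FLOOR)
    weights = weights / weights.sum()
    if kind == "k466a_24h":
        # plant alternating up/down fold changes on mid-ranked major joints
        for i in range(2 * N_PLANTED_EACH_WAY):
            rank = PLANT_RANK_START + i
            if rank >= len(weights):
                break
            weights[rank] *= PLANTED_FOLD if i % 2 == 0 else 1.0 / PLANTED_FOLD
        weights = weights / weights.sum()
    imprecise_mass = IMPRECISE_MASS[kind]
    freqs = {PRECISE_ID: 1.0 - imprecise_mass}
    for joint_id, w in zip(chosen, weights):
        freqs[joint_id] = imprecise_mass * float(w)
    # absorb float round-off into the precise mass
    freqs[PRECISE_ID] += 1.0 - sum(freqs.values())
    return SpectrumConfig(
        locus=locus,
        sample_frequencies={kind: freqs},
        reads_per_sample=reads,
        sample_indexes=default_indexes([kind]),
        seed=seed,
        error_rate=error_rate,
        contaminant_fraction=contaminant_fraction,
    )


def merge_configs(configs: Sequence[SpectrumConfig], sample_names: Sequence[str], seed: int) -> SpectrumConfig:
    """Combine single-sample configs into one multi-sample run."""
    freqs: dict[str, Mapping[str, float]] = {}
    reads: dict[str, int] = {}
    for cfg, name in zip(configs, sample_names):
        (only,) = cfg.sample_frequencies
        freqs[name] = cfg.sample_frequencies[only]
        reads[name] = cfg.reads_for(only)
    first = configs[0]
    return SpectrumConfig(
        locus=first.locus,
        sample_frequencies=freqs,
        reads_per_sample=reads,
        sample_indexes=default_indexes(list(sample_names)),
        seed=seed,
        error_rate=first.error_rate,
        contaminant_fraction=first.contaminant_fraction,
    )


def _mutate(codes: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    if error_rate <= 0:
        return codes
    mask = rng.random(codes.shape) < error_rate
    shift = rng.integers(1, 4, size=codes.shape).astype(np.uint8)
    out = codes.copy()
    out[mask] = (out[mask] + shift[mask]) % 4
    return out


def simulate_reads(
    config: SpectrumConfig,
    layout: ReadLayout,
    out_fastq,
    templates: Sequence[JointTemplate] | None = None,
    contaminant_ref: str | None = None,
) -> pd.DataFrame:
    """Write a FASTQ for the configured samples; return the planted truth.

    Per sample, the contaminant read count is ``round(fraction x reads)`` and
    the remainder is a multinomial draw over the sample's joint frequencies —
    the returned table holds those exact planted counts (joints as rows, plus
    a ``contaminant`` row).  Reads are the sample index plus the joint's read
    template with i.i.d. substitution errors over the whole read, index
    included; contaminant reads are random windows of the contaminant
    reference on either strand.  Fully deterministic given the config seed.
    """
    if templates is None:
        templates = enumerate_joints(config.locus, layout, JointLimits(left_max=6, right_max=6, mh_max=4))
    by_id = {tm.joint_id: tm for tm in templates}
    rng = np.random.default_rng(config.seed)
    if config.contaminant_fraction > 0:
        if contaminant_ref is None:
            contaminant_ref = synthetic_contaminant()
        cont_fwd = _encode_seq(contaminant_ref)
        cont_rev = 3 - cont_fwd[::-1]

    samples = list(config.sample_frequencies)
    truth = pd.DataFrame(
        0,
        index=[tm.joint_id for tm in templates] + ["contaminant"],
        columns=samples,
        dtype=np.int64,
    )
    all_rows: list[np.ndarray] = []
    for sample in samples:
        freqs = config.sample_frequencies[sample]
        n_total = config.reads_for(sample)
        n_cont = int(round(config.contaminant_fraction * n_total))
        n_joint = n_total - n_cont
        joint_ids = list(freqs)
        missing = [j for j in joint_ids if j not in by_id]
        if missing:
            raise SimulateError(f"spectrum joints not covered by templates: {missing[:5]}")
        probs = np.array([freqs[j] for j in joint_ids], dtype=float)
        counts = rng.multinomial(n_joint, probs / probs.sum())
        index_codes = _encode_seq(config.sample_indexes[sample])
        for joint_id, count in zip(joint_ids, counts):
            truth.loc[joint_id, sample] = int(count)
            if count == 0:
                continue
            tmpl = np.concatenate(
                [index_codes, _encode_seq(by_id[joint_id].read_template[layout.index_len :])]
            )
            rows = np.tile(tmpl, (count, 1))
            all_rows.append(_mutate(rows, config.error_rate, rng))
        if n_cont:
            truth.loc["contaminant", sample] = n_cont
            starts = rng.integers(0, len(cont_fwd) - layout.read_len + 1, size=n_cont)
            strands = rng.integers(0, 2, size=n_cont)
            rows = np.empty((n_cont, layout.read_len), dtype=np.uint8)
            for i, (s, st) in enumerate(zip(starts, strands)):
                src = cont_fwd if st == 0 else cont_rev
                rows[i] = src[s : s + layout.read_len]
            all_rows.append(_mutate(rows, config.error_rate, rng))

    reads = np.vstack(all_rows) if all_rows else np.empty((0, layout.read_len), dtype=np.uint8)
    order = rng.permutation(reads.shape[0])
    qual = "I" * layout.read_len
    opener = open
    if str(out_fastq).endswith(".gz"):
        import gzip

        opener = lambda p, m: gzip.open(p, m)  # noqa: E731
    with opener(str(out_fastq), "wt") as fh:
        for i, row_ix in enumerate(order):
            fh.write(f"@sim_{i:07d}\n{_decode(reads[row_ix])}\n+\n{qual}\n")
    return truth


def simulate_count_table(
    sample_frequencies: Mapping[str, Mapping[str, float]],
    library_sizes: Mapping[str, int],
    dispersion: float,
    seed: int,
) -> pd.DataFrame:
    """Draw a joints-by-samples count table with NB noise.

    Each count is NB with mean ``library_size x frequency`` and the given
    dispersion (``variance = mu + dispersion x mu^2``); ``dispersion = 0``
    gives Poisson counts.  Deterministic given the seed.
    """
    if dispersion < 0:
        raise SimulateError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    joints = sorted({j for freqs in sample_frequencies.values() for j in freqs})
    table = pd.DataFrame(0, index=joints, columns=list(sample_frequencies), dtype=np.int64)
    for sample, freqs in sample_frequencies.items():
        lib = library_sizes[sample]
        mu = np.array([lib * freqs.get(j, 0.0) for j in joints], dtype=float)
        if dispersion > 0:
            size = 1.0 / dispersion
            prob = size / (size + np.where(mu > 0, mu, 1.0))
            draw = rng.negative_binomial(size, prob)
            draw[mu == 0] = 0
        else:
            draw = rng.poisson(mu)
        table[sample] = draw
    return table
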