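"""Synthetic single-end amplicon read simulator with known ground truth.

Emits FASTQ samples drawn from a mixture of outcome classes — unmodified,
HDR (donor SNPs incorporated), indel (one insertion or deletion anchored in
the quantification window), HDR+indel, and donor-oligo contamination — plus
uniform per-base substitution errors, so the alignment/classification and
quantification stages can be tested against exact truth labels without any
real sequencing deposit.

Reads are full effective amplicons (amplicons longer than 270 nt are trimmed
to 250 nt around the window, matching 230-270 nt single-end sequencing) with
constant quality 'I'; contamination reads are bare donor oligos, the in-silico
analogue of the donor ssODN acting as a PCR primer, which downstream analysis
must remove (the study removed them physically by size selection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .locus import (
    AmpliconLocus,
    DonorTemplate,
    apply_hdr,
    rebase_donor,
    trim_to_read_length,
)

__all__ = [
    "IndelSizeLaw",
    "OutcomeMix",
    "IndelEvent",
    "TruthRecord",
    "SimulatedSample",
    "apply_hdr",
    "apply_indel",
    "apply_sequencing_errors",
    "simulate_sample",
    "write_fastq",
    "write_truth",
    "read_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
LABELS = ("unmodified", "hdr", "indel", "hdr_and_indel", "contamination")


@dataclass(frozen=True)
class IndelSizeLaw:
    """Indel size/type model: deletion vs insertion equiprobable by default,
    sizes geometric (support 1, 2, ...) with the given mean, clipped at
    ``max_size``."""

    p_deletion: float = 0.5
    mean_size: float = 3.0
    max_size: int = 20

    def draw(self, rng: np.random.Generator) -> tuple[str, int]:
        kind = "deletion" if rng.random() < self.p_deletion else "insertion"
        size = int(min(rng.geometric(1.0 / self.mean_size), self.max_size))
        return kind, size


@dataclass(frozen=True)
class OutcomeMix:
    """Ground-truth mixture parameters for one simulated sample.

    The four ``f_*`` fractions describe the genomic read population and must
    sum to 1; ``contamination_fraction`` is the share of *emitted* reads that
    are bare donor oligos (drawn on top of the genomic mixture).
    """

    f_unmodified: float
    f_hdr: float
    f_indel: float
    f_hdr_and_indel: float
    n_reads: int = 10000
    error_rate: float = 0.001
    contamination_fraction: float = 0.0
    indel_size_law: IndelSizeLaw = field(default_factory=IndelSizeLaw)
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = (self.f_unmodified, self.f_hdr, self.f_indel, self.f_hdr_and_indel)
        for f in fractions:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"outcome fractions must lie in [0, 1], got {f}")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError(
                f"outcome fractions must sum to 1 (got {sum(fractions)!r})"
            )
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must lie in [0, 0.05]")
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ValueError("contamination_fraction must lie in [0, 1]")

    @property
    def label_probabilities(self) -> np.ndarray:
        cf = self.contamination_fraction
        genomic = np.array(
            [self.f_unmodified, self.f_hdr, self.f_indel, self.f_hdr_and_indel]
        )
        return np.append(genomic * (1.0 - cf), cf)


@dataclass(frozen=True)
class IndelEvent:
    kind: str  # 'deletion' or 'insertion'
    position: int  # reference anchor (inter-base for insertions)
    size: int
    inserted: str = ""


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    label: str
    indel: Optional[IndelEvent] = None


@dataclass(frozen=True)
class SimulatedSample:
    """FASTQ records (id, sequence, quality) with per-read truth labels."""

    records: tuple[tuple[str, str, str], ...]
    truth: tuple[TruthRecord, ...]
    locus: AmpliconLocus  # effective (possibly trimmed) locus the reads derive from
    mix: OutcomeMix


def apply_indel(
    reference: str,
    window: tuple[int, int],
    size_law: IndelSizeLaw,
    rng: np.random.Generator,
) -> tuple[str, IndelEvent]:
    """Introduce exactly one indel whose anchor lies inside the window.

    Deletions start at a uniform position inside the window and remove
    ``size`` reference bases (clipped at the amplicon end); insertions place
    ``size`` random bases at a uniform inter-base anchor inside the window.
    """
    w_start, w_end = window
    if not (0 <= w_start < w_end <= len(reference)):
        raise ValueError("window must lie inside the reference")
    kind, size = size_law.draw(rng)
    anchor = int(rng.integers(w_start, w_end))
    if kind == "deletion":
        size = min(size, len(reference) - anchor)
        seq = reference[:anchor] + reference[anchor + size :]
        return seq, IndelEvent("deletion", anchor, size)
    inserted = "".join(chr(b) for b in _BASES[rng.integers(0, 4, size)])
    seq = reference[:anchor] + inserted + reference[anchor:]
    return seq, IndelEvent("insertion", anchor, size, inserted)


def apply_sequencing_errors(
    read: str, error_rate: float, rng: np.random.Generator
) -> str:
    """Independently substitute each base with probability ``error_rate``
    (uniform over the three alternative bases)."""
    if error_rate == 0.0:
        return read
    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < error_rate
    n_hit = int(hit.sum())
    if n_hit == 0:
        return read
    # shift by 1..3 within the 4-letter alphabet => never the original base
    idx = np.searchsorted(_BASES, arr[hit])
    arr[hit] = _BASES[(idx + rng.integers(1, 4, n_hit)) % 4]
    return arr.tobytes().decode()


def simulate_sample(
    locus: AmpliconLocus, donor: DonorTemplate, mix: OutcomeMix
) -> SimulatedSample:
    """Generate one synthetic sample: ``mix.n_reads`` reads plus truth labels.

    Deterministic given ``mix.seed``: class counts are a single multinomial
    draw, read order is a seeded permutation, and all mutations and errors
    come from one RNG stream.
    """
    rng = np.random.default_rng(mix.seed)
    eff = trim_to_read_length(locus)
    reference = eff.reference
    donor_eff = rebase_donor(donor, locus, eff)
    hdr_reference = apply_hdr(reference, donor_eff)

    counts = rng.multinomial(mix.n_reads, mix.label_probabilities)
    labels = np.repeat(np.arange(len(LABELS)), counts)
    labels = labels[rng.permutation(mix.n_reads)]

    records: list[tuple[str, str, str]] = []
    truth: list[TruthRecord] = []
    for i, lab_idx in enumerate(labels):
        label = LABELS[lab_idx]
        read_id = f"{locus.name}_read{i:06d}"
        event: Optional[IndelEvent] = None
        if label == "unmodified":
            seq = reference
        elif label == "hdr":
            seq = hdr_reference
        elif label == "indel":
            seq, event = apply_indel(reference, eff.window, mix.indel_size_law, rng)
        elif label == "hdr_and_indel":
            # donor SNPs first, then one windowed indel (order is observationally
            # irrelevant; fixed for determinism)
            seq, event = apply_indel(hdr_reference, eff.window, mix.indel_size_law, rng)
        else:  # contamination: the bare donor oligo
            seq = donor_eff.sequence
        seq = apply_sequencing_errors(seq, mix.error_rate, rng)
        records.append((read_id, seq, "I" * len(seq)))
        truth.append(TruthRecord(read_id, label, event))

    return SimulatedSample(tuple(records), tuple(truth), eff, mix)


def write_fastq(sample: SimulatedSample | Iterable[tuple[str, str, str]], path) -> None:
    """Write 4-line FASTQ records."""
    records = sample.records if isinstance(sample, SimulatedSample) else sample
    with open(path, "w") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def write_truth(sample: SimulatedSample, path) -> None:
    """Write the truth table as TSV: read id, label, indel description."""
    with open(path, "w") as fh:
        fh.write("read_id\tlabel\tindel_kind\tindel_position\tindel_size\tinserted\n")
        for rec in sample.truth:
            if rec.indel is None:
                fh.write(f"{rec.read_id}\t{rec.label}\t.\t.\t.\t.\n")
            else:
                e = rec.indel
                fh.write(
                    f"{rec.read_id}\t{rec.label}\t{e.kind}\t{e.position}\t{e.size}"
                    f"\t{e.inserted or '.'}\n"
                )


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read single-end FASTQ into (id, sequence, quality) tuples."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        out.append((rec.id, str(rec.seq).upper(), qual))
    return out
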