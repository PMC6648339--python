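"""Demultiplexing and read qualification.

Reads are assigned to samples by Hamming distance over the barcode region
of the raw read, then pass a quality screen, alignment, and the 10G
marker screen.  The marker — a deliberate single-base mismatch at primer
position 10 — distinguishes primer-extension products (analysable) from
template-extension products (contaminants); only marker-carrying reads
enter the denominator population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import AlignedRead, AlignmentScoring, align_read
from .amplicon import AmpliconLayout, TemplateSpec
from .errors import ConfigurationError

UNASSIGNED = "unassigned"


@dataclass
class ReadRecord:
    read_id: str
    bases: str
    qualities: np.ndarray  # phred scores, same length as bases
    assigned_sample: str | None = None

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"read {self.read_id!r}: bases/qualities length mismatch")

    @property
    def mean_quality(self) -> float:
        return float(self.qualities.mean()) if len(self.qualities) else 0.0


def parse_fastq(path) -> list[ReadRecord]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(path, "fastq"):
        out.append(
            ReadRecord(
                read_id=rec.id,
                bases=str(rec.seq).upper(),
                qualities=np.array(rec.letter_annotations["phred_quality"]),
            )
        )
    return out


def write_fastq(reads: list[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(int(q) + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{qual}\n")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: list[ReadRecord],
    barcode_table: dict[str, str],
    barcode_region: tuple[int, int] = (1, 6),
    max_mismatches: int = 0,
) -> dict[str, list[ReadRecord]]:
    """Group reads by sample barcode; ambiguous/unmatched reads go unassigned.

    Barcodes must be pairwise separable at the requested tolerance: a
    pairwise Hamming distance of at least 2 * max_mismatches (ties at the
    boundary are resolved to the unassigned bin, never arbitrarily).
    """
    samples = sorted(barcode_table)
    codes = [barcode_table[s].upper() for s in samples]
    lens = {len(c) for c in codes}
    if len(lens) != 1:
        raise ConfigurationError("barcodes must share a single length")
    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            if _hamming(codes[i], codes[j]) < 2 * max_mismatches or codes[i] == codes[j]:
                raise ConfigurationError(
                    f"barcodes for {samples[i]!r} and {samples[j]!r} are "
                    f"indistinguishable at {max_mismatches} mismatches"
                )
    b0, b1 = barcode_region
    bins: dict[str, list[ReadRecord]] = {s: [] for s in samples}
    bins[UNASSIGNED] = []
    for r in reads:
        region = r.bases[b0 - 1 : b1]
        dists = [_hamming(region, c) for c in codes]
        best = min(dists)
        if best > max_mismatches or dists.count(best) > 1 or len(region) < b1 - b0 + 1:
            r.assigned_sample = UNASSIGNED
        else:
            r.assigned_sample = samples[dists.index(best)]
        bins[r.assigned_sample].append(r)
    return bins


def quality_filter(
    read: ReadRecord,
    min_mean_quality: float = 20.0,
    max_ambiguous: int = 2,
    layout: AmpliconLayout | None = None,
) -> bool:
    """Keep a read iff its mean quality and ambiguous-base counts pass.

    With a layout, ambiguous (non-ACGT) bases are forbidden inside the
    primer/barcode region and limited to ``max_ambiguous`` elsewhere.
    """
    if read.mean_quality < min_mean_quality:
        return False
    ambiguous = [i for i, b in enumerate(read.bases) if b not in "ACGT"]
    if layout is not None:
        p0, p1 = layout.primer_region
        in_primer = sum(1 for i in ambiguous if p0 <= i + 1 <= p1)
        if in_primer > 0:
            return False
        return len(ambiguous) - in_primer <= max_ambiguous
    return len(ambiguous) <= max_ambiguous


def marker_qualify(aligned: AlignedRead, layout: AmpliconLayout) -> bool:
    """Qualified iff the aligned base at the marker position is the marker base."""
    pos = layout.marker_position
    if pos > len(aligned.calls):
        return False
    return aligned.call(pos) == layout.marker_base


@dataclass
class QualifiedReadSet:
    """Reads surviving all qualification stages, with rejection accounting."""

    sample_id: str
    reads: list[ReadRecord] = field(default_factory=list)
    aligned: list[AlignedRead] = field(default_factory=list)
    rejection_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_qualified(self) -> int:
        return len(self.reads)

    @property
    def n_input(self) -> int:
        return self.n_qualified + sum(self.rejection_counts.values())


def qualify_reads(
    reads: list[ReadRecord],
    template: TemplateSpec,
    scoring: AlignmentScoring = AlignmentScoring(),
    min_mean_quality: float = 20.0,
    max_ambiguous: int = 2,
    require_full_length: bool = True,
) -> QualifiedReadSet:
    """Quality-screen, align, and 10G-screen reads for one sample.

    Marker screening is applied post-alignment so that indels upstream of
    the marker cannot shift it out of register.
    """
    layout = template.layout
    rej = {"low_quality": 0, "unalignable": 0, "no_marker": 0, "not_full_length": 0}
    qset = QualifiedReadSet(sample_id=template.template_id, rejection_counts=rej)
    for r in reads:
        if not quality_filter(r, min_mean_quality, max_ambiguous, layout):
            rej["low_quality"] += 1
            continue
        ar = align_read(r.bases, template.product_reference, scoring, read_id=r.read_id)
        if ar.score < scoring.min_score:
            rej["unalignable"] += 1
            continue
        if not marker_qualify(ar, layout):
            rej["no_marker"] += 1
            continue
        if require_full_length and not ar.full_length:
            rej["not_full_length"] += 1
            continue
        qset.reads.append(r)
        qset.aligned.append(ar)
    return qset
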