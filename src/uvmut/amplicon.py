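"""Reference system for the primer-extension amplicon assay.

The assay sequences a fixed-length region of the primer-extension product
(the *extending strand*): a 20-nt sequencing primer carrying a sample
barcode and a deliberate single-base mismatch ("10G") followed by a
variable region copied from the UV-exposed single-stranded template.
Coordinates are 1-based closed intervals throughout.  Two coordinate
systems exist and are never mixed implicitly:

* **read positions** — positions 1..read_length on the product/read,
  5'->3' of the extending strand;
* **template positions** — positions 1..len(template) on the UV-exposed
  strand, 5'->3'.

Because the product is synthesised 3'->5' along the template, read
position ``r`` maps to template position ``len(template) + 1 - r``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from .errors import ConfigurationError

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")
BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AmpliconLayout:
    """Geometry of the sequenced 73-nt product region.

    Defaults follow the assay design: primer #1-20 with the 10G marker,
    variable region #21-73, and an aggregation region #22-71 that drops
    the position adjacent to the primer and the last two positions.
    """

    read_length: int = 73
    primer_region: tuple[int, int] = (1, 20)
    marker_position: int = 10
    marker_base: str = "G"
    variable_region: tuple[int, int] = (21, 73)
    aggregation_region: tuple[int, int] = (22, 71)
    barcode_region: tuple[int, int] = (1, 6)

    def __post_init__(self) -> None:
        p0, p1 = self.primer_region
        v0, v1 = self.variable_region
        a0, a1 = self.aggregation_region
        b0, b1 = self.barcode_region
        if not (1 <= p0 <= p1 and p1 + 1 == v0 and v1 == self.read_length):
            raise ConfigurationError(
                "primer_region and variable_region must partition 1..read_length"
            )
        if not (p0 <= self.marker_position <= p1):
            raise ConfigurationError("marker_position must lie inside primer_region")
        if self.marker_base not in BASES:
            raise ConfigurationError("marker_base must be one of ACGT")
        # aggregation drops the first variable position and the last two
        if not (v0 < a0 and a1 < v1 - 1):
            raise ConfigurationError(
                "aggregation_region must exclude the first variable position "
                "and the last two variable positions"
            )
        if not (p0 <= b0 <= b1 <= p1):
            raise ConfigurationError("barcode_region must lie inside primer_region")

    @property
    def variable_positions(self) -> range:
        return range(self.variable_region[0], self.variable_region[1] + 1)

    @property
    def aggregation_positions(self) -> range:
        return range(self.aggregation_region[0], self.aggregation_region[1] + 1)

    def in_aggregation_region(self, read_pos: int) -> bool:
        return self.aggregation_region[0] <= read_pos <= self.aggregation_region[1]


def read_to_template(read_pos: int, template_length: int) -> int:
    """Map a read position to the template position it pairs with."""
    return template_length + 1 - read_pos


def template_to_read(template_pos: int, template_length: int) -> int:
    return template_length + 1 - template_pos


@dataclass(frozen=True)
class TemplateSpec:
    """One defined ssDNA template and its expected error-free product.

    ``template_sequence`` is the UV-exposed strand 5'->3'.  The expected
    read (``product_reference``) is the reverse complement of the
    template's 3' portion, with the sample barcode and the 10G marker
    substituted inside the primer region.
    """

    template_id: str
    template_sequence: str
    barcode: str = ""
    methylated_positions: frozenset[int] = field(default_factory=frozenset)
    three_prime_blocked: bool = True
    layout: AmpliconLayout = field(default_factory=AmpliconLayout)
    product_reference: str = ""

    def __post_init__(self) -> None:
        seq = self.template_sequence.upper()
        if set(seq) - set(BASES):
            bad = sorted(set(seq) - set(BASES))
            raise ConfigurationError(
                f"template {self.template_id!r}: non-ACGT characters {bad}"
            )
        object.__setattr__(self, "template_sequence", seq)
        if len(seq) < self.layout.read_length:
            raise ConfigurationError(
                f"template {self.template_id!r}: shorter than read_length"
            )
        if not self.product_reference:
            object.__setattr__(self, "product_reference", self._derive_product())
        if len(self.product_reference) != self.layout.read_length:
            raise ConfigurationError(
                f"template {self.template_id!r}: product_reference length "
                f"{len(self.product_reference)} != read_length"
            )
        for pos in self.methylated_positions:
            if self.template_sequence[pos - 1] != "C":
                raise ConfigurationError(
                    f"template {self.template_id!r}: methylated position {pos} is not C"
                )
            if pos == len(seq) or self.template_sequence[pos] != "G":
                raise ConfigurationError(
                    f"template {self.template_id!r}: methylated position {pos} "
                    "is not a CpG cytosine"
                )

    def _derive_product(self) -> str:
        lay = self.layout
        prod = list(reverse_complement(self.template_sequence)[: lay.read_length])
        if self.barcode:
            b0, b1 = lay.barcode_region
            if len(self.barcode) != b1 - b0 + 1:
                raise ConfigurationError(
                    f"template {self.template_id!r}: barcode length does not "
                    "match barcode_region"
                )
            prod[b0 - 1 : b1] = list(self.barcode.upper())
        prod[lay.marker_position - 1] = lay.marker_base
        return "".join(prod)

    @property
    def template_length(self) -> int:
        return len(self.template_sequence)

    def template_base(self, template_pos: int) -> str:
        return self.template_sequence[template_pos - 1]

    def reference_base(self, read_pos: int) -> str:
        return self.product_reference[read_pos - 1]

    def cpg_positions(self) -> frozenset[int]:
        """Template positions of CpG cytosines within the variable region."""
        lo = read_to_template(self.layout.variable_region[1], self.template_length)
        hi = read_to_template(self.layout.variable_region[0], self.template_length)
        out = set()
        for t in range(lo, hi + 1):
            if (
                self.template_sequence[t - 1] == "C"
                and t < self.template_length
                and self.template_sequence[t] == "G"
            ):
                out.add(t)
        return frozenset(out)


@dataclass(frozen=True)
class DipyrimidineSite:
    """An adjacent pyrimidine pair on the template strand (a photodimer site)."""

    template_positions: tuple[int, int]  # (5' position, 3' position)
    site_type: str  # TT / TC / CT / CC, template 5'->3'
    read_positions: tuple[int, int] | None  # ascending read positions, if mapped

    @property
    def five_prime(self) -> int:
        return self.template_positions[0]

    @property
    def three_prime(self) -> int:
        return self.template_positions[1]


def find_dipyrimidine_sites(template: TemplateSpec | str) -> list[DipyrimidineSite]:
    """Enumerate all adjacent pyrimidine pairs on the template strand.

    Every maximal run of >=2 pyrimidines contributes all of its adjacent
    pairs; the list is ordered by 5' template position.  ``read_positions``
    is filled when both bases fall inside the sequenced read region.  A
    bare sequence may be passed instead of a TemplateSpec, in which case
    read positions are left unmapped.
    """
    if isinstance(template, str):
        seq = template.upper()
        n = len(seq)
        rl = 0
    else:
        seq = template.template_sequence
        n = template.template_length
        rl = template.layout.read_length
    sites = []
    for t in range(1, n):
        a, b = seq[t - 1], seq[t]
        if a in PYRIMIDINES and b in PYRIMIDINES:
            r5 = template_to_read(t, n)
            r3 = template_to_read(t + 1, n)
            rp: tuple[int, int] | None = None
            if 1 <= r3 <= rl and 1 <= r5 <= rl:
                rp = (r3, r5)  # read 5'->3' order (3' template base is read first)
            sites.append(DipyrimidineSite((t, t + 1), a + b, rp))
    return sites


def pyrimidine_centered_class(
    product_reference: str, read_position: int, observed_base: str
) -> tuple[str, str, str]:
    """Classify a substitution into the pyrimidine-centered 96-class scheme.

    Returns ``(triplet, substitution, strand_component)`` where the triplet
    center is always a pyrimidine.  When the reference base on the
    extending strand is a purine, the reverse-complemented triplet and the
    complemented substitution are reported with ``strand_component =
    'purine'``; otherwise the triplet is taken as read with
    ``strand_component = 'pyrimidine'``.
    """
    if read_position < 2 or read_position > len(product_reference) - 1:
        raise ValueError(
            f"read position {read_position} is at the read edge: unclassifiable"
        )
    ref = product_reference[read_position - 1]
    if observed_base == ref:
        raise ValueError("observed base equals the reference base")
    triplet = product_reference[read_position - 2 : read_position + 1]
    if ref in PYRIMIDINES:
        return triplet, f"{ref}>{observed_base}", "pyrimidine"
    return (
        reverse_complement(triplet),
        f"{complement(ref)}>{complement(observed_base)}",
        "purine",
    )


def load_references(
    reference_file, annotation_file
) -> tuple[list[TemplateSpec], AmpliconLayout]:
    """Load template FASTA + annotation TSV into validated specs.

    The annotation TSV has columns: template_id, barcode, primer_start,
    primer_end, marker_pos, marker_base, var_start, var_end, agg_start,
    agg_end, methylated_positions (comma-joined template positions, may be
    empty), biotin_flag.  The barcode is assumed to occupy the first
    ``len(barcode)`` primer positions.
    """
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(reference_file, "fasta")}
    templates: list[TemplateSpec] = []
    layout: AmpliconLayout | None = None
    with open(annotation_file, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            tid = row["template_id"]
            if tid not in seqs:
                raise ConfigurationError(f"annotation references unknown template {tid!r}")
            barcode = row["barcode"].strip()
            this_layout = AmpliconLayout(
                read_length=int(row["var_end"]),
                primer_region=(int(row["primer_start"]), int(row["primer_end"])),
                marker_position=int(row["marker_pos"]),
                marker_base=row["marker_base"].strip(),
                variable_region=(int(row["var_start"]), int(row["var_end"])),
                aggregation_region=(int(row["agg_start"]), int(row["agg_end"])),
                barcode_region=(1, max(len(barcode), 1)),
            )
            if layout is None:
                layout = this_layout
            meth = frozenset(
                int(x) for x in row.get("methylated_positions", "").split(",") if x.strip()
            )
            templates.append(
                TemplateSpec(
                    template_id=tid,
                    template_sequence=seqs[tid],
                    barcode=barcode,
                    methylated_positions=meth,
                    three_prime_blocked=str(row.get("biotin_flag", "1")).strip()
                    in ("1", "true", "True"),
                    layout=this_layout,
                )
            )
    if layout is None:
        raise ConfigurationError("annotation file contains no records")
    return templates, layout


def write_references(templates: list[TemplateSpec], fasta_path, annotation_path) -> None:
    """Write templates as FASTA + annotation TSV (inverse of load_references)."""
    with open(fasta_path, "w") as fa:
        for t in templates:
            fa.write(f">{t.template_id}\n{t.template_sequence}\n")
    cols = (
        "template_id\tbarcode\tprimer_start\tprimer_end\tmarker_pos\tmarker_base\t"
        "var_start\tvar_end\tagg_start\tagg_end\tmethylated_positions\tbiotin_flag\n"
    )
    with open(annotation_path, "w") as an:
        an.write(cols)
        for t in templates:
            lay = t.layout
            meth = ",".join(str(p) for p in sorted(t.methylated_positions))
            an.write(
                f"{t.template_id}\t{t.barcode}\t{lay.primer_region[0]}\t"
                f"{lay.primer_region[1]}\t{lay.marker_position}\t{lay.marker_base}\t"
                f"{lay.variable_region[0]}\t{lay.variable_region[1]}\t"
                f"{lay.aggregation_region[0]}\t{lay.aggregation_region[1]}\t"
                f"{meth}\t{1 if t.three_prime_blocked else 0}\n"
            )
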