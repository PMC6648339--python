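"""Per-position misincorporation frequencies (% of full-length products).

All frequencies are expressed per full-length primer-extension product:
``100 * count / n_full_length``.  Background tables from the matching
unirradiated arm are subtracted per position and channel; the signed
difference is retained for QC while the channel used for spectra is
clamped at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .align import PositionCounts
from .amplicon import AmpliconLayout
from .errors import DataError, EmptyPileupError

CHANNELS = ["A", "C", "G", "T", "del", "ins"]


@dataclass
class FreqTable:
    """Per-position substitution/indel frequencies for one sample arm.

    ``data`` is indexed by read position (1-based) with a ``ref_base``
    column and one column per channel (A/C/G/T/del/ins) in % of
    full-length products.  After background subtraction ``data`` holds the
    clamped-at-zero adjusted values, ``signed`` the signed differences and
    ``raw`` the pre-subtraction table.
    """

    sample_id: str
    template_id: str
    n_full_length: int
    data: pd.DataFrame
    background_subtracted: bool = False
    paired_control_id: str | None = None
    signed: pd.DataFrame | None = None
    raw: pd.DataFrame | None = None

    @property
    def positions(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def frequency(self, position: int, channel: str) -> float:
        return float(self.data.loc[position, channel])

    def mutation_mass(self, position: int) -> float:
        """Sum of non-reference base-call frequencies at a position."""
        ref = self.data.loc[position, "ref_base"]
        return float(
            sum(self.data.loc[position, b] for b in "ACGT" if b != ref)
        )

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "position", out.index)
        out["n_full_length"] = self.n_full_length
        out["control_id"] = self.paired_control_id or ""
        out.to_csv(path, sep="\t", index=False)


def misincorporation_frequency(
    pileup: PositionCounts, sample_id: str = "", template_id: str = ""
) -> FreqTable:
    """Convert a pileup into % frequencies per full-length product."""
    if pileup.n_full_length == 0:
        raise EmptyPileupError(
            f"sample {sample_id!r}: no qualified full-length products"
        )
    n = pileup.n_full_length
    freq = 100.0 * pileup.counts / n
    ins = 100.0 * pileup.insertion_counts[1 : len(pileup.reference) + 1] / n
    df = pd.DataFrame(
        freq,
        columns=["A", "C", "G", "T", "del"],
        index=pd.RangeIndex(1, len(pileup.reference) + 1, name="position"),
    )
    df["ins"] = ins
    df.insert(0, "ref_base", list(pileup.reference))
    return FreqTable(
        sample_id=sample_id, template_id=template_id, n_full_length=n, data=df
    )


def subtract_background(sample: FreqTable, control: FreqTable) -> FreqTable:
    """Subtract an unirradiated-control (or reference-arm) frequency table.

    Also serves as the difference-spectrum operation between two
    experimental arms: the contract is identical, only the provenance
    labels differ.
    """
    if sample.template_id != control.template_id:
        raise DataError(
            f"template mismatch: {sample.template_id!r} vs {control.template_id!r}"
        )
    if not sample.data.index.equals(control.data.index) or list(
        sample.data["ref_base"]
    ) != list(control.data["ref_base"]):
        raise DataError("sample and control tables cover different references")
    signed = sample.data[CHANNELS] - control.data[CHANNELS]
    clamped = signed.clip(lower=0.0)
    clamped.insert(0, "ref_base", sample.data["ref_base"])
    signed = signed.copy()
    signed.insert(0, "ref_base", sample.data["ref_base"])
    return FreqTable(
        sample_id=sample.sample_id,
        template_id=sample.template_id,
        n_full_length=sample.n_full_length,
        data=clamped,
        background_subtracted=True,
        paired_control_id=control.sample_id,
        signed=signed,
        raw=sample.data.copy(),
    )


def aggregation_view(freq: FreqTable, layout: AmpliconLayout) -> FreqTable:
    """Restrict a table to the aggregation region (e.g. #22-71, 50 nt)."""
    lo, hi = layout.aggregation_region
    keep = [p for p in freq.data.index if lo <= p <= hi]
    if not keep:
        warnings.warn(
            f"sample {freq.sample_id!r}: aggregation region is empty", stacklevel=2
        )
    out = replace(freq, data=freq.data.loc[keep])
    if freq.signed is not None:
        out.signed = freq.signed.loc[keep]
    if freq.raw is not None:
        out.raw = freq.raw.loc[keep]
    return out
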