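"""Multinucleotide events at dipyrimidine sites, CC>TT calls, and
deamination-bias statistics.

Sequence contexts are evaluated on the *template* strand (the assay's
template-centric convention: a CC>TT dinucleotide substitution is the
insertion of two dAMPs opposite a CC dimer, observed as GG>AA on the
extending strand) and then mapped to read coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import AlignedRead, DELETION, NOT_COVERED
from .amplicon import PURINES, DipyrimidineSite, TemplateSpec, template_to_read
from .errors import DataError
from .frequency import FreqTable


@dataclass(frozen=True)
class MultiNucEvent:
    read_id: str
    site: DipyrimidineSite
    event_class: str  # multi_substitution | multi_deletion | mixed
    observed_bases: tuple[str, str]  # extending-strand calls, read 5'->3'
    is_cc_to_tt: bool


@dataclass
class CCSiteSummary:
    site: DipyrimidineSite
    cc_tt_frequency: float  # % of full-length products
    other_multi_sub_frequency: float
    purine_flanked: bool
    c_to_t_5prime: float | None = None  # single C>T at the 5' C (template-centric)
    c_to_t_3prime: float | None = None


def purine_flanked(site: DipyrimidineSite, template: TemplateSpec) -> bool:
    """True for RpCpCpR context: both template neighbours of the pair are purines."""
    t5, t3 = site.template_positions
    if t5 <= 1 or t3 >= template.template_length:
        return False
    return (
        template.template_base(t5 - 1) in PURINES
        and template.template_base(t3 + 1) in PURINES
    )


def call_multinuc_events(
    aligned_reads: list[AlignedRead],
    sites: list[DipyrimidineSite],
    product_reference: str,
) -> list[MultiNucEvent]:
    """Emit one event per read x site where BOTH site positions deviate.

    Single-position deviations are not multinucleotide events; they stay
    in the per-position frequency tables.
    """
    mapped = [s for s in sites if s.read_positions is not None]
    events: list[MultiNucEvent] = []
    for ar in aligned_reads:
        for s in mapped:
            r1, r2 = s.read_positions
            c1, c2 = ar.call(r1), ar.call(r2)
            if NOT_COVERED in (c1, c2):
                continue
            ref1, ref2 = product_reference[r1 - 1], product_reference[r2 - 1]
            d1, d2 = c1 != ref1, c2 != ref2
            if not (d1 and d2):
                continue
            if c1 == DELETION and c2 == DELETION:
                klass = "multi_deletion"
            elif DELETION in (c1, c2):
                klass = "mixed"
            else:
                klass = "multi_substitution"
            events.append(
                MultiNucEvent(
                    read_id=ar.read_id,
                    site=s,
                    event_class=klass,
                    observed_bases=(c1, c2),
                    is_cc_to_tt=(s.site_type == "CC" and (c1, c2) == ("A", "A")),
                )
            )
    return events


def cc_tt_site_frequencies(
    events: list[MultiNucEvent],
    n_full_length: int,
    sites: list[DipyrimidineSite],
    template: TemplateSpec,
) -> list[CCSiteSummary]:
    """Per-CpC-site CC>TT and other multinucleotide-substitution frequencies."""
    if n_full_length <= 0:
        raise DataError("n_full_length must be positive")
    out = []
    for s in sites:
        if s.site_type != "CC" or s.read_positions is None:
            continue
        cc_tt = sum(
            1 for e in events if e.site == s and e.is_cc_to_tt
        )
        other = sum(
            1
            for e in events
            if e.site == s and e.event_class == "multi_substitution" and not e.is_cc_to_tt
        )
        out.append(
            CCSiteSummary(
                site=s,
                cc_tt_frequency=100.0 * cc_tt / n_full_length,
                other_multi_sub_frequency=100.0 * other / n_full_length,
                purine_flanked=purine_flanked(s, template),
            )
        )
    return out


def cc_positional_bias(
    freq: FreqTable,
    template: TemplateSpec,
    sites: list[DipyrimidineSite],
) -> pd.DataFrame:
    """Single C>T frequency at the 5' C and 3' C of purine-flanked CC sites.

    Only RpCpCpR sites (no adjacent pyrimidine) are analysed so that a
    single dimer explains the signal.  A template C>T is observed as a
    G>A on the extending strand.  Returns one row per qualifying site
    with columns c_to_t_5prime / c_to_t_3prime (% of full-length
    products); empty with a warning-free empty frame if none qualify.
    """
    n = template.template_length
    rows = []
    for s in sites:
        if s.site_type != "CC" or s.read_positions is None:
            continue
        if not purine_flanked(s, template):
            continue
        r5 = template_to_read(s.five_prime, n)
        r3 = template_to_read(s.three_prime, n)
        if r5 not in freq.data.index or r3 not in freq.data.index:
            continue
        rows.append(
            {
                "template_id": template.template_id,
                "t5": s.five_prime,
                "t3": s.three_prime,
                "c_to_t_5prime": freq.frequency(r5, "A"),
                "c_to_t_3prime": freq.frequency(r3, "A"),
            }
        )
    return pd.DataFrame(rows, columns=["template_id", "t5", "t3", "c_to_t_5prime", "c_to_t_3prime"])


def _context_c_positions(template: TemplateSpec) -> dict[str, list[int]]:
    """Template C positions in TpCpR (TC-dimer C) and RpCpT (CT-dimer C) contexts."""
    seq = template.template_sequence
    out = {"TpCpR": [], "RpCpT": []}
    for t in range(2, template.template_length):
        if seq[t - 1] != "C":
            continue
        left, right = seq[t - 2], seq[t]
        if left == "T" and right in PURINES:
            out["TpCpR"].append(t)
        elif left in PURINES and right == "T":
            out["RpCpT"].append(t)
    return out


def deamination_ratio(
    pairs: list[tuple[FreqTable, FreqTable, TemplateSpec]],
    floor: float = 0.05,
) -> pd.DataFrame:
    """Ratio of C>T frequencies (no-TLS / TLS) at TpCpR vs RpCpT contexts.

    ``pairs`` holds (freq_no_tls, freq_tls, template) per template from
    the same protocol family.  Positions whose TLS-arm frequency is below
    ``floor`` (% of full-length products) are excluded and counted.
    Returns one row per context with mean, SD, n and excluded counts.
    """
    values: dict[str, list[float]] = {"TpCpR": [], "RpCpT": []}
    excluded = {"TpCpR": 0, "RpCpT": 0}
    for f_no, f_tls, tmpl in pairs:
        ctx = _context_c_positions(tmpl)
        n = tmpl.template_length
        for name, positions in ctx.items():
            for t in positions:
                r = template_to_read(t, n)
                if r not in f_tls.data.index or r not in f_no.data.index:
                    continue
                tls = f_tls.frequency(r, "A")
                if tls < floor:
                    excluded[name] += 1
                    continue
                values[name].append(f_no.frequency(r, "A") / tls)
    if not values["TpCpR"] and not values["RpCpT"]:
        raise DataError(
            f"all candidate positions excluded (TLS frequency floor {floor}%)"
        )
    rows = []
    for name in ("TpCpR", "RpCpT"):
        v = np.array(values[name], dtype=float)
        rows.append(
            {
                "context": name,
                "n_positions": v.size,
                "mean": float(v.mean()) if v.size else np.nan,
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "excluded_count": excluded[name],
            }
        )
    return pd.DataFrame(rows)
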