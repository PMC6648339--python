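"""Shared fixtures: fixture templates and one jointly-used protocol run.

The protocol bundle simulates the study's experimental arms once per
session (fixed seed) and runs the full pipeline on them; many tests
interrogate different aspects of the same run.
"""

from __future__ import annotations

from types import SimpleNamespace

import pytest

from uvmut import pipeline as pl
from uvmut import simulate as sim
from uvmut.amplicon import AmpliconLayout, TemplateSpec


@pytest.fixture(scope="session")
def templates():
    return sim.generate_templates(n_templates=7, seed=1)


@pytest.fixture(scope="session")
def lesion(templates):
    return sim.LesionModel(k_form_uvb=sim.calibrate_k_form(templates))


@pytest.fixture(scope="session")
def by_id(templates):
    return {t.template_id: t for t in templates}


BUNDLE_ARMS = {
    "unirradiated:poldelta": [("replicate", "poldelta")],
    "unirradiated:poldelta_tls": [("replicate", "poldelta_tls")],
    "first_hit_only:poldelta": sim.STANDARD_ARM_STEPS["first_hit_only"]
    + [("replicate", "poldelta")],
    "first_hit_only:poldelta_tls": sim.STANDARD_ARM_STEPS["first_hit_only"]
    + [("replicate", "poldelta_tls")],
    "two_hit_complete:poldelta": sim.STANDARD_ARM_STEPS["two_hit_complete"]
    + [("replicate", "poldelta")],
    "two_hit_complete:poldelta_tls": sim.STANDARD_ARM_STEPS["two_hit_complete"]
    + [("replicate", "poldelta_tls")],
    "two_hit_no_second_hit:poldelta": sim.STANDARD_ARM_STEPS["two_hit_no_second_hit"]
    + [("replicate", "poldelta")],
    "two_hit_no_incubation:poldelta": sim.STANDARD_ARM_STEPS["two_hit_no_incubation"]
    + [("replicate", "poldelta")],
    "single_60:poldelta": sim.STANDARD_ARM_STEPS["single_60"]
    + [("replicate", "poldelta")],
    "udg:poldelta": sim.STANDARD_ARM_STEPS["udg"] + [("replicate", "poldelta")],
}


@pytest.fixture(scope="session")
def bundle(templates, lesion, by_id):
    """One simulated protocol (3000 molecules/template/arm) plus its analysis."""
    config = sim.SimulationConfig(
        n_molecules=3000, seed=2026, lesion=lesion, arms=dict(BUNDLE_ARMS)
    )
    results = sim.run_protocol(config, templates)
    analyses = pl.analyze_arms(
        {arm: r.reads for arm, r in results.items()}, templates
    )
    return SimpleNamespace(
        config=config, results=results, analyses=analyses, by_id=by_id
    )


def make_template(var_seq: str, template_id: str = "X", barcode: str = "ACGTAC"):
    """Build a TemplateSpec whose variable region (template 5'->3') is var_seq."""
    layout = AmpliconLayout()
    primer = barcode + sim._PRIMER_SUFFIX
    var_len = layout.variable_region[1] - layout.variable_region[0] + 1
    if len(var_seq) != var_len:
        raise ValueError(f"variable region must be {var_len} nt")
    adaptor = "AG" * 13  # 26 nt, no dipyrimidines
    from uvmut.amplicon import reverse_complement

    tail = list(reverse_complement(primer))
    tail[layout.primer_region[1] - layout.marker_position] = "T"
    return TemplateSpec(
        template_id=template_id,
        template_sequence=adaptor + var_seq + "".join(tail),
        barcode=barcode,
        layout=layout,
    )
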