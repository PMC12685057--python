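import pytest

from cladon.io import CodonAlignment, GeneRecord
from cladon.simulate import (
    CladeSpec,
    ScenarioConfig,
    generate_gene_family_scenario,
)

BOTH = ("Malacalcyonacea", "Scleralcyonacea")


@pytest.fixture
def tiny_alignment():
    return CodonAlignment(
        (
            GeneRecord("g1", "ATGAAATTTGGG", species="sp1", order_label="O1", clade_label="c1"),
            GeneRecord("g2", "ATGAAATTCGGG", species="sp2", order_label="O2", clade_label="c1"),
            GeneRecord("g3", "ATGAATTTTGGC", species="sp3", order_label="O1", clade_label="c2"),
            GeneRecord("g4", "ATGAACTTTGGA", species="sp4", order_label="O2", clade_label="c2"),
        )
    )


@pytest.fixture(scope="session")
def small_scenario():
    """A small two-clade scenario with a 3x fast clade, shared by tests."""
    cfg = ScenarioConfig(
        seed=11,
        L_codons=200,
        clades=(
            CladeSpec("fast", 6, BOTH, rate_scale=3.0, omega=1.0, kappa=1.0),
            CladeSpec("slow", 6, BOTH, rate_scale=1.0, omega=1.0, kappa=1.0),
        ),
        reference_omega=1.0,
        reference_kappa=1.0,
        reference_gc_bias=0.5,
    )
    return generate_gene_family_scenario(cfg)
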