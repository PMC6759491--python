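import pytest

from crosskit.genotypes import LineGenotype, MarkerPanel, allele_frequencies
from crosskit.simulate import default_loci_spec, simulate_dh_panel


def dh_line(line_id, alleles, loci, role="parent", maternal_id=None):
    """Homozygous line from one allele per locus."""
    return LineGenotype(
        line_id,
        {l: (a, a) for l, a in zip(loci, alleles)},
        role=role,
        maternal_id=maternal_id,
    )


@pytest.fixture
def two_locus_panel():
    loci = ["L1", "L2"]
    lines = [
        dh_line("A", [100, 200], loci),
        dh_line("B", [103, 203], loci),
        dh_line("C", [106, 200], loci),
    ]
    return MarkerPanel(loci=loci, lines=lines)


@pytest.fixture(scope="session")
def dh36():
    """36 distinct DH lines on the default 8-locus panel, with frequencies."""
    panel = simulate_dh_panel(36, default_loci_spec(), seed=20190918)
    return panel, allele_frequencies(panel)
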