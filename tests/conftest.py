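"""Shared fixtures: one seeded toy plastome and its derived objects."""

import pytest

from codoncompress.codon_model import (
    cai_weights,
    count_codon_usage,
    partition_isoacceptor_boxes,
)
from codoncompress.fixtures import TOY_USAGE, make_toy_plastome
from codoncompress.scheme import derive_defined_scheme


@pytest.fixture(scope="session")
def toy():
    return make_toy_plastome(n_genes=20, length_mean=150, seed=11)


@pytest.fixture(scope="session")
def toy_usage(toy):
    return count_codon_usage(toy.cds_records, include_stops=True)


@pytest.fixture(scope="session")
def toy_boxes(toy):
    return partition_isoacceptor_boxes(toy.roster)


@pytest.fixture(scope="session")
def toy_scheme(toy_usage, toy_boxes):
    return derive_defined_scheme(toy_usage, toy_boxes)


@pytest.fixture(scope="session")
def toy_cai(toy_usage):
    return cai_weights(toy_usage, reference_description="toy plastome usage")


# The eliminated set implied by the TOY usage profile: for each dual
# family the minority box (CTN, ATA, AGY, AGR, GGR) goes, and the
# majority box's top codon is the replacement.
TOY_ELIMINATED_SENSE = frozenset({
    "CTT", "CTC", "CTA", "CTG", "ATA", "AGT", "AGC", "AGA", "AGG",
    "GGA", "GGG",
})
TOY_REPLACEMENTS = {
    "CTT": "TTA", "CTC": "TTA", "CTA": "TTA", "CTG": "TTA",
    "ATA": "ATT",
    "AGT": "TCT", "AGC": "TCT",
    "AGA": "CGT", "AGG": "CGT",
    "GGA": "GGT", "GGG": "GGT",
}
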