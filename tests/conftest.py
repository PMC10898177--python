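"""Shared fixtures: hand-built gene models with known event labels and a
small synthetic bundle reused across test modules."""

from __future__ import annotations

import pytest

from cisplice.annotation_io import GeneModel, TranscriptModel
from cisplice.synthetic import SyntheticSpec, generate


def _gene(gene_id, strand, *transcripts, chrom="chrT"):
    return GeneModel(
        gene_id,
        chrom,
        strand,
        tuple(
            TranscriptModel(f"{gene_id}.T{i + 1}", tuple(exons))
            for i, exons in enumerate(transcripts)
        ),
    )


@pytest.fixture(scope="session")
def hand_labeled():
    """20 hand-built genes covering every pattern, with the expected
    (pattern, annotated) label for a probe region of each gene.

    Returns (genes, cases) where cases maps gene_id -> (region, pattern,
    annotated) for the event to probe.
    """
    genes = [
        # cassette exons, both strands
        _gene("g01_ec", "+", [(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)]),
        _gene("g02_ec_minus", "-", [(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)]),
        # annotated intron retention, both strands
        _gene("g03_ir", "+", [(0, 100), (200, 300)], [(0, 300)]),
        _gene("g04_ir_minus", "-", [(0, 100), (200, 300)], [(0, 300)]),
        # alternative last exons (transcription order)
        _gene("g05_ale", "+",
              [(0, 100), (200, 300), (400, 500)], [(0, 100), (200, 300), (600, 700)]),
        _gene("g06_ale_minus", "-",
              [(200, 300), (400, 500), (600, 700)], [(0, 100), (400, 500), (600, 700)]),
        # alternative first exons
        _gene("g07_afe", "+",
              [(0, 100), (400, 500), (600, 700)], [(200, 300), (400, 500), (600, 700)]),
        _gene("g08_afe_minus", "-",
              [(0, 100), (200, 300), (400, 500)], [(0, 100), (200, 300), (600, 700)]),
        # alternative 5' / 3' splice sites
        _gene("g09_alt5", "+", [(0, 100), (200, 300)], [(0, 150), (200, 300)]),
        _gene("g10_alt3", "+", [(0, 100), (200, 300)], [(0, 100), (170, 300)]),
        _gene("g11_alt5_minus", "-", [(0, 100), (200, 300)], [(0, 100), (170, 300)]),
        _gene("g12_alt3_minus", "-", [(0, 100), (200, 300)], [(0, 150), (200, 300)]),
        # mutually exclusive exons
        _gene("g13_mxe", "+",
              [(0, 100), (200, 300), (600, 700)], [(0, 100), (400, 500), (600, 700)]),
        # two independent cassettes (co-occurring, so not MXE)
        _gene("g14_two_ec", "+",
              [(0, 100), (200, 300), (400, 500), (600, 700)], [(0, 100), (600, 700)]),
        # constitutive-only genes: novel IR and UNKNOWN probes
        _gene("g15_const", "+", [(0, 100), (200, 300), (400, 500)]),
        _gene("g16_const_minus", "-", [(0, 100), (200, 300)]),
        _gene("g17_intronless", "+", [(0, 500)]),
        _gene("g18_unknown", "+", [(0, 100), (200, 300)]),
        # cassette with three transcripts (exon in some but not all)
        _gene("g19_ec3", "+",
              [(0, 100), (200, 300), (400, 500)],
              [(0, 100), (400, 500)],
              [(0, 100), (200, 300), (400, 500)]),
        # retained intron contained in a single-exon isoform
        _gene("g20_ir_onexon", "+", [(0, 100), (200, 300), (400, 500)], [(0, 500)]),
    ]
    cases = {
        "g01_ec": ((200, 300), "EC", True),
        "g02_ec_minus": ((200, 300), "EC", True),
        "g03_ir": ((100, 200), "IR", True),
        "g04_ir_minus": ((100, 200), "IR", True),
        "g05_ale": ((400, 500), "ALE", True),
        "g06_ale_minus": ((0, 100), "ALE", True),
        "g07_afe": ((0, 100), "AFE", True),
        "g08_afe_minus": ((400, 500), "AFE", True),
        "g09_alt5": ((100, 150), "ALT5SS", True),
        "g10_alt3": ((170, 200), "ALT3SS", True),
        "g11_alt5_minus": ((170, 200), "ALT5SS", True),
        "g12_alt3_minus": ((100, 150), "ALT3SS", True),
        "g13_mxe": ((400, 500), "MXE", True),
        "g14_two_ec": ((400, 500), "EC", True),
        "g15_const": ((100, 200), "IR", False),   # constitutive intron -> novel IR
        "g16_const_minus": ((100, 200), "IR", False),
        "g17_intronless": ((50, 120), "UNKNOWN", False),
        "g18_unknown": ((120, 180), "UNKNOWN", False),  # overlaps the intron, not equal
        "g19_ec3": ((200, 300), "EC", True),
        "g20_ir_onexon": ((100, 200), "IR", True),
    }
    return genes, cases


@pytest.fixture(scope="session")
def small_bundle():
    """A 300-gene synthetic bundle with the default injected effects."""
    return generate(SyntheticSpec.sized(300), seed=7)


@pytest.fixture(scope="session")
def small_catalog(small_bundle):
    from cisplice.event_catalog import build_catalog

    return build_catalog(small_bundle.genes)
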