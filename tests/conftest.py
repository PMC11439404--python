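"""Shared fixtures: a small hand-built genome set and its taxonomy.

The fixture taxonomy (all sizes chosen so means are exact in floating
point):

    d__Bacteria
      p__P1; c__C1; o__O1; f__F1
        g__G1: s__S1 (2 Mbp), s__S2 (4 Mbp)   -> genus AGS 3 Mbp
        g__G2: s__S3 (6 Mbp)                  -> genus AGS 6 Mbp
                                               -> family AGS 4.5 Mbp
    d__Archaea
      p__PA; c__CA; o__OA; f__FA; g__GA: s__SA (1 Mbp)

Root AGS = mean(4.5, 1.0) = 2.75 Mbp (single-child chains propagate
unchanged above family/genus).
"""

import pytest

from microfrac import GenomeRecord, Lineage, build_taxonomy

MBP = 1e6


def _rec(acc, names, size_mbp, completeness=100.0, contamination=0.0):
    return GenomeRecord(
        accession=acc,
        lineage=Lineage.from_names(*names),
        assembly_size=int(size_mbp * MBP),
        completeness=completeness,
        contamination=contamination,
    )


@pytest.fixture
def fixture_records():
    return [
        _rec("G001", ("Bacteria", "P1", "C1", "O1", "F1", "G1", "S1"), 2),
        _rec("G002", ("Bacteria", "P1", "C1", "O1", "F1", "G1", "S2"), 4),
        _rec("G003", ("Bacteria", "P1", "C1", "O1", "F1", "G2", "S3"), 6),
        _rec("G004", ("Archaea", "PA", "CA", "OA", "FA", "GA", "SA"), 1),
    ]


@pytest.fixture
def fixture_taxonomy(fixture_records):
    return build_taxonomy(fixture_records)


def lineage(*names):
    """Convenience: build a (possibly truncated) lineage from bare names."""
    return Lineage.from_names(*names)
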