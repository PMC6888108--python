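import pytest

from cladesites import FamilySpec, LabeledAlignment, default_scheme, simulate_family


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture
def small_alignment():
    """2 clades x 3 seqs, 8 columns, hand-built with known structure.

    Columns (1-based), clade A = a1..a3, clade B = b1..b3:
      1: all C                                  -> UNIVERSAL
      2: A fixed basic (K/R), B mixed, no basic -> CLADE_SPECIFIC for A
      3: A fixed aliphatic, one B aliphatic (M) -> CLADE_SHARED for A
      4: both clades mixed                      -> VARIABLE
      5: gap in A, B mixed                      -> VARIABLE
      6: A fixed E, B shows G or gap            -> CLADE_SPECIFIC for A
      7: all small hydrophilic (S/T/A), no gaps -> UNIVERSAL
      8: X in A, B mixed                        -> VARIABLE
    """
    rows = {
        "a1": "CKVDSESX",
        "a2": "CRLK-ETK",
        "a3": "CKIATEAD",
        "b1": "CDFVSGSD",
        "b2": "CEWKK-TN",
        "b3": "CWMHDGSC",
    }
    clade_of = {sid: sid[0].upper() for sid in rows}
    return LabeledAlignment(
        records=tuple(rows.items()), clade_of=clade_of,
        reference_of={"A": "a1", "B": "b1"},
    )


@pytest.fixture(scope="session")
def default_family():
    return simulate_family(FamilySpec(seed=7))
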