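import pytest

import statincost as sc


@pytest.fixture
def toy_table():
    """Two-statin toy equivalence table (A = atorvastatin, B = simvastatin):
    A: 10 mg -> 35%, 20 mg -> 42%; B: 10 -> 30%, 20 -> 36%, 40 -> 43%."""
    return sc.EquivalenceTable(
        {
            (sc.Statin.ATORVASTATIN, 10.0): 35.0,
            (sc.Statin.ATORVASTATIN, 20.0): 42.0,
            (sc.Statin.SIMVASTATIN, 10.0): 30.0,
            (sc.Statin.SIMVASTATIN, 20.0): 36.0,
            (sc.Statin.SIMVASTATIN, 40.0): 43.0,
        }
    )


@pytest.fixture
def flat_deflators():
    return sc.DeflatorSeries({y: 100.0 for y in range(2003, 2019)})
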