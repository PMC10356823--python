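import numpy as np
import pandas as pd
import pytest

from plumeomics import geochem, synthio


def make_matrix(rows, contig="genome"):
    """Build an allele matrix from (pos, group, (nA, nC, nG, nT)) tuples."""
    recs = [{"contig": contig, "pos": pos, "group": group,
             "nA": c[0], "nC": c[1], "nG": c[2], "nT": c[3]}
            for pos, group, c in rows]
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def default_scenario():
    return synthio.SyntheticScenario(seed=7)


@pytest.fixture(scope="session")
def pileups(default_scenario):
    return synthio.generate_two_population_pileups(default_scenario)


@pytest.fixture(scope="session")
def reactions():
    return geochem.default_reactions()


@pytest.fixture(scope="session")
def sulfide_landscape(reactions):
    vent, sw = synthio.generate_vent_chemistry("sulfide-rich")
    f = (3.0 - sw.temperature) / (vent.temperature - sw.temperature)
    state = geochem.mix_fluids(vent, sw, f)
    return geochem.energy_landscape(reactions, state), state
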