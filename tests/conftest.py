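import numpy as np
import pandas as pd
import pytest

import complexome as cx
from complexome import simulate as sim


@pytest.fixture(scope="session")
def digitonin_bundle():
    return sim.default_scenario("digitonin")


@pytest.fixture(scope="session")
def ddm_bundle():
    return sim.default_scenario("DDM")


@pytest.fixture(scope="session")
def digitonin_pair(digitonin_bundle):
    """One reciprocal pair at default noise, plus its design."""
    t1, t2, design = sim.simulate_reciprocal_pair(
        digitonin_bundle.scenario, seeds=(1001, 1002)
    )
    return t1, t2, design


@pytest.fixture(scope="session")
def digitonin_curve(digitonin_bundle):
    return cx.fit_calibration(digitonin_bundle.standards)


@pytest.fixture()
def tiny_table():
    """A hand-written 3-slice peptide table (one experiment, one channel)."""
    rows = [
        ("e1", "H", "P1", "A", 2, 2.0),
        ("e1", "H", "P1", "B", 1, 1.0),
        ("e1", "H", "P1", "B", 2, 1.0),
    ]
    return pd.DataFrame(
        rows,
        columns=["experiment_id", "channel", "protein_id", "peptide_id", "slice", "intensity"],
    )


def single_species_scenario(mass_kda=500.0, abundance=(4.0, 1.0), n_peptides=1):
    """One protein, one species: the minimal closed-form test scenario."""
    proteins = {"P1": sim.ProteinGenerativeModel("P1", n_peptides=n_peptides)}
    species = (
        sim.SpeciesDefinition(
            name="S",
            composition={"P1": 1},
            mass_kda=mass_kda,
            abundance={"control": abundance[0], "mutant": abundance[1]},
        ),
    )
    return sim.GroundTruthScenario(species=species, proteins=proteins)
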