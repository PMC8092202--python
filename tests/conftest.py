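import pytest
from hypothesis import settings

from panerosion import orthology

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from panerosion.simulate import PathwaySpec, SimulationConfig, simulate_pangenome


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured simulated pangenome (loss + lesions)."""
    cfg = SimulationConfig(n_taxa=8, n_families=60, seed=3)
    return simulate_pangenome(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """A tiny pangenome with no loss and no pseudogenes (4 genomes, 4 families)."""
    cfg = SimulationConfig(
        n_taxa=4,
        n_families=4,
        family_length_codons=40,
        pathways=(PathwaySpec("J", 0.0, 0.0),),
        mech_probs={"gap_decay": 1.0},
        seed=5,
    )
    return simulate_pangenome(cfg)


def groups_from_truth(sim):
    """Build OrthoGroups directly from the simulator's planted families."""
    by_key = {r.key: r for r in sim.records}
    groups = []
    for fam, members in sorted(sim.truth.true_groups.items()):
        recs = [by_key[m] for m in sorted(members) if m in by_key]
        if recs:
            groups.append(orthology.OrthoGroup(group_id=fam, members=recs))
    return groups


@pytest.fixture(scope="session")
def small_sim_groups(small_sim):
    return groups_from_truth(small_sim)
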