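import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dnaends import ExperimentDesign, SimConfig, default_roster, simulate


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated study (20 proteins) shared across tests."""
    roster, proteins = default_roster(
        seed=7, n_ends_specific=8, n_generic=8, n_contaminant=4
    )
    return simulate(SimConfig(roster=roster, seed=7))


@pytest.fixture(scope="session")
def sim_dir(small_sim, tmp_path_factory):
    """The small simulation written to disk in the pipeline's input dialect."""
    from dnaends.simulate import write_simulation

    out = tmp_path_factory.mktemp("sim")
    write_simulation(small_sim, out)
    class_map = small_sim.truth[["accession", "class"]].rename(
        columns={"class": "classes"}
    )
    class_map.to_csv(out / "class_map.tsv", sep="\t", index=False)
    return out
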