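import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_instance(tmp_path_factory):
    """One generated synthetic instance (seed 1), shared across tests."""
    from mirseed.synthetic_data import GeneratorParams, generate_instance

    out = tmp_path_factory.mktemp("instance")
    paths, manifest = generate_instance(GeneratorParams(), seed=1, out_dir=out)
    return paths, manifest


@pytest.fixture(scope="session")
def pipeline_run(default_instance, tmp_path_factory):
    """A full pipeline run over the shared instance."""
    from mirseed.pipeline import RunConfig, run_all

    paths, manifest = default_instance
    out = tmp_path_factory.mktemp("run")
    config = RunConfig(
        genome=str(paths.genome),
        tblout=str(paths.tblout),
        repeats=str(paths.repeats),
        known=str(paths.known),
        families_dir=str(paths.families_dir),
        chain=str(paths.chain),
        reads_dir=str(paths.reads_dir),
        sample_sheet=str(paths.sample_sheet),
        out_dir=str(out),
    )
    return run_all(config), manifest


@pytest.fixture(scope="session")
def toy_family():
    """A small generated family alignment (no subtypes)."""
    from mirseed.synthetic_data import GeneratorParams, generate_family

    return generate_family(GeneratorParams(), seed=11, index=0)
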