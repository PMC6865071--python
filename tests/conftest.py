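import pytest

from smmipseq import simulate as sim


@pytest.fixture(scope="session")
def small_panel():
    """Four regular genes plus an IDH1-like marker gene; EGFR and CA12
    junction genes included."""
    return sim.synthetic_panel(
        genes=["G001", "G002", "G003", "G004", "IDH1"], seed=0
    )


@pytest.fixture(scope="session")
def junction_panel():
    """Panel including the VEGFA-style isoform probe trio."""
    return sim.synthetic_panel(genes=["G001"], include_vegfa=True, seed=0)


@pytest.fixture(scope="session")
def small_catalog(small_panel):
    return sim.hotspot_catalog(small_panel)


@pytest.fixture
def clean_run():
    """Noise-free run: no PCR duplication, no sequencing errors."""
    return sim.RunConfig(mean_duplication=1.0, error_rate=0.0)


def single_sample_truth(panel, abundance, isoforms=None, variants=None, sample_id="S001"):
    """Minimal truth record for direct library simulation in tests."""
    return sim.SampleTruth(
        sample_id=sample_id,
        group="A",
        abundance=abundance,
        isoform_fractions=isoforms or {},
        variants=variants or [],
        survival_days=100.0,
        event=True,
    )
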