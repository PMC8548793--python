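import pytest

from zooms.panel import bundled_panel


@pytest.fixture(scope="session")
def panel():
    return bundled_panel()


def noise_free_spectrum(panel, taxon, seed=1):
    """Idealized spectrum: every MALDI-visible marker, exact masses, no noise."""
    from zooms.simulate import SimulationParams, simulate_spectrum

    params = SimulationParams(
        target=taxon, mass_sd=0.0, calibration_offset=0.0,
        detection=1.0, noise_peaks=0, seed=seed,
    )
    return simulate_spectrum(panel, params)
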