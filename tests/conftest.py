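import numpy as np
import pytest

from paintsofi.blink_sim import (
    KineticParams,
    OpticsCamera,
    Phantom,
    DockingSite,
    make_filament_phantom,
    render_movie,
)


@pytest.fixture(scope="session")
def dense_kinetics() -> KineticParams:
    """SOFI-optimized kinetics: repeat-motif strand, high imager
    concentration (short dark time), duplex destabilizer (short bright time)."""
    return KineticParams(
        per_site_binding_rate=1.0,
        mean_bound_time=0.25,
        n_repeat_motifs=5,
        destabilizer_on_time_factor=0.2,
        imager_concentration_nM=5.0,
    )


@pytest.fixture(scope="session")
def sparse_kinetics() -> KineticParams:
    """SMLM-optimized kinetics: low imager concentration, long dwells."""
    return KineticParams(
        per_site_binding_rate=0.01,
        mean_bound_time=0.5,
        n_repeat_motifs=1,
        imager_concentration_nM=0.2,
    )


@pytest.fixture(scope="session")
def single_emitter_movie(dense_kinetics):
    """Bright isolated blinking emitter, 32 x 32 px, shot + read noise."""
    kin = KineticParams(
        per_site_binding_rate=0.4, mean_bound_time=0.5, n_repeat_motifs=1, destabilizer_on_time_factor=0.5
    )
    optics = OpticsCamera(
        n_frames=6000,
        pixel_size=100.0,
        psf_fwhm=400.0,
        frame_time=0.01,
        seed=5,
        background_photons_per_pixel_per_frame=2.0,
        photons_per_bound_imager_per_s=2e5,
    )
    phantom = Phantom([DockingSite((1650.0, 1650.0), kin)], (3200.0, 3200.0))
    return render_movie(phantom, optics)


@pytest.fixture(scope="session")
def filament_movie(dense_kinetics):
    """3000-frame, 64 x 64 px filament movie under dense (SOFI) kinetics."""
    kin = KineticParams(
        per_site_binding_rate=0.4, mean_bound_time=0.5, n_repeat_motifs=5, destabilizer_on_time_factor=0.2
    )
    phantom = make_filament_phantom(3, (6400.0, 6400.0), 0.04, kin, curvature=0.5, seed=11)
    optics = OpticsCamera(
        n_frames=3000,
        pixel_size=100.0,
        psf_fwhm=300.0,
        frame_time=0.01,
        seed=7,
        background_photons_per_pixel_per_frame=10.0,
        photons_per_bound_imager_per_s=2e5,
    )
    return render_movie(phantom, optics), phantom, optics
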