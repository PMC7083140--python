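import pytest

import myoslice as ms


@pytest.fixture(scope="session")
def sheet_phantom():
    """Thin-sheet phantom (spacing 1 um) with exact analytic mean distance."""
    spec = ms.TubulePhantomSpec(
        cell_extent_um=(5.8, 5.8, 5.8), geometry="sheets", lattice_spacing_um=1.0
    )
    stack, truth = ms.gen_tsystem_stack(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def lattice_phantom():
    """Thin-line lattice phantom (spacing 1 um), radius->0 limit."""
    spec = ms.TubulePhantomSpec(
        cell_extent_um=(5.8, 5.8, 5.8), geometry="full-lattice", lattice_spacing_um=1.0
    )
    stack, truth = ms.gen_tsystem_stack(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def noiseless_staircase():
    """Noiseless default staircase trace with per-frequency amplitudes."""
    amps = {0.2: 2.2, 0.5: 2.5, 1.0: 2.7, 2.0: 2.0}
    trace, truth = ms.gen_force_trace(amplitudes=amps, noise_sd=0.0)
    return trace, truth


def masks_from_truth(truth) -> ms.SegmentationMasks:
    """SegmentationMasks assembled directly from generator ground truth."""
    membrane = truth.tubule_mask | truth.surface_mask
    return ms.SegmentationMasks(
        membrane_mask=membrane,
        cell_mask=truth.cell_mask,
        tubule_mask=truth.tubule_mask,
        surface_mask=truth.surface_mask,
    )
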