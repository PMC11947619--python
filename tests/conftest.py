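import numpy as np
import pytest

from mad2nmr.spectra import PeakAssignment
from mad2nmr.synthetic import (AcquisitionSpec, KineticModelSpec,
                               build_reference_structure,
                               simulate_conversion_series)

FULL_ACQ = AcquisitionSpec(n_spectra=500, dt=5.0)


@pytest.fixture(scope="session")
def full_acq():
    """The standard 500-spectrum / 5-min acquisition schedule (42 h)."""
    return FULL_ACQ


@pytest.fixture(scope="session")
def short_acq():
    return AcquisitionSpec(n_spectra=60, dt=5.0)


def make_peaks(residues, states=("O", "C_empty")):
    """Well-separated unit-amplitude peaks for the given residues."""
    peaks, amps = [], {}
    for i, res in enumerate(residues):
        for j, state in enumerate(states):
            peaks.append(PeakAssignment(res, "A", state,
                                        delta_H=7.0 + 0.05 * (i * len(states) + j),
                                        delta_N=110.0 + 0.7 * (i * len(states) + j)))
            amps[(res, state)] = 1.0
    return peaks, amps


def two_state_series(k1=0.01, residues=(1, 2, 3), noise_sd=0.0, seed=0,
                     acq=FULL_ACQ, rate_scales=None, amplitudes=None):
    peaks, amps = make_peaks(residues)
    if amplitudes:
        amps.update(amplitudes)
    model = KineticModelSpec(scheme="two_state", k1=k1,
                             per_residue_rate_scale=rate_scales or {},
                             amplitudes=amps, noise_sd=noise_sd, seed=seed)
    return simulate_conversion_series(model, acq, peaks)


def three_state_series(k1=0.01, k2=0.001, residues=(1, 2, 3), noise_sd=0.0,
                       seed=0, acq=FULL_ACQ):
    peaks, amps = make_peaks(residues)
    model = KineticModelSpec(scheme="three_state", k1=k1, k2=k2,
                             amplitudes=amps, noise_sd=noise_sd, seed=seed)
    return simulate_conversion_series(model, acq, peaks)


@pytest.fixture(scope="session")
def reference_structure():
    """30-residue synthetic fold with a glycine and a 10-residue ligand chain."""
    return build_reference_structure(30, glycines=(15,),
                                     ligand_sequence="FDVEEAKILR",
                                     ligand_offset=6.0)
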