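import numpy as np
import pandas as pd
import pytest

from sleepspec import FREQ_BINS, SpectraTable
from sleepspec.scoring import NormTables


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_norms():
    """Hand-built norm tables with known lookup chains.

    Age band 20-30: CFT 30 -> IQ 100; band 30.01-40 shifts IQ down by 5.
    APM table: percentile 10 -> raw 15, 50 -> 21, 90 -> 27.
    """
    cft = pd.DataFrame({
        "age_lo": [20.0] * 3 + [30.01] * 3,
        "age_hi": [30.0] * 3 + [40.0] * 3,
        "cft_raw": [20.0, 30.0, 40.0] * 2,
        "iq": [80.0, 100.0, 120.0, 75.0, 95.0, 115.0],
    })
    apm = pd.DataFrame({"percentile": [10.0, 50.0, 90.0],
                        "raven_raw": [15.0, 21.0, 27.0]})
    return NormTables(cft_to_iq=cft, apm_table=apm)


def random_spectra(rng, n_subjects=10, electrodes=("F3", "F4", "Cz"),
                   state="REM", missing=()):
    """A valid random SpectraTable; ``missing`` is a list of (subj_idx, elec)."""
    vals = rng.normal(-2.2, 0.2, size=(n_subjects, len(electrodes), len(FREQ_BINS)))
    vals = vals - np.log10((10.0 ** vals).sum(axis=2, keepdims=True))
    for si, el in missing:
        vals[si, list(electrodes).index(el)] = np.nan
    return SpectraTable(state=state,
                        subjects=[f"s{i:02d}" for i in range(n_subjects)],
                        electrodes=list(electrodes), values=vals)
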