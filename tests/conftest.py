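"""Shared fixtures: one synthetic study dataset reused across test modules."""
from __future__ import annotations

import numpy as np
import pytest

from hsimoist import (
    PreprocessSpec,
    Preprocessor,
    SyntheticConfig,
    default_trim,
    generate_spectra,
    spxy_split,
)


@pytest.fixture(scope="session")
def study():
    """An 80-sample study at default conditions: trimmed, split, pretreated."""
    config = SyntheticConfig(n_samples=80, seed=7)
    spectra, moisture = generate_spectra(config)
    trimmed = default_trim(spectra)
    split = spxy_split(trimmed, moisture, 0.75)
    xcal_raw = trimmed.select_samples(split.calibration_idx)
    xpred_raw = trimmed.select_samples(split.prediction_idx)
    pre = Preprocessor(PreprocessSpec(method="normalization")).fit(xcal_raw)
    return {
        "config": config,
        "spectra": trimmed,
        "moisture": moisture,
        "split": split,
        "xcal": pre.transform(xcal_raw),
        "xpred": pre.transform(xpred_raw),
        "ycal": moisture[split.calibration_idx],
        "ypred": moisture[split.prediction_idx],
        "preprocessor": pre,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
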