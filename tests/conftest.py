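import warnings

import numpy as np
import pytest

from stressnmr.chemometrics import fit_oplsda
from stressnmr.discrimination import (
    annotation_from_templates,
    recovery_report,
    select_discriminating,
)
from stressnmr.preprocess import (
    DEFAULT_SCHEMES,
    apply_exclusions,
    bin_cohort,
    normalize_rows,
)
from stressnmr.simulate import CohortDesign, Spectrum, load_templates, simulate_cohort


@pytest.fixture(scope="session")
def templates():
    return load_templates()


@pytest.fixture(scope="session")
def annotation(templates):
    return annotation_from_templates(templates, half_window_ppm=0.015)


@pytest.fixture
def make_spectrum():
    def _make(ppm, intensity, sample_id="s1", group="control"):
        return Spectrum(np.asarray(ppm, float), np.asarray(intensity, float),
                        sample_id, group)

    return _make


@pytest.fixture(scope="session")
def run_cohort_selection(templates, annotation):
    """Simulate -> bin -> exclude -> normalize -> OPLS-DA -> select, returning
    the recovery report against the simulated ground truth."""

    def _run(effects, seed, matrix_type="plasma", **design_kw):
        design = CohortDesign(metabolite_effects=effects, seed=seed, **design_kw)
        spectra, truth = simulate_cohort(templates, design)
        binned = bin_cohort(spectra, 0.005)
        binned = apply_exclusions(binned, DEFAULT_SCHEMES[matrix_type])
        binned = normalize_rows(binned)
        model = fit_oplsda(binned.values, binned.groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = select_discriminating(
                model.corr_loadings, binned.bin_centers, annotation
            )
        return table, recovery_report(table, truth)

    return _run
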