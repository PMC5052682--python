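"""Shared fixtures: small synthetic cohorts with known ground truth."""

import pandas as pd
import pytest

import sigimmune as si
from sigimmune import synthetic as syn


@pytest.fixture(scope="session")
def toy_catalog():
    return syn.make_toy_catalog(["age_like", "apobec_CtoT", "apobec_CtoG", "flat"])


@pytest.fixture(scope="session")
def small_cohort():
    """30 samples, ~60 mutations each, planted effects at the defaults."""
    cfg = syn.SyntheticCohortConfig(
        n_samples=30, n_genes=10, cds_length_range=(300, 600),
        mutations_per_sample_mean=60.0, seed=11,
    )
    return syn.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def attributed_cohort(small_cohort):
    """The small cohort run through classify -> refit -> attribute."""
    classified = si.classify_mutations(small_cohort.mutations, small_cohort.cds)
    spectra = si.build_spectrum(classified, per_sample=True)
    exposures = si.fit_exposures_per_sample(spectra, small_cohort.catalog)
    attr = si.attribute_mutations(
        classified, small_cohort.catalog,
        exposures[list(small_cohort.catalog.columns)],
    )
    return small_cohort, attr


@pytest.fixture(scope="session")
def annotated_cohort(attributed_cohort):
    cohort, attr = attributed_cohort
    ann = si.annotate_cohort(attr, cohort.cds, si.HashPredictor())
    return cohort, ann
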