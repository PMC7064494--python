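import numpy as np
import pytest

import blastomorph as bm
from blastomorph.annotation_io import SampleRecord
from blastomorph.feature_pipeline import FeatureTable, build_feature_table
from blastomorph.morphometry import FeatureConfig
from blastomorph.phantom import RegionTexture


def table_from_cohort(cohort, config: FeatureConfig | None = None) -> FeatureTable:
    """Extract the feature table of a generated cohort."""
    entries = [
        (
            s.micrograph,
            s.masks,
            SampleRecord(
                sample_id=s.micrograph.sample_id,
                age_years=s.age_years,
                microns_per_pixel=s.micrograph.microns_per_pixel,
                bhcg_mUI_per_mL=s.bhcg_mUI_per_mL,
            ),
        )
        for s in cohort.samples
    ]
    return build_feature_table(entries, config or FeatureConfig())


def zero_noise_spec(**kwargs) -> bm.PhantomSpec:
    """Phantom spec with perfectly flat region textures."""
    base = bm.PhantomSpec()
    textures = {
        name: RegionTexture(mean=t.mean, noise_sd=0.0, smoothing_px=t.smoothing_px)
        for name, t in base.region_texture.items()
    }
    kwargs.setdefault("region_texture", textures)
    kwargs.setdefault("te_noise_sd_jitter", 0.0)
    return bm.PhantomSpec(**kwargs)


#: Outcome-model coefficient settings used as the study's signal levels.
SIGNAL_COEFFS = {
    "zero": {},
    "moderate": {"zp_thickness": 0.8, "te_texture_sd": 0.6, "age": 0.4},
    "strong": {"zp_thickness": 2.0, "te_texture_sd": 1.5, "age": 1.0},
}


@pytest.fixture(scope="session")
def small_cohort():
    """Ten-sample cohort across both calibration regimes, 5/5 classes."""
    return bm.generate_cohort(bm.PhantomSpec(prevalence_target=0.5), 10,
                              seed=101, exact_prevalence=True)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return table_from_cohort(small_cohort)


@pytest.fixture(scope="session")
def table134():
    """Cohort emulating the larger clinical database: n=134, 53% positive."""
    cohort = bm.generate_cohort(bm.PhantomSpec(), 134, seed=202,
                                exact_prevalence=True)
    return table_from_cohort(cohort)


@pytest.fixture(scope="session")
def signal_tables():
    """Feature tables at three outcome-signal strengths, n=200 each."""
    out = {}
    for name, coeffs in SIGNAL_COEFFS.items():
        cohort = bm.generate_cohort(
            bm.PhantomSpec(outcome_coeffs=coeffs), 200, seed=303)
        out[name] = table_from_cohort(cohort)
    return out
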