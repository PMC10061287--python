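import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from clonarch.pipeline import PipelineConfig, Thresholds, run_pipeline
from clonarch.simulate import (
    CohortSpec,
    default_arm_model,
    synthetic_reference_spectra,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_spectra() -> pd.DataFrame:
    return synthetic_reference_spectra(5)


@pytest.fixture(scope="session")
def arm_model():
    return default_arm_model()


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """A small but complete cohort: three populations, planted subtypes with
    distinct drivers, arm events and immune shifts."""
    return CohortSpec(
        populations={"Asian": 12, "Black": 8, "White": 20},
        mutations_per_sample=60.0,
        subtype_driver_rates={
            "A": {"TP53": 0.7, "RB1": 0.6},
            "B": {"FGFR3": 0.7, "HRAS": 0.6},
        },
        subtype_arm_rates={"A": {"del(9p)": (0.7, 0.1)}},
        immune_shifts={
            "B": {"CD8 T cells": 1.2, "Th17 cells": 1.2},
            "A": {"Th2 cells": 1.0, "Macrophages": 1.0},
        },
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def tiny_run(tiny_spec, tmp_path_factory):
    """One full pipeline run on the tiny cohort, shared by readers."""
    import dataclasses

    outdir = tmp_path_factory.mktemp("tiny_run")
    cfg = PipelineConfig(
        outdir=str(outdir),
        rng_seed=7,
        synthetic={
            f.name: getattr(tiny_spec, f.name)
            for f in dataclasses.fields(tiny_spec)
            if f.name != "reference_spectra"
        },
        thresholds=Thresholds(n_perm=100, nmf_restarts=2),
    )
    run_pipeline(cfg)
    return outdir
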