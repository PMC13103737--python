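import json
import os
from types import SimpleNamespace

import pytest

from canisv.pipeline import PipelineConfig, run_full_pipeline
from canisv.synthetic_data import CohortParams, build_repeat_library, simulate_cohort


@pytest.fixture(scope="session")
def library():
    return build_repeat_library(1)


@pytest.fixture(scope="session")
def small_cohort(library):
    """A reduced cohort for fast unit-level checks."""
    params = CohortParams(
        seed=7,
        sinec_rate=0.004,
        line1_rate=0.001,
        n_transductions=6,
        n_doomed_transductions=1,
        n_str=6, n_vntr=4, n_ltr=3, n_satellite=2, n_mixed=3,
        n_partial=3, n_unclassified=3, n_deletion=4, n_intra_l1_deletion=2,
        n_ref_sinec=60, n_ref_line1=4, n_dup_pairs=8,
    )
    return simulate_cohort(library, params)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """The full pipeline at the default cohort scale, run once per session."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    config = PipelineConfig(outdir=str(outdir), seed=1)
    report = run_full_pipeline(config)
    with open(outdir / "sim" / "truth.json") as fh:
        truth = json.load(fh)
    return SimpleNamespace(config=config, report=report, truth=truth, outdir=str(outdir))
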