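import warnings

import numpy as np
import pandas as pd
import pytest

import p180
from p180.panel import MeasurementMatrix, STATUS_VALID


def make_matrix(values, samples, status=None):
    """Small-matrix builder for unit tests.

    ``values``: dict analyte -> list; ``samples``: list of dicts with
    sample_id and optional subject_id/plate_id/role/duplicate_group.
    """
    index = [s["sample_id"] for s in samples]
    vals = pd.DataFrame(values, index=index, dtype=float)
    if status is None:
        stat = pd.DataFrame(STATUS_VALID, index=index, columns=vals.columns)
    else:
        stat = pd.DataFrame(status, index=index)[list(vals.columns)]
    meta = pd.DataFrame(
        [
            {
                "subject_id": s.get("subject_id", s["sample_id"]),
                "plate_id": s.get("plate_id", "P01"),
                "role": s.get("role", "study"),
                "duplicate_group": s.get("duplicate_group", np.nan),
            }
            for s in samples
        ],
        index=index,
        columns=["subject_id", "plate_id", "role", "duplicate_group"],
    )
    for frame in (vals, stat, meta):
        frame.index.name = "sample_id"
    return MeasurementMatrix(vals, stat, meta)


def load_cohort(outdir):
    """Read a simulated cohort directory into pipeline inputs."""
    paths = p180.cohort_paths(outdir)
    matrix, runs = p180.read_level0(paths["plates"], paths["manifest"], paths["lod"])
    clinical = p180.read_clinical(paths["clinical"])
    lods = p180.read_lod_table(paths["lod"])
    return matrix, runs, clinical, lods, paths


def run_cohort(outdir, gt, pipe_outdir=None, config=None):
    matrix, runs, clinical, lods, paths = load_cohort(outdir)
    cfg = config or p180.PipelineConfig(exclusion_list=gt.thawed_samples)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final, audit, inter = p180.run_pipeline(matrix, clinical, lods, cfg, outdir=pipe_outdir)
    return final, audit, inter


def small_cohort_config(seed, **overrides):
    """A fast defect-planted cohort: 3 plates, 40 analytes, 20 blinded pairs."""
    base = dict(
        seed=seed,
        n_plates=3,
        study_wells_per_plate=40,
        n_study_samples=120,
        n_duplicate_pairs=20,
        n_analytes=40,
        n_high_cv=2,
        n_low_icc=2,
        n_high_censor=2,
        n_outlier_subjects=1,
        outlier_n_analytes=10,
        n_thawed=2,
        n_nonfasting=3,
        n_missing_bmi=1,
        n_missing_meds=1,
    )
    base.update(overrides)
    return p180.SimulationConfig(**base)


@pytest.fixture(scope="session")
def reference_fixture(tmp_path_factory):
    """The deterministic packaged fixture plus its ground truth."""
    d = tmp_path_factory.mktemp("reffix")
    gt = p180.make_reference_fixture(d)
    return d, gt


@pytest.fixture(scope="session")
def fixture_run(reference_fixture, tmp_path_factory):
    """Fixture cohort run end-to-end once, shared across tests."""
    d, gt = reference_fixture
    out = tmp_path_factory.mktemp("reffix_out")
    final, audit, inter = run_cohort(d, gt, pipe_outdir=out)
    return {"dir": d, "gt": gt, "out": out, "final": final, "audit": audit, "inter": inter}
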