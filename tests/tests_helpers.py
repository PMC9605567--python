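"""Shared test-data builders."""

import numpy as np

from harmoz import CovariateSpec, SubjectRecord, VolumeTable
from harmoz.model import build_design_row


def surface_cohort(n, rng, noise=0.0, n_rois=2):
    """Cohort whose volumes sit exactly on (or near) a variant-(d)
    generative surface; used where exact recovery matters."""
    betas = [
        (3.5, (-0.001, -0.02, 0.01, 0.7)),
        (4.0, (-0.0008, -0.015, 0.02, 0.6)),
        (3.2, (-0.0012, -0.025, 0.005, 0.8)),
    ]
    spec = CovariateSpec()
    subjects, rows = [], []
    for i in range(n):
        s = SubjectRecord(
            f"s{i}",
            age=float(rng.uniform(45, 90)),
            sex=int(rng.integers(2)),
            field_strength=int(rng.integers(2)),
            etiv=float(rng.uniform(1.2e6, 1.8e6)),
        )
        x = build_design_row(s, spec)
        row = []
        for j in range(n_rois):
            b0, b = betas[j % len(betas)]
            row.append(10.0 ** (b0 + float(np.dot(b, x)) + rng.normal(0, noise)))
        subjects.append(s)
        rows.append(row)
    table = VolumeTable(
        [s.subject_id for s in subjects], [f"roi{j}" for j in range(n_rois)], rows
    )
    return subjects, table
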