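"""File I/O: volume/metadata/Z-score tables (CSV/TSV) and model JSON.

Dialect: comma-separated with a header row, UTF-8; files ending in
``.tsv`` are tab-separated. Column names are case-sensitive. Lines
starting with ``#`` are provenance comments and are skipped on read.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    Group,
    SubjectRecord,
    VolumeTable,
    ZScoreTable,
)
from .model import CovariateSpec, HarmonizationModel, RoiAdjustment

__all__ = [
    "read_volume_table",
    "write_volume_table",
    "read_subject_metadata",
    "write_subject_metadata",
    "read_zscore_table",
    "write_zscore_table",
    "save_model",
    "load_model",
    "MODEL_FORMAT_VERSION",
]

MODEL_FORMAT_VERSION = 1

_SEX_ALIASES = {
    "0": 0, "1": 1, "f": 0, "m": 1, "female": 0, "male": 1,
}
_FIELD_ALIASES = {
    "0": 0, "1": 1, "3t": 0, "1.5t": 1, "3": 0, "1.5": 1, "3.0": 0,
}

_METADATA_COLUMNS = ("subject_id", "age", "sex", "field_strength", "etiv")


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str)


def _provenance_header(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def read_volume_table(
    path: str | Path, roi_names: list[str] | None = None
) -> VolumeTable:
    """Read a wide subjects x ROIs volume table (mm^3).

    The first column is the subject id; every other column is an ROI.
    Empty cells are missing measurements; zero, negative or non-numeric
    volumes are validation errors naming the offending cell. If
    ``roi_names`` is given, the file's ROI columns must match it exactly
    (order included).
    """
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a subject_id column plus at least one ROI column")
    sid_col = df.columns[0]
    subject_ids = [str(s) for s in df[sid_col]]
    rois = [str(c) for c in df.columns[1:]]
    if roi_names is not None and rois != list(roi_names):
        raise ValueError(
            f"{path}: ROI columns do not match the expected catalog "
            f"(expected {len(roi_names)} ROIs, found {len(rois)})"
        )
    values = np.empty((len(subject_ids), len(rois)))
    for j, roi in enumerate(rois):
        col = df[roi].to_numpy()
        for i, cell in enumerate(col):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                values[i, j] = np.nan
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric volume {cell!r} for subject "
                    f"{subject_ids[i]!r}, ROI {roi!r}"
                ) from None
            if not (np.isfinite(v) and v > 0):
                raise ValueError(
                    f"{path}: invalid volume {v} for subject {subject_ids[i]!r}, "
                    f"ROI {roi!r} (must be strictly positive and finite)"
                )
            values[i, j] = v
    return VolumeTable(subject_ids=subject_ids, roi_names=rois, volumes=values)


def write_volume_table(
    table: VolumeTable, path: str | Path, provenance: dict | None = None
) -> None:
    path = Path(path)
    buf = _io.StringIO()
    buf.write(_provenance_header(provenance))
    table.to_dataframe().to_csv(buf, sep=_sep_for(path), float_format="%.17g")
    path.write_text(buf.getvalue(), encoding="utf-8")


def _parse_code(token: str, aliases: dict[str, int], what: str, sid: str) -> int:
    key = str(token).strip().lower()
    if key in aliases:
        return aliases[key]
    raise ValueError(f"subject {sid!r}: unknown {what} token {token!r}")


def read_subject_metadata(path: str | Path) -> list[SubjectRecord]:
    """Read subject metadata (subject_id, age, sex, field_strength, etiv,
    optional group).

    Textual codes are accepted: sex "F"/"M"/"female"/"male" map to 0/1,
    field strength "3T"/"1.5T" map to 0/1 (3 T is the reference coding 0).
    Missing ``group`` defaults to "other".
    """
    df = _read_table(path)
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required metadata column(s): {missing}")
    records: list[SubjectRecord] = []
    has_group = "group" in df.columns
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        try:
            age = float(row["age"])
            etiv = float(row["etiv"])
        except (TypeError, ValueError):
            raise ValueError(f"{path}: non-numeric age or eTIV for subject {sid!r}") from None
        records.append(
            SubjectRecord(
                subject_id=sid,
                age=age,
                sex=_parse_code(row["sex"], _SEX_ALIASES, "sex", sid),
                field_strength=_parse_code(
                    row["field_strength"], _FIELD_ALIASES, "field strength", sid
                ),
                etiv=etiv,
                group=Group.parse(row["group"]) if has_group and not pd.isna(row["group"]) else Group.OTHER,
            )
        )
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate subject_id(s): {dup[:5]}")
    return records


def write_subject_metadata(
    subjects: list[SubjectRecord], path: str | Path, provenance: dict | None = None
) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "field_strength": [s.field_strength for s in subjects],
            "etiv": [s.etiv for s in subjects],
            "group": [s.group.value for s in subjects],
        }
    )
    buf = _io.StringIO()
    buf.write(_provenance_header(provenance))
    df.to_csv(buf, sep=_sep_for(path), index=False, float_format="%.17g")
    path.write_text(buf.getvalue(), encoding="utf-8")


def write_zscore_table(
    table: ZScoreTable, path: str | Path, mask_path: str | Path | None = None,
    provenance: dict | None = None,
) -> None:
    """Write Z values (CSV/TSV); optionally write the per-cell mask beside
    them. Missing cells are empty fields."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write(_provenance_header(provenance))
    table.to_dataframe().to_csv(buf, sep=_sep_for(path), float_format="%.17g")
    path.write_text(buf.getvalue(), encoding="utf-8")
    if mask_path is not None:
        mask_path = Path(mask_path)
        table.mask_dataframe().to_csv(mask_path, sep=_sep_for(mask_path))


def read_zscore_table(
    path: str | Path, mask_path: str | Path | None = None
) -> ZScoreTable:
    """Read a Z table; if no mask file is given, NaN cells are ``missing``
    and everything else ``scored``."""
    df = _read_table(path)
    sid_col = df.columns[0]
    z = df.iloc[:, 1:].astype(float).to_numpy()
    mask = None
    if mask_path is not None:
        mdf = pd.read_csv(mask_path, sep=_sep_for(mask_path), comment="#", dtype=str)
        mask = mdf.iloc[:, 1:].to_numpy(dtype=object)
    return ZScoreTable(
        subject_ids=[str(s) for s in df[sid_col]],
        roi_names=[str(c) for c in df.columns[1:]],
        z=z,
        mask=mask,
    )


def save_model(
    model: HarmonizationModel, path: str | Path, provenance: dict | None = None
) -> None:
    """Serialize a fitted model to JSON with explicit covariate ordering.

    All floats are written at full precision (repr round-trip), so
    load(save(m)) reproduces every coefficient bitwise.
    """
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "covariates": list(model.spec.included),
        "n_ref": model.n_ref,
        "xbar": model.xbar.tolist(),
        "cov": model.cov.tolist(),
        "rois": {
            roi: {
                "intercept": float(model.intercepts[j]),
                "slopes": model.slopes[j].tolist(),
                "sigma2": float(model.sigma2[j]),
            }
            for j, roi in enumerate(model.roi_names)
        },
        "roi_adjustments": {
            roi: {
                "n": adj.n,
                "xbar": adj.xbar.tolist(),
                "cov": adj.cov.tolist(),
                "excluded_subjects": list(adj.excluded_subjects),
            }
            for roi, adj in model.roi_adjustments.items()
        },
    }
    if provenance:
        payload["provenance"] = provenance
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def load_model(
    path: str | Path, expected_spec: CovariateSpec | None = None
) -> HarmonizationModel:
    """Load a model JSON; errors on format-version or covariate-spec
    mismatch."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported model format version {version!r} "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    spec = CovariateSpec(tuple(payload["covariates"]))
    if expected_spec is not None and spec != expected_spec:
        raise ValueError(
            f"{path}: model covariates {spec.included} do not match the "
            f"expected spec {expected_spec.included}"
        )
    rois = payload["rois"]
    roi_names = list(rois.keys())
    adjustments = {
        roi: RoiAdjustment(
            n=int(a["n"]),
            xbar=np.array(a["xbar"], dtype=float),
            cov=np.array(a["cov"], dtype=float),
            excluded_subjects=list(a["excluded_subjects"]),
        )
        for roi, a in payload.get("roi_adjustments", {}).items()
    }
    return HarmonizationModel(
        spec=spec,
        roi_names=roi_names,
        intercepts=np.array([rois[r]["intercept"] for r in roi_names]),
        slopes=np.array([rois[r]["slopes"] for r in roi_names]),
        sigma2=np.array([rois[r]["sigma2"] for r in roi_names]),
        n_ref=int(payload["n_ref"]),
        xbar=np.array(payload["xbar"], dtype=float),
        cov=np.array(payload["cov"], dtype=float),
        roi_adjustments=adjustments,
    )
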