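"""Reading and writing the pipeline's on-disk formats.

Cohorts travel as two delimited text tables (a long-format region-sample
table and a clinical table); similarity matrices as an HDF5 container
keyed by subject and timepoint, or as delimited text with a header row
of region labels. Every table written by a pipeline run carries the run
config hash in a ``#`` header comment.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .cohort import SubjectProfile, clinical_table
from .similarity import SimilarityMatrix

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_matrices_h5",
    "read_matrices_h5",
    "write_matrix_text",
    "read_matrix_text",
    "write_table",
]

SAMPLE_COLUMNS = ("subject_id", "group", "arm", "timepoint", "region", "value")


def write_table(df: pd.DataFrame, path: str, config_hash: str | None = None) -> str:
    """Write a CSV with an optional config-hash header comment."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)
    return path


def _read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_cohort(
    profiles: Sequence[SubjectProfile], out_dir: str, config_hash: str | None = None
) -> dict[str, str]:
    """Write the long-format sample table and the clinical table."""
    os.makedirs(out_dir, exist_ok=True)
    samples_path = os.path.join(out_dir, "samples.csv")
    clinical_path = os.path.join(out_dir, "clinical.csv")

    with open(samples_path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        fh.write(",".join(SAMPLE_COLUMNS) + "\n")
        for p in profiles:
            n_regions, n_vox = p.region_samples.shape
            prefix = f"{p.subject_id},{p.group},{p.arm},{p.timepoint},"
            for r in range(n_regions):
                row = p.region_samples[r]
                fh.writelines(
                    prefix + f"{r + 1},{row[v]:.10g}\n" for v in range(n_vox)
                )
    write_table(clinical_table(profiles), clinical_path, config_hash)
    return {"samples": samples_path, "clinical": clinical_path}


def read_cohort(samples_path: str, clinical_path: str) -> tuple[list[SubjectProfile], pd.DataFrame]:
    """Parse a cohort written by :func:`write_cohort` (lossless round trip).

    Validates required columns, region-index completeness per
    subject-timepoint, and uniqueness of clinical rows; failures name
    the offending column/indices.
    """
    samples = _read_table(samples_path)
    clinical = _read_table(clinical_path)

    missing_cols = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing_cols:
        raise ValueError(f"sample table missing required column(s): {missing_cols}")
    for col in ("subject_id", "timepoint", "ymrs"):
        if col not in clinical.columns:
            raise ValueError(f"clinical table missing required column(s): ['{col}']")
    dup = clinical.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        dupes = clinical.loc[dup, ["subject_id", "timepoint"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate subject-timepoint clinical rows: {dupes}")

    regions = samples["region"].unique()
    n_regions = int(regions.max())
    expected = set(range(1, n_regions + 1))
    clin_ix = clinical.set_index(["subject_id", "timepoint"])

    profiles: list[SubjectProfile] = []
    # preserve file order of subject-timepoint blocks
    for (sid, tp), block in samples.groupby(["subject_id", "timepoint"], sort=False):
        present = set(block["region"].unique())
        if present != expected:
            missing = sorted(expected - present)
            raise ValueError(
                f"subject {sid} at {tp}: missing region index(es) {missing}"
            )
        counts = block.groupby("region").size()
        if counts.nunique() != 1:
            raise ValueError(f"subject {sid} at {tp}: unequal sample counts per region")
        n_vox = int(counts.iloc[0])
        mat = np.empty((n_regions, n_vox))
        for r, sub in block.groupby("region"):
            mat[int(r) - 1] = sub["value"].to_numpy()
        try:
            clin = clin_ix.loc[(sid, tp)]
        except KeyError:
            raise ValueError(f"subject {sid} at {tp}: no matching clinical row") from None
        responder = clin.get("responder")
        profiles.append(
            SubjectProfile(
                subject_id=str(sid),
                group=str(block["group"].iloc[0]),
                arm=str(block["arm"].iloc[0]),
                timepoint=str(tp),
                age=float(clin.get("age", np.nan)),
                sex=str(clin.get("sex", "")),
                ymrs=int(clin["ymrs"]),
                cdrs=int(clin.get("cdrs", 0)),
                cgis=int(clin.get("cgis", 0)),
                responder=None if pd.isna(responder) else bool(responder),
                region_samples=mat,
            )
        )
    return profiles, clinical


def write_matrices_h5(matrices: Iterable[SimilarityMatrix], path: str) -> str:
    """Store similarity matrices keyed by ``subject_id/timepoint``."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with h5py.File(path, "w") as f:
        for m in matrices:
            ds = f.create_dataset(
                f"{m.subject_id}/{m.timepoint}", data=m.values, track_times=False
            )
            ds.attrs["region_labels"] = list(m.region_labels)
    return path


def read_matrices_h5(path: str) -> list[SimilarityMatrix]:
    out: list[SimilarityMatrix] = []
    with h5py.File(path, "r") as f:
        for sid in f:
            for tp in f[sid]:
                ds = f[sid][tp]
                labels = tuple(
                    s.decode() if isinstance(s, bytes) else str(s)
                    for s in ds.attrs["region_labels"]
                )
                out.append(
                    SimilarityMatrix(
                        values=ds[()], region_labels=labels, subject_id=sid, timepoint=tp
                    )
                )
    return out


def write_matrix_text(matrix: SimilarityMatrix, path: str) -> str:
    """One matrix as delimited text with a header row of region labels."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        fh.write(",".join(matrix.region_labels) + "\n")
        np.savetxt(fh, matrix.values, delimiter=",", fmt="%.10g")
    return path


def read_matrix_text(path: str, subject_id: str = "", timepoint: str = "") -> SimilarityMatrix:
    with open(path) as fh:
        labels = tuple(fh.readline().strip().split(","))
        values = np.loadtxt(fh, delimiter=",")
    return SimilarityMatrix(
        values=values, region_labels=labels, subject_id=subject_id, timepoint=timepoint
    )
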