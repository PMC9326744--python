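"""Loading a phantom-style cohort directory back into subjects."""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .image_io import read_nifti
from .phantom import PhantomSubject

__all__ = ["load_cohort"]


def load_cohort(data_dir: str | Path) -> list[PhantomSubject]:
    """Read ``<id>_image.nii.gz`` / ``<id>_truth.nii.gz`` pairs plus
    ``manifest.csv`` as written by :func:`adpkdvol.phantom.write_cohort`."""
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    subjects = []
    for row in manifest.itertuples():
        image = read_nifti(data_dir / f"{row.subject_id}_image.nii.gz", kind="image")
        truth = read_nifti(data_dir / f"{row.subject_id}_truth.nii.gz", kind="labels")
        subjects.append(
            PhantomSubject(
                image=image,
                truth=truth,
                height_m=float(row.height_m),
                sequence_name=str(row.sequence_name),
                subject_id=str(row.subject_id),
            )
        )
    return subjects
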