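"""Core data types and file I/O for cine sequences and survival tables.

A cine sequence is a 2D+t grayscale stack — the four-chamber view of the
beating heart sampled over one cardiac cycle.  Sequences travel as NIfTI
volumes whose slice axis is time; per-subject outcomes travel as a
comma-delimited survival table with an integer event code
(0 = censored, 1 = primary event, 2 = competing death).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CineSequence",
    "SurvivalRecord",
    "CohortTable",
    "read_cine",
    "write_cine",
    "read_survival_table",
    "write_survival_table",
    "crop_and_resample",
    "estimate_heart_center",
]

EVENT_CODES = (0, 1, 2)


@dataclass
class CineSequence:
    """A 2D+t grayscale image stack with spatial spacing and frame timing.

    Parameters
    ----------
    frames
        Intensity array indexed ``(t, row, col)``; arbitrary non-negative units.
    pixel_spacing_mm
        In-plane spacing, (row, col), millimetres.
    frame_interval_ms
        Time between consecutive frames, milliseconds.
    subject_id
        Opaque identifier.
    """

    frames: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    frame_interval_ms: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3D (t, row, col); got ndim={self.frames.ndim}")
        if self.frames.shape[0] < 2:
            raise ValueError("a cine sequence needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if np.any(self.frames < 0):
            raise ValueError("frame intensities must be non-negative")
        sr, sc = self.pixel_spacing_mm
        if sr <= 0 or sc <= 0:
            raise ValueError(f"pixel spacing must be positive; got {self.pixel_spacing_mm}")
        self.pixel_spacing_mm = (float(sr), float(sc))
        if self.frame_interval_ms <= 0:
            raise ValueError("frame interval must be positive")
        self.frame_interval_ms = float(self.frame_interval_ms)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]


@dataclass
class SurvivalRecord:
    """Time-to-event outcome for one subject.

    ``event_code`` 0 = right-censored, 1 = primary event (e.g. ventricular
    arrhythmia), 2 = competing death.  Time is in years.
    """

    subject_id: str
    time: float
    event_code: int
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = float(self.time)
        if self.time <= 0:
            raise ValueError(f"time must be positive; got {self.time} for {self.subject_id!r}")
        self.event_code = int(self.event_code)
        if self.event_code not in EVENT_CODES:
            raise ValueError(f"event_code must be in {EVENT_CODES}; got {self.event_code}")
        self.covariates = {str(k): float(v) for k, v in dict(self.covariates).items()}
        for k, v in self.covariates.items():
            if not np.isfinite(v):
                raise ValueError(f"covariate {k!r} is not finite for {self.subject_id!r}")


@dataclass
class CohortTable:
    """Ordered collection of survival records for one outcome."""

    records: list[SurvivalRecord]
    outcome_label: str = "VA"

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("cohort must be non-empty")
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records], dtype=float)

    def event_codes(self) -> np.ndarray:
        return np.array([r.event_code for r in self.records], dtype=int)

    def event_flags(self, outcome: str | None = None) -> np.ndarray:
        """Binary event indicator under the outcome's censoring semantics.

        The primary outcome counts code-1 events; competing deaths (code 2)
        are censoring for it.  ``all_cause_death`` counts codes 1 and 2.
        """
        label = (outcome or self.outcome_label).lower()
        codes = self.event_codes()
        if label in ("all_cause", "all_cause_death"):
            return (codes > 0).astype(int)
        return (codes == 1).astype(int)

    def covariate(self, name: str) -> np.ndarray:
        try:
            return np.array([r.covariates[name] for r in self.records], dtype=float)
        except KeyError:
            raise KeyError(f"covariate {name!r} missing from at least one record") from None

    def covariate_names(self) -> list[str]:
        names: list[str] = []
        for r in self.records:
            for k in r.covariates:
                if k not in names:
                    names.append(k)
        return names

    def subset(self, subject_ids: Sequence[str]) -> "CohortTable":
        wanted = set(subject_ids)
        recs = [r for r in self.records if r.subject_id in wanted]
        missing = wanted - {r.subject_id for r in recs}
        if missing:
            raise KeyError(f"subjects not in cohort: {sorted(missing)}")
        return CohortTable(records=recs, outcome_label=self.outcome_label)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"subject_id": r.subject_id, "time": r.time, "event_code": r.event_code}
            row.update(r.covariates)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NIfTI cine I/O.  Convention: on-disk array axes are (row, col, t) so the
# NIfTI slice axis is time; pixdim carries (row mm, col mm, frame ms).
# ---------------------------------------------------------------------------


def read_cine(path: str | Path, subject_id: str | None = None) -> CineSequence:
    """Read a cine sequence from a NIfTI volume (slice axis = time)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such cine file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume (row, col, t); got ndim={data.ndim}")
    zooms = img.header.get_zooms()
    sr, sc, dt = float(zooms[0]), float(zooms[1]), float(zooms[2])
    if sr <= 0 or sc <= 0:
        raise ValueError(f"{path}: non-positive pixel spacing {zooms[:2]}")
    frames = np.moveaxis(data, 2, 0)  # (t, row, col)
    return CineSequence(
        frames=frames,
        pixel_spacing_mm=(sr, sc),
        frame_interval_ms=dt if dt > 0 else 1.0,
        subject_id=subject_id if subject_id is not None else path.stem.replace(".nii", ""),
    )


def write_cine(seq: CineSequence, path: str | Path) -> Path:
    """Write a cine sequence as NIfTI; inverse of :func:`read_cine`."""
    path = Path(path)
    data = np.moveaxis(seq.frames, 0, 2)  # (row, col, t)
    img = nib.Nifti1Image(data.astype(np.float32), affine=np.eye(4))
    img.header.set_zooms((seq.pixel_spacing_mm[0], seq.pixel_spacing_mm[1], seq.frame_interval_ms))
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Survival tables: CSV with header subject_id, time, event_code, covariates.
# ---------------------------------------------------------------------------

_RESERVED_COLUMNS = ("subject_id", "time", "event_code")


def read_survival_table(path: str | Path, outcome_label: str = "VA") -> CohortTable:
    """Read a per-subject survival table; unknown columns become covariates."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such survival table: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _RESERVED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    covariate_cols = [c for c in df.columns if c not in _RESERVED_COLUMNS]
    records = [
        SurvivalRecord(
            subject_id=str(row["subject_id"]),
            time=row["time"],
            event_code=row["event_code"],
            covariates={c: row[c] for c in covariate_cols},
        )
        for _, row in df.iterrows()
    ]
    return CohortTable(records=records, outcome_label=outcome_label)


def write_survival_table(cohort: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_frame().to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Geometric preprocessing
# ---------------------------------------------------------------------------


def estimate_heart_center(seq: CineSequence) -> tuple[float, float]:
    """Fallback localizer: intensity centroid of above-median pixels, frame 0."""
    f0 = seq.frames[0]
    thresh = np.median(f0)
    mask = f0 > thresh
    if not mask.any():
        return ((f0.shape[0] - 1) / 2.0, (f0.shape[1] - 1) / 2.0)
    weights = np.where(mask, f0, 0.0)
    total = weights.sum()
    rows, cols = np.mgrid[0 : f0.shape[0], 0 : f0.shape[1]]
    return (float((rows * weights).sum() / total), float((cols * weights).sum() / total))


def crop_and_resample(
    seq: CineSequence,
    center_rc: tuple[float, float] | None = None,
    out_size: int = 128,
    out_spacing_mm: float = 2.2,
) -> CineSequence:
    """Crop around the heart and resample to an isotropic square grid.

    Every frame is bilinearly resampled onto an ``out_size`` x ``out_size``
    grid with isotropic ``out_spacing_mm`` centred at ``center_rc``
    (0-based pixel coordinates, row/col, pixel-centre convention).  Samples
    falling outside the source extent are 0.  Intensities are then min-max
    normalised to [0, 1] per sequence; a constant sequence maps to all zeros.
    """
    if out_size < 8:
        raise ValueError("out_size must be >= 8")
    if out_spacing_mm <= 0:
        raise ValueError("out_spacing_mm must be positive")
    nrow, ncol = seq.frame_shape
    if nrow < 2 or ncol < 2:
        raise ValueError("degenerate input frame")
    if center_rc is None:
        center_rc = estimate_heart_center(seq)
    cr, cc = float(center_rc[0]), float(center_rc[1])
    if not (0 <= cr <= nrow - 1 and 0 <= cc <= ncol - 1):
        raise ValueError(f"center {center_rc} outside image of shape {(nrow, ncol)}")

    # Physical offsets of output pixel centres from the crop centre, in mm,
    # mapped back to fractional source-pixel coordinates.
    half = (out_size - 1) / 2.0
    offsets_mm = (np.arange(out_size) - half) * out_spacing_mm
    src_rows = cr + offsets_mm / seq.pixel_spacing_mm[0]
    src_cols = cc + offsets_mm / seq.pixel_spacing_mm[1]
    grid_r, grid_c = np.meshgrid(src_rows, src_cols, indexing="ij")
    coords = np.stack([grid_r.ravel(), grid_c.ravel()])

    out = np.empty((seq.n_frames, out_size, out_size), dtype=np.float64)
    for t in range(seq.n_frames):
        out[t] = ndimage.map_coordinates(
            seq.frames[t], coords, order=1, mode="constant", cval=0.0
        ).reshape(out_size, out_size)

    lo, hi = out.min(), out.max()
    out = (out - lo) / (hi - lo) if hi > lo else np.zeros_like(out)
    return CineSequence(
        frames=out,
        pixel_spacing_mm=(out_spacing_mm, out_spacing_mm),
        frame_interval_ms=seq.frame_interval_ms,
        subject_id=seq.subject_id,
    )
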