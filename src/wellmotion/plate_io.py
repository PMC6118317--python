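"""Plate image-directory and table I/O.

The on-disk contract is deliberately simple: one subfolder per
timepoint named ``t{index:04d}``, each holding two single-plane
grayscale TIFFs per well named ``{WellID}_f1.tif`` and
``{WellID}_f2.tif``, where a well ID is a row letter plus zero-padded
column (``A01`` .. ``H12``).  Timepoint index 0 is acquisition start;
minutes = index x cadence (default 5 min over a 3-hr run, i.e. 37
timepoints).  A plate-map CSV assigns each well its compound, dose,
strain, stage and control flag.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .segmentation import MobilityRecord, SegmentationParams

__all__ = [
    "WELL_RE",
    "PlateMap",
    "PlateImageSet",
    "scan_image_directory",
    "read_frame_pair",
    "write_results",
    "read_results",
    "load_plate_config",
]

WELL_RE = re.compile(r"^[A-H](0[1-9]|1[0-2])$")
_FRAME_RE = re.compile(r"^(?P<well>[A-Ha-h]\d{2})_f(?P<frame>[12])\.tiff?$", re.I)
_TDIR_RE = re.compile(r"^t(?P<idx>\d+)$")

PLATE_MAP_COLUMNS = ["well", "compound", "dose", "unit", "strain", "stage", "is_control"]
RESULT_COLUMNS = [
    "well", "time_min", "compound", "dose", "unit", "strain", "stage",
    "is_control", "fms", "moving_px", "total_px", "valid",
]
STAGES = {"L1", "L2", "L3", "L4", "adult"}


@dataclass
class PlateMap:
    """Well annotations for one plate, backed by a DataFrame."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = set(PLATE_MAP_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"plate map missing columns: {sorted(missing)}")
        if df["well"].duplicated().any():
            dups = sorted(df.loc[df["well"].duplicated(), "well"])
            raise ValueError(f"duplicate well ids in plate map: {dups}")
        bad = [w for w in df["well"] if not WELL_RE.match(str(w))]
        if bad:
            raise ValueError(f"malformed well ids: {bad}")
        df["is_control"] = df["is_control"].astype(bool)
        df["dose"] = df["dose"].astype(float)
        if (df["dose"] < 0).any():
            raise ValueError("doses must be non-negative")
        noctrl = df[~df["is_control"]]
        if (noctrl["dose"] == 0).any():
            zero = sorted(noctrl.loc[noctrl["dose"] == 0, "well"])
            raise ValueError(
                f"non-control wells with dose 0: {zero} (flag them is_control)"
            )
        # one unit per compound series
        units = df[~df["is_control"]].groupby("compound")["unit"].nunique()
        mixed = units[units > 1]
        if not mixed.empty:
            raise ValueError(f"mixed dose units within compound(s): {list(mixed.index)}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlateMap":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def wells(self) -> list[str]:
        return list(self.table["well"])

    @property
    def control_wells(self) -> list[str]:
        return list(self.table.loc[self.table["is_control"], "well"])


@dataclass
class PlateImageSet:
    """Index of a plate's image files on disk.

    ``frame_pairs`` maps (well_id, timepoint_index) to the two frame
    paths; ``timepoints_min`` converts indices to minutes via the
    cadence.
    """

    root: Path
    timepoint_indices: list[int]
    frame_pairs: dict[tuple[str, int], tuple[Path, Path]]
    bit_depth: int
    cadence_min: float = 5.0
    warnings_: list[str] = field(default_factory=list)

    @property
    def timepoints_min(self) -> list[float]:
        return [i * self.cadence_min for i in self.timepoint_indices]

    @property
    def wells(self) -> list[str]:
        return sorted({w for w, _ in self.frame_pairs})


def _bit_depth_of(path: Path) -> int:
    dtype = tifffile.imread(path).dtype
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    raise ValueError(f"{path}: unsupported TIFF dtype {dtype}; need uint8 or uint16")


def scan_image_directory(root: str | Path, cadence_min: float = 5.0) -> PlateImageSet:
    """Index a plate directory into a :class:`PlateImageSet`.

    Wells missing one frame of a pair are dropped for that timepoint
    with a warning (long acquisitions commonly lose frames); an empty
    directory or mixed bit depths are fatal.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"plate directory not found: {root}")
    tdirs = sorted(
        (int(m.group("idx")), p)
        for p in root.iterdir()
        if p.is_dir() and (m := _TDIR_RE.match(p.name))
    )
    if not tdirs:
        raise ValueError(f"no timepoint subfolders (t0000, t0001, ...) under {root}")

    notes: list[str] = []
    frame_pairs: dict[tuple[str, int], tuple[Path, Path]] = {}
    sample_files: list[Path] = []
    for t_idx, tdir in tdirs:
        frames: dict[tuple[str, int], Path] = {}
        for f in sorted(tdir.iterdir()):
            if not f.is_file():
                continue
            m = _FRAME_RE.match(f.name)
            if not m:
                msg = f"unparseable filename skipped: {f}"
                notes.append(msg)
                warnings.warn(msg)
                continue
            frames[(m.group("well").upper(), int(m.group("frame")))] = f
        wells_here = {w for w, _ in frames}
        for well in sorted(wells_here):
            f1, f2 = frames.get((well, 1)), frames.get((well, 2))
            if f1 is None or f2 is None:
                msg = f"well {well} at t{t_idx:04d} missing a frame; pair dropped"
                notes.append(msg)
                warnings.warn(msg)
                continue
            frame_pairs[(well, t_idx)] = (f1, f2)
            if not sample_files:
                sample_files.append(f1)
    if not frame_pairs:
        raise ValueError(f"no complete frame pairs under {root}")

    depths = {_bit_depth_of(p) for p in {paths[0] for paths in list(frame_pairs.values())[:: max(1, len(frame_pairs) // 8)]}}
    if len(depths) > 1:
        raise ValueError(f"mixed TIFF bit depths in plate: {sorted(depths)}")

    return PlateImageSet(
        root=root,
        timepoint_indices=[i for i, _ in tdirs],
        frame_pairs=frame_pairs,
        bit_depth=depths.pop(),
        cadence_min=cadence_min,
        warnings_=notes,
    )


def _load_gray(path: Path) -> np.ndarray:
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-plane grayscale TIFF")
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    if img.dtype == np.uint16:
        return img.astype(float) / 65535.0
    raise ValueError(f"{path}: unsupported dtype {img.dtype}")


def read_frame_pair(
    image_set: PlateImageSet, well_id: str, timepoint_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Load one well's frame pair, rescaled to [0, 1] floats.

    The rescaling makes 8- and 16-bit plates interchangeable
    downstream.
    """
    key = (well_id, timepoint_index)
    if key not in image_set.frame_pairs:
        raise KeyError(f"no frame pair for well {well_id} at t{timepoint_index:04d}")
    p1, p2 = image_set.frame_pairs[key]
    f1, f2 = _load_gray(p1), _load_gray(p2)
    if f1.shape != f2.shape:
        raise ValueError(
            f"well {well_id} t{timepoint_index:04d}: frame shapes differ "
            f"({f1.shape} vs {f2.shape})"
        )
    return f1, f2


def write_results(
    records: list[MobilityRecord], plate_map: PlateMap, out: str | Path
) -> pd.DataFrame:
    """Write the tidy long-format results CSV (one row per record).

    Rows are ordered by well then time; invalid records carry an empty
    ``fms`` field and ``valid=False``.
    """
    if not records:
        raise ValueError("no records to write")
    pm = plate_map.table.set_index("well")
    known = set(pm.index)
    rows = []
    for r in records:
        if r.well_id not in known:
            raise ValueError(f"record references well {r.well_id} absent from plate map")
        meta = pm.loc[r.well_id]
        rows.append(
            {
                "well": r.well_id,
                "time_min": r.timepoint_min,
                "compound": meta["compound"],
                "dose": meta["dose"],
                "unit": meta["unit"],
                "strain": meta["strain"],
                "stage": meta["stage"],
                "is_control": bool(meta["is_control"]),
                "fms": r.fms if r.valid else np.nan,
                "moving_px": r.moving_px,
                "total_px": r.total_px,
                "valid": r.valid,
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df = df.sort_values(["well", "time_min"], kind="stable").reset_index(drop=True)
    df.to_csv(out, index=False)
    return df


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results CSV back into the tidy table."""
    df = pd.read_csv(path)
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"results file missing columns: {sorted(missing)}")
    df["valid"] = df["valid"].astype(bool)
    return df


def load_plate_config(path: str | Path) -> dict:
    """Load a plate-level YAML config.

    Recognized keys: ``cadence_min``, ``adult_mode``, ``seed`` and a
    ``segmentation`` mapping whose entries override
    :class:`SegmentationParams` defaults.  Returns a dict with a
    ``segmentation`` entry holding the constructed params object.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seg_kw = raw.pop("segmentation", {}) or {}
    params = SegmentationParams(**seg_kw)
    if raw.get("adult_mode") and params.min_object_px == 0:
        params = params.with_adult_mode()
    cfg = {
        "cadence_min": float(raw.get("cadence_min", 5.0)),
        "adult_mode": bool(raw.get("adult_mode", False)),
        "seed": int(raw.get("seed", 0)),
        "segmentation": params,
    }
    return cfg
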