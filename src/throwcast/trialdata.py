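"""Canonical marker taxonomy, trial data model and trajectory file I/O.

The analysis tracks 18 joint markers spanning both legs, both arms, the trunk
and the head, plus five markers glued asymmetrically to the ball surface.
Internally everything is meters and seconds; trajectory files are plain CSV
(long or wide form) with blank cells marking missing samples.

Coordinate frame convention: x = thrower's right (+), y = forward toward the
target board (+), z = up (+); origin at the floor mark of the starting
position. "Right" throws therefore land at positive x.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical ordering of the 18 analyzed joint markers. The order is fixed:
#: it defines feature-row ordering and deterministic tie-breaking everywhere.
CANONICAL_MARKERS: tuple[str, ...] = (
    "l_foot", "r_foot",
    "l_ankle", "r_ankle",
    "l_knee", "r_knee",
    "l_hip", "r_hip",
    "l_shoulder", "r_shoulder",
    "l_elbow", "r_elbow",
    "l_wrist", "r_wrist",
    "l_hand", "r_hand",
    "cv7", "head",
)

#: Six body segments partitioning the canonical marker set.
SEGMENTS: dict[str, tuple[str, ...]] = {
    "trunk": ("l_shoulder", "r_shoulder", "l_hip", "r_hip"),
    "head": ("head", "cv7"),
    "right_arm": ("r_elbow", "r_wrist", "r_hand"),
    "left_arm": ("l_elbow", "l_wrist", "l_hand"),
    "right_leg": ("r_knee", "r_ankle", "r_foot"),
    "left_leg": ("l_knee", "l_ankle", "l_foot"),
}

SEGMENT_NAMES: tuple[str, ...] = tuple(SEGMENTS)

_SEGMENT_OF = {m: seg for seg, members in SEGMENTS.items() for m in members}

BALL_MARKERS: tuple[str, ...] = tuple(f"ball_{i}" for i in range(1, 6))

BALL_RADIUS_M = 0.045


def body_segment_of(marker: str) -> str:
    """Return the body segment (one of six districts) owning ``marker``."""
    try:
        return _SEGMENT_OF[marker]
    except KeyError:
        raise KeyError(f"unknown canonical marker: {marker!r}") from None


def segment_markers(segment: str) -> tuple[str, ...]:
    try:
        return SEGMENTS[segment]
    except KeyError:
        raise KeyError(f"unknown body segment: {segment!r}") from None


@dataclass(frozen=True)
class BoardGeometry:
    """Target board placed orthogonal to y at ``distance_m`` from the origin.

    The four 40 cm targets sit on a rectangular layout with 80 cm lateral and
    70 cm vertical spacing between centers.
    """

    distance_m: float = 6.0
    target_spacing_x_m: float = 0.80
    target_spacing_z_m: float = 0.70
    target_radius_m: float = 0.20
    center_x_m: float = -0.20   # targets midline: 60 cm left / 20 cm right
    center_z_m: float = 1.50

    def __post_init__(self):
        if self.distance_m <= 0:
            raise ValueError("board distance must be positive")

    @property
    def target_centers(self) -> np.ndarray:
        """(4, 2) array of (x, z) target centers on the board plane."""
        dx = self.target_spacing_x_m / 2
        dz = self.target_spacing_z_m / 2
        return np.array(
            [
                [self.center_x_m - dx, self.center_z_m + dz],
                [self.center_x_m + dx, self.center_z_m + dz],
                [self.center_x_m - dx, self.center_z_m - dz],
                [self.center_x_m + dx, self.center_z_m - dz],
            ]
        )


@dataclass
class TrialRecord:
    """One throw's raw marker time series plus metadata.

    ``positions[m]`` is an (n, 3) float array (NaN where invalid) and
    ``valid[m]`` the matching (n,) boolean mask, sharing the common ``times``
    base. Ball surface markers live in ``ball_positions`` / ``ball_valid``.
    """

    participant_id: str
    trial_id: str
    times: np.ndarray
    positions: dict[str, np.ndarray]
    valid: dict[str, np.ndarray]
    ball_positions: dict[str, np.ndarray] = field(default_factory=dict)
    ball_valid: dict[str, np.ndarray] = field(default_factory=dict)
    sample_rate: float = 120.0
    instructed_target: int | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.times.ndim != 1 or (len(self.times) > 1 and np.any(np.diff(self.times) <= 0)):
            raise ValueError("time base must be one-dimensional and strictly increasing")
        n = len(self.times)
        for name, arr in {**self.positions, **self.ball_positions}.items():
            if arr.shape != (n, 3):
                raise ValueError(f"series {name!r} shape {arr.shape} != ({n}, 3)")
        for name, mask in {**self.valid, **self.ball_valid}.items():
            if mask.shape != (n,):
                raise ValueError(f"mask {name!r} does not share the time base")
            vals = (self.positions | self.ball_positions)[name]
            if not np.all(np.isfinite(vals[mask])):
                raise ValueError(f"series {name!r} has non-finite values on valid frames")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def marker_names(self) -> list[str]:
        return list(self.positions)

    def copy(self) -> "TrialRecord":
        return replace(
            self,
            times=self.times.copy(),
            positions={k: v.copy() for k, v in self.positions.items()},
            valid={k: v.copy() for k, v in self.valid.items()},
            ball_positions={k: v.copy() for k, v in self.ball_positions.items()},
            ball_valid={k: v.copy() for k, v in self.ball_valid.items()},
            flags=dict(self.flags),
        )


def merge_head_markers(left: np.ndarray, right: np.ndarray,
                       left_valid: np.ndarray | None = None,
                       right_valid: np.ndarray | None = None):
    """Per-sample mean of the two anterior head markers.

    Returns ``(series, valid)``; a frame is valid only where both inputs are.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left/right head series have mismatched lengths")
    if left_valid is None:
        left_valid = np.all(np.isfinite(left), axis=-1)
    if right_valid is None:
        right_valid = np.all(np.isfinite(right), axis=-1)
    valid = np.asarray(left_valid, bool) & np.asarray(right_valid, bool)
    merged = np.where(valid[..., None], 0.5 * (left + right), np.nan)
    return merged, valid


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_LONG_COLUMNS = ["time_s", "marker", "x_m", "y_m", "z_m"]


def write_trial(record: TrialRecord, path, format: str = "long") -> None:
    """Write a trial to CSV (long form by default, UTF-8, '.' decimal)."""
    if format == "long":
        _write_long(record, path)
    elif format == "wide":
        _write_wide(record, path)
    else:
        raise ValueError(f"unsupported write format: {format!r}")


def _all_series(record: TrialRecord):
    for name in list(record.positions) + list(record.ball_positions):
        pos = (record.positions | record.ball_positions)[name]
        mask = (record.valid | record.ball_valid)[name]
        yield name, pos, mask


def _write_long(record: TrialRecord, path) -> None:
    frames = []
    for name, pos, mask in _all_series(record):
        df = pd.DataFrame(
            {
                "time_s": record.times,
                "marker": name,
                "x_m": np.where(mask, pos[:, 0], np.nan),
                "y_m": np.where(mask, pos[:, 1], np.nan),
                "z_m": np.where(mask, pos[:, 2], np.nan),
            }
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        _write_meta_header(fh, record)
        out.to_csv(fh, index=False, float_format="%.9f")


def _write_wide(record: TrialRecord, path) -> None:
    data = {"time_s": record.times}
    for name, pos, mask in _all_series(record):
        for j, ax in enumerate("xyz"):
            data[f"{name}_{ax}"] = np.where(mask, pos[:, j], np.nan)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        _write_meta_header(fh, record)
        pd.DataFrame(data).to_csv(fh, index=False, float_format="%.9f")


def _write_meta_header(fh, record: TrialRecord) -> None:
    fh.write(f"# participant_id={record.participant_id}\n")
    fh.write(f"# trial_id={record.trial_id}\n")
    fh.write(f"# sample_rate_hz={record.sample_rate:g}\n")
    fh.write("# units=m\n")
    if record.instructed_target is not None:
        fh.write(f"# instructed_target={record.instructed_target}\n")
    for key, val in record.flags.items():
        fh.write(f"# flag.{key}={val}\n")


def _read_meta_header(path):
    meta = {}
    body = io.StringIO()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" in stripped:
                    key, val = stripped.split("=", 1)
                    meta[key.strip()] = val.strip()
            else:
                body.write(line)
    body.seek(0)
    return meta, body


def read_trial(path, format: str = "long",
               require_markers: tuple[str, ...] | None = CANONICAL_MARKERS) -> TrialRecord:
    """Read a trial file; missing/blank samples come back as invalid frames.

    ``format`` is one of ``long``, ``wide`` or ``c3d``. Files whose header
    declares ``units=mm`` are converted to meters on read. If
    ``require_markers`` is given, the file must contain every listed marker.
    """
    if format == "c3d":
        raise ValueError(
            "C3D ingestion requires the optional 'ezc3d' dependency; "
            "convert to long/wide CSV instead"
        )
    if format not in ("long", "wide"):
        raise ValueError(f"unsupported read format: {format!r}")

    meta, body = _read_meta_header(path)
    df = pd.read_csv(body)
    scale = 1e-3 if meta.get("units") == "mm" else 1.0

    if format == "long":
        missing = [c for c in _LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"malformed long CSV, missing columns: {missing}")
        times = np.unique(df["time_s"].to_numpy(float))
        if np.any(np.diff(times) <= 0):
            raise ValueError("non-monotone time column")
        index = {t: i for i, t in enumerate(times)}
        n = len(times)
        names = list(dict.fromkeys(df["marker"]))
        series = {}
        for name, grp in df.groupby("marker", sort=False):
            pos = np.full((n, 3), np.nan)
            rows = np.array([index[t] for t in grp["time_s"]])
            pos[rows] = grp[["x_m", "y_m", "z_m"]].to_numpy(float) * scale
            series[name] = pos
        series = {name: series[name] for name in names}
    else:
        if "time_s" not in df.columns:
            raise ValueError("malformed wide CSV: no time_s column")
        times = df["time_s"].to_numpy(float)
        if np.any(np.diff(times) <= 0):
            raise ValueError("non-monotone time column")
        names = list(dict.fromkeys(c.rsplit("_", 1)[0] for c in df.columns if c != "time_s"))
        series = {}
        for name in names:
            cols = [f"{name}_{ax}" for ax in "xyz"]
            if any(c not in df.columns for c in cols):
                raise ValueError(f"marker {name!r} missing coordinate columns")
            series[name] = df[cols].to_numpy(float) * scale

    if require_markers is not None:
        absent = [m for m in require_markers if m not in series]
        if absent:
            raise ValueError(f"trial file missing required markers: {absent}")

    positions, valid, ball_positions, ball_valid = {}, {}, {}, {}
    for name, pos in series.items():
        mask = np.all(np.isfinite(pos), axis=1)
        if name in BALL_MARKERS:
            ball_positions[name], ball_valid[name] = pos, mask
        else:
            positions[name], valid[name] = pos, mask

    flags = {k[5:]: _parse_flag(v) for k, v in meta.items() if k.startswith("flag.")}
    target = meta.get("instructed_target")
    return TrialRecord(
        participant_id=meta.get("participant_id", "unknown"),
        trial_id=meta.get("trial_id", "unknown"),
        times=times,
        positions=positions,
        valid=valid,
        ball_positions=ball_positions,
        ball_valid=ball_valid,
        sample_rate=float(meta.get("sample_rate_hz", 120.0)),
        instructed_target=int(target) if target is not None else None,
        flags=flags,
    )


def _parse_flag(value: str):
    if value in ("True", "False"):
        return value == "True"
    try:
        return int(value)
    except ValueError:
        return value
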