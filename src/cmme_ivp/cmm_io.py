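"""Domain types and on-disk formats for color M-mode velocity maps and study tables.

A color M-mode (CMM) recording is a 2-D map ``v(s, t)`` of axial blood
velocity along a single ultrasound scanline (the transmitral inflow
streamline) imaged over time.  Row index 0 is the most proximal
(left-atrial) sample; ``s`` increases toward the LV apex; positive ``v``
is flow toward the apex.  All internal units are SI (m, s, m/s); mmHg
appears only in reported pressures.

On disk a velocity map is a plain-text CSV matrix (rows = scanline
positions, columns = time samples) next to a JSON sidecar carrying the
grid geometry, annulus/apex landmarks and per-beat ECG timing anchors.
Measurement tables are ordinary CSV in long format.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BeatTimings",
    "VelocityMap",
    "StudyTable",
    "PairedTable",
    "FormatError",
    "ValidationError",
    "read_velocity_map",
    "write_velocity_map",
    "read_study_table",
    "write_study_table",
    "read_paired_table",
    "write_paired_table",
]

#: physiologic sanity bound on |v| after unit normalisation (m/s)
MAX_SPEED_MPS = 5.0

_SUPPORTED_UNITS = {"m/s": 1.0, "cm/s": 0.01}


class FormatError(ValueError):
    """A file does not conform to the on-disk format."""


class ValidationError(ValueError):
    """A domain invariant is violated."""


@dataclass(frozen=True)
class BeatTimings:
    """ECG-derived timing anchors for one cardiac beat.

    All times are seconds on the velocity map's time axis; durations are
    measured from the Q wave.  These arrive as manually measured numbers
    (from aortic-flow and mitral-inflow spectral images), not from ECG
    waveform processing.
    """

    t_q: float
    q_to_mv_open: float
    q_to_peak_e: float
    aortic_open: float
    aortic_close: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.t_q, self.q_to_mv_open, self.q_to_peak_e,
                                self.aortic_open, self.aortic_close])):
            raise ValidationError("beat timings must be finite")
        if self.q_to_mv_open <= 0:
            raise ValidationError("q_to_mv_open must be > 0")
        if self.q_to_peak_e <= self.q_to_mv_open:
            raise ValidationError("q_to_peak_e must exceed q_to_mv_open "
                                  "(peak inflow follows valve opening)")
        if self.aortic_close <= self.aortic_open:
            raise ValidationError("aortic_close must exceed aortic_open")

    @property
    def t_mv_open(self) -> float:
        return self.t_q + self.q_to_mv_open

    @property
    def t_peak_e(self) -> float:
        return self.t_q + self.q_to_peak_e

    def check_within(self, t_max: float) -> None:
        """Raise if any marker falls outside the map's time extent [0, t_max]."""
        markers = (self.t_q, self.t_mv_open, self.t_peak_e,
                   self.aortic_open, self.aortic_close)
        if min(markers) < 0 or max(markers) > t_max:
            raise ValidationError(
                f"beat timing markers {markers} outside map time extent [0, {t_max:.4f}]")


@dataclass
class VelocityMap:
    """A CMM velocity map on a regular scanline x time grid.

    Parameters
    ----------
    v
        Axial velocity in m/s, shape (n_s, n_t); rows are scanline
        positions (proximal first), columns time samples.
    ds, dt
        Spatial (m) and temporal (s) sample spacing, both > 0.
    s0_annulus_index
        Row index of the mitral annulus (LV base).  The scanline may
        extend proximal to it, into the left atrium.
    apex_index
        Row index of the LV apex (last LV sample).
    lv_length
        LV long-axis length in m (annulus to apex, as traced on the
        acquisition image; used only to normalise IVPD into IVPG).
    units_in
        Declared source unit of the file the map was loaded from
        ("m/s" or "cm/s"); stored values are always m/s.
    nyquist
        Optional aliasing (Nyquist) velocity in m/s.
    beats
        Timing anchors for each beat visible on the map.
    """

    v: np.ndarray
    ds: float
    dt: float
    s0_annulus_index: int
    apex_index: int
    lv_length: float
    units_in: str = "m/s"
    nyquist: float | None = None
    beats: list[BeatTimings] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.validate()

    def validate(self, max_speed: float = MAX_SPEED_MPS) -> None:
        if self.v.ndim != 2:
            raise ValidationError("v must be a 2-D matrix")
        n_rows = self.v.shape[0]
        if not (self.ds > 0 and self.dt > 0):
            raise ValidationError("ds and dt must be > 0")
        if not (0 <= self.s0_annulus_index < self.apex_index < n_rows):
            raise ValidationError(
                f"need 0 <= s0_annulus_index ({self.s0_annulus_index}) < "
                f"apex_index ({self.apex_index}) < n_rows ({n_rows})")
        if not np.all(np.isfinite(self.v)):
            raise ValidationError("velocity map contains non-finite values")
        if self.lv_length <= 0:
            raise ValidationError("lv_length must be > 0")
        if self.units_in not in _SUPPORTED_UNITS:
            raise ValidationError(f"unsupported units_in {self.units_in!r}")
        if self.nyquist is not None and self.nyquist <= 0:
            raise ValidationError("nyquist must be > 0 when set")
        vmax = float(np.max(np.abs(self.v))) if self.v.size else 0.0
        if vmax >= max_speed:
            raise ValidationError(
                f"max |v| = {vmax:.3f} m/s exceeds physiologic bound {max_speed} m/s")
        t_max = self.t_extent
        for b in self.beats:
            b.check_within(t_max)

    # -- grid accessors -------------------------------------------------
    @property
    def n_s(self) -> int:
        return self.v.shape[0]

    @property
    def n_t(self) -> int:
        return self.v.shape[1]

    @property
    def s_axis(self) -> np.ndarray:
        """Scanline positions in m, 0 at the proximal end."""
        return np.arange(self.n_s) * self.ds

    @property
    def t_axis(self) -> np.ndarray:
        return np.arange(self.n_t) * self.dt

    @property
    def t_extent(self) -> float:
        return (self.n_t - 1) * self.dt

    @property
    def s_annulus(self) -> float:
        return self.s0_annulus_index * self.ds

    @property
    def s_apex(self) -> float:
        return self.apex_index * self.ds

    def with_v(self, v: np.ndarray, **changes) -> "VelocityMap":
        """Copy of this map with new velocity data (and optional field changes)."""
        return replace(self, v=np.asarray(v, dtype=float), **changes)

    def __eq__(self, other) -> bool:  # bitwise equality on all fields
        if not isinstance(other, VelocityMap):
            return NotImplemented
        return (np.array_equal(self.v, other.v)
                and self.ds == other.ds and self.dt == other.dt
                and self.s0_annulus_index == other.s0_annulus_index
                and self.apex_index == other.apex_index
                and self.lv_length == other.lv_length
                and self.units_in == other.units_in
                and self.nyquist == other.nyquist
                and self.beats == other.beats)


def snap_to_grid(t: float, dt: float, n: int, what: str = "marker") -> int:
    """Snap a time to the nearest sample index, warning on a coarse snap."""
    i = int(round(t / dt))
    if i < 0 or i >= n:
        raise ValidationError(f"{what} at t={t:.4f} s is outside the map extent")
    if abs(t - i * dt) > dt / 2 + 1e-12:
        warnings.warn(f"{what} at t={t:.4f} s snapped by more than dt/2", stacklevel=2)
    return i


# ---------------------------------------------------------------------------
# velocity map files: CSV matrix + JSON sidecar
# ---------------------------------------------------------------------------

_BEAT_KEYS = ("t_q", "q_to_mv_open", "q_to_peak_e", "aortic_open", "aortic_close")
_REQUIRED_META = ("ds_m", "dt_s", "units_in", "s0_annulus_index",
                  "apex_index", "lv_length_m")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_velocity_map(vmap: VelocityMap, path: str | Path) -> None:
    """Write ``path`` (CSV matrix) and its JSON sidecar ``path.with_suffix('.json')``.

    Values are written in ``vmap.units_in`` units with full precision so
    that a read round-trips bitwise.
    """
    path = Path(path)
    scale = _SUPPORTED_UNITS[vmap.units_in]
    np.savetxt(path, vmap.v / scale, delimiter=",", fmt="%.17g")
    meta: dict = {
        "ds_m": vmap.ds,
        "dt_s": vmap.dt,
        "units_in": vmap.units_in,
        "s0_annulus_index": vmap.s0_annulus_index,
        "apex_index": vmap.apex_index,
        "lv_length_m": vmap.lv_length,
        "beats": [{k: getattr(b, k) for k in _BEAT_KEYS} for b in vmap.beats],
    }
    if vmap.nyquist is not None:
        meta["nyquist_mps"] = vmap.nyquist
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_velocity_map(path: str | Path) -> VelocityMap:
    """Read a velocity map written by :func:`write_velocity_map`.

    Velocities are normalised to m/s according to the sidecar's
    ``units_in`` declaration; the declaration itself is preserved on the
    returned map.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"invalid JSON sidecar {sidecar}: {e}") from e
    for key in _REQUIRED_META:
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} missing required key {key!r}")
    units = meta["units_in"]
    if units not in _SUPPORTED_UNITS:
        raise FormatError(f"sidecar key 'units_in' has unsupported value {units!r}")
    try:
        raw = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as e:
        raise FormatError(f"non-rectangular or non-numeric matrix in {path}: {e}") from e
    beats = []
    for i, b in enumerate(meta.get("beats", [])):
        missing = [k for k in _BEAT_KEYS if k not in b]
        if missing:
            raise FormatError(f"beat {i} in {sidecar} missing keys {missing}")
        beats.append(BeatTimings(**{k: float(b[k]) for k in _BEAT_KEYS}))
    return VelocityMap(
        v=raw * _SUPPORTED_UNITS[units],
        ds=float(meta["ds_m"]),
        dt=float(meta["dt_s"]),
        s0_annulus_index=int(meta["s0_annulus_index"]),
        apex_index=int(meta["apex_index"]),
        lv_length=float(meta["lv_length_m"]),
        units_in=units,
        nyquist=float(meta["nyquist_mps"]) if "nyquist_mps" in meta else None,
        beats=beats,
    )


# ---------------------------------------------------------------------------
# long-format measurement tables
# ---------------------------------------------------------------------------

STUDY_COLUMNS = ["goat_id", "scan_id", "cycle_index", "variable", "value"]
PAIRED_COLUMNS = ["goat_id", "condition", "variable", "value"]
CONDITIONS = ("baseline", "post")


@dataclass
class StudyTable:
    """Repeatability measurements: goat x scan (observer) x cycle x variable."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in STUDY_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"study table missing columns {missing}")
        if len(self.df) == 0:
            raise ValidationError("study table is empty")
        self.df = self.df[STUDY_COLUMNS].copy()
        self.df["value"] = self.df["value"].astype(float)
        self.df["cycle_index"] = self.df["cycle_index"].astype(int)
        if not np.all(np.isfinite(self.df["value"])):
            raise ValidationError("study table contains non-finite values")

    def variables(self) -> list[str]:
        return sorted(self.df["variable"].unique())

    def values_for(self, variable: str) -> pd.DataFrame:
        sub = self.df[self.df["variable"] == variable]
        if len(sub) == 0:
            raise ValidationError(f"no records for variable {variable!r}")
        return sub

    def check_balanced(self, variable: str | None = None) -> None:
        """Raise unless every goat x scan cell holds the same cycle count."""
        df = self.df if variable is None else self.values_for(variable)
        for var, sub in df.groupby("variable"):
            counts = sub.groupby(["goat_id", "scan_id"])["cycle_index"].count()
            if counts.nunique() != 1:
                raise ValidationError(
                    f"unbalanced design for {var!r}: cycle counts per goat x scan "
                    f"are {sorted(counts.unique())}")
            n_scans = sub.groupby("goat_id")["scan_id"].nunique()
            if n_scans.nunique() != 1:
                raise ValidationError(f"unbalanced design for {var!r}: uneven scan counts")


@dataclass
class PairedTable:
    """Paired baseline / post-treatment measurements per goat and variable."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PAIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"paired table missing columns {missing}")
        if len(self.df) == 0:
            raise ValidationError("paired table is empty")
        self.df = self.df[PAIRED_COLUMNS].copy()
        self.df["value"] = self.df["value"].astype(float)
        bad = set(self.df["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
        if not np.all(np.isfinite(self.df["value"])):
            raise ValidationError("paired table contains non-finite values")
        self._check_pairing()

    def _check_pairing(self) -> None:
        for var, sub in self.df.groupby("variable"):
            piv = sub.pivot_table(index="goat_id", columns="condition",
                                  values="value", aggfunc="count")
            unpaired = []
            for cond in CONDITIONS:
                if cond not in piv.columns:
                    unpaired = sorted(piv.index)
                    break
                unpaired += list(piv.index[piv[cond].isna() | (piv[cond] != 1)])
            if unpaired:
                raise ValidationError(
                    f"variable {var!r}: goats not paired exactly once per condition: "
                    f"{sorted(set(unpaired))}")

    def variables(self) -> list[str]:
        return sorted(self.df["variable"].unique())

    def pairs_for(self, variable: str) -> tuple[np.ndarray, np.ndarray]:
        """(baseline, post) arrays aligned on goat_id (sorted)."""
        sub = self.df[self.df["variable"] == variable]
        if len(sub) == 0:
            raise ValidationError(f"no records for variable {variable!r}")
        piv = sub.pivot(index="goat_id", columns="condition", values="value").sort_index()
        return piv["baseline"].to_numpy(), piv["post"].to_numpy()


def _read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as e:
        raise FormatError(f"empty table file {path}") from e
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path} missing required columns {missing}")
    if len(df) == 0:
        raise ValidationError(f"{path} has a header but no records")
    return df


def read_study_table(path: str | Path) -> StudyTable:
    return StudyTable(_read_table(path, STUDY_COLUMNS))


def write_study_table(table: StudyTable, path: str | Path,
                      header_comment: str | None = None) -> None:
    _write_table(table.df, path, header_comment)


def read_paired_table(path: str | Path) -> PairedTable:
    return PairedTable(_read_table(path, PAIRED_COLUMNS))


def write_paired_table(table: PairedTable, path: str | Path,
                       header_comment: str | None = None) -> None:
    _write_table(table.df, path, header_comment)


def _write_table(df: pd.DataFrame, path: str | Path, header_comment: str | None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
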