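"""TPS landmark file I/O, sliders files, and landmark configurations.

The TPS dialect accepted here is the common one produced by the tpsDig /
tpsUtil family of digitizing tools::

    LM=10
    x y            (10 lines: the fixed landmarks)
    CURVES=4
    POINTS=13
    x y            (13 lines: semilandmarks of curve 1)
    POINTS=...
    IMAGE=skull_001.tif
    ID=skull_001
    SCALE=0.0312

Keys are case-insensitive; coordinates are whitespace-separated; unknown keys
are preserved on read and ignored semantically. Coordinates use the
mathematical y-up convention. Point indices are 1-based in files and 0-based
internally. When a SCALE factor is present every coordinate is multiplied by
it at parse time (converting digitizer pixels to millimetres); configurations
lacking SCALE are accepted with a logged warning, since Procrustes alignment
removes size anyway.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

from .outlines import resample_curve  # noqa: F401  (re-export: curve utility)

logger = logging.getLogger(__name__)

VIEWS = ("dorsal", "ventral", "lateral")

__all__ = [
    "LandmarkConfiguration",
    "SliderTriple",
    "TPSParseError",
    "parse_tps",
    "write_tps",
    "parse_sliders",
    "write_sliders",
    "reflect",
    "read_specimen_table",
]


class TPSParseError(ValueError):
    """Malformed TPS or sliders input; message names the record and line."""


@dataclasses.dataclass
class LandmarkConfiguration:
    """One specimen's scaled 2D landmark configuration.

    Attributes
    ----------
    specimen_id, species, family, view : str
        Identity and grouping labels; ``view`` is one of dorsal, ventral,
        lateral.
    points : ndarray of shape (k, 2)
        Ordered coordinates in millimetres (after scaling): fixed landmarks
        first, then curve semilandmarks in file order.
    fixed_count : int
        Number of fixed landmarks (points ``0..fixed_count-1``).
    curves : list of (start, stop)
        Half-open 0-based index ranges into ``points`` for each open curve;
        they tile ``fixed_count..k`` contiguously.
    scale_applied : bool
        Whether a SCALE factor was applied.
    extras : list of str
        Unknown ``KEY=VALUE`` lines preserved from the source file.
    """

    specimen_id: str
    species: str
    family: str
    view: str
    points: np.ndarray
    fixed_count: int
    curves: list[tuple[int, int]] = dataclasses.field(default_factory=list)
    scale_applied: bool = False
    extras: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (k, 2) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("all coordinates must be finite")
        if self.fixed_count < 3:
            raise ValueError("fixed_count must be >= 3")
        k = len(self.points)
        expect = self.fixed_count
        for start, stop in self.curves:
            if start != expect:
                raise ValueError("curve index ranges must be contiguous and disjoint")
            if stop <= start:
                raise ValueError("curves must contain at least one point")
            expect = stop
        if expect != k:
            raise ValueError(
                f"total point count {k} != fixed landmarks {self.fixed_count} "
                f"+ curve points {expect - self.fixed_count}"
            )

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_semilandmarks(self) -> int:
        return self.n_points - self.fixed_count

    def curve_points(self, i: int) -> np.ndarray:
        start, stop = self.curves[i]
        return self.points[start:stop]


@dataclasses.dataclass(frozen=True)
class SliderTriple:
    """A before/slider/after index triple (internal 0-based convention).

    The slider point is a semilandmark allowed to move along the chord from
    its before-neighbour to its after-neighbour during superimposition.
    """

    before: int
    slider: int
    after: int

    def __post_init__(self):
        if len({self.before, self.slider, self.after}) != 3:
            raise ValueError("slider triple indices must be distinct")


# ---------------------------------------------------------------------------
# TPS records

_KEY_RE = re.compile(r"^\s*([A-Za-z][A-Za-z0-9_]*)\s*=\s*(.*?)\s*$")


def _lookup(table: Mapping | pd.DataFrame, key: str):
    if isinstance(table, pd.DataFrame):
        hit = table[table["specimen_id"].astype(str) == key]
        if len(hit) == 0:
            return None
        row = hit.iloc[0]
        return {
            "species": str(row["species"]),
            "family": str(row["family"]),
            "view": str(row["view"]),
        }
    return table.get(key)


def parse_tps(stream, specimen_table, apply_scale: bool = True) -> list[LandmarkConfiguration]:
    """Parse a TPS stream into landmark configurations.

    Parameters
    ----------
    stream : file-like or iterable of str
        TPS records in the dialect documented in the module docstring.
    specimen_table : DataFrame or mapping
        Maps specimen id (the ID value, falling back to the IMAGE stem) to
        species / family / view. A DataFrame must have columns specimen_id,
        species, family, view.
    apply_scale : bool
        Multiply coordinates by the SCALE value when present.
    """
    lines = stream.read().splitlines() if hasattr(stream, "read") else list(stream)
    records: list[dict] = []
    cur: dict | None = None
    pending: list[np.ndarray] | None = None  # coordinate sink
    pending_need = 0

    def fail(msg: str, lineno: int):
        rec = len(records) + (1 if cur is not None else 0)
        raise TPSParseError(f"record {rec}, line {lineno}: {msg}")

    def close_record(lineno: int):
        nonlocal cur, pending, pending_need
        if cur is None:
            return
        if pending_need > 0:
            fail(f"expected {pending_need} more coordinate line(s)", lineno)
        records.append(cur)
        cur = None
        pending = None
        pending_need = 0

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        m = _KEY_RE.match(line)
        if m and not _is_coordinate(line):
            key, value = m.group(1).upper(), m.group(2)
            if key == "LM":
                close_record(lineno)
                try:
                    k = int(value)
                except ValueError:
                    fail(f"malformed count line {line!r}", lineno)
                cur = {
                    "lm": k, "fixed": [], "curves": [], "id": None,
                    "image": None, "scale": None, "extras": [], "line": lineno,
                }
                pending = cur["fixed"]
                pending_need = k
                continue
            if cur is None:
                fail(f"key {key} before any LM record", lineno)
            if pending_need > 0:
                fail(f"expected {pending_need} more coordinate line(s)", lineno)
            if key == "CURVES":
                try:
                    cur["n_curves"] = int(value)
                except ValueError:
                    fail(f"malformed count line {line!r}", lineno)
            elif key == "POINTS":
                try:
                    npts = int(value)
                except ValueError:
                    fail(f"malformed count line {line!r}", lineno)
                curve: list[np.ndarray] = []
                cur["curves"].append(curve)
                pending = curve
                pending_need = npts
            elif key == "ID":
                cur["id"] = value
            elif key == "IMAGE":
                cur["image"] = value
            elif key == "SCALE":
                try:
                    cur["scale"] = float(value)
                except ValueError:
                    fail(f"non-numeric SCALE {value!r}", lineno)
            else:
                cur["extras"].append(f"{key}={value}")
            continue
        # coordinate line
        if cur is None:
            fail(f"unexpected content {line!r} outside a record", lineno)
        if pending_need <= 0:
            fail(f"unexpected coordinate line {line!r}", lineno)
        parts = line.split()
        if len(parts) != 2:
            fail(f"expected 'x y' coordinate pair, got {line!r}", lineno)
        try:
            xy = np.array([float(parts[0]), float(parts[1])])
        except ValueError:
            fail(f"non-numeric coordinate in {line!r}", lineno)
        pending.append(xy)
        pending_need -= 1

    close_record(len(lines))

    configs = []
    for i, rec in enumerate(records, start=1):
        if "n_curves" in rec and rec["n_curves"] != len(rec["curves"]):
            raise TPSParseError(
                f"record {i}: CURVES={rec['n_curves']} but {len(rec['curves'])} "
                "POINTS blocks found"
            )
        key = rec["id"]
        if key is None and rec["image"] is not None:
            key = rec["image"].rsplit(".", 1)[0]
        if key is None:
            key = f"record_{i}"
        meta = _lookup(specimen_table, key)
        if meta is None:
            raise TPSParseError(f"record {i}: unknown specimen id {key!r} in table")
        pts = rec["fixed"] + [p for c in rec["curves"] for p in c]
        points = np.array(pts, dtype=float).reshape(len(pts), 2)
        curves = []
        start = rec["lm"]
        for c in rec["curves"]:
            curves.append((start, start + len(c)))
            start += len(c)
        scale_applied = False
        if rec["scale"] is not None and apply_scale:
            points = points * rec["scale"]
            scale_applied = True
        elif rec["scale"] is None:
            logger.warning(
                "record %d (%s): no SCALE present; coordinates left in "
                "digitizer units", i, key,
            )
        configs.append(
            LandmarkConfiguration(
                specimen_id=key,
                species=meta["species"],
                family=meta["family"],
                view=meta["view"],
                points=points,
                fixed_count=rec["lm"],
                curves=curves,
                scale_applied=scale_applied,
                extras=rec["extras"],
            )
        )
    return configs


def _is_coordinate(line: str) -> bool:
    parts = line.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0]), float(parts[1])
    except ValueError:
        return False
    return True


def write_tps(configs: Iterable[LandmarkConfiguration], stream: IO[str],
              scales=None) -> None:
    """Write configurations as TPS records accepted by :func:`parse_tps`.

    Round-trips through :func:`parse_tps` up to floating-point formatting.
    Scaled configurations are written with ``SCALE=1`` so the millimetre
    units survive a round trip; alternatively ``scales`` supplies one
    mm-per-pixel factor per configuration, in which case coordinates are
    emitted in pixel units with the matching SCALE line (the raw-digitizer
    representation).
    """
    configs = list(configs)
    if scales is not None and len(scales) != len(configs):
        raise ValueError("scales must match the number of configurations")
    for i, cfg in enumerate(configs):
        scale = None if scales is None else float(scales[i])
        pts = cfg.points if scale is None else cfg.points / scale
        stream.write(f"LM={cfg.fixed_count}\n")
        for x, y in pts[: cfg.fixed_count]:
            stream.write(f"{x:.17g} {y:.17g}\n")
        if cfg.curves:
            stream.write(f"CURVES={len(cfg.curves)}\n")
            for start, stop in cfg.curves:
                stream.write(f"POINTS={stop - start}\n")
                for x, y in pts[start:stop]:
                    stream.write(f"{x:.17g} {y:.17g}\n")
        for extra in cfg.extras:
            stream.write(extra + "\n")
        stream.write(f"ID={cfg.specimen_id}\n")
        if scale is not None:
            stream.write(f"SCALE={scale:.17g}\n")
        elif cfg.scale_applied:
            stream.write("SCALE=1\n")


# ---------------------------------------------------------------------------
# Sliders files


def parse_sliders(stream, fixed_count: int, n_points: int | None = None) -> list[SliderTriple]:
    """Parse a sliders file: one before/slide/after triple per line, 1-based.

    A single non-numeric header line is tolerated. Triples are converted to
    the internal 0-based convention and validated: the slider must index a
    semilandmark (file index > ``fixed_count``), indices must be in range
    when ``n_points`` is given, and no semilandmark may slide twice.
    """
    lines = stream.read().splitlines() if hasattr(stream, "read") else list(stream)
    triples: list[SliderTriple] = []
    seen: set[int] = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip().replace(",", " ")
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        try:
            vals = [int(p) for p in parts]
        except ValueError:
            if lineno == 1 or (not triples and not seen):
                continue  # header line
            raise TPSParseError(f"sliders line {lineno}: non-integer entry in {raw!r}")
        if len(vals) != 3:
            raise TPSParseError(f"sliders line {lineno}: expected 3 columns, got {len(vals)}")
        before, slider, after = vals
        if slider <= fixed_count:
            raise TPSParseError(
                f"sliders line {lineno}: point {slider} is a fixed landmark "
                f"(fixed_count={fixed_count}) and cannot slide"
            )
        for v in vals:
            if v < 1 or (n_points is not None and v > n_points):
                raise TPSParseError(f"sliders line {lineno}: index {v} out of range")
        if slider in seen:
            raise TPSParseError(f"sliders line {lineno}: duplicate slider {slider}")
        seen.add(slider)
        triples.append(SliderTriple(before - 1, slider - 1, after - 1))
    return triples


def write_sliders(triples: Iterable[SliderTriple], stream: IO[str], header: bool = True) -> None:
    """Write slider triples in the 1-based 3-column file dialect."""
    if header:
        stream.write("before slide after\n")
    for t in triples:
        stream.write(f"{t.before + 1} {t.slider + 1} {t.after + 1}\n")


# ---------------------------------------------------------------------------


def reflect(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Mirror a configuration about the vertical axis through its centroid.

    Computational stand-in for photographing the left side of a specimen and
    reflecting the image: x-coordinates are negated about the centroid's
    vertical axis, point order and curve structure are unchanged, and
    applying the operation twice returns the original (to floating-point
    round-off).
    """
    pts = config.points.copy()
    cx = pts[:, 0].mean()
    pts[:, 0] = 2.0 * cx - pts[:, 0]
    return dataclasses.replace(config, points=pts)


def read_specimen_table(path_or_buf) -> pd.DataFrame:
    """Read the specimen table CSV (specimen_id, species, family, view[, side])."""
    df = pd.read_csv(path_or_buf, dtype=str)
    required = {"specimen_id", "species", "family", "view"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"specimen table missing columns: {sorted(missing)}")
    bad = set(df["view"]) - set(VIEWS)
    if bad:
        raise ValueError(f"unknown view labels: {sorted(bad)}")
    return df
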