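"""Kymograph, track-table, FASTA and config I/O.

Conventions used throughout the package:

* pixels are 0-based; physical position (µm) = ``origin + pixel * pixel_size/1000``
* frame 0 starts at t = 0; time (s) = ``frame * line_time``
* intervals are half-open ``[start, end)``

Kymographs are stored either as multi-page TIFF (one page per channel, physical
calibration in the ImageDescription tag as JSON) or as an HDF5 container with
one dataset per channel under ``/kymograph/<channel>`` and calibration as root
attributes.  Both round-trip losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO

from .errors import InvalidInputError, MetadataError, ParseError

__all__ = [
    "Kymograph",
    "read_kymograph",
    "write_kymograph",
    "read_tracks",
    "write_tracks",
    "read_fasta",
    "read_config",
    "TRACK_COLUMNS",
]

# IUPAC nucleotide codes plus gap
_NUCLEOTIDES = set("ACGTURYSWKMBDHVN-")

TRACK_COLUMNS = [
    "track_id",
    "channel",
    "frame",
    "time_s",
    "position_um",
    "intensity_photons",
]


@dataclass
class Kymograph:
    """Multi-channel photon-count kymograph with physical calibration.

    Parameters
    ----------
    counts
        Integer photon counts, shape ``(n_channels, n_lines, n_pixels)``.
    pixel_size
        Pixel size along the tether, nm.
    line_time
        Wall time per scanned line, s (includes any inter-line pause).
    channel_names
        One name per channel.
    exposure_scheme
        Per-channel ``(exposure_s, pause_s)``; continuous scanning is
        ``(line_time, 0.0)``.
    origin
        Physical position of pixel 0, µm.
    """

    counts: np.ndarray
    pixel_size: float
    line_time: float
    channel_names: list[str] = field(default_factory=list)
    exposure_scheme: list[tuple[float, float]] = field(default_factory=list)
    origin: float = 0.0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim == 2:
            self.counts = self.counts[None]
        if self.counts.ndim != 3:
            raise InvalidInputError("counts must be (n_channels, n_lines, n_pixels)")
        if self.pixel_size <= 0 or self.line_time <= 0:
            raise InvalidInputError("pixel_size and line_time must be positive")
        n_ch = self.counts.shape[0]
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(n_ch)]
        if len(self.channel_names) != n_ch:
            raise InvalidInputError(
                f"{len(self.channel_names)} channel names for {n_ch} channels"
            )
        if not self.exposure_scheme:
            self.exposure_scheme = [(self.line_time, 0.0)] * n_ch
        if len(self.exposure_scheme) != n_ch:
            raise InvalidInputError("one exposure scheme entry required per channel")

    @property
    def n_channels(self) -> int:
        return self.counts.shape[0]

    @property
    def n_lines(self) -> int:
        return self.counts.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.counts.shape[2]

    @property
    def duration(self) -> float:
        """Total wall time covered by the kymograph, s."""
        return self.n_lines * self.line_time

    def pixel_to_um(self, pixel) -> np.ndarray:
        return self.origin + np.asarray(pixel, dtype=float) * self.pixel_size / 1000.0

    def um_to_pixel(self, position_um) -> np.ndarray:
        return (np.asarray(position_um, dtype=float) - self.origin) * 1000.0 / self.pixel_size

    def _metadata(self) -> dict:
        return {
            "pixel_size_nm": self.pixel_size,
            "line_time_s": self.line_time,
            "channel_names": list(self.channel_names),
            "exposure_scheme": [list(e) for e in self.exposure_scheme],
            "origin_um": self.origin,
        }


def write_kymograph(kymo: Kymograph, path: str | Path) -> None:
    """Write a kymograph to TIFF (``.tif``/``.tiff``) or HDF5 (anything else)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            kymo.counts.astype(np.uint32),
            description=json.dumps(kymo._metadata()),
            photometric="minisblack",
        )
    else:
        with h5py.File(path, "w") as f:
            grp = f.create_group("kymograph")
            for name, plane in zip(kymo.channel_names, kymo.counts):
                grp.create_dataset(name, data=plane.astype(np.uint32))
            for k, v in kymo._metadata().items():
                if k == "channel_names":
                    f.attrs[k] = [str(s) for s in v]
                elif k == "exposure_scheme":
                    f.attrs[k] = np.asarray(v, dtype=float)
                else:
                    f.attrs[k] = v


def _from_metadata(counts: np.ndarray, meta: dict, path: Path) -> Kymograph:
    for key in ("pixel_size_nm", "line_time_s"):
        if key not in meta or meta[key] is None:
            raise MetadataError(f"{path}: missing required calibration '{key}'")
    names = list(meta.get("channel_names", []))
    if names and len(names) != counts.shape[0]:
        raise InvalidInputError(
            f"{path}: {counts.shape[0]} channel pages but {len(names)} channel names"
        )
    scheme = [tuple(e) for e in meta.get("exposure_scheme", [])]
    return Kymograph(
        counts=counts,
        pixel_size=float(meta["pixel_size_nm"]),
        line_time=float(meta["line_time_s"]),
        channel_names=names,
        exposure_scheme=scheme,
        origin=float(meta.get("origin_um", 0.0)),
    )


def read_kymograph(path: str | Path, metadata_override: dict | None = None) -> Kymograph:
    """Read a kymograph written by :func:`write_kymograph`.

    ``metadata_override`` supplies calibration for files that lack it; a file
    without ``pixel_size_nm``/``line_time_s`` and no override raises
    :class:`~kymotrace.errors.MetadataError` rather than assuming defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            counts = tf.asarray()
            desc = tf.pages[0].description
        meta = {}
        if desc:
            try:
                meta = json.loads(desc)
            except json.JSONDecodeError:
                meta = {}
    else:
        with h5py.File(path, "r") as f:
            if "kymograph" not in f:
                raise ParseError(f"{path}: no /kymograph group")
            grp = f["kymograph"]
            meta = {k: f.attrs[k] for k in f.attrs}
            if "channel_names" in meta:
                names = [
                    s.decode() if isinstance(s, bytes) else str(s)
                    for s in meta["channel_names"]
                ]
            else:
                names = sorted(grp.keys())
            meta["channel_names"] = names
            counts = np.stack([grp[name][...] for name in names])
    if metadata_override:
        meta = {**meta, **metadata_override}
    if counts.ndim == 2:
        counts = counts[None]
    return _from_metadata(counts, meta, path)


def write_tracks(tracks: pd.DataFrame, path: str | Path) -> None:
    """Write a track table to CSV at full float precision.

    The table must carry the canonical columns (:data:`TRACK_COLUMNS`); an
    empty table produces a header-only file.
    """
    df = pd.DataFrame(tracks, columns=TRACK_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read a CSV track table; malformed rows raise :class:`ParseError` with the line."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pandas reports the bad line in its message
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}", line=1)
    for col in ("track_id", "frame"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ParseError(f"{path}: non-numeric '{col}'", line=int(bad.idxmax()) + 2)
        df[col] = coerced.astype(int)
    for col in ("time_s", "position_um", "intensity_photons"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ParseError(f"{path}: non-numeric '{col}'", line=int(bad.idxmax()) + 2)
        df[col] = coerced.astype(float)
    # within a track, frames must strictly increase
    for tid, sub in df.groupby("track_id"):
        if not np.all(np.diff(sub["frame"].to_numpy()) > 0):
            raise ParseError(f"{path}: frames not strictly increasing in track {tid}")
    return df


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA records as ``{name: uppercase sequence}``, in file order.

    IUPAC nucleotide codes (including N) are accepted; anything else raises
    :class:`ParseError`.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    out: dict[str, str] = {}
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - _NUCLEOTIDES
        if bad:
            raise ParseError(f"{path}: non-nucleotide characters {sorted(bad)} in {rec.id}")
        out[rec.id] = seq
    return out


def read_config(path: str | Path) -> dict:
    """Read a JSON configuration file."""
    with open(path) as f:
        return json.load(f)
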