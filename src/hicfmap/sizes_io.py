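"""Reading and writing HICF fingerprint band files and ground-truth intervals.

The on-disk fingerprint format is a single-column ``.sizes`` dialect, the
shape consumed by FPC-style assemblers: one header line per clone
(``<clone_id> <n_bands>``) followed by one encoded band value per line.
Because the four labeled restriction channels (EcoRI, XbaI, BamHI, XhoI)
must never cross-match at the 0.4-bp size tolerance, each band is encoded
as ``1000 * channel + size``: the >=500-unit gap between channel blocks
makes cross-channel matches impossible while keeping a single numeric
column.

Peak heights are not representable in ``.sizes``; height-based QC must run
before export, or heights travel in a sidecar TSV (see
:func:`write_clone_meta`). Ground truth is plain BED3+1 (0-based,
half-open). Both formats are gzip-transparent (``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

__all__ = [
    "Band",
    "Fingerprint",
    "CloneInterval",
    "SizesParseError",
    "CHANNEL_NAMES",
    "CHANNEL_CODES",
    "N_CHANNELS",
    "CHANNEL_OFFSET",
    "encode_band",
    "decode_band_value",
    "band_sort_key",
    "write_sizes",
    "read_sizes",
    "write_truth",
    "read_truth",
    "write_clone_meta",
    "read_clone_meta",
]

#: Labeled 6-bp cutters, in channel-index order 0..3.
CHANNEL_NAMES = ("EcoRI", "XbaI", "BamHI", "XhoI")
#: One-letter channel codes (E, X, B, H) in the same order.
CHANNEL_CODES = "EXBH"
N_CHANNELS = 4
#: Width of one channel block in the encoded single-column value.
CHANNEL_OFFSET = 1000.0


class Band(NamedTuple):
    """One labeled restriction fragment: channel index, size (bp), peak height (RFU).

    ``height`` is ``None`` when unknown (e.g. after reading a ``.sizes``
    file, which does not carry heights).
    """

    channel: int
    size: float
    height: float | None = None


class CloneInterval(NamedTuple):
    """True genomic placement of one clone: 0-based half-open interval."""

    replicon: str
    start: int
    end: int
    clone_id: str


class SizesParseError(ValueError):
    """Raised when a ``.sizes`` file does not conform to the dialect."""


def band_sort_key(band: Band) -> tuple[int, float, float]:
    """Total serialization order: channel, then size, ties by height."""
    h = band.height if band.height is not None else float("-inf")
    return (band.channel, band.size, h)


@dataclass
class Fingerprint:
    """A clone's multiset of bands plus plate/well provenance."""

    clone_id: str
    bands: list[Band] = field(default_factory=list)
    plate: str = ""
    well: str = ""

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def sorted_bands(self) -> list[Band]:
        return sorted(self.bands, key=band_sort_key)

    def channel_sizes(self) -> list[list[float]]:
        """Per-channel ascending size lists (the matcher's working form)."""
        by_ch: list[list[float]] = [[] for _ in range(N_CHANNELS)]
        for b in self.bands:
            by_ch[b.channel].append(b.size)
        for sizes in by_ch:
            sizes.sort()
        return by_ch


def encode_band(band: Band, offset: float = CHANNEL_OFFSET) -> float:
    """Encode a band as the single-column value ``offset * channel + size``."""
    if not 0 <= band.channel < N_CHANNELS:
        raise ValueError(f"channel index {band.channel} not in 0..{N_CHANNELS - 1}")
    return offset * band.channel + band.size


def decode_band_value(value: float, offset: float = CHANNEL_OFFSET) -> Band:
    """Invert :func:`encode_band`; size is re-quantized to 0.1 bp.

    The re-quantization keeps decode(encode(b)) exact for in-window bands
    (sizes carry one decimal place in the file).
    """
    channel = int(value // offset)
    if not 0 <= channel < N_CHANNELS:
        raise ValueError(f"encoded value {value} outside channel blocks 0..{N_CHANNELS - 1}")
    size = round(value - offset * channel, 1)
    return Band(channel=channel, size=size, height=None)


def _open_text(path: str | Path, mode: str) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t", newline="")  # type: ignore[return-value]
    return open(path, mode, newline="")


def write_sizes(
    fingerprints: Sequence[Fingerprint], path: str | Path, offset: float = CHANNEL_OFFSET
) -> None:
    """Write fingerprints in the single-column ``.sizes`` dialect.

    Clones appear in input order; bands ascending by (channel, size);
    values carry exactly one decimal place. Byte-for-byte deterministic.
    """
    seen: set[str] = set()
    for fp in fingerprints:
        if fp.clone_id in seen:
            raise ValueError(f"duplicate clone_id {fp.clone_id!r}")
        seen.add(fp.clone_id)
    with _open_text(path, "w") as fh:
        for fp in fingerprints:
            fh.write(f"{fp.clone_id} {fp.n_bands}\n")
            for band in fp.sorted_bands():
                fh.write(f"{encode_band(band, offset):.1f}\n")


def read_sizes(path: str | Path, offset: float = CHANNEL_OFFSET) -> list[Fingerprint]:
    """Read a ``.sizes`` file; heights come back as ``None`` (unknown)."""
    fingerprints: list[Fingerprint] = []
    current: Fingerprint | None = None
    expected = 0
    with _open_text(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            tokens = line.split()
            if current is not None and len(current.bands) < expected:
                if len(tokens) != 1:
                    raise SizesParseError(
                        f"line {lineno}: expected a band value for clone "
                        f"{current.clone_id!r} ({len(current.bands)}/{expected} read)"
                    )
                current.bands.append(decode_band_value(float(tokens[0]), offset))
                continue
            # header line
            if len(tokens) != 2:
                raise SizesParseError(
                    f"line {lineno}: expected '<clone_id> <n_bands>' header, got {line!r}"
                )
            try:
                expected = int(tokens[1])
            except ValueError as exc:
                raise SizesParseError(f"line {lineno}: bad band count {tokens[1]!r}") from exc
            current = Fingerprint(clone_id=tokens[0])
            fingerprints.append(current)
    if current is not None and len(current.bands) != expected:
        raise SizesParseError(
            f"end of file: clone {current.clone_id!r} declared {expected} bands, "
            f"found {len(current.bands)}"
        )
    return fingerprints


def write_truth(intervals: Iterable[CloneInterval], path: str | Path) -> None:
    """Write clone intervals as BED3+1, sorted by (replicon, start).

    Overlapping intervals are expected (clones tile the genome redundantly).
    """
    rows = sorted(intervals, key=lambda iv: (iv.replicon, iv.start, iv.end, iv.clone_id))
    for iv in rows:
        if iv.end <= iv.start:
            raise ValueError(f"interval for {iv.clone_id!r} has end <= start: {iv}")
    with _open_text(path, "w") as fh:
        for iv in rows:
            fh.write(f"{iv.replicon}\t{iv.start}\t{iv.end}\t{iv.clone_id}\n")


def read_truth(path: str | Path) -> list[CloneInterval]:
    """Read BED3+1 clone intervals; returned sorted by (replicon, start)."""
    out: list[CloneInterval] = []
    with _open_text(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"line {lineno}: BED3+1 needs 4 columns, got {len(fields)}")
            start, end = int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"line {lineno}: end <= start")
            out.append(CloneInterval(fields[0], start, end, fields[3]))
    out.sort(key=lambda iv: (iv.replicon, iv.start, iv.end, iv.clone_id))
    return out


def write_clone_meta(fingerprints: Sequence[Fingerprint], path: str | Path) -> None:
    """Sidecar TSV holding plate, well and per-band heights.

    Heights align with the band order of :meth:`Fingerprint.sorted_bands`,
    comma-joined at one decimal; ``.`` when heights are unknown.
    """
    with _open_text(path, "w") as fh:
        fh.write("clone_id\tplate\twell\theights\n")
        for fp in fingerprints:
            bands = fp.sorted_bands()
            if bands and all(b.height is not None for b in bands):
                heights = ",".join(f"{b.height:.1f}" for b in bands)
            else:
                heights = "."
            fh.write(f"{fp.clone_id}\t{fp.plate}\t{fp.well}\t{heights}\n")


def read_clone_meta(
    fingerprints: Sequence[Fingerprint], path: str | Path
) -> list[Fingerprint]:
    """Apply a sidecar TSV onto fingerprints (matched by clone_id), in place."""
    meta: dict[str, tuple[str, str, list[float] | None]] = {}
    with _open_text(path, "r") as fh:
        header = fh.readline()
        if not header.startswith("clone_id"):
            raise ValueError("clone meta sidecar must start with a 'clone_id' header")
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            clone_id, plate, well, heights_s = line.split("\t")
            heights = None if heights_s == "." else [float(h) for h in heights_s.split(",")]
            meta[clone_id] = (plate, well, heights)
    for fp in fingerprints:
        if fp.clone_id not in meta:
            continue
        plate, well, heights = meta[fp.clone_id]
        fp.plate, fp.well = plate, well
        if heights is not None:
            bands = fp.sorted_bands()
            if len(heights) != len(bands):
                raise ValueError(
                    f"clone {fp.clone_id!r}: {len(heights)} heights for {len(bands)} bands"
                )
            fp.bands = [Band(b.channel, b.size, h) for b, h in zip(bands, heights)]
    return list(fingerprints)
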