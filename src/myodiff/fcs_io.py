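"""FCS 3.0 reading/writing and population-statistics CSV export.

The reader targets list-mode FCS 3.0/3.1 files as exported by bench-top
cytometers such as the Guava easyCyte family: datatype ``F`` (float32) or
``I`` (unsigned integer up to 32 bit), single TEXT segment, no ANALYSIS
segment.  Datatypes ``A`` (ASCII) and ``D`` (double) are rejected loudly.

Merged files chain several datasets in one file.  Offset convention used by
both reader and writer (and stated here because the standard is ambiguous in
practice): every HEADER offset and the ``$NEXTDATA`` keyword are byte offsets
*relative to the start of the dataset they belong to*; for the first dataset
this coincides with absolute file offsets.  A ``$NEXTDATA`` of 0 terminates
the chain.

The writer emits a single dialect — float32, little-endian, TEXT delimiter
``/`` — so that write→read round-trips are bit-exact at float32 precision.

Integer data declared with a decadic log amplifier (``$PnE`` = ``f1,f2`` with
``f1 > 0``) is linearized to RFU on read as ``f2 * 10**(f1 * x / R)`` with
``R = $PnR`` and ``f2 == 0`` treated as 1 — the standard convention — because
every gate in this package is expressed in linear RFU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    ChannelResolutionError,
    ConfigurationError,
    FcsParseError,
    IntegrityError,
    UnsupportedFormatError,
)

__all__ = [
    "ChannelInfo",
    "Sample",
    "Experiment",
    "read_fcs",
    "write_fcs",
    "export_population_stats",
    "read_population_stats",
    "validate_population_stats",
    "POPULATION_STATS_COLUMNS",
]

_HEADER_LEN = 58
_MAGICS = (b"FCS3.0", b"FCS3.1")
_DELIM = "/"

#: Precedence list of TEXT keywords that may carry the acquisition well
#: identity.  The vendor keyword is not standardized, so the reader tries
#: these in order and falls back to no well id.
WELL_KEYWORD_PRECEDENCE = ("$WELLID", "WELL ID", "WELLID", "WELL", "$SMNO")

#: Channels of a Guava-style two-laser acquisition as used throughout this
#: package (forward/side scatter, GFP on Green-B, MyHC label on Red-R, plus
#: forward-scatter height for doublet checks).
GUAVA_CHANNELS = ("FSC-HLin", "SSC-HLin", "GRN-B-HLin", "RED-R-HLin", "FSC-H")

ROLES = ("double_negative", "myhc_positive", "gfp_positive", "target")

POPULATION_STATS_COLUMNS = ("sample", "pop", "count")


def normalize_channel_name(name: str) -> str:
    """Canonical channel key: '.' and '-' are interchangeable separators and
    matching is case-insensitive (``GRN.B.HLin`` == ``GRN-B-HLin``)."""
    return name.strip().replace(".", "-").upper()


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one acquisition channel.

    ``amplification`` is the ``$PnE`` pair ``(decades, offset)``; ``(0, 0)``
    means linearly stored data.
    """

    name: str
    index: int  # 1-based position
    range: float = 1048576.0
    amplification: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("channel name must be non-empty")
        if self.index < 1:
            raise ConfigurationError("channel index is 1-based")
        if not self.range > 0:
            raise ConfigurationError("channel range must be > 0")


@dataclass
class Sample:
    """One acquisition: an events × channels intensity matrix in RFU.

    ``truth`` is only populated by the simulator (per-event ground truth for
    testing); real files never carry it.
    """

    sample_id: str
    events: np.ndarray
    channels: list[ChannelInfo]
    keywords: dict[str, str] = field(default_factory=dict)
    well_id: str | None = None
    truth: object | None = None

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.float64)
        if self.events.ndim != 2:
            self.events = self.events.reshape(-1, len(self.channels))
        if self.events.shape[1] != len(self.channels):
            raise ConfigurationError(
                f"event matrix has {self.events.shape[1]} columns but {len(self.channels)} channels"
            )
        if self.events.size and not np.all(np.isfinite(self.events)):
            raise ConfigurationError("event intensities must be finite")
        names = [normalize_channel_name(c.name) for c in self.channels]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate channel names: {names}")
        if [c.index for c in self.channels] != list(range(1, len(self.channels) + 1)):
            raise ConfigurationError("channel indices must be contiguous from 1")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def channel_index(self, name: str) -> int:
        """0-based column index for a channel name ('.'/'-' equivalent)."""
        key = normalize_channel_name(name)
        for i, c in enumerate(self.channels):
            if normalize_channel_name(c.name) == key:
                return i
        raise ChannelResolutionError(
            f"channel {name!r} not found in sample {self.sample_id!r}; available: {self.channel_names}"
        )

    def channel_data(self, name: str) -> np.ndarray:
        return self.events[:, self.channel_index(name)]


@dataclass
class Experiment:
    """A set of samples with control/target role assignments.

    ``roles`` maps each role in :data:`ROLES` to a list of sample ids; the
    double-negative and MyHC+ controls must each name exactly one sample.
    """

    samples: list[Sample]
    roles: dict[str, list[str]]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate sample ids: {ids}")
        for role, assigned in self.roles.items():
            if role not in ROLES:
                raise ConfigurationError(f"unknown role {role!r}; expected one of {ROLES}")
            for sid in assigned:
                if sid not in ids:
                    raise ConfigurationError(f"role {role!r} names unknown sample {sid!r}")
        for role in ("double_negative", "myhc_positive"):
            if len(self.roles.get(role, [])) != 1:
                raise ConfigurationError(f"exactly one {role} control required")

    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def control(self, role: str) -> Sample:
        return self.sample(self.roles[role][0])

    def targets(self) -> list[Sample]:
        return [self.sample(sid) for sid in self.roles.get("target", [])]


# ---------------------------------------------------------------------------
# reading


def _parse_header(data: bytes, start: int) -> tuple[int, int, int, int]:
    magic = data[start : start + 6]
    if magic not in _MAGICS:
        raise UnsupportedFormatError(
            f"not an FCS 3.0/3.1 dataset at offset {start}: magic {magic!r}"
        )
    offsets = []
    for i in range(4):  # TEXT begin/end, DATA begin/end (ANALYSIS ignored)
        fld = data[start + 10 + 8 * i : start + 18 + 8 * i]
        try:
            offsets.append(int(fld))
        except ValueError as exc:
            raise FcsParseError(
                f"HEADER offset field {i} is not an integer: {fld!r}", offset=start + 10 + 8 * i
            ) from exc
    return tuple(offsets)  # type: ignore[return-value]


def _parse_text(data: bytes, tb: int, te: int) -> dict[str, str]:
    if te <= tb or te >= len(data):
        raise FcsParseError("TEXT segment offsets out of bounds", offset=tb)
    raw = data[tb : te + 1]
    delim = raw[0:1]
    if raw[-1:] != delim:
        raise FcsParseError("TEXT segment does not end with its delimiter", offset=te)
    parts = raw[1:-1].split(delim)
    if any(p == b"" for p in parts):
        # doubled (escaped) delimiters are not part of the dialect we write;
        # treat them as an inconsistency rather than guessing.
        raise FcsParseError("empty key or value in TEXT (doubled delimiter?)", offset=tb)
    if len(parts) % 2:
        raise FcsParseError("odd number of TEXT tokens (unpaired keyword)", offset=tb)
    kw: dict[str, str] = {}
    for k, v in zip(parts[::2], parts[1::2]):
        key = k.decode("latin-1").strip()
        key = key.upper() if key.startswith("$") else key
        kw[key] = v.decode("latin-1").strip()
    return kw


def _required(kw: Mapping[str, str], key: str, tb: int) -> str:
    try:
        return kw[key]
    except KeyError as exc:
        raise FcsParseError(f"required keyword {key} missing from TEXT", offset=tb) from exc


def _decode_dataset(data: bytes, start: int, path: Path, ordinal: int) -> tuple[Sample, int]:
    tb_r, te_r, db_r, de_r = _parse_header(data, start)
    tb, te = start + tb_r, start + te_r
    kw = _parse_text(data, tb, te)

    datatype = _required(kw, "$DATATYPE", tb).upper()
    if datatype in ("A", "D"):
        raise UnsupportedFormatError(f"datatype {datatype!r} is not supported (only 'F' and 'I')")
    if datatype not in ("F", "I"):
        raise UnsupportedFormatError(f"unknown $DATATYPE {datatype!r}")
    mode = kw.get("$MODE", "L").upper()
    if mode != "L":
        raise UnsupportedFormatError(f"only list mode ($MODE L) is supported, got {mode!r}")

    byteord = _required(kw, "$BYTEORD", tb)
    endian = "<" if byteord.strip().startswith("1") else ">"
    par = int(_required(kw, "$PAR", tb))
    tot = int(_required(kw, "$TOT", tb))

    channels: list[ChannelInfo] = []
    bits: list[int] = []
    for i in range(1, par + 1):
        name = _required(kw, f"$P{i}N", tb)
        bits.append(int(_required(kw, f"$P{i}B", tb)))
        rng = float(kw.get(f"$P{i}R", 1048576))
        amp = (0.0, 0.0)
        if f"$P{i}E" in kw:
            d, o = (float(x) for x in kw[f"$P{i}E"].split(","))
            amp = (d, o)
        channels.append(ChannelInfo(name=name, index=i, range=rng, amplification=amp))

    # DATA segment: header offsets of 0 defer to $BEGINDATA/$ENDDATA
    if db_r == 0 and de_r == 0:
        db_r = int(_required(kw, "$BEGINDATA", tb))
        de_r = int(_required(kw, "$ENDDATA", tb))
    db, de = start + db_r, start + de_r

    if datatype == "F":
        if any(b != 32 for b in bits):
            raise UnsupportedFormatError("$DATATYPE F requires $PnB 32 for every parameter")
        expected = 4 * par * tot
        raw = data[db : de + 1] if expected else b""
        if len(raw) != expected:
            raise IntegrityError(
                f"DATA segment holds {len(raw)} bytes but $TOT={tot}, $PAR={par} imply {expected}"
            )
        events = np.frombuffer(raw, dtype=endian + "f4").reshape(tot, par).astype(np.float64)
    else:  # "I"
        nbits = set(bits)
        if len(nbits) != 1 or bits[0] not in (8, 16, 32):
            raise UnsupportedFormatError(
                f"integer data requires a uniform $PnB of 8/16/32, got {bits}"
            )
        width = bits[0] // 8
        expected = width * par * tot
        raw = data[db : de + 1] if expected else b""
        if len(raw) != expected:
            raise IntegrityError(
                f"DATA segment holds {len(raw)} bytes but $TOT={tot}, $PAR={par}, $PnB={bits[0]} imply {expected}"
            )
        dtype = {1: "u1", 2: "u2", 4: "u4"}[width]
        events = np.frombuffer(raw, dtype=endian + dtype).reshape(tot, par).astype(np.float64)
        # linearize log-amplified channels to RFU
        for j, ch in enumerate(channels):
            d, o = ch.amplification
            if d > 0:
                scale = o if o != 0 else 1.0
                events[:, j] = scale * np.power(10.0, d * events[:, j] / ch.range)

    well_id = None
    for key in WELL_KEYWORD_PRECEDENCE:
        if kw.get(key):
            well_id = kw[key]
            break

    sample_id = kw.get("$FIL") or f"{path.stem}-{ordinal}"
    nextdata = int(kw.get("$NEXTDATA", "0"))
    sample = Sample(
        sample_id=sample_id,
        events=events,
        channels=channels,
        keywords=kw,
        well_id=well_id,
    )
    return sample, (start + nextdata if nextdata else 0)


def read_fcs(path: str | Path) -> list[Sample]:
    """Read an FCS 3.0/3.1 file into one :class:`Sample` per dataset.

    Merged files are followed along the ``$NEXTDATA`` chain until it is 0.
    """
    path = Path(path)
    data = path.read_bytes()
    if len(data) < _HEADER_LEN:
        raise FcsParseError(f"file too short for an FCS HEADER ({len(data)} bytes)", offset=0)
    samples: list[Sample] = []
    start, ordinal = 0, 1
    seen = set()
    while True:
        if start in seen:
            raise IntegrityError("circular $NEXTDATA chain")
        seen.add(start)
        sample, nxt = _decode_dataset(data, start, path, ordinal)
        samples.append(sample)
        if nxt == 0:
            break
        start, ordinal = nxt, ordinal + 1
    return samples


# ---------------------------------------------------------------------------
# writing


def _text_bytes(pairs: list[tuple[str, str]]) -> bytes:
    for k, v in pairs:
        if _DELIM in k or _DELIM in v:
            raise ConfigurationError(f"keyword {k!r}={v!r} contains the TEXT delimiter {_DELIM!r}")
        if not k or not v:
            raise ConfigurationError(f"empty keyword or value ({k!r}={v!r}) cannot be serialized")
    body = _DELIM + _DELIM.join(x for kv in pairs for x in kv) + _DELIM
    return body.encode("latin-1")


_RESERVED = {
    "$BEGINANALYSIS", "$ENDANALYSIS", "$BEGINSTEXT", "$ENDSTEXT",
    "$BEGINDATA", "$ENDDATA", "$NEXTDATA", "$BYTEORD", "$DATATYPE",
    "$MODE", "$PAR", "$TOT", "$FIL",
}


def _dataset_bytes(sample: Sample, is_last: bool) -> bytes:
    if not sample.channels:
        raise ConfigurationError(f"sample {sample.sample_id!r} has no channels")
    events32 = np.ascontiguousarray(sample.events, dtype="<f4")
    if sample.events.size and not np.all(np.isfinite(events32)):
        raise ConfigurationError("intensities not representable as float32")
    data = events32.tobytes()
    par, tot = len(sample.channels), sample.n_events

    extra: list[tuple[str, str]] = []
    for k, v in sample.keywords.items():
        key = k.upper() if k.startswith("$") else k
        if key in _RESERVED or (key.startswith("$P") and key[-1] in "NBER"):
            continue
        if key in WELL_KEYWORD_PRECEDENCE:
            continue
        extra.append((key, str(v)))

    db = de = nd = 0
    for _ in range(8):  # iterate offsets to a fixed point (digit widths vary)
        pairs: list[tuple[str, str]] = [
            ("$BEGINANALYSIS", "0"), ("$ENDANALYSIS", "0"),
            ("$BEGINSTEXT", "0"), ("$ENDSTEXT", "0"),
            ("$BEGINDATA", str(db)), ("$ENDDATA", str(de)),
            ("$NEXTDATA", str(nd)),
            ("$BYTEORD", "1,2,3,4"), ("$DATATYPE", "F"), ("$MODE", "L"),
            ("$PAR", str(par)), ("$TOT", str(tot)),
            ("$FIL", sample.sample_id),
        ]
        if sample.well_id:
            pairs.append(("$WELLID", sample.well_id))
        for ch in sample.channels:
            i = ch.index
            pairs += [
                (f"$P{i}N", ch.name),
                (f"$P{i}B", "32"),
                (f"$P{i}E", "0,0"),
                (f"$P{i}R", f"{ch.range:g}"),
            ]
        pairs += extra
        text = _text_bytes(pairs)
        tb = _HEADER_LEN
        te = tb + len(text) - 1
        if data:
            new_db, new_de = te + 1, te + len(data)
        else:
            new_db, new_de = 0, 0
        new_nd = 0 if is_last else te + 1 + len(data)
        if (new_db, new_de, new_nd) == (db, de, nd):
            break
        db, de, nd = new_db, new_de, new_nd
    else:  # pragma: no cover - the iteration converges in <= 3 passes
        raise RuntimeError("offset fixed point not reached")

    header = b"FCS3.0    " + b"".join(
        str(x).rjust(8).encode("ascii") for x in (tb, te, db, de, 0, 0)
    )
    assert len(header) == _HEADER_LEN
    return header + text + data


def write_fcs(samples: Sample | Iterable[Sample], path: str | Path) -> None:
    """Write one or more samples as a (possibly merged) FCS 3.0 file."""
    if isinstance(samples, Sample):
        samples = [samples]
    samples = list(samples)
    if not samples:
        raise ConfigurationError("cannot write an FCS file with no samples")
    chunks = [
        _dataset_bytes(s, is_last=(i == len(samples) - 1)) for i, s in enumerate(samples)
    ]
    Path(path).write_bytes(b"".join(chunks))


# ---------------------------------------------------------------------------
# population statistics CSV


def export_population_stats(stats: pd.DataFrame, path: str | Path) -> None:
    """Write population counts as CSV with header exactly ``sample,pop,count``."""
    validate_population_stats(stats)
    out = stats.loc[:, list(POPULATION_STATS_COLUMNS)].copy()
    out["count"] = out["count"].astype(np.int64)
    out.to_csv(path, index=False)


def read_population_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample": str, "pop": str})
    if tuple(df.columns) != POPULATION_STATS_COLUMNS:
        raise ConfigurationError(
            f"expected columns {POPULATION_STATS_COLUMNS}, got {tuple(df.columns)}"
        )
    df["count"] = df["count"].astype(np.int64)
    return df


def validate_population_stats(stats: pd.DataFrame) -> None:
    """Check the shape and the child ≤ parent rule along population paths."""
    if list(stats.columns) != list(POPULATION_STATS_COLUMNS):
        raise ConfigurationError(
            f"population stats must have columns {POPULATION_STATS_COLUMNS}, got {list(stats.columns)}"
        )
    if (stats["count"] < 0).any():
        raise ConfigurationError("population counts must be non-negative")
    for sample_id, grp in stats.groupby("sample"):
        counts = dict(zip(grp["pop"], grp["count"]))
        for pop, count in counts.items():
            if pop == "root":
                continue
            parent = pop.rsplit("/", 1)[0] or "root"
            if parent == "":
                parent = "root"
            if parent in counts and count > counts[parent]:
                raise ConfigurationError(
                    f"sample {sample_id!r}: count({pop})={count} exceeds count({parent})={counts[parent]}"
                )
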