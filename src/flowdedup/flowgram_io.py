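"""SFF and FASTA input/output and the central ``Flowgram`` record.

Flow values are stored internally as decimals quantized to hundredths,
mirroring the SFF on-disk encoding (unsigned 16-bit hundredths).  Clip
points live in 1-based base coordinates as in SFF; conversion to flow
coordinates is performed by :func:`base_to_flow` by walking the called
sequence.  Flows are 0-based internally and 1-based only in logs and
error messages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO import SffIO
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Flowgram",
    "SffFormatError",
    "read_sff",
    "write_sff",
    "flow_to_bases",
    "write_fasta",
    "base_to_flow",
    "round_half_up",
]

#: Phred quality assigned to every base written to SFF (the model carries
#: no per-base qualities; a constant keeps write->read->write byte-stable).
_DEFAULT_QUALITY = 30

_FASTA_WIDTH = 70


class SffFormatError(ValueError):
    """Raised when an SFF file is malformed (bad magic, truncation...)."""


def round_half_up(values):
    """Round to nearest integer with ties at .5 rounding up.

    A flow value of exactly 0.5 leads to at least one called base, so the
    boundary belongs to the positive side.
    """
    return np.floor(np.asarray(values, dtype=float) + 0.5).astype(int)


@dataclass
class Flowgram:
    """One read's flow values with trim points, key and flow order.

    ``clip_left``/``clip_right`` are 1-based base coordinates (first and
    last informative base); 0 means "no clipping" on that side.  When
    ``trim_flow_start``/``trim_flow_end`` are set they directly define the
    informative flow window (0-based, half-open) and take precedence over
    the base-coordinate clips; this is used for consensus flowgrams whose
    window is defined in flow space.
    """

    read_id: str
    flow_values: np.ndarray
    flow_order: str
    key_sequence: str = "TCAG"
    clip_left: int = 0
    clip_right: int = 0
    trim_flow_start: int | None = None
    trim_flow_end: int | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.flow_values, dtype=float)
        if values.ndim != 1:
            raise ValueError("flow_values must be one-dimensional")
        if np.any(values < 0):
            raise ValueError(f"negative flow value in read {self.read_id!r}")
        if len(self.flow_order) != len(values):
            raise ValueError(
                f"flow_order length {len(self.flow_order)} != "
                f"n_flows {len(values)} for read {self.read_id!r}"
            )
        self.flow_values = values

    @property
    def n_flows(self) -> int:
        return len(self.flow_values)

    @property
    def bases(self) -> str:
        return flow_to_bases(self)

    def base_calls(self) -> np.ndarray:
        """Integer number of bases called by each flow."""
        return round_half_up(self.flow_values)

    def flow_window(self) -> tuple[int, int]:
        """Informative flow range as a 0-based half-open interval.

        Derived from the explicit flow trims when present, otherwise from
        the base-coordinate clip points via :func:`base_to_flow`.
        """
        if self.trim_flow_start is not None and self.trim_flow_end is not None:
            return self.trim_flow_start, self.trim_flow_end
        calls = self.base_calls()
        total = int(calls.sum())
        if total == 0:
            return 0, 0
        first = self.clip_left if self.clip_left else 1
        last = self.clip_right if self.clip_right else total
        last = min(last, total)
        if first > last:
            return 0, 0
        return base_to_flow(calls, first), base_to_flow(calls, last) + 1

    def trimmed_values(self) -> np.ndarray:
        start, end = self.flow_window()
        return self.flow_values[start:end]

    def trimmed_bases(self) -> str:
        """Called nucleotides of the informative region."""
        calls = self.base_calls()
        start, end = self.flow_window()
        out = []
        for i in range(start, end):
            out.append(self.flow_order[i] * calls[i])
        return "".join(out)

    def with_values(self, values: np.ndarray, **kwargs) -> "Flowgram":
        return replace(self, flow_values=np.asarray(values, dtype=float), **kwargs)


def base_to_flow(calls: Sequence[int], base_position: int) -> int:
    """Map a 1-based called-base position to its 0-based flow index."""
    if base_position < 1:
        raise ValueError("base positions are 1-based")
    cumulative = np.cumsum(calls)
    idx = int(np.searchsorted(cumulative, base_position))
    if idx >= len(cumulative) or cumulative[-1] < base_position:
        raise ValueError(
            f"base position {base_position} beyond called sequence "
            f"({int(cumulative[-1]) if len(cumulative) else 0} bases)"
        )
    return idx


def flow_to_bases(fg: Flowgram) -> str:
    """Call bases by rounding each flow value (ties at .5 round up)."""
    calls = fg.base_calls()
    return "".join(
        ch * n for ch, n in zip(fg.flow_order, calls) if n > 0
    )


def _flow_index(calls: np.ndarray) -> list[int]:
    """SFF per-base flow-index deltas (1-based, delta-encoded)."""
    deltas = []
    previous = 0
    for i, n in enumerate(calls):
        for k in range(n):
            deltas.append(i + 1 - previous)
            previous = i + 1
    return deltas


def _to_seqrecord(fg: Flowgram) -> SeqRecord:
    hundredths = np.round(fg.flow_values * 100).astype(int)
    if np.any(np.abs(fg.flow_values * 100 - hundredths) > 1e-6):
        logger.warning(
            "read %s: flow values with more than two decimals quantized "
            "to hundredths on write",
            fg.read_id,
        )
    values = [int(v) for v in hundredths]
    calls = round_half_up(np.asarray(values) / 100.0)
    seq = "".join(ch * n for ch, n in zip(fg.flow_order, calls) if n > 0)
    record = SeqRecord(Seq(seq), id=fg.read_id, description="")
    record.annotations = {
        "flow_values": values,
        "flow_index": _flow_index(calls),
        "flow_chars": fg.flow_order,
        "flow_key": fg.key_sequence,
        # Biopython stores clip_qual_left as the count of clipped bases.
        "clip_qual_left": max(fg.clip_left - 1, 0),
        "clip_qual_right": fg.clip_right,
        "clip_adapter_left": 0,
        "clip_adapter_right": 0,
        "molecule_type": "DNA",
    }
    record.letter_annotations["phred_quality"] = [_DEFAULT_QUALITY] * len(seq)
    return record


def _from_seqrecord(record: SeqRecord) -> Flowgram:
    ann = record.annotations
    values = np.asarray(ann["flow_values"], dtype=float) / 100.0
    return Flowgram(
        read_id=record.id,
        flow_values=values,
        flow_order=ann["flow_chars"],
        key_sequence=ann["flow_key"],
        clip_left=int(ann["clip_qual_left"]) + 1,
        clip_right=int(ann["clip_qual_right"]),
    )


def read_sff(path) -> list[Flowgram]:
    """Read all reads of an SFF file, preserving order.

    Raises :class:`SffFormatError` on a bad magic number or a truncated
    record, naming the offending offset or read index.
    """
    path = Path(path)
    with open(path, "rb") as handle:
        magic = handle.read(4)
        if magic != b".sff":
            raise SffFormatError(
                f"{path}: bad SFF magic number at offset 0: {magic!r}"
            )
    import struct

    flowgrams: list[Flowgram] = []
    try:
        with open(path, "rb") as handle:
            for record in SeqIO.parse(handle, "sff"):
                flowgrams.append(_from_seqrecord(record))
    except (ValueError, struct.error, EOFError) as exc:
        raise SffFormatError(
            f"{path}: malformed SFF near read index {len(flowgrams)}: {exc}"
        ) from exc
    return flowgrams


def write_sff(
    flowgrams: Iterable[Flowgram],
    path,
    *,
    flow_order: str | None = None,
    key_sequence: str = "TCAG",
) -> int:
    """Write flowgrams to a valid SFF file; returns the read count.

    All flowgrams must share flow order, key sequence and flow count.
    ``flow_order`` / ``key_sequence`` are only consulted for an empty
    collection, where a header-only SFF is emitted.
    """
    flowgrams = list(flowgrams)
    path = Path(path)
    if not flowgrams:
        _write_empty_sff(path, flow_order or "TACG" * 100, key_sequence)
        return 0
    first = flowgrams[0]
    for fg in flowgrams[1:]:
        if fg.flow_order != first.flow_order:
            raise ValueError(
                f"heterogeneous flow orders: read {fg.read_id!r} does not "
                f"match read {first.read_id!r}"
            )
        if fg.key_sequence != first.key_sequence:
            raise ValueError(
                f"heterogeneous key sequences: read {fg.read_id!r} does not "
                f"match read {first.read_id!r}"
            )
        if fg.n_flows != first.n_flows:
            raise ValueError(
                f"heterogeneous flow counts: read {fg.read_id!r} has "
                f"{fg.n_flows} flows, expected {first.n_flows}"
            )
    with open(path, "wb") as handle:
        writer = SffIO.SffWriter(handle, index=False)
        count = writer.write_file(_to_seqrecord(fg) for fg in flowgrams)
    return count


def _write_empty_sff(path: Path, flow_order: str, key_sequence: str) -> None:
    import struct

    key = key_sequence.encode()
    flows = flow_order.encode()
    header = struct.pack(
        ">IIQIIHHHB",
        0x2E736666,  # ".sff"
        1,  # version 0001
        0,  # index offset
        0,  # index length
        0,  # number of reads
        0,  # header length, patched below
        len(key),
        len(flows),
        1,  # flowgram format code
    )
    header += flows + key
    padding = (8 - len(header) % 8) % 8
    header += b"\x00" * padding
    header = header[:24] + struct.pack(">H", len(header)) + header[26:]
    path.write_bytes(header)


def write_fasta(records: Iterable[tuple[str, str]], path) -> int:
    """Write (id, sequence) records as wrapped FASTA; returns the count."""
    count = 0
    with open(path, "w") as handle:
        for read_id, sequence in records:
            if not read_id:
                raise ValueError("FASTA records require a non-empty id")
            handle.write(f">{read_id}\n")
            for i in range(0, max(len(sequence), 1), _FASTA_WIDTH):
                handle.write(sequence[i : i + _FASTA_WIDTH] + "\n")
            count += 1
    return count
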