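"""FASTQ input/output and the read data model.

A :class:`Read` carries its sequence together with per-base error
probabilities decoded from the Phred-scaled quality string.  Quality values
are clamped strictly inside (0, 1): downstream stages multiply error
probabilities across read occurrences (in log-space), and an exact 0 or 1
would collapse those products.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Tuple

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

#: Default clamp for per-base error probabilities.
DEFAULT_CLAMP: Tuple[float, float] = (1e-10, 1.0 - 1e-10)

# parsing is the single masking point: anything outside ACGT becomes N here
_ACGTN = set("ACGTN")


class FastqParseError(ValueError):
    """Malformed FASTQ record; carries the file path and an approximate line number."""

    def __init__(self, path, line: int, message: str):
        self.path = str(path)
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


@dataclass
class Read:
    """A sequencing read with decoded per-base error probabilities.

    Attributes
    ----------
    id : str
        Record identifier (full FASTQ title line, without the leading ``@``).
    seq : str
        Upper-case sequence over {A, C, G, T, N}.
    qual : numpy.ndarray
        Per-base error probabilities q_r[i], each strictly inside (0, 1).
    raw_qual : str
        The original quality string, preserved verbatim for output.
    """

    id: str
    seq: str
    qual: np.ndarray
    raw_qual: str

    def __post_init__(self):
        if not (len(self.seq) == len(self.qual) == len(self.raw_qual)):
            raise ValueError(
                f"read {self.id!r}: seq/qual length mismatch "
                f"({len(self.seq)}/{len(self.qual)}/{len(self.raw_qual)})"
            )

    def __len__(self) -> int:
        return len(self.seq)


def phred_to_error_prob(qual_char: str, offset: int = 33,
                        clamp: Tuple[float, float] = DEFAULT_CLAMP) -> float:
    """Decode one quality character into an error probability 10^(-Q/10).

    Q = ord(qual_char) - offset; the result is clamped into ``clamp``.
    Raises ValueError for characters below the offset.
    """
    if offset not in (33, 64):
        raise ValueError(f"unsupported Phred offset {offset}")
    q = ord(qual_char) - offset
    if q < 0:
        raise ValueError(
            f"quality character {qual_char!r} (ord {ord(qual_char)}) below Phred offset {offset}"
        )
    p = 10.0 ** (-q / 10.0)
    return float(min(max(p, clamp[0]), clamp[1]))


def quality_to_probs(raw_qual: str, offset: int = 33,
                     clamp: Tuple[float, float] = DEFAULT_CLAMP) -> np.ndarray:
    """Vectorized decoding of a whole quality string."""
    codes = np.frombuffer(raw_qual.encode("latin-1"), dtype=np.uint8).astype(np.int64)
    q = codes - offset
    if np.any(q < 0):
        pos = int(np.argmax(q < 0))
        raise ValueError(
            f"quality character {raw_qual[pos]!r} at position {pos} below Phred offset {offset}"
        )
    return np.clip(10.0 ** (-q / 10.0), clamp[0], clamp[1])


def _open_read(path) -> io.TextIOBase:
    path = Path(path)
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=fh))
    return io.TextIOWrapper(fh)


def _open_write(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "wb"))
    return open(path, "w")


def normalize_sequence(seq: str) -> str:
    """Uppercase and map every base outside {A,C,G,T} to N."""
    s = seq.upper()
    if set(s) <= _ACGTN:
        return s
    return "".join(c if c in _ACGTN else "N" for c in s)


def read_fastq(path, offset: int = 33,
               clamp: Tuple[float, float] = DEFAULT_CLAMP) -> Iterator[Read]:
    """Yield :class:`Read` objects from a (possibly gzipped) FASTQ file.

    Lowercase bases are uppercased and non-ACGT bases mapped to N. Truncated
    records or seq/qual length mismatches raise :class:`FastqParseError`
    with an approximate line number (records are assumed 4-line).
    """
    n_records = 0
    handle = _open_read(path)
    try:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, raw_qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise FastqParseError(path, 4 * n_records + 1, str(exc)) from exc
            try:
                qual = quality_to_probs(raw_qual, offset=offset, clamp=clamp)
            except ValueError as exc:
                raise FastqParseError(
                    path, 4 * n_records + 4, f"record {title!r}: {exc}") from exc
            yield Read(id=title, seq=normalize_sequence(seq), qual=qual, raw_qual=raw_qual)
            n_records += 1
    finally:
        handle.close()


def write_fastq(reads: Iterable[Read], path) -> None:
    """Write reads as 4-line FASTQ (gzipped when the path ends in .gz).

    Corrected reads keep their original quality strings, so
    ``read_fastq(write_fastq(R))`` reproduces ids, sequences and quality
    strings byte-identically.
    """
    with _open_write(path) as out:
        for r in reads:
            out.write(f"@{r.id}\n{r.seq}\n+\n{r.raw_qual}\n")
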