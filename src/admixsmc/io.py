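"""Reading and writing binned heterozygosity tracks (psmcfa).

The observation track is one symbol per non-overlapping 100-bp bin of a
diploid genome: homozygous, heterozygous, or missing.  Two FASTA-like
dialects are supported per record:

* ``psmcfa``: ``T`` homozygous, ``K`` heterozygous, ``N`` missing;
* ``ternary``: ``0`` homozygous, ``1`` heterozygous, ``.`` missing.

Symbols are case-insensitive; the two dialects may not be mixed inside one
record.  The format is deliberately simple (headers plus fixed-width symbol
lines), and the reader is written directly so that parse errors can name the
offending line and symbol.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "HOM",
    "HET",
    "MISSING",
    "TernarySequence",
    "ParseError",
    "read_psmcfa",
    "write_psmcfa",
]

HOM, HET, MISSING = 0, 1, 2

_DECODE = {
    "T": (HOM, "psmcfa"),
    "K": (HET, "psmcfa"),
    "N": (MISSING, "psmcfa"),
    "0": (HOM, "ternary"),
    "1": (HET, "ternary"),
    ".": (MISSING, "ternary"),
}
_ENCODE = {
    "psmcfa": np.array(list("TKN")),
    "ternary": np.array(list("01.")),
}
_LINE_WIDTH = 60


class ParseError(ValueError):
    """Malformed psmcfa input."""


@dataclass
class TernarySequence:
    """Per-bin observation track over {HOM, HET, MISSING}.

    Attributes
    ----------
    name : str
        Record identifier (FASTA header without '>').
    codes : ndarray of int8
        One code per bin: 0 = HOM, 1 = HET, 2 = MISSING.
    bin_size : int
        Bases per bin; metadata only, not encoded in the file.
    """

    name: str
    codes: np.ndarray
    bin_size: int = 100

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.size == 0:
            raise ParseError(f"record {self.name!r} is empty")
        if self.bin_size < 1:
            raise ParseError("bin_size must be >= 1")
        if self.codes.min() < 0 or self.codes.max() > 2:
            raise ParseError("codes must be in {0, 1, 2}")

    def __len__(self) -> int:
        return self.codes.size

    def het_fraction(self) -> float:
        """Heterozygous fraction among non-missing bins (0 if none)."""
        obs = self.codes != MISSING
        if not obs.any():
            return 0.0
        return float((self.codes[obs] == HET).mean())


def _open_maybe(source, mode):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


def read_psmcfa(source, bin_size: int = 100) -> list[TernarySequence]:
    """Read all records from a psmcfa file or text stream.

    Parameters
    ----------
    source : path or text stream
    bin_size : int
        Bases per bin to attach to every record.

    Returns
    -------
    list of TernarySequence

    Raises
    ------
    ParseError
        On unknown symbols (with line number), mixed dialects within a
        record, empty records, or data before the first header.
    """
    stream, close = _open_maybe(source, "r")
    try:
        seqs: list[TernarySequence] = []
        name = None
        codes: list[int] = []
        dialect = None

        def flush():
            if name is None:
                return
            if not codes:
                raise ParseError(f"record {name!r} has no sequence data")
            seqs.append(TernarySequence(name, np.array(codes, dtype=np.int8), bin_size))

        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if line[1:].split() else line[1:]
                codes = []
                dialect = None
                continue
            if name is None:
                raise ParseError(f"line {lineno}: sequence data before first '>' header")
            for ch in line:
                try:
                    code, dia = _DECODE[ch.upper()]
                except KeyError:
                    raise ParseError(
                        f"line {lineno}: unknown symbol {ch!r} in record {name!r}"
                    ) from None
                if dialect is None:
                    dialect = dia
                elif dia != dialect:
                    raise ParseError(
                        f"line {lineno}: symbol {ch!r} mixes dialect {dia!r} "
                        f"into {dialect!r} record {name!r}"
                    )
                codes.append(code)
        flush()
        return seqs
    finally:
        if close:
            stream.close()


def write_psmcfa(seqs, dest, dialect: str = "psmcfa") -> None:
    """Write sequences as psmcfa, 60 symbols per line.

    Parameters
    ----------
    seqs : iterable of TernarySequence
    dest : path or text stream
    dialect : {"psmcfa", "ternary"}
    """
    if dialect not in _ENCODE:
        raise ValueError(f"unknown dialect {dialect!r}")
    alphabet = _ENCODE[dialect]
    stream, close = _open_maybe(dest, "w")
    try:
        for seq in seqs:
            stream.write(f">{seq.name}\n")
            chars = alphabet[seq.codes]
            for start in range(0, chars.size, _LINE_WIDTH):
                stream.write("".join(chars[start : start + _LINE_WIDTH]))
                stream.write("\n")
    finally:
        if close:
            stream.close()


def psmcfa_to_string(seqs, dialect: str = "psmcfa") -> str:
    buf = _io.StringIO()
    write_psmcfa(seqs, buf, dialect=dialect)
    return buf.getvalue()
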