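"""Transcript FASTA / site-table I/O, window extraction and one-hot coding.

Candidate 5-methyluridine (m5U) sites are uridines on mature transcripts.
A model example is a fixed-length window (default 41 nt) centred on the
candidate uridine, one-hot encoded with channel order (A, C, G, U) and
``N`` as the all-zero row. Coordinates are 0-based transcript offsets on
the sense strand; windows running past a transcript end are N-padded so
every site keeps its fixed input shape (a strict mode drops them).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "ALPHABET", "CHANNELS", "TranscriptSet", "SiteRecord", "SequenceWindow",
    "read_fasta", "write_fasta", "read_site_table", "write_site_table",
    "read_bed", "extract_window", "one_hot_encode", "decode_one_hot",
]

CHANNELS = "ACGU"
ALPHABET = set(CHANNELS) | {"N"}

_ONE_HOT = {base: np.eye(4)[i] for i, base in enumerate(CHANNELS)}
_ONE_HOT["N"] = np.zeros(4)

SITE_TABLE_HEADER = ["transcript_id", "position", "label", "domain"]


class FastaError(ValueError):
    """Malformed or inconsistent FASTA input."""


@dataclass
class TranscriptSet:
    """Mapping of transcript identifiers to RNA sequences over {A,C,G,U,N}."""

    entries: dict[str, str] = field(default_factory=dict)

    def __len__(self):
        return len(self.entries)

    def __getitem__(self, key: str) -> str:
        return self.entries[key]

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def add(self, name: str, seq: str):
        if name in self.entries:
            raise FastaError(f"duplicate transcript id: {name!r}")
        seq = seq.upper().replace("T", "U")
        if not seq:
            raise FastaError(f"empty sequence for transcript {name!r}")
        bad = set(seq) - ALPHABET
        if bad:
            raise FastaError(
                f"transcript {name!r} contains invalid characters {sorted(bad)}")
        self.entries[name] = seq


@dataclass(frozen=True)
class SiteRecord:
    """One candidate uridine on a transcript.

    ``position`` is a 0-based offset; ``label`` 1 for an experimentally
    detected site, 0 for a sampled negative; ``domain`` is ``"source"``
    (tRNA + other RNAs) or ``"target"`` (mRNA). ``tags`` carries optional
    metadata such as cell line or detection technique.
    """

    transcript_id: str
    position: int
    label: int
    domain: str
    tags: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label!r}")
        if self.domain not in ("source", "target"):
            raise ValueError(f"domain must be source/target, got {self.domain!r}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.transcript_id, self.position)


@dataclass(frozen=True)
class SequenceWindow:
    """Fixed odd-length window with the candidate uridine at the centre."""

    seq: str
    n_padded: int = 0

    def __post_init__(self):
        if len(self.seq) % 2 == 0:
            raise ValueError("window length must be odd")
        center = self.seq[len(self.seq) // 2]
        if center not in ("U", "N"):
            warnings.warn(
                f"window centre base is {center!r}, expected U", stacklevel=2)

    @property
    def center_index(self) -> int:
        return len(self.seq) // 2


def read_fasta(path) -> TranscriptSet:
    """Load a transcript FASTA; uppercases, maps T->U, rejects duplicates."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ts = TranscriptSet()
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    for rec in records:
        ts.add(rec.id, str(rec.seq))
    return ts

def write_fasta(transcripts: TranscriptSet, path):
    with open(path, "w") as fh:
        for name, seq in transcripts.entries.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_site_table(path) -> list[SiteRecord]:
    """Read a TSV site table: transcript_id, position, label, domain[, tags].

    ``label`` may be 0/1 or the words positive/negative; tag columns are
    ``key=value`` strings. A header line matching the canonical column
    names is skipped.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:4] == SITE_TABLE_HEADER:
                continue
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=4 columns, "
                    f"got {len(parts)}")
            tid, pos, label, domain = parts[:4]
            label_map = {"positive": 1, "negative": 0, "1": 1, "0": 0}
            if label not in label_map:
                raise ValueError(f"{path}: line {lineno}: bad label {label!r}")
            tags = tuple(tuple(p.split("=", 1)) for p in parts[4:] if p)
            records.append(SiteRecord(tid, int(pos), label_map[label],
                                      domain, tags))
    return records

def write_site_table(records: list[SiteRecord], path):
    with open(path, "w") as fh:
        fh.write("\t".join(SITE_TABLE_HEADER) + "\n")
        for r in records:
            cols = [r.transcript_id, str(r.position), str(r.label), r.domain]
            cols += [f"{k}={v}" for k, v in r.tags]
            fh.write("\t".join(cols) + "\n")


def read_bed(path, domain: str = "target") -> list[SiteRecord]:
    """Import BED6 where ``chrom`` is a transcript id.

    The site position is ``chromStart`` (BED is 0-based); ``name`` is kept
    as a tag, ``score`` > 0 marks a positive.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: not BED")
            tid, start = parts[0], int(parts[1])
            name = parts[3] if len(parts) > 3 else ""
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 1.0
            tags = (("name", name),) if name else ()
            records.append(SiteRecord(tid, start, int(score > 0), domain, tags))
    return records


def extract_window(transcripts: TranscriptSet, site: SiteRecord,
                   flank: int = 20, strict: bool = False) -> SequenceWindow:
    """Extract a (2*flank + 1)-nt window centred on the site.

    Positions outside the transcript are filled with N and counted in
    ``n_padded``; with ``strict=True`` such windows raise instead. A
    positive site whose centre base is not U triggers a warning but the
    window is still returned.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if site.transcript_id not in transcripts:
        raise KeyError(f"unknown transcript {site.transcript_id!r}")
    seq = transcripts[site.transcript_id]
    if not 0 <= site.position < len(seq):
        raise IndexError(
            f"site position {site.position} outside transcript "
            f"{site.transcript_id!r} (length {len(seq)})")
    lo = site.position - flank
    hi = site.position + flank + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(seq))
    if strict and (left_pad or right_pad):
        raise ValueError(
            f"window for {site.transcript_id}:{site.position} overlaps "
            "a transcript end (strict mode)")
    core = seq[max(lo, 0):min(hi, len(seq))]
    window = "N" * left_pad + core + "N" * right_pad
    center = window[flank]
    if site.label == 1 and center not in ("U", "N"):
        warnings.warn(
            f"positive site {site.transcript_id}:{site.position} centre "
            f"base is {center!r}, expected U", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return SequenceWindow(window, n_padded=left_pad + right_pad)


def one_hot_encode(window) -> np.ndarray:
    """One-hot encode a window as an L x 4 matrix, channels (A, C, G, U).

    N maps to the all-zero row. Accepts a :class:`SequenceWindow` or a
    plain string.
    """
    seq = window.seq if isinstance(window, SequenceWindow) else window
    mat = np.zeros((len(seq), 4))
    for i, base in enumerate(seq):
        try:
            mat[i] = _ONE_HOT[base]
        except KeyError:
            raise ValueError(
                f"invalid character {base!r} at offset {i}") from None
    return mat


def decode_one_hot(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; all-zero rows decode to N."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != 4:
        raise ValueError(f"expected an L x 4 matrix, got shape {matrix.shape}")
    if not np.isin(matrix, (0, 1)).all():
        raise ValueError("matrix must be binary")
    sums = matrix.sum(axis=1)
    if (sums > 1).any():
        bad = int(np.argmax(sums > 1))
        raise ValueError(f"row {bad} has sum > 1; not one-hot")
    out = []
    for row in matrix:
        out.append("N" if row.sum() == 0 else CHANNELS[int(np.argmax(row))])
    return "".join(out)
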