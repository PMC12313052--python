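"""Barcode counting from amplicon FASTQ reads.

Each read carries a fixed-length DNA barcode between two known flanking
anchor sequences (the amplicon adapter context).  The barcode window is
located by anchor search, then assigned to the library barcode with the
smallest Hamming distance, provided (i) the mismatch fraction does not
exceed ``max_error_rate`` (default 0.2) and (ii) the best hit is strictly
better than the second best — a uniqueness proxy for a mapping-quality >= 1
filter.  Indels inside the barcode window make a read unmatched by design:
barcodes are fixed length and flank-anchored, so Hamming distance keeps the
assignment simple and deterministic.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

# Amplicon adapter context flanking the 20-nt barcode.
UPSTREAM_ANCHOR = "GTCTAGAATCGCCGAAAGTAATTCAACTCCATTAA"
DOWNSTREAM_ANCHOR = "TCTAGATGCTTACTAGTTACCGCGGCCA"

__all__ = [
    "BarcodeLibrary",
    "UPSTREAM_ANCHOR",
    "DOWNSTREAM_ANCHOR",
    "match_read",
    "count_reads",
]


@dataclass
class BarcodeLibrary:
    """Barcode id -> sequence map plus the flanking anchor context."""

    barcodes: dict[str, str]
    upstream: str = UPSTREAM_ANCHOR
    downstream: str = DOWNSTREAM_ANCHOR
    _ids: list = field(init=False, repr=False)
    _matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError("empty barcode library")
        lengths = {len(b) for b in self.barcodes.values()}
        if len(lengths) != 1:
            raise ValueError(f"barcodes of unequal length: {sorted(lengths)}")
        if len(set(self.barcodes.values())) != len(self.barcodes):
            raise ValueError("duplicate barcode sequences in library")
        self._ids = list(self.barcodes)
        self._matrix = np.array(
            [[ord(c) for c in self.barcodes[i]] for i in self._ids], dtype=np.uint8
        )

    @property
    def barcode_length(self) -> int:
        return self._matrix.shape[1]

    @classmethod
    def from_library(cls, library, **kwargs) -> "BarcodeLibrary":
        """Build from a :class:`~evoscreen.design.CombinatorialLibrary`."""
        mapping = {}
        for v in library.members:
            if v.barcode is None:
                raise ValueError(f"member {v.label} has no barcode assigned")
            mapping[v.label] = v.barcode
        return cls(barcodes=mapping, **kwargs)


def _find_anchor(read: str, anchor: str, max_mismatch_rate: float = 0.2) -> int | None:
    """Best approximate occurrence of ``anchor``; returns start index or None."""
    pos = read.find(anchor)
    if pos >= 0:
        return pos
    la = len(anchor)
    if len(read) < la:
        return None
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    a = np.frombuffer(anchor.encode(), dtype=np.uint8)
    n_windows = len(read) - la + 1
    windows = np.lib.stride_tricks.sliding_window_view(r, la)
    mism = (windows != a).sum(axis=1)
    best = int(mism.argmin())
    if mism[best] / la <= max_mismatch_rate:
        return best
    return None


def match_read(
    read: str,
    lib: BarcodeLibrary,
    max_error_rate: float = 0.2,
    anchor_error_rate: float = 0.2,
) -> str | None:
    """Assign a read to a barcode id, or return None if unmatched.

    The barcode window is the stretch after the upstream anchor (confirmed
    against the downstream anchor when present).  A read equidistant to two
    library barcodes is unmatched.
    """
    read = read.upper()
    blen = lib.barcode_length
    start = _find_anchor(read, lib.upstream, anchor_error_rate)
    if start is None:
        # fall back to locating the downstream anchor and counting back
        ds = _find_anchor(read, lib.downstream, anchor_error_rate)
        if ds is None or ds < blen:
            return None
        window = read[ds - blen : ds]
    else:
        begin = start + len(lib.upstream)
        if begin + blen > len(read):
            return None
        window = read[begin : begin + blen]

    w = np.frombuffer(window.encode(), dtype=np.uint8)
    dists = (lib._matrix != w).sum(axis=1)
    order = np.argsort(dists, kind="stable")
    best = int(order[0])
    best_d = int(dists[best])
    if best_d / blen > max_error_rate:
        return None
    if len(order) > 1 and int(dists[order[1]]) == best_d:
        return None  # ambiguous: fails the uniqueness (mapq) proxy
    return lib._ids[best]


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def count_reads(
    fastq_paths: dict,
    lib: BarcodeLibrary,
    sample_meta: pd.DataFrame | None = None,
    max_error_rate: float = 0.2,
    keep_unmatched_row: bool = True,
):
    """Stream FASTQ files into a barcode x sample count matrix.

    Parameters
    ----------
    fastq_paths
        Mapping of sample id -> FASTQ path (gzip transparent).
    sample_meta
        Optional sample sheet indexed by sample id with columns
        ``condition``, ``replicate``, ``generation``.

    Returns a :class:`~evoscreen.screen.CountMatrix`.
    """
    from .screen import CountMatrix

    rows = lib._ids + (["_unmatched"] if keep_unmatched_row else [])
    counts = pd.DataFrame(0, index=rows, columns=list(fastq_paths), dtype=np.int64)
    for sample, path in fastq_paths.items():
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"FASTQ file not found: {path}")
        n_total = 0
        tally: dict[str, int] = {}
        try:
            with _open_maybe_gzip(path) as fh:
                for rec in SeqIO.parse(fh, "fastq"):
                    n_total += 1
                    hit = match_read(str(rec.seq), lib, max_error_rate=max_error_rate)
                    key = hit if hit is not None else "_unmatched"
                    tally[key] = tally.get(key, 0) + 1
        except ValueError as exc:
            logger.warning("malformed FASTQ record in %s (%s); file truncated here", path, exc)
        for key, c in tally.items():
            if key in counts.index:
                counts.loc[key, sample] = c
        if n_total == 0:
            logger.warning("empty FASTQ file: %s", path)
    if sample_meta is None:
        sample_meta = pd.DataFrame(index=list(fastq_paths))
    return CountMatrix(counts=counts, samples=sample_meta.loc[list(fastq_paths)])
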