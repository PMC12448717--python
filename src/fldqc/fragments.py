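"""Fragment input and per-barcode fragment length histograms.

Fragments are the deduplicated intermediate of scATAC-seq pipelines: genomic
intervals tagged with a cell barcode, provided either as a BED-like fragments
file (``chrom  start  end  barcode  [count]``, 0-based half-open) or as a
coordinate-sorted, indexed, paired-end BAM with a per-read barcode tag.
This module streams those records, restricts them to a barcode universe
(typically the observation index of an AnnData object), and accumulates
per-barcode fragment length histograms — the raw input of the periodicity
score and of the nucleosome-signal metric.

No Tn5 +4/−5 shift is applied: fragments files are assumed to already encode
their producer's convention, and a constant shift only translates the length
axis, which the scoring mask can absorb.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pysam

__all__ = [
    "FragmentRecord",
    "FLDHistogram",
    "BarcodeUniverse",
    "ReadStats",
    "read_fragments_bed",
    "write_fragments_bed",
    "read_fragments_bam",
    "build_fld_histograms",
]

DEFAULT_L_MAX = 1000


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced fragment: interval + cell barcode + duplicate count.

    Coordinates are BED-style 0-based half-open; ``length = end - start``.
    """

    chrom: str
    start: int
    end: int
    barcode: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"zero- or negative-length fragment: {self.chrom}:{self.start}-{self.end}"
            )
        if self.count < 1:
            raise ValueError(f"duplicate count must be >= 1, got {self.count}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FLDHistogram:
    """Integer counts of fragment lengths for one barcode over [0, l_max].

    ``counts[l]`` is the number of fragments of length ``l`` bp; fragments
    longer than ``l_max`` are tallied in ``overflow`` and excluded.
    """

    barcode: str
    counts: np.ndarray
    overflow: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def l_max(self) -> int:
        return len(self.counts) - 1


class BarcodeUniverse:
    """Ordered set of cell barcodes defining which fragments are kept."""

    def __init__(self, barcodes: Iterable[str]):
        self._barcodes = tuple(barcodes)
        if not self._barcodes:
            raise ValueError("barcode universe is empty")
        self._index = {bc: i for i, bc in enumerate(self._barcodes)}
        if len(self._index) != len(self._barcodes):
            raise ValueError("barcode universe contains duplicates")

    @classmethod
    def from_anndata(cls, adata) -> "BarcodeUniverse":
        """Take the universe from an AnnData observation index."""
        return cls(map(str, adata.obs_names))

    @classmethod
    def from_text(cls, path: str | Path) -> "BarcodeUniverse":
        """One barcode per line; blank lines ignored."""
        with open(path) as fh:
            return cls(line.strip() for line in fh if line.strip())

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self._barcodes)

    def __len__(self) -> int:
        return len(self._barcodes)

    def index(self, barcode: str) -> int:
        return self._index[barcode]

    @property
    def barcodes(self) -> tuple[str, ...]:
        return self._barcodes


@dataclass
class ReadStats:
    """Per-stage counters mutated in place by the streaming readers."""

    parsed: int = 0
    skipped_barcode: int = 0
    skipped_chrom: int = 0
    skipped_unpaired: int = 0
    skipped_no_tag: int = 0
    overflow: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith((".gz", ".bgz")):
        return gzip.open(path, "rt")
    return open(path)


def read_fragments_bed(
    path: str | Path,
    universe: BarcodeUniverse | None = None,
    *,
    exclude_chroms: Iterable[str] = (),
    stats: ReadStats | None = None,
) -> Iterator[FragmentRecord]:
    """Stream fragment records from a (possibly gzipped) BED fragments file.

    Records whose barcode is outside ``universe`` are skipped and tallied in
    ``stats.skipped_barcode``; malformed lines raise ``ValueError``.
    ``exclude_chroms`` implements the recommended removal of mitochondrial
    (and other unwanted) contigs.
    """
    denylist = set(exclude_chroms)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 tab-separated columns")
            chrom, start_s, end_s, barcode = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            count = 1
            if len(fields) >= 5:
                try:
                    count = int(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer count column") from exc
            if chrom in denylist:
                if stats:
                    stats.skipped_chrom += 1
                continue
            if universe is not None and barcode not in universe:
                if stats:
                    stats.skipped_barcode += 1
                continue
            try:
                rec = FragmentRecord(chrom, start, end, barcode, count)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if stats:
                stats.parsed += 1
            yield rec


def write_fragments_bed(records: Iterable[FragmentRecord], path: str | Path) -> None:
    """Write records as a 5-column tab-separated fragments file."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.barcode}\t{rec.count}\n")


def read_fragments_bam(
    path: str | Path,
    universe: BarcodeUniverse | None = None,
    *,
    barcode_tag: str = "CB",
    exclude_chroms: Iterable[str] = (),
    stats: ReadStats | None = None,
) -> Iterator[FragmentRecord]:
    """Stream fragments from a coordinate-sorted, indexed, paired-end BAM.

    One fragment is emitted per properly paired read pair, from the leftmost
    mate (template length > 0); fragment length is the absolute template
    length. Secondary/supplementary/unmapped reads and reads missing the
    barcode tag are skipped (tallied, not fatal).
    """
    denylist = set(exclude_chroms)
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for read in bam.fetch():
            if (
                read.is_secondary
                or read.is_supplementary
                or read.is_unmapped
                or not read.is_proper_pair
            ):
                if stats:
                    stats.skipped_unpaired += 1
                continue
            tlen = read.template_length
            if tlen <= 0:  # emit once, from the leftmost mate
                continue
            if read.reference_name in denylist:
                if stats:
                    stats.skipped_chrom += 1
                continue
            try:
                barcode = read.get_tag(barcode_tag)
            except KeyError:
                if stats:
                    stats.skipped_no_tag += 1
                continue
            if universe is not None and barcode not in universe:
                if stats:
                    stats.skipped_barcode += 1
                continue
            start = read.reference_start
            if stats:
                stats.parsed += 1
            yield FragmentRecord(read.reference_name, start, start + tlen, str(barcode))


def build_fld_histograms(
    fragments: Iterable[FragmentRecord],
    universe: BarcodeUniverse,
    l_max: int = DEFAULT_L_MAX,
    *,
    use_counts: bool = True,
    stats: ReadStats | None = None,
) -> dict[str, FLDHistogram]:
    """Accumulate one fragment length histogram per barcode in the universe.

    Every barcode gets a histogram (all-zero when it has no fragments).
    With ``use_counts`` (default) each record contributes its duplicate
    count; with ``use_counts=False`` each record contributes 1 (unique
    fragments only). Lengths beyond ``l_max`` increment the per-barcode
    overflow tally instead of the histogram.
    """
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    hists = {
        bc: FLDHistogram(bc, np.zeros(l_max + 1, dtype=np.int64)) for bc in universe
    }
    for rec in fragments:
        h = hists.get(rec.barcode)
        if h is None:
            if stats:
                stats.skipped_barcode += 1
            continue
        weight = rec.count if use_counts else 1
        if rec.length > l_max:
            h.overflow += weight
            if stats:
                stats.overflow += weight
            continue
        h.counts[rec.length] += weight
    return hists
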