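"""Synthetic scATAC-seq data with controlled statistical structure.

Every other module is testable without downloads against libraries drawn
from a generative model of the fragment length distribution: a mixture of
nucleosomal Gaussian components (nucleosome-free ~50 bp, mono ~200 bp,
di ~400 bp, tri ~600 bp) and a truncated-exponential noise floor that
mimics the short-fragment-dominated profile of degraded or apoptotic
material. A single ``theta`` in [0, 1] interpolates from pure noise
(theta=0) to a fully periodic pattern (theta=1):

    p(x) = theta * sum_j w_j N(x; c_j, sd_j) + (1 - theta) * noise(x),

restricted to [l_min, l_max] by rejection.

Fragments are placed on a toy genome (2 chromosomes x 1 Mb) carrying 50
peak intervals and 100 TSSs laid out so peak windows and TSS windows never
overlap; the fraction of fragments placed inside peaks and the TSS
enrichment are per-cell dials, so FRiP and TSSe converge to known targets.
The same library can be emitted as a sorted fragments BED or as an indexed
paired-end BAM encoding identical fragments.

The generator also produces embedding fixtures for the distance score:
Gaussian blobs in 2-D with cluster-prototype feature sets sharing a
controlled overlap fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .fragments import FragmentRecord, write_fragments_bed

__all__ = [
    "FLDModel",
    "SyntheticLibrary",
    "sample_cell_lengths",
    "make_library",
    "emit_fragments",
    "emit_embedding",
    "default_genome",
    "default_peaks",
    "default_tss",
    "write_peaks_bed",
    "write_tss_bed",
]

DEFAULT_CENTERS = (50.0, 200.0, 400.0, 600.0)
DEFAULT_SDS = (15.0, 25.0, 35.0, 45.0)


@dataclass(frozen=True)
class FLDModel:
    """Generative model of one cell's fragment length distribution."""

    theta: float = 1.0  # periodicity strength in [0, 1]
    centers: tuple[float, ...] = DEFAULT_CENTERS
    component_sds: tuple[float, ...] = DEFAULT_SDS
    component_weights: tuple[float, ...] | None = None  # uniform if None
    noise_mean: float = 250.0  # exponential noise scale (bp)
    l_min: int = 20
    l_max: int = 1000
    depth: int = 5000  # fragments per cell

    def __post_init__(self):
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0, 1]")
        if len(self.centers) != len(self.component_sds):
            raise ValueError("centers and component_sds length mismatch")
        if self.component_weights is not None:
            w = np.asarray(self.component_weights, dtype=float)
            if len(w) != len(self.centers) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError("component_weights must be a simplex over the centers")

    @property
    def weights(self) -> np.ndarray:
        if self.component_weights is None:
            return np.full(len(self.centers), 1.0 / len(self.centers))
        return np.asarray(self.component_weights, dtype=float)


def sample_cell_lengths(
    model: FLDModel, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n`` i.i.d. integer fragment lengths from the mixture,
    restricted to [l_min, l_max] by rejection."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers = np.asarray(model.centers)
    sds = np.asarray(model.component_sds)
    weights = model.weights
    out = np.empty(0, dtype=np.int64)
    need = n
    while need > 0:
        m = int(need * 1.3) + 16  # headroom for rejected draws
        is_signal = rng.random(m) < model.theta
        lengths = np.empty(m)
        n_sig = int(is_signal.sum())
        if n_sig:
            comp = rng.choice(len(centers), size=n_sig, p=weights)
            lengths[is_signal] = rng.normal(centers[comp], sds[comp])
        n_noise = m - n_sig
        if n_noise:
            lengths[~is_signal] = model.l_min + rng.exponential(
                model.noise_mean, size=n_noise
            )
        lengths = np.rint(lengths).astype(np.int64)
        ok = (lengths >= model.l_min) & (lengths <= model.l_max)
        out = np.concatenate([out, lengths[ok]])
        need = n - len(out)
    return out[:n]


def default_genome() -> tuple[tuple[str, int], ...]:
    return (("chr1", 1_000_000), ("chr2", 1_000_000))


def default_peaks() -> tuple[tuple[str, int, int], ...]:
    """25 peaks of 500 bp per chromosome, placed clear of TSS windows."""
    peaks = []
    for chrom, _ in default_genome():
        for i in range(25):
            start = 12_000 + i * 40_000
            peaks.append((chrom, start, start + 500))
    return tuple(peaks)


def default_tss() -> tuple[tuple[str, int, str], ...]:
    """50 TSSs per chromosome, two per 40 kb block, alternating strand;
    their +/-2 kb windows never touch a peak."""
    sites = []
    for chrom, _ in default_genome():
        for i in range(25):
            base = 32_000 + i * 40_000
            sites.append((chrom, base, "+"))
            sites.append((chrom, base + 8_000, "-"))
    return tuple(sites)


@dataclass(frozen=True)
class SyntheticLibrary:
    """A reproducible synthetic library: per-cell FLD models plus genomic
    placement targets for FRiP and TSSe."""

    cells: tuple[tuple[str, FLDModel], ...]
    genome: tuple[tuple[str, int], ...] = field(default_factory=default_genome)
    peaks: tuple[tuple[str, int, int], ...] = field(default_factory=default_peaks)
    tss: tuple[tuple[str, int, str], ...] = field(default_factory=default_tss)
    fraction_in_peaks: float = 0.0
    tss_enrichment_factor: float = 1.0
    seed: int = 0


def make_library(
    n_cells: int,
    theta: float | Sequence[float] = 1.0,
    depth: int = 5000,
    seed: int = 0,
    *,
    fraction_in_peaks: float = 0.0,
    tss_enrichment_factor: float = 1.0,
    model: FLDModel | None = None,
) -> SyntheticLibrary:
    """Build a library of ``n_cells`` barcodes (CELL000000...) sharing a
    base model; ``theta`` may be a scalar or one value per cell."""
    base = model if model is not None else FLDModel()
    thetas = np.broadcast_to(np.asarray(theta, dtype=float), (n_cells,))
    cells = tuple(
        (f"CELL{i:06d}", replace(base, theta=float(thetas[i]), depth=depth))
        for i in range(n_cells)
    )
    return SyntheticLibrary(
        cells,
        fraction_in_peaks=fraction_in_peaks,
        tss_enrichment_factor=tss_enrichment_factor,
        seed=seed,
    )


def _place_fragments(lib: SyntheticLibrary) -> list[FragmentRecord]:
    """Assign genomic positions to every cell's fragments.

    Background fragments get uniform starts; a ``fraction_in_peaks`` share
    is centred inside a random peak; for tss_enrichment_factor f > 1 a
    computed share is emitted as 101 bp fragments exactly covering a TSS
    +/-50 bp so the expected aggregate center/flank coverage ratio is f.
    """
    rng = np.random.default_rng(lib.seed)
    chroms = [c for c, _ in lib.genome]
    chrom_lens = {c: L for c, L in lib.genome}
    total_len = sum(chrom_lens.values())
    records: list[FragmentRecord] = []
    tss_list = lib.tss
    for barcode, model in lib.cells:
        lengths = sample_cell_lengths(model, model.depth, rng)
        n = len(lengths)
        mean_len = float(lengths.mean())
        # split depth into tss-spike / peak / background fragments
        f = lib.tss_enrichment_factor
        if f > 1.0 and tss_list:
            # background coverage per profile position: n_b * mean_len * n_tss / G;
            # each spike fragment adds 1 to the aggregate center mean
            c = mean_len * len(tss_list) / total_len
            n_bg_equiv = n / (1.0 + (f - 1.0) * c)
            n_tss = int(round((f - 1.0) * n_bg_equiv * c))
        else:
            n_tss = 0
        n_peak = int(round(lib.fraction_in_peaks * (n - n_tss)))
        kinds = np.array(
            ["t"] * n_tss + ["p"] * n_peak + ["b"] * (n - n_tss - n_peak)
        )
        rng.shuffle(kinds)
        for length, kind in zip(lengths, kinds):
            length = int(length)
            if kind == "t":
                chrom, pos, _ = tss_list[rng.integers(len(tss_list))]
                records.append(FragmentRecord(chrom, pos - 50, pos + 51, barcode))
                continue
            if kind == "p":
                pc, ps, pe = lib.peaks[rng.integers(len(lib.peaks))]
                mid = int(rng.integers(ps, pe))
                start = max(0, mid - length // 2)
                records.append(FragmentRecord(pc, start, start + length, barcode))
                continue
            chrom = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(0, chrom_lens[chrom] - length))
            records.append(FragmentRecord(chrom, start, start + length, barcode))
    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.barcode))
    return records


def emit_fragments(lib: SyntheticLibrary, fmt: str, path: str | Path) -> Path:
    """Write the library's fragments as a sorted BED fragments file or as a
    coordinate-sorted, indexed, paired-end BAM encoding the same fragments.
    Deterministic given the library seed."""
    path = Path(path)
    records = _place_fragments(lib)
    if fmt == "bed":
        write_fragments_bed(records, path)
    elif fmt == "bam":
        _write_bam(records, lib.genome, path)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'bed' or 'bam')")
    return path


def _write_bam(
    records: Sequence[FragmentRecord],
    genome: Sequence[tuple[str, int]],
    path: Path,
) -> None:
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": L} for c, L in genome],
    }
    tid = {c: i for i, (c, _) in enumerate(genome)}
    # records are position-sorted; emit both mates in coordinate order
    reads = []
    for qi, rec in enumerate(records):
        rl = min(50, rec.length)
        for mate in (0, 1):
            a = pysam.AlignedSegment()
            a.query_name = f"frag{qi}"
            a.reference_id = tid[rec.chrom]
            a.next_reference_id = a.reference_id
            a.mapping_quality = 60
            a.cigarstring = f"{rl}M"
            a.query_sequence = "A" * rl
            a.query_qualities = pysam.qualitystring_to_array("I" * rl)
            if mate == 0:
                a.reference_start = rec.start
                a.next_reference_start = rec.end - rl
                a.template_length = rec.length
                a.flag = 0x1 | 0x2 | 0x20 | 0x40  # paired, proper, mate rev, first
            else:
                a.reference_start = rec.end - rl
                a.next_reference_start = rec.start
                a.template_length = -rec.length
                a.flag = 0x1 | 0x2 | 0x10 | 0x80  # paired, proper, rev, second
            a.set_tag("CB", rec.barcode)
            reads.append(a)
    reads.sort(key=lambda a: (a.reference_id, a.reference_start))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for a in reads:
            bam.write(a)
    pysam.index(str(path))


def write_peaks_bed(lib: SyntheticLibrary, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, start, end in lib.peaks:
            fh.write(f"{chrom}\t{start}\t{end}\n")
    return path


def write_tss_bed(lib: SyntheticLibrary, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for i, (chrom, pos, strand) in enumerate(lib.tss):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\ttss{i}\t0\t{strand}\n")
    return path


def emit_embedding(
    n_clusters: int = 3,
    cells_per_cluster: int = 50,
    separation: float = 5.0,
    feature_overlap: float = 0.8,
    n_features_per_cell: int = 30,
    cluster_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[str], dict[str, np.ndarray]]:
    """2-D Gaussian blobs with cluster-prototype feature sets.

    Cluster centres sit on a circle whose adjacent-centre spacing equals
    ``separation``. Each cluster owns a disjoint block of prototype
    features; every cell keeps a ``feature_overlap`` share of its
    prototype and fills the rest with cell-private features, so within-
    cluster normalised Levenshtein is ~(1 - feature_overlap) and across-
    cluster it is ~1. Returns (coords, barcodes, feature sets).
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if not 0.0 <= feature_overlap <= 1.0:
        raise ValueError("feature_overlap must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if n_clusters == 1:
        centers = np.zeros((1, 2))
    else:
        radius = separation / (2.0 * np.sin(np.pi / n_clusters))
        ang = 2.0 * np.pi * np.arange(n_clusters) / n_clusters
        centers = radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    m = n_features_per_cell
    n_keep = int(round(feature_overlap * m))
    coords = []
    barcodes = []
    features: dict[str, np.ndarray] = {}
    private_base = n_clusters * m  # private ids start above all prototypes
    cell_idx = 0
    for c in range(n_clusters):
        proto = np.arange(c * m, (c + 1) * m)
        for _ in range(cells_per_cluster):
            bc = f"CELL{cell_idx:06d}"
            coords.append(centers[c] + rng.normal(0.0, cluster_sd, size=2))
            kept = rng.choice(proto, size=n_keep, replace=False)
            private = private_base + cell_idx * m + np.arange(m - n_keep)
            features[bc] = np.sort(np.concatenate([kept, private]))
            barcodes.append(bc)
            cell_idx += 1
    return np.asarray(coords), barcodes, features
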