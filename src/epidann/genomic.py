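"""Genomic input handling: regions, fixed-length windows, one-hot encoding.

Coordinates follow the BED convention throughout: 0-based, half-open
[start, end).  Enhancer windows are 3000 nt and promoter windows 2000 nt,
centered on the annotated element midpoint; positions falling outside the
chromosome are padded with 'N', which one-hot encodes as an all-zero row.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np

ENHANCER_WINDOW = 3000
PROMOTER_WINDOW = 2000

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_ALPHABET = frozenset("ACGTN")
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE_LUT[ord(_b)] = _i
_ENCODE_LUT[ord("N")] = 4


class RegionError(ValueError):
    """Malformed or invalid genomic interval input."""


@dataclass(frozen=True)
class GenomicRegion:
    """A 0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    kind: Optional[str] = None  # "enhancer" | "promoter"

    def __post_init__(self):
        if not self.chrom:
            raise RegionError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise RegionError(f"invalid interval [{self.start}, {self.end}) on {self.chrom}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def coords(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class DnaWindow:
    """A fixed-length sequence window derived from a region."""

    region: GenomicRegion
    seq: str

    def __post_init__(self):
        self.seq = self.seq.upper()
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise RegionError(f"window contains non-ACGTN characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class EncodedSample:
    """One-hot enhancer/promoter matrices with optional labels."""

    enh: np.ndarray  # (enh_len, 4)
    prom: np.ndarray  # (prom_len, 4)
    epi_label: Optional[int] = None
    domain_label: Optional[int] = None


def region_center(region: GenomicRegion) -> int:
    """Element midpoint, floor of (start+end)/2 for odd lengths."""
    return region.center


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_regions(path, kind: Optional[str] = None) -> list[GenomicRegion]:
    """Read BED3+ intervals; returns regions in file order.

    Lines starting with ``#`` or ``track`` are skipped.  Raises
    :class:`RegionError` naming the offending line on malformed input.
    """
    regions = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RegionError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise RegionError(f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                regions.append(GenomicRegion(fields[0], start, end, kind=kind))
            except RegionError as exc:
                raise RegionError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_regions(regions: Iterable[GenomicRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_pairs(path) -> list[tuple[GenomicRegion, GenomicRegion, Optional[int]]]:
    """Read a pair table: enh_chrom, enh_start, enh_end, prom_chrom,
    prom_start, prom_end[, label].  The label column is optional (target-domain
    tables are unlabeled)."""
    pairs = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (6, 7):
                raise RegionError(f"{path}:{lineno}: expected 6 or 7 columns, got {len(fields)}")
            try:
                enh = GenomicRegion(fields[0], int(fields[1]), int(fields[2]), kind="enhancer")
                prom = GenomicRegion(fields[3], int(fields[4]), int(fields[5]), kind="promoter")
            except (ValueError, RegionError) as exc:
                raise RegionError(f"{path}:{lineno}: {exc}") from exc
            label: Optional[int] = None
            if len(fields) == 7 and fields[6] != "":
                if fields[6] not in ("0", "1"):
                    raise RegionError(f"{path}:{lineno}: label must be 0 or 1, got {fields[6]!r}")
                label = int(fields[6])
            pairs.append((enh, prom, label))
    return pairs


def write_pairs(pairs, path) -> None:
    """Write (enh, prom, label) triples as the TSV consumed by read_pairs."""
    with open(path, "w") as fh:
        for enh, prom, label in pairs:
            row = [enh.chrom, str(enh.start), str(enh.end), prom.chrom, str(prom.start), str(prom.end)]
            if label is not None:
                row.append(str(int(label)))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# genome access
# ---------------------------------------------------------------------------


def load_genome(path) -> Mapping[str, str]:
    """Open a FASTA with indexed access; returns a chrom -> sequence mapping."""
    from pyfaidx import Fasta

    return _FaidxGenome(Fasta(str(path), sequence_always_upper=True))


class _FaidxGenome(Mapping):
    def __init__(self, fasta):
        self._fasta = fasta

    def __getitem__(self, chrom):
        return _FaidxChrom(self._fasta[chrom])

    def __iter__(self):
        return iter(self._fasta.keys())

    def __len__(self):
        return len(self._fasta.keys())


class _FaidxChrom:
    """String-like view over one pyfaidx record (len + non-negative slicing)."""

    def __init__(self, record):
        self._record = record

    def __len__(self):
        return len(self._record)

    def __getitem__(self, sl: slice) -> str:
        return str(self._record[sl.start : sl.stop])


def extract_window(region: GenomicRegion, window_length: int, genome: Mapping) -> DnaWindow:
    """Extract the length-``window_length`` window centered on the region.

    The window spans [center - L/2, center + L/2); out-of-bounds positions are
    filled with 'N' so every returned window has exactly the requested length.
    """
    if window_length <= 0 or window_length % 2 != 0:
        raise ValueError(f"window_length must be even and positive, got {window_length}")
    if region.chrom not in genome:
        raise KeyError(f"chromosome {region.chrom!r} not in genome")
    chrom_seq = genome[region.chrom]
    chrom_len = len(chrom_seq)
    half = window_length // 2
    center = region.center
    lo, hi = center - half, center + half
    core = str(chrom_seq[max(lo, 0) : min(hi, chrom_len)]).upper()
    left_pad = max(0, -lo)
    right_pad = max(0, hi - chrom_len)
    seq = "N" * left_pad + core + "N" * right_pad
    if len(seq) != window_length:  # pragma: no cover - defensive
        raise RuntimeError(f"window length {len(seq)} != requested {window_length}")
    return DnaWindow(region=region, seq=seq)


# ---------------------------------------------------------------------------
# one-hot coding
# ---------------------------------------------------------------------------


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a DNA string as an (L, 4) one-hot matrix, columns A,C,G,T.

    Case-insensitive; 'N' becomes an all-zero row.  Any other character
    raises a ValueError naming its position.
    """
    try:
        codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    except UnicodeEncodeError as exc:
        raise ValueError(f"cannot encode non-ASCII sequence: {exc}") from exc
    mapped = _ENCODE_LUT[codes]
    if (mapped == 255).any():
        pos = int(np.argmax(mapped == 255))
        raise ValueError(f"cannot encode character {seq[pos]!r} at position {pos}")
    out = np.zeros((len(seq), 5), dtype=np.float32)
    out[np.arange(len(seq)), mapped] = 1.0
    return np.ascontiguousarray(out[:, :4])  # 5th column absorbed 'N'; dropping it leaves zero rows


def one_hot_decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` (all-zero rows decode to 'N')."""
    bases = np.array(list("ACGT"))
    known = matrix.sum(axis=1) > 0
    out = np.full(matrix.shape[0], "N", dtype="<U1")
    out[known] = bases[matrix[known].argmax(axis=1)]
    return "".join(out)


def encode_window_pair(
    enh_window: DnaWindow,
    prom_window: DnaWindow,
    epi_label: Optional[int] = None,
    domain_label: Optional[int] = None,
) -> EncodedSample:
    return EncodedSample(
        enh=one_hot_encode(enh_window.seq),
        prom=one_hot_encode(prom_window.seq),
        epi_label=epi_label,
        domain_label=domain_label,
    )


# ---------------------------------------------------------------------------
# dataset container serialization
# ---------------------------------------------------------------------------


def save_encoded(path, enh, prom, epi_label=None, domain_label=None) -> None:
    """Serialize encoded arrays to one .npz container with named arrays."""
    arrays = {"enh": np.asarray(enh, dtype=np.float32), "prom": np.asarray(prom, dtype=np.float32)}
    if epi_label is not None:
        arrays["epi_label"] = np.asarray(epi_label, dtype=np.int8)
    if domain_label is not None:
        arrays["domain_label"] = np.asarray(domain_label, dtype=np.int8)
    np.savez_compressed(path, **arrays)


def load_encoded(path) -> dict:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}
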