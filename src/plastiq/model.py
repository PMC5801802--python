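"""Core data model and I/O for circular plastomes.

A plastome is a circular DNA molecule; internally every coordinate is
0-based, half-open, on the forward strand.  An interval ``(start, end)``
may have ``end > genome length``, which denotes wrapping through the
origin; ``start`` is always normalised into ``[0, n)``.  All report
output is 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

import numpy as np

ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_CLASSES = ("protein", "tRNA", "rRNA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# circular interval helpers
# ---------------------------------------------------------------------------

def interval_len(iv: tuple[int, int]) -> int:
    return iv[1] - iv[0]


def normalize_interval(iv: tuple[int, int], n: int) -> tuple[int, int]:
    """Normalise so that start lies in [0, n) (end may exceed n = wrap)."""
    start, end = iv
    if end - start > n or end <= start:
        raise ValueError(f"invalid circular interval {iv} for genome length {n}")
    start_mod = start % n
    return (start_mod, start_mod + (end - start))


def interval_positions(iv: tuple[int, int], n: int) -> np.ndarray:
    """All genome positions covered by a (possibly wrapping) interval."""
    start, end = normalize_interval(iv, n)
    return np.arange(start, end) % n


def in_interval(pos: int, iv: tuple[int, int], n: int) -> bool:
    start, end = normalize_interval(iv, n)
    p = pos % n
    return start <= p < end or start <= p + n < end


def overlap_len(a: tuple[int, int], b: tuple[int, int], n: int) -> int:
    """Number of genome positions covered by both circular intervals."""
    a = normalize_interval(a, n)
    b = normalize_interval(b, n)
    total = 0
    for sa in (a, (a[0] + n, a[1] + n)):
        lo = max(sa[0], b[0])
        hi = min(sa[1], b[1])
        if hi > lo:
            total += hi - lo
    return total


def intervals_disjoint(a: tuple[int, int], b: tuple[int, int], n: int) -> bool:
    return overlap_len(a, b, n) == 0


def slice_circular(seq: str, iv: tuple[int, int]) -> str:
    """Extract a (possibly wrapping) interval from a circular sequence."""
    n = len(seq)
    start, end = normalize_interval(iv, n)
    if end <= n:
        return seq[start:end]
    return seq[start:] + seq[: end - n]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Plastome:
    """A single circular plastome sequence."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty plastome sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                "illegal characters in sequence: " + ", ".join(sorted(bad))
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def rotated(self, offset: int) -> "Plastome":
        """Rotate so that the base at ``offset`` becomes position 0."""
        n = self.length
        k = offset % n
        return Plastome(self.id, self.sequence[k:] + self.sequence[:k])


@dataclass
class GeneFeature:
    """A gene annotation with one or more exons on the circular genome.

    ``exons`` are ordered genomic intervals (0-based half-open,
    wrap-aware).  ``region`` is filled in by region assignment; for IR
    residents it is the label ``"IR"`` regardless of arm.
    """

    name: str
    feature_class: str
    exons: list[tuple[int, int]]
    strand: str
    region: str | None = None
    copy_number: int = 1
    straddles_junction: bool = False
    recruited_from: str | None = None  # set by the simulator / expansion mapper
    wraps_origin: bool = False

    def __post_init__(self):
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"unknown feature class {self.feature_class!r} for {self.name}"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"feature {self.name} has no exons")
        if self.copy_number not in (1, 2):
            raise ValueError("copy_number must be 1 or 2")
        for a, b in zip(self.exons, self.exons[1:]):
            if a[1] > b[0]:
                raise ValueError(f"overlapping exons in {self.name}")
        if self.feature_class == "protein" and self.total_exon_len < 3:
            raise ValueError(
                f"protein feature {self.name} has exon length "
                f"{self.total_exon_len} < 3"
            )

    @property
    def total_exon_len(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint from first exon start to last exon end."""
        return (self.start, self.end)

    def midpoint(self, n: int) -> int:
        s, e = self.span
        return ((s + e) // 2) % n

    def shifted(self, offset: int, n: int) -> "GeneFeature":
        """Shift all exon coordinates by ``offset`` on a circle of size n."""
        new_exons = []
        wraps = False
        for s, e in self.exons:
            length = e - s
            ns = (s + offset) % n
            new_exons.append((ns, ns + length))
            if ns + length > n:
                wraps = True
        return replace(self, exons=new_exons, wraps_origin=wraps)


@dataclass
class CoverageTrack:
    """Per-base read depth over a circular genome."""

    depths: np.ndarray

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.ndim != 1 or len(self.depths) == 0:
            raise ValueError("coverage track must be a non-empty 1-D array")
        if (self.depths < 0).any():
            raise ValueError("negative depths in coverage track")

    def __len__(self) -> int:
        return len(self.depths)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_plastome(fasta_path: str | Path) -> Plastome:
    """Read a single-record FASTA into a :class:`Plastome`.

    The sequence is uppercased and U (RNA alphabet) is mapped to T.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected 1 record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper().replace("U", "T")
    if not seq:
        raise ValueError(f"record {rec.id} has an empty sequence")
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(
            "illegal characters in sequence: " + ", ".join(sorted(bad))
        )
    return Plastome(id=rec.id, sequence=seq)


def write_plastome(plastome: Plastome, fasta_path: str | Path) -> None:
    rec = SeqRecord(Seq(plastome.sequence), id=plastome.id, description="")
    SeqIO.write([rec], str(fasta_path), "fasta")


def _parse_exon_ranges(text: str, genome_length: int, name: str,
                       wrap_declared: bool) -> list[tuple[int, int]]:
    """Parse comma-separated 1-based inclusive ranges into internal coords."""
    exons: list[tuple[int, int]] = []
    for part in text.split(","):
        lo_s, hi_s = part.split("-")
        lo, hi = int(lo_s), int(hi_s)
        if lo < 1 or hi < lo:
            raise ValueError(f"bad exon range {part!r} in feature {name}")
        if hi > genome_length:
            if not wrap_declared:
                raise ValueError(
                    f"exon end {hi} of {name} beyond genome length "
                    f"{genome_length} without wrap declaration"
                )
        exons.append((lo - 1, hi))
    return exons


def load_features(table_path: str | Path, genome_length: int) -> list[GeneFeature]:
    """Load gene annotations from GFF3 or the minimal TSV dialect.

    TSV dialect: ``name  class  strand  exon_ranges`` where exon ranges
    are comma-separated 1-based inclusive (e.g. ``100-639,1740-2292``).
    A trailing ``wrap`` token declares that a range runs through the
    origin.  GFF3 is recognised by a ``##gff-version`` header.
    """
    path = Path(table_path)
    text = path.read_text()
    if text.startswith("##gff-version"):
        return _load_features_gff3(text, genome_length)
    features = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"malformed feature row: {line!r}")
        name, cls, strand, ranges = fields[:4]
        wrap_declared = len(fields) > 4 and fields[4].strip().lower() == "wrap"
        exons = _parse_exon_ranges(ranges, genome_length, name, wrap_declared)
        feat = GeneFeature(name=name, feature_class=cls, strand=strand,
                           exons=exons,
                           wraps_origin=any(e > genome_length for _, e in exons))
        features.append(feat)
    features.sort(key=lambda f: f.start)
    return features


_GFF_TYPE_MAP = {"CDS": "protein", "tRNA": "tRNA", "rRNA": "rRNA"}


def _load_features_gff3(text: str, genome_length: int) -> list[GeneFeature]:
    """Minimal GFF3 reader: CDS/tRNA/rRNA rows grouped by gene/Name/ID."""
    grouped: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"malformed GFF3 row: {line!r}")
        _, _, ftype, start, end, _, strand, _, attrs = cols
        if ftype not in _GFF_TYPE_MAP:
            continue
        attr_map = dict(
            kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
        )
        name = attr_map.get("gene") or attr_map.get("Name") or attr_map.get("ID")
        if name is None:
            raise ValueError(f"GFF3 row lacks gene/Name/ID attribute: {line!r}")
        lo, hi = int(start), int(end)
        if hi > genome_length:
            raise ValueError(
                f"feature {name} end {hi} beyond genome length {genome_length}"
            )
        grouped.setdefault((name, _GFF_TYPE_MAP[ftype], strand), []).append(
            (lo - 1, hi)
        )
    features = []
    for (name, cls, strand), exons in grouped.items():
        exons.sort()
        features.append(
            GeneFeature(name=name, feature_class=cls, strand=strand, exons=exons)
        )
    features.sort(key=lambda f: f.start)
    return features


def write_features(features: Iterable[GeneFeature], table_path: str | Path,
                   genome_length: int | None = None) -> None:
    """Write features in the minimal TSV dialect (1-based inclusive)."""
    lines = ["#name\tclass\tstrand\texons"]
    for f in features:
        ranges = ",".join(f"{s + 1}-{e}" for s, e in f.exons)
        row = f"{f.name}\t{f.feature_class}\t{f.strand}\t{ranges}"
        if f.wraps_origin:
            row += "\twrap"
        lines.append(row)
    Path(table_path).write_text("\n".join(lines) + "\n")


def load_coverage(path: str | Path, genome_length: int | None = None) -> CoverageTrack:
    """Read a coverage track from BedGraph or two-column TSV (1-based pos, depth)."""
    rows = []
    bedgraph = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track")):
            continue
        cols = line.split("\t")
        if len(cols) >= 4:
            bedgraph = True
        rows.append(cols)
    if not rows:
        raise ValueError(f"no coverage rows in {path}")
    if bedgraph:
        n = max(int(r[2]) for r in rows)
        depths = np.zeros(n)
        for r in rows:
            depths[int(r[1]):int(r[2])] = float(r[3])
    else:
        n = max(int(r[0]) for r in rows)
        depths = np.zeros(n)
        for r in rows:
            depths[int(r[0]) - 1] = float(r[1])
    if genome_length is not None and n != genome_length:
        raise ValueError(
            f"coverage length {n} does not match genome length {genome_length}"
        )
    return CoverageTrack(depths)


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    lines = [f"{i + 1}\t{int(d) if float(d).is_integer() else d}"
             for i, d in enumerate(track.depths)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick species tree and validate its leaf labels."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf names in tree")
    return tree


# ---------------------------------------------------------------------------
# canonical presentation
# ---------------------------------------------------------------------------

def canonicalize(plastome: Plastome, structure) -> tuple[Plastome, int]:
    """Rotate a plastome so the LSC starts at position 0 (IRa follows LSC).

    Returns the rotated plastome and the rotation offset; features are
    brought along with ``GeneFeature.shifted(-offset, n)``.  Applying
    the returned offset to the canonical genome round-trips.
    """
    offset = structure.lsc[0] % plastome.length
    return plastome.rotated(offset), offset


def extract_cds(plastome: Plastome, feature: GeneFeature) -> str:
    """Concatenate exon sequences (reverse-complemented for '-' strand)."""
    parts = [slice_circular(plastome.sequence, ex) for ex in feature.exons]
    seq = "".join(parts)
    return revcomp(seq) if feature.strand == "-" else seq
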