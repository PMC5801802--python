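"""Inverted-repeat detection and quadripartite partitioning.

Plastomes carry two near-identical inverted repeats (IRa/IRb) separating
a large and a small single-copy region (LSC/SSC).  Two independent
detectors are provided:

* :func:`find_inverted_repeat` — sequence self-comparison.  Exact
  21-mer seeds between the sequence and its reverse complement identify
  candidate anti-diagonals (an IR pair lies on a single anti-diagonal
  of the circular self-comparison matrix); on each candidate diagonal
  the maximal window whose mismatch count stays within the budget is
  found exactly from the mismatch positions.  For ``min_len >= 50`` and
  mismatch fraction <= 2% every qualifying repeat contains an exact
  21-mer (pigeonhole: L/(0.02 L + 1) >= 21), so seeding loses nothing.
* :func:`detect_ir_from_coverage` — read-depth doubling: the IR is
  present twice per molecule, so reads map at about twice the depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .model import (
    CoverageTrack,
    Plastome,
    intervals_disjoint,
    interval_len,
    normalize_interval,
    revcomp,
    slice_circular,
)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N


@dataclass(frozen=True)
class QuadripartiteStructure:
    """The LSC/SSC/IRa/IRb partition of a circular genome.

    Intervals are 0-based half-open and wrap-aware; IRa is the arm that
    immediately follows the LSC on the forward strand.
    """

    genome_length: int
    lsc: tuple[int, int]
    ir_a: tuple[int, int]
    ssc: tuple[int, int]
    ir_b: tuple[int, int]
    mismatch_count: int = 0

    def __post_init__(self):
        n = self.genome_length
        if interval_len(self.ir_a) != interval_len(self.ir_b):
            raise ValueError("IR arms differ in length")
        total = sum(
            interval_len(iv) for iv in (self.lsc, self.ssc, self.ir_a, self.ir_b)
        )
        if total != n:
            raise ValueError(
                f"regions cover {total} bp but genome is {n} bp"
            )
        if interval_len(self.lsc) < interval_len(self.ssc):
            raise ValueError("LSC shorter than SSC")
        # adjacency chain LSC -> IRa -> SSC -> IRb -> LSC
        order = (self.lsc, self.ir_a, self.ssc, self.ir_b)
        for prev, nxt in zip(order, order[1:] + order[:1]):
            if prev[1] % n != nxt[0] % n:
                raise ValueError("regions are not contiguous on the circle")

    @property
    def lsc_len(self) -> int:
        return interval_len(self.lsc)

    @property
    def ssc_len(self) -> int:
        return interval_len(self.ssc)

    @property
    def ir_len(self) -> int:
        return interval_len(self.ir_a)

    def region_of(self, pos: int) -> str:
        from .model import in_interval

        n = self.genome_length
        for label, iv in (("LSC", self.lsc), ("IRa", self.ir_a),
                          ("SSC", self.ssc), ("IRb", self.ir_b)):
            if in_interval(pos, iv, n):
                return label
        raise ValueError(f"position {pos} outside genome")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.encode().translate(bytes.maketrans(b"ACGTN", bytes(range(5)))),
        dtype=np.uint8,
    )


def _candidate_diagonals(seq: str, k: int) -> set[int]:
    """Anti-diagonals carrying at least one exact inverted k-mer seed."""
    n = len(seq)
    circ = seq + seq[: k - 1]
    index: dict[str, list[int]] = {}
    for i in range(n):
        index.setdefault(circ[i:i + k], []).append(i)
    diags: set[int] = set()
    for j in range(n):
        rk = revcomp(circ[j:j + k])
        for i in index.get(rk, ()):
            diags.add((i + j + k - 1) % n)
    return diags


def _best_window_on_diagonal(
    match: np.ndarray, frac: float, n: int
) -> tuple[int, int, int] | None:
    """Longest circular window with mismatches <= floor(frac * length).

    Returns ``(length, start, mismatches)`` with the smallest start
    among maximal windows, or None if every window fails.
    """
    p = np.flatnonzero(~match)
    m = len(p)
    if m == 0:
        return (n, 0, 0)
    p2 = np.concatenate([p, p + n])
    max_budget = int(frac * n)
    best: tuple[int, int, int] | None = None
    for mc in range(0, min(max_budget, 2 * m - 1) + 1):
        i = np.arange(m)
        j = i + mc + 1
        valid_j = j < 2 * m
        i, j = i[valid_j], j[valid_j]
        if len(i) == 0:
            break
        raw = p2[j] - p2[i] - 1
        length = np.minimum(raw, n)
        ok = (length >= 1) & (mc <= np.floor(frac * length).astype(int))
        if not ok.any():
            continue
        lmax = int(length[ok].max())
        starts = (p2[i[ok]][length[ok] == lmax] + 1) % n
        cand = (lmax, int(starts.min()), mc)
        if best is None or (cand[0], -cand[1]) > (best[0], -best[1]):
            best = cand
    return best


def _pair_from_window(
    c: int, start: int, length: int, n: int, min_len: int
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Turn a diagonal window into a disjoint interval pair, shrinking
    symmetrically through the palindromic-centre degenerate case."""
    for L in range(length, min_len - 1, -1):
        x = normalize_interval((start, start + L), n)
        ys = (c - (start + L - 1)) % n
        y = (ys, ys + L)
        if intervals_disjoint(x, y, n):
            if x[0] > y[0]:
                x, y = y, x
            return x, y
    return None


def find_inverted_repeat(
    plastome: Plastome,
    min_len: int = 1000,
    max_mismatch_frac: float = 0.005,
    k: int = 21,
) -> tuple[tuple[int, int], tuple[int, int], int] | None:
    """Find the maximal inverted-repeat pair of a circular plastome.

    Returns ``(interval_a, interval_b, mismatch_count)`` where
    ``sequence(interval_a)`` equals the reverse complement of
    ``sequence(interval_b)`` up to ``floor(max_mismatch_frac * length)``
    mismatches, or ``None`` when no pair of at least ``min_len`` exists
    (the expected outcome for IR-loss plastomes).  Ties on length break
    to the pair whose first interval starts at the smallest coordinate.
    """
    if min_len < 50:
        raise ValueError("min_len must be >= 50")
    if not 0 <= max_mismatch_frac <= 0.02:
        raise ValueError("max_mismatch_frac must lie in [0, 0.02]")
    seq = plastome.sequence
    n = plastome.length
    if n < 2 * min_len:
        return None
    code = _encode(seq)
    comp = _COMP_CODE[code]
    idx = np.arange(n)
    best: tuple | None = None  # (length, a_start, b_start, pair)
    for c in sorted(_candidate_diagonals(seq, min(k, n))):
        partner = comp[(c - idx) % n]
        match = (code == partner) & (code != 4)
        win = _best_window_on_diagonal(match, max_mismatch_frac, n)
        if win is None:
            continue
        length, start, _ = win
        pair = _pair_from_window(c, start, length, n, min_len)
        if pair is None:
            continue
        a, b = pair
        L = interval_len(a)
        key = (L, -a[0], -b[0])
        if best is None or key > best[0]:
            best = ((L, -a[0], -b[0]), a, b)
    if best is None:
        return None
    _, a, b = best
    mism = sum(
        1
        for x, y in zip(slice_circular(seq, a), revcomp(slice_circular(seq, b)))
        if x != y or x == "N"
    )
    return a, b, mism


def partition_quadripartite(
    plastome: Plastome,
    ir_pair: tuple[tuple[int, int], tuple[int, int]],
) -> QuadripartiteStructure:
    """Derive the quadripartite structure from an IR interval pair.

    The two arcs between the arms become the single-copy regions; the
    longer is the LSC.  On an exact tie the arc containing coordinate 0
    is taken as the LSC, with a warning.
    """
    n = plastome.length
    a, b = (normalize_interval(iv, n) for iv in ir_pair)
    if interval_len(a) != interval_len(b):
        raise ValueError("IR intervals differ in length")
    if not intervals_disjoint(a, b, n):
        raise ValueError("IR intervals overlap")
    if a[0] > b[0]:
        a, b = b, a

    def arc(from_iv, to_iv):
        start = from_iv[1] % n
        length = (to_iv[0] - start) % n
        return (start, start + length)

    arc1 = arc(a, b)  # after arm a
    arc2 = arc(b, a)  # after arm b
    if interval_len(arc1) == 0 or interval_len(arc2) == 0:
        raise ValueError("IR arms are adjacent; no single-copy region between them")
    if interval_len(arc1) > interval_len(arc2):
        lsc, ssc = arc1, arc2
    elif interval_len(arc2) > interval_len(arc1):
        lsc, ssc = arc2, arc1
    else:
        from .model import in_interval

        warnings.warn("single-copy arcs have equal length; "
                      "assigning the arc containing coordinate 0 as LSC")
        if in_interval(0, arc1, n):
            lsc, ssc = arc1, arc2
        else:
            lsc, ssc = arc2, arc1
    # IRa is the arm that follows the LSC
    if lsc[1] % n == a[0]:
        ir_a, ir_b = a, b
    else:
        ir_a, ir_b = b, a
    mism = sum(
        1
        for x, y in zip(
            slice_circular(plastome.sequence, ir_a),
            revcomp(slice_circular(plastome.sequence, ir_b)),
        )
        if x != y or x == "N"
    )
    return QuadripartiteStructure(
        genome_length=n, lsc=lsc, ir_a=ir_a, ssc=ssc, ir_b=ir_b,
        mismatch_count=mism,
    )


def detect_ir_from_coverage(
    track: CoverageTrack,
    window: int = 200,
    low: float = 1.7,
    high: float = 2.5,
) -> list[tuple[int, int]]:
    """Locate IR arms as runs of roughly doubled read depth.

    Depth is smoothed with a centred circular rolling median of width
    ``window`` and divided by the genome-wide median; maximal runs of
    positions whose ratio lies in ``[low, high]`` and that are at least
    ``window`` long are returned.  Because the IR occupies roughly a
    third of a plastome, the genome-wide median sits above the
    single-copy depth and the doubled ratio can flicker across ``low``
    at isolated positions, so gaps shorter than ``window`` between
    qualifying runs are closed before filtering.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if low >= high:
        raise ValueError("low must be < high")
    depths = track.depths
    med = float(np.median(depths))
    if med == 0:
        raise ValueError("no coverage")
    smoothed = ndimage.median_filter(depths, size=window, mode="wrap")
    mask = (smoothed / med >= low) & (smoothed / med <= high)
    n = len(mask)
    if mask.all():
        return [(0, n)]
    # circular runs: rotate so position 0 is outside a run
    zero = int(np.flatnonzero(~mask)[0])
    rolled = np.roll(mask, -zero)
    edges = np.flatnonzero(np.diff(rolled.astype(int)))
    starts = edges[::2] + 1
    ends = edges[1::2] + 1
    if len(ends) < len(starts):
        ends = np.append(ends, n)
    runs = [(int(s), int(e)) for s, e in zip(starts, ends)]
    # close sub-window gaps between qualifying runs (rolled coordinates
    # are gap-free at the origin, so plain adjacency merging suffices)
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < window:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    if len(merged) > 1 and (n - merged[-1][1]) + merged[0][0] < window:
        merged[0][0] = merged[-1][0] - n
        merged.pop()
    out = []
    for s, e in merged:
        if e - s >= window:
            out.append(((s + zero) % n, (s + zero) % n + (e - s)))
    out.sort()
    return out
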