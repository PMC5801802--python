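"""Global pairwise nucleotide alignment with affine gap costs.

The pseudogene caller compares each target coding sequence against the
functional outgroup copy with a Needleman-Wunsch/Gotoh global
alignment.  Determinism matters more than speed here: mutation
coordinates are read off the alignment, so tie-breaking is fixed —
aligned pairs are preferred over gaps, gaps in the target over gaps in
the reference, and equal-scoring gaps take their leftmost placement
(the traceback walks right to left preferring the aligned state, which
pushes gap runs as far left as they can slide).

The DP is banded around the main diagonal and re-run with a doubled
band whenever the optimal path touches the band edge, so the result is
always the exact full-matrix optimum while typical near-identical CDS
pairs stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

_NEG = -(2**40)


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap scoring; a gap of length g costs open + g * extend."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -8
    gap_extend: int = -2


DEFAULT_SCORING = AlignmentScoring()


@dataclass(frozen=True)
class PairwiseAlignment:
    score: int
    ref_aln: str
    target_aln: str

    def __post_init__(self):
        if len(self.ref_aln) != len(self.target_aln):
            raise ValueError("gapped strings differ in length")

    @property
    def columns(self) -> list[tuple[str | None, str | None]]:
        return [
            (r if r != "-" else None, t if t != "-" else None)
            for r, t in zip(self.ref_aln, self.target_aln)
        ]


def _fill_and_trace(ref: str, tgt: str, sc: AlignmentScoring,
                    dlo: int, dhi: int):
    """One banded Gotoh pass.  Returns (score, ref_aln, tgt_aln, touched)."""
    R, T = len(ref), len(tgt)
    W = dhi - dlo + 1
    go, ge = sc.gap_open, sc.gap_extend
    goe = go + ge
    M = [[_NEG] * W for _ in range(R + 1)]
    X = [[_NEG] * W for _ in range(R + 1)]  # gap in target (consumes ref)
    Y = [[_NEG] * W for _ in range(R + 1)]  # gap in reference (consumes target)
    if not (dlo <= 0 <= dhi):
        raise ValueError("band must contain the origin")
    M[0][-dlo] = 0
    for j in range(1, min(T, dhi) + 1):
        Y[0][j - dlo] = go + j * ge
    for i in range(1, R + 1):
        jmin = max(0, i + dlo)
        jmax = min(T, i + dhi)
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        ri = ref[i - 1]
        for j in range(jmin, jmax + 1):
            col = j - i - dlo
            if j == 0:
                Xi[col] = go + i * ge
                continue
            # diagonal predecessor shares the same column index
            d = Mp[col]
            if Xp[col] > d:
                d = Xp[col]
            if Yp[col] > d:
                d = Yp[col]
            if d > _NEG:
                sub = sc.match if ri == tgt[j - 1] and ri != "N" else sc.mismatch
                Mi[col] = d + sub
            if col + 1 < W:
                v = Mp[col + 1] + goe
                w = Xp[col + 1] + ge
                if w > v:
                    v = w
                w = Yp[col + 1] + goe
                if w > v:
                    v = w
                if v > _NEG // 2:
                    Xi[col] = v
            if col - 1 >= 0:
                v = Mi[col - 1] + goe
                w = Xi[col - 1] + goe
                if w > v:
                    v = w
                w = Yi[col - 1] + ge
                if w > v:
                    v = w
                if v > _NEG // 2:
                    Yi[col] = v
    # traceback
    i, j = R, T
    col = j - i - dlo
    vals = (M[i][col], X[i][col], Y[i][col])
    score = max(vals)
    state = vals.index(score)  # tie preference: M, then X, then Y
    ref_parts: list[str] = []
    tgt_parts: list[str] = []
    touched = False
    while i > 0 or j > 0:
        col = j - i - dlo
        if col == 0 or col == W - 1:
            touched = True
        cur = (M, X, Y)[state][i][col]
        if state == 0:
            ref_parts.append(ref[i - 1])
            tgt_parts.append(tgt[j - 1])
            sub = (sc.match if ref[i - 1] == tgt[j - 1] and ref[i - 1] != "N"
                   else sc.mismatch)
            need = cur - sub
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            pcol = j - i - dlo
            for s, v in ((0, M[i][pcol]), (1, X[i][pcol]), (2, Y[i][pcol])):
                if v == need:
                    state = s
                    break
        elif state == 1:
            ref_parts.append(ref[i - 1])
            tgt_parts.append("-")
            i -= 1
            if i == 0 and j == 0:
                break
            pcol = j - i - dlo
            for s, v in ((0, M[i][pcol] + sc.gap_open + sc.gap_extend),
                         (1, X[i][pcol] + sc.gap_extend),
                         (2, Y[i][pcol] + sc.gap_open + sc.gap_extend)):
                if v == cur:
                    state = s
                    break
        else:
            ref_parts.append("-")
            tgt_parts.append(tgt[j - 1])
            j -= 1
            if i == 0 and j == 0:
                break
            pcol = j - i - dlo
            for s, v in ((0, M[i][pcol] + sc.gap_open + sc.gap_extend),
                         (1, X[i][pcol] + sc.gap_open + sc.gap_extend),
                         (2, Y[i][pcol] + sc.gap_extend)):
                if v == cur:
                    state = s
                    break
    return score, "".join(reversed(ref_parts)), "".join(reversed(tgt_parts)), touched


def global_affine_alignment(
    reference: str,
    target: str,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> PairwiseAlignment:
    """Optimal global alignment of ``target`` against ``reference``."""
    R, T = len(reference), len(target)
    if R == 0 and T == 0:
        return PairwiseAlignment(0, "", "")
    if R == 0:
        return PairwiseAlignment(
            scoring.gap_open + T * scoring.gap_extend, "-" * T, target
        )
    if T == 0:
        return PairwiseAlignment(
            scoring.gap_open + R * scoring.gap_extend, reference, "-" * R
        )
    pad = 12
    while True:
        dlo = min(0, T - R) - pad
        dhi = max(0, T - R) + pad
        full = dlo <= -R and dhi >= T
        dlo = max(dlo, -R)
        dhi = min(dhi, T)
        score, ra, ta, touched = _fill_and_trace(
            reference, target, scoring, dlo, dhi
        )
        # Any path leaving the band carries at least |T-R| + 2(pad+1) gap
        # bases; its score cannot exceed this ceiling, so beating the
        # ceiling certifies the banded optimum as the global optimum.
        exit_ceiling = (
            scoring.match * min(R, T)
            + scoring.gap_open
            + scoring.gap_extend * (abs(T - R) + 2 * (pad + 1))
        )
        if full or (not touched and score >= exit_ceiling):
            return PairwiseAlignment(score, ra, ta)
        pad *= 2
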