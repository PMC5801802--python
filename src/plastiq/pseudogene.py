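"""Codon-frame-aware pseudogene calling.

Each target coding sequence is aligned against the functional outgroup
copy; indel runs whose length is not a multiple of 3 are frameshifts
(FS), and in-frame TAA/TAG/TGA codons arising in the target before the
reference's terminal stop are premature stop codons (SC).  A gene with
at least one FS or SC is a potential pseudogene; genes with little or
no aligned sequence are absent, and genes missing one exon while
retaining another are partial.

Coordinates are reported two ways: ``aa_ref`` projects the site onto
the reference protein (well-defined across species) and ``aa_target``
counts codons in the target's own running frame (the species-local
numbering that drifts downstream of indels).  Shared-event matching
uses the reference-anchored nucleotide position and the exact change.

Terminal gap runs (a target truncated at either end) are treated as
missing sequence — they contribute to coverage, not to frameshifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .alignment import (
    AlignmentScoring,
    DEFAULT_SCORING,
    global_affine_alignment,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODONS = {"ATG", "GTG", "TTG", "ACG"}

ABSENT_COVERAGE = 0.20
PARTIAL_PRESENT_COVERAGE = 0.80


@dataclass
class CdsAlignment:
    """A target CDS globally aligned to the reference (outgroup) CDS."""

    gene: str
    species: str
    ref_aln: str
    target_aln: str
    ref_length_nt: int
    coverage_frac: float

    def __post_init__(self):
        if self.ref_length_nt % 3 != 0:
            raise ValueError("reference CDS length not divisible by 3")

    @property
    def columns(self) -> list[tuple[str | None, str | None]]:
        return [
            (r if r != "-" else None, t if t != "-" else None)
            for r, t in zip(self.ref_aln, self.target_aln)
        ]


@dataclass(frozen=True)
class InactivatingMutation:
    gene: str
    species: str
    kind: str  # FS | SC | exon_loss | gene_loss
    aa_ref: int
    aa_target: int
    ref_nt_pos: int  # 1-based, reference-anchored
    change: str
    frame_state_at_site: int = 0
    frameshift_induced: bool | None = None  # SC only
    ref_length_nt: int | None = None

    def __post_init__(self):
        if self.kind not in ("FS", "SC", "exon_loss", "gene_loss"):
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.aa_ref < 1:
            raise ValueError("aa_ref must be >= 1")


@dataclass
class GeneStatus:
    gene: str
    species: str
    status: str  # intact | potential_pseudogene | partial | absent
    mutations: list[InactivatingMutation] = field(default_factory=list)
    missing_exons: list[int] = field(default_factory=list)
    coverage_frac: float = 0.0
    note: str = ""


def align_cds(
    target_nt: str,
    reference_nt: str,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    gene: str = "",
    species: str = "",
) -> CdsAlignment | None:
    """Align a target CDS to the functional reference copy.

    Returns None for an empty target (an absence signal, not an
    alignment).  The reference must be a well-formed CDS: length
    divisible by 3, opening with a start codon and closing with a stop.
    """
    if len(reference_nt) % 3 != 0:
        raise ValueError("reference CDS length not divisible by 3")
    if reference_nt[:3] not in START_CODONS:
        raise ValueError(f"reference does not start with a start codon: "
                         f"{reference_nt[:3]}")
    if reference_nt[-3:] not in STOP_CODONS:
        raise ValueError(f"reference does not end with a stop codon: "
                         f"{reference_nt[-3:]}")
    if not target_nt:
        return None
    aln = global_affine_alignment(reference_nt, target_nt, scoring)
    covered = sum(
        1 for r, t in zip(aln.ref_aln, aln.target_aln) if r != "-" and t != "-"
    )
    return CdsAlignment(
        gene=gene,
        species=species,
        ref_aln=aln.ref_aln,
        target_aln=aln.target_aln,
        ref_length_nt=len(reference_nt),
        coverage_frac=covered / len(reference_nt),
    )


def _alignment_walk(alignment: CdsAlignment):
    """Single pass over alignment columns.

    Returns ``(runs, per_target_base)`` where ``runs`` is a list of
    interior indel runs ``(kind, length, ref_idx, bases, d_before)``
    (kind 'ins'/'del'; ref_idx is the 0-based reference position of the
    first deleted base, or of the base the insertion precedes) and
    ``per_target_base[t] = (ref_idx_at, d_at)`` maps each 0-based
    target base to the reference offset consumed before its column and
    the cumulative net indel length at that point.
    """
    ra, ta = alignment.ref_aln, alignment.target_aln
    ncol = len(ra)
    # terminal target-gap runs = truncation, not indels
    first_pair = next(
        (c for c in range(ncol) if ra[c] != "-" and ta[c] != "-"), ncol
    )
    last_pair = next(
        (c for c in range(ncol - 1, -1, -1) if ra[c] != "-" and ta[c] != "-"),
        -1,
    )
    runs = []
    per_target: list[tuple[int, int]] = []
    ref_idx = 0
    d = 0
    c = 0
    while c < ncol:
        r, t = ra[c], ta[c]
        if r != "-" and t != "-":
            per_target.append((ref_idx, d))
            ref_idx += 1
            c += 1
            continue
        kind = "ins" if r == "-" else "del"
        start = c
        bases = []
        while c < ncol and ((ra[c] == "-") != (ta[c] == "-")) \
                and (ra[c] == "-") == (kind == "ins"):
            if kind == "ins":
                per_target.append((ref_idx, d))
                bases.append(ta[c])
            c += 1
        length = c - start
        # a run is interior when it lies strictly between the first and
        # last aligned pair of columns; terminal runs are truncation
        interior = start > first_pair and c - 1 < last_pair
        if kind == "del":
            if interior:
                runs.append(("del", length, ref_idx, "", d))
                d -= length
            ref_idx += length
        else:
            if interior:
                runs.append(("ins", length, ref_idx, "".join(bases), d))
                d += length
    return runs, per_target


def scan_frameshifts(alignment: CdsAlignment) -> list[InactivatingMutation]:
    """Emit one FS per interior indel run whose length is not 0 mod 3.

    The cumulative net indel length d tracks the running frame; the
    frame is restored wherever d returns to 0 mod 3.
    """
    runs, _ = _alignment_walk(alignment)
    out = []
    for kind, length, ref_idx, bases, d_before in runs:
        if length % 3 == 0:
            continue
        pos1 = ref_idx + 1
        if kind == "del":
            change = f"del{length}@{pos1}"
        else:
            change = f"ins{length}:{bases}@{pos1}"
        out.append(
            InactivatingMutation(
                gene=alignment.gene,
                species=alignment.species,
                kind="FS",
                aa_ref=1 + ref_idx // 3,
                aa_target=1 + _target_codon_of_run(alignment, ref_idx),
                ref_nt_pos=pos1,
                change=change,
                frame_state_at_site=d_before % 3,
                ref_length_nt=alignment.ref_length_nt,
            )
        )
    return out


def _target_codon_of_run(alignment: CdsAlignment, ref_idx: int) -> int:
    """0-based target codon index at (or just after) a reference offset."""
    consumed_t = 0
    consumed_r = 0
    for r, t in zip(alignment.ref_aln, alignment.target_aln):
        if consumed_r >= ref_idx:
            break
        if r != "-":
            consumed_r += 1
        if t != "-":
            consumed_t += 1
    return consumed_t // 3


def scan_stops(
    alignment: CdsAlignment,
    fs_list: list[InactivatingMutation] | None = None,
) -> list[InactivatingMutation]:
    """Translate the target in its running frame and emit premature stops.

    Stops aligned at or beyond the reference's terminal stop codon are
    never premature.  Stops arising while the cumulative indel length
    is not 0 mod 3 are retained but flagged ``frameshift_induced`` —
    Dollo/shared-event analysis excludes them, since they are a
    consequence of the frameshift rather than an independent change.
    """
    _, per_target = _alignment_walk(alignment)
    target_seq = alignment.target_aln.replace("-", "")
    ref_aa_len = alignment.ref_length_nt // 3
    out = []
    for cidx in range(len(target_seq) // 3):
        codon = target_seq[3 * cidx: 3 * cidx + 3]
        if codon not in STOP_CODONS:
            continue
        ref_idx, d = per_target[3 * cidx]
        aa_ref = 1 + ref_idx // 3
        if aa_ref >= ref_aa_len:  # terminal or beyond: not premature
            continue
        out.append(
            InactivatingMutation(
                gene=alignment.gene,
                species=alignment.species,
                kind="SC",
                aa_ref=aa_ref,
                aa_target=cidx + 1,
                ref_nt_pos=ref_idx + 1,
                change=f"{codon}@{ref_idx + 1}",
                frame_state_at_site=d % 3,
                frameshift_induced=(d % 3) != 0,
                ref_length_nt=alignment.ref_length_nt,
            )
        )
    return out


def call_status(
    gene: str,
    species: str,
    alignment: CdsAlignment | None,
    fs_list: list[InactivatingMutation] | None = None,
    sc_list: list[InactivatingMutation] | None = None,
    exon_map: list[tuple[int, int]] | None = None,
    absent_threshold: float = ABSENT_COVERAGE,
    present_threshold: float = PARTIAL_PRESENT_COVERAGE,
) -> GeneStatus:
    """Classify a gene as intact / potential_pseudogene / partial / absent.

    ``exon_map`` gives reference exon boundaries in CDS coordinates
    (0-based half-open); per-exon coverage below ``absent_threshold``
    alongside another exon above ``present_threshold`` yields partial.
    """
    if alignment is None:
        return GeneStatus(gene, species, "absent")
    fs_list = fs_list if fs_list is not None else scan_frameshifts(alignment)
    sc_list = sc_list if sc_list is not None else scan_stops(alignment, fs_list)
    cov = alignment.coverage_frac
    if cov < absent_threshold:
        return GeneStatus(gene, species, "absent", coverage_frac=cov)
    mutations = list(fs_list) + list(sc_list)
    note = ""
    tgt = alignment.target_aln.replace("-", "")
    if tgt[:3] not in START_CODONS:
        note = "start codon lost"
    missing: list[int] = []
    if exon_map and len(exon_map) > 1:
        ref_covered = []
        for r, t in zip(alignment.ref_aln, alignment.target_aln):
            if r != "-":
                ref_covered.append(t != "-")
        covs = []
        for s, e in exon_map:
            span = ref_covered[s:e]
            covs.append(sum(span) / len(span) if span else 0.0)
        missing = [i + 1 for i, c in enumerate(covs) if c < absent_threshold]
        if missing and any(c > present_threshold for c in covs):
            return GeneStatus(
                gene, species, "partial", mutations=mutations,
                missing_exons=missing, coverage_frac=cov, note=note,
            )
    if mutations:
        return GeneStatus(
            gene, species, "potential_pseudogene", mutations=mutations,
            missing_exons=missing, coverage_frac=cov, note=note,
        )
    return GeneStatus(gene, species, "intact", coverage_frac=cov,
                      missing_exons=missing, note=note)


def tabulate_gene_content(
    statuses: list[GeneStatus],
    features_by_species: dict[str, list],
) -> pd.DataFrame:
    """Per-species gene-content tallies.

    Total protein genes count IR-duplicated genes twice (the duplicated
    count is shown alongside); the pseudogene column counts genes whose
    status is potential_pseudogene or partial (exon loss inactivates a
    gene as surely as a frameshift); tRNA/rRNA columns count distinct
    types.
    """
    status_map: dict[str, dict[str, str]] = {}
    for st in statuses:
        status_map.setdefault(st.species, {})[st.gene] = st.status
    rows = []
    for species, feats in features_by_species.items():
        by_name: dict[str, int] = {}
        trna, rrna = set(), set()
        for f in feats:
            if f.feature_class == "protein":
                by_name[f.name] = max(by_name.get(f.name, 1), f.copy_number)
            elif f.feature_class == "tRNA":
                trna.add(f.name)
            else:
                rrna.add(f.name)
        total = sum(by_name.values())
        # the parenthetical of a gene-content table counts gene copies
        # residing in the IR, i.e. two per duplicated gene
        duplicated = sum(c for c in by_name.values() if c == 2)
        pseudo = sum(
            1
            for g, s in status_map.get(species, {}).items()
            if s in ("potential_pseudogene", "partial")
        )
        rows.append(
            {
                "species": species,
                "total_protein_genes": total,
                "duplicated": duplicated,
                "potential_pseudogenes": pseudo,
                "tRNA_types": len(trna),
                "rRNA_types": len(rrna),
            }
        )
    return pd.DataFrame(rows)
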