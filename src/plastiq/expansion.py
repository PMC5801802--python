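"""IR-expansion quantification against an autotrophic outgroup.

When an inverted-repeat boundary migrates into a single-copy region,
formerly single-copy sequence and genes are duplicated into both arms.
This module labels every gene by the region holding the majority of
its exon bp, then measures — per species, relative to the outgroup —
how many bp and genes the IR has recruited from the LSC and from the
SSC.

Homology is by gene name (plastid gene names are stable across the
family), and bp attribution uses a boundary-anchor midpoint rule: each
maximal run of recruited genes claims the arm sequence from the
midpoint of the intergenic gap at each end of the run, clipped to the
arm.  The midpoint is symmetric and deterministic; nothing in a
gene-wise comparison pins junction bp between two genes more finely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .irdetect import QuadripartiteStructure
from .model import GeneFeature, Plastome, overlap_len, normalize_interval


@dataclass
class ExpansionReport:
    """Per-species IR expansion relative to the outgroup (one arm's worth)."""

    species: str
    ir_len: int
    expansion_total: int
    from_lsc_bp: int
    from_ssc_bp: int
    genes_from_lsc: int
    genes_from_ssc: int
    recruited_genes: list[tuple[str, str, bool]] = field(default_factory=list)
    ir_len_diff_vs_outgroup: int | None = None

    def __post_init__(self):
        if self.from_lsc_bp < 0 or self.from_ssc_bp < 0 or self.ir_len < 0:
            raise ValueError("bp fields must be non-negative")
        if self.expansion_total != self.from_lsc_bp + self.from_ssc_bp:
            raise ValueError(
                "expansion_total must equal from_lsc_bp + from_ssc_bp "
                f"({self.expansion_total} != "
                f"{self.from_lsc_bp} + {self.from_ssc_bp})"
            )
        n_lsc = sum(1 for _, src, _ in self.recruited_genes if src == "LSC")
        n_ssc = sum(1 for _, src, _ in self.recruited_genes if src == "SSC")
        if self.recruited_genes and (
            n_lsc != self.genes_from_lsc or n_ssc != self.genes_from_ssc
        ):
            raise ValueError("gene counts disagree with recruited_genes")


def assign_gene_regions(
    structure: QuadripartiteStructure,
    features: list[GeneFeature],
) -> list[GeneFeature]:
    """Label each feature with the region holding most of its exon bp.

    Junction-straddling features are labelled by majority rule and
    flagged.  Features sharing a name whose majority regions are the
    two IR arms get ``copy_number`` 2.
    """
    n = structure.genome_length
    regions = {
        "LSC": structure.lsc,
        "IRa": structure.ir_a,
        "SSC": structure.ssc,
        "IRb": structure.ir_b,
    }
    arm_of: dict[int, str] = {}
    for idx, f in enumerate(features):
        for s, e in f.exons:
            if s < 0 or s >= n or e - s > n:
                raise ValueError(
                    f"feature {f.name} exon ({s}, {e}) outside genome bounds"
                )
        overlaps = {}
        total = 0
        for label, iv in regions.items():
            bp = sum(overlap_len(ex, iv, n) for ex in f.exons)
            overlaps[label] = bp
            total += bp
        if total != f.total_exon_len:
            raise ValueError(f"feature {f.name} extends outside the genome")
        best = max(overlaps, key=lambda k: (overlaps[k], k))
        f.region = "IR" if best in ("IRa", "IRb") else best
        f.straddles_junction = overlaps[best] != f.total_exon_len
        f.copy_number = 1
        arm_of[idx] = best
    by_name: dict[str, list[int]] = {}
    for idx, f in enumerate(features):
        by_name.setdefault(f.name, []).append(idx)
    for name, idxs in by_name.items():
        arms = {arm_of[i] for i in idxs if features[i].region == "IR"}
        if {"IRa", "IRb"} <= arms:
            for i in idxs:
                if features[i].region == "IR":
                    features[i].copy_number = 2
    return features


def _arm_label(structure: QuadripartiteStructure, feature: GeneFeature) -> str:
    """Which arm (IRa/IRb) holds the majority of an IR-resident feature."""
    n = structure.genome_length
    bp_a = sum(overlap_len(ex, structure.ir_a, n) for ex in feature.exons)
    bp_b = sum(overlap_len(ex, structure.ir_b, n) for ex in feature.exons)
    return "IRa" if bp_a >= bp_b else "IRb"


def map_ir_expansion(
    target: tuple[Plastome, list[GeneFeature], QuadripartiteStructure],
    outgroup: tuple[Plastome, list[GeneFeature], QuadripartiteStructure],
) -> ExpansionReport:
    """Quantify target IR expansion relative to the outgroup.

    Both genomes must be canonicalized (LSC first, then IRa) with
    regions assigned.  A target-IR gene whose outgroup namesake is
    LSC-resident (resp. SSC-resident) counts toward
    ``genes_from_lsc`` (``genes_from_ssc``); genes already duplicated
    in the outgroup IR contribute nothing.  bp are attributed per arm
    (IRa) with the boundary-anchor midpoint rule.
    """
    t_plastome, t_feats, t_struct = target
    o_plastome, o_feats, o_struct = outgroup
    out_region: dict[str, str] = {}
    for f in o_feats:
        if f.region is None:
            raise ValueError("outgroup features lack region assignment; "
                             "run assign_gene_regions first")
        out_region.setdefault(f.name, f.region)
    if not (set(out_region) & {f.name for f in t_feats}):
        raise ValueError("cannot anchor homology: no shared gene names")
    n = t_struct.genome_length

    # anchors: genes whose majority arm is IRa, ordered along the arm,
    # plus the nearest flanking non-IR gene on each side
    ira = normalize_interval(t_struct.ir_a, n)
    in_arm = [
        f for f in t_feats
        if f.region == "IR" and _arm_label(t_struct, f) == "IRa"
    ]
    in_arm.sort(key=lambda f: ((f.start - ira[0]) % n))

    def source_of(f: GeneFeature) -> str | None:
        src = out_region.get(f.name)
        return src if src in ("LSC", "SSC") else None

    # unique recruited gene names (count each once even though duplicated)
    recruited: list[tuple[str, str, bool]] = []
    seen: set[str] = set()
    labels = [source_of(f) for f in in_arm]
    # contiguity: a recruited run is contiguous with its source region's
    # junction if no differently-labelled gene lies between run and edge
    # (LSC faces the arm start in canonical orientation, SSC the arm end)
    first_non_lsc = next(
        (i for i, lab in enumerate(labels) if lab != "LSC"), len(labels)
    )
    last_non_ssc = next(
        (i for i in range(len(labels) - 1, -1, -1) if labels[i] != "SSC"), -1
    )
    for i, f in enumerate(in_arm):
        lab = labels[i]
        if lab is None or f.name in seen:
            continue
        seen.add(f.name)
        contiguous = (i < first_non_lsc) if lab == "LSC" else (i > last_non_ssc)
        recruited.append((f.name, lab, not contiguous))

    # nearest non-arm neighbours flanking the arm (canonical order:
    # ... LSC | IRa | SSC ...)
    lsc_genes = [f for f in t_feats if f.region == "LSC"]
    ssc_genes = [f for f in t_feats if f.region == "SSC"]
    left_neighbor_end = max((f.end for f in lsc_genes), default=None)
    right_neighbor_start = min(
        ((f.start - ira[0]) % n + ira[0] for f in ssc_genes), default=None
    )

    arm_start, arm_end = ira

    def anchor_bounds(i: int) -> tuple[int, int]:
        """Midpoint-rule bounds around arm gene i, clipped to the arm."""
        f = in_arm[i]
        s = (f.start - arm_start) % n + arm_start
        e = s + (f.end - f.start)
        if i > 0:
            prev = in_arm[i - 1]
            pe = (prev.start - arm_start) % n + arm_start + (prev.end - prev.start)
            lo = (pe + s) // 2
        elif left_neighbor_end is not None:
            pe = left_neighbor_end - n if left_neighbor_end > arm_start else left_neighbor_end
            lo = (pe + s) // 2
        else:
            lo = arm_start
        if i + 1 < len(in_arm):
            nxt = in_arm[i + 1]
            ns = (nxt.start - arm_start) % n + arm_start
            hi = (e + ns) // 2
        elif right_neighbor_start is not None:
            hi = (e + right_neighbor_start) // 2
        else:
            hi = arm_end
        return max(lo, arm_start), min(hi, arm_end)

    from_lsc_bp = 0
    from_ssc_bp = 0
    i = 0
    while i < len(in_arm):
        lab = labels[i]
        if lab is None:
            i += 1
            continue
        j = i
        while j + 1 < len(in_arm) and labels[j + 1] == lab:
            j += 1
        lo = anchor_bounds(i)[0]
        hi = anchor_bounds(j)[1]
        run_bp = max(0, hi - lo)
        if lab == "LSC":
            from_lsc_bp += run_bp
        else:
            from_ssc_bp += run_bp
        i = j + 1

    n_lsc = sum(1 for _, src, _ in recruited if src == "LSC")
    n_ssc = sum(1 for _, src, _ in recruited if src == "SSC")
    return ExpansionReport(
        species=t_plastome.id,
        ir_len=t_struct.ir_len,
        expansion_total=from_lsc_bp + from_ssc_bp,
        from_lsc_bp=from_lsc_bp,
        from_ssc_bp=from_ssc_bp,
        genes_from_lsc=n_lsc,
        genes_from_ssc=n_ssc,
        recruited_genes=recruited,
        ir_len_diff_vs_outgroup=t_struct.ir_len - o_struct.ir_len,
    )


def summarize_structures(
    rows: list[dict],
    reports: dict[str, ExpansionReport] | None = None,
) -> pd.DataFrame:
    """Compose a per-species structural summary table.

    Each row dict provides ``species``, ``plastome_length``, ``lsc``,
    ``ssc``, ``ir`` (bp).  The plastome length is recomputed as
    LSC + SSC + 2*IR and any mismatch with the measured length is
    flagged (and warned about) rather than treated as an error — such
    discrepancies do occur in published component tables.
    """
    reports = reports or {}
    out = []
    for row in rows:
        composed = row["lsc"] + row["ssc"] + 2 * row["ir"]
        ok = composed == row["plastome_length"]
        if not ok:
            warnings.warn(
                f"{row['species']}: components compose to {composed} bp "
                f"but plastome length is {row['plastome_length']} bp"
            )
        rec = {
            "species": row["species"],
            "plastome_length": row["plastome_length"],
            "lsc": row["lsc"],
            "ssc": row["ssc"],
            "ir": row["ir"],
            "composed_length": composed,
            "composition_ok": ok,
        }
        rep = reports.get(row["species"])
        if rep is not None:
            rec.update(
                expansion_total=rep.expansion_total,
                from_lsc_bp=rep.from_lsc_bp,
                from_ssc_bp=rep.from_ssc_bp,
                genes_from_lsc=rep.genes_from_lsc,
                genes_from_ssc=rep.genes_from_ssc,
            )
        out.append(rec)
    columns = [
        "species", "plastome_length", "lsc", "ssc", "ir", "composed_length",
        "composition_ok", "expansion_total", "from_lsc_bp", "from_ssc_bp",
        "genes_from_lsc", "genes_from_ssc",
    ]
    df = pd.DataFrame(out)
    if df.empty:
        return pd.DataFrame(columns=columns)
    for c in columns:
        if c not in df:
            df[c] = pd.NA
    return df[columns]
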