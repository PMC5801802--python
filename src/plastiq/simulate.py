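"""Synthetic plastome evolution with a known ground truth.

An ancestral quadripartite genome (default 1/10 the scale of a real
plastome: LSC 8 kb, SSC 1.8 kb, IR 2.6 kb) is evolved depth-first
along a rooted species tree.  Branches accumulate Jukes-Cantor-style
point substitutions plus engineered events — IR boundary migrations,
frame-disrupting indels, stop-gain substitutions, exon and gene
deletions — and every engineered change is recorded in a
:class:`TruthLedger`, the parameter-recovery oracle for the pipeline.

Modelling choices that keep the ledger an exact oracle:

* The two IR arms are kept byte-identical on every branch by applying
  all change to the IRa haplotype and mirroring IRb at assembly —
  emulating the gene-conversion homogenisation that keeps real arms
  virtually identical.
* Substitutions never create or destroy stop/start codons in protein
  genes (rejection sampling of the replacement base) and never touch
  genes targeted by engineered events, so the ledger is the complete
  inventory of inactivating changes and indel left-normalisation is
  stable across species.
* Region junctions and engineered boundary shifts sit at intergenic
  midpoints, so gene-anchor midpoint mapping can recover boundary
  positions exactly; the half-gap width is recorded as the anchor
  resolution.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .irdetect import QuadripartiteStructure
from .model import (
    CoverageTrack,
    GeneFeature,
    Plastome,
    interval_positions,
    revcomp,
)

STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"

DEFAULT_TREE = "(Lphil,(Avir,(Bam,(Sfor,(Sher,Sasp)n5)n4)n3)n2)root;"

# (name, class, n_codons or nt length, strand); two-exon genes give a
# tuple of exon codon counts plus an intron length
_LSC_GENES = [
    ("trnH", "tRNA", 72, "+"),
    ("psbA", "protein", 105, "+"),
    ("matK", "protein", 120, "-"),
    ("atpA", "protein", 100, "+"),
    ("rbcL", "protein", 110, "+"),
    ("ndhC", "protein", 60, "+"),
    ("ndhJ", "protein", 53, "+"),
    ("ndhK", "protein", 75, "+"),
    ("accD", "protein", 120, "+"),
    ("psbB", "protein", 100, "-"),
    ("petA", "protein", 90, "+"),
    ("ycf3", "protein", 55, "+"),
]
_SSC_GENES = [
    ("ndhF", "protein", 95, "+"),
    ("ndhA", "protein", ((60, 61), 120), "+"),  # two exons + 120 nt intron
    ("ndhG", "protein", 59, "+"),
    ("ndhH", "protein", 66, "+"),
]
_IR_GENES = [
    ("rrn16", "rRNA", 420, "+"),
    ("trnI", "tRNA", 72, "+"),
    ("rrn23", "rRNA", 600, "+"),
    ("ycf2", "protein", 130, "+"),
    ("ndhB", "protein", 110, "+"),
]

_MARGIN = 30  # bp kept gene-free at each region end; junction gap = 2*margin


@dataclass(frozen=True)
class EngineeredEvent:
    """One engineered change assigned to a tree branch.

    kind ∈ {ir_expand, fs, stop_gain, delete_gene, delete_exon}.
    ``fs`` plants an indel of ``indel_len`` nt (negative = deletion) at
    ``codon``; ``ir_expand`` migrates the IR boundary ``target_bp``
    into ``source_region`` (snapped to an intergenic midpoint).
    """

    branch: str
    kind: str
    gene: str | None = None
    codon: int | None = None
    indel_len: int | None = None
    bases: str | None = None
    source_region: str | None = None
    target_bp: int | None = None
    exon: int | None = None

    def __post_init__(self):
        if self.kind not in ("ir_expand", "fs", "stop_gain", "delete_gene",
                             "delete_exon"):
            raise ValueError(f"unknown event kind {self.kind!r}")


def default_events() -> list[EngineeredEvent]:
    """The standard 5-event scenario: one boundary migration and four
    pseudogenizing events echoing the patterns seen in hemiparasites
    (a clade-shared frameshift, a clade-shared stop gain, a gene loss,
    and a terminal exon loss)."""
    return [
        EngineeredEvent(branch="n4", kind="ir_expand",
                        source_region="LSC", target_bp=1200),
        EngineeredEvent(branch="n5", kind="fs", gene="ndhB", codon=24,
                        indel_len=-1),
        EngineeredEvent(branch="n4", kind="stop_gain", gene="ndhA", codon=20),
        EngineeredEvent(branch="n5", kind="delete_gene", gene="ndhG"),
        EngineeredEvent(branch="Sher", kind="delete_exon", gene="ndhA", exon=2),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    lsc_len: int = 8000
    ssc_len: int = 1800
    ir_len: int = 2600
    sub_rate: float = 0.01  # substitutions per unique site per branch
    tree_newick: str = DEFAULT_TREE
    events: list[EngineeredEvent] = field(default_factory=default_events)

    def __post_init__(self):
        for ev in self.events:
            if ev.kind == "ir_expand" and ev.target_bp is not None:
                limit = self.lsc_len if ev.source_region == "LSC" else self.ssc_len
                if ev.target_bp >= limit:
                    raise ValueError("target_bp exceeds source region length")


@dataclass
class TruthLedger:
    """The simulator's record of everything it engineered."""

    structures: dict[str, QuadripartiteStructure] = field(default_factory=dict)
    events: list[dict] = field(default_factory=list)

    def events_for_leaf(self, leaf: str, kinds: tuple[str, ...] | None = None):
        out = []
        for ev in self.events:
            if leaf in ev["affected_leaves"] and (
                kinds is None or ev["kind"] in kinds
            ):
                out.append(ev)
        return out


# ---------------------------------------------------------------------------
# internal genome state: region-local sequences + features
# ---------------------------------------------------------------------------

@dataclass
class _SimFeature:
    name: str
    cls: str
    region: str  # LSC | IRa | SSC
    exons: list[tuple[int, int]]  # region-local
    strand: str
    recruited_from: str | None = None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class _GenomeState:
    lsc: list[str]
    ira: list[str]
    ssc: list[str]
    feats: list[_SimFeature]

    def region_seq(self, region: str) -> list[str]:
        return {"LSC": self.lsc, "IRa": self.ira, "SSC": self.ssc}[region]

    def feature(self, name: str) -> _SimFeature:
        for f in self.feats:
            if f.name == name:
                return f
        raise ValueError(f"gene {name!r} not present (deleted or never existed)")

    def cds_of(self, f: _SimFeature) -> str:
        seq = self.region_seq(f.region)
        s = "".join("".join(seq[a:b]) for a, b in f.exons)
        return revcomp(s) if f.strand == "-" else s


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random stop-free codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(_BASES[i] for i in rng.integers(0, 4, size=3))
        if c not in STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _layout_region(
    rng: np.random.Generator,
    region_len: int,
    gene_specs: list,
    region_label: str,
) -> tuple[list[str], list[_SimFeature]]:
    """Place genes left to right with equal intergenic gaps and fixed
    margins, filling intergenic space with random sequence."""
    pieces: list[tuple[str, object]] = []  # (kind, payload)
    footprint = 0
    feats_spec = []
    for name, cls, size, strand in gene_specs:
        if cls == "protein" and isinstance(size, tuple):
            (ex1, ex2), intron_len = size
            cds = _random_cds(rng, ex1 + ex2)
            exon1, exon2 = cds[: ex1 * 3], cds[ex1 * 3:]
            genomic = exon1 + _random_seq(rng, intron_len) + exon2
            exon_offsets = [(0, len(exon1)),
                            (len(exon1) + intron_len, len(genomic))]
        elif cls == "protein":
            cds = _random_cds(rng, size)
            genomic = revcomp(cds) if strand == "-" else cds
            exon_offsets = [(0, len(genomic))]
        else:
            genomic = _random_seq(rng, size)
            exon_offsets = [(0, len(genomic))]
        feats_spec.append((name, cls, strand, genomic, exon_offsets))
        footprint += len(genomic)
    n_gaps = len(gene_specs) - 1
    free = region_len - 2 * _MARGIN - footprint
    if free < n_gaps:
        raise ValueError(
            f"{region_label}: genes ({footprint} bp) exceed region capacity"
        )
    gap = free // n_gaps if n_gaps else 0
    seq_parts = [_random_seq(rng, _MARGIN)]
    pos = _MARGIN
    feats = []
    for idx, (name, cls, strand, genomic, exon_offsets) in enumerate(feats_spec):
        feats.append(
            _SimFeature(
                name=name, cls=cls, region=region_label,
                exons=[(pos + a, pos + b) for a, b in exon_offsets],
                strand=strand,
            )
        )
        seq_parts.append(genomic)
        pos += len(genomic)
        if idx < n_gaps:
            g = gap if idx < n_gaps - 1 else free - gap * (n_gaps - 1)
            seq_parts.append(_random_seq(rng, g))
            pos += g
    seq_parts.append(_random_seq(rng, _MARGIN))
    pos += _MARGIN
    assert pos == region_len, (pos, region_len)
    return list("".join(seq_parts)), feats


def generate_ancestor(config: SimulationConfig) -> _GenomeState:
    """Build the ancestral quadripartite genome state."""
    rng = np.random.default_rng(config.seed)
    lsc, f1 = _layout_region(rng, config.lsc_len, _LSC_GENES, "LSC")
    ira, f2 = _layout_region(rng, config.ir_len, _IR_GENES, "IRa")
    ssc, f3 = _layout_region(rng, config.ssc_len, _SSC_GENES, "SSC")
    state = _GenomeState(lsc=lsc, ira=ira, ssc=ssc, feats=f1 + f2 + f3)
    _fix_guards(state)
    return state


def _fix_guards(state: _GenomeState) -> None:
    """Junction-flanking bases are set so that IR extension past an arm
    end hits an immediate mismatch (A never pairs with A)."""
    state.lsc[0] = "A"
    state.lsc[-1] = "A"
    state.ssc[0] = "A"
    state.ssc[-1] = "A"


def _guard_positions(state: _GenomeState) -> set[int]:
    ll, il = len(state.lsc), len(state.ira)
    return {0, ll - 1, ll + il, ll + il + len(state.ssc) - 1}


def assemble(state: _GenomeState, name: str) -> tuple[
    Plastome, list[GeneFeature], QuadripartiteStructure
]:
    """Materialise a genome state as (plastome, features, structure).

    IRb is the reverse complement of IRa; IRa-resident features are
    emitted twice (mirrored into IRb, strand flipped, copy_number 2).
    """
    lsc = "".join(state.lsc)
    ira = "".join(state.ira)
    ssc = "".join(state.ssc)
    genome = lsc + ira + ssc + revcomp(ira)
    n = len(genome)
    off = {"LSC": 0, "IRa": len(lsc), "SSC": len(lsc) + len(ira)}
    irb_off = len(lsc) + len(ira) + len(ssc)
    il = len(ira)
    features: list[GeneFeature] = []
    for f in state.feats:
        base = off[f.region]
        exons = [(base + a, base + b) for a, b in f.exons]
        region = "IR" if f.region == "IRa" else f.region
        copies = 2 if f.region == "IRa" else 1
        features.append(
            GeneFeature(
                name=f.name, feature_class=f.cls, exons=exons,
                strand=f.strand, region=region, copy_number=copies,
                recruited_from=f.recruited_from,
            )
        )
        if f.region == "IRa":
            mirror = [(irb_off + il - b, irb_off + il - a) for a, b in f.exons]
            mirror.sort()
            features.append(
                GeneFeature(
                    name=f.name, feature_class=f.cls, exons=mirror,
                    strand="-" if f.strand == "+" else "+", region="IR",
                    copy_number=2, recruited_from=f.recruited_from,
                )
            )
    features.sort(key=lambda g: g.start)
    structure = QuadripartiteStructure(
        genome_length=n,
        lsc=(0, len(lsc)),
        ir_a=(len(lsc), len(lsc) + il),
        ssc=(len(lsc) + il, irb_off),
        ir_b=(irb_off, n),
        mismatch_count=0,
    )
    return Plastome(id=name, sequence=genome), features, structure


# ---------------------------------------------------------------------------
# branch operations
# ---------------------------------------------------------------------------

def _protein_site_map(state: _GenomeState, frozen_genes: set[str]):
    """Map unique-genome position -> (feature, cds_index) for protein
    CDS sites that substitutions are allowed to touch, plus the set of
    positions substitutions must avoid entirely."""
    off = {"LSC": 0, "IRa": len(state.lsc), "SSC": len(state.lsc) + len(state.ira)}
    site_map: dict[int, tuple[_SimFeature, int, str]] = {}
    forbidden: set[int] = set(_guard_positions(state))
    for f in state.feats:
        base = off[f.region]
        span = set(range(base + f.start, base + f.end))
        if f.name in frozen_genes:
            forbidden |= span
            continue
        if f.cls != "protein":
            continue
        cds = state.cds_of(f)
        L = len(cds)
        cds_positions: list[int] = []
        for a, b in f.exons:
            cds_positions.extend(range(base + a, base + b))
        if f.strand == "-":
            cds_positions = cds_positions[::-1]
        for ci, gp in enumerate(cds_positions):
            if ci < 3 or ci >= L - 3:  # keep start & terminal stop intact
                forbidden.add(gp)
            else:
                site_map[gp] = (f, ci, cds)
    return site_map, forbidden


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _apply_substitutions(
    state: _GenomeState, rng: np.random.Generator, rate: float,
    frozen_genes: set[str],
) -> int:
    """Jukes-Cantor-style substitutions over the unique genome
    (LSC + IRa + SSC); IRb mirrors IRa.  Never creates a stop codon in
    a protein gene, never touches frozen genes or junction guards."""
    unique = state.lsc + state.ira + state.ssc
    U = len(unique)
    n_sub = rng.binomial(U, rate)
    if n_sub == 0:
        return 0
    site_map, forbidden = _protein_site_map(state, frozen_genes)
    ll, il = len(state.lsc), len(state.ira)

    def region_at(p):
        if p < ll:
            return state.lsc, p
        if p < ll + il:
            return state.ira, p - ll
        return state.ssc, p - ll - il

    positions = rng.choice(U, size=min(n_sub, U), replace=False)
    applied = 0
    for p in positions:
        p = int(p)
        if p in forbidden:
            continue
        seq, local = region_at(p)
        old = seq[local]
        if p in site_map:
            f, ci, cds = site_map[p]
            old_cds_base = cds[ci] if f.strand == "+" else _COMP[old]
            k = ci // 3
            codon = cds[3 * k: 3 * k + 3]
            r = ci % 3
            safe = []
            for b in _BASES:
                if b == old_cds_base:
                    continue
                cand = codon[:r] + b + codon[r + 1:]
                if cand not in STOPS:
                    safe.append(b)
            if not safe:
                continue
            new_cds_base = safe[int(rng.integers(0, len(safe)))]
            seq[local] = new_cds_base if f.strand == "+" else _COMP[new_cds_base]
            # keep the cached cds current for later hits in this codon
            site_map[p] = (f, ci, cds[:ci] + new_cds_base + cds[ci + 1:])
            for q, (g, cj, _) in list(site_map.items()):
                if g is f:
                    site_map[q] = (g, cj, site_map[p][2])
        else:
            choices = [b for b in _BASES if b != old]
            seq[local] = choices[int(rng.integers(0, 3))]
        applied += 1
    return applied


def _gaps_of_region(state: _GenomeState, region: str) -> list[tuple[int, int]]:
    """Intergenic intervals (region-local) including the end margins."""
    seq_len = len(state.region_seq(region))
    spans = sorted(
        (f.start, f.end) for f in state.feats if f.region == region
    )
    gaps = []
    prev = 0
    for s, e in spans:
        if s > prev:
            gaps.append((prev, s))
        prev = e
    if prev < seq_len:
        gaps.append((prev, seq_len))
    return gaps


def _shift_coords(state: _GenomeState, region: str, pos: int, delta: int):
    """Shift all feature coordinates strictly after ``pos`` by delta."""
    for f in state.feats:
        if f.region != region:
            continue
        f.exons = [
            (a + delta if a > pos else a, b + delta if b > pos else b)
            for a, b in f.exons
        ]


def _normalize_del(cds: str, o: int, L: int) -> int:
    while o > 0 and cds[o - 1] == cds[o + L - 1]:
        o -= 1
    return o


def _normalize_ins(cds: str, o: int, bases: str) -> tuple[int, str]:
    b = bases
    while o > 0 and b[-1] == cds[o - 1]:
        b = cds[o - 1] + b[:-1]
        o -= 1
    return o, b


def _apply_event(
    state: _GenomeState, ev: EngineeredEvent, rng: np.random.Generator,
    affected_leaves: list[str],
) -> dict:
    record: dict = {
        "branch": ev.branch,
        "kind": ev.kind,
        "gene": ev.gene,
        "affected_leaves": affected_leaves,
    }
    if ev.kind == "ir_expand":
        source = ev.source_region
        if source not in ("LSC", "SSC"):
            raise ValueError("source_region must be LSC or SSC")
        gaps = _gaps_of_region(state, source)
        if source == "LSC":
            target_boundary = len(state.lsc) - ev.target_bp
        else:
            target_boundary = ev.target_bp
        mids = [((a + b) // 2, b - a) for a, b in gaps[1:-1]]  # interior gaps
        snap, gap_w = min(mids, key=lambda m: abs(m[0] - target_boundary))
        if source == "LSC":
            s = len(state.lsc) - snap
            segment = state.lsc[snap:]
            recruited = [f for f in state.feats
                         if f.region == "LSC" and f.start >= snap]
            for f in state.feats:
                if f.region == "IRa":
                    f.exons = [(a + s, b + s) for a, b in f.exons]
            for f in recruited:
                f.region = "IRa"
                f.recruited_from = "LSC"
                f.exons = [(a - snap, b - snap) for a, b in f.exons]
            state.ira = segment + state.ira
            state.lsc = state.lsc[:snap]
        else:
            s = snap
            segment = state.ssc[:snap]
            recruited = [f for f in state.feats
                         if f.region == "SSC" and f.end <= snap]
            il = len(state.ira)
            for f in recruited:
                f.region = "IRa"
                f.recruited_from = "SSC"
                f.exons = [(a + il, b + il) for a, b in f.exons]
            for f in state.feats:
                if f.region == "SSC":
                    f.exons = [(a - snap, b - snap) for a, b in f.exons]
            state.ira = state.ira + segment
            state.ssc = state.ssc[snap:]
        _fix_guards(state)
        record.update(
            source=source,
            requested_bp=ev.target_bp,
            actual_bp=s,
            recruited_genes=sorted(f.name for f in recruited),
            anchor_resolution=(gap_w + 1) // 2,
        )
        return record

    f = state.feature(ev.gene)
    if f.strand != "+":
        raise ValueError("engineered mutations support '+' strand genes only")
    if ev.kind in ("fs", "stop_gain"):
        cds = state.cds_of(f)
        o = (ev.codon - 1) * 3
        if o + 3 > len(cds):
            raise ValueError(f"codon {ev.codon} beyond {ev.gene} length")
        # genomic position of CDS offset o
        consumed = 0
        gpos = None
        exon_hi = None
        for a, b in f.exons:
            if o < consumed + (b - a):
                gpos = a + (o - consumed)
                exon_hi = b
                break
            consumed += b - a
        seq = state.region_seq(f.region)
        if ev.kind == "stop_gain":
            assert gpos + 3 <= exon_hi, "stop_gain codon crosses exon boundary"
            seq[gpos: gpos + 3] = list("TAA")
            record.update(
                codon=ev.codon,
                ref_nt_pos=o + 1,
                aa_ref=ev.codon,
                change=f"TAA@{o + 1}",
                mut_kind="SC",
            )
            return record
        L = ev.indel_len
        if L is None or L == 0:
            raise ValueError("fs event needs a non-zero indel_len")
        if L < 0:
            dl = -L
            assert gpos + dl <= exon_hi, "deletion crosses exon boundary"
            del seq[gpos: gpos + dl]
            _shift_coords(state, f.region, gpos, -dl)
            no = _normalize_del(cds, o, dl)
            record.update(
                codon=ev.codon,
                ref_nt_pos=no + 1,
                aa_ref=1 + no // 3,
                change=f"del{dl}@{no + 1}",
                mut_kind="FS" if dl % 3 else None,
            )
        else:
            bases = ev.bases or _random_seq(rng, L)
            seq[gpos:gpos] = list(bases)
            _shift_coords(state, f.region, gpos, L)
            no, nb = _normalize_ins(cds, o, bases)
            record.update(
                codon=ev.codon,
                ref_nt_pos=no + 1,
                aa_ref=1 + no // 3,
                change=f"ins{L}:{nb}@{no + 1}",
                bases=bases,
                mut_kind="FS" if L % 3 else None,
            )
        return record

    if ev.kind == "delete_gene":
        seq = state.region_seq(f.region)
        s, e = f.start, f.end
        del seq[s:e]
        state.feats.remove(f)
        _shift_coords(state, f.region, s, -(e - s))
        record["mut_kind"] = "gene_loss"
        return record

    if ev.kind == "delete_exon":
        idx = ev.exon - 1
        if idx < 0 or idx >= len(f.exons):
            raise ValueError(f"{ev.gene} has no exon {ev.exon}")
        a, b = f.exons[idx]
        seq = state.region_seq(f.region)
        del seq[a:b]
        f.exons = [x for i, x in enumerate(f.exons) if i != idx]
        _shift_coords(state, f.region, a, -(b - a))
        record.update(exon=ev.exon, mut_kind="exon_loss")
        return record

    raise AssertionError(ev.kind)


# ---------------------------------------------------------------------------
# tree traversal
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    config: SimulationConfig
    tree: dendropy.Tree
    ancestor: tuple
    leaves: dict[str, tuple]
    ledger: TruthLedger


def _branch_name(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or ""


def evolve_along_tree(
    ancestor: _GenomeState,
    tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, _GenomeState], TruthLedger]:
    """Depth-first evolution from the root; per branch, substitutions
    first, then that branch's engineered events in config order."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    frozen = {ev.gene for ev in config.events if ev.gene}
    branch_events: dict[str, list[EngineeredEvent]] = {}
    for ev in config.events:
        branch_events.setdefault(ev.branch, []).append(ev)
    known_branches = {
        _branch_name(n) for n in tree.preorder_node_iter()
        if n.parent_node is not None
    }
    missing = set(branch_events) - known_branches
    if missing:
        raise ValueError(f"events reference unknown branches: {sorted(missing)}")
    descendants = {
        _branch_name(n): sorted(l.taxon.label for l in n.leaf_iter())
        for n in tree.preorder_node_iter()
    }
    ledger = TruthLedger()
    leaves: dict[str, _GenomeState] = {}

    def visit(node: dendropy.Node, state: _GenomeState):
        for child in node.child_nodes():
            cstate = copy.deepcopy(state)
            bname = _branch_name(child)
            _apply_substitutions(cstate, rng, config.sub_rate, frozen)
            _fix_guards(cstate)
            for ev in branch_events.get(bname, ()):
                rec = _apply_event(cstate, ev, rng, descendants[bname])
                ledger.events.append(rec)
            if child.is_leaf():
                leaves[bname] = cstate
            else:
                visit(child, cstate)

    visit(tree.seed_node, ancestor)
    return leaves, ledger


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the full simulation and assemble every leaf genome."""
    tree = dendropy.Tree.get(data=config.tree_newick, schema="newick")
    tree.is_rooted = True
    ancestor_state = generate_ancestor(config)
    leaf_states, ledger = evolve_along_tree(ancestor_state, tree, config)
    leaves = {}
    for name, st in leaf_states.items():
        plastome, feats, struct = assemble(st, name)
        leaves[name] = (plastome, feats, struct)
        ledger.structures[name] = struct
    return SimulationResult(
        config=config,
        tree=tree,
        ancestor=assemble(ancestor_state, "ancestor"),
        leaves=leaves,
        ledger=ledger,
    )


def simulate_coverage(
    structure: QuadripartiteStructure,
    base_depth: int = 40,
    seed: int = 0,
) -> CoverageTrack:
    """Poisson read depth: base_depth in single copy, doubled in the IR."""
    if base_depth < 10:
        raise ValueError("base_depth must be >= 10")
    rng = np.random.default_rng(seed)
    n = structure.genome_length
    lam = np.full(n, float(base_depth))
    for arm in (structure.ir_a, structure.ir_b):
        lam[interval_positions(arm, n)] = 2.0 * base_depth
    return CoverageTrack(rng.poisson(lam).astype(float))


# ---------------------------------------------------------------------------
# on-disk bundle
# ---------------------------------------------------------------------------

def write_bundle(result: SimulationResult, outdir: str | Path,
                 base_depth: int = 40) -> None:
    """Write per-leaf FASTA + feature TSV + coverage TSV, the tree and
    the truth ledger as JSON."""
    from .model import write_coverage, write_features, write_plastome

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for i, (name, (plastome, feats, struct)) in enumerate(
        sorted(result.leaves.items())
    ):
        write_plastome(plastome, out / f"{name}.fasta")
        write_features(feats, out / f"{name}.features.tsv")
        track = simulate_coverage(struct, base_depth,
                                  seed=result.config.seed * 1000 + i)
        write_coverage(track, out / f"{name}.coverage.tsv")
    (out / "tree.nwk").write_text(result.config.tree_newick + "\n")
    ledger_json = {
        "structures": {
            name: {
                "genome_length": s.genome_length,
                "lsc": list(s.lsc), "ir_a": list(s.ir_a),
                "ssc": list(s.ssc), "ir_b": list(s.ir_b),
            }
            for name, s in result.ledger.structures.items()
        },
        "events": result.ledger.events,
    }
    (out / "ledger.json").write_text(json.dumps(ledger_json, indent=2))
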