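"""Full-pipeline orchestration and publication-shaped report writers.

Stages: IR detection -> quadripartite partition -> canonical rotation
-> gene region assignment -> IR-expansion mapping vs the outgroup ->
pseudogene calling -> shared-event detection -> Dollo placement.
Reports mirror the shapes a comparative plastome paper prints: a
structural component table, a gene-content table, a shared-mutation
table, per-gene frame/stop tracks, and a decorated tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import pandas as pd
import yaml

from . import __version__
from .alignment import AlignmentScoring
from .expansion import (
    ExpansionReport,
    assign_gene_regions,
    map_ir_expansion,
    summarize_structures,
)
from .irdetect import (
    QuadripartiteStructure,
    find_inverted_repeat,
    partition_quadripartite,
)
from .model import (
    GeneFeature,
    Plastome,
    canonicalize,
    extract_cds,
    load_features,
    load_plastome,
    load_tree,
)
from .pseudogene import (
    ABSENT_COVERAGE,
    PARTIAL_PRESENT_COVERAGE,
    GeneStatus,
    InactivatingMutation,
    align_cds,
    call_status,
    scan_frameshifts,
    scan_stops,
    tabulate_gene_content,
)
from .placement import PlacedEvent, decorate_tree, place_event
from .shared import SharedEvent, collect_events, write_shared_table

STAGES = (
    "detect_ir",
    "partition",
    "assign_regions",
    "expansion",
    "pseudogenes",
    "shared_events",
    "placement",
)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; unknown YAML keys are rejected."""

    species: dict[str, dict[str, str]]  # name -> {fasta, features}
    outgroup: str
    tree: str
    outdir: str | None = None
    min_ir_len: int = 1000
    max_mismatch_frac: float = 0.005
    coverage_window: int = 200
    coverage_low: float = 1.7
    coverage_high: float = 2.5
    absent_threshold: float = ABSENT_COVERAGE
    present_threshold: float = PARTIAL_PRESENT_COVERAGE
    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "scoring" in data:
            data["scoring"] = AlignmentScoring(**data["scoring"])
        return cls(**data)


@dataclass
class PipelineResults:
    structures: dict[str, QuadripartiteStructure]
    features: dict[str, list[GeneFeature]]
    plastomes: dict[str, Plastome]
    reports: dict[str, ExpansionReport]
    structure_table: pd.DataFrame
    statuses: list[GeneStatus]
    mutations: list[InactivatingMutation]
    gene_content_table: pd.DataFrame
    shared_events: list[SharedEvent]
    shared_table: pd.DataFrame
    placements: list[PlacedEvent]
    placement_table: pd.DataFrame
    decorated_newick: str
    tracks: dict
    manifest: dict


class StageError(RuntimeError):
    def __init__(self, stage: str, fingerprint: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {fingerprint}: {cause}")
        self.stage = stage
        self.cause = cause


def _exon_map_cds(feature: GeneFeature) -> list[tuple[int, int]]:
    """Reference exon boundaries in CDS coordinates (0-based half-open)."""
    lengths = [e - s for s, e in feature.exons]
    if feature.strand == "-":
        lengths = lengths[::-1]
    bounds = []
    pos = 0
    for L in lengths:
        bounds.append((pos, pos + L))
        pos += L
    return bounds


def _frame_track(alignment) -> dict:
    """Fig-1-style per-gene track: shifted-frame segments (aa, ref
    coordinates), stop positions, and missing terminal segments."""
    from .pseudogene import _alignment_walk

    runs, _ = _alignment_walk(alignment)
    ref_aa_len = alignment.ref_length_nt // 3
    segments = []
    d = 0
    open_start = None
    for kind, length, ref_idx, _, d_before in runs:
        d = d_before + (length if kind == "ins" else -length)
        aa = 1 + ref_idx // 3
        if d % 3 != 0 and open_start is None:
            open_start = aa
        elif d % 3 == 0 and open_start is not None:
            segments.append([open_start, aa])
            open_start = None
    if open_start is not None:
        segments.append([open_start, ref_aa_len])
    ref_covered = [
        t != "-" for r, t in zip(alignment.ref_aln, alignment.target_aln)
        if r != "-"
    ]
    missing = []
    run_start = None
    for i, cov in enumerate(ref_covered + [True]):
        if not cov and run_start is None:
            run_start = i
        elif cov and run_start is not None:
            missing.append([1 + run_start // 3, 1 + (i - 1) // 3])
            run_start = None
    return {
        "shifted_frame_aa": segments,
        "stops_aa": [],
        "missing_aa": missing,
        "coverage": round(alignment.coverage_frac, 4),
    }


def analyze_bundle(
    genomes: dict[str, tuple[Plastome, list[GeneFeature]]],
    outgroup: str,
    tree: dendropy.Tree,
    config: PipelineConfig | None = None,
) -> PipelineResults:
    """Run every analysis stage on in-memory genomes.

    ``genomes`` maps species name to (plastome, features); ``outgroup``
    names the functional reference species, which must be present.
    """
    cfg = config or PipelineConfig(species={}, outgroup=outgroup, tree="")
    if outgroup not in genomes:
        raise ValueError(f"outgroup {outgroup!r} not among inputs")

    structures: dict[str, QuadripartiteStructure] = {}
    canon: dict[str, tuple[Plastome, list[GeneFeature]]] = {}
    for name, (plastome, feats) in genomes.items():
        try:
            hit = find_inverted_repeat(
                plastome, min_len=cfg.min_ir_len,
                max_mismatch_frac=cfg.max_mismatch_frac,
            )
            if hit is None:
                raise ValueError("no IR found")
            structure = partition_quadripartite(plastome, (hit[0], hit[1]))
        except Exception as e:  # noqa: BLE001
            raise StageError("detect_ir", name, e) from e
        rotated, offset = canonicalize(plastome, structure)
        n = plastome.length
        feats = [f.shifted(-offset, n) for f in feats]
        structure = partition_quadripartite(
            rotated,
            (
                ((structure.ir_a[0] - offset) % n,
                 (structure.ir_a[0] - offset) % n + structure.ir_len),
                ((structure.ir_b[0] - offset) % n,
                 (structure.ir_b[0] - offset) % n + structure.ir_len),
            ),
        )
        structures[name] = structure
        canon[name] = (rotated, feats)

    for name, (plastome, feats) in canon.items():
        try:
            assign_gene_regions(structures[name], feats)
        except Exception as e:  # noqa: BLE001
            raise StageError("assign_regions", name, e) from e

    out_plastome, out_feats = canon[outgroup]
    out_struct = structures[outgroup]
    reports: dict[str, ExpansionReport] = {}
    for name, (plastome, feats) in canon.items():
        if name == outgroup:
            continue
        try:
            reports[name] = map_ir_expansion(
                (plastome, feats, structures[name]),
                (out_plastome, out_feats, out_struct),
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("expansion", name, e) from e

    rows = [
        {
            "species": name,
            "plastome_length": canon[name][0].length,
            "lsc": structures[name].lsc_len,
            "ssc": structures[name].ssc_len,
            "ir": structures[name].ir_len,
        }
        for name in sorted(canon)
    ]
    structure_table = summarize_structures(rows, reports)

    # reference CDS set from the outgroup
    ref_feats: dict[str, GeneFeature] = {}
    for f in out_feats:
        if f.feature_class == "protein" and f.name not in ref_feats:
            ref_feats[f.name] = f
    statuses: list[GeneStatus] = []
    mutations: list[InactivatingMutation] = []
    tracks: dict[str, dict] = {}
    for name, (plastome, feats) in sorted(canon.items()):
        if name == outgroup:
            continue
        tgt_by_name: dict[str, GeneFeature] = {}
        for f in feats:
            if f.feature_class == "protein" and f.name not in tgt_by_name:
                tgt_by_name[f.name] = f
        for gene, rf in sorted(ref_feats.items()):
            try:
                ref_cds = extract_cds(out_plastome, rf)
                tf = tgt_by_name.get(gene)
                tgt_cds = extract_cds(plastome, tf) if tf is not None else ""
                aln = align_cds(tgt_cds, ref_cds, cfg.scoring,
                                gene=gene, species=name)
                fs = scan_frameshifts(aln) if aln else []
                sc = scan_stops(aln, fs) if aln else []
                st = call_status(
                    gene, name, aln, fs, sc, _exon_map_cds(rf),
                    absent_threshold=cfg.absent_threshold,
                    present_threshold=cfg.present_threshold,
                )
                statuses.append(st)
                mutations.extend(fs)
                mutations.extend(sc)
                if aln is not None and (fs or sc or st.status != "intact"):
                    track = _frame_track(aln)
                    track["stops_aa"] = [m.aa_ref for m in sc]
                    track["status"] = st.status
                    tracks.setdefault(gene, {})[name] = track
            except Exception as e:  # noqa: BLE001
                raise StageError("pseudogenes", f"{name}/{gene}", e) from e

    try:
        events = collect_events(mutations)
        shared_table = write_shared_table(events)
    except Exception as e:  # noqa: BLE001
        raise StageError("shared_events", "all species", e) from e

    loss_events = _loss_events(statuses)
    to_place: list = list(events) + loss_events
    placements = []
    try:
        for ev in to_place:
            placements.append(place_event(ev, tree))
        newick, placement_table = decorate_tree(placements, tree)
    except Exception as e:  # noqa: BLE001
        raise StageError("placement", "event set", e) from e

    features_by_species = {
        name: feats for name, (_, feats) in canon.items()
    }
    gene_content = tabulate_gene_content(statuses, features_by_species)

    manifest = {
        "tool": "plastiq",
        "version": __version__,
        "stages": list(STAGES),
        "outgroup": outgroup,
        "species": sorted(canon),
        "seed": cfg.seed,
        "thresholds": {
            "min_ir_len": cfg.min_ir_len,
            "max_mismatch_frac": cfg.max_mismatch_frac,
            "coverage_window": cfg.coverage_window,
            "coverage_low": cfg.coverage_low,
            "coverage_high": cfg.coverage_high,
            "absent_threshold": cfg.absent_threshold,
            "present_threshold": cfg.present_threshold,
            "scoring": asdict(cfg.scoring),
        },
    }
    return PipelineResults(
        structures=structures,
        features={n: f for n, (_, f) in canon.items()},
        plastomes={n: p for n, (p, _) in canon.items()},
        reports=reports,
        structure_table=structure_table,
        statuses=statuses,
        mutations=mutations,
        gene_content_table=gene_content,
        shared_events=events,
        shared_table=shared_table,
        placements=placements,
        placement_table=placement_table,
        decorated_newick=newick,
        tracks=tracks,
        manifest=manifest,
    )


def _loss_events(statuses: list[GeneStatus]) -> list:
    """Gene-absence and exon-loss events, shared or single-species."""
    out: list = []
    absent: dict[str, list[str]] = {}
    exon_lost: dict[tuple[str, int], list[str]] = {}
    for st in statuses:
        if st.status == "absent":
            absent.setdefault(st.gene, []).append(st.species)
        for ex in st.missing_exons:
            exon_lost.setdefault((st.gene, ex), []).append(st.species)

    def make(gene, kind, change, species_list):
        species_list = sorted(species_list)
        if len(species_list) == 1:
            return InactivatingMutation(
                gene=gene, species=species_list[0], kind=kind,
                aa_ref=1, aa_target=1, ref_nt_pos=1, change=change,
            )
        return SharedEvent(
            gene=gene, kind=kind, ref_nt_pos=1, change=change,
            species_set=frozenset(species_list),
            per_species_aa=tuple((s, 1) for s in species_list),
            identity_class="identical",
        )

    for gene, spp in sorted(absent.items()):
        out.append(make(gene, "gene_loss", "gene_loss", spp))
    for (gene, ex), spp in sorted(exon_lost.items()):
        out.append(make(gene, "exon_loss", f"exon{ex}_loss", spp))
    return out


def write_reports(results: PipelineResults, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results.structure_table.to_csv(out / "structure_table.tsv", sep="\t",
                                   index=False)
    results.gene_content_table.to_csv(out / "gene_content_table.tsv", sep="\t",
                                      index=False)
    results.shared_table.to_csv(out / "shared_events.tsv", sep="\t",
                                index=False)
    results.placement_table.to_csv(out / "placements.tsv", sep="\t",
                                   index=False)
    mut_rows = [
        {
            "gene": m.gene, "species": m.species, "kind": m.kind,
            "aa_ref": m.aa_ref, "aa_target": m.aa_target,
            "ref_nt_pos": m.ref_nt_pos, "change": m.change,
            "frameshift_induced": m.frameshift_induced,
        }
        for m in results.mutations
    ]
    pd.DataFrame(
        mut_rows,
        columns=["gene", "species", "kind", "aa_ref", "aa_target",
                 "ref_nt_pos", "change", "frameshift_induced"],
    ).to_csv(out / "mutations.tsv", sep="\t", index=False)
    status_rows = [
        {
            "gene": s.gene, "species": s.species, "status": s.status,
            "coverage": round(s.coverage_frac, 4),
            "missing_exons": ",".join(map(str, s.missing_exons)),
            "note": s.note,
        }
        for s in results.statuses
    ]
    pd.DataFrame(
        status_rows,
        columns=["gene", "species", "status", "coverage", "missing_exons",
                 "note"],
    ).to_csv(out / "gene_status.tsv", sep="\t", index=False)
    (out / "gene_tracks.json").write_text(
        json.dumps(results.tracks, indent=2, sort_keys=True)
    )
    (out / "decorated_tree.nwk").write_text(results.decorated_newick + "\n")
    (out / "manifest.json").write_text(
        json.dumps(results.manifest, indent=2, sort_keys=True)
    )


def run_pipeline(config: PipelineConfig) -> PipelineResults:
    """Load inputs from disk, run every stage, write the report bundle."""
    genomes = {}
    for name, paths in config.species.items():
        plastome = load_plastome(paths["fasta"])
        feats = load_features(paths["features"], plastome.length)
        genomes[name] = (plastome, feats)
    tree = load_tree(config.tree)
    results = analyze_bundle(genomes, config.outgroup, tree, config)
    if config.outdir:
        write_reports(results, config.outdir)
    return results
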