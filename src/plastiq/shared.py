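"""Shared inactivating-mutation detection.

Two species share an event when they carry the identical nucleotide
change at the identical reference-anchored position — the operative
definition of a single ancestral mutation.  Different changes at the
same reference codon are convergent same-site events (independent
origins).  Frameshift-induced stop codons are excluded before
grouping: they are consequences of an upstream frameshift, not events
of their own.

Amino-acid numbering drifts between species downstream of indels, so
event identity never uses aa positions; the per-species aa coordinates
are carried along for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .pseudogene import InactivatingMutation


@dataclass(frozen=True)
class SharedEvent:
    gene: str
    kind: str  # FS | SC
    ref_nt_pos: int
    change: str  # canonical descriptor; "|"-joined when convergent
    species_set: frozenset[str]
    per_species_aa: tuple[tuple[str, int], ...]
    identity_class: str  # identical | convergent_same_site
    members: tuple[InactivatingMutation, ...] = ()

    def __post_init__(self):
        if len(self.species_set) < 2:
            raise ValueError("a shared event needs >= 2 species")
        if self.identity_class not in ("identical", "convergent_same_site"):
            raise ValueError(f"bad identity_class {self.identity_class!r}")


def collect_events(
    mutations: list[InactivatingMutation],
    codon_window: bool = True,
) -> list[SharedEvent]:
    """Group per-species mutations into shared events.

    Groups with byte-identical change descriptors at one reference
    position are ``identical``; groups at the same reference codon with
    differing descriptors are ``convergent_same_site`` (set
    ``codon_window=False`` to suppress convergent detection).
    Singletons are dropped, as are frameshift-induced stop codons.
    """
    usable = [
        m for m in mutations
        if m.kind in ("FS", "SC") and not (m.kind == "SC" and m.frameshift_induced)
    ]
    ref_lens: dict[str, set[int]] = {}
    for m in usable:
        if m.ref_length_nt is not None:
            ref_lens.setdefault(m.gene, set()).add(m.ref_length_nt)
    for gene, lens in ref_lens.items():
        if len(lens) > 1:
            raise ValueError(
                f"mutations of {gene} reference different CDS lengths: "
                f"{sorted(lens)}"
            )
    events: list[SharedEvent] = []
    ident_keys: dict[tuple, list[InactivatingMutation]] = {}
    for m in usable:
        ident_keys.setdefault((m.gene, m.kind, m.ref_nt_pos, m.change), []).append(m)
    claimed: set[int] = set()
    for (gene, kind, pos, change), members in sorted(
        ident_keys.items(), key=lambda kv: kv[0]
    ):
        species = {m.species for m in members}
        if len(species) < 2:
            continue
        members = sorted(members, key=lambda m: m.species)
        events.append(
            SharedEvent(
                gene=gene,
                kind=kind,
                ref_nt_pos=pos,
                change=change,
                species_set=frozenset(species),
                per_species_aa=tuple((m.species, m.aa_target) for m in members),
                identity_class="identical",
                members=tuple(members),
            )
        )
        claimed.update(id(m) for m in members)
    if codon_window:
        codon_keys: dict[tuple, list[InactivatingMutation]] = {}
        for m in usable:
            codon_keys.setdefault(
                (m.gene, m.kind, (m.ref_nt_pos - 1) // 3), []
            ).append(m)
        for (gene, kind, codon), members in sorted(
            codon_keys.items(), key=lambda kv: kv[0]
        ):
            changes = {m.change for m in members}
            species = {m.species for m in members}
            if len(changes) < 2 or len(species) < 2:
                continue
            members = sorted(members, key=lambda m: (m.species, m.change))
            events.append(
                SharedEvent(
                    gene=gene,
                    kind=kind,
                    ref_nt_pos=min(m.ref_nt_pos for m in members),
                    change="|".join(sorted(changes)),
                    species_set=frozenset(species),
                    per_species_aa=tuple(
                        (m.species, m.aa_target) for m in members
                    ),
                    identity_class="convergent_same_site",
                    members=tuple(members),
                )
            )
    return events


def write_shared_table(events: list[SharedEvent]) -> pd.DataFrame:
    """One row per (event, species), grouped rows sharing an event id."""
    rows = []
    for eid, ev in enumerate(events):
        for species, aa in ev.per_species_aa:
            rows.append(
                {
                    "event_id": eid,
                    "gene": ev.gene,
                    "species": species,
                    "aa_target": aa,
                    "kind": ev.kind,
                    "ref_nt_pos": ev.ref_nt_pos,
                    "identity_class": ev.identity_class,
                }
            )
    columns = ["event_id", "gene", "species", "aa_target", "kind",
               "ref_nt_pos", "identity_class"]
    return pd.DataFrame(rows, columns=columns)
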