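"""Intron positions and phases, and their projection onto protein
alignments.

Intron phase is the number of CDS nucleotides 5' of the boundary mod 3:
phase 0 falls between codons, phases 1 and 2 interrupt a codon.  A
phase-1/2 boundary is assigned to the residue whose codon it interrupts;
a phase-0 boundary to the residue immediately following it.  Shared
boundaries between gene groups — the same alignment column AND the same
phase — are evidence of homologous gene structure (e.g. the boundary
cnidopsins share with bilaterian xenopsins).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .errors import GeneModelError
from .io_core import GeneModel


@dataclass
class IntronBoundary:
    gene_id: str
    intron_index: int          # 1-based, 5'->3'
    phase: int                 # {0, 1, 2}
    residue_index: int         # 1-based residue holding / following the boundary
    alignment_column: int | None = None  # 1-based, once projected

    def __post_init__(self) -> None:
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0/1/2, got {self.phase}")


def cds_intron_phases(model: GeneModel) -> list[IntronBoundary]:
    """One boundary per intron of a complete-CDS gene model, in order.

    Intronless models yield an empty list — the hallmark of duplication
    by retrotransposition.
    """
    if not model.complete or model.cds_length % 3 != 0:
        raise GeneModelError(f"{model.gene_id}: incomplete CDS; cannot compute phases")
    boundaries = []
    upstream = 0
    for i, (s, e) in enumerate(model.exons[:-1], start=1):
        upstream += e - s
        phase = upstream % 3
        # phase 1/2: the residue whose codon the boundary interrupts;
        # phase 0: the residue immediately following the boundary.
        residue = upstream // 3 + 1
        boundaries.append(
            IntronBoundary(gene_id=model.gene_id, intron_index=i, phase=phase,
                           residue_index=residue)
        )
    return boundaries


def project_to_alignment(
    boundaries: Sequence[IntronBoundary],
    aligned_row: str,
    protein: str | None = None,
) -> list[IntronBoundary]:
    """Attach alignment columns to boundaries using one gapped row.

    ``aligned_row`` is the gene's row of a protein alignment; its
    ungapped residues must equal the model's protein (checked when
    ``protein`` is given).  The returned boundaries carry 1-based
    alignment columns; inputs are not mutated.
    """
    ungapped = aligned_row.replace("-", "")
    if protein is not None and ungapped != protein:
        raise GeneModelError("aligned row does not match the model's protein")
    # residue index (1-based) -> column index (1-based)
    res_to_col: dict[int, int] = {}
    res = 0
    for col, ch in enumerate(aligned_row, start=1):
        if ch != "-":
            res += 1
            res_to_col[res] = col
    out = []
    for b in boundaries:
        if b.residue_index not in res_to_col:
            raise GeneModelError(
                f"{b.gene_id}: residue {b.residue_index} beyond aligned row "
                f"({len(ungapped)} residues)"
            )
        out.append(replace(b, alignment_column=res_to_col[b.residue_index]))
    return out


@dataclass
class SharedBoundary:
    alignment_column: int
    phase: int
    members_a: list[str]
    members_b: list[str]


def shared_boundaries(
    group_a: Iterable[Sequence[IntronBoundary]],
    group_b: Iterable[Sequence[IntronBoundary]],
    slop: int = 0,
) -> list[SharedBoundary]:
    """Boundaries shared between two gene groups on a common alignment.

    A shared boundary is an (alignment column, phase) pair present in at
    least one member of each group.  Column matching is exact by
    default; ``slop`` allows +/-N columns for noisy alignments (phases
    must still match exactly).
    """
    def collect(group):
        sites: dict[tuple[int, int], list[str]] = {}
        for boundary_set in group:
            for b in boundary_set:
                if b.alignment_column is None:
                    raise GeneModelError(
                        f"{b.gene_id}: boundary not projected to the alignment"
                    )
                sites.setdefault((b.alignment_column, b.phase), []).append(b.gene_id)
        return sites

    sites_a = collect(group_a)
    sites_b = collect(group_b)
    shared = []
    for (col, phase), members_a in sorted(sites_a.items()):
        members_b: list[str] = []
        for dc in range(-slop, slop + 1):
            members_b.extend(sites_b.get((col + dc, phase), []))
        if members_b:
            shared.append(
                SharedBoundary(alignment_column=col, phase=phase,
                               members_a=sorted(set(members_a)),
                               members_b=sorted(set(members_b)))
            )
    return shared
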