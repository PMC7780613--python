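"""Viability, 5-FOA counterselection, and an exhaustive single-deletion oracle.

A strain is viable when every strictly essential gene is present in at least
one copy -- on the chromosome or, when the episomal essential-gene array
(eArray) is carried, on the plasmid -- and the chromosome carries exactly one
centromere (zero is an acentric loss, two a lethal dicentric).  Loss of a
quasi-essential gene is viable but flags slow growth; loss of a gene tagged
for the active growth condition (e.g. 37C, YPG) flags a conditional defect.
5-FOA kills every cell that still carries the URA3 reporter, so plating on
5-FOA enriches for strains whose reporter-bearing LU was deleted.

Excised circles are discarded: they lack a centromere and are lost at
mitosis, so genes on them do not rescue viability.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_model import ESSENTIAL, QUASI, EArray, SyntheticChromosome
from .scramble_engine import (
    ChromosomeState,
    RecombinationEvent,
    Strain,
    apply_event,
    reference_state,
)

__all__ = [
    "ViabilityReport",
    "assess",
    "select_population",
    "enumerate_single_deletions",
]


@dataclass(frozen=True)
class ViabilityReport:
    viable: bool
    missing_essential: frozenset[str]
    centromere_count: int
    slow_growth: bool
    foa_resistant: bool
    conditional_defects: frozenset[str] = frozenset()


def _as_state(strain) -> ChromosomeState:
    return strain.state if isinstance(strain, Strain) else strain


def assess(strain, chrom: SyntheticChromosome, earray: EArray | None = None,
           condition: str = "YPD30") -> ViabilityReport:
    """Score one strain's genotype against the reference annotation.

    ``earray`` supplies episomal copies of its gene set when given.  A gene
    replaced by the URA3 reporter is physically absent even when its LU is
    retained.  A reference whose centromere lies outside the modeled region
    (``chrom.centromere is None``) always counts one centromere.
    """
    state = _as_state(strain)
    copies = state.lu_copies()
    present: set[str] = set()
    cen_count = 0
    for u in chrom.lus:
        c = copies.get(u.lu_id, 0)
        if c == 0:
            continue
        if u.has_centromere:
            cen_count += c
        present.update(g for g in u.gene_ids
                       if not chrom.genes[g].replaced_by_reporter)
    if earray is not None:
        present |= set(earray.gene_ids)
    if chrom.centromere is None:
        cen_count = 1

    missing_ess = frozenset(
        g.id for g in chrom.genes.values()
        if g.essentiality == ESSENTIAL and g.id not in present)
    slow = any(g.essentiality == QUASI and g.id not in present
               for g in chrom.genes.values())
    defects = frozenset(
        g.id for g in chrom.genes.values()
        if condition in g.conditional_tags and g.id not in present)
    ura_lu = chrom.markers.get("URA3")
    foa = ura_lu is None or copies.get(ura_lu, 0) == 0
    return ViabilityReport(
        viable=(not missing_ess) and cen_count == 1,
        missing_essential=missing_ess,
        centromere_count=cen_count,
        slow_growth=slow,
        foa_resistant=foa,
        conditional_defects=defects,
    )


def select_population(strains, chrom: SyntheticChromosome,
                      earray: EArray | None = None, medium: str = "5FOA",
                      condition: str = "YPD30") -> list:
    """Keep viable strains; on 5-FOA additionally require URA3 loss."""
    if medium not in ("5FOA", "SC", "YPD"):
        raise ValueError(f"unknown medium {medium!r}")
    survivors = []
    for s in strains:
        rep = assess(s, chrom, earray, condition)
        if not rep.viable:
            continue
        if medium == "5FOA" and not rep.foa_resistant:
            continue
        if isinstance(s, Strain):
            s.flags["slow_growth"] = rep.slow_growth
            if rep.conditional_defects:
                s.flags["conditional"] = sorted(rep.conditional_defects)
        survivors.append(s)
    return survivors


def enumerate_single_deletions(chrom: SyntheticChromosome,
                               earray: EArray | None = None,
                               require_5foa: bool = True
                               ) -> list[tuple[int, int, tuple[str, ...]]]:
    """Brute-force oracle: test every O(n^2) site pair as a single Cre
    deletion and return the pairs whose product is viable (and 5-FOA
    resistant when required), with the LU ids each pair deletes."""
    base = reference_state(chrom)
    out = []
    n = len(base.sites)
    for i in range(n - 1):
        for j in range(i + 1, n):
            child = apply_event(base, RecombinationEvent("deletion", i, j))
            rep = assess(child, chrom, earray)
            if rep.viable and (rep.foa_resistant or not require_5foa):
                deleted = tuple(lu for lu, _ in base.segments[i:j])
                out.append((i, j, deleted))
    return out
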