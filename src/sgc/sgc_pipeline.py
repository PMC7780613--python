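"""End-to-end orchestration of iterative SCRaMbLE-based genome compaction.

One round of SGC is: integrate the URA3 reporter into a chosen LU ->
induce Cre in a population of cells -> plate on 5-FOA (keep viable strains
that lost the reporter) -> profile survivors -> carry the strains with the
most deleted sequence into the next round.  The chosen strain's rearranged
chromosome becomes the next round's reference, and a compaction ledger
accumulates the deletions round over round.

"No colonies" is a first-class outcome, not an error: it diagnoses that the
genes in the reporter-bearing LU (or its undeletable neighborhood) are
required under the selection applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

from .genome_model import (
    ESSENTIAL,
    QUASI,
    EArray,
    Gene,
    LoxPsymSite,
    SyntheticChromosome,
    build_earray,
    emit_arm_sequence,
    integrate_ura3,
    lu_sequence,
    segment_lus,
)
from .hic_proximity import CidSegmentation, ContactMatrix, weights_for_sites
from .lu_profiler import (
    CompactionLedger,
    RoundResult,
    compaction_stats,
    profile_from_state,
    update_ledger,
)
from .scramble_engine import (
    DEFAULT_LAMBDA,
    DEFAULT_TYPE_PROBS,
    site_positions,
    site_ref_positions,
    simulate_population,
)
from .selection import select_population

__all__ = [
    "RoundConfig",
    "RoundOutcome",
    "default_round_config",
    "rank_ura3_sites",
    "derive_round_reference",
    "run_round",
    "run_iterative",
]

log = logging.getLogger("sgc")

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass(frozen=True)
class RoundConfig:
    round_id: str
    ura3_lu: str
    ura3_mode: str = "chunk_split"
    ura3_args: dict = field(default_factory=dict)
    earray: bool = False
    earray_cutoff: int = 140_000
    n_cells: int = 10_000
    lambda_events: float = DEFAULT_LAMBDA
    weight_model: str = "power_law"   # power_law | cid_boost | hic_contact | uniform
    weight_params: dict = field(default_factory=dict)
    type_probs: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_PROBS))
    medium: str = "5FOA"
    top_k: int = 1
    seed: int = 0


def default_round_config(round_id: str, ura3_lu: str, **kw) -> RoundConfig:
    return RoundConfig(round_id=round_id, ura3_lu=ura3_lu, **kw)


@dataclass
class RoundOutcome:
    round_id: str
    reference: SyntheticChromosome        # the round's URA3-integrated reference
    survivors: list
    profiles: dict
    stats: dict
    chosen: list
    result: RoundResult | None
    no_colonies: bool = False
    message: str = ""


# ---------------------------------------------------------------------------
# URA3 site ranking
# ---------------------------------------------------------------------------

def rank_ura3_sites(chrom: SyntheticChromosome,
                    cids: CidSegmentation | None = None) -> list[str]:
    """Candidate LUs for reporter integration, best first.

    Candidates carry no essential or quasi-essential gene and no centromere
    (their loss must not cost robust growth).  With a CID segmentation they
    are ranked by the bp span of the containing domain -- a reporter inside a
    long domain lets a single synapsis delete more sequence; otherwise by the
    bp span of the surrounding run of candidate LUs.
    """
    def deletable(u):
        return (not u.has_centromere
                and all(chrom.genes[g].essentiality not in (ESSENTIAL, QUASI)
                        for g in u.gene_ids))

    cands = [u for u in chrom.lus if deletable(u)]
    if not cands:
        raise ValueError("no deletable LU available for URA3 integration")

    if cids is not None:
        def span(u):
            k = cids.domain_of_bp((u.start + u.end) // 2)
            return 0 if k is None else cids.domain_span_bp(k)
    else:
        runs: dict[str, int] = {}
        block: list = []
        for u in chrom.lus:
            if deletable(u):
                block.append(u)
            else:
                for b in block:
                    runs[b.lu_id] = block[-1].end - block[0].start
                block = []
        for b in block:
            runs[b.lu_id] = block[-1].end - block[0].start

        def span(u):
            return runs.get(u.lu_id, 0)

    order = {u.lu_id: k for k, u in enumerate(chrom.lus)}
    return [u.lu_id for u in
            sorted(cands, key=lambda u: (-span(u), order[u.lu_id]))]


# ---------------------------------------------------------------------------
# Deriving a new reference from a rearranged strain
# ---------------------------------------------------------------------------

def derive_round_reference(chrom: SyntheticChromosome, state,
                           name: str | None = None) -> SyntheticChromosome:
    """Linearize a strain's rearranged chromosome into a fresh reference.

    Surviving segments become the new LU table in their current order (ids
    retained; extra copies of a duplicated unit get a ``~n`` suffix), gene
    coordinates are remapped (and strands flipped inside inverted units),
    and the sequence -- when present -- is re-emitted accordingly.
    """
    genes: dict[str, Gene] = {}
    positions = [0]
    names: list[str] = []
    centromere = None
    lu_seqs: list[str] = []
    seen: dict[str, int] = {}
    for lu_id, orient in state.segments:
        u = chrom.lu(lu_id)
        seen[lu_id] = seen.get(lu_id, 0) + 1
        new_id = lu_id if seen[lu_id] == 1 else f"{lu_id}~{seen[lu_id]}"
        start = positions[-1]
        for gid in u.gene_ids:
            g = chrom.genes[gid]
            if orient > 0:
                ns = start + (g.start - u.start)
                strand = g.strand
            else:
                ns = start + (u.end - g.end)
                strand = "-" if g.strand == "+" else "+"
            ngid = gid if gid not in genes else f"{gid}~{seen[lu_id]}"
            genes[ngid] = dc_replace(g, id=ngid, start=ns, end=ns + g.length,
                                     strand=strand)
        if u.has_centromere and centromere is None:
            c0, c1 = chrom.centromere
            if orient > 0:
                centromere = (start + (c0 - u.start), start + (c1 - u.start))
            else:
                centromere = (start + (u.end - c1), start + (u.end - c0))
        if chrom.sequence is not None:
            s = lu_sequence(chrom, lu_id)
            lu_seqs.append(s if orient > 0 else s.translate(_COMP)[::-1])
        positions.append(start + u.length_bp)
        names.append(new_id)
    sites = tuple(LoxPsymSite(i, p) for i, p in enumerate(positions))
    lus = segment_lus(positions, (0, positions[-1]), genes, centromere,
                      names=names)
    return SyntheticChromosome(
        name=name or f"{chrom.name}+",
        region_start=0, region_end=positions[-1], genes=genes, sites=sites,
        lus=lus, centromere=centromere, markers={},
        sequence=emit_arm_sequence(lu_seqs) if chrom.sequence is not None
        else None,
    )


# ---------------------------------------------------------------------------
# One SGC round
# ---------------------------------------------------------------------------

def _weight_fn_for(chrom, config, matrix, cids):
    model = config.weight_model
    if model == "uniform":
        return None

    def fn(state):
        return weights_for_sites(
            site_positions(chrom, state), model=model,
            params=config.weight_params, matrix=matrix, cids=cids,
            ref_positions=site_ref_positions(chrom, state),
        ).matrix

    return fn


def run_round(chrom: SyntheticChromosome, config: RoundConfig,
              earray: EArray | None = None,
              matrix: ContactMatrix | None = None,
              cids: CidSegmentation | None = None) -> RoundOutcome:
    """Integrate URA3, SCRaMbLE a population, select, profile, and rank."""
    target, mode, args = config.ura3_lu, config.ura3_mode, config.ura3_args
    if not any(u.lu_id == target for u in chrom.lus):
        # the configured LU was lost in an earlier round: integrate into the
        # best-ranked retained candidate instead
        target = rank_ura3_sites(chrom)[0]
        mode, args = "chunk_split", {}
        log.warning("round %s: %s no longer present; integrating URA3 into %s",
                    config.round_id, config.ura3_lu, target)
    integrated = integrate_ura3(chrom, target, mode, **args)
    if config.earray and earray is None:
        earray = build_earray(integrated, config.earray_cutoff)
    ea = earray if config.earray else None
    episomes = frozenset({"eArray"}) if config.earray else frozenset()

    strains = simulate_population(
        integrated, config.n_cells, config.lambda_events,
        weight_fn=_weight_fn_for(integrated, config, matrix, cids),
        type_probs=config.type_probs, seed=config.seed, episomes=episomes)
    survivors = select_population(strains, integrated, ea,
                                  medium=config.medium)
    if not survivors:
        msg = ("no colonies: genes in the URA3-integrated LU (or its "
               "undeletable neighborhood) are required under this selection")
        log.info("round %s: simulated %d cells, no survivors", config.round_id,
                 config.n_cells)
        return RoundOutcome(config.round_id, integrated, [], {}, {}, [], None,
                            no_colonies=True, message=msg)

    profiles = {s.id: profile_from_state(integrated, s.state, s.id)
                for s in survivors}
    stats = {sid: compaction_stats(p, integrated)
             for sid, p in profiles.items()}

    def sort_key(s):
        non_del = sum(1 for e in s.events if e.type != "deletion")
        return (-stats[s.id]["bp_deleted"], non_del, s.id)

    chosen = sorted(survivors, key=sort_key)[:config.top_k]
    best = chosen[0]
    deleted = {
        lu: (integrated.lu(lu).length_bp, len(integrated.lu(lu).gene_ids))
        for lu in profiles[best.id].deleted_lus()
    }
    result = RoundResult(round_id=config.round_id, strain_id=best.id,
                         deleted=deleted)
    log.info(
        "round %s: simulated %d, survivors %d, best %s: %d LUs / %d bp / %d "
        "genes deleted", config.round_id, config.n_cells, len(survivors),
        best.id, stats[best.id]["n_lus_deleted"], stats[best.id]["bp_deleted"],
        stats[best.id]["n_genes_deleted"])
    return RoundOutcome(config.round_id, integrated, survivors, profiles,
                        stats, chosen, result)


def run_iterative(chrom: SyntheticChromosome, rounds,
                  matrix: ContactMatrix | None = None,
                  cids: CidSegmentation | None = None):
    """Run scripted SGC rounds, each starting from the previous round's best
    strain; returns ``(ledger, outcomes)``.  Stops early on "no colonies".

    Contact-map-informed weight models use reference-coordinate lookups and
    are therefore only offered to the first round (the map no longer
    describes a rearranged chromosome); later rounds fall back to the
    distance-decay model if configured with a contact-based one.
    """
    if not rounds:
        raise ValueError("need at least one round")
    ledger = CompactionLedger.from_chromosome(chrom)
    earray = None
    current = chrom
    outcomes = []
    for k, cfg in enumerate(rounds):
        use_matrix, use_cids = (matrix, cids) if k == 0 else (None, None)
        if k > 0 and cfg.weight_model in ("cid_boost", "hic_contact"):
            cfg = dc_replace(cfg, weight_model="power_law")
        if cfg.earray and earray is None:
            # the eArray is assembled once, from the original arm annotation
            earray = build_earray(chrom, cfg.earray_cutoff)
        outcome = run_round(current, cfg, earray=earray, matrix=use_matrix,
                            cids=use_cids)
        outcomes.append(outcome)
        if outcome.no_colonies:
            break
        update_ledger(ledger, outcome.result)
        current = derive_round_reference(outcome.reference,
                                         outcome.chosen[0].state,
                                         name=f"{chrom.name}.{cfg.round_id}")
    return ledger, outcomes
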