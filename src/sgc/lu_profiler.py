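"""LU-level profiling of rearranged strains, in-silico PCRtag screening, and
compaction bookkeeping.

After SCRaMbLE a strain's chromosome is summarized as an *LU profile*: per
reference LU the copy number and whether any copy is inverted, plus the
maximal contiguous deleted reference ranges.  Profiles can be derived either
by replaying the strain's event log or by exact tiling of an error-free
assembled contig with the reference LU sequences -- the two routes must
agree on simulated data.

PCRtags are short primer pairs recoded into the synthetic sequence; an
amplicon is expected exactly when the tag's LU is present, which makes a tag
panel a cheap deletion screen (LUs without tags fall back to sequence or
event profiling, as in the wet workflow).

The CompactionLedger accumulates the per-round deletion bookkeeping of
iterative compaction: LUs, base pairs and genes deleted per round, and the
cumulative retained totals.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .genome_model import LOXPSYM_SEQ, SyntheticChromosome, lu_sequence
from .scramble_engine import ChromosomeState, apply_events, reference_state

__all__ = [
    "LuProfile",
    "PcrTag",
    "CompactionLedger",
    "RoundResult",
    "profile_from_state",
    "profile_from_events",
    "profile_from_sequence",
    "emit_contig",
    "default_pcrtags",
    "insilico_pcrtag",
    "compaction_stats",
    "update_ledger",
]

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass(frozen=True)
class LuProfile:
    strain_id: str
    status: dict          # lu_id -> {"copies": int, "inverted": bool}
    deleted_segments: tuple[tuple[int, int], ...]  # merged ref bp ranges

    def deleted_lus(self) -> tuple[str, ...]:
        return tuple(lu for lu, st in self.status.items() if st["copies"] == 0)


@dataclass(frozen=True)
class PcrTag:
    lu_id: str
    forward: str | None = None   # primer on the + strand
    reverse: str | None = None   # primer on the - strand (as written 5'->3')
    max_amplicon_bp: int = 20000


def _profile(chrom: SyntheticChromosome, copies: dict, inverted: set,
             strain_id: str) -> LuProfile:
    status = {
        u.lu_id: {"copies": copies.get(u.lu_id, 0),
                  "inverted": u.lu_id in inverted}
        for u in chrom.lus
    }
    segments, run = [], None
    for u in chrom.lus:
        if status[u.lu_id]["copies"] == 0:
            run = [u.start, u.end] if run is None else [run[0], u.end]
        elif run is not None:
            segments.append(tuple(run))
            run = None
    if run is not None:
        segments.append(tuple(run))
    return LuProfile(strain_id=strain_id, status=status,
                     deleted_segments=tuple(segments))


def profile_from_state(chrom: SyntheticChromosome, state: ChromosomeState,
                       strain_id: str = "strain") -> LuProfile:
    copies = state.lu_copies()
    inverted = {lu for lu, o in state.segments if o < 0}
    return _profile(chrom, copies, inverted, strain_id)


def profile_from_events(chrom: SyntheticChromosome, events,
                        strain_id: str = "strain") -> LuProfile:
    """Replay an event log from the reference and profile the result."""
    state = apply_events(reference_state(chrom), events)
    return profile_from_state(chrom, state, strain_id)


# ---------------------------------------------------------------------------
# Sequence-mode profiling (error-free simulated contigs)
# ---------------------------------------------------------------------------

def emit_contig(chrom: SyntheticChromosome, state: ChromosomeState) -> str:
    """Emit the rearranged chromosome's sequence: signed LU sequences joined
    by loxPsym 34-mers, sites flanking both ends."""
    if not state.segments:
        return LOXPSYM_SEQ  # everything deleted: one hybrid site remains
    parts = []
    for lu, orient in state.segments:
        s = lu_sequence(chrom, lu)
        parts.append(s if orient > 0 else _revcomp(s))
    return LOXPSYM_SEQ + LOXPSYM_SEQ.join(parts) + LOXPSYM_SEQ


def profile_from_sequence(chrom: SyntheticChromosome, contig: str,
                          strain_id: str = "strain") -> LuProfile:
    """Greedy left-to-right exact tiling of ``contig`` by reference LU
    sequences (both orientations) separated by loxPsym 34-mers."""
    if chrom.sequence is None:
        raise ValueError("reference carries no sequence")
    lut = {}
    for u in chrom.lus:
        s = lu_sequence(chrom, u.lu_id)
        lut[u.lu_id] = (s, _revcomp(s))
    L = len(LOXPSYM_SEQ)
    if not contig.startswith(LOXPSYM_SEQ):
        raise ValueError("unrecognized sequence: contig must begin at a loxPsym site")
    pos = L
    copies: dict[str, int] = {}
    inverted: set[str] = set()
    while pos < len(contig):
        hit = None
        for lu_id, (fwd, rev) in lut.items():
            if contig.startswith(fwd, pos):
                hit = (lu_id, False, len(fwd))
                break
            if fwd != rev and contig.startswith(rev, pos):
                hit = (lu_id, True, len(rev))
                break
        if hit is None:
            raise ValueError(f"unrecognized sequence at contig offset {pos}")
        lu_id, inv, ln = hit
        copies[lu_id] = copies.get(lu_id, 0) + 1
        if inv:
            inverted.add(lu_id)
        pos += ln
        if not contig.startswith(LOXPSYM_SEQ, pos):
            raise ValueError(f"missing loxPsym junction at contig offset {pos}")
        pos += L
    return _profile(chrom, copies, inverted, strain_id)


# ---------------------------------------------------------------------------
# In-silico PCRtag screening
# ---------------------------------------------------------------------------

def default_pcrtags(chrom: SyntheticChromosome, primer_bp: int = 20,
                    min_lu_bp: int = 300) -> list[PcrTag]:
    """One tag per LU large enough to host a primer pair.  Shorter LUs get
    no tag, mirroring the real panel where some units lack PCRtags."""
    tags = []
    for u in chrom.lus:
        if u.length_bp < min_lu_bp:
            continue
        s = lu_sequence(chrom, u.lu_id)
        tags.append(PcrTag(
            lu_id=u.lu_id,
            forward=s[10:10 + primer_bp],
            reverse=_revcomp(s[-(10 + primer_bp):-10]),
            max_amplicon_bp=u.length_bp,
        ))
    return tags


def _amplifies(molecule: str, tag: PcrTag) -> bool:
    fwd, rc_rev = tag.forward, _revcomp(tag.reverse)
    for strand in (molecule, _revcomp(molecule)):
        start = strand.find(fwd)
        while start != -1:
            hit = strand.find(rc_rev, start + len(fwd))
            if hit != -1 and hit + len(rc_rev) - start <= tag.max_amplicon_bp:
                return True
            start = strand.find(fwd, start + 1)
    return False


def insilico_pcrtag(target, tags, chrom: SyntheticChromosome | None = None
                    ) -> dict[str, bool]:
    """Presence table {lu_id: amplicon expected}.

    ``target`` may be an LuProfile (tag positive iff its LU is present in at
    least one copy) or a contig string (tag positive iff both primers are
    found convergent on one molecule within the amplicon limit).
    """
    if isinstance(target, LuProfile):
        known = set(target.status)
        for t in tags:
            if t.lu_id not in known:
                raise KeyError(f"PCRtag references unknown LU {t.lu_id}")
        return {t.lu_id: target.status[t.lu_id]["copies"] >= 1 for t in tags}
    if isinstance(target, str):
        for t in tags:
            if t.forward is None or t.reverse is None:
                raise ValueError(f"tag for {t.lu_id} lacks primer sequences")
        return {t.lu_id: _amplifies(target, t) for t in tags}
    raise TypeError("target must be an LuProfile or a contig string")


# ---------------------------------------------------------------------------
# Compaction statistics and ledger
# ---------------------------------------------------------------------------

def compaction_stats(profile: LuProfile, chrom: SyntheticChromosome) -> dict:
    """Per-strain deletion statistics against the reference LU table.

    ``bp_deleted`` sums reference LU lengths (loxPsym sites excluded by
    convention); genes are counted by reference LU content, so a gene
    replaced by the URA3 reporter still counts when its LU is lost, while
    the reporter itself never does.
    """
    deleted = set(profile.deleted_lus())
    n_genes = sum(len(u.gene_ids) for u in chrom.lus if u.lu_id in deleted)
    bp = sum(u.length_bp for u in chrom.lus if u.lu_id in deleted)
    return {"n_lus_deleted": len(deleted), "bp_deleted": bp,
            "n_genes_deleted": n_genes}


_SUBLU = re.compile(r"^(?P<parent>.*?)(?:-[a-c])?(?:~\d+)?$")


def parent_lu(lu_id: str) -> str:
    """Collapse split ("-a/-b/-c") and duplicated ("~n") unit ids onto the
    original reference LU id."""
    return _SUBLU.match(lu_id).group("parent")


@dataclass(frozen=True)
class RoundResult:
    """One compaction round's deletions: unit id -> (bp, n_genes)."""
    round_id: str
    strain_id: str
    deleted: dict


@dataclass
class CompactionLedger:
    total_lus: int
    total_bp: int
    total_genes: int
    lu_lengths: dict = field(default_factory=dict)   # original id -> bp
    rounds: list = field(default_factory=list)
    _deleted_bp_by_parent: dict = field(default_factory=dict)
    _deleted_ids: set = field(default_factory=set)

    @classmethod
    def from_chromosome(cls, chrom: SyntheticChromosome) -> "CompactionLedger":
        return cls(
            total_lus=len(chrom.lus),
            total_bp=chrom.region_length,
            total_genes=len(chrom.genes),
            lu_lengths={u.lu_id: u.length_bp for u in chrom.lus},
        )

    # -- cumulative views ----------------------------------------------------
    @property
    def deleted_bp(self) -> int:
        return sum(bp for r in self.rounds for bp, _ in r.deleted.values())

    @property
    def deleted_genes(self) -> int:
        return sum(g for r in self.rounds for _, g in r.deleted.values())

    @property
    def deleted_lu_count(self) -> int:
        """Original LUs wholly deleted (a split unit counts only once all of
        its parts are gone)."""
        count = 0
        for parent, bp in self._deleted_bp_by_parent.items():
            full = self.lu_lengths.get(parent)
            count += 1 if (full is None and bp > 0) or (full is not None
                                                        and bp >= full) else 0
        return count

    @property
    def retained_lus(self) -> int:
        return self.total_lus - self.deleted_lu_count

    @property
    def retained_bp(self) -> int:
        return self.total_bp - self.deleted_bp

    @property
    def retained_genes(self) -> int:
        return self.total_genes - self.deleted_genes

    def to_dict(self) -> dict:
        return {
            "rounds": [
                {"round_id": r.round_id, "strain": r.strain_id,
                 "lus_deleted": sorted(r.deleted),
                 "n_lus_deleted": len(r.deleted),
                 "bp_deleted": sum(bp for bp, _ in r.deleted.values()),
                 "genes_deleted": sum(g for _, g in r.deleted.values())}
                for r in self.rounds
            ],
            "cumulative": {"retained_lus": self.retained_lus,
                           "retained_bp": self.retained_bp,
                           "retained_genes": self.retained_genes,
                           "deleted_bp": self.deleted_bp},
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_tsv(self) -> str:
        lines = ["round_id\tstrain\tn_lus_deleted\tbp_deleted\tgenes_deleted"
                 "\tretained_bp"]
        running = self.total_bp
        for r in self.rounds:
            bp = sum(b for b, _ in r.deleted.values())
            running -= bp
            lines.append(f"{r.round_id}\t{r.strain_id}\t{len(r.deleted)}"
                         f"\t{bp}\t{sum(g for _, g in r.deleted.values())}"
                         f"\t{running}")
        return "\n".join(lines) + "\n"


def update_ledger(ledger: CompactionLedger, result: RoundResult
                  ) -> CompactionLedger:
    """Append one round; rounds must not re-delete a previously deleted unit."""
    overlap = set(result.deleted) & ledger._deleted_ids
    if overlap:
        raise ValueError(f"round {result.round_id} re-deletes {sorted(overlap)}")
    for lu_id, (bp, _) in result.deleted.items():
        p = parent_lu(lu_id)
        ledger._deleted_bp_by_parent[p] = \
            ledger._deleted_bp_by_parent.get(p, 0) + bp
    ledger._deleted_ids |= set(result.deleted)
    ledger.rounds.append(result)
    if ledger.retained_bp < 0:
        raise ValueError("deleted more bp than the reference contains")
    return ledger
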