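"""Reference data model for a loxPsym-segmented synthetic chromosome arm.

A synthetic Sc2.0-style chromosome arm carries loxPsym recombination sites
3 bp downstream of the stop codon of nonessential genes.  The sequence
between two adjacent sites is one *loxPsym unit* (LU) -- the atomic segment
that Cre-mediated SCRaMbLE can delete, invert or duplicate.  This module
parses/writes arm annotations, tiles the arm into LUs, integrates the URA3
counterselection reporter, and derives the episomal essential-gene array
(eArray) content from the annotation.

Coordinates are 0-based half-open throughout; GFF3 I/O converts to/from the
1-based closed convention.  loxPsym sites are 34 bp in sequence space but are
treated as zero-width points for LU length accounting, so LU lengths tile the
declared synthetic region exactly.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "LOXPSYM_SEQ",
    "AnnotationError",
    "Gene",
    "LoxPsymSite",
    "LoxPsymUnit",
    "SyntheticChromosome",
    "EArray",
    "segment_lus",
    "lu_stats",
    "integrate_ura3",
    "default_chunk_split_offsets",
    "build_earray",
    "load_annotation",
    "write_annotation",
    "lu_sequence",
    "emit_arm_sequence",
]

#: The 34 bp symmetric loxPsym site: 13 bp inverted repeats around a
#: palindromic 8 bp spacer, hence no orientation constraint on recombination.
LOXPSYM_SEQ = "ATAACTTCGTATA" + "ATGTACAT" + "TATACGAAGTTAT"

ESSENTIAL = "essential"
QUASI = "quasi_essential"
NONESSENTIAL = "nonessential"
_CLASSES = (ESSENTIAL, QUASI, NONESSENTIAL)


class AnnotationError(ValueError):
    """Malformed or inconsistent chromosome annotation."""


@dataclass(frozen=True)
class Gene:
    id: str
    start: int
    end: int
    strand: str = "+"
    essentiality: str = NONESSENTIAL
    conditional_tags: frozenset[str] = frozenset()
    replaced_by_reporter: bool = False

    def __post_init__(self):
        if not self.start < self.end:
            raise AnnotationError(f"gene {self.id}: empty/inverted interval")
        if self.essentiality not in _CLASSES:
            raise AnnotationError(
                f"gene {self.id}: unknown essentiality {self.essentiality!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LoxPsymSite:
    index: int
    position: int  # between-base coordinate on the reference arm


@dataclass(frozen=True)
class LoxPsymUnit:
    lu_id: str
    start: int
    end: int
    gene_ids: tuple[str, ...] = ()
    has_essential: bool = False   # contains an essential OR quasi-essential gene
    has_centromere: bool = False

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class EArray:
    """Episomal essential-gene array: a loxPsym-free centromeric plasmid.

    ``loci`` are (label, start, end, gene ids) tuples in reference
    coordinates; the plasmid is selected on SC-His (HIS3 marker).
    """

    gene_ids: frozenset[str]
    loci: tuple[tuple[str, int, int, tuple[str, ...]], ...]
    marker: str = "HIS3"
    contains_loxpsym: bool = False


@dataclass(frozen=True)
class SyntheticChromosome:
    name: str
    region_start: int
    region_end: int
    genes: dict[str, Gene]
    sites: tuple[LoxPsymSite, ...]
    lus: tuple[LoxPsymUnit, ...]
    centromere: tuple[int, int] | None = None
    markers: dict[str, str] = field(default_factory=dict)
    sequence: str | None = None  # emitted arm sequence incl. 34 bp sites

    def __post_init__(self):
        _validate(self)

    # -- convenience lookups -------------------------------------------------
    def lu(self, lu_id: str) -> LoxPsymUnit:
        for u in self.lus:
            if u.lu_id == lu_id:
                return u
        raise KeyError(f"no such LU: {lu_id}")

    def lu_index(self, lu_id: str) -> int:
        for k, u in enumerate(self.lus):
            if u.lu_id == lu_id:
                return k
        raise KeyError(f"no such LU: {lu_id}")

    def lu_of_gene(self, gene_id: str) -> LoxPsymUnit:
        for u in self.lus:
            if gene_id in u.gene_ids:
                return u
        raise KeyError(f"gene {gene_id} not assigned to any LU")

    def genes_in_lu(self, lu_id: str) -> tuple[Gene, ...]:
        return tuple(self.genes[g] for g in self.lu(lu_id).gene_ids)

    def essential_gene_ids(self, include_quasi: bool = False) -> frozenset[str]:
        keep = {ESSENTIAL, QUASI} if include_quasi else {ESSENTIAL}
        return frozenset(g.id for g in self.genes.values() if g.essentiality in keep)

    @property
    def region_length(self) -> int:
        return self.region_end - self.region_start


def _validate(chrom: SyntheticChromosome) -> None:
    sites = chrom.sites
    if len(sites) < 2:
        raise AnnotationError("need at least 2 loxPsym sites")
    pos = [s.position for s in sites]
    if pos != sorted(pos) or len(set(pos)) != len(pos):
        raise AnnotationError("loxPsym site positions must be strictly increasing")
    if len(chrom.lus) != len(sites) - 1:
        raise AnnotationError("LU count must equal site count - 1")
    # LUs tile the region without gaps or overlap
    cursor = chrom.region_start
    for u in chrom.lus:
        if u.start != cursor:
            raise AnnotationError(f"LU table does not tile the region at {u.lu_id}")
        if u.length_bp <= 0:
            raise AnnotationError(f"{u.lu_id}: non-positive length")
        cursor = u.end
    if cursor != chrom.region_end:
        raise AnnotationError("LU table does not reach the region end")
    # every gene wholly inside exactly one LU
    assigned: dict[str, str] = {}
    for u in chrom.lus:
        for gid in u.gene_ids:
            if gid in assigned:
                raise AnnotationError(f"gene {gid} assigned to two LUs")
            assigned[gid] = u.lu_id
            g = chrom.genes[gid]
            if not (u.start <= g.start and g.end <= u.end):
                raise AnnotationError(
                    f"gene {gid} crosses a loxPsym site (not inside {u.lu_id})"
                )
    for gid in chrom.genes:
        if gid not in assigned:
            raise AnnotationError(f"gene {gid} not contained in any LU")
    if chrom.centromere is not None:
        c0, c1 = chrom.centromere
        holders = [u for u in chrom.lus if u.start <= c0 and c1 <= u.end]
        if len(holders) != 1:
            raise AnnotationError("centromere must lie wholly inside exactly one LU")
        if not all(u.has_centromere == (u in holders) for u in chrom.lus):
            raise AnnotationError("has_centromere flags inconsistent with interval")


# ---------------------------------------------------------------------------
# LU segmentation
# ---------------------------------------------------------------------------

def segment_lus(
    sites: "list[LoxPsymSite] | list[int]",
    region: tuple[int, int],
    genes: "dict[str, Gene] | list[Gene]",
    centromere: tuple[int, int] | None = None,
    names: list[str] | None = None,
) -> tuple[LoxPsymUnit, ...]:
    """Tile ``region`` into loxPsym units between adjacent sites.

    ``sites`` must include the two region boundaries, so n sites yield n-1
    units.  Each unit is annotated with the genes it wholly contains, an
    essential flag (essential or quasi-essential gene present) and a
    centromere flag.  A gene overlapping a site is an error.
    """
    pos = [s.position if isinstance(s, LoxPsymSite) else int(s) for s in sites]
    if pos != sorted(pos) or len(set(pos)) != len(pos):
        raise AnnotationError("sites must be sorted and unique")
    if len(pos) < 2:
        raise AnnotationError("need at least 2 sites")
    if pos[0] != region[0] or pos[-1] != region[1]:
        raise AnnotationError("sites must include both region boundaries")
    gene_list = list(genes.values()) if isinstance(genes, dict) else list(genes)
    if names is not None and len(names) != len(pos) - 1:
        raise AnnotationError("names length must equal LU count")

    units = []
    for k in range(len(pos) - 1):
        lo, hi = pos[k], pos[k + 1]
        inside = sorted(
            (g for g in gene_list if lo <= g.start and g.end <= hi),
            key=lambda g: g.start,
        )
        for g in gene_list:
            if g.start < hi and g.end > lo and not (lo <= g.start and g.end <= hi):
                raise AnnotationError(
                    f"gene {g.id} crosses the loxPsym site at "
                    f"{hi if g.start > lo else lo}")
        has_ess = any(g.essentiality in (ESSENTIAL, QUASI) for g in inside)
        has_cen = centromere is not None and lo <= centromere[0] and centromere[1] <= hi
        units.append(
            LoxPsymUnit(
                lu_id=names[k] if names else f"LU-{k + 1}",
                start=lo,
                end=hi,
                gene_ids=tuple(g.id for g in inside),
                has_essential=has_ess,
                has_centromere=has_cen,
            )
        )
    return tuple(units)


def lu_stats(chrom: SyntheticChromosome) -> dict:
    """Summary statistics of the LU table.

    Quasi-essential genes count toward the essential-LU flag but are reported
    inside ``n_nonessential`` (the arm's published 81 = 16 + 65 accounting,
    where the two quasi-essential genes sit in the nonessential column).
    """
    genes = list(chrom.genes.values())
    n_ess = sum(g.essentiality == ESSENTIAL for g in genes)
    return {
        "n_lus": len(chrom.lus),
        "n_essential_lus": sum(u.has_essential for u in chrom.lus),
        "n_genes": len(genes),
        "n_essential": n_ess,
        "n_nonessential": len(genes) - n_ess,
        "min_lu_bp": min(u.length_bp for u in chrom.lus),
        "max_lu_bp": max(u.length_bp for u in chrom.lus),
        "max_genes_per_lu": max(len(u.gene_ids) for u in chrom.lus),
        "total_synthetic_bp": chrom.region_length,
    }


# ---------------------------------------------------------------------------
# URA3 reporter integration
# ---------------------------------------------------------------------------

def default_chunk_split_offsets(chrom: SyntheticChromosome, lu_id: str,
                                middle_bp: int = 400) -> tuple[int, int]:
    """Offsets (relative to the LU start) for a chunk-split URA3 integration.

    The two new loxPsym sites are placed in the gene-free tail of the LU so
    that the middle sub-unit (which receives URA3) is ``middle_bp`` wide and
    no gene is cut.
    """
    u = chrom.lu(lu_id)
    tail = max((chrom.genes[g].end for g in u.gene_ids), default=u.start) - u.start
    free = u.length_bp - tail
    if free < 120:
        raise AnnotationError(f"{lu_id}: no room for a chunk-split integration")
    o1 = tail + (free - min(middle_bp, free - 80)) // 2
    o2 = o1 + min(middle_bp, free - 80)
    return o1, o2


def integrate_ura3(chrom: SyntheticChromosome, target_lu: str, mode: str,
                   gene_id: str | None = None,
                   between: tuple[str, str] | None = None,
                   offsets: tuple[int, int] | None = None) -> SyntheticChromosome:
    """Integrate the URA3 counterselection reporter into ``target_lu``.

    Modes
    -----
    ``replace_gene``
        Replace a nonessential gene of the LU by URA3.  The gene is flagged
        ``replaced_by_reporter`` (it still counts in reference gene tallies
        when its LU is later lost, the reporter itself never does).
    ``insert_between``
        Insert URA3 intergenically between two named genes of the LU.
    ``chunk_split``
        Integration construct carries two extra loxPsym sites, splitting the
        LU into "-a"/"-b"/"-c" sub-units with URA3 in the middle one.
    """
    u = chrom.lu(target_lu)
    markers = dict(chrom.markers)

    if mode == "replace_gene":
        if gene_id is None or gene_id not in u.gene_ids:
            raise AnnotationError(f"replace_gene: gene must lie inside {target_lu}")
        g = chrom.genes[gene_id]
        if g.essentiality == ESSENTIAL:
            raise AnnotationError(f"cannot replace essential gene {gene_id}")
        genes = dict(chrom.genes)
        genes[gene_id] = replace(g, replaced_by_reporter=True)
        markers["URA3"] = target_lu
        return replace(chrom, genes=genes, markers=markers)

    if mode == "insert_between":
        if between is None:
            raise AnnotationError("insert_between requires a gene pair")
        a, b = between
        if a not in u.gene_ids or b not in u.gene_ids:
            raise AnnotationError(f"insert_between: both genes must be in {target_lu}")
        markers["URA3"] = target_lu
        return replace(chrom, markers=markers)

    if mode == "chunk_split":
        if offsets is None:
            offsets = default_chunk_split_offsets(chrom, target_lu)
        o1, o2 = sorted(offsets)
        if not (0 < o1 < o2 < u.length_bp):
            raise AnnotationError(f"chunk_split offsets outside {target_lu}")
        p1, p2 = u.start + o1, u.start + o2
        for g in (chrom.genes[g] for g in u.gene_ids):
            if g.start < p1 < g.end or g.start < p2 < g.end:
                raise AnnotationError(f"chunk_split offset cuts gene {g.id}")
        new_pos, new_names = [], []
        for k, old in enumerate(chrom.lus):
            new_pos.append(old.start)
            if old.lu_id == target_lu:
                new_pos.extend([p1, p2])
                new_names.extend([f"{target_lu}-a", f"{target_lu}-b", f"{target_lu}-c"])
            else:
                new_names.append(old.lu_id)
        new_pos.append(chrom.region_end)
        sites = tuple(LoxPsymSite(i, p) for i, p in enumerate(new_pos))
        lus = segment_lus(list(new_pos), (chrom.region_start, chrom.region_end),
                          chrom.genes, chrom.centromere, names=new_names)
        markers["URA3"] = f"{target_lu}-b"
        seq = chrom.sequence
        if seq is not None:
            seq = _reemit_sequence(chrom, sites)
        return replace(chrom, sites=sites, lus=lus, markers=markers, sequence=seq)

    raise AnnotationError(f"unknown URA3 integration mode {mode!r}")


# ---------------------------------------------------------------------------
# eArray construction
# ---------------------------------------------------------------------------

def build_earray(chrom: SyntheticChromosome, region_cutoff_bp: int) -> EArray:
    """Group the essential genes starting before ``region_cutoff_bp`` into loci.

    A locus is a maximal run of essential genes uninterrupted by a
    nonessential coding sequence; its interval runs from the inner boundary of
    the nearest upstream nonessential CDS to that of the nearest downstream
    one (clamped to the containing LU so the copied fragment carries no
    loxPsym site).  Overlapping loci are merged.
    """
    if not (chrom.region_start <= region_cutoff_bp <= chrom.region_end):
        raise AnnotationError("cutoff outside the synthetic region")
    ordered = sorted(chrom.genes.values(), key=lambda g: g.start)
    runs: list[list[Gene]] = []
    current: list[Gene] = []
    for g in ordered:
        if g.essentiality == ESSENTIAL and g.start < region_cutoff_bp:
            current.append(g)
        else:
            if current:
                runs.append(current)
            current = []
    if current:
        runs.append(current)

    loci: list[tuple[int, int, tuple[str, ...]]] = []
    for run in runs:
        lu = chrom.lu_of_gene(run[0].id)
        prev = [g for g in ordered
                if g.essentiality != ESSENTIAL and g.end <= run[0].start]
        nxt = [g for g in ordered
               if g.essentiality != ESSENTIAL and g.start >= run[-1].end]
        lo = max(prev[-1].end, lu.start) if prev else lu.start
        hi = min(nxt[0].start, lu.end) if nxt else lu.end
        loci.append((lo, hi, tuple(g.id for g in run)))
    loci.sort()
    merged: list[list] = []
    for lo, hi, gids in loci:
        if merged and lo < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
            merged[-1][2] = merged[-1][2] + gids
        else:
            merged.append([lo, hi, gids])

    labelled = tuple(
        (chr(ord("a") + k), lo, hi, gids) for k, (lo, hi, gids) in enumerate(merged)
    )
    site_pos = {s.position for s in chrom.sites}
    for label, lo, hi, _ in labelled:
        if any(lo < p < hi for p in site_pos):
            raise AnnotationError(f"eArray locus {label} would contain a loxPsym site")
    return EArray(
        gene_ids=frozenset(g for _, _, _, gids in labelled for g in gids),
        loci=labelled,
    )


# ---------------------------------------------------------------------------
# Sequence emission
# ---------------------------------------------------------------------------

def lu_sequence(chrom: SyntheticChromosome, lu_id: str) -> str:
    """Slice one LU's sequence out of the emitted arm sequence."""
    if chrom.sequence is None:
        raise AnnotationError("chromosome carries no sequence")
    k = chrom.lu_index(lu_id)
    u = chrom.lus[k]
    off = (u.start - chrom.region_start) + len(LOXPSYM_SEQ) * (k + 1)
    return chrom.sequence[off:off + u.length_bp]


def emit_arm_sequence(lu_seqs: list[str]) -> str:
    """Join per-LU sequences with loxPsym 34-mers, sites flanking both ends."""
    return LOXPSYM_SEQ + LOXPSYM_SEQ.join(lu_seqs) + LOXPSYM_SEQ


def _reemit_sequence(chrom: SyntheticChromosome,
                     new_sites: tuple[LoxPsymSite, ...]) -> str:
    """Rebuild the emitted sequence after extra sites were inserted."""
    old_pos = [s.position for s in chrom.sites]
    parts = []
    for a, b in zip(new_sites[:-1], new_sites[1:]):
        # locate slice in the OLD emitted sequence by unit coordinates
        n_old_before = sum(1 for p in old_pos if p <= a.position)
        off = (a.position - chrom.region_start) + len(LOXPSYM_SEQ) * n_old_before
        parts.append(chrom.sequence[off:off + (b.position - a.position)])
    return emit_arm_sequence(parts)


# ---------------------------------------------------------------------------
# Canonical TSV dialect
# ---------------------------------------------------------------------------
# One row per LU (gene_id ".") carrying the LU interval, then one row per
# contained gene.  Flags: centromere / ura3_reporter on LU rows,
# replaced_by_reporter / conditional:<tag> on gene rows.

_TSV_HEADER = "lu_id\tstart\tend\tgene_id\tstrand\tessentiality\tflags"


def write_annotation(chrom: SyntheticChromosome, path=None, fmt: str = "tsv"):
    """Write the annotation as canonical TSV or GFF3; returns the text."""
    if fmt == "tsv":
        text = _to_tsv(chrom)
    elif fmt == "gff3":
        text = _to_gff3(chrom)
    else:
        raise AnnotationError(f"unknown annotation format {fmt!r}")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _to_tsv(chrom: SyntheticChromosome) -> str:
    out = io.StringIO()
    cen = (f"{chrom.centromere[0]}..{chrom.centromere[1]}"
           if chrom.centromere else ".")
    out.write("# sgc-annotation v1\n")
    out.write(f"# name={chrom.name}\n")
    out.write(f"# region={chrom.region_start}..{chrom.region_end}\n")
    out.write(f"# centromere={cen}\n")
    for m, loc in sorted(chrom.markers.items()):
        out.write(f"# marker={m}:{loc}\n")
    out.write(_TSV_HEADER + "\n")
    for u in chrom.lus:
        flags = []
        if u.has_centromere:
            flags.append("centromere")
        if chrom.markers.get("URA3") == u.lu_id:
            flags.append("ura3_reporter")
        out.write(f"{u.lu_id}\t{u.start}\t{u.end}\t.\t.\t.\t"
                  f"{','.join(flags) or '.'}\n")
        for gid in u.gene_ids:
            g = chrom.genes[gid]
            gf = []
            if g.replaced_by_reporter:
                gf.append("replaced_by_reporter")
            gf.extend(f"conditional:{t}" for t in sorted(g.conditional_tags))
            out.write(f"{u.lu_id}\t{g.start}\t{g.end}\t{g.id}\t{g.strand}\t"
                      f"{g.essentiality}\t{','.join(gf) or '.'}\n")
    return out.getvalue()


def _from_tsv(text: str) -> SyntheticChromosome:
    name, region, cen = None, None, None
    markers: dict[str, str] = {}
    genes: dict[str, Gene] = {}
    lu_rows: list[tuple[str, int, int]] = []
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ").strip()
            if body.startswith("name="):
                name = body[5:]
            elif body.startswith("region="):
                a, b = body[7:].split("..")
                region = (int(a), int(b))
            elif body.startswith("centromere="):
                v = body[11:]
                cen = None if v == "." else tuple(int(x) for x in v.split(".."))
            elif body.startswith("marker="):
                m, loc = body[7:].split(":", 1)
                markers[m] = loc
            continue
        if line == _TSV_HEADER:
            continue
        lu_id, start, end, gene_id, strand, ess, flags = line.split("\t")
        start, end = int(start), int(end)
        flagset = set() if flags == "." else set(flags.split(","))
        if gene_id == ".":
            lu_rows.append((lu_id, start, end))
        else:
            tags = frozenset(f.split(":", 1)[1] for f in flagset
                             if f.startswith("conditional:"))
            genes[gene_id] = Gene(
                gene_id, start, end, strand, ess, tags,
                replaced_by_reporter="replaced_by_reporter" in flagset,
            )
    if region is None:
        raise AnnotationError("TSV lacks a region header")
    if cen is None and "# centromere=." not in text:
        raise AnnotationError("TSV lacks a centromere declaration")
    if not lu_rows:
        raise AnnotationError("TSV contains no LU rows (loxPsym sites missing)")
    lu_rows.sort(key=lambda r: r[1])
    positions = [r[1] for r in lu_rows] + [lu_rows[-1][2]]
    sites = tuple(LoxPsymSite(i, p) for i, p in enumerate(positions))
    lus = segment_lus(list(positions), region, genes, cen,
                      names=[r[0] for r in lu_rows])
    return SyntheticChromosome(
        name=name or "arm", region_start=region[0], region_end=region[1],
        genes=genes, sites=sites, lus=lus, centromere=cen, markers=markers,
    )


# ---------------------------------------------------------------------------
# GFF3 dialect (feature types: gene, loxPsym_site, centromere, reporter)
# ---------------------------------------------------------------------------

def _to_gff3(chrom: SyntheticChromosome) -> str:
    out = io.StringIO()
    out.write("##gff-version 3\n")
    out.write(f"##sequence-region {chrom.name} 1 {chrom.region_end}\n")
    src = "sgc"

    def row(ftype, start, end, strand, attrs):
        a = ";".join(f"{k}={v}" for k, v in attrs.items())
        out.write(f"{chrom.name}\t{src}\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{a}\n")

    for g in sorted(chrom.genes.values(), key=lambda g: g.start):
        attrs = {"ID": g.id, "essentiality": g.essentiality}
        if g.conditional_tags:
            attrs["conditional"] = ",".join(sorted(g.conditional_tags))
        if g.replaced_by_reporter:
            attrs["replaced_by_reporter"] = "true"
        row("gene", g.start + 1, g.end, g.strand, attrs)
    for s in chrom.sites:
        # zero-width point feature anchored at the following base; the exact
        # between-base coordinate is kept in the `position` attribute
        row("loxPsym_site", max(s.position, 1), max(s.position, 1), ".",
            {"ID": f"loxPsym_{s.index}", "position": s.position})
    if chrom.centromere:
        row("centromere", chrom.centromere[0] + 1, chrom.centromere[1], ".",
            {"ID": "CEN"})
    if "URA3" in chrom.markers:
        u = chrom.lu(chrom.markers["URA3"])
        row("reporter", u.start + 1, u.end, ".",
            {"ID": "URA3", "lu_id": u.lu_id})
    return out.getvalue()


def _from_gff3(text: str) -> SyntheticChromosome:
    import gffutils

    db = gffutils.create_db(text, dbfn=":memory:", from_string=True,
                            merge_strategy="create_unique", keep_order=True)
    name, region = None, None
    for line in text.splitlines():
        if line.startswith("##sequence-region"):
            _, name, a, b = line.split()
            region = (int(a) - 1, int(b))
    if region is None:
        raise AnnotationError("GFF3 lacks a ##sequence-region directive")

    genes, positions, cen, markers = {}, [], None, {}
    for f in db.all_features():
        if f.featuretype == "gene":
            tags = frozenset(f.attributes["conditional"][0].split(",")) \
                if "conditional" in f.attributes else frozenset()
            gid = f.attributes["ID"][0]
            genes[gid] = Gene(
                gid, f.start - 1, f.end, f.strand,
                f.attributes.get("essentiality", [NONESSENTIAL])[0], tags,
                replaced_by_reporter="replaced_by_reporter" in f.attributes,
            )
        elif f.featuretype == "loxPsym_site":
            positions.append(int(f.attributes["position"][0]))
        elif f.featuretype == "centromere":
            cen = (f.start - 1, f.end)
        elif f.featuretype == "reporter":
            markers[f.attributes["ID"][0]] = f.attributes["lu_id"][0]
    if not positions:
        raise AnnotationError("GFF3 contains no loxPsym_site features")
    if cen is None:
        raise AnnotationError("GFF3 lacks a centromere feature")
    positions = sorted(positions)
    sites = tuple(LoxPsymSite(i, p) for i, p in enumerate(positions))
    lus = segment_lus(positions, region, genes, cen)
    # recover sub-LU naming for markers if the plain ordinal names differ
    if markers:
        named = {u.lu_id for u in lus}
        markers = {m: (loc if loc in named else loc) for m, loc in markers.items()}
    return SyntheticChromosome(
        name=name, region_start=region[0], region_end=region[1], genes=genes,
        sites=sites, lus=lus, centromere=cen, markers=markers,
    )


def load_annotation(path, fmt: str | None = None) -> SyntheticChromosome:
    """Load a chromosome annotation from canonical TSV or GFF3."""
    path = str(path)
    if fmt is None:
        fmt = "gff3" if re.search(r"\.gff3?$", path) else "tsv"
    with open(path) as fh:
        text = fh.read()
    return _from_tsv(text) if fmt == "tsv" else _from_gff3(text)
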