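"""Deterministic synthetic data generators.

The real annotation of the 170 kbp synthetic chromosome XII left arm
(per-LU coordinates, per-gene essentiality) lives in a supplementary table
that is not redistributed here, and the Hi-C library behind its contact map
is an SRA download.  These generators build synthetic stand-ins that
reproduce every published summary statistic of the arm exactly -- 46 LUs
tiling 170,000 bp, LU lengths from 50 to 16,404 bp, 81 genes (16 essential +
65 nonessential, two of the latter quasi-essential), 9 essential-flag LUs,
at most 8 genes per LU, the centromere in LU-37, and the 10 essential genes
before 140 kbp arranged across 7 eArray loci -- while everything the paper
does not pin down (gene order, exact coordinates, sequence) is
arbitrary-but-fixed given the seed.

All generators are pure functions of (spec, seed); two calls with the same
seed emit byte-identical files.
"""

from __future__ import annotations

import numpy as np

from .genome_model import (
    ESSENTIAL,
    NONESSENTIAL,
    QUASI,
    Gene,
    LoxPsymSite,
    SyntheticChromosome,
    emit_arm_sequence,
    build_earray,
    lu_stats,
    segment_lus,
    write_annotation,
)
from .hic_proximity import ContactMatrix, write_triplet

__all__ = [
    "make_synxiil_fixture",
    "make_toy_chromosome",
    "make_synthetic_hic",
    "make_synxiil_hic",
]

# ---------------------------------------------------------------------------
# synXIIL-like arm
# ---------------------------------------------------------------------------

N_LUS = 46
TOTAL_BP = 170_000
MIN_LU_BP = 50
MAX_LU_BP = 16_404
CUTOFF_BP = 140_000  # first-140-kbp eArray cutoff; LU-37|LU-38 boundary

# fixed lengths: the global min/max LUs, the LU-23..27 interacting-domain
# block around the LU-24 reporter site, and the centromeric LU-37
_PINNED_LEN = {3: 50, 5: MAX_LU_BP, 23: 2000, 24: 2600, 25: 1800, 26: 2200,
               27: 2400, 37: 1000}

# LUs receiving unnamed nonessential filler genes (first 7 take two each)
_FILLER_LUS = (1, 2, 4, 6, 7, 9, 11, 12, 14, 17, 19, 21, 22, 23, 25, 26, 27,
               29, 30, 31, 32, 33, 35, 36, 41, 42, 43, 44)

_E, _Q, _N = ESSENTIAL, QUASI, NONESSENTIAL


def _gene_schedule() -> dict[int, list[tuple[str, str, frozenset]]]:
    """Per-LU ordered gene layout (id, class, conditional tags)."""
    filler = iter(f"YLL9{i:02d}{'W' if i % 2 else 'C'}" for i in range(1, 60))
    f = lambda: (next(filler), _N, frozenset())
    sched: dict[int, list] = {}
    for k, lu in enumerate(_FILLER_LUS):
        sched[lu] = [f(), f()] if k < 7 else [f()]
    sched[5] = [f() for _ in range(8)]                       # busiest LU: 8 genes
    sched[8] = [("YLL054C", _N, frozenset())]                # URA3 replace target
    sched[10] = [f(), ("DRS1", _E, frozenset()), f(),
                 ("SOF1", _E, frozenset()), f()]             # 2 singleton loci
    sched[13] = [f(), ("PRP19", _E, frozenset()), ("GRC3", _E, frozenset()),
                 ("RIX7", _E, frozenset()), f()]             # 3-gene locus run
    sched[15] = [("SDH2", _N, frozenset({"YPG"}))]           # glycerol-conditional
    sched[16] = [("VPS13", _N, frozenset())]
    sched[18] = [f(), ("DPS1", _E, frozenset()), f(),
                 ("COF1", _E, frozenset()), f()]             # 2 singleton loci
    sched[20] = [("YLL032C", _N, frozenset()), ("GPI13", _E, frozenset()),
                 ("RRT7", _N, frozenset()), ("FRA1", _N, frozenset())]
    sched[24] = [("SSA2", _N, frozenset())]                  # chunk-split target
    sched[28] = [f(), ("SFI1", _E, frozenset()),
                 ("ORC3", _E, frozenset()), f()]             # 2-gene locus run
    sched[34] = [("MMM1", _Q, frozenset()), ("RTT109", _Q, frozenset()), f()]
    sched[38] = [("YLL811W", _E, frozenset()), ("YLL812C", _E, frozenset())]
    sched[39] = [("YLL821W", _E, frozenset()), ("YLL822C", _E, frozenset())]
    sched[40] = [("YLL831W", _E, frozenset()), ("YLL832C", _E, frozenset())]
    sched[45] = [("PML1", _N, frozenset({"37C"}))]           # heat-conditional
    sched[46] = [("MEU1", _N, frozenset())]
    return sched


def _distribute_lengths(rng, lu_nums, mins, group_total, pinned):
    """Seeded LU lengths: minimum feasible length per LU plus a log-normal
    share of the slack, rescaled so the group sums exactly; the rounding
    residual lands on the LU with the largest share."""
    unpinned = [n for n in lu_nums if n not in pinned]
    budget = group_total - sum(pinned[n] for n in lu_nums if n in pinned)
    slack = budget - sum(mins[n] for n in unpinned)
    if slack < 0:
        raise AssertionError("fixture layout infeasible: minimum lengths too large")
    w = rng.lognormal(0.0, 0.6, size=len(unpinned))
    extras = np.floor(slack * w / w.sum()).astype(int)
    extras[int(np.argmax(extras))] += slack - int(extras.sum())
    lens = {}
    for n, e in zip(unpinned, extras):
        lens[n] = mins[n] + int(e)
    # keep every unpinned LU strictly inside the pinned global min/max
    for n in unpinned:
        if lens[n] > 15_000:
            excess = lens[n] - 15_000
            lens[n] = 15_000
            smallest = min(unpinned, key=lambda m: lens[m])
            lens[smallest] += excess
    for n in lu_nums:
        if n in pinned:
            lens[n] = pinned[n]
    assert sum(lens[n] for n in lu_nums) == group_total
    assert all(MIN_LU_BP < lens[n] < MAX_LU_BP for n in unpinned)
    return lens


def make_synxiil_fixture(seed: int = 0, out_dir=None,
                         with_sequence: bool = True) -> SyntheticChromosome:
    """Build the synXIIL-like reference arm; optionally write TSV+GFF3+FASTA.

    The generator re-checks every published summary statistic on its own
    output and raises if a future edit breaks one.
    """
    rng = np.random.default_rng(seed)
    sched = _gene_schedule()

    # 1. gene lengths (drawn first: LU minima depend on them)
    glen: dict[str, int] = {}
    for lu in range(1, N_LUS + 1):
        for gid, cls, _ in sched.get(lu, []):
            lo, hi = (900, 2000) if cls in (_E, _Q) else (400, 1400)
            glen[gid] = int(rng.integers(lo, hi))

    # 2. LU lengths: group A (LU-1..37) tiles [0, 140 kbp), group B the rest
    mins = {}
    for lu in range(1, N_LUS + 1):
        gs = sched.get(lu, [])
        mins[lu] = max(300, sum(glen[g] for g, _, _ in gs) + 30 * (len(gs) + 1))
    lens = _distribute_lengths(rng, list(range(1, 38)), mins, CUTOFF_BP,
                               _PINNED_LEN)
    lens.update(_distribute_lengths(rng, list(range(38, 47)), mins,
                                    TOTAL_BP - CUTOFF_BP, _PINNED_LEN))

    # 3. coordinates: sites at cumulative LU boundaries; genes evenly packed
    positions = [0]
    for lu in range(1, N_LUS + 1):
        positions.append(positions[-1] + lens[lu])
    genes: dict[str, Gene] = {}
    for lu in range(1, N_LUS + 1):
        gs = sched.get(lu, [])
        if not gs:
            continue
        start = positions[lu - 1]
        gap = (lens[lu] - sum(glen[g] for g, _, _ in gs)) // (len(gs) + 1)
        cursor = start + gap
        for gid, cls, tags in gs:
            strand = "+" if rng.integers(2) else "-"
            genes[gid] = Gene(gid, cursor, cursor + glen[gid], strand, cls, tags)
            cursor += glen[gid] + gap
    cen_start = positions[36] + 440
    centromere = (cen_start, cen_start + 120)

    sites = tuple(LoxPsymSite(i, p) for i, p in enumerate(positions))
    lus = segment_lus(positions, (0, TOTAL_BP), genes, centromere)
    sequence = None
    if with_sequence:
        lu_seqs = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, lens[lu])])
                   for lu in range(1, N_LUS + 1)]
        sequence = emit_arm_sequence(lu_seqs)
    chrom = SyntheticChromosome(
        name="synXIIL", region_start=0, region_end=TOTAL_BP, genes=genes,
        sites=sites, lus=lus, centromere=centromere, markers={},
        sequence=sequence,
    )
    _check_fixture(chrom)
    if out_dir is not None:
        _write_fixture_files(chrom, out_dir, seed)
    return chrom


def _check_fixture(chrom: SyntheticChromosome) -> None:
    s = lu_stats(chrom)
    expected = {"n_lus": 46, "n_essential_lus": 9, "n_genes": 81,
                "n_essential": 16, "n_nonessential": 65, "min_lu_bp": MIN_LU_BP,
                "max_lu_bp": MAX_LU_BP, "max_genes_per_lu": 8,
                "total_synthetic_bp": TOTAL_BP}
    if s != expected:
        raise AssertionError(f"fixture violates published statistics: {s}")
    if not chrom.lu("LU-37").has_centromere:
        raise AssertionError("centromere must sit in LU-37")
    ea = build_earray(chrom, CUTOFF_BP)
    if len(ea.gene_ids) != 10 or len(ea.loci) != 7:
        raise AssertionError("eArray layout broken: need 10 genes in 7 loci")
    run_sets = {frozenset(g) for _, _, _, g in ea.loci}
    if (frozenset({"PRP19", "GRC3", "RIX7"}) not in run_sets
            or frozenset({"SFI1", "ORC3"}) not in run_sets):
        raise AssertionError("pinned multi-gene eArray loci missing")


def _write_fixture_files(chrom, out_dir, seed) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tsv = write_annotation(chrom, fmt="tsv")
    (out / "synxiil.tsv").write_text(
        tsv.replace("# sgc-annotation v1\n",
                    f"# sgc-annotation v1\n# seed={seed}\n"))
    write_annotation(chrom, out / "synxiil.gff3", fmt="gff3")
    if chrom.sequence is not None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        rec = SeqRecord(Seq(chrom.sequence), id=chrom.name,
                        description=f"synthetic arm with loxPsym sites seed={seed}")
        seqio_write([rec], str(out / "synxiil.fasta"), "fasta")


def make_toy_chromosome(n_lus: int, lengths=None, essential_lus=(),
                        seed: int = 0, centromere_lu: int | None = None,
                        ura3_lu: int | None = None,
                        with_sequence: bool = False) -> SyntheticChromosome:
    """Small parametric arm for unit tests: one gene per LU (essential where
    requested).  ``centromere_lu=None`` models an arm whose centromere lies
    outside the synthetic region and therefore cannot be lost."""
    if n_lus < 1:
        raise ValueError("n_lus must be >= 1")
    if lengths is None:
        lengths = [1000] * n_lus
    lengths = list(lengths)
    if len(lengths) != n_lus:
        raise ValueError("lengths list inconsistent with n_lus")
    rng = np.random.default_rng(seed)
    positions = [0]
    for L in lengths:
        positions.append(positions[-1] + int(L))
    genes = {}
    for k, L in enumerate(lengths, start=1):
        if L < 200:
            if k in essential_lus:
                raise ValueError(f"LU {k} too short to host an essential gene")
            continue
        gl = min(L - 60, 600)
        start = positions[k - 1] + 30
        cls = ESSENTIAL if k in essential_lus else NONESSENTIAL
        genes[f"G{k}"] = Gene(f"G{k}", start, start + gl, "+", cls)
    centromere = None
    if centromere_lu is not None:
        mid = (positions[centromere_lu - 1] + positions[centromere_lu]) // 2
        centromere = (mid - 40, mid + 40)
    sites = tuple(LoxPsymSite(i, p) for i, p in enumerate(positions))
    lus = segment_lus(positions, (0, positions[-1]), genes, centromere)
    sequence = None
    if with_sequence:
        lu_seqs = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, int(L))])
                   for L in lengths]
        sequence = emit_arm_sequence(lu_seqs)
    markers = {"URA3": f"LU-{ura3_lu}"} if ura3_lu is not None else {}
    return SyntheticChromosome(
        name="toy", region_start=0, region_end=positions[-1], genes=genes,
        sites=sites, lus=lus, centromere=centromere, markers=markers,
        sequence=sequence,
    )


# ---------------------------------------------------------------------------
# synthetic Hi-C
# ---------------------------------------------------------------------------

def make_synthetic_hic(n_bins: int, bin_bp: int, boundaries,
                       alpha: float = 1.0, noise: float = 0.0, seed: int = 0,
                       d0_bp: float | None = None, boost: float = 4.0,
                       base: float = 1000.0, path=None) -> ContactMatrix:
    """Block-CID contact matrix: power-law distance decay ``(d+d0)^-alpha``
    times a same-domain boost, times multiplicative log-normal noise.

    ``boundaries`` are the bin indices where a new domain starts (0 and
    n_bins are implicit).  With ``noise=0`` the insulation score has its
    minimum exactly at each planted boundary bin.
    """
    boundaries = sorted(int(b) for b in boundaries)
    if any(not 0 < b < n_bins for b in boundaries):
        raise ValueError("boundaries must lie strictly inside the bin range")
    if boundaries != sorted(set(boundaries)):
        raise ValueError("boundaries must be unique and sorted")
    rng = np.random.default_rng(seed)
    d0 = float(bin_bp if d0_bp is None else d0_bp)
    idx = np.arange(n_bins)
    d = np.abs(idx[:, None] - idx[None, :]) * bin_bp
    counts = base * (d + d0) ** (-alpha)
    dom = np.searchsorted(boundaries, idx, side="right")
    counts = counts * np.where(dom[:, None] == dom[None, :], boost, 1.0)
    if noise > 0:
        eps = rng.normal(0.0, noise, size=(n_bins, n_bins))
        eps = np.triu(eps) + np.triu(eps, 1).T
        counts = counts * np.exp(eps)
    mat = ContactMatrix(counts=counts, bin_bp=bin_bp)
    if path is not None:
        write_triplet(mat, path)
    return mat


def make_synxiil_hic(chrom: SyntheticChromosome, seed: int = 0,
                     noise: float = 0.05, bin_bp: int = 2000,
                     alpha: float = 1.0, boost: float = 4.0,
                     min_domain_bp: int = 8000, edge_margin_bins: int = 5,
                     path=None):
    """Contact matrix for the arm fixture with domains aligned to LU
    boundaries, forcing one domain to cover exactly LU-23..LU-27 (the
    interacting domain the reporter-flanking deletions are confined to).

    Returns ``(ContactMatrix, planted_boundary_bins)``.
    """
    n_bins = chrom.region_length // bin_bp
    min_gap = max(2, min_domain_bp // bin_bp)
    f_lo = round(chrom.lu("LU-23").start / bin_bp)
    f_hi = round(chrom.lu("LU-28").start / bin_bp)
    bins: list[int] = []
    last = 0
    for u in chrom.lus:
        b = round(u.end / bin_bp)
        if f_lo < b < f_hi:
            continue  # forced single domain LU-23..27
        forced = b in (f_lo, f_hi)
        # boundaries closer to the matrix edge than the insulation window
        # cannot be called; terminal domains absorb them
        if not (edge_margin_bins <= b <= n_bins - edge_margin_bins):
            continue
        if not forced and b < f_lo and f_lo - b < min_gap:
            continue  # would crowd the forced LU-23 boundary
        if forced or b - last >= min_gap:
            bins.append(b)
            last = b
    mat = make_synthetic_hic(n_bins, bin_bp, bins, alpha=alpha, noise=noise,
                             seed=seed, boost=boost, path=path)
    return mat, bins
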