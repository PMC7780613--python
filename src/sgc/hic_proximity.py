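"""Hi-C contact handling, CID detection, and recombination-weight models.

Cre-loxP deletion requires four Cre monomers, bound at two loxPsym sites, to
synapse; the closer two sites sit in the 3D fold of the chromosome, the more
likely they recombine.  Yeast chromosome arms fold into chromosomal
interacting domains (CIDs, 2-10 kbp self-interacting blocks), so site pairs
within one CID recombine preferentially.  This module balances binned
contact matrices (iterative correction), calls CIDs by insulation-score
minima, and turns either a fitted distance-decay law or the contact map
itself into per-site-pair recombination weights for the event simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "ContactMatrix",
    "CidSegmentation",
    "ProximityWeights",
    "read_triplet",
    "write_triplet",
    "ice_balance",
    "insulation_cids",
    "weights_for_sites",
    "deletion_cid_concordance",
    "DEFAULT_ALPHA",
    "DEFAULT_D0_BP",
    "DEFAULT_BETA",
]

# Default distance-decay / CID-boost parameters for the recombination-weight
# model.  Calibrated once so that the default end-to-end simulation on the
# arm fixture reproduces the observed median selected-deletion span (7 kbp);
# see docs/methods.md.
DEFAULT_ALPHA = 0.85
DEFAULT_D0_BP = 5000.0
DEFAULT_BETA = 6.0


@dataclass(frozen=True)
class ContactMatrix:
    counts: np.ndarray
    bin_bp: int
    balanced: bool = False
    masked_bins: frozenset[int] = frozenset()

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(c, c.T):
            raise ValueError("contact matrix must be symmetric")
        if (c < 0).any():
            raise ValueError("contact counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class CidSegmentation:
    boundaries: tuple[int, ...]           # bin indices where a domain starts
    domains: tuple[tuple[int, int], ...]  # half-open bin intervals
    insulation: np.ndarray                # per-bin log2 insulation (NaN at edges)
    bin_bp: int

    def domain_of_bp(self, pos: int) -> int | None:
        """Index of the domain containing base-pair position ``pos``."""
        b = pos // self.bin_bp
        for k, (lo, hi) in enumerate(self.domains):
            if lo <= b < hi:
                return k
        return None

    def domain_span_bp(self, k: int) -> int:
        lo, hi = self.domains[k]
        return (hi - lo) * self.bin_bp


@dataclass(frozen=True)
class ProximityWeights:
    model: str
    params: dict = field(default_factory=dict)
    matrix: np.ndarray = None  # symmetric, zero-diagonal, over current sites


# ---------------------------------------------------------------------------
# I/O: triplet text (bin_i <TAB> bin_j <TAB> count)
# ---------------------------------------------------------------------------

def read_triplet(path, bin_bp: int, n_bins: int | None = None) -> ContactMatrix:
    """Read a sparse triplet text file into a symmetrized dense matrix."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i, j, c = line.split()
            rows.append((int(i), int(j), float(c)))
    if n_bins is None:
        n_bins = max((max(i, j) for i, j, _ in rows), default=-1) + 1
    counts = np.zeros((n_bins, n_bins))
    for i, j, c in rows:
        if c < 0:
            raise ValueError(f"negative count at ({i},{j})")
        if not (0 <= i < n_bins and 0 <= j < n_bins):
            raise ValueError(f"bin index out of range at ({i},{j})")
        counts[i, j] = c
        counts[j, i] = c
    return ContactMatrix(counts=counts, bin_bp=bin_bp)


def write_triplet(matrix: ContactMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bin_bp={matrix.bin_bp}\tn_bins={matrix.n_bins}\n")
        iu = np.triu_indices(matrix.n_bins)
        for i, j in zip(*iu):
            c = matrix.counts[i, j]
            if c != 0:
                fh.write(f"{i}\t{j}\t{c:.6g}\n")


# ---------------------------------------------------------------------------
# ICE balancing
# ---------------------------------------------------------------------------

def ice_balance(matrix: ContactMatrix, filter_low_pct: float = 2.0,
                tol: float = 1e-5, max_iter: int = 100) -> ContactMatrix:
    """Iterative correction: scale rows/columns by the square root of their
    coverage until all unmasked bin sums agree to ``tol``.

    Bins with zero coverage, or coverage below the ``filter_low_pct``
    percentile, are masked before correction.
    """
    counts = matrix.counts.copy()
    cov = counts.sum(axis=1)
    masked = set(int(b) for b in np.flatnonzero(cov == 0))
    if filter_low_pct > 0 and (cov > 0).any():
        thr = np.percentile(cov[cov > 0], filter_low_pct)
        masked |= set(int(b) for b in np.flatnonzero(cov < thr))
    live = np.array([b for b in range(matrix.n_bins) if b not in masked])
    if live.size == 0:
        raise ValueError("all bins masked; nothing to balance")
    counts[list(masked), :] = 0.0
    counts[:, list(masked)] = 0.0

    for _ in range(max_iter):
        s = counts[np.ix_(live, live)].sum(axis=1)
        s = s / s.mean()
        if np.abs(s - 1.0).max() < tol:
            break
        b = np.sqrt(s)
        counts[np.ix_(live, live)] /= np.outer(b, b)
    return ContactMatrix(counts=counts, bin_bp=matrix.bin_bp, balanced=True,
                         masked_bins=frozenset(masked))


# ---------------------------------------------------------------------------
# Insulation-score CID calling
# ---------------------------------------------------------------------------

def insulation_score(matrix: ContactMatrix, window_bins: int = 5) -> np.ndarray:
    """Per-bin log2 insulation, NaN within ``window_bins`` of either edge.

    The score at bin *b* is the mean contact inside the ``window x window``
    square straddling the gap between bins *b-1* and *b*, normalized by the
    genome-wide mean so it is invariant to global scaling.
    """
    n, w = matrix.n_bins, window_bins
    if 2 * w > n:
        raise ValueError("insulation window larger than the matrix")
    raw = np.full(n, np.nan)
    for b in range(w, n - w + 1):
        sq = matrix.counts[b - w:b, b:b + w]
        if b < n:
            raw[b] = sq.mean()
    valid = raw[~np.isnan(raw)]
    mean = valid.mean()
    if mean == 0:
        raise ValueError("empty contact matrix")
    with np.errstate(divide="ignore"):
        return np.log2(raw / mean)


def insulation_cids(matrix: ContactMatrix, window_bins: int = 5,
                    delta_threshold: float = 0.1) -> CidSegmentation:
    """Call CID boundaries as insulation-score local minima with prominence
    at least ``delta_threshold`` (in log2 units); domains tile the bin range
    between consecutive boundaries."""
    score = insulation_score(matrix, window_bins)
    finite = np.where(np.isnan(score), np.nanmax(score), score)
    peaks, _ = find_peaks(-finite, prominence=delta_threshold)
    boundaries = tuple(int(p) for p in peaks
                       if window_bins <= p <= matrix.n_bins - window_bins)
    edges = [0, *boundaries, matrix.n_bins]
    domains = tuple((edges[k], edges[k + 1]) for k in range(len(edges) - 1))
    return CidSegmentation(boundaries=boundaries, domains=domains,
                           insulation=score, bin_bp=matrix.bin_bp)


# ---------------------------------------------------------------------------
# Recombination weights
# ---------------------------------------------------------------------------

def weights_for_sites(positions, model: str = "power_law", params=None,
                      matrix: ContactMatrix | None = None,
                      cids: CidSegmentation | None = None,
                      ref_positions=None) -> ProximityWeights:
    """Pairwise recombination weights for the current loxPsym sites.

    Parameters
    ----------
    positions : linear coordinates (bp) of the surviving sites on the
        *current* (possibly rearranged) chromosome.
    model : ``power_law`` -- ``w = (d + d0)^-alpha`` on current separation;
        ``hic_contact`` -- balanced contact of the sites' reference bins;
        ``cid_boost`` -- power law times ``beta`` when both sites map into
        the same CID of the reference.
    ref_positions : reference-origin coordinate of each surviving site
        (needed by ``hic_contact`` and ``cid_boost``).
    """
    params = dict(params or {})
    pos = np.asarray(positions, dtype=float)
    n = pos.size
    d = np.abs(pos[:, None] - pos[None, :])

    if model == "power_law" or model == "cid_boost":
        alpha = float(params.get("alpha", DEFAULT_ALPHA))
        d0 = float(params.get("d0", DEFAULT_D0_BP))
        w = (d + d0) ** (-alpha)
    elif model == "hic_contact":
        if matrix is None:
            raise ValueError("hic_contact model requires a contact matrix")
        rp = np.asarray(ref_positions if ref_positions is not None else positions)
        bins = np.clip(rp // matrix.bin_bp, 0, matrix.n_bins - 1).astype(int)
        w = matrix.counts[np.ix_(bins, bins)].astype(float)
    else:
        raise ValueError(f"unknown weight model {model!r}")

    if model == "cid_boost":
        if cids is None:
            raise ValueError("cid_boost model requires a CID segmentation")
        beta = float(params.get("beta", DEFAULT_BETA))
        rp = np.asarray(ref_positions if ref_positions is not None else positions)
        dom = np.array([-1 if (k := cids.domain_of_bp(int(p))) is None else k
                        for p in rp])
        same = (dom[:, None] == dom[None, :]) & (dom[:, None] >= 0)
        w = w * np.where(same, beta, 1.0)

    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return ProximityWeights(model=model, params=params, matrix=w)


def deletion_cid_concordance(profiles, cids: CidSegmentation) -> float:
    """Fraction of maximal contiguous deleted reference segments that fall
    wholly inside a single CID.  NaN when there are no deleted segments."""
    total = concordant = 0
    for p in profiles:
        for start, end in p.deleted_segments:
            total += 1
            a = cids.domain_of_bp(start)
            b = cids.domain_of_bp(max(start, end - 1))
            if a is not None and a == b:
                concordant += 1
    return math.nan if total == 0 else concordant / total
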