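"""Cre/loxPsym recombination simulator.

A chromosome state is an ordered list of signed LU segments separated by
surviving loxPsym sites (always one more site than segments, because a site
flanks each end of the synthetic region).  A single Cre event acts on a pair
of surviving sites (i < j):

* deletion  -- everything strictly between the two sites is excised as a
  circle; the two sites resolve into ONE hybrid site (the left site id is
  kept as its reference origin);
* inversion -- the block between the sites is reversed and every segment's
  orientation flipped; both sites survive;
* duplication -- the block is tandem-duplicated with one extra hybrid site
  at the internal junction.

loxPsym sites are palindromic, so deletion and inversion are both available
for every pair regardless of orientation.  Translocation is out of scope
(single-chromosome model).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome_model import SyntheticChromosome

__all__ = [
    "ChromosomeState",
    "RecombinationEvent",
    "Strain",
    "reference_state",
    "apply_event",
    "apply_events",
    "site_positions",
    "total_bp",
    "sample_events",
    "simulate_population",
    "DEFAULT_TYPE_PROBS",
    "DEFAULT_LAMBDA",
]

#: Event-type priors: deletions and inversions dominate SCRaMbLE outcomes,
#: duplication is rare on this arm.
DEFAULT_TYPE_PROBS = {"deletion": 0.45, "inversion": 0.45, "duplication": 0.10}

#: Mean Cre events per induced cell over the 2 h induction window.
DEFAULT_LAMBDA = 2.0


class RecombinationError(ValueError):
    pass


@dataclass(frozen=True)
class RecombinationEvent:
    type: str                 # deletion | inversion | duplication
    i: int                    # indices into the CURRENT site list, i < j
    j: int
    order: int = 0

    def __post_init__(self):
        if self.type not in ("deletion", "inversion", "duplication"):
            raise RecombinationError(f"unknown event type {self.type!r}")
        if self.i == self.j:
            raise RecombinationError("degenerate pair")
        if self.j < self.i:
            raise RecombinationError("site pair must satisfy i < j")


@dataclass(frozen=True)
class ChromosomeState:
    segments: tuple[tuple[str, int], ...]  # (lu_id, +1/-1)
    sites: tuple[int, ...]                 # surviving reference site ids
    episomes: frozenset[str] = frozenset()
    provenance: str | None = None

    def __post_init__(self):
        if len(self.sites) != len(self.segments) + 1:
            raise RecombinationError("need exactly one more site than segments")

    def lu_copies(self) -> dict[str, int]:
        copies: dict[str, int] = {}
        for lu, _ in self.segments:
            copies[lu] = copies.get(lu, 0) + 1
        return copies


@dataclass
class Strain:
    id: str
    state: ChromosomeState
    events: list[RecombinationEvent] = field(default_factory=list)
    flags: dict = field(default_factory=dict)


def reference_state(chrom: SyntheticChromosome,
                    episomes: frozenset[str] = frozenset()) -> ChromosomeState:
    return ChromosomeState(
        segments=tuple((u.lu_id, +1) for u in chrom.lus),
        sites=tuple(s.index for s in chrom.sites),
        episomes=episomes,
        provenance=chrom.name,
    )


def apply_event(state: ChromosomeState,
                event: RecombinationEvent) -> ChromosomeState:
    """Apply one Cre outcome; pure (returns a new state)."""
    i, j = event.i, event.j
    n_sites = len(state.sites)
    if not (0 <= i < j < n_sites):
        raise RecombinationError(
            f"site pair ({i},{j}) invalid for {n_sites} surviving sites")
    seg, sit = list(state.segments), list(state.sites)
    if event.type == "deletion":
        # segments i..j-1 and interior sites excised; sites i and j resolve
        # into one hybrid site keeping the left reference origin
        seg = seg[:i] + seg[j:]
        sit = sit[:i + 1] + sit[j + 1:]
    elif event.type == "inversion":
        block = [(lu, -o) for lu, o in reversed(seg[i:j])]
        seg = seg[:i] + block + seg[j:]
        sit = sit[:i + 1] + list(reversed(sit[i + 1:j])) + sit[j:]
    elif event.type == "duplication":
        seg = seg[:j] + seg[i:j] + seg[j:]
        sit = sit[:j] + [sit[j]] + sit[i + 1:j] + sit[j:]
    return replace(state, segments=tuple(seg), sites=tuple(sit))


def apply_events(state: ChromosomeState, events) -> ChromosomeState:
    for e in sorted(events, key=lambda e: e.order):
        state = apply_event(state, e)
    return state


def site_positions(chrom: SyntheticChromosome,
                   state: ChromosomeState) -> np.ndarray:
    """Linear coordinates of the surviving sites on the CURRENT chromosome
    (cumulative LU lengths; the 34 bp sites are excluded by convention)."""
    lens = {u.lu_id: u.length_bp for u in chrom.lus}
    pos = np.zeros(len(state.sites), dtype=float)
    for k, (lu, _) in enumerate(state.segments):
        pos[k + 1] = pos[k] + lens[lu]
    return pos


def site_ref_positions(chrom: SyntheticChromosome,
                       state: ChromosomeState) -> np.ndarray:
    """Reference-origin coordinate of each surviving site (hybrid sites
    inherit the origin of the retained reference site id)."""
    ref = {s.index: s.position for s in chrom.sites}
    return np.array([ref[sid] for sid in state.sites], dtype=float)


def total_bp(chrom: SyntheticChromosome, state: ChromosomeState) -> int:
    lens = {u.lu_id: u.length_bp for u in chrom.lus}
    return sum(lens[lu] for lu, _ in state.segments)


# ---------------------------------------------------------------------------
# Event sampling
# ---------------------------------------------------------------------------

def _normalize_type_probs(type_probs) -> tuple[list[str], np.ndarray]:
    types = list(type_probs)
    p = np.array([type_probs[t] for t in types], dtype=float)
    if p.sum() <= 0:
        raise RecombinationError("type probabilities must sum to a positive value")
    return types, p / p.sum()


def sample_events(state: ChromosomeState, n_events: int, weights,
                  type_probs=None, rng=None) -> list[RecombinationEvent]:
    """Draw ``n_events`` i.i.d. events for the given state: site pairs with
    probability proportional to ``weights[i, j]``, types from ``type_probs``.

    ``weights`` is a symmetric matrix over the state's current site indices.
    Note that applying the returned events sequentially shifts later site
    indices; ``simulate_population`` therefore resamples after each
    application instead of batching.
    """
    rng = np.random.default_rng(rng)
    type_probs = type_probs or DEFAULT_TYPE_PROBS
    w = np.asarray(weights, dtype=float)
    n = len(state.sites)
    if w.shape != (n, n):
        raise RecombinationError("weight matrix does not match the site list")
    iu = np.triu_indices(n, k=1)
    flat = w[iu]
    if flat.sum() <= 0:
        raise RecombinationError("all pair weights are zero")
    types, p_types = _normalize_type_probs(type_probs)
    pick = rng.choice(flat.size, size=n_events, p=flat / flat.sum())
    tsel = rng.choice(len(types), size=n_events, p=p_types)
    return [
        RecombinationEvent(types[t], int(iu[0][k]), int(iu[1][k]), order=o)
        for o, (k, t) in enumerate(zip(pick, tsel))
    ]


def simulate_population(chrom: SyntheticChromosome, n_cells: int,
                        lambda_events: float = DEFAULT_LAMBDA,
                        weight_fn=None, type_probs=None, seed: int = 0,
                        fixed_events: int | None = None,
                        episomes: frozenset[str] = frozenset()) -> list[Strain]:
    """Simulate Cre induction in ``n_cells`` independent cells.

    Each cell experiences ``Poisson(lambda_events)`` events (or exactly
    ``fixed_events``), applied sequentially; after each application the pair
    weights are recomputed on the rearranged chromosome via ``weight_fn``
    (default: uniform).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    type_probs = type_probs or DEFAULT_TYPE_PROBS
    base = reference_state(chrom, episomes=episomes)

    def uniform(state):
        n = len(state.sites)
        w = np.ones((n, n))
        np.fill_diagonal(w, 0.0)
        return w

    weight_fn = weight_fn or uniform
    w0 = weight_fn(base)  # all cells share the unrearranged starting state

    strains = []
    width = max(5, len(str(n_cells)))
    for c in range(n_cells):
        k = int(rng.poisson(lambda_events)) if fixed_events is None \
            else int(fixed_events)
        state, log = base, []
        for order in range(k):
            if len(state.sites) < 2:
                break  # arm fully deleted: no substrate left for Cre
            w = w0 if state is base else weight_fn(state)
            if np.asarray(w).sum() <= 0:
                break
            ev = sample_events(state, 1, w, type_probs, rng)[0]
            ev = replace(ev, order=order)
            state = apply_event(state, ev)
            log.append(ev)
        strains.append(Strain(id=f"S{c:0{width}d}", state=state, events=log))
    return strains
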