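"""Per-generation life cycle and full simulation runs.

Each generation proceeds in a fixed order: census of allele frequencies at
birth, migration, then mating with divergent selection.  Generations do not
overlap; every island produces exactly its configured number of offspring
and all adults die.

Genotypes are stored as one small integer array per island with shape
``(n, ploidy * (1 + q))``: the adaptation-locus copies come first, then the
``q`` dispersal loci (copies of a locus adjacent in the diploid mode).
Allele 0 is the primitive state everywhere: it promotes dispersal at the
dispersal loci and is adapted to the low-altitude islands B and C at the
adaptation locus (taxon-cycle orientation; the derived allele 1 is adapted
to the high-altitude island A).

All stochastic draws consume a single per-run generator in a documented
order (leave/stay decisions for islands A, B, C; destination draws A, B, C;
then per island A, B, C: parent draws, inheritance coin flips, mutation),
so runs are bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ISLANDS, PAIRS, ArchipelagoGeometry, SimulationParams, build_geometry
from .speciation import OnsetDetector, SpeciationResult

ISLAND_INDEX = {name: i for i, name in enumerate(ISLANDS)}
#: Unordered pair index lookup by island-index pair.
PAIR_INDEX = {
    (ISLAND_INDEX[i], ISLAND_INDEX[j]): k for k, (i, j) in enumerate(PAIRS)
}
for (a, b), k in list(PAIR_INDEX.items()):
    PAIR_INDEX[(b, a)] = k


class ExtinctionError(RuntimeError):
    """An island's mating pool emptied after migration."""


@dataclass
class PopulationState:
    """Residents of each island at birth.

    ``genotypes[i]`` holds the island-``i`` residents; at birth every
    individual resides on its natal island, so no separate natal label is
    needed until migration regroups the pools.
    """

    generation: int
    genotypes: list[np.ndarray]

    def sizes(self) -> tuple[int, ...]:
        return tuple(len(g) for g in self.genotypes)


@dataclass
class MatingPools:
    """Post-migration pools: genotypes plus natal-island labels."""

    genotypes: list[np.ndarray]
    natal: list[np.ndarray]


@dataclass
class GenerationRecord:
    """Census of one generation: birth frequencies and migrant counts.

    ``adapt_freq`` and ``dispersal_freq`` are the per-island frequencies of
    the primitive allele 0 (at the adaptation locus and averaged over the
    dispersal loci, respectively).  ``migrants`` counts migrants that
    participated in mating, per unordered island pair (A-B, A-C, B-C),
    under the configured counting mode; this is the series fed to the
    one-migrant-per-generation detector.  ``migration_events`` counts the
    raw island-changing moves this generation regardless of mating.
    """

    generation: int
    adapt_freq: tuple[float, float, float]
    dispersal_freq: tuple[float, float, float]
    migrants: tuple[int, int, int]
    migration_events: tuple[int, int, int] = (0, 0, 0)


def initialize_population(params: SimulationParams) -> PopulationState:
    """All loci fixed to the primitive allele 0 on every island."""
    cols = params.ploidy * params.n_loci
    genotypes = [
        np.zeros((n, cols), dtype=np.int8) for n in params.sizes
    ]
    return PopulationState(generation=0, genotypes=genotypes)


def dispersal_probability(derived_count, params: SimulationParams):
    """Migration probability of an individual carrying ``derived_count``
    derived dispersal alleles.

    Each derived allele lowers the probability by ``M / q`` (haploid) or
    ``M / (2 q)`` (diploid, additive over the two copies); a fully derived
    genotype never leaves its natal island.
    """
    d = np.asarray(derived_count)
    total = params.ploidy * params.q
    if np.any(d < 0) or np.any(d > total):
        raise ValueError(
            f"derived_count must lie in [0, {total}], got {derived_count!r}"
        )
    return params.M * (1.0 - d / total)


def _derived_dispersal_counts(genotypes: np.ndarray, params: SimulationParams) -> np.ndarray:
    return genotypes[:, params.ploidy:].sum(axis=1)


def fitness_weight(adapt_allele, island: str, params: SimulationParams):
    """Relative parent-draw weight: 1 if locally adapted, 1 - DS otherwise.

    In the two-environment default, allele 0 is adapted on the low-altitude
    islands B and C and allele 1 on the high-altitude island A.  In the
    three-environment mode allele i is adapted on island i (A=0, B=1, C=2).
    Diploid adaptation is additive: each maladapted copy costs DS/2.
    """
    a = np.asarray(adapt_allele)
    if params.n_env_types == 2:
        adapted_allele = 1 if island == "A" else 0
    else:
        adapted_allele = ISLAND_INDEX[island]
    if params.ploidy == 1:
        return np.where(a == adapted_allele, 1.0, 1.0 - params.DS)
    # a has shape (..., 2): count maladapted copies
    maladapted = (a != adapted_allele).sum(axis=-1)
    return 1.0 - params.DS * maladapted / 2.0


def _pool_weights(genotypes: np.ndarray, island: str, params: SimulationParams) -> np.ndarray:
    adapt = genotypes[:, : params.ploidy]
    if params.ploidy == 1:
        return fitness_weight(adapt[:, 0], island, params)
    return fitness_weight(adapt, island, params)


def _maladapted_counts(
    genotypes: np.ndarray, island: str, params: SimulationParams
) -> np.ndarray:
    """Maladapted allele copies per pool member (0..ploidy)."""
    if params.n_env_types == 2:
        adapted_allele = 1 if island == "A" else 0
    else:
        adapted_allele = ISLAND_INDEX[island]
    return (genotypes[:, : params.ploidy] != adapted_allele).sum(axis=1)


def migrate(
    state: PopulationState,
    geometry: ArchipelagoGeometry,
    params: SimulationParams,
    rng: np.random.Generator,
) -> tuple[MatingPools, np.ndarray]:
    """Disperse individuals just before mating.

    Every individual leaves its natal island with its genotype's dispersal
    probability; a leaver picks one of the two other islands with the
    reciprocal-distance destination probabilities.  Returns the regrouped
    mating pools and the count of migration events per unordered pair.

    Raises :class:`ExtinctionError` if any pool empties.
    """
    leavers = []
    for i, isl in enumerate(ISLANDS):
        g = state.genotypes[i]
        p = dispersal_probability(_derived_dispersal_counts(g, params), params)
        leavers.append(rng.random(len(g)) < p)

    dest = []
    for i, isl in enumerate(ISLANDS):
        others = [k for k in range(3) if k != i]
        p_first = geometry.dest_probs[isl][ISLANDS[others[0]]]
        n_leave = int(leavers[i].sum())
        u = rng.random(n_leave)
        dest.append(np.where(u < p_first, others[0], others[1]).astype(np.int8))

    migrants = np.zeros(3, dtype=np.int64)
    pool_geno: list[list[np.ndarray]] = [[], [], []]
    pool_natal: list[list[np.ndarray]] = [[], [], []]
    for i in range(3):
        g = state.genotypes[i]
        stay = ~leavers[i]
        pool_geno[i].append(g[stay])
        pool_natal[i].append(np.full(int(stay.sum()), i, dtype=np.int8))
        movers = g[leavers[i]]
        for j in (k for k in range(3) if k != i):
            sel = dest[i] == j
            n_mov = int(sel.sum())
            if n_mov:
                pool_geno[j].append(movers[sel])
                pool_natal[j].append(np.full(n_mov, i, dtype=np.int8))
                migrants[PAIR_INDEX[(i, j)]] += n_mov

    genotypes = [np.concatenate(gs, axis=0) for gs in pool_geno]
    natal = [np.concatenate(ns) for ns in pool_natal]
    for i, g in enumerate(genotypes):
        if len(g) == 0:
            raise ExtinctionError(
                f"island {ISLANDS[i]} emptied by migration at generation "
                f"{state.generation}"
            )
    return MatingPools(genotypes=genotypes, natal=natal), migrants


def _draw_parent_indices(
    weights: np.ndarray, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_draws`` pool indices with replacement, probability
    proportional to ``weights``."""
    cum = np.cumsum(weights)
    u = rng.random(n_draws) * cum[-1]
    return np.searchsorted(cum, u, side="right")


def _draw_parents_grouped(
    maladapted: np.ndarray,
    DS: float,
    ploidy: int,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Weighted parent draws exploiting the few-valued fitness weights.

    ``maladapted`` counts maladapted allele copies per pool member (0 or 1
    haploid; 0, 1 or 2 diploid), so the pool splits into at most three
    fitness groups with weights ``1 - DS * m / ploidy``.  A draw picks a
    group with probability proportional to (group size x group weight),
    then a member uniformly — equivalent to per-individual weighted
    sampling but O(1) per draw.
    """
    m_max = int(maladapted.max()) if len(maladapted) else 0
    if m_max == 0 or DS == 0.0:
        return rng.integers(0, len(maladapted), n_draws)
    groups = [np.flatnonzero(maladapted == m) for m in range(m_max + 1)]
    sizes = np.array([len(g) for g in groups], dtype=float)
    wg = 1.0 - DS * np.arange(m_max + 1) / ploidy
    pg = sizes * wg
    cum = np.cumsum(pg)
    labels = np.searchsorted(cum, rng.random(n_draws) * cum[-1], side="right")
    out = np.empty(n_draws, dtype=np.int64)
    for g, gi in enumerate(groups):
        sel = labels == g
        k = int(sel.sum())
        if k:
            out[sel] = gi[rng.integers(0, len(gi), k)]
    return out


def _mutate(genotypes: np.ndarray, params: SimulationParams, rng: np.random.Generator) -> None:
    """Symmetric per-allele mutation, in place.

    Biallelic loci flip with probability mu.  In the three-environment mode
    the adaptation locus is triallelic and steps to each of the two other
    alleles with probability mu/2.
    """
    if params.mu == 0.0:
        return
    u = rng.random(genotypes.shape)
    if params.n_env_types == 2:
        genotypes ^= (u < params.mu).astype(np.int8)
        return
    pl = params.ploidy
    adapt = genotypes[:, :pl]
    ua = u[:, :pl]
    shift = np.where(ua < params.mu / 2, 1, np.where(ua < params.mu, 2, 0))
    genotypes[:, :pl] = (adapt + shift) % 3
    disp = genotypes[:, pl:]
    disp ^= (u[:, pl:] < params.mu).astype(np.int8)


def reproduce(
    pools: MatingPools,
    params: SimulationParams,
    rng: np.random.Generator,
) -> tuple[PopulationState, np.ndarray | None]:
    """Selective mating with free recombination and mutation.

    For each island, exactly ``N_island`` offspring are produced; each
    offspring's two parents are drawn with replacement from the island's
    pool with probability proportional to local fitness weight, each locus
    is inherited from either parent with equal probability, and every
    allele then mutates independently.

    Returns the next :class:`PopulationState` and the per-pair counts of
    migrants that participated in mating.  In the default ``"matings"``
    mode every parent draw of a migrant counts (a locally maladapted
    migrant is drawn less often than it entered the pool, and a migrant
    drawn repeatedly counts repeatedly); ``"unique_parents"`` counts each
    migrant drawn at least once; in ``"pool"`` mode the counts are None
    (the caller uses the migration events instead).
    """
    next_genotypes = []
    count_mode = params.migrant_counting
    drawn_migrants = np.zeros(3, dtype=np.int64) if count_mode != "pool" else None
    pl = params.ploidy
    L = params.n_loci
    for i, isl in enumerate(ISLANDS):
        g = pools.genotypes[i]
        n_off = params.sizes[i]
        mal = _maladapted_counts(g, isl, params)
        idx = _draw_parents_grouped(mal, params.DS, params.ploidy, 2 * n_off, rng)
        pa, pb = idx[:n_off], idx[n_off:]
        if drawn_migrants is not None:
            natal = pools.natal[i]
            chosen = idx if count_mode == "matings" else np.unique(idx)
            origin_counts = np.bincount(natal[chosen], minlength=3)
            for origin in range(3):
                if origin != i and origin_counts[origin]:
                    drawn_migrants[PAIR_INDEX[(i, origin)]] += int(
                        origin_counts[origin]
                    )
        if pl == 1:
            ga, gb = g[pa], g[pb]
            pick = rng.random((n_off, L)) < 0.5
            off = np.where(pick, ga, gb)
        else:
            # one gamete per parent: per locus, a uniformly chosen copy
            ga = g[pa].reshape(n_off, L, 2)
            gb = g[pb].reshape(n_off, L, 2)
            pick_a = (rng.random((n_off, L)) < 0.5).astype(np.int8)
            pick_b = (rng.random((n_off, L)) < 0.5).astype(np.int8)
            gam_a = np.take_along_axis(ga, pick_a[:, :, None], axis=2)[:, :, 0]
            gam_b = np.take_along_axis(gb, pick_b[:, :, None], axis=2)[:, :, 0]
            off = np.empty((n_off, 2 * L), dtype=np.int8)
            off[:, 0::2] = gam_a
            off[:, 1::2] = gam_b
        off = np.ascontiguousarray(off, dtype=np.int8)
        _mutate(off, params, rng)
        next_genotypes.append(off)
    return PopulationState(generation=0, genotypes=next_genotypes), drawn_migrants


def _census(state: PopulationState, params: SimulationParams):
    pl = params.ploidy
    adapt_freq = []
    disp_freq = []
    for g in state.genotypes:
        adapt_freq.append(float((g[:, :pl] == 0).mean()))
        disp_freq.append(float((g[:, pl:] == 0).mean()))
    return tuple(adapt_freq), tuple(disp_freq)


def step_generation(
    state: PopulationState,
    params: SimulationParams,
    geometry: ArchipelagoGeometry,
    rng: np.random.Generator,
) -> tuple[PopulationState, GenerationRecord]:
    """Advance one generation: census, migrate, mate.

    The returned record carries the allele frequencies at birth of the
    *current* generation together with this generation's migration events.
    """
    adapt_freq, disp_freq = _census(state, params)
    pools, events = migrate(state, geometry, params, rng)
    new_state, drawn = reproduce(pools, params, rng)
    new_state.generation = state.generation + 1
    counts = drawn if drawn is not None else events
    record = GenerationRecord(
        generation=state.generation,
        adapt_freq=adapt_freq,
        dispersal_freq=disp_freq,
        migrants=tuple(int(c) for c in counts),
        migration_events=tuple(int(c) for c in events),
    )
    return new_state, record


# ---------------------------------------------------------------------------
# Genotype-class-count engine (haploid, q = 1, two environments)
#
# With a single dispersal locus there are only four haploid genotypes
# (adaptation allele x dispersal allele), so the population is fully
# described by per-island class counts and every step can be sampled
# exactly with binomial/multinomial draws over exchangeable individuals.
# This is the same stochastic model as the per-individual engine — only
# the representation differs — and it runs in O(1) time per generation
# regardless of population size.

#: class code g = 2 * adapt_allele + dispersal_allele
_N_CLASSES = 4


def _offspring_table() -> np.ndarray:
    """P(offspring class | parent classes), free recombination."""
    t = np.zeros((4, 4, 4))
    for g1 in range(4):
        a1, d1 = g1 >> 1, g1 & 1
        for g2 in range(4):
            a2, d2 = g2 >> 1, g2 & 1
            for g in range(4):
                a, d = g >> 1, g & 1
                pa = (1.0 if a == a1 else 0.0) / 2 + (1.0 if a == a2 else 0.0) / 2
                pd = (1.0 if d == d1 else 0.0) / 2 + (1.0 if d == d2 else 0.0) / 2
                t[g1, g2, g] = pa * pd
    return t


_OFFSPRING_P = _offspring_table()
#: XOR flip patterns for the two loci: none, dispersal, adaptation, both
_FLIP_PATTERNS = (0, 1, 2, 3)


def _class_weights(DS: float) -> np.ndarray:
    """Parent-draw weight per class on each island (island, class)."""
    w = np.ones((3, 4))
    w[0, 0] = w[0, 1] = 1.0 - DS  # allele 0 maladapted on A
    w[1, 2] = w[1, 3] = 1.0 - DS  # allele 1 maladapted on B
    w[2, 2] = w[2, 3] = 1.0 - DS  # ... and on C
    return w


def _run_counts(
    params: SimulationParams,
    geometry: ArchipelagoGeometry,
    detector: OnsetDetector,
    keep_records: bool,
) -> tuple[list[GenerationRecord], SpeciationResult]:
    rng = np.random.default_rng(params.seed)
    counts = np.zeros((3, 4), dtype=np.int64)
    counts[:, 0] = params.sizes  # all primitive at colonization
    sizes = np.asarray(params.sizes)
    M, mu = params.M, params.mu
    weights = _class_weights(params.DS)
    others = [(1, 2), (0, 2), (0, 1)]
    p_first = [
        geometry.dest_probs[ISLANDS[i]][ISLANDS[others[i][0]]] for i in range(3)
    ]
    count_matings = params.migrant_counting == "matings"
    mut_p = np.array(
        [(1 - mu) ** 2, mu * (1 - mu), mu * (1 - mu), mu * mu]
    )
    records: list[GenerationRecord] = []
    generation = 0
    while generation < params.max_generations:
        tot = counts.sum(axis=1)
        adapt_freq = tuple(counts[:, :2].sum(axis=1) / tot)
        disp_freq = tuple(counts[:, [0, 2]].sum(axis=1) / tot)

        # migration: only dispersal-primitive classes (0 and 2) can move
        pool = np.zeros((3, 4, 3), dtype=np.int64)  # island, class, natal
        events = np.zeros(3, dtype=np.int64)
        for i in range(3):
            pool[i, 1, i] = counts[i, 1]
            pool[i, 3, i] = counts[i, 3]
            for g in (0, 2):
                n = int(counts[i, g])
                leave = rng.binomial(n, M) if n and M > 0 else 0
                pool[i, g, i] += n - leave
                if leave:
                    j1, j2 = others[i]
                    to1 = rng.binomial(leave, p_first[i])
                    pool[j1, g, i] += to1
                    pool[j2, g, i] += leave - to1
                    events[PAIR_INDEX[(i, j1)]] += to1
                    events[PAIR_INDEX[(i, j2)]] += leave - to1
        pool_sizes = pool.sum(axis=(1, 2))
        if np.any(pool_sizes == 0):
            empty = ISLANDS[int(np.argmin(pool_sizes))]
            return records, SpeciationResult.censored_result(
                generation=generation,
                cutoff=params.simultaneous_cutoff,
                reason=(
                    f"island {empty} emptied by migration at generation "
                    f"{generation}"
                ),
            )

        # mating: joint parent-pair multinomial over (class, natal) cells
        mated = np.zeros(3, dtype=np.int64)
        for i in range(3):
            m = pool[i].reshape(12).astype(float)  # class-major x natal
            p = m * np.repeat(weights[i], 3)
            p /= p.sum()
            joint = rng.multinomial(
                int(sizes[i]), np.outer(p, p).ravel()
            ).reshape(12, 12)
            if count_matings:
                draws_per_cell = joint.sum(axis=1) + joint.sum(axis=0)
                natal_tot = draws_per_cell.reshape(4, 3).sum(axis=0)
                for o in range(3):
                    if o != i and natal_tot[o]:
                        mated[PAIR_INDEX[(i, o)]] += int(natal_tot[o])
            gp = joint.reshape(4, 3, 4, 3).sum(axis=(1, 3))
            off = np.zeros(4, dtype=np.int64)
            for g1 in range(4):
                for g2 in range(4):
                    c = int(gp[g1, g2])
                    if c:
                        off += rng.multinomial(c, _OFFSPRING_P[g1, g2])
            if mu > 0.0:
                mutated = np.zeros(4, dtype=np.int64)
                for g in range(4):
                    if off[g]:
                        fl = rng.multinomial(int(off[g]), mut_p)
                        for pat in _FLIP_PATTERNS:
                            mutated[g ^ pat] += fl[pat]
                off = mutated
            counts[i] = off

        migrant_series = mated if count_matings else events
        record = GenerationRecord(
            generation=generation,
            adapt_freq=adapt_freq,
            dispersal_freq=disp_freq,
            migrants=tuple(int(c) for c in migrant_series),
            migration_events=tuple(int(c) for c in events),
        )
        if keep_records:
            records.append(record)
        detector.update(np.asarray(record.migrants) / 2.0)
        generation += 1
        if detector.onset_second is not None:
            break
    return records, detector.result(
        generation=generation, cutoff=params.simultaneous_cutoff
    )


try:  # compiled fast path for record-free batch runs
    import numba as _numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @_numba.njit(cache=True)
    def _counts_kernel(
        seed,
        sizes,
        M,
        mu,
        DS,
        p_first,
        max_gen,
        window,
        threshold,
        count_matings,
        off_p,
    ):  # pragma: no cover - exercised via run_simulation
        """Record-free class-count run; returns (status, gen, onset1,
        onset2, first_isolated, extinct_island) with status 0 = second
        onset reached, 1 = generation cap, 2 = extinction."""
        np.random.seed(seed)
        counts = np.zeros((3, 4), np.int64)
        for i in range(3):
            counts[i, 0] = sizes[i]
        weights = np.ones((3, 4))
        weights[0, 0] = weights[0, 1] = 1.0 - DS
        weights[1, 2] = weights[1, 3] = 1.0 - DS
        weights[2, 2] = weights[2, 3] = 1.0 - DS
        mut_p = np.array([(1 - mu) ** 2, mu * (1 - mu), mu * (1 - mu), mu * mu])
        mut_p *= (1.0 - 1e-9) / mut_p.sum()
        others = np.array([[1, 2], [0, 2], [0, 1]])
        pair_idx = np.array([[-1, 0, 1], [0, -1, 2], [1, 2, -1]])
        buf = np.zeros((window, 3))
        sums = np.zeros(3)
        onset1 = -1
        onset2 = -1
        iso1 = -1
        gen = 0
        disp_classes = np.array([0, 2])
        while gen < max_gen:
            pool = np.zeros((3, 4, 3), np.int64)
            events = np.zeros(3, np.int64)
            for i in range(3):
                pool[i, 1, i] += counts[i, 1]
                pool[i, 3, i] += counts[i, 3]
                for ci in range(2):
                    gcl = disp_classes[ci]
                    n = counts[i, gcl]
                    leave = 0
                    if n > 0 and M > 0.0:
                        leave = np.random.binomial(n, M)
                    pool[i, gcl, i] += n - leave
                    if leave > 0:
                        j1, j2 = others[i, 0], others[i, 1]
                        to1 = np.random.binomial(leave, p_first[i])
                        pool[j1, gcl, i] += to1
                        pool[j2, gcl, i] += leave - to1
                        events[pair_idx[i, j1]] += to1
                        events[pair_idx[i, j2]] += leave - to1
            for i in range(3):
                if pool[i].sum() == 0:
                    return 2, gen, onset1, onset2, iso1, i
            mated = np.zeros(3, np.int64)
            for i in range(3):
                p = np.zeros(12)
                tot = 0.0
                for gcl in range(4):
                    for o in range(3):
                        v = pool[i, gcl, o] * weights[i, gcl]
                        p[gcl * 3 + o] = v
                        tot += v
                for a in range(12):
                    p[a] /= tot
                pp = np.zeros(144)
                pptot = 0.0
                for a in range(12):
                    for b in range(12):
                        v = p[a] * p[b]
                        pp[a * 12 + b] = v
                        pptot += v
                # deflate a hair below 1 so the conditional-binomial
                # sampler stays in range despite float drift
                scale = (1.0 - 1e-9) / pptot
                for a in range(144):
                    pp[a] *= scale
                joint = np.random.multinomial(sizes[i], pp)
                if count_matings:
                    for a in range(12):
                        o = a % 3
                        if o != i:
                            da = 0
                            for b in range(12):
                                da += joint[a * 12 + b] + joint[b * 12 + a]
                            mated[pair_idx[i, o]] += da
                gp = np.zeros((4, 4), np.int64)
                for a in range(12):
                    for b in range(12):
                        c = joint[a * 12 + b]
                        if c > 0:
                            gp[a // 3, b // 3] += c
                off = np.zeros(4, np.int64)
                for g1 in range(4):
                    for g2 in range(4):
                        c = gp[g1, g2]
                        if c > 0:
                            off += np.random.multinomial(c, off_p[g1, g2])
                if mu > 0.0:
                    mutated = np.zeros(4, np.int64)
                    for g in range(4):
                        if off[g] > 0:
                            fl = np.random.multinomial(off[g], mut_p)
                            for pat in range(4):
                                mutated[g ^ pat] += fl[pat]
                    off = mutated
                for g in range(4):
                    counts[i, g] = off[g]
            # rolling-window OMPG detection
            slot = gen % window
            for k in range(3):
                v = (mated[k] if count_matings else events[k]) / 2.0
                sums[k] += v - buf[slot, k]
                buf[slot, k] = v
            gen += 1
            if gen >= window and onset2 < 0:
                n_below = 0
                b0 = sums[0] / window < threshold
                b1 = sums[1] / window < threshold
                b2 = sums[2] / window < threshold
                if b0:
                    n_below += 1
                if b1:
                    n_below += 1
                if b2:
                    n_below += 1
                g_now = gen - 1
                if onset1 < 0 and n_below >= 2:
                    onset1 = g_now
                    if n_below == 3:
                        iso1 = -1
                    elif b0 and b1:
                        iso1 = 0  # A common to pairs A-B, A-C
                    elif b0 and b2:
                        iso1 = 1  # B
                    else:
                        iso1 = 2  # C
                if n_below == 3:
                    onset2 = g_now
                    return 0, gen, onset1, onset2, iso1, -1
        return 1, gen, onset1, onset2, iso1, -1


def _run_counts_compiled(
    params: SimulationParams, geometry: ArchipelagoGeometry
) -> tuple[list[GenerationRecord], SpeciationResult]:
    others = [(1, 2), (0, 2), (0, 1)]
    p_first = np.array(
        [geometry.dest_probs[ISLANDS[i]][ISLANDS[others[i][0]]] for i in range(3)]
    )
    status, gen, onset1, onset2, iso1, extinct = _counts_kernel(
        params.seed,
        np.asarray(params.sizes, dtype=np.int64),
        params.M,
        params.mu,
        params.DS,
        p_first,
        params.max_generations,
        params.window,
        params.ompg_threshold,
        params.migrant_counting == "matings",
        _OFFSPRING_P,
    )
    cutoff = params.simultaneous_cutoff
    first_isolated = ISLANDS[iso1] if iso1 >= 0 else None
    if status == 2:
        return [], SpeciationResult.censored_result(
            generation=gen,
            cutoff=cutoff,
            reason=(
                f"island {ISLANDS[extinct]} emptied by migration at "
                f"generation {gen}"
            ),
            onset_first=onset1 if onset1 >= 0 else None,
            first_isolated=first_isolated,
        )
    if status == 1:
        return [], SpeciationResult.censored_result(
            generation=gen,
            cutoff=cutoff,
            reason="max_generations reached before second onset",
            onset_first=onset1 if onset1 >= 0 else None,
            first_isolated=first_isolated,
        )
    interval = onset2 - onset1
    return [], SpeciationResult(
        onset_first=onset1,
        onset_second=onset2,
        interval=interval,
        simultaneous=interval <= cutoff,
        censored=False,
        first_isolated=first_isolated,
        n_generations=gen,
    )


def _counts_engine_applicable(params: SimulationParams) -> bool:
    return (
        params.ploidy == 1
        and params.q == 1
        and params.n_env_types == 2
        and params.migrant_counting != "unique_parents"
    )


def run_simulation(
    params: SimulationParams,
    keep_records: bool = True,
    engine: str = "auto",
) -> tuple[list[GenerationRecord], SpeciationResult]:
    """Run one replicate to the second speciation onset or the cap.

    Per-pair migrant counts are fed to the one-migrant-per-generation onset
    detector each generation; the run stops as soon as all three pairs have
    crossed below threshold (second onset) or at ``max_generations``
    (censored), or on chance extinction (censored with reason).

    ``engine`` selects the representation: ``"array"`` is the
    per-individual engine; ``"counts"`` is the exact genotype-class-count
    engine available for haploid q=1 two-environment runs (identical model,
    O(1) per generation in population size); ``"auto"`` picks ``"counts"``
    whenever applicable.  The two engines consume random numbers
    differently, so matched seeds give matched results only within one
    engine.

    Set ``keep_records=False`` to discard the per-generation time series
    (replicate batches only need the speciation result).
    """
    from .params import validate_params

    params = validate_params(params)
    geometry = build_geometry(params.x, params.y)
    detector = OnsetDetector(
        window=params.window, threshold=params.ompg_threshold
    )
    if engine not in ("auto", "array", "counts"):
        raise ValueError(f"unknown engine {engine!r}")
    if engine == "counts" and not _counts_engine_applicable(params):
        raise ValueError(
            "counts engine requires haploid q=1, two environments and "
            "migrant_counting != 'unique_parents'"
        )
    if engine == "counts" or (engine == "auto" and _counts_engine_applicable(params)):
        if not keep_records and _HAVE_NUMBA:
            return _run_counts_compiled(params, geometry)
        return _run_counts(params, geometry, detector, keep_records)

    rng = np.random.default_rng(params.seed)
    state = initialize_population(params)
    records: list[GenerationRecord] = []
    while state.generation < params.max_generations:
        try:
            state, record = step_generation(state, params, geometry, rng)
        except ExtinctionError as exc:
            return records, SpeciationResult.censored_result(
                generation=state.generation,
                cutoff=params.simultaneous_cutoff,
                reason=str(exc),
            )
        if keep_records:
            records.append(record)
        detector.update(np.asarray(record.migrants) / 2.0)
        if detector.onset_second is not None:
            break
    return records, detector.result(
        generation=state.generation, cutoff=params.simultaneous_cutoff
    )
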