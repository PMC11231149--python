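"""One-individual-at-a-time reference implementation of a single
generation, used as an independent oracle against the vectorized engine.

Deliberately naive: Python lists, one random draw per decision, no numpy
vectorization.  Shares only the parameter/geometry containers with the
package.
"""

import random

from islandrad.params import ISLANDS, PAIRS

PAIR_OF = {frozenset(p): k for k, p in enumerate(PAIRS)}


class NaiveIndividual:
    __slots__ = ("adapt", "disp", "natal")

    def __init__(self, adapt, disp, natal):
        self.adapt = adapt
        self.disp = list(disp)
        self.natal = natal


def naive_initial_population(params):
    pops = {}
    for isl, n in zip(ISLANDS, params.sizes):
        pops[isl] = [
            NaiveIndividual(0, [0] * params.q, isl) for _ in range(n)
        ]
    return pops


def naive_generation(pops, params, geometry, rnd: random.Random):
    """Migration then mating, one individual at a time.

    Returns (offspring pools, per-pair migration-event counts, per-pair
    mated-migrant draw counts).
    """
    # migration
    pools = {isl: [] for isl in ISLANDS}
    events = [0, 0, 0]
    for isl in ISLANDS:
        for ind in pops[isl]:
            p_move = params.M * (1 - sum(ind.disp) / params.q)
            if rnd.random() < p_move:
                others = [k for k in ISLANDS if k != isl]
                p_first = geometry.dest_probs[isl][others[0]]
                dest = others[0] if rnd.random() < p_first else others[1]
                pools[dest].append(ind)
                events[PAIR_OF[frozenset((isl, dest))]] += 1
            else:
                pools[isl].append(ind)

    # mating with divergent selection
    offspring = {isl: [] for isl in ISLANDS}
    mated = [0, 0, 0]
    for isl, n_off in zip(ISLANDS, params.sizes):
        pool = pools[isl]
        adapted_allele = 1 if isl == "A" else 0
        weights = [
            1.0 if ind.adapt == adapted_allele else 1.0 - params.DS
            for ind in pool
        ]
        for _ in range(n_off):
            parents = rnd.choices(pool, weights=weights, k=2)
            for par in parents:
                if par.natal != isl:
                    mated[PAIR_OF[frozenset((isl, par.natal))]] += 1
            a = parents[rnd.randrange(2)].adapt
            disp = [
                parents[rnd.randrange(2)].disp[l] for l in range(params.q)
            ]
            if params.mu > 0:
                if rnd.random() < params.mu:
                    a = 1 - a
                disp = [
                    (1 - d) if rnd.random() < params.mu else d for d in disp
                ]
            offspring[isl].append(NaiveIndividual(a, disp, isl))
    return offspring, events, mated
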