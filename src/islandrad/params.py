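"""Simulation parameters and archipelago geometry.

The model archipelago consists of three point islands in a dimensionless
plane.  Islands B and C are pinned at (-0.5, 0) and (0.5, 0); island A is
placed at a configurable (x, y).  All migration behaviour depends only on
the relative distances between islands ("strait widths"), so moving island
A alone spans every distinct three-island arrangement up to similarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

ISLANDS = ("A", "B", "C")
#: Unordered island pairs in canonical order.
PAIRS = (("A", "B"), ("A", "C"), ("B", "C"))
PAIR_LABELS = ("A-B", "A-C", "B-C")

B_COORD = (-0.5, 0.0)
C_COORD = (0.5, 0.0)


class ParameterError(ValueError):
    """A simulation parameter violates one of the model invariants."""


class GeometryError(ValueError):
    """An island placement is degenerate (two islands coincide)."""


@dataclass(frozen=True)
class SimulationParams:
    """All model constants and run controls.

    Parameters
    ----------
    x, y
        Coordinates of island A in the dimensionless plane.  Islands B and
        C sit at (-0.5, 0) and (0.5, 0).
    N_A, N_B, N_C
        Offspring produced per island per generation; also the census size
        of each island population at birth.
    mu
        Per-allele per-generation probability of a symmetric mutation flip.
    q
        Number of biallelic dispersal loci.  Each derived allele lowers the
        migration probability by ``M / q`` (``M / (2 q)`` per allele copy
        in the diploid mode).
    DS
        Divergent-selection strength: a locally maladapted adult is drawn
        as a parent with relative weight ``1 - DS`` versus 1.
    M
        Baseline migration probability of a fully primitive genotype.
    ploidy
        1 (haploid, default) or 2 (diploid mode).
    n_env_types
        2 (island A unique, B = C; default) or 3 (every island unique).
    window
        Span in generations of the trailing moving average applied to the
        per-pair migrant counts.
    ompg_threshold
        Mean migrants per population per generation below which a pair of
        islands counts as genetically isolated (one-migrant-per-generation
        rule).
    simultaneous_cutoff
        Largest speciation interval, in generations, classified as
        simultaneous speciation.
    max_generations
        Hard cap on run length; runs reaching it are censored.
    seed
        Base RNG seed for a single run.
    migrant_counting
        How migrants "participating in mating" are counted for the OMPG
        series.  ``"matings"`` (default) counts every parent draw of a
        migrant, so a migrant mating twice counts twice and a pool member
        never drawn counts zero; ``"pool"`` counts migrants on entering a
        mating pool; ``"unique_parents"`` counts migrants drawn at least
        once.  Migration events themselves are always recorded separately.
    """

    x: float = 0.0
    y: float = 0.0
    N_A: int = 100
    N_B: int = 100
    N_C: int = 100
    mu: float = 1e-4
    q: int = 1
    DS: float = 0.7
    M: float = 0.5
    ploidy: int = 1
    n_env_types: int = 2
    window: int = 50
    ompg_threshold: float = 1.0
    simultaneous_cutoff: int = 10
    max_generations: int = 1_000_000
    seed: int = 0
    migrant_counting: str = "matings"

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (self.N_A, self.N_B, self.N_C)

    @property
    def n_loci(self) -> int:
        """Loci per genome copy: one adaptation locus plus q dispersal loci."""
        return 1 + self.q

    def replace(self, **kwargs) -> "SimulationParams":
        return validate_params(replace(self, **kwargs))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def validate_params(params: SimulationParams) -> SimulationParams:
    """Check every model invariant, returning the (normalised) bundle.

    Raises :class:`ParameterError` naming the first violated invariant.
    """
    p = params
    for name in ("N_A", "N_B", "N_C"):
        n = getattr(p, name)
        if not isinstance(n, (int, np.integer)) or n < 2:
            raise ParameterError(f"{name} must be an integer >= 2, got {n!r}")
    if not 0.0 <= p.mu <= 1.0:
        raise ParameterError(f"mu must lie in [0, 1], got {p.mu!r}")
    if not isinstance(p.q, (int, np.integer)) or p.q < 1:
        raise ParameterError(f"q must be a positive integer, got {p.q!r}")
    if not 0.0 <= p.DS < 1.0:
        raise ParameterError(f"DS must lie in [0, 1), got {p.DS!r}")
    if not 0.0 <= p.M <= 1.0:
        raise ParameterError(f"M must lie in [0, 1], got {p.M!r}")
    if p.ploidy not in (1, 2):
        raise ParameterError(f"ploidy must be 1 or 2, got {p.ploidy!r}")
    if p.n_env_types not in (2, 3):
        raise ParameterError(f"n_env_types must be 2 or 3, got {p.n_env_types!r}")
    if p.window < 1:
        raise ParameterError(f"window must be >= 1, got {p.window!r}")
    if p.ompg_threshold <= 0:
        raise ParameterError(
            f"ompg_threshold must be positive, got {p.ompg_threshold!r}"
        )
    if p.simultaneous_cutoff < 0:
        raise ParameterError(
            f"simultaneous_cutoff must be >= 0, got {p.simultaneous_cutoff!r}"
        )
    if p.max_generations < p.window:
        raise ParameterError(
            f"max_generations ({p.max_generations}) must be >= window ({p.window})"
        )
    if p.migrant_counting not in ("matings", "pool", "unique_parents"):
        raise ParameterError(
            "migrant_counting must be 'matings', 'pool' or 'unique_parents', "
            f"got {p.migrant_counting!r}"
        )
    # Geometry degeneracy is a parameter error too: fail fast here.
    try:
        build_geometry(p.x, p.y)
    except GeometryError as exc:
        raise ParameterError(str(exc)) from exc
    return p


@dataclass(frozen=True)
class ArchipelagoGeometry:
    """Island coordinates, strait widths and derived migration geometry.

    ``dest_probs[origin]`` maps each of the two other islands to the
    probability that a migrant leaving ``origin`` heads there.  Destination
    choice weights each candidate island by the reciprocal of its distance,
    so for an individual leaving A::

        p_AB = (1/AB) / (1/AB + 1/AC) = AC / (AB + AC)

    ``isolation_index`` is log10(longest strait / shortest strait): 0 for an
    equilateral arrangement, growing as one island becomes remote.
    """

    coords: dict[str, tuple[float, float]]
    distances: dict[tuple[str, str], float]
    dest_probs: dict[str, dict[str, float]]
    isolation_index: float = field(default=0.0)

    def distance(self, i: str, j: str) -> float:
        return self.distances[tuple(sorted((i, j)))]

    @property
    def isolated_island(self) -> str:
        """The island not incident to the shortest strait.

        This is the island whose two incident straits are the longest,
        i.e. the geographically isolated member of the archipelago.
        """
        shortest = min(self.distances, key=self.distances.get)
        (other,) = set(ISLANDS) - set(shortest)
        return other


def build_geometry(x: float, y: float) -> ArchipelagoGeometry:
    """Construct the archipelago with island A at ``(x, y)``.

    Raises :class:`GeometryError` if A coincides with B or C.
    """
    coords = {"A": (float(x), float(y)), "B": B_COORD, "C": C_COORD}
    distances = {}
    for i, j in PAIRS:
        d = math.dist(coords[i], coords[j])
        if d == 0.0:
            raise GeometryError(
                f"islands {i} and {j} coincide at {coords[i]}; "
                "island A may not be placed on top of B or C"
            )
        distances[(i, j)] = d
    dest_probs: dict[str, dict[str, float]] = {}
    for origin in ISLANDS:
        others = [k for k in ISLANDS if k != origin]
        inv = {k: 1.0 / distances[tuple(sorted((origin, k)))] for k in others}
        total = sum(inv.values())
        dest_probs[origin] = {k: inv[k] / total for k in others}
    widths = list(distances.values())
    iso = math.log10(max(widths) / min(widths))
    return ArchipelagoGeometry(
        coords=coords,
        distances=distances,
        dest_probs=dest_probs,
        isolation_index=iso,
    )


def isolation_index(geometry: ArchipelagoGeometry) -> float:
    """log10(longest strait width / shortest strait width), always >= 0."""
    return geometry.isolation_index
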