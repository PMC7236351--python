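"""Core domain model: genomes as explicitly annotated linear chromosomes.

The simulator tracks the position of every gene and every transposable
element (TE) as a fixed-length interval on a single linear chromosome laid
over a non-coding background.  Genes and TEs are both 1000 bp, so the
chromosome length is always ``nc_bp + 1000 * (number of elements)``: every
insertion grows the chromosome by exactly 1000 bp and every excision shrinks
it by the same amount.  There is no sequence-level representation — an
element is just (kind, start) — and no mechanism for genes to be created or
destroyed, so the gene count of a genome is an invariant of a run.

Coordinates are 0-based, half-open: an element occupies ``[start,
start + 1000)``.  Element intervals never overlap and the element table is
kept sorted by start at all times.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

#: Length of every gene, in base pairs.
GENE_LENGTH = 1000
#: Length of every transposable element, in base pairs.
TE_LENGTH = 1000
#: Genes and TEs share one fixed element length.
ELEMENT_LENGTH = 1000
#: One simulation cycle stands for this many host generations; per-generation
#: rates from the literature are multiplied by it to give per-cycle rates.
GENERATIONS_PER_CYCLE = 10_000_000


def per_cycle_rate(per_generation_rate: float,
                   generations_per_cycle: int = GENERATIONS_PER_CYCLE) -> float:
    """Convert a per-element, per-generation rate into a per-cycle rate.

    A replicative transposition rate of 4e-8 per element per generation, for
    instance, corresponds to ``4e-8 * 1e7 = 0.4`` excisions per element per
    cycle.
    """
    return per_generation_rate * generations_per_cycle


class ElementKind(enum.IntEnum):
    """What an annotated interval on the chromosome is."""

    GENE = 0
    TE_ACTIVE = 1
    TE_INACTIVE = 2


class FitnessEffect(enum.Enum):
    """Category of a mutation's (or genic TE insertion's) effect on fitness."""

    LETHAL = "lethal"
    DELETERIOUS = "deleterious"
    NEUTRAL = "neutral"
    BENEFICIAL = "beneficial"


_EFFECT_ORDER = (
    FitnessEffect.LETHAL,
    FitnessEffect.DELETERIOUS,
    FitnessEffect.NEUTRAL,
    FitnessEffect.BENEFICIAL,
)


class EffectTable:
    """Categorical distribution over the four fitness-effect classes.

    Parameters are the probabilities of lethal, mildly deleterious, neutral
    and mildly beneficial outcomes, in that order; they must sum to 1.
    """

    __slots__ = ("probs", "_cum")

    def __init__(self, lethal: float, deleterious: float,
                 neutral: float, beneficial: float):
        p = np.asarray([lethal, deleterious, neutral, beneficial], dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"effect probabilities must be non-negative and sum to 1, got {p}")
        self.probs = p
        self._cum = np.cumsum(p)

    def sample(self, rng: np.random.Generator) -> FitnessEffect:
        """Draw one effect category."""
        i = int(np.searchsorted(self._cum, rng.random(), side="right"))
        return _EFFECT_ORDER[min(i, 3)]

    def sample_many(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` category codes (0=lethal .. 3=beneficial)."""
        codes = np.searchsorted(self._cum, rng.random(n), side="right")
        return np.minimum(codes, 3)

    def __eq__(self, other):
        return isinstance(other, EffectTable) and np.array_equal(self.probs, other.probs)

    def __hash__(self):
        return hash(tuple(self.probs))

    def __repr__(self):
        return f"EffectTable({', '.join(f'{p:g}' for p in self.probs)})"


#: Effect of a spontaneous host mutation (lethal 40%, deleterious 30%,
#: neutral 15%, beneficial 15%).
HOST_MUTATION_TABLE = EffectTable(0.40, 0.30, 0.15, 0.15)
#: Effect of a TE inserting into a gene (lethal 30%, deleterious 20%,
#: neutral 30%, beneficial 20%).
INSERTION_EFFECT_TABLE = EffectTable(0.30, 0.20, 0.30, 0.20)


class ProgenyDistribution:
    """Distribution over the number of copies (0-3) a TE reinserts after excising."""

    __slots__ = ("probs", "_cum")

    def __init__(self, p0: float, p1: float, p2: float, p3: float):
        p = np.asarray([p0, p1, p2, p3], dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"progeny probabilities must be non-negative and sum to 1, got {p}")
        self.probs = p
        self._cum = np.cumsum(p)

    @property
    def mean(self) -> float:
        """Expected number of reinserted copies per excision."""
        return float(np.dot(self.probs, [0, 1, 2, 3]))

    def sample(self, rng: np.random.Generator) -> int:
        i = int(np.searchsorted(self._cum, rng.random(), side="right"))
        return min(i, 3)

    def sample_many(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.minimum(np.searchsorted(self._cum, rng.random(n), side="right"), 3)

    def __eq__(self, other):
        return (isinstance(other, ProgenyDistribution)
                and np.array_equal(self.probs, other.probs))

    def __hash__(self):
        return hash(tuple(self.probs))

    def __repr__(self):
        return f"ProgenyDistribution({', '.join(f'{p:g}' for p in self.probs)})"


#: Aggressive reinsertion: never lost on excision, up to 3 copies (mean 1.60).
PROGENY_HIGH = ProgenyDistribution(0.00, 0.55, 0.30, 0.15)
#: Restrained reinsertion: 15% of excisions are lost outright (mean 1.15).
PROGENY_LOW = ProgenyDistribution(0.15, 0.55, 0.30, 0.00)


class PositionDistribution:
    """A probability density over relative chromosome position in [0, 1).

    Insertion positions are sampled in relative coordinates and rescaled to
    the current chromosome length, so biased zones track the chromosome as it
    grows.  Three shapes exist:

    ``uniform``
        every position equally likely (the Low-bias scenario for both genes
        and TEs);
    ``gene_biased``
        density decreasing linearly from the left end to zero at 80% of the
        chromosome — gene-rich left end;
    ``te_biased``
        the mirror image, increasing linearly from zero at 20% — TEs prefer
        the gene-poor right end, with a 20-80% overlap zone where both
        genes lie and TEs insert.
    """

    __slots__ = ("shape",)

    _SHAPES = ("uniform", "gene_biased", "te_biased")

    def __init__(self, shape: str):
        if shape not in self._SHAPES:
            raise ValueError(f"unknown shape {shape!r}; expected one of {self._SHAPES}")
        self.shape = shape

    def sample_relative(self, rng: np.random.Generator, size=None):
        """Draw relative positions in [0, 1) by inverse-CDF sampling."""
        u = rng.random(size)
        if self.shape == "uniform":
            return u
        if self.shape == "gene_biased":
            return 0.8 * (1.0 - np.sqrt(1.0 - u))
        return 0.2 + 0.8 * np.sqrt(u)

    def pdf(self, x):
        """Density at relative position ``x`` (vectorized)."""
        x = np.asarray(x, dtype=float)
        if self.shape == "uniform":
            return np.where((x >= 0) & (x < 1), 1.0, 0.0)
        if self.shape == "gene_biased":
            return np.where((x >= 0) & (x < 0.8), 2.5 * (1.0 - x / 0.8), 0.0)
        return np.where((x >= 0.2) & (x < 1.0), 2.5 * (x - 0.2) / 0.8, 0.0)

    def __eq__(self, other):
        return isinstance(other, PositionDistribution) and self.shape == other.shape

    def __hash__(self):
        return hash(self.shape)

    def __repr__(self):
        return f"PositionDistribution({self.shape!r})"


UNIFORM = PositionDistribution("uniform")
GENE_BIASED = PositionDistribution("gene_biased")
TE_BIASED = PositionDistribution("te_biased")


def insertion_distributions(bias: str):
    """Return ``(gene_distribution, te_distribution)`` for a bias level.

    ``"H"`` gives the biased pair (genes left, TE insertions right);
    ``"L"`` gives uniform distributions for both.
    """
    if bias == "H":
        return GENE_BIASED, TE_BIASED
    if bias == "L":
        return UNIFORM, UNIFORM
    raise ValueError(f"insertion bias must be 'H' or 'L', got {bias!r}")


def sample_position(dist: PositionDistribution, genome_length: int,
                    rng: np.random.Generator) -> int:
    """Sample a base-pair offset in ``[0, genome_length)`` from ``dist``.

    The relative draw is scaled to the current chromosome length, so the same
    distribution object serves throughout a run as the genome grows.
    """
    if genome_length <= 0:
        raise ValueError(f"genome_length must be positive, got {genome_length}")
    pos = int(dist.sample_relative(rng) * genome_length)
    return min(pos, genome_length - 1)


@dataclass(frozen=True)
class Element:
    """An annotated interval ``[start, start + length)`` on the chromosome."""

    kind: ElementKind
    start: int
    length: int = ELEMENT_LENGTH

    @property
    def end(self) -> int:
        return self.start + self.length


class Genome:
    """A linear chromosome: non-coding background plus sorted 1000-bp elements.

    Internally the element table is a pair of parallel numpy buffers
    (``starts``, ``kinds``) kept sorted by start, with spare capacity so that
    inserting or deleting an element is a contiguous memmove plus a suffix
    shift — cheap even with thousands of TEs.  ``starts`` and ``kinds`` are
    views onto the live prefix of the buffers.
    """

    __slots__ = ("nc_bp", "_n", "_starts", "_kinds")

    def __init__(self, nc_bp: int, starts=None, kinds=None):
        if nc_bp <= 0:
            raise ValueError(f"nc_bp must be positive, got {nc_bp}")
        self.nc_bp = int(nc_bp)
        s = (np.array([], dtype=np.int64) if starts is None
             else np.asarray(starts, dtype=np.int64))
        k = (np.array([], dtype=np.int8) if kinds is None
             else np.asarray(kinds, dtype=np.int8))
        if s.shape != k.shape:
            raise ValueError("starts and kinds must have matching shapes")
        self._n = int(s.size)
        cap = max(8, self._n)
        self._starts = np.empty(cap, dtype=np.int64)
        self._kinds = np.empty(cap, dtype=np.int8)
        self._starts[:self._n] = s
        self._kinds[:self._n] = k

    @property
    def starts(self) -> np.ndarray:
        """Element start coordinates, sorted ascending (live view)."""
        return self._starts[:self._n]

    @property
    def kinds(self) -> np.ndarray:
        """Element kinds, parallel to :attr:`starts` (live view)."""
        return self._kinds[:self._n]

    def _insert_at(self, j: int, start: int, kind: ElementKind) -> None:
        n = self._n
        if n == self._starts.size:
            self._starts = np.concatenate(
                [self._starts, np.empty(max(8, n), dtype=np.int64)])
            self._kinds = np.concatenate(
                [self._kinds, np.empty(max(8, n), dtype=np.int8)])
        self._starts[j + 1:n + 1] = self._starts[j:n]
        self._kinds[j + 1:n + 1] = self._kinds[j:n]
        self._starts[j] = start
        self._kinds[j] = np.int8(kind)
        self._n = n + 1

    def _delete_at(self, j: int) -> None:
        n = self._n
        self._starts[j:n - 1] = self._starts[j + 1:n]
        self._kinds[j:n - 1] = self._kinds[j + 1:n]
        self._n = n - 1

    # -- derived quantities -------------------------------------------------
    @property
    def n_elements(self) -> int:
        return self._n

    @property
    def length(self) -> int:
        """Total chromosome length: non-coding bp plus 1000 bp per element."""
        return self.nc_bp + ELEMENT_LENGTH * self.n_elements

    @property
    def n_genes(self) -> int:
        return int(np.count_nonzero(self.kinds == ElementKind.GENE))

    @property
    def n_active_te(self) -> int:
        return int(np.count_nonzero(self.kinds == ElementKind.TE_ACTIVE))

    @property
    def n_inactive_te(self) -> int:
        return int(np.count_nonzero(self.kinds == ElementKind.TE_INACTIVE))

    @property
    def elements(self) -> list[Element]:
        return [Element(ElementKind(k), int(s))
                for s, k in zip(self.starts, self.kinds)]

    def copy(self) -> "Genome":
        return Genome(self.nc_bp, self.starts.copy(), self.kinds.copy())

    def __eq__(self, other):
        return (isinstance(other, Genome)
                and self.nc_bp == other.nc_bp
                and np.array_equal(self.starts, other.starts)
                and np.array_equal(self.kinds, other.kinds))

    def __repr__(self):
        return (f"Genome(nc_bp={self.nc_bp}, genes={self.n_genes}, "
                f"active_te={self.n_active_te}, inactive_te={self.n_inactive_te})")


def _containing_index(genome: Genome, position: int) -> int:
    """Index of the element whose interval contains ``position``, else -1."""
    i = int(np.searchsorted(genome.starts, position, side="right")) - 1
    if i >= 0 and position < genome.starts[i] + ELEMENT_LENGTH:
        return i
    return -1


def classify_site(genome: Genome, position: int) -> Element | None:
    """Return the element containing ``position``, or ``None`` for non-coding.

    ``position`` must lie in ``[0, genome.length)``; intervals are half-open,
    so the base at an element's ``end`` belongs to whatever follows it.
    """
    if not 0 <= position < genome.length:
        raise ValueError(
            f"position {position} outside genome of length {genome.length}")
    i = _containing_index(genome, position)
    if i < 0:
        return None
    return Element(ElementKind(genome.kinds[i]), int(genome.starts[i]))


@dataclass(frozen=True)
class InsertionOutcome:
    """What an insertion landed in, and the coordinate shifts it caused.

    ``site`` is one of ``"noncoding"``, ``"gene"``, ``"te"``.  ``shift_from``
    is the old coordinate from which downstream starts moved +1000 bp; callers
    tracking element positions across insertions use it to update their own
    bookkeeping.  ``dest_start`` is the (unshifted) start of the element that
    was hit, if any.
    """

    site: str
    new_start: int
    shift_from: int
    dest_start: int | None = None
    dest_kind: ElementKind | None = None


def _insert_element(genome: Genome, position: int, kind: ElementKind,
                    deactivate_dest_te: bool = False) -> InsertionOutcome:
    """Insert a 1000-bp element of ``kind`` at ``position`` (in-place).

    A position inside an existing element does not split it: the incoming
    element is placed immediately after the destination element, which keeps
    every interval exactly 1000 bp and pairwise disjoint.  With
    ``deactivate_dest_te`` a destination TE is marked permanently inactive.
    """
    if not 0 <= position < genome.length:
        raise ValueError(
            f"position {position} outside genome of length {genome.length}")
    i = _containing_index(genome, position)
    if i < 0:
        site, dest_start, dest_kind = "noncoding", None, None
        shift_from = position
    else:
        dest_start = int(genome.starts[i])
        dest_kind = ElementKind(genome.kinds[i])
        site = "gene" if dest_kind == ElementKind.GENE else "te"
        shift_from = dest_start + ELEMENT_LENGTH
        if deactivate_dest_te and dest_kind != ElementKind.GENE:
            genome.kinds[i] = ElementKind.TE_INACTIVE
    # starts are sorted, so everything shifting (start >= shift_from) is the
    # suffix beginning at the insertion index
    j = int(np.searchsorted(genome.starts, shift_from, side="left"))
    genome.starts[j:] += ELEMENT_LENGTH
    genome._insert_at(j, shift_from, kind)
    return InsertionOutcome(site, shift_from, shift_from, dest_start, dest_kind)


def insert_te(genome: Genome, position: int) -> InsertionOutcome:
    """Insert a new active TE at ``position`` (in-place).

    The chromosome grows by exactly 1000 bp and downstream elements shift
    right.  A destination TE (active or already inactive) is rendered
    permanently inactive; a destination gene is left in place — the gene
    count never changes — and the ``"gene"`` outcome tells the caller to
    apply the insertion-effect draw to the host's survival likelihood.
    """
    return _insert_element(genome, position, ElementKind.TE_ACTIVE,
                           deactivate_dest_te=True)


def excise_te(genome: Genome, start: int) -> None:
    """Remove the active TE whose interval begins at ``start`` (in-place).

    The chromosome shrinks by 1000 bp and downstream elements shift left.
    Only active TEs may excise; asking to excise a gene, an inactive TE or a
    position with no element is a contract violation.
    """
    i = int(np.searchsorted(genome.starts, start, side="left"))
    if i >= genome.n_elements or genome.starts[i] != start:
        raise ValueError(f"no element starts at {start}")
    if genome.kinds[i] != ElementKind.TE_ACTIVE:
        raise ValueError(f"element at {start} is not an active TE")
    genome._delete_at(i)
    # all remaining elements from i onward lay strictly downstream
    genome.starts[i:] -= ELEMENT_LENGTH


@dataclass
class Host:
    """A host organism: one genome plus a non-negative survival likelihood.

    The likelihood starts at 1, is driven to exactly 0 by a lethal event,
    never goes below 0, and has no upper cap.
    """

    genome: Genome
    survival_likelihood: float = 1.0

    def clone(self) -> "Host":
        """Deep copy: the clone's genome is independent of the parent's."""
        return Host(self.genome.copy(), self.survival_likelihood)


@dataclass
class ParameterSet:
    """All fixed and varied parameters of one experimental condition.

    The eight varied parameters each take a High or Low value in the
    factorial design (see :mod:`transposim.experiments`); ``initial_genes``
    and ``host_mutation_rate`` move together as the single "corrected
    mutation rate" factor, because the mutation rate is per host rather than
    per gene.  Defaults are the all-Low condition.
    """

    carrying_capacity: int = 30
    mutation_effect: float = 0.01
    nc_bp: int = 1_400_000
    initial_genes: int = 500
    host_mutation_rate: float = 0.03
    insertion_bias: str = "L"
    te_death_rate: float = 0.005
    te_excision_rate: float = 0.1
    te_progeny: ProgenyDistribution = field(default=PROGENY_LOW)
    gene_length: int = GENE_LENGTH
    te_length: int = TE_LENGTH
    host_mutation_table: EffectTable = field(default=HOST_MUTATION_TABLE)
    insertion_effect_table: EffectTable = field(default=INSERTION_EFFECT_TABLE)
    max_cycles: int = 500
    seed: int | None = None
    design: tuple | None = None

    def __post_init__(self):
        if self.carrying_capacity < 1:
            raise ValueError("carrying_capacity must be >= 1")
        if self.nc_bp <= 0:
            raise ValueError("nc_bp must be positive")
        if self.initial_genes < 0:
            raise ValueError("initial_genes must be >= 0")
        for name in ("host_mutation_rate", "te_death_rate", "te_excision_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.mutation_effect < 0:
            raise ValueError("mutation_effect must be >= 0")
        if self.insertion_bias not in ("H", "L"):
            raise ValueError("insertion_bias must be 'H' or 'L'")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")

    @property
    def gene_distribution(self) -> PositionDistribution:
        return insertion_distributions(self.insertion_bias)[0]

    @property
    def te_distribution(self) -> PositionDistribution:
        return insertion_distributions(self.insertion_bias)[1]

    def to_dict(self) -> dict:
        """Flat config mapping; keys use the field's conventional names."""
        return {
            "Carrying_capacity": self.carrying_capacity,
            "Mutation_effect": self.mutation_effect,
            "NC_BP": self.nc_bp,
            "Initial_genes": self.initial_genes,
            "Host_mutation_rate": self.host_mutation_rate,
            "Insertion_bias": self.insertion_bias,
            "TE_death_rate": self.te_death_rate,
            "TE_excision_rate": self.te_excision_rate,
            "TE_progeny": [float(p) for p in self.te_progeny.probs],
            "Gene_length": self.gene_length,
            "TE_length": self.te_length,
            "Host_mutation": [float(p) for p in self.host_mutation_table.probs],
            "Insertion_effect": [float(p) for p in self.insertion_effect_table.probs],
            "max_cycles": self.max_cycles,
            "seed": self.seed,
            "design": list(self.design) if self.design is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        design = d.get("design")
        return cls(
            carrying_capacity=int(d["Carrying_capacity"]),
            mutation_effect=float(d["Mutation_effect"]),
            nc_bp=int(d["NC_BP"]),
            initial_genes=int(d["Initial_genes"]),
            host_mutation_rate=float(d["Host_mutation_rate"]),
            insertion_bias=str(d["Insertion_bias"]),
            te_death_rate=float(d["TE_death_rate"]),
            te_excision_rate=float(d["TE_excision_rate"]),
            te_progeny=ProgenyDistribution(*d.get("TE_progeny", PROGENY_LOW.probs)),
            gene_length=int(d.get("Gene_length", GENE_LENGTH)),
            te_length=int(d.get("TE_length", TE_LENGTH)),
            host_mutation_table=EffectTable(
                *d.get("Host_mutation", HOST_MUTATION_TABLE.probs)),
            insertion_effect_table=EffectTable(
                *d.get("Insertion_effect", INSERTION_EFFECT_TABLE.probs)),
            max_cycles=int(d.get("max_cycles", 500)),
            seed=None if d.get("seed") is None else int(d["seed"]),
            design=None if design is None else tuple(design),
        )


def init_genome(params: ParameterSet, rng: np.random.Generator) -> Genome:
    """Build the founder genome: non-coding background, genes, one active TE.

    Genes are inserted one at a time at positions drawn from the gene
    insertion distribution (each insertion growing the chromosome by
    1000 bp), then a single founder TE is placed from the TE insertion
    distribution.  The founder insertion applies no fitness effect.
    """
    if params.nc_bp <= 0:
        raise ValueError("NC_BP must be positive")
    if params.initial_genes < 0:
        raise ValueError("Initial_genes must be >= 0")
    genome = Genome(params.nc_bp)
    gene_dist, te_dist = insertion_distributions(params.insertion_bias)
    for _ in range(params.initial_genes):
        pos = sample_position(gene_dist, genome.length, rng)
        _insert_element(genome, pos, ElementKind.GENE)
    pos = sample_position(te_dist, genome.length, rng)
    _insert_element(genome, pos, ElementKind.TE_ACTIVE)
    return genome
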