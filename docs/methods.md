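# Methods

## Model

`transposim` simulates a clonal population of single-celled hosts, each
carrying one linear chromosome on which every gene and transposable element
(TE) is an explicit, fixed-length interval. The model is deliberately
minimal: no nucleotide sequence, no introns, no recombination, no
horizontal transfer, and no evolution of TE or host properties within a
run. TEs interact with the host only through two channels — insertions
into genes perturb the host's survival likelihood, and the growing mass of
TE-derived DNA changes the target landscape for future insertions.

### Genome representation

A genome is a non-coding background of `nc_bp` base pairs plus a sorted
table of elements, each occupying a half-open interval `[start,
start+1000)`. Genes and TEs are both 1000 bp, so the chromosome length is
identically `nc_bp + 1000 × (element count)`. Inserting an element grows
the chromosome by 1000 bp and shifts everything downstream; excising an
active TE reverses that. An insertion whose sampled position falls inside
an existing element does not split it: the incoming TE is placed
immediately after the destination element. This adjacency convention keeps
every element exactly 1000 bp and the interval table disjoint while
preserving all counts; functionally it is equivalent to splitting the
destination and tracking the fragments as one element. A destination TE
(active or not) is rendered permanently inactive; a destination gene stays
in place — genes are never created or destroyed, so the gene count is a
run invariant — and the host takes an insertion-effect draw instead.

Internally the element table is a pair of capacity-backed numpy buffers
(starts and kinds) with suffix-shift updates, so a single
insertion/excision costs a binary search plus one contiguous move. This
matters because persistent runs grow exponentially in element count.

### Initialization

A founder genome receives `initial_genes` genes one at a time at positions
drawn from the gene insertion distribution, then a single active founder
TE from the TE insertion distribution (the founder insertion applies no
fitness effect — at this point there is nothing meaningful to damage, and
the choice is recorded here because it is not forced by anything else in
the model). The founder host (survival likelihood 1) is cloned to exactly
the carrying capacity.

### Position distributions and insertion bias

Insertion positions are sampled in *relative* coordinates on [0, 1) and
scaled to the current chromosome length, so biased zones track the genome
as it grows. Low bias uses uniform distributions for both genes and TE
insertions. High bias concentrates genes at the left end (density falling
linearly to zero at 80% of the chromosome) and TE insertions at the right
end (the mirror image, rising from zero at 20%), leaving a broad overlap
zone in which genes lie and TEs still land. The triangular shapes are a
modelling choice; only the qualitative structure — opposite ends, with
overlap — carries meaning.

### The cycle

Each cycle stands for ~10⁷ host generations; published per-generation
rates are multiplied by that factor (`per_cycle_rate`), e.g. a replicative
transposition rate of 4×10⁻⁸/element/generation becomes 0.4/element/cycle.
The eight steps run in a fixed order (clone → clone mutation → TE death →
excision → reinsertion with effects → selection), with these resolutions
of points the step list leaves open:

- only clones take the step-2 mutation draw, at most one per clone per
  cycle; parents are not re-mutated;
- TE death is evaluated before excision, so no TE both dies and excises in
  one cycle;
- per-TE events (death, excision, progeny count, positions) are
  independent draws; there is no within-genome coupling;
- the copies an excised TE reinserts are placed sequentially, each
  position drawn from the genome as already modified; copies inserted this
  cycle are not death/excision candidates until the next cycle;
- if a reinsertion lands inside a TE that is itself still awaiting
  excision this cycle, the destination is inactivated and loses its turn
  (only active TEs excise);
- survival probabilities are clamped at 1 (the normalization can exceed 1
  in small populations); survival likelihoods are clamped at 0 from below
  and uncapped above;
- all randomness flows through one numpy `Generator` per run, so a
  (parameter set, seed) pair reproduces a trajectory bit for bit.

Termination is checked after selection: host extinction (no hosts) takes
precedence over TE extinction (no active TEs anywhere); a run that reaches
the cycle cap with both present is TE accumulation. The cap replaces a
fixed walltime budget so that results are machine-independent; it is a
free parameter reported with every result.

One asymmetry worth noting: an excised TE whose progeny draw is 0 removes
1000 bp from the chromosome. Excision-loss is therefore the model's only
deletion channel; everywhere else DNA only accumulates.

## Parameters

Fixed: gene and TE length 1000 bp; host-mutation effect table
lethal/deleterious/neutral/beneficial = 40/30/15/15%; genic-insertion
effect table 30/20/30/20%. Varied (High/Low factorial levels):

| factor | High | Low |
|---|---|---|
| carrying capacity K (hosts) | 300 | 30 |
| mutation effect E | 0.1 | 0.01 |
| non-coding background (bp) | 14×10⁶ | 1.4×10⁶ |
| corrected mutation rate (genes, μ/host/cycle) | (5000, 0.3) | (500, 0.03) |
| insertion bias | biased ends | uniform |
| TE death rate d (/TE/cycle) | 0.0005 | 0.005 |
| TE excision rate e (/TE/cycle) | 0.5 | 0.1 |
| TE progeny (P(0..3 copies)) | 0/.55/.30/.15 | .15/.55/.30/0 |

"High" throughout means high *TE proliferation*, which is why the High
death rate is the numerically smaller one. The corrected-mutation-rate
factor moves gene count and host mutation rate together because the
mutation rate is per host: ten-fold more genes implies a ten-fold higher
chance that some gene mutates. Mild fitness effects are ±U(0,1)·E.

The grid has 2⁸ = 256 design points; the reference experiment runs each 3
times (768 runs). Run seeds derive from `SeedSequence(base_seed,
spawn_key=(design_index, replicate))`, so results are independent of
execution order and safe to parallelize externally.

## Metrics and the plateau detector

Per cycle the engine records hosts alive, mean active TEs per host, mean
genome size, and mean TE density. Density is computed per host (active
TEs / that host's genome length) and then averaged — not as the ratio of
the two population means, though that variant is available
(`compute_density_series(..., method="ratio_of_means")`) and the choice is
recorded in the per-run output metadata.

`detect_plateau` smooths a series with a rolling mean of `window` cycles
(default 50) and flags a plateau when adjacent windowed means differ by at
most `tolerance` (default 5%) from there to the end of the series, with
the onset reported as the first cycle of the earlier window of the first
persistently flat comparison. Comparing windowed means rather than raw
values makes the verdict about the *level* of the series: a per-host-
averaged density over a few dozen hosts fluctuates several percent cycle
to cycle even deep in a plateau, and a raw-range criterion at any useful
tolerance would reject genuine plateaus. A series shorter than two
windows yields an "insufficient data" verdict (`plateau=None`).

## Problem sizes

Runs whose TE load grows exponentially become quadratically more expensive
(per-cycle work scales with element count times event count), so grid-scale
work uses a desk preset: the Low-carrying-capacity half of the grid (128
designs), one replicate, 150-cycle cap — about two minutes on one CPU.
Two consequences of the reduced cap: slow purges that would end in TE
extinction at full scale are classified as accumulation (the desk
accumulation share is therefore inflated relative to the full-scale
reference mix of roughly 75% TE extinction / 22% host extinction / 3%
accumulation), and absolute abundances stay modest. The direction of the
regime — TE extinction most frequent, host extinction a minority,
accumulation rarest at matched caps — is stable across base seeds.

The conservation test suite checks gene count, the length identity and
interval disjointness after every cycle of 20 randomly drawn Low-capacity
conditions capped at 200 cycles. The plateau test engineers an
accumulation-friendly regime (no TE death, restrained excision with
always-two progeny, biased insertion, fitness-neutral genic hits, 60
hosts, small background) so that the density plateau emerges within ~170
cycles while abundance is still climbing; neutralizing fitness isolates
the habitat-saturation mechanism from selection noise.

## What the synthetic conditions do and do not show

All inputs are synthetic by construction — the model is the object of
study, and the factorial conditions are its study design. Passing tests
demonstrate internal consistency (conservation laws, seeded determinism,
correct distributional behaviour) and the qualitative phenomena the model
is built to exhibit (the three-way outcome taxonomy, density saturation
under restrained transposition). They do not validate the parameter
values against any real organism, and the fixed 1000-bp element size,
single uncapped fitness scalar, and per-host mutation draw are idealized
stand-ins for far richer biology.

## Known limitations

- Element coordinates are bookkeeping, not sequence; "mutation" and
  "inactivation" are rate parameters, not molecular events.
- The survival-likelihood scalar is heritable and unbounded above; a long
  run of beneficial draws can make a lineage near-immortal under
  selection, which real fitness landscapes would not sustain.
- Population-level metrics are noisy at Low carrying capacity; density
  plateau calls on single runs need the windowed-mean smoothing and are
  not meaningful for populations of a handful of hosts.
- The cycle cap is a free parameter: outcome proportions at small caps are
  not comparable with effectively uncapped references, only their ordering
  is.
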