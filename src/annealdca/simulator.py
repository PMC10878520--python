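"""Synthetic selection-and-sequencing experiments with known ground truth.

A Wright–Fisher-with-selection style generative process: an initial library
of N individuals is drawn from P_0 ∝ e^{−G}; each round optionally applies
per-site mutagenesis (the experimental-evolution regime), then survival
reweighting p_v ∝ c_v · e^{−α_t E(v)} followed by a multinomial resample
back to constant N. A subset of rounds is "sequenced" by a further
multinomial draw of finite depth, which reproduces the undersampling regime
of repertoire sequencing when depth ≪ library diversity.

Under this process (μ = 0) the expected round-t composition is exactly the
annealed distribution P_t ∝ e^{−β_t E − G} with β_t = Σ_{t'≤t} α_{t'}, so
the exact-oracle module can validate the simulator and vice versa.

Randomness: a single seed expands into independent per-stage streams via
``np.random.SeedSequence.spawn`` in a fixed order (truth-E, truth-G,
library, then one stream per round for mutation/selection and one per
sequenced round), so any stage is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.special import softmax

from .data_model import Alphabet, ScreeningDataset, SequenceRound
from .energy_models import PottsEnergy, one_hot
from .errors import DataError, NumericError
from .exact_oracle import MAX_ENUMERATION, enumerate_sequences

_MUTATE_CHUNK = 2_000_000  # expanded individuals per block


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Populations and ground-truth energies
# ---------------------------------------------------------------------------

@dataclass
class Population:
    """A variant count table: unique sequences with positive counts."""

    sequences: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype=np.uint8)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts <= 0):
            raise DataError("population counts must be positive")

    @property
    def size(self) -> int:
        return int(self.counts.sum())

    @property
    def n_variants(self) -> int:
        return self.sequences.shape[0]

    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @staticmethod
    def from_individuals(individuals: np.ndarray) -> "Population":
        uniq, inv = np.unique(individuals, axis=0, return_inverse=True)
        return Population(uniq, np.bincount(inv.ravel()).astype(np.int64))


@dataclass
class EnergyPrior:
    """Random ground-truth energy generator.

    Fields are i.i.d. Normal(0, field_scale); with ``pairwise``, each i < j
    coupling block is present with probability ``coupling_density`` and its
    entries are i.i.d. Normal(0, coupling_scale).
    """

    field_scale: float = 1.0
    coupling_scale: float = 0.0
    coupling_density: float = 1.0
    pairwise: bool = False

    def sample(self, L: int, q: int, seed) -> PottsEnergy:
        rng = _rng(seed)
        h = rng.normal(0.0, self.field_scale, size=(L, q))
        if not self.pairwise:
            return PottsEnergy(h)
        J = np.zeros((L, L, q, q))
        for i in range(L):
            for j in range(i + 1, L):
                if rng.random() < self.coupling_density:
                    block = rng.normal(0.0, self.coupling_scale, size=(q, q))
                    J[i, j] = block
                    J[j, i] = block.T
        return PottsEnergy(h, J)


@dataclass
class SimConfig:
    """Study conditions for one synthetic experiment.

    ``alpha_schedule`` gives the selective pressure α_t > 0 of each round
    t = 1..T; ``sequenced_rounds`` is the subset τ of {0, ..., T} that gets
    sequenced at ``sequencing_depth`` reads. ``mutation_rate`` is the
    per-site per-round substitution probability (0 = DMS-like fixed
    library). Energies may be concrete :class:`PottsEnergy` instances or
    :class:`EnergyPrior` generators sampled from the seed.
    """

    L: int
    q: int
    truth_E: PottsEnergy | EnergyPrior
    truth_G: PottsEnergy | EnergyPrior
    alpha_schedule: tuple[float, ...]
    population_size: int
    sequencing_depth: int
    sequenced_rounds: tuple[int, ...]
    initial_library_size: int | None = None
    mutation_rate: float = 0.0
    gibbs_burn_in: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        self.alpha_schedule = tuple(float(a) for a in self.alpha_schedule)
        self.sequenced_rounds = tuple(sorted(int(t) for t in self.sequenced_rounds))
        T = len(self.alpha_schedule)
        if any(a <= 0 for a in self.alpha_schedule):
            raise DataError("selective pressures alpha_t must be positive")
        if not all(0 <= t <= T for t in self.sequenced_rounds):
            raise DataError(f"sequenced rounds must lie in [0, {T}]")
        if min(self.population_size, self.sequencing_depth) < 1:
            raise DataError("population size and sequencing depth must be positive")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise DataError("mutation rate must be in [0, 1)")


@dataclass
class SimulationTruth:
    """Everything the simulator knows that the inference must recover."""

    truth_E: PottsEnergy
    truth_G: PottsEnergy
    alpha_schedule: tuple[float, ...]
    betas: dict[int, float] = dc_field(init=False)
    trajectories: dict[int, Population] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        beta = {0: 0.0}
        for t, alpha in enumerate(self.alpha_schedule, start=1):
            beta[t] = beta[t - 1] + alpha
        self.betas = beta


# ---------------------------------------------------------------------------
# Generative stages
# ---------------------------------------------------------------------------

def sample_initial_library(
    truth_G: PottsEnergy, size: int, seed, gibbs_burn_in: int = 50
) -> Population:
    """Draw an initial library of ``size`` individuals from P_0 ∝ e^{−G}.

    Sampling is exact when G is independent-site (sites factorize) or when
    q^L fits the enumeration guard (categorical draw over the full space);
    otherwise a vectorized Gibbs sampler with ``gibbs_burn_in`` full sweeps
    is used.
    """
    rng = _rng(seed)
    L, q = truth_G.L, truth_G.q
    if not truth_G.is_pairwise:
        # P_0 factorizes: site i state a with probability ∝ e^{h_i(a)}
        probs = softmax(truth_G.h, axis=1)
        individuals = np.empty((size, L), dtype=np.uint8)
        for i in range(L):
            individuals[:, i] = rng.choice(q, size=size, p=probs[i])
        return Population.from_individuals(individuals)
    if q ** L <= MAX_ENUMERATION:
        seqs = enumerate_sequences(L, q)
        logp = -truth_G.energy(seqs)
        counts = rng.multinomial(size, softmax(logp))
        keep = counts > 0
        return Population(seqs[keep], counts[keep])
    return _gibbs_sample(truth_G, size, rng, gibbs_burn_in)


def _gibbs_sample(G: PottsEnergy, size: int, rng: np.random.Generator,
                  burn_in: int) -> Population:
    L, q = G.L, G.q
    probs = softmax(G.h, axis=1)
    chains = np.empty((size, L), dtype=np.uint8)
    for i in range(L):
        chains[:, i] = rng.choice(q, size=size, p=probs[i])
    jm = G._coupling_matrix()
    X = one_hot(chains, q)
    for _ in range(burn_in):
        for i in range(L):
            cols = slice(i * q, (i + 1) * q)
            # diagonal blocks of jm are zero, so the j = i term drops out
            logits = G.h[i][None, :] + X @ jm[:, cols]
            gumbel = -np.log(-np.log(rng.random((size, q))))
            states = np.argmax(logits + gumbel, axis=1)
            X[:, cols] = 0.0
            X[np.arange(size), i * q + states] = 1.0
            chains[:, i] = states
    return Population.from_individuals(chains)


def selection_round(
    population: Population, truth_E: PottsEnergy, alpha: float, N: int, seed
) -> Population:
    """One round of exponential survival + multinomial resampling to size N.

    Survival weight of variant v: c_v · exp(−α E(v)), computed in log space
    with max-subtraction.
    """
    rng = _rng(seed)
    logw = np.log(population.counts.astype(float)) - alpha * truth_E.energy(
        population.sequences
    )
    if not np.any(np.isfinite(logw)):
        raise NumericError("all survival weights vanished")
    counts = rng.multinomial(N, softmax(logw))
    keep = counts > 0
    return Population(population.sequences[keep], counts[keep])


def mutate(population: Population, mu: float, seed, q: int | None = None) -> Population:
    """Independent per-site mutagenesis: each site of each individual is
    replaced by a uniformly random *different* state with probability μ.

    ``q`` is the alphabet size; when omitted it is inferred from the data
    (safe only if the top state is present)."""
    if mu == 0.0:
        return population
    rng = _rng(seed)
    if q is None:
        q = int(population.sequences.max(initial=1)) + 1
    if q < 2:
        raise DataError("mutation needs q >= 2")
    expanded = np.repeat(population.sequences, population.counts, axis=0)
    for start in range(0, expanded.shape[0], _MUTATE_CHUNK):
        block = expanded[start:start + _MUTATE_CHUNK]
        mask = rng.random(block.shape) < mu
        offsets = rng.integers(1, q, size=int(mask.sum()))
        block[mask] = (block[mask] + offsets) % q
    return Population.from_individuals(expanded)


def sequence_sample(population: Population, depth: int, round_label: int, seed
                    ) -> SequenceRound:
    """Multinomial draw of ``depth`` reads from the population frequencies."""
    if population.n_variants == 0:
        raise DataError("cannot sequence an empty population")
    if depth < 1:
        raise DataError("sequencing depth must be >= 1")
    rng = _rng(seed)
    counts = rng.multinomial(depth, population.frequencies())
    keep = counts > 0
    return SequenceRound(round_label, population.sequences[keep], counts[keep])


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------

def simulate_experiment(config: SimConfig) -> tuple[ScreeningDataset, SimulationTruth]:
    """Run the generative process end to end.

    Rounds iterate mutate (if μ > 0) → select → resample; the sequenced
    subset is subsampled at the configured depth. Deterministic given the
    config (including its seed).
    """
    T = len(config.alpha_schedule)
    n_streams = 3 + 2 * T + len(config.sequenced_rounds)
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(config.seed).spawn(n_streams)]
    s_truth_e, s_truth_g, s_lib = streams[:3]
    s_rounds = streams[3:3 + 2 * T]
    s_seq = streams[3 + 2 * T:]

    E = (config.truth_E.sample(config.L, config.q, s_truth_e)
         if isinstance(config.truth_E, EnergyPrior) else config.truth_E)
    G = (config.truth_G.sample(config.L, config.q, s_truth_g)
         if isinstance(config.truth_G, EnergyPrior) else config.truth_G)
    if (E.L, E.q) != (config.L, config.q) or (G.L, G.q) != (config.L, config.q):
        raise DataError("truth energies disagree with configured L, q")

    truth = SimulationTruth(E, G, config.alpha_schedule)
    n0 = config.initial_library_size or config.population_size
    pop = sample_initial_library(G, n0, s_lib, config.gibbs_burn_in)
    truth.trajectories[0] = pop
    for t, alpha in enumerate(config.alpha_schedule, start=1):
        s_mut, s_sel = s_rounds[2 * (t - 1):2 * t]
        if config.mutation_rate > 0.0:
            pop = mutate(pop, config.mutation_rate, s_mut, q=config.q)
        pop = selection_round(pop, E, alpha, config.population_size, s_sel)
        truth.trajectories[t] = pop

    rounds = [
        sequence_sample(truth.trajectories[t], config.sequencing_depth, t, stream)
        for t, stream in zip(config.sequenced_rounds, s_seq)
    ]
    dataset = ScreeningDataset(rounds, Alphabet.generic(config.q))
    return dataset, truth
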