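"""Brute-force reference computations on fully enumerated sequence spaces.

For tiny instances (q^L bounded by a hard guard) the round distribution
P_t(S) = exp(−β_t E(S) − G(S)) / Z_t can be computed exactly by summing over
all q^L sequences. These routines validate the trainer and the simulator;
they are never used in production fitting.

Sequences are enumerated in lexicographic order (site 0 most significant),
so enumerated outputs are comparable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data_model import ScreeningDataset
from .energy_models import AnnealModel
from .errors import SizeError

MAX_ENUMERATION = 10 ** 6


def enumerate_sequences(L: int, q: int) -> np.ndarray:
    """All q^L state vectors, lexicographic, as a (q^L, L) uint8 matrix."""
    if q ** L > MAX_ENUMERATION:
        raise SizeError(f"q^L = {q ** L} exceeds the enumeration guard {MAX_ENUMERATION}")
    idx = np.arange(q ** L)
    out = np.empty((q ** L, L), dtype=np.uint8)
    for site in range(L - 1, -1, -1):
        out[:, site] = idx % q
        idx //= q
    return out


@dataclass
class EnumeratedDistribution:
    """Exact P_t over the full sequence space, in enumeration order."""

    sequences: np.ndarray
    probabilities: np.ndarray
    round_label: int

    def __post_init__(self) -> None:
        assert abs(self.probabilities.sum() - 1.0) < 1e-12
        assert (self.probabilities >= 0).all()


def log_partition_function(model: AnnealModel, round_label: int) -> float:
    """log Z_t = log Σ_S exp(−β_t E(S) − G(S)), via log-sum-exp."""
    seqs = enumerate_sequences(model.L, model.q)
    return float(logsumexp(-model.total_exponent(seqs, round_label)))


def partition_function(model: AnnealModel, round_label: int) -> float:
    """Z_t itself; may overflow for extreme energies — prefer the log form."""
    return float(np.exp(log_partition_function(model, round_label)))


def exact_round_distribution(model: AnnealModel, round_label: int) -> EnumeratedDistribution:
    """Normalized P_t(S) over all q^L sequences."""
    seqs = enumerate_sequences(model.L, model.q)
    logp = -model.total_exponent(seqs, round_label)
    logp -= logsumexp(logp)
    return EnumeratedDistribution(seqs, np.exp(logp), round_label)


def exact_loglik(model: AnnealModel, dataset: ScreeningDataset) -> float:
    """Exact weighted log-likelihood of the dataset under the model:

    −Σ_{t∈τ} Σ_m w_t^m (β_t E(S_m) + G(S_m) + log Z_t).
    """
    total = 0.0
    for r in dataset.rounds:
        log_z = log_partition_function(model, r.round_label)
        exponents = model.total_exponent(r.sequences, r.round_label)
        total += float(np.dot(r.weights, -(exponents + log_z)))
    return total
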