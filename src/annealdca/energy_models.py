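"""Potts-parameterized statistical energies and the annealed model.

The selection energy E and the background energy G are both of the form

    E(S) = − Σ_i h_i(σ_i) − Σ_{i<j} J_ij(σ_i, σ_j),

with per-site fields h_i(a) and optional pairwise couplings J_ij(a, b)
(an independent-site model stores no couplings). Lower energy means higher
inferred fitness. The round-t variant distribution is the annealed form

    P_t(S) ∝ exp(−β_t E(S) − G(S)),

where β_t, the cumulative selective pressure, acts as an inverse
temperature. :class:`AnnealModel` bundles (E, G, β).

Couplings are stored as a full (L, L, q, q) array with the Potts symmetry
J[i, j, a, b] == J[j, i, b, a] and zero diagonal blocks; the free parameters
are the i < j blocks. The zero-sum (Ising) gauge is the canonical gauge for
reporting, and contact scores are gauge-fixed Frobenius norms of the
coupling blocks with the average product correction (APC).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import Alphabet
from .errors import DataError, UnsupportedModelError

_CHUNK = 20_000  # rows per one-hot matmul block, bounds memory


def one_hot(sequences: np.ndarray, q: int) -> np.ndarray:
    """(M, L) state indices → (M, L*q) one-hot encoding (float64)."""
    sequences = np.atleast_2d(sequences)
    M, L = sequences.shape
    out = np.zeros((M, L * q))
    out[np.arange(M)[:, None], np.arange(L)[None, :] * q + sequences] = 1.0
    return out


@dataclass
class PottsEnergy:
    """Fields and (optional) couplings over L sites and q states.

    Arrays are treated as immutable after construction; ``J is None`` marks
    an independent-site model, which behaves as all-zero couplings.
    """

    h: np.ndarray
    J: np.ndarray | None = None
    _jmat: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        if self.h.ndim != 2:
            raise DataError("h must be an (L, q) array")
        if not np.all(np.isfinite(self.h)):
            raise DataError("non-finite field values")
        if self.J is not None:
            self.J = np.asarray(self.J, dtype=np.float64)
            L, q = self.h.shape
            if self.J.shape != (L, L, q, q):
                raise DataError(f"J must have shape {(L, L, q, q)}, got {self.J.shape}")
            if not np.all(np.isfinite(self.J)):
                raise DataError("non-finite coupling values")
            if not np.allclose(self.J, self.J.transpose(1, 0, 3, 2), atol=1e-10):
                raise DataError("J must satisfy J[i,j,a,b] == J[j,i,b,a]")
            if np.abs(self.J[np.arange(L), np.arange(L)]).max(initial=0.0) > 1e-12:
                raise DataError("diagonal coupling blocks must be zero")

    # -- basic structure ----------------------------------------------------

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    @property
    def is_pairwise(self) -> bool:
        return self.J is not None

    @classmethod
    def zeros(cls, L: int, q: int, pairwise: bool = False) -> "PottsEnergy":
        J = np.zeros((L, L, q, q)) if pairwise else None
        return cls(np.zeros((L, q)), J)

    @classmethod
    def from_blocks(cls, h: np.ndarray, blocks: dict) -> "PottsEnergy":
        """Build a pairwise model from ``{(i, j): q×q block}`` with i < j."""
        h = np.asarray(h, dtype=np.float64)
        L, q = h.shape
        J = np.zeros((L, L, q, q))
        for (i, j), block in blocks.items():
            if not 0 <= i < j < L:
                raise DataError(f"block key {(i, j)} must satisfy 0 <= i < j < L")
            J[i, j] = block
            J[j, i] = np.asarray(block).T
        return cls(h, J)

    def scaled(self, c: float) -> "PottsEnergy":
        return PottsEnergy(c * self.h, None if self.J is None else c * self.J)

    # -- evaluation ---------------------------------------------------------

    def _coupling_matrix(self) -> np.ndarray:
        """J reshaped to a symmetric (L*q, L*q) matrix, cached."""
        if self._jmat is None:
            L, q = self.h.shape
            self._jmat = self.J.transpose(0, 2, 1, 3).reshape(L * q, L * q)
        return self._jmat

    def energy(self, sequences: np.ndarray) -> np.ndarray | float:
        """E(S) for one (L,) sequence or a batch of (M, L) sequences."""
        seqs = np.atleast_2d(np.asarray(sequences))
        M, L = seqs.shape
        if L != self.L:
            raise DataError(f"sequence length {L} != model L {self.L}")
        if seqs.size and (seqs.min() < 0 or seqs.max() >= self.q):
            raise DataError("state index out of range [0, q)")
        e = -self.h[np.arange(L), seqs].sum(axis=1)
        if self.J is not None:
            jm = self._coupling_matrix()
            for start in range(0, M, _CHUNK):
                block = seqs[start:start + _CHUNK]
                x = one_hot(block, self.q)
                # Σ_{i<j} J = ½ Σ_{i≠j}; diagonal blocks are zero
                e[start:start + block.shape[0]] -= 0.5 * ((x @ jm) * x).sum(axis=1)
        return float(e[0]) if np.asarray(sequences).ndim == 1 else e

    def fields_felt(self, sequences: np.ndarray) -> np.ndarray:
        """Local field at each site: h_i(a) + Σ_{j≠i} J_ij(a, σ_j).

        Returns an (M, L, q) array; minus this is the single-site energy
        e_i(a; S) entering the pseudo-likelihood conditionals.
        """
        seqs = np.atleast_2d(np.asarray(sequences))
        M = seqs.shape[0]
        out = np.broadcast_to(self.h, (M, self.L, self.q)).copy()
        if self.J is not None:
            jm = self._coupling_matrix()
            for start in range(0, M, _CHUNK):
                x = one_hot(seqs[start:start + _CHUNK], self.q)
                out[start:start + x.shape[0]] += (x @ jm).reshape(-1, self.L, self.q)
        return out


def count_parameters(L: int, q: int, pairwise: bool = True, formula: str = "exact") -> int:
    """Number of model parameters.

    ``formula="exact"`` counts stored free parameters: L(L−1)/2 · q² + L·q
    for a pairwise model, L·q for independent-site. ``formula="loose"`` is
    the order-of-magnitude form L²·q² + q·L often quoted for pairwise models.
    """
    if L < 1 or q < 2:
        raise DataError("need L >= 1 and q >= 2")
    if formula == "loose":
        return L * L * q * q + q * L
    if formula != "exact":
        raise DataError(f"unknown formula {formula!r}")
    n = L * q
    if pairwise:
        n += (L * (L - 1) // 2) * q * q
    return n


# ---------------------------------------------------------------------------
# Gauge and contact scores
# ---------------------------------------------------------------------------

def to_zero_sum_gauge(model: PottsEnergy) -> PottsEnergy:
    """Reparameterize a pairwise model into the zero-sum (Ising) gauge.

    Every coupling block gets zero row and column sums and every field
    zero mean over states; energies change by one sequence-independent
    constant. This is the canonical gauge for Frobenius contact scoring.
    """
    if not model.is_pairwise:
        raise UnsupportedModelError("zero-sum gauge applies to pairwise models")
    J = model.J
    rowm = J.mean(axis=3)            # mean over partner state b: (L, L, q)
    colm = J.mean(axis=2)            # mean over own state a:     (L, L, q)
    allm = J.mean(axis=(2, 3))       # block mean:                (L, L)
    Jz = J - rowm[:, :, :, None] - colm[:, :, None, :] + allm[:, :, None, None]
    # absorb the removed row means into the fields, then center per site;
    # the leftover block means are a sequence-independent constant
    hz = model.h + rowm.sum(axis=1)
    hz = hz - hz.mean(axis=1, keepdims=True)
    return PottsEnergy(hz, Jz)


def coupling_scores(
    model: PottsEnergy,
    apc: bool = True,
    exclude_gap: bool = True,
    gap_index: int | None = None,
) -> pd.DataFrame:
    """Rank site pairs by coupling strength for contact prediction.

    The model is moved to the zero-sum gauge, then F_ij is the Frobenius
    norm of the J_ij block (restricted to non-gap states when
    ``exclude_gap`` and a ``gap_index`` is given). With ``apc`` the average
    product correction F'_ij = F_ij − F_i·F_·j / F_·· is subtracted, which
    removes the rank-one background of conservation/phylogeny effects.

    Returns a DataFrame with 0-based columns ``i, j, raw, apc``, sorted by
    decreasing score (apc if enabled, raw otherwise).
    """
    if not model.is_pairwise:
        raise UnsupportedModelError("contact scores require a pairwise model")
    gauged = to_zero_sum_gauge(model)
    J = gauged.J
    if exclude_gap and gap_index is not None:
        keep = np.array([s for s in range(model.q) if s != gap_index])
        J = J[:, :, keep][:, :, :, keep]
    F = np.sqrt((J ** 2).sum(axis=(2, 3)))
    np.fill_diagonal(F, 0.0)
    iu, ju = np.triu_indices(model.L, k=1)
    df = pd.DataFrame(
        {"i": iu, "j": ju, "raw": F[iu, ju],
         "apc": apc_correction(F)[iu, ju] if apc else np.nan}
    )
    key = "apc" if apc else "raw"
    return df.sort_values(key, ascending=False, kind="mergesort").reset_index(drop=True)


def apc_correction(F: np.ndarray) -> np.ndarray:
    """Average product correction on a symmetric score matrix.

    F'_ij = F_ij − (F_i·)(F_·j)/F_·· with row and overall means taken over
    the full matrix, so a rank-one matrix F_ij = a_i a_j is annihilated
    exactly. (Contact scoring zeroes the diagonal before calling this; the
    zero diagonal then simply participates in the means.)
    """
    L = F.shape[0]
    if L < 2:
        raise DataError("APC needs at least two sites")
    row_mean = F.mean(axis=1)
    col_mean = F.mean(axis=0)
    overall = F.mean()
    if overall == 0.0:
        return F.copy()
    return F - np.outer(row_mean, col_mean) / overall


def write_contact_scores(df: pd.DataFrame, path: str | Path, apc: bool = True) -> None:
    """Write ranked pair scores as TSV ``i  j  score`` (1-based residues)."""
    key = "apc" if apc else "raw"
    out = pd.DataFrame({"i": df["i"] + 1, "j": df["j"] + 1, "score": df[key]})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annealed model
# ---------------------------------------------------------------------------

@dataclass
class AnnealModel:
    """Selection energy E, background energy G, and inverse temperatures β.

    ``betas`` maps each sequenced round label to its cumulative inverse
    temperature. Fitted models fix the scale with β = 0 at the first
    sequenced round and β = 1 at the second; pass ``fixed_scale=False`` to
    hold an arbitrary schedule (e.g. a simulation ground truth evaluated by
    the exact oracle).
    """

    E: PottsEnergy
    G: PottsEnergy
    betas: dict[int, float]
    alphabet: Alphabet | None = None
    fixed_scale: bool = True

    def __post_init__(self) -> None:
        if (self.E.L, self.E.q) != (self.G.L, self.G.q):
            raise DataError("E and G must share L and q")
        if not self.betas:
            raise DataError("betas must cover at least one sequenced round")
        self.betas = {int(t): float(b) for t, b in sorted(self.betas.items())}
        if not all(np.isfinite(list(self.betas.values()))):
            raise DataError("non-finite beta value")
        if self.fixed_scale:
            labels = list(self.betas)
            if self.betas[labels[0]] != 0.0:
                raise DataError("beta at the first sequenced round must be 0")
            if len(labels) >= 2 and self.betas[labels[1]] != 1.0:
                raise DataError("beta at the second sequenced round must be 1")

    @property
    def L(self) -> int:
        return self.E.L

    @property
    def q(self) -> int:
        return self.E.q

    @property
    def round_labels(self) -> list[int]:
        return list(self.betas)

    @property
    def alphas(self) -> dict[int, float]:
        """Per-interval selective pressures α_t = β_t − β_(previous)."""
        labels = self.round_labels
        vals = [self.betas[t] for t in labels]
        return {t: b - a for t, a, b in zip(labels[1:], vals[:-1], vals[1:])}

    def beta(self, round_label: int) -> float:
        try:
            return self.betas[int(round_label)]
        except KeyError:
            raise DataError(
                f"round {round_label} not sequenced (rounds {self.round_labels})"
            ) from None

    def total_exponent(self, sequences: np.ndarray, round_label: int):
        """β_t·E(S) + G(S): minus the log of the unnormalized P_t(S)."""
        return self.beta(round_label) * self.E.energy(sequences) + self.G.energy(sequences)

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path, metadata: dict | None = None) -> None:
        """Write a self-describing JSON container (round-trips bit-exactly)."""
        def _energy(e: PottsEnergy) -> dict:
            return {"h": e.h.tolist(), "J": None if e.J is None else e.J.tolist()}

        payload = {
            "format": "annealdca-model",
            "version": 1,
            "L": self.L,
            "q": self.q,
            "alphabet": None if self.alphabet is None else {
                "symbols": self.alphabet.symbols,
                "gap_symbol": self.alphabet.gap_symbol,
            },
            "betas": {str(t): b for t, b in self.betas.items()},
            "fixed_scale": self.fixed_scale,
            "E": _energy(self.E),
            "G": _energy(self.G),
            "metadata": metadata or {},
        }
        Path(path).write_text(json.dumps(payload, separators=(",", ":")) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "AnnealModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "annealdca-model":
            raise DataError(f"{path} is not an annealdca model file")

        def _energy(d: dict) -> PottsEnergy:
            J = d["J"]
            return PottsEnergy(np.array(d["h"]), None if J is None else np.array(J))

        alpha = payload.get("alphabet")
        return cls(
            E=_energy(payload["E"]),
            G=_energy(payload["G"]),
            betas={int(t): float(b) for t, b in payload["betas"].items()},
            alphabet=None if alpha is None else Alphabet(alpha["symbols"], alpha["gap_symbol"]),
            fixed_scale=bool(payload.get("fixed_scale", True)),
        )
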