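"""Round-structured sequence count data.

A selection-and-sequencing experiment yields, for a subset of rounds
t ∈ {τ0, τ1, ...}, a sample of aligned sequences with read counts N_t^m.
This module holds that data: an :class:`Alphabet` mapping residue characters
to Potts states, a :class:`SequenceRound` per sequenced round (unique
variants, counts, normalized abundance weights w_t^m = N_t^m / Σ N_t^m'),
and the :class:`ScreeningDataset` that the likelihood consumes.

Two on-disk dialects are supported: per-round FASTA with a ``count=<int>``
header token, and a long-format TSV with columns
``sequence<TAB>round<TAB>count``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, AlphabetError, DataError

logger = logging.getLogger("annealdca")

_WEIGHT_TOL = 1e-12


# ---------------------------------------------------------------------------
# Alphabet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alphabet:
    """Ordered set of residue characters defining the Potts state space.

    Parameters
    ----------
    symbols
        Unique characters; their order fixes the 0-based state encoding.
    gap_symbol
        Character treated as the gap state, or ``None`` for a gapless
        alphabet. Must be a member of ``symbols`` when given.
    """

    symbols: str
    gap_symbol: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise AlphabetError(f"duplicate symbols in alphabet {self.symbols!r}")
        if self.gap_symbol is not None and self.gap_symbol not in self.symbols:
            raise AlphabetError(
                f"gap symbol {self.gap_symbol!r} not in alphabet {self.symbols!r}"
            )

    @property
    def q(self) -> int:
        """Number of Potts states."""
        return len(self.symbols)

    @property
    def gap_index(self) -> int | None:
        return None if self.gap_symbol is None else self.symbols.index(self.gap_symbol)

    def _lookup(self) -> np.ndarray:
        table = np.full(256, -1, dtype=np.int16)
        for idx, ch in enumerate(self.symbols):
            table[ord(ch)] = idx
        return table

    def encode(self, sequences: Iterable[str], permissive: bool = False) -> np.ndarray:
        """Encode equal-length strings to an (M, L) array of state indices.

        With ``permissive=True``, characters outside the alphabet map to the
        gap state (a warning is logged); otherwise they raise
        :class:`AlphabetError`.
        """
        seqs = list(sequences)
        if not seqs:
            raise DataError("no sequences to encode")
        L = len(seqs[0])
        if any(len(s) != L for s in seqs):
            raise AlignmentError("sequences have unequal lengths; inputs must be aligned")
        raw = np.frombuffer("".join(seqs).encode("ascii", "replace"), dtype=np.uint8)
        enc = self._lookup()[raw].reshape(len(seqs), L)
        bad = enc < 0
        if bad.any():
            chars = sorted({seqs[m][i] for m, i in zip(*np.nonzero(bad))})
            if permissive and self.gap_index is not None:
                logger.warning(
                    "mapping %d occurrences of unknown symbols %s to gap",
                    int(bad.sum()), chars,
                )
                enc[bad] = self.gap_index
            else:
                raise AlphabetError(f"characters {chars} not in alphabet {self.symbols!r}")
        return enc.astype(np.uint8)

    def decode(self, encoded: np.ndarray) -> list[str]:
        """Inverse of :meth:`encode` on valid state-index arrays."""
        encoded = np.atleast_2d(np.asarray(encoded))
        if encoded.size and (encoded.min() < 0 or encoded.max() >= self.q):
            raise AlphabetError("state index out of range for this alphabet")
        chars = np.frombuffer(self.symbols.encode("ascii"), dtype=np.uint8)
        return [bytes(chars[row]).decode("ascii") for row in encoded]

    @staticmethod
    def protein(gapped: bool = True) -> "Alphabet":
        """Canonical protein alphabet: 20 amino acids, optionally + gap.

        The gapped 21-state form (gap first) is the DCA convention for
        alignments; the gapless form suits fixed-length mutant libraries.
        """
        aa = "ACDEFGHIKLMNPQRSTVWY"
        return Alphabet("-" + aa, gap_symbol="-") if gapped else Alphabet(aa)

    @staticmethod
    def generic(q: int) -> "Alphabet":
        """Small q-state alphabet (subset of amino-acid letters) for
        simulations and tests."""
        letters = "ACDEFGHIKLMNPQRSTVWY"
        if not 2 <= q <= len(letters):
            raise DataError(f"generic alphabet supports 2 <= q <= {len(letters)}")
        return Alphabet(letters[:q])


PROTEIN = Alphabet.protein(gapped=True)
PROTEIN_NOGAP = Alphabet.protein(gapped=False)


# ---------------------------------------------------------------------------
# Rounds and datasets
# ---------------------------------------------------------------------------

def round_weights(counts: np.ndarray) -> np.ndarray:
    """Normalized abundances w_t^m = N_t^m / Σ_m' N_t^m'."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise DataError("empty count vector")
    if np.any(counts <= 0):
        raise DataError("read counts must be positive integers")
    return counts / counts.sum()


@dataclass
class SequenceRound:
    """One sequenced round: unique variants, read counts, abundance weights.

    ``sequences`` is an (M, L) state-index matrix; duplicates are merged at
    construction by summing counts, so rows are unique and sorted
    lexicographically (a canonical, input-order-independent layout).
    """

    round_label: int
    sequences: np.ndarray
    counts: np.ndarray
    weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype=np.uint8)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.sequences.ndim != 2 or self.sequences.shape[0] != self.counts.shape[0]:
            raise DataError("sequences and counts shapes disagree")
        if np.any(self.counts <= 0):
            raise DataError("read counts must be positive")
        uniq, inverse = np.unique(self.sequences, axis=0, return_inverse=True)
        merged = np.bincount(inverse.ravel(), weights=self.counts.astype(float))
        self.sequences = uniq
        self.counts = merged.astype(np.int64)
        self.weights = round_weights(self.counts)
        assert abs(self.weights.sum() - 1.0) < _WEIGHT_TOL

    @property
    def n_variants(self) -> int:
        return self.sequences.shape[0]

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    @property
    def L(self) -> int:
        return self.sequences.shape[1]


@dataclass
class ScreeningDataset:
    """Ordered sequenced rounds sharing one alignment length and alphabet."""

    rounds: list[SequenceRound]
    alphabet: Alphabet

    def __post_init__(self) -> None:
        if len(self.rounds) < 2:
            raise DataError(
                "a screening dataset needs at least 2 sequenced rounds "
                "(a reference round and one selected round)"
            )
        labels = [r.round_label for r in self.rounds]
        if any(b <= a for a, b in zip(labels, labels[1:])):
            raise DataError(f"round labels must be strictly increasing, got {labels}")
        lengths = {r.L for r in self.rounds}
        if len(lengths) != 1:
            raise AlignmentError(f"rounds have differing sequence lengths {sorted(lengths)}")
        q = self.alphabet.q
        for r in self.rounds:
            if r.sequences.size and r.sequences.max() >= q:
                raise AlphabetError("state index exceeds alphabet size")

    @property
    def L(self) -> int:
        return self.rounds[0].L

    @property
    def round_labels(self) -> list[int]:
        return [r.round_label for r in self.rounds]

    def round(self, label: int) -> SequenceRound:
        for r in self.rounds:
            if r.round_label == label:
                return r
        raise DataError(f"round {label} not in dataset (rounds {self.round_labels})")

    def unique_variants(self) -> np.ndarray:
        """Union of variant rows across all rounds, lexicographically sorted."""
        return np.unique(np.vstack([r.sequences for r in self.rounds]), axis=0)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_count(description: str) -> int:
    for token in description.split():
        if token.startswith("count="):
            try:
                count = int(token[len("count="):])
            except ValueError as exc:
                raise DataError(f"malformed count token {token!r}") from exc
            if count <= 0:
                raise DataError(f"non-positive count in header: {token!r}")
            return count
    return 1


def read_fasta_round(
    path: str | Path,
    round_label: int,
    alphabet: Alphabet,
    permissive: bool = False,
) -> SequenceRound:
    """Read one round from an aligned FASTA file.

    Read counts come from a ``count=<int>`` token in the record description;
    a record without the token counts as a single read.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataError(f"no FASTA records in {path}")
    seqs = [str(r.seq).upper() for r in records]
    counts = np.array([_parse_count(r.description) for r in records], dtype=np.int64)
    encoded = alphabet.encode(seqs, permissive=permissive)
    return SequenceRound(round_label, encoded, counts)


def read_rounds(
    sources,
    alphabet: Alphabet = PROTEIN,
    fmt: str = "tsv",
    permissive: bool = False,
) -> ScreeningDataset:
    """Build a :class:`ScreeningDataset` from files.

    Parameters
    ----------
    sources
        For ``fmt="tsv"``: one path to a long-format table with header
        ``sequence  round  count`` (tab-separated). For ``fmt="fasta"``: a
        mapping ``{round_label: path}`` or sequence of ``(label, path)``
        pairs, one aligned FASTA per round.
    """
    if fmt == "tsv":
        return read_table(sources, alphabet, permissive=permissive)
    if fmt == "fasta":
        items = sources.items() if hasattr(sources, "items") else sources
        rounds = [
            read_fasta_round(path, int(label), alphabet, permissive=permissive)
            for label, path in sorted(items, key=lambda kv: int(kv[0]))
        ]
        return ScreeningDataset(rounds, alphabet)
    raise DataError(f"unknown format {fmt!r} (expected 'tsv' or 'fasta')")


def read_table(
    path: str | Path,
    alphabet: Alphabet = PROTEIN,
    permissive: bool = False,
) -> ScreeningDataset:
    """Read the long-format TSV dialect (``sequence  round  count``)."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "round": int, "count": int})
    missing = {"sequence", "round", "count"} - set(df.columns)
    if missing:
        raise DataError(f"table {path} missing columns {sorted(missing)}")
    if df.empty:
        raise DataError(f"table {path} has no rows")
    if (df["count"] <= 0).any():
        raise DataError("table contains non-positive counts")
    rounds = []
    for label, grp in df.groupby("round", sort=True):
        encoded = alphabet.encode(grp["sequence"].tolist(), permissive=permissive)
        rounds.append(SequenceRound(int(label), encoded, grp["count"].to_numpy()))
    return ScreeningDataset(rounds, alphabet)


def write_table(dataset: ScreeningDataset, path: str | Path) -> None:
    """Serialize to the long-format TSV dialect; ``read_table`` of the output
    reproduces the dataset exactly (canonical row order)."""
    rows = []
    for r in dataset.rounds:
        for seq, count in zip(dataset.alphabet.decode(r.sequences), r.counts):
            rows.append((seq, r.round_label, int(count)))
    pd.DataFrame(rows, columns=["sequence", "round", "count"]).to_csv(
        path, sep="\t", index=False
    )


def write_fasta_round(round_: SequenceRound, alphabet: Alphabet, path: str | Path) -> None:
    """Write one round as FASTA with ``count=`` header tokens."""
    records = [
        SeqRecord(Seq(seq), id=f"r{round_.round_label}_v{m}",
                  description=f"count={int(count)}")
        for m, (seq, count) in enumerate(
            zip(alphabet.decode(round_.sequences), round_.counts)
        )
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Cross-validation splits
# ---------------------------------------------------------------------------

def split_folds(
    dataset: ScreeningDataset, k: int, seed: int
) -> list[tuple[ScreeningDataset, ScreeningDataset]]:
    """Partition *variants* (not reads) into k folds for cross-validation.

    A variant is assigned to the same fold in every round it appears, so no
    sequence leaks between a train and test split. Weights are recomputed
    within each split. Returns k (train, test) dataset pairs whose test
    variant sets are pairwise disjoint and jointly cover the dataset.
    """
    if k < 2:
        raise DataError("k must be >= 2")
    variants = dataset.unique_variants()
    n = variants.shape[0]
    if k > n:
        raise DataError(f"k={k} exceeds the {n} unique variants")
    for r in dataset.rounds:
        if r.n_variants < k:
            raise DataError(f"round {r.round_label} has fewer than k={k} unique variants")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=np.int64)
    perm = rng.permutation(n)
    fold_of[perm] = np.arange(n) % k

    # rows viewed as fixed-width byte strings sort identically to
    # np.unique(axis=0)'s lexicographic row order, so searchsorted locates
    # each sequence in the variant table
    void = np.dtype((np.void, variants.shape[1]))
    keys = np.ascontiguousarray(variants).view(void).ravel()

    def _variant_fold(seqs: np.ndarray) -> np.ndarray:
        return fold_of[np.searchsorted(keys, np.ascontiguousarray(seqs).view(void).ravel())]

    splits = []
    for fold in range(k):
        train_rounds, test_rounds = [], []
        for r in dataset.rounds:
            folds = _variant_fold(r.sequences)
            test_mask = folds == fold
            if (~test_mask).any():
                train_rounds.append(
                    SequenceRound(r.round_label, r.sequences[~test_mask], r.counts[~test_mask])
                )
            if test_mask.any():
                test_rounds.append(
                    SequenceRound(r.round_label, r.sequences[test_mask], r.counts[test_mask])
                )
        splits.append(
            (ScreeningDataset(train_rounds, dataset.alphabet),
             ScreeningDataset(test_rounds, dataset.alphabet))
        )
    return splits
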