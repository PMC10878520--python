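"""Validation procedures for fitted models.

Four checks mirror how selection-energy models are judged in practice:

* **Empirical selectivity** — per-variant enrichment, the slope of
  log-frequency against round label, with the regression standard error as
  its uncertainty; correlating it with the model energy tests the fitness
  map on deep-mutational-scanning-like data (variants must be observable in
  at least two rounds).
* **Binder classification** — ROC/AUC of the selection energy on a
  positive (selected) vs negative (background) sequence set; lower energy
  predicts the positive class.
* **Energy vs external measurement** — Pearson/Spearman correlation with
  independent fitness or affinity measurements.
* **Contact prediction** — positive predictive value of coupling-score
  ranked residue pairs against a known contact list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .data_model import ScreeningDataset
from .energy_models import AnnealModel
from .errors import DataError, NumericError

logger = logging.getLogger("annealdca")

DEFAULT_PRUNE_GRID = tuple(np.round(np.linspace(0.1, 1.0, 10), 10))
DEFAULT_MIN_SEPARATION = 5


# ---------------------------------------------------------------------------
# Selectivity
# ---------------------------------------------------------------------------

@dataclass
class SelectivityTable:
    """Per-variant log-selectivity θ^m and its regression uncertainty.

    Only variants observed in at least two sequenced rounds are listed
    (``sequences`` holds their encoded rows); higher θ means stronger
    enrichment through selection.
    """

    sequences: np.ndarray
    theta: np.ndarray
    uncertainty: np.ndarray
    n_rounds: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.uncertainty < 0):
            raise DataError("uncertainties must be non-negative")
        if np.any(self.n_rounds < 2):
            raise DataError("selectivity requires presence in >= 2 rounds")

    def __len__(self) -> int:
        return len(self.theta)


def log_selectivity(
    dataset: ScreeningDataset,
    pseudocount: float = 0.0,
    method: str = "regression",
) -> SelectivityTable:
    """Empirical log-selectivity per variant.

    Frequencies are (N_t^m + pseudocount) / (Σ N_t + pseudocount·V) with V
    the number of distinct variants across rounds. Eligibility always
    requires real reads in at least two rounds. With the default
    pseudocount 0 a variant's regression uses only the rounds where it was
    read; a positive pseudocount (0.5 reads is customary for zero-inflated
    series) completes the series over every round, which also gives
    two-round variants a non-trivial uncertainty. ``method="regression"``
    (default) fits ordinary
    least squares of log frequency against the *experimental* round labels
    and reports the slope with its standard error (0 when the fit is exact
    or has no residual degrees of freedom); ``method="ratio"`` uses the
    two-point log-ratio between the first and last observed rounds, with
    uncertainty 0.
    """
    if len(dataset.rounds) < 2:
        raise DataError("selectivity needs >= 2 sequenced rounds")
    variants = dataset.unique_variants()
    V = variants.shape[0]
    R = len(dataset.rounds)
    void = np.dtype((np.void, variants.shape[1]))
    keys = np.ascontiguousarray(variants).view(void).ravel()
    freq = np.zeros((V, R))
    observed = np.zeros((V, R), dtype=bool)  # actually read (count > 0)
    for r_idx, r in enumerate(dataset.rounds):
        rows = np.searchsorted(keys, np.ascontiguousarray(r.sequences).view(void).ravel())
        total = r.counts.sum() + pseudocount * V
        freq[rows, r_idx] = (r.counts + pseudocount) / total
        observed[rows, r_idx] = True
        if pseudocount > 0:
            # a pseudocount makes the whole series usable for regression,
            # including rounds where the variant drew zero reads
            freq[~observed[:, r_idx], r_idx] = pseudocount / total
    # eligibility always requires real reads in >= 2 rounds; the regression
    # itself uses the pseudocount-completed series when one is available
    present = np.ones_like(observed) if pseudocount > 0 else observed
    n_obs = observed.sum(axis=1)
    keep = n_obs >= 2
    if not keep.any():
        logger.warning(
            "no variant appears in two or more rounds; selectivity is empty "
            "(this is the disjoint-samples regime)"
        )
        empty = np.empty(0)
        return SelectivityTable(variants[:0], empty, empty,
                                np.full(0, 2, dtype=np.int64))

    x = np.array(dataset.round_labels, dtype=float)[None, :]
    m = present[keep]
    y = np.where(m, np.log(np.where(freq[keep] > 0, freq[keep], 1.0)), 0.0)
    n = m.sum(axis=1).astype(float)
    sx = (m * x).sum(axis=1)
    sy = y.sum(axis=1)
    sxx = (m * x * x).sum(axis=1)
    sxy = (x * y).sum(axis=1)
    denom = n * sxx - sx ** 2
    if np.any(denom <= 0):
        raise DataError("degenerate round labels in selectivity regression")
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n

    if method == "ratio":
        first = np.argmax(m, axis=1)
        last = m.shape[1] - 1 - np.argmax(m[:, ::-1], axis=1)
        rows = np.arange(m.shape[0])
        dt = x[0, last] - x[0, first]
        theta = (y[rows, last] - y[rows, first]) / dt
        se = np.zeros_like(theta)
    elif method == "regression":
        theta = slope
        resid = np.where(m, y - intercept[:, None] - slope[:, None] * x, 0.0)
        rss = (resid ** 2).sum(axis=1)
        dof = n - 2
        with np.errstate(invalid="ignore", divide="ignore"):
            s2 = np.where(dof > 0, rss / np.maximum(dof, 1), 0.0)
            se = np.sqrt(np.maximum(s2 * n / denom, 0.0))
    else:
        raise DataError(f"unknown selectivity method {method!r}")
    return SelectivityTable(variants[keep], theta, se, n_obs[keep].astype(np.int64))


def energy_selectivity_correlation(
    model: AnnealModel,
    table: SelectivityTable,
    prune_fraction_grid=DEFAULT_PRUNE_GRID,
) -> pd.DataFrame:
    """Pearson correlation between −E and θ^m along an uncertainty-pruning
    curve.

    Sign convention: lower selection energy means higher fitness, so −E is
    correlated against the log-selectivity and a perfect model scores +1.
    For each retained fraction the variants with the smallest uncertainty
    are kept; fractions leaving fewer than 3 variants are skipped.
    """
    if len(table) == 0:
        raise DataError("empty selectivity table")
    energies = np.asarray(model.E.energy(table.sequences), dtype=float)
    order = np.argsort(table.uncertainty, kind="mergesort")
    rows = []
    for frac in sorted(prune_fraction_grid):
        n_keep = int(round(frac * len(table)))
        if n_keep < 3:
            continue
        idx = order[:n_keep]
        r, _ = stats.pearsonr(-energies[idx], table.theta[idx])
        rows.append({"retained_fraction": float(frac), "n": n_keep, "pearson": float(r)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Classification and correlation
# ---------------------------------------------------------------------------

def roc_auc(
    scores_positive: np.ndarray,
    scores_negative: np.ndarray,
    lower_is_positive: bool = True,
) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC for separating two score groups.

    Default orientation treats *lower* selection energy as the positive
    (binder) class. The AUC equals the Mann–Whitney probability that a
    random positive out-scores a random negative, ties counted 1/2.
    """
    pos = np.asarray(scores_positive, dtype=float)
    neg = np.asarray(scores_negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DataError("both score groups must be non-empty")
    y_true = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    y_score = np.concatenate([pos, neg])
    if lower_is_positive:
        y_score = -y_score
    fpr, tpr, _ = roc_curve(y_true, y_score, drop_intermediate=False)
    auc = float(roc_auc_score(y_true, y_score))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr}), auc


def rank_correlation(
    energies: np.ndarray, measurements: np.ndarray, method: str = "pearson"
) -> float:
    """Pearson or Spearman correlation between model energies and external
    measurements (Spearman uses average ranks for ties)."""
    e = np.asarray(energies, dtype=float)
    m = np.asarray(measurements, dtype=float)
    if e.shape != m.shape or e.size < 3:
        raise DataError("need two equal-length vectors with >= 3 entries")
    if np.ptp(e) == 0 or np.ptp(m) == 0:
        raise NumericError("correlation undefined for a zero-variance vector")
    if method == "pearson":
        return float(stats.pearsonr(e, m)[0])
    if method == "spearman":
        return float(stats.spearmanr(e, m)[0])
    raise DataError(f"unknown correlation method {method!r}")


# ---------------------------------------------------------------------------
# Contact prediction
# ---------------------------------------------------------------------------

@dataclass
class ContactEvaluation:
    """Ranked predictions against a true contact set.

    ``ppv[k-1]`` is the fraction of the top-k predicted pairs that are true
    contacts; pairs closer than the minimum separation were excluded from
    both prediction and truth before ranking.
    """

    pairs: np.ndarray
    scores: np.ndarray
    true_contacts: set
    ppv: np.ndarray
    min_separation: int

    def __post_init__(self) -> None:
        assert ((self.ppv >= 0) & (self.ppv <= 1)).all()

    def ppv_at(self, k: int) -> float:
        if not 1 <= k <= len(self.ppv):
            raise DataError(f"rank {k} outside 1..{len(self.ppv)}")
        return float(self.ppv[k - 1])


def _canonical_pairs(pairs) -> list[tuple[int, int]]:
    return [(min(int(i), int(j)), max(int(i), int(j))) for i, j in pairs]


def ppv_curve(
    scores: pd.DataFrame,
    true_contacts,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> ContactEvaluation:
    """Positive predictive value at every rank of a contact-score list.

    ``scores`` is a DataFrame with 0-based columns ``i, j`` and a score
    column (``apc`` if present, else ``raw`` or ``score``), already ranked
    or rankable by decreasing score; ``true_contacts`` is an iterable of
    residue pairs (0-based, unordered).
    """
    truth = {p for p in _canonical_pairs(true_contacts)
             if p[1] - p[0] >= min_separation}
    if not truth:
        raise DataError("no true contacts beyond the separation cutoff")
    key = next(c for c in ("apc", "raw", "score") if c in scores.columns)
    df = scores.sort_values(key, ascending=False, kind="mergesort")
    pairs = _canonical_pairs(df[["i", "j"]].to_numpy())
    keep = [k for k, (i, j) in enumerate(pairs) if j - i >= min_separation]
    pairs = [pairs[k] for k in keep]
    vals = df[key].to_numpy()[keep]
    hits = np.cumsum([p in truth for p in pairs])
    ranks = np.arange(1, len(pairs) + 1)
    return ContactEvaluation(
        np.array(pairs), vals, truth, hits / ranks, min_separation
    )


def read_contacts(path) -> set[tuple[int, int]]:
    """Read a TSV of 1-based residue pairs ``i<TAB>j`` into 0-based tuples."""
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c.lower() in ("i", "j")]
    if len(cols) != 2:
        df = pd.read_csv(path, sep="\t", header=None, names=["i", "j"])
    return {(int(i) - 1, int(j) - 1) for i, j in df[["i", "j"]].to_numpy()}
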