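"""Model fitting by regularized weighted pseudo-likelihood maximization.

The likelihood of a screening dataset under the annealed model weighs each
unique variant by its normalized read abundance w_t^m and treats sequenced
rounds as independent samples. The intractable partition function is
replaced by site conditionals: at round t the probability of state a at
site i given the rest of sequence S is

    P_t(σ_i = a | S_{\\i}) = softmax_a [ β_t f_i^E(a; S) + f_i^G(a; S) ],

where f_i(a; S) = h_i(a) + Σ_{j≠i} J_ij(a, σ_j) is the local field (minus
the single-site energy). The objective

    PL(θ, β) = Σ_{t∈τ} Σ_m w_t^m Σ_i log P_t(σ_i^m | S_{\\i}^m) − R(θ),

with an L2 penalty R, is separately concave in the energetic parameters θ
and in each β_t, so fitting alternates a quasi-Newton θ step (L-BFGS) with
per-round scalar β maximization until both stabilize. The scale freedom of
(β, E) is removed by fixing β = 0 at the first sequenced round and β = 1 at
the second; those two values are never part of the parameter vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

from .data_model import ScreeningDataset
from .energy_models import AnnealModel, PottsEnergy, one_hot
from .errors import DataError

logger = logging.getLogger("annealdca")

_TRACE_TOL = 1e-9   # alternating ascent slack
_BETA_BOUND = 50.0  # search interval half-width for scalar beta updates


# ---------------------------------------------------------------------------
# Configuration and result containers
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Inference knobs.

    lambda_h / lambda_j are per-parameter L2 strengths on fields and
    couplings of the selection energy E (defaults follow common
    pseudo-likelihood DCA practice); the ``*_g`` values override them for
    the background energy G and default to the same values. ``beta_init``
    maps sequenced-round labels to starting β; when ``None``, β starts at
    the 0-based index of each round in sequencing order (a constant-pressure
    neutral guess).
    """

    e_family: Literal["potts", "indep"] = "potts"
    g_family: Literal["potts", "indep"] = "potts"
    lambda_h: float = 1e-4
    lambda_j: float = 1e-2
    lambda_h_g: float | None = None
    lambda_j_g: float | None = None
    max_outer_iterations: int = 50
    theta_tol: float = 1e-4
    beta_tol: float = 1e-4
    max_inner_iterations: int = 300
    grad_tol: float = 1e-7
    inner_ftol: float = 1e-11
    beta_init: dict[int, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lambda_h", "lambda_j"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")
        if self.theta_tol <= 0 or self.beta_tol <= 0:
            raise DataError("tolerances must be positive")

    @property
    def lam(self) -> tuple[float, float, float, float]:
        """(λ_h^E, λ_J^E, λ_h^G, λ_J^G)."""
        return (
            self.lambda_h,
            self.lambda_j,
            self.lambda_h if self.lambda_h_g is None else self.lambda_h_g,
            self.lambda_j if self.lambda_j_g is None else self.lambda_j_g,
        )


@dataclass
class FitResult:
    model: AnnealModel
    objective_trace: np.ndarray
    converged: bool
    n_outer: int


@dataclass
class PseudoGradient:
    """Gradient of the pseudo-log-likelihood, mirroring (θ^E, θ^G, β).

    Coupling gradients are over the free i < j blocks, shaped (n_pairs, q, q)
    in ``np.triu_indices`` order, or ``None`` for independent-site energies.
    ``betas`` holds entries only for the free rounds (beyond the two fixed
    by the scale convention).
    """

    h_e: np.ndarray
    j_e: np.ndarray | None
    h_g: np.ndarray
    j_g: np.ndarray | None
    betas: dict[int, float]


# ---------------------------------------------------------------------------
# Parameter packing
# ---------------------------------------------------------------------------

class _ParamSpec:
    """Flat-vector layout for (h^E, J^E, h^G, J^G)."""

    def __init__(self, L: int, q: int, e_pairwise: bool, g_pairwise: bool):
        self.L, self.q = L, q
        self.e_pairwise, self.g_pairwise = e_pairwise, g_pairwise
        self.iu, self.ju = np.triu_indices(L, k=1)
        self.n_pairs = len(self.iu)
        nj = self.n_pairs * q * q
        sizes = [L * q, nj if e_pairwise else 0, L * q, nj if g_pairwise else 0]
        self.offsets = np.concatenate([[0], np.cumsum(sizes)])
        self.size = int(self.offsets[-1])

    def pack(self, E: PottsEnergy, G: PottsEnergy) -> np.ndarray:
        parts = [E.h.ravel()]
        if self.e_pairwise:
            parts.append(E.J[self.iu, self.ju].ravel())
        parts.append(G.h.ravel())
        if self.g_pairwise:
            parts.append(G.J[self.iu, self.ju].ravel())
        return np.concatenate(parts)

    def unpack(self, vec: np.ndarray) -> tuple[PottsEnergy, PottsEnergy]:
        L, q, o = self.L, self.q, self.offsets
        h_e = vec[o[0]:o[1]].reshape(L, q)
        j_e = self._blocks_to_full(vec[o[1]:o[2]]) if self.e_pairwise else None
        h_g = vec[o[2]:o[3]].reshape(L, q)
        j_g = self._blocks_to_full(vec[o[3]:o[4]]) if self.g_pairwise else None
        return PottsEnergy(h_e.copy(), j_e), PottsEnergy(h_g.copy(), j_g)

    def _blocks_to_full(self, flat: np.ndarray) -> np.ndarray:
        blocks = flat.reshape(self.n_pairs, self.q, self.q)
        J = np.zeros((self.L, self.L, self.q, self.q))
        J[self.iu, self.ju] = blocks
        J[self.ju, self.iu] = blocks.transpose(0, 2, 1)
        return J

    def grad_to_free_blocks(self, g_full: np.ndarray) -> np.ndarray:
        """Fold a gradient over the full (L,L,q,q) array onto free blocks."""
        return g_full[self.iu, self.ju] + g_full[self.ju, self.iu].transpose(0, 2, 1)


# ---------------------------------------------------------------------------
# Objective engine
# ---------------------------------------------------------------------------

class _PseudoLikelihood:
    """Precomputed one-hot data with objective/gradient evaluation."""

    def __init__(self, dataset: ScreeningDataset, config: FitConfig):
        if not dataset.rounds:
            raise DataError("empty dataset")
        self.config = config
        L, q = dataset.L, dataset.alphabet.q
        self.spec = _ParamSpec(
            L, q, config.e_family == "potts", config.g_family == "potts"
        )
        self.L, self.q = L, q
        self.rounds = []
        for r in dataset.rounds:
            X = one_hot(r.sequences, q)                      # (M, L*q)
            take = np.arange(L) * q + r.sequences            # (M, L) index into L*q
            self.rounds.append(
                {"label": r.round_label, "X": X, "take": take, "w": r.weights.copy(),
                 "S": r.sequences}
            )
        self.labels = [r["label"] for r in self.rounds]

    # -- pieces -------------------------------------------------------------

    def _fields(self, energy_part: tuple[np.ndarray, np.ndarray | None],
                X: np.ndarray) -> np.ndarray:
        """Local fields f_i(a; S) for every sequence: (M, L, q)."""
        h, jmat = energy_part
        M = X.shape[0]
        fe = np.broadcast_to(h.ravel(), (M, self.L * self.q)).copy()
        if jmat is not None:
            fe += X @ jmat
        return fe.reshape(M, self.L, self.q)

    def _split(self, vec: np.ndarray):
        """Vector → ((h_E, Jmat_E), (h_G, Jmat_G)) with symmetric (Lq, Lq)
        coupling matrices."""
        E, G = self.spec.unpack(vec)

        def part(e: PottsEnergy):
            jm = None
            if e.is_pairwise:
                jm = e.J.transpose(0, 2, 1, 3).reshape(self.L * self.q, self.L * self.q)
            return e.h, jm

        return part(E), part(G)

    def _penalty(self, vec: np.ndarray) -> tuple[float, np.ndarray]:
        lh_e, lj_e, lh_g, lj_g = self.config.lam
        o = self.spec.offsets
        lam_vec = np.empty_like(vec)
        lam_vec[o[0]:o[1]] = lh_e
        lam_vec[o[1]:o[2]] = lj_e
        lam_vec[o[2]:o[3]] = lh_g
        lam_vec[o[3]:o[4]] = lj_g
        return float(np.dot(lam_vec * vec, vec)), 2.0 * lam_vec * vec

    # -- full objective -----------------------------------------------------

    def value(self, vec: np.ndarray, betas: dict[int, float]) -> float:
        e_part, g_part = self._split(vec)
        total = 0.0
        for rd in self.rounds:
            beta = betas[rd["label"]]
            logits = self._fields(g_part, rd["X"])
            if beta != 0.0:  # at the reference round E drops out entirely
                logits = logits + beta * self._fields(e_part, rd["X"])
            total += self._round_data_term(logits, rd)
        pen, _ = self._penalty(vec)
        return total - pen

    @staticmethod
    def _round_data_term(logits: np.ndarray, rd: dict) -> float:
        lse = logsumexp(logits, axis=2)                      # (M, L)
        M = logits.shape[0]
        taken = logits.reshape(M, -1)[np.arange(M)[:, None], rd["take"]]
        return float(np.dot(rd["w"], (taken - lse).sum(axis=1)))

    def value_and_grad(
        self, vec: np.ndarray, betas: dict[int, float], free_beta_labels=()
    ) -> tuple[float, np.ndarray, dict[int, float]]:
        e_part, g_part = self._split(vec)
        L, q = self.L, self.q
        total = 0.0
        gh_e = np.zeros((L, q))
        gh_g = np.zeros((L, q))
        gj_e = np.zeros((L * q, L * q)) if self.spec.e_pairwise else None
        gj_g = np.zeros((L * q, L * q)) if self.spec.g_pairwise else None
        gbeta: dict[int, float] = {}
        for rd in self.rounds:
            beta = betas[rd["label"]]
            # at beta = 0 the E-fields neither enter the logits nor receive
            # gradient, so their matmuls are skipped on the reference round
            need_e = beta != 0.0 or rd["label"] in free_beta_labels
            fe = self._fields(e_part, rd["X"]) if need_e else None
            fg = self._fields(g_part, rd["X"])
            logits = fg if beta == 0.0 else beta * fe + fg
            lse = logsumexp(logits, axis=2)
            M = logits.shape[0]
            flat = logits.reshape(M, -1)
            taken = flat[np.arange(M)[:, None], rd["take"]]
            total += float(np.dot(rd["w"], (taken - lse).sum(axis=1)))

            P = np.exp(logits - lse[:, :, None])             # (M, L, q)
            gl = -P.reshape(M, -1)
            gl[np.arange(M)[:, None], rd["take"]] += 1.0
            gl *= rd["w"][:, None]                           # (M, L*q)

            gsum = gl.sum(axis=0).reshape(L, q)
            if beta != 0.0:
                gh_e += beta * gsum
            gh_g += gsum
            if gj_e is not None or gj_g is not None:
                need_cross_e = gj_e is not None and beta != 0.0
                if need_cross_e or gj_g is not None:
                    gcross = gl.T @ rd["X"]                  # (L*q, L*q)
                    if need_cross_e:
                        gj_e += beta * gcross
                    if gj_g is not None:
                        gj_g += gcross
            if rd["label"] in free_beta_labels:
                gbeta[rd["label"]] = float((gl * fe.reshape(M, -1)).sum())

        grad = np.empty(self.spec.size)
        o = self.spec.offsets
        grad[o[0]:o[1]] = gh_e.ravel()
        if gj_e is not None:
            grad[o[1]:o[2]] = self.spec.grad_to_free_blocks(
                gj_e.reshape(L, q, L, q).transpose(0, 2, 1, 3)
            ).ravel()
        grad[o[2]:o[3]] = gh_g.ravel()
        if gj_g is not None:
            grad[o[3]:o[4]] = self.spec.grad_to_free_blocks(
                gj_g.reshape(L, q, L, q).transpose(0, 2, 1, 3)
            ).ravel()
        pen, pen_grad = self._penalty(vec)
        return total - pen, grad - pen_grad, gbeta

    # -- restricted beta objective ------------------------------------------

    def beta_objective(self, rd: dict, fe: np.ndarray, fg: np.ndarray):
        """Closure evaluating the round-t data term as a function of β_t
        (fields precomputed at fixed θ)."""

        def obj(beta: float) -> float:
            logits = beta * fe + fg
            return self._round_data_term(logits, rd)

        return obj


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def _config_for_model(model: AnnealModel, config: FitConfig | None) -> FitConfig:
    cfg = config or FitConfig()
    fam_e = "potts" if model.E.is_pairwise else "indep"
    fam_g = "potts" if model.G.is_pairwise else "indep"
    if (cfg.e_family, cfg.g_family) != (fam_e, fam_g):
        cfg = FitConfig(**{**cfg.__dict__, "e_family": fam_e, "g_family": fam_g})
    return cfg


def pseudo_loglik(
    model: AnnealModel, dataset: ScreeningDataset, config: FitConfig | None = None
) -> float:
    """Regularized weighted pseudo-log-likelihood of the dataset."""
    cfg = _config_for_model(model, config)
    engine = _PseudoLikelihood(dataset, cfg)
    _check_rounds(model, dataset)
    return engine.value(engine.spec.pack(model.E, model.G), model.betas)


def pseudo_grad(
    model: AnnealModel, dataset: ScreeningDataset, config: FitConfig | None = None
) -> PseudoGradient:
    """Analytic gradient of :func:`pseudo_loglik` for all free parameters."""
    cfg = _config_for_model(model, config)
    engine = _PseudoLikelihood(dataset, cfg)
    _check_rounds(model, dataset)
    free = model.round_labels[2:]
    _, grad, gbeta = engine.value_and_grad(
        engine.spec.pack(model.E, model.G), model.betas, free_beta_labels=free
    )
    o = engine.spec.offsets
    q = engine.q

    def blocks(seg: np.ndarray):
        return seg.reshape(-1, q, q) if seg.size else None

    return PseudoGradient(
        h_e=grad[o[0]:o[1]].reshape(engine.L, q),
        j_e=blocks(grad[o[1]:o[2]]) if cfg.e_family == "potts" else None,
        h_g=grad[o[2]:o[3]].reshape(engine.L, q),
        j_g=blocks(grad[o[3]:o[4]]) if cfg.g_family == "potts" else None,
        betas=gbeta,
    )


def _check_rounds(model: AnnealModel, dataset: ScreeningDataset) -> None:
    missing = [t for t in dataset.round_labels if t not in model.betas]
    if missing:
        raise DataError(f"model has no beta for sequenced rounds {missing}")
    if model.L != dataset.L or model.q != dataset.alphabet.q:
        raise DataError("model and dataset disagree on L or q")


def _default_betas(labels: list[int], config: FitConfig) -> dict[int, float]:
    if config.beta_init is not None:
        betas = {int(t): float(config.beta_init[t]) for t in labels}
    else:
        betas = {t: float(k) for k, t in enumerate(labels)}
    betas[labels[0]] = 0.0
    if len(labels) >= 2:
        betas[labels[1]] = 1.0
    return betas


def fit_theta(
    dataset: ScreeningDataset,
    betas: dict[int, float],
    config: FitConfig | None = None,
    _engine: _PseudoLikelihood | None = None,
    _x0: np.ndarray | None = None,
):
    """Maximize the pseudo-likelihood over θ at fixed β (convex sub-problem).

    Returns ``(E, G, info)`` where ``info`` carries the achieved objective
    and optimizer diagnostics.
    """
    cfg = config or FitConfig()
    engine = _engine or _PseudoLikelihood(dataset, cfg)
    x0 = np.zeros(engine.spec.size) if _x0 is None else _x0

    def fun(x):
        val, grad, _ = engine.value_and_grad(x, betas)
        return -val, -grad

    res = minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": cfg.max_inner_iterations, "gtol": cfg.grad_tol,
                 "ftol": cfg.inner_ftol},
    )
    E, G = engine.spec.unpack(res.x)
    info = {"objective": -float(res.fun), "n_iter": int(res.nit),
            "converged": bool(res.success), "x": res.x}
    return E, G, info


def fit_betas(
    dataset: ScreeningDataset,
    E: PottsEnergy,
    G: PottsEnergy,
    betas: dict[int, float],
    config: FitConfig | None = None,
    _engine: _PseudoLikelihood | None = None,
) -> dict[int, float]:
    """Update each free β_t (rounds beyond the two fixed ones) by scalar
    maximization of its round-restricted pseudo-likelihood.

    Each sub-problem is concave in β_t, so a bounded 1-D search suffices.
    With fewer than 3 sequenced rounds the constraints fully determine β
    and the input is returned unchanged.
    """
    cfg = config or FitConfig()
    engine = _engine or _PseudoLikelihood(dataset, cfg)
    labels = engine.labels
    out = dict(betas)
    if len(labels) < 3:
        logger.info("fewer than 3 sequenced rounds: beta fixed by constraints")
        return out
    e_part, g_part = engine._split(engine.spec.pack(E, G))
    for rd in engine.rounds:
        t = rd["label"]
        if t in labels[:2]:
            continue
        fe = engine._fields(e_part, rd["X"])
        fg = engine._fields(g_part, rd["X"])
        obj = engine.beta_objective(rd, fe, fg)
        res = minimize_scalar(
            lambda b: -obj(b), bounds=(-_BETA_BOUND, _BETA_BOUND),
            method="bounded", options={"xatol": 1e-8},
        )
        # never step downhill: keep the old value if the search ties/loses
        if obj(float(res.x)) >= obj(out[t]):
            out[t] = float(res.x)
    return out


def fit(
    dataset: ScreeningDataset, config: FitConfig | None = None
) -> FitResult:
    """Alternating θ / β maximization of the regularized pseudo-likelihood.

    Deterministic given the dataset and configuration. The objective trace
    (recorded after every outer iteration) is non-decreasing up to numerical
    tolerance; convergence is declared when both the maximum θ change and
    the maximum β change fall below their tolerances.
    """
    cfg = config or FitConfig()
    engine = _PseudoLikelihood(dataset, cfg)
    labels = engine.labels
    betas = _default_betas(labels, cfg)
    x = np.zeros(engine.spec.size)
    trace: list[float] = []
    converged = False
    n_outer = 0
    for n_outer in range(1, cfg.max_outer_iterations + 1):
        E, G, info = fit_theta(dataset, betas, cfg, _engine=engine, _x0=x)
        dx = float(np.max(np.abs(info["x"] - x))) if trace else np.inf
        x = info["x"]
        new_betas = fit_betas(dataset, E, G, betas, cfg, _engine=engine)
        dbeta = max(abs(new_betas[t] - betas[t]) for t in labels)
        betas = new_betas
        obj = engine.value(x, betas)
        trace.append(obj)
        logger.info("outer %d: objective %.10g (dtheta %.3g, dbeta %.3g)",
                    n_outer, obj, dx, dbeta)
        if dx < cfg.theta_tol and dbeta < cfg.beta_tol:
            converged = True
            break
    E, G = engine.spec.unpack(x)
    model = AnnealModel(E, G, betas, alphabet=dataset.alphabet)
    return FitResult(model, np.array(trace), converged, n_outer)
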