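"""Multivariate Bernoulli hidden Markov model of chromatin states.

A genomic bin carries a binary vector of histone-mark presence calls.  The
model assumes a hidden chromatin state per 150-bp bin following a first-order
Markov chain shared across chromosomes (each chromosome is an independent
observation sequence re-using the initial distribution), with
conditionally independent Bernoulli emissions per mark:

    P(x_t | z_t = k) = prod_m p[k, m]^x_tm (1 - p[k, m])^(1 - x_tm)

Parameters are estimated by Baum-Welch (EM) from several random restarts,
keeping the restart with the highest final log-likelihood.  The forward and
backward recursions run in scaled linear space with a per-frame log-offset,
so likelihoods of sequences of millions of bins are computed without
underflow.  Decoding is per-bin posterior argmax by default (matching
ChromHMM's segmentation semantics), with Viterbi available.

Model-size selection follows the emission-correlation criterion: the
smallest K whose fitted model has, for every state of a large reference
model, some state whose emission vector correlates above a threshold
(0.7 by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import linear_sum_assignment

from .core_io import BinGrid, EmissionMatrix, PeakSet, ValidationError, rasterize

__all__ = [
    "BinarizedMatrix",
    "HMMModel",
    "StateSegmentation",
    "binarize",
    "fit_hmm",
    "decode",
    "state_posteriors",
    "sequence_loglik",
    "compare_models",
    "select_model",
    "match_states",
    "emission_recovery",
    "order_states",
]

_PROB_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# containers


@dataclass
class BinarizedMatrix:
    """Bins x marks 0/1 presence calls on a fixed grid.

    Rows follow the grid's genome-wide bin order; chromosome boundaries
    partition the rows into independent observation sequences.
    """

    grid: BinGrid
    marks: tuple[str, ...]
    values: np.ndarray  # (total_bins, n_marks) uint8

    def __post_init__(self):
        self.marks = tuple(self.marks)
        self.values = np.ascontiguousarray(self.values, dtype=np.uint8)
        if self.values.shape != (self.grid.total_bins, len(self.marks)):
            raise ValidationError(
                f"binarized shape {self.values.shape} != "
                f"({self.grid.total_bins}, {len(self.marks)})"
            )

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def sequences(self) -> list[slice]:
        """Row slices of the independent per-chromosome sequences."""
        return list(self.grid.chrom_slices().values())

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.bins_frame()
        for j, m in enumerate(self.marks):
            df[m] = self.values[:, j]
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class HMMModel:
    """Fitted chromatin-state HMM parameters plus the optimization trace."""

    initial: np.ndarray  # (K,)
    transition: np.ndarray  # (K, K), row-stochastic
    emission: EmissionMatrix  # (K, M) Bernoulli
    loglik_traces: list[list[float]] = field(default_factory=list)  # one per restart
    best_restart: int = 0
    seed: int = 0
    refine_trace: list[float] = field(default_factory=list)  # accepted split-merge LLs

    def __post_init__(self):
        self.initial = np.asarray(self.initial, float)
        self.transition = np.asarray(self.transition, float)
        K = self.K
        if self.transition.shape != (K, K):
            raise ValidationError("transition matrix shape mismatch")
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ValidationError("initial distribution must sum to 1")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-9):
            raise ValidationError("transition rows must sum to 1")

    @property
    def K(self) -> int:
        return self.emission.n_states

    @property
    def marks(self) -> tuple[str, ...]:
        return self.emission.marks

    @property
    def trace(self) -> list[float]:
        return self.loglik_traces[self.best_restart] if self.loglik_traces else []

    def to_json(self, path: str | Path) -> None:
        payload = {
            "states": list(self.emission.states),
            "marks": list(self.marks),
            "initial": self.initial.tolist(),
            "transition": self.transition.tolist(),
            "emission": self.emission.probs.tolist(),
            "loglik_traces": self.loglik_traces,
            "best_restart": self.best_restart,
            "seed": self.seed,
            "refine_trace": self.refine_trace,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "HMMModel":
        d = json.loads(Path(path).read_text())
        return cls(
            initial=np.array(d["initial"]),
            transition=np.array(d["transition"]),
            emission=EmissionMatrix(np.array(d["emission"]), d["states"], d["marks"]),
            loglik_traces=d.get("loglik_traces", []),
            best_restart=d.get("best_restart", 0),
            seed=d.get("seed", 0),
            refine_trace=d.get("refine_trace", []),
        )


@dataclass
class StateSegmentation:
    """Per-bin chromatin-state assignments on a grid.

    ``labels`` are 0-based state indices; ``state_names`` give the reporting
    names.  ``segments()`` collapses runs of equal labels into BED-ready
    intervals that tile exactly the binned genome.
    """

    grid: BinGrid
    labels: np.ndarray  # (total_bins,) int
    state_names: tuple[str, ...]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.state_names = tuple(self.state_names)
        if self.labels.shape != (self.grid.total_bins,):
            raise ValidationError("label count must equal grid bin count")
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= len(self.state_names)):
            raise ValidationError("state label out of range")

    @property
    def K(self) -> int:
        return len(self.state_names)

    def segments(self) -> pd.DataFrame:
        rows = []
        w = self.grid.width
        for chrom, sl in self.grid.chrom_slices().items():
            lab = self.labels[sl]
            if len(lab) == 0:
                continue
            clen = self.grid.layout.length_of(chrom)
            change = np.flatnonzero(np.diff(lab)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(lab)]))
            for s, e in zip(starts, ends):
                rows.append((chrom, int(s) * w, min(int(e) * w, clen), int(lab[s])))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state_index"])
        df["state"] = [self.state_names[i] for i in df["state_index"]]
        return df

    def to_bed(self, path: str | Path) -> None:
        seg = self.segments()
        with open(path, "w") as fh:
            for r in seg.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.state}\t0\t.\n")

    @classmethod
    def from_bed(cls, path: str | Path, grid: BinGrid, state_names: Sequence[str]) -> "StateSegmentation":
        from .core_io import read_bed

        seg = read_bed(path)
        name_to_idx = {n: i for i, n in enumerate(state_names)}
        labels = np.full(grid.total_bins, -1, dtype=np.int64)
        w = grid.width
        for r in seg.itertuples(index=False):
            sl = grid.chrom_slices()[r.chrom]
            first, last = r.start // w, (r.end - 1) // w
            labels[sl.start + first : sl.start + last + 1] = name_to_idx[r.name]
        if (labels < 0).any():
            raise ValidationError("segments do not tile the binned genome")
        return cls(grid, labels, tuple(state_names))


# ---------------------------------------------------------------------------
# binarization


def binarize(
    consolidated: Mapping[str, PeakSet],
    grid: BinGrid,
    marks: Sequence[str] | None = None,
    min_overlap: float = 0.0,
) -> BinarizedMatrix:
    """Rasterize consolidated peak tracks into a bins x marks 0/1 matrix.

    A cell is 1 iff a peak of the mark overlaps the bin by >= 1 bp, or by at
    least ``min_overlap`` of the bin length when that fraction is positive.
    """
    marks = tuple(marks) if marks is not None else tuple(consolidated)
    missing = [m for m in marks if m not in consolidated]
    if missing:
        raise ValidationError(f"marks missing from input: {missing}")
    cols = [rasterize(consolidated[m].df, grid, min_overlap=min_overlap) for m in marks]
    return BinarizedMatrix(grid, marks, np.stack(cols, axis=1).astype(np.uint8))


# ---------------------------------------------------------------------------
# numerics


@njit(cache=True)
def _forward_backward(B, pi, A):  # pragma: no cover - exercised via fit/decode
    """Scaled forward-backward for one sequence.

    ``B`` holds per-frame emission likelihoods already normalized by their
    frame maximum (the caller re-adds the log offsets).  Returns
    (gamma, xi_sum, log-likelihood-minus-offsets).
    """
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    for k in range(K):
        alpha[0, k] = pi[k] * B[0, k]
    c[0] = alpha[0].sum()
    for k in range(K):
        alpha[0, k] /= c[0]
    for t in range(1, T):
        for j in range(K):
            acc = 0.0
            for i in range(K):
                acc += alpha[t - 1, i] * A[i, j]
            alpha[t, j] = acc * B[t, j]
        c[t] = alpha[t].sum()
        for j in range(K):
            alpha[t, j] /= c[t]

    beta = np.empty((T, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
    xi = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        for i in range(K):
            acc = 0.0
            for j in range(K):
                acc += A[i, j] * B[t + 1, j] * beta[t + 1, j]
            beta[t, i] = acc / c[t + 1]
        for i in range(K):
            for j in range(K):
                xi[i, j] += (
                    alpha[t, i] * A[i, j] * B[t + 1, j] * beta[t + 1, j] / c[t + 1]
                )

    gamma = alpha * beta
    ll = 0.0
    for t in range(T):
        ll += np.log(c[t])
    return gamma, xi, ll


@njit(cache=True)
def _viterbi(framelog, logpi, logA):  # pragma: no cover - exercised via decode
    T, K = framelog.shape
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = logpi[k] + framelog[0, k]
    for t in range(1, T):
        for j in range(K):
            best = -np.inf
            arg = 0
            for i in range(K):
                v = delta[t - 1, i] + logA[i, j]
                if v > best:
                    best = v
                    arg = i
            delta[t, j] = best + framelog[t, j]
            psi[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = np.argmax(delta[T - 1])
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def _frame_loglik(X: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Per-bin log P(x | state) for all states; probabilities are floored."""
    q = np.clip(p, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    lp = np.log(q)
    l1 = np.log1p(-q)
    return X @ (lp - l1).T + l1.sum(axis=1)


def sequence_loglik(model: "HMMModel", data: BinarizedMatrix) -> float:
    """Total log-likelihood of the data under the model (all chromosomes)."""
    X = data.values.astype(np.float64)
    fl = _frame_loglik(X, model.emission.probs)
    total = 0.0
    for sl in data.sequences():
        sub = fl[sl]
        if sub.shape[0] == 0:
            continue
        off = sub.max(axis=1)
        B = np.exp(sub - off[:, None])
        _, _, ll = _forward_backward(B, model.initial, model.transition)
        total += ll + off.sum()
    return total


# ---------------------------------------------------------------------------
# fitting


def _em_run(
    X: np.ndarray,
    seqs: list[slice],
    p: np.ndarray,
    A: np.ndarray,
    pi: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    """Baum-Welch iterations from one starting point; returns the trace."""
    K, M = p.shape
    trace: list[float] = []
    for _it in range(max_iter):
        fl = _frame_loglik(X, p)
        gamma_sum = np.zeros(K)
        gamma_X = np.zeros((K, M))
        xi_sum = np.zeros((K, K))
        init_sum = np.zeros(K)
        ll = 0.0
        for sl in seqs:
            sub = fl[sl]
            off = sub.max(axis=1)
            B = np.exp(sub - off[:, None])
            gamma, xi, ll_seq = _forward_backward(B, pi, A)
            ll += ll_seq + off.sum()
            gamma_sum += gamma.sum(axis=0)
            gamma_X += gamma.T @ X[sl]
            xi_sum += xi
            init_sum += gamma[0]
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            break
        pi = init_sum / init_sum.sum()
        rowsum = xi_sum.sum(axis=1, keepdims=True)
        A = np.where(rowsum > 0, xi_sum / np.where(rowsum == 0, 1, rowsum), 1.0 / K)
        A /= A.sum(axis=1, keepdims=True)
        p = gamma_X / np.where(gamma_sum == 0, 1, gamma_sum)[:, None]
        p = np.clip(p, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    return p, A, pi, trace


def _posteriors_raw(
    X: np.ndarray, seqs: list[slice], p: np.ndarray, A: np.ndarray, pi: np.ndarray
) -> np.ndarray:
    fl = _frame_loglik(X, p)
    out = np.empty((X.shape[0], p.shape[0]))
    for sl in seqs:
        sub = fl[sl]
        off = sub.max(axis=1)
        B = np.exp(sub - off[:, None])
        gamma, _, _ = _forward_backward(B, pi, A)
        out[sl] = gamma
    return out


def _split_merge_proposals(
    X: np.ndarray,
    seqs: list[slice],
    p: np.ndarray,
    A: np.ndarray,
    pi: np.ndarray,
    n_merge: int,
    n_split: int,
) -> list[np.ndarray]:
    """Candidate emission matrices that merge a redundant state pair and
    split a heterogeneous state.

    Redundancy is ranked by emission-row correlation.  Heterogeneity is the
    posterior-mass-weighted excess top eigenvalue of the within-state
    covariance over the product-Bernoulli prediction ``diag(p (1-p))`` --
    identically zero for a pure state, large for a state absorbing a
    mixture.  The split displaces the state's emissions along the excess
    principal direction.
    """
    K, M = p.shape
    gamma = _posteriors_raw(X, seqs, p, A, pi)
    gs = np.maximum(gamma.sum(axis=0), 1e-9)
    Z = p - p.mean(axis=1, keepdims=True)
    nrm = np.sqrt((Z**2).sum(axis=1))
    nrm[nrm == 0] = 1.0
    C = (Z @ Z.T) / np.outer(nrm, nrm)
    iu = np.triu_indices(K, 1)
    pairs = [
        (int(iu[0][t]), int(iu[1][t]))
        for t in np.argsort(-C[iu], kind="stable")[:n_merge]
    ]
    scores, dirs = [], []
    for s in range(K):
        Exx = (gamma[:, s : s + 1] * X).T @ X / gs[s]
        cov = Exx - np.outer(p[s], p[s]) - np.diag(p[s] * (1 - p[s]))
        evals, evecs = np.linalg.eigh((cov + cov.T) / 2)
        top = max(float(evals[-1]), 0.0)
        scores.append(gs[s] * top)
        dirs.append(evecs[:, -1] * np.sqrt(top))
    splits = list(np.argsort(-np.array(scores), kind="stable")[:n_split])
    out = []
    for i, j in pairs:
        for s in splits:
            if s in (i, j):
                continue
            p2 = p.copy()
            p2[i] = (gs[i] * p[i] + gs[j] * p[j]) / (gs[i] + gs[j])
            p2[j] = np.clip(p[s] + dirs[s], 0.01, 0.99)
            p2[s] = np.clip(p[s] - dirs[s], 0.01, 0.99)
            # remap Markov mass: the merged slot absorbs both incoming flows,
            # the split halves share the split state's transition profile --
            # otherwise the half placed in the vacated slot starves
            A2 = A.copy()
            A2[i] = (gs[i] * A[i] + gs[j] * A[j]) / (gs[i] + gs[j])
            A2[:, i] = A[:, i] + A[:, j]
            A2[j] = A[s]
            A2[:, j] = A2[:, s] / 2
            A2[:, s] = A2[:, s] / 2
            A2 /= A2.sum(axis=1, keepdims=True)
            pi2 = pi.copy()
            pi2[i] = pi[i] + pi[j]
            pi2[j] = pi2[s] / 2
            pi2[s] = pi2[s] / 2
            pi2 /= pi2.sum()
            out.append((p2, A2, pi2))
    return out


def fit_hmm(
    data: BinarizedMatrix,
    K: int,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-4,
    n_candidates: int = 8,
    burn_iter: int = 8,
    sm_budget: int = 24,
    sm_margin: float = 2.0,
) -> HMMModel:
    """Fit a K-state Bernoulli HMM by Baum-Welch with random restarts.

    Each restart draws ``n_candidates`` random starting points (emissions
    uniform on (0.1, 0.9), transition and initial rows from a symmetric
    Dirichlet), advances each by ``burn_iter`` EM iterations, and continues
    full EM from the best of them -- the short-run ("small-EM") selection
    that is standard practice against the many shallow local optima of
    high-K mixture likelihoods.  The restart with the highest final
    log-likelihood wins.  Within a restart the recorded log-likelihood
    trace is non-decreasing up to the floating tolerance of the emission
    floor; EM stops when the absolute gain drops below ``tol``.

    The winning restart is then refined by split-merge moves (Ueda-style):
    up to ``sm_budget`` proposals merge the most redundant state pair while
    splitting the state with the largest excess within-state covariance,
    each re-optimized by EM and accepted only if the log-likelihood improves
    by more than ``sm_margin``.  Accepted refinements are recorded in
    ``refine_trace`` (monotone by construction); ``sm_budget=0`` disables
    refinement.  This escapes the characteristic local optimum in which two
    similar chromatin states collapse into one while a spare state
    duplicates the zero state.

    ``K = 1`` is solved in closed form: the emission row equals the column
    means of the data exactly and the transition matrix is ``[[1]]``.
    """
    if K < 1:
        raise ValidationError(f"K must be >= 1, got {K}")
    if data.n_bins == 0:
        raise ValidationError("empty binarized matrix")
    if K > data.n_bins:
        raise ValidationError(f"K={K} exceeds bin count {data.n_bins}")
    X = data.values.astype(np.float64)
    state_names = tuple(f"S{i + 1}" for i in range(K))

    if K == 1:
        em = EmissionMatrix(X.mean(axis=0)[None, :], state_names, data.marks)
        model = HMMModel(
            initial=np.array([1.0]),
            transition=np.array([[1.0]]),
            emission=em,
            seed=seed,
        )
        ll = float(_frame_loglik(X, em.probs).sum())
        model.loglik_traces = [[ll]]
        return model

    if len(np.unique(data.values, axis=0)) == 1:
        warnings.warn("all observation rows identical; K > 1 fit is degenerate")

    seqs = [sl for sl in data.sequences() if sl.stop > sl.start]
    M = X.shape[1]
    rng = np.random.default_rng(seed)
    best = None
    traces: list[list[float]] = []
    for _ in range(n_restarts):
        cands = []
        for _c in range(max(1, n_candidates)):
            p0 = rng.uniform(0.1, 0.9, size=(K, M))
            A0 = rng.dirichlet(np.ones(K), size=K)
            pi0 = rng.dirichlet(np.ones(K))
            cands.append(_em_run(X, seqs, p0, A0, pi0, min(burn_iter, max_iter), tol))
        p, A, pi, burn_trace = max(cands, key=lambda c: c[3][-1])
        p, A, pi, trace = _em_run(X, seqs, p, A, pi, max_iter, tol)
        trace = burn_trace + trace
        traces.append(trace)
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], pi.copy(), A.copy(), p.copy(), len(traces) - 1)

    ll, pi, A, p, idx = best
    refine_trace: list[float] = []
    if sm_budget > 0 and K >= 3:
        budget, stuck = sm_budget, 0
        while budget > 0 and stuck < 2:
            accepted = False
            for p2, A2, pi2 in _split_merge_proposals(X, seqs, p, A, pi, 3 + stuck, 3 + stuck):
                if budget <= 0:
                    break
                budget -= 1
                p3, A3, pi3, tr3 = _em_run(X, seqs, p2, A2, pi2, max_iter, tol)
                if tr3[-1] > ll + sm_margin:
                    p, A, pi, ll = p3, A3, pi3, tr3[-1]
                    refine_trace.append(ll)
                    accepted = True
                    break
            stuck = 0 if accepted else stuck + 1

    em = EmissionMatrix(p, state_names, data.marks)
    model = HMMModel(initial=pi, transition=A, emission=em, seed=seed)
    model.loglik_traces = traces
    model.best_restart = idx
    model.refine_trace = refine_trace
    return model


# ---------------------------------------------------------------------------
# decoding


def state_posteriors(model: HMMModel, data: BinarizedMatrix) -> np.ndarray:
    """Forward-backward posterior P(state | data) per bin; rows sum to 1."""
    if tuple(model.marks) != tuple(data.marks):
        raise ValidationError("model marks do not match data marks")
    X = data.values.astype(np.float64)
    fl = _frame_loglik(X, model.emission.probs)
    out = np.empty((data.n_bins, model.K))
    for sl in data.sequences():
        sub = fl[sl]
        if sub.shape[0] == 0:
            continue
        off = sub.max(axis=1)
        B = np.exp(sub - off[:, None])
        gamma, _, _ = _forward_backward(B, model.initial, model.transition)
        out[sl] = gamma
    return out


def decode(
    model: HMMModel,
    data: BinarizedMatrix,
    method: str = "posterior",
) -> StateSegmentation:
    """Assign a chromatin state to every bin.

    ``posterior`` (default) takes the per-bin argmax of the forward-backward
    state posterior; ``viterbi`` returns the jointly most probable path.
    """
    if method == "posterior":
        labels = np.argmax(state_posteriors(model, data), axis=1)
    elif method == "viterbi":
        if tuple(model.marks) != tuple(data.marks):
            raise ValidationError("model marks do not match data marks")
        X = data.values.astype(np.float64)
        fl = _frame_loglik(X, model.emission.probs)
        with np.errstate(divide="ignore"):
            logpi = np.log(np.clip(model.initial, 1e-300, None))
            logA = np.log(np.clip(model.transition, 1e-300, None))
        labels = np.empty(data.n_bins, dtype=np.int64)
        for sl in data.sequences():
            if sl.stop > sl.start:
                labels[sl] = _viterbi(fl[sl], logpi, logA)
    else:
        raise ValidationError(f"unknown decode method {method!r}")
    return StateSegmentation(data.grid, labels, model.emission.states)


# ---------------------------------------------------------------------------
# model comparison / selection


def _emission_correlations(a: EmissionMatrix, b: EmissionMatrix) -> np.ndarray:
    """Pearson correlation of every emission row of ``a`` with every row of
    ``b``; rows with zero variance yield NaN."""
    if tuple(a.marks) != tuple(b.marks):
        raise ValidationError("emission matrices are over different mark sets")
    A = a.probs - a.probs.mean(axis=1, keepdims=True)
    B = b.probs - b.probs.mean(axis=1, keepdims=True)
    sa = np.sqrt((A**2).sum(axis=1))
    sb = np.sqrt((B**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (A @ B.T) / np.outer(sa, sb)
    corr[sa == 0, :] = np.nan
    corr[:, sb == 0] = np.nan
    return corr


def compare_models(a: HMMModel, b: HMMModel) -> np.ndarray:
    """For each state of ``a``: the maximum Pearson correlation of its
    emission vector against all states of ``b`` (NaN if undefined)."""
    corr = _emission_correlations(a.emission, b.emission)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmax(corr, axis=1)
    flat = np.isnan(corr).all(axis=1)
    if flat.any():
        warnings.warn(
            f"constant emission vectors in states {np.flatnonzero(flat).tolist()}; "
            "correlation undefined"
        )
        out[flat] = np.nan
    return out


def select_model(
    models: Sequence[HMMModel],
    reference: HMMModel,
    rho: float = 0.7,
    require: str = "every",
) -> int:
    """Choose the smallest model size that captures the reference states.

    A candidate qualifies when, for every state of the reference model, some
    candidate state's emission vector correlates above ``rho``
    (``require="every"``, the default) or when the mean of those per-state
    maxima exceeds ``rho`` (``require="mean"``).  Returns the chosen K; if no
    candidate qualifies, returns the reference K with a warning.
    """
    if require not in ("every", "mean"):
        raise ValidationError(f"unknown capture criterion {require!r}")
    for m in sorted(models, key=lambda m: m.K):
        if m.K > reference.K:
            raise ValidationError("reference must be the largest model")
        caps = compare_models(reference, m)
        if np.isnan(caps).any():
            continue
        ok = bool(np.all(caps > rho)) if require == "every" else bool(caps.mean() > rho)
        if ok:
            return m.K
    warnings.warn(f"no model captures all reference states at rho={rho}; returning reference K")
    return reference.K


def match_states(learned: EmissionMatrix, planted: EmissionMatrix) -> np.ndarray:
    """Hungarian matching of learned states to planted states.

    Returns an array ``perm`` with ``perm[i]`` = learned-state index matched
    to planted state ``i``, maximizing total emission-row correlation
    (falling back on negative absolute error for constant rows).
    """
    corr = _emission_correlations(planted, learned)
    err = np.abs(planted.probs[:, None, :] - learned.probs[None, :, :]).mean(axis=2)
    cost = np.where(np.isnan(corr), err, -corr)
    _, cols = linear_sum_assignment(cost)
    return cols


def emission_recovery(learned: EmissionMatrix, planted: EmissionMatrix) -> tuple[float, np.ndarray]:
    """Max absolute emission error after Hungarian state matching."""
    perm = match_states(learned, planted)
    err = np.abs(learned.probs[perm] - planted.probs).max()
    return float(err), perm


def order_states(model: HMMModel, active_marks: Sequence[str]) -> HMMModel:
    """Reorder states by decreasing mean emission over the active marks.

    Mirrors the reporting convention that lists states by decreasing
    involvement with the active genic environment; ties break by original
    index.  State names are reassigned S1..SK in the new order.
    """
    idx = [model.marks.index(m) for m in active_marks]
    if not idx:
        raise ValidationError("no active marks given")
    score = model.emission.probs[:, idx].mean(axis=1)
    order = np.argsort(-score, kind="stable")
    em = EmissionMatrix(
        model.emission.probs[order],
        tuple(f"S{i + 1}" for i in range(model.K)),
        model.marks,
    )
    out = HMMModel(
        initial=model.initial[order],
        transition=model.transition[np.ix_(order, order)],
        emission=em,
        seed=model.seed,
    )
    out.loglik_traces = model.loglik_traces
    out.best_restart = model.best_restart
    out.refine_trace = model.refine_trace
    return out
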