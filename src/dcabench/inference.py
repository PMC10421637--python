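"""Interaction scoring from spin samples.

Two routes are benchmarked against each other:

* **local** — rank pairs by their raw empirical pair statistics (Ising: the
  pair correlation ``<s_i s_j>``; Potts: the Frobenius norm of the pair's
  connected-correlation block);
* **global** — naive mean-field inversion ``beta J_hat = -C^{-1}`` of the
  connected correlation matrix, with pairs ranked by the correlation of the
  induced two-spin direct distribution (Ising) or by the Frobenius norm of
  the zero-sum-gauge coupling block (Potts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .graph_ensemble import CouplingMatrix
from .spin_sampler import SampleSet

__all__ = [
    "MomentEstimates",
    "InferredCouplings",
    "DirectPairModel",
    "ScoredPairs",
    "SingularMomentsError",
    "DegenerateMarginalError",
    "DegenerateMarginalWarning",
    "estimate_moments",
    "mean_field_inversion",
    "local_scores",
    "direct_pair_model",
    "global_scores",
]


class SingularMomentsError(np.linalg.LinAlgError):
    """Connected correlation matrix is singular and no ridge was supplied."""


class DegenerateMarginalError(ValueError):
    """A single-spin marginal sits on the boundary |m| = 1."""


class DegenerateMarginalWarning(UserWarning):
    pass


@dataclass
class MomentEstimates:
    """Plug-in sample moments of a :class:`SampleSet`.

    For Ising data ``connected_correlations`` is the n x n spin covariance
    and ``raw_pair_correlations`` holds ``<s_i s_j>``. For Potts data sites
    are one-hot encoded with the reference state (the q-th) dropped, so
    ``connected_correlations`` is n(q-1) x n(q-1); ``state_frequencies``
    keeps all q per-site frequencies and ``full_covariance`` the n*q x n*q
    indicator covariance used for gauge-free local scores.
    """

    means: np.ndarray
    connected_correlations: np.ndarray
    sample_size: int
    num_states: int = 2
    raw_pair_correlations: np.ndarray | None = None
    state_frequencies: np.ndarray | None = None
    full_covariance: np.ndarray | None = None
    reference_state: int = -1  # index of the dropped Potts state

    @property
    def n(self) -> int:
        if self.num_states == 2:
            return self.means.shape[0]
        return self.state_frequencies.shape[0]


def estimate_moments(
    samples: SampleSet, reference_state: int | None = None
) -> MomentEstimates:
    """Empirical means and connected correlations (plug-in, 1/K normalized).

    ``reference_state`` picks which Potts state (0-based) is dropped from the
    one-hot encoding; the default is the last. Downstream scores are gauge
    invariant to this choice.
    """
    if samples.K < 2:
        raise ValueError("need at least two samples")
    K = samples.K
    if samples.num_states == 2:
        S = samples.configurations.astype(np.float64)
        m = S.mean(axis=0)
        raw = (S.T @ S) / K
        np.fill_diagonal(raw, 1.0)
        C = raw - np.outer(m, m)
        return MomentEstimates(
            means=m,
            connected_correlations=C,
            sample_size=K,
            num_states=2,
            raw_pair_correlations=raw,
        )
    q = samples.num_states
    n = samples.n
    ref = q - 1 if reference_state is None else int(reference_state)
    if not 0 <= ref < q:
        raise ValueError(f"reference state must lie in 0..{q - 1}")
    states = samples.configurations.astype(np.int64) - 1  # 0..q-1
    X = np.zeros((K, n * q))
    rows = np.repeat(np.arange(K), n)
    cols = (np.tile(np.arange(n), K) * q + states.ravel())
    X[rows, cols] = 1.0
    freq = X.mean(axis=0)
    cov = (X.T @ X) / K - np.outer(freq, freq)
    keep = np.array([i * q + a for i in range(n) for a in range(q) if a != ref])
    return MomentEstimates(
        means=freq.reshape(n, q),
        connected_correlations=cov[np.ix_(keep, keep)],
        sample_size=K,
        num_states=q,
        state_frequencies=freq.reshape(n, q),
        full_covariance=cov,
        reference_state=ref,
    )


def exact_moments(
    dist, num_states: int = 2, reference_state: int | None = None
) -> MomentEstimates:
    """Moments of an :class:`~dcabench.spin_sampler.ExactDistribution`.

    Convenience for oracle tests: packs enumerated moments into the same
    container the estimators produce (sample_size is set to 0).
    """
    if num_states == 2:
        raw = dist.second_moments()
        m = dist.mean_spins().astype(np.float64)
        return MomentEstimates(
            means=m,
            connected_correlations=raw - np.outer(m, m),
            sample_size=0,
            num_states=2,
            raw_pair_correlations=raw,
        )
    q = num_states
    ref = q - 1 if reference_state is None else int(reference_state)
    configs = dist.configurations.astype(np.int64) - 1
    M, n = configs.shape
    X = np.zeros((M, n * q))
    rows = np.repeat(np.arange(M), n)
    cols = np.tile(np.arange(n), M) * q + configs.ravel()
    X[rows, cols] = 1.0
    freq = dist.probabilities @ X
    cov = (X * dist.probabilities[:, None]).T @ X - np.outer(freq, freq)
    keep = np.array([i * q + a for i in range(n) for a in range(q) if a != ref])
    return MomentEstimates(
        means=freq.reshape(n, q),
        connected_correlations=cov[np.ix_(keep, keep)],
        sample_size=0,
        num_states=q,
        state_frequencies=freq.reshape(n, q),
        full_covariance=cov,
        reference_state=ref,
    )


@dataclass
class InferredCouplings:
    """Output of naive mean-field inversion.

    ``beta_couplings`` is the n x n matrix of beta*J_hat (Ising) with an
    ignored diagonal; for Potts models ``potts_blocks`` holds the per-pair
    q x q coupling blocks in the zero-sum gauge and ``beta_couplings`` their
    Frobenius norms.
    """

    beta_couplings: np.ndarray
    regularization_used: float
    temperature_assumed: float
    num_states: int = 2
    potts_blocks: np.ndarray | None = None  # (n, n, q, q)

    @property
    def couplings(self) -> np.ndarray:
        """De-dimensionalized J_hat = T * beta * J_hat."""
        return self.temperature_assumed * self.beta_couplings

    @property
    def n(self) -> int:
        return self.beta_couplings.shape[0]


def _zero_sum_gauge(block: np.ndarray) -> np.ndarray:
    row = block.mean(axis=1, keepdims=True)
    col = block.mean(axis=0, keepdims=True)
    return block - row - col + block.mean()


def mean_field_inversion(
    moments: MomentEstimates,
    temperature: float = 1.0,
    ridge: float | None = None,
) -> InferredCouplings:
    """Naive mean-field inversion ``beta J_hat_ij = -(C^{-1})_ij``.

    ``ridge`` is added to the diagonal before inversion; the default is
    ``1e-8 * trace(C) / dim`` so degenerate correlation matrices (constant
    spins, K < dim) remain invertible reproducibly. Pass ``ridge=0`` for the
    bare estimator, which raises on rank deficiency.
    """
    C = np.asarray(moments.connected_correlations, dtype=np.float64)
    dim = C.shape[0]
    if C.shape != (dim, dim) or not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("connected correlation matrix must be square symmetric")
    if ridge is None:
        ridge = 1e-8 * np.trace(C) / dim
    if ridge == 0:
        rank = np.linalg.matrix_rank(C)
        if rank < dim:
            raise SingularMomentsError(
                f"correlation matrix is rank deficient ({dim - rank} null "
                f"directions out of {dim}); supply a positive ridge"
            )
    Cinv = np.linalg.inv(C + ridge * np.eye(dim))
    Cinv = 0.5 * (Cinv + Cinv.T)
    if moments.num_states == 2:
        beta_J = -Cinv
        np.fill_diagonal(beta_J, 0.0)
        return InferredCouplings(
            beta_couplings=beta_J,
            regularization_used=float(ridge),
            temperature_assumed=float(temperature),
        )
    # Potts: extract (q-1)x(q-1) blocks, complete with the reference row and
    # column at zero, then project to the zero-sum gauge
    q = moments.num_states
    n = moments.n
    ref = moments.reference_state
    blocks = np.zeros((n, n, q, q))
    norms = np.zeros((n, n))
    d = q - 1
    for i in range(n):
        for j in range(i + 1, n):
            sub = -Cinv[i * d : (i + 1) * d, j * d : (j + 1) * d]
            raw = np.insert(np.insert(sub, ref, 0.0, axis=0), ref, 0.0, axis=1)
            gauged = _zero_sum_gauge(raw)
            blocks[i, j] = gauged
            blocks[j, i] = gauged.T
            norms[i, j] = norms[j, i] = np.linalg.norm(gauged)
    return InferredCouplings(
        beta_couplings=norms,
        regularization_used=float(ridge),
        temperature_assumed=float(temperature),
        num_states=q,
        potts_blocks=blocks,
    )


@dataclass
class ScoredPairs:
    """Per-pair interaction scores plus ground-truth labels."""

    pairs: np.ndarray  # (P, 2) int, i < j
    scores: np.ndarray  # (P,)
    labels: np.ndarray | None  # (P,) bool, None until attached
    method: str

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=bool)
            if self.labels.shape != self.scores.shape:
                raise ValueError("labels and scores must align")
        if self.pairs.shape != (self.scores.shape[0], 2):
            raise ValueError("pairs and scores must align")

    @property
    def num_pairs(self) -> int:
        return self.scores.shape[0]

    def with_labels(self, truth: CouplingMatrix) -> "ScoredPairs":
        labels = truth.entries[self.pairs[:, 0], self.pairs[:, 1]].astype(bool)
        return ScoredPairs(self.pairs, self.scores, labels, self.method)

    def subset(self, idx: np.ndarray) -> "ScoredPairs":
        return ScoredPairs(
            self.pairs[idx],
            self.scores[idx],
            None if self.labels is None else self.labels[idx],
            self.method,
        )

    def split(self, validation_fraction: float, seed: int):
        """Random disjoint (validation, test) split of the pairs."""
        if not 0 < validation_fraction < 1:
            raise ValueError("validation fraction must lie in (0, 1)")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(self.num_pairs)
        n_val = int(round(validation_fraction * self.num_pairs))
        return self.subset(np.sort(perm[:n_val])), self.subset(np.sort(perm[n_val:]))


def _all_pairs(n: int) -> np.ndarray:
    iu, ju = np.triu_indices(n, k=1)
    return np.column_stack([iu, ju])


def local_scores(
    moments: MomentEstimates, truth: CouplingMatrix | None = None
) -> ScoredPairs:
    """Local-statistics scores: raw pair correlations, no global model.

    Ising: ``<s_i s_j>``. Potts: Frobenius norm of the full q x q
    connected-correlation block of the pair (independent of any reference
    state by construction).
    """
    n = moments.n
    pairs = _all_pairs(n)
    if moments.num_states == 2:
        scores = moments.raw_pair_correlations[pairs[:, 0], pairs[:, 1]]
    else:
        q = moments.num_states
        cov = moments.full_covariance
        scores = np.empty(pairs.shape[0])
        for k, (i, j) in enumerate(pairs):
            block = cov[i * q : (i + 1) * q, j * q : (j + 1) * q]
            scores[k] = np.linalg.norm(block)
    scored = ScoredPairs(pairs, scores, None, method="local")
    return scored.with_labels(truth) if truth is not None else scored


# -- two-spin direct distribution (global Ising scores) ----------------------


def _direct_correlation_closed_form(a, m1, m2):
    """Correlation of the two-spin model with coupling a and marginals m1, m2.

    Parametrizing by c = <s1 s2>, the marginals are enforced exactly and the
    odds-ratio constraint ``p11 p00 / (p10 p01) = exp(4a)`` becomes the
    quadratic ``(1-A) c^2 + 2 (1+A) c + (1 - s^2) - A (1 - d^2) = 0`` with
    ``s = m1 + m2``, ``d = m1 - m2``. Computed with ``A = exp(-4|a|)`` to
    avoid overflow; vectorized over arrays.
    """
    a = np.asarray(a, dtype=np.float64)
    m1 = np.asarray(m1, dtype=np.float64)
    m2 = np.asarray(m2, dtype=np.float64)
    s = m1 + m2
    d = m1 - m2
    sign = np.where(a >= 0, 1.0, -1.0)
    A = np.exp(-4.0 * np.abs(a))  # in (0, 1]
    # for a >= 0 the equation is multiplied through by A = e^{-4a}:
    #   (A-1) c^2 + 2 (A+1) c + A(1-s^2) - (1-d^2) = 0
    # for a < 0 use the original form with A = e^{4a}
    aq = np.where(sign > 0, A - 1.0, 1.0 - A)
    bq = 2.0 * (A + 1.0)
    cq = np.where(
        sign > 0,
        A * (1.0 - s**2) - (1.0 - d**2),
        (1.0 - s**2) - A * (1.0 - d**2),
    )
    disc = np.maximum(bq**2 - 4.0 * aq * cq, 0.0)
    qterm = -0.5 * (bq + np.sqrt(disc))  # bq > 0 always
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.where(aq != 0.0, qterm / np.where(aq == 0.0, 1.0, aq), np.inf)
        r2 = cq / qterm
    lo = np.abs(s) - 1.0
    hi = 1.0 - np.abs(d)
    mid = 0.5 * (lo + hi)
    in1 = (r1 >= lo - 1e-9) & (r1 <= hi + 1e-9)
    c = np.where(in1, r1, r2)
    c = np.where(aq == 0.0, m1 * m2, c)  # a == 0: independent spins
    c = np.where(np.isfinite(c), c, mid)
    return np.clip(c, lo, hi)


def _two_spin_moments(a, h1, h2):
    """Model moments (m1, m2, c) of P ~ exp(a s1 s2 + h1 s1 + h2 s2)."""
    # the four states (s1, s2) in {+-1}^2, computed in log space
    e11 = a + h1 + h2
    e10 = -a + h1 - h2
    e01 = -a - h1 + h2
    e00 = a - h1 - h2
    mx = np.maximum.reduce([e11, e10, e01, e00])
    w11 = np.exp(e11 - mx)
    w10 = np.exp(e10 - mx)
    w01 = np.exp(e01 - mx)
    w00 = np.exp(e00 - mx)
    Z = w11 + w10 + w01 + w00
    m1 = (w11 + w10 - w01 - w00) / Z
    m2 = (w11 - w10 + w01 - w00) / Z
    c = (w11 - w10 - w01 + w00) / Z
    return m1, m2, c


def _log_cosh(y):
    y = np.abs(y)
    return y + np.log1p(np.exp(-2.0 * y)) - np.log(2.0)


def _match_fields(a, m1, m2, tol=1e-12, max_iter=200):
    """Fields (h1, h2) matching marginals (m1, m2) at coupling a, vectorized.

    Marginalizing one spin gives ``artanh(m1) = h1 + phi(h2)`` with
    ``phi(x) = 0.5 * log(cosh(a + x) / cosh(a - x))``; damped Newton on this
    2x2 system is well conditioned even for extreme couplings (|phi'| < 1).
    Initialized from the closed-form correlation solution.
    """
    a = np.asarray(a, dtype=np.float64)
    t1 = np.arctanh(m1)
    t2 = np.arctanh(m2)

    def phi(x):
        return 0.5 * (_log_cosh(a + x) - _log_cosh(a - x))

    # closed-form init: correlation -> table -> fields (loses precision only
    # in near-degenerate corners, which Newton then repairs)
    c = _direct_correlation_closed_form(a, m1, m2)
    p11 = np.clip((1 + m1 + m2 + c) / 4, 1e-300, None)
    p10 = np.clip((1 + m1 - m2 - c) / 4, 1e-300, None)
    p01 = np.clip((1 - m1 + m2 - c) / 4, 1e-300, None)
    p00 = np.clip((1 - m1 - m2 + c) / 4, 1e-300, None)
    h1 = 0.25 * np.log(p11 * p10 / (p01 * p00))
    h2 = 0.25 * np.log(p11 * p01 / (p10 * p00))

    def residual(x1, x2):
        return x1 + phi(x2) - t1, x2 + phi(x1) - t2

    r1, r2 = residual(h1, h2)
    norm = np.hypot(r1, r2)
    for _ in range(max_iter):
        if np.max(norm) < tol:
            break
        j12 = 0.5 * (np.tanh(a + h2) + np.tanh(a - h2))  # d r1 / d h2
        j21 = 0.5 * (np.tanh(a + h1) + np.tanh(a - h1))  # d r2 / d h1
        det = np.clip(1.0 - j12 * j21, 1e-15, None)  # |j| < 1 so det > 0
        dh1 = (r1 - j12 * r2) / det
        dh2 = (r2 - j21 * r1) / det
        step = np.ones_like(norm)
        improved = np.zeros(norm.shape, dtype=bool)
        for _ls in range(60):  # per-component backtracking on residual norm
            n1, n2 = h1 - step * dh1, h2 - step * dh2
            q1, q2 = residual(n1, n2)
            qn = np.hypot(q1, q2)
            improved = qn <= norm
            if improved.all():
                break
            step = np.where(improved, step, 0.5 * step)
        h1 = np.where(improved, n1, h1)
        h2 = np.where(improved, n2, h2)
        r1 = np.where(improved, q1, r1)
        r2 = np.where(improved, q2, r2)
        norm = np.hypot(r1, r2)
    return h1, h2


@dataclass(frozen=True)
class DirectPairModel:
    """Two-spin model with inferred coupling and marginal-matched fields."""

    pair: tuple
    coupling: float
    matching_fields: tuple
    direct_correlation: float


def direct_pair_model(
    coupling: float,
    empirical_means: tuple[float, float],
    pair: tuple = (0, 1),
    tol: float = 1e-10,
) -> DirectPairModel:
    """Fit the two-spin direct distribution for one pair.

    Finds fields so that the model's single-spin marginals equal the
    empirical ones (to well below 1e-8) and returns the model's pair
    correlation — the global interaction score.
    """
    m1, m2 = empirical_means
    if abs(m1) >= 1 or abs(m2) >= 1:
        raise DegenerateMarginalError(
            f"marginals must satisfy |m| < 1 strictly, got ({m1}, {m2})"
        )
    a = np.array([coupling])
    h1, h2 = _match_fields(a, np.array([m1]), np.array([m2]), tol=tol)
    _, _, c = _two_spin_moments(a, h1, h2)
    return DirectPairModel(
        pair=tuple(pair),
        coupling=float(coupling),
        matching_fields=(float(h1[0]), float(h2[0])),
        direct_correlation=float(c[0]),
    )


def global_scores(
    inferred: InferredCouplings,
    moments: MomentEstimates,
    truth: CouplingMatrix | None = None,
) -> ScoredPairs:
    """Global (mean-field DCA) scores.

    Ising: the direct correlation of each pair's two-spin model built from
    ``beta J_hat`` and the empirical means. Pairs with a degenerate marginal
    (|m| = 1) get the forced score ``m_i m_j`` and trigger a warning. Potts:
    the Frobenius norm of the zero-sum-gauge coupling block.
    """
    n = inferred.n
    pairs = _all_pairs(n)
    if inferred.num_states != 2:
        scores = inferred.beta_couplings[pairs[:, 0], pairs[:, 1]]
        scored = ScoredPairs(pairs, scores, None, method="global")
        return scored.with_labels(truth) if truth is not None else scored
    m = moments.means
    a = inferred.beta_couplings[pairs[:, 0], pairs[:, 1]]
    m1 = m[pairs[:, 0]]
    m2 = m[pairs[:, 1]]
    degenerate = (np.abs(m1) >= 1) | (np.abs(m2) >= 1)
    scores = np.empty(pairs.shape[0])
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} pairs have degenerate marginals |m| = 1; "
            "their direct correlations are forced to m_i * m_j",
            DegenerateMarginalWarning,
            stacklevel=2,
        )
        scores[degenerate] = m1[degenerate] * m2[degenerate]
    ok = ~degenerate
    if ok.any():
        h1, h2 = _match_fields(a[ok], m1[ok], m2[ok])
        _, _, c = _two_spin_moments(a[ok], h1, h2)
        scores[ok] = c
    scored = ScoredPairs(pairs, scores, None, method="global")
    return scored.with_labels(truth) if truth is not None else scored


def scores_table(
    local: ScoredPairs,
    global_: ScoredPairs,
    inferred: InferredCouplings,
    path,
) -> None:
    """Write the tab-separated pair-score table (i, j, label, local, global, bJ)."""
    if not np.array_equal(local.pairs, global_.pairs):
        raise ValueError("score sets must cover the same pairs")
    with open(path, "w") as fh:
        fh.write("i\tj\tlabel\tlocal_score\tglobal_score\tbeta_J_hat\n")
        for k, (i, j) in enumerate(local.pairs):
            lab = int(local.labels[k]) if local.labels is not None else -1
            fh.write(
                f"{i + 1}\t{j + 1}\t{lab}\t{local.scores[k]:.10g}\t"
                f"{global_.scores[k]:.10g}\t{inferred.beta_couplings[i, j]:.10g}\n"
            )
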