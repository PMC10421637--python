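"""Sampling from the Boltzmann distribution of Ising and Potts models.

Three routes with one contract (exactness against enumeration):

* :func:`exact_distribution` — brute-force enumeration, the test oracle;
* :func:`sample_ising_exact` — monotone coupling from the past (Propp–Wilson),
  provably exact for ferromagnetic Ising models;
* :func:`sample_gibbs` — random-scan heat bath with a global relabeling move
  after each retained configuration, the workhorse for Potts models and for
  large systems in the ordered phase where coupling from the past is slow.

Ising spins are +-1; Potts states are reported as 1..q in :class:`SampleSet`
configurations (0..q-1 internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .graph_ensemble import CouplingMatrix

__all__ = [
    "SpinModel",
    "SampleSet",
    "energy",
    "exact_distribution",
    "ExactDistribution",
    "sample_ising_exact",
    "sample_gibbs",
    "CoalescenceError",
]

GIBBS_BURN_IN = 1_000  # sweeps
GIBBS_THINNING = 10  # sweeps
CFTP_EPOCH_CAP = 2**20  # sweeps


class CoalescenceError(RuntimeError):
    """Coupling from the past failed to coalesce within the epoch cap."""


@dataclass(frozen=True)
class SpinModel:
    """An Ising (q=2, spins +-1) or Potts (q>2, Kronecker-delta) model."""

    couplings: CouplingMatrix
    temperature: float
    num_states: int = 2
    fields: np.ndarray | None = None

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be strictly positive")
        if int(self.num_states) != self.num_states or self.num_states < 2:
            raise ValueError("num_states must be an integer >= 2")
        h = self.fields
        if h is None:
            h = np.zeros(self.couplings.n)
        h = np.asarray(h, dtype=np.float64)
        if h.shape != (self.couplings.n,):
            raise ValueError("fields must have one entry per vertex")
        if self.num_states > 2 and np.any(h != 0):
            raise ValueError("nonzero fields are only supported for Ising models")
        object.__setattr__(self, "fields", h)

    @property
    def n(self) -> int:
        return self.couplings.n

    @property
    def beta(self) -> float:
        return 1.0 / self.temperature

    @property
    def is_ising(self) -> bool:
        return self.num_states == 2


@dataclass
class SampleSet:
    """K spin configurations plus full sampling provenance."""

    configurations: np.ndarray  # (K, n); Ising +-1, Potts 1..q
    temperature: float
    num_states: int
    model_description: dict = field(default_factory=dict)

    def __post_init__(self):
        self.configurations = np.asarray(self.configurations, dtype=np.int8)
        if self.configurations.ndim != 2 or self.configurations.shape[0] < 1:
            raise ValueError("configurations must be a (K, n) matrix with K >= 1")
        vals = np.unique(self.configurations)
        if self.num_states == 2:
            if not np.isin(vals, (-1, 1)).all():
                raise ValueError("Ising configurations must take values -1/+1")
        else:
            if vals.min() < 1 or vals.max() > self.num_states:
                raise ValueError(f"Potts states must lie in 1..{self.num_states}")

    @property
    def K(self) -> int:
        return self.configurations.shape[0]

    @property
    def n(self) -> int:
        return self.configurations.shape[1]

    def to_tsv(self, path) -> None:
        desc = self.model_description
        with open(path, "w") as fh:
            fh.write(
                f"# n={self.n} q={self.num_states} T={self.temperature!r} K={self.K}\n"
            )
            for key in ("sampler", "seed", "graph_checksum", "burn_in", "thinning"):
                if key in desc:
                    fh.write(f"# {key}={desc[key]}\n")
            np.savetxt(fh, self.configurations, fmt="%d", delimiter="\t")

    @classmethod
    def from_tsv(cls, path) -> "SampleSet":
        meta: dict = {}
        with open(path) as fh:
            lines = fh.readlines()
        rows = []
        for line in lines:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.lstrip("#").split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                continue
            rows.append([int(x) for x in line.split()])
        return cls(
            configurations=np.array(rows, dtype=np.int8),
            temperature=float(meta.get("T", "nan")),
            num_states=int(meta.get("q", 2)),
            model_description={
                k: v for k, v in meta.items() if k not in ("n", "q", "T", "K")
            },
        )


def _validate_config(model: SpinModel, configuration: np.ndarray) -> np.ndarray:
    config = np.asarray(configuration)
    if config.shape != (model.n,):
        raise ValueError(f"configuration must have length {model.n}")
    if model.is_ising:
        if not np.isin(config, (-1, 1)).all():
            raise ValueError("Ising spins must be -1 or +1")
    else:
        if not np.isin(config, np.arange(1, model.num_states + 1)).all():
            raise ValueError(f"Potts states must lie in 1..{model.num_states}")
    return config


def energy(model: SpinModel, configuration: np.ndarray) -> float:
    """Hamiltonian value of one configuration.

    Ising: ``-sum_{i<j} J_ij s_i s_j - sum_i h_i s_i``. Potts: Kronecker-delta
    interactions ``-sum_{i<j} J_ij delta(s_i, s_j)`` (zero field).
    """
    config = _validate_config(model, configuration)
    J = model.couplings.entries
    if model.is_ising:
        s = config.astype(np.float64)
        return float(-0.5 * s @ J @ s - model.fields @ s)
    same = config[:, None] == config[None, :]
    return float(-0.5 * np.sum(J * same))


@dataclass
class ExactDistribution:
    """Enumerated Boltzmann distribution over all q^n configurations."""

    configurations: np.ndarray  # (M, n), Ising +-1 / Potts 1..q
    probabilities: np.ndarray  # (M,)

    def mean_spins(self) -> np.ndarray:
        return self.probabilities @ self.configurations

    def second_moments(self) -> np.ndarray:
        """Matrix of <s_i s_j> (Ising) with ones on the diagonal."""
        X = self.configurations.astype(np.float64)
        return (X * self.probabilities[:, None]).T @ X

    def coincidence_probabilities(self) -> np.ndarray:
        """Matrix of <delta(s_i, s_j)> (any q)."""
        M, n = self.configurations.shape
        out = np.zeros((n, n))
        for i in range(n):
            same = self.configurations == self.configurations[:, [i]]
            out[i] = self.probabilities @ same
        return out

    def connected_correlations(self) -> np.ndarray:
        mom = self.second_moments()
        m = self.mean_spins().astype(np.float64)
        return mom - np.outer(m, m)


def exact_distribution(model: SpinModel, max_states: int = 2**20) -> ExactDistribution:
    """Enumerate the Boltzmann distribution; refuses beyond ``max_states``.

    This is the oracle used by the test suite, not a production sampler.
    """
    n, q = model.n, model.num_states
    if q**n > max_states:
        raise ValueError(
            f"state space q^n = {q}^{n} exceeds the enumeration cap {max_states}"
        )
    grids = np.indices((q,) * n).reshape(n, -1).T  # (q^n, n) of 0..q-1
    if model.is_ising:
        configs = (2 * grids - 1).astype(np.int8)
    else:
        configs = (grids + 1).astype(np.int8)
    J = model.couplings.entries.astype(np.float64)
    if model.is_ising:
        X = configs.astype(np.float64)
        energies = -0.5 * np.einsum("ki,ij,kj->k", X, J, X) - X @ model.fields
    else:
        energies = np.zeros(configs.shape[0])
        iu, ju = np.triu_indices(n, k=1)
        for i, j in zip(iu, ju):
            if J[i, j]:
                energies -= J[i, j] * (configs[:, i] == configs[:, j])
    logw = -model.beta * energies
    logw -= logw.max()
    w = np.exp(logw)
    return ExactDistribution(configs, w / w.sum())


def sample_ising_exact(
    model: SpinModel,
    K: int,
    seed: int,
    epoch_cap: int = CFTP_EPOCH_CAP,
) -> SampleSet:
    """K exact independent draws by monotone coupling from the past.

    Bounding chains start all-up and all-down; shared heat-bath randomness
    keeps them ordered (ferromagnetic monotonicity), and coalescence at time
    zero certifies an exact draw from the stationary distribution. Epochs
    double (1, 2, 4, ... sweeps into the past) and randomness is reused across
    restarts, as exactness requires.
    """
    if not model.is_ising:
        raise ValueError("coupling from the past requires an Ising model (q=2)")
    if np.any(model.couplings.entries < 0):
        raise ValueError("negative couplings break monotone coupling")
    if K < 1:
        raise ValueError("K must be >= 1")
    n = model.n
    J = model.couplings.entries.astype(np.float64)
    max_epoch = max(0, int(np.ceil(np.log2(epoch_cap))))
    out, sandwich_ok, failed_at = _kernels.cftp_ising_batch(
        J, model.fields, model.beta, K, seed, max_epoch
    )
    if failed_at >= 0:
        raise CoalescenceError(
            f"no coalescence within {2**max_epoch} sweeps for sample "
            f"{failed_at} (n={n}, T={model.temperature}); the chain may be in "
            "the ordered phase where monotone coupling is impractical"
        )
    if not sandwich_ok:
        raise AssertionError("monotone sandwich violated; sampler bug")
    return SampleSet(
        configurations=out,
        temperature=model.temperature,
        num_states=2,
        model_description={
            "sampler": "cftp",
            "seed": seed,
            "graph_checksum": model.couplings.checksum(),
        },
    )


def sample_gibbs(
    model: SpinModel,
    K: int,
    seed: int,
    burn_in: int = GIBBS_BURN_IN,
    thinning: int = GIBBS_THINNING,
) -> SampleSet:
    """Heat-bath Gibbs sampling with a symmetry-restoring relabeling move.

    After every retained configuration the chain undergoes a uniformly random
    global relabeling (Ising: +-1 flip; Potts: label permutation), which
    leaves the zero-field Boltzmann distribution invariant while mixing
    between symmetry-broken modes at low temperature. The move is suppressed
    automatically when an Ising model carries nonzero fields.
    """
    if K < 1 or burn_in < 1 or thinning < 1:
        raise ValueError("K, burn_in and thinning must be positive")
    J = model.couplings.entries.astype(np.float64)
    beta = model.beta
    if model.is_ising:
        relabel = bool(np.all(model.fields == 0))
        configs = _kernels.gibbs_ising(
            J, model.fields, beta, burn_in, K, thinning, seed, relabel
        )
    else:
        configs = _kernels.gibbs_potts(
            J, model.num_states, beta, burn_in, K, thinning, seed, True
        )
        configs = configs + 1  # report states as 1..q
    return SampleSet(
        configurations=configs,
        temperature=model.temperature,
        num_states=model.num_states,
        model_description={
            "sampler": "gibbs",
            "seed": seed,
            "burn_in": burn_in,
            "thinning": thinning,
            "graph_checksum": model.couplings.checksum(),
        },
    )
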