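"""Tiny exactly-solvable fixtures shared across the test suite.

Every stored quantity is recomputable from the enumeration oracle at load
time; fixtures are generated programmatically, never shipped as data files.
State spaces are capped at 2**20 enumerated configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_ensemble import CouplingMatrix
from .spin_sampler import SpinModel, exact_distribution

__all__ = ["Fixture", "two_spin_fixture", "chain_fixture", "planted_motif_graph"]


@dataclass
class Fixture:
    name: str
    model: SpinModel
    exact_quantities: dict = field(default_factory=dict)

    def verify(self, atol: float = 1e-10) -> None:
        """Re-derive every stored exact quantity from the enumeration oracle."""
        dist = exact_distribution(self.model)
        eq = self.exact_quantities
        if "second_moments" in eq:
            np.testing.assert_allclose(dist.second_moments(), eq["second_moments"], atol=atol)
        if "connected_correlations" in eq:
            np.testing.assert_allclose(
                dist.connected_correlations(), eq["connected_correlations"], atol=atol
            )
        if "means" in eq:
            np.testing.assert_allclose(dist.mean_spins(), eq["means"], atol=atol)


def _chain_couplings(n: int) -> CouplingMatrix:
    entries = np.zeros((n, n), dtype=np.int8)
    for i in range(n - 1):
        entries[i, i + 1] = entries[i + 1, i] = 1
    return CouplingMatrix(entries)


def two_spin_fixture(beta_J: float) -> Fixture:
    """Two Ising spins with coupling J at beta*J = ``beta_J``.

    Exact pair correlation tanh(beta J); exact naive-inversion value
    t / (1 - t^2) with t = tanh(beta J).
    """
    J = _chain_couplings(2)
    model = SpinModel(couplings=J, temperature=1.0 / beta_J if beta_J > 0 else 1.0)
    if beta_J == 0:
        # realize beta*J = 0 with an edgeless graph at T = 1
        model = SpinModel(couplings=CouplingMatrix(np.zeros((2, 2), dtype=np.int8)), temperature=1.0)
    t = np.tanh(beta_J)
    second = np.array([[1.0, t], [t, 1.0]])
    return Fixture(
        name=f"two_spin(bJ={beta_J})",
        model=model,
        exact_quantities={
            "means": np.zeros(2),
            "second_moments": second,
            "connected_correlations": second,
            "pair_correlation": t,
            "inversion_beta_J": t / (1.0 - t**2) if abs(t) < 1 else np.inf,
        },
    )


def chain_fixture(n: int, beta: float) -> Fixture:
    """Open Ising chain: transfer-matrix correlations (tanh beta)^{|i-j|}.

    Demonstrates the direct/indirect distinction: raw correlations decay
    geometrically with graph distance while the true couplings sit only on
    adjacent pairs.
    """
    if n > 12:
        raise ValueError("chain fixtures are capped at n = 12 for enumeration")
    J = _chain_couplings(n)
    model = SpinModel(couplings=J, temperature=1.0 / beta if beta > 0 else 1.0)
    if beta == 0:
        model = SpinModel(couplings=J, temperature=1e12)
    t = np.tanh(beta)
    idx = np.arange(n)
    second = t ** np.abs(idx[:, None] - idx[None, :]).astype(np.float64)
    np.fill_diagonal(second, 1.0)
    return Fixture(
        name=f"chain(n={n}, beta={beta})",
        model=model,
        exact_quantities={
            "means": np.zeros(n),
            "second_moments": second,
            "connected_correlations": second,
        },
    )


def planted_motif_graph(common_neighbor_counts: list[int]) -> tuple[CouplingMatrix, list[tuple]]:
    """Graph with designated noninteracting pairs of prescribed multiplicity.

    For each m in ``common_neighbor_counts`` a pair of anchor vertices is
    joined through m independent common neighbors (and no direct edge), so
    the pair has graph distance 2 and exactly m shortest paths. Returns the
    coupling matrix and the list of anchor pairs, one per motif. An empty
    list yields an empty graph on two vertices.
    """
    if not common_neighbor_counts:
        return CouplingMatrix(np.zeros((2, 2), dtype=np.int8)), []
    if any(m < 1 for m in common_neighbor_counts):
        raise ValueError("each motif needs at least one common neighbor")
    n = sum(2 + m for m in common_neighbor_counts)
    entries = np.zeros((n, n), dtype=np.int8)
    anchors = []
    offset = 0
    for m in common_neighbor_counts:
        a, b = offset, offset + 1
        for k in range(m):
            mid = offset + 2 + k
            entries[a, mid] = entries[mid, a] = 1
            entries[b, mid] = entries[mid, b] = 1
        anchors.append((a, b))
        offset += 2 + m
    return CouplingMatrix(entries), anchors
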