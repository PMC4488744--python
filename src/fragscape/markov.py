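"""Discrete-time homogeneous Markov chains over structural classes.

The landscape is viewed as a large set of cells whose state is the occupying
class; the state space is fixed to the seven foreground structural classes
plus ``non_farmland`` (the background), in a fixed order for stable
serialization.  From two co-registered class maps the per-cell transition
counts give a row-stochastic matrix P, analyzed through

* the stationary distribution pi (left eigenvector of P for eigenvalue 1),
* the convergence rate rho = 1 / |lambda_2| (lambda_2 the eigenvalue of
  second-largest modulus): larger rho means faster approach to pi,
* the normalized entropy H(P) = -sum_i pi_i sum_j P_ij ln P_ij / ln s in
  [0, 1] (s = number of states with nonzero stationary mass): 0 for a
  deterministic transition structure, 1 for maximal randomness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .landscape import ALL_LABELS
from .mspa import MSPAClassMap

#: Fixed state order: the seven structural classes then the background state.
STATES: tuple[str, ...] = (
    "core",
    "perforation",
    "edge",
    "islet",
    "bridge",
    "loop",
    "branch",
    "non_farmland",
)

_EIG_TOL = 1e-10


@dataclass
class TransitionModel:
    """Transition counts and row-stochastic probabilities between two dates."""

    states: tuple[str, ...]
    counts: np.ndarray  # s x s integer cell counts
    probabilities: np.ndarray  # s x s row-stochastic
    n_pixels: int

    def __post_init__(self) -> None:
        s = len(self.states)
        if self.counts.shape != (s, s) or self.probabilities.shape != (s, s):
            raise ValueError("matrix shapes must match the state list")
        rows = self.probabilities.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError("probability rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probabilities, index=self.states, columns=self.states)


def _labels_to_state_indices(class_map: MSPAClassMap | np.ndarray) -> np.ndarray:
    """Map a class map (or default-code grid) onto indices into STATES."""
    if isinstance(class_map, MSPAClassMap):
        codes = class_map.labels
    else:
        codes = np.asarray(class_map)
        if codes.dtype.kind not in "iu":
            raise ValueError("expected an integer label-code grid")
        if codes.min() < 0 or codes.max() >= len(ALL_LABELS):
            raise ValueError("unknown state code in grid (expected 0..7)")
    lut = np.empty(len(ALL_LABELS), dtype=np.int64)
    for i, label in enumerate(ALL_LABELS):
        state = "non_farmland" if label == "background" else label
        lut[i] = STATES.index(state)
    return lut[codes]


def estimate_transitions(
    map_t1: MSPAClassMap | np.ndarray, map_t2: MSPAClassMap | np.ndarray
) -> TransitionModel:
    """Tally per-cell state transitions between two co-registered class maps.

    Rows with zero counts (state absent at t1) are set to the identity row
    (absorbing) with a warning, keeping P stochastic without inventing flow.
    """
    a = _labels_to_state_indices(map_t1)
    b = _labels_to_state_indices(map_t2)
    if a.shape != b.shape:
        raise ValueError(f"grid shapes differ: {a.shape} vs {b.shape}")
    s = len(STATES)
    counts = np.bincount(a.ravel() * s + b.ravel(), minlength=s * s).reshape(s, s)
    return model_from_counts(counts)


def model_from_counts(counts: np.ndarray, states: tuple[str, ...] = STATES) -> TransitionModel:
    counts = np.asarray(counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("transition counts must be non-negative")
    probabilities = np.zeros(counts.shape, dtype=float)
    row_sums = counts.sum(axis=1)
    empty = row_sums == 0
    if empty.any():
        warnings.warn(
            f"states absent at t1 treated as absorbing: "
            f"{[states[i] for i in np.flatnonzero(empty)]}",
            stacklevel=2,
        )
    for i in range(counts.shape[0]):
        if row_sums[i]:
            probabilities[i] = counts[i] / row_sums[i]
        else:
            probabilities[i, i] = 1.0
    return TransitionModel(
        states=tuple(states),
        counts=counts,
        probabilities=probabilities,
        n_pixels=int(counts.sum()),
    )


def model_from_probabilities(
    P: np.ndarray, states: tuple[str, ...] | None = None
) -> TransitionModel:
    """Wrap a pre-computed row-stochastic matrix (e.g. read from CSV)."""
    P = np.asarray(P, dtype=float)
    if states is None:
        states = tuple(f"state_{i}" for i in range(P.shape[0])) if P.shape[0] != len(
            STATES
        ) else STATES
    return TransitionModel(
        states=tuple(states), counts=np.zeros(P.shape, dtype=np.int64), probabilities=P, n_pixels=0
    )


def restrict_to_observed(model: TransitionModel) -> TransitionModel:
    """Sub-chain over the states actually observed at the first date.

    States absent at t1 carry synthetic identity rows (see
    :func:`model_from_counts`); each such row contributes an exact eigenvalue
    of 1 and collapses the convergence rate to its degenerate value. Dropping
    them (and the flow into them, which is necessarily zero) gives the
    spectral diagnostics of the chain that was actually sampled. Requires
    count data; raises on probability-only models.
    """
    if model.counts.sum() == 0:
        raise ValueError("restriction requires transition counts")
    observed = np.flatnonzero(model.counts.sum(axis=1) > 0)
    if observed.size == len(model.states):
        return model
    inflow_to_absent = np.delete(model.counts, observed, axis=1)[observed]
    if inflow_to_absent.sum() > 0:
        raise ValueError("cells flow into a state absent at t1; cannot restrict")
    counts = model.counts[np.ix_(observed, observed)]
    return model_from_counts(counts, states=tuple(model.states[i] for i in observed))


def stationary_distribution(model: TransitionModel) -> np.ndarray:
    """Left eigenvector of P for the dominant eigenvalue, normalized to sum 1.

    For reducible chains (eigenvalue 1 with multiplicity > 1) one valid
    stationary vector is returned with a reducibility warning.
    """
    P = model.probabilities
    values, vectors = linalg.eig(P, left=True, right=False)
    close_to_one = np.isclose(values, 1.0, atol=1e-8)
    if close_to_one.sum() > 1:
        warnings.warn("chain is reducible; stationary distribution is not unique", stacklevel=2)
    idx = int(np.argmin(np.abs(values - 1.0)))
    pi = np.real(vectors[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def subdominant_modulus(model: TransitionModel) -> float:
    """|lambda_2|: modulus of the eigenvalue of second-largest modulus
    (multiplicities respected)."""
    values = linalg.eigvals(model.probabilities)
    order = np.argsort(-np.abs(values))
    values = values[order]
    # drop exactly one dominant eigenvalue (the one closest to 1)
    drop = int(np.argmin(np.abs(values - 1.0)))
    remaining = np.delete(values, drop)
    if remaining.size == 0:
        return 0.0
    return float(np.max(np.abs(remaining)))


def convergence_rate(model: TransitionModel) -> float:
    """rho = 1 / |lambda_2|; +inf when |lambda_2| = 0 (one-step convergence),
    1 with a warning when |lambda_2| = 1 (periodic or reducible chain)."""
    lam2 = subdominant_modulus(model)
    if lam2 < _EIG_TOL:
        return float("inf")
    if lam2 >= 1.0 - _EIG_TOL:
        warnings.warn(
            "subdominant eigenvalue has modulus 1 (periodic or reducible chain); rho = 1",
            stacklevel=2,
        )
        return 1.0
    return 1.0 / lam2


def normalized_entropy(
    model: TransitionModel,
    pi: np.ndarray | None = None,
    weights: str = "stationary",
) -> float:
    """Normalized transition entropy of the chain, in [0, 1].

    With ``weights="stationary"`` (default) this is the entropy rate
    H(P) = -sum_i pi_i sum_j P_ij ln P_ij / ln(s), s the number of states
    carrying stationary mass (0 ln 0 = 0).  With ``weights="uniform"`` rows
    are averaged equally and s is the full state count — useful when an
    absorbing state would otherwise swallow the stationary mass.
    """
    P = model.probabilities
    terms = np.where(P > 0, P * np.log(np.where(P > 0, P, 1.0)), 0.0)
    row_h = -terms.sum(axis=1)
    if weights == "uniform":
        s_eff = len(model.states)
        return float(row_h.mean() / np.log(s_eff))
    if weights != "stationary":
        raise ValueError("weights must be 'stationary' or 'uniform'")
    if pi is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pi = stationary_distribution(model)
    s_eff = int((pi > 1e-12).sum())
    if s_eff < 2:
        return 0.0
    return float((pi * row_h).sum() / np.log(s_eff))


def chain_summary(model: TransitionModel) -> dict[str, float | np.ndarray]:
    """Stationary distribution, |lambda_2|, rho and H(P) in one report."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pi = stationary_distribution(model)
    return {
        "stationary": pi,
        "lambda2": subdominant_modulus(model),
        "rho": convergence_rate(model),
        "entropy": normalized_entropy(model, pi),
        "entropy_uniform": normalized_entropy(model, weights="uniform"),
    }


def conversion_sources(model: TransitionModel, sink: str) -> dict[str, float]:
    """Share of the flow into ``sink`` contributed by each other state,
    excluding sink->sink persistence.  Shares sum to 1."""
    if sink not in model.states:
        raise ValueError(f"unknown sink state {sink!r}")
    j = model.states.index(sink)
    inflow = model.counts[:, j].astype(float)
    inflow[j] = 0.0
    total = inflow.sum()
    if total == 0:
        raise ValueError(f"no transitions into {sink!r}")
    return {
        state: float(inflow[i] / total)
        for i, state in enumerate(model.states)
        if i != j
    }


def project(model: TransitionModel, initial: np.ndarray, steps: int) -> np.ndarray:
    """Iterate x, xP, xP^2, ... for ``steps`` steps; returns an array of
    shape (steps + 1, s)."""
    if steps < 0:
        raise ValueError("steps must be >= 0")
    x = np.asarray(initial, dtype=float)
    if x.shape != (len(model.states),):
        raise ValueError("initial distribution has wrong length")
    if (x < 0).any() or not np.isclose(x.sum(), 1.0):
        raise ValueError("initial must be a probability distribution")
    out = np.empty((steps + 1, x.size))
    out[0] = x
    for k in range(1, steps + 1):
        out[k] = out[k - 1] @ model.probabilities
    return out


def write_matrix_csv(model: TransitionModel, path) -> None:
    model.to_frame().to_csv(path, index_label="state")


def read_matrix_csv(path) -> TransitionModel:
    df = pd.read_csv(path, index_col=0)
    return model_from_probabilities(df.to_numpy(), states=tuple(df.columns))
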