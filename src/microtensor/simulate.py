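"""Synthetic longitudinal abundance tensors with planted microbial modules.

The generator mirrors the factorization model itself: subject activities are
standard Gaussian, each planted module loads on a random subset of taxa with
positive activities, and visit trajectories are Gaussian random walks, so the
noiseless tensor is exactly a rank-C CP product.  Case/control cohorts shift
the affected modules' subject activities between groups.  Clipping negative
cells to zero (the default) emulates the nonnegativity of real relative
abundances; it can be disabled to stay exactly in model space, and closure to
per-sample proportions is available as a further realism toggle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .tensor import LongitudinalTensor

__all__ = [
    "GroundTruth",
    "simulate_tensor",
    "simulate_case_control",
    "membership_recovery",
]


@dataclass
class GroundTruth:
    """Planted factors and bookkeeping of a simulated tensor."""

    H: np.ndarray  # (N, C) subject activities
    M: np.ndarray  # (C, L) taxon activities (0 for non-members)
    S: np.ndarray  # (C, L) binary membership
    T: np.ndarray  # (K, C) visit trajectories
    noise_sd: float
    seed: int | None
    labels: np.ndarray | None = None  # case/control labels if simulated
    affected_modules: tuple = ()
    effect_size: float = 0.0

    @property
    def member_sets(self) -> list[set]:
        return [set(np.flatnonzero(row)) for row in self.S]


def _plant_factors(N, L, K, C, module_size_range, temporal_precision, rng):
    lo, hi = module_size_range
    if not (1 <= lo <= hi) or lo > L:
        raise ValueError("infeasible module size range for L taxa")
    hi = min(hi, L)
    H = rng.standard_normal((N, C))
    S = np.zeros((C, L), dtype=int)
    M = np.zeros((C, L))
    for c in range(C):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(L, size=size, replace=False)
        S[c, members] = 1
        # positive activities: members of a module co-vary with the same sign
        M[c, members] = rng.uniform(0.5, 1.5, size=size)
    # random walk: unit-variance start, step sd set by the temporal precision;
    # columns normalized to unit RMS so every module carries the nominal SNR
    # (an unnormalized walk's magnitude is essentially random across modules)
    steps = rng.standard_normal((K, C)) / np.sqrt(temporal_precision)
    steps[0] = rng.standard_normal(C)
    T = np.cumsum(steps, axis=0)
    T /= np.sqrt((T**2).mean(axis=0, keepdims=True))
    return H, M, S, T


def simulate_tensor(
    N: int = 60,
    L: int = 80,
    K: int = 10,
    C: int = 6,
    module_size_range: tuple = (5, 15),
    temporal_precision: float = 4.0,
    noise_sd: float | None = None,
    snr: float = 10.0,
    seed=None,
    clip_negative: bool = True,
    close_to_proportions: bool = False,
    _H=None,
):
    """Simulate a (tensor, ground-truth) pair with planted modules.

    ``noise_sd`` overrides ``snr``; with ``snr`` the noise standard deviation
    is set to (realized signal SD) / sqrt(snr).  ``clip_negative=False``
    returns the raw Gaussian-model tensor (possibly negative), which for
    ``noise_sd=0`` equals the CP product of the planted factors exactly.
    """
    if min(N, L, K, C) < 1:
        raise ValueError("all dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    H, M, S, T = _plant_factors(N, L, K, C, module_size_range, temporal_precision, rng)
    if _H is not None:
        H = np.asarray(_H, dtype=float)
    signal = np.einsum("nc,cl,kc->nlk", H, M, T)
    if noise_sd is None:
        noise_sd = float(signal.std() / np.sqrt(snr)) if snr and snr > 0 else 0.0
    data = signal + noise_sd * rng.standard_normal(signal.shape) if noise_sd > 0 else signal.copy()
    if clip_negative:
        data = np.clip(data, 0.0, None)
    if close_to_proportions:
        totals = data.sum(axis=1, keepdims=True)
        np.divide(data, totals, out=data, where=totals > 0)
    tensor = LongitudinalTensor(data)
    truth = GroundTruth(H=H, M=M, S=S, T=T, noise_sd=float(noise_sd), seed=seed)
    return tensor, truth


def simulate_case_control(
    N_case: int = 30,
    N_control: int = 30,
    affected_modules: tuple = (0,),
    effect_size: float = 2.0,
    C: int = 6,
    seed=None,
    **kwargs,
):
    """Simulate a labeled cohort where affected modules shift between groups.

    Cases' subject activities in each affected module are raised by
    ``effect_size`` standard deviations (H has unit SD by construction).
    Returns (tensor, labels, truth) with labels 1 = case, 0 = control.
    """
    if any(c not in range(C) for c in affected_modules):
        raise ValueError("affected_modules must be module indices < C")
    rng = np.random.default_rng(seed)
    N = N_case + N_control
    labels = np.array([1] * N_case + [0] * N_control)
    perm = rng.permutation(N)
    labels = labels[perm]
    H = rng.standard_normal((N, C))
    for c in affected_modules:
        H[labels == 1, c] += effect_size
    tensor, truth = simulate_tensor(N=N, C=C, seed=int(rng.integers(2**31)), _H=H, **kwargs)
    truth.labels = labels
    truth.affected_modules = tuple(affected_modules)
    truth.effect_size = float(effect_size)
    truth.seed = seed
    return tensor, labels, truth


def simulate_validation_cohort(
    truth: GroundTruth,
    N_case: int = 20,
    N_control: int = 20,
    K: int | None = None,
    temporal_precision: float = 4.0,
    snr: float = 10.0,
    seed=None,
    clip_negative: bool = True,
):
    """Simulate an external cohort sharing a discovery cohort's modules.

    The taxon loadings M and visit trajectories T (the shared biology and
    dynamics) are carried over from ``truth``; the subjects (with the same
    affected-module shifts) and the noise are drawn fresh, emulating an
    independent cohort profiled for the same taxa.  With ``fresh_visits=True``
    new random-walk trajectories are drawn instead; note that fixed-loadings
    projection then recovers each module's activity only up to sign (the
    likelihood constrains the product H'T' alone).  Returns
    (tensor, labels, truth').
    """
    fresh_visits = K is not None and K != truth.T.shape[0]
    rng = np.random.default_rng(seed)
    C, L = truth.M.shape
    K = K if K is not None else truth.T.shape[0]
    N = N_case + N_control
    labels = np.array([1] * N_case + [0] * N_control)[rng.permutation(N)]
    H = rng.standard_normal((N, C))
    for c in truth.affected_modules:
        H[labels == 1, c] += truth.effect_size
    if fresh_visits:
        steps = rng.standard_normal((K, C)) / np.sqrt(temporal_precision)
        steps[0] = rng.standard_normal(C)
        T = np.cumsum(steps, axis=0)
        T /= np.sqrt((T**2).mean(axis=0, keepdims=True))
    else:
        T = truth.T
    signal = np.einsum("nc,cl,kc->nlk", H, truth.M, T)
    noise_sd = float(signal.std() / np.sqrt(snr)) if snr and snr > 0 else 0.0
    data = signal + noise_sd * rng.standard_normal(signal.shape)
    if clip_negative:
        data = np.clip(data, 0.0, None)
    tensor = LongitudinalTensor(data)
    new_truth = GroundTruth(
        H=H, M=truth.M, S=truth.S, T=T, noise_sd=noise_sd, seed=seed,
        labels=labels, affected_modules=truth.affected_modules,
        effect_size=truth.effect_size,
    )
    return tensor, labels, new_truth


def _member_sets(estimated, n_taxa=None) -> list[set]:
    if hasattr(estimated, "ndim"):  # binary matrix
        return [set(np.flatnonzero(row)) for row in np.asarray(estimated)]
    sets = []
    for m in estimated:
        if hasattr(m, "member_indices"):
            sets.append(set(int(i) for i in m.member_indices))
        else:
            sets.append(set(int(i) for i in m))
    return sets


def membership_recovery(true_S, estimated):
    """Score estimated module memberships against the planted truth.

    Hungarian matching between true and estimated modules maximizing the
    summed Jaccard index; returns (mean per-true-module F1, mean Jaccard,
    matching) where unmatched true modules score 0 and ``matching`` maps
    true-module index -> estimated-module index (or None).
    """
    true_sets = [set(np.flatnonzero(row)) for row in np.asarray(true_S)]
    est_sets = _member_sets(estimated)
    ct, ce = len(true_sets), len(est_sets)
    if ce == 0 or ct == 0:
        return 0.0, 0.0, {i: None for i in range(ct)}
    jac = np.zeros((ct, ce))
    f1 = np.zeros((ct, ce))
    for i, a in enumerate(true_sets):
        for j, b in enumerate(est_sets):
            inter = len(a & b)
            union = len(a | b)
            jac[i, j] = inter / union if union else 0.0
            f1[i, j] = 2 * inter / (len(a) + len(b)) if (a or b) else 0.0
    rows, cols = linear_sum_assignment(-jac)
    matching = {i: None for i in range(ct)}
    f1_scores = np.zeros(ct)
    jac_scores = np.zeros(ct)
    for i, j in zip(rows, cols):
        matching[int(i)] = int(j)
        f1_scores[i] = f1[i, j]
        jac_scores[i] = jac[i, j]
    return float(f1_scores.mean()), float(jac_scores.mean()), matching
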