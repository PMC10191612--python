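"""Variance partitioning and module-factor association testing.

PERMANOVA partitions the variation of a distance matrix (Bray-Curtis between
taxonomic profiles, Euclidean between subjects' module-activity vectors) by a
single grouping factor; R^2 = SS_between / SS_total is computed from the
Gower-centred distance matrix and the pseudo-F null distribution by free
permutation of labels.  Module-factor associations are per-module Wilcoxon
rank-sum (or Kruskal-Wallis for >2 groups) tests on the subject-activity
columns of H, with Benjamini-Hochberg control and a significance call at
FDR <= 0.25.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal, mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "bray_curtis",
    "euclidean_distances",
    "permanova",
    "module_variance_explained",
    "associate_modules",
    "bh_fdr",
    "collapse_sample_factors",
]


@dataclass
class AssociationResult:
    """Per-module association tests against one clinical factor."""

    factor: str
    module_ids: np.ndarray
    statistic: np.ndarray
    pvalue: np.ndarray
    fdr: np.ndarray
    significant: np.ndarray  # fdr <= cutoff
    fdr_cut: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "factor": self.factor,
                "module_id": self.module_ids,
                "statistic": self.statistic,
                "p": self.pvalue,
                "fdr": self.fdr,
                "flag": self.significant,
            }
        )


def bray_curtis(values: np.ndarray) -> np.ndarray:
    """Bray-Curtis dissimilarity between the rows (samples) of a matrix.

    ``values`` is (samples x features) nonnegative; returns the (samples x
    samples) dissimilarity matrix, with d = 0 for two all-zero samples by
    convention.
    """
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("Bray-Curtis requires nonnegative values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = squareform(pdist(x, metric="braycurtis"))
    return np.nan_to_num(d, nan=0.0)


def euclidean_distances(values: np.ndarray) -> np.ndarray:
    return squareform(pdist(np.asarray(values, dtype=float), metric="euclidean"))


def _pseudo_f_r2(gower, groups, n):
    """Pseudo-F and R^2 for one labeling, from the Gower-centred matrix."""
    ss_total = np.trace(gower)
    ss_within = 0.0
    n_groups = 0
    for gval in np.unique(groups):
        idx = np.flatnonzero(groups == gval)
        n_groups += 1
        ss_within += np.trace(gower[np.ix_(idx, idx)]) - np.sum(
            gower[np.ix_(idx, idx)]
        ) / len(idx)
    # ss_within per Anderson (2001): total SS minus between-group SS, computed
    # from within-group centred blocks
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if df_within <= 0:
        raise ValueError("PERMANOVA needs more samples than groups")
    f = (ss_between / df_between) / (ss_within / df_within)
    r2 = ss_between / ss_total
    return f, r2


def permanova(dist, grouping, n_perm: int = 999, seed=None, exhaustive: bool = False):
    """Single-factor PERMANOVA on a distance matrix.

    Returns (R2, pseudo-F, p); p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) for
    ``n_perm`` random label permutations.  With ``exhaustive=True`` every
    label permutation is enumerated (small n only) and the exact p-value
    #{F_perm >= F_obs} / n! is returned (the identity permutation counts).
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dist must be a square distance matrix")
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("dist must be symmetric with zero diagonal")
    groups = np.asarray(grouping)
    n = d.shape[0]
    if len(groups) != n:
        raise ValueError("grouping length must match distance matrix")
    if len(np.unique(groups)) < 2:
        raise ValueError("PERMANOVA requires at least two groups")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    # Gower centring of -d^2/2
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    gower = a - row - col + a.mean()
    f_obs, r2 = _pseudo_f_r2(gower, groups, n)
    if exhaustive:
        from itertools import permutations

        count = 0
        total = 0
        for perm in permutations(range(n)):
            f_perm, _ = _pseudo_f_r2(gower, groups[list(perm)], n)
            count += f_perm >= f_obs - 1e-12
            total += 1
        return float(r2), float(f_obs), float(count / total)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_perm, _ = _pseudo_f_r2(gower, groups[rng.permutation(n)], n)
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(r2), float(f_obs), float(p)


def collapse_sample_factors(metadata, factor: str) -> pd.Series:
    """Collapse a sample-level factor to one value per subject.

    Subject-level factors (constant within subject) pass through; sample-level
    binary status factors collapse to the overall state: "Yes" if any sample
    week of the subject records the factor, else "No".
    """
    t = metadata.table if hasattr(metadata, "table") else metadata
    per_subject = t.groupby("subject_id")[factor]
    nunique = per_subject.nunique(dropna=True)
    if (nunique <= 1).all():
        return per_subject.first()
    yes = {"yes", "y", "true", "1", "current", "positive"}

    def overall(vals):
        return "Yes" if any(str(v).strip().lower() in yes for v in vals.dropna()) else "No"

    return per_subject.apply(overall)


def module_variance_explained(
    H: np.ndarray,
    metadata,
    factors=None,
    n_perm: int = 999,
    seed=None,
    subjects=None,
) -> pd.DataFrame:
    """One PERMANOVA per clinical factor on Euclidean distances of H rows.

    ``H`` is (subjects x modules); ``metadata`` a SampleMetadata (or a
    DataFrame with subject_id + factor columns).  Factors with a single level
    are skipped with a warning.  Returns a table (factor, R2, pseudo_F, p).
    """
    t = metadata.table if hasattr(metadata, "table") else metadata
    if factors is None:
        factors = [
            c for c in t.columns if c not in ("subject_id", "sample_id", "visit_time")
        ]
    subj_order = list(subjects) if subjects is not None else list(
        pd.unique(t["subject_id"])
    )
    if len(subj_order) != H.shape[0]:
        raise ValueError("H rows must correspond to subjects in metadata")
    d = euclidean_distances(H)
    rows = []
    rng = np.random.default_rng(seed)
    for factor in factors:
        collapsed = collapse_sample_factors(t, factor).reindex(subj_order)
        labels = collapsed.astype(str).to_numpy()
        if len(np.unique(labels)) < 2:
            warnings.warn(f"factor {factor!r} has one level; skipped", UserWarning)
            continue
        r2, f, p = permanova(d, labels, n_perm=n_perm, seed=int(rng.integers(2**31)))
        rows.append({"factor": factor, "R2": r2, "pseudo_F": f, "p": p})
    return pd.DataFrame(rows, columns=["factor", "R2", "pseudo_F", "p"])


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def associate_modules(
    H: np.ndarray,
    factor_labels,
    test: str = "wilcoxon",
    fdr_cut: float = 0.25,
    module_ids=None,
    factor_name: str = "factor",
) -> AssociationResult:
    """Test each module's subject activities for differences between groups.

    Two-sided Wilcoxon rank-sum (Mann-Whitney U; exact for small groups
    without ties, normal approximation with tie correction otherwise) for two
    groups, Kruskal-Wallis for more.  P-values are BH-adjusted across modules
    and flagged at FDR <= ``fdr_cut``.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    labels = np.asarray(factor_labels)
    if len(labels) != H.shape[0]:
        raise ValueError("labels length must match H rows")
    uniq = np.unique(labels)
    counts = {u: int(np.sum(labels == u)) for u in uniq}
    if any(c < 2 for c in counts.values()):
        raise ValueError(f"every group needs >= 2 subjects, got {counts}")
    if test == "wilcoxon":
        if len(uniq) != 2:
            raise ValueError("wilcoxon requires exactly two groups")
        ga = H[labels == uniq[0]]
        gb = H[labels == uniq[1]]
        n_small = min(len(ga), len(gb))
        method = "exact" if n_small <= 25 else "asymptotic"
        stats, ps = [], []
        for j in range(H.shape[1]):
            a, b = ga[:, j], gb[:, j]
            meth = method
            if meth == "exact" and len(np.unique(np.concatenate([a, b]))) < len(a) + len(b):
                meth = "asymptotic"  # ties: exact distribution unavailable
            res = mannwhitneyu(a, b, alternative="two-sided", method=meth)
            stats.append(res.statistic)
            ps.append(res.pvalue)
    elif test == "kruskal":
        if len(uniq) < 2:
            raise ValueError("kruskal requires at least two groups")
        stats, ps = [], []
        for j in range(H.shape[1]):
            res = kruskal(*[H[labels == u, j] for u in uniq])
            stats.append(res.statistic)
            ps.append(res.pvalue)
    else:
        raise ValueError("test must be 'wilcoxon' or 'kruskal'")
    stats = np.asarray(stats)
    ps = np.asarray(ps)
    fdr = bh_fdr(ps)
    ids = np.asarray(module_ids if module_ids is not None else np.arange(H.shape[1]))
    return AssociationResult(
        factor=factor_name,
        module_ids=ids,
        statistic=stats,
        pvalue=ps,
        fdr=fdr,
        significant=fdr <= fdr_cut,
        fdr_cut=fdr_cut,
    )
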