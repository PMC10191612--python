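"""Intramodule co-occurrence, functional similarity, and random-group nulls.

Co-occurrence between two taxa is measured by the Dice index on presence
(abundance > 0) and by the absolute Spearman correlation of their abundance
series, either per subject (statistic on each subject's visit series,
averaged over subjects) or across all samples (flattened subject x visit
vectors).  Module cohesion is the mean pairwise statistic over member pairs,
compared against size-matched random groups built from taxa pairs that do not
co-occur in any module.  Functional similarity uses taxon-stratified pathway
contributions (HUMAnN-style): cosine similarity of two members' pathway
vectors within a sample, averaged over samples and member pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .tensor import as_tensor

__all__ = [
    "PairwiseMatrix",
    "dice_index",
    "pairwise_cooccurrence",
    "intramodule_score",
    "random_group_null",
    "functional_similarity",
    "top_pathways",
    "read_pathway_contributions",
]


@dataclass
class PairwiseMatrix:
    """Symmetric taxa x taxa matrix of a pairwise statistic (NaN = undefined)."""

    values: np.ndarray
    taxa: list
    statistic: str  # "dice" | "abs_spearman"
    mode: str  # "per_subject_mean" | "across_samples"


def dice_index(x, y) -> float:
    """Dice index on presence sets: 2|A & B| / (|A| + |B|); both empty -> 0."""
    a = np.asarray(x) > 0
    b = np.asarray(y) > 0
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.sum(a & b) / denom)


def _dice_matrix(presence: np.ndarray) -> np.ndarray:
    """Pairwise Dice over rows of a boolean (taxa x observations) matrix."""
    p = presence.astype(float)
    inter = p @ p.T
    sizes = p.sum(axis=1)
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 2.0 * inter / denom
    d[denom == 0] = 0.0
    return d


def _spearman_matrix(obs: np.ndarray) -> np.ndarray:
    """Pairwise |Spearman| over rows (taxa x observations); constant rows -> NaN.

    Spearman's rho is Pearson correlation of the ranks (ties averaged);
    computed directly so that constant rows degrade to NaN entries instead of
    collapsing the whole matrix (a scipy.stats.spearmanr quirk).
    """
    L = obs.shape[0]
    if obs.shape[1] < 2:
        return np.full((L, L), np.nan)
    ranks = rankdata(obs, axis=1)
    constant = ranks.std(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    out = np.abs(np.atleast_2d(rho))
    out[constant, :] = np.nan
    out[:, constant] = np.nan
    np.fill_diagonal(out, np.where(constant, np.nan, 1.0))
    return out


def pairwise_cooccurrence(
    tensor, statistic: str = "dice", mode: str = "per_subject_mean"
) -> PairwiseMatrix:
    """All-pairs co-occurrence matrix of the taxa in a longitudinal tensor.

    ``per_subject_mean`` computes the statistic on each subject's visit series
    (observed visits only) and averages over subjects; pairs undefined for a
    subject (constant series under Spearman) are dropped from that average.
    ``across_samples`` computes it once on the flattened observed samples.
    """
    t = as_tensor(tensor)
    if statistic not in ("dice", "abs_spearman"):
        raise ValueError("statistic must be 'dice' or 'abs_spearman'")
    if mode not in ("per_subject_mean", "across_samples"):
        raise ValueError("mode must be 'per_subject_mean' or 'across_samples'")
    N, L, K = t.shape
    if mode == "across_samples":
        obs_cols = t.mask.any(axis=1)  # (N, K) sample observed?
        flat = t.data.transpose(1, 0, 2).reshape(L, N * K)
        keep = obs_cols.reshape(N * K)
        obs = flat[:, keep]
        vals = _dice_matrix(obs > 0) if statistic == "dice" else _spearman_matrix(obs)
    else:
        acc = np.zeros((L, L))
        cnt = np.zeros((L, L))
        for n in range(N):
            visits = t.mask[n].any(axis=0)
            if visits.sum() < (2 if statistic == "abs_spearman" else 1):
                continue
            series = t.data[n][:, visits]
            m = (
                _dice_matrix(series > 0)
                if statistic == "dice"
                else _spearman_matrix(series)
            )
            ok = np.isfinite(m)
            acc[ok] += m[ok]
            cnt[ok] += 1
        with np.errstate(invalid="ignore"):
            vals = acc / cnt
        vals[cnt == 0] = np.nan
    return PairwiseMatrix(values=vals, taxa=list(t.taxa), statistic=statistic, mode=mode)


def _pair_values(pm: PairwiseMatrix, indices) -> np.ndarray:
    idx = np.asarray(sorted(indices))
    iu = np.triu_indices(len(idx), k=1)
    return pm.values[np.ix_(idx, idx)][iu]


def intramodule_score(modules, pm: PairwiseMatrix) -> pd.DataFrame:
    """Mean pairwise statistic over member pairs of each module.

    Single-member modules are skipped (no pairs).  Pairs undefined in the
    pairwise matrix are excluded from the average.
    """
    rows = []
    for m in modules:
        idx = m.member_indices if hasattr(m, "member_indices") else m
        if len(idx) < 2:
            continue
        vals = _pair_values(pm, idx)
        vals = vals[np.isfinite(vals)]
        rows.append(
            {
                "module_id": getattr(m, "index", None),
                "n_members": len(idx),
                "score": float(vals.mean()) if vals.size else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["module_id", "n_members", "score"])


def random_group_null(
    modules,
    pm: PairwiseMatrix,
    n_groups: int = 100,
    seed=None,
):
    """Size-matched random-group null for intramodule cohesion.

    A random group matched to a module of size m is a set of C(m, 2) taxa
    pairs drawn from the pairs that do not co-occur in any module; its score
    is the mean pairwise statistic, mirroring the intramodule score.  Group
    sizes are sampled from the empirical module-size distribution.  Returns
    (module_scores, null_scores, p) with p from a one-sided Wilcoxon rank-sum
    test (modules greater).
    """
    L = pm.values.shape[0]
    member_sets = [
        set(np.asarray(m.member_indices if hasattr(m, "member_indices") else m))
        for m in modules
    ]
    member_sets = [s for s in member_sets if len(s) >= 2]
    if not member_sets:
        raise ValueError("no modules with >= 2 members")
    eligible = np.ones((L, L), dtype=bool)
    for s in member_sets:
        idx = np.asarray(sorted(s))
        eligible[np.ix_(idx, idx)] = False
    pairs = np.argwhere(np.triu(eligible, k=1))
    if len(pairs) == 0:
        raise ValueError("no taxa pairs outside the modules to build random groups")
    pair_vals = pm.values[pairs[:, 0], pairs[:, 1]]
    sizes = np.asarray([len(s) for s in member_sets])
    rng = np.random.default_rng(seed)
    null_scores = []
    for _ in range(n_groups):
        m = int(rng.choice(sizes))
        n_pairs = min(m * (m - 1) // 2, len(pairs))
        take = rng.choice(len(pairs), size=n_pairs, replace=False)
        vals = pair_vals[take]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            null_scores.append(float(vals.mean()))
    null_scores = np.asarray(null_scores)
    if null_scores.size == 0:
        raise ValueError("could not form any random group")
    mod_scores = intramodule_score(modules, pm)["score"].dropna().to_numpy()
    p = float(
        mannwhitneyu(mod_scores, null_scores, alternative="greater").pvalue
    )
    return mod_scores, null_scores, p


# -- functional similarity ----------------------------------------------------

def read_pathway_contributions(path) -> pd.DataFrame:
    """Read a HUMAnN-style stratified pathway table (pathway|taxon rows).

    Returns a DataFrame indexed by a (pathway, taxon) MultiIndex with sample
    columns; unstratified (community-total) rows are dropped.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    keep = [i for i in df.index if "|" in str(i)]
    df = df.loc[keep]
    tuples = [tuple(str(i).rsplit("|", 1)) for i in df.index]
    df.index = pd.MultiIndex.from_tuples(tuples, names=["pathway", "taxon"])
    return df


def _taxon_profiles(contrib: pd.DataFrame) -> dict:
    """taxon -> (pathways x samples) contribution matrix, aligned on pathways."""
    pathways = contrib.index.get_level_values("pathway").unique()
    out = {}
    for taxon, grp in contrib.groupby(level="taxon"):
        mat = grp.droplevel("taxon").reindex(pathways).fillna(0.0)
        out[taxon] = mat.to_numpy(dtype=float)
    return out


def _cosine_over_samples(a: np.ndarray, b: np.ndarray) -> float:
    """Mean per-sample cosine similarity of two pathway-contribution matrices."""
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    ok = (na > 0) & (nb > 0)
    if not ok.any():
        return np.nan
    cos = (a[:, ok] * b[:, ok]).sum(axis=0) / (na[ok] * nb[ok])
    return float(cos.mean())


def functional_similarity(contrib: pd.DataFrame, modules, metric=None) -> pd.DataFrame:
    """Per-module mean pairwise functional similarity of member taxa.

    Similarity of a member pair is the cosine of their pathway-contribution
    vectors within each sample, averaged over samples where both contribute;
    the module score averages over member pairs.  Members absent from the
    contribution table are excluded with a warning.  ``metric`` may override
    the per-sample pair similarity with any f(matrix, matrix) -> float.
    """
    profiles = _taxon_profiles(contrib)
    pair_sim = metric if metric is not None else _cosine_over_samples
    rows = []
    for m in modules:
        members = list(m.members) if hasattr(m, "members") else list(m)
        present = [t for t in members if t in profiles]
        absent = [t for t in members if t not in profiles]
        if absent:
            warnings.warn(
                f"taxa absent from pathway table excluded: {absent}", UserWarning
            )
        sims = []
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                s = pair_sim(profiles[present[i]], profiles[present[j]])
                if np.isfinite(s):
                    sims.append(s)
        rows.append(
            {
                "module_id": getattr(m, "index", None),
                "n_members": len(present),
                "similarity": float(np.mean(sims)) if sims else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["module_id", "n_members", "similarity"])


def top_pathways(contrib: pd.DataFrame, module, top_n: int = 20) -> pd.Series:
    """Pathways ranked by total abundance contributed by module members.

    Sums each pathway's contributions from the member taxa over all samples
    and returns the ``top_n`` most abundant as a Series (pathway -> total).
    """
    members = set(module.members if hasattr(module, "members") else module)
    sub = contrib[contrib.index.get_level_values("taxon").isin(members)]
    totals = sub.groupby(level="pathway").sum().sum(axis=1).sort_values(ascending=False)
    return totals.head(top_n)
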