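"""Calling discrete microbial modules from posterior inclusion probabilities.

A fitted factorization yields a PIP matrix (modules x taxa) holding the
posterior probability that each taxon loads on each module.  A taxon is a
member of a module when its PIP strictly exceeds the threshold (default 0.5);
modules without members are inactive and dropped from downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Module", "compute_pip", "call_modules", "modules_to_frame"]


@dataclass
class Module:
    """One microbial module: member taxa plus their latent activities."""

    index: int
    members: list  # taxon labels with PIP > threshold
    member_indices: np.ndarray
    activities: np.ndarray  # posterior-mean loadings M[c, members]
    pips: np.ndarray
    subject_activities: np.ndarray  # H[:, c]
    visit_trajectory: np.ndarray  # T[:, c]

    @property
    def size(self) -> int:
        return len(self.members)


def compute_pip(fit) -> np.ndarray:
    """Posterior inclusion probabilities E_q[s] of a fitted model."""
    pip = np.asarray(fit.pip_ if hasattr(fit, "pip_") else fit, dtype=float)
    if pip.min() < 0 or pip.max() > 1:
        raise ValueError("PIP values must lie in [0, 1]")
    return pip


def call_modules(fit, threshold: float = 0.5, taxa=None) -> list[Module]:
    """Extract active modules (those with >= 1 member at PIP > threshold).

    ``fit`` is a fitted :class:`~microtensor.btf.BayesianTensorFactorization`
    (or any object exposing ``pip_``, ``taxon_factors_``, ``subject_factors_``,
    ``visit_factors_``).  Membership uses a strict inequality.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    pip = compute_pip(fit)
    taxa = list(taxa if taxa is not None else getattr(fit, "taxa_", range(pip.shape[1])))
    out = []
    for c in range(pip.shape[0]):
        idx = np.flatnonzero(pip[c] > threshold)
        if idx.size == 0:
            continue
        out.append(
            Module(
                index=c,
                members=[taxa[i] for i in idx],
                member_indices=idx,
                activities=np.asarray(fit.taxon_factors_[c, idx], dtype=float),
                pips=pip[c, idx],
                subject_activities=np.asarray(fit.subject_factors_[:, c], dtype=float),
                visit_trajectory=np.asarray(fit.visit_factors_[:, c], dtype=float),
            )
        )
    return out


def modules_to_frame(modules: list[Module]) -> pd.DataFrame:
    """Long-format export: one row per (module, member taxon)."""
    rows = [
        {
            "module_id": m.index,
            "taxon": t,
            "activity": float(a),
            "pip": float(p),
        }
        for m in modules
        for t, a, p in zip(m.members, m.activities, m.pips)
    ]
    return pd.DataFrame(rows, columns=["module_id", "taxon", "activity", "pip"])
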