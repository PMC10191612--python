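"""Longitudinal abundance tensor container.

A :class:`LongitudinalTensor` holds a third-order array of abundances indexed
``(subject, taxon, visit)`` together with an observation mask for incomplete
sampling designs.  Abundance tensors built from real profiles are nonnegative;
model-space tensors (e.g. simulated from the unconstrained Gaussian
factorization model) may carry negative entries, so nonnegativity is enforced
only when requested at the IO boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class LongitudinalTensor:
    """Third-order abundance tensor (subjects x taxa x visits) with a mask.

    Parameters
    ----------
    data : ndarray of shape (N, L, K)
        Abundance values. Entries at masked-out cells are ignored (kept as 0).
    mask : ndarray of bool, shape (N, L, K), optional
        True where an observation exists. Defaults to all-true (complete
        design). The mask is constant along the taxon axis for tensors built
        from samples, but arbitrary masks are accepted.
    subjects, taxa, visits : sequences of labels, optional
        Axis labels; default to integer ranges.
    """

    data: np.ndarray
    mask: np.ndarray | None = None
    subjects: list = field(default=None)  # type: ignore[assignment]
    taxa: list = field(default=None)  # type: ignore[assignment]
    visits: list = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-dimensional, got shape {self.data.shape}")
        if self.mask is None:
            self.mask = np.ones(self.data.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape must match data shape")
        n, l, k = self.data.shape
        if self.subjects is None:
            self.subjects = list(range(n))
        if self.taxa is None:
            self.taxa = list(range(l))
        if self.visits is None:
            self.visits = list(range(k))
        if (len(self.subjects), len(self.taxa), len(self.visits)) != (n, l, k):
            raise ValueError("label lengths inconsistent with data shape")
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("observed cells must be finite")

    # -- basic properties -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    @property
    def n_visits(self) -> int:
        return self.data.shape[2]

    @property
    def is_complete(self) -> bool:
        return bool(self.mask.all())

    def validate_nonnegative(self) -> "LongitudinalTensor":
        """Check the abundance invariant (observed cells >= 0)."""
        if np.any(self.data[self.mask] < 0):
            raise ValueError("abundance tensor has negative observed values")
        return self

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        """Write the tensor as an .npz array container plus a JSON label sidecar."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), data=self.data, mask=self.mask)
        sidecar = {
            "subjects": [str(s) for s in self.subjects],
            "taxa": [str(t) for t in self.taxa],
            "visits": [str(v) for v in self.visits],
        }
        path.with_suffix(".labels.json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path) -> "LongitudinalTensor":
        path = Path(path)
        arrs = np.load(path.with_suffix(".npz"))
        labels = json.loads(path.with_suffix(".labels.json").read_text())
        return cls(
            data=arrs["data"],
            mask=arrs["mask"],
            subjects=labels["subjects"],
            taxa=labels["taxa"],
            visits=labels["visits"],
        )


def as_tensor(x) -> LongitudinalTensor:
    """Coerce a raw 3-d array or LongitudinalTensor to LongitudinalTensor."""
    if isinstance(x, LongitudinalTensor):
        return x
    return LongitudinalTensor(np.asarray(x, dtype=float))
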