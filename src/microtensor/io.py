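"""Reading abundance profiles and metadata, cohort filters, tensor assembly.

Profiles are MetaPhlAn-style tab-separated tables: first column taxon
identifier (pipe-delimited clade string or plain name), remaining columns one
sample each, values in percent or proportion.  Metadata is a CSV/TSV with
required columns ``subject_id``, ``sample_id``, ``visit_time`` plus arbitrary
clinical factor columns.

The cohort filters mirror common longitudinal-microbiome preprocessing: drop
taxa seen in fewer than 10% of samples, drop subjects with fewer than 10
samples, and reduce each subject's series to 10 visits at roughly equal
sampling intervals so that a complete subjects x taxa x visits tensor can be
assembled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tensor import LongitudinalTensor

__all__ = [
    "AbundanceTable",
    "SampleMetadata",
    "read_profiles",
    "read_metadata",
    "filter_prevalence",
    "filter_subjects",
    "select_equal_interval_visits",
    "build_tensor",
]


class ProfileParseError(ValueError):
    """Raised when an abundance profile violates the format contract."""


@dataclass
class AbundanceTable:
    """Taxa x samples relative-abundance matrix.

    ``scale`` records the unit: ``"percent"`` (columns sum to ~100) or
    ``"proportion"`` (columns sum to <= 1).
    """

    taxa: list
    samples: list
    values: np.ndarray
    scale: str = "proportion"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.taxa), len(self.samples)):
            raise ValueError("values shape inconsistent with labels")
        if len(set(self.taxa)) != len(self.taxa):
            raise ProfileParseError("duplicate taxon identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise ProfileParseError("duplicate sample identifiers")
        if np.any(self.values < 0):
            raise ProfileParseError("negative abundance value")
        if self.scale not in ("proportion", "percent"):
            raise ValueError(f"unknown scale {self.scale!r}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.samples)

    def as_proportion(self) -> "AbundanceTable":
        """Return the table on the proportion ([0, 1]) scale."""
        if self.scale == "proportion":
            return self
        return AbundanceTable(
            list(self.taxa), list(self.samples), self.values / 100.0, "proportion"
        )

    def write(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "taxon"
        df.to_csv(path, sep="\t")


@dataclass
class SampleMetadata:
    """Per-sample metadata: subject assignment, visit time, factor columns."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("subject_id", "sample_id", "visit_time")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        t = self.table
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        # visit times strictly increasing within subject after sort
        for subj, grp in t.groupby("subject_id", sort=False):
            vt = grp.sort_values("visit_time")["visit_time"].to_numpy()
            if len(vt) > 1 and not np.all(np.diff(vt) > 0):
                raise ValueError(f"visit times not strictly increasing for subject {subj}")
        self.table = t.reset_index(drop=True)

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.table["subject_id"]))

    @property
    def samples(self) -> list:
        return list(self.table["sample_id"])

    def factor_columns(self) -> list:
        return [c for c in self.table.columns if c not in self.REQUIRED]

    def samples_of(self, subject) -> pd.DataFrame:
        grp = self.table[self.table["subject_id"] == subject]
        return grp.sort_values("visit_time")


def read_profiles(
    path,
    scale: str = "infer",
    rank: str | None = None,
    exclude_viruses: bool = False,
) -> AbundanceTable:
    """Read a MetaPhlAn-style TSV profile into an :class:`AbundanceTable`.

    Parameters
    ----------
    path : file path
    scale : {"infer", "percent", "proportion"}
        With "infer", values above 1.5 anywhere mark the table as percent.
    rank : str, optional
        Taxonomic rank prefix to keep, e.g. ``"s__"`` keeps rows whose most
        specific clade is a species (pipe-delimited MetaPhlAn identifiers).
    exclude_viruses : bool
        Drop rows whose clade string contains ``k__Viruses``.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ProfileParseError(f"cannot parse profile table: {exc}") from exc
    if df.shape[1] == 0:
        raise ProfileParseError("profile has no sample columns")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ProfileParseError(f"non-numeric abundance cell: {exc}") from exc
    taxa = [str(t) for t in df.index]
    if rank is not None:
        keep = [i for i, t in enumerate(taxa) if _terminal_rank(t).startswith(rank)]
        taxa = [taxa[i] for i in keep]
        values = values[keep]
    if exclude_viruses:
        keep = [i for i, t in enumerate(taxa) if "k__Viruses" not in t]
        taxa = [taxa[i] for i in keep]
        values = values[keep]
    if scale == "infer":
        scale = "percent" if values.size and np.nanmax(values) > 1.5 else "proportion"
    return AbundanceTable(taxa, [str(s) for s in df.columns], values, scale)


def _terminal_rank(clade: str) -> str:
    return clade.split("|")[-1]


def read_metadata(path, sep: str | None = None) -> SampleMetadata:
    """Read the sample metadata table (CSV or TSV, sniffed by extension)."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return SampleMetadata(pd.read_csv(path, sep=sep))


def filter_prevalence(table: AbundanceTable, min_fraction: float = 0.10) -> AbundanceTable:
    """Drop taxa with nonzero abundance in fewer than ``min_fraction`` of samples."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    prevalence = (table.values > 0).mean(axis=1)
    keep = prevalence >= min_fraction
    if not keep.any():
        warnings.warn("prevalence filter removed every taxon", UserWarning)
    return AbundanceTable(
        [t for t, k in zip(table.taxa, keep) if k],
        list(table.samples),
        table.values[keep],
        table.scale,
    )


def filter_subjects(metadata: SampleMetadata, min_samples: int = 10) -> SampleMetadata:
    """Drop subjects with fewer than ``min_samples`` samples (and their samples)."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    counts = metadata.table.groupby("subject_id")["sample_id"].count()
    keep = set(counts[counts >= min_samples].index)
    kept = metadata.table[metadata.table["subject_id"].isin(keep)].reset_index(drop=True)
    return SampleMetadata(kept)


def select_equal_interval_visits(visit_times, k: int = 10) -> list[int]:
    """Pick ``k`` samples at roughly equal intervals from one subject's series.

    Always includes the first and the last sample; each remaining slot takes
    the unused sample nearest in time to its ideal equally spaced target
    (ties broken toward the earlier sample; an already-used nearest sample is
    skipped in favour of the next-nearest unused one).

    Returns indices into ``visit_times`` (which must be sorted ascending).
    """
    t = np.asarray(visit_times, dtype=float)
    m = len(t)
    if np.any(np.diff(t) <= 0):
        raise ValueError("visit_times must be strictly increasing")
    if m < k:
        raise ValueError(f"subject has {m} samples, fewer than k={k}")
    if k == 1:
        return [0]
    if m == k:
        return list(range(m))
    ideal = t[0] + np.arange(k) * (t[-1] - t[0]) / (k - 1)
    used = np.zeros(m, dtype=bool)
    chosen = {0: 0, k - 1: m - 1}
    used[0] = used[m - 1] = True
    for j in range(1, k - 1):
        dist = np.abs(t - ideal[j])
        dist[used] = np.inf
        # argmin returns the earliest index on ties
        pick = int(np.argmin(dist))
        chosen[j] = pick
        used[pick] = True
    return [chosen[j] for j in range(k)]


def build_tensor(
    table: AbundanceTable,
    metadata: SampleMetadata,
    complete: bool = True,
) -> LongitudinalTensor:
    """Assemble a (subjects x taxa x visits) tensor from table + metadata.

    Abundances are converted to the proportion scale.  Visits are aligned by
    within-subject sample order; for incomplete designs K is the maximum visit
    count and trailing cells of shorter series are masked out.
    """
    table = table.as_proportion()
    col_index = {s: j for j, s in enumerate(table.samples)}
    subjects = metadata.subjects
    per_subject = []
    for subj in subjects:
        samples = list(metadata.samples_of(subj)["sample_id"])
        missing = [s for s in samples if s not in col_index]
        if missing:
            raise KeyError(
                f"samples {missing} of subject {subj} absent from abundance table"
            )
        per_subject.append(samples)
    counts = [len(s) for s in per_subject]
    if complete and len(set(counts)) > 1:
        raise ValueError(
            "complete tensor requested but subjects have unequal visit counts: "
            f"{dict(zip(subjects, counts))}"
        )
    K = max(counts)
    N, L = len(subjects), len(table.taxa)
    data = np.zeros((N, L, K))
    mask = np.zeros((N, L, K), dtype=bool)
    for i, samples in enumerate(per_subject):
        for j, s in enumerate(samples):
            data[i, :, j] = table.values[:, col_index[s]]
            mask[i, :, j] = True
    return LongitudinalTensor(
        data, mask, subjects=list(subjects), taxa=list(table.taxa), visits=list(range(K))
    ).validate_nonnegative()
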