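"""OTU count tables: data model, TSV I/O, and preprocessing.

The preprocessing steps implemented here are the standard front end of a
cross-study body-site analysis: richness-based sample filtering,
per-sample relative-abundance normalization, presence/absence
binarization, and redundancy clustering of OTUs whose detection patterns
are nearly identical (normalized mutual information above a threshold),
which would otherwise be indistinguishable to local causal discovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "OtuTable",
    "SampleMeta",
    "RedundancyGrouping",
    "read_table",
    "write_table",
    "read_meta",
    "write_meta",
    "filter_low_richness",
    "to_relative_abundance",
    "binarize",
    "nmi",
    "nmi_matrix",
    "redundancy_groups",
    "reduce_to_representatives",
]


@dataclass
class OtuTable:
    """Integer count matrix of shape (n_otus, n_samples) with identifiers.

    The universal exchange object of the pipeline.  ``counts[i, j]`` is the
    number of reads of OTU ``otu_ids[i]`` in sample ``sample_ids[j]``.
    """

    counts: np.ndarray
    otu_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.otu_ids = list(self.otu_ids)
        self.sample_ids = list(self.sample_ids)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (OTUs x samples)")
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.otu_ids)} OTU ids and {len(self.sample_ids)} sample ids"
            )
        if self.counts.size and not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.mod(self.counts, 1) == 0):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        for name, ids in (("otu_id", self.otu_ids), ("sample_id", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {name}: {i!r}")
                seen.add(i)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def depths(self) -> np.ndarray:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def richness(self) -> np.ndarray:
        """Number of detected OTUs (count >= 1) per sample."""
        return (self.counts >= 1).sum(axis=0)

    def select_samples(self, sample_ids: list[str]) -> "OtuTable":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return OtuTable(self.counts[:, cols], self.otu_ids, list(sample_ids))

    def select_otus(self, otu_ids: list[str]) -> "OtuTable":
        idx = {o: i for i, o in enumerate(self.otu_ids)}
        rows = [idx[o] for o in otu_ids]
        return OtuTable(self.counts[rows, :], list(otu_ids), self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.otu_ids, name="otu_id"),
            columns=self.sample_ids,
        )


@dataclass
class SampleMeta:
    """Per-sample body-site and study labels.

    Stored as a DataFrame indexed by sample id with columns ``body_site``
    and ``study_id``; drives stratification, study weighting, and the
    construction of biased subsets.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"body_site", "study_id"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"SampleMeta missing columns: {sorted(missing)}")
        if self.frame.index.has_duplicates:
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise ValueError(f"duplicate sample_id in metadata: {dup!r}")

    @classmethod
    def from_arrays(cls, sample_ids, body_sites, study_ids) -> "SampleMeta":
        return cls(pd.DataFrame(
            {"body_site": list(body_sites), "study_id": list(study_ids)},
            index=pd.Index(sample_ids, name="sample_id"),
        ))

    def sites_for(self, sample_ids) -> np.ndarray:
        return self.frame.loc[list(sample_ids), "body_site"].to_numpy()

    def studies_for(self, sample_ids) -> np.ndarray:
        return self.frame.loc[list(sample_ids), "study_id"].to_numpy()

    def align(self, table: OtuTable) -> "SampleMeta":
        """Return metadata restricted to (and ordered like) the table's samples."""
        missing = [s for s in table.sample_ids if s not in self.frame.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}")
        return SampleMeta(self.frame.loc[table.sample_ids])


# ---------------------------------------------------------------------------
# TSV I/O.  Dialect: tab-separated, UTF-8, header row mandatory, first column
# `otu_id`, no quoting.

def read_table(path) -> OtuTable:
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if df.columns[0] != "otu_id":
        raise ValueError(
            f"malformed header: first column must be 'otu_id', got {df.columns[0]!r}"
        )
    otu_ids = df.iloc[:, 0].tolist()
    body = df.iloc[:, 1:]
    for col in body.columns:
        vals = body[col]
        if not np.issubdtype(vals.dtype, np.number) or not np.all(np.mod(vals, 1) == 0):
            bad = vals[~vals.astype(str).str.fullmatch(r"-?\d+")] if vals.dtype == object else vals
            raise ValueError(f"non-integer cell in column {col!r}: {bad.iloc[0]!r}")
    counts = body.to_numpy(dtype=np.int64) if body.shape[1] else np.zeros((len(otu_ids), 0), dtype=np.int64)
    return OtuTable(counts, otu_ids, [str(c) for c in body.columns])


def write_table(table: OtuTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index=True)


def read_meta(path) -> SampleMeta:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError("metadata TSV must have a 'sample_id' column")
    return SampleMeta(df.set_index("sample_id"))


def write_meta(meta: SampleMeta, path) -> None:
    meta.frame.to_csv(path, sep="\t", index=True)


# ---------------------------------------------------------------------------
# Preprocessing

def filter_low_richness(table: OtuTable, min_unique: int = 20) -> OtuTable:
    """Drop samples detecting fewer than ``min_unique`` distinct OTUs.

    Low-richness samples are typically shallowly sequenced or failed runs
    and behave as noise downstream; the conventional cutoff keeps samples
    with at least 20 detected OTUs.
    """
    keep = table.richness() >= min_unique
    return OtuTable(table.counts[:, keep], table.otu_ids,
                    [s for s, k in zip(table.sample_ids, keep) if k])


def to_relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Normalize each sample by its total mapped reads.

    Returns a DataFrame (OTUs x samples) whose columns each sum to 1.
    Zero-depth samples are rejected: filter first.
    """
    depths = table.depths()
    if np.any(depths == 0):
        bad = table.sample_ids[int(np.argmax(depths == 0))]
        raise ValueError(f"zero-depth sample: {bad!r}; filter before normalizing")
    rel = table.counts / depths[np.newaxis, :]
    return pd.DataFrame(rel, index=pd.Index(table.otu_ids, name="otu_id"),
                        columns=table.sample_ids)


def binarize(table: OtuTable) -> pd.DataFrame:
    """Presence/absence: 1 iff at least one read mapped to the OTU.

    Binarization enables discretized mutual-information tests and damps
    sequencing-depth bias.
    """
    return pd.DataFrame((table.counts >= 1).astype(np.int8),
                        index=pd.Index(table.otu_ids, name="otu_id"),
                        columns=table.sample_ids)


# ---------------------------------------------------------------------------
# Normalized mutual information on binary vectors

def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def nmi(x, y, normalization: str = "geometric") -> float:
    """Normalized mutual information between two binary vectors.

    I(X;Y) / f(H(X), H(Y)) with natural-log plug-in entropies, where f is
    the geometric mean (default), arithmetic mean, or minimum of the two
    marginal entropies.  Returns 0.0 when either variable is constant.
    """
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size == 0:
        raise ValueError("empty vectors")
    n = x.size
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum((x == 1) & (y == 0)))
    n01 = int(np.sum((x == 0) & (y == 1)))
    n00 = n - n11 - n10 - n01
    joint = np.array([n00, n01, n10, n11], dtype=float) / n
    px = np.array([n00 + n01, n10 + n11], dtype=float) / n
    py = np.array([n00 + n10, n01 + n11], dtype=float) / n
    hx, hy = _entropy(px), _entropy(py)
    if hx == 0.0 or hy == 0.0:
        return 0.0
    outer = np.array([px[0] * py[0], px[0] * py[1], px[1] * py[0], px[1] * py[1]])
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / outer[nz])).sum())
    mi = max(mi, 0.0)
    if normalization == "geometric":
        denom = np.sqrt(hx * hy)
    elif normalization == "arithmetic":
        denom = 0.5 * (hx + hy)
    elif normalization == "min":
        denom = min(hx, hy)
    else:
        raise ValueError(f"unknown normalization: {normalization!r}")
    return min(mi / denom, 1.0)


def nmi_matrix(binary: pd.DataFrame, normalization: str = "geometric") -> np.ndarray:
    """All-pairs NMI between rows of a 0/1 DataFrame, vectorized via joint counts."""
    b = binary.to_numpy(dtype=np.float64)
    m, n = b.shape
    n11 = b @ b.T
    rowsums = b.sum(axis=1)
    n10 = rowsums[:, None] - n11
    n01 = rowsums[None, :] - n11
    n00 = n - n11 - n10 - n01
    p1 = rowsums / n
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(np.where(p1 > 0, p1 * np.log(p1), 0.0)
              + np.where(p1 < 1, (1 - p1) * np.log(1 - p1), 0.0))

    def term(nij, pi, pj):
        pij = nij / n
        with np.errstate(divide="ignore", invalid="ignore"):
            t = pij * np.log(pij / np.outer(pi, pj))
        return np.where(nij > 0, t, 0.0)

    mi = (term(n00, 1 - p1, 1 - p1) + term(n01, 1 - p1, p1)
          + term(n10, p1, 1 - p1) + term(n11, p1, p1))
    mi = np.clip(mi, 0.0, None)
    if normalization == "geometric":
        denom = np.sqrt(np.outer(h, h))
    elif normalization == "arithmetic":
        denom = 0.5 * (h[:, None] + h[None, :])
    elif normalization == "min":
        denom = np.minimum(h[:, None], h[None, :])
    else:
        raise ValueError(f"unknown normalization: {normalization!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, mi / denom, 0.0)
    np.fill_diagonal(out, 1.0)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Redundancy clustering

@dataclass
class RedundancyGrouping:
    """Partition of OTUs into redundancy groups with a seeded representative each."""

    groups: list[set] = field(default_factory=list)
    representative: dict = field(default_factory=dict)  # group index -> otu id
    nmi_threshold: float = 0.9

    def to_json(self) -> str:
        return json.dumps({
            "nmi_threshold": self.nmi_threshold,
            "groups": [sorted(g) for g in self.groups],
            "representative": {str(k): v for k, v in self.representative.items()},
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RedundancyGrouping":
        d = json.loads(text)
        return cls(groups=[set(g) for g in d["groups"]],
                   representative={int(k): v for k, v in d["representative"].items()},
                   nmi_threshold=d["nmi_threshold"])


def redundancy_groups(
    binary: pd.DataFrame,
    threshold: float = 0.9,
    seed: int | None = 0,
    normalization: str = "geometric",
    mode: str = "nmi-distance",
) -> tuple[RedundancyGrouping, pd.DataFrame]:
    """Group OTUs whose detection patterns are nearly interchangeable.

    Complete-linkage agglomerative clustering; in the default
    ``nmi-distance`` mode the metric is d = 1 - NMI and the tree is cut at
    d = 1 - threshold, so complete linkage guarantees every within-group
    pair has NMI >= threshold.  The alternative ``euclidean-nmi-rows``
    mode clusters the rows of the NMI matrix under Euclidean distance and
    cuts where the group NMI criterion holds only approximately.

    Returns the grouping and the reduced table containing one seeded
    random representative row per group.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    otu_ids = list(binary.index)
    m = len(otu_ids)
    if m == 0:
        raise ValueError("need at least one OTU")
    rng = np.random.default_rng(seed)
    if m == 1:
        grouping = RedundancyGrouping([{otu_ids[0]}], {0: otu_ids[0]}, threshold)
        return grouping, binary.copy()
    sim = nmi_matrix(binary, normalization=normalization)
    if mode == "nmi-distance":
        dist = 1.0 - sim
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        z = linkage(condensed, method="complete")
        labels = fcluster(z, t=1.0 - threshold, criterion="distance")
    elif mode == "euclidean-nmi-rows":
        z = linkage(sim, method="complete", metric="euclidean")
        labels = fcluster(z, t=np.sqrt(2 * (1 - threshold) * m), criterion="distance")
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    groups: list[set] = []
    representative: dict[int, str] = {}
    for lab in np.unique(labels):
        members = [otu_ids[i] for i in np.flatnonzero(labels == lab)]
        gi = len(groups)
        groups.append(set(members))
        representative[gi] = members[int(rng.integers(len(members)))]
    grouping = RedundancyGrouping(groups, representative, threshold)
    reps = [grouping.representative[i] for i in range(len(groups))]
    # preserve source row order for determinism of downstream tie-breaks
    reps_ordered = [o for o in otu_ids if o in set(reps)]
    return grouping, binary.loc[reps_ordered]


def reduce_to_representatives(table: OtuTable, grouping: RedundancyGrouping) -> OtuTable:
    """Restrict a count table to the grouping's representative OTUs."""
    reps = {grouping.representative[i] for i in range(len(grouping.groups))}
    keep = [o for o in table.otu_ids if o in reps]
    return table.select_otus(keep)
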