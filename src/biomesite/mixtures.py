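"""In silico two-source mixtures of microbiome samples.

A mixed sample is drawn multinomially from the convex combination of the
two parents' relative OTU frequencies, p = (1 - F) * p_target +
F * p_background, at a depth equal to the correspondingly weighted
average of the parents' depths.  Grids of mixed evaluation sets along a
mixture-fraction gradient support detection-limit analysis, and training
tables can be contaminated with a background pool (e.g., soil) to harden
a classifier.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .otu_table import OtuTable, SampleMeta

__all__ = ["MixtureSpec", "MixedSample", "MixedEvalSet", "mix_pair",
           "build_mixture_grid", "contaminate_training", "default_fraction_grid"]

logger = logging.getLogger(__name__)


def default_fraction_grid() -> list[float]:
    """Ten steps of 10%: the standard grid for threshold tables."""
    return [round(0.1 * k, 10) for k in range(1, 11)]


def fine_fraction_grid() -> list[float]:
    """Trace-detection grid starting at 1% of the community."""
    return [0.01, 0.02, 0.05, 0.10, 0.15, 0.20, 0.30, 0.50, 0.70, 1.00]


@dataclass(frozen=True)
class MixtureSpec:
    """Which two sites are mixed and how much background goes in."""

    target_site: str
    background_site: str
    fraction: float

    def __post_init__(self) -> None:
        if self.target_site == self.background_site:
            raise ValueError("target and background sites must differ")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError(f"fraction {self.fraction} not in [0, 1]")


@dataclass
class MixedSample:
    counts: np.ndarray
    depth: int
    provenance: tuple  # (target sample id, background sample id, fraction)

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.depth:
            raise ValueError("mixed counts do not sum to the drawn depth")


@dataclass
class MixedEvalSet:
    """Positives: mixed samples; negatives: unmixed background-site sample ids."""

    positives: list = field(default_factory=list)
    negatives: list = field(default_factory=list)
    spec: MixtureSpec | None = None

    def manifest(self) -> str:
        return json.dumps({
            "spec": {"target_site": self.spec.target_site,
                     "background_site": self.spec.background_site,
                     "fraction": self.spec.fraction},
            "positives": [{"target": p.provenance[0], "background": p.provenance[1],
                           "fraction": p.provenance[2], "depth": p.depth}
                          for p in self.positives],
            "negatives": list(self.negatives),
        }, indent=2)


def mix_pair(target_counts, background_counts, fraction: float,
             rng: np.random.Generator,
             provenance: tuple = ("?", "?", None)) -> MixedSample:
    """Mix one target sample with one background sample.

    Per-OTU relative frequencies of the two parents are weighted
    (1 - F, F) to form the draw probabilities; the mixed depth n is the
    equally weighted average of the parents' depths, rounded to the
    nearest integer with a floor of 1; counts are one multinomial draw.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction {fraction} not in [0, 1]")
    t = np.asarray(target_counts, dtype=np.float64)
    b = np.asarray(background_counts, dtype=np.float64)
    if t.shape != b.shape:
        raise ValueError("parent count vectors must share the OTU universe")
    nt, nb = t.sum(), b.sum()
    if nt == 0 or nb == 0:
        raise ValueError("zero-depth parent sample")
    p = (1.0 - fraction) * (t / nt) + fraction * (b / nb)
    n = max(1, int(round((1.0 - fraction) * nt + fraction * nb)))
    counts = rng.multinomial(n, p / p.sum())
    prov = (provenance[0], provenance[1],
            fraction if provenance[2] is None else provenance[2])
    return MixedSample(counts=counts, depth=n, provenance=prov)


def build_mixture_grid(table: OtuTable, meta: SampleMeta,
                       spec_list: list[MixtureSpec],
                       rng: np.random.Generator) -> list[MixedEvalSet]:
    """Build one mixed evaluation set per spec from a validation table.

    Every target-site sample is mixed with one background-site sample
    drawn uniformly with replacement; negatives are all unmixed
    background-site samples.  Specs with an empty site stratum are
    skipped with a warning.
    """
    meta = meta.align(table)
    sites = meta.sites_for(table.sample_ids)
    out: list[MixedEvalSet] = []
    for spec in spec_list:
        t_idx = np.flatnonzero(sites == spec.target_site)
        b_idx = np.flatnonzero(sites == spec.background_site)
        if t_idx.size == 0 or b_idx.size == 0:
            logger.warning("skipping spec %s: empty site stratum", spec)
            continue
        positives = []
        partners = b_idx[rng.integers(b_idx.size, size=t_idx.size)]
        for ti, bi in zip(t_idx, partners):
            positives.append(mix_pair(
                table.counts[:, ti], table.counts[:, bi], spec.fraction, rng,
                provenance=(table.sample_ids[ti], table.sample_ids[bi],
                            spec.fraction)))
        negatives = [table.sample_ids[i] for i in b_idx]
        out.append(MixedEvalSet(positives=positives, negatives=negatives, spec=spec))
    return out


def contaminate_training(table: OtuTable, meta: SampleMeta,
                         background_pool: OtuTable,
                         sample_fraction: float = 0.5,
                         mix_fraction: float = 0.3,
                         rng: np.random.Generator | None = None) -> OtuTable:
    """Replace a random subset of training samples by background mixtures.

    Default regime: half the training samples are mixed with 30%
    background (e.g., soil); labels are untouched, so the returned table
    pairs with the original metadata.
    """
    if not (0.0 <= sample_fraction <= 1.0):
        raise ValueError(f"sample_fraction {sample_fraction} not in [0, 1]")
    if not (0.0 <= mix_fraction <= 1.0):
        raise ValueError(f"mix_fraction {mix_fraction} not in [0, 1]")
    if background_pool.n_samples == 0:
        raise ValueError("background pool is empty")
    if background_pool.otu_ids != table.otu_ids:
        raise ValueError("background pool must share the table's OTU universe")
    rng = np.random.default_rng() if rng is None else rng
    counts = table.counts.copy()
    n_pick = int(round(sample_fraction * table.n_samples))
    picked = rng.choice(table.n_samples, size=n_pick, replace=False)
    for j in picked:
        bg = int(rng.integers(background_pool.n_samples))
        mixed = mix_pair(counts[:, j], background_pool.counts[:, bg],
                         mix_fraction, rng,
                         provenance=(table.sample_ids[j],
                                     background_pool.sample_ids[bg], mix_fraction))
        counts[:, j] = mixed.counts
    return OtuTable(counts, table.otu_ids, table.sample_ids)
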