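"""Synthetic OTU-table generator with planted ground truth.

Emulates the statistical regime of a large multi-study 16S body-site
collection: several body-site classes, samples spread over studies with
study-specific detection dropout (primer/amplification bias), log-normal
sequencing depth, and four OTU categories —

* direct positively associated (PA) markers: presence probability is
  elevated (``p_high``) in their own site and at background (``p_base``)
  elsewhere;
* direct negatively associated (NA) markers: presence depressed
  (``p_low``) in their own site, background elsewhere;
* indirect OTUs: presence depends on the site *only through* a direct
  parent marker (``q1`` given parent present, ``q0`` given absent) — the
  planted targets that local causal discovery should explain away;
* noise OTUs: background presence everywhere.

Counts are allocated multinomially across present OTUs with log-normal
abundance weights, so column sums equal the drawn depths exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .otu_table import OtuTable, SampleMeta

__all__ = ["GeneratorConfig", "GroundTruth", "TraitTable",
           "generate_dataset", "generate_trait_table",
           "TRAIT_VOCABULARY", "default_config"]

#: fixed trait vocabulary: category -> allowed sub-categories
TRAIT_VOCABULARY: dict[str, tuple[str, ...]] = {
    "aerobicity": ("aerobe", "anaerobe", "facultative"),
    "gram": ("positive", "negative"),
    "shape": ("rod", "spherical", "helical"),
    "spores": ("yes", "no"),
    "motility": ("motile", "non-motile"),
}

_SITE_NAMES = ("skin", "saliva", "vagina", "nostril", "feces", "soil")


@dataclass
class GeneratorConfig:
    """Parameters of the generative model; defaults define the study conditions.

    Probabilities refer to latent presence before study dropout.
    ``study_dropout_range`` bounds the per-(study, OTU) extra nondetection
    probability drawn uniformly, emulating primer bias.
    """

    n_sites: int = 5
    samples_per_site: list[int] = field(default_factory=lambda: [300] * 5)
    n_studies: int = 6
    study_dropout_range: tuple[float, float] = (0.0, 0.3)
    depth_log_mean: float = 9.0     # median depth ~ 8100 reads
    depth_log_sd: float = 0.6
    n_direct_pa_per_site: int = 4
    n_direct_na_per_site: int = 4
    n_indirect: int = 25
    n_noise: int = 200
    p_high: float = 0.9
    p_base: float = 0.3
    p_low: float = 0.05
    q1: float = 0.9
    q0: float = 0.1
    abundance_log_mean: float = 0.0
    abundance_log_sd: float = 1.0
    marker_abundance_boost: float = 6.0
    # trait-table layer
    trait_enriched_site_index: int = 0
    trait_enriched_category: str = "aerobicity"
    trait_enriched_subcategory: str = "anaerobe"
    trait_enrich_p: float = 0.9
    trait_background_p: float = 0.2
    trait_missing_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 2:
            raise ValueError("invariant violated: n_sites must be >= 2")
        if len(self.samples_per_site) != self.n_sites:
            raise ValueError(
                "invariant violated: samples_per_site length "
                f"({len(self.samples_per_site)}) must equal n_sites ({self.n_sites})")
        if self.n_studies < 1:
            raise ValueError("invariant violated: n_studies must be >= 1")
        lo, hi = self.study_dropout_range
        for name, p in [("study_dropout lower", lo), ("study_dropout upper", hi),
                        ("p_high", self.p_high), ("p_base", self.p_base),
                        ("p_low", self.p_low), ("q1", self.q1), ("q0", self.q0),
                        ("trait_enrich_p", self.trait_enrich_p),
                        ("trait_background_p", self.trait_background_p),
                        ("trait_missing_fraction", self.trait_missing_fraction)]:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"invariant violated: {name} = {p} not in [0, 1]")
        if lo > hi:
            raise ValueError("invariant violated: study_dropout_range lower > upper")
        if not (self.p_low < self.p_base < self.p_high):
            raise ValueError("invariant violated: require p_low < p_base < p_high")
        if not (self.q0 < self.q1):
            raise ValueError("invariant violated: require q0 < q1")
        if self.marker_abundance_boost <= 0:
            raise ValueError("invariant violated: marker_abundance_boost must be > 0")
        if any(s < 1 for s in self.samples_per_site):
            raise ValueError("invariant violated: samples_per_site entries must be >= 1")
        for n, v in [("n_direct_pa_per_site", self.n_direct_pa_per_site),
                     ("n_direct_na_per_site", self.n_direct_na_per_site),
                     ("n_indirect", self.n_indirect), ("n_noise", self.n_noise)]:
            if v < 0:
                raise ValueError(f"invariant violated: {n} must be >= 0")
        cat = self.trait_enriched_category
        if cat not in TRAIT_VOCABULARY:
            raise ValueError(f"invariant violated: unknown trait category {cat!r}")
        if self.trait_enriched_subcategory not in TRAIT_VOCABULARY[cat]:
            raise ValueError(
                f"invariant violated: {self.trait_enriched_subcategory!r} "
                f"not a sub-category of {cat!r}")

    def site_names(self) -> list[str]:
        return [(_SITE_NAMES[i] if i < len(_SITE_NAMES) else f"site{i}")
                for i in range(self.n_sites)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["study_dropout_range"] = list(self.study_dropout_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "study_dropout_range" in d:
            d["study_dropout_range"] = tuple(d["study_dropout_range"])
        return cls(**d)


def default_config(**overrides) -> GeneratorConfig:
    cfg = GeneratorConfig(**overrides)
    cfg.validate()
    return cfg


@dataclass
class GroundTruth:
    """Planted marker structure: the parameter-recovery oracle."""

    direct_pa: dict[str, set]          # site -> OTU ids
    direct_na: dict[str, set]
    indirect_edges: list[tuple]        # (parent otu, child otu, q1, q0)
    noise_otus: set

    def __post_init__(self) -> None:
        cats = [set().union(*self.direct_pa.values()) if self.direct_pa else set(),
                set().union(*self.direct_na.values()) if self.direct_na else set(),
                {c for _, c, _, _ in self.indirect_edges},
                set(self.noise_otus)]
        for i in range(len(cats)):
            for j in range(i + 1, len(cats)):
                if cats[i] & cats[j]:
                    raise ValueError(
                        f"OTU categories overlap: {sorted(cats[i] & cats[j])[:3]}")
        direct = cats[0] | cats[1]
        for parent, _, _, _ in self.indirect_edges:
            if parent not in direct:
                raise ValueError(f"indirect parent {parent!r} is not a direct marker")

    def all_direct(self) -> set:
        out: set = set()
        for d in (self.direct_pa, self.direct_na):
            for s in d.values():
                out |= s
        return out

    def indirect_otus(self) -> set:
        return {c for _, c, _, _ in self.indirect_edges}

    def parent_of(self) -> dict:
        return {c: p for p, c, _, _ in self.indirect_edges}

    def site_of_direct(self) -> dict:
        """Map each direct marker OTU to its own site."""
        out = {}
        for d in (self.direct_pa, self.direct_na):
            for site, otus in d.items():
                for o in otus:
                    out[o] = site
        return out

    def to_json(self) -> str:
        return json.dumps({
            "direct_pa": {s: sorted(v) for s, v in self.direct_pa.items()},
            "direct_na": {s: sorted(v) for s, v in self.direct_na.items()},
            "indirect_edges": [list(e) for e in self.indirect_edges],
            "noise_otus": sorted(self.noise_otus),
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(direct_pa={s: set(v) for s, v in d["direct_pa"].items()},
                   direct_na={s: set(v) for s, v in d["direct_na"].items()},
                   indirect_edges=[tuple(e) for e in d["indirect_edges"]],
                   noise_otus=set(d["noise_otus"]))


@dataclass
class TraitTable:
    """genus -> category -> set of sub-categories (missing category = unknown)."""

    traits: dict

    def __post_init__(self) -> None:
        for genus, cats in self.traits.items():
            for cat, subs in cats.items():
                if cat not in TRAIT_VOCABULARY:
                    raise ValueError(f"unknown trait category {cat!r} for {genus!r}")
                bad = set(subs) - set(TRAIT_VOCABULARY[cat])
                if bad:
                    raise ValueError(f"unknown sub-categories {sorted(bad)} in {cat!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for genus, cats in sorted(self.traits.items()):
            row = {"genus": genus}
            for cat in TRAIT_VOCABULARY:
                row[cat] = "|".join(sorted(cats[cat])) if cat in cats and cats[cat] else ""
            rows.append(row)
        return pd.DataFrame(rows, columns=["genus", *TRAIT_VOCABULARY])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "TraitTable":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        traits: dict = {}
        for _, row in df.iterrows():
            cats = {}
            for cat in TRAIT_VOCABULARY:
                if cat in row and row[cat]:
                    cats[cat] = set(row[cat].split("|"))
            traits[row["genus"]] = cats
        return cls(traits)


# ---------------------------------------------------------------------------

def _otu_layout(config: GeneratorConfig):
    """Assign OTU ids to categories and sites, deterministically from config."""
    sites = config.site_names()
    n_direct = (config.n_direct_pa_per_site + config.n_direct_na_per_site) * config.n_sites
    n_total = n_direct + config.n_indirect + config.n_noise
    width = max(4, len(str(n_total)))
    otu_ids = [f"OTU_{i:0{width}d}" for i in range(n_total)]
    pos = 0
    direct_pa: dict[str, set] = {s: set() for s in sites}
    direct_na: dict[str, set] = {s: set() for s in sites}
    for s in sites:
        for _ in range(config.n_direct_pa_per_site):
            direct_pa[s].add(otu_ids[pos]); pos += 1
        for _ in range(config.n_direct_na_per_site):
            direct_na[s].add(otu_ids[pos]); pos += 1
    indirect = otu_ids[pos:pos + config.n_indirect]
    pos += config.n_indirect
    noise = otu_ids[pos:]
    return otu_ids, direct_pa, direct_na, indirect, noise


def generate_dataset(config: GeneratorConfig) -> tuple[OtuTable, SampleMeta, GroundTruth]:
    """Draw one dataset: counts, metadata, and the planted ground truth.

    Reproducible: identical config (including seed) gives byte-identical
    output.  Independent random streams for the layout, presence,
    dropout, depth, and count stages are spawned from the master seed.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_layout, rng_presence, rng_dropout, rng_depth, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(5))

    sites = config.site_names()
    otu_ids, direct_pa, direct_na, indirect, noise = _otu_layout(config)
    n_otus = len(otu_ids)
    otu_index = {o: i for i, o in enumerate(otu_ids)}

    # indirect children adopt a uniformly chosen direct PA parent (or any
    # direct marker if no PA markers exist)
    parent_pool = sorted(set().union(*direct_pa.values())) or sorted(
        set().union(*direct_na.values()))
    if config.n_indirect > 0 and not parent_pool:
        raise ValueError("invariant violated: indirect OTUs require direct markers")
    edges = []
    for child in indirect:
        parent = parent_pool[int(rng_layout.integers(len(parent_pool)))]
        edges.append((parent, child, config.q1, config.q0))
    truth = GroundTruth(direct_pa, direct_na, edges, set(noise))

    # samples: site blocks, study uniformly at random
    n_samples = int(sum(config.samples_per_site))
    site_of = np.repeat(np.arange(config.n_sites), config.samples_per_site)
    study_of = rng_layout.integers(config.n_studies, size=n_samples)
    sample_ids = [f"S{j:05d}" for j in range(n_samples)]

    # base presence probabilities for non-indirect OTUs: (otu, site) grid
    base_p = np.full((n_otus, config.n_sites), config.p_base)
    for si, s in enumerate(sites):
        for o in direct_pa[s]:
            base_p[otu_index[o], si] = config.p_high
        for o in direct_na[s]:
            base_p[otu_index[o], si] = config.p_low
    indirect_idx = np.array([otu_index[c] for _, c, _, _ in edges], dtype=int)

    presence = (rng_presence.random((n_otus, n_samples))
                < base_p[:, site_of]).astype(np.int8)

    # per-(study, OTU) dropout: detection bias fixed within a study
    lo, hi = config.study_dropout_range
    dropout = rng_dropout.uniform(lo, hi, size=(config.n_studies, n_otus))
    keep = rng_dropout.random((n_otus, n_samples)) >= dropout[study_of, :].T
    presence &= keep.astype(np.int8)

    # indirect children: presence depends on the site only through the
    # parent's observed (post-dropout) state; then their own dropout
    if len(edges):
        parent_idx = np.array([otu_index[p] for p, _, _, _ in edges], dtype=int)
        pp = np.where(presence[parent_idx, :] == 1, config.q1, config.q0)
        child_pres = (rng_presence.random(pp.shape) < pp).astype(np.int8)
        child_keep = (rng_dropout.random(pp.shape)
                      >= dropout[study_of, :][:, indirect_idx].T)
        presence[indirect_idx, :] = child_pres & child_keep.astype(np.int8)

    # guarantee every sample has support
    empty = np.flatnonzero(presence.sum(axis=0) == 0)
    for j in empty:
        presence[int(rng_presence.integers(n_otus)), j] = 1

    depths = np.maximum(
        1, np.ceil(rng_depth.lognormal(config.depth_log_mean, config.depth_log_sd,
                                       size=n_samples))).astype(np.int64)

    # abundance weights: log-normal per present cell; a direct PA marker that
    # is present in its own site dominates its community (boost factor),
    # mirroring the site-characteristic taxa of real body-site data
    boost = np.ones((n_otus, config.n_sites))
    for si, s in enumerate(sites):
        for o in direct_pa[s]:
            boost[otu_index[o], si] = config.marker_abundance_boost
    counts = np.zeros((n_otus, n_samples), dtype=np.int64)
    for j in range(n_samples):
        present = np.flatnonzero(presence[:, j])
        w = rng_counts.lognormal(config.abundance_log_mean, config.abundance_log_sd,
                                 size=present.size)
        w *= boost[present, site_of[j]]
        counts[present, j] = rng_counts.multinomial(depths[j], w / w.sum())

    table = OtuTable(counts, otu_ids, sample_ids)
    meta = SampleMeta.from_arrays(
        sample_ids,
        [sites[s] for s in site_of],
        [f"study{int(t)}" for t in study_of],
    )
    return table, meta, truth


def genus_of(otu_id: str) -> str:
    """Synthetic genus label: one genus per OTU keeps extrapolation exact."""
    return "g_" + otu_id


def generate_trait_table(truth: GroundTruth, config: GeneratorConfig) -> TraitTable:
    """Draw a genus->trait table with one planted enrichment.

    PA markers of the designated site receive the enriched sub-category
    with probability ``trait_enrich_p``; every other marker draws it with
    ``trait_background_p``.  All other (category, sub-category) slots are
    background for everyone, and a ``trait_missing_fraction`` of genera
    lose each category independently (unknown status).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[5])
    sites = config.site_names()
    enriched_site = sites[config.trait_enriched_site_index % len(sites)]
    enriched_otus = truth.direct_pa.get(enriched_site, set())
    marker_otus = sorted(truth.all_direct() | truth.indirect_otus())
    traits: dict = {}
    for otu in marker_otus:
        cats: dict = {}
        for cat, subs in TRAIT_VOCABULARY.items():
            if rng.random() < config.trait_missing_fraction:
                continue
            chosen = set()
            for sub in subs:
                if cat == config.trait_enriched_category and \
                        sub == config.trait_enriched_subcategory:
                    p = (config.trait_enrich_p if otu in enriched_otus
                         else config.trait_background_p)
                else:
                    p = config.trait_background_p
                if rng.random() < p:
                    chosen.add(sub)
            if not chosen:
                # single-valued fallback: pick one sub-category uniformly so a
                # known category is never empty
                chosen = {subs[int(rng.integers(len(subs)))]}
            cats[cat] = chosen
        traits[genus_of(otu)] = cats
    return TraitTable(traits)
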