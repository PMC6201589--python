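"""Physiological-trait enrichment among biomarker OTUs.

For each (body site, association type, trait sub-category), the focal
markers — the site's markers of that type with a known status for the
trait category — are tested against the background of same-type markers
of all other sites by a one-tailed (enrichment) Fisher exact test, with
Benjamini-Hochberg FDR control over all records jointly.  Multi-valued
traits count an OTU once per alternative; OTUs with unknown status for a
category are excluded from that category's tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .gll import BiomarkerSet
from .synthetic import TRAIT_VOCABULARY, TraitTable, genus_of

__all__ = ["EnrichmentRecord", "enrich"]


@dataclass
class EnrichmentRecord:
    site: str
    association: str          # "+" or "-"
    category: str
    subcategory: str
    a: int                    # focal markers with the sub-category
    b: int                    # focal markers without it (known status)
    c: int                    # background markers with it
    d: int                    # background markers without it
    p: float
    p_adj: float | None = None
    enriched: bool = False


def _trait_status(traits: TraitTable, otu_id: str, category: str):
    """Known sub-categories of an OTU for one category, or None if unknown."""
    cats = traits.traits.get(genus_of(otu_id))
    if cats is None or category not in cats or not cats[category]:
        return None
    return cats[category]


def enrich(markers: BiomarkerSet, traits: TraitTable,
           alpha: float = 0.05) -> list[EnrichmentRecord]:
    """One-tailed Fisher enrichment per (site, type, sub-category), with FDR.

    Records with an empty focal or background margin are skipped.  Trait
    information is looked up at the genus level and extrapolated to the
    member OTUs.
    """
    records: list[EnrichmentRecord] = []
    sites = markers.sites()
    for sign, sign_label in ((1, "+"), (-1, "-")):
        per_site = {s: markers.otus_for(s, sign) for s in sites}
        for site in sites:
            focal = per_site[site]
            background = set().union(*(per_site[s] for s in sites if s != site)) \
                if len(sites) > 1 else set()
            for category, subs in TRAIT_VOCABULARY.items():
                focal_known = {o: _trait_status(traits, o, category)
                               for o in focal}
                focal_known = {o: v for o, v in focal_known.items() if v}
                bg_known = {o: _trait_status(traits, o, category)
                            for o in background}
                bg_known = {o: v for o, v in bg_known.items() if v}
                if not focal_known or not bg_known:
                    continue  # empty margin: nothing to test
                for sub in subs:
                    a = sum(1 for v in focal_known.values() if sub in v)
                    b = len(focal_known) - a
                    c = sum(1 for v in bg_known.values() if sub in v)
                    d = len(bg_known) - c
                    p = float(fisher_exact([[a, b], [c, d]],
                                           alternative="greater").pvalue)
                    records.append(EnrichmentRecord(
                        site=site, association=sign_label, category=category,
                        subcategory=sub, a=a, b=b, c=c, d=d, p=p))
    if records:
        adj = multipletests([r.p for r in records], method="fdr_bh")[1]
        for r, q in zip(records, adj):
            r.p_adj = float(q)
            r.enriched = q <= alpha
    return records


def enrichment_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    cols = ["site", "association", "category", "subcategory",
            "a", "b", "c", "d", "p", "p_adj", "enriched"]
    return pd.DataFrame([vars(r) for r in records], columns=cols)
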