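"""Ecologically informed biomarker discovery via local causal learning.

For each body site, a one-vs-rest indicator is tested against binarized
OTU detection patterns.  The univariate screen applies G-tests of
independence (the likelihood-ratio statistic, equal to 2N times mutual
information in natural-log units) with Benjamini-Hochberg FDR control.
The surviving candidates are then pruned by semi-interleaved HITON-PC, a
Generalized Local Learning (GLL) member: candidates are admitted in
priority order to a tentative parents-and-children set (TPC), and a
candidate is discarded as *indirectly* associated as soon as some
conditioning subset of the TPC renders it independent of the site.  The
result is the parsimonious set of OTUs whose association with the site
cannot be explained away by other OTUs.

Conditioning subsets are limited to size ``max_k`` (default 3) and drawn
from the ``h_ps`` (default 5) TPC members with the strongest
unconditional association — an efficiency heuristic that bounds the
number of tests per candidate.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .otu_table import SampleMeta, nmi

__all__ = ["GllConfig", "IndependenceTestRecord", "MarkerRecord", "BiomarkerSet",
           "g_test", "univariate_screen", "hiton_pc", "hiton_pc_core",
           "association_sign",
           "discover_all", "marker_set_summaries"]


@dataclass
class GllConfig:
    max_k: int = 3
    h_ps: int = 5
    alpha: float = 0.05
    fdr_method: str = "fdr_bh"

    def validate(self) -> None:
        if self.max_k < 0:
            raise ValueError("max_k must be >= 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.h_ps < 1:
            raise ValueError("h_ps must be >= 1")


@dataclass
class IndependenceTestRecord:
    otu_id: str
    target_site: str
    conditioning: tuple
    g: float
    df: int
    p: float


@dataclass
class MarkerRecord:
    otu_id: str
    site: str
    sign: int | None          # +1, -1, or None (indeterminate)
    strength: float           # NMI with the site indicator
    importance_percentile: float | None
    prevalence: int
    tests: list = field(default_factory=list)


@dataclass
class BiomarkerSet:
    """Per-site marker lists; an OTU appears at most once per site."""

    markers: dict = field(default_factory=dict)  # site -> list[MarkerRecord]

    def sites(self) -> list[str]:
        return list(self.markers)

    def otus_for(self, site: str, sign: int | None = None) -> set:
        recs = self.markers.get(site, [])
        if sign is None:
            return {r.otu_id for r in recs}
        return {r.otu_id for r in recs if r.sign == sign}

    def all_otus(self) -> set:
        out: set = set()
        for recs in self.markers.values():
            out |= {r.otu_id for r in recs}
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for site, recs in self.markers.items():
            for r in recs:
                rows.append({
                    "otu_id": r.otu_id, "site": site,
                    "sign": {1: "+", -1: "-", None: "indeterminate"}[r.sign],
                    "strength_nmi": r.strength,
                    "prevalence": r.prevalence,
                    "importance_percentile": r.importance_percentile,
                })
        return pd.DataFrame(rows, columns=["otu_id", "site", "sign", "strength_nmi",
                                           "prevalence", "importance_percentile"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# G-test of (conditional) independence for binary variables

def g_test(x, y, conditioning=(), otu_id: str = "", target_site: str = "",
           max_k: int | None = None) -> IndependenceTestRecord:
    """Likelihood-ratio (G) test of X ⟂ Y | Z for binary vectors.

    G = 2 * N * MI(X; Y | Z) in natural-log units, summed over the
    strata defined by the joint assignment of the conditioning vectors;
    empty strata are skipped and zero cells contribute nothing.
    Degrees of freedom are (levels(X) - 1) * (levels(Y) - 1) per
    non-empty stratum; df = 0 (either variable constant) yields p = 1.
    """
    x = np.asarray(x, dtype=np.int8).ravel()
    y = np.asarray(y, dtype=np.int8).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    zs = [np.asarray(z, dtype=np.int8).ravel() for z in conditioning]
    for z in zs:
        if z.shape != x.shape:
            raise ValueError("conditioning vector length mismatch")
    if max_k is not None and len(zs) > max_k:
        raise ValueError(f"conditioning set size {len(zs)} exceeds max_k={max_k}")

    lx = int(x.max()) + 1 if x.size else 1
    ly = int(y.max()) + 1 if y.size else 1
    levels_x = len(np.unique(x))
    levels_y = len(np.unique(y))

    # stratum index: little-endian binary code of the conditioning assignment
    if zs:
        code = np.zeros(x.size, dtype=np.int64)
        for k, z in enumerate(zs):
            code |= z.astype(np.int64) << k
        n_strata_max = 1 << len(zs)
    else:
        code = np.zeros(x.size, dtype=np.int64)
        n_strata_max = 1

    g_total = 0.0
    nonempty = 0
    for s in range(n_strata_max):
        mask = code == s
        ns = int(mask.sum())
        if ns == 0:
            continue
        nonempty += 1
        xs, ys = x[mask], y[mask]
        tab = np.zeros((max(lx, 2), max(ly, 2)), dtype=np.int64)
        np.add.at(tab, (xs, ys), 1)
        rows = tab.sum(axis=1, keepdims=True)
        cols = tab.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            expected = rows * cols / ns
            term = tab * np.log(tab / expected)
        g_total += 2.0 * float(np.nansum(np.where(tab > 0, term, 0.0)))

    df = (levels_x - 1) * (levels_y - 1) * nonempty
    g_total = max(g_total, 0.0)
    p = 1.0 if df == 0 else float(chi2.sf(g_total, df))
    return IndependenceTestRecord(otu_id=otu_id, target_site=target_site,
                                  conditioning=(), g=g_total, df=df, p=p)


def _g_test_named(binary_np, idx_of, otu, target, target_site, cond_ids, max_k):
    rec = g_test(binary_np[idx_of[otu]], target,
                 [binary_np[idx_of[c]] for c in cond_ids],
                 otu_id=otu, target_site=target_site, max_k=max_k)
    rec.conditioning = tuple(cond_ids)
    return rec


# ---------------------------------------------------------------------------
# Univariate screen with FDR

def univariate_screen(binary: pd.DataFrame, target, config: GllConfig,
                      target_site: str = "") -> pd.DataFrame:
    """Unconditional G-test of every OTU against the site indicator.

    Benjamini-Hochberg adjustment over all OTUs; candidates are the rows
    with adjusted p <= alpha, ordered by decreasing G (ties broken by
    OTU id ascending).  Returns a DataFrame with columns otu_id, g, df,
    p, p_adj, candidate.
    """
    config.validate()
    target = np.asarray(target, dtype=np.int8).ravel()
    if len(np.unique(target)) < 2:
        raise ValueError("target indicator is constant")
    b = binary.to_numpy(dtype=np.int8)
    rows = []
    for i, otu in enumerate(binary.index):
        rec = g_test(b[i], target, otu_id=str(otu), target_site=target_site)
        rows.append({"otu_id": str(otu), "g": rec.g, "df": rec.df, "p": rec.p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["p"].to_numpy(), method=config.fdr_method)[1]
    else:
        df["p_adj"] = []
    df["candidate"] = df["p_adj"] <= config.alpha
    df = df.sort_values(["g", "otu_id"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Semi-interleaved HITON-PC

def _conditioning_pool(tpc: list[str], uni_g: dict, h_ps: int,
                       exclude: str | None = None) -> list[str]:
    pool = [o for o in tpc if o != exclude]
    pool.sort(key=lambda o: (-uni_g[o], o))
    return pool[:h_ps]


def hiton_pc_core(order: list[str], uni_g: dict, ci_test, config: GllConfig):
    """Semi-interleaved HITON-PC over an abstract conditional-independence test.

    ``order`` lists screened candidates by decreasing priority; ``ci_test``
    maps (candidate id, conditioning-id tuple) to an
    IndependenceTestRecord.  Returns (tpc ids, audit map).  Factored out
    so an exact d-separation oracle can stand in for the data-driven
    G-test when validating the search itself.
    """

    def independent_given_some_subset(otu, pool, audit):
        for k in range(1, min(config.max_k, len(pool)) + 1):
            for subset in itertools.combinations(pool, k):
                rec = ci_test(otu, subset)
                audit.append(rec)
                if rec.p > config.alpha:
                    return True
        return False

    audit: dict[str, list[IndependenceTestRecord]] = {o: [] for o in order}
    tpc: list[str] = []
    for otu in order:
        pool = _conditioning_pool(tpc, uni_g, config.h_ps)
        if not independent_given_some_subset(otu, pool, audit[otu]):
            tpc.append(otu)

    # backward elimination to a fixed point
    changed = True
    while changed:
        changed = False
        for otu in list(tpc):
            pool = _conditioning_pool(tpc, uni_g, config.h_ps, exclude=otu)
            if independent_given_some_subset(otu, pool, audit[otu]):
                tpc.remove(otu)
                changed = True
    return tpc, audit


def hiton_pc(binary: pd.DataFrame, target, config: GllConfig,
             target_site: str = "",
             screen: pd.DataFrame | None = None) -> list[MarkerRecord]:
    """Semi-interleaved HITON-PC around a binary site indicator.

    Forward phase: FDR-screened candidates enter in order of decreasing
    unconditional G; each is admitted to the tentative set (TPC) unless
    some conditioning subset (size <= max_k, drawn from the h_ps
    strongest TPC members) makes it independent of the target, in which
    case it is discarded permanently.  Backward phase: each TPC member is
    re-tested against subsets of the remaining TPC until the set is
    stable.  Returns marker records (sign unset) with supporting tests.
    """
    config.validate()
    target = np.asarray(target, dtype=np.int8).ravel()
    if screen is None:
        screen = univariate_screen(binary, target, config, target_site)
    cand = screen[screen["candidate"]]
    order = cand["otu_id"].tolist()
    uni_g = dict(zip(cand["otu_id"], cand["g"]))
    binary_np = binary.to_numpy(dtype=np.int8)
    idx_of = {str(o): i for i, o in enumerate(binary.index)}

    def ci_test(otu, subset):
        return _g_test_named(binary_np, idx_of, otu, target, target_site,
                             list(subset), config.max_k)

    tpc, audit = hiton_pc_core(order, uni_g, ci_test, config)

    prevalence = {o: int(binary_np[idx_of[o]].sum()) for o in tpc}
    out = []
    for otu in tpc:
        uni_rec = g_test(binary_np[idx_of[otu]], target, otu_id=otu,
                         target_site=target_site)
        out.append(MarkerRecord(
            otu_id=otu, site=target_site, sign=None,
            strength=nmi(binary_np[idx_of[otu]], target),
            importance_percentile=None,
            prevalence=prevalence[otu],
            tests=[uni_rec, *audit[otu]],
        ))
    return out


def association_sign(otu, target) -> int | None:
    """Sign of the association between a binary OTU and a site indicator.

    Equals the sign of the Spearman rank correlation of the two binary
    vectors, i.e. sign(ad - bc) in the 2x2 table; exactly zero (or a
    constant input) is indeterminate (None).
    """
    x = np.asarray(otu, dtype=np.int64).ravel()
    y = np.asarray(target, dtype=np.int64).ravel()
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        return None
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    det = a * d - b * c
    if det > 0:
        return 1
    if det < 0:
        return -1
    return None


def discover_all(binary: pd.DataFrame, meta: SampleMeta, config: GllConfig,
                 importances: dict | None = None) -> BiomarkerSet:
    """Run screen -> HITON-PC -> sign assignment for every body site.

    Expects a redundancy-reduced binary table.  ``importances`` is an
    optional OTU -> feature-importance map from a trained classifier used
    to attach an importance percentile to each marker (percentile within
    the site's own marker list).  Sites with fewer than 2 samples are
    skipped.
    """
    config.validate()
    meta_frame = meta.frame.loc[list(binary.columns)]
    sites_arr = meta_frame["body_site"].to_numpy()
    result: dict[str, list[MarkerRecord]] = {}
    for site in pd.unique(sites_arr):
        indicator = (sites_arr == site).astype(np.int8)
        if indicator.sum() < 2:
            logging.getLogger(__name__).warning(
                "site %r has < 2 samples; skipped", site)
            continue
        markers = hiton_pc(binary, indicator, config, target_site=str(site))
        for m in markers:
            m.sign = association_sign(binary.loc[m.otu_id].to_numpy(), indicator)
        if importances:
            vals = np.array([importances.get(m.otu_id, 0.0) for m in markers])
            if len(vals):
                ranks = vals.argsort().argsort()
                denom = max(len(vals) - 1, 1)
                for m, r in zip(markers, ranks):
                    m.importance_percentile = 100.0 * r / denom
        result[str(site)] = markers
    return BiomarkerSet(result)


def marker_set_summaries(bset: BiomarkerSet):
    """Pairwise Jaccard matrix over sites, PA/NA counts, prevalence table."""
    sites = bset.sites()
    jac = pd.DataFrame(np.ones((len(sites), len(sites))), index=sites, columns=sites)
    for i, si in enumerate(sites):
        for j, sj in enumerate(sites):
            a, b = bset.otus_for(si), bset.otus_for(sj)
            union = a | b
            jac.iloc[i, j] = (len(a & b) / len(union)) if union else 1.0
    counts = pd.DataFrame(
        [{"site": s,
          "pa": sum(1 for r in bset.markers[s] if r.sign == 1),
          "na": sum(1 for r in bset.markers[s] if r.sign == -1),
          "indeterminate": sum(1 for r in bset.markers[s] if r.sign is None)}
         for s in sites]).set_index("site") if sites else pd.DataFrame()
    prev = pd.DataFrame(
        [{"otu_id": r.otu_id, "site": s, "prevalence": r.prevalence}
         for s in sites for r in bset.markers[s]])
    return jac, counts, prev
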