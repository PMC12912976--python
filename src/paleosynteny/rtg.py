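"""Retained triplicated genes: multispecies calling, hotspots, enrichment, tau.

A gene (anchored on the outgroup reference) is a retained triplicated
gene (RTG) when, for each of the three homoeolog slots separately, the
fraction of surveyed species retaining a syntenic copy in that slot
reaches ``species_fraction``.  Hotspots are windows whose RTG count
exceeds a seeded permutation null at exact level 0.05 (randomized at
the discrete boundary so the null flag rate is calibrated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GenomeAnnotation, ValidationError

log = logging.getLogger(__name__)

SLOTS = ("a", "b", "c")

__all__ = [
    "build_copy_matrix", "call_rtgs", "rtg_hotspots",
    "overrepresentation", "tau", "tau_matrix", "tau_contrast",
]


def build_copy_matrix(presence_by_species: dict, reference: GenomeAnnotation) -> pd.DataFrame:
    """Binary presence matrix: reference genes x (species, slot) columns.

    ``presence_by_species`` maps species to a gene x slot boolean frame
    (painting- or truth-derived).  Species missing a slot get an
    all-zero column with a warning.
    """
    genes = [g for c in reference.chromosomes for g in reference.genes_on(c)]
    cols = {}
    for sp in sorted(presence_by_species):
        pres = presence_by_species[sp]
        for slot in SLOTS:
            if slot in pres.columns:
                col = pres.reindex(genes)[slot].fillna(False).astype(int)
            else:
                log.warning("species %s lacks slot %s; filled with 0", sp, slot)
                col = pd.Series(0, index=genes)
            cols[(sp, slot)] = col.to_numpy()
    out = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["species", "slot"])
    return out


def call_rtgs(matrix: pd.DataFrame, species_fraction: float = 0.8) -> pd.DataFrame:
    """Call RTGs: every slot retained in >= ``species_fraction`` of species."""
    if not (0.0 < species_fraction <= 1.0):
        raise ValidationError("species_fraction must be in (0, 1]")
    species = matrix.columns.get_level_values("species").unique()
    if len(species) < 2:
        raise ValidationError("RTG calling needs >= 2 species")
    out = pd.DataFrame(index=matrix.index)
    for slot in SLOTS:
        sub = matrix.xs(slot, axis=1, level="slot")
        out[f"frac_{slot}"] = sub.mean(axis=1)
    out["copies"] = matrix.sum(axis=1)
    out["rtg"] = np.logical_and.reduce(
        [out[f"frac_{s}"] >= species_fraction for s in SLOTS]
    )
    return out


def rtg_hotspots(is_rtg: pd.Series, annotation: GenomeAnnotation, window: int = 50,
                 n_perm: int = 1000, alpha: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Window RTG counts with permutation-calibrated hotspot flags.

    Non-overlapping ``window``-gene windows along each chromosome; the
    null shuffles RTG labels over genes.  The flag threshold is the
    randomized upper-``alpha`` quantile of the pooled null window
    counts, so under uniform placement about ``alpha`` of windows are
    flagged; with zero RTGs nothing is flagged.
    """
    genes = [g for c in annotation.chromosomes for g in annotation.genes_on(c)]
    flags = is_rtg.reindex(genes).fillna(False).to_numpy(dtype=bool)
    rows = []
    pos = 0
    for chrom in annotation.chromosomes:
        n = annotation.n_genes_on(chrom)
        for start in range(0, n, window):
            size = min(window, n - start)
            rows.append(dict(chrom=chrom, start=start, size=size,
                             count=int(flags[pos + start : pos + start + size].sum())))
        pos += n
    df = pd.DataFrame(rows, columns=["chrom", "start", "size", "count"])
    total = int(flags.sum())
    if total == 0 or df.empty:
        df["hotspot"] = False
        return df

    rng = np.random.default_rng(seed)
    sizes = df["size"].to_numpy()
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    null_counts = []
    for _ in range(n_perm):
        perm = rng.permutation(flags)
        csum = np.concatenate([[0], np.cumsum(perm)])
        null_counts.append(csum[bounds[1:]] - csum[bounds[:-1]])
    null = np.concatenate(null_counts)

    # randomized threshold: P(X > c) + gamma * P(X = c) = alpha under the null
    c = int(np.quantile(null, 1 - alpha, method="inverted_cdf"))
    p_gt = float((null > c).mean())
    p_eq = float((null == c).mean())
    gamma = (alpha - p_gt) / p_eq if p_eq > 0 else 0.0
    gamma = min(max(gamma, 0.0), 1.0)
    u = rng.random(len(df))
    counts = df["count"].to_numpy()
    df["hotspot"] = (counts > c) | ((counts == c) & (u < gamma) & (counts > 0))
    df.attrs["threshold"] = c
    df.attrs["gamma"] = gamma
    return df


def overrepresentation(target: set, labels: dict, background: set) -> pd.DataFrame:
    """Per-label 2x2 Fisher exact tests with BH correction.

    ``labels`` maps gene -> set of annotation labels; ``background``
    must contain the target set.
    """
    background = set(background)
    target = set(target)
    if not background:
        raise ValidationError("empty background")
    if not target <= background:
        raise ValidationError("target set must be contained in background")
    all_labels = sorted({l for g in background for l in labels.get(g, ())})
    rows = []
    for lab in all_labels:
        with_lab = {g for g in background if lab in labels.get(g, ())}
        a = len(target & with_lab)
        b = len(target - with_lab)
        cc = len(with_lab - target)
        d = len(background) - a - b - cc
        if a + cc == 0:
            log.warning("label %s absent from background; skipped", lab)
            continue
        odds = (a * d) / (b * cc) if b * cc > 0 else float("inf")
        _, p = stats.fisher_exact([[a, b], [cc, d]], alternative="two-sided")
        rows.append(dict(label=lab, target_with=a, target_without=b,
                         background_with=cc, background_without=d,
                         odds_ratio=odds, p=float(p)))
    df = pd.DataFrame(rows, columns=["label", "target_with", "target_without",
                                     "background_with", "background_without",
                                     "odds_ratio", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["q"] = []
    return df


def tau(expression) -> float:
    """Tissue-specificity index: sum(1 - x_i/max) / (n - 1), in [0, 1].

    Returns NaN for an all-zero vector; scale-invariant by construction.
    """
    x = np.asarray(expression, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("tau needs a vector over >= 2 tissues")
    if (x < 0).any():
        raise ValidationError("negative expression values")
    m = x.max()
    if m == 0:
        return float("nan")
    return float((1.0 - x / m).sum() / (len(x) - 1))


def tau_matrix(expression: pd.DataFrame) -> pd.Series:
    """Per-gene tau over a gene x tissue matrix."""
    if expression.shape[1] < 2:
        raise ValidationError("expression matrix needs >= 2 tissues")
    return expression.apply(lambda row: tau(row.to_numpy()), axis=1).rename("tau")


@dataclass
class TauContrast:
    tau_a: pd.Series
    tau_b: pd.Series
    statistic: float
    p_value: float
    zscores: pd.DataFrame


def tau_contrast(group_a, group_b, expression: pd.DataFrame) -> TauContrast:
    """Compare tissue specificity between two gene groups (Mann-Whitney).

    Also returns per-gene z-scored expression for heatmap export.
    """
    group_a = [g for g in group_a if g in expression.index]
    group_b = [g for g in group_b if g in expression.index]
    if not group_a or not group_b:
        raise ValidationError("both groups must be present in the expression matrix")
    taus = tau_matrix(expression.loc[sorted(set(group_a) | set(group_b))])
    ta = taus.loc[sorted(group_a)].dropna()
    tb = taus.loc[sorted(group_b)].dropna()
    res = stats.mannwhitneyu(ta, tb, alternative="two-sided")
    sub = expression.loc[sorted(set(group_a) | set(group_b))]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1).replace(0, np.nan)
    z = sub.sub(mu, axis=0).div(sd, axis=0)
    return TauContrast(ta, tb, float(res.statistic), float(res.pvalue), z)
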