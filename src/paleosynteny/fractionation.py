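"""Gene retention per homoeolog, reciprocity, and pairwise Ks (NG86).

Retention is synteny-anchored: a reference gene counts as retained in
a homoeolog slot when a syntenic ortholog of it lies in that slot.
Presence calls may come from block paintings (real mode) or from
simulation truth (test mode); the painting route is biased slightly
downward because genes in dropped micro-blocks are invisible.

Ks/Ka follow Nei & Gojobori (1986): per-codon synonymous site counts
averaged over the two sequences (mutations to stop codons count as
nonsynonymous, so sites always sum to three per codon), multi-hit
codons averaged over all substitution pathways that avoid stop
codons, and a Jukes-Cantor multiple-hit correction
ks = -3/4 ln(1 - 4/3 ps).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

from .io import GenomeAnnotation, ValidationError

log = logging.getLogger(__name__)

SLOTS = ("a", "b", "c")

__all__ = [
    "RetentionProfile", "KsEstimate",
    "presence_from_labels", "retention_windows", "reciprocity",
    "ks_ng86", "ks_distributions_by_slot",
]


# ---------------------------------------------------------------------
# retention
# ---------------------------------------------------------------------

@dataclass
class RetentionProfile:
    windows: pd.DataFrame      # chrom, start, size, one column per slot, combined
    slots: tuple = SLOTS

    @property
    def combined(self) -> pd.Series:
        return self.windows["combined"]

    def slot_means(self) -> pd.Series:
        return self.windows[list(self.slots)].mean()

    def mean_combined(self, weight_by_size: bool = True) -> float:
        """Global mean combined retention (fraction of 3).

        Sliding windows overlap, so the size-weighted mean over windows
        and the unweighted mean differ slightly for partial windows;
        both are reported by the pipeline.
        """
        if weight_by_size:
            w = self.windows["size"]
            return float((self.windows["combined"] * w).sum() / w.sum())
        return float(self.windows["combined"].mean())


def presence_from_labels(reference: GenomeAnnotation, anchors,
                         slot_labels: Mapping[str, str]) -> pd.DataFrame:
    """Presence calls from AGB paintings.

    ``anchors`` are (reference gene, descendant gene) pairs;
    ``slot_labels`` maps descendant genes to their painted slot.  A
    reference gene is retained in a slot if any of its syntenic
    orthologs was painted into that slot.
    """
    present = {s: set() for s in SLOTS}
    for a in anchors:
        slot = slot_labels.get(a.gene_b)
        if slot in present:
            present[slot].add(a.gene_a)
    rows = []
    for chrom in reference.chromosomes:
        for g in reference.genes_on(chrom):
            rows.append([g] + [g in present[s] for s in SLOTS])
    return pd.DataFrame(rows, columns=["gene_id", *SLOTS]).set_index("gene_id")


def retention_windows(reference: GenomeAnnotation, presence: pd.DataFrame,
                      window: int = 100, step: int = 50) -> RetentionProfile:
    """Sliding-window retention per slot along the reference.

    The final partial window is kept when it holds at least ``step``
    genes.  ``combined`` is the row sum over slots (ceiling 3.0).
    """
    if window < 2:
        raise ValidationError("window must be >= 2")
    if step < 1 or step > window:
        raise ValidationError("step must be in [1, window]")
    slots = [c for c in presence.columns]
    rows = []
    for chrom in reference.chromosomes:
        genes = reference.genes_on(chrom)
        vals = presence.loc[genes, slots].to_numpy(dtype=float)
        n = len(genes)
        start = 0
        while start < n:
            size = min(window, n - start)
            if size < window and size < step:
                break
            mean = vals[start : start + size].mean(axis=0)
            rows.append([chrom, start, size, *mean, float(mean.sum())])
            if start + window >= n:
                break
            start += step
    df = pd.DataFrame(rows, columns=["chrom", "start", "size", *slots, "combined"])
    return RetentionProfile(df, tuple(slots))


def reciprocity(profile: RetentionProfile) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-window retention deviations.

    Deviations are retention minus the slot mean; under the shared
    retention-budget model the correlations are negative, under
    independent fractionation they are near zero.  Zero-variance slots
    yield NaN for their pairs.
    """
    df = profile.windows
    if len(df) < 10:
        raise ValidationError("reciprocity needs >= 10 windows")
    slots = list(profile.slots)
    dev = df[slots] - df[slots].mean()
    rows = []
    for i, a in enumerate(slots):
        for b in slots[i + 1 :]:
            if dev[a].std() == 0 or dev[b].std() == 0:
                r = float("nan")
            else:
                r = float(np.corrcoef(dev[a], dev[b])[0, 1])
            rows.append(dict(slot_a=a, slot_b=b, pearson_r=r))
    out = pd.DataFrame(rows)
    out.attrs["mean_r"] = float(np.nanmean(out["pearson_r"])) if len(out) else float("nan")
    return out


# ---------------------------------------------------------------------
# NG86 Ks/Ka
# ---------------------------------------------------------------------

_BASES = "ACGT"
_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


def _aa(codon: str):
    return "*" if codon in _STOPS else _CODON_TABLE[codon]


def _codon_sites(codon: str):
    """(synonymous, nonsynonymous) site counts for one codon.

    Each position contributes its fraction of synonymous single-base
    changes; changes creating a stop codon count as nonsynonymous, so
    the two counts always sum to 3.
    """
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in _STOPS and _aa(alt) == _aa(codon):
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _codon_diffs(c1: str, c2: str):
    """(syn, nonsyn) differences averaged over stop-free pathways.

    All orders of the differing positions are enumerated; pathways
    passing through a stop codon are excluded (if every pathway hits a
    stop, all are used — a stated convention for pathological codons).
    """
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        cur = c1
        syn = nonsyn = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                blocked = True
            if _aa(nxt) == _aa(cur):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        paths.append((blocked, syn, nonsyn))
    valid = [(s, n) for blocked, s, n in paths if not blocked]
    if not valid:
        valid = [(s, n) for _, s, n in paths]
    syn = sum(s for s, _ in valid) / len(valid)
    nonsyn = sum(n for _, n in valid) / len(valid)
    return syn, nonsyn


@dataclass
class KsEstimate:
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    ks: float            # NaN when saturated
    ka: float
    saturated_s: bool = False
    saturated_n: bool = False


def _jc(p: float):
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return float("nan"), True
    return -0.75 * math.log(arg), False


def _validate_codon_seq(seq: str, name: str):
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValidationError(f"{name}: length not divisible by 3")
    if set(seq) - set(_BASES):
        raise ValidationError(f"{name}: non-ACGT characters")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if any(c in _STOPS for c in codons[:-1]):
        raise ValidationError(f"{name}: internal stop codon")
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    return codons


def ks_ng86(codon_seq_a: str, codon_seq_b: str) -> KsEstimate:
    """Nei-Gojobori (1986) Ks/Ka for an aligned codon pair."""
    ca = _validate_codon_seq(codon_seq_a, "sequence a")
    cb = _validate_codon_seq(codon_seq_b, "sequence b")
    if len(ca) != len(cb):
        raise ValidationError("sequences differ in codon length")
    if not ca:
        raise ValidationError("empty alignment")
    S = N = Sd = Nd = 0.0
    for x, y in zip(ca, cb):
        sx, nx = _codon_sites(x)
        sy, ny = _codon_sites(y)
        S += (sx + sy) / 2.0
        N += (nx + ny) / 2.0
        sd, nd = _codon_diffs(x, y)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks, sat_s = _jc(ps)
    ka, sat_n = _jc(pn)
    return KsEstimate(S, N, Sd, Nd, ks, ka, sat_s, sat_n)


def ks_distributions_by_slot(estimates: pd.DataFrame, n_perm: int = 999,
                             seed: int = 0, min_n: int = 10):
    """Per-slot Ks summaries and pairwise Kolmogorov-Smirnov distances.

    ``estimates`` needs columns 'ks' and 'slot'.  P-values come from a
    seeded label-permutation null; slots with fewer than ``min_n``
    finite values are reported as NA and excluded from pairs.
    """
    df = estimates.dropna(subset=["ks"])
    rng = np.random.default_rng(seed)
    summaries = []
    groups = {}
    for slot, sub in df.groupby("slot"):
        vals = sub["ks"].to_numpy()
        row = dict(slot=slot, n=len(vals))
        if len(vals) >= min_n:
            row.update(median=float(np.median(vals)),
                       iqr=float(np.percentile(vals, 75) - np.percentile(vals, 25)))
            groups[slot] = vals
        else:
            row.update(median=float("nan"), iqr=float("nan"))
        summaries.append(row)
    pairs = []
    slots = sorted(groups)
    for i, a in enumerate(slots):
        for b in slots[i + 1 :]:
            xa, xb = groups[a], groups[b]
            obs = float(stats.ks_2samp(xa, xb, method="asymp").statistic)
            pooled = np.concatenate([xa, xb])
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(pooled)
                st = float(stats.ks_2samp(perm[: len(xa)], perm[len(xa) :],
                                          method="asymp").statistic)
                if st >= obs:
                    count += 1
            pairs.append(dict(slot_a=a, slot_b=b, ks_stat=obs,
                              p_perm=(count + 1) / (n_perm + 1)))
    return (pd.DataFrame(summaries, columns=["slot", "n", "median", "iqr"]),
            pd.DataFrame(pairs, columns=["slot_a", "slot_b", "ks_stat", "p_perm"]))
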