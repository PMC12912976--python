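"""Synthetic clade generator with full ground truth.

The generator emulates the study design this package analyses: a
diploid outgroup that diverged before a two-step whole-genome
triplication, plus a clade of descendants of the triplicated ancestor.
Each descendant lineage independently loses duplicated copies
(fractionation that is locally biased but globally unbiased across the
three subgenomes, with a reciprocal pattern produced by a shared
Dirichlet budget per window) and reshuffles its karyotype through
fissions, fusions, inversions and reciprocal translocations.  A
planted set of loss-immune triple-copy genes carries
tissue-partitioned expression.

Modelling choices that matter for identifiability:

* fission/translocation breakpoints keep at least
  ``min_fission_fragment`` genes on each side — fragments smaller than
  the minimum detectable block are invisible to any synteny method;
* a fusion never recreates a previously broken adjacency, and
  inversions are internal (at least one flanking gene on both sides),
  so event counts remain recoverable from block adjacencies;
* the per-window Dirichlet retention probabilities are rescaled so
  that the realized per-copy marginal retention equals
  ``retention_mean`` *including* the planted loss-immune set.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AnchorPair, GenomeAnnotation, ValidationError, write_anchors, write_bed, write_tsv

log = logging.getLogger(__name__)

SLOTS = ("a", "b", "c")

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulationResult",
    "simulate_ancestor",
    "apply_wgt",
    "apply_fractionation",
    "apply_rearrangements",
    "simulate_clade",
    "write_clade",
    "random_codon_alignment",
]


@dataclass
class SimulationConfig:
    n_chrom: int = 8
    genes_per_chrom: int = 500
    n_species: int = 5                  # 4 descendants + 1 outgroup
    retention_mean: float = 0.41        # per-copy marginal retention
    window_bias_block: int = 100        # genes per Dirichlet window
    bias_concentration: float = 3.0     # symmetric Dirichlet parameter
    rtg_fraction: float = 0.02          # loss-immune fraction of ancestral genes
    n_fissions: int = 2                 # per descendant lineage
    n_fusions: int = 2
    n_inversions: int = 3
    n_translocations: int = 1
    outgroup_fissions: int = 0
    outgroup_fusions: int = 0
    outgroup_inversions: int = 0
    outgroup_translocations: int = 0
    n_tissues: int = 12
    min_fission_fragment: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_chrom < 1 or self.genes_per_chrom < 1 or self.n_species < 2:
            raise ValidationError("n_chrom, genes_per_chrom >= 1 and n_species >= 2 required")
        if not (0.0 < self.retention_mean <= 1.0):
            raise ValidationError("retention_mean must be in (0, 1]")
        if not (0.0 <= self.rtg_fraction <= 1.0):
            raise ValidationError("rtg_fraction must be in [0, 1]")
        for f in ("n_fissions", "n_fusions", "n_inversions", "n_translocations",
                  "outgroup_fissions", "outgroup_fusions", "outgroup_inversions",
                  "outgroup_translocations"):
            if getattr(self, f) < 0:
                raise ValidationError(f"{f} must be >= 0")
        if self.n_tissues < 2:
            raise ValidationError("n_tissues must be >= 2")
        if self.bias_concentration <= 0:
            raise ValidationError("bias_concentration must be > 0")

    @classmethod
    def from_json(cls, path_or_dict) -> "SimulationConfig":
        if isinstance(path_or_dict, (str, Path)):
            with open(path_or_dict) as fh:
                data = json.load(fh)
        else:
            data = dict(path_or_dict)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class SimulationTruth:
    subgenome_of: dict = field(default_factory=dict)       # gene -> a|b|c
    ancestral_gene_of: dict = field(default_factory=dict)  # gene -> ancestral id
    event_log: list = field(default_factory=list)
    rtg_set: set = field(default_factory=set)              # ancestral ids
    homoeologous_set_of: dict = field(default_factory=dict)  # ancestral id -> 1..2*n_chrom
    deletions: dict = field(default_factory=dict)          # species -> deleted copy count

    def presence_matrix(self, species: str, reference: GenomeAnnotation) -> pd.DataFrame:
        """Truth-mode presence calls: reference gene x subgenome slot.

        Entry is True iff the species retains a copy of the reference
        gene's ancestral gene in that subgenome.
        """
        present = {s: set() for s in SLOTS}
        for gene, anc in self.ancestral_gene_of.items():
            if gene.startswith(species + "."):
                present[self.subgenome_of[gene]].add(anc)
        rows = []
        for chrom in reference.chromosomes:
            for g in reference.genes_on(chrom):
                anc = self.ancestral_gene_of.get(g, g)
                rows.append([g] + [anc in present[s] for s in SLOTS])
        return pd.DataFrame(rows, columns=["gene_id", *SLOTS]).set_index("gene_id")


@dataclass
class SimulationResult:
    config: SimulationConfig
    genomes: dict                      # species -> GenomeAnnotation
    truth: SimulationTruth
    anchors: dict                      # (species_a, species_b) -> [AnchorPair]
    expression: pd.DataFrame           # genes (expression species) x tissues
    expression_species: str = "sp1"

    @property
    def outgroup(self) -> str:
        return "og"

    @property
    def descendants(self) -> list:
        return [s for s in self.genomes if s != "og"]


# ---------------------------------------------------------------------
# internal karyotype machinery (lists of (gene_id, strand) per chromosome)
# ---------------------------------------------------------------------

def _flip(genes):
    return [(g, "-" if s == "+" else "+") for g, s in reversed(genes)]


class _ConfigError(ValidationError):
    pass


def _eligible_gaps(chroms, margin, used):
    gaps = []
    for ci, genes in enumerate(chroms):
        for p in range(margin, len(genes) - margin + 1):
            if p < 1 or p >= len(genes):
                continue
            adj = frozenset((genes[p - 1][0], genes[p][0]))
            if adj not in used:
                gaps.append((ci, p))
    return gaps


def _apply_events(chroms, counts, rng, lineage, margin, used=None, log_out=None):
    """Apply fission -> fusion -> inversion -> translocation in order."""
    used = used if used is not None else set()
    events = log_out if log_out is not None else []
    n_fis, n_fus, n_inv, n_tra = counts

    for _ in range(n_fis):
        gaps = _eligible_gaps(chroms, margin, used)
        if not gaps:
            raise _ConfigError("requested fissions exceed available breakpoint gaps")
        ci, p = gaps[rng.integers(len(gaps))]
        genes = chroms[ci]
        used.add(frozenset((genes[p - 1][0], genes[p][0])))
        chroms[ci] = genes[:p]
        chroms.append(genes[p:])
        events.append(dict(lineage=lineage, type="fission",
                           left=genes[p - 1][0], right=genes[p][0]))

    for _ in range(n_fus):
        if len(chroms) < 2:
            raise _ConfigError("not enough chromosomes to fuse")
        for _try in range(200):
            i = int(rng.integers(len(chroms)))
            j = int(rng.integers(len(chroms) - 1))
            if j >= i:
                j += 1
            a = _flip(chroms[i]) if rng.integers(2) else list(chroms[i])
            b = _flip(chroms[j]) if rng.integers(2) else list(chroms[j])
            junction = frozenset((a[-1][0], b[0][0]))
            if junction not in used:
                break
        else:
            raise _ConfigError("could not place fusion without breakpoint reuse")
        used.add(junction)
        events.append(dict(lineage=lineage, type="fusion", left=a[-1][0], right=b[0][0]))
        for k in sorted((i, j), reverse=True):
            del chroms[k]
        chroms.append(a + b)

    for _ in range(n_inv):
        cands = [ci for ci, g in enumerate(chroms) if len(g) >= 4]
        if not cands:
            raise _ConfigError("no chromosome long enough for an internal inversion")
        for _try in range(200):
            ci = cands[int(rng.integers(len(cands)))]
            genes = chroms[ci]
            max_len = min(len(genes) // 2, len(genes) - 2)
            length = int(rng.integers(2, max_len + 1))
            s = int(rng.integers(1, len(genes) - length))
            left = frozenset((genes[s - 1][0], genes[s][0]))
            right = frozenset((genes[s + length - 1][0], genes[s + length][0]))
            if left not in used and right not in used and left != right:
                break
        else:
            raise _ConfigError("could not place inversion without breakpoint reuse")
        used.update((left, right))
        chroms[ci] = genes[:s] + _flip(genes[s : s + length]) + genes[s + length :]
        events.append(dict(lineage=lineage, type="inversion",
                           left=genes[s][0], right=genes[s + length - 1][0]))

    for _ in range(n_tra):
        if len(chroms) < 2:
            raise _ConfigError("not enough chromosomes for a translocation")
        for _try in range(200):
            gaps = _eligible_gaps(chroms, margin, used)
            if not gaps:
                raise _ConfigError("no eligible translocation breakpoints")
            ci, p = gaps[int(rng.integers(len(gaps)))]
            others = [g for g in gaps if g[0] != ci]
            if not others:
                raise _ConfigError("no eligible translocation breakpoints")
            cj, q = others[int(rng.integers(len(others)))]
            a, b = chroms[ci], chroms[cj]
            j1 = frozenset((a[p - 1][0], b[q][0]))
            j2 = frozenset((b[q - 1][0], a[p][0]))
            if j1 not in used and j2 not in used and j1 != j2:
                break
        else:
            raise _ConfigError("could not place translocation without breakpoint reuse")
        used.update((frozenset((a[p - 1][0], a[p][0])), frozenset((b[q - 1][0], b[q][0])), j1, j2))
        chroms[ci], chroms[cj] = a[:p] + b[q:], b[:q] + a[p:]
        events.append(dict(lineage=lineage, type="translocation",
                           left=a[p - 1][0], right=b[q][0]))

    return chroms, events


def _to_annotation(species, chroms) -> GenomeAnnotation:
    """Convert chromosome lists to an annotation; bp coords encode rank order."""
    rows = []
    for ci, genes in enumerate(chroms):
        name = f"chr{ci + 1:02d}"
        for idx, (gid, strand) in enumerate(genes):
            start = (idx + 1) * 100
            rows.append(dict(gene_id=gid, chrom=name, start=start, end=start + 50, strand=strand))
    return GenomeAnnotation.from_genes(species, rows)


# ---------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------

def _ancestor_chroms(config):
    return [
        [(f"g{c + 1:02d}_{i:04d}", "+") for i in range(config.genes_per_chrom)]
        for c in range(config.n_chrom)
    ]


def simulate_ancestor(config: SimulationConfig) -> GenomeAnnotation:
    """The pre-triplication diploid: n_chrom x genes_per_chrom genes."""
    return _to_annotation("ancestor", _ancestor_chroms(config))


def _ann_to_chroms(ann: GenomeAnnotation):
    return [
        [(g, ann.df.loc[ann.df.gene_id == g, "strand"].iloc[0]) for g in ann.genes_on(c)]
        for c in ann.chromosomes
    ]


def apply_wgt(ancestor: GenomeAnnotation):
    """Two-step whole-genome triplication: duplicate (a, b) then add c.

    The two steps are simulated without divergence in between; no
    tetraploid-intermediate-specific loss is modelled.
    """
    truth = SimulationTruth()
    chroms = []
    strands = {g: st for g, st in zip(ancestor.df.gene_id, ancestor.df.strand)}
    for sub in SLOTS:
        for c in ancestor.chromosomes:
            copy = []
            for gid in ancestor.genes_on(c):
                new = f"{gid}.{sub}"
                truth.subgenome_of[new] = sub
                truth.ancestral_gene_of[new] = gid
                copy.append((new, strands[gid]))
            chroms.append(copy)
    return _to_annotation(ancestor.species, chroms), truth


def _window_probs(config, rng, eff_mean):
    """Per (ancestral chrom, window) retention-probability triple.

    A symmetric Dirichlet allocates a fixed retention budget of
    3*eff_mean across the three subgenome copies, which yields the
    reciprocal local pattern while keeping the global marginal at
    eff_mean per copy.
    """
    n_win = math.ceil(config.genes_per_chrom / config.window_bias_block)
    probs = {}
    for c in range(config.n_chrom):
        for w in range(n_win):
            d = rng.dirichlet([config.bias_concentration] * 3)
            probs[(c, w)] = _fill_budget(d * 3.0 * eff_mean)
    return probs


def _fill_budget(p: np.ndarray) -> np.ndarray:
    """Cap probabilities at 1, redistributing the excess proportionally
    to the remaining headroom.  Keeps the triple exchangeable and its
    sum exact, so the per-copy marginal mean is preserved."""
    p = np.asarray(p, dtype=float).copy()
    for _ in range(4):
        over = p > 1.0
        if not over.any():
            return p
        excess = float((p[over] - 1.0).sum())
        p[over] = 1.0
        room = 1.0 - p[~over]
        total_room = float(room.sum())
        if total_room <= excess + 1e-12:
            p[:] = np.minimum(p + 1.0, 1.0)
            return p
        p[~over] = p[~over] + excess * room / total_room
    return np.minimum(p, 1.0)


def _effective_mean(config):
    if config.rtg_fraction >= 1.0:
        return 0.0
    eff = (config.retention_mean - config.rtg_fraction) / (1.0 - config.rtg_fraction)
    return float(np.clip(eff, 0.0, 1.0))


def _fractionate(chroms, config, rng, rtg_set, anc_pos, sub_of, anc_of):
    """Bernoulli survival with window-level Dirichlet probabilities."""
    eff = _effective_mean(config)
    probs = _window_probs(config, rng, eff)
    out, deleted = [], 0
    for genes in chroms:
        kept = []
        for gid, strand in genes:
            anc = anc_of[gid]
            if anc in rtg_set:
                kept.append((gid, strand))
                continue
            c, r = anc_pos[anc]
            p = probs[(c, r // config.window_bias_block)][SLOTS.index(sub_of[gid])]
            if rng.random() < p:
                kept.append((gid, strand))
            else:
                deleted += 1
        if kept:
            out.append(kept)
        else:
            log.warning("chromosome emptied by fractionation; dropped")
    return out, deleted


def apply_fractionation(polyploid: GenomeAnnotation, truth: SimulationTruth,
                        config: SimulationConfig, rng) -> GenomeAnnotation:
    strands = {g: st for g, st in zip(polyploid.df.gene_id, polyploid.df.strand)}
    chroms = [[(g, strands[g]) for g in polyploid.genes_on(c)] for c in polyploid.chromosomes]
    anc_pos = _anc_positions(config)
    out, deleted = _fractionate(chroms, config, rng, truth.rtg_set, anc_pos,
                                truth.subgenome_of, truth.ancestral_gene_of)
    truth.deletions[polyploid.species] = deleted
    return _to_annotation(polyploid.species, out)


def _anc_positions(config):
    return {
        f"g{c + 1:02d}_{i:04d}": (c, i)
        for c in range(config.n_chrom)
        for i in range(config.genes_per_chrom)
    }


def apply_rearrangements(genome: GenomeAnnotation, config: SimulationConfig, rng,
                         counts=None, lineage=None):
    """Apply fission/fusion/inversion/translocation events; return (genome, log)."""
    counts = counts or (config.n_fissions, config.n_fusions,
                        config.n_inversions, config.n_translocations)
    strands = {g: st for g, st in zip(genome.df.gene_id, genome.df.strand)}
    chroms = [[(g, strands[g]) for g in genome.genes_on(c)] for c in genome.chromosomes]
    chroms, events = _apply_events(chroms, counts, rng,
                                   lineage or genome.species,
                                   config.min_fission_fragment)
    return _to_annotation(genome.species, chroms), events


def simulate_clade(config: SimulationConfig) -> SimulationResult:
    """Full study design: outgroup + descendants of the triplicated ancestor."""
    rng = np.random.default_rng(config.seed)
    truth = SimulationTruth()
    anc_chroms = _ancestor_chroms(config)
    anc_pos = _anc_positions(config)
    anc_ids = sorted(anc_pos)

    n_rtg = int(round(config.rtg_fraction * len(anc_ids)))
    truth.rtg_set = set(rng.choice(anc_ids, size=n_rtg, replace=False)) if n_rtg else set()

    # outgroup: no triplication, optional outgroup-specific rearrangements
    og_chroms = [[(f"og.{g}", s) for g, s in genes] for genes in anc_chroms]
    for genes in og_chroms:
        for gid, _ in genes:
            truth.ancestral_gene_of[gid] = gid[3:]
    og_counts = (config.outgroup_fissions, config.outgroup_fusions,
                 config.outgroup_inversions, config.outgroup_translocations)
    og_chroms, _ = _apply_events(og_chroms, og_counts, rng, "og",
                                 config.min_fission_fragment, log_out=truth.event_log)
    og = _to_annotation("og", og_chroms)

    # truth homoeologous sets: halves of the final outgroup chromosomes
    # (the study's regions are defined on the outgroup gene order)
    for ci, chrom in enumerate(og.chromosomes):
        genes = og.genes_on(chrom)
        half = len(genes) / 2.0
        for r, g in enumerate(genes):
            truth.homoeologous_set_of[truth.ancestral_gene_of[g]] = (
                2 * ci + 1 if r < half else 2 * ci + 2
            )

    genomes = {"og": og}
    n_desc = config.n_species - 1
    for k in range(1, n_desc + 1):
        sp = f"sp{k}"
        chroms = []
        sub_of, anc_of = {}, {}
        for sub in SLOTS:
            for genes in anc_chroms:
                copy = []
                for gid, strand in genes:
                    new = f"{sp}.{gid}.{sub}"
                    sub_of[new] = sub
                    anc_of[new] = gid
                    copy.append((new, strand))
                chroms.append(copy)
        chroms, deleted = _fractionate(chroms, config, rng, truth.rtg_set,
                                       anc_pos, sub_of, anc_of)
        truth.deletions[sp] = deleted
        survivors = {g for genes in chroms for g, _ in genes}
        truth.subgenome_of.update({g: sub_of[g] for g in survivors})
        truth.ancestral_gene_of.update({g: anc_of[g] for g in survivors})
        counts = (config.n_fissions, config.n_fusions,
                  config.n_inversions, config.n_translocations)
        chroms, _ = _apply_events(chroms, counts, rng, sp,
                                  config.min_fission_fragment, log_out=truth.event_log)
        genomes[sp] = _to_annotation(sp, chroms)

    anchors = _truth_anchors(genomes, truth)
    expression = _expression(genomes, truth, config, rng, species="sp1")
    return SimulationResult(config, genomes, truth, anchors, expression, "sp1")


def _truth_anchors(genomes, truth):
    """Ortholog anchor lists: outgroup->descendant and descendant<->descendant."""
    species = list(genomes)
    by_anc = {}
    for sp in species:
        ann = genomes[sp]
        for g in ann.df.gene_id:
            anc = truth.ancestral_gene_of[g]
            sub = truth.subgenome_of.get(g)  # None for outgroup
            by_anc.setdefault(anc, []).append((sp, g, sub))
    anchors = {}
    descendants = [s for s in species if s != "og"]
    for sp in descendants:
        anchors[("og", sp)] = []
    for i, a in enumerate(descendants):
        for b in descendants[i + 1 :]:
            anchors[(a, b)] = []
    for anc in sorted(by_anc):
        entries = by_anc[anc]
        og_genes = [g for sp, g, _ in entries if sp == "og"]
        for sp, g, sub in entries:
            if sp == "og":
                continue
            for ogg in og_genes:
                anchors[("og", sp)].append(AnchorPair(ogg, g))
        for i, a in enumerate(descendants):
            for b in descendants[i + 1 :]:
                ga = [(g, sub) for sp, g, sub in entries if sp == a]
                gb = [(g, sub) for sp, g, sub in entries if sp == b]
                for g1, s1 in ga:
                    for g2, s2 in gb:
                        if s1 == s2:  # orthologs share the subgenome
                            anchors[(a, b)].append(AnchorPair(g1, g2))
    return anchors


def _expression(genomes, truth, config, rng, species="sp1"):
    """TPM-like matrix: planted triplicates tissue-partitioned, controls flat."""
    ann = genomes[species]
    tissues = [f"tissue{t + 1:02d}" for t in range(config.n_tissues)]
    genes = list(ann.df.gene_id)
    values = np.empty((len(genes), len(tissues)))
    pref_of = {}
    for anc in sorted(truth.rtg_set):
        picks = rng.choice(config.n_tissues, size=3, replace=False)
        for sub, t in zip(SLOTS, picks):
            pref_of[f"{species}.{anc}.{sub}"] = int(t)
    for i, g in enumerate(genes):
        if g in pref_of:
            base = rng.lognormal(mean=np.log(2.0), sigma=0.25, size=len(tissues))
            base[pref_of[g]] = rng.lognormal(mean=np.log(50.0), sigma=0.25)
            values[i] = base
        else:
            values[i] = rng.lognormal(mean=np.log(10.0), sigma=0.25, size=len(tissues))
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=tissues)


# ---------------------------------------------------------------------
# codon-sequence helper for substitution-rate analyses
# ---------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


def random_codon_alignment(n_codons: int, max_diffs: int, rng):
    """A random stop-free codon sequence and a mutated partner.

    Substitutions are placed at random positions but rejected if they
    create an internal stop codon; at most ``max_diffs`` nucleotide
    differences are introduced.
    """
    while True:
        codons = ["".join(rng.choice(list(_BASES), 3)) for _ in range(n_codons)]
        if not any(c in _STOPS for c in codons):
            break
    seq_a = "".join(codons)
    seq_b = list(seq_a)
    n_mut = int(rng.integers(0, max_diffs + 1))
    placed = 0
    attempts = 0
    while placed < n_mut and attempts < 100 * (n_mut + 1):
        attempts += 1
        pos = int(rng.integers(len(seq_b)))
        old = seq_b[pos]
        new = _BASES[int(rng.integers(4))]
        if new == old:
            continue
        seq_b[pos] = new
        codon = "".join(seq_b[3 * (pos // 3) : 3 * (pos // 3) + 3])
        if codon in _STOPS:
            seq_b[pos] = old
            continue
        placed += 1
    return seq_a, "".join(seq_b)


# ---------------------------------------------------------------------
# on-disk export
# ---------------------------------------------------------------------

def write_clade(result: SimulationResult, outdir) -> list:
    """Write per-species BEDs, anchor TSVs, truth tables and expression."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _mark(path):
        written.append(Path(path))
        return path

    for sp, ann in sorted(result.genomes.items()):
        write_bed(ann, _mark(outdir / f"{sp}.bed"))
    for (a, b), pairs in sorted(result.anchors.items()):
        write_anchors(pairs, _mark(outdir / f"anchors_{a}_{b}.tsv"))
    t = result.truth
    genes = sorted(t.ancestral_gene_of)
    write_tsv(
        pd.DataFrame(
            dict(
                gene_id=genes,
                ancestral_gene=[t.ancestral_gene_of[g] for g in genes],
                subgenome=[t.subgenome_of.get(g, ".") for g in genes],
            )
        ),
        _mark(outdir / "truth_genes.tsv"),
    )
    anc = sorted(t.homoeologous_set_of)
    write_tsv(
        pd.DataFrame(
            dict(
                ancestral_gene=anc,
                homoeologous_set=[t.homoeologous_set_of[a] for a in anc],
                rtg=[a in t.rtg_set for a in anc],
            )
        ),
        _mark(outdir / "truth_sets.tsv"),
    )
    write_tsv(pd.DataFrame(t.event_log), _mark(outdir / "truth_events.tsv"))
    expr = result.expression.reset_index()
    write_tsv(expr, _mark(outdir / "expression.tsv"))
    result.config.to_json(_mark(outdir / "sim_config.json"))
    return written
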