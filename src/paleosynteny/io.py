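"""Annotation / anchor readers and writers, and the gene-rank coordinate convention.

Every algorithm in this package runs in *gene-rank* space: on each
chromosome genes are sorted by (start, end, gene_id) and indexed
0..n-1.  Base-pair coordinates are carried through unchanged but never
enter any computation — block sizes, gaps and windows are all counted
in genes.

BED input is 0-based half-open, GFF3 is 1-based closed; both are
normalized to ranks on load, which removes dialect ambiguity from the
core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd
from gffutils.iterators import DataIterator

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "AnchorPair",
    "GeneModel",
    "GenomeAnnotation",
    "read_gff3",
    "read_bed",
    "read_anchors",
    "write_bed",
    "write_anchors",
    "write_tsv",
]


class FormatError(ValueError):
    """A file could not be parsed in its declared format."""


class ValidationError(ValueError):
    """Parsed content violates an invariant (duplicate IDs, empty intervals...)."""


class AnchorPair(NamedTuple):
    """A homology anchor with fixed (query, target) polarity."""

    gene_a: str
    gene_b: str
    score: float = 1.0


class GeneModel(NamedTuple):
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    rank: int
    species: str = ""


@dataclass
class GenomeAnnotation:
    """Ordered gene models for one genome, rank-indexed per chromosome.

    ``df`` holds columns gene_id/chrom/start/end/strand/rank sorted by
    (chrom, rank); ranks are 0-based, dense and unique per chromosome.
    """

    species: str
    df: pd.DataFrame
    chromosomes: list = field(default_factory=list)

    def __post_init__(self):
        self._loc = {
            g: (c, r)
            for g, c, r in zip(self.df["gene_id"], self.df["chrom"], self.df["rank"])
        }
        self._by_chrom = {
            c: list(sub["gene_id"]) for c, sub in self.df.groupby("chrom", sort=False)
        }

    # -- construction -------------------------------------------------
    @classmethod
    def from_genes(cls, species: str, records: Iterable[Mapping]) -> "GenomeAnnotation":
        """Build an annotation from raw gene records, assigning ranks.

        Genes are sorted by (start, end, gene_id) within each chromosome;
        the (end, gene_id) tie-break makes rank assignment deterministic.
        """
        rows = list(records)
        cols = ["gene_id", "chrom", "start", "end", "strand"]
        if not rows:
            df = pd.DataFrame(columns=cols + ["rank"])
            return cls(species, df, [])
        df = pd.DataFrame(rows)[cols]
        dup = df["gene_id"].duplicated()
        if dup.any():
            raise ValidationError(
                f"duplicate gene_id(s): {sorted(df.loc[dup, 'gene_id'].unique())[:5]}"
            )
        bad = df["start"] >= df["end"]
        if bad.any():
            g = df.loc[bad, "gene_id"].iloc[0]
            raise ValidationError(f"empty or inverted interval for gene {g!r}")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValidationError("strand must be '+' or '-'")
        chroms = sorted(df["chrom"].unique())
        df["chrom"] = pd.Categorical(df["chrom"], categories=chroms, ordered=True)
        df = df.sort_values(["chrom", "start", "end", "gene_id"]).reset_index(drop=True)
        df["rank"] = df.groupby("chrom", observed=True).cumcount()
        df["chrom"] = df["chrom"].astype(str)
        return cls(species, df, chroms)

    # -- queries ------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.df)

    def genes_on(self, chrom: str) -> list:
        """Gene ids on ``chrom`` in rank order."""
        return self._by_chrom.get(chrom, [])

    def n_genes_on(self, chrom: str) -> int:
        return len(self._by_chrom.get(chrom, []))

    def rank_of(self, gene_id: str) -> int:
        return self._loc[gene_id][1]

    def chrom_of(self, gene_id: str) -> str:
        return self._loc[gene_id][0]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._loc

    def gene_at(self, chrom: str, rank: int) -> str:
        return self._by_chrom[chrom][rank]

    def key_frame(self) -> pd.DataFrame:
        """The identity-defining columns, for round-trip comparisons."""
        return (
            self.df[["gene_id", "chrom", "rank", "strand"]]
            .sort_values("gene_id")
            .reset_index(drop=True)
        )


# ---------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------

def read_gff3(
    path,
    species: str | None = None,
    feature_type: str = "gene",
    id_attr: str = "ID",
) -> GenomeAnnotation:
    """Read gene features from a GFF3 file (1-based closed coordinates).

    ``feature_type`` and ``id_attr`` are knobs because annotation sets
    disagree on whether gene models live on gene or mRNA features.
    """
    path = Path(path)
    species = species or path.stem
    rows = []
    try:
        for n, feat in enumerate(DataIterator(str(path)), start=1):
            if feat.featuretype != feature_type:
                continue
            ids = feat.attributes.get(id_attr)
            if not ids:
                raise FormatError(
                    f"{path}: feature near record {n} lacks attribute {id_attr!r}"
                )
            strand = feat.strand if feat.strand in ("+", "-") else "+"
            rows.append(
                dict(
                    gene_id=ids[0],
                    chrom=feat.seqid,
                    start=int(feat.start),
                    end=int(feat.end),
                    strand=strand,
                )
            )
    except (ValidationError, FormatError):
        raise
    except Exception as exc:  # gffutils raises plain ValueError/AttributeError
        raise FormatError(f"{path}: malformed GFF3 ({exc})") from exc
    return GenomeAnnotation.from_genes(species, rows)


def read_bed(path, species: str | None = None) -> GenomeAnnotation:
    """Read a 4+ column BED (0-based half-open); missing strand defaults '+'."""
    path = Path(path)
    species = species or path.stem
    rows = []
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{n}: expected >=4 BED columns")
            chrom, start, end, name = parts[:4]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{n}: non-integer coordinate") from exc
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "+"
            if start_i >= end_i:
                raise ValidationError(f"{path}:{n}: empty interval for {name!r}")
            rows.append(
                dict(gene_id=name, chrom=chrom, start=start_i, end=end_i, strand=strand)
            )
    return GenomeAnnotation.from_genes(species, rows)


def read_anchors(path, query: GenomeAnnotation, target: GenomeAnnotation) -> list:
    """Read a TSV of anchor pairs ``gene_a<TAB>gene_b[<TAB>score]``.

    Anchors referencing genes absent from either annotation are dropped
    with a logged count.
    """
    anchors, dropped = [], 0
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{n}: expected >=2 tab-separated columns")
            a, b = parts[0], parts[1]
            try:
                score = float(parts[2]) if len(parts) > 2 and parts[2] else 1.0
            except ValueError as exc:
                raise FormatError(f"{path}:{n}: bad score {parts[2]!r}") from exc
            if a not in query or b not in target:
                dropped += 1
                continue
            anchors.append(AnchorPair(a, b, score))
    if dropped:
        log.warning("%s: dropped %d anchors with unknown genes", path, dropped)
    return anchors


# ---------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------

def write_bed(ann: GenomeAnnotation, path) -> None:
    """Write a BED6 whose read-back reproduces (gene_id, chrom, rank, strand)."""
    with open(path, "w") as fh:
        fh.write(f"# species={ann.species}\n")
        for row in ann.df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}\t0\t{row.strand}\n"
            )


def write_anchors(anchors: Iterable[AnchorPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_a\tgene_b\tscore\n")
        for a in anchors:
            fh.write(f"{a.gene_a}\t{a.gene_b}\t{a.score:g}\n")


def write_tsv(df: pd.DataFrame, path, comment: str | None = None) -> None:
    """Deterministic TSV output with a '#'-prefixed header line."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("# " + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6g", lineterminator="\n")


def read_tsv(path, columns=None) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv` (header in the last '#' line)."""
    header = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# "):
                header = line[2:].rstrip("\n").split("\t")
            else:
                break
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if header and len(header) == df.shape[1]:
        df.columns = header
    elif columns:
        df.columns = columns
    return df
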