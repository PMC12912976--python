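"""End-to-end orchestration: simulate/load -> chain -> depth -> clusters ->
rearrangements -> AGB build -> AGB map -> fractionation -> RTGs -> manifest.

Stages communicate through on-disk TSV/BED/JSON artifacts so each one
is independently inspectable and replaceable; the manifest records
parameters, seeds and per-output SHA-256 checksums and is byte-stable
across reruns of the same configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import __version__
from .agb import (assign_homoeologs, build_model_genome, define_regions,
                  lift_anchors, map_to_agbs, merge_level2, order_level4)
from .fractionation import presence_from_labels, reciprocity, retention_windows
from .io import (AnchorPair, GenomeAnnotation, ValidationError, read_anchors,
                 read_bed, write_bed, write_tsv)
from .karyotype import count_fissions_fusions, paint_genome
from .rtg import build_copy_matrix, call_rtgs, rtg_hotspots, tau_contrast
from .simulate import SimulationConfig, simulate_clade, write_clade
from .synteny import (ChainParams, blocks_frame, build_clusters, chain_anchors,
                      phylogenomic_profile, shared_cluster_counts,
                      syntenic_depth, syntenic_gene_pairs)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    seed: int = 0
    simulate: dict | None = None        # SimulationConfig fields, or None
    inputs: dict | None = None          # {'bed': {species: path}, 'anchors': {...}, 'expression': path}
    outgroup: str = "og"
    ingroup: str = "sp1"
    block_size: int = 5
    gap_size: int = 5
    min_species: int = 2
    ploidy: int = 3
    min_segment: int = 3
    adjacency_tol: int = 5
    merge_min_size: int = 3
    merge_tol: int = 15
    n_regions: int | str = 16
    window: int = 100
    step: int = 50
    species_fraction: float = 0.8
    hotspot_window: int = 50
    hotspot_permutations: int = 1000
    clades: dict = field(default_factory=dict)   # species -> clade (optional)

    @classmethod
    def from_json(cls, path_or_dict) -> "RunConfig":
        if isinstance(path_or_dict, (str, Path)):
            with open(path_or_dict) as fh:
                data = json.load(fh)
        else:
            data = dict(path_or_dict)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown run config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.simulate is not None:
            sim = dict(cfg.simulate)
            sim.setdefault("seed", cfg.seed)
            cfg.simulate = asdict(SimulationConfig.from_json(sim))
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _transpose(anchors):
    return [AnchorPair(a.gene_b, a.gene_a, a.score) for a in anchors]


def _load_inputs(cfg: RunConfig):
    if not cfg.inputs or "bed" not in cfg.inputs:
        raise ValidationError("simulate disabled and no 'inputs.bed' provided")
    genomes = {sp: read_bed(path, species=sp) for sp, path in sorted(cfg.inputs["bed"].items())}
    if cfg.outgroup not in genomes:
        raise ValidationError(f"outgroup {cfg.outgroup!r} missing from inputs.bed")
    anchors = {}
    for key, path in sorted(cfg.inputs.get("anchors", {}).items()):
        a, b = key.split(":")
        if a not in genomes or b not in genomes:
            raise ValidationError(f"anchor file {key!r} references unknown species")
        anchors[(a, b)] = read_anchors(path, genomes[a], genomes[b])
    expression = None
    if cfg.inputs.get("expression"):
        expression = pd.read_csv(cfg.inputs["expression"], sep="\t", comment="#",
                                 header=None)
        expression = expression.set_index(0)
        expression.index.name = "gene_id"
    return genomes, anchors, expression


def _pair(anchors, a, b):
    """Anchors with gene_a in species a, regardless of stored key order."""
    if (a, b) in anchors:
        return anchors[(a, b)]
    if (b, a) in anchors:
        return _transpose(anchors[(b, a)])
    return []


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = dict(tool="paleosynteny", version=__version__,
                    config=json.loads(json.dumps(asdict(cfg), default=str)),
                    stages=[])
    outputs_index = {}

    def record(stage, status, outputs=(), **extra):
        entry = dict(stage=stage, status=status,
                     outputs={str(Path(p).relative_to(outdir)): _sha256(Path(p))
                              for p in outputs}, **extra)
        manifest["stages"].append(entry)
        outputs_index.update(entry["outputs"])

    try:
        # -- simulate / load ------------------------------------------
        if cfg.simulate is not None:
            sim_cfg = SimulationConfig.from_json(cfg.simulate)
            result = simulate_clade(sim_cfg)
            written = write_clade(result, outdir / "sim")
            genomes, anchors, expression = result.genomes, result.anchors, result.expression
            record("simulate", "ok", written, n_species=len(genomes))
        else:
            genomes, anchors, expression = _load_inputs(cfg)
            record("load", "ok", [], n_species=len(genomes))

        og = cfg.outgroup
        ingroup = cfg.ingroup
        descendants = sorted(s for s in genomes if s != og)
        if ingroup not in genomes:
            raise ValidationError(f"ingroup {ingroup!r} not among genomes")
        params = ChainParams(cfg.block_size, cfg.gap_size)

        # -- chain ----------------------------------------------------
        bdir = outdir / "blocks"
        bdir.mkdir(exist_ok=True)
        blocks_og_q, blocks_sp_q, files = {}, {}, []
        for sp in descendants:
            pa = _pair(anchors, og, sp)
            blocks_og_q[sp] = chain_anchors(pa, genomes[og], genomes[sp], params)
            blocks_sp_q[sp] = chain_anchors(_transpose(pa), genomes[sp], genomes[og], params)
            f = bdir / f"{og}_vs_{sp}.tsv"
            write_tsv(blocks_frame(blocks_og_q[sp]), f)
            files.append(f)
        desc_pair_blocks = {}
        for i, a in enumerate(descendants):
            for b in descendants[i + 1 :]:
                pa = _pair(anchors, a, b)
                if pa:
                    desc_pair_blocks[(a, b)] = chain_anchors(pa, genomes[a], genomes[b], params)
        record("chain", "ok", files,
               n_blocks={sp: len(blocks_og_q[sp]) for sp in descendants})

        # -- depth ----------------------------------------------------
        ddir = outdir / "depth"
        ddir.mkdir(exist_ok=True)
        files, modes = [], {}
        for sp in descendants:
            depth = syntenic_depth(blocks_og_q[sp], genomes[og])
            modes[sp] = int(depth.value_counts().idxmax())
            f = ddir / f"{og}_depth_vs_{sp}.tsv"
            write_tsv(depth.rename_axis("gene_id").reset_index(), f)
            files.append(f)
        record("depth", "ok", files, modal_depth=modes)

        # -- microsynteny clusters ------------------------------------
        cdir = outdir / "clusters"
        cdir.mkdir(exist_ok=True)
        pairs = []
        for sp in descendants:
            pairs += syntenic_gene_pairs(blocks_og_q[sp])
        for blk in desc_pair_blocks.values():
            pairs += syntenic_gene_pairs(blk)
        species_of = {g: sp for sp, ann in genomes.items() for g in ann.df.gene_id}
        clusters = build_clusters(pairs, species_of, cfg.min_species)
        cl_rows = [dict(cluster_id=c.cluster_id,
                        n_species=len(c.copy_number),
                        n_members=len(c.members),
                        members=";".join(sorted(g for _, g in c.members)))
                   for c in clusters]
        f1 = cdir / "clusters.tsv"
        write_tsv(pd.DataFrame(cl_rows, columns=["cluster_id", "n_species",
                                                 "n_members", "members"]), f1)
        files = [f1]
        if clusters:
            profile, order = phylogenomic_profile(clusters, [og] + descendants)
            f2 = cdir / "profile.tsv"
            write_tsv(profile.reset_index(names="species"), f2)
            files.append(f2)
        if cfg.clades:
            counts = shared_cluster_counts(clusters, cfg.clades)
            f3 = cdir / "shared_counts.tsv"
            write_tsv(pd.DataFrame(
                [dict(clades="+".join(k), count=v) for k, v in sorted(counts.items())],
                columns=["clades", "count"]), f3)
            files.append(f3)
        record("clusters", "ok", files, n_clusters=len(clusters))

        # -- rearrangements -------------------------------------------
        rdir = outdir / "rearrange"
        rdir.mkdir(exist_ok=True)
        rows = []
        for sp in descendants:
            painting = paint_genome(blocks_sp_q[sp], genomes[sp])
            counts = count_fissions_fusions(painting, genomes[og], cfg.ploidy,
                                            cfg.min_segment, cfg.adjacency_tol)
            rows.append(dict(species=sp, fissions=counts.fissions,
                             fusions=counts.fusions,
                             painted_chroms=counts.c_descendant,
                             ref_chroms=counts.c_reference))
        f = rdir / "fission_fusion.tsv"
        write_tsv(pd.DataFrame(rows, columns=["species", "fissions", "fusions",
                                              "painted_chroms", "ref_chroms"]), f)
        record("rearrange", "ok", [f])

        # -- AGB build ------------------------------------------------
        adir = outdir / "agb"
        adir.mkdir(exist_ok=True)
        level2 = merge_level2(blocks_sp_q[ingroup], genomes[ingroup], genomes[og],
                              cfg.merge_min_size, cfg.merge_tol)
        regions = define_regions(genomes[og], level2, cfg.n_regions)
        agb_sets, conflicts = assign_homoeologs(level2, regions, genomes[ingroup])
        agb_sets = order_level4(agb_sets, genomes[og])
        model = build_model_genome(agb_sets, genomes[ingroup])
        fb = adir / "model_genome.bed"
        write_bed(model.annotation, fb)
        fm = adir / "model_manifest.json"
        with open(fm, "w") as fh:
            json.dump(dict(
                n_sets=len(agb_sets), n_agbs=model.n_agbs,
                slot_totals=model.slot_totals,
                regions=[dict(region_id=r.region_id, chrom=r.chrom,
                              start=r.start, end=r.end) for r in regions],
                provenance={k: model.provenance[k] for k in sorted(model.provenance)},
            ), fh, indent=1, sort_keys=True)
            fh.write("\n")
        fc = adir / "conflicts.tsv"
        write_tsv(conflicts, fc)
        record("agb_build", "ok", [fb, fm, fc], n_level2=len(level2),
               n_agbs=model.n_agbs, slot_totals=model.slot_totals)

        # -- AGB map --------------------------------------------------
        mdir = outdir / "map"
        mdir.mkdir(exist_ok=True)
        labels_by_species, files = {}, []
        for sp in descendants:
            if sp == ingroup:
                placed = sorted(model.source_of)
                sp_anchors = [AnchorPair(g, g) for g in placed]
            else:
                sp_anchors = _pair(anchors, sp, ingroup)
            lifted = lift_anchors(sp_anchors, model)
            blk = chain_anchors(lifted, genomes[sp], model.annotation, params)
            labels = map_to_agbs(genomes[sp], blk, model)
            labels_by_species[sp] = labels
            f = mdir / f"{sp}_agb_painting.tsv"
            write_tsv(labels.reset_index(), f)
            files.append(f)
        record("agb_map", "ok", files,
               labeled={sp: len(labels_by_species[sp]) for sp in descendants})

        # -- fractionation --------------------------------------------
        fdir = outdir / "fractionation"
        fdir.mkdir(exist_ok=True)
        presence = {}
        files = []
        profiles = {}
        for sp in descendants:
            slot_of = labels_by_species[sp]["slot"].dropna().to_dict()
            pres = presence_from_labels(genomes[og], _pair(anchors, og, sp), slot_of)
            presence[sp] = pres
            profiles[sp] = retention_windows(genomes[og], pres, cfg.window, cfg.step)
            f = fdir / f"retention_{sp}.tsv"
            write_tsv(profiles[sp].windows, f)
            files.append(f)
        rec = reciprocity(profiles[ingroup])
        f = fdir / "reciprocity.tsv"
        write_tsv(rec, f)
        files.append(f)
        record("fractionation", "ok", files,
               mean_combined={sp: round(profiles[sp].mean_combined(), 4)
                              for sp in descendants},
               reciprocity_mean_r=round(rec.attrs["mean_r"], 4))

        # -- RTGs -----------------------------------------------------
        gdir = outdir / "rtg"
        gdir.mkdir(exist_ok=True)
        matrix = build_copy_matrix(presence, genomes[og])
        calls = call_rtgs(matrix, cfg.species_fraction)
        f1 = gdir / "rtg_calls.tsv"
        write_tsv(calls.reset_index(), f1)
        files = [f1]
        rtg_ref_genes = set(calls.index[calls["rtg"]])
        # put RTG flags on model coordinates via the ingroup orthologs
        ing_of_ref = {}
        for a in _pair(anchors, og, ingroup):
            ing_of_ref.setdefault(a.gene_a, []).append(a.gene_b)
        rtg_model = set()
        for g in rtg_ref_genes:
            for ing in ing_of_ref.get(g, ()):
                mg = model.source_of.get(ing)
                if mg:
                    rtg_model.add(mg)
        is_rtg = pd.Series({g: g in rtg_model for g in model.annotation.df.gene_id})
        hotspots = rtg_hotspots(is_rtg, model.annotation, cfg.hotspot_window,
                                cfg.hotspot_permutations, seed=cfg.seed)
        f2 = gdir / "hotspots.tsv"
        write_tsv(hotspots, f2)
        files.append(f2)
        extra = dict(n_rtg=int(calls["rtg"].sum()),
                     n_paleoparalogs=3 * int(calls["rtg"].sum()),
                     n_hotspots=int(hotspots["hotspot"].sum()))
        if expression is not None and len(expression):
            ing_rtg = [g for ref in rtg_ref_genes for g in ing_of_ref.get(ref, ())]
            single_refs = calls.index[(calls["copies"] == len(descendants))]
            single = [g for ref in single_refs for g in ing_of_ref.get(ref, ())]
            ing_genes = set(genomes[ingroup].df.gene_id)
            ing_rtg = [g for g in ing_rtg if g in ing_genes and g in expression.index]
            single = [g for g in single if g in ing_genes and g in expression.index]
            if ing_rtg and single:
                contrast = tau_contrast(ing_rtg, single, expression)
                f3 = gdir / "tau.tsv"
                write_tsv(pd.concat([
                    pd.DataFrame(dict(gene_id=contrast.tau_a.index,
                                      group="rtg", tau=contrast.tau_a.values)),
                    pd.DataFrame(dict(gene_id=contrast.tau_b.index,
                                      group="single_copy", tau=contrast.tau_b.values)),
                ]), f3)
                files.append(f3)
                extra.update(tau_p=float(contrast.p_value),
                             tau_rtg_median=float(contrast.tau_a.median()),
                             tau_single_median=float(contrast.tau_b.median()))
        record("rtg", "ok", files, **extra)

    except Exception as exc:
        record("failed", f"error: {type(exc).__name__}: {exc}")
        _write_manifest(manifest, outdir)
        raise

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest, outdir: Path):
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
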