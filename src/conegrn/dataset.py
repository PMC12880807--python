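"""On-disk layout for a two-species multiome dataset.

Everything is plain text: MatrixMarket + name files for the count
matrices, BED for peaks and histone peak calls, bedGraph for insertion
and histone signal, FASTA for peak sequences, TSV for cell annotations,
gene models, TF-motif assignments and orthology, a JASPAR-style file for
PWMs, YAML for the config and JSON for the planted truth.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .errors import PipelineError
from .genome import GenomicInterval
from .io import (
    read_bed,
    read_bed_named,
    read_bedgraph,
    read_cell_annotations,
    read_fasta,
    read_gene_models,
    read_mtx,
    read_orthology,
    read_pwm_counts,
    write_bed,
    write_bedgraph,
    write_cell_annotations,
    write_fasta,
    write_gene_models,
    write_mtx,
    write_orthology,
    write_pwm_counts,
)
from .matrix import normalize_counts
from .motifs import build_pwm
from .synthetic import (
    PlantedSite,
    SpeciesData,
    SyntheticDataset,
    SyntheticTruth,
)

MARKS = ["H3K4me3", "H3K27ac", "H3K4me1"]


def _slug(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9.]+", "_", name)


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.config.save(out / "config.yaml")
    write_orthology(ds.truth.ortholog_map, out / "orthology.tsv")
    _write_truth(ds.truth, out / "truth.json")
    # PWMs shared between species: serialize probability matrices scaled x100
    pwm_records = {
        mid: (pwm.tf_name, np.round(pwm.matrix * 100, 6)) for mid, pwm in ds.pwms.items()
    }
    write_pwm_counts(pwm_records, out / "pwms.txt")
    for sp, data in ds.species.items():
        d = out / f"species_{sp}"
        d.mkdir(exist_ok=True)
        write_mtx(data.rna, d / "rna.mtx", d / "rna.cells.txt", d / "rna.genes.txt")
        write_mtx(data.atac, d / "atac.mtx", d / "atac.cells.txt", d / "atac.peaks.txt")
        peak_ids = list(data.peaks)
        write_bed([data.peaks[p] for p in peak_ids], d / "peaks.bed", names=peak_ids)
        write_fasta({p: data.sequences[p] for p in peak_ids}, d / "peaks.fa")
        write_gene_models(data.gene_models, d / "genes.tsv")
        write_cell_annotations(
            {
                c: {"cell_type": data.cell_types[c], "time_point": data.time_points[c]}
                for c in data.rna.cell_ids
            },
            d / "cells.tsv",
        )
        with open(d / "tf_motifs.tsv", "w") as fh:
            fh.write("tf\tmotif_id\n")
            for tf, m in data.tf_motifs.items():
                fh.write(f"{tf}\t{m}\n")
        with open(d / "chroms.tsv", "w") as fh:
            fh.write("chrom\tlength\n")
            for c, ln in data.chrom_lengths.items():
                fh.write(f"{c}\t{ln}\n")
        for ct, track in data.insertion_by_celltype.items():
            write_bedgraph(track, d / f"insertion.{_slug(ct)}.bedGraph")
        for mark in MARKS:
            write_bed(data.histone_peaks.get(mark, []), d / f"{mark}.peaks.bed")
            write_bedgraph(data.histone_tracks[mark], d / f"{mark}.bedGraph")


def load_dataset(path: str | Path) -> SyntheticDataset:
    root = Path(path)
    if not root.is_dir():
        raise PipelineError("missing-dataset", f"{root} is not a directory")
    cfg = PipelineConfig.load(root / "config.yaml")
    omap = read_orthology(root / "orthology.tsv")
    pwm_counts = read_pwm_counts(root / "pwms.txt")
    pwms = {
        mid: build_pwm(counts, pseudocount=0.0, motif_id=mid, tf_name=tf)
        for mid, (tf, counts) in pwm_counts.items()
    }
    truth = _read_truth(root / "truth.json", omap) if (root / "truth.json").exists() else None
    species = {}
    for d in sorted(root.glob("species_*")):
        sp = d.name.split("_", 1)[1]
        rna = normalize_counts(
            read_mtx(d / "rna.mtx", d / "rna.cells.txt", d / "rna.genes.txt"),
            cfg.normalize_scale,
        )
        atac = normalize_counts(
            read_mtx(d / "atac.mtx", d / "atac.cells.txt", d / "atac.peaks.txt"),
            cfg.normalize_scale,
        )
        ivs, names = read_bed_named(d / "peaks.bed")
        peaks = dict(zip(names, ivs))
        sequences = read_fasta(d / "peaks.fa")
        annot = read_cell_annotations(d / "cells.tsv")
        cell_types = {c: v["cell_type"] for c, v in annot.items()}
        time_points = {c: v.get("time_point", "") for c, v in annot.items()}
        tf_motifs = {}
        for ln in (d / "tf_motifs.tsv").read_text().splitlines()[1:]:
            if ln.strip():
                tf, m = ln.split("\t")
                tf_motifs[tf] = m
        chrom_lengths = {}
        for ln in (d / "chroms.tsv").read_text().splitlines()[1:]:
            if ln.strip():
                c, ln2 = ln.split("\t")
                chrom_lengths[c] = int(ln2)
        insertion = {}
        cts = sorted({v for v in cell_types.values()})
        for ct in cts:
            insertion[ct] = read_bedgraph(d / f"insertion.{_slug(ct)}.bedGraph")
        histone_peaks, histone_tracks = {}, {}
        for mark in MARKS:
            bed = d / f"{mark}.peaks.bed"
            histone_peaks[mark] = read_bed(bed) if bed.read_text().strip() else []
            histone_tracks[mark] = read_bedgraph(d / f"{mark}.bedGraph")
        species[sp] = SpeciesData(
            name=sp,
            rna=rna,
            atac=atac,
            peaks=peaks,
            gene_models=read_gene_models(d / "genes.tsv"),
            cell_types=cell_types,
            time_points=time_points,
            tf_ids=sorted(tf_motifs),
            tf_motifs=tf_motifs,
            sequences=sequences,
            insertion_by_celltype=insertion,
            histone_peaks=histone_peaks,
            histone_tracks=histone_tracks,
            chrom_lengths=chrom_lengths,
        )
    if truth is None:
        truth = SyntheticTruth({}, {}, [], [], {}, omap)
    return SyntheticDataset(species=species, pwms=pwms, truth=truth, config=cfg)


def _write_truth(truth: SyntheticTruth, path: Path) -> None:
    payload = {
        "planted_regulons": truth.planted_regulons,
        "bound_sites": {
            sp: [
                {
                    "peak_id": s.peak_id,
                    "motif_id": s.motif_id,
                    "chrom": s.site.chrom,
                    "start": s.site.start,
                    "end": s.site.end,
                    "strand": s.strand,
                    "bound_cell_types": list(s.bound_cell_types),
                }
                for s in sites
            ]
            for sp, sites in truth.bound_sites.items()
        },
        "conserved_pairs": truth.conserved_pairs,
        "cone_tfs": truth.cone_tfs,
        "element_classes": truth.element_classes,
    }
    path.write_text(json.dumps(payload, indent=1))


def _read_truth(path: Path, omap) -> SyntheticTruth:
    raw = json.loads(path.read_text())
    bound = {
        sp: [
            PlantedSite(
                s["peak_id"],
                s["motif_id"],
                GenomicInterval(s["chrom"], s["start"], s["end"]),
                s["strand"],
                tuple(s["bound_cell_types"]),
            )
            for s in sites
        ]
        for sp, sites in raw["bound_sites"].items()
    }
    regs = {
        sp: [tuple(r) for r in rows] for sp, rows in raw["planted_regulons"].items()
    }
    return SyntheticTruth(
        planted_regulons=regs,
        bound_sites=bound,
        conserved_pairs=[tuple(p) for p in raw["conserved_pairs"]],
        cone_tfs=raw["cone_tfs"],
        element_classes=raw["element_classes"],
        ortholog_map=omap,
    )
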