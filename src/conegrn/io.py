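"""Readers and writers for the on-disk dataset formats.

Text-only formats throughout: MatrixMarket coordinate (.mtx) with sidecar
row/column name files, BED3/BED6, bedGraph, FASTA, plain TSV tables for
cell annotations / gene models / orthology, and JASPAR-style PWM count
files. Every reader has a matching writer and round-trips are exact for
the canonical dialects.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
from scipy import io as spio
from scipy import sparse

from .errors import PipelineError
from .genome import GeneModel, GenomicInterval, SignalTrack
from .matrix import CountMatrix, OrthologyMap

# ---------------------------------------------------------------- MatrixMarket


def read_mtx(path_matrix, path_rows, path_cols) -> CountMatrix:
    """Read a cells x features MatrixMarket file plus row/col name files.

    Rows are cells, columns are features. Raises ``mtx-shape`` when the
    header disagrees with the name files, ``mtx-negative`` on negative
    entries.
    """
    try:
        mat = spio.mmread(str(path_matrix))
    except Exception as exc:
        raise PipelineError("mtx-parse", f"{path_matrix}: {exc}") from exc
    mat = sparse.coo_matrix(mat)
    cells = _read_lines(path_rows)
    feats = _read_lines(path_cols)
    if mat.shape != (len(cells), len(feats)):
        raise PipelineError(
            "mtx-shape",
            f"matrix {mat.shape} vs {len(cells)} rows / {len(feats)} cols",
        )
    if mat.data.size and mat.data.min() < 0:
        raise PipelineError("mtx-negative", "negative entry in matrix file")
    dense = np.asarray(mat.todense())
    if np.allclose(dense, np.round(dense)):
        dense = np.round(dense).astype(np.int64)
    return CountMatrix(cells, feats, dense)


def write_mtx(m: CountMatrix, path_matrix, path_rows, path_cols) -> None:
    spio.mmwrite(str(path_matrix), sparse.coo_matrix(m.counts))
    _write_lines(path_rows, m.cell_ids)
    _write_lines(path_cols, m.feature_ids)


def _read_lines(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def _write_lines(path, lines) -> None:
    Path(path).write_text("".join(f"{ln}\n" for ln in lines))


# ------------------------------------------------------------------------ BED


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6; 0-based half-open preserved verbatim."""
    out = []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), 1):
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise PipelineError("bed-columns", f"{path}:{lineno}: need >= 3 columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        strand = parts[5] if len(parts) >= 6 and parts[5] in {"+", "-"} else "."
        if start >= end:
            raise PipelineError(
                "bed-empty-interval", f"{path}:{lineno}: start {start} >= end {end}"
            )
        out.append(GenomicInterval(chrom, start, end, strand))
    return out


def write_bed(intervals, path, names=None) -> None:
    """BED3 by default; BED6 (name, score 0, strand) when names are given."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\t0\t{iv.strand}\n")


def read_bed_named(path) -> tuple[list[GenomicInterval], list[str]]:
    """BED with a 4th name column; returns (intervals, names)."""
    ivs, names = [], []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), 1):
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 4:
            raise PipelineError("bed-columns", f"{path}:{lineno}: need >= 4 columns")
        start, end = int(parts[1]), int(parts[2])
        if start >= end:
            raise PipelineError("bed-empty-interval", f"{path}:{lineno}")
        strand = parts[5] if len(parts) >= 6 and parts[5] in {"+", "-"} else "."
        ivs.append(GenomicInterval(parts[0], start, end, strand))
        names.append(parts[3])
    return ivs, names


# -------------------------------------------------------------------- bedGraph


def read_bedgraph(path) -> SignalTrack:
    intervals, values = [], []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), 1):
        if not ln.strip() or ln.startswith(("track", "#")):
            continue
        parts = ln.split("\t")
        if len(parts) < 4:
            raise PipelineError("bedgraph-columns", f"{path}:{lineno}")
        intervals.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
        values.append(float(parts[3]))
    return SignalTrack(intervals, values)


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for iv, v in zip(track.intervals, track.values):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v:g}\n")


# ---------------------------------------------------------------------- FASTA

ALPHABET = set("ACGTN")


def read_fasta(path) -> dict[str, str]:
    """FASTA -> {name: uppercase sequence}; name is first whitespace token."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    def _flush():
        if name is None:
            return
        seq = "".join(chunks).upper()
        bad = set(seq) - ALPHABET
        if bad:
            raise PipelineError("fasta-alphabet", f"{name}: invalid characters {sorted(bad)}")
        if name in seqs:
            raise PipelineError("fasta-dup", f"duplicate record {name}")
        seqs[name] = seq
    for ln in Path(path).read_text().splitlines():
        if ln.startswith(">"):
            _flush()
            name = ln[1:].split()[0] if len(ln) > 1 else ""
            chunks = []
        elif ln.strip():
            if name is None:
                raise PipelineError("fasta-parse", "sequence before first header")
            chunks.append(ln.strip())
    _flush()
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ------------------------------------------------------------------ TSV tables


def read_cell_annotations(path) -> dict[str, dict]:
    """TSV with header: cell_id, cell_type, time_point (extra columns kept)."""
    import csv

    out: dict[str, dict] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if "cell_id" not in (reader.fieldnames or []):
            raise PipelineError("annot-columns", "missing cell_id column")
        for row in reader:
            out[row["cell_id"]] = {k: v for k, v in row.items() if k != "cell_id"}
    return out


def write_cell_annotations(annotations: dict[str, dict], path) -> None:
    cols = sorted({k for v in annotations.values() for k in v})
    with open(path, "w") as fh:
        fh.write("cell_id\t" + "\t".join(cols) + "\n")
        for cell, row in annotations.items():
            fh.write(cell + "\t" + "\t".join(str(row.get(c, "")) for c in cols) + "\n")


def read_gene_models(path) -> list[GeneModel]:
    """TSV: gene_id, chrom, strand, body_start, body_end (0-based half-open)."""
    models = []
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("gene_id"):
        raise PipelineError("genemodel-header", "expected header starting with gene_id")
    for ln in lines[1:]:
        if not ln.strip():
            continue
        gene_id, chrom, strand, start, end = ln.split("\t")[:5]
        models.append(
            GeneModel(gene_id, GenomicInterval(chrom, int(start), int(end), strand), strand)
        )
    return models


def write_gene_models(models, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\tbody_start\tbody_end\n")
        for g in models:
            fh.write(f"{g.gene_id}\t{g.body.chrom}\t{g.strand}\t{g.body.start}\t{g.body.end}\n")


def read_orthology(path) -> OrthologyMap:
    pairs = []
    lines = Path(path).read_text().splitlines()
    start = 1 if lines and lines[0].startswith("gene_a") else 0
    for ln in lines[start:]:
        if ln.strip():
            a, b = ln.split("\t")[:2]
            pairs.append((a, b))
    return OrthologyMap(pairs)


def write_orthology(omap: OrthologyMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in omap.pairs:
            fh.write(f"{a}\t{b}\n")


# --------------------------------------------------------------- JASPAR PWMs


def read_pwm_counts(path) -> dict[str, tuple[str, np.ndarray]]:
    """JASPAR-style count matrices.

    Format per record::

        >MOTIF_ID TF_NAME
        A [ 3 10  0 ]
        C [ 1  0 12 ]
        G [ 5  2  1 ]
        T [ 4  1  0 ]

    Returns {motif_id: (tf_name, counts L x 4 in A,C,G,T order)}.
    """
    text = Path(path).read_text()
    records: dict[str, tuple[str, np.ndarray]] = {}
    blocks = [b for b in text.split(">") if b.strip()]
    for block in blocks:
        lines = [ln for ln in block.splitlines() if ln.strip()]
        header = lines[0].split()
        motif_id = header[0]
        tf_name = header[1] if len(header) > 1 else motif_id
        rows = {}
        for ln in lines[1:5]:
            base = ln.split()[0].upper()
            nums = ln.replace("[", " ").replace("]", " ").split()[1:]
            rows[base] = [float(x) for x in nums]
        if set(rows) != set("ACGT"):
            raise PipelineError("pwm-rows", f"{motif_id}: need A/C/G/T rows")
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise PipelineError("pwm-shape", f"{motif_id}: ragged rows")
        counts = np.array([rows["A"], rows["C"], rows["G"], rows["T"]]).T
        if motif_id in records:
            raise PipelineError("pwm-dup", f"duplicate motif {motif_id}")
        records[motif_id] = (tf_name, counts)
    return records


def write_pwm_counts(records: dict[str, tuple[str, np.ndarray]], path) -> None:
    with open(path, "w") as fh:
        for motif_id, (tf_name, counts) in records.items():
            fh.write(f">{motif_id} {tf_name}\n")
            for i, base in enumerate("ACGT"):
                vals = " ".join(f"{v:g}" for v in np.asarray(counts)[:, i])
                fh.write(f"{base} [ {vals} ]\n")


# --------------------------------------------------------------- generic TSV


def write_tsv(rows: list[dict], path, columns: list[str] | None = None) -> None:
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    buf = _io.StringIO()
    buf.write("\t".join(columns) + "\n")
    for row in rows:
        buf.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")
    Path(path).write_text(buf.getvalue())
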