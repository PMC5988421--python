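"""Synthetic inputs with ground truth for every pipeline stage.

Each generator emulates one of the experimental designs the pipeline
analyses and ships a truth table sufficient to score the downstream
stage without re-deriving ground truth:

* a two-gene fusion transcriptome and 2x75 bp-style paired-end reads
  tiled across the junction (per-read spanning truth);
* a three-condition expression study -- control, wild-type factor and
  fusion factor (GFP / PAX3 / PAX3-FOXO1), technical triplicates --
  with planted shared and fusion-unique up-regulated genes;
* qRT-PCR Ct tables realizing requested fold changes in expectation;
* paired nuclei / myosin-positive-cell label masks with known per-cell
  nucleus counts;
* two-channel intensity images with exact positive-pixel counts;
* grouped time-to-event tables with geometric (daily-observation)
  event times.

Every generator is a pure function of its parameters and seed:
reruns are bit-identical.  Geometry in the mask generator is
deliberately schematic (non-overlapping disks and rectangles); only
containment matters to the statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fusion_junction import (
    FusionReference,
    build_junction_reference,
    reverse_complement,
)
from .phenotype_quant import CellMasks
from .target_discovery import ExpressionStudy

__all__ = [
    "ReadTruth",
    "ExpressionTruth",
    "MaskTruth",
    "sim_fusion_transcriptome",
    "sim_reads",
    "sim_expression_study",
    "sim_ct_table",
    "sim_cell_masks",
    "sim_intensity_pair",
    "sim_survival",
    "write_fastq",
    "write_fasta",
    "read_truth_frame",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ReadTruth:
    """Ground truth for one simulated read.

    When the read spans the junction, left_overlap + right_overlap
    equals the read length and both are >= 1; otherwise both are 0.
    Overlaps are in reference (junction-window) orientation.
    """

    read_id: str
    spans_junction: bool
    left_overlap: int
    right_overlap: int
    strand: str


@dataclass(frozen=True)
class ExpressionTruth:
    """Planted class and effect for one gene in the expression study."""

    gene_id: str
    klass: str  # null | shared_up | pf_unique_up | pax3_unique_up
    planted_log2fc: float
    has_human_ortholog: bool


@dataclass(frozen=True)
class MaskTruth:
    """Planted nucleus count for one myosin-positive cell."""

    cell_id: int
    nuclei_count: int
    myosin_positive: bool


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def sim_fusion_transcriptome(
    seed: int, up_len: int = 300, down_len: int = 300, flank: int = 80
) -> tuple[FusionReference, str, str]:
    """Random two-gene fusion reference plus the two wild-type sequences.

    The junction window is the last ``flank`` bases of the upstream
    fragment joined to the first ``flank`` of the downstream fragment.
    The default flank of 80 keeps every true 75 bp spanning read fully
    inside the window at the default 6 bp overlap filter.
    """
    if up_len < 20 or down_len < 20:
        raise ValueError("fragment lengths must be >= 20 bases")
    if flank > min(up_len, down_len):
        raise ValueError("flank cannot exceed either fragment length")
    rng = np.random.default_rng(seed)
    upstream = _random_seq(rng, up_len)
    downstream = _random_seq(rng, down_len)
    ref = build_junction_reference(upstream, downstream, flank)
    return ref, upstream, downstream


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate == 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < error_rate
    if hit.any():
        # substitute with one of the three other bases
        for i in np.flatnonzero(hit):
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _truth_for_interval(
    read_id: str, start: int, end: int, breakpoint: int, strand: str, on_fusion: bool
) -> ReadTruth:
    spans = on_fusion and start < breakpoint < end
    return ReadTruth(
        read_id=read_id,
        spans_junction=spans,
        left_overlap=breakpoint - start if spans else 0,
        right_overlap=end - breakpoint if spans else 0,
        strand=strand,
    )


def sim_reads(
    ref: FusionReference,
    n_pairs: int,
    read_len: int = 75,
    spanning_fraction: float = 0.5,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[SeqRecord], list[ReadTruth]]:
    """Simulate paired-end reads over the fusion and wild-type transcripts.

    A fixed ``round(n_pairs * spanning_fraction)`` pairs carry a read
    placed uniformly over start offsets crossing the breakpoint of the
    fusion transcript (upstream + downstream fragment); the remaining
    pairs are drawn from the two wild-type sequences in equal
    proportion.  Fragments are ``2 * read_len + 50`` long with one mate
    per end (the far mate reverse-complemented); fragment orientation is
    randomized so spanning reads occur on both strands.  Base qualities
    are constant 'I' (Phred 40): the downstream filter uses sequence
    identity, not quality.  Substitution errors are applied per base at
    ``error_rate``.

    Returns 2*n_pairs FASTQ records and one truth row per read.
    """
    if not 0 <= spanning_fraction <= 1:
        raise ValueError("spanning_fraction must be in [0, 1]")
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    if read_len > len(ref.junction_window):
        raise ValueError("read_len exceeds the junction window length")
    frag_len = 2 * read_len + 50
    fusion = ref.upstream_seq + ref.downstream_seq
    bp = len(ref.upstream_seq)
    wild = [ref.upstream_seq, ref.downstream_seq]
    if any(len(w) < frag_len for w in wild) or len(fusion) < frag_len:
        raise ValueError(
            f"transcripts must be at least fragment length ({frag_len}) long"
        )
    # spanning mate start range: crosses breakpoint with >= 1 base each side,
    # and the whole fragment must fit on the fusion transcript
    s_lo = max(0, bp - read_len + 1)
    s_hi = min(bp - 1, len(fusion) - frag_len)
    if s_hi < s_lo:
        raise ValueError("fusion transcript too short for spanning fragments")

    rng = np.random.default_rng(seed)
    n_span = int(round(n_pairs * spanning_fraction))
    records: list[SeqRecord] = []
    truths: list[ReadTruth] = []
    for i in range(n_pairs):
        if i < n_span:
            source, on_fusion = fusion, True
            start = int(rng.integers(s_lo, s_hi + 1))
        else:
            source, on_fusion = wild[(i - n_span) % 2], False
            start = int(rng.integers(0, len(source) - frag_len + 1))
        flip = bool(rng.integers(2))  # which fragment end is sequenced first
        left = (start, start + read_len)
        right = (start + frag_len - read_len, start + frag_len)
        stem = f"pair{i:06d}"
        for mate, ((a, b), rev) in enumerate(
            [(right, True), (left, False)] if flip else [(left, False), (right, True)],
            start=1,
        ):
            seq = source[a:b]
            strand = "reverse" if rev else "forward"
            if rev:
                seq = reverse_complement(seq)
            seq = _apply_errors(seq, error_rate, rng)
            read_id = f"{stem}/{mate}"
            rec = SeqRecord(Seq(seq), id=read_id, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            records.append(rec)
            truths.append(
                _truth_for_interval(
                    read_id, a, b, bp if on_fusion else -1, strand, on_fusion
                )
            )
    return records, truths


def read_truth_frame(truths: list[ReadTruth]) -> pd.DataFrame:
    """Truth rows as a DataFrame (one row per read)."""
    return pd.DataFrame(
        {
            "read_id": [t.read_id for t in truths],
            "spans_junction": [t.spans_junction for t in truths],
            "left_overlap": [t.left_overlap for t in truths],
            "right_overlap": [t.right_overlap for t in truths],
            "strand": [t.strand for t in truths],
        }
    )


def write_fastq(records: list[SeqRecord], path: str | Path) -> None:
    SeqIO.write(records, str(path), "fastq")


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(recs, str(path), "fasta")


def sim_expression_study(
    n_genes: int = 1000,
    n_shared: int = 30,
    n_pf_unique: int = 20,
    n_pax3_unique: int = 15,
    effect_log2fc: float = 2.0,
    noise_sd: float = 0.25,
    n_reps: int = 3,
    ortholog_fraction: float = 0.7,
    seed: int = 0,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.0,
) -> tuple[ExpressionStudy, pd.DataFrame, pd.DataFrame]:
    """Three-condition expression study with planted up-regulated genes.

    Conditions ``gfp`` (control), ``pax3`` and ``pax3_foxo1`` each get
    ``n_reps`` technical-replicate columns.  Log2 values are a per-gene
    baseline plus the planted effect (added to pax3_foxo1 columns for
    pf_unique genes, pax3 columns for pax3_unique, both for shared) plus
    Gaussian noise of sd ``noise_sd``.  Human-ortholog flags are
    Bernoulli(``ortholog_fraction``).

    Returns (study, truth table, ortholog map).  The truth table has
    columns gene_id, klass, planted_log2fc, has_human_ortholog; the
    ortholog map has organism_gene / human_gene rows for flagged genes.
    """
    if n_shared + n_pf_unique + n_pax3_unique > n_genes:
        raise ValueError("planted gene counts exceed n_genes")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    order = rng.permutation(n_genes)
    klass = np.array(["null"] * n_genes, dtype=object)
    klass[order[:n_shared]] = "shared_up"
    klass[order[n_shared : n_shared + n_pf_unique]] = "pf_unique_up"
    klass[
        order[n_shared + n_pf_unique : n_shared + n_pf_unique + n_pax3_unique]
    ] = "pax3_unique_up"
    planted = np.where(klass == "null", 0.0, effect_log2fc)
    if effect_log2fc == 0.0:
        klass[:] = "null"

    conditions = ["gfp", "pax3", "pax3_foxo1"]
    cols = [f"{c}_{r + 1}" for c in conditions for r in range(n_reps)]
    baseline = rng.normal(baseline_mean, baseline_sd, n_genes)
    values = np.tile(baseline[:, None], (1, len(cols)))
    for j, col in enumerate(cols):
        cond = col.rsplit("_", 1)[0]
        if cond == "pax3":
            bump = np.isin(klass, ["shared_up", "pax3_unique_up"])
        elif cond == "pax3_foxo1":
            bump = np.isin(klass, ["shared_up", "pf_unique_up"])
        else:
            bump = np.zeros(n_genes, dtype=bool)
        values[:, j] += np.where(bump, planted, 0.0)
    values += rng.normal(0.0, noise_sd, values.shape)

    has_ortholog = rng.random(n_genes) < ortholog_fraction
    study = ExpressionStudy(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=cols),
        sample_conditions=pd.Series(
            {c: c.rsplit("_", 1)[0] for c in cols}, name="condition"
        ),
        replicate_index=pd.Series(
            {c: int(c.rsplit("_", 1)[1]) for c in cols}, name="replicate_index"
        ),
    )
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "klass": klass,
            "planted_log2fc": np.where(klass == "null", 0.0, planted),
            "has_human_ortholog": has_ortholog,
        }
    )
    ortho = pd.DataFrame(
        {
            "organism_gene": [g for g, h in zip(genes, has_ortholog) if h],
            "human_gene": [g.upper() + "_HS" for g, h in zip(genes, has_ortholog) if h],
        }
    )
    return study, truth, ortho


def sim_ct_table(
    genes: list[str],
    samples: list[str],
    true_fold_changes: dict[str, dict[str, float]],
    ref_gene: str,
    rep_sd: float = 0.0,
    seed: int = 0,
    n_reps: int = 3,
    calibrator: str | None = None,
    ref_ct: float = 20.0,
    target_base_ct: float = 25.0,
) -> pd.DataFrame:
    """Ct table whose ΔΔCt fold changes equal the requested values.

    ``true_fold_changes[gene][sample]`` is the fold change relative to
    the calibrator sample (default: first of ``samples``).  The
    reference gene must have fold change 1 everywhere.  Technical
    replicates get independent Gaussian noise of sd ``rep_sd`` cycles,
    so 2^(-ΔΔCt) recovers the requested fold in expectation.
    """
    if rep_sd < 0:
        raise ValueError("rep_sd must be >= 0")
    if ref_gene not in genes:
        raise ValueError(f"reference gene {ref_gene!r} missing from gene list")
    calibrator = calibrator or samples[0]
    ref_folds = true_fold_changes.get(ref_gene, {s: 1.0 for s in samples})
    if any(ref_folds.get(s, 1.0) != 1.0 for s in samples):
        raise ValueError("reference gene fold change must be 1 in every sample")
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        for sample in samples:
            if gene == ref_gene:
                clean = ref_ct
            else:
                fold = true_fold_changes[gene][sample]
                cal_fold = true_fold_changes[gene][calibrator]
                if cal_fold != 1.0:
                    raise ValueError("calibrator fold change must be 1")
                if fold <= 0:
                    raise ValueError("fold changes must be positive")
                clean = target_base_ct - math.log2(fold)
            for rep in range(1, n_reps + 1):
                rows.append(
                    {
                        "gene_id": gene,
                        "sample_id": sample,
                        "replicate_index": rep,
                        "ct": clean + (rng.normal(0.0, rep_sd) if rep_sd else 0.0),
                    }
                )
    return pd.DataFrame(rows)


def sim_cell_masks(
    n_cells: int,
    nuclei_per_cell: list[int],
    n_free_nuclei: int,
    image_size: int = 256,
    seed: int = 0,
) -> tuple[CellMasks, list[MaskTruth]]:
    """Paired nuclei/cell label images with known per-cell nucleus counts.

    Myosin-positive cells are rectangles laid out on a grid in the top
    part of the image; each holds its planted nuclei (small disks) on an
    internal sub-grid.  Free nuclei sit on background rows at the
    bottom.  Positions get a small seeded jitter; shapes never overlap.
    """
    if len(nuclei_per_cell) != n_cells:
        raise ValueError("nuclei_per_cell length must equal n_cells")
    if any(k < 0 for k in nuclei_per_cell) or n_free_nuclei < 0:
        raise ValueError("nucleus counts must be non-negative")
    rng = np.random.default_rng(seed)
    nuclei = np.zeros((image_size, image_size), dtype=np.uint16)
    cells = np.zeros((image_size, image_size), dtype=np.uint16)
    radius = 3
    pitch = 10  # nucleus grid spacing inside a cell
    next_nucleus = 1

    def draw_nucleus(cy: int, cx: int, label: int) -> None:
        yy, xx = np.ogrid[:image_size, :image_size]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        if nuclei[disk].any():
            raise ValueError("nucleus placement overlap (image too small)")
        nuclei[disk] = label

    y = 4
    x = 4
    row_height = 0
    for cell_id, k in enumerate(nuclei_per_cell, start=1):
        ncols = max(1, min(k, 4))
        nrows = max(1, math.ceil(k / 4)) if k else 1
        w = ncols * pitch + 4
        h = nrows * pitch + 4
        if x + w + 4 > image_size:
            x = 4
            y += row_height + 6
            row_height = 0
        if y + h + 4 > image_size:
            raise ValueError("cells do not fit in the image")
        cells[y : y + h, x : x + w] = cell_id
        for j in range(k):
            r, c = divmod(j, 4)
            jy = int(rng.integers(-1, 2))
            jx = int(rng.integers(-1, 2))
            draw_nucleus(
                y + 2 + pitch * r + pitch // 2 + jy,
                x + 2 + pitch * c + pitch // 2 + jx,
                next_nucleus,
            )
            next_nucleus += 1
        row_height = max(row_height, h)
        x += w + 6
    # free nuclei on background rows below the cells
    fy = y + row_height + 12
    fx = 8
    for _ in range(n_free_nuclei):
        if fx + pitch > image_size:
            fx = 8
            fy += pitch + 2
        if fy + pitch > image_size:
            raise ValueError("free nuclei do not fit in the image")
        jy = int(rng.integers(-1, 2))
        jx = int(rng.integers(-1, 2))
        draw_nucleus(fy + pitch // 2 + jy, fx + pitch // 2 + jx, next_nucleus)
        next_nucleus += 1
        fx += pitch + 2
    truths = [
        MaskTruth(cell_id=i + 1, nuclei_count=k, myosin_positive=True)
        for i, k in enumerate(nuclei_per_cell)
    ]
    return CellMasks(nuclei_labels=nuclei, cell_labels=cells), truths


def sim_intensity_pair(
    image_size: int,
    n_positive_a: int,
    n_positive_b: int,
    background: int = 10,
    signal: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two 16-bit intensity images with exact positive-pixel counts."""
    if signal <= background:
        raise ValueError("signal intensity must exceed background")
    n_pix = image_size * image_size
    if n_positive_a > n_pix or n_positive_b > n_pix:
        raise ValueError("positive counts exceed the pixel count")
    rng = np.random.default_rng(seed)
    images = []
    for count in (n_positive_a, n_positive_b):
        img = np.full((image_size, image_size), background, dtype=np.uint16)
        idx = rng.choice(n_pix, size=count, replace=False)
        img.flat[idx] = signal
        images.append(img)
    return images[0], images[1]


def sim_survival(
    group_sizes: dict[str, int],
    event_rates: dict[str, float],
    censor_day: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Grouped time-to-event table with geometric (daily) event times.

    Each subject's event day is geometric with its group's per-day
    hazard; subjects still event-free at ``censor_day`` are censored
    there.  Matches a design where embryos are observed once per day.
    """
    if censor_day < 1:
        raise ValueError("censor_day must be >= 1")
    if not group_sizes or any(n <= 0 for n in group_sizes.values()):
        raise ValueError("every group must have at least one subject")
    for g in group_sizes:
        h = event_rates.get(g)
        if h is None or not 0 < h <= 1:
            raise ValueError(f"hazard for group {g!r} must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for g, n in group_sizes.items():
        days = rng.geometric(event_rates[g], size=n)
        for i, day in enumerate(days):
            event = int(day <= censor_day)
            rows.append(
                {
                    "subject_id": f"{g}_{i:04d}",
                    "group": g,
                    "time": int(min(day, censor_day)),
                    "event": event,
                }
            )
    return pd.DataFrame(rows)


def write_masks_tiff(masks: CellMasks, nuclei_path: str | Path, cells_path: str | Path) -> None:
    """Write the two label images as 16-bit TIFFs."""
    tifffile.imwrite(str(nuclei_path), masks.nuclei_labels.astype(np.uint16))
    tifffile.imwrite(str(cells_path), masks.cell_labels.astype(np.uint16))
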