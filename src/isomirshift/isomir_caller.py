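"""Read collapsing, hairpin alignment, 5'-offset classification and counting.

The caller turns per-sample small-RNA reads into an isoform count matrix
keyed by (locus, arm, signed 5' offset).  3'-end variants of the same 5'
end are collapsed into one key — the 5' end defines the seed and hence the
isoform identity — but their distribution over 3'-end offsets is retained
per key for Dicer-rule diagnostics.

Alignment is exact-substring (optionally up to 2 mismatches) against the
hairpin catalog: hairpins are ~70-100 nt, so exhaustive scanning is exact
and needs no external aligner.  Reads overlapping an N in the reference
never match.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .annotations import ARM_3P, ARM_5P, HairpinLocus, MatureAnnotation, to_rna

logger = logging.getLogger(__name__)

DEFAULT_LENGTH_BOUNDS = (15, 35)
DEFAULT_MAX_OFFSET = 5

KEY_LEVELS = ["locus_id", "arm", "mature_name", "offset"]


@dataclass(frozen=True, order=True)
class IsomiRKey:
    """Identity of a 5'-isoform: locus, arm and signed 5' offset.

    Positive offsets mean the isoform starts downstream (toward the hairpin
    3' end) of the canonical 5' end, i.e. a "+1" isoform is one nucleotide
    shorter at its 5' end under this convention.
    """

    locus_id: str
    arm: str
    mature_name: str
    five_prime_offset: int

    @property
    def display_name(self) -> str:
        if self.five_prime_offset == 0:
            return self.mature_name
        if "miR-" in self.mature_name:
            base = self.mature_name.replace("miR-", "isomiR-", 1)
        else:
            base = f"isomiR-{self.mature_name}"
        return f"{base} | {self.five_prime_offset:+d}"

    def as_tuple(self) -> tuple[str, str, str, int]:
        return (self.locus_id, self.arm, self.mature_name, self.five_prime_offset)


@dataclass
class CollapsedRead:
    sequence: str
    counts: np.ndarray  # one entry per sample


class Alignment(NamedTuple):
    locus_id: str
    start: int
    end: int
    mismatches: int


@dataclass
class IsoformCountMatrix:
    """Counts per (IsomiRKey, sample) plus the per-key 3'-offset profile.

    ``counts`` is indexed by a (locus_id, arm, mature_name, offset)
    MultiIndex; ``three_prime`` is a long table (key levels + offset3 +
    count) whose per-key marginal equals the key's total count.
    """

    counts: pd.DataFrame
    three_prime: pd.DataFrame
    qc: dict = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def keys(self) -> list[IsomiRKey]:
        return [IsomiRKey(*idx) for idx in self.counts.index]


def _read_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"pre-collapsed table {path} needs >=2 columns")
    df = df.iloc[:, :2]
    df.columns = ["sequence", "count"]
    return df


def _iter_sample_reads(path: Path):
    """Yield (sequence, count) from FASTA/FASTQ/TSV input for one sample."""
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".txt", ".counts"):
        for row in _read_table(path).itertuples(index=False):
            yield str(row.sequence), int(row.count)
    else:
        fmt = "fastq" if suffix in (".fastq", ".fq") else "fasta"
        for record in SeqIO.parse(str(path), fmt):
            yield str(record.seq), 1


def collapse_reads(
    sources: Sequence[Path | str | pd.DataFrame],
    sample_ids: Sequence[str] | None = None,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
) -> tuple[list[CollapsedRead], dict]:
    """Collapse identical read sequences into per-sample count vectors.

    ``sources`` is one FASTA/FASTQ file, pre-collapsed TSV (sequence, count)
    or DataFrame per sample.  Reads outside ``length_bounds`` are dropped
    and tallied in the QC report.  3' adapters are assumed removed.
    """
    n = len(sources)
    if sample_ids is None:
        sample_ids = [f"S{i+1}" for i in range(n)]
    lo, hi = length_bounds
    table: dict[str, np.ndarray] = {}
    qc = {"length_filtered": dict.fromkeys(sample_ids, 0),
          "input_reads": dict.fromkeys(sample_ids, 0)}
    for i, (src, sid) in enumerate(zip(sources, sample_ids)):
        if isinstance(src, pd.DataFrame):
            items = ((str(r.sequence), int(r.count)) for r in src.itertuples(index=False))
        else:
            path = Path(src)
            if not path.exists():
                raise IOError(f"unreadable read file for sample {sid!r}: {path}")
            items = _iter_sample_reads(path)
        for seq, count in items:
            seq = to_rna(seq, record=sid)
            qc["input_reads"][sid] += count
            if not lo <= len(seq) <= hi:
                qc["length_filtered"][sid] += count
                continue
            if seq not in table:
                table[seq] = np.zeros(n, dtype=float)
            table[seq][i] += count
    reads = [CollapsedRead(sequence=s, counts=c) for s, c in table.items()]
    return reads, qc


class HairpinAligner:
    """Exhaustive ungapped aligner over a hairpin catalog.

    With ``max_mismatches=0`` matching goes through a substring index
    (exact); otherwise every window of every hairpin is compared.  Windows
    containing N never match.
    """

    def __init__(
        self,
        catalog: Sequence[HairpinLocus],
        max_mismatches: int = 0,
        length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
    ):
        if not catalog:
            raise ValueError("empty hairpin catalog")
        if not 0 <= max_mismatches <= 2:
            raise ValueError("max_mismatches must be in 0..2")
        self.catalog = list(catalog)
        self.by_id = {loc.locus_id: loc for loc in self.catalog}
        self.max_mismatches = max_mismatches
        self.length_bounds = length_bounds
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        lo, hi = length_bounds
        for loc in self.catalog:
            seq = loc.sequence
            for L in range(lo, min(hi, len(seq)) + 1):
                for start in range(len(seq) - L + 1):
                    window = seq[start : start + L]
                    if "N" in window:
                        continue
                    self._index[window].append((loc.locus_id, start))
        # byte arrays for the mismatch path; N encoded as 0 so it never matches
        self._encoded = {
            loc.locus_id: np.frombuffer(
                loc.sequence.replace("N", "\x00").encode(), dtype=np.uint8
            )
            for loc in self.catalog
        }

    def align(self, sequence: str) -> list[Alignment]:
        """All ungapped occurrences with <= max_mismatches mismatches."""
        L = len(sequence)
        if self.max_mismatches == 0:
            return [
                Alignment(locus_id, start, start + L, 0)
                for locus_id, start in self._index.get(sequence, ())
            ]
        hits = []
        read = np.frombuffer(sequence.encode(), dtype=np.uint8)
        for loc in self.catalog:
            ref = self._encoded[loc.locus_id]
            if len(ref) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(ref, L)
            mm = (windows != read).sum(axis=1)
            for start in np.nonzero(mm <= self.max_mismatches)[0]:
                hits.append(Alignment(loc.locus_id, int(start), int(start) + L, int(mm[start])))
        return hits


def classify_alignment(
    alignment: Alignment,
    locus: HairpinLocus,
    *,
    max_offset: int = DEFAULT_MAX_OFFSET,
    flip_sign: bool = False,
) -> tuple[IsomiRKey, int] | None:
    """Classify an alignment by its 5' offset from the nearest mature.

    Returns ``(key, three_prime_offset)`` or None when no annotated mature
    5' end lies within ``max_offset`` (the read is then "unassigned").
    Ties between the two arms go to 5p.
    """
    best: tuple[int, int, MatureAnnotation] | None = None
    for m in locus.matures:
        dist = abs(alignment.start - m.start)
        if dist > max_offset:
            continue
        arm_rank = 0 if m.arm == ARM_5P else 1
        if best is None or (dist, arm_rank) < (best[0], best[1]):
            best = (dist, arm_rank, m)
    if best is None:
        return None
    m = best[2]
    offset = alignment.start - m.start
    if flip_sign:
        offset = -offset
    key = IsomiRKey(
        locus_id=locus.locus_id,
        arm=m.arm,
        mature_name=m.mature_name,
        five_prime_offset=offset,
    )
    return key, alignment.end - m.end


MULTIMAP_POLICIES = ("fractional", "discard", "all")


def aggregate_counts(
    reads: Sequence[CollapsedRead],
    catalog: Sequence[HairpinLocus],
    sample_ids: Sequence[str],
    *,
    aligner: HairpinAligner | None = None,
    max_mismatches: int = 0,
    max_offset: int = DEFAULT_MAX_OFFSET,
    multimap_policy: str = "fractional",
    flip_sign: bool = False,
) -> IsoformCountMatrix:
    """Align, classify and sum collapsed reads into an IsoformCountMatrix.

    A read classified at k distinct loci contributes count/k to each under
    the "fractional" policy ("discard": dropped and tallied; "all": full
    count to each).  Reads with no classified hit are tallied as
    unassigned.  The per-key 3'-offset profile is recorded alongside.
    """
    if multimap_policy not in MULTIMAP_POLICIES:
        raise ValueError(f"unknown multimap policy {multimap_policy!r}")
    if aligner is None:
        aligner = HairpinAligner(catalog, max_mismatches=max_mismatches)
    n = len(sample_ids)
    counts: dict[tuple, np.ndarray] = {}
    profile: dict[tuple, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    unassigned = np.zeros(n)
    discarded = np.zeros(n)
    for read in reads:
        classified: dict[str, tuple[IsomiRKey, int]] = {}
        for aln in aligner.align(read.sequence):
            hit = classify_alignment(
                aln, aligner.by_id[aln.locus_id], max_offset=max_offset, flip_sign=flip_sign
            )
            if hit is not None:
                # one classification per locus; exact duplicates cannot occur
                classified[aln.locus_id] = hit
        k = len(classified)
        if k == 0:
            unassigned += read.counts
            continue
        if k > 1 and multimap_policy == "discard":
            discarded += read.counts
            continue
        weight = 1.0 / k if (k > 1 and multimap_policy == "fractional") else 1.0
        for key, d3 in classified.values():
            tup = key.as_tuple()
            if tup not in counts:
                counts[tup] = np.zeros(n)
            counts[tup] += weight * read.counts
            profile[tup][d3] += weight * float(read.counts.sum())
    if counts:
        index = pd.MultiIndex.from_tuples(sorted(counts), names=KEY_LEVELS)
    else:
        index = pd.MultiIndex.from_arrays([[], [], [], []], names=KEY_LEVELS)
    mat = pd.DataFrame(
        [counts[tup] for tup in index] if len(index) else None,
        index=index,
        columns=list(sample_ids),
        dtype=float,
    )
    rows = [
        tup + (d3, c)
        for tup in sorted(profile)
        for d3, c in sorted(profile[tup].items())
    ]
    three_prime = pd.DataFrame(rows, columns=KEY_LEVELS + ["offset3", "count"])
    qc = {
        "unassigned": dict(zip(sample_ids, unassigned)),
        "multimap_discarded": dict(zip(sample_ids, discarded)),
    }
    return IsoformCountMatrix(counts=mat, three_prime=three_prime, qc=qc)


def compute_rpm(
    matrix: IsoformCountMatrix | pd.DataFrame,
    denominator: str = "assigned",
    mapped_totals: pd.Series | None = None,
) -> pd.DataFrame:
    """Reads-per-million normalization of the count matrix.

    ``denominator="assigned"`` (default) divides by the per-sample sum over
    all keys in the matrix; ``"mapped"`` uses externally supplied totals.
    """
    counts = matrix.counts if isinstance(matrix, IsoformCountMatrix) else matrix
    if denominator == "assigned":
        totals = counts.sum(axis=0)
    elif denominator == "mapped":
        if mapped_totals is None:
            raise ValueError("denominator='mapped' requires mapped_totals")
        totals = mapped_totals.reindex(counts.columns)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    zero = totals[(totals <= 0) | totals.isna()]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return counts.div(totals, axis=1) * 1e6


def filter_expressed(
    expr: pd.DataFrame, min_rpm: float = 1.0, min_samples: int = 7
) -> pd.DataFrame:
    """Keep keys with RPM >= min_rpm in at least min_samples samples."""
    if min_rpm < 0 or min_samples < 1:
        raise ValueError("min_rpm must be >=0 and min_samples >=1")
    if min_samples > expr.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds sample count {expr.shape[1]}"
        )
    keep = (expr >= min_rpm).sum(axis=1) >= min_samples
    return expr.loc[keep]


def reannotate_dominant_5p(
    matrix: IsoformCountMatrix,
    catalog: Sequence[HairpinLocus],
) -> tuple[IsoformCountMatrix, list[HairpinLocus], pd.DataFrame]:
    """Move the canonical 5' end of arms dominantly processed off-annotation.

    Per (locus, arm): if the isoform with the largest summed count has
    offset d != 0 and its total strictly exceeds the canonical's, the
    canonical 5' end is moved by d and every offset o on that arm becomes
    o - d (the former canonical becomes the isoform at -d).  Idempotent.
    """
    counts = matrix.counts
    totals = counts.sum(axis=1)
    shifts: dict[tuple[str, str], int] = {}
    report_rows = []
    for (locus_id, arm), sub in totals.groupby(level=["locus_id", "arm"]):
        offs = sub.index.get_level_values("offset")
        per_offset = pd.Series(sub.values, index=offs).groupby(level=0).sum()
        canonical_total = float(per_offset.get(0, 0.0))
        # deterministic dominant choice: largest total, then smaller |d|, then negative
        order = sorted(per_offset.items(), key=lambda kv: (-kv[1], abs(kv[0]), kv[0]))
        d, top_total = order[0]
        if d != 0 and top_total > canonical_total:
            shifts[(locus_id, arm)] = int(d)
            report_rows.append(
                {"locus_id": locus_id, "arm": arm, "shift": int(d),
                 "new_dominant_total": top_total, "old_canonical_total": canonical_total}
            )
    report = pd.DataFrame(report_rows, columns=[
        "locus_id", "arm", "shift", "new_dominant_total", "old_canonical_total"])
    if not shifts:
        return matrix, list(catalog), report

    def remap(idx_tuple):
        locus_id, arm, name, off = idx_tuple
        d = shifts.get((locus_id, arm), 0)
        return (locus_id, arm, name, off - d)

    new_index = pd.MultiIndex.from_tuples(
        [remap(t) for t in counts.index], names=KEY_LEVELS
    )
    new_counts = pd.DataFrame(counts.values, index=new_index, columns=counts.columns)
    new_counts = new_counts.sort_index()

    tp = matrix.three_prime.copy()
    if len(tp):
        d_per_row = tp.apply(lambda r: shifts.get((r.locus_id, r.arm), 0), axis=1)
        tp["offset"] = tp["offset"] - d_per_row
        tp["offset3"] = tp["offset3"] - d_per_row  # mature end moves with the start

    new_catalog = []
    for loc in catalog:
        new_mats = []
        for m in loc.matures:
            d = shifts.get((loc.locus_id, m.arm), 0)
            new_mats.append(
                MatureAnnotation(m.mature_name, m.arm, m.start + d, m.end + d)
            )
        new_catalog.append(loc.with_matures(new_mats))
    new_matrix = IsoformCountMatrix(counts=new_counts, three_prime=tp, qc=dict(matrix.qc))
    return new_matrix, new_catalog, report


def quantify(
    sources: Sequence[Path | str | pd.DataFrame],
    catalog: Sequence[HairpinLocus],
    sample_ids: Sequence[str] | None = None,
    *,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
    max_mismatches: int = 0,
    max_offset: int = DEFAULT_MAX_OFFSET,
    multimap_policy: str = "fractional",
    reannotate: bool = True,
) -> tuple[IsoformCountMatrix, list[HairpinLocus], dict]:
    """End-to-end: collapse -> align -> classify -> count (-> re-annotate)."""
    reads, qc_collapse = collapse_reads(sources, sample_ids, length_bounds)
    sample_ids = list(qc_collapse["input_reads"].keys())
    matrix = aggregate_counts(
        reads, catalog, sample_ids,
        max_mismatches=max_mismatches, max_offset=max_offset,
        multimap_policy=multimap_policy,
    )
    report = pd.DataFrame()
    if reannotate:
        matrix, catalog, report = reannotate_dominant_5p(matrix, catalog)
    qc = {**qc_collapse, **matrix.qc, "reannotated": report.to_dict("records")}
    matrix.qc = qc
    return matrix, list(catalog), qc
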