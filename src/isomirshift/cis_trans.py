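"""Pri-miRNA cis-element scanning and RBP (trans-factor) association.

Cis side: the Microprocessor-orienting motifs — basal UG upstream of the
5p mature start, apical UGU/GUG in the loop, CNNC in the 3' basal segment
— plus poly-(U) tracts (hnRNPC-type binding motifs) in the flanking
sequence.  Window defaults reflect the known motif geometry (basal UG
~13 nt upstream of the Drosha cut, CNNC ~17 nt downstream) and are fully
configurable; flanks default to 250 nt.

Trans side: eCLIP peak overlap with pre-miRNA +/- flank windows (BED-style
0-based half-open intervals) and association of RBP expression with the
isomiR ratio, univariate (Pearson) and multivariate (OLS on min-max-scaled
variables, controlling for host-transcript and canonical-miRNA levels),
BH-corrected across RBPs.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotations import ARM_3P, ARM_5P, HairpinLocus
from .ratio_stats import bh_fdr, minmax_ols

logger = logging.getLogger(__name__)

MOTIF_TYPES = ("basal_UG", "apical_UGU_GUG", "CNNC", "polyU")

DEFAULT_BASAL_WINDOW = (-17, -11)  # UG start relative to the 5p mature start
DEFAULT_CNNC_WINDOW = (15, 21)  # first C relative to the 3p mature end
DEFAULT_MIN_POLYU = 4
DEFAULT_FLANK = 250


@dataclass(frozen=True)
class MotifHit:
    locus_id: str
    motif_type: str
    position: int  # relative to the motif's reference point (see scanner)
    sequence: str


def scan_primirna_motifs(
    locus: HairpinLocus,
    *,
    basal_window: tuple[int, int] = DEFAULT_BASAL_WINDOW,
    cnnc_window: tuple[int, int] = DEFAULT_CNNC_WINDOW,
    min_polyu: int = DEFAULT_MIN_POLYU,
) -> list[MotifHit]:
    """Scan a flanked hairpin for basal UG, apical UGU/GUG, CNNC and polyU.

    Positions are reported relative to each motif's reference point:
    basal_UG to the 5p mature start (negative = upstream), apical to the
    5p mature end (loop-local), CNNC to the 3p mature end, polyU to the
    hairpin start (negative values fall in the 5' flank).  Searches that
    run past the available flank are truncated with a warning.
    """
    full = locus.flank5 + locus.sequence + locus.flank3
    off = len(locus.flank5)
    m5 = locus.mature(ARM_5P)
    m3 = locus.mature(ARM_3P)
    hits: list[MotifHit] = []

    if m5 is not None:
        ref = off + m5.start
        for rel in range(basal_window[0], basal_window[1] + 1):
            idx = ref + rel
            if idx < 0:
                logger.warning(
                    "locus %s: basal window truncated by short 5' flank", locus.locus_id
                )
                continue
            if full[idx : idx + 2] == "UG":
                hits.append(MotifHit(locus.locus_id, "basal_UG", rel, "UG"))

    if m5 is not None and m3 is not None:
        loop = full[off + m5.end : off + m3.start]
        for i in range(len(loop) - 2):
            tri = loop[i : i + 3]
            if tri in ("UGU", "GUG"):
                hits.append(MotifHit(locus.locus_id, "apical_UGU_GUG", i, tri))

    if m3 is not None:
        ref = off + m3.end
        for rel in range(cnnc_window[0], cnnc_window[1] + 1):
            idx = ref + rel
            if idx + 4 > len(full):
                logger.warning(
                    "locus %s: CNNC window truncated by short 3' flank", locus.locus_id
                )
                break
            quad = full[idx : idx + 4]
            if quad[0] == "C" and quad[3] == "C":
                hits.append(MotifHit(locus.locus_id, "CNNC", rel, quad))

    pattern = re.compile("U{%d,}" % min_polyu)
    for match in pattern.finditer(locus.flank5):
        hits.append(
            MotifHit(
                locus.locus_id,
                "polyU",
                match.start() - len(locus.flank5),
                match.group(),
            )
        )
    for match in pattern.finditer(locus.flank3):
        hits.append(
            MotifHit(locus.locus_id, "polyU", locus.length + match.start(), match.group())
        )
    return hits


@dataclass(frozen=True)
class GenomicInterval:
    """BED-convention interval: 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")


def read_bed(path) -> list[GenomicInterval]:
    """Read intervals from a BED file (first 6 columns honored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            out.append(
                GenomicInterval(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3] if len(fields) > 3 else "",
                    strand=fields[5] if len(fields) > 5 else ".",
                )
            )
    return out


def eclip_overlap(
    peaks: list[GenomicInterval],
    premirs: list[GenomicInterval],
    flank: int = DEFAULT_FLANK,
    *,
    stranded: bool = False,
) -> pd.DataFrame:
    """Peaks intersecting each pre-miRNA's [start - flank, end + flank).

    Returns one row per (premir, peak) overlap with the overlap length
    against the flanked window.  Strand is ignored unless ``stranded``.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    trees: dict[tuple, IntervalTree] = {}
    for i, peak in enumerate(peaks):
        group = (peak.chrom, peak.strand) if stranded else (peak.chrom,)
        trees.setdefault(group, IntervalTree()).addi(peak.start, peak.end, i)
    rows = []
    for pre in premirs:
        lo = max(0, pre.start - flank)
        hi = pre.end + flank
        group = (pre.chrom, pre.strand) if stranded else (pre.chrom,)
        tree = trees.get(group)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(lo, hi)):
            peak = peaks[iv.data]
            rows.append(
                {
                    "premir": pre.name,
                    "rbp": peak.name,
                    "chrom": pre.chrom,
                    "overlap": min(peak.end, hi) - max(peak.start, lo),
                }
            )
    return pd.DataFrame(rows, columns=["premir", "rbp", "chrom", "overlap"])


@dataclass
class RBPAssociation:
    rbp: str
    pearson_r: float
    pearson_p: float
    coefficient: float  # multivariate, min-max scaled
    coefficient_p: float
    q: float = np.nan


def rbp_ratio_association(
    rbp_expr: pd.DataFrame,
    ratio: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Associate each RBP's expression with the isomiR ratio.

    Univariate Pearson r/p plus a multivariate OLS coefficient for the RBP
    with host-transcript / canonical-miRNA covariates, all min-max scaled;
    BH FDR across RBPs.  ``rbp_expr`` rows are RBPs, columns samples.
    """
    shared = [s for s in rbp_expr.columns if s in ratio.index]
    if covariates is not None:
        shared = [s for s in shared if s in covariates.index]
    if not shared:
        raise ValueError("no sample overlap between RBP expression and ratios")
    if len(shared) < 5:
        raise ValueError(f"need >=5 complete cases, got {len(shared)}")
    results = []
    for rbp, row in rbp_expr[shared].iterrows():
        y = ratio[shared]
        mask = row.notna() & y.notna()
        r, p = stats.pearsonr(row[mask], y[mask])
        X = pd.DataFrame({str(rbp): row})
        if covariates is not None:
            X = pd.concat([X, covariates.loc[shared]], axis=1)
        fit = minmax_ols(y, X, response_name="isomir_ratio")
        results.append(
            RBPAssociation(
                rbp=str(rbp),
                pearson_r=float(r),
                pearson_p=float(p),
                coefficient=float(fit.coefficients[0]),
                coefficient_p=float(fit.pvalues[0]),
            )
        )
    out = pd.DataFrame([vars(a) for a in results]).set_index("rbp")
    out["q"] = bh_fdr(out["pearson_p"].to_numpy())
    return out
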