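"""Hairpin precursor catalog and mature-miRNA coordinate handling.

The catalog is the reference frame for everything downstream: each hairpin
precursor carries its sequence (RNA alphabet) and the hairpin-local,
0-based half-open coordinates of its canonical mature products.  All
genomic input (miRBase-dialect GFF3, 1-based inclusive, linked by
``Derives_from``) is converted to this internal convention at the boundary,
including reflection through the precursor for minus-strand records.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGUN")

ARM_5P = "5p"
ARM_3P = "3p"


def to_rna(sequence: str, *, record: str = "") -> str:
    """Uppercase, convert T->U and validate against the ACGUN alphabet."""
    seq = str(sequence).upper().replace("T", "U")
    for pos, base in enumerate(seq):
        if base not in _VALID_BASES:
            raise ValueError(
                f"invalid base {base!r} at position {pos} in record {record!r}"
            )
    return seq


@dataclass(frozen=True)
class MatureAnnotation:
    """A canonical mature product, in hairpin-local 0-based half-open coords."""

    mature_name: str
    arm: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.arm not in (ARM_5P, ARM_3P):
            raise ValueError(f"arm must be '5p' or '3p', got {self.arm!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid mature interval [{self.start}, {self.end}) "
                f"for {self.mature_name}"
            )
        length = self.end - self.start
        if not 16 <= length <= 30:
            raise ValueError(
                f"mature {self.mature_name} length {length} outside [16, 30]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class HairpinLocus:
    """A hairpin precursor with optional flanking sequence and matures.

    ``flank5``/``flank3`` extend the hairpin for pri-miRNA motif scanning;
    they are not part of the alignment reference.
    """

    locus_id: str
    name: str
    sequence: str
    matures: list[MatureAnnotation] = field(default_factory=list)
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for locus {self.locus_id!r}")
        self._check_matures(self.matures)

    def _check_matures(self, matures: Iterable[MatureAnnotation]) -> None:
        seen_arms: set[str] = set()
        for m in matures:
            if m.end > self.length:
                raise ValueError(
                    f"mature {m.mature_name} [{m.start},{m.end}) outside "
                    f"hairpin {self.locus_id} of length {self.length}"
                )
            if m.arm in seen_arms:
                raise ValueError(
                    f"locus {self.locus_id}: more than one mature on arm {m.arm}"
                )
            seen_arms.add(m.arm)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def mature(self, arm: str) -> MatureAnnotation | None:
        for m in self.matures:
            if m.arm == arm:
                return m
        return None

    def with_matures(self, matures: list[MatureAnnotation]) -> "HairpinLocus":
        new = replace(self, matures=list(matures))
        return new


def read_hairpin_fasta(path: str | Path) -> list[HairpinLocus]:
    """Read hairpin precursors from FASTA (sequences only, matures empty).

    Identifiers are the first whitespace-delimited token of the header.
    T is converted to U; duplicate identifiers and non-ACGUTN characters
    raise ``ValueError``.  An empty file yields an empty catalog with a
    logged warning.
    """
    catalog: list[HairpinLocus] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate hairpin identifier {record.id!r}")
        seen.add(record.id)
        seq = to_rna(str(record.seq), record=record.id)
        catalog.append(HairpinLocus(locus_id=record.id, name=record.id, sequence=seq))
    if not catalog:
        logger.warning("no hairpin records found in %s", path)
    return catalog


def _genomic_to_local(
    pre_start: int, pre_end: int, strand: str, mat_start: int, mat_end: int
) -> tuple[int, int]:
    """Map a 1-based inclusive genomic mature interval to hairpin-local
    0-based half-open coordinates on the hairpin's 5'->3' sense."""
    if strand == "-":
        local_start = pre_end - mat_end
        local_end = pre_end - mat_start + 1
    else:
        local_start = mat_start - pre_start
        local_end = mat_end - pre_start + 1
    return local_start, local_end


def _arm_from_name_or_midpoint(name: str, start: int, end: int, hairpin_len: int) -> str:
    lowered = name.lower()
    if lowered.endswith("-5p"):
        return ARM_5P
    if lowered.endswith("-3p"):
        return ARM_3P
    midpoint = (start + end) / 2
    return ARM_5P if midpoint < hairpin_len / 2 else ARM_3P


def read_mature_gff3(path: str | Path, catalog: list[HairpinLocus]) -> list[HairpinLocus]:
    """Attach mature annotations from a miRBase-dialect GFF3 to the catalog.

    ``miRNA`` features are linked to their ``miRNA_primary_transcript`` via
    the ``Derives_from`` attribute; coordinates are converted to
    hairpin-local.  Arm assignment: an explicit ``-5p``/``-3p`` name suffix
    wins; otherwise the midpoint rule applies.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )
    by_id = {loc.locus_id: loc for loc in catalog}
    by_name = {loc.name: loc for loc in catalog}

    precursors: dict[str, tuple[int, int, str, str]] = {}
    for feat in db.features_of_type("miRNA_primary_transcript"):
        pid = feat.attributes.get("ID", [feat.id])[0]
        name = feat.attributes.get("Name", [pid])[0]
        precursors[pid] = (feat.start, feat.end, feat.strand, name)

    matures_by_locus: dict[str, list[MatureAnnotation]] = {}
    for feat in db.features_of_type("miRNA"):
        derives = feat.attributes.get("Derives_from")
        if not derives:
            raise ValueError(f"miRNA feature {feat.id} lacks Derives_from")
        pid = derives[0]
        if pid not in precursors:
            raise ValueError(f"miRNA {feat.id} derives from unknown precursor {pid!r}")
        pre_start, pre_end, strand, pre_name = precursors[pid]
        locus = by_id.get(pid) or by_name.get(pre_name) or by_id.get(pre_name)
        if locus is None:
            raise ValueError(
                f"precursor {pid!r} ({pre_name!r}) absent from the hairpin catalog"
            )
        mat_name = feat.attributes.get("Name", [feat.id])[0]
        ls, le = _genomic_to_local(pre_start, pre_end, strand, feat.start, feat.end)
        if ls < 0 or le > locus.length:
            raise ValueError(
                f"mature {mat_name} [{ls},{le}) outside precursor {locus.locus_id}"
            )
        arm = _arm_from_name_or_midpoint(mat_name, ls, le, locus.length)
        matures_by_locus.setdefault(locus.locus_id, []).append(
            MatureAnnotation(mature_name=mat_name, arm=arm, start=ls, end=le)
        )

    out = []
    for loc in catalog:
        mats = matures_by_locus.get(loc.locus_id, list(loc.matures))
        out.append(loc.with_matures(mats))
    return out


def write_mature_gff3(
    catalog: list[HairpinLocus],
    path: str | Path,
    *,
    strands: dict[str, str] | None = None,
    chrom: str = "chrSim",
    spacing: int = 1000,
) -> None:
    """Write the catalog as miRBase-dialect GFF3 (synthetic genomic placement).

    Each precursor is placed on ``chrom`` at successive offsets; ``strands``
    may assign '-' per locus to exercise the reflection path.  Round-tripping
    through :func:`read_mature_gff3` reproduces hairpin-local coordinates.
    """
    strands = strands or {}
    lines = ["##gff-version 3"]
    origin = 1
    for loc in catalog:
        strand = strands.get(loc.locus_id, "+")
        p1 = origin
        pe = p1 + loc.length - 1
        lines.append(
            f"{chrom}\t.\tmiRNA_primary_transcript\t{p1}\t{pe}\t.\t{strand}\t.\t"
            f"ID={loc.locus_id};Name={loc.name}"
        )
        for m in loc.matures:
            if strand == "-":
                ms = pe - m.end + 1
                me = pe - m.start
            else:
                ms = p1 + m.start
                me = p1 + m.end - 1
            lines.append(
                f"{chrom}\t.\tmiRNA\t{ms}\t{me}\t.\t{strand}\t.\t"
                f"ID={m.mature_name};Name={m.mature_name};Derives_from={loc.locus_id}"
            )
        origin += loc.length + spacing
    Path(path).write_text("\n".join(lines) + "\n")
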