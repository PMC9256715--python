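"""Seed extraction and canonical target-site identification in 3'-UTRs.

A miRNA's seed is nt 2-7 from its 5' end (extended seed: nt 2-8), so a
5'-shifted isoform carries a shifted seed and a rewired target set.  Site
types follow the canonical definitions: on the UTR read 5'->3',

* 8mer      — reverse complement of the extended seed followed by A,
* 7mer-m8   — reverse complement of the extended seed,
* 7mer-A1   — reverse complement of the 6-nt seed followed by A,
* 6mer      — reverse complement of the 6-nt seed,

with precedence 8mer > 7mer-m8 > 7mer-A1 > 6mer at a given seed-match
anchor.  A gene qualifies as a putative target on any 7/8mer site, or on a
6mer site carrying a supplied (external) context score below -0.1; 6mer
sites without a score never qualify on their own.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotations import to_rna
from .isomir_caller import IsomiRKey

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
STRONG_SITES = frozenset({"8mer", "7mer-m8", "7mer-A1"})
SIX_MER_SCORE_CUTOFF = -0.1


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedSpec:
    mature_sequence: str
    seed6: str
    seed7: str
    nt1: str
    key: IsomiRKey | None = None


def seed_of(mature_sequence: str, key: IsomiRKey | None = None) -> SeedSpec:
    """Extract seed6 (nt 2-7) and seed7 (nt 2-8) from a mature sequence."""
    seq = to_rna(mature_sequence)
    if len(seq) < 8:
        raise ValueError(f"mature sequence too short for a seed: {len(seq)} nt")
    return SeedSpec(
        mature_sequence=seq, seed6=seq[1:7], seed7=seq[1:8], nt1=seq[0], key=key
    )


@dataclass(frozen=True)
class SiteMatch:
    gene_id: str
    utr_position: int  # 0-based start of the full matched pattern on the UTR
    site_type: str
    key: IsomiRKey | None = None
    context_score: float | None = None


def find_seed_sites(
    spec: SeedSpec, utr: str, gene_id: str = ""
) -> list[SiteMatch]:
    """All canonical seed-match sites of one miRNA in one UTR.

    Anchored at each occurrence of the seed6 reverse complement; the m8
    base (one upstream) and the A1 base (one downstream) refine the type,
    with the stated precedence.
    """
    utr = to_rna(utr, record=gene_id)
    m6 = reverse_complement(spec.seed6)
    m8_base = reverse_complement(spec.seed7)[0]  # pairs with seed nt 8
    sites: list[SiteMatch] = []
    start = utr.find(m6)
    while start != -1:
        has_m8 = start >= 1 and utr[start - 1] == m8_base
        has_a1 = start + 6 < len(utr) and utr[start + 6] == "A"
        if has_m8 and has_a1:
            site_type, pos = "8mer", start - 1
        elif has_m8:
            site_type, pos = "7mer-m8", start - 1
        elif has_a1:
            site_type, pos = "7mer-A1", start
        else:
            site_type, pos = "6mer", start
        sites.append(SiteMatch(gene_id=gene_id, utr_position=pos,
                               site_type=site_type, key=spec.key))
        start = utr.find(m6, start + 1)
    return sites


@dataclass
class TargetCall:
    gene_id: str
    qualifies: bool
    sites: list[SiteMatch] = field(default_factory=list)
    qualifying_sites: list[SiteMatch] = field(default_factory=list)


def _attach_scores(
    sites: list[SiteMatch], scores: pd.DataFrame | None
) -> list[SiteMatch]:
    if scores is None:
        return sites
    required = {"gene_id", "position", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"score table must have columns {sorted(required)}")
    lookup = {
        (str(r.gene_id), int(r.position)): float(r.score)
        for r in scores.itertuples(index=False)
    }
    out = []
    for s in sites:
        score = lookup.get((s.gene_id, s.utr_position))
        out.append(
            SiteMatch(s.gene_id, s.utr_position, s.site_type, s.key, score)
        )
    return out


def putative_targets(
    sites_by_gene: dict[str, list[SiteMatch]],
    scores: pd.DataFrame | None = None,
) -> dict[str, TargetCall]:
    """Call putative target genes from their site lists.

    Qualifying: >=1 site of a 7/8mer type, or a 6mer with supplied context
    score below -0.1.
    """
    calls: dict[str, TargetCall] = {}
    for gene, sites in sites_by_gene.items():
        sites = _attach_scores(sites, scores)
        qualifying = [
            s
            for s in sites
            if s.site_type in STRONG_SITES
            or (
                s.site_type == "6mer"
                and s.context_score is not None
                and s.context_score < SIX_MER_SCORE_CUTOFF
            )
        ]
        calls[gene] = TargetCall(
            gene_id=gene,
            qualifies=bool(qualifying),
            sites=sites,
            qualifying_sites=qualifying,
        )
    return calls


@dataclass
class SharedTargets:
    shared: set[str]
    gained_a: set[str]
    lost_a: set[str]
    gained_b: set[str]
    lost_b: set[str]


def shared_targets(
    calls_a: dict[str, TargetCall],
    calls_b: dict[str, TargetCall],
    calls_canonical: dict[str, TargetCall] | None = None,
) -> SharedTargets:
    """Genes qualifying for both isoforms, plus gained/lost vs canonical.

    "Gained" = qualifies for the isoform but not the canonical miRNA;
    "lost" = the reverse.  Empty sets when no canonical calls are given.
    """
    qa = {g for g, c in calls_a.items() if c.qualifies}
    qb = {g for g, c in calls_b.items() if c.qualifies}
    qc = (
        {g for g, c in calls_canonical.items() if c.qualifies}
        if calls_canonical
        else set()
    )
    return SharedTargets(
        shared=qa & qb,
        gained_a=qa - qc if calls_canonical else set(),
        lost_a=qc - qa if calls_canonical else set(),
        gained_b=qb - qc if calls_canonical else set(),
        lost_b=qc - qb if calls_canonical else set(),
    )
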