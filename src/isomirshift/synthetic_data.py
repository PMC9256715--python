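"""Synthetic small-RNA cohorts with Drosha/Dicer cleavage heterogeneity.

The generator emulates the processes the pipeline is built to measure:

* per-locus 5'-cleavage-offset distributions pi over a small support
  (default -2..+2), drawn from a Dirichlet concentrated on the canonical
  cut, with per-sample biological jitter on the log-weights;
* a Dicer "5'-counting" length model — the duplex length is measured from
  the drawn 5' end (length ~ round(Normal(22, 1))), so the 3' end is
  partially dependent on the 5' end;
* group-dependent ratio shifts at planted loci, driven by a simulated
  per-sample RBP expression acting log-additively on the weights of the
  +/-1 offsets (tumor samples carry higher RBP, shifting cleavage);
* negative-binomial count noise on per-locus totals (gamma-Poisson);
* optional untemplated 3' tailing whose added base never matches the
  hairpin, exercising the aligner's mismatch policy;
* exponential survival with hazard proportional to exp(beta * marker) and
  independent exponential censoring tuned to a target censoring fraction.

Everything is a deterministic function of the seed; planted truths are
exported alongside the data so every pipeline stage can be checked
against what the sampler actually used.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import ARM_3P, ARM_5P, HairpinLocus, MatureAnnotation
from .isomir_caller import KEY_LEVELS

BASES = np.array(list("ACGU"))


@dataclass
class SimConfig:
    """Full parameterization of a synthetic cohort.

    Defaults describe the study conditions used throughout the tests:
    50 hairpin loci, 20 non-tumor + 20 tumor samples, 50,000
    miRNA-assigned reads per sample.
    """

    seed: int = 0
    n_loci: int = 50
    n_nontumor: int = 20
    n_tumor: int = 20
    depth: int = 50_000
    offsets: tuple[int, ...] = (-2, -1, 0, 1, 2)
    # Dirichlet concentration for baseline pi; mean P(offset 0) = 0.75
    pi_alpha: tuple[float, ...] = (2.0, 8.0, 60.0, 8.0, 2.0)
    jitter_sd: float = 0.15  # per-sample log-weight jitter (biological noise)
    abundance_sigma: float = 1.0  # log-normal spread of locus abundance
    nb_dispersion: float = 20.0  # NB size parameter; larger = closer to Poisson
    arm_frac_5p: float = 0.8
    duplex_mean: float = 22.0  # Dicer 5'-counting rule, nt from the 5' end
    duplex_sd: float = 1.0
    tail_prob: float = 0.02
    # planted group effect: log-additive RBP-driven shift of the +/-1 weights
    n_planted: int = 0
    delta_ratio: float = 0.15  # target increase of P(+1)+P(-1) at mean tumor RBP
    rbp_mean_nontumor: float = 1.0
    rbp_mean_tumor: float = 2.0
    rbp_sd: float = 0.25
    # survival
    beta_surv: float = 0.0
    baseline_hazard: float = 1.0 / 365.0
    censoring: float = 0.4
    # catalog geometry
    hairpin_len: int = 72
    mature_5p: tuple[int, int] = (12, 34)
    mature_3p: tuple[int, int] = (38, 60)
    flank_len: int = 250
    plant_motifs: bool = False

    def __post_init__(self) -> None:
        if len(self.pi_alpha) != len(self.offsets):
            raise ValueError("pi_alpha and offsets must have equal length")
        if 0 not in self.offsets:
            raise ValueError("offset support must include the canonical 0")
        if self.n_planted > self.n_loci:
            raise ValueError("cannot plant more loci than exist")

    @property
    def sample_ids(self) -> list[str]:
        return [f"NT{i+1:02d}" for i in range(self.n_nontumor)] + [
            f"TU{i+1:02d}" for i in range(self.n_tumor)
        ]

    @property
    def groups(self) -> pd.Series:
        return pd.Series(
            ["non_tumor"] * self.n_nontumor + ["tumor"] * self.n_tumor,
            index=self.sample_ids,
            name="condition",
        )


@dataclass
class GroundTruth:
    """Exactly the values the sampler used."""

    baseline_pi: np.ndarray  # (n_loci, n_offsets), 5p arm
    sample_pi: np.ndarray  # (n_loci, n_samples, n_offsets), 5p arm
    locus_totals: pd.DataFrame  # realized per-locus 5p-arm totals per sample
    rbp: pd.Series  # per-sample simulated RBP expression
    groups: pd.Series
    planted: list[int]  # indices of loci with a group effect
    motif_positions: dict[str, dict[str, int]] = field(default_factory=dict)

    def group_ratio(self, expected: bool = False) -> pd.DataFrame:
        """Count-weighted true isomiR fraction per (locus, offset, group).

        Weighted by realized per-sample totals, i.e. the exact expectation
        of the pooled pipeline estimate given the sampled totals.
        """
        rows = []
        totals = self.locus_totals.to_numpy(dtype=float)
        for g in pd.unique(self.groups):
            cols = np.flatnonzero((self.groups == g).to_numpy())
            w = totals[:, cols]
            denom = w.sum(axis=1, keepdims=True)
            denom[denom == 0] = np.nan
            pi_g = (self.sample_pi[:, cols, :] * w[:, :, None]).sum(axis=1) / denom
            for li in range(pi_g.shape[0]):
                for oi in range(pi_g.shape[1]):
                    rows.append(
                        {
                            "locus": li,
                            "group": g,
                            "offset_index": oi,
                            "true_fraction": pi_g[li, oi],
                        }
                    )
        return pd.DataFrame(rows)

    def sample_marker(self) -> pd.Series:
        """Per-sample mean isomiR fraction over planted (or all) loci."""
        loci = self.planted if self.planted else list(range(self.sample_pi.shape[0]))
        zero_idx = None  # filled by caller via config offsets; recompute here
        # isomiR fraction = 1 - P(offset 0); offset order matches config
        return pd.Series(
            1.0 - self.sample_pi[loci][:, :, self._zero_index].mean(axis=0),
            index=self.groups.index,
            name="isomir_fraction",
        )

    _zero_index: int = 2


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([stream, seed]))


def simulate_catalog(config: SimConfig) -> list[HairpinLocus]:
    """Random hairpin catalog, optionally with planted flanking motifs.

    Deterministic under the seed (byte-identical FASTA).  When
    ``plant_motifs`` is set: a basal UG at -14 from the 5p mature start,
    a CNNC with first C at +16 from the 3p mature end, and a 6-U run in
    the 5' flank 100 nt upstream of the hairpin.
    """
    rng = _rng(config.seed, 1)
    catalog = []
    for i in range(config.n_loci):
        seq = "".join(rng.choice(BASES, size=config.hairpin_len))
        flank5 = "".join(rng.choice(BASES, size=config.flank_len))
        flank3 = "".join(rng.choice(BASES, size=config.flank_len))
        s5, e5 = config.mature_5p
        s3, e3 = config.mature_3p
        if config.plant_motifs:
            # basal UG at -14 relative to the 5p mature start
            pos = s5 - 14
            if pos >= 0:
                seq = seq[:pos] + "UG" + seq[pos + 2 :]
            else:
                fpos = config.flank_len + pos
                flank5 = flank5[:fpos] + "UG" + flank5[fpos + 2 :]
            # CNNC with first C at +16 from the 3p mature end (in the 3' flank
            # when the window extends past the hairpin)
            cpos = e3 + 16
            if cpos + 4 <= config.hairpin_len:
                seq = seq[:cpos] + "C" + seq[cpos + 1 : cpos + 3] + "C" + seq[cpos + 4 :]
            else:
                fpos = cpos - config.hairpin_len
                flank3 = (
                    flank3[:fpos] + "C" + flank3[fpos + 1 : fpos + 3] + "C" + flank3[fpos + 4 :]
                )
            # poly-U run of 6 in the 5' flank
            upos = config.flank_len - 100
            flank5 = flank5[:upos] + "UUUUUU" + flank5[upos + 6 :]
            # keep the run maximal: cap its neighbours away from U
            if upos > 0 and flank5[upos - 1] == "U":
                flank5 = flank5[: upos - 1] + "A" + flank5[upos:]
            if flank5[upos + 6 : upos + 7] == "U":
                flank5 = flank5[: upos + 6] + "A" + flank5[upos + 7 :]
        name = f"mir-sim-{i+1}"
        locus = HairpinLocus(
            locus_id=f"sim{i+1:03d}",
            name=name,
            sequence=seq,
            matures=[
                MatureAnnotation(f"miR-sim-{i+1}-5p", ARM_5P, s5, e5),
                MatureAnnotation(f"miR-sim-{i+1}-3p", ARM_3P, s3, e3),
            ],
            flank5=flank5,
            flank3=flank3,
        )
        catalog.append(locus)
    return catalog


def _planted_shift(pi: np.ndarray, offsets: Sequence[int], delta: float) -> float:
    """Log-weight increment c on the +/-1 offsets raising their combined
    probability by ``delta`` (solved in closed form)."""
    idx = [i for i, o in enumerate(offsets) if abs(o) == 1]
    q = float(pi[idx].sum())
    target = min(q + delta, 0.95)
    return float(np.log((target * (1 - q)) / (q * (1 - target))))


def _sample_pi(
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, pd.Series, list[int]]:
    """Baseline and per-sample offset distributions for the 5p arm."""
    n_off = len(config.offsets)
    baseline = rng.dirichlet(config.pi_alpha, size=config.n_loci)
    n_samples = config.n_nontumor + config.n_tumor
    rbp = np.concatenate(
        [
            rng.normal(config.rbp_mean_nontumor, config.rbp_sd, config.n_nontumor),
            rng.normal(config.rbp_mean_tumor, config.rbp_sd, config.n_tumor),
        ]
    )
    rbp_series = pd.Series(rbp, index=config.sample_ids, name="rbp")
    planted = list(range(config.n_planted))
    pm_idx = np.array([i for i, o in enumerate(config.offsets) if abs(o) == 1])
    rbp_span = config.rbp_mean_tumor - config.rbp_mean_nontumor
    logw_base = np.log(np.clip(baseline, 1e-12, None))
    sample_pi = np.empty((config.n_loci, n_samples, n_off))
    for li in range(config.n_loci):
        jitter = rng.normal(0.0, config.jitter_sd, size=(n_samples, n_off))
        logw = logw_base[li][None, :] + jitter
        if li in planted and rbp_span > 0:
            c = _planted_shift(baseline[li], config.offsets, config.delta_ratio)
            beta = c / rbp_span
            shift = beta * (rbp - config.rbp_mean_nontumor)
            logw[:, pm_idx] += shift[:, None]
        w = np.exp(logw - logw.max(axis=1, keepdims=True))
        sample_pi[li] = w / w.sum(axis=1, keepdims=True)
    return baseline, sample_pi, rbp_series, planted


def _duplex_length_probs(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.arange(
        int(round(config.duplex_mean - 3)), int(round(config.duplex_mean + 3)) + 1
    )
    edges = np.concatenate([[-np.inf], lengths[:-1] + 0.5, [np.inf]])
    from scipy.stats import norm

    cdf = norm.cdf(edges, loc=config.duplex_mean, scale=config.duplex_sd)
    return lengths, np.diff(cdf)


def simulate_offset_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Fast path: 5p-arm counts per (locus, offset) x sample, no sequences.

    Same generative model as :func:`simulate_reads` (NB totals,
    jittered/shifted multinomial offsets) without the read-string and
    3'-end layers.  The returned counts carry the standard key MultiIndex
    so RPM/ratio/differential stages apply directly.
    """
    rng = _rng(config.seed, 2)
    baseline, sample_pi, rbp, planted = _sample_pi(config, rng)
    n_samples = config.n_nontumor + config.n_tumor
    weights = rng.lognormal(0.0, config.abundance_sigma, config.n_loci)
    weights /= weights.sum()
    means = weights * config.depth
    k = config.nb_dispersion
    totals = rng.poisson(rng.gamma(k, means[:, None] / k, (config.n_loci, n_samples)))
    counts = np.zeros((config.n_loci, len(config.offsets), n_samples), dtype=float)
    for li in range(config.n_loci):
        for si in range(n_samples):
            counts[li, :, si] = rng.multinomial(totals[li, si], sample_pi[li, si])
    index = pd.MultiIndex.from_tuples(
        [
            (f"sim{li+1:03d}", ARM_5P, f"miR-sim-{li+1}-5p", o)
            for li in range(config.n_loci)
            for o in config.offsets
        ],
        names=KEY_LEVELS,
    )
    frame = pd.DataFrame(
        counts.reshape(config.n_loci * len(config.offsets), n_samples),
        index=index,
        columns=config.sample_ids,
    )
    truth = GroundTruth(
        baseline_pi=baseline,
        sample_pi=sample_pi,
        locus_totals=pd.DataFrame(
            totals, columns=config.sample_ids,
            index=[f"sim{li+1:03d}" for li in range(config.n_loci)],
        ),
        rbp=rbp,
        groups=config.groups,
        planted=planted,
    )
    truth._zero_index = list(config.offsets).index(0)
    return frame, truth


def simulate_reads(
    config: SimConfig, catalog: list[HairpinLocus]
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-sample collapsed read tables from the full cleavage model.

    Returns (reads, truth): ``reads`` is a DataFrame indexed by read
    sequence with one count column per sample.  Each read draws a 5'
    offset from the sample's (possibly RBP-shifted) pi, a 3' end from the
    Dicer 5'-counting length model anchored at the drawn 5' end, and an
    optional untemplated 3' tail base that never matches the hairpin.
    """
    if len(catalog) != config.n_loci:
        raise ValueError("catalog size does not match config.n_loci")
    rng = _rng(config.seed, 2)
    baseline, sample_pi, rbp, planted = _sample_pi(config, rng)
    n_samples = config.n_nontumor + config.n_tumor
    weights = rng.lognormal(0.0, config.abundance_sigma, config.n_loci)
    weights /= weights.sum()
    means = weights * config.depth
    k = config.nb_dispersion
    arm_totals = rng.poisson(
        rng.gamma(k, means[:, None] / k, (config.n_loci, n_samples))
    )
    lengths, length_probs = _duplex_length_probs(config)
    acc: dict[str, np.ndarray] = {}
    totals_5p = np.zeros((config.n_loci, n_samples), dtype=int)

    def add(seq: str, si: int, count: int) -> None:
        if count <= 0:
            return
        if seq not in acc:
            acc[seq] = np.zeros(n_samples, dtype=int)
        acc[seq][si] += count

    for li, locus in enumerate(catalog):
        hp = locus.sequence
        for arm, (ms, me) in ((ARM_5P, config.mature_5p), (ARM_3P, config.mature_3p)):
            for si in range(n_samples):
                total = arm_totals[li, si]
                if arm == ARM_5P:
                    n_arm = rng.binomial(total, config.arm_frac_5p)
                    totals_5p[li, si] = n_arm
                    pi = sample_pi[li, si]
                else:
                    n_arm = total - totals_5p[li, si]
                    pi = baseline[li]  # 3p arm keeps the baseline distribution
                if n_arm == 0:
                    continue
                per_offset = rng.multinomial(n_arm, pi)
                for oi, m in enumerate(per_offset):
                    if m == 0:
                        continue
                    d5 = config.offsets[oi]
                    start = ms + d5
                    per_len = rng.multinomial(m, length_probs)
                    for L, cnt in zip(lengths, per_len):
                        if cnt == 0:
                            continue
                        end = min(start + int(L), len(hp))
                        read = hp[start:end]
                        n_tail = rng.binomial(cnt, config.tail_prob)
                        add(read, si, cnt - n_tail)
                        if n_tail:
                            nxt = hp[end] if end < len(hp) else None
                            choices = [b for b in "ACGU" if b != nxt]
                            tail = rng.choice(choices)
                            add(read + tail, si, n_tail)
    reads = pd.DataFrame(
        acc.values(), index=list(acc.keys()), columns=config.sample_ids
    ).sort_index()
    reads.index.name = "sequence"
    truth = GroundTruth(
        baseline_pi=baseline,
        sample_pi=sample_pi,
        locus_totals=pd.DataFrame(
            totals_5p, columns=config.sample_ids,
            index=[loc.locus_id for loc in catalog],
        ),
        rbp=rbp,
        groups=config.groups,
        planted=planted,
    )
    truth._zero_index = list(config.offsets).index(0)
    return reads, truth


def reads_frame_to_sample_tables(reads: pd.DataFrame) -> list[pd.DataFrame]:
    """Split the combined read matrix into per-sample (sequence, count)
    tables, the collapse_reads input format."""
    tables = []
    for col in reads.columns:
        sub = reads[reads[col] > 0]
        tables.append(
            pd.DataFrame({"sequence": sub.index, "count": sub[col].to_numpy()})
        )
    return tables


def simulate_clinical(
    config: SimConfig,
    marker: pd.Series,
    *,
    stream: int = 3,
) -> pd.DataFrame:
    """Exponential survival with hazard ~ exp(beta_surv * marker).

    Censoring is independent exponential, its rate tuned analytically so
    the expected censored fraction matches ``config.censoring``.
    """
    if len(marker) == 0:
        raise ValueError("no samples to simulate survival for")
    rng = _rng(config.seed, stream)
    hazards = config.baseline_hazard * np.exp(
        config.beta_surv * marker.to_numpy(dtype=float)
    )
    event_times = rng.exponential(1.0 / hazards)
    c = config.censoring
    if c > 0:
        cens_rate = hazards.mean() * c / (1.0 - c)
        censor_times = rng.exponential(1.0 / cens_rate, size=len(marker))
    else:
        censor_times = np.full(len(marker), np.inf)
    observed = np.minimum(event_times, censor_times)
    return pd.DataFrame(
        {
            "sample_id": marker.index,
            "time": observed,
            "event": event_times <= censor_times,
        }
    ).set_index("sample_id")
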