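"""Synthetic multi-sample TCR cohort generator.

Emulates the statistical structure of a post-transplant repertoire study so
that every downstream stage (normalization, diversity, motif clustering,
similarity classification, tracking, annotation) can be exercised without
any external data:

* per-sample clone sizes follow a rank-abundance power law
  ``count(r) ∝ r ** -exponent`` scaled to a configured sequencing depth;
* clinical groups differ in richness (active-GVHD and healthy repertoires
  configured richer than the no-GVHD group, reflecting the polyclonal
  activation seen during early acute GVHD);
* a small panel of interior k-mer motifs is spiked into a fraction of the
  clonotypes of designated "GVHD-like" groups, giving those samples shared
  specificity groups that motif clustering can recover;
* a panel of full-length "planted" CDR3 sequences is inserted at
  above-threshold frequency into the same groups, emulating the tissue- and
  pathogen-associated clones that annotation scoring intersects with;
* per-subject stage dynamics: the active-disease repertoire (stage 1) is
  preceded by a near-identical pre-symptomatic snapshot (stage 0) and
  followed by a resolution snapshot (stage 2) in which the stage-1 dominant
  clones contract and a fresh oligoclonal head expands, so diversity falls
  as symptoms resolve.

Determinism: every subject draws from an RNG stream derived from the master
seed and the subject's identity alone, so adding a subject never perturbs
the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .repertoire import ConfigError, Repertoire

# Interior amino-acid frequency profile, loosely modelled on human TRB CDR3
# composition: small/polar residues (G, S, A, T) common, W/C/M rare.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_WEIGHTS = {
    "A": 0.055, "C": 0.005, "D": 0.045, "E": 0.065, "F": 0.030,
    "G": 0.110, "H": 0.020, "I": 0.025, "K": 0.025, "L": 0.060,
    "M": 0.008, "N": 0.040, "P": 0.045, "Q": 0.060, "R": 0.060,
    "S": 0.130, "T": 0.085, "V": 0.045, "W": 0.007, "Y": 0.080,
}
AA_PROFILE = np.array([_AA_WEIGHTS[a] for a in AA_ORDER])
AA_PROFILE = AA_PROFILE / AA_PROFILE.sum()

DEFAULT_V_GENES = tuple(f"TRBV{i}" for i in range(1, 31))
DEFAULT_J_GENES = tuple(f"TRBJ{i}-{j}" for i in (1, 2) for j in range(1, 7))

#: interior motifs spiked into GVHD-like samples; built from rare residues so
#: chance occurrence in unspiked repertoires is negligible
DEFAULT_MOTIF_PANEL = ("WQHY", "MKWH", "YHWM")

#: full-length CDR3s planted into GVHD-like samples at high frequency,
#: standing in for tissue/pathogen-associated clones shared across patients
DEFAULT_PLANTED_CDR3S = (
    "CASSWQHYEQYF",
    "CASMKWHSYEQYF",
    "CASRYHWMTGELFF",
    "CASSWMHQPLHF",
    "CASKYWHMNTEAFF",
)


def _zipf_freqs(n: int, s: float, rng: np.random.Generator) -> dict[str, float]:
    w = 1.0 / np.arange(1, n + 1) ** s
    w = w / w.sum()
    return w


def default_gene_freqs(genes: Sequence[str], skew: float = 0.7) -> dict[str, float]:
    """Mildly skewed (Zipf-like) default usage over a gene panel."""
    w = 1.0 / np.arange(1, len(genes) + 1) ** skew
    w = w / w.sum()
    return dict(zip(genes, w))


@dataclass(frozen=True)
class StageTransition:
    """How a subject's repertoire changes from one stage to another.

    ``dominant_fold`` multiplies the counts of the top ``dominant_top_n``
    clones of the source stage (0.05 = strong contraction).  ``jitter_sd``
    is the log-SD of a lognormal perturbation applied to all other clones.
    If ``new_head_n`` > 0, that many randomly chosen non-dominant clones are
    promoted to a fresh power-law head holding ``new_head_mass`` of all
    reads, emulating the oligoclonal expansions that accompany resolution.
    """

    dominant_fold: float = 1.0
    dominant_top_n: int = 20
    jitter_sd: float = 0.0
    new_head_n: int = 0
    new_head_mass: float = 0.0


#: stage 1 (active disease) is the reference; stage 0 is a lightly jittered
#: copy (pre-symptomatic repertoires closely resemble onset), stage 2
#: contracts the onset dominants and promotes a new oligoclonal head
DEFAULT_STAGE_DYNAMICS: Mapping[tuple[int, int], StageTransition] = {
    (1, 0): StageTransition(dominant_fold=1.0, jitter_sd=0.15),
    (1, 2): StageTransition(
        dominant_fold=0.05,
        dominant_top_n=20,
        jitter_sd=0.2,
        new_head_n=20,
        new_head_mass=0.55,
    ),
}


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration.

    Defaults mirror the study design the pipeline targets: 15 active-GVHD,
    13 no-GVHD and 15 healthy-individual samples plus pre-symptomatic
    (GVHD_PRE) subjects; ~1.2 M reads per sample before normalization to
    1 M; richer repertoires in the GVHD and healthy groups than in the
    no-GVHD group.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"GVHD": 15, "NO_GVHD": 13, "HI": 15, "GVHD_PRE": 3}
    )
    richness: Mapping[str, int] = field(
        default_factory=lambda: {
            "GVHD": 20_000,
            "NO_GVHD": 6_000,
            "HI": 18_000,
            "GVHD_PRE": 20_000,
        }
    )
    clone_size_exponent: float = 1.0
    total_reads: int = 1_200_000
    cdr3_length_mean: float = 14.5
    cdr3_length_sd: float = 1.5
    v_gene_freqs: Mapping[str, float] = field(
        default_factory=lambda: default_gene_freqs(DEFAULT_V_GENES)
    )
    j_gene_freqs: Mapping[str, float] = field(
        default_factory=lambda: default_gene_freqs(DEFAULT_J_GENES)
    )
    motif_panel: tuple[str, ...] = DEFAULT_MOTIF_PANEL
    motif_spike_fraction: float = 0.05
    spiked_groups: frozenset = frozenset({"GVHD", "GVHD_PRE"})
    planted_cdr3s: tuple[str, ...] = DEFAULT_PLANTED_CDR3S
    planted_freq: float = 0.0005
    stages_per_group: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    stage_dynamics: Mapping[tuple[int, int], StageTransition] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_DYNAMICS)
    )
    chain: str = "TRB"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, freqs in (("v_gene_freqs", self.v_gene_freqs),
                            ("j_gene_freqs", self.j_gene_freqs)):
            total = float(sum(freqs.values()))
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {total})")
        if not 0.0 <= self.motif_spike_fraction <= 1.0:
            raise ConfigError("motif_spike_fraction must lie in [0, 1]")
        if self.clone_size_exponent < 0:
            raise ConfigError("clone_size_exponent must be non-negative")


def subject_seed(master_seed: int, label: str) -> np.random.SeedSequence:
    """Stable per-entity RNG stream: depends only on the master seed and the
    entity label, never on how many other entities exist."""
    return np.random.SeedSequence([int(master_seed) % 2**31, zlib.crc32(label.encode())])


# -- CDR3 sampling ----------------------------------------------------------


def sample_cdr3(
    length_sampler,
    rng: np.random.Generator,
    forced_motif: Optional[str] = None,
) -> str:
    """Draw one CDR3: 'C' + interior from the fixed amino-acid profile + 'F'.

    ``length_sampler(rng) -> int``; draws below 8 are rejected and resampled.
    When ``forced_motif`` is given it is placed at a uniformly random offset
    within the trim-protected interior (never touching the first or last
    three residues).
    """
    letters = np.array(list(AA_ORDER))
    for _ in range(1000):
        length = int(length_sampler(rng))
        if length >= 8:
            break
    else:
        raise ConfigError("length sampler never produced a length >= 8")
    body = rng.choice(letters, size=length - 2, p=AA_PROFILE)
    seq = "C" + "".join(body) + "F"
    if forced_motif is not None:
        m = len(forced_motif)
        hi = length - 3 - m  # last admissible start (0-based), interior is [3, length-3)
        if hi < 3:
            raise ConfigError(
                f"forced motif {forced_motif!r} does not fit the interior of a "
                f"length-{length} CDR3"
            )
        off = int(rng.integers(3, hi + 1))
        seq = seq[:off] + forced_motif + seq[off + m:]
    return seq


def _sample_lengths(
    n: int, rng: np.random.Generator, mean: float, sd: float, floor: int
) -> np.ndarray:
    lengths = np.rint(rng.normal(mean, sd, size=n)).astype(int)
    bad = lengths < floor
    while bad.any():
        lengths[bad] = np.rint(rng.normal(mean, sd, size=int(bad.sum()))).astype(int)
        bad = lengths < floor
    return lengths


def _sample_cdr3_batch(
    n: int,
    rng: np.random.Generator,
    mean: float,
    sd: float,
    forced_motif: Optional[str] = None,
) -> list[str]:
    """Vectorized batch draw matching the distribution of :func:`sample_cdr3`."""
    if n == 0:
        return []
    m = len(forced_motif) if forced_motif else 0
    floor = max(8, m + 7) if forced_motif else 8
    lengths = _sample_lengths(n, rng, mean, sd, floor)
    max_body = int(lengths.max()) - 2
    letters = np.array(list(AA_ORDER))
    chars = rng.choice(letters, size=(n, max_body), p=AA_PROFILE)
    if forced_motif:
        offs = rng.integers(3, lengths - 3 - m + 1)
    out = []
    motif = forced_motif or ""
    for i in range(n):
        L = lengths[i]
        s = "C" + "".join(chars[i, : L - 2]) + "F"
        if forced_motif:
            o = int(offs[i])
            s = s[:o] + motif + s[o + m:]
        out.append(s)
    return out


# -- repertoire generation --------------------------------------------------


def _power_law_counts(
    richness: int, exponent: float, total: int
) -> np.ndarray:
    ranks = np.arange(1, richness + 1, dtype=float)
    w = ranks ** -exponent
    counts = np.rint(w / w.sum() * total).astype(np.int64)
    if (counts <= 0).any():
        raise ConfigError(
            f"richness {richness} at depth {total} with exponent {exponent} "
            "rounds some clone to zero reads; lower the exponent or raise the depth"
        )
    return counts


def _draw_unique_clonotypes(
    n: int,
    rng: np.random.Generator,
    config: CohortConfig,
    forced_motifs: Optional[Sequence[Optional[str]]] = None,
    exclude: Optional[set] = None,
) -> pd.DataFrame:
    """Draw ``n`` clonotypes unique on (cdr3, v, j), optionally forcing interior
    motifs (``forced_motifs[i]`` applies to the i-th requested clonotype)."""
    v_names = list(config.v_gene_freqs)
    v_p = np.array([config.v_gene_freqs[g] for g in v_names])
    j_names = list(config.j_gene_freqs)
    j_p = np.array([config.j_gene_freqs[g] for g in j_names])

    seen = set(exclude or ())
    rows: list[tuple[str, str, str]] = []
    want = [forced_motifs[i] if forced_motifs else None for i in range(n)]
    # group requests by motif so each group can be drawn as one batch
    pending: dict[Optional[str], int] = {}
    for mtf in want:
        pending[mtf] = pending.get(mtf, 0) + 1
    out_by_motif: dict[Optional[str], list[tuple[str, str, str]]] = {m: [] for m in pending}
    for mtf, need in pending.items():
        got = out_by_motif[mtf]
        while len(got) < need:
            k = max(32, int((need - len(got)) * 1.15))
            cdr3s = _sample_cdr3_batch(
                k, rng, config.cdr3_length_mean, config.cdr3_length_sd, mtf
            )
            vs = rng.choice(v_names, size=k, p=v_p)
            js = rng.choice(j_names, size=k, p=j_p)
            for key in zip(cdr3s, vs, js):
                if key in seen:
                    continue
                seen.add(key)
                got.append(key)
                if len(got) == need:
                    break
    for mtf in want:
        rows.append(out_by_motif[mtf].pop())
    return pd.DataFrame(rows, columns=["cdr3_aa", "v_gene", "j_gene"])


def generate_repertoire(
    config: CohortConfig,
    group: str,
    subject_id: str,
    stage: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Repertoire:
    """Generate one sample: power-law clone sizes, configured richness, and —
    for spiked groups — panel motifs and planted shared clones."""
    if group not in config.richness:
        raise ConfigError(f"no configured richness for group {group!r}")
    if rng is None:
        rng = np.random.default_rng(subject_seed(config.seed, f"{group}/{subject_id}"))
    richness = int(config.richness[group])
    spiked = group in config.spiked_groups

    planted = list(config.planted_cdr3s) if spiked else []
    n_planted = len(planted)
    if n_planted >= richness:
        raise ConfigError("planted panel larger than configured richness")
    planted_count = int(round(config.planted_freq * config.total_reads))
    base_total = config.total_reads - n_planted * planted_count
    n_base = richness - n_planted

    counts = _power_law_counts(n_base, config.clone_size_exponent, base_total)

    forced: Optional[list[Optional[str]]] = None
    if spiked and config.motif_panel and config.motif_spike_fraction > 0:
        n_spike = int(round(config.motif_spike_fraction * n_base))
        forced = [None] * n_base
        for i in range(n_spike):
            forced[i] = config.motif_panel[i % len(config.motif_panel)]
    keys = _draw_unique_clonotypes(
        n_base, rng, config, forced_motifs=forced,
        exclude={(c, "", "") for c in planted} or None,
    )
    # counts are rank-ordered; a random permutation places spiked clonotypes
    # (and everything else) at random abundance ranks
    order = rng.permutation(n_base)
    df = keys.iloc[order].reset_index(drop=True)
    df["count"] = counts

    if planted:
        v_names = list(config.v_gene_freqs)
        j_names = list(config.j_gene_freqs)
        extra = pd.DataFrame(
            {
                "cdr3_aa": planted,
                "v_gene": [v_names[i % len(v_names)] for i in range(n_planted)],
                "j_gene": [j_names[i % len(j_names)] for i in range(n_planted)],
                "count": planted_count,
            }
        )
        df = pd.concat([df, extra], ignore_index=True)

    sample_id = subject_id if stage is None else f"{subject_id}_st{stage}"
    return Repertoire(
        sample_id=sample_id,
        clonotypes=df,
        chain=config.chain,
        subject_id=subject_id,
        group=group,
        stage=stage,
    )


def apply_stage_dynamics(
    repertoire: Repertoire,
    stage_from: int,
    stage_to: int,
    config: CohortConfig,
    rng: np.random.Generator,
) -> Repertoire:
    """Derive the ``stage_to`` snapshot of a subject from its ``stage_from``
    repertoire (see :class:`StageTransition`).  The result is renormalized to
    the source depth; clones whose count rounds to zero disappear."""
    tr = config.stage_dynamics.get((stage_from, stage_to), StageTransition())
    if tr.dominant_fold < 0:
        raise ConfigError("dominant_fold must be non-negative")
    df = repertoire.clonotypes
    counts = df["count"].to_numpy(dtype=float).copy()
    total = counts.sum()

    order = np.lexsort((df["v_gene"].to_numpy(), df["cdr3_aa"].to_numpy(), -counts))
    dominant = order[: tr.dominant_top_n]
    rest = order[tr.dominant_top_n:]

    identity = tr.dominant_fold == 1.0 and tr.jitter_sd == 0.0 and tr.new_head_n == 0
    counts[dominant] *= tr.dominant_fold
    if tr.jitter_sd > 0:
        counts[rest] *= rng.lognormal(0.0, tr.jitter_sd, size=rest.size)
    if tr.new_head_n > 0:
        head = rng.choice(rest, size=min(tr.new_head_n, rest.size), replace=False)
        head_w = 1.0 / np.arange(1, head.size + 1)
        budget = tr.new_head_mass * total
        counts[head] = budget * head_w / head_w.sum()
    if not identity:
        counts = np.rint(counts * (total / counts.sum())).astype(np.int64)
    else:
        counts = counts.astype(np.int64)
    out = repertoire.with_counts(counts)
    return replace(
        out, stage=stage_to, sample_id=f"{repertoire.subject_id}_st{stage_to}"
    )


def generate_cohort(config: CohortConfig) -> list[Repertoire]:
    """One repertoire per (group, subject) — or per stage when the group has
    configured stages, with stage 1 generated first and the other stages
    derived from it."""
    cohort: list[Repertoire] = []
    for group in config.n_per_group:
        for i in range(1, int(config.n_per_group[group]) + 1):
            subject = f"{group}_{i:02d}"
            rng = np.random.default_rng(subject_seed(config.seed, f"{group}/{subject}"))
            stages = config.stages_per_group.get(group)
            if not stages:
                cohort.append(
                    generate_repertoire(config, group, subject, stage=None, rng=rng)
                )
                continue
            base = generate_repertoire(config, group, subject, stage=1, rng=rng)
            by_stage = {1: base}
            for st in stages:
                if st != 1:
                    by_stage[st] = apply_stage_dynamics(base, 1, st, config, rng)
            cohort.extend(by_stage[st] for st in sorted(stages))
    return cohort


def generate_reference(
    n_cdr3: int,
    seed: int = 0,
    cdr3_length_mean: float = 14.5,
    cdr3_length_sd: float = 1.5,
    chain: str = "TRB",
) -> Repertoire:
    """Motif-free naive reference repertoire (uniform gene usage, count 1 per
    clonotype) used as the enrichment null for motif clustering."""
    rng = np.random.default_rng(subject_seed(seed, "reference"))
    cdr3s: list[str] = []
    seen: set[str] = set()
    while len(cdr3s) < n_cdr3:
        k = max(32, int((n_cdr3 - len(cdr3s)) * 1.05))
        for s in _sample_cdr3_batch(k, rng, cdr3_length_mean, cdr3_length_sd):
            if s in seen:
                continue
            seen.add(s)
            cdr3s.append(s)
            if len(cdr3s) == n_cdr3:
                break
    n = len(cdr3s)
    v = [DEFAULT_V_GENES[i % len(DEFAULT_V_GENES)] for i in range(n)]
    j = [DEFAULT_J_GENES[i % len(DEFAULT_J_GENES)] for i in range(n)]
    df = pd.DataFrame({"cdr3_aa": cdr3s, "v_gene": v, "j_gene": j, "count": 1})
    return Repertoire(sample_id="reference", clonotypes=df, chain=chain)


def planted_annotation_records(config: CohortConfig, species: str = "synthetic_gvhd"):
    """Annotation records for the generator's planted shared-clone panel
    (synthetic stand-in for tissue/pathogen-derived CDR3 sets)."""
    from .repertoire import AnnotationRecord

    return [
        AnnotationRecord(cdr3_aa=c, antigen_species=species, source="synthetic")
        for c in config.planted_cdr3s
    ]
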